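"""End-to-end orchestration: preprocess -> detect -> primers -> optional
mapping / diversity / transferability / enrichment stages, a joined marker
table and a flat-file marker-database export.

Every stage writes its own artifact so stages can also be run standalone
from the CLI; the joined ``markers.tsv`` uses the locus id
``<seq_id>:<start>-<end>`` as the key across all stages. All randomness
flows from the single config seed, so reruns with an identical config are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .records import SequenceRecord, read_fasta, write_fasta
from .preprocess import PreprocessConfig, preprocess
from .ssr import (CompoundSSR, SSRLocus, find_ssrs, get_preset, loci_to_tsv,
                  merge_compound, resolve_overlaps, summarize)
from .primers import (PrimerConstraints, PrimerPair, add_m13_tail,
                      design_primers, primers_to_tsv)
from .genome import (MappingConfig, distribution_table, place_loci,
                     read_gene_models, read_hits)
from .diversity import call_polymorphic, diversity_table, read_genotypes
from .enrichment import enrich, enrichment_to_tsv, read_annotations
from .transfer import (binary_distance, bootstrap_support, distances_to_tsv,
                       read_transfer_matrix, write_newick)

log = logging.getLogger("estssr")

STAGE_EXIT_CODES = {
    "preprocess": 10, "detect": 11, "primers": 12, "map": 13,
    "stats": 14, "enrich": 15, "transfer": 16, "export": 17,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; optional stages activate when
    their input path is set."""

    fasta: str
    out_dir: str
    preset: str = "misa_default"
    seed: int = 0
    contaminants: Mapping[str, str] = field(default_factory=dict)
    hits: str | None = None
    gff3: str | None = None
    genotypes: str | None = None
    annotations: str | None = None
    transfer_matrix: str | None = None
    bootstrap_replicates: int = 1000
    fdr_alpha: float = 0.05
    preprocess_config: PreprocessConfig = field(default_factory=PreprocessConfig)
    primer_constraints: PrimerConstraints = field(default_factory=PrimerConstraints)
    mapping_config: MappingConfig = field(default_factory=MappingConfig)
    m13_tails: bool = True


def locus_id(locus: SSRLocus) -> str:
    return f"{locus.seq_id}:{locus.start}-{locus.end}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the artifact dictionary.

    Any stage failure raises :class:`StageError` carrying a stage-specific
    exit code for the CLI.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    logging.basicConfig(level=logging.INFO, format="%(message)s")
    log.info("estssr %s | seed=%d | preset=%s", __version__, config.seed,
             config.preset)
    (out / "run_config.json").write_text(json.dumps({
        "version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "fasta": str(config.fasta),
        "fdr_alpha": config.fdr_alpha,
        "bootstrap_replicates": config.bootstrap_replicates,
        "preprocess": asdict(config.preprocess_config),
        "primers": asdict(config.primer_constraints),
        "mapping": asdict(config.mapping_config),
    }, indent=2))

    # ---- preprocess -------------------------------------------------
    try:
        records = read_fasta(config.fasta)
        contaminant_sets = {cls: read_fasta(path)
                            for cls, path in config.contaminants.items()}
        reps, clusters, report = preprocess(
            records, contaminant_sets, config.preprocess_config)
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc
    write_fasta(reps, out / "nonredundant.fasta")
    (out / "preprocess_report.json").write_text(report.to_json())
    (out / "preprocess_report.txt").write_text(report.to_text() + "\n")
    artifacts["preprocess"] = report
    artifacts["representatives"] = reps
    log.info("preprocess: %d -> %d valid -> %d non-redundant",
             report.n_input, report.n_valid, report.n_clusters)

    # ---- detect -----------------------------------------------------
    try:
        preset = get_preset(config.preset)
        loci = resolve_overlaps(find_ssrs(reps, preset))
        compounds, singletons = merge_compound(loci, preset)
        total_bases = sum(len(r) for r in reps)
        summary = summarize(loci, compounds, total_bases, len(reps))
    except Exception as exc:
        raise StageError("detect", str(exc)) from exc
    (out / "ssr_loci.tsv").write_text(loci_to_tsv(loci, compounds))
    (out / "ssr_summary.json").write_text(json.dumps(summary, indent=2))
    artifacts["loci"] = loci
    artifacts["compounds"] = compounds
    artifacts["summary"] = summary
    log.info("detect: %d loci (%d compound groups) in %d sequences",
             len(loci), len(compounds), summary["n_ssr_containing"])

    # ---- primers ----------------------------------------------------
    try:
        rec_by_id = {r.id: r for r in reps}
        primer_map: dict[str, list[PrimerPair]] = {}
        for locus in loci:
            pairs = design_primers(rec_by_id[locus.seq_id], locus,
                                   config.primer_constraints)
            if config.m13_tails:
                pairs = [add_m13_tail(p) for p in pairs]
            primer_map[locus_id(locus)] = pairs
    except Exception as exc:
        raise StageError("primers", str(exc)) from exc
    (out / "primers.tsv").write_text(primers_to_tsv(primer_map))
    artifacts["primers"] = primer_map
    n_with = sum(1 for v in primer_map.values() if v)
    log.info("primers: designed for %d / %d loci", n_with, len(loci))

    # ---- optional: genome mapping -----------------------------------
    placements = None
    if config.hits:
        try:
            hits = read_hits(config.hits)
            gene_models = read_gene_models(config.gff3) if config.gff3 else ()
            placements = place_loci(loci, hits, gene_models,
                                    config.mapping_config)
            dist_table = distribution_table(placements)
        except Exception as exc:
            raise StageError("map", str(exc)) from exc
        (out / "placements.tsv").write_text(_placements_tsv(placements))
        (out / "placement_summary.json").write_text(
            json.dumps(dist_table, indent=2))
        artifacts["placements"] = placements
        artifacts["placement_summary"] = dist_table

    # ---- optional: diversity stats ----------------------------------
    diversity = None
    if config.genotypes:
        try:
            table = read_genotypes(config.genotypes)
            diversity = diversity_table(table)
            flags, rate = call_polymorphic(table)
        except Exception as exc:
            raise StageError("stats", str(exc)) from exc
        diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
        artifacts["diversity"] = diversity
        artifacts["polymorphic_rate_pct"] = rate
        log.info("stats: %d loci, polymorphic rate %.1f%%", len(diversity),
                 rate)

    # ---- optional: transferability ----------------------------------
    if config.transfer_matrix:
        try:
            matrix = read_transfer_matrix(config.transfer_matrix)
            dist = binary_distance(matrix)
            tree, support = bootstrap_support(
                matrix, replicates=config.bootstrap_replicates,
                seed=config.seed)
        except Exception as exc:
            raise StageError("transfer", str(exc)) from exc
        distances_to_tsv(dist, out / "transfer_distances.tsv")
        write_newick(tree, out / "transfer_tree.nwk")
        artifacts["transfer_tree"] = tree
        artifacts["transfer_support"] = support
        artifacts["transfer_rates"] = matrix.transfer_rates()

    # ---- optional: GO enrichment ------------------------------------
    if config.annotations:
        try:
            annmap = read_annotations(config.annotations)
            subset = sorted({l.seq_id for l in loci}
                            & set(annmap.annotations))
            if not subset:
                raise ValueError("no SSR-containing sequence has annotations")
            results = enrich(subset, annmap, fdr_alpha=config.fdr_alpha)
        except Exception as exc:
            raise StageError("enrich", str(exc)) from exc
        enrichment_to_tsv(results, out / "enrichment.tsv")
        artifacts["enrichment"] = results

    # ---- join + export ----------------------------------------------
    markers = build_marker_table(loci, primer_map, placements, diversity)
    markers.to_csv(out / "markers.tsv", sep="\t", index=False)
    artifacts["markers"] = markers
    report_text = summary_report(artifacts)
    (out / "summary_report.txt").write_text(report_text)
    artifacts["report"] = report_text
    export_marker_db(artifacts, out / "marker_db")
    return artifacts


def _placements_tsv(placements) -> str:
    rows = ["\t".join(("locus", "chromosome", "genomic_start", "genomic_end",
                       "strand", "region_class"))]
    for pl in placements:
        rows.append("\t".join(map(str, (
            locus_id(pl.locus), pl.chromosome or ".",
            pl.genomic_start or ".", pl.genomic_end or ".",
            pl.strand or ".", pl.region_class))))
    return "\n".join(rows) + "\n"


def build_marker_table(loci, primer_map, placements=None,
                       diversity=None) -> pd.DataFrame:
    """One row per locus joining motif data, the rank-1 primer pair, the
    genome placement and (when locus ids match) diversity statistics."""
    pl_by_locus = {}
    if placements:
        pl_by_locus = {locus_id(p.locus): p for p in placements}
    div_by_locus = {}
    if diversity is not None and len(diversity):
        div_by_locus = {str(r["locus"]): r for _, r in diversity.iterrows()}
    rows = []
    for locus in loci:
        lid = locus_id(locus)
        row: dict = {
            "locus": lid, "seq_id": locus.seq_id, "motif": locus.motif,
            "canonical_class": locus.canonical_class,
            "repeat_count": locus.repeat_count,
            "start": locus.start, "end": locus.end,
        }
        pairs = primer_map.get(lid, [])
        if pairs:
            best = pairs[0]
            row.update(forward=best.forward, reverse=best.reverse,
                       product_size=best.product_size,
                       penalty=round(best.penalty, 4))
        pl = pl_by_locus.get(lid)
        if pl is not None:
            row.update(chromosome=pl.chromosome, region_class=pl.region_class)
        dv = div_by_locus.get(lid)
        if dv is not None:
            row.update(NA=dv["NA"], He=dv["He"], PIC=dv["PIC_printed"],
                       polymorphic=dv["polymorphic"])
        rows.append(row)
    return pd.DataFrame(rows)


def summary_report(artifacts: Mapping) -> str:
    """Headline summary in the shape of a marker-survey results section."""
    lines: list[str] = []
    rep = artifacts.get("preprocess")
    if rep is not None:
        lines.append(
            f"Sequences: {rep.n_input} input, {rep.n_valid} valid, "
            f"{rep.n_clusters} non-redundant")
    s = artifacts.get("summary")
    if s:
        lines.append(f"SSR loci: {s['n_loci']} in {s['n_ssr_containing']} "
                     f"sequences ({s['n_single_ssr']} single, "
                     f"{s['n_multi_ssr']} multiple)")
        for period, row in s.get("by_period", {}).items():
            lines.append(f"  {period}: {row['count']} ({row['pct']}%)")
        top = list(s.get("class_pct", {}).items())[:3]
        if top:
            lines.append("  top classes: " + ", ".join(
                f"{cls} {pct}%" for cls, pct in top))
        if s.get("n_compound"):
            lines.append(f"  compound SSRs: {s['n_compound']} "
                         f"({s['compound_share_pct']}%)")
        if s.get("density_kb_per_ssr") is not None:
            lines.append(f"  density: one SSR per "
                         f"{s['density_kb_per_ssr']} kb")
        elif s.get("density_undefined"):
            lines.append("  density: undefined (no loci)")
    ps = artifacts.get("placement_summary")
    if ps:
        lines.append(f"Genome placement: {ps['n_placed']} / {ps['n_total']} "
                     f"({ps['placed_pct']}%) placed")
        for cls, pct in ps.get("region_pct", {}).items():
            lines.append(f"  {cls}: {pct}%")
    if "polymorphic_rate_pct" in artifacts:
        lines.append(f"Polymorphic loci: "
                     f"{artifacts['polymorphic_rate_pct']}%")
    tr = artifacts.get("transfer_rates")
    if tr:
        lines.append("Transferability (% of scored loci amplified):")
        for sp, rate in tr.items():
            lines.append(f"  {sp}: {rate}%")
    enr = artifacts.get("enrichment")
    if enr is not None:
        sig = [r for r in enr if r.significant]
        lines.append(f"GO enrichment: {len(sig)} / {len(enr)} terms "
                     f"significant")
    if not lines:
        lines.append("no artifacts")
    return "\n".join(lines) + "\n"


def export_marker_db(artifacts: Mapping, db_dir: str | Path) -> None:
    """Flat-file marker database: normalized TSV tables plus a column
    dictionary, keyed by locus id throughout."""
    db = Path(db_dir)
    db.mkdir(parents=True, exist_ok=True)
    markers: pd.DataFrame = artifacts["markers"]
    if markers["locus"].duplicated().any():
        dup = markers.loc[markers["locus"].duplicated(), "locus"].tolist()
        raise StageError("export", f"duplicate locus ids: {dup[:5]}")
    markers.to_csv(db / "loci.tsv", sep="\t", index=False)

    seq_rows = [{"seq_id": r.id, "length": len(r), "source": r.source_tag}
                for r in artifacts.get("representatives", [])]
    pd.DataFrame(seq_rows).to_csv(db / "sequences.tsv", sep="\t", index=False)

    primer_rows = []
    for lid, pairs in artifacts.get("primers", {}).items():
        for rank, p in enumerate(pairs, start=1):
            primer_rows.append({
                "locus": lid, "rank": rank, "forward": p.forward,
                "reverse": p.reverse, "tm_f": round(p.tm_forward, 2),
                "tm_r": round(p.tm_reverse, 2),
                "product_size": p.product_size,
                "penalty": round(p.penalty, 4),
                "m13_tailed": p.m13_tailed,
            })
    pd.DataFrame(primer_rows).to_csv(db / "primers.tsv", sep="\t",
                                     index=False)
    dictionary = {
        "loci.tsv": "one row per SSR locus; key column `locus` "
                    "(<seq_id>:<start>-<end>)",
        "sequences.tsv": "non-redundant sequence set",
        "primers.tsv": "up to three ranked primer pairs per locus",
    }
    (db / "column_dictionary.json").write_text(json.dumps(dictionary,
                                                          indent=2))


def query_markers(markers: pd.DataFrame, *, locus: str | None = None,
                  canonical_class: str | None = None,
                  region_class: str | None = None) -> pd.DataFrame:
    """Filter the joined marker table by locus id, motif class or region."""
    out = markers
    if locus is not None:
        out = out[out["locus"] == locus]
    if canonical_class is not None:
        out = out[out["canonical_class"] == canonical_class]
    if region_class is not None:
        if "region_class" not in out.columns:
            return out.iloc[0:0]
        out = out[out["region_class"] == region_class]
    return out.reset_index(drop=True)
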