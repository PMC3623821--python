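"""Seeded generators for every input the pipeline consumes, with recorded
ground truth.

Each generator is a pure function of its spec (which carries the seed):
outputs are byte-identical across runs. Sequence backgrounds are rejection
sampled against the package's own detector so they contain no repeat that
any built-in criteria preset would call — planted SSRs are therefore the
only detectable loci and detector recall/precision against the ground truth
are exact quantities, not approximations. The generators deliberately do
not model expression levels, isoforms or sequencing error; they emulate the
*formats* and *signal structure* of real EST collections, genotype tables,
transferability matrices and GO annotation maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import SequenceRecord
from .ssr import (CriteriaPreset, SSRLocus, canonical_motif, find_perfect_ssrs,
                  is_primitive)

#: background screening preset: the union of the built-in presets' minima —
#: a background passing this screen is SSR-free under all three presets.
_SCREEN = CriteriaPreset("screen", {2: 7, 3: 5, 4: 4, 5: 3, 6: 3})

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _clean_background(rng: np.random.Generator, length: int,
                      max_tries: int = 200) -> str:
    for _ in range(max_tries):
        seq = _random_dna(rng, length)
        rec = SequenceRecord("bg", seq)
        if not find_perfect_ssrs(rec, _SCREEN):
            return seq
    raise RuntimeError(f"could not draw an SSR-free background of {length} bp")


def _random_primitive_motif(rng: np.random.Generator, period: int) -> str:
    while True:
        motif = _random_dna(rng, period)
        if is_primitive(motif) and len(set(motif)) > 1:
            return motif


# ---------------------------------------------------------------------------
# EST set

@dataclass(frozen=True)
class PlantedSSR:
    seq_id: str
    motif: str
    repeat_count: int
    start: int  # 1-based inclusive
    end: int

    @property
    def canonical_class(self) -> str:
        return canonical_motif(self.motif)


@dataclass
class EstSetSpec:
    """Composition of a synthetic EST collection.

    ``planted_per_period`` gives how many sequences carry one planted SSR of
    each period; ``extra_repeats`` is added on top of the detection minimum
    of the target preset so every planted locus clears its threshold.
    """

    seed: int
    n_plain: int = 10
    planted_per_period: Mapping[int, int] = field(
        default_factory=lambda: {2: 6, 3: 6, 4: 3, 5: 3, 6: 4})
    extra_repeats: int = 3
    n_compound_pairs: int = 0
    compound_gap: int = 50
    n_duplicates: int = 0
    n_contaminants_per_class: int = 0
    n_short: int = 0
    n_polya_tails: int = 0
    length_min: int = 300
    length_max: int = 600
    preset: CriteriaPreset = field(
        default_factory=lambda: CriteriaPreset(
            "misa_default", {2: 10, 3: 6, 4: 5, 5: 4, 6: 3}))


@dataclass
class EstGroundTruth:
    planted: list[PlantedSSR]
    duplicate_of: dict[str, str]           # duplicate id -> original id
    contaminant_ids: dict[str, list[str]]  # class -> spiked ids
    short_ids: list[str]
    polya_ids: list[str]

    def to_json(self) -> str:
        return json.dumps({
            "planted": [asdict(p) for p in self.planted],
            "duplicate_of": self.duplicate_of,
            "contaminant_ids": self.contaminant_ids,
            "short_ids": self.short_ids,
            "polya_ids": self.polya_ids,
        }, indent=2)


def _plant(rng: np.random.Generator, seq_id: str, length: int,
           inserts: Sequence[tuple[str, int]], gap: int,
           preset: CriteriaPreset,
           max_tries: int = 200, jitter: bool = True
           ) -> tuple[str, list[PlantedSSR]]:
    """Background with SSR blocks inserted at recorded coordinates; the
    assembled sequence is verified against the detector and redrawn until
    the detected loci equal the plan exactly."""
    blocks = [motif * count for motif, count in inserts]
    total_ssr = sum(len(b) for b in blocks)
    spacer = max(gap, 1)
    needed = total_ssr + spacer * (len(blocks) + 1)
    if needed > length:
        raise ValueError(
            f"{seq_id}: planted SSRs ({total_ssr} bp + spacing) do not fit "
            f"in {length} bp")
    for _ in range(max_tries):
        bg_len = length - total_ssr
        bg = _clean_background(rng, bg_len)
        # place blocks left to right with at least `spacer` background bp
        # between and around them; remaining slack goes to the front
        slack = bg_len - spacer * (len(blocks) + 1)
        if jitter:
            offsets = sorted(int(v) for v in
                             rng.integers(0, slack + 1, size=len(blocks)))
        else:
            # fixed inter-block gaps (exactly `spacer` background bp)
            off0 = int(rng.integers(0, slack + 1))
            offsets = [off0] * len(blocks)
        parts: list[str] = []
        truth: list[PlantedSSR] = []
        bg_pos = 0
        out_pos = 0
        prev_off = 0
        for (motif, count), off in zip(inserts, offsets):
            chunk = spacer + (off - prev_off)
            prev_off = off
            parts.append(bg[bg_pos : bg_pos + chunk])
            bg_pos += chunk
            out_pos += chunk
            parts.append(motif * count)
            truth.append(PlantedSSR(seq_id, motif, count, out_pos + 1,
                                    out_pos + count * len(motif)))
            out_pos += count * len(motif)
        parts.append(bg[bg_pos:])
        seq = "".join(parts)
        detected = find_perfect_ssrs(SequenceRecord(seq_id, seq), preset)
        want = {(p.start, p.end, p.motif, p.repeat_count) for p in truth}
        got = {(l.start, l.end, l.motif, l.repeat_count) for l in detected}
        if want == got:
            return seq, truth
    raise RuntimeError(f"{seq_id}: could not assemble a clean planted sequence")


def make_est_set(spec: EstSetSpec) -> tuple[
        list[SequenceRecord], dict[str, list[SequenceRecord]], EstGroundTruth]:
    """Generate (records, contaminant reference sets, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    truth = EstGroundTruth([], {}, {}, [], [])
    idx = 0

    def next_id() -> str:
        nonlocal idx
        idx += 1
        return f"est{idx:05d}"

    for _ in range(spec.n_plain):
        sid = next_id()
        length = int(rng.integers(spec.length_min, spec.length_max + 1))
        records.append(SequenceRecord(sid, _clean_background(rng, length),
                                      "plain"))

    for period, n in sorted(spec.planted_per_period.items()):
        min_rep = spec.preset.min_repeats.get(period)
        if min_rep is None:
            continue
        for _ in range(n):
            sid = next_id()
            length = int(rng.integers(spec.length_min, spec.length_max + 1))
            motif = _random_primitive_motif(rng, period)
            count = min_rep + int(rng.integers(0, spec.extra_repeats + 1))
            seq, planted = _plant(rng, sid, length, [(motif, count)],
                                  110, spec.preset)
            records.append(SequenceRecord(sid, seq, "planted"))
            truth.planted.extend(planted)

    for _ in range(spec.n_compound_pairs):
        sid = next_id()
        length = int(rng.integers(max(spec.length_min, 400),
                                  spec.length_max + 1))
        m1 = _random_primitive_motif(rng, 2)
        m2 = _random_primitive_motif(rng, 3)
        c1 = spec.preset.min_repeats[2] + 1
        c2 = spec.preset.min_repeats[3] + 1
        seq, planted = _plant(rng, sid, length, [(m1, c1), (m2, c2)],
                              spec.compound_gap, spec.preset, jitter=False)
        records.append(SequenceRecord(sid, seq, "compound"))
        truth.planted.extend(planted)

    # duplicates: exact copies of existing records (ids sort after originals,
    # so greedy longest-first clustering keeps the original as representative)
    originals = list(records)
    for k in range(spec.n_duplicates):
        src = originals[int(rng.integers(0, len(originals)))]
        dup_id = f"{src.id}_dup{k}"
        records.append(SequenceRecord(dup_id, src.residues, "duplicate"))
        truth.duplicate_of[dup_id] = src.id

    # contaminant references and spiked near-copies
    contaminant_sets: dict[str, list[SequenceRecord]] = {}
    if spec.n_contaminants_per_class:
        for cls in ("vector", "chloroplast", "mitochondrial"):
            ref = SequenceRecord(f"{cls}_ref", _clean_background(rng, 900),
                                 cls)
            contaminant_sets[cls] = [ref]
            truth.contaminant_ids[cls] = []
            for _ in range(spec.n_contaminants_per_class):
                sid = next_id()
                start = int(rng.integers(0, 900 - 300))
                records.append(SequenceRecord(
                    sid, ref.residues[start : start + 300], "contaminant"))
                truth.contaminant_ids[cls].append(sid)

    for _ in range(spec.n_short):
        sid = next_id()
        length = int(rng.integers(40, 100))
        records.append(SequenceRecord(sid, _clean_background(rng, length),
                                      "short"))
        truth.short_ids.append(sid)

    # poly-A/T tails appended to clean sequences whose terminal base differs
    # from the tail base, so trimming removes exactly the added run
    tail_targets = [r for r in records if r.source_tag == "plain"]
    for k in range(min(spec.n_polya_tails, len(tail_targets))):
        rec = tail_targets[k]
        run = 10 + int(rng.integers(0, 10))
        if rec.residues[-1] != "A":
            new = rec.residues + "A" * run
        else:
            new = rec.residues + "C" + "A" * run
        i = records.index(rec)
        records[i] = SequenceRecord(rec.id, new, "polya")
        truth.polya_ids.append(rec.id)

    return records, contaminant_sets, truth


# ---------------------------------------------------------------------------
# genotypes

@dataclass
class GenotypeSpec:
    seed: int
    n_individuals: int = 24
    #: locus id -> {allele: frequency}; generated when empty
    loci: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    n_loci: int = 10
    n_alleles: int = 4
    missing_rate: float = 0.0


def make_genotypes(spec: GenotypeSpec) -> tuple["GenotypeTable", dict]:
    """Diploid calls drawn from per-locus allele frequencies under random
    mating, with per-cell missingness."""
    from .diversity import GenotypeTable

    rng = np.random.default_rng(spec.seed)
    loci = dict(spec.loci)
    if not loci:
        for i in range(spec.n_loci):
            freqs = rng.dirichlet(np.ones(spec.n_alleles))
            alleles = 100 + 2 * np.arange(spec.n_alleles)
            loci[f"locus{i + 1:03d}"] = {
                int(a): float(f) for a, f in zip(alleles, freqs)}
    individuals = [f"ind{i + 1:03d}" for i in range(spec.n_individuals)]
    calls = {}
    for locus, freqs in loci.items():
        alleles = np.array(sorted(freqs))
        p = np.array([freqs[a] for a in alleles])
        p = p / p.sum()
        for ind in individuals:
            if rng.random() < spec.missing_rate:
                calls[(ind, locus)] = None
            else:
                a, b = rng.choice(alleles, size=2, p=p)
                calls[(ind, locus)] = (int(min(a, b)), int(max(a, b)))
    truth = {"allele_freqs": {l: {str(a): f for a, f in fr.items()}
                              for l, fr in loci.items()}}
    return GenotypeTable(individuals, list(loci), calls), truth


# ---------------------------------------------------------------------------
# transferability

@dataclass
class TransferSpec:
    seed: int
    n_species: int = 8
    chars_per_edge: int = 25
    noise: float = 0.0          # per-cell flip probability on top of signal
    missing_rate: float = 0.0
    mode: str = "exact"         # "exact" or "stochastic"


def _random_topology(rng: np.random.Generator,
                     names: list[str]) -> tuple:
    """Random unrooted binary topology as nested tuples (rooted at a
    trifurcation for n >= 3)."""
    clusters: list = list(names)
    while len(clusters) > 3:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        merged = (clusters[i], clusters[j])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return tuple(clusters)


def _edges_below(node, acc: list[frozenset[str]]) -> frozenset[str]:
    if isinstance(node, str):
        leaves = frozenset([node])
    else:
        leaves = frozenset()
        for child in node:
            leaves |= _edges_below(child, acc)
    acc.append(leaves)
    return leaves


def _topology_newick(node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(_topology_newick(c) for c in node) + ")"


def make_transfer_matrix(spec: TransferSpec) -> tuple["TransferMatrix", dict]:
    """Binary characters evolved on a random tree.

    ``exact`` mode assigns every character to exactly one edge (each edge
    receiving ``chars_per_edge`` characters); a character differs between
    two species iff its edge lies on the path between them, so pairwise
    mismatch proportions are exactly additive on the tree and NJ recovery
    is deterministic. ``stochastic`` mode instead flips characters along
    each edge with probability proportional to the edge share. Optional
    ``noise`` flips every cell independently afterwards.
    """
    if spec.n_species < 4:
        raise ValueError("need at least 4 species")
    from .transfer import TransferMatrix

    rng = np.random.default_rng(spec.seed)
    names = [f"sp{i + 1:02d}" for i in range(spec.n_species)]
    topo = _random_topology(rng, names)
    acc: list[frozenset[str]] = []
    for child in topo:
        _edges_below(child, acc)
    # every edge of the unrooted tree = every proper non-root cluster
    edges = [e for e in acc if 0 < len(e) < spec.n_species]
    n_loci = spec.chars_per_edge * len(edges)
    root_state = rng.integers(0, 2, size=n_loci)
    mat = np.tile(root_state, (spec.n_species, 1)).astype(float)
    name_idx = {n: i for i, n in enumerate(names)}

    if spec.mode == "exact":
        col = 0
        for e in edges:
            rows = [name_idx[n] for n in e]
            for _ in range(spec.chars_per_edge):
                mat[rows, col] = 1.0 - mat[rows, col]
                col += 1
    elif spec.mode == "stochastic":
        for e in edges:
            rows = [name_idx[n] for n in e]
            flips = rng.random(n_loci) < (spec.chars_per_edge / n_loci)
            for c in np.flatnonzero(flips):
                mat[rows, c] = 1.0 - mat[rows, c]
    else:
        raise ValueError(f"unknown mode {spec.mode!r}")

    if spec.noise > 0:
        flip = rng.random(mat.shape) < spec.noise
        mat[flip] = 1.0 - mat[flip]
    if spec.missing_rate > 0:
        miss = rng.random(mat.shape) < spec.missing_rate
        mat[miss] = np.nan

    df = pd.DataFrame(mat, index=names,
                      columns=[f"L{j + 1:04d}" for j in range(n_loci)])
    all_names = frozenset(names)
    ref = min(names)
    canonical = [
        sorted(all_names - e if ref in e else e)
        for e in edges if 2 <= len(e) <= spec.n_species - 2
    ]
    truth = {
        "newick": _topology_newick(topo) + ";",
        # internal-edge bipartitions, each encoded as the side that does
        # not contain the lexicographically smallest species
        "bipartitions": sorted(canonical),
    }
    return TransferMatrix(df), truth


# ---------------------------------------------------------------------------
# GO annotations

@dataclass
class AnnotationSpec:
    seed: int
    n_background: int = 2000
    subset_size: int = 200
    n_terms: int = 20
    base_prob: float = 0.05
    #: term index -> fold enrichment in the subset
    enriched: Mapping[int, float] = field(default_factory=lambda: {0: 5.0})


def make_annotations(spec: AnnotationSpec) -> tuple["AnnotationMap",
                                                    list[str], dict]:
    """Background term assignment with planted fold enrichment in a
    designated subset. Returns (annotation map, subset ids, ground truth)."""
    from .enrichment import AnnotationMap

    rng = np.random.default_rng(spec.seed)
    ids = [f"est{i + 1:05d}" for i in range(spec.n_background)]
    subset = ids[: spec.subset_size]
    subset_set = set(subset)
    annotations: dict[str, set[str]] = {i: set() for i in ids}
    terms = [f"GO:{7000000 + t:07d}" for t in range(spec.n_terms)]
    share = spec.subset_size / spec.n_background
    for t, term in enumerate(terms):
        fold = spec.enriched.get(t, 1.0)
        # solve for the in-subset probability so the *expected measured*
        # fold — (a/subset)/(term total/background), subset included in the
        # background — equals the planted fold
        if fold * share >= 1.0:
            raise ValueError(f"planted fold {fold} infeasible at subset "
                             f"share {share:.2f}")
        p_sub = min(1.0, fold * spec.base_prob * (1.0 - share)
                    / (1.0 - fold * share))
        for sid in ids:
            p = p_sub if sid in subset_set else spec.base_prob
            if rng.random() < p:
                annotations[sid].add(term)
    truth = {"enriched_terms": [terms[t] for t in sorted(spec.enriched)
                                if spec.enriched[t] > 1.0]}
    return AnnotationMap(annotations), subset, truth


# ---------------------------------------------------------------------------
# genome-mapping fixture

@dataclass
class GenomeSpec:
    seed: int
    n_loci: int = 50
    shares: Mapping[str, float] = field(default_factory=lambda: {
        "CDS": 0.72, "UTR5": 0.18, "UTR3": 0.10})
    n_chromosomes: int = 3


def make_genome_fixture(spec: GenomeSpec) -> tuple[
        list[SSRLocus], str, str, dict]:
    """SSR loci, BLAST-tabular hit text and GFF3 gene-model text with known
    region classes.

    Each locus sits in its own EST, mapped full-length to a chromosome
    block that carries one gene whose CDS/UTR layout makes the locus fall
    in the planted class. Returns (loci, hits_text, gff3_text, truth).
    """
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.shares)
    probs = np.array([spec.shares[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    n_per = np.floor(probs * spec.n_loci).astype(int)
    while n_per.sum() < spec.n_loci:
        n_per[int(np.argmax(probs * spec.n_loci - n_per))] += 1
    assignment = [c for c, n in zip(classes, n_per) for _ in range(n)]

    loci: list[SSRLocus] = []
    hit_lines: list[str] = []
    gff_lines = ["##gff-version 3"]
    truth_classes: dict[str, str] = {}
    block = 5000  # one gene block per locus on its chromosome
    per_chrom_offset = {f"chr{i + 1}": 0 for i in range(spec.n_chromosomes)}

    for k, region in enumerate(assignment):
        sid = f"q{k + 1:04d}"
        chrom = f"chr{(k % spec.n_chromosomes) + 1}"
        base = per_chrom_offset[chrom]
        per_chrom_offset[chrom] += block
        # gene layout inside the block (1-based genomic):
        g0 = base + 1000
        utr5 = (g0, g0 + 199)
        cds = (g0 + 200, g0 + 999)
        utr3 = (g0 + 1000, g0 + 1199)
        target = {"CDS": cds, "UTR5": utr5, "UTR3": utr3}[region]
        motif = _random_primitive_motif(rng, 3)
        count = 6 + int(rng.integers(0, 3))
        length = count * 3
        # place the locus fully inside the target feature
        gstart = int(rng.integers(target[0], target[1] - length))
        # the EST covers the locus plus 100 bp flanks
        q_genomic_start = gstart - 100
        q_len = length + 200
        locus = SSRLocus(seq_id=sid, motif=motif,
                         canonical_class=canonical_motif(motif),
                         repeat_count=count, start=101, end=100 + length,
                         preset_name="misa_default")
        loci.append(locus)
        truth_classes[sid] = region
        pid = 95.0 + float(rng.random()) * 5.0
        hit_lines.append("\t".join(map(str, [
            sid, chrom, f"{pid:.2f}", q_len, 0, 0, 1, q_len,
            q_genomic_start, q_genomic_start + q_len - 1, "1e-50", 500.0])))
        gid = f"gene{k + 1:04d}"
        strand = "+"
        gff_lines += [
            f"{chrom}\tsim\tgene\t{g0}\t{g0 + 1199}\t.\t{strand}\t.\tID={gid}",
            f"{chrom}\tsim\tmRNA\t{g0}\t{g0 + 1199}\t.\t{strand}\t.\t"
            f"ID={gid}.1;Parent={gid}",
            f"{chrom}\tsim\tfive_prime_UTR\t{utr5[0]}\t{utr5[1]}\t.\t{strand}"
            f"\t.\tID={gid}.utr5;Parent={gid}.1",
            f"{chrom}\tsim\tCDS\t{cds[0]}\t{cds[1]}\t.\t{strand}\t0\t"
            f"ID={gid}.cds;Parent={gid}.1",
            f"{chrom}\tsim\tthree_prime_UTR\t{utr3[0]}\t{utr3[1]}\t.\t{strand}"
            f"\t.\tID={gid}.utr3;Parent={gid}.1",
        ]
    truth = {"region_class": truth_classes,
             "shares": {c: float(n) / spec.n_loci
                        for c, n in zip(classes, n_per)}}
    return loci, "\n".join(hit_lines) + "\n", "\n".join(gff_lines) + "\n", truth
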