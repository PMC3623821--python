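"""Projection of SSR loci onto a reference genome and CDS/UTR classification.

EST-to-genome placements are consumed as standard 12-column BLAST tabular
hits. For each query the best hit above the identity cutoff (strictly > 0.8
by default) is chosen; an SSR locus fully contained in the hit's query
interval is projected onto the subject by affine offset (or, optionally, by
a global pairwise realignment of the matched segments). The projected
interval is classified against GFF3 gene models as CDS, 5'UTR, 3'UTR or
intergenic by largest base overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

from . import align
from .ssr import SSRLocus

REGION_CLASSES = ("CDS", "UTR5", "UTR3", "intergenic", "unplaced")
_FEATURE_TO_CLASS = {"CDS": "CDS", "five_prime_UTR": "UTR5",
                     "three_prime_UTR": "UTR3"}
_CLASS_PRIORITY = {"CDS": 0, "UTR5": 1, "UTR3": 2}


@dataclass(frozen=True)
class AlignmentHit:
    """One row of BLAST tabular output (coordinates 1-based inclusive;
    subject_start > subject_end encodes the minus strand)."""

    query_id: str
    subject_id: str
    identity: float  # fraction, 0-1
    length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0,1]")

    @property
    def strand(self) -> str:
        return "-" if self.subject_start > self.subject_end else "+"


@dataclass(frozen=True)
class MappingConfig:
    min_identity: float = 0.80  # strict >
    refine: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 1.0):
            raise ValueError("min_identity must be in [0,1]")


@dataclass(frozen=True)
class GeneModel:
    """CDS/UTR intervals of one gene (1-based inclusive)."""

    gene_id: str
    chromosome: str
    strand: str
    cds: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def intervals(self, region_class: str) -> tuple[tuple[int, int], ...]:
        return {"CDS": self.cds, "UTR5": self.utr5, "UTR3": self.utr3}[region_class]


@dataclass(frozen=True)
class LocusPlacement:
    locus: SSRLocus
    chromosome: str | None
    genomic_start: int | None
    genomic_end: int | None
    strand: str | None
    region_class: str = "unplaced"

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"bad region class {self.region_class!r}")


def read_hits(path: str | Path) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular hits; malformed rows raise with the
    offending line number. Percent identity (0-100) becomes a fraction."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"found {len(cols)}")
            try:
                hits.append(AlignmentHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    identity=float(cols[2]) / 100.0,
                    length=int(cols[3]),
                    query_start=int(cols[6]),
                    query_end=int(cols[7]),
                    subject_start=int(cols[8]),
                    subject_end=int(cols[9]),
                    bitscore=float(cols[11]),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def select_best_hit(hits: Sequence[AlignmentHit],
                    config: MappingConfig | None = None) -> AlignmentHit | None:
    """Best qualifying hit for one query.

    Hits with identity <= min_identity are discarded (the cutoff is strict);
    the survivor with the highest bitscore wins, ties broken by longer
    alignment, then lexicographic subject id, then smaller subject start.
    """
    config = config or MappingConfig()
    survivors = [h for h in hits if h.identity > config.min_identity]
    if not survivors:
        return None
    return min(survivors, key=lambda h: (-h.bitscore, -h.length,
                                         h.subject_id,
                                         min(h.subject_start, h.subject_end)))


def project_locus(locus: SSRLocus, hit: AlignmentHit,
                  config: MappingConfig | None = None,
                  query_seq: str | None = None,
                  subject_seq: str | None = None) -> LocusPlacement:
    """Map a locus through a hit by affine offset (default) or realignment.

    The locus must lie fully inside the hit's query interval, otherwise the
    placement is ``unplaced``. On the plus strand
    ``g = subject_start + (q - query_start)``; on the minus strand
    ``g = subject_start - (q - query_start)``. With ``refine=True`` and both
    segment sequences supplied, a global pairwise alignment (match +1,
    mismatch -1, gap -2) of the query segment to the subject segment
    replaces the affine offset.
    """
    config = config or MappingConfig()
    if locus.seq_id != hit.query_id:
        raise ValueError(f"locus {locus.seq_id} vs hit {hit.query_id}: "
                         "mismatched ids")
    if not (hit.query_start <= locus.start and locus.end <= hit.query_end):
        return LocusPlacement(locus, None, None, None, None, "unplaced")

    if config.refine and query_seq is not None and subject_seq is not None:
        # query_seq/subject_seq are the aligned segments, query orientation
        pos = align.global_position_map(query_seq, subject_seq)
        off_s = pos[locus.start - hit.query_start]
        off_e = pos[locus.end - hit.query_start]
        if off_s is None or off_e is None:
            return LocusPlacement(locus, None, None, None, None, "unplaced")
    else:
        off_s = locus.start - hit.query_start
        off_e = locus.end - hit.query_start

    if hit.strand == "+":
        g1 = hit.subject_start + off_s
        g2 = hit.subject_start + off_e
    else:
        g1 = hit.subject_start - off_s
        g2 = hit.subject_start - off_e
    lo, hi = (g1, g2) if g1 <= g2 else (g2, g1)
    return LocusPlacement(locus, hit.subject_id, lo, hi, hit.strand,
                          "intergenic")


def read_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Load CDS / five_prime_UTR / three_prime_UTR features from GFF3,
    grouped by their top-level gene."""
    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique",
                            keep_order=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        buckets: dict[str, list[tuple[int, int]]] = {
            "CDS": [], "UTR5": [], "UTR3": []}
        for ftype, cls in _FEATURE_TO_CLASS.items():
            for feat in db.children(gene, featuretype=ftype):
                buckets[cls].append((feat.start, feat.end))
        models.append(GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            cds=tuple(sorted(buckets["CDS"])),
            utr5=tuple(sorted(buckets["UTR5"])),
            utr3=tuple(sorted(buckets["UTR3"])),
        ))
    return models


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def classify_region(placement: LocusPlacement,
                    gene_models: Sequence[GeneModel]) -> LocusPlacement:
    """Assign CDS/UTR5/UTR3/intergenic by largest base overlap.

    When several genes overlap the placement, the gene with the largest
    total overlap is chosen first; within that gene the feature class with
    the largest overlap wins, ties broken CDS > UTR5 > UTR3. No overlap
    with any feature gives ``intergenic``; a placement on a chromosome
    absent from the annotation stays ``unplaced``.
    """
    from dataclasses import replace

    if placement.chromosome is None:
        return placement
    chrom_models = [g for g in gene_models
                    if g.chromosome == placement.chromosome]
    if not chrom_models and not any(True for _ in gene_models):
        return replace(placement, region_class="unplaced")
    span = (placement.genomic_start, placement.genomic_end)
    annotated_chroms = {g.chromosome for g in gene_models}
    if placement.chromosome not in annotated_chroms:
        return replace(placement, region_class="unplaced")

    best_gene = None
    best_total = 0
    for gene in chrom_models:
        total = sum(_overlap(span, iv)
                    for cls in ("CDS", "UTR5", "UTR3")
                    for iv in gene.intervals(cls))
        if total > best_total or (total == best_total and total > 0
                                  and best_gene is not None
                                  and gene.gene_id < best_gene.gene_id):
            best_gene, best_total = gene, total
    if best_gene is None or best_total == 0:
        return replace(placement, region_class="intergenic")
    per_class = {
        cls: sum(_overlap(span, iv) for iv in best_gene.intervals(cls))
        for cls in ("CDS", "UTR5", "UTR3")
    }
    winner = min(per_class,
                 key=lambda c: (-per_class[c], _CLASS_PRIORITY[c]))
    return replace(placement, region_class=winner)


def place_loci(loci: Sequence[SSRLocus],
               hits: Sequence[AlignmentHit],
               gene_models: Sequence[GeneModel] = (),
               config: MappingConfig | None = None) -> list[LocusPlacement]:
    """Full placement of many loci: best hit per query, projection and
    (when gene models are given) region classification."""
    config = config or MappingConfig()
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    placements: list[LocusPlacement] = []
    for locus in loci:
        best = select_best_hit(by_query.get(locus.seq_id, ()), config)
        if best is None:
            placements.append(
                LocusPlacement(locus, None, None, None, None, "unplaced"))
            continue
        pl = project_locus(locus, best, config)
        if gene_models and pl.chromosome is not None:
            pl = classify_region(pl, gene_models)
        placements.append(pl)
    return placements


def distribution_table(placements: Sequence[LocusPlacement]) -> dict:
    """Counts and percentages by chromosome and region class, plus the
    region-class x motif-period cross-table."""
    by_chrom: dict[str, int] = {}
    by_region: dict[str, int] = {}
    cross: dict[str, dict[int, int]] = {}
    placed = 0
    for pl in placements:
        by_region[pl.region_class] = by_region.get(pl.region_class, 0) + 1
        if pl.chromosome is not None:
            placed += 1
            by_chrom[pl.chromosome] = by_chrom.get(pl.chromosome, 0) + 1
        cross.setdefault(pl.region_class, {})
        p = pl.locus.period
        cross[pl.region_class][p] = cross[pl.region_class].get(p, 0) + 1
    n = len(placements)
    return {
        "n_total": n,
        "n_placed": placed,
        "placed_pct": round(100.0 * placed / n, 1) if n else None,
        "by_chromosome": dict(sorted(by_chrom.items())),
        "by_region": dict(sorted(by_region.items())),
        "region_pct": {
            cls: round(100.0 * c / placed, 1)
            for cls, c in sorted(by_region.items()) if cls != "unplaced"
        } if placed else {},
        "region_by_period": {cls: dict(sorted(d.items()))
                             for cls, d in sorted(cross.items())},
    }
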