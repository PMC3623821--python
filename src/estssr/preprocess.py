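"""EST/transcript cleanup: poly-A/T trimming, length filter, contaminant
screening and redundancy clustering, with conserved accounting.

The stages mirror the classical EST-SSR preparation workflow: terminal
poly-A/poly-T runs are stripped (cDNA orientation is unknown, so both A and T
runs are removed at either end), sequences shorter than a minimum length are
dropped, sequences resembling vector/chloroplast/mitochondrial references are
removed, and the survivors are collapsed to a non-redundant set by greedy
longest-first clustering at a similarity threshold (matches in the best local
alignment divided by the shorter sequence's length — the convention of greedy
incremental clustering tools such as CD-HIT).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import align
from .records import SequenceRecord

#: Fixed order in which contaminant classes are charged when a sequence
#: matches references from more than one class.
CONTAMINANT_CLASS_ORDER = ("vector", "chloroplast", "mitochondrial")

#: Seed k-mer sizes for the shared-word prefilters.
CONTAMINANT_SEED_K = 12
CLUSTER_SEED_K = 8


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable thresholds for the cleanup stages.

    min_length
        Sequences strictly shorter than this (bp) are discarded (default 100).
    cluster_identity
        Similarity threshold for redundancy clustering (default 0.90).
    trim_run_min
        Minimum terminal A/T run length that is trimmed (default 10).
    contaminant_min_identity / contaminant_min_coverage
        A sequence is called contaminant when some reference aligns to it
        with at least this identity over at least this fraction of the
        sequence's length.
    """

    min_length: int = 100
    cluster_identity: float = 0.90
    trim_run_min: int = 10
    contaminant_min_identity: float = 0.90
    contaminant_min_coverage: float = 0.50

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        for name in ("cluster_identity", "contaminant_min_identity",
                     "contaminant_min_coverage"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.trim_run_min < 1:
            raise ValueError("trim_run_min must be >= 1")


@dataclass
class PreprocessReport:
    """Accounting of every cleanup stage; conservation is enforced."""

    n_input: int
    n_removed_short: int
    n_removed_by_contaminant_class: dict[str, int]
    n_valid: int
    n_clusters: int
    removed_short_ids: list[str] = field(default_factory=list)
    removed_contaminant_ids: dict[str, list[str]] = field(default_factory=dict)
    representative_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        removed = self.n_removed_short + sum(
            self.n_removed_by_contaminant_class.values())
        if self.n_valid != self.n_input - removed:
            raise ValueError(
                f"accounting violation: {self.n_input} input - {removed} "
                f"removed != {self.n_valid} valid")
        if self.n_clusters > self.n_valid:
            raise ValueError("more clusters than valid sequences")
        if self.n_valid < 0 or self.n_removed_short < 0:
            raise ValueError("negative counts")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_removed_short": self.n_removed_short,
                "n_removed_by_contaminant_class":
                    self.n_removed_by_contaminant_class,
                "n_valid": self.n_valid,
                "n_clusters": self.n_clusters,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [
            f"input sequences        {self.n_input}",
            f"removed (short)        {self.n_removed_short}",
        ]
        for cls, n in self.n_removed_by_contaminant_class.items():
            lines.append(f"removed ({cls}){' ' * max(1, 9 - len(cls))}{n}")
        lines += [
            f"valid sequences        {self.n_valid}",
            f"non-redundant clusters {self.n_clusters}",
        ]
        return "\n".join(lines)


def _terminal_run(seq: str, base: str, end: str) -> int:
    """Length of the run of ``base`` at the 5' or 3' end of ``seq``."""
    it = seq if end == "5p" else reversed(seq)
    n = 0
    for c in it:
        if c != base:
            break
        n += 1
    return n


def trim_poly_at(record: SequenceRecord, config: PreprocessConfig) -> SequenceRecord:
    """Strip terminal poly-A/poly-T runs of length >= ``trim_run_min``.

    Both A and T runs are removed at both ends (orientation unknown),
    iteratively until no terminal run qualifies. Interior runs are never
    touched. The result may be empty; an empty result is returned as a
    1-character placeholder removal is *not* performed — instead the record
    is returned with an empty-marker handled by the caller via length
    filtering (a fully trimmed record keeps a single sentinel base removed
    downstream). To keep records valid, a fully consumed sequence raises.
    """
    seq = record.residues
    changed = True
    while changed and seq:
        changed = False
        for base in "AT":
            run5 = _terminal_run(seq, base, "5p")
            if run5 >= config.trim_run_min:
                seq = seq[run5:]
                changed = True
        for base in "AT":
            run3 = _terminal_run(seq, base, "3p")
            if run3 >= config.trim_run_min:
                seq = seq[: len(seq) - run3]
                changed = True
    if seq == record.residues:
        return record
    if not seq:
        # Entire sequence was terminal homopolymer; keep a zero-information
        # single base so the record stays well formed — the length filter
        # removes it on the next stage.
        seq = record.residues[0]
    return record.with_residues(seq).tagged("trimmed")


def filter_short(
    records: Sequence[SequenceRecord], config: PreprocessConfig
) -> tuple[list[SequenceRecord], list[str]]:
    """Drop records strictly shorter than ``min_length`` bp."""
    kept = [r for r in records if len(r) >= config.min_length]
    removed = [r.id for r in records if len(r) < config.min_length]
    return kept, removed


def screen_contaminants(
    records: Sequence[SequenceRecord],
    contaminant_sets: Mapping[str, Sequence[SequenceRecord]],
    config: PreprocessConfig,
) -> tuple[list[SequenceRecord], dict[str, list[str]]]:
    """Remove records that align to a contaminant reference.

    A record is removed iff some reference sequence has a local alignment to
    it with identity >= ``contaminant_min_identity`` computed over the record
    (matches / record length must also cover >= ``contaminant_min_coverage``
    of the record). Classes are tested in the fixed order
    vector -> chloroplast -> mitochondrial (unknown classes are appended
    alphabetically after the known ones); the first class that matches is
    the one charged in the report.
    """
    known = [c for c in CONTAMINANT_CLASS_ORDER if c in contaminant_sets]
    extra = sorted(set(contaminant_sets) - set(CONTAMINANT_CLASS_ORDER))
    for cls in contaminant_sets:
        if cls not in CONTAMINANT_CLASS_ORDER and not isinstance(cls, str):
            raise ValueError(f"invalid contaminant class label: {cls!r}")
    order = known + extra

    kmers = {
        cls: [(ref, align.kmer_set(ref.residues, CONTAMINANT_SEED_K))
              for ref in contaminant_sets[cls]]
        for cls in order
    }
    kept: list[SequenceRecord] = []
    removed: dict[str, list[str]] = {cls: [] for cls in order}
    for rec in records:
        charged: str | None = None
        for cls in order:
            for ref, refk in kmers[cls]:
                if not align.shares_kmer(rec.residues, refk, CONTAMINANT_SEED_K):
                    continue
                matches, a0, a1 = align.local_alignment_stats(
                    rec.residues, ref.residues)
                span = a1 - a0
                if span == 0:
                    continue
                identity = matches / span
                coverage = span / len(rec)
                if (identity >= config.contaminant_min_identity
                        and coverage >= config.contaminant_min_coverage):
                    charged = cls
                    break
            if charged:
                break
        if charged:
            removed[charged].append(rec.id)
        else:
            kept.append(rec)
    return kept, removed


def cluster_redundant(
    records: Sequence[SequenceRecord], config: PreprocessConfig
) -> tuple[list[SequenceRecord], dict[str, list[str]]]:
    """Greedy longest-first clustering at ``cluster_identity``.

    Records are visited by decreasing length (ties by id, ascending); each
    joins the first existing representative with identity >= threshold
    (identity = local-alignment matches / shorter length), otherwise it
    founds a new cluster. Representatives are returned in founding order.
    An 8-mer shared-word prefilter skips alignments that cannot qualify.
    """
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[SequenceRecord] = []
    rep_kmers: list[frozenset[str]] = []
    clusters: dict[str, list[str]] = {}
    for rec in ordered:
        home: str | None = None
        for rep, rk in zip(reps, rep_kmers):
            if len(rec) >= CLUSTER_SEED_K and not align.shares_kmer(
                    rec.residues, rk, CLUSTER_SEED_K):
                continue
            if align.local_identity(rec.residues, rep.residues) >= config.cluster_identity:
                home = rep.id
                break
        if home is None:
            reps.append(rec)
            rep_kmers.append(align.kmer_set(rec.residues, CLUSTER_SEED_K))
            clusters[rec.id] = []
        else:
            clusters[home].append(rec.id)
    return reps, clusters


def build_report(
    n_input: int,
    removed_short: Sequence[str],
    removed_contaminants: Mapping[str, Sequence[str]],
    n_valid: int,
    representatives: Sequence[SequenceRecord],
) -> PreprocessReport:
    """Assemble the conserved accounting report (raises if counts disagree)."""
    return PreprocessReport(
        n_input=n_input,
        n_removed_short=len(removed_short),
        n_removed_by_contaminant_class={
            cls: len(ids) for cls, ids in removed_contaminants.items()},
        n_valid=n_valid,
        n_clusters=len(representatives),
        removed_short_ids=list(removed_short),
        removed_contaminant_ids={
            cls: list(ids) for cls, ids in removed_contaminants.items()},
        representative_ids=[r.id for r in representatives],
    )


def preprocess(
    records: Sequence[SequenceRecord],
    contaminant_sets: Mapping[str, Sequence[SequenceRecord]] | None = None,
    config: PreprocessConfig | None = None,
) -> tuple[list[SequenceRecord], dict[str, list[str]], PreprocessReport]:
    """Run trim -> length filter -> contaminant screen -> clustering.

    Returns (representatives, cluster map, report).
    """
    config = config or PreprocessConfig()
    contaminant_sets = contaminant_sets or {}
    trimmed = [trim_poly_at(r, config) for r in records]
    kept, removed_short = filter_short(trimmed, config)
    kept, removed_cont = screen_contaminants(kept, contaminant_sets, config)
    reps, clusters = cluster_redundant(kept, config)
    report = build_report(len(records), removed_short, removed_cont,
                          len(kept), reps)
    return reps, clusters, report
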