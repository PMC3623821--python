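"""Perfect microsatellite (SSR) detection, motif canonicalization, compound
merging and summary statistics.

An SSR here is a maximal perfect tandem run of a *primitive* motif of period
2-6 bp (mononucleotide runs are deliberately excluded). Motifs are grouped
into canonical classes invariant to reading phase and strand: the class of a
motif is written ``M/M'`` where ``M`` is the lexicographic minimum over all
cyclic rotations of the motif and of its reverse complement, and ``M'`` is
the reverse complement of ``M`` (so AG, GA, CT and TC all belong to "AG/CT").

Three named criteria presets are built in:

``misa_default``
    repeat-count thresholds di>=10, tri>=6, tetra>=5, penta>=4, hexa>=3,
    compound-merge interruption 100 bp — the classical MISA search settings
    for EST surveys.
``cardle``
    di>=7, tri>=5, tetra>=4, penta>=3 — the density-comparison thresholds
    of Cardle et al.; no hexanucleotide threshold is defined, so
    hexanucleotides are not searched under this preset.
``len20``
    total repeat length strictly greater than 20 bp, any period 2-6 with at
    least two copies — an approximation of SSRLocator-style length-based
    searches used for cross-taxon frequency comparisons.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import SequenceRecord, reverse_complement

MIN_PERIOD = 2
MAX_PERIOD = 6

_PERIOD_NAMES = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class CriteriaPreset:
    """A named SSR search criterion.

    ``min_repeats`` maps motif period (2-6) to the minimum number of full
    tandem copies; periods absent from the map are not searched.
    ``min_total_length`` (bp), when set, additionally requires the locus
    length to be strictly greater than the given value.
    ``max_interruption`` is the largest gap (bp) between consecutive loci
    that still merges them into a compound SSR.
    """

    name: str
    min_repeats: Mapping[int, int]
    min_total_length: int | None = None
    max_interruption: int = 100

    def __post_init__(self) -> None:
        for p, m in self.min_repeats.items():
            if not (MIN_PERIOD <= p <= MAX_PERIOD):
                raise ValueError(f"period {p} outside 2-6")
            if m < 1:
                raise ValueError("min_repeats entries must be >= 1")
        if self.max_interruption < 0:
            raise ValueError("max_interruption must be >= 0")


@dataclass(frozen=True)
class SSRLocus:
    """A maximal perfect tandem repeat (1-based inclusive coordinates)."""

    seq_id: str
    motif: str
    canonical_class: str
    repeat_count: int
    start: int
    end: int
    preset_name: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.repeat_count * len(self.motif):
            raise ValueError(
                f"{self.seq_id}:{self.start}-{self.end}: span does not equal "
                f"repeat_count x period")

    @property
    def period(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CompoundSSR:
    """Two or more SSR runs separated by gaps within the interruption limit."""

    seq_id: str
    members: tuple[SSRLocus, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a compound SSR needs >= 2 members")
        for a, b in zip(self.members, self.members[1:]):
            if b.start <= a.end:
                raise ValueError("compound members overlap or are unordered")

    @property
    def gaps(self) -> tuple[int, ...]:
        return tuple(b.start - a.end - 1
                     for a, b in zip(self.members, self.members[1:]))

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return self.members[-1].end


def is_primitive(motif: str) -> bool:
    """True iff the motif is not a whole-number power of a shorter word."""
    if not (1 <= len(motif) <= MAX_PERIOD):
        raise ValueError("motif length must be 1-6")
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical class ``M/M'`` of a primitive 2-6 bp motif.

    ``M`` is the lexicographic minimum over all cyclic rotations of the motif
    and of its reverse complement; ``M'`` is the reverse complement of ``M``.
    The grouping is therefore invariant to phase and strand.
    """
    if not (MIN_PERIOD <= len(motif) <= MAX_PERIOD):
        raise ValueError(f"motif {motif!r} outside period range 2-6")
    if any(c not in "ACGT" for c in motif):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = reverse_complement(motif)
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
    m = min(rotations)
    return f"{m}/{reverse_complement(m)}"


def canonical_classes(period: int) -> set[str]:
    """All canonical classes of a given period (exhaustive enumeration)."""
    out = set()
    for word in itertools.product("ACGT", repeat=period):
        motif = "".join(word)
        if is_primitive(motif):
            out.add(canonical_motif(motif))
    return out


def builtin_presets() -> list[CriteriaPreset]:
    return [
        CriteriaPreset("misa_default", {2: 10, 3: 6, 4: 5, 5: 4, 6: 3}),
        CriteriaPreset("cardle", {2: 7, 3: 5, 4: 4, 5: 3}),
        CriteriaPreset("len20", {p: 2 for p in range(2, 7)},
                       min_total_length=20),
    ]


def get_preset(name: str) -> CriteriaPreset:
    for p in builtin_presets():
        if p.name == name:
            return p
    raise KeyError(f"unknown preset {name!r}; "
                   f"choose from {[p.name for p in builtin_presets()]}")


def find_perfect_ssrs(record: SequenceRecord,
                      preset: CriteriaPreset) -> list[SSRLocus]:
    """All maximal perfect tandem repeats in one sequence under a preset.

    For each period the sequence is scanned for maximal stretches where
    ``s[i] == s[i+p]`` (N and ambiguity codes break a run); each stretch
    yields at most one locus whose motif is the leftmost full copy. Loci
    whose motif is non-primitive are skipped — they are reported at their
    true (shorter) period instead. Trailing partial motif copies are
    excluded from both the repeat count and the end coordinate. When two
    periods describe the identical interval, the shorter period wins.
    Output coordinates are 1-based inclusive, sorted by (start, period).
    """
    seq = record.residues
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    acgt = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))

    found: dict[tuple[int, int], SSRLocus] = {}
    for p, min_rep in sorted(preset.min_repeats.items()):
        if n < 2 * p:
            continue
        eq = (arr[p:] == arr[:-p]) & acgt[:-p]
        if not eq.any():
            continue
        # run-length encode the boolean match vector
        idx = np.flatnonzero(np.diff(np.concatenate(
            ([False], eq, [False])).astype(np.int8)))
        for run_start, run_end in zip(idx[::2], idx[1::2]):
            region_len = int(run_end - run_start) + p
            count = int(region_len // p)
            if count < min_rep:
                continue
            length = count * p
            if preset.min_total_length is not None and length <= preset.min_total_length:
                continue
            start0 = int(run_start)
            motif = seq[start0 : start0 + p]
            if not is_primitive(motif):
                continue
            key = (start0, start0 + length)
            prev = found.get(key)
            if prev is None or p < prev.period:
                found[key] = SSRLocus(
                    seq_id=record.id,
                    motif=motif,
                    canonical_class=canonical_motif(motif),
                    repeat_count=count,
                    start=start0 + 1,
                    end=start0 + length,
                    preset_name=preset.name,
                )
    return sorted(found.values(), key=lambda l: (l.start, l.period))


def find_ssrs(records: Iterable[SequenceRecord],
              preset: CriteriaPreset) -> list[SSRLocus]:
    """Detect SSRs in many records; sorted by (seq_id, start, period)."""
    out: list[SSRLocus] = []
    for rec in records:
        out.extend(find_perfect_ssrs(rec, preset))
    return sorted(out, key=lambda l: (l.seq_id, l.start, l.period))


def resolve_overlaps(loci: Sequence[SSRLocus]) -> list[SSRLocus]:
    """Drop overlapping loci on the same sequence, keeping at each conflict
    the longer locus (ties: shorter period, then smaller start)."""
    kept: list[SSRLocus] = []
    by_seq: dict[str, list[SSRLocus]] = {}
    for l in loci:
        by_seq.setdefault(l.seq_id, []).append(l)
    for seq_id in sorted(by_seq):
        ranked = sorted(by_seq[seq_id],
                        key=lambda l: (-l.length, l.period, l.start))
        chosen: list[SSRLocus] = []
        for cand in ranked:
            if all(cand.end < c.start or cand.start > c.end for c in chosen):
                chosen.append(cand)
        kept.extend(sorted(chosen, key=lambda l: l.start))
    return sorted(kept, key=lambda l: (l.seq_id, l.start))


def merge_compound(
    loci: Sequence[SSRLocus], preset: CriteriaPreset
) -> tuple[list[CompoundSSR], list[SSRLocus]]:
    """Chain same-sequence loci with gaps <= ``max_interruption`` into
    compound SSRs; the rest are returned as singletons.

    Input must be sorted by (seq_id, start) and non-overlapping (overlaps
    must be resolved upstream; they raise here).
    """
    compounds: list[CompoundSSR] = []
    singletons: list[SSRLocus] = []
    chain: list[SSRLocus] = []

    def flush() -> None:
        if len(chain) >= 2:
            compounds.append(CompoundSSR(chain[0].seq_id, tuple(chain)))
        elif chain:
            singletons.append(chain[0])
        chain.clear()

    for locus in loci:
        if chain and locus.seq_id == chain[-1].seq_id:
            if locus.start <= chain[-1].end:
                raise ValueError(
                    f"overlapping loci on {locus.seq_id}: "
                    f"{chain[-1].start}-{chain[-1].end} vs "
                    f"{locus.start}-{locus.end}")
            gap = locus.start - chain[-1].end - 1
            if gap <= preset.max_interruption:
                chain.append(locus)
                continue
        flush()
        chain.append(locus)
    flush()
    return compounds, singletons


def summarize(
    loci: Sequence[SSRLocus],
    compounds: Sequence[CompoundSSR],
    total_bases: int,
    n_sequences: int,
) -> dict:
    """Frequency/density summary of a detection run.

    density_kb = total bases / number of loci, in kb per SSR (None when no
    loci were found); frequency = fraction of sequences containing at least
    one SSR. Counts are broken down by period and canonical class.
    """
    n_loci = len(loci)
    by_period: dict[int, int] = {}
    by_class: dict[str, int] = {}
    per_seq: dict[str, int] = {}
    total_repeats = 0
    for l in loci:
        by_period[l.period] = by_period.get(l.period, 0) + 1
        by_class[l.canonical_class] = by_class.get(l.canonical_class, 0) + 1
        per_seq[l.seq_id] = per_seq.get(l.seq_id, 0) + 1
        total_repeats += l.repeat_count
    n_containing = len(per_seq)
    n_multi = sum(1 for v in per_seq.values() if v > 1)
    return {
        "n_loci": n_loci,
        "n_compound": len(compounds),
        "compound_share_pct": round(100.0 * len(compounds) / n_loci, 1)
        if n_loci else None,
        "by_period": {
            _PERIOD_NAMES[p]: {
                "count": c,
                "pct": round(100.0 * c / n_loci, 1),
            }
            for p, c in sorted(by_period.items())
        },
        "by_class": dict(sorted(by_class.items(),
                                key=lambda kv: (-kv[1], kv[0]))),
        "class_pct": {
            cls: round(100.0 * c / n_loci, 1)
            for cls, c in sorted(by_class.items(),
                                 key=lambda kv: (-kv[1], kv[0]))
        } if n_loci else {},
        "mean_repeat_count": round(total_repeats / n_loci, 2) if n_loci else None,
        "n_sequences": n_sequences,
        "n_ssr_containing": n_containing,
        "n_single_ssr": n_containing - n_multi,
        "n_multi_ssr": n_multi,
        "frequency_pct": round(100.0 * n_containing / n_sequences, 1)
        if n_sequences else None,
        "total_bases": total_bases,
        "density_kb_per_ssr": round(total_bases / n_loci / 1000.0, 1)
        if n_loci else None,
        "density_undefined": n_loci == 0,
    }


SSR_TSV_COLUMNS = ("seq_id", "preset", "motif", "canonical_class",
                   "repeat_count", "start", "end", "length")


def loci_to_tsv(loci: Sequence[SSRLocus],
                compounds: Sequence[CompoundSSR] = ()) -> str:
    """MISA-like TSV: one row per locus; compound rows list member indices."""
    lines = ["\t".join(SSR_TSV_COLUMNS)]
    index: dict[tuple, int] = {}
    for i, l in enumerate(loci, start=1):
        index[(l.seq_id, l.start, l.end)] = i
        lines.append("\t".join(map(str, (
            l.seq_id, l.preset_name, l.motif, l.canonical_class,
            l.repeat_count, l.start, l.end, l.length))))
    for c in compounds:
        members = ",".join(
            str(index[(m.seq_id, m.start, m.end)]) for m in c.members)
        lines.append("\t".join(map(str, (
            c.seq_id, c.members[0].preset_name, f"compound[{members}]",
            "*", len(c.members), c.start, c.end, c.end - c.start + 1))))
    return "\n".join(lines) + "\n"
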