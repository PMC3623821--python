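"""Primer-pair enumeration and scoring for SSR loci.

Candidate forward primers are taken from the 5' flank and reverse primers
(reverse-complement orientation) from the 3' flank of each locus; every pair
satisfying the length / Tm / GC% / product-size constraints is scored by a
transparent penalty — weighted absolute deviation of each primer from the
length and Tm optima plus a pair Tm-difference term — and the three smallest
penalties are kept. Enumeration is exhaustive within the constraint windows,
so the returned optimum is the global one by construction.

Melting temperatures use nearest-neighbor thermodynamics (unified DNA/DNA
parameters of SantaLucia 1998, 50 mM Na+, 250 nM total oligo) by default,
or the Wallace 2(A+T)+4(G+C) rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from .records import SequenceRecord, reverse_complement
from .ssr import SSRLocus

#: M13(-21) universal forward tail used for fluorescent genotyping.
M13_TAIL = "TGTAAAACGACGGCCAGT"

# Unified nearest-neighbor parameters (SantaLucia 1998): kcal/mol, cal/(mol K)
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# terminal initiation corrections
NN_INIT_GC = (0.1, -2.8)
NN_INIT_AT = (2.3, 4.1)

_R = 1.987  # gas constant, cal/(mol K)
DEFAULT_NA_MM = 50.0      # monovalent cation, mM
DEFAULT_OLIGO_NM = 250.0  # total oligo concentration, nM


@dataclass(frozen=True)
class PrimerConstraints:
    """Design window and penalty weights.

    Defaults follow common microsatellite-genotyping practice: primers of
    18-27 nt (optimum 20), Tm 57-63 degC (optimum 60), GC 30-70%, amplicons
    of 100-300 bp, and at least 50 bp of flank on each side of the repeat.
    """

    length_min: int = 18
    length_max: int = 27
    length_opt: int = 20
    tm_min: float = 57.0
    tm_max: float = 63.0
    tm_opt: float = 60.0
    gc_min: float = 30.0
    gc_max: float = 70.0
    product_min: int = 100
    product_max: int = 300
    min_flank: int = 50
    weight_length: float = 1.0
    weight_tm: float = 1.0
    weight_tm_diff: float = 1.0
    max_self_complement: int = 7   # longest allowed self-revcomp match, bp
    tm_method: str = "nn"

    def __post_init__(self) -> None:
        if self.length_min > self.length_max:
            raise ValueError("empty primer length range")
        if self.product_min > self.product_max:
            raise ValueError("empty product size range")
        if self.min_flank < self.length_min:
            raise ValueError("min_flank must be >= minimum primer length")


@dataclass(frozen=True)
class PrimerPair:
    """A scored forward/reverse oligo pair flanking an SSR locus."""

    locus: SSRLocus
    forward: str
    reverse: str
    tm_forward: float
    tm_reverse: float
    product_size: int
    penalty: float
    m13_tailed: bool = False
    forward_start: int = 0  # 1-based position of the forward primer 5' end


def gc_fraction(oligo: str) -> float:
    return 100.0 * sum(c in "GC" for c in oligo) / len(oligo)


def melting_temperature(oligo: str, method: str = "nn",
                        na_mm: float = DEFAULT_NA_MM,
                        oligo_nm: float = DEFAULT_OLIGO_NM) -> float:
    """Melting temperature in degC.

    ``wallace``: 2(A+T) + 4(G+C).
    ``nn`` (default): Tm = 1000*dH / (dS' + R ln(Ct/4)) - 273.15 where dH/dS
    sum the SantaLucia (1998) unified dinucleotide parameters plus terminal
    initiation terms, and dS' applies the salt correction
    dS + 0.368 (N-1) ln[Na+].
    """
    if len(oligo) < 8:
        raise ValueError("oligo must be >= 8 nt")
    if any(c not in "ACGT" for c in oligo):
        raise ValueError(f"ambiguity bases not allowed in oligo {oligo!r}")
    if method == "wallace":
        at = sum(c in "AT" for c in oligo)
        return float(2 * at + 4 * (len(oligo) - at))
    if method != "nn":
        raise ValueError(f"unknown Tm method {method!r}")
    dh = ds = 0.0
    for a, b in ((oligo[0], None), (oligo[-1], None)):
        h, s = NN_INIT_GC if a in "GC" else NN_INIT_AT
        dh += h
        ds += s
    for i in range(len(oligo) - 1):
        h, s = NN_PARAMS[oligo[i : i + 2]]
        dh += h
        ds += s
    ds_corr = ds + 0.368 * (len(oligo) - 1) * math.log(na_mm / 1000.0)
    ct = oligo_nm * 1e-9
    tm_k = (dh * 1000.0) / (ds_corr + _R * math.log(ct / 4.0))
    return tm_k - 273.15


def longest_self_complement(oligo: str) -> int:
    """Length of the longest substring whose reverse complement also occurs
    in the oligo (a cheap hairpin/self-dimer screen)."""
    n = len(oligo)
    best = 0
    for k in range(n, 0, -1):
        subs = {oligo[i : i + k] for i in range(n - k + 1)}
        if any(reverse_complement(s) in subs for s in subs):
            best = k
            break
    return best


def check_flanks(record: SequenceRecord, locus: SSRLocus,
                 constraints: PrimerConstraints) -> tuple[bool, str]:
    """True iff >= min_flank bases exist on both sides of the locus."""
    if not (1 <= locus.start <= locus.end <= len(record)):
        raise ValueError(f"locus {locus.start}-{locus.end} outside record "
                         f"{record.id} (length {len(record)})")
    if locus.start - 1 < constraints.min_flank:
        return False, "flank_too_short_5p"
    if len(record) - locus.end < constraints.min_flank:
        return False, "flank_too_short_3p"
    return True, "ok"


def _candidates(seq: str, lo: int, hi: int,
                constraints: PrimerConstraints,
                orientation: str) -> list[tuple[int, str, float]]:
    """Enumerate constraint-satisfying oligos in seq[lo:hi).

    Returns (start0, oligo, tm); for the reverse orientation the oligo is the
    reverse complement of the genomic window while start0 stays genomic.
    """
    out = []
    for length in range(constraints.length_min, constraints.length_max + 1):
        for s0 in range(lo, hi - length + 1):
            window = seq[s0 : s0 + length]
            if any(c not in "ACGT" for c in window):
                continue
            oligo = window if orientation == "fwd" else reverse_complement(window)
            gc = gc_fraction(oligo)
            if not (constraints.gc_min <= gc <= constraints.gc_max):
                continue
            tm = melting_temperature(oligo, constraints.tm_method)
            if not (constraints.tm_min <= tm <= constraints.tm_max):
                continue
            if longest_self_complement(oligo) > constraints.max_self_complement:
                continue
            out.append((s0, oligo, tm))
    return out


def pair_penalty(f_oligo: str, f_tm: float, r_oligo: str, r_tm: float,
                 constraints: PrimerConstraints) -> float:
    """Weighted deviation of both primers from the optima plus the pair
    Tm-difference term. Lower is better; 0 is a perfect pair."""
    c = constraints
    return (c.weight_length * (abs(len(f_oligo) - c.length_opt)
                               + abs(len(r_oligo) - c.length_opt))
            + c.weight_tm * (abs(f_tm - c.tm_opt) + abs(r_tm - c.tm_opt))
            + c.weight_tm_diff * abs(f_tm - r_tm))


def design_primers(record: SequenceRecord, locus: SSRLocus,
                   constraints: PrimerConstraints | None = None,
                   n_best: int = 3) -> list[PrimerPair]:
    """Up to ``n_best`` lowest-penalty primer pairs for one locus.

    All forward windows in the 5' flank and reverse windows in the 3' flank
    that satisfy the per-primer constraints are paired; pairs whose product
    (forward 5' end to reverse 5' end, spanning the SSR) falls inside the
    product-size window are ranked by penalty with deterministic tie-breaks
    (smaller product size, then leftmost forward start). Returns an empty
    list when no pair is feasible.
    """
    constraints = constraints or PrimerConstraints()
    ok, _reason = check_flanks(record, locus, constraints)
    if not ok:
        return []
    seq = record.residues
    ssr_lo, ssr_hi = locus.start - 1, locus.end  # 0-based half-open
    # limit the search window: the product cannot exceed product_max
    span = ssr_hi - ssr_lo
    reach = constraints.product_max - span
    if reach < 2 * constraints.length_min:
        return []
    f_lo = max(0, ssr_lo - reach)
    r_hi = min(len(seq), ssr_hi + reach)
    fwd = _candidates(seq, f_lo, ssr_lo, constraints, "fwd")
    rev = _candidates(seq, ssr_hi, r_hi, constraints, "rev")
    scored: list[tuple[float, int, int, PrimerPair]] = []
    for fs, fo, ftm in fwd:
        for rs, ro, rtm in rev:
            product = (rs + len(ro)) - fs
            if not (constraints.product_min <= product <= constraints.product_max):
                continue
            pen = pair_penalty(fo, ftm, ro, rtm, constraints)
            pair = PrimerPair(locus=locus, forward=fo, reverse=ro,
                              tm_forward=ftm, tm_reverse=rtm,
                              product_size=product, penalty=pen,
                              forward_start=fs + 1)
            scored.append((pen, product, fs, pair))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    return [pair for _, _, _, pair in scored[:n_best]]


def add_m13_tail(pair: PrimerPair, tail: str = M13_TAIL) -> PrimerPair:
    """Prefix the forward primer with the M13(-21) tail."""
    if pair.m13_tailed:
        raise ValueError("primer pair is already M13-tailed")
    return replace(pair, forward=tail + pair.forward,
                   product_size=pair.product_size + len(tail),
                   m13_tailed=True)


PRIMER_TSV_COLUMNS = ("locus", "rank", "forward", "reverse", "tm_f", "tm_r",
                      "product_size", "penalty", "tailed_forward")


def primers_to_tsv(pairs_by_locus: dict[str, Sequence[PrimerPair]]) -> str:
    lines = ["\t".join(PRIMER_TSV_COLUMNS)]
    for locus_id, pairs in pairs_by_locus.items():
        for rank, p in enumerate(pairs, start=1):
            tailed = p.forward if p.m13_tailed else M13_TAIL + p.forward
            lines.append("\t".join(map(str, (
                locus_id, rank, p.forward, p.reverse,
                f"{p.tm_forward:.2f}", f"{p.tm_reverse:.2f}",
                p.product_size, f"{p.penalty:.4f}", tailed))))
    return "\n".join(lines) + "\n"
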