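"""Pairwise alignment utilities shared by preprocessing and genome mapping.

Identity here follows the convention of greedy incremental clustering tools:
the number of matched bases in the best local alignment divided by the length
of the shorter sequence. Ambiguity bases (N and the other IUPAC codes) never
count as matches. Scoring is match +1, mismatch -1, gap -2 (linear), for both
the local mode used in screening/clustering and the global mode used to
refine coordinate projections.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

_ALPHABET = "ACGTN"
_AMBIG = set("NRYSWKMBDHV")


def _collapse(seq: str) -> str:
    """Map every ambiguity code to N so it can never score as a match."""
    return "".join(c if c in "ACGT" else "N" for c in seq)


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            mat[a, b] = 1.0 if (a == b and a != "N") else -1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


def _count_matches(alignment, a: str, b: str) -> tuple[int, int, int]:
    """Return (matches, query_aln_start, query_aln_end) for an alignment of a vs b."""
    matches = 0
    blocks_a, blocks_b = alignment.aligned
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        for i in range(ae - as_):
            ca, cb = a[as_ + i], b[bs + i]
            if ca == cb and ca not in _AMBIG:
                matches += 1
    if len(blocks_a):
        span = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    else:
        span = (0, 0)
    return matches, span[0], span[1]


def local_alignment_stats(a: str, b: str) -> tuple[int, int, int]:
    """Best local alignment of ``a`` against ``b``.

    Returns ``(matches, a_start, a_end)`` where the span is the aligned
    interval on ``a`` (0-based half-open).
    """
    a2, b2 = _collapse(a), _collapse(b)
    aln = _aligner("local").align(a2, b2)
    if len(aln) == 0:
        return 0, 0, 0
    return _count_matches(aln[0], a, b)


def local_identity(a: str, b: str) -> float:
    """Matches in the best local alignment / length of the shorter sequence."""
    matches, _, _ = local_alignment_stats(a, b)
    return matches / min(len(a), len(b))


def shares_kmer(a: str, b_kmers: frozenset[str] | set[str], k: int) -> bool:
    """True iff ``a`` shares at least one exact k-mer with the prebuilt set."""
    return any(a[i : i + k] in b_kmers for i in range(len(a) - k + 1))


def kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def global_position_map(query: str, subject: str) -> list[int | None]:
    """Global alignment of ``query`` to ``subject``; per-base coordinate map.

    Returns, for every position of ``query`` (0-based), the aligned position
    on ``subject`` or None where the query base sits in a gap. Used by the
    optional projection-refinement step in genome mapping.
    """
    aln = _aligner("global").align(_collapse(query), _collapse(subject))[0]
    pos: list[int | None] = [None] * len(query)
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        for i in range(qe - qs):
            pos[qs + i] = ss + i
    return pos
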