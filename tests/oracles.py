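"""Independent reference implementations used only by the tests.

Each oracle is deliberately written with a different formulation from the
package code it checks (direct enumeration, combinatorial closed forms,
per-base labelling, textbook DP), so agreement is meaningful.
"""

from __future__ import annotations

from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# SSR detection: direct per-position enumeration

def primitive(motif: str) -> bool:
    """A word is primitive iff it is not a rotation of itself at a smaller
    shift (classic doubling trick)."""
    return (motif + motif).find(motif, 1) == len(motif)


def brute_force_ssrs(seq: str, preset) -> set[tuple[int, int, str, int]]:
    """Every maximal perfect tandem run meeting the preset, found by testing
    each (start, period) pair directly. Returns {(start1, end1, motif,
    count)} with 1-based inclusive coordinates."""
    n = len(seq)
    found: dict[tuple[int, int], tuple[int, str, int]] = {}
    for p, min_rep in preset.min_repeats.items():
        for i in range(n - p + 1):
            motif = seq[i : i + p]
            if any(ch not in "ACGT" for ch in motif):
                continue
            # character-level left maximality: the periodicity must not
            # extend one base to the left
            if i > 0 and i - 1 + p < n and seq[i - 1] in "ACGT" \
                    and seq[i - 1] == seq[i - 1 + p]:
                continue
            count = 1
            while seq[i + count * p : i + (count + 1) * p] == motif:
                count += 1
            if count < min_rep:
                continue
            length = count * p
            if preset.min_total_length is not None \
                    and length <= preset.min_total_length:
                continue
            if not primitive(motif):
                continue
            key = (i + 1, i + length)
            if key not in found or p < found[key][0]:
                found[key] = (p, motif, count)
    return {(s, e, motif, count)
            for (s, e), (p, motif, count) in found.items()}


# ---------------------------------------------------------------------------
# Fisher's exact test: hypergeometric enumeration

def fisher_enum(a: int, b: int, c: int, d: int,
                sided: str = "greater") -> float:
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    denom = comb(n, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    lo, hi = max(0, c1 - r2), min(r1, c1)
    if sided == "greater":
        return sum(prob(x) for x in range(a, hi + 1))
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg: direct step-up formula

def bh_direct(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(1.0, running)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# local alignment: exhaustive Smith-Waterman DP, match-count semantics

def sw_identity(a: str, b: str) -> float:
    """Best-local-alignment matches / shorter length, scoring +1/-1/-2."""
    na, nb = len(a), len(b)
    score = np.zeros((na + 1, nb + 1))
    matches = np.zeros((na + 1, nb + 1), dtype=int)
    best = (0.0, 0)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            is_match = a[i - 1] == b[j - 1] and a[i - 1] in "ACGT"
            diag = score[i - 1, j - 1] + (1.0 if is_match else -1.0)
            up = score[i - 1, j] - 2.0
            left = score[i, j - 1] - 2.0
            s = max(0.0, diag, up, left)
            score[i, j] = s
            if s == 0.0:
                matches[i, j] = 0
            elif s == diag:
                matches[i, j] = matches[i - 1, j - 1] + int(is_match)
            elif s == up:
                matches[i, j] = matches[i - 1, j]
            else:
                matches[i, j] = matches[i, j - 1]
            if s > best[0] or (s == best[0] and matches[i, j] > best[1]):
                best = (s, matches[i, j])
    return best[1] / min(na, nb)


# ---------------------------------------------------------------------------
# region classification: per-base labelling

def classify_by_base(span: tuple[int, int], gene_models) -> str:
    votes = {"CDS": 0, "UTR5": 0, "UTR3": 0}
    per_gene: dict[str, dict[str, int]] = {}
    for g in gene_models:
        gv = {"CDS": 0, "UTR5": 0, "UTR3": 0}
        for cls in gv:
            for lo, hi in g.intervals(cls):
                for pos in range(span[0], span[1] + 1):
                    if lo <= pos <= hi:
                        gv[cls] += 1
        per_gene[g.gene_id] = gv
    totals = {gid: sum(v.values()) for gid, v in per_gene.items()}
    if not totals or max(totals.values()) == 0:
        return "intergenic"
    best_gene = min(totals, key=lambda g: (-totals[g], g))
    gv = per_gene[best_gene]
    prio = {"CDS": 0, "UTR5": 1, "UTR3": 2}
    return min(gv, key=lambda c: (-gv[c], prio[c]))


# ---------------------------------------------------------------------------
# four-taxon least-squares topology fit

def four_taxon_ls(dist: dict[tuple[str, str], float],
                  taxa: list[str]) -> tuple[frozenset, float]:
    """Fit all three resolved quartet topologies by unweighted least squares;
    return (winning sister pair as a frozenset, residual)."""
    a, b, c, d = taxa

    def resid(pair):
        # topology: pair vs rest; parameters: 4 pendant + 1 internal
        (x, y), (u, v) = pair, tuple(t for t in taxa if t not in pair)
        rows, rhs = [], []
        names = [x, y, u, v]
        idx = {t: i for i, t in enumerate(names)}
        for i in range(4):
            for j in range(i + 1, 4):
                ti, tj = names[i], names[j]
                row = [0.0] * 5
                row[idx[ti]] = 1.0
                row[idx[tj]] = 1.0
                same_side = {ti, tj} in ({x, y}, {u, v})
                if not same_side:
                    row[4] = 1.0
                rows.append(row)
                rhs.append(dist[tuple(sorted((ti, tj)))])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs),
                                       rcond=None)
        fitted = np.array(rows) @ sol
        return float(np.sum((fitted - np.array(rhs)) ** 2))

    pairs = [frozenset((a, b)), frozenset((a, c)), frozenset((a, d))]
    scored = [(resid(tuple(p)), p) for p in pairs]
    scored.sort(key=lambda t: t[0])
    return scored[0][1], scored[0][0]
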