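"""GO-term overrepresentation among SSR-containing sequences.

Each term present in the background annotation map is tested with Fisher's
exact test on the 2x2 table (term&subset, term&background-only, subset-only,
neither); one-sided (overrepresentation) by default, with the two-sided
variant selectable. P-values are adjusted with the Benjamini-Hochberg
step-up procedure and results with q below the FDR level are flagged.
No GO-graph ancestor propagation is performed — the input map is taken as
given.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationMap:
    """sequence id -> set of GO term ids, with optional term metadata."""

    annotations: dict[str, set[str]]
    term_names: dict[str, str] | None = None

    def terms(self) -> set[str]:
        out: set[str] = set()
        for t in self.annotations.values():
            out |= t
        return out


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    a: int  # term & subset
    b: int  # term & background-only
    c: int  # subset without term
    d: int  # neither
    fold: float
    p: float
    q: float
    significant: bool


def read_annotations(path: str | Path) -> AnnotationMap:
    """Read a two-column TSV of (seq_id, GO:ID) pairs, one pair per line."""
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            seq_id, term = parts
            annotations.setdefault(seq_id, set()).add(term)
    return AnnotationMap(annotations)


def write_annotations(annmap: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id in sorted(annmap.annotations):
            for term in sorted(annmap.annotations[seq_id]):
                fh.write(f"{seq_id}\t{term}\n")


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     sided: str = "greater") -> float:
    """Fisher's exact test p-value for the table [[a, b], [c, d]].

    ``greater`` (default) sums hypergeometric probabilities of tables at
    least as extreme in ``a``; ``two-sided`` sums all same-margin tables
    with probability <= that observed. Computation is in log space
    (scipy's hypergeometric machinery), safe for margins up to ~1e6.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table counts must be non-negative integers")
    alternative = {"greater": "greater", "two-sided": "two-sided"}.get(sided)
    if alternative is None:
        raise ValueError(f"sided must be 'greater' or 'two-sided', got {sided!r}")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(min(1.0, p))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values, input order preserved:
    q_(i) = min_{j >= i} m * p_(j) / j (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich(subset_ids: Iterable[str], background: AnnotationMap,
           fdr_alpha: float = 0.05,
           sided: str = "greater") -> list[EnrichmentResult]:
    """Test every background term for overrepresentation in the subset.

    ``fold`` is (a / subset size) / (term total / background size). Results
    are sorted by q then descending fold; those with q < fdr_alpha are
    flagged significant.
    """
    subset = set(subset_ids)
    if not subset:
        raise ValueError("subset is empty")
    universe = set(background.annotations)
    missing = subset - universe
    if missing:
        raise ValueError(f"subset ids absent from background: "
                         f"{sorted(missing)[:5]}")
    n_bg = len(universe)
    n_sub = len(subset)
    terms = sorted(background.terms())
    rows = []
    for term in terms:
        with_term = {s for s, ts in background.annotations.items() if term in ts}
        a = len(with_term & subset)
        b = len(with_term) - a
        c = n_sub - a
        d = n_bg - a - b - c
        fold = ((a / n_sub) / (len(with_term) / n_bg)) if with_term else float("nan")
        p = fisher_exact_2x2(a, b, c, d, sided=sided)
        rows.append((term, a, b, c, d, fold, p))
    qvals = bh_fdr([r[6] for r in rows])
    results = [
        EnrichmentResult(term=t, a=a, b=b, c=c, d=d, fold=fold, p=p,
                         q=float(q), significant=bool(q < fdr_alpha))
        for (t, a, b, c, d, fold, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q, -r.fold, r.term))
    return results


ENRICH_TSV_COLUMNS = ("term", "a", "b", "c", "d", "fold", "p", "q",
                      "significant")


def enrichment_to_tsv(results: Sequence[EnrichmentResult],
                      path: str | Path | None = None) -> str:
    df = pd.DataFrame([{
        "term": r.term, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
        "fold": round(r.fold, 4), "p": r.p, "q": r.q,
        "significant": r.significant,
    } for r in results], columns=list(ENRICH_TSV_COLUMNS))
    text = df.to_csv(sep="\t", index=False)
    if path is not None:
        Path(path).write_text(text)
    return text
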