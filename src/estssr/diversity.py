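"""Per-locus marker diversity: allele frequencies, expected heterozygosity,
polymorphism information content, polymorphism calls and the
polymorphism-vs-repeat-count logistic regression.

Alleles are opaque integer labels (typically fragment sizes). Missing calls
are excluded locus-by-locus (pairwise deletion). Two PIC conventions are
offered: ``printed`` — PIC = 1 - sum(Pi^2), identical to expected
heterozygosity — and ``botstein`` — the original Botstein et al. form
1 - sum(Pi^2) - sum_{i<j} 2 Pi^2 Pj^2, which is what dedicated PIC
calculators implement. The He/uHe pair follows the GenAlEx convention,
uHe = 2n/(2n-1) * He.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = "NA"

#: an unordered diploid call, or None for missing
Call = tuple[int, int] | None


@dataclass
class GenotypeTable:
    """Individuals x loci diploid calls."""

    individuals: list[str]
    loci: list[str]
    calls: dict[tuple[str, str], Call]  # (individual, locus) -> call

    def calls_at(self, locus: str) -> list[tuple[int, int]]:
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")
        out = []
        for ind in self.individuals:
            c = self.calls.get((ind, locus))
            if c is not None:
                out.append(c)
        return out


@dataclass(frozen=True)
class LocusDiversity:
    locus: str
    n_typed: int
    n_alleles: int
    allele_freqs: Mapping[int, float]
    he: float
    uhe: float | None
    pic_printed: float
    pic_botstein: float
    polymorphic: bool


@dataclass(frozen=True)
class PolymorphismRegressionResult:
    """IRLS logistic fit of polymorphism (0/1) on repeat count, plus the
    point-biserial Pearson correlation reported alongside."""

    slope: float | None
    intercept: float | None
    slope_se: float | None
    wald_z: float | None
    wald_p: float | None
    pearson_r: float
    pearson_p: float
    n: int
    converged: bool
    separation: bool


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read a genotype TSV: header of locus ids, one row per individual,
    cells ``a/b`` or ``NA``."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    individuals = [str(i) for i in df.index]
    loci = [str(c) for c in df.columns]
    calls: dict[tuple[str, str], Call] = {}
    for ind in individuals:
        for locus in loci:
            raw = df.loc[ind, locus]
            if pd.isna(raw) or str(raw).strip().upper() == MISSING:
                calls[(ind, locus)] = None
            else:
                a, b = str(raw).split("/")
                calls[(ind, locus)] = (int(a), int(b))
    return GenotypeTable(individuals, loci, calls)


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    rows = {}
    for ind in table.individuals:
        row = {}
        for locus in table.loci:
            c = table.calls.get((ind, locus))
            row[locus] = MISSING if c is None else f"{c[0]}/{c[1]}"
        rows[ind] = row
    pd.DataFrame.from_dict(rows, orient="index").to_csv(
        path, sep="\t", index_label="individual")


def allele_frequencies(table: GenotypeTable, locus: str) -> dict[int, float]:
    """Relative allele frequencies Pi at a locus; missing calls excluded."""
    calls = table.calls_at(locus)
    if not calls:
        raise ValueError(f"locus {locus!r} has no non-missing calls")
    counts: dict[int, int] = {}
    for a, b in calls:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = 2 * len(calls)
    return {al: c / total for al, c in sorted(counts.items())}


def _check_normalized(freqs: Mapping[int, float]) -> None:
    s = sum(freqs.values())
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies sum to {s}, not 1")


def pic(freqs: Mapping[int, float], formula: str = "printed") -> float:
    """Polymorphism information content.

    ``printed``: 1 - sum(Pi^2).
    ``botstein``: 1 - sum(Pi^2) - sum_{i<j} 2 Pi^2 Pj^2.
    """
    _check_normalized(freqs)
    p = list(freqs.values())
    homo = sum(x * x for x in p)
    if formula == "printed":
        return 1.0 - homo
    if formula == "botstein":
        cross = sum(2.0 * p[i] ** 2 * p[j] ** 2
                    for i in range(len(p)) for j in range(i + 1, len(p)))
        return 1.0 - homo - cross
    raise ValueError(f"unknown PIC formula {formula!r}")


def expected_heterozygosity(freqs: Mapping[int, float],
                            variant: str = "He",
                            n_typed: int | None = None) -> float:
    """He = 1 - sum(Pi^2); uHe = 2n/(2n-1) * He (n = typed individuals)."""
    _check_normalized(freqs)
    he = 1.0 - sum(x * x for x in freqs.values())
    if variant == "He":
        return he
    if variant == "uHe":
        if n_typed is None or n_typed < 2:
            raise ValueError("uHe needs n_typed >= 2")
        return (2 * n_typed) / (2 * n_typed - 1) * he
    raise ValueError(f"unknown variant {variant!r}")


def locus_diversity(table: GenotypeTable, locus: str) -> LocusDiversity:
    calls = table.calls_at(locus)
    freqs = allele_frequencies(table, locus)
    n = len(calls)
    he = expected_heterozygosity(freqs, "He")
    uhe = expected_heterozygosity(freqs, "uHe", n) if n >= 2 else None
    return LocusDiversity(
        locus=locus, n_typed=n, n_alleles=len(freqs), allele_freqs=freqs,
        he=he, uhe=uhe, pic_printed=pic(freqs, "printed"),
        pic_botstein=pic(freqs, "botstein"),
        polymorphic=len(freqs) >= 2)


def diversity_table(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus diversity statistics as a DataFrame (loci with no calls
    are skipped)."""
    rows = []
    for locus in table.loci:
        if not table.calls_at(locus):
            continue
        d = locus_diversity(table, locus)
        rows.append({
            "locus": d.locus, "n": d.n_typed, "NA": d.n_alleles,
            "He": d.he, "uHe": d.uhe,
            "PIC_printed": d.pic_printed, "PIC_botstein": d.pic_botstein,
            "polymorphic": d.polymorphic,
        })
    return pd.DataFrame(rows)


def call_polymorphic(table: GenotypeTable) -> tuple[dict[str, bool], float]:
    """Per-locus polymorphism (>= 2 alleles among typed individuals) and the
    overall rate as a one-decimal percentage."""
    flags: dict[str, bool] = {}
    for locus in table.loci:
        calls = table.calls_at(locus)
        if not calls:
            continue
        alleles = {a for c in calls for a in c}
        flags[locus] = len(alleles) >= 2
    rate = polymorphic_rate(sum(flags.values()), len(flags)) if flags else 0.0
    return flags, rate


def polymorphic_rate(n_polymorphic: int, n_analyzed: int) -> float:
    """Share of polymorphic loci, as a percentage rounded to one decimal."""
    if n_analyzed <= 0:
        raise ValueError("n_analyzed must be positive")
    return round(100.0 * n_polymorphic / n_analyzed, 1)


def _irls_logistic(x: np.ndarray, y: np.ndarray,
                   max_iter: int = 25, tol: float = 1e-8
                   ) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """Maximum-likelihood logistic fit by iteratively reweighted least
    squares. Returns (beta, standard errors, converged, separation)."""
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    beta = np.zeros(2)
    converged = False
    separation = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1.0 - mu)
        if np.max(w) < 1e-12 or np.max(np.abs(beta)) > 30:
            separation = True
            break
        WX = X * w[:, None]
        try:
            delta = np.linalg.solve(X.T @ WX, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            separation = True
            break
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = mu * (1.0 - mu)
    try:
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
    if not converged and np.max(np.abs(beta)) > 30:
        separation = True
    return beta, se, converged, separation


def polymorphism_regression(
    repeat_counts: Sequence[int | float],
    polymorphic: Sequence[bool | int],
) -> PolymorphismRegressionResult:
    """Logistic regression of the 0/1 polymorphism outcome on repeat count.

    Fits by IRLS (Newton scoring, at most 25 iterations, tolerance 1e-8)
    with Wald tests on the slope, and reports the point-biserial Pearson
    correlation between repeat count and the outcome alongside. Complete
    separation is flagged and no finite slope is reported in that case.
    """
    x = np.asarray(repeat_counts, dtype=float)
    y = np.asarray(polymorphic, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("repeat_counts and polymorphic must be equal-length 1-D")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.ptp(x) == 0:
        # constant predictor: slope is undefined at 0; report a null fit
        r, rp = 0.0, 1.0
    else:
        r, rp = stats.pearsonr(x, y)
    beta, se, converged, separation = _irls_logistic(x, y)
    if separation:
        return PolymorphismRegressionResult(
            slope=None, intercept=None, slope_se=None, wald_z=None,
            wald_p=None, pearson_r=float(r), pearson_p=float(rp),
            n=n, converged=False, separation=True)
    z = beta[1] / se[1] if se[1] > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return PolymorphismRegressionResult(
        slope=float(beta[1]), intercept=float(beta[0]),
        slope_se=float(se[1]), wald_z=float(z), wald_p=float(p),
        pearson_r=float(r), pearson_p=float(rp),
        n=n, converged=converged, separation=False)
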