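"""Cross-species transferability: binary amplification matrices, p-distances,
neighbor-joining trees and bootstrap bipartition support.

A transfer matrix scores, for every (species, locus) pair, whether a primer
pair developed in the focal species amplified in that species (1), failed
(0), or was not assayed (missing). Pairwise distances are the mismatch
proportion over loci scored in both species (pairwise deletion). Trees are
built with the Saitou-Nei neighbor-joining agglomeration and annotated with
bootstrap support obtained by resampling loci (columns) with replacement.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode


@dataclass
class TransferMatrix:
    """Species x loci matrix of 1/0/NaN amplification scores."""

    data: pd.DataFrame  # index: species, columns: loci, values 0/1/NaN

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValueError("transfer matrix cells must be 1, 0 or missing")
        if any(np.isnan(vals[i]).all() for i in range(vals.shape[0])):
            raise ValueError("a species row is entirely missing")

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def loci(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def transfer_rates(self) -> dict[str, float]:
        """Per-species share of scored loci that amplified, as percentages."""
        out = {}
        for sp in self.species:
            row = self.data.loc[sp].to_numpy(dtype=float)
            scored = ~np.isnan(row)
            out[sp] = round(100.0 * np.nansum(row) / scored.sum(), 1)
        return out


def read_transfer_matrix(path: str | Path) -> TransferMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return TransferMatrix(df.astype(float))


def write_transfer_matrix(matrix: TransferMatrix, path: str | Path) -> None:
    out = matrix.data.map(
        lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index_label="species")


def binary_distance(matrix: TransferMatrix) -> DistanceMatrix:
    """Mismatch proportion between species rows, with pairwise deletion of
    missing cells. A pair with no jointly scored locus raises."""
    vals = matrix.data.to_numpy(dtype=float)
    n = vals.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(vals[i]) & ~np.isnan(vals[j])
            if not both.any():
                raise ValueError(
                    f"species pair ({matrix.species[i]}, {matrix.species[j]})"
                    " shares no scored locus")
            d[i, j] = d[j, i] = np.mean(vals[i][both] != vals[j][both])
    return DistanceMatrix(d, ids=matrix.species)


class _Node:
    __slots__ = ("children", "name", "length")

    def __init__(self, name=None, children=(), length=0.0):
        self.name = name
        self.children = list(children)
        self.length = length


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree as a
    trifurcating-root scikit-bio ``TreeNode``.

    Ties on the Q criterion are broken by the lexicographically smallest
    (label_i, label_j) pair, where a cluster is labelled by its smallest
    leaf name — the agglomeration is therefore fully deterministic.
    Negative branch lengths are clamped to zero with the deficit
    transferred to the sibling branch.
    """
    ids = list(dist.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = {(a, b): dist[a, b] for a in ids for b in ids}
    nodes: dict[str, _Node] = {t: _Node(name=t) for t in ids}
    labels: dict[str, str] = {t: t for t in ids}  # cluster -> smallest leaf
    active = list(ids)

    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[a, b] for b in active if b != a) for a in active}
        best = None
        for ia in range(m):
            for ib in range(ia + 1, m):
                a, b = active[ia], active[ib]
                q = (m - 2) * d[a, b] - r[a] - r[b]
                key = tuple(sorted((labels[a], labels[b])))
                if best is None or (q, key) < (best[0], best[1]):
                    best = (q, key, a, b)
        _, _, a, b = best
        la = 0.5 * d[a, b] + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = d[a, b] - la
        # clamp-and-transfer for negative branch lengths
        if la < 0:
            lb += -la
            la = 0.0
        elif lb < 0:
            la += -lb
            lb = 0.0
        new = f"__nj{counter}"
        counter += 1
        child_a, child_b = nodes[a], nodes[b]
        child_a.length, child_b.length = la, lb
        nodes[new] = _Node(children=[child_a, child_b])
        labels[new] = min(labels[a], labels[b])
        for c in active:
            if c in (a, b):
                continue
            dn = 0.5 * (d[a, c] + d[b, c] - d[a, b])
            d[new, c] = d[c, new] = dn
        d[new, new] = 0.0
        active = [c for c in active if c not in (a, b)] + [new]

    # closed-form three-point solution for the final join
    a, b, c = sorted(active, key=lambda t: labels[t])
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lens = [max(0.0, v) for v in (la, lb, lc)]
    root = _Node(children=[nodes[a], nodes[b], nodes[c]])
    for child, ln in zip(root.children, lens):
        child.length = ln

    return TreeNode.read(io.StringIO(_to_newick(root)))


def _to_newick(node: _Node) -> str:
    def rec(n: _Node) -> str:
        if not n.children:
            return f"{n.name}:{n.length:.10g}"
        inner = ",".join(rec(c) for c in n.children)
        label = n.name if n.name else ""
        return f"({inner}){label}:{n.length:.10g}"
    inner = ",".join(rec(c) for c in node.children)
    return f"({inner});"


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal-edge bipartitions as canonical leaf-name sets.

    Each internal edge splits the leaves in two; the side *not* containing
    the lexicographically smallest leaf represents the split, making the
    encoding invariant to rooting and leaf order.
    """
    leaves = sorted(n.name for n in tree.tips())
    ref = leaves[0]
    all_set = frozenset(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        side = all_set - below if ref in below else below
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def bootstrap_support(matrix: TransferMatrix, replicates: int = 1000,
                      seed: int | None = None,
                      max_failures: int = 0) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree of the full matrix with per-edge bootstrap support.

    Loci (columns) are resampled with replacement ``replicates`` times; each
    replicate matrix is rebuilt into distances and an NJ tree, and the
    support of every internal edge of the full-data tree is the percentage
    of replicate trees containing the same bipartition. Supports are
    attached to the returned tree as internal node names. Replicates in
    which some species pair shares no scored locus are re-drawn up to
    ``max_failures`` times in total before raising.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducible bootstraps")
    rng = np.random.default_rng(seed)
    full_tree = neighbor_joining(binary_distance(matrix))
    target = bipartitions(full_tree)
    counts = {split: 0 for split in target}
    n_loci = len(matrix.loci)
    failures = 0
    done = 0
    while done < replicates:
        cols = rng.integers(0, n_loci, size=n_loci)
        try:
            resampled = TransferMatrix(matrix.data.iloc[:, cols])
            rep_tree = neighbor_joining(binary_distance(resampled))
        except ValueError:
            failures += 1
            if failures > max_failures:
                raise ValueError(
                    f"bootstrap failures ({failures}) exceeded tolerance "
                    f"({max_failures}): too much missing data")
            continue
        rep_splits = bipartitions(rep_tree)
        for split in target:
            if split in rep_splits:
                counts[split] += 1
        done += 1
    support = {s: 100.0 * c / replicates for s, c in counts.items()}

    leaves = sorted(n.name for n in full_tree.tips())
    ref = leaves[0]
    all_set = frozenset(leaves)
    for node in full_tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        side = all_set - below if ref in below else below
        if side in support:
            node.name = str(int(round(support[side])))
    return full_tree, support


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize to Newick (branch lengths; bootstrap supports, when
    present, appear as internal node labels)."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_newick(source: str | Path) -> TreeNode:
    text = Path(source).read_text() if isinstance(source, Path) else source
    if isinstance(source, str) and "(" not in source:
        text = Path(source).read_text()
    return TreeNode.read(io.StringIO(text))


def distances_to_tsv(dist: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dist.data, index=list(dist.ids),
                 columns=list(dist.ids)).to_csv(path, sep="\t",
                                                index_label="species")
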