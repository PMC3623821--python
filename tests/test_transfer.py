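"""Binary distances, neighbor joining, bootstrap support, Newick round-trip."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from estssr.transfer import (TransferMatrix, binary_distance, bipartitions,
                             bootstrap_support, neighbor_joining,
                             read_newick, read_transfer_matrix, write_newick,
                             write_transfer_matrix)
from estssr import simulate as sim

from oracles import four_taxon_ls


def matrix_from(rows, loci=None):
    species = sorted(rows)
    loci = loci or [f"L{i}" for i in range(len(next(iter(rows.values()))))]
    df = pd.DataFrame([rows[s] for s in species], index=species,
                      columns=loci, dtype=float)
    return TransferMatrix(df)


def tip_distances(tree):
    tips = sorted(t.name for t in tree.tips())
    return {(a, b): tree.find(a).distance(tree.find(b))
            for a in tips for b in tips if a < b}


def random_additive_tree(rng, n_taxa):
    """Random topology with positive branch lengths and its leaf-to-leaf
    additive distance matrix."""
    names = [f"t{i:02d}" for i in range(n_taxa)]
    clusters = [frozenset([n]) for n in names]
    below = {frozenset([n]): {n: 0.0} for n in names}  # leaf depths
    d: dict[tuple[str, str], float] = {}
    internal: list[frozenset] = []
    while len(clusters) > 3:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        a, b = clusters[i], clusters[j]
        la = float(rng.uniform(0.1, 1.0))
        lb = float(rng.uniform(0.1, 1.0))
        # leaves joined for the first time meet at this new node
        for lx, dx in below[a].items():
            for ly, dy in below[b].items():
                d[tuple(sorted((lx, ly)))] = dx + la + dy + lb
        merged = a | b
        below[merged] = {
            **{k: v + la for k, v in below[a].items()},
            **{k: v + lb for k, v in below[b].items()},
        }
        internal.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    # final trifurcation
    lens = [float(rng.uniform(0.1, 1.0)) for _ in clusters]
    for x in range(3):
        for y in range(x + 1, 3):
            for lx, dx in below[clusters[x]].items():
                for ly, dy in below[clusters[y]].items():
                    d[tuple(sorted((lx, ly)))] = dx + lens[x] + dy + lens[y]
    mat = np.zeros((n_taxa, n_taxa))
    for (x, y), v in d.items():
        ix, iy = names.index(x), names.index(y)
        mat[ix, iy] = mat[iy, ix] = v
    splits = {c for c in internal + clusters
              if 2 <= len(c) <= n_taxa - 2}
    return DistanceMatrix(mat, ids=names), splits


def canonical_splits(raw, names):
    ref = min(names)
    full = frozenset(names)
    return {full - s if ref in s else s for s in raw}


class TestDistance:
    def test_identical_and_complementary_rows(self):
        m = matrix_from({"a": [1, 1, 0, 0], "b": [1, 1, 0, 0],
                         "c": [0, 0, 1, 1]})
        d = binary_distance(m)
        assert d["a", "b"] == 0.0
        assert d["a", "c"] == 1.0

    def test_pairwise_deletion(self):
        m = matrix_from({"a": [1, 1, 0, np.nan], "b": [1, 0, 0, 1],
                         "c": [1, 1, 1, 1]})
        d = binary_distance(m)
        assert d["a", "b"] == pytest.approx(1 / 3)

    def test_zero_overlap_raises(self):
        m = matrix_from({"a": [1, np.nan], "b": [np.nan, 1],
                         "c": [1, 1]})
        with pytest.raises(ValueError, match="a.*b"):
            binary_distance(m)

    def test_axioms_on_fixture(self):
        m, _ = sim.make_transfer_matrix(sim.TransferSpec(seed=5))
        d = binary_distance(m)
        arr = d.data
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert (arr >= 0).all()


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(np.array([[0, 0.4, 0.6],
                                     [0.4, 0, 0.8],
                                     [0.6, 0.8, 0]]), ids=["A", "B", "C"])
        tree = neighbor_joining(d)
        td = tip_distances(tree)
        assert td[("A", "B")] == pytest.approx(0.4)
        assert td[("A", "C")] == pytest.approx(0.6)
        assert td[("B", "C")] == pytest.approx(0.8)

    @pytest.mark.parametrize("n_taxa", [4, 6, 8])
    def test_additive_recovery(self, n_taxa, rng):
        for _ in range(10):
            dm, want = random_additive_tree(rng, n_taxa)
            tree = neighbor_joining(dm)
            got = bipartitions(tree)
            names = list(dm.ids)
            assert got == canonical_splits(want, names)
            td = tip_distances(tree)
            for (a, b), v in td.items():
                assert v == pytest.approx(dm[a, b], abs=1e-9)

    def test_four_taxon_least_squares_oracle_agrees(self, rng):
        dm, _ = random_additive_tree(rng, 4)
        tree = neighbor_joining(dm)
        (split,) = bipartitions(tree)
        dist = {(a, b): dm[a, b] for a in dm.ids for b in dm.ids if a < b}
        pair, resid = four_taxon_ls(dist, list(dm.ids))
        assert resid < 1e-18
        names = list(dm.ids)
        assert split in (canonical_splits({pair}, names))

    def test_matches_skbio(self, rng):
        m, _ = sim.make_transfer_matrix(sim.TransferSpec(seed=17,
                                                         n_species=7))
        d = binary_distance(m)
        assert bipartitions(neighbor_joining(d)) == \
            bipartitions(skbio_nj(d))

    def test_label_permutation_isomorphic(self, rng):
        dm, _ = random_additive_tree(rng, 6)
        perm = list(rng.permutation(list(dm.ids)))
        dm2 = dm.filter(perm)
        assert bipartitions(neighbor_joining(dm)) == \
            bipartitions(neighbor_joining(dm2))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(Exception):
            DistanceMatrix(np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]),
                           ids=list("abc"))


class TestBootstrap:
    def test_same_seed_identical(self):
        m, _ = sim.make_transfer_matrix(sim.TransferSpec(seed=9, noise=0.1))
        _, s1 = bootstrap_support(m, replicates=50, seed=4)
        _, s2 = bootstrap_support(m, replicates=50, seed=4)
        assert s1 == s2

    def test_perfect_signal_full_support(self):
        m, truth = sim.make_transfer_matrix(sim.TransferSpec(seed=2,
                                                             n_species=6))
        tree, support = bootstrap_support(m, replicates=100, seed=1)
        assert len(support) == 6 - 3
        assert all(v == 100.0 for v in support.values())
        assert {frozenset(b) for b in truth["bipartitions"]} == \
            set(support)

    def test_supports_bounded_and_edge_count(self):
        m, _ = sim.make_transfer_matrix(sim.TransferSpec(
            seed=13, n_species=8, noise=0.15))
        _, support = bootstrap_support(m, replicates=60, seed=3)
        assert len(support) == 8 - 3
        assert all(0.0 <= v <= 100.0 for v in support.values())

    def test_seed_required(self):
        m, _ = sim.make_transfer_matrix(sim.TransferSpec(seed=2))
        with pytest.raises(ValueError):
            bootstrap_support(m, replicates=10, seed=None)


class TestNewick:
    def test_round_trip(self):
        m, _ = sim.make_transfer_matrix(sim.TransferSpec(seed=6,
                                                         n_species=6))
        tree, support = bootstrap_support(m, replicates=20, seed=2)
        text = write_newick(tree)
        back = read_newick(text)
        assert bipartitions(back) == bipartitions(tree)
        # integer supports appear as internal labels
        assert any(tok.isdigit() for tok in
                   text.replace("(", " ").replace(")", " ")
                       .replace(":", " ").replace(",", " ").split())

    def test_file_round_trip(self, tmp_path):
        m, _ = sim.make_transfer_matrix(sim.TransferSpec(seed=6))
        tree = neighbor_joining(binary_distance(m))
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        assert bipartitions(read_newick(p)) == bipartitions(tree)


class TestMatrixIO:
    def test_tsv_round_trip(self, tmp_path):
        m, _ = sim.make_transfer_matrix(sim.TransferSpec(
            seed=3, missing_rate=0.1))
        p = tmp_path / "m.tsv"
        write_transfer_matrix(m, p)
        back = read_transfer_matrix(p)
        pd.testing.assert_frame_equal(back.data, m.data,
                                      check_names=False)

    def test_bad_cells_rejected(self):
        df = pd.DataFrame([[1, 2]], index=["a"], columns=["L1", "L2"])
        with pytest.raises(ValueError):
            TransferMatrix(df.astype(float))
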