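"""Microsatellite detection, motif canonicalization and compound merging."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from estssr.records import SequenceRecord, reverse_complement
from estssr.ssr import (CriteriaPreset, canonical_classes, canonical_motif,
                        builtin_presets, find_perfect_ssrs, get_preset,
                        is_primitive, merge_compound, resolve_overlaps,
                        summarize)

from oracles import brute_force_ssrs, primitive

MISA = get_preset("misa_default")
CARDLE = get_preset("cardle")
LEN20 = get_preset("len20")


def random_sequence(rng, length, plant_prob=0.5):
    """Random DNA with occasional planted repeat blocks and N bases."""
    seq = list(rng.choice(list("ACGT"), length))
    if rng.random() < 0.05:
        for i in rng.choice(length, size=max(1, length // 200)):
            seq[i] = "N"
    if rng.random() < plant_prob:
        for _ in range(int(rng.integers(1, 4))):
            p = int(rng.integers(2, 7))
            motif = "".join(rng.choice(list("ACGT"), p))
            count = int(rng.integers(2, 15))
            block = motif * count
            if len(block) < length:
                start = int(rng.integers(0, length - len(block)))
                seq[start : start + len(block)] = list(block)
    return "".join(seq)


class TestMotifAlgebra:
    @pytest.mark.parametrize("motif,expected", [
        ("GA", "AG/CT"), ("AG", "AG/CT"), ("TC", "AG/CT"), ("CT", "AG/CT"),
        ("CTT", "AAG/CTT"), ("GAA", "AAG/CTT"),
        ("AC", "AC/GT"), ("TA", "AT/AT"),
    ])
    def test_canonical_examples(self, motif, expected):
        assert canonical_motif(motif) == expected

    def test_nonprimitive_rejected(self):
        with pytest.raises(ValueError):
            canonical_motif("ATAT")

    @pytest.mark.parametrize("period,n_classes", [
        (2, 4), (3, 10), (4, 33), (5, 102), (6, 350)])
    def test_class_counts(self, period, n_classes):
        assert len(canonical_classes(period)) == n_classes

    def test_primitive_examples_and_count(self):
        assert not is_primitive("ATAT")
        assert is_primitive("AAG")
        words4 = ["".join(w) for w in itertools.product("ACGT", repeat=4)]
        assert sum(map(is_primitive, words4)) == 240
        # agreement with the doubling-trick formulation
        for w in words4:
            assert is_primitive(w) == primitive(w)

    @given(st.text(alphabet="ACGT", min_size=2, max_size=6))
    def test_rotation_and_strand_invariance(self, motif):
        if not is_primitive(motif):
            return
        cls = canonical_motif(motif)
        for i in range(len(motif)):
            rot = motif[i:] + motif[:i]
            assert canonical_motif(rot) == cls
            assert canonical_motif(reverse_complement(rot)) == cls


class TestPresets:
    def test_builtin_thresholds(self):
        by_name = {p.name: p for p in builtin_presets()}
        assert by_name["misa_default"].min_repeats == {2: 10, 3: 6, 4: 5,
                                                       5: 4, 6: 3}
        assert by_name["cardle"].min_repeats == {2: 7, 3: 5, 4: 4, 5: 3}
        assert 6 not in by_name["cardle"].min_repeats
        assert by_name["len20"].min_total_length == 20

    def test_len20_strict_inequality(self):
        rec20 = SequenceRecord("a", "C" * 30 + "AG" * 10 + "C" * 30)
        rec22 = SequenceRecord("b", "C" * 30 + "AG" * 11 + "C" * 30)
        assert find_perfect_ssrs(rec20, LEN20) == []
        found = find_perfect_ssrs(rec22, LEN20)
        assert len(found) == 1 and found[0].repeat_count == 11


class TestDetection:
    def test_simple_di_locus(self):
        rec = SequenceRecord("t", "C" + "AG" * 10 + "C")
        (locus,) = find_perfect_ssrs(rec, MISA)
        assert (locus.motif, locus.canonical_class) == ("AG", "AG/CT")
        assert (locus.repeat_count, locus.start, locus.end) == (10, 2, 21)

    def test_threshold_presets_differ(self):
        rec = SequenceRecord("t", "AT" * 9)
        assert find_perfect_ssrs(rec, MISA) == []
        (locus,) = find_perfect_ssrs(rec, CARDLE)
        assert locus.repeat_count == 9

    def test_trailing_partial_copy_excluded(self):
        rec = SequenceRecord("t", "G" + "CAT" * 7 + "CA" + "GGG")
        (locus,) = find_perfect_ssrs(rec, MISA)
        assert locus.repeat_count == 7
        assert locus.end == 1 + 21  # partial CA not included

    def test_ambiguity_breaks_run(self):
        rec = SequenceRecord("t", "AG" * 6 + "NN" + "AG" * 6)
        assert find_perfect_ssrs(rec, MISA) == []
        assert len(find_perfect_ssrs(rec, CARDLE)) == 0  # 6 < 7 each side

    @pytest.mark.parametrize("preset", [MISA, CARDLE, LEN20],
                             ids=lambda p: p.name)
    def test_matches_enumeration_oracle(self, preset, rng):
        for _ in range(200):
            seq = random_sequence(rng, int(rng.integers(50, 800)))
            rec = SequenceRecord("r", seq)
            got = {(l.start, l.end, l.motif, l.repeat_count)
                   for l in find_perfect_ssrs(rec, preset)}
            assert got == brute_force_ssrs(seq, preset)

    def test_strand_symmetry(self, rng):
        for _ in range(50):
            seq = random_sequence(rng, 400, plant_prob=0.9)
            fwd = find_perfect_ssrs(SequenceRecord("f", seq), MISA)
            rev = find_perfect_ssrs(
                SequenceRecord("r", reverse_complement(seq)), MISA)
            assert sorted((l.canonical_class, l.repeat_count) for l in fwd) \
                == sorted((l.canonical_class, l.repeat_count) for l in rev)
            # intervals mirror up to the sub-period phase of partial copies
            n = len(seq)
            for lf, lr in zip(
                    sorted(fwd, key=lambda l: l.start),
                    sorted(rev, key=lambda l: -l.end)):
                mirrored_start = n - lr.end + 1
                assert abs(mirrored_start - lf.start) < lf.period

    def test_coordinate_round_trip(self, rng):
        for _ in range(50):
            seq = random_sequence(rng, 500, plant_prob=0.9)
            for locus in find_perfect_ssrs(SequenceRecord("r", seq), MISA):
                sub = seq[locus.start - 1 : locus.end]
                redetect = find_perfect_ssrs(
                    SequenceRecord("sub", sub),
                    CriteriaPreset("one", {locus.period: 2}))
                match = [l for l in redetect
                         if l.start == 1 and l.end == len(sub)]
                assert match and match[0].motif == locus.motif
                assert match[0].repeat_count == locus.repeat_count


class TestCompound:
    def _locus(self, seq_id, start, count=10, motif="AG"):
        from estssr.ssr import SSRLocus
        return SSRLocus(seq_id, motif, "AG/CT", count, start,
                        start + count * len(motif) - 1, "misa_default")

    def test_gap_within_limit_merges(self):
        a = self._locus("s", 1)
        b = self._locus("s", a.end + 51)  # gap of 50
        compounds, singles = merge_compound([a, b], MISA)
        assert len(compounds) == 1 and compounds[0].gaps == (50,)
        assert singles == []

    def test_gap_boundary(self):
        a = self._locus("s", 1)
        b_in = self._locus("s", a.end + 101)   # gap exactly 100
        compounds, singles = merge_compound([a, b_in], MISA)
        assert len(compounds) == 1
        c = self._locus("s", a.end + 102)      # gap 101
        compounds, singles = merge_compound([a, c], MISA)
        assert compounds == [] and len(singles) == 2

    def test_three_member_chain(self):
        a = self._locus("s", 1)
        b = self._locus("s", a.end + 11)
        c = self._locus("s", b.end + 11)
        compounds, singles = merge_compound([a, b, c], MISA)
        assert len(compounds) == 1 and len(compounds[0].members) == 3

    def test_overlap_raises(self):
        a = self._locus("s", 1)
        b = self._locus("s", 5)
        with pytest.raises(ValueError):
            merge_compound([a, b], MISA)

    def test_conservation(self, rng):
        loci = []
        pos = 1
        for i in range(30):
            loci.append(self._locus("s", pos))
            pos = loci[-1].end + 1 + int(rng.integers(1, 200))
        compounds, singles = merge_compound(loci, MISA)
        assert len(singles) + sum(len(c.members) for c in compounds) \
            == len(loci)

    def test_resolve_overlaps_keeps_longer(self):
        a = self._locus("s", 1, count=12)          # 24 bp
        b = self._locus("s", 20, count=10)         # overlaps a
        kept = resolve_overlaps([a, b])
        assert kept == [a]


class TestSummary:
    def _loci(self, n, distinct_seqs=None):
        from estssr.ssr import SSRLocus
        loci = []
        for i in range(n):
            sid = f"s{i if distinct_seqs is None else i % distinct_seqs}"
            loci.append(SSRLocus(sid, "AG", "AG/CT", 10, 1, 20,
                                 "misa_default"))
        return loci

    def test_density_examples(self):
        s = summarize(self._loci(4202), [], 62_650_653, 94_090)
        assert s["density_kb_per_ssr"] == 14.9
        s2 = summarize(self._loci(6573), [], 62_650_653, 94_090)
        assert s2["density_kb_per_ssr"] == 9.5

    def test_zero_loci_density_undefined(self):
        s = summarize([], [], 1000, 10)
        assert s["density_undefined"] and s["density_kb_per_ssr"] is None

    def test_single_vs_multi_counts(self):
        loci = self._loci(6, distinct_seqs=4)  # s0,s1 twice; s2,s3 once
        s = summarize(loci, [], 10_000, 10)
        assert s["n_ssr_containing"] == 4
        assert s["n_multi_ssr"] == 2 and s["n_single_ssr"] == 2
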