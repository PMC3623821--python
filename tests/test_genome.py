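"""BLAST-tabular parsing, best-hit selection, coordinate projection and
CDS/UTR classification."""

import pytest

from estssr.genome import (AlignmentHit, MappingConfig, GeneModel,
                           LocusPlacement, classify_region,
                           distribution_table, place_loci, project_locus,
                           read_gene_models, read_hits, select_best_hit)
from estssr.ssr import SSRLocus
from estssr import simulate as sim

from oracles import classify_by_base


def _hit(**kw):
    base = dict(query_id="q1", subject_id="chr1", identity=0.95, length=200,
                query_start=1, query_end=200, subject_start=1001,
                subject_end=1200, bitscore=300.0)
    base.update(kw)
    return AlignmentHit(**base)


def _locus(start, end, seq_id="q1"):
    period = 2
    count = (end - start + 1) // period
    return SSRLocus(seq_id, "AG", "AG/CT", count, start, end, "misa_default")


class TestReadHits:
    def test_parse_and_strand(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\tchr1\t80.1\t100\t5\t1\t1\t100\t500\t401\t1e-20\t150.5\n")
        (hit,) = read_hits(path)
        assert hit.identity == pytest.approx(0.801)
        assert hit.strand == "-"
        assert hit.bitscore == 150.5

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\tchr1\t80.1\t100\t5\t1\t1\t100\t500\t401\t1e-20\t150\n"
                        "q2\tchr1\t90\t100\t5\t1\t1\t100\t500\t401\t1e-20\n")
        with pytest.raises(ValueError, match="2"):
            read_hits(path)


class TestBestHit:
    def test_identity_cutoff_is_strict(self):
        assert select_best_hit([_hit(identity=0.799)]) is None
        assert select_best_hit([_hit(identity=0.80)]) is None
        assert select_best_hit([_hit(identity=0.801)]) is not None

    def test_bitscore_then_length_tiebreak(self):
        h1 = _hit(bitscore=100.0, length=400)
        h2 = _hit(bitscore=90.0, length=500)
        assert select_best_hit([h1, h2]) is h1
        h3 = _hit(bitscore=100.0, length=500)
        assert select_best_hit([h1, h3]) is h3


class TestProjection:
    def test_plus_strand_offset(self):
        hit = _hit()
        pl = project_locus(_locus(8, 27), hit)
        assert (pl.genomic_start, pl.genomic_end) == (1008, 1027)
        assert pl.strand == "+"

    def test_locus_outside_hit_unplaced(self):
        hit = _hit(query_end=100)
        pl = project_locus(_locus(95, 104), hit)
        assert pl.region_class == "unplaced"

    def test_minus_strand_matches_enumerated_map(self):
        # toy minus-strand hit: enumerate the full position correspondence
        hit = _hit(query_start=1, query_end=60, subject_start=560,
                   subject_end=501, length=60)
        mapping = {q: 560 - (q - 1) for q in range(1, 61)}
        locus = _locus(11, 20)
        pl = project_locus(locus, hit)
        expect = sorted((mapping[11], mapping[20]))
        assert [pl.genomic_start, pl.genomic_end] == expect
        assert pl.strand == "-"

    def test_round_trip_inverse(self):
        hit = _hit()
        locus = _locus(13, 32)
        pl = project_locus(locus, hit)
        # invert the affine map back to query coordinates
        q1 = pl.genomic_start - hit.subject_start + hit.query_start
        q2 = pl.genomic_end - hit.subject_start + hit.query_start
        assert (q1, q2) == (locus.start, locus.end)

    def test_strand_flip_mirrors(self):
        locus = _locus(8, 27)
        plus = project_locus(locus, _hit())
        minus = project_locus(locus, _hit(subject_start=1200,
                                          subject_end=1001))
        assert plus.strand == "+" and minus.strand == "-"
        # mirrored within the subject interval
        assert minus.genomic_end == 1200 - (plus.genomic_start - 1001)

    def test_mismatched_ids_raise(self):
        with pytest.raises(ValueError):
            project_locus(_locus(1, 20, seq_id="other"), _hit())

    def test_refine_identical_segments_matches_affine(self):
        hit = _hit(query_end=60, length=60, subject_end=1060)
        seg = "ACGTA" * 12
        locus = _locus(11, 20)
        affine = project_locus(locus, hit)
        refined = project_locus(locus, hit, MappingConfig(refine=True),
                                query_seq=seg, subject_seq=seg)
        assert (refined.genomic_start, refined.genomic_end) == \
            (affine.genomic_start, affine.genomic_end)


class TestClassification:
    GENES = [GeneModel("g1", "chr1", "+",
                       cds=((200, 800),), utr5=((100, 199),),
                       utr3=((801, 1000),))]

    def _placement(self, lo, hi):
        return LocusPlacement(_locus(1, 20), "chr1", lo, hi, "+",
                              "intergenic")

    def test_inside_cds(self):
        pl = classify_region(self._placement(300, 340), self.GENES)
        assert pl.region_class == "CDS"

    def test_no_features_intergenic(self):
        pl = classify_region(self._placement(5000, 5040), self.GENES)
        assert pl.region_class == "intergenic"

    def test_larger_overlap_wins(self):
        # 10 bp in CDS (200-209), 14 bp in UTR5 (186-199)
        pl = classify_region(self._placement(186, 209), self.GENES)
        assert pl.region_class == "UTR5"
        assert classify_by_base((186, 209), self.GENES) == "UTR5"

    def test_tie_prefers_cds(self):
        # 10 bp in UTR5 (190-199), 10 bp in CDS (200-209)
        pl = classify_region(self._placement(190, 209), self.GENES)
        assert pl.region_class == "CDS"

    def test_absent_chromosome_unplaced(self):
        pl = LocusPlacement(_locus(1, 20), "chrZ", 100, 119, "+",
                            "intergenic")
        assert classify_region(pl, self.GENES).region_class == "unplaced"

    def test_fuzz_against_per_base_oracle(self, rng):
        for _ in range(60):
            lo = int(rng.integers(50, 1100))
            hi = lo + int(rng.integers(5, 80))
            pl = classify_region(self._placement(lo, hi), self.GENES)
            assert pl.region_class == classify_by_base((lo, hi), self.GENES)


class TestEndToEnd:
    def test_planted_region_shares_recovered(self, tmp_path):
        loci, hits_text, gff_text, truth = sim.make_genome_fixture(
            sim.GenomeSpec(seed=21, n_loci=50))
        (tmp_path / "h.tsv").write_text(hits_text)
        (tmp_path / "g.gff3").write_text(gff_text)
        placements = place_loci(loci, read_hits(tmp_path / "h.tsv"),
                                read_gene_models(tmp_path / "g.gff3"))
        for pl in placements:
            assert pl.region_class == truth["region_class"][pl.locus.seq_id]
        table = distribution_table(placements)
        assert table["region_pct"] == {
            "CDS": 72.0, "UTR5": 18.0, "UTR3": 10.0}
        assert table["placed_pct"] == 100.0

    def test_classification_total(self, tmp_path):
        loci, hits_text, gff_text, _ = sim.make_genome_fixture(
            sim.GenomeSpec(seed=3, n_loci=12))
        (tmp_path / "h.tsv").write_text(hits_text)
        (tmp_path / "g.gff3").write_text(gff_text)
        placements = place_loci(loci, read_hits(tmp_path / "h.tsv"),
                                read_gene_models(tmp_path / "g.gff3"))
        assert all(pl.region_class in
                   {"CDS", "UTR5", "UTR3", "intergenic", "unplaced"}
                   for pl in placements)
        assert len(placements) == len(loci)
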