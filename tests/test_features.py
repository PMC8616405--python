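"""Conservation, promoter, read-support, context and polyA annotations."""

import numpy as np
import pytest

from altorf.core import GenomicInterval, OrfRecord, SpeciesLocus
from altorf.features import (
    ConservationTrack,
    GeneFeature,
    PromoterCall,
    ReadSupport,
    classify_context,
    mean_conservation,
    nearest_upstream_promoter,
    polya_scan,
    read_promoter_bed,
    read_support,
)


def _orf(start, end, strand="+", chrom="c"):
    aa = (end - start) // 3 - 1
    return OrfRecord(
        orf_id="o",
        species_id="x",
        interval=GenomicInterval(chrom, start, end, strand),
        frame=start % 3,
        aa_length=aa,
        peptide="M" * aa,
    )


class TestConservation:
    def test_constant_track(self):
        track = ConservationTrack(np.full(100, 0.5))
        iv = GenomicInterval("c", 10, 40, "+")
        assert mean_conservation(track, iv) == pytest.approx(0.5)

    def test_direct_mean(self):
        track = ConservationTrack(np.array([0.0, 1.0, 1.0, 0.0]))
        assert mean_conservation(track, GenomicInterval("c", 0, 4, "+")) == 0.5

    def test_missing_bases_ignored(self):
        track = ConservationTrack(np.array([0.2, np.nan, 0.4, np.nan]))
        assert mean_conservation(
            track, GenomicInterval("c", 0, 4, "+")
        ) == pytest.approx(0.3)

    def test_all_missing_is_nan(self):
        track = ConservationTrack(np.full(4, np.nan))
        assert np.isnan(mean_conservation(track, GenomicInterval("c", 0, 4, "+")))

    def test_outside_extent_errors(self):
        track = ConservationTrack(np.zeros(10))
        with pytest.raises(ValueError):
            mean_conservation(track, GenomicInterval("c", 5, 15, "+"))

    def test_concatenation_weighting(self):
        rng = np.random.default_rng(0)
        track = ConservationTrack(rng.uniform(0, 1, 60))
        left = GenomicInterval("c", 0, 20, "+")
        right = GenomicInterval("c", 20, 60, "+")
        both = GenomicInterval("c", 0, 60, "+")
        weighted = (
            20 * mean_conservation(track, left)
            + 40 * mean_conservation(track, right)
        ) / 60
        assert mean_conservation(track, both) == pytest.approx(weighted)

    def test_bedgraph_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        scores = np.round(rng.uniform(0, 1, 200), 4)
        track = ConservationTrack(scores, offset=50, chrom="chrZ")
        path = tmp_path / "t.bedgraph"
        track.to_bedgraph(path)
        back = ConservationTrack.from_bedgraph(path, "chrZ", 50, 200)
        np.testing.assert_allclose(back.scores, scores, atol=1e-9)


class TestPromoter:
    def test_promoter_at_atg(self):
        p = [PromoterCall(100, 0.9, "+", "c")]
        assert nearest_upstream_promoter(p, _orf(100, 190)) == (0, 0.9)

    def test_nearest_wins(self):
        calls = [PromoterCall(50, 0.7, "+", "c"), PromoterCall(200, 0.9, "+", "c")]
        dist, score = nearest_upstream_promoter(calls, _orf(250, 340))
        assert (dist, score) == (50, 0.9)

    def test_minus_strand_upstream_is_rightward(self):
        calls = [PromoterCall(500, 0.8, "-", "c"), PromoterCall(100, 0.9, "-", "c")]
        orf = _orf(300, 390, strand="-")
        dist, score = nearest_upstream_promoter(calls, orf)
        assert dist == 500 - 389 and score == 0.8

    def test_wrong_strand_ignored(self):
        calls = [PromoterCall(90, 0.9, "-", "c")]
        assert nearest_upstream_promoter(calls, _orf(100, 190)) is None

    def test_linear_scan_oracle(self):
        rng = np.random.default_rng(8)
        calls = [
            PromoterCall(int(rng.integers(0, 1000)),
                         float(rng.uniform(0, 1)),
                         "+" if rng.random() < 0.5 else "-", "c")
            for _ in range(60)
        ]
        for start in (100, 400, 900):
            orf = _orf(start, start + 90)
            got = nearest_upstream_promoter(calls, orf)
            ups = [(start - p.position, p.score) for p in calls
                   if p.strand == "+" and p.position <= start]
            expected = min(ups, key=lambda t: (t[0], -t[1])) if ups else None
            assert got == expected

    def test_bed_reader(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("c\t10\t11\tp1\t0.55\t+\nc\t40\t41\tp2\t0.9\t-\n")
        calls = read_promoter_bed(path)
        assert calls[0] == PromoterCall(10, 0.55, "+", "c")
        assert calls[1] == PromoterCall(40, 0.9, "-", "c")


class TestReadSupport:
    def test_no_reads(self):
        assert read_support([], _orf(0, 99)) == ReadSupport(0, 0.0)

    def test_coverage_oracle(self):
        orf = _orf(0, 99)
        reads = [GenomicInterval("c", 10 * i, 10 * i + 10, "+") for i in range(6)]
        rs = read_support(reads, orf)
        cov = np.zeros(99, dtype=bool)
        for r in reads:
            cov[r.start : r.end] = True
        assert rs.n_reads == 6
        assert rs.breadth_pct == pytest.approx(100 * cov.sum() / 99)

    def test_breadth_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        orf = _orf(0, 120)
        reads = []
        prev = 0.0
        for _ in range(30):
            s = int(rng.integers(0, 150))
            reads.append(GenomicInterval("c", s, s + 30, "+"))
            b = read_support(reads, orf).breadth_pct
            assert prev <= b <= 100.0
            prev = b

    def test_zero_reads_implies_zero_breadth(self):
        with pytest.raises(ValueError):
            ReadSupport(0, 10.0)


class TestContext:
    CDS = GeneFeature("cds1", "CDS", GenomicInterval("c", 100, 400, "+"), 0)
    LNC = GeneFeature("lnc1", "lnc_RNA", GenomicInterval("c", 600, 900, "+"))
    UTR5 = GeneFeature("u5", "five_prime_UTR", GenomicInterval("c", 50, 100, "+"))

    def test_cds_same_frame_sense(self):
        orf = _orf(103, 202, "+")  # offset 3 from CDS start, phase 0
        label = classify_context(orf, [self.CDS])
        assert label.category == "cds_overlap_same_frame"
        assert label.orientation == "sense"

    def test_cds_diff_frame_sense(self):
        orf = _orf(104, 203, "+")
        label = classify_context(orf, [self.CDS])
        assert label.category == "cds_overlap_diff_frame"

    def test_cds_antisense(self):
        orf = _orf(103, 202, "-")
        label = classify_context(orf, [self.CDS])
        assert label.category == "cds_overlap_diff_frame"
        assert label.orientation == "antisense"

    def test_lncrna_antisense(self):
        orf = _orf(650, 749, "-")
        label = classify_context(orf, [self.CDS, self.LNC])
        assert label.category == "lncRNA"
        assert label.orientation == "antisense"
        assert label.host_feature_id == "lnc1"

    def test_priority_cds_over_utr(self):
        orf = _orf(97, 196, "+")  # spans UTR5 and CDS
        label = classify_context(orf, [self.CDS, self.UTR5])
        assert label.category.startswith("cds_overlap")

    def test_intergenic_fallback(self):
        orf = _orf(2000, 2099, "+")
        label = classify_context(orf, [self.CDS, self.LNC, self.UTR5])
        assert label.category == "intergenic"

    def test_every_orf_gets_exactly_one_category(self):
        rng = np.random.default_rng(3)
        feats = [self.CDS, self.LNC, self.UTR5]
        for _ in range(50):
            s = int(rng.integers(0, 2500))
            orf = _orf(s, s + 99, "+" if rng.random() < 0.5 else "-")
            label = classify_context(orf, feats)
            assert label.category in {
                "cds_overlap_same_frame", "cds_overlap_diff_frame",
                "utr5", "utr3", "lncRNA", "intergenic",
            }


class TestPolyA:
    def _locus_with_downstream(self, downstream):
        seq = "ATG" + "GCA" * 11 + "TAA" + downstream
        return SpeciesLocus(species_id="x", sequence=seq), _orf(0, 39, "+", "locus")

    def test_hit_at_offset(self):
        locus, orf = self._locus_with_downstream("CCCCAATAAACCCC")
        assert polya_scan(locus, orf, 150) == [4]

    def test_no_hexamer_empty(self):
        locus, orf = self._locus_with_downstream("C" * 150)
        assert polya_scan(locus, orf, 150) == []

    def test_alternative_hexamer_and_window_cut(self):
        locus, orf = self._locus_with_downstream("ATTAAA" + "C" * 30 + "AATAAA")
        assert polya_scan(locus, orf, 10) == [0]

    def test_minus_strand_reads_on_orf_strand(self):
        plus_view = "ATG" + "GCA" * 11 + "TAA" + "CCAATAAACC"
        from altorf.core import reverse_complement

        seq = reverse_complement(plus_view)
        locus = SpeciesLocus(species_id="x", sequence=seq)
        orf = _orf(10, 49, "-", "locus")
        assert polya_scan(locus, orf, 10) == [2]

    def test_window_too_small_errors(self):
        locus, orf = self._locus_with_downstream("C" * 20)
        with pytest.raises(ValueError):
            polya_scan(locus, orf, 3)
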