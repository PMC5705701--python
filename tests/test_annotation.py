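"""Origin hierarchy, exon structure, Alu pairing, splice conservation."""

import numpy as np
import pandas as pd
import pytest

import circprof as cp
from circprof.annotation import (
    build_alu_index,
    build_region_index,
    classify_splice_site,
    nearest_inverted_alu_pair,
)
from circprof.intervals import ConservationTrack, GenomicInterval, IntervalIndex


def exon_df(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "gene_id", "transcript_id",
                 "exon_number", "region"],
    )


class TestSpliceSiteHierarchy:
    REGIONS = exon_df([
        ("chr1", 100, 200, "+", "G1", "G1.t1", 1, "CDS"),
        ("chr1", 198, 300, "+", "G1", "G1.t1", 2, "UTR3"),
        ("chr1", 400, 500, "+", "G2", "G2.t1", 1, "ncRNA"),
    ])

    def test_cds_beats_utr3_when_window_overlaps_both(self):
        idx = build_region_index(self.REGIONS)
        assert classify_splice_site("chr1", 199, idx, 6) == "CDS"

    def test_ncrna_only_window(self):
        idx = build_region_index(self.REGIONS)
        assert classify_splice_site("chr1", 450, idx, 6) == "ncRNA"

    def test_unannotated_intron_is_none(self):
        idx = build_region_index(self.REGIONS)
        assert classify_splice_site("chr1", 350, idx, 6) == "none"

    def test_odd_window_rejected(self):
        idx = build_region_index(self.REGIONS)
        with pytest.raises(ValueError, match="even"):
            classify_splice_site("chr1", 199, idx, 5)


class TestOriginFractions:
    def _tables(self, circ_site, lin_site, n=10):
        circ = pd.DataFrame(
            [{"chrom": "chr1", "start": circ_site, "end": circ_site + 10,
              "total_reads": 10}] * n
        )
        lin = pd.DataFrame(
            [{"chrom": "chr1", "start": lin_site, "end": lin_site + 10,
              "total_reads": 10}] * n
        )
        return circ, lin

    def test_maximal_separation_gives_tiny_p(self):
        regions = exon_df([
            ("chr1", 100, 160, "+", "G1", "G1.t1", 1, "CDS"),
            ("chr1", 400, 460, "+", "G2", "G2.t1", 1, "ncRNA"),
        ])
        idx = build_region_index(regions)
        circ, lin = self._tables(120, 420)
        fr, tests = cp.origin_fractions(circ, lin, idx)
        cds = fr.set_index("region")
        assert cds.loc["CDS", "circular_site_fraction"] == 1.0
        assert cds.loc["ncRNA", "linear_site_fraction"] == 1.0
        assert tests["sites"]["p_value"] < 1e-4

    def test_identical_distributions_give_zero_statistic(self):
        regions = exon_df([("chr1", 100, 160, "+", "G1", "G1.t1", 1, "CDS")])
        idx = build_region_index(regions)
        circ, lin = self._tables(120, 120)
        _fr, tests = cp.origin_fractions(circ, lin, idx)
        assert tests["sites"]["statistic"] == pytest.approx(0.0)

    def test_fractions_sum_to_one(self, small_pipeline):
        res, _truth, _ = small_pipeline
        fr = res.origin_fractions
        for col in ("circular_site_fraction", "linear_site_fraction",
                    "circular_read_fraction", "linear_read_fraction"):
            assert fr[col].sum() == pytest.approx(1.0, abs=1e-9)


def test_chi_square_two_by_two_diagonal_is_twenty():
    """Pearson chi-square of [[10,0],[0,10]] is 20 without continuity
    correction (hand computation of sum (O-E)^2/E: 8 cells ... = 20)."""
    from scipy.stats import chi2_contingency
    res = chi2_contingency(np.array([[10, 0], [0, 10]]), correction=False)
    assert res.statistic == pytest.approx(20.0)


class TestExonStructure:
    def _index(self, spans):
        ivs = [GenomicInterval("chr1", s, e, "+") for s, e in spans]
        return IntervalIndex.build(ivs, payloads=[(iv, "CDS") for iv in ivs])

    def test_overlapping_exons_collapse_to_union(self):
        idx = self._index([(100, 200), (150, 250)])
        circ = GenomicInterval("chr1", 100, 250, "+")
        assert cp.exon_structure(circ, idx) == (1, 150, True)

    def test_disjoint_exons_counted_separately(self):
        idx = self._index([(100, 200), (300, 400)])
        circ = GenomicInterval("chr1", 100, 400, "+")
        assert cp.exon_structure(circ, idx) == (2, 200, True)

    def test_non_exonic_circle_reports_span_length(self):
        idx = self._index([(10_000, 10_100)])
        circ = GenomicInterval("chr1", 100, 400, "+")
        assert cp.exon_structure(circ, idx) == (0, 300, False)

    def test_exons_clipped_to_span(self):
        idx = self._index([(50, 150), (350, 450)])
        circ = GenomicInterval("chr1", 100, 400, "+")
        n, length, exonic = cp.exon_structure(circ, idx)
        assert (n, length, exonic) == (2, 100, True)
        assert length <= circ.length


class TestInternalExonControls:
    def _exons(self, n, tx="T1"):
        return [
            ("chr1", 1000 * (i + 1), 1000 * (i + 1) + 100, "+", "G1", tx, i + 1, "CDS")
            for i in range(n)
        ]

    def test_three_exon_transcript_yields_middle_exon(self):
        out = cp.internal_exon_controls(exon_df(self._exons(3)))
        assert out == [GenomicInterval("chr1", 2000, 2100, "+")]

    def test_two_exon_transcript_contributes_nothing(self):
        assert cp.internal_exon_controls(exon_df(self._exons(2))) == []

    def test_five_exon_transcript_yields_three_internal(self):
        out = cp.internal_exon_controls(exon_df(self._exons(5)))
        assert len(out) == 3
        assert all(iv.start in (2000, 3000, 4000) for iv in out)


def alu_table(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "subfamily"])
    return df


class TestAluPairs:
    def test_direct_distance_sum(self):
        # AluS(+) ending 500 bp upstream, AluS(-) starting 300 bp downstream
        feature = GenomicInterval("chr1", 10_000, 12_000)
        idx = build_alu_index(alu_table([
            ("chr1", 9200, 9500, "+", "AluS"),
            ("chr1", 12_300, 12_600, "-", "AluS"),
        ]))
        res = nearest_inverted_alu_pair(feature, idx, 20_000)
        assert res.distance_bp == 800

    def test_subfamily_mismatch_gives_no_pair(self):
        feature = GenomicInterval("chr1", 10_000, 12_000)
        idx = build_alu_index(alu_table([
            ("chr1", 9200, 9500, "+", "AluS"),
            ("chr1", 12_300, 12_600, "-", "AluJ"),
        ]))
        res = nearest_inverted_alu_pair(feature, idx, 20_000)
        assert res.distance_bp is None

    def test_same_strand_pair_invalid(self):
        feature = GenomicInterval("chr1", 10_000, 12_000)
        idx = build_alu_index(alu_table([
            ("chr1", 9200, 9500, "+", "AluS"),
            ("chr1", 12_300, 12_600, "+", "AluS"),
        ]))
        assert nearest_inverted_alu_pair(feature, idx, 20_000).distance_bp is None

    def test_overlapping_alu_gap_clamps_to_zero(self):
        feature = GenomicInterval("chr1", 10_000, 12_000)
        idx = build_alu_index(alu_table([
            ("chr1", 9900, 10_050, "+", "AluY"),  # overlaps feature start
            ("chr1", 12_100, 12_400, "-", "AluY"),
        ]))
        assert nearest_inverted_alu_pair(feature, idx, 20_000).distance_bp == 100

    def test_mirror_symmetry_of_distances(self):
        """Reflecting the whole fixture through a point preserves distances."""
        rng = np.random.default_rng(4)
        n = 200
        starts = rng.integers(30_000, 800_000, n)
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        subs = np.array(["AluJ", "AluS", "AluY"])[rng.integers(0, 3, n)]
        alus = alu_table(list(zip(["chr1"] * n, starts, starts + 300, strands, subs)))
        feats = [GenomicInterval("chr1", int(s), int(s) + 500)
                 for s in rng.integers(40_000, 700_000, 50)]
        idx = build_alu_index(alus)
        direct = [nearest_inverted_alu_pair(f, idx, 20_000).distance_bp for f in feats]

        m = 1_000_000  # reflect: x -> m - x (strands flip)
        alus_m = alu_table(list(zip(
            ["chr1"] * n, m - (starts + 300), m - starts,
            np.where(strands == "+", "-", "+"), subs)))
        feats_m = [GenomicInterval("chr1", m - f.end, m - f.start) for f in feats]
        idx_m = build_alu_index(alus_m)
        mirrored = [nearest_inverted_alu_pair(f, idx_m, 20_000).distance_bp
                    for f in feats_m]
        assert direct == mirrored

    def test_small_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(7)
        n = 400
        starts = rng.integers(0, 300_000, n)
        alus = alu_table(list(zip(
            ["chr1"] * n, starts, starts + 300,
            np.where(rng.random(n) < 0.5, "+", "-"),
            np.array(["AluJ", "AluS", "AluY"])[rng.integers(0, 3, n)])))
        idx = build_alu_index(alus)
        recs = list(alus.itertuples())
        for s in rng.integers(25_000, 250_000, 40):
            f = GenomicInterval("chr1", int(s), int(s) + 1000)
            got = nearest_inverted_alu_pair(f, idx, 20_000).distance_bp
            best = None
            for a in recs:
                if not (a.end > f.start - 20_000 and a.start < f.start):
                    continue
                for b in recs:
                    if not (b.end > f.end and b.start < f.end + 20_000):
                        continue
                    if a.subfamily != b.subfamily or a.strand == b.strand:
                        continue
                    d = max(0, f.start - a.end) + max(0, b.start - f.end)
                    best = d if best is None else min(best, d)
            assert got == best


class TestConservation:
    def _track(self, chrom, pos_scores):
        t = ConservationTrack()
        for p, s in pos_scores.items():
            t.set_score(chrom, p, s)
        return t

    def test_mean_of_four_core_bases(self):
        iv = GenomicInterval("chr1", 100, 200)
        t = self._track("chr1", {98: 2, 99: 2, 200: 4, 201: 4})
        sc = cp.splice_site_conservation(iv, t)
        assert sc.mean_score == pytest.approx(3.0)
        assert sc.n_scored == 4

    def test_reported_abundant_level_reproduced_exactly(self):
        iv = GenomicInterval("chr1", 100, 200)
        t = self._track("chr1", {98: 6.15, 99: 6.15, 200: 6.15, 201: 6.15})
        assert cp.splice_site_conservation(iv, t).mean_score == pytest.approx(6.15)

    def test_missing_positions_skipped_with_coverage(self):
        iv = GenomicInterval("chr1", 100, 200)
        t = self._track("chr1", {98: 3, 99: 3, 200: 3})
        sc = cp.splice_site_conservation(iv, t)
        assert sc.mean_score == pytest.approx(3.0)
        assert sc.n_scored == 3

    def test_all_missing_flagged_undefined(self):
        iv = GenomicInterval("chr1", 100, 200)
        sc = cp.splice_site_conservation(iv, ConservationTrack())
        assert not sc.defined and np.isnan(sc.mean_score)

    def test_exonic_side_option(self):
        iv = GenomicInterval("chr1", 100, 200)
        t = self._track("chr1", {100: 1, 101: 1, 198: 5, 199: 5})
        sc = cp.splice_site_conservation(iv, t, side="exonic")
        assert sc.mean_score == pytest.approx(3.0)
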