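"""Coding exon groups, containment, observed-vs-expected, sponge stat."""

import numpy as np
import pandas as pd
import pytest

import circprof as cp
from circprof.enrichment import circ_included_regions, collapse_exons
from circprof.intervals import (
    GenomicInterval,
    IntervalIndex,
    merge_intervals,
    total_length,
)


def exon_df(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "gene_id", "transcript_id",
                 "exon_number", "region"],
    )


def iv(s, e, chrom="chr1", strand="."):
    return GenomicInterval(chrom, s, e, strand)


class TestCodingExonGroups:
    def _exons(self, cds_bp):
        # a 100 bp exon whose first `cds_bp` bases are CDS, rest UTR3
        rows = [("chr1", 0, cds_bp, "+", "G1", "G1.t1", 1, "CDS")]
        if cds_bp < 100:
            rows.append(("chr1", cds_bp, 100, "+", "G1", "G1.t1", 1, "UTR3"))
        return exon_df(rows)

    def test_ninety_percent_cds_boundary_inclusive(self):
        groups, _ = cp.build_coding_exon_groups(self._exons(90), {}, set())
        assert total_length(groups.linear_only) == 100

    def test_below_ninety_percent_not_coding(self):
        groups, _ = cp.build_coding_exon_groups(self._exons(89), {}, set())
        assert groups.linear_only == []

    def test_abundant_takes_precedence_over_nonabundant(self):
        exons = exon_df([("chr1", 100, 200, "+", "G1", "G1.t1", 1, "CDS")])
        circs = {
            "ab": iv(50, 250, strand="+"),
            "non": iv(80, 260, strand="+"),
        }
        groups, per_circ = cp.build_coding_exon_groups(exons, circs, {"ab"})
        assert len(groups.abundant_circ) == 1
        assert groups.nonabundant_circ == []
        assert per_circ["ab"] == per_circ["non"]

    def test_partial_containment_is_not_circularized(self):
        exons = exon_df([("chr1", 100, 200, "+", "G1", "G1.t1", 1, "CDS")])
        circs = {"c": iv(150, 400, strand="+")}  # clips the exon
        groups, per_circ = cp.build_coding_exon_groups(exons, circs, {"c"})
        assert per_circ["c"] == []
        assert len(groups.linear_only) == 1

    def test_groups_partition_all_coding_exons(self, small_pipeline):
        res, _truth, _ = small_pipeline
        g = res.exon_groups
        sets = [set(g.abundant_circ), set(g.nonabundant_circ), set(g.linear_only)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2])
        assert not (sets[1] & sets[2])


class TestMergeSemantics:
    def test_touching_sites_merge(self):
        merged = merge_intervals([iv(10, 20), iv(20, 30)])
        assert total_length(merged) == 20

    def test_overlapping_sites_union(self):
        merged = merge_intervals([iv(10, 20), iv(15, 25)])
        assert total_length(merged) == 15

    def test_merged_never_longer_than_raw(self):
        rng = np.random.default_rng(0)
        ivs = [iv(int(s), int(s) + int(l))
               for s, l in zip(rng.integers(0, 1000, 50), rng.integers(1, 60, 50))]
        assert total_length(merge_intervals(ivs)) <= total_length(ivs)


class TestContainmentFractions:
    def _groups(self):
        return cp.CodingExonGroups(
            abundant_circ=[iv(0, 100), iv(200, 300), iv(400, 500), iv(600, 700)],
            nonabundant_circ=[iv(1000, 1100)],
            linear_only=[iv(2000, 2100)],
        )

    def test_quarter_containment(self):
        summary, _ = cp.containment_fractions(self._groups(), [iv(50, 60)])
        row = summary.set_index("group").loc["abundant_circ"]
        assert row["fraction"] == pytest.approx(0.25)

    def test_empty_elements_give_zero_fractions(self):
        summary, _ = cp.containment_fractions(self._groups(), [])
        assert (summary["fraction"] == 0).all()

    def test_null_chi_square_p_is_uniformish(self):
        """Equal element density in two groups: p should not concentrate
        near 0 (type-I behavior over seeded replicates)."""
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(40):
            exA = [iv(1000 * i, 1000 * i + 100) for i in range(200)]
            exB = [iv(1_000_000 + 1000 * i, 1_000_000 + 1000 * i + 100)
                   for i in range(200)]
            groups = cp.CodingExonGroups(exA, [], exB)
            hitsA = rng.random(200) < 0.3
            hitsB = rng.random(200) < 0.3
            elements = [iv(1000 * i + 10, 1000 * i + 20)
                        for i in range(200) if hitsA[i]]
            elements += [iv(1_000_000 + 1000 * i + 10, 1_000_000 + 1000 * i + 20)
                         for i in range(200) if hitsB[i]]
            _s, pw = cp.containment_fractions(groups, elements)
            p = pw.set_index(["group_a", "group_b"]).loc[
                ("abundant_circ", "linear_only"), "chi2_p"]
            ps.append(p)
        assert 0.01 < np.mean(ps) < 0.99
        assert (np.array(ps) < 0.05).mean() < 0.2


class TestSceObservedVsExpected:
    def test_direct_expected_formula(self):
        # L_SCE / L_coding_exons = 1000/10000 -> expected 50 on 500 bp
        exons = {
            "c1": [iv(0, 500)],
            "c2": [iv(10_000, 19_500)],
        }
        circs = {"c1": iv(0, 500), "c2": iv(10_000, 19_500)}
        sce = [iv(10_000, 11_000)]
        table, exp = cp.sce_observed_vs_expected(circs, exons, sce)
        assert exp.l_coding_exons == 10_000 and exp.l_sce == 1000
        row = table.set_index("circ_id").loc["c1"]
        assert row["expected_bp"] == pytest.approx(50.0)
        assert row["observed_bp"] == 0

    def test_full_coverage_observed_equals_coding_length(self):
        circs = {"c1": iv(100, 300)}
        exons = {"c1": [iv(100, 300)]}
        table, _ = cp.sce_observed_vs_expected(circs, exons, [iv(0, 1000)])
        assert table.iloc[0]["observed_bp"] == 200

    def test_no_coding_exons_is_an_error(self):
        with pytest.raises(ValueError, match="L_coding_exons"):
            cp.sce_observed_vs_expected({"c1": iv(0, 100)}, {"c1": []}, [])


class TestMirnaObservedVsExpected:
    def _exon_index(self, spans):
        ivs = [GenomicInterval("chr1", s, e, "+") for s, e in spans]
        return IntervalIndex.build(ivs, payloads=[(i, "CDS") for i in ivs])

    def _sites(self, positions):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": p, "end": p + 7, "mirna_id": "miR-7",
              "experiment_id": "brain", "conserved": True} for p in positions]
        )

    def test_expected_rate_formula(self):
        idx = self._exon_index([(0, 500), (1000, 1500)])
        circs = {"a": iv(0, 500, strand="+"), "b": iv(1000, 1500, strand="+")}
        sites = self._sites([10, 20, 30, 40, 1100])  # 4 in a, 1 in b
        table, exp = cp.mirna_observed_vs_expected(circs, idx, sites)
        assert exp.t_mirnas == 5 and exp.l_exons == 1000
        got = table.set_index("circ_id")
        assert got.loc["a", "expected_sites"] == pytest.approx(2.5)
        assert got.loc["a", "observed_sites"] == 4

    def test_long_nonexonic_circle_excluded(self):
        idx = self._exon_index([])
        circs = {
            "long": iv(0, 12_000),
            "short": iv(50_000, 52_000),
        }
        table, _ = cp.mirna_observed_vs_expected(circs, idx, self._sites([50_100]))
        assert list(table["circ_id"]) == ["short"]

    def test_unmerged_sites_counted_individually(self):
        idx = self._exon_index([(0, 500)])
        circs = {"a": iv(0, 500, strand="+")}
        table, _ = cp.mirna_observed_vs_expected(
            circs, idx, self._sites([10, 12, 14])  # heavily overlapping
        )
        assert table.iloc[0]["observed_sites"] == 3


class TestSpongeStatistic:
    def _sites(self, spec):
        rows = []
        for (mirna, exp), n in spec.items():
            for k in range(n):
                rows.append({"chrom": "chr1", "start": 100 + 10 * len(rows),
                             "end": 107 + 10 * len(rows), "mirna_id": mirna,
                             "experiment_id": exp, "conserved": True})
        return pd.DataFrame(rows)

    def test_max_same_mirna_site_count(self):
        sites = self._sites({("miR-7", "brain"): 3, ("miR-124", "HeLa"): 1})
        stat = cp.sponge_statistic(iv(0, 1000), sites, "c")
        assert (stat.best_mirna, stat.best_experiment,
                stat.max_same_mirna_sites) == ("miR-7", "brain", 3)

    def test_no_sites_gives_zero(self):
        stat = cp.sponge_statistic(iv(0, 1000), self._sites({}), "c")
        assert stat.max_same_mirna_sites == 0 and stat.best_mirna == ""

    def test_tie_broken_lexicographically(self):
        sites = self._sites({("miR-9", "brain"): 2, ("miR-124", "HeLa"): 2})
        stat = cp.sponge_statistic(iv(0, 1000), sites, "c")
        assert stat.best_mirna == "miR-124"

    def test_random_fixture_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(300):
            pos = int(rng.integers(0, 5000))
            rows.append({"chrom": "chr1", "start": pos, "end": pos + 7,
                         "mirna_id": f"miR-{rng.integers(1, 6)}",
                         "experiment_id": ["brain", "HeLa"][rng.integers(2)],
                         "conserved": True})
        sites = pd.DataFrame(rows)
        circ = iv(1000, 3000)
        stat = cp.sponge_statistic(circ, sites, "c")
        counts: dict = {}
        for r in rows:
            if r["start"] < circ.end and r["end"] > circ.start:
                key = (r["mirna_id"], r["experiment_id"])
                counts[key] = counts.get(key, 0) + 1
        assert stat.max_same_mirna_sites == max(counts.values())


def test_planted_enrichment_recovered_in_abundant_group(small_pipeline):
    """With SCE/miRNA density planted in abundant-circle exons, the
    abundant group's containment fraction exceeds the linear group's."""
    res, _truth, _ = small_pipeline
    s = res.sce_containment.set_index("group")
    m = res.mirna_containment.set_index("group")
    assert s.loc["abundant_circ", "fraction"] > s.loc["linear_only", "fraction"]
    assert m.loc["abundant_circ", "fraction"] > m.loc["linear_only", "fraction"]


def test_collapse_exons_unions_per_strand():
    exons = exon_df([
        ("chr1", 100, 200, "+", "G1", "t1", 1, "CDS"),
        ("chr1", 150, 250, "+", "G1", "t2", 1, "CDS"),
        ("chr1", 150, 250, "-", "G2", "t3", 1, "CDS"),
    ])
    out = collapse_exons(exons)
    assert len(out) == 2  # one merged "+" exon, one "-" exon
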