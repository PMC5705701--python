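"""Rank-sum DE, BH adjustment, Spearman correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import circprof as cp


def naive_bh(p):
    """Independent step-up oracle: sort, scale, enforce monotonicity."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    running = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(running, 1.0)
    return q


def enumeration_p(x, y):
    """Exhaustive two-sided rank-sum p over all group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    center = n * m / 2
    total = hits = 0
    for comb in itertools.combinations(range(n + m), n):
        u = ranks[list(comb)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return min(1.0, hits / total)


class TestRanksum:
    def test_textbook_exact_p(self):
        # {1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 splits -> 2/20
        assert cp.ranksum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        assert cp.ranksum_test([5, 5, 5], [5, 5, 5]) == 1.0

    @pytest.mark.parametrize("n,m", [(2, 3), (3, 3), (4, 4), (5, 3), (8, 4)])
    def test_exact_branch_matches_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        for _ in range(5):
            x, y = rng.normal(size=n), rng.normal(size=m)
            assert cp.ranksum_test(x, y) == pytest.approx(
                enumeration_p(x, y), abs=1e-12
            )


class TestBH:
    def test_all_equal_adjusted_values(self):
        q = cp.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert cp.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cp.bh_adjust([0.1, 1.2])

    def test_matches_naive_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(cp.bh_adjust(p), naive_bh(p), atol=1e-12)

    def test_nan_preserved_and_excluded_from_family(self):
        q = cp.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], naive_bh([0.01, 0.04]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_at_least_p_and_rank_monotone(self, p):
        q = cp.bh_adjust(p)
        p = np.asarray(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestWilcoxonDE:
    def _matrix(self, rows, labels_classes):
        cols = [f"S{i}" for i in range(len(labels_classes))]
        labels = pd.Series(labels_classes, index=cols)
        return pd.DataFrame(rows, columns=cols), labels

    def test_sign_convention_positive_means_higher_in_class1(self):
        m, labels = self._matrix(
            [[30, 31, 32, 2, 3, 4], [2, 3, 4, 30, 31, 32]],
            [1, 1, 1, 2, 2, 2],
        )
        de = cp.wilcoxon_de(m, labels, 1, 2)
        assert de.iloc[0]["log2_fold_change"] > 0
        assert de.iloc[1]["log2_fold_change"] < 0

    def test_constant_row_flagged_with_p_one(self):
        m, labels = self._matrix([[7, 7, 7, 7]], [1, 1, 2, 2])
        de = cp.wilcoxon_de(m, labels, 1, 2)
        assert de.iloc[0]["constant"] and de.iloc[0]["p_value"] == 1.0

    def test_too_small_group_is_an_error(self):
        m, labels = self._matrix([[1, 2, 3]], [1, 2, 2])
        with pytest.raises(ValueError, match=">= 2 samples"):
            cp.wilcoxon_de(m, labels, 1, 2)

    def test_host_gene_driven_change_invisible_to_ratio_de(self):
        """Circ scaling with its host gene is significant at the level
        scale but not at the circ-to-lin ratio scale."""
        rng = np.random.default_rng(2)
        n = 60
        labels = pd.Series(np.repeat([1, 2], n // 2),
                           index=[f"S{i}" for i in range(n)])
        host = np.where(labels.to_numpy() == 1, 40.0, 10.0) * np.exp(
            rng.normal(0, 0.05, n))
        circ = pd.DataFrame([np.round(host)], columns=labels.index)
        # linear = 2*circ + 1 makes (c+1)/(l+1) exactly 0.5 everywhere
        linear = circ * 2 + 1
        de = cp.wilcoxon_de(circ, labels, 1, 2)
        ratios = cp.circ_to_lin(circ, linear)
        rde = cp.ratio_de(ratios, labels, 1, 2)
        assert de.iloc[0]["p_value"] < 0.01
        assert rde.iloc[0]["p_value"] > 0.1

    def test_all_ratios_one_give_p_one(self):
        m, labels = self._matrix([[1.0, 1.0, 1.0, 1.0]], [1, 1, 2, 2])
        rde = cp.ratio_de(m, labels, 1, 2)
        assert rde.iloc[0]["p_value"] == 1.0


class TestTotals:
    def test_planted_ordering_detected(self):
        rng = np.random.default_rng(8)
        n = 60
        labels = pd.Series(np.repeat([1, 2, 3], n),
                           index=[f"S{i}" for i in range(3 * n)])
        scale = np.repeat([3.0, 2.0, 1.0], n)
        m = pd.DataFrame(rng.poisson(20 * scale, size=(30, 3 * n)),
                         columns=labels.index)
        summary, tests = cp.total_expression_comparison(m, labels)
        med = summary.set_index("risk_class")["median_total_cpm"]
        assert med[1] > med[2] > med[3]
        assert (tests["p_value"] < 0.05).all()

    def test_single_sample_class_flagged(self):
        labels = pd.Series([1, 2, 2, 2], index=list("abcd"))
        m = pd.DataFrame([[1, 2, 3, 4]], columns=list("abcd"))
        _s, tests = cp.total_expression_comparison(m, labels)
        assert tests.iloc[0]["insufficient_n"]


class TestCorrelations:
    def _setup(self, values, partner):
        cols = [f"S{i}" for i in range(len(partner))]
        cpm = pd.DataFrame([values], index=["c1"], columns=cols)
        gene = pd.DataFrame([partner, np.ones(len(partner))],
                            index=["QKI", "ADAR1"], columns=cols)
        return cpm, gene

    def test_perfect_monotone_gives_rho_one(self):
        cpm, gene = self._setup([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        per_circ, _ = cp.regulator_correlation(cpm, gene, ("QKI",))
        assert per_circ.iloc[0]["spearman_rho"] == pytest.approx(1.0)

    def test_anti_monotone_gives_rho_minus_one(self):
        cpm, gene = self._setup([5, 4, 3, 2, 1], [10, 20, 30, 40, 50])
        per_circ, _ = cp.regulator_correlation(cpm, gene, ("QKI",))
        assert per_circ.iloc[0]["spearman_rho"] == pytest.approx(-1.0)

    def test_rho_matches_rank_formula_without_ties(self):
        rng = np.random.default_rng(1)
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        cpm, gene = self._setup(x, y)
        per_circ, _ = cp.regulator_correlation(cpm, gene, ("QKI",))
        d = sps.rankdata(x) - sps.rankdata(y)
        expected = 1 - 6 * (d**2).sum() / (10 * (100 - 1))
        assert per_circ.iloc[0]["spearman_rho"] == pytest.approx(expected)

    def test_too_few_matched_samples_error(self):
        cpm, gene = self._setup([1, 2], [3, 4])
        with pytest.raises(ValueError, match="matched samples"):
            cp.regulator_correlation(cpm, gene, ("QKI",))

    def test_constant_eortc_flagged_degenerate(self):
        cpm = pd.DataFrame([[1, 2, 3, 4]], index=["c1"],
                           columns=list("abcd"))
        eortc = pd.Series([5, 5, 5, 5], index=list("abcd"))
        out = cp.eortc_correlation(cpm, eortc)
        assert out.iloc[0]["degenerate"] and np.isnan(out.iloc[0]["spearman_rho"])

    def test_permuted_eortc_controls_significance_rate(self):
        rng = np.random.default_rng(9)
        cols = [f"S{i}" for i in range(80)]
        sig_frac = []
        for _ in range(20):
            cpm = pd.DataFrame(rng.poisson(15, (40, 80)), columns=cols)
            eortc = pd.Series(rng.permutation(np.arange(80)), index=cols)
            out = cp.eortc_correlation(cpm, eortc, fdr_level=0.1)
            sig_frac.append(out["significant"].mean())
        assert np.mean(sig_frac) <= 0.1
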