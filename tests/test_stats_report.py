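"""Group-comparison statistics: oracles, calibration, and bookkeeping.

Frozen expected values were computed with an independent reference
implementation (R 4.3: kruskal.test, chisq.test(correct=FALSE), aov,
multcomp::glht with Dunnett contrasts).
"""

import numpy as np
import pytest
from scipy import stats as sps

from dcquant import stats_report as sr

G1 = [1.1, 2.3, 3.1, 4.8, 5.2]
G2 = [2.0, 3.5, 4.1, 6.3, 7.0]
G3 = [10.1, 11.2, 9.8, 12.5, 13.0]

CTRL = [5.1, 4.8, 5.6, 5.0, 4.7, 5.3]
TRT_A = [6.2, 6.8, 5.9, 6.5, 7.1, 6.0]
TRT_B = [4.9, 5.2, 4.6, 5.5, 5.0, 4.8]


def _groups(ref, *others, labels=None):
    labels = labels or ["ref"] + [f"g{i}" for i in range(len(others))]
    out = [sr.GroupData(labels[0], ref, is_reference=True)]
    out += [sr.GroupData(lbl, vals) for lbl, vals in zip(labels[1:], others)]
    return out


class TestNormality:
    def test_normal_draws_rarely_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=500)
            _, _, is_normal = sr.normality(x)
            hits += is_normal
        assert hits >= 95

    def test_exponential_draws_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=500)
            _, p, _ = sr.normality(x)
            hits += p < 0.05
        assert hits >= 95

    def test_small_n_errors(self):
        with pytest.raises(ValueError, match="insufficient"):
            sr.normality([1.0, 2.0, 3.0, 4.0, 5.0])


class TestKruskalWallisDunn:
    def test_h_and_p_match_reference(self):
        res = sr.kw_dunn(_groups(G3, G1, G2))
        # R: kruskal.test(list(g1,g2,g3)) -> H = 9.78, p = 0.0075214225
        assert res.statistic == pytest.approx(9.78, abs=1e-9)
        assert res.pvalue == pytest.approx(0.0075214225, abs=1e-6)

    def test_tie_correction_matches_reference(self):
        t1, t2, t3 = [1, 2, 2, 3, 5, 5], [2, 4, 4, 6, 6, 7], [5, 6, 7, 8, 8, 9]
        res = sr.kw_dunn(_groups(t1, t2, t3))
        # R: H = 9.5365129280, p = 0.0084951789 (tie-corrected)
        assert res.statistic == pytest.approx(9.5365129280, abs=1e-9)
        assert res.pvalue == pytest.approx(0.0084951789, abs=1e-6)

    def test_separated_groups_significant(self):
        res = sr.kw_dunn(
            _groups([51, 52, 53], [1, 2, 3], [101, 102, 103])
        )
        assert res.pvalue < 0.05

    def test_identical_groups_dunn_adjusted_p_one(self):
        res = sr.kw_dunn(_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        _, p_adj, stars = res.comparisons["g0"]
        assert p_adj == 1.0 and stars == "ns"

    def test_all_identical_values_flagged_not_raised(self):
        res = sr.kw_dunn(_groups([2.0, 2.0], [2.0, 2.0]))
        assert res.statistic == 0.0 and res.pvalue == 1.0
        assert res.flags

    def test_dunn_z_matches_independent_recomputation(self, rng):
        """Dunn z from first principles: pooled mean ranks over the
        tie-corrected variance, on random small datasets."""
        for _ in range(50):
            sizes = rng.integers(3, 9, size=3)
            vals = [np.round(rng.normal(size=n), 1) for n in sizes]
            res = sr.kw_dunn(_groups(vals[0], vals[1], vals[2]))
            pooled = np.concatenate(vals)
            ranks = sps.rankdata(pooled)
            N = pooled.size
            rbar = [
                ranks[sum(sizes[:i]): sum(sizes[: i + 1])].mean() for i in range(3)
            ]
            _, cnt = np.unique(pooled, return_counts=True)
            var = N * (N + 1) / 12 - np.sum(cnt**3 - cnt) / (12 * (N - 1))
            for i, lbl in enumerate(["g0", "g1"]):
                z_exp = (rbar[i + 1] - rbar[0]) / np.sqrt(
                    var * (1 / sizes[i + 1] + 1 / sizes[0])
                )
                assert res.comparisons[lbl][0] == pytest.approx(z_exp, abs=1e-9)

    def test_type_one_error_calibrated(self):
        """Permuting labels of one distribution: KW rejection near α."""
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            pool = rng.normal(size=30)
            res = sps.kruskal(pool[:10], pool[10:20], pool[20:])
            rejections += res.pvalue <= 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestAnovaDunnett:
    def test_f_and_p_match_reference(self):
        res = sr.anova_dunnett(_groups(CTRL, TRT_A, TRT_B))
        # R: aov -> F = 26.3717156105, p = 1.2279495e-05
        assert res.statistic == pytest.approx(26.3717156105, abs=1e-8)
        assert res.pvalue == pytest.approx(1.2279495323e-05, abs=1e-6)

    def test_dunnett_statistics_match_reference(self):
        res = sr.anova_dunnett(_groups(CTRL, TRT_A, TRT_B))
        # R multcomp::glht Dunnett: t = 6.09050747, -0.38065672
        assert res.comparisons["g0"][0] == pytest.approx(6.09050747, abs=1e-6)
        assert res.comparisons["g1"][0] == pytest.approx(-0.38065672, abs=1e-6)
        # adjusted p from the multivariate t: 0.00004002, 0.90076741
        assert res.comparisons["g0"][1] == pytest.approx(4.002e-05, abs=2e-4)
        assert res.comparisons["g1"][1] == pytest.approx(0.90076741, abs=2e-4)

    def test_identical_groups_f_near_zero(self):
        res = sr.anova_dunnett(
            _groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            sr.anova_dunnett(_groups([2.0, 2.0], [3.0, 3.0]))

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            g = rng.normal(size=(3, 8))
            _, p = sps.f_oneway(*g)
            rejections += p <= 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_large_shift(self):
        """2-sd shift at n = 20/group: Dunnett comparison nearly always
        significant (closed-form power > 0.9)."""
        rng = np.random.default_rng(3)
        hits = 0
        reps = 200
        for _ in range(reps):
            ctrl = rng.normal(size=20)
            trt = rng.normal(loc=2.0, size=20)
            other = rng.normal(size=20)
            res = sr.anova_dunnett(_groups(ctrl, trt, other), rng=0)
            hits += res.comparisons["g0"][1] <= 0.05
        assert hits / reps > 0.9

    def test_location_shift_monotone_in_adjusted_p(self):
        # start the treated group identical to control so the comparison
        # statistic grows monotonically with the shift
        rng = np.random.default_rng(12)
        ctrl = rng.normal(size=12)
        other = rng.normal(size=12)
        trt = ctrl.copy()
        prev = 1.0
        for shift in [0.0, 0.8, 1.6, 2.4]:
            res = sr.anova_dunnett(_groups(ctrl, trt + shift, other), rng=0)
            p = res.comparisons["g0"][1]
            assert p <= prev + 1e-6
            prev = p


class TestChiSquare:
    def test_pearson_value_matches_hand_computation(self):
        res = sr.phenotype_chisq([[50, 3], [10, 32]])
        # expected counts from the marginals give χ² = 50.0932 (R agrees)
        assert res.statistic == pytest.approx(50.0931630514, abs=1e-8)
        assert res.pvalue == pytest.approx(1.46617e-12, rel=1e-4)

    def test_identical_rows_null(self):
        res = sr.phenotype_chisq([[5, 10, 5], [5, 10, 5]])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_negative_count_errors(self):
        with pytest.raises(ValueError, match="non-negative"):
            sr.phenotype_chisq([[5, -1], [2, 3]])

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError, match="marginal"):
            sr.phenotype_chisq([[5, 0], [3, 0]])

    def test_per_mutant_tables_vs_reference_row(self):
        import pandas as pd

        table = pd.DataFrame(
            [[40, 5, 5], [20, 15, 15], [38, 6, 6]],
            index=["WT", "mutA", "mutB"],
        )
        out = sr.phenotype_chisq(table, reference="WT")
        assert set(out) == {"mutA", "mutB"}
        solo = sr.phenotype_chisq(table.loc[["WT", "mutA"]])
        assert out["mutA"].statistic == pytest.approx(solo.statistic)


class TestStars:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.2, "ns"), (0.051, "ns"), (0.05, "*"), (0.02, "*"),
            (0.01, "**"), (0.001, "***"), (0.0001, "****"), (0.0, "****"),
        ],
    )
    def test_threshold_mapping_closed_boundaries(self, p, label):
        assert sr.star_map(p) == label

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            sr.star_map(1.5)
        with pytest.raises(ValueError):
            sr.star_map(-0.1)


class TestSummaryTable:
    def test_empty_results_header_only(self):
        table = sr.summary_table({})
        assert table.empty

    def test_populated_row_carries_n_and_stars(self):
        res = sr.kw_dunn(_groups(G3, G1, labels=["WT", "frl"]))
        table = sr.summary_table({"DC duration": res})
        cell = table.loc["DC duration", "frl"]
        assert cell.startswith("n=5;") and "(" in cell
        assert table.loc["DC duration", "WT"] == "n=5"
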