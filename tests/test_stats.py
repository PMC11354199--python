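import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ciliafreq import (
    build_report,
    correlate,
    ks_normality,
    welch_t,
    wilcoxon_one_sample,
)


class TestKsNormality:
    def test_gaussian_sample_passes(self, rng):
        res = ks_normality(rng.normal(10.0, 1.0, 200))
        assert res.normal

    def test_exponential_sample_fails(self, rng):
        res = ks_normality(rng.exponential(1.0, 200))
        assert not res.normal

    def test_constant_sample_is_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ks_normality([3.0] * 10)

    def test_tiny_sample_is_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            ks_normality([1.0, 2.0, 3.0])


class TestWelch:
    def test_hand_computed_example(self):
        # t = -3 / sqrt(1/3 + 1/3) = -3.674, Welch-Satterthwaite df = 4.0
        res = welch_t([1, 2, 3], [4, 5, 6])
        assert round(res.statistic, 3) == -3.674
        assert round(res.df, 3) == 4.0

    def test_identical_groups_give_t_zero_p_one(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("c", [-2.0, 3.0])
    def test_sign_tracks_location_shift(self, rng, c):
        a = rng.normal(10, 1, 30)
        res = welch_t(a, a + c)
        assert np.sign(res.statistic) == -np.sign(c)

    def test_undersized_group_is_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])


class TestWilcoxonOneSample:
    def test_symmetric_differences_give_p_one(self):
        res = wilcoxon_one_sample([1.0, 2.0, 3.0], 2.0)
        assert res.p_value == 1.0

    def test_uniformly_signed_differences_give_extreme_exact_p(self):
        # all 12 values above the hypothesized median: p = 2 / 2^12
        res = wilcoxon_one_sample(np.arange(1, 13, dtype=float), 0.0)
        assert res.p_value == pytest.approx(2 / 2**12, abs=0)

    def test_all_values_at_the_median_is_rejected(self):
        with pytest.raises(ValueError, match="equal the hypothesized median"):
            wilcoxon_one_sample([5.0, 5.0, 5.0], 5.0)

    def test_exact_enumeration_matches_scipy_on_tiefree_data(self, rng):
        v = rng.normal(0.3, 1.0, 15)
        ours = wilcoxon_one_sample(v, 0.0)
        ref = sps.wilcoxon(v, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_exact_and_normal_approximation_agree_at_n20(self, rng):
        for _ in range(5):
            v = rng.normal(0.2, 1.0, 20)
            exact = wilcoxon_one_sample(v, 0.0)
            approx = wilcoxon_one_sample(v, 0.0, exact_max_n=0)
            assert abs(exact.p_value - approx.p_value) < 0.01


class TestCorrelate:
    def test_pearson_on_exact_linearity(self):
        r, _ = correlate([1, 2, 3], [2, 4, 6], parametric=True)
        assert r == pytest.approx(1.0)

    def test_spearman_is_invariant_to_monotone_transforms(self):
        x = np.arange(1.0, 11.0)
        r, _ = correlate(x, np.exp(x), parametric=False)
        assert r == pytest.approx(1.0)

    def test_spearman_equals_pearson_on_ranks(self, rng):
        x = rng.permutation(20).astype(float)  # tie-free by construction
        y = rng.normal(0, 1, 20)
        r_s, _ = correlate(x, y, parametric=False)
        r_ref, _ = correlate(sps.rankdata(x), sps.rankdata(y), parametric=True)
        assert r_s == pytest.approx(r_ref, rel=1e-12)

    def test_constant_input_is_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], parametric=True)

    def test_length_mismatch_is_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            correlate([1.0, 2.0], [1.0, 2.0, 3.0], parametric=True)


def cohort_frame(rows):
    return pd.DataFrame(rows, columns=["subject", "group", "recording", "method", "cbf_hz"])


def synthetic_cohort_table(rng, n_case=40, n_hc=25, skewed_method=None):
    """Three-method cohort with normal CBFs, optionally one skewed case arm."""
    rows = []
    for g, n, mu in (("PCD", n_case, 9.0), ("HC", n_hc, 11.0)):
        for i in range(n):
            subject = f"{g}{i // 5}"
            rec = f"{g}R{i}"
            base = rng.normal(mu, 0.5)
            for m in ("manual", "mean_psd", "histogram"):
                v = base + rng.normal(0, 0.1)
                if m == skewed_method and g == "PCD":
                    v = mu - 1.5 + rng.exponential(1.5) ** 2  # visibly skewed
                rows.append((subject, g, rec, m, max(v, 0.5)))
    return cohort_frame(rows)


class TestBuildReport:
    def test_medians_differences_and_counts(self, rng):
        table = synthetic_cohort_table(rng)
        report = build_report(table)
        assert report.observation_points == 65
        assert report.recording_counts == {"PCD": 40, "HC": 25}
        for m in report.methods.values():
            assert m.median_difference == pytest.approx(
                m.medians["HC"] - m.medians["PCD"]
            )
            assert m.medians["HC"] > m.medians["PCD"]

    def test_report_is_invariant_to_row_order(self, rng):
        table = synthetic_cohort_table(rng)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = build_report(table)
        b = build_report(shuffled)
        for m in a.methods:
            assert a.methods[m].medians == b.methods[m].medians
            assert a.methods[m].iqrs == b.methods[m].iqrs
            # p-values agree up to float summation order
            assert a.methods[m].test.p_value == pytest.approx(
                b.methods[m].test.p_value, rel=1e-9
            )

    def test_skewed_method_routes_nonparametric_others_parametric(self):
        rng = np.random.default_rng(2024)
        table = synthetic_cohort_table(rng, skewed_method="histogram")
        report = build_report(table)
        assert report.methods["histogram"].test.test == "wilcoxon_one_sample"
        assert report.methods["manual"].test.test == "welch_t"
        assert report.methods["mean_psd"].test.test == "welch_t"
        assert report.methods["histogram"].correlation_type == "spearman"
        assert report.methods["mean_psd"].correlation_type == "pearson"

    def test_iqr_uses_inclusive_linear_interpolation(self, rng):
        table = synthetic_cohort_table(rng)
        report = build_report(table)
        v = table.query("method == 'manual' and group == 'HC'")["cbf_hz"].to_numpy()
        q1, q3 = np.percentile(v, [25, 75], method="linear")
        assert report.methods["manual"].iqrs["HC"] == pytest.approx(q3 - q1)
        assert "linear interpolation" in report.quartile_rule

    def test_missing_group_is_rejected(self):
        table = cohort_frame([("s1", "PCD", "r1", "manual", 9.0)])
        with pytest.raises(ValueError, match="no rows for group"):
            build_report(table)

    def test_duplicate_rows_are_rejected(self):
        table = cohort_frame(
            [("s1", "PCD", "r1", "manual", 9.0), ("s1", "PCD", "r1", "manual", 9.5),
             ("s2", "HC", "r2", "manual", 11.0)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            build_report(table)

    def test_constant_valued_groups_degrade_gracefully(self):
        # medians and differences stay exact even when no test is computable
        rows = [("s1", "PCD", f"r{i}", "manual", 9.2) for i in range(10)]
        rows += [("s2", "HC", f"q{i}", "manual", 11.1) for i in range(5)]
        report = build_report(cohort_frame(rows))
        m = report.methods["manual"]
        assert m.medians == {"PCD": 9.2, "HC": 11.1}
        assert m.median_difference == pytest.approx(1.9)
        assert m.normality == {"PCD": None, "HC": None}
        assert m.test is not None  # Wilcoxon still runs against the HC median
        assert m.test.test == "wilcoxon_one_sample"
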