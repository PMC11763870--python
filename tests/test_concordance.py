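import itertools
import math

import numpy as np
import pytest
from scipy import stats

from umprofiler.concordance import (
    AgreementResult,
    ConcordanceTable,
    KappaBand,
    agreement,
    bland_altman,
    coverage_stats,
    linear_fit,
    percent_concordance,
    rout_outliers,
    validation_concordance,
)


class TestCoverageStats:
    def test_uniform_depth(self):
        recs = coverage_stats({"P1": [100, 100, 100]}, [200, 200, 200])
        assert recs[0].mean_depth == pytest.approx(100.0)
        assert recs[0].uniformity_pct == pytest.approx(100.0)
        assert recs[0].total_reads == 300

    def test_low_amplicon_fails_point2x_rule(self):
        # one amplicon at 10x against mean ~100x: 10 < 0.2 * mean
        reads = [100] * 9 + [10]
        recs = coverage_stats({"P1": reads}, [100] * 10)
        assert recs[0].uniformity_pct == pytest.approx(90.0)

    def test_reads_vs_depth_correlation_on_cohort(self, rng):
        per_patient = {}
        for i in range(44):
            scale = rng.uniform(0.5, 2.0)
            per_patient[f"P{i}"] = (scale * rng.poisson(500, size=50)).astype(int).tolist()
        recs = coverage_stats(per_patient, [150] * 50)
        r = np.corrcoef([r.total_reads for r in recs], [r.mean_depth for r in recs])[0, 1]
        assert r > 0.99  # depth is reads-per-base: near-perfect linearity by construction

    def test_zero_target_length_rejected(self):
        with pytest.raises(ValueError):
            coverage_stats({"P1": [1]}, [0])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="amplicon counts"):
            coverage_stats({"P1": [1, 2]}, [100])


class TestRoutOutliers:
    def test_clean_data_no_outliers(self):
        assert rout_outliers([10, 11, 9, 10, 12, 10, 11], 1.0) == set()

    def test_single_gross_outlier(self):
        # oracle: robust residual 990/1.4826 on t(6) has a two-sided tail
        # probability of 7.6e-16, far below the Q=1% BH threshold 0.01/7
        values = [10, 11, 9, 10, 12, 10, 1000]
        med = np.median(values)
        rsdr = stats.median_abs_deviation(values, scale="normal")
        p = 2 * stats.t.sf(abs(1000 - med) / rsdr, df=6)
        assert p < 0.01 / 7
        assert rout_outliers(values, 1.0) == {6}

    def test_identical_values_zero_spread(self):
        assert rout_outliers([5.0] * 10, 1.0) == set()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            rout_outliers([1, 2], 1.0)

    def test_q_to_zero_no_detections_on_gaussian(self, rng):
        """On clean Gaussian cohorts a tiny Q yields <= 1% false positives."""
        flagged = 0
        for _ in range(100):
            x = rng.normal(100, 10, size=44)
            flagged += bool(rout_outliers(x, 0.01))
        assert flagged <= 1

    def test_two_outliers_both_found(self):
        values = [10.0, 11, 9, 10, 12, 10, 11, 9.5, 500, -400]
        assert rout_outliers(values, 1.0) == {8, 9}


class TestLinearFit:
    def test_perfect_fit(self):
        slope, intercept, r, p = linear_fit([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0)

    def test_anticorrelation(self):
        _, _, r, _ = linear_fit([1, 2, 3], [-1, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 10, 50)
        y = 3 * x + 1 + rng.normal(0, 0.5, 50)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        slope, intercept, r, p = linear_fit(x, y)
        assert slope == pytest.approx(beta[0], abs=1e-9)
        assert intercept == pytest.approx(beta[1], abs=1e-9)
        assert 0 <= p < 1e-6

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([1, 1, 1], [1, 2, 3])


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([(50, 50), (60, 60), (70, 70)])
        assert res.mean_diff == 0 == res.loa_low == res.loa_high

    def test_hand_computed_example(self):
        # diffs {10, 0, -10}: mean 0, sample SD exactly 10
        res = bland_altman([(50, 40), (60, 60), (40, 50)])
        assert res.mean_diff == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(10.0)
        assert res.loa_low == pytest.approx(-19.6)
        assert res.loa_high == pytest.approx(19.6)

    def test_limits_bracket_95pct_on_large_n(self, rng):
        a = rng.uniform(10, 90, 5000)
        b = a + rng.normal(1.0, 3.0, 5000)
        res = bland_altman(list(zip(a, b)))
        diffs = a - b
        frac = np.mean((diffs >= res.loa_low) & (diffs <= res.loa_high))
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_negation_swaps_limits(self, rng):
        pairs = [(x, y) for x, y in zip(rng.uniform(0, 100, 20), rng.uniform(0, 100, 20))]
        res = bland_altman(pairs)
        neg = bland_altman([(y, x) for x, y in pairs])
        assert neg.mean_diff == pytest.approx(-res.mean_diff)
        assert neg.loa_low == pytest.approx(-res.loa_high)
        assert neg.loa_high == pytest.approx(-res.loa_low)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([(1, 2)])


def brute_force_kappa(a, b, c, d):
    """Independent oracle: expand the table into label vectors and use
    scikit-learn's chance-corrected agreement."""
    from sklearn.metrics import cohen_kappa_score

    ya = [1] * a + [1] * b + [0] * c + [0] * d
    yb = [1] * a + [0] * b + [1] * c + [0] * d
    return cohen_kappa_score(ya, yb)


class TestAgreement:
    def test_printed_2x2(self):
        res = agreement(ConcordanceTable(8, 0, 0, 1))
        assert res.kappa == pytest.approx(1.0)
        assert res.sensitivity == pytest.approx(100.0)
        assert res.specificity == pytest.approx(100.0)
        assert res.sensitivity_a_ref == pytest.approx(100.0)
        assert res.specificity_a_ref == pytest.approx(100.0)
        assert res.kappa_band is KappaBand.STRONG

    def test_chance_agreement(self):
        assert agreement(ConcordanceTable(5, 5, 5, 5)).kappa == pytest.approx(0.0)

    def test_hand_computed_kappa(self):
        # po = 0.6, pe = 0.54, kappa = 0.06/0.46 = 3/23
        res = agreement(ConcordanceTable(45, 15, 25, 15))
        assert res.kappa == pytest.approx(3 / 23)
        assert res.kappa_band is KappaBand.WEAK

    @pytest.mark.parametrize(
        "kappa,band",
        [(0.39, KappaBand.WEAK), (0.4, KappaBand.MODERATE), (0.8, KappaBand.MODERATE)],
    )
    def test_band_boundaries(self, kappa, band):
        from umprofiler.concordance import _kappa_band

        assert _kappa_band(kappa) is band

    def test_empty_reference_class_undefined(self):
        res = agreement(ConcordanceTable(3, 0, 2, 0))  # B never negative
        assert res.specificity is None
        assert res.sensitivity == pytest.approx(60.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            agreement(ConcordanceTable(0, 0, 0, 0))

    def test_exhaustive_vs_brute_force(self):
        """All 2401 tables with cells <= 6 match the independent oracle."""
        checked = 0
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if a + b + c + d == 0:
                continue
            res = agreement(ConcordanceTable(a, b, c, d))
            oracle = brute_force_kappa(a, b, c, d)
            if math.isnan(oracle):
                # degenerate margins: our convention is kappa = 1 when
                # expected agreement is already 1
                assert res.kappa == 1.0
            else:
                assert res.kappa == pytest.approx(oracle, abs=1e-12)
            checked += 1
        assert checked == 7**4 - 1

    def test_kappa_one_iff_no_discordance(self):
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if a == 0 or d == 0:
                continue  # need both classes present
            res = agreement(ConcordanceTable(a, b, c, d))
            assert (res.kappa == pytest.approx(1.0)) == (b == 0 and c == 0)


class TestValidationConcordance:
    def test_sanger_11_loci(self):
        assert validation_concordance({"L1"}, set(), 11) == 91.0

    def test_giab_truncation(self):
        assert validation_concordance({"rs10921611"}, set(), 104, decimals=2, truncate=True) == 99.03

    def test_identical_sets(self):
        assert validation_concordance({"a", "b"}, {"a", "b"}, 10) == 100.0

    def test_zero_universe_rejected(self):
        with pytest.raises(ValueError):
            validation_concordance(set(), set(), 0)

    def test_truncation_vs_rounding(self):
        assert percent_concordance(103, 104, 2, truncate=True) == 99.03
        assert percent_concordance(103, 104, 2, truncate=False) == 99.04
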