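"""Major-axis slopes, small-sample inference, and the isometry test."""

import numpy as np
import pytest

import leggrowth as lg
from leggrowth.allometry import (
    DegenerateDataError,
    SingularCovarianceError,
    _ma_slope_test_full,
)


def _bivariate(rng, n=60, slope=1.0, noise=0.3):
    x = rng.normal(0, 1, n)
    return x + rng.normal(0, noise, n), slope * x + rng.normal(0, noise, n)


class TestMASlope:
    def test_identity_line(self, rng):
        x = rng.normal(0, 1, 30)
        assert lg.ma_slope(x, x) == pytest.approx(1.0)

    def test_noise_free_doubling(self, rng):
        x = rng.normal(0, 1, 30)
        assert lg.ma_slope(x, 2 * x) == pytest.approx(2.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(200):
            x, y = _bivariate(rng, slope=rng.uniform(0.3, 3.0))
            S = np.cov(x, y, ddof=1)
            vals, vecs = np.linalg.eigh(S)
            v = vecs[:, np.argmax(vals)]
            assert lg.ma_slope(x, y) == pytest.approx(v[1] / v[0], abs=1e-10)

    def test_reciprocality(self, rng):
        x, y = _bivariate(rng, slope=1.7)
        assert lg.ma_slope(x, y) * lg.ma_slope(y, x) == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_sample_rejected(self):
        x = np.array([1.0, -1.0, 0.0, 0.0])
        y = np.array([0.0, 0.0, 1.0, -1.0])
        with pytest.raises(DegenerateDataError):
            lg.ma_slope(x, y)


class TestMASlopeTest:
    def test_collinear_on_null_returns_one(self, rng):
        x = rng.normal(0, 1, 20)
        p, collinear = _ma_slope_test_full(x, x, 1.0)
        assert p == 1.0 and collinear

    def test_size_close_to_nominal(self, rng):
        """Under a true slope of 1, the rotated-scores t-test is exact,
        so its rejection rate sits at the nominal level."""
        rej = sum(
            lg.ma_slope_test(*_bivariate(rng, n=50), 1.0) < 0.05 for _ in range(2000)
        )
        assert 0.03 <= rej / 2000 <= 0.07

    def test_power_against_steeper_slope(self, rng):
        rej = 0
        for _ in range(100):
            x = rng.normal(0, 1, 200)
            y = 1.5 * x + rng.normal(0, 0.3, 200)
            xo = x + rng.normal(0, 0.3, 200)
            rej += lg.ma_slope_test(xo, y, 1.0) < 0.05
        assert rej / 100 > 0.99

    def test_shift_invariance_exact(self, rng):
        """Multiplying raw volumes by constants shifts logs; slopes and
        p-values are unchanged."""
        x, y = _bivariate(rng, slope=1.3)
        assert lg.ma_slope(x + 5.0, y - 2.0) == pytest.approx(
            lg.ma_slope(x, y), rel=1e-12
        )
        assert lg.ma_slope_test(x + 5.0, y - 2.0, 1.0) == pytest.approx(
            lg.ma_slope_test(x, y, 1.0), rel=1e-9
        )

    def test_log_base_invariance(self, rng):
        x, y = _bivariate(rng, slope=0.8)
        scale = 1.0 / np.log(10.0)
        assert lg.ma_slope(scale * x, scale * y) == pytest.approx(
            lg.ma_slope(x, y), abs=1e-12
        )
        assert lg.ma_slope_test(scale * x, scale * y, 1.0) == pytest.approx(
            lg.ma_slope_test(x, y, 1.0), abs=1e-12
        )


class TestMASlopeCI:
    def test_contains_point_estimate(self, rng):
        x, y = _bivariate(rng, slope=1.2)
        lo, hi = lg.ma_slope_ci(x, y)
        assert lo <= lg.ma_slope(x, y) <= hi

    def test_inverts_slope_test(self, rng):
        """b0 is inside the 95% CI exactly when its test p-value
        exceeds 0.05."""
        for _ in range(20):
            x, y = _bivariate(rng, n=40, slope=rng.uniform(0.5, 2.0))
            lo, hi = lg.ma_slope_ci(x, y, 0.95)
            for b0 in np.linspace(lo - 0.5, hi + 0.5, 41):
                p = lg.ma_slope_test(x, y, b0)
                inside = lo <= b0 <= hi
                if abs(p - 0.05) > 1e-6:
                    assert inside == (p > 0.05)

    def test_width_shrinks_with_n(self, rng):
        x1, y1 = _bivariate(rng, n=100, slope=1.0)
        x2, y2 = _bivariate(rng, n=10_000, slope=1.0)
        w1 = np.diff(lg.ma_slope_ci(x1, y1))[0]
        w2 = np.diff(lg.ma_slope_ci(x2, y2))[0]
        assert w2 < w1

    def test_unbounded_interval_flagged(self, rng):
        # nearly isotropic cloud at tiny n: orientation unidentified
        x = rng.normal(0, 1, 6)
        y = rng.normal(0, 1, 6)
        lo, hi = lg.ma_slope_ci(x, y)
        fit = lg.ma_fit(x, y)
        assert fit.ci_unbounded == (not np.isfinite(lo))


class TestPairwiseSlopes:
    def test_forty_five_pairs_in_canonical_order(self, calibrated_cohort):
        logv = lg.log_volume_matrix(calibrated_cohort)
        fits = lg.pairwise_slopes(logv)
        assert len(fits) == 45
        assert fits[0].pair == ("LG", "MG") and fits[-1].pair == ("FDL", "FHL")

    def test_identical_columns_all_unit_slopes(self, rng):
        col = rng.normal(0, 1, 50)
        logv = np.tile(col[:, None], (1, 10))
        fits = lg.pairwise_slopes(logv)
        assert all(f.slope == pytest.approx(1.0) for f in fits)

    def test_holm_adjustment_monotone(self, calibrated_cohort):
        logv = lg.log_volume_matrix(calibrated_cohort)
        table = lg.pairwise_table(lg.pairwise_slopes(logv))
        assert (table["p_slope1_holm"] >= table["p_slope1"] - 1e-15).all()


class TestIsometryTest:
    def test_exact_isometric_axis_gives_zero_statistic(self, rng):
        """Data whose sample covariance has the isometric direction as
        an exact leading eigenvector produce X² = 0, p = 1."""
        n, p = 80, 10
        c = np.ones(p) / np.sqrt(p)
        target = 0.5 * np.outer(c, c) + 0.01 * (np.eye(p) - np.outer(c, c))
        z = rng.normal(size=(n, p))
        z -= z.mean(axis=0)
        S_emp = np.cov(z, rowvar=False, ddof=1)
        # whiten empirically, then color: sample covariance is exactly target
        w = np.linalg.cholesky(np.linalg.inv(S_emp))
        x = z @ w @ np.linalg.cholesky(target).T
        res = lg.isometry_test(x, calibration="chi2")
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            lg.isometry_test(rng.normal(size=(11, 10)))

    def test_singular_covariance_names_collinear_columns(self, rng):
        x = rng.normal(size=(40, 10))
        x[:, 3] = x[:, 7]  # TA duplicated into POP
        with pytest.raises(SingularCovarianceError, match="TA"):
            lg.isometry_test(x, calibration="chi2")

    def test_eigenvalue_multiplicity_flagged(self, rng):
        # color to an exactly spherical sample covariance: the leading
        # eigenvalue is tied and the eigenvector test is unreliable
        z = rng.normal(size=(200, 10))
        z -= z.mean(axis=0)
        w = np.linalg.cholesky(np.linalg.inv(np.cov(z, rowvar=False, ddof=1)))
        res = lg.isometry_test(z @ w, calibration="chi2")
        assert res.eigen_multiplicity_flag

    def test_bootstrap_and_chi2_agree_on_strong_signal(self, calibrated_cohort):
        boys = calibrated_cohort.query("sex == 'boy'")
        logv = lg.log_volume_matrix(boys)
        boot = lg.isometry_test(logv, calibration="bootstrap", n_boot=199, seed=0)
        assert boot.p_chi2 < 1e-6
        assert boot.p_value == pytest.approx(1 / 200)


class TestRunStratified:
    def test_single_sex_cohort_skips_other(self, calibrated_spec):
        df = lg.simulate_cohort(calibrated_spec, {"boy": lg.GROUP_N["boy"]}, seed=5)
        res = lg.run_stratified(df, calibration="chi2")
        assert res["girl"] is None and res["boy"] is not None

    def test_row_order_invariance(self, calibrated_cohort, rng):
        shuffled = calibrated_cohort.sample(frac=1.0, random_state=9)
        a = lg.run_stratified(calibrated_cohort, calibration="chi2")
        b = lg.run_stratified(shuffled, calibration="chi2")
        for sex in lg.SEXES:
            assert a[sex].statistic == pytest.approx(b[sex].statistic, rel=1e-12)

    def test_min_age_filter_reduces_n(self, calibrated_cohort):
        full = lg.run_stratified(calibrated_cohort, calibration="chi2")
        kids = lg.run_stratified(calibrated_cohort, min_age=5.0, calibration="chi2")
        for sex in lg.SEXES:
            assert kids[sex].n < full[sex].n

    def test_exclusion_flags_respected(self, calibrated_cohort):
        df = calibrated_cohort.copy()
        drop = df.query("sex == 'boy'").index[:3]
        df.loc[drop, "included"] = False
        res = lg.run_stratified(df, calibration="chi2")
        assert res["boy"].n == (calibrated_cohort["sex"] == "boy").sum() - 3
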