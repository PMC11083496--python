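"""Background model, detection filter, quantile normalization, log2."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

import uromir
from uromir.preprocess import (
    FilterThresholds,
    NormExpBackground,
    NormexpParams,
    background_correct,
    detection_filter,
    estimate_normexp_params,
    log2_transform,
    preprocess,
    quantile_normalize,
)


def conditional_mean_by_quadrature(x, mu, sigma, theta):
    """Independent oracle: E[S | X=x] by one-dimensional numerical
    integration of the posterior s * f(s|x) over s in (0, inf).

    The Gaussian factor is written with its constant exp(-d^2/2sigma^2)
    divided out of the ratio (it cancels between numerator and denominator),
    so the oracle stays finite even when x sits hundreds of background SDs
    below mu.  The surviving integrand peaks at max(0, d - sigma^2/theta)
    with width ~sigma; fifteen sigmas either side bound it."""
    d = x - mu
    shifted_peak = max(0.0, d - sigma**2 / theta)

    def weight(s):
        expo = -s / theta + d * s / sigma**2 - s * s / (2 * sigma**2)
        # second rescaling: keep the maximum of the exponent at 0
        peak_expo = (
            -shifted_peak / theta
            + d * shifted_peak / sigma**2
            - shifted_peak**2 / (2 * sigma**2)
        )
        return np.exp(expo - peak_expo)

    lo = max(0.0, shifted_peak - 15 * sigma)
    hi = shifted_peak + 15 * sigma
    kw = dict(points=[shifted_peak], limit=200, epsabs=0.0, epsrel=1e-12)
    num, _ = integrate.quad(lambda s: s * weight(s), lo, hi, **kw)
    den, _ = integrate.quad(weight, lo, hi, **kw)
    return num / den


class TestBackgroundCorrect:
    def test_agrees_with_quadrature_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            mu = rng.uniform(1, 1000)
            sigma = rng.uniform(0.5, 100)
            theta = rng.uniform(0.5, 2000)
            x = mu + rng.uniform(-3, 5) * sigma
            got = background_correct(x, NormexpParams(mu, sigma, theta))
            want = conditional_mean_by_quadrature(x, mu, sigma, theta)
            assert got == pytest.approx(want, rel=1e-6)

    def test_specific_point_against_oracle(self):
        got = background_correct(120.0, NormexpParams(50.0, 10.0, 100.0))
        want = conditional_mean_by_quadrature(120.0, 50.0, 10.0, 100.0)
        assert got == pytest.approx(want, rel=1e-6)

    def test_vanishing_background_limit(self):
        # sigma -> 0, mu = 0: the observation is (almost) pure signal
        assert background_correct(100.0, NormexpParams(0.0, 1e-9, 500.0)) == pytest.approx(100.0)

    def test_strictly_positive_and_increasing(self):
        params = NormexpParams(50.0, 10.0, 200.0)
        xs = np.array([-500.0, 0.0, 10.0, 50.0, 55.0, 100.0, 1e4])
        vals = background_correct(xs, params)
        assert (vals > 0).all()
        assert (np.diff(vals) > 0).all()

    def test_deep_left_tail_is_finite_and_continuous(self):
        params = NormexpParams(0.0, 1.0, 1.0)
        # monotone and positive across the series switchover at z = -100
        xs = [-95.0, -98.0, -99.0, -99.5, -100.5, -103.0, -110.0]
        vals = [background_correct(x, params) for x in xs]
        assert all(v > 0 for v in vals)
        assert vals == sorted(vals, reverse=True)
        # deep-branch value agrees with the quadrature oracle
        got = background_correct(-110.0, params)
        want = conditional_mean_by_quadrature(-110.0, 0.0, 1.0, 1.0)
        assert got == pytest.approx(want, rel=1e-6)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            background_correct(np.nan, NormexpParams(50.0, 10.0, 200.0))


class TestNormexpEstimation:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        n = 20000
        x = rng.normal(50, 10, n) + rng.exponential(200, n)
        p = estimate_normexp_params(x)
        assert p.mu == pytest.approx(50, rel=0.1)
        assert p.sigma == pytest.approx(10, rel=0.1)
        assert p.theta == pytest.approx(200, rel=0.1)

    def test_location_equivariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(50, 10, 5000) + rng.exponential(200, 5000)
        p = estimate_normexp_params(x)
        q = estimate_normexp_params(x + 137.0)
        assert q.mu - p.mu == pytest.approx(137.0, abs=0.5)
        assert q.sigma == pytest.approx(p.sigma, rel=0.01)
        assert q.theta == pytest.approx(p.theta, rel=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            NormExpBackground(np.full(100, 7.0))
        with pytest.raises(ValueError, match="at least 50"):
            NormExpBackground(np.arange(10.0))
        with pytest.raises(ValueError, match="finite"):
            NormExpBackground(np.r_[np.arange(60.0), np.nan])

    def test_results_object_reports_fit(self):
        rng = np.random.default_rng(5)
        x = rng.normal(30, 5, 2000) + rng.exponential(100, 2000)
        res = NormExpBackground(x).fit()
        assert res.llf == pytest.approx(res.model.loglike(res.params))
        assert "mu" in res.summary()
        # correcting the data it was fitted on keeps everything positive
        assert (res.correct(x) > 0).all()


class TestDetectionFilter:
    THRESH = FilterThresholds(detect_threshold=64.0, detect_fraction=0.5)

    def test_feature_above_cutoff_in_enough_samples_is_retained(self):
        mat = pd.DataFrame(
            [[70.0, 10.0, 80.0, 90.0], [70.0, 10.0, 10.0, 10.0]],
            index=["keep", "drop"],
        )
        assert detection_filter(mat, self.THRESH) == ["keep"]

    def test_boundary_counts_use_ceil_of_fraction(self):
        # 5 samples at fraction 0.5 -> need ceil(2.5) = 3 exceedances
        mat = pd.DataFrame([[70, 70, 70, 10, 10], [70, 70, 10, 10, 10]],
                           index=["keep", "drop"], dtype=float)
        assert detection_filter(mat, self.THRESH) == ["keep"]

    def test_strict_inequality_at_cutoff(self):
        mat = pd.DataFrame([[64.0, 64.0]], index=["f"])
        assert detection_filter(mat, self.THRESH) == []

    def test_order_preserved_and_empty_matrix_rejected(self):
        mat = pd.DataFrame(np.full((3, 2), 100.0), index=["c", "a", "b"])
        assert detection_filter(mat, self.THRESH) == ["c", "a", "b"]
        with pytest.raises(ValueError, match="empty"):
            detection_filter(pd.DataFrame(), self.THRESH)


class TestQuantileNormalize:
    def test_hand_computed_two_column_example(self):
        mat = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]})
        out = quantile_normalize(mat)
        # sorted-row means are (2, 3); both columns become (2, 3) in rank order
        pd.testing.assert_frame_equal(
            out, pd.DataFrame({"s1": [2.0, 3.0], "s2": [2.0, 3.0]})
        )

    def test_rank_order_reversal_respected(self):
        mat = pd.DataFrame({"s1": [2.0, 1.0], "s2": [3.0, 4.0]})
        out = quantile_normalize(mat)
        assert out["s1"].tolist() == [3.0, 2.0]
        assert out["s2"].tolist() == [2.0, 3.0]

    def test_identical_columns_are_a_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0])
        mat = pd.DataFrame({"a": col, "b": col})
        pd.testing.assert_frame_equal(quantile_normalize(mat), mat)

    def test_ties_get_mean_of_reference_span(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(mat)
        ref = np.sort(mat.to_numpy(), axis=0).mean(axis=1)
        assert out["a"].tolist() == [ref[:2].mean(), ref[:2].mean(), ref[2]]

    def test_idempotent_and_column_multisets_identical(self):
        # continuous draws: tie-free within columns, as for real fluorescence
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.exponential(100.0, size=(60, 5)))
        once = quantile_normalize(mat)
        sorted_cols = np.sort(once.to_numpy(), axis=0)
        for j in range(1, 5):
            np.testing.assert_array_equal(sorted_cols[:, j], sorted_cols[:, 0])
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(twice, once)

    def test_single_sample_is_identity_with_warning(self, caplog):
        mat = pd.DataFrame({"only": [1.0, 2.0]})
        with caplog.at_level("WARNING", logger="uromir.preprocess"):
            out = quantile_normalize(mat)
        pd.testing.assert_frame_equal(out, mat)
        assert "single sample" in caplog.text


class TestLog2AndChain:
    def test_log2_floor_rule(self):
        mat = pd.DataFrame({"s": [64.0, 1.0, 0.5]})
        assert log2_transform(mat)["s"].tolist() == [6.0, 0.0, 0.0]
        with pytest.raises(ValueError, match="floor"):
            log2_transform(mat, floor=0.0)

    def test_chain_postconditions(self, small_expr):
        expr, log, _, _ = small_expr
        counts = list(log.stage_counts.values())
        assert counts == sorted(counts, reverse=True)  # non-increasing funnel
        sorted_cols = np.sort(expr.to_numpy(), axis=0)
        for j in range(1, expr.shape[1]):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_no_subthreshold_features_removes_nothing(self):
        cfg = uromir.SimulationConfig(
            n_features=80, n_hc=8, n_sec=4, n_aec=8, n_planted_up=0,
            n_planted_down=0, frac_undetectable=0.0,
            signal_mean_baseline=2000.0, seed=11,
        )
        sig, _, _ = uromir.generate_cohort_signals(cfg)
        _, log = preprocess(sig)
        assert log.n_detected == log.n_input

    def test_undetectable_fraction_is_removed(self):
        cfg = uromir.SimulationConfig(
            n_features=600, n_hc=8, n_sec=4, n_aec=8, n_planted_up=0,
            n_planted_down=0, frac_undetectable=0.3, seed=11,
        )
        sig, _, _ = uromir.generate_cohort_signals(cfg)
        _, log = preprocess(sig)
        removed = 1.0 - log.n_detected / log.n_input
        assert removed == pytest.approx(0.3, abs=0.07)

    def test_all_features_below_threshold_is_a_clear_error(self):
        rng = np.random.default_rng(0)
        sig = pd.DataFrame(
            rng.normal(50, 5, size=(60, 6)).clip(min=0) + rng.exponential(2, size=(60, 6)),
            index=[f"f{i}" for i in range(60)],
        )
        with pytest.raises(ValueError, match="detection filter"):
            preprocess(sig)


@given(st.floats(min_value=-1e3, max_value=1e3), st.floats(min_value=1e-2, max_value=1e3))
def test_background_correct_monotone_property(x, dx):
    """Posterior-mean correction is strictly increasing in the raw value."""
    params = NormexpParams(50.0, 10.0, 200.0)
    assert background_correct(x + dx, params) > background_correct(x, params)
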