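"""Scalar effect-size math: conversions, bias correction, exact CIs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from escimap import (
    TTestEffectSize,
    ci_g,
    correction_factor_j,
    dp_from_t,
    equivalence_test,
    hedges_g,
    inferiority_test,
    ncp_ci,
    ncp_ci_array,
    one_sample_scale,
    pooled_sd,
    se_g_approx,
    two_sample_scale,
)


def bisect_ncp(t, dof, target, tol=1e-8):
    """Independent brute-force bisection oracle on the noncentral-t CDF."""

    def cdf(delta):
        v = sps.nct.cdf(t, dof, delta)
        if not math.isfinite(v):  # scipy NaN in the far tail: reflect
            v = sps.nct.sf(-t, dof, -delta)
        return v if math.isfinite(v) else float(t >= delta)

    lo, hi = t - 20 * math.sqrt(dof) - 10, t + 20 * math.sqrt(dof) + 10
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if cdf(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestPooledSd:
    @pytest.mark.parametrize(
        "n1,s1,n2,s2,expected",
        [
            (3, 2.0, 3, 2.0, 2.0),  # equal SDs pool to themselves
            (10, 1.0, 20, 2.0, math.sqrt((9 * 1 + 19 * 4) / 28)),
            (2, 1.0, 2, 1.0, 1.0),
        ],
    )
    def test_values(self, n1, s1, n2, s2, expected):
        assert pooled_sd(n1, s1, n2, s2) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(n1=1, s1=1, n2=3, s2=1),
        dict(n1=3, s1=0.0, n2=3, s2=1),
        dict(n1=3, s1=1, n2=3, s2=-2.0),
    ])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            pooled_sd(**bad)


class TestDpFromT:
    def test_zero_t(self):
        assert dp_from_t(0.0, 0.37) == 0.0

    def test_two_sample_convenience(self):
        assert dp_from_t(2.0, two_sample_scale(50, 50)) == pytest.approx(0.4)

    def test_one_sample_convenience(self):
        assert dp_from_t(3.0, one_sample_scale(36)) == pytest.approx(0.5)

    def test_nonfinite_t_raises(self):
        with pytest.raises(ValueError):
            dp_from_t(float("nan"), 0.2)

    def test_pooled_sd_route_agrees(self, rng):
        # converting t back to d must match the direct standardized
        # mean difference computed from the raw two-group data
        a = rng.normal(0.0, 1.0, size=40)
        b = rng.normal(0.5, 1.3, size=55)
        t = sps.ttest_ind(b, a, equal_var=True).statistic
        d_direct = (b.mean() - a.mean()) / pooled_sd(
            len(a), a.std(ddof=1), len(b), b.std(ddof=1)
        )
        assert dp_from_t(t, two_sample_scale(len(a), len(b))) == pytest.approx(
            d_direct, rel=1e-10
        )


class TestCorrectionFactor:
    @pytest.mark.parametrize("dof,expected", [(10, 1 - 3 / 39), (2, 1 - 3 / 7)])
    def test_approximation(self, dof, expected):
        assert correction_factor_j(dof) == pytest.approx(expected, abs=1e-6)

    def test_limit(self):
        assert correction_factor_j(10 ** 6) == pytest.approx(1.0, abs=1e-5)

    def test_monotone_increasing(self):
        js = [correction_factor_j(d) for d in range(1, 200)]
        assert all(b > a for a, b in zip(js, js[1:]))

    def test_exact_form_close_to_approximation(self):
        for dof in (5, 10, 30, 100):
            approx = correction_factor_j(dof)
            exact = correction_factor_j(dof, exact=True)
            assert exact == pytest.approx(approx, abs=2e-3)

    def test_invalid_dof(self):
        with pytest.raises(ValueError):
            correction_factor_j(0)


class TestHedgesG:
    @pytest.mark.parametrize("d_p,dof,expected", [
        (0.0, 10, 0.0),
        (1.0, 10, 1 - 3 / 39),
        (-0.5, 2, -0.5 * (1 - 3 / 7)),
    ])
    def test_values(self, d_p, dof, expected):
        assert hedges_g(d_p, dof) == pytest.approx(expected, abs=1e-6)

    def test_shrinkage(self):
        for d_p in (-2.0, -0.3, 0.7, 4.0):
            for dof in (2, 10, 50):
                g = hedges_g(d_p, dof)
                assert abs(g) < abs(d_p)
                assert math.copysign(1, g) == math.copysign(1, d_p)
                assert g / d_p == pytest.approx(correction_factor_j(dof))


class TestSeApprox:
    def test_values(self):
        assert se_g_approx(0.0, 2, 2) == pytest.approx(1.0)
        assert se_g_approx(0.5, 50, 50) == pytest.approx(
            math.sqrt(100 / 2500 + 0.25 / 196), abs=1e-9
        )

    def test_symmetric_reduction(self):
        for n in (5, 20, 80):
            assert se_g_approx(0.0, n, n) == pytest.approx(math.sqrt(2 / n))


class TestNcpCi:
    def test_central_symmetry(self):
        iv = ncp_ci(0.0, 30, 0.90)
        assert iv.delta_lower == pytest.approx(-iv.delta_upper, abs=1e-8)

    def test_defining_property(self):
        iv = ncp_ci(2.0, 40, 0.90)
        assert sps.nct.cdf(2.0, 40, iv.delta_lower) == pytest.approx(0.95, abs=1e-6)
        assert sps.nct.cdf(2.0, 40, iv.delta_upper) == pytest.approx(0.05, abs=1e-6)

    @pytest.mark.parametrize("t", [-3.0, 0.0, 3.0, 5.0])
    @pytest.mark.parametrize("dof", [5, 60])
    def test_matches_bisection_oracle(self, t, dof):
        iv = ncp_ci(t, dof, 0.95)
        assert iv.delta_lower == pytest.approx(
            bisect_ncp(t, dof, 0.975), abs=1e-4)
        assert iv.delta_upper == pytest.approx(
            bisect_ncp(t, dof, 0.025), abs=1e-4)

    def test_contains_t(self):
        for t in (-2.0, 0.5, 4.0):
            iv = ncp_ci(t, 25, 0.90)
            assert iv.delta_lower <= t <= iv.delta_upper

    def test_monotone_in_t(self):
        ts = np.linspace(-2, 4, 9)
        lows, highs = ncp_ci_array(ts, 40, 0.90)
        assert (np.diff(lows) > 0).all()
        assert (np.diff(highs) > 0).all()

    def test_nesting(self):
        narrow = ncp_ci(2.5, 60, 0.90)
        wide = ncp_ci(2.5, 60, 0.999)
        assert wide.delta_lower < narrow.delta_lower
        assert narrow.delta_upper < wide.delta_upper

    def test_array_matches_scalar(self):
        ts = np.array([-1.0, 0.0, 2.2, 4.7])
        lo, hi = ncp_ci_array(ts, 35, 0.95)
        for i, t in enumerate(ts):
            iv = ncp_ci(float(t), 35, 0.95)
            assert lo[i] == pytest.approx(iv.delta_lower, abs=1e-6)
            assert hi[i] == pytest.approx(iv.delta_upper, abs=1e-6)

    def test_array_propagates_nan(self):
        lo, hi = ncp_ci_array(np.array([np.nan, 1.0]), 30, 0.90)
        assert np.isnan(lo[0]) and np.isnan(hi[0])
        assert np.isfinite(lo[1]) and np.isfinite(hi[1])

    def test_invalid_confidence(self):
        with pytest.raises(ValueError):
            ncp_ci(1.0, 10, 1.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        t=st.floats(-5, 5),
        dof=st.integers(2, 300),
        confidence=st.floats(0.5, 0.995),
    )
    def test_plugback_property(self, t, dof, confidence):
        iv = ncp_ci(t, dof, confidence)
        alpha = 1 - confidence
        assert iv.delta_lower <= t <= iv.delta_upper
        assert sps.nct.cdf(t, dof, iv.delta_lower) == pytest.approx(
            1 - alpha / 2, abs=1e-6)
        assert sps.nct.cdf(t, dof, iv.delta_upper) == pytest.approx(
            alpha / 2, abs=1e-6)


class TestCiG:
    def test_symmetric_about_zero(self):
        est = ci_g(0.0, 40, 0.2, 0.90)
        assert est.ci_lower == pytest.approx(-est.ci_upper, abs=1e-8)
        assert est.g == 0.0

    def test_limits_are_scaled_ncp_limits(self):
        scale = two_sample_scale(50, 50)
        est = ci_g(3.0, 98, scale, 0.90)
        iv = ncp_ci(3.0, 98, 0.90)
        assert est.ci_lower == pytest.approx(iv.delta_lower * scale)
        assert est.ci_upper == pytest.approx(iv.delta_upper * scale)

    def test_one_sample_scaling(self):
        # one-sample n=25: CI limits are the ncp limits times sqrt(1/25)
        for t in (0.7, 2.4):
            est = ci_g(t, 24, one_sample_scale(25), 0.90)
            iv = ncp_ci(t, 24, 0.90)
            assert est.ci_lower == pytest.approx(iv.delta_lower * 0.2)
            assert est.ci_upper == pytest.approx(iv.delta_upper * 0.2)

    def test_point_estimate_inside_ci_and_corrected(self):
        est = ci_g(2.0, 30, 0.25, 0.90)
        assert est.ci_lower <= est.d_p <= est.ci_upper
        assert est.g == pytest.approx(est.d_p * correction_factor_j(30))

    @pytest.mark.parametrize("alpha", [0.05, 0.01, 0.001])
    @pytest.mark.parametrize("dof", [10, 40, 98])
    def test_nhst_correspondence(self, alpha, dof):
        # lower bound of the two-sided (1-2a) CI is positive exactly when
        # the one-sided p-value is below a
        for t in (0.5, 1.0, 2.0, 2.5, 3.0, 4.0):
            est = ci_g(t, dof, 0.2, confidence=1 - 2 * alpha)
            p_one_sided = sps.t.sf(t, dof)
            assert (est.ci_lower > 0) == (p_one_sided < alpha)

    def test_coverage_two_sample(self, rng):
        # 10,000 simulated two-group studies with a true standardized
        # difference of 0.5: the 90% CI must cover it ~90% of the time
        n, delta, reps = 50, 0.5, 10_000
        a = rng.normal(0.0, 1.0, size=(reps, n))
        b = rng.normal(delta, 1.0, size=(reps, n))
        t = sps.ttest_ind(b, a, axis=1, equal_var=True).statistic
        scale = two_sample_scale(n, n)
        lo, hi = ncp_ci_array(t, 2 * n - 2, 0.90)
        covered = ((lo * scale <= delta) & (delta <= hi * scale)).mean()
        mc_err = 3 * math.sqrt(0.9 * 0.1 / reps)
        assert covered == pytest.approx(0.90, abs=mc_err)


class TestEquivalenceAndInferiority:
    def make(self, lo, hi):
        return ci_g(0.0, 30, 0.2, 0.90).__class__(
            d_p=(lo + hi) / 2, g=(lo + hi) / 2 * correction_factor_j(30),
            ci_lower=lo, ci_upper=hi, confidence=0.90, dof=30, scale=0.2,
        )

    def test_inferiority(self):
        assert inferiority_test(self.make(0.1, 0.4), 0.5)
        assert not inferiority_test(self.make(0.1, 0.6), 0.5)
        # an upper limit exactly at the bound is not inferior
        assert not inferiority_test(self.make(0.1, 0.5), 0.5)

    def test_equivalence(self):
        assert equivalence_test(self.make(-0.1, 0.1), -0.3, 0.3)
        assert not equivalence_test(self.make(-0.4, 0.1), -0.3, 0.3)
        # boundary contact does not count as strict containment
        assert not equivalence_test(self.make(-0.3, 0.1), -0.3, 0.3)

    def test_reversed_bounds_raise(self):
        with pytest.raises(ValueError):
            equivalence_test(self.make(-0.1, 0.1), 0.3, -0.3)


class TestScalarModel:
    def test_two_sample_shortcut(self):
        est = TTestEffectSize(3.0, n1=50, n2=50).fit(confidence=0.90)
        ref = ci_g(3.0, 98, two_sample_scale(50, 50), 0.90)
        assert est == ref

    def test_one_sample_shortcut(self):
        est = TTestEffectSize(3.0, n=36).fit()
        assert est.d_p == pytest.approx(0.5)
        assert est.dof == 35

    def test_summary_mentions_key_quantities(self):
        text = TTestEffectSize(2.0, 60, scale=0.25).fit().summary()
        assert "Hedges" in text and "90.0% CI" in text

    def test_conflicting_specifications_raise(self):
        with pytest.raises(ValueError):
            TTestEffectSize(1.0, 10, scale=0.2, n=25)
        with pytest.raises(ValueError):
            TTestEffectSize(1.0, n1=10)
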