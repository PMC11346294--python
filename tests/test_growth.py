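"""Forward solution, exact three-point fit, least-squares fit, categorization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from nodulegrowth import (
    GrowthCategory,
    ScanObservation,
    classify_growth,
    vb_fit_exact3,
    vb_fit_ls,
    vb_solve_forward,
)
from nodulegrowth.errors import BlowUpError, DomainError, FitConvergenceError, ParameterError
from nodulegrowth.growth import blow_up_time

from conftest import forward_series, make_series

ALPHA_14 = 0.007027198864042431  # dV/dt = a V^1.4 with V0=100 reaching 400 at t=24


def ode_volumes(v0, alpha, beta, times):
    """Independent oracle: numerically integrate dV/dt = alpha*V**beta."""
    sol = solve_ivp(
        lambda t, v: alpha * v**beta,
        (0.0, max(times)),
        [v0],
        t_eval=times,
        rtol=1e-11,
        atol=1e-12,
        method="DOP853",
    )
    return sol.y[0]


class TestForward:
    def test_exponential_closed_form(self):
        v = vb_solve_forward(100, 0.1, 1.0, [0, 12, 24])
        assert np.allclose(v, [100, 100 * math.e**1.2, 100 * math.e**2.4], rtol=1e-12)

    def test_linear_closed_form(self):
        assert np.allclose(vb_solve_forward(100, 10, 0.0, [0, 12, 24]), [100, 220, 340])

    def test_v0_exact_at_t0(self):
        assert vb_solve_forward(123.4, 0.5, 0.7, [0.0])[0] == 123.4

    @pytest.mark.parametrize("beta", [-1.5, -0.3, 0.4, 0.999999999, 1.0, 1.4, 2.2])
    def test_matches_ode_integration(self, beta):
        v0, c = 100.0, 1.0 - beta
        # alpha chosen so V(24) = 4*V0: no blow-up inside the horizon
        alpha = math.log(4.0) / 24.0 if abs(c) < 1e-9 else v0**c * (4.0**c - 1) / (c * 24.0)
        times = [0.0, 6.0, 12.0, 24.0]
        ours = vb_solve_forward(v0, alpha, beta, times)
        oracle = ode_volumes(v0, alpha, beta, times)
        assert np.allclose(ours, oracle, rtol=1e-6)

    def test_accelerated_value_at_12_months(self):
        # V0=100, beta=1.4, alpha chosen so V(24)=400
        v12 = vb_solve_forward(100, ALPHA_14, 1.4, [12.0])[0]
        assert v12 == pytest.approx(ode_volumes(100, ALPHA_14, 1.4, [0, 12.0])[-1], rel=1e-6)
        assert vb_solve_forward(100, ALPHA_14, 1.4, [24.0])[0] == pytest.approx(400, rel=1e-12)

    def test_blow_up_refused(self):
        t_star = blow_up_time(100, ALPHA_14, 1.4)
        with pytest.raises(BlowUpError) as exc:
            vb_solve_forward(100, ALPHA_14, 1.4, [t_star + 1])
        assert exc.value.t_star == pytest.approx(t_star)

    def test_negative_domain_refused(self):
        # beta < 1 with alpha < 0: solution hits zero in finite time
        with pytest.raises(DomainError):
            vb_solve_forward(100, -10.0, 0.0, [0, 20])

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            vb_solve_forward(-1, 0.1, 1.0, [0])
        with pytest.raises(DomainError):
            vb_solve_forward(100, 0.1, 1.0, [-1])


class TestExact3:
    def test_exponential_identity(self):
        s = forward_series(100, 0.1, 1.0)
        fit = vb_fit_exact3(s.observations)
        assert fit.beta == pytest.approx(1.0, abs=1e-9)
        assert fit.alpha == pytest.approx(0.1, abs=1e-9)

    def test_linear_identity(self):
        s = make_series([0, 12, 24], [100, 220, 340])
        fit = vb_fit_exact3(s.observations)
        assert fit.beta == pytest.approx(0.0, abs=1e-9)
        assert fit.alpha == pytest.approx(10.0, rel=1e-9)

    def test_recovers_known_parameters(self):
        s = forward_series(150, 0.003, 1.4)
        fit = vb_fit_exact3(s.observations)
        assert fit.beta == pytest.approx(1.4, abs=1e-6)
        assert fit.alpha == pytest.approx(0.003, rel=1e-6)
        assert fit.residual < 1e-9
        assert fit.method == "exact3" and fit.converged

    def test_matches_grid_search_oracle(self):
        """Brute-force grid over beta minimising the 3-point consistency
        residual agrees with the root-finder."""
        s = forward_series(150, 0.003, 1.4)
        t, v = s.times, s.volumes
        a1, a2 = np.log(v[1] / v[0]), np.log(v[2] / v[0])
        r = t[1] / t[2]
        grid = np.arange(-5, 5, 1e-4)
        c = 1.0 - grid
        with np.errstate(over="ignore", invalid="ignore"):
            resid = np.abs(np.expm1(c * a1) / np.expm1(c * a2) - r)
        resid[~np.isfinite(resid)] = np.inf
        beta_grid = grid[np.argmin(resid)]
        assert vb_fit_exact3(s.observations).beta == pytest.approx(beta_grid, abs=2e-4)

    def test_round_trip_over_beta_grid(self):
        """Forward-solve then refit recovers (alpha, beta) to 1e-6 across
        beta in [-3, 3], including the beta=1 singular branch."""
        for beta in np.arange(-3.0, 3.0 + 1e-9, 0.1):
            beta = round(float(beta), 10)
            v0 = 120.0
            c = 1.0 - beta
            alpha = math.log(3.0) / 24.0 if abs(c) < 1e-12 else v0**c * (3.0**c - 1) / (c * 24.0)
            fit = vb_fit_exact3(forward_series(v0, alpha, beta).observations)
            assert fit.beta == pytest.approx(beta, abs=1e-6)
            assert fit.alpha == pytest.approx(alpha, rel=1e-6)

    def test_beta_one_exactly_on_singular_branch(self):
        s = forward_series(100, 0.05, 1.0)
        assert vb_fit_exact3(s.observations).beta == 1.0

    def test_unique_root_for_random_increasing_triples(self, rng):
        """f(c) is strictly decreasing with range (0,1): bracketing always
        succeeds and the recovered exponent is unique (matches the truth)."""
        for _ in range(1000):
            beta = rng.uniform(-6, 6)
            v0 = rng.uniform(20, 800)
            fc = rng.uniform(1.1, 6.0)
            t1 = rng.uniform(3, 20)
            t2 = t1 + rng.uniform(2, 20)
            c = 1.0 - beta
            alpha = math.log(fc) / t2 if abs(c) < 1e-12 else v0**c * (fc**c - 1) / (c * t2)
            s = forward_series(v0, alpha, beta, (0.0, t1, t2))
            assert vb_fit_exact3(s.observations).beta == pytest.approx(beta, abs=1e-6)

    def test_non_increasing_raises(self):
        s = make_series([0, 12, 24], [100, 95, 120])
        with pytest.raises(DomainError):
            vb_fit_exact3(s.observations)

    def test_out_of_bracket_raises_not_clamps(self):
        # beta = 12 truth lies outside the default [-10, 10] search range
        beta, v0, c = 12.0, 100.0, -11.0
        alpha = v0**c * (3.0**c - 1) / (c * 24.0)  # V(24) = 3*V0
        s = forward_series(v0, alpha, beta, (0.0, 12.0, 24.0))
        with pytest.raises(FitConvergenceError):
            vb_fit_exact3(s.observations)

    def test_wrong_arity_raises(self):
        with pytest.raises(ParameterError):
            vb_fit_exact3(make_series([0, 12], [1, 2]).observations)


class TestLeastSquares:
    def test_n3_equals_exact(self):
        s = forward_series(100, 0.004, 1.2)
        ls, ex = vb_fit_ls(s.observations), vb_fit_exact3(s.observations)
        assert (ls.alpha, ls.beta, ls.method) == (ex.alpha, ex.beta, "exact3")

    def test_noiseless_five_points(self):
        times = [0.0, 6.0, 12.0, 18.0, 24.0]
        vols = vb_solve_forward(100, 2.0, 0.5, times)
        fit = vb_fit_ls([ScanObservation(t, v) for t, v in zip(times, vols)])
        assert fit.beta == pytest.approx(0.5, abs=1e-6)
        assert fit.alpha == pytest.approx(2.0, rel=1e-6)
        assert fit.converged and fit.method == "least_squares"

    def test_noisy_median_recovery(self, rng):
        """1% multiplicative noise, 500 replicates: median beta-hat within
        0.1 of the truth."""
        times = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
        vols = vb_solve_forward(100, 2.0, 0.5, times)
        betas = []
        for _ in range(500):
            noisy = vols * (1 + rng.uniform(-0.01, 0.01, len(vols)))
            fit = vb_fit_ls([ScanObservation(t, v) for t, v in zip(times, noisy)])
            if fit.converged:
                betas.append(fit.beta)
        assert abs(np.median(betas) - 0.5) < 0.1


class TestClassify:
    @pytest.mark.parametrize(
        "beta,expected",
        [
            (-0.1, GrowthCategory.DECELERATED),
            (-0.0999999, GrowthCategory.LINEAR),
            (0.0, GrowthCategory.LINEAR),
            (0.1, GrowthCategory.LINEAR),
            (0.77, GrowthCategory.SUBEXPONENTIAL),
            (0.9, GrowthCategory.SUBEXPONENTIAL),
            (1.0, GrowthCategory.EXPONENTIAL),
            (1.1, GrowthCategory.EXPONENTIAL),
            (1.1000001, GrowthCategory.ACCELERATED),
            (-5.0, GrowthCategory.DECELERATED),
        ],
    )
    def test_boundaries_upper_inclusive(self, beta, expected):
        assert classify_growth(beta) is expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(allow_nan=False, allow_infinity=False, width=64))
    def test_bins_partition_the_line(self, beta):
        assert classify_growth(beta) in GrowthCategory

    @pytest.mark.parametrize("bad", [math.nan, math.inf, -math.inf])
    def test_non_finite_raises(self, bad):
        with pytest.raises(DomainError):
            classify_growth(bad)
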