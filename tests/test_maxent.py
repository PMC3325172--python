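import numpy as np
import pytest
from scipy.special import digamma

from isilaw import (
    DiscreteRateModel,
    GammaGenerator,
    GammaRateModel,
    ValidationError,
    conditional_entropy,
    duality_check,
    grid_maxent,
    mmi_contrast,
    rate_entropy,
    solve_cmfe,
    solve_mfe,
)
from isilaw.maxent import MaxEntProblem


class TestMfe:
    def test_solution_is_exponential(self):
        sol = solve_mfe(10.0)
        assert sol.family == "exponential"
        assert sol.rate_model.alpha == 1.0
        assert sol.rate_model.rate_hz == 10.0

    def test_compound_tail_exponent_is_two(self):
        from isilaw import compound_params

        sol = solve_mfe(10.0)
        params = compound_params(GammaGenerator(2.0), sol.rate_model)
        assert params.eta == pytest.approx(2.0)

    def test_achieved_entropy(self):
        sol = solve_mfe(10.0)
        assert sol.achieved_H_rate == pytest.approx(1.0 + np.log(0.01), abs=1e-12)

    def test_grid_agrees_with_closed_form(self):
        sol = solve_mfe(10.0)
        grid = grid_maxent(10.0)
        k_exact = sol.rate_model.pdf_per_ms(grid.grid_xi_per_ms)
        dev = np.max(np.abs(grid.grid_density - k_exact)) / k_exact.max()
        assert dev < 1e-4
        assert grid.achieved_R_hz == pytest.approx(10.0, abs=1e-8)


class TestCmfe:
    def test_self_consistency(self):
        gen = GammaGenerator(2.0)
        target = GammaRateModel(alpha=1.91, rate_hz=10.0)
        i_bound = conditional_entropy(gen, target)
        sol = solve_cmfe(10.0, i_bound, gen)
        assert sol.rate_model.alpha == pytest.approx(1.91, abs=1e-8)
        assert sol.achieved_R_hz == pytest.approx(10.0, abs=1e-8)
        assert sol.achieved_I == pytest.approx(i_bound, abs=1e-8)

    def test_loose_bound_reduces_to_mfe(self):
        gen = GammaGenerator(2.0)
        i_at_one = conditional_entropy(gen, GammaRateModel(1.0, 10.0))
        sol = solve_cmfe(10.0, i_at_one + 1.0, gen)
        assert sol.rate_model.alpha == 1.0
        assert sol.family == "exponential"

    def test_cmfe_contains_mfe(self):
        gen = GammaGenerator(2.0)
        i_at_one = conditional_entropy(gen, GammaRateModel(1.0, 10.0))
        sol = solve_cmfe(10.0, i_at_one, gen)
        assert sol.rate_model.alpha == pytest.approx(1.0, abs=1e-9)

    def test_infeasible_bound_rejected(self):
        gen = GammaGenerator(2.0)
        from isilaw import generator_entropy

        floor = generator_entropy(2.0) - np.log(0.01)
        with pytest.raises(ValidationError):
            solve_cmfe(10.0, floor - 0.5, gen)

    def test_digamma_gap_monotone(self):
        # psi(alpha) - log(alpha) rises toward 0: unique root guaranteed
        alphas = np.geomspace(1e-2, 1e5, 200)
        gap = digamma(alphas) - np.log(alphas)
        assert np.all(np.diff(gap) > 0)
        assert gap[-1] < 0


class TestGridMaxent:
    def test_unconstrained_is_uniform(self):
        sol = grid_maxent(None)
        k = sol.grid_density
        assert np.allclose(k, k[0], rtol=1e-9)

    @pytest.mark.parametrize("alpha_star", [1.5, 2.0, 3.0])
    def test_both_constraints_recover_gamma(self, alpha_star):
        gen = GammaGenerator(2.0)
        target = GammaRateModel(alpha=alpha_star, rate_hz=10.0)
        i_bound = conditional_entropy(gen, target)
        sol = grid_maxent(10.0, i_bound, gen)
        k_exact = target.pdf_per_ms(sol.grid_xi_per_ms)
        dev = np.max(np.abs(sol.grid_density - k_exact)) / k_exact.max()
        assert dev < 1e-4
        assert sol.achieved_R_hz == pytest.approx(10.0, abs=1e-8)
        assert sol.achieved_I == pytest.approx(i_bound, abs=1e-8)

    def test_constraints_active_to_tolerance(self):
        gen = GammaGenerator(1.0)
        target = GammaRateModel(alpha=2.0, rate_hz=25.0)
        i_bound = conditional_entropy(gen, target)
        sol = grid_maxent(25.0, i_bound, gen)
        assert sol.achieved_R_hz == pytest.approx(25.0, abs=1e-8)
        assert sol.achieved_I == pytest.approx(i_bound, abs=1e-8)

    def test_local_optimality(self):
        # no feasible perturbation of the discrete solution raises entropy
        gen = GammaGenerator(2.0)
        target = GammaRateModel(alpha=2.0, rate_hz=10.0)
        i_bound = conditional_entropy(gen, target)
        sol = grid_maxent(10.0, i_bound, gen, n_grid=800)
        xi = sol.grid_xi_per_ms
        w = np.empty_like(xi)
        w[1:-1] = 0.5 * (xi[2:] - xi[:-2])
        w[0] = 0.5 * (xi[1] - xi[0])
        w[-1] = 0.5 * (xi[-1] - xi[-2])
        p = sol.grid_density * w

        def entropy(p):
            pos = p > 0
            return -(p[pos] * np.log(p[pos] / w[pos])).sum()

        from isilaw import generator_entropy

        s = generator_entropy(2.0)
        constraints = np.stack([np.ones_like(xi), xi, s - np.log(xi)])
        rng = np.random.default_rng(55)
        h0 = entropy(p)
        for _ in range(10):
            d = rng.normal(size=xi.size)
            # project onto the null space of the constraint rows
            q, _ = np.linalg.qr(constraints.T)
            d = d - q @ (q.T @ d)
            d /= np.max(np.abs(d))
            eps = 1e-4 * p.max()
            p_new = p + eps * d
            if np.any(p_new < 0):
                continue
            assert entropy(p_new) <= h0 + 1e-12


class TestDuality:
    def test_gap_vanishes_for_interior_solution(self):
        gen = GammaGenerator(2.0)
        h_bound = rate_entropy(GammaRateModel(alpha=1.5, rate_hz=10.0))
        verdict = duality_check(10.0, h_bound, gen)
        assert verdict.alpha_primal == pytest.approx(1.5, abs=1e-6)
        assert verdict.gap < 1e-6

    def test_boundary_case_alpha_one(self):
        gen = GammaGenerator(2.0)
        h_bound = rate_entropy(GammaRateModel(alpha=1.0, rate_hz=10.0))
        verdict = duality_check(10.0, h_bound, gen)
        assert verdict.alpha_primal == 1.0
        assert verdict.alpha_dual == 1.0

    def test_slack_bound_reported_without_assertion(self):
        gen = GammaGenerator(2.0)
        h_bound = rate_entropy(GammaRateModel(alpha=1.5, rate_hz=10.0)) + 0.3
        verdict = duality_check(10.0, h_bound, gen)
        assert verdict.alpha_dual == 1.0  # looser than the exponential optimum


class TestMmiContrast:
    def test_binary_mixture_is_exponential(self):
        model = DiscreteRateModel(rates_hz=(2.0, 20.0), weights=(0.5, 0.5))
        result = mmi_contrast(1.0, model, n_spikes=100_000, seed=1)
        assert result.tail_class.verdict == "exponential"

    def test_single_rate_is_exponential_family(self):
        model = DiscreteRateModel(rates_hz=(10.0,), weights=(1.0,))
        result = mmi_contrast(1.0, model, n_spikes=100_000, seed=2)
        assert result.tail_class.cd_semilog > 0.95

    def test_gamma_rates_contrast(self):
        # the same pipeline applied to the compound process: power law
        from isilaw import classify_tail, compute_isis, log_binned_histogram, simulate_superstat

        train = simulate_superstat(100_001, 1.0, GammaRateModel(1.91, 10.0), seed=3)
        hist = log_binned_histogram(compute_isis(train))
        assert classify_tail(hist).verdict == "power_law"


class TestProblemValidation:
    def test_rate_bound_positive(self):
        with pytest.raises(ValidationError):
            MaxEntProblem(R_bound_hz=-1.0)

    def test_entropy_constraint_needs_generator(self):
        with pytest.raises(ValidationError):
            MaxEntProblem(R_bound_hz=10.0, I_bound=3.0)
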