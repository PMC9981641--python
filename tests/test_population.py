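import numpy as np
import pytest

from emabayes.population import (
    GmmHyper,
    PopulationGMM,
    expected_log_pdf,
    expected_log_pdf_grad,
    init_population,
    responsibilities,
    sample_population_mean,
    sample_random_individual,
    update_population,
)


def normal_gamma_posterior(x, hyper: GmmHyper, n_obs: int = 1):
    """Closed-form conjugate posterior for M=1 given point observations x (n, D)."""
    x = np.atleast_2d(x)
    n = len(x)
    xbar = x.mean(axis=0)
    scatter = ((x - xbar) ** 2).sum(axis=0)
    kappa = hyper.mean_scale + n
    m = n * xbar / kappa
    a = hyper.prec_shape + n / 2
    b = hyper.prec_rate + 0.5 * (
        scatter + hyper.mean_scale * n / kappa * xbar**2
    )
    return kappa, m, a, b


class TestInit:
    def test_invariants_hold(self):
        pop = init_population(6, 4)
        assert np.all(pop.alpha > 0) and np.all(pop.kappa > 0)
        assert np.all(pop.a > 0) and np.all(pop.b > 0)
        assert pop.m.shape == (4, 6)
        assert pop.expected_weights == pytest.approx(np.full(4, 0.25))

    def test_single_component_reduces_to_diagonal_gaussian_prior(self):
        pop = init_population(3, 1)
        assert pop.n_components == 1
        assert np.allclose(pop.m, 0.0)

    def test_bad_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            GmmHyper(prior_scale=-1)
        with pytest.raises(ValueError):
            init_population(0, 1)

    def test_prior_predictive_scale_matches_direct_simulation(self):
        # independent oracle: draw the hierarchy directly with scipy
        from scipy.stats import gamma as gamma_dist, norm

        hyper = GmmHyper(prior_scale=10.0)
        pop = init_population(2, 1, hyper)
        draws = sample_random_individual(pop, 8000, seed=0)
        oracle_rng = np.random.default_rng(999)
        lam = gamma_dist.rvs(
            hyper.prec_shape, scale=1 / hyper.prec_rate, size=8000,
            random_state=oracle_rng,
        )
        x = norm.rvs(
            scale=np.sqrt((1 + 1 / hyper.mean_scale) / lam), random_state=oracle_rng
        )
        iqr_got = np.subtract(*np.percentile(draws, [75, 25], axis=0))
        iqr_want = np.subtract(*np.percentile(x, [75, 25]))
        assert np.all(np.abs(iqr_got / iqr_want - 1) < 0.2)


class TestConjugateUpdate:
    def test_single_sample_matches_closed_form(self):
        hyper = GmmHyper()
        pop = init_population(3, 1, hyper)
        x = np.array([[1.0, -2.0, 0.5]])
        new = update_population([x], pop)
        kappa, m, a, b = normal_gamma_posterior(x, hyper)
        assert new.kappa[0] == pytest.approx(kappa, abs=1e-10)
        assert np.allclose(new.m[0], m, atol=1e-10)
        assert np.allclose(new.a[0], a, atol=1e-10)
        assert np.allclose(new.b[0], b, atol=1e-10)
        # posterior mean shrinks from the prior mean (0) toward the sample
        assert np.all(np.abs(new.m[0]) < np.abs(x[0]))
        assert np.all(np.sign(new.m[0]) == np.sign(x[0]))

    def test_multi_participant_point_samples_match_closed_form(self, rng):
        hyper = GmmHyper()
        pop = init_population(2, 1, hyper)
        X = rng.normal(size=(8, 2))
        new = update_population([x[None] for x in X], pop)
        kappa, m, a, b = normal_gamma_posterior(X, hyper)
        assert np.allclose(new.m[0], m, atol=1e-10)
        assert np.allclose(new.b[0], b, atol=1e-10)

    def test_duplicating_sample_sets_leaves_update_unchanged(self, rng):
        # each participant carries total weight 1 regardless of sample count
        pop = init_population(2, 3, rng=rng)
        sets = [rng.normal(size=(5, 2)) + i for i in range(4)]
        doubled = [np.vstack([s, s]) for s in sets]
        p1 = update_population(sets, pop)
        p2 = update_population(doubled, pop)
        assert np.allclose(p1.alpha, p2.alpha)
        assert np.allclose(p1.m, p2.m)
        assert np.allclose(p1.b, p2.b)

    def test_replicated_participant_weight_stays_one(self, rng):
        # a participant with 10x the samples still contributes weight 1
        pop = init_population(1, 1)
        a = rng.normal(size=(3, 1))
        b = rng.normal(size=(3, 1)) + 5
        heavy = update_population([np.tile(a, (10, 1)), b], pop)
        fair = update_population([a, b], pop)
        assert heavy.alpha[0] == pytest.approx(fair.alpha[0])
        assert np.allclose(heavy.m, fair.m, atol=1e-10)


class TestOccam:
    @pytest.mark.parametrize("rep", range(5))
    def test_single_cluster_data_keeps_one_dominant_component(self, rep):
        rng = np.random.default_rng(100 + rep)
        pop = init_population(3, 5, rng=rng)
        sets = [rng.normal(size=(10, 3)) * 0.5 + 1.0 for _ in range(20)]
        for _ in range(40):
            pop = update_population(sets, pop)
        w = np.sort(pop.expected_weights)[::-1]
        assert w[0] >= 0.95
        assert not np.any(w[1:] > 0.05)

    def test_pruning_drops_empty_components(self, rng):
        pop = init_population(2, 5, rng=rng)
        sets = [rng.normal(size=(10, 2)) for _ in range(20)]
        for _ in range(30):
            pop = update_population(sets, pop)
        pruned = pop.prune()
        assert pruned.n_components < 5
        assert np.all(pruned.expected_weights >= 0.0)


class TestExpectedLogPdf:
    def test_symmetric_two_component_midpoint_responsibilities(self):
        pop = init_population(1, 1)
        pop = PopulationGMM(
            alpha=np.array([5.0, 5.0]),
            kappa=np.array([10.0, 10.0]),
            m=np.array([[-2.0], [2.0]]),
            a=np.full((2, 1), 5.0),
            b=np.full((2, 1), 5.0),
            hyper=GmmHyper(),
        )
        r = responsibilities(np.array([[0.0]]), pop)
        assert np.allclose(r, [[0.5, 0.5]])

    def test_tight_single_component_matches_gaussian_logpdf(self):
        from scipy.stats import norm

        prec = 4.0
        big = 1e7
        pop = PopulationGMM(
            alpha=np.array([big]),
            kappa=np.array([big]),
            m=np.array([[1.0, -1.0]]),
            a=np.full((1, 2), big),
            b=np.full((1, 2), big / prec),
            hyper=GmmHyper(),
        )
        x = np.array([0.3, 0.7])
        got = expected_log_pdf(x, pop)
        want = norm.logpdf(x, loc=[1.0, -1.0], scale=1 / np.sqrt(prec)).sum()
        assert got == pytest.approx(want, abs=1e-3)

    def test_decreases_away_from_single_component_mean(self):
        pop = init_population(2, 1)
        base = expected_log_pdf(np.zeros(2), pop)
        vals = [expected_log_pdf(np.array([d, 0.0]), pop) for d in (1.0, 5.0, 20.0)]
        assert base > vals[0] > vals[1] > vals[2]

    def test_gradient_matches_finite_differences(self, rng):
        pop = init_population(3, 4, rng=rng)
        x = rng.normal(size=3)
        _, g = expected_log_pdf_grad(x, pop)
        eps = 1e-6
        for d in range(3):
            xp, xm = x.copy(), x.copy()
            xp[d] += eps
            xm[d] -= eps
            fd = (expected_log_pdf(xp, pop) - expected_log_pdf(xm, pop)) / (2 * eps)
            assert g[d] == pytest.approx(fd, abs=1e-6)


@pytest.fixture(scope="module")
def fitted_pop():
    rng = np.random.default_rng(3)
    pop = init_population(2, 1)
    sets = [rng.normal(size=(20, 2)) * 0.5 + [1.0, -2.0] for _ in range(25)]
    for _ in range(20):
        pop = update_population(sets, pop)
    return pop


class TestPredictiveSamplers:
    def test_random_individual_mean_near_component_mean(self, fitted_pop):
        draws = sample_random_individual(fitted_pop, 4000, seed=1)
        assert np.allclose(draws.mean(axis=0), [1.0, -2.0], atol=0.3)

    def test_population_mean_dispersion_smaller_than_individual(self, fitted_pop):
        ind = sample_random_individual(fitted_pop, 4000, seed=2)
        mean = sample_population_mean(fitted_pop, 4000, seed=2)
        assert np.all(mean.var(axis=0) < ind.var(axis=0))

    def test_fixed_seed_reproducible(self, fitted_pop):
        a = sample_random_individual(fitted_pop, 10, seed=42)
        b = sample_random_individual(fitted_pop, 10, seed=42)
        assert np.array_equal(a, b)
        c = sample_population_mean(fitted_pop, 10, seed=42)
        d = sample_population_mean(fitted_pop, 10, seed=42)
        assert np.array_equal(c, d)

    def test_single_component_mean_draws_center_on_m(self, fitted_pop):
        draws = sample_population_mean(fitted_pop, 4000, seed=3)
        assert np.allclose(draws.mean(axis=0), fitted_pop.m[0], atol=0.05)
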