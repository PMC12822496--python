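"""Mixture estimation: weighted MLEs against closed forms and grid oracles,
EM behaviour, KS main-part diagnostics and model selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import thyromix as tx
from thyromix.errors import (
    DegenerateComponentError,
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
)
from thyromix.mixture import Component, ComponentSpec, MixtureFit, histogram_loglik


def single_family_fit(values, family, npatho=0, **kwargs):
    """Density → init → EM for one candidate component set."""
    specs = tx.default_spec_sets(families=(family,), patho_counts=(npatho,))[0]
    density = tx.estimate_density(values)
    init = tx.initialize_fit(density, values, specs, kwargs.pop("healthy_fraction_init", 0.9))
    return tx.fit_mixture_em(values, init, **kwargs)


class TestWeightedNormalMLE:
    def test_hand_example(self):
        mean, sd = tx.weighted_normal_mle([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(np.sqrt(2.0 / 3.0))  # ML variance 2/3

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000), k=st.integers(2, 19))
    def test_zero_one_weights_equal_subset_mle(self, seed, k):
        rng = np.random.default_rng(seed)
        x = rng.normal(5.0, 2.0, 20)
        w = np.zeros(20)
        w[rng.choice(20, size=k, replace=False)] = 1.0
        sub = x[w == 1]
        mean, sd = tx.weighted_normal_mle(x, w)
        assert mean == pytest.approx(sub.mean())
        assert sd == pytest.approx(sub.std(ddof=0))

    def test_degenerate_cases(self):
        with pytest.raises(Exception):
            tx.weighted_normal_mle([1.0, 2.0], [0.0, 0.0])
        with pytest.raises(DegenerateComponentError):
            tx.weighted_normal_mle([1.0, 2.0], [0.0, 1.0])  # single point, sd 0


class TestWeightedGammaMLE:
    def test_recovers_true_params(self, rng):
        x = rng.gamma(2.0, 1.0, 50000)
        k, r = tx.weighted_gamma_mle(x, np.ones_like(x))
        assert k == pytest.approx(2.0, rel=0.05)
        assert r == pytest.approx(1.0, rel=0.05)

    def test_beats_grid_search_oracle(self, rng):
        """The Newton solution's log-likelihood is at least that of a brute
        force 100x100 parameter grid."""
        x = rng.gamma(2.0, 1.0, 200)
        k, r = tx.weighted_gamma_mle(x, np.ones_like(x))
        ll_hat = stats.gamma.logpdf(x, k, scale=1 / r).sum()
        ks = np.linspace(0.5, 5.0, 100)
        rs = np.linspace(0.2, 3.0, 100)
        grid_ll = stats.gamma.logpdf(
            x[None, None, :], ks[:, None, None], scale=1 / rs[None, :, None]
        ).sum(axis=2)
        assert ll_hat >= grid_ll.max() - 1e-9

    def test_zero_one_weights_equal_subset(self, rng):
        x = rng.gamma(3.0, 2.0, 40)
        w = (rng.random(40) < 0.5).astype(float)
        k_w, r_w = tx.weighted_gamma_mle(x, w)
        k_s, r_s = tx.weighted_gamma_mle(x[w == 1], np.ones(int(w.sum())))
        assert k_w == pytest.approx(k_s)
        assert r_w == pytest.approx(r_s)

    def test_constant_values_capped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            k, r = tx.weighted_gamma_mle(np.full(50, 3.0), np.ones(50))
        assert k == pytest.approx(1e6)
        assert k / r == pytest.approx(3.0)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(DomainError):
            tx.weighted_gamma_mle([1.0, -1.0], [1.0, 1.0])


class TestDensityEstimate:
    def test_gamma_mode_near_closed_form(self, rng):
        x = rng.gamma(2.0, 1.0, 50000)
        dens = tx.estimate_density(x)
        assert dens.mode() == pytest.approx(1.0, abs=0.15)  # mode (k-1)/r = 1

    def test_symmetric_data_symmetric_density(self, rng):
        half = rng.normal(0.0, 1.0, 2000)
        x = np.concatenate([half, -half])  # exactly symmetric about 0
        dens = tx.estimate_density(x)
        assert np.allclose(dens.density, dens.density[::-1], atol=1e-9 * dens.density.max())

    def test_density_integrates_to_one(self, rng):
        x = rng.gamma(3.0, 0.5, 5000)
        dens = tx.estimate_density(x)
        assert np.trapezoid(dens.density, dens.grid) == pytest.approx(1.0, abs=0.01)
        assert (dens.density >= 0).all()

    def test_insufficient_or_degenerate(self):
        with pytest.raises(InsufficientDataError):
            tx.estimate_density(np.arange(10.0))
        with pytest.raises(DegenerateDataError):
            tx.estimate_density(np.full(100, 2.0))


class TestInitialization:
    def test_unimodal_center_at_mode(self, rng):
        x = rng.normal(10.0, 1.5, 5000)
        dens = tx.estimate_density(x)
        init = tx.initialize_fit(dens, x, [ComponentSpec("normal", "healthy")])
        assert init.healthy.params[0] == dens.mode()
        assert init.healthy.params[0] == pytest.approx(10.0, abs=0.5)

    def test_bimodal_center_at_dominant_mode(self, rng):
        x = np.concatenate([rng.normal(0.0, 1.0, 1500), rng.normal(10.0, 1.0, 3500)])
        dens = tx.estimate_density(x)
        specs = [ComponentSpec("normal", "healthy"), ComponentSpec("normal", "patho_low")]
        init = tx.initialize_fit(dens, x, specs, healthy_fraction_init=0.7)
        grid_argmax = dens.grid[int(np.argmax(dens.density))]
        assert init.healthy.params[0] == grid_argmax
        assert init.healthy.params[0] == pytest.approx(10.0, abs=0.5)
        assert init.healthy.weight == pytest.approx(0.7)


class TestEM:
    def test_single_normal_matches_closed_form(self, rng):
        x = rng.normal(3.0, 2.0, 2000)
        fit = single_family_fit(x, "normal")
        mean, sd = fit.healthy.params
        assert mean == pytest.approx(x.mean(), abs=1e-9)
        assert sd == pytest.approx(x.std(ddof=0), abs=1e-9)
        assert fit.converged

    def test_two_separated_normals_weights_recovered(self, rng):
        x = np.concatenate([rng.normal(0, 1, 14000), rng.normal(10, 1, 6000)])
        specs = [ComponentSpec("normal", "healthy"), ComponentSpec("normal", "patho_high")]
        dens = tx.estimate_density(x)
        init = tx.initialize_fit(dens, x, specs, healthy_fraction_init=0.7)
        fit = tx.fit_mixture_em(x, init)
        assert fit.healthy.weight == pytest.approx(0.7, abs=0.02)
        assert fit.healthy.params[0] == pytest.approx(0.0, abs=0.1)

    def test_loglik_trace_nondecreasing(self, rng):
        x = np.concatenate([rng.gamma(3.0, 0.5, 4000), rng.gamma(3.0, 0.5, 400) * 4])
        fit = single_family_fit(x, "gamma", npatho=2)
        trace = np.array(fit.ll_trace)
        assert (np.diff(trace) >= -1e-9 * np.abs(trace[1:])).all()

    def test_weights_sum_to_one(self, rng):
        x = np.concatenate([rng.gamma(3.0, 0.5, 4000), rng.gamma(3.0, 0.5, 400) * 4])
        fit = single_family_fit(x, "gamma", npatho=2)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_scale_equivariance(self, rng):
        x = np.concatenate([rng.gamma(3.3, 0.53, 8000), rng.gamma(3.3, 0.53, 600) * 4])
        c = 7.3
        fit1 = single_family_fit(x, "gamma", npatho=2)
        fit2 = single_family_fit(c * x, "gamma", npatho=2)
        q1 = fit1.healthy.ppf([0.025, 0.975])
        q2 = fit2.healthy.ppf([0.025, 0.975])
        assert np.allclose(q2, c * q1, rtol=1e-3)
        assert np.allclose(sorted(fit1.weights), sorted(fit2.weights), atol=1e-3)
        assert fit2.ks_main_part == pytest.approx(fit1.ks_main_part, abs=1e-3)

    def test_histogram_likelihood_prefers_fitted_model(self, rng):
        """Binned-likelihood cross-check: the raw-value fit scores at least as
        well as a perturbed model on the histogram counts."""
        x = rng.gamma(3.0, 0.5, 10000)
        fit = single_family_fit(x, "gamma")
        k, r = fit.healthy.params
        worse = MixtureFit(
            components=[Component(ComponentSpec("gamma", "healthy"), (k * 1.3, r), 1.0)],
            converged=True,
        )
        assert histogram_loglik(fit, x) > histogram_loglik(worse, x)


class TestKSMainPart:
    def test_consistency_on_correct_model(self, rng):
        x = rng.gamma(3.0, 0.5, 20000)
        fit = single_family_fit(x, "gamma")
        assert 0.0 <= fit.ks_main_part <= 1.0
        assert fit.ks_main_part < 0.02

    def test_misspecified_family_scores_worse(self, rng):
        x = rng.gamma(2.0, 1.0, 20000)  # strongly skewed
        ks_gamma = single_family_fit(x, "gamma").ks_main_part
        ks_normal = single_family_fit(x, "normal").ks_main_part
        assert ks_normal > ks_gamma

    def test_requires_converged_fit(self, rng):
        x = rng.gamma(3.0, 0.5, 1000)
        bad = MixtureFit(
            components=[Component(ComponentSpec("gamma", "healthy"), (3.0, 2.0), 1.0)],
            converged=False,
        )
        with pytest.raises(tx.errors.FitError):
            tx.ks_main_part(bad, x)


class TestModelSelection:
    def test_skewed_data_selects_gamma(self, rng):
        x = rng.gamma(3.3, 1 / 1.88, 20000)
        fit = tx.select_model(x, tx.default_spec_sets())
        assert fit.healthy.spec.family == "gamma"

    def test_symmetric_data_selects_normal(self, rng):
        x = rng.normal(16.35, 2.117, 20000)
        fit = tx.select_model(x, tx.default_spec_sets())
        assert fit.healthy.spec.family == "normal"

    def test_single_candidate_returned(self, rng):
        x = rng.gamma(3.0, 0.5, 2000)
        specs = tx.default_spec_sets(families=("gamma",), patho_counts=(0,))
        fit = tx.select_model(x, specs)
        assert len(fit.components) == 1
        assert fit.healthy.spec.family == "gamma"

    def test_no_candidates_rejected(self, rng):
        with pytest.raises(tx.errors.InvalidParameterError):
            tx.select_model(rng.normal(size=100), [])

    def test_parsimony_on_pure_data(self, rng):
        """With no contamination, the healthy-only candidate is selected over
        the equally-well-fitting contaminated candidates."""
        x = rng.gamma(3.3, 1 / 1.88, 20000)
        fit = tx.select_model(x, tx.default_spec_sets(families=("gamma",)))
        assert len(fit.components) == 1


class TestInitializationRobustness:
    def test_healthy_fraction_init_does_not_move_limits(self, contaminated_cohort_30k):
        """The assumed healthy:pathologic ratio barely matters: inits from
        0.80 to 0.95 move the estimated limits by well under 1%."""
        cohort, _ = contaminated_cohort_30k
        x = cohort.values("TSH", "first")
        limits = []
        for frac in (0.80, 0.85, 0.90, 0.95):
            fit = tx.select_model(
                x, tx.default_spec_sets(families=("gamma",)), healthy_fraction_init=frac
            )
            limits.append(fit.healthy.ppf([0.025, 0.975]))
        limits = np.array(limits)
        spread = (limits.max(axis=0) - limits.min(axis=0)) / limits.mean(axis=0)
        assert (spread < 0.01).all()
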