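"""Posterior sampling, convergence diagnostics, GOF and recovery scoring."""

import arviz as az
import numpy as np
import pandas as pd
import pytest

import stagecast as sc
from stagecast.inference import (
    PosteriorSamples,
    _estimate_rho,
    _species_param_names,
    diagnose,
    posterior_predictive_gof,
    recovery_experiment,
    rhat,
)
from stagecast.synth import DEFAULT_STD


def degenerate_posterior(truth, rho, n_draws=60, jitter=0.0, seed=0):
    """A PosteriorSamples object whose draws all sit at the generating truth
    (optionally jittered) — lets predictive machinery be tested without MCMC."""
    rng = np.random.default_rng(seed)
    vec = np.concatenate(
        [np.concatenate([sp.theta_coefs, sp.phi_coefs, [sp.tau, sp.gamma]]) for sp in truth]
    )
    draws = np.tile(vec, (2, n_draws, 1))
    if jitter:
        draws = draws + rng.normal(0, jitter, draws.shape)
        for i in range(len(truth)):
            draws[:, :, 10 * i + 8 : 10 * i + 10] = np.clip(
                draws[:, :, 10 * i + 8 : 10 * i + 10], 1e-4, 1 - 1e-4
            )
    names = [n for sp in truth for n in _species_param_names(sp.name)]
    return PosteriorSamples(
        species=[sp.name for sp in truth],
        param_names=names,
        draws=draws,
        rho=np.asarray(rho, dtype=float),
        std=DEFAULT_STD,
    )


class TestRhat:
    def test_identical_chains_give_exactly_one(self):
        chain = np.random.default_rng(0).normal(size=500)
        assert rhat(np.stack([chain, chain])) == 1.0

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 800), rng.normal(3, 1, 800)])
        assert rhat(chains) > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))

    def test_agrees_with_arviz_on_dispersed_chains(self):
        """Independent cross-check: the classic Gelman-Rubin estimator and
        arviz's rank-normalized split-R-hat agree for long AR(1) chains."""
        rng = np.random.default_rng(2)
        for shift in (0.0, 0.05, 0.1):
            a = rng.normal(0, 1, 4000)
            b = rng.normal(shift, 1, 4000)
            ours = rhat(np.stack([a, b]))
            theirs = az.rhat(az.convert_to_dataset(np.stack([a, b])[:, :, None]))["x"].values.item()
            assert ours == pytest.approx(theirs, abs=0.02)
        # both estimators flag grossly separated chains
        a = rng.normal(0, 1, 4000)
        b = rng.normal(2, 1, 4000)
        assert rhat(np.stack([a, b])) > 1.1
        assert az.rhat(az.convert_to_dataset(np.stack([a, b])[:, :, None]))["x"].values.item() > 1.1


class TestFitModel:
    def test_reduced_fit_converges(self, fitted):
        """All coefficients reach R-hat < 1.1 on the reduced synthetic design."""
        summ = fitted.summary()
        assert summ["rhat"].max() < 1.1
        assert fitted.flat().shape[0] >= 2100

    def test_posterior_percentiles_ordered(self, fitted):
        summ = fitted.summary()
        assert (summ["q2.5"] <= summ["q97.5"]).all()

    def test_tight_prior_dominates_slopes(self, small_dataset):
        """Shrinking the coefficient prior to SD 0.01 pins the slope
        posteriors at the prior centre (0) regardless of the data."""
        data, _ = small_dataset
        cfg = sc.RunConfig(chains=2, warmup=400, draws=300, target_samples=600,
                           coef_prior_sd=0.01)
        samples = sc.fit_model(data, cfg, seed=3)
        summ = samples.summary()
        slopes = [n for n in samples.param_names if n.endswith((".rain", ".intra", ".inter"))]
        assert np.all(np.abs(summ.loc[slopes, "mean"]) < 0.05)

    def test_rho_fixed_at_pooled_empirical_ratio(self, small_dataset, small_truth):
        data, _ = small_dataset
        rho = _estimate_rho(data)
        true_rho = np.array([sp.rho for sp in small_truth])
        assert np.all(np.abs(rho - true_rho) / true_rho < 0.5)

    def test_too_few_occasions_rejected(self, small_truth):
        rain = sc.make_rainfall(1, seed=0)
        topo = sc.grid_topology(3)
        data, _ = sc.simulate_community(small_truth, topo, 1, rain, seed=0,
                                        r_observed_years=[0])
        with pytest.raises(sc.ValidationError):
            sc.fit_model(data, sc.RunConfig(chains=2, draws=1100, target_samples=2100))

    def test_detection_latent_path_smoke(self):
        """Imperfect detection: discrete latent updates run and produce a
        posterior with latent-consistent support."""
        truth = sc.make_truth(2, effect_scale=0.2, seed=4)
        truth = [sp.with_(detection=(0.8, 0.8, 0.8)) for sp in truth]
        topo = sc.grid_topology(4)
        rain = sc.make_rainfall(6, seed=1)
        data, _ = sc.simulate_community(truth, topo, 6, rain, detection_on=True, seed=2)
        cfg = sc.RunConfig(chains=2, warmup=60, draws=60, target_samples=100,
                           detection_enabled=True, detection_p=0.8)
        samples = sc.fit_model(data, cfg, seed=5)
        summ = samples.summary()
        assert np.isfinite(summ["mean"]).all()
        assert samples.detection == 0.8


class TestDiagnose:
    def test_requires_two_chains(self, fitted):
        single = PosteriorSamples(
            species=fitted.species, param_names=fitted.param_names,
            draws=fitted.draws[:1], rho=fitted.rho, std=fitted.std,
        )
        with pytest.raises(ValueError):
            diagnose(single)

    def test_converged_fit_has_no_flags(self, fitted):
        table = diagnose(fitted)
        assert not table["flagged"].any()
        assert (table["ess_bulk"] > 0).all()

    def test_shifted_chains_are_flagged(self, small_truth):
        post = degenerate_posterior(small_truth, rho=np.ones(3), n_draws=200, jitter=0.01, seed=1)
        post.draws[1, :, 0] += 1.0  # move one chain of one parameter
        table = diagnose(post)
        assert table.iloc[0]["flagged"]
        assert not table.iloc[5]["flagged"]


class TestGof:
    def test_pvalues_calibrated_under_self_simulation(self, fitted, small_dataset):
        """Posterior-predictive checks on data that do come from the model
        yield central Bayesian p-values for the fitted stages (S, A).

        Seedling cells are reported too but lean conservative (p near 1):
        rho is a plug-in ratio estimated from exactly those cells, so the
        observed seedling discrepancy is systematically small.
        """
        data, _ = small_dataset
        table = posterior_predictive_gof(fitted, data, seed=3)
        assert ((table["p_value"] >= 0) & (table["p_value"] <= 1)).all()
        sa = table[table["stage"].isin(["S", "A"])]
        central = ((sa["p_value"] > 0.05) & (sa["p_value"] < 0.95)).mean()
        assert central >= 0.9

    def test_corrupted_adults_detected_as_misfit(self, small_truth, small_dataset):
        data, _ = small_dataset
        rho = _estimate_rho(data)
        post = degenerate_posterior(small_truth, rho=rho, n_draws=150, jitter=0.02, seed=2)
        bad = sc.CountDataset(
            species=data.species, plots=data.plots, years=data.years,
            counts=np.where(np.isnan(data.counts), np.nan, data.counts * 10),
            rainfall=data.rainfall, topology=data.topology,
            standardization=data.standardization,
        )
        table = posterior_predictive_gof(post, bad, seed=3)
        assert (table.loc[table["stage"] == "A", "p_value"] < 0.05).all()


class TestRecovery:
    def test_small_run_structure_and_flags(self):
        cfg = sc.RunConfig(chains=2, warmup=300, draws=250, target_samples=500)
        rep = recovery_experiment(
            design=dict(n_species=2, n_plots=6, n_years=10, first_year=2007),
            n_replicates=2, seed=5, config=cfg,
        )
        assert 0.0 <= rep.coverage <= 1.0
        assert set(rep.table["kind"]) == {"coef", "rate"}
        # 2 replicates x 2 species x 10 parameters
        assert len(rep.table) == 40
        assert rep.table["converged"].dtype == bool

    def test_replicate_count_validated(self):
        with pytest.raises(ValueError):
            recovery_experiment(n_replicates=0)
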