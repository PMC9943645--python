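"""Bayesian fitting of the dynamic multi-species N-mixture model.

The joint model places logit-linear regressions on sapling survival
(theta) and adult survival (phi) — covariates: standardized rainfall,
intra- and interspecific adult densities at the start of each step —
plus constant per-species transition (tau) and gains (gamma)
probabilities.  Seedling production rho is fixed at the empirical
seedlings_{t+1}/adults_t ratio from the years with seedling data.

With perfect detection (the default; plants in fixed plots) the latent
abundances are pinned to the observed counts and the transition
likelihood is evaluated exactly by finite convolution, which makes the
posterior factorize over species; each block is sampled with adaptive
random-walk Metropolis.  Under imperfect detection the discrete latent
abundances are sampled with single-site Metropolis updates.

Priors: Normal(0, 1.5) on all logit-scale coefficients, uniform (Beta(1,1))
on tau and gamma, expressed as a standard-logistic density on their
logit transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import _lik
from ._mcmc import adaptive_metropolis
from .demography import SpeciesParams, Standardization
from .io import CountDataset, RunConfig, ValidationError
from .metapop import build_dispersal_matrix

__all__ = [
    "PosteriorSamples",
    "RecoveryReport",
    "fit_model",
    "diagnose",
    "rhat",
    "posterior_predictive_gof",
    "recovery_experiment",
]

_COEF_LABELS = ["int", "rain", "intra", "inter"]


def _species_param_names(name: str) -> list[str]:
    return (
        [f"{name}.theta.{c}" for c in _COEF_LABELS]
        + [f"{name}.phi.{c}" for c in _COEF_LABELS]
        + [f"{name}.tau", f"{name}.gamma"]
    )


@dataclass
class PosteriorSamples:
    """MCMC draws of all species' parameters plus fit metadata.

    ``draws`` has shape (chains, draws_per_chain, n_params) on the
    reporting scale (tau and gamma as probabilities).  rho is the fixed
    per-species seedling ratio, not a sampled parameter.
    """

    species: list
    param_names: list
    draws: np.ndarray
    rho: np.ndarray
    std: Standardization
    detection: float = 1.0
    accept_rates: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.param_names):
            raise ValueError("draws must have shape (chains, draws, n_params)")
        target = self.meta.get("target_samples")
        if target and self.draws.shape[0] * self.draws.shape[1] < target:
            raise ValueError("retained draws fewer than configured posterior sample count")

    # -- basic accessors -------------------------------------------------
    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def _index(self, name: str) -> int:
        return self.param_names.index(name)

    def to_arviz(self) -> az.InferenceData:
        data = {
            name: self.draws[:, :, k] for k, name in enumerate(self.param_names)
        }
        return az.convert_to_inference_data(data)

    # -- parameter realizations ------------------------------------------
    def _params_from_vector(self, vec: np.ndarray) -> list[SpeciesParams]:
        out = []
        for i, name in enumerate(self.species):
            base = 10 * i
            out.append(
                SpeciesParams(
                    name=name,
                    theta_coefs=vec[base : base + 4],
                    phi_coefs=vec[base + 4 : base + 8],
                    tau=float(vec[base + 8]),
                    gamma=float(vec[base + 9]),
                    rho=float(self.rho[i]),
                )
            )
        return out

    def mean_params(self) -> list[SpeciesParams]:
        """Posterior-mean point parameters (used for default projections)."""
        return self._params_from_vector(self.flat().mean(axis=0))

    def draw_params(self, index: int) -> list[SpeciesParams]:
        return self._params_from_vector(self.flat()[index])

    def sample_param_sets(self, n: int, rng: np.random.Generator) -> list[list[SpeciesParams]]:
        idx = rng.choice(self.flat().shape[0], size=n, replace=n > self.flat().shape[0])
        return [self.draw_params(i) for i in idx]

    # -- summaries -------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        flat = self.flat()
        qs = np.percentile(flat, [2.5, 97.5], axis=0)
        rows = {
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "q2.5": qs[0],
            "q97.5": qs[1],
            "rhat": [rhat(self.draws[:, :, k]) for k in range(flat.shape[1])],
        }
        return pd.DataFrame(rows, index=self.param_names)

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        chains, ndraw, npar = self.draws.shape
        rec = []
        for k, name in enumerate(self.param_names):
            for c in range(chains):
                rec.append(
                    pd.DataFrame(
                        {
                            "parameter": name,
                            "chain": c,
                            "draw": np.arange(ndraw),
                            "value": self.draws[c, :, k],
                        }
                    )
                )
        return pd.concat(rec, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``chains`` has shape (m, n).  The between/within variance ratio is
    floored at 1 so identical chains report exactly 1.0 (values below 1
    are estimator noise).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("rhat needs at least 2 chains")
    n = chains.shape[1]
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(max(1.0, var_plus / W)))


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _estimate_rho(data: CountDataset) -> np.ndarray:
    """Fixed per-species seedling ratio: pooled sum R_{t} / sum A_{t-1}.

    Pooling numerator and denominator over all observed-seedling years
    and plots is the ratio estimator with the smallest variance when
    seedling production is proportional to adults; dispersal conserves
    seeds across plots, so plot sums are unaffected by the topology.
    """
    r_years = data.observed_r_years()
    rho = np.ones(data.n_species)
    for i in range(data.n_species):
        num = den = 0.0
        for t in r_years:
            if t == 0:
                continue
            num += np.nansum(data.counts[i, :, t, 0])
            den += np.nansum(data.counts[i, :, t - 1, 2])
        if den > 0:
            rho[i] = num / den
    return rho


def _prepare_arrays(data: CountDataset, detection_p: float = 1.0, rho=None):
    """Per-species likelihood inputs from an observed dataset."""
    if data.standardization is None:
        raise ValidationError("dataset lacks standardization constants")
    if data.rainfall is None or data.topology is None:
        raise ValidationError("dataset needs rainfall and topology attached")
    std = data.standardization
    K, P, T = data.n_species, data.n_plots, data.n_years
    D = build_dispersal_matrix(data.topology)
    rho = _estimate_rho(data) if rho is None else np.asarray(rho, dtype=float)

    rain = np.array([std.rain(data.rainfall.value(int(y))) for y in data.years])
    adults = data.counts[:, :, :, 2] / detection_p  # (K, P, T), moment-corrected
    S = np.nan_to_num(data.counts[:, :, :, 1]).astype(np.int64)
    A_cnt = np.nan_to_num(data.counts[:, :, :, 2]).astype(np.int64)
    Rv = data.counts[:, :, :, 0]
    r_mask = ~np.isnan(Rv)
    Rv_int = np.nan_to_num(Rv).astype(np.int64)

    # all-zero species contribute nothing to heterospecific sums; warn
    dead = [data.species[i] for i in range(K) if not np.any(adults[i]) and not np.any(S[i])]
    if dead:
        warnings.warn(
            f"species with all-zero counts excluded from interspecific sums: {dead}",
            stacklevel=3,
        )

    per_species = []
    total_adults = adults.sum(axis=0)  # (P, T)
    for i in range(K):
        intra = std.intra(adults[i]).T.copy()       # (T, P)
        inter = std.inter(total_adults - adults[i]).T.copy()
        mu = np.empty((T, P))
        mu[0] = rho[i] * (D @ adults[i, :, 0])
        for t in range(1, T):
            mu[t] = rho[i] * (D @ adults[i, :, t - 1])
        per_species.append(
            dict(
                S=S[i].T.copy(),
                A=A_cnt[i].T.copy(),
                r_obs=r_mask[i].T.copy(),
                R=Rv_int[i].T.copy(),
                rain=rain,
                intra=intra,
                inter=inter,
                mu=mu,
            )
        )
    return per_species, rho, D


def _initial_vector(arr: dict) -> np.ndarray:
    """Empirical-ratio initialization of the unconstrained parameter vector."""
    S, A = arr["S"], arr["A"]
    s_ratio = S[1:].sum() / max(S[:-1].sum(), 1)
    a_ratio = A[1:].sum() / max(A[:-1].sum(), 1)
    x0 = np.zeros(10)
    x0[0] = logit(np.clip(s_ratio, 0.05, 0.95))
    x0[4] = logit(np.clip(a_ratio, 0.05, 0.95))
    x0[8] = logit(0.2)
    x0[9] = logit(0.2)
    return x0


def _make_logpost(arr: dict, coef_sd: float):
    S, A = arr["S"], arr["A"]
    r_obs, R = arr["r_obs"], arr["R"]
    rain, intra, inter, mu = arr["rain"], arr["intra"], arr["inter"], arr["mu"]

    def logpost(x: np.ndarray) -> float:
        th_c, ph_c = x[:4], x[4:8]
        u_tau, u_gamma = x[8], x[9]
        tau = float(expit(u_tau))
        gamma = float(expit(u_gamma))
        lp = -0.5 * np.sum((x[:8] / coef_sd) ** 2)
        # Beta(1,1) on tau/gamma => standard logistic on the logit scale
        for u in (u_tau, u_gamma):
            lp += -u - 2.0 * np.log1p(np.exp(-u))
        ll = _lik.species_loglik(
            th_c, ph_c, tau, gamma, S, A, r_obs, R, rain, intra, inter, mu
        )
        return lp + ll

    return logpost


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_model(data: CountDataset, config: RunConfig, seed: int | None = None) -> PosteriorSamples:
    """Fit the joint model; returns pooled posterior samples for all species.

    With detection fixed at 1 the posterior factorizes exactly over
    species (density covariates are observed), so species blocks are
    sampled independently and concatenated.
    """
    if data.n_years < 2:
        raise ValidationError("need at least 2 survey occasions")
    if seed is None:
        seed = config.seed
    detection_p = config.detection_p if config.detection_enabled else 1.0
    per_species, rho, _ = _prepare_arrays(data, detection_p)

    n_chains, n_warmup, n_draws = config.chains, config.warmup, config.draws
    K = data.n_species
    all_draws = np.empty((n_chains, n_draws, 10 * K))
    accept = np.empty((K, n_chains))
    ss = np.random.SeedSequence([int(seed) % (2**31), 17])
    children = ss.spawn(K)
    for i in range(K):
        arr = per_species[i]
        if detection_p < 1.0:
            draws_i, rates = _fit_species_latent(
                arr, config, children[i], detection_p
            )
        else:
            logpost = _make_logpost(arr, config.coef_prior_sd)
            draws_i, rates = adaptive_metropolis(
                logpost,
                _initial_vector(arr),
                n_chains=n_chains,
                n_warmup=n_warmup,
                n_draws=n_draws,
                seed=children[i],
            )
        # report tau/gamma on the probability scale
        draws_i = draws_i.copy()
        draws_i[:, :, 8] = expit(draws_i[:, :, 8])
        draws_i[:, :, 9] = expit(draws_i[:, :, 9])
        all_draws[:, :, 10 * i : 10 * (i + 1)] = draws_i
        accept[i] = rates

    names = [n for sp in data.species for n in _species_param_names(sp)]
    return PosteriorSamples(
        species=list(data.species),
        param_names=names,
        draws=all_draws,
        rho=rho,
        std=data.standardization,
        detection=detection_p,
        accept_rates=accept,
        meta={
            "seed": int(seed),
            "target_samples": config.target_samples,
            "config_hash": config.hash(),
        },
    )


def _fit_species_latent(arr: dict, config: RunConfig, seed, p: float):
    """Metropolis-within-Gibbs with discrete latent abundance updates.

    Latent sapling/adult abundances (and seedling abundances in observed
    years) are updated one site at a time with +/-1, +/-2 random-walk
    proposals bounded below by the observed counts; parameters move with
    a fixed-scale random-walk block between sweeps.
    """
    S_obs, A_obs = arr["S"], arr["A"]
    r_obs, R_obs = arr["r_obs"], arr["R"]
    rain, intra, inter, mu = arr["rain"], arr["intra"], arr["inter"], arr["mu"]
    T, P = S_obs.shape
    coef_sd = config.coef_prior_sd
    n_chains, n_warmup, n_draws = config.chains, config.warmup, config.draws

    def full_loglik(x, latS, latA, latR):
        th_c, ph_c = x[:4], x[4:8]
        tau, gamma = float(expit(x[8])), float(expit(x[9]))
        lp = -0.5 * np.sum((x[:8] / coef_sd) ** 2)
        for u in (x[8], x[9]):
            lp += -u - 2.0 * np.log1p(np.exp(-u))
        ll = _lik.species_loglik(
            th_c, ph_c, tau, gamma, latS, latA, r_obs, latR, rain, intra, inter, mu
        )
        full_mask = np.ones_like(r_obs)
        ll += _lik.observation_loglik(latS, S_obs, full_mask, p)
        ll += _lik.observation_loglik(latA, A_obs, full_mask, p)
        ll += _lik.observation_loglik(latR, R_obs, r_obs, p)
        # Poisson prior on latent seedlings in observed years
        for t in range(T):
            for j in range(P):
                if r_obs[t, j]:
                    ll += _lik._log_poispmf(latR[t, j], mu[t, j])
        return lp + ll

    draws = np.empty((n_chains, n_draws, 10))
    rates = np.empty(n_chains)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for c, child in enumerate(ss.spawn(n_chains)):
        rng = np.random.default_rng(child)
        x = _initial_vector(arr) + 0.05 * rng.standard_normal(10)
        latS = np.ceil(S_obs / p).astype(np.int64)
        latA = np.ceil(A_obs / p).astype(np.int64)
        latR = np.ceil(R_obs / p).astype(np.int64)
        lp = full_loglik(x, latS, latA, latR)
        n_acc = 0
        for it in range(n_warmup + n_draws):
            # parameter block
            prop = x + 0.05 * rng.standard_normal(10)
            lp_prop = full_loglik(prop, latS, latA, latR)
            if np.isfinite(lp_prop) and np.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                if it >= n_warmup:
                    n_acc += 1
            # latent sweep (single-site random walk)
            for lat, obs, mask in (
                (latS, S_obs, None),
                (latA, A_obs, None),
                (latR, R_obs, r_obs),
            ):
                for t in range(T):
                    for j in range(P):
                        if mask is not None and not mask[t, j]:
                            continue
                        delta = int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
                        new = lat[t, j] + delta
                        if new < obs[t, j]:
                            continue
                        old = lat[t, j]
                        lat[t, j] = new
                        lp_new = full_loglik(x, latS, latA, latR)
                        if np.isfinite(lp_new) and np.log(rng.random()) < lp_new - lp:
                            lp = lp_new
                        else:
                            lat[t, j] = old
            if it >= n_warmup:
                draws[c, it - n_warmup] = x
        rates[c] = n_acc / max(n_draws, 1)
    return draws, rates


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def diagnose(samples: PosteriorSamples, rhat_threshold: float = 1.1) -> pd.DataFrame:
    """Convergence table: R-hat, bulk ESS, moments, acceptance, flags."""
    if samples.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    idata = samples.to_arviz()
    ess = az.ess(idata)
    flat = samples.flat()
    rows = []
    for k, name in enumerate(samples.param_names):
        r = rhat(samples.draws[:, :, k])
        rows.append(
            {
                "parameter": name,
                "mean": flat[:, k].mean(),
                "sd": flat[:, k].std(ddof=1),
                "rhat": r,
                "ess_bulk": float(ess[name].values),
                "flagged": bool(r >= rhat_threshold),
            }
        )
    df = pd.DataFrame(rows).set_index("parameter")
    if samples.accept_rates is not None:
        df.attrs["mean_accept_rate"] = float(np.mean(samples.accept_rates))
    return df


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def posterior_predictive_gof(
    samples: PosteriorSamples,
    data: CountDataset,
    seed: int = 0,
    n_rep: int = 200,
) -> pd.DataFrame:
    """Bayesian p-values from chi-squared discrepancies per species/stage.

    For each posterior draw, one-step-ahead replicate counts are
    simulated from each observed state; the discrepancy
    sum (x - E)^2 / (E + 0.5) of the replicate is compared with that of
    the observations under the same draw.  p is the fraction of draws
    where the replicate discrepancy is at least the observed one.
    """
    rng = np.random.default_rng(seed)
    per_species, rho, D = _prepare_arrays(data, samples.detection, rho=samples.rho)
    flat = samples.flat()
    idx = rng.choice(flat.shape[0], size=min(n_rep, flat.shape[0]), replace=False)

    K = data.n_species
    exceed = np.zeros((K, 3))
    for draw_i in idx:
        vec = flat[draw_i]
        for i in range(K):
            arr = per_species[i]
            S, A = arr["S"], arr["A"]
            th_c, ph_c = vec[10 * i : 10 * i + 4], vec[10 * i + 4 : 10 * i + 8]
            tau, gamma = vec[10 * i + 8], vec[10 * i + 9]
            eta_th = (
                th_c[0] + th_c[1] * arr["rain"][:-1, None]
                + th_c[2] * arr["intra"][:-1] + th_c[3] * arr["inter"][:-1]
            )
            eta_ph = (
                ph_c[0] + ph_c[1] * arr["rain"][:-1, None]
                + ph_c[2] * arr["intra"][:-1] + ph_c[3] * arr["inter"][:-1]
            )
            th, ph = expit(eta_th), expit(eta_ph)
            gains_mean = np.where(
                arr["r_obs"][:-1], gamma * arr["R"][:-1], gamma * arr["mu"][:-1]
            )
            E_S = S[:-1] * th * (1 - tau) + gains_mean
            E_A = A[:-1] * ph + S[:-1] * th * tau
            movers = rng.binomial(S[:-1], th * tau)
            denom = 1.0 - th * tau
            q = np.where(denom > 0, th * (1 - tau) / np.where(denom > 0, denom, 1), 0.0)
            stayers = rng.binomial(S[:-1] - movers, np.clip(q, 0, 1))
            gains = np.where(
                arr["r_obs"][:-1],
                rng.binomial(arr["R"][:-1], gamma),
                rng.poisson(gamma * arr["mu"][:-1]),
            )
            rep_S = stayers + gains
            rep_A = rng.binomial(A[:-1], ph) + movers
            for s_idx, (obs_next, rep, E) in enumerate(
                ((S[1:], rep_S, E_S), (A[1:], rep_A, E_A))
            ):
                d_obs = np.sum((obs_next - E) ** 2 / (E + 0.5))
                d_rep = np.sum((rep - E) ** 2 / (E + 0.5))
                exceed[i, 1 + s_idx] += d_rep >= d_obs
            # seedlings: observed years t >= 1 against Poisson(mu_t)
            r_rows = [t for t in range(1, S.shape[0]) if arr["r_obs"][t].all()]
            if r_rows:
                E_R = np.stack([arr["mu"][t] for t in r_rows])
                obs_R = np.stack([arr["R"][t] for t in r_rows])
                rep_R = rng.poisson(E_R)
                d_obs = np.sum((obs_R - E_R) ** 2 / (E_R + 0.5))
                d_rep = np.sum((rep_R - E_R) ** 2 / (E_R + 0.5))
                exceed[i, 0] += d_rep >= d_obs
    pvals = exceed / len(idx)
    rows = []
    for i, sp in enumerate(data.species):
        r_rows = data.observed_r_years()
        for s_idx, stage in enumerate(("R", "S", "A")):
            if stage == "R" and len([t for t in r_rows if t >= 1]) == 0:
                continue
            rows.append({"species": sp, "stage": stage, "p_value": pvals[i, s_idx]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Simulate -> fit -> score results across replicate synthetic datasets."""

    table: pd.DataFrame
    coverage: float
    correlation: float
    mean_ci_halfwidth: float
    n_not_converged: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")


def recovery_experiment(
    design: dict | None = None,
    n_replicates: int = 20,
    seed: int = 0,
    config: RunConfig | None = None,
    effect_scale: float = 0.3,
) -> RecoveryReport:
    """Repeatedly simulate a community, refit it, and score the estimates.

    Coverage and correlation aggregate over the logit-scale theta/phi
    coefficients (rows with kind == "coef"); tau and gamma are reported
    alongside with kind == "rate".  Replicates whose fit fails the R-hat
    threshold are flagged in the table, never dropped.
    """
    from .synth import REDUCED_DESIGN, grid_topology, make_rainfall, make_truth, simulate_community

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if design is None:
        design = dict(REDUCED_DESIGN)
    if config is None:
        config = RunConfig(
            chains=2, warmup=1500, draws=1100, target_samples=2100
        )
    ss = np.random.SeedSequence([int(seed) % (2**31), 101])
    rows = []
    n_bad = 0
    for rep, child in enumerate(ss.spawn(n_replicates)):
        s_truth, s_rain, s_sim, s_fit = [int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(4)]
        truth = make_truth(design["n_species"], effect_scale=effect_scale, seed=s_truth)
        rain = make_rainfall(design["n_years"], seed=s_rain, first_year=design.get("first_year", 2007))
        topo = grid_topology(design["n_plots"])
        data, _ = simulate_community(
            truth, topo, design["n_years"], rain, seed=s_sim
        )
        samples = fit_model(data, config, seed=s_fit)
        summ = samples.summary()
        max_rhat = summ["rhat"].max()
        converged = bool(max_rhat < 1.1)
        if not converged:
            n_bad += 1
        for i, sp in enumerate(truth):
            entries = (
                [(f"{sp.name}.theta.{c}", sp.theta_coefs[k], "coef") for k, c in enumerate(_COEF_LABELS)]
                + [(f"{sp.name}.phi.{c}", sp.phi_coefs[k], "coef") for k, c in enumerate(_COEF_LABELS)]
                + [(f"{sp.name}.tau", sp.tau, "rate"), (f"{sp.name}.gamma", sp.gamma, "rate")]
            )
            for pname, true_val, kind in entries:
                row = summ.loc[pname]
                rows.append(
                    {
                        "replicate": rep,
                        "parameter": pname,
                        "kind": kind,
                        "truth": float(true_val),
                        "post_mean": row["mean"],
                        "q2.5": row["q2.5"],
                        "q97.5": row["q97.5"],
                        "covered": bool(row["q2.5"] <= true_val <= row["q97.5"]),
                        "ci_halfwidth": (row["q97.5"] - row["q2.5"]) / 2.0,
                        "converged": converged,
                        "max_rhat": max_rhat,
                    }
                )
    table = pd.DataFrame(rows)
    coefs = table[table["kind"] == "coef"]
    coverage = float(coefs["covered"].mean())
    correlation = float(np.corrcoef(coefs["truth"], coefs["post_mean"])[0, 1])
    return RecoveryReport(
        table=table,
        coverage=coverage,
        correlation=correlation,
        mean_ci_halfwidth=float(coefs["ci_halfwidth"].mean()),
        n_not_converged=n_bad,
    )
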