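"""Synthetic multi-species count datasets with known ground truth.

Emulates the monitoring design of a Mediterranean shrub community: five
interacting species surveyed annually in 18 fixed 5 x 5 m plots over 8
occasions, three stages (seedlings R, saplings S, adults A), with sapling
and adult survival driven by rainfall and by intra-/interspecific adult
densities, and seedling counts available for only two survey years.
Every dimension is a parameter so recovery experiments can run at reduced
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import (
    A,
    R,
    S,
    SpeciesParams,
    Standardization,
    compute_rates,
    step_stochastic,
)
from .io import CountDataset, DispersalTopology, RainfallSeries
from .metapop import build_dispersal_matrix

__all__ = [
    "DEFAULT_DESIGN",
    "REDUCED_DESIGN",
    "LatentTrajectory",
    "make_truth",
    "make_rainfall",
    "grid_topology",
    "simulate_community",
]

#: Study-scale design: 5 species, 18 plots, 8 consecutive survey occasions.
DEFAULT_DESIGN = dict(n_species=5, n_plots=18, n_years=8, first_year=2007)
#: Desk-scale design used for recovery experiments.
REDUCED_DESIGN = dict(n_species=3, n_plots=10, n_years=15, first_year=2007)

#: Generator-wide covariate standardization constants.  Fixed a priori so
#: the meaning of the generating coefficients does not depend on the
#: realized abundances.
DEFAULT_STD = Standardization(
    rain_mean=500.0, rain_sd=150.0, intra_center=10.0, intra_scale=10.0,
    inter_center=20.0, inter_scale=20.0,
)

DEFAULT_INIT = {"R": 10, "S": 5, "A": 10}
EXPLOSION_CAP = 5e5


@dataclass
class LatentTrajectory:
    """True stage abundances and the realized survival rates behind them."""

    N: np.ndarray        # (K, P, T, 3) integer abundances
    theta: np.ndarray    # (K, P, T-1) realized sapling survival
    phi: np.ndarray      # (K, P, T-1) realized adult survival

    def __post_init__(self) -> None:
        if np.any(self.N < 0):
            raise ValueError("latent abundances must be non-negative")
        for name in ("theta", "phi"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"realized {name} outside [0, 1]")


def make_truth(
    n_species: int,
    effect_scale: float = 0.3,
    seed: int = 0,
    baseline_range: tuple[float, float] = (0.3, 0.95),
    equilibrium_band: tuple[float, float] = (4.0, 120.0),
    max_attempts: int = 500,
) -> list[SpeciesParams]:
    """Draw ground-truth demographic parameters for a synthetic community.

    Intercepts put baseline survivals uniformly in ``baseline_range``.
    Rainfall and interspecific slopes are N(0, effect_scale); the
    intraspecific slopes are N(-2*effect_scale, effect_scale), making
    self-limitation stronger on average than cross-species effects — the
    classic coexistence condition.  The first species is forced to a
    positive interspecific effect on sapling survival and a negative one
    on adult survival, so every community mixes juvenile facilitation
    with adult competition.

    Candidate communities are rejection-sampled (deterministically, from
    ``seed``) until the joint mean-field equilibrium keeps every
    species' adult density inside ``equilibrium_band`` per plot: the
    target system is a set of common, coexisting perennials, not a
    community collapsing to a few relict individuals.  With
    ``effect_scale=0`` there is no density regulation and no interior
    equilibrium, so the viability screen is skipped and all slopes are
    exactly zero.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if effect_scale < 0:
        raise ValueError("effect_scale must be non-negative")
    rng = np.random.default_rng(seed)
    lo, hi = baseline_range

    def draw() -> list[SpeciesParams]:
        params = []
        for i in range(n_species):
            base_theta = rng.uniform(lo, hi)
            base_phi = rng.uniform(max(lo, 0.5), hi)  # adults longer-lived
            slopes = rng.normal(0.0, effect_scale, size=6) if effect_scale > 0 else np.zeros(6)
            # intra slopes get a -2*effect_scale mean shift: self-regulation
            a_rain, a_intra, a_inter = slopes[0], slopes[1] - 2 * effect_scale, slopes[2]
            b_rain, b_intra, b_inter = slopes[3], slopes[4] - 2 * effect_scale, slopes[5]
            if i == 0:
                a_inter = abs(a_inter)
                b_inter = -abs(b_inter)
            theta_coefs = np.array([_logit(base_theta), a_rain, a_intra, a_inter])
            phi_coefs = np.array([_logit(base_phi), b_rain, b_intra, b_inter])
            params.append(
                SpeciesParams(
                    name=f"sp{i + 1}",
                    theta_coefs=theta_coefs,
                    phi_coefs=phi_coefs,
                    tau=float(rng.uniform(0.1, 0.4)),
                    gamma=float(rng.uniform(0.1, 0.4)),
                    rho=float(rng.uniform(1.0, 4.0)),
                )
            )
        return params

    if effect_scale == 0.0:
        return draw()

    from .metapop import find_equilibrium

    lo_eq, hi_eq = equilibrium_band
    for _ in range(max_attempts):
        params = draw()
        try:
            eq = find_equilibrium(
                params, rain=DEFAULT_STD.rain_mean, D=np.eye(1), std=DEFAULT_STD,
                init=np.full((n_species, 1, 3), 10.0), tol=1e-8, max_iter=4000,
            )
        except (FloatingPointError, OverflowError):
            continue
        adults = eq.state[:, 0, 2]
        if np.all(np.isfinite(adults)) and np.all(adults >= lo_eq) and np.all(adults <= hi_eq):
            return params
    raise RuntimeError(
        "could not draw a viable coexisting community; widen equilibrium_band "
        "or reduce effect_scale"
    )


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def make_rainfall(
    n_years: int,
    mean: float = 500.0,
    sd: float = 150.0,
    seed: int = 0,
    first_year: int = 2007,
) -> RainfallSeries:
    """I.i.d. normal annual rainfall, truncated at zero."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    values = np.maximum(rng.normal(mean, sd, size=n_years), 0.0) if sd > 0 else np.full(n_years, float(mean))
    years = np.arange(first_year, first_year + n_years)
    return RainfallSeries(years=years, values=values)


def grid_topology(n_plots: int, retention: float = 0.9) -> DispersalTopology:
    """Plots on a line (a transect); plot j is adjacent to j-1 and j+1."""
    plots = [f"p{j + 1:02d}" for j in range(n_plots)]
    edges = [(plots[j], plots[j + 1]) for j in range(n_plots - 1)]
    return DispersalTopology(plots=plots, edges=edges, retention=retention)


def simulate_community(
    params: list[SpeciesParams],
    topology: DispersalTopology,
    n_years: int,
    rainfall: RainfallSeries,
    init: dict | np.ndarray | None = None,
    detection_on: bool = False,
    seed: int = 0,
    std: Standardization = DEFAULT_STD,
    r_observed_years: list[int] | None = None,
    first_year: int | None = None,
    explosion_cap: float = EXPLOSION_CAP,
    init_dispersion: float = 0.6,
) -> tuple[CountDataset, LatentTrajectory]:
    """Iterate the stochastic process kernel and emit observed counts.

    Seedling counts are reported for only the years in
    ``r_observed_years`` (default: the last two survey years), mirroring
    sparse recruitment data; other seedling cells are explicit NAs.  With
    ``detection_on`` the counts are Binomial(N, p) thinned per stage,
    otherwise counts equal the latent abundances.

    When ``init`` is a dict of per-stage means, initial abundances are
    drawn as Poisson counts around those means with a lognormal
    per-(species, plot) multiplier (sigma ``init_dispersion``), so plots
    start with distinct community compositions the way real monitoring
    plots do; pass an explicit (K, P, 3) array (or
    ``init_dispersion=0``) for homogeneous starts.
    """
    k = len(params)
    p = len(topology.plots)
    if first_year is None:
        first_year = int(rainfall.years[0])
    years = np.arange(first_year, first_year + n_years)
    if not set(years.tolist()) <= set(rainfall.years.tolist()):
        raise ValueError("rainfall series does not cover every survey year")
    if r_observed_years is None:
        r_observed_years = [n_years - 2, n_years - 1]

    rng = np.random.default_rng(seed)
    D = build_dispersal_matrix(topology)

    if init is None:
        init = DEFAULT_INIT
    if isinstance(init, dict):
        means = np.empty((k, p, 3))
        means[:, :, R] = init["R"]
        means[:, :, S] = init["S"]
        means[:, :, A] = init["A"]
        if init_dispersion > 0:
            mult = rng.lognormal(-init_dispersion**2 / 2, init_dispersion, (k, p))
            means *= mult[:, :, None]
            state = rng.poisson(means).astype(np.int64)
        else:
            state = np.rint(means).astype(np.int64)
        # first-census seedlings are last season's seed rain from the
        # initial adults, keeping the first transition on-model
        for i, sp in enumerate(params):
            state[i, :, R] = rng.poisson(sp.rho * (D @ state[i, :, A]))
    else:
        state = np.asarray(init, dtype=np.int64).copy()
    if np.any(state < 0):
        raise ValueError("initial abundances must be non-negative")

    N = np.zeros((k, p, n_years, 3), dtype=np.int64)
    theta = np.zeros((k, p, n_years - 1))
    phi = np.zeros((k, p, n_years - 1))
    N[:, :, 0, :] = state
    for t in range(n_years - 1):
        rain_std = float(std.rain(rainfall.value(int(years[t]))))
        rates = compute_rates(params, rain_std, state[:, :, A], std)
        theta[:, :, t] = rates.theta
        phi[:, :, t] = rates.phi
        state = step_stochastic(state, rates, D, rng)
        if state.sum() > explosion_cap:
            raise RuntimeError(
                "simulated community exceeded the abundance cap; "
                "weaken rho/gamma or strengthen negative density dependence"
            )
        N[:, :, t + 1, :] = state

    counts = N.astype(float).copy()
    if detection_on:
        for i, sp in enumerate(params):
            for s in range(3):
                counts[i, :, :, s] = rng.binomial(N[i, :, :, s], sp.detection[s])
    r_mask = np.ones(n_years, dtype=bool)
    r_mask[list(r_observed_years)] = False
    counts[:, :, r_mask, 0] = np.nan

    dataset = CountDataset(
        species=[sp.name for sp in params],
        plots=list(topology.plots),
        years=years,
        counts=counts,
        rainfall=rainfall,
        topology=topology,
        standardization=std,
    )
    latent = LatentTrajectory(N=N, theta=theta, phi=phi)
    return dataset, latent
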