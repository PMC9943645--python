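"""Shared process model for stage-structured, density-coupled shrub demography.

The life cycle has three stages per species and plot — seedlings (R),
saplings (S) and reproductive adults (A) — advanced by an annual census
step.  Five demographic rates drive the step:

* ``theta``  sapling survival, logit-linear in rainfall and in intra- and
  interspecific adult densities,
* ``phi``    adult survival, same linear predictor structure,
* ``tau``    sapling-to-adult transition probability (constant per species),
* ``gamma``  per-seedling probability of recruiting into the sapling stage
  (constant per species),
* ``rho``    per-capita seedlings produced per adult, with seeds spread
  across plots by a column-stochastic dispersal matrix.

The same kernel backs the stochastic simulator, the inference likelihood
and the mean-field projection/equilibrium machinery, so the three never
drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

STAGES = ("R", "S", "A")
R, S, A = 0, 1, 2

__all__ = [
    "STAGES",
    "Standardization",
    "SpeciesParams",
    "RateSet",
    "CovariateFrame",
    "survival_prob",
    "interspecific_density",
    "compute_rates",
    "step_stochastic",
    "expected_step",
]


@dataclass(frozen=True)
class Standardization:
    """Constants used to centre/scale the covariates of the rate models.

    These are fixed once (by the generator, or at data-read time) and
    shared by every downstream consumer: simulator, likelihood,
    equilibrium solver, perturbation analyses and scenario projections.
    Recomputing them from projected or perturbed values would silently
    change the meaning of the fitted coefficients.
    """

    rain_mean: float = 0.0
    rain_sd: float = 1.0
    intra_center: float = 10.0
    intra_scale: float = 10.0
    inter_center: float = 20.0
    inter_scale: float = 20.0

    def __post_init__(self) -> None:
        for name in ("rain_sd", "intra_scale", "inter_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def rain(self, value):
        return (np.asarray(value, dtype=float) - self.rain_mean) / self.rain_sd

    def intra(self, value):
        return (np.asarray(value, dtype=float) - self.intra_center) / self.intra_scale

    def inter(self, value):
        return (np.asarray(value, dtype=float) - self.inter_center) / self.inter_scale


@dataclass
class SpeciesParams:
    """Demographic parameters of one species.

    ``theta_coefs`` and ``phi_coefs`` are 4-vectors on the logit scale:
    (intercept, rainfall slope, intraspecific-density slope,
    interspecific-density slope), applied to standardized covariates.
    """

    name: str
    theta_coefs: np.ndarray
    phi_coefs: np.ndarray
    tau: float
    gamma: float
    rho: float
    detection: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.theta_coefs = np.asarray(self.theta_coefs, dtype=float)
        self.phi_coefs = np.asarray(self.phi_coefs, dtype=float)
        if self.theta_coefs.shape != (4,) or self.phi_coefs.shape != (4,):
            raise ValueError("coefficient vectors must have exactly 4 entries")
        for name in ("tau", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rho < 0:
            raise ValueError(f"rho must be non-negative, got {self.rho}")
        det = tuple(float(p) for p in self.detection)
        if len(det) != 3 or any(not 0.0 < p <= 1.0 for p in det):
            raise ValueError("detection probabilities must be in (0, 1] per stage")
        self.detection = det

    def with_(self, **kw) -> "SpeciesParams":
        return replace(self, **kw)


@dataclass
class RateSet:
    """Realized demographic rates for K species across P plots.

    theta/phi have shape (K, P); tau, gamma, rho have shape (K,).
    """

    theta: np.ndarray
    phi: np.ndarray
    tau: np.ndarray
    gamma: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if self.theta.shape != self.phi.shape:
            raise ValueError("theta and phi must share shape (K, P)")
        k = self.theta.shape[0]
        if not (self.tau.shape == self.gamma.shape == self.rho.shape == (k,)):
            raise ValueError("tau, gamma, rho must have shape (K,)")
        for name in ("theta", "phi"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} outside [0, 1]")
        if np.any(self.tau < 0) or np.any(self.tau > 1):
            raise ValueError("tau outside [0, 1]")
        if np.any(self.gamma < 0) or np.any(self.gamma > 1):
            raise ValueError("gamma outside [0, 1]")
        if np.any(self.rho < 0):
            raise ValueError("rho must be non-negative")

    @property
    def n_species(self) -> int:
        return self.theta.shape[0]

    @property
    def n_plots(self) -> int:
        return self.theta.shape[1]


@dataclass(frozen=True)
class CovariateFrame:
    """Standardized covariates entering one species' survival models."""

    rain_std: float
    intra: float
    inter: float
    std: Standardization = field(default_factory=Standardization)

    def __post_init__(self) -> None:
        if self.intra < 0 or self.inter < 0:
            raise ValueError("densities must be non-negative")

    @property
    def intra_std(self) -> float:
        return float(self.std.intra(self.intra))

    @property
    def inter_std(self) -> float:
        return float(self.std.inter(self.inter))


def survival_prob(coefs, cov: CovariateFrame) -> float:
    """Inverse-logit survival from a 4-vector of coefficients.

    Linear predictor: a0 + a_rain*rain_std + a_intra*intra_std +
    a_inter*inter_std, with densities standardized by the stored
    constants of ``cov.std``.
    """
    coefs = np.asarray(coefs, dtype=float)
    if coefs.shape != (4,):
        raise ValueError("coefs must be a 4-vector")
    eta = (
        coefs[0]
        + coefs[1] * cov.rain_std
        + coefs[2] * cov.intra_std
        + coefs[3] * cov.inter_std
    )
    return float(expit(eta))


def interspecific_density(adults, focal: int) -> int:
    """Summed adult abundance of all heterospecific neighbours in a plot."""
    adults = np.asarray(adults)
    if not 0 <= focal < adults.shape[0]:
        raise IndexError(f"focal species index {focal} out of range")
    return int(adults.sum() - adults[focal])


def _linpred(coefs_mat, rain_std, intra_std, inter_std):
    # coefs_mat (K,4); intra_std/inter_std (K,P); rain_std scalar or (K,1)
    return (
        coefs_mat[:, 0, None]
        + coefs_mat[:, 1, None] * rain_std
        + coefs_mat[:, 2, None] * intra_std
        + coefs_mat[:, 3, None] * inter_std
    )


def compute_rates(
    params: list[SpeciesParams],
    rain_std: float,
    adults: np.ndarray,
    std: Standardization,
    inter_override: np.ndarray | None = None,
) -> RateSet:
    """Realize theta/phi from current adult densities and rainfall.

    Parameters
    ----------
    adults : (K, P) adult abundances at the start of the step (the lagged
        census used as the density covariate).
    inter_override : optional (K, P) raw interspecific densities replacing
        the dynamically computed heterospecific sums (used by the
        "no-dynamic" scenario ablation).

    ``rain_std`` may be a scalar (shared driver) or a (K,) vector giving
    each species its own rainfall value (used by the indirect
    rainfall-perturbation analysis, where only heterospecific neighbours
    see the perturbed rainfall).
    """
    adults = np.atleast_2d(np.asarray(adults, dtype=float))
    k, p = adults.shape
    rain_std = np.asarray(rain_std, dtype=float)
    if rain_std.ndim == 1:
        rain_std = rain_std[:, None]
    elif rain_std.ndim != 0:
        raise ValueError("rain_std must be scalar or (K,)")
    inter_raw = adults.sum(axis=0, keepdims=True) - adults  # (K, P)
    if inter_override is not None:
        inter_raw = np.atleast_2d(np.asarray(inter_override, dtype=float))
    intra_std = std.intra(adults)
    inter_std = std.inter(inter_raw)
    th_coefs = np.stack([sp.theta_coefs for sp in params])
    ph_coefs = np.stack([sp.phi_coefs for sp in params])
    theta = expit(_linpred(th_coefs, rain_std, intra_std, inter_std))
    phi = expit(_linpred(ph_coefs, rain_std, intra_std, inter_std))
    return RateSet(
        theta=theta,
        phi=phi,
        tau=np.array([sp.tau for sp in params]),
        gamma=np.array([sp.gamma for sp in params]),
        rho=np.array([sp.rho for sp in params]),
    )


def _check_state(state, integer: bool) -> np.ndarray:
    state = np.asarray(state)
    if state.ndim != 3 or state.shape[2] != 3:
        raise ValueError("state must have shape (K, P, 3) in stage order (R, S, A)")
    if np.any(state < 0):
        raise ValueError("state must be non-negative")
    if integer:
        if not np.issubdtype(state.dtype, np.integer):
            rounded = np.rint(state)
            if not np.allclose(state, rounded):
                raise ValueError("stochastic stepping requires integer abundances")
            state = rounded.astype(np.int64)
        else:
            state = state.astype(np.int64)
    else:
        state = state.astype(float)
    return state


def step_stochastic(
    state: np.ndarray,
    rates: RateSet,
    dispersal: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance a (K, P, 3) integer state one census with demographic noise.

    Per species and plot: each of the S saplings independently moves to
    the adult stage (prob theta*tau), stays a sapling (prob
    theta*(1-tau)) or dies; gains ~ Binomial(R, gamma) join the saplings;
    adults survive ~ Binomial(A, phi); new seedlings are
    Poisson(rho * (D @ A)) using start-of-step adults, so seeds disperse
    before germination.
    """
    state = _check_state(state, integer=True)
    k, p, _ = state.shape
    D = np.asarray(dispersal, dtype=float)
    if D.shape != (p, p):
        raise ValueError(f"dispersal matrix must be ({p}, {p})")

    out = np.empty_like(state)
    for i in range(k):
        th, ph = rates.theta[i], rates.phi[i]
        tau, gam, rho = rates.tau[i], rates.gamma[i], rates.rho[i]
        s_i, a_i, r_i = state[i, :, S], state[i, :, A], state[i, :, R]
        movers = rng.binomial(s_i, th * tau)
        denom = 1.0 - th * tau
        p_stay = np.divide(th * (1 - tau), denom, out=np.zeros(p), where=denom > 0)
        stayers = rng.binomial(s_i - movers, np.clip(p_stay, 0.0, 1.0))
        gains = rng.binomial(r_i, gam)
        surv_a = rng.binomial(a_i, ph)
        out[i, :, S] = stayers + gains
        out[i, :, A] = surv_a + movers
        out[i, :, R] = rng.poisson(rho * (D @ a_i))
    return out


def expected_step(
    state: np.ndarray,
    rates: RateSet,
    dispersal: np.ndarray,
) -> np.ndarray:
    """Mean-field counterpart of :func:`step_stochastic` (exact expectation)."""
    state = _check_state(state, integer=False)
    k, p, _ = state.shape
    D = np.asarray(dispersal, dtype=float)
    if D.shape != (p, p):
        raise ValueError(f"dispersal matrix must be ({p}, {p})")

    out = np.empty_like(state)
    th, ph = rates.theta, rates.phi
    tau = rates.tau[:, None]
    gam = rates.gamma[:, None]
    rho = rates.rho[:, None]
    out[:, :, S] = state[:, :, S] * th * (1 - tau) + state[:, :, R] * gam
    out[:, :, A] = state[:, :, A] * ph + state[:, :, S] * th * tau
    out[:, :, R] = rho * (state[:, :, A] @ D.T)
    return out
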