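"""Exact transition likelihood for the dynamic N-mixture process.

With perfect detection the latent stage abundances are pinned to the
observed counts, and the one-step transition probability
P(S_{t+1}, A_{t+1} | S_t, A_t, R_t) is an exact finite sum: saplings are
multinomially thinned into movers / stayers / deaths, gains from
seedlings are Binomial(R, gamma) (or, with R unobserved and
Poisson-distributed, exactly marginalized to Poisson(gamma * mu)), and
adult survivors are Binomial(A, phi).  The sum runs over the number of
movers m and the number of gains g; both ranges are bounded by the
observed counts, so each cell costs O(S * min(R, S')) log-pmf
evaluations.  numba JIT keeps the full-dataset scan in the tens of
microseconds.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def _log_binpmf(n: int, k: int, p: float) -> float:
    if k < 0 or k > n:
        return NEG_INF
    if p <= 0.0:
        return 0.0 if k == 0 else NEG_INF
    if p >= 1.0:
        return 0.0 if k == n else NEG_INF
    return (
        math.lgamma(n + 1.0)
        - math.lgamma(k + 1.0)
        - math.lgamma(n - k + 1.0)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )


@njit(cache=True)
def _log_poispmf(k: int, mu: float) -> float:
    if k < 0:
        return NEG_INF
    if mu <= 0.0:
        return 0.0 if k == 0 else NEG_INF
    return k * math.log(mu) - mu - math.lgamma(k + 1.0)


@njit(cache=True)
def cell_loglik(
    s0: int,
    a0: int,
    s1: int,
    a1: int,
    theta: float,
    phi: float,
    tau: float,
    gamma: float,
    r_obs: bool,
    r0: int,
    mu_gain: float,
) -> float:
    """log P(S_{t+1}=s1, A_{t+1}=a1 | S_t=s0, A_t=a0, seedling info).

    ``r_obs`` selects Binomial(r0, gamma) gains; otherwise gains are
    Poisson(gamma * mu_gain), the exact marginal over a
    Poisson(mu_gain)-distributed unobserved seedling count.
    """
    p_move = theta * tau
    denom = 1.0 - p_move
    q_stay = theta * (1.0 - tau) / denom if denom > 0.0 else 0.0
    if q_stay > 1.0:
        q_stay = 1.0

    m_hi = s0 if s0 < a1 else a1
    best = NEG_INF
    acc = 0.0
    for m in range(m_hi + 1):
        lm = _log_binpmf(s0, m, p_move) + _log_binpmf(a0, a1 - m, phi)
        if lm == NEG_INF:
            continue
        # convolve stayers (Binomial(s0 - m, q_stay)) with gains at s1
        rem = s0 - m
        g_lo = s1 - rem
        if g_lo < 0:
            g_lo = 0
        g_hi = s1
        if r_obs and r0 < g_hi:
            g_hi = r0
        cbest = NEG_INF
        cacc = 0.0
        for g in range(g_lo, g_hi + 1):
            if r_obs:
                lg = _log_binpmf(r0, g, gamma)
            else:
                lg = _log_poispmf(g, gamma * mu_gain)
            lv = lg + _log_binpmf(rem, s1 - g, q_stay)
            if lv == NEG_INF:
                continue
            if lv > cbest:
                cacc = cacc * math.exp(cbest - lv) + 1.0
                cbest = lv
            else:
                cacc += math.exp(lv - cbest)
        if cbest == NEG_INF:
            continue
        lv = lm + cbest + math.log(cacc)
        if lv > best:
            acc = acc * math.exp(best - lv) + 1.0
            best = lv
        else:
            acc += math.exp(lv - best)
    if best == NEG_INF:
        return NEG_INF
    return best + math.log(acc)


@njit(cache=True)
def species_loglik(
    theta_c: np.ndarray,
    phi_c: np.ndarray,
    tau: float,
    gamma: float,
    S: np.ndarray,
    A: np.ndarray,
    r_obs: np.ndarray,
    R: np.ndarray,
    rain: np.ndarray,
    intra: np.ndarray,
    inter: np.ndarray,
    mu_gain: np.ndarray,
) -> float:
    """Summed transition log-likelihood for one species.

    S, A : (T, P) observed sapling/adult counts (latent = observed).
    r_obs, R : (T, P) seedling observation mask and values.
    rain : (T,) standardized rainfall; intra, inter : (T, P) standardized
    density covariates at the start of each step.
    mu_gain : (T, P) Poisson mean of the unobserved seedling count.
    """
    T, P = S.shape
    total = 0.0
    for t in range(T - 1):
        for j in range(P):
            eta_th = (
                theta_c[0]
                + theta_c[1] * rain[t]
                + theta_c[2] * intra[t, j]
                + theta_c[3] * inter[t, j]
            )
            eta_ph = (
                phi_c[0]
                + phi_c[1] * rain[t]
                + phi_c[2] * intra[t, j]
                + phi_c[3] * inter[t, j]
            )
            th = 1.0 / (1.0 + math.exp(-eta_th))
            ph = 1.0 / (1.0 + math.exp(-eta_ph))
            ll = cell_loglik(
                S[t, j], A[t, j], S[t + 1, j], A[t + 1, j],
                th, ph, tau, gamma,
                r_obs[t, j], R[t, j], mu_gain[t, j],
            )
            if ll == NEG_INF:
                return NEG_INF
            total += ll
    return total


@njit(cache=True)
def observation_loglik(
    lat: np.ndarray, obs: np.ndarray, mask: np.ndarray, p: float
) -> float:
    """Binomial(N, p) thinning term for one latent stage array (T, P)."""
    T, P = lat.shape
    total = 0.0
    for t in range(T):
        for j in range(P):
            if mask[t, j]:
                ll = _log_binpmf(lat[t, j], obs[t, j], p)
                if ll == NEG_INF:
                    return NEG_INF
                total += ll
    return total
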