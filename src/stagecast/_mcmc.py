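"""Adaptive random-walk Metropolis for the per-species parameter blocks.

Haario-style: during warmup the proposal covariance is periodically
re-estimated from the chain history (scaled by 2.38^2/d) and the global
step-size is tuned toward a target acceptance rate; after warmup the
proposal is frozen so the retained draws come from a fixed kernel.
"""

from __future__ import annotations

import numpy as np

__all__ = ["adaptive_metropolis"]


def _run_chain(
    logpost,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float,
):
    d = x0.size
    x = x0.copy()
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("log-posterior not finite at the initial point")
    log_scale = np.log(0.3 / np.sqrt(d))
    chol = np.eye(d)
    history = np.empty((n_warmup, d))
    draws = np.empty((n_draws, d))
    n_accept = 0
    since_update = 0
    total = n_warmup + n_draws
    for it in range(total):
        step = np.exp(log_scale) * (chol @ rng.standard_normal(d))
        prop = x + step
        lp_prop = logpost(prop)
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted = 1.0
        else:
            accepted = 0.0
        if it < n_warmup:
            history[it] = x
            # diminishing-adaptation step-size tuning toward target_accept
            since_update += 1
            log_scale += (accepted - target_accept) * min(0.5, 5.0 / since_update**0.7)
            if it >= 200 and (it + 1) % 200 == 0:
                # covariance from the most recent half of the warmup history
                recent = history[(it + 1) // 2 : it + 1]
                cov = np.cov(recent.T) + 1e-8 * np.eye(d)
                try:
                    chol = np.linalg.cholesky((2.38**2 / d) * cov)
                    log_scale = 0.0  # covariance now carries the scale
                    since_update = 0
                except np.linalg.LinAlgError:
                    pass
        else:
            draws[it - n_warmup] = x
            n_accept += accepted
    return draws, n_accept / max(n_draws, 1)


def adaptive_metropolis(
    logpost,
    x0: np.ndarray,
    n_chains: int,
    n_warmup: int,
    n_draws: int,
    seed,
    init_jitter: float = 0.1,
    target_accept: float = 0.3,
):
    """Run ``n_chains`` independent adaptive Metropolis chains.

    Returns (draws, accept_rates) with draws of shape
    (n_chains, n_draws, d); chains start from ``x0`` plus independent
    N(0, init_jitter^2) dispersion so between-chain diagnostics are
    meaningful.
    """
    x0 = np.asarray(x0, dtype=float)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    draws = np.empty((n_chains, n_draws, x0.size))
    rates = np.empty(n_chains)
    for c, child in enumerate(ss.spawn(n_chains)):
        rng = np.random.default_rng(child)
        start = x0 + init_jitter * rng.standard_normal(x0.size)
        lp = logpost(start)
        tries = 0
        while not np.isfinite(lp) and tries < 50:
            start = x0 + init_jitter * rng.standard_normal(x0.size)
            lp = logpost(start)
            tries += 1
        if not np.isfinite(lp):
            start = x0.copy()
        draws[c], rates[c] = _run_chain(
            logpost, start, n_warmup, n_draws, rng, target_accept
        )
    return draws, rates
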