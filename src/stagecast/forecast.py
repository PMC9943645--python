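"""Climate-scenario projections and hold-out forecast evaluation.

Scenarios are resampling rules over the observed rainfall series:

* baseline — each projected year draws uniformly, with replacement, from
  all observed rainfall values;
* climate_change — with probability ``p_below`` (default 0.8) the draw
  comes uniformly from the below-mean subset of observed values,
  otherwise from the remaining values, emulating a higher prevalence of
  dry years.

Projections are stochastic community runs; the "no-dynamic" ablation
severs the climate -> neighbours -> focal pathway by drawing each
species' interspecific-density covariate from the plot's historically
observed values instead of the projected community state (intraspecific
densities stay dynamic).  Forecast skill is mean squared error plus
Pearson correlation with a Fisher-z confidence interval, computed on
posterior-mean predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .demography import A, R, S, STAGES, SpeciesParams, Standardization
from .io import CountDataset, RainfallSeries
from .metapop import build_dispersal_matrix, project

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "ForecastReport",
    "sample_rainfall",
    "run_scenario",
    "compare_scenarios",
    "forecast_holdout",
    "evaluate_forecast",
]


@dataclass
class ScenarioSpec:
    kind: str = "baseline"  # "baseline" | "climate_change"
    p_below: float = 0.8
    horizon: int = 50
    n_runs: int = 100
    dynamic_interspecific: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("baseline", "climate_change"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if not 0.0 <= self.p_below <= 1.0:
            raise ValueError("p_below must be in [0, 1]")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class ScenarioResult:
    """Per-plot/species abundances averaged over time steps and runs."""

    species: list
    plots: list
    spec: ScenarioSpec
    mean_adults: np.ndarray          # (K, P)
    mean_stages: np.ndarray          # (K, P, 3)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sp in enumerate(self.species):
            for j, plot in enumerate(self.plots):
                rows.append(
                    {"species": sp, "plot": plot, "mean_adults": self.mean_adults[i, j]}
                )
        return pd.DataFrame(rows)


def sample_rainfall(
    series: RainfallSeries,
    spec: ScenarioSpec,
    n_steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a natural-scale rainfall sequence under a scenario rule.

    "Below average" is relative to the stored mean of the observed
    series, never recomputed from the resampled values.
    """
    if series.degenerate:
        raise ValueError("observed rainfall series is constant; scenarios undefined")
    values = series.values
    if spec.kind == "baseline":
        return rng.choice(values, size=n_steps, replace=True)
    below = values[series.below_mean]
    above = values[~series.below_mean]
    if below.size == 0:
        raise ValueError("no below-mean rainfall values to sample from")
    out = np.empty(n_steps)
    for t in range(n_steps):
        if rng.random() < spec.p_below:
            out[t] = rng.choice(below)
        else:
            out[t] = rng.choice(above) if above.size else rng.choice(below)
    return out


def _historical_inter(data_or_adults) -> np.ndarray:
    """(K, P, T) observed raw interspecific densities."""
    if isinstance(data_or_adults, CountDataset):
        adults = np.nan_to_num(data_or_adults.counts[:, :, :, 2])
    else:
        adults = np.asarray(data_or_adults, dtype=float)
    return adults.sum(axis=0, keepdims=True) - adults


def run_scenario(
    params: list[SpeciesParams],
    initial: np.ndarray,
    spec: ScenarioSpec,
    D: np.ndarray,
    std: Standardization,
    rain_series: RainfallSeries,
    inter_hist: np.ndarray | None = None,
    seed: int | None = None,
) -> ScenarioResult:
    """Stochastic community projections under a rainfall scenario.

    ``inter_hist`` ((K, P, T) observed interspecific densities) is
    required when ``spec.dynamic_interspecific`` is False: each step and
    plot then draws its interspecific covariate from a uniformly chosen
    observed year.  Separate random streams drive demography, rainfall
    and the historical resampling, so ablation comparisons at equal
    seeds share identical demographic noise.
    """
    if not spec.dynamic_interspecific and inter_hist is None:
        raise ValueError("no-dynamic scenarios need historical interspecific densities")
    if seed is None:
        seed = spec.seed
    k, p, _ = np.asarray(initial).shape
    ss = np.random.SeedSequence([int(seed) % (2**31), 29])
    acc_stages = np.zeros((k, p, 3))
    for run, child in enumerate(ss.spawn(spec.n_runs)):
        rng_demo, rng_env, rng_inter = (np.random.default_rng(c) for c in child.spawn(3))
        rain_seq = sample_rainfall(rain_series, spec, spec.horizon, rng_env)
        override = None
        if not spec.dynamic_interspecific:
            t_obs = inter_hist.shape[2]
            idx = rng_inter.integers(0, t_obs, size=(spec.horizon, p))
            override = np.empty((spec.horizon, k, p))
            for t in range(spec.horizon):
                for j in range(p):
                    override[t, :, j] = inter_hist[:, j, idx[t, j]]
        traj = project(
            initial, params, rain_seq, spec.horizon, D, std,
            mode="stochastic", rng=rng_demo, inter_override=override,
        )
        if spec.horizon == 0:
            acc_stages += traj[0]
        else:
            acc_stages += traj[1:].mean(axis=0)
    mean_stages = acc_stages / spec.n_runs
    return ScenarioResult(
        species=[sp.name for sp in params],
        plots=list(range(p)),
        spec=spec,
        mean_adults=mean_stages[:, :, A],
        mean_stages=mean_stages,
    )


def compare_scenarios(climate: ScenarioResult, baseline: ScenarioResult) -> pd.DataFrame:
    """Per plot/species abundance change (climate - baseline)."""
    if climate.species != baseline.species or list(climate.plots) != list(baseline.plots):
        raise ValueError("scenario results cover different designs")
    rows = []
    for i, sp in enumerate(climate.species):
        for j, plot in enumerate(climate.plots):
            rows.append(
                {
                    "species": sp,
                    "plot": plot,
                    "delta_adults": climate.mean_adults[i, j] - baseline.mean_adults[i, j],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hold-out forecasting
# ---------------------------------------------------------------------------

@dataclass
class ForecastReport:
    """Per-cell predictions with credible bounds plus aggregate skill."""

    frame: pd.DataFrame       # plot, species, stage, observed, pred_mean, lo, hi
    metrics: dict             # per stage: mse, r, r_low, r_high, n
    start_year: int
    target_year: int
    n_draws: int
    dynamic: bool = True
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = self.frame["lo"] > self.frame["hi"]
        if bad.any():
            raise ValueError("credible bounds out of order")


def forecast_holdout(
    data: CountDataset,
    posterior,
    start_year: int,
    target_year: int,
    dynamic: bool = True,
    seed: int = 0,
    n_draws: int | None = None,
) -> ForecastReport:
    """Project from observed start-year abundances to a target year.

    One stochastic trajectory is run per retained posterior draw using
    the observed rainfall over the span; per plot/species/stage the
    across-draw mean and central 95% interval are reported and compared
    with the observed target-year counts (skill metrics on the
    posterior-mean predictions).  With ``dynamic=False`` interspecific
    densities are resampled each step from the plot's observed history
    *up to the start year* — the data actually available at forecast
    issue time — instead of being propagated from the projected
    community.
    """
    years = data.years.tolist()
    if start_year not in years:
        raise ValueError(f"start year {start_year} not in data")
    n_steps = int(target_year - start_year)
    if n_steps < 0:
        raise ValueError("target year precedes start year")
    t0 = years.index(start_year)
    K, P = data.n_species, data.n_plots
    std = posterior.std
    D = build_dispersal_matrix(data.topology)

    init = np.nan_to_num(data.counts[:, :, t0, :]).copy()
    if np.isnan(data.counts[:, :, t0, 0]).any():
        # unobserved start-year seedlings: plug in their expected count
        for i in range(K):
            init[i, :, R] = np.rint(posterior.rho[i] * (D @ init[i, :, A]))

    rain_seq = np.array(
        [data.rainfall.value(int(y)) for y in range(start_year, target_year)]
    ) if n_steps > 0 else np.empty(0)

    flat = posterior.flat()
    total = flat.shape[0]
    if n_draws is None or n_draws >= total:
        draw_idx = np.arange(total)
    else:
        draw_idx = np.linspace(0, total - 1, n_draws).astype(int)

    inter_hist = _historical_inter(data)[:, :, : t0 + 1] if not dynamic else None
    ss = np.random.SeedSequence([int(seed) % (2**31), 43])
    preds = np.empty((len(draw_idx), K, P, 3))
    for d, (di, child) in enumerate(zip(draw_idx, ss.spawn(len(draw_idx)))):
        rng_demo, rng_inter = (np.random.default_rng(c) for c in child.spawn(2))
        params = posterior.draw_params(int(di))
        override = None
        if not dynamic and n_steps > 0:
            t_obs = inter_hist.shape[2]
            idx = rng_inter.integers(0, t_obs, size=(n_steps, P))
            override = np.empty((n_steps, K, P))
            for t in range(n_steps):
                for j in range(P):
                    override[t, :, j] = inter_hist[:, j, idx[t, j]]
        traj = project(
            init, params, rain_seq, n_steps, D, std,
            mode="stochastic", rng=rng_demo, inter_override=override,
        )
        preds[d] = traj[-1]

    pred_mean = preds.mean(axis=0)
    lo = np.percentile(preds, 2.5, axis=0)
    hi = np.percentile(preds, 97.5, axis=0)

    observed = None
    if target_year in years:
        observed = data.counts[:, :, years.index(target_year), :]

    rows = []
    for i, sp in enumerate(data.species):
        for j, plot in enumerate(data.plots):
            for s, stage in enumerate(STAGES):
                obs_v = np.nan if observed is None else observed[i, j, s]
                rows.append(
                    {
                        "plot": plot,
                        "species": sp,
                        "stage": stage,
                        "observed": obs_v,
                        "pred_mean": pred_mean[i, j, s],
                        "lo": lo[i, j, s],
                        "hi": hi[i, j, s],
                    }
                )
    frame = pd.DataFrame(rows)

    metrics = {}
    if observed is not None:
        for s, stage in enumerate(STAGES):
            obs_v = observed[:, :, s].ravel()
            pv = pred_mean[:, :, s].ravel()
            ok = ~np.isnan(obs_v)
            if ok.sum() >= 3:
                metrics[stage] = evaluate_forecast(pv[ok], obs_v[ok])
    return ForecastReport(
        frame=frame,
        metrics=metrics,
        start_year=int(start_year),
        target_year=int(target_year),
        n_draws=len(draw_idx),
        dynamic=dynamic,
    )


def evaluate_forecast(predicted, observed) -> dict:
    """MSE and Pearson r with a Fisher-z 95% confidence interval.

    r (and its CI) is reported as NaN when either vector has zero
    variance; the zero-step identity forecast (predicted == observed)
    returns MSE 0 and r 1.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-d arrays")
    n = predicted.size
    if n < 3:
        raise ValueError("need at least 3 paired points")
    mse = float(np.mean((predicted - observed) ** 2))
    if predicted.std() == 0.0 or observed.std() == 0.0:
        return {"mse": mse, "r": np.nan, "r_low": np.nan, "r_high": np.nan, "n": n}
    if mse == 0.0:
        return {"mse": 0.0, "r": 1.0, "r_low": 1.0, "r_high": 1.0, "n": n}
    r = float(np.corrcoef(predicted, observed)[0, 1])
    if abs(r) >= 1.0:
        lo = hi = float(np.sign(r))
    else:
        z = np.arctanh(r)
        half = norm.ppf(0.975) / np.sqrt(n - 3)
        lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    return {"mse": mse, "r": r, "r_low": lo, "r_high": hi, "n": n}
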