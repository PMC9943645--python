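"""Reading, writing and validation of the pipeline's file formats.

All inputs are plain UTF-8 CSV with a header row:

* ``counts.csv``   — long format, one row per (plot, year, species, stage),
  stage codes R/S/A, empty or ``NA`` count marking an explicit missing
  observation (never silently omitted rows);
* ``rainfall.csv`` — columns year, rainfall;
* ``topology.csv`` — two-column plot-pair edge list;
* ``config.yaml``  — one structured run configuration, hashed so every
  artifact can be traced to the settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .demography import STAGES, Standardization

__all__ = [
    "CountDataset",
    "DispersalTopology",
    "RainfallSeries",
    "RunConfig",
    "ValidationError",
    "read_counts",
    "write_counts",
    "read_rainfall",
    "write_rainfall",
    "read_topology",
    "write_topology",
]

_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


class ValidationError(ValueError):
    """A dataset violated one of its declared invariants."""


@dataclass
class DispersalTopology:
    """Abstract plot adjacency plus the natal seed-retention fraction."""

    plots: list
    edges: list  # unordered plot pairs
    retention: float = 0.9
    loss: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.retention <= 1.0:
            raise ValidationError(f"retention must be in (0, 1], got {self.retention}")
        if self.loss < 0 or self.retention + self.loss > 1.0 + 1e-12:
            raise ValidationError("retention + loss must not exceed 1")
        plotset = set(self.plots)
        seen = set()
        norm_edges = []
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-edge on plot {a!r}")
            for x in (a, b):
                if x not in plotset:
                    raise ValidationError(f"edge references unknown plot {x!r}")
            key = (a, b) if str(a) <= str(b) else (b, a)
            if key in seen:
                continue
            seen.add(key)
            norm_edges.append(key)
        self.edges = norm_edges

    def neighbours(self, plot) -> list:
        return sorted(
            {b for a, b in self.edges if a == plot} | {a for a, b in self.edges if b == plot},
            key=str,
        )


@dataclass
class RainfallSeries:
    """Annual rainfall values with stored standardization constants.

    The mean and SD of the *observed* series are computed once here and
    reused everywhere (covariate standardization, the "below-average"
    threshold of the climate scenario); downstream code never recomputes
    them from resampled or perturbed values.
    """

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape or self.years.ndim != 1:
            raise ValidationError("years and values must be equal-length 1-d arrays")
        if len(np.unique(self.years)) != len(self.years):
            raise ValidationError("duplicate years in rainfall series")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("non-numeric rainfall value")
        order = np.argsort(self.years)
        self.years = self.years[order]
        self.values = self.values[order]
        self.mean = float(self.values.mean())
        self.sd = float(self.values.std(ddof=0))

    @property
    def degenerate(self) -> bool:
        """True when the series is constant and standardization is impossible."""
        return self.sd == 0.0

    @property
    def below_mean(self) -> np.ndarray:
        return self.values < self.mean

    def value(self, year: int) -> float:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise KeyError(f"no rainfall for year {year}")
        return float(self.values[idx[0]])

    def to_dict(self) -> dict:
        return dict(zip(self.years.tolist(), self.values.tolist()))


@dataclass
class CountDataset:
    """Observed stage-specific counts plus covariate inputs.

    ``counts`` has shape (K species, P plots, T years, 3 stages) in stage
    order (R, S, A); NaN marks an explicitly missing observation.
    """

    species: list
    plots: list
    years: np.ndarray
    counts: np.ndarray
    rainfall: RainfallSeries | None = None
    topology: DispersalTopology | None = None
    standardization: Standardization | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        k, p, t = len(self.species), len(self.plots), len(self.years)
        if self.counts.shape != (k, p, t, 3):
            raise ValidationError(
                f"counts shape {self.counts.shape} != ({k}, {p}, {t}, 3)"
            )
        if t > 1 and np.any(np.diff(self.years) != 1):
            raise ValidationError("survey years must be consecutive integers")
        obs = ~np.isnan(self.counts)
        vals = self.counts[obs]
        if np.any(vals < 0):
            raise ValidationError("negative count")
        if np.any(vals != np.rint(vals)):
            raise ValidationError("non-integer count")
        # stages S and A must be observed everywhere; R may be partial
        for s in (1, 2):
            if np.any(np.isnan(self.counts[:, :, :, s])):
                raise ValidationError(
                    f"stage {STAGES[s]} has missing cells; only stage R may be partial"
                )
        if self.topology is not None:
            if set(self.plots) - set(self.topology.plots):
                raise ValidationError("topology does not cover every plot")
        if self.rainfall is not None:
            missing = set(self.years.tolist()) - set(self.rainfall.years.tolist())
            if missing:
                raise ValidationError(f"rainfall missing for survey years {sorted(missing)}")

    # -- accessors ------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def observed_r_years(self) -> np.ndarray:
        """Indices of years where seedling (R) counts are fully observed."""
        return np.nonzero(~np.isnan(self.counts[:, :, :, 0]).any(axis=(0, 1)))[0]

    def adults(self) -> np.ndarray:
        """(K, P, T) observed adult abundances."""
        return self.counts[:, :, :, 2]

    # -- frames ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sp in enumerate(self.species):
            for j, plot in enumerate(self.plots):
                for t, year in enumerate(self.years):
                    for s, stage in enumerate(STAGES):
                        v = self.counts[i, j, t, s]
                        rows.append(
                            {
                                "plot": plot,
                                "year": int(year),
                                "species": sp,
                                "stage": stage,
                                "count": "NA" if np.isnan(v) else int(v),
                            }
                        )
        return pd.DataFrame(rows, columns=["plot", "year", "species", "stage", "count"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "CountDataset":
        required = {"plot", "year", "species", "stage", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"counts table missing columns {sorted(missing)}")
        bad_stage = set(df["stage"].unique()) - set(STAGES)
        if bad_stage:
            raise ValidationError(f"unknown stage code(s) {sorted(bad_stage)}")
        dup = df.duplicated(subset=["plot", "year", "species", "stage"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate row for plot={row['plot']} year={row['year']} "
                f"species={row['species']} stage={row['stage']}"
            )
        species = sorted(df["species"].unique(), key=str)
        plots = sorted(df["plot"].unique(), key=str)
        years = np.sort(df["year"].astype(int).unique())
        counts = np.full((len(species), len(plots), len(years), 3), np.nan)
        si = {s: i for i, s in enumerate(species)}
        pi = {p: j for j, p in enumerate(plots)}
        yi = {int(y): t for t, y in enumerate(years)}
        for idx, row in df.iterrows():
            raw = row["count"]
            if pd.isna(raw) or (isinstance(raw, str) and raw.strip() in ("", "NA", "NaN")):
                continue
            v = float(raw)
            if v < 0:
                raise ValidationError(f"negative count in row {idx}: {raw}")
            if v != np.rint(v):
                raise ValidationError(f"non-integer count in row {idx}: {raw}")
            counts[si[row["species"]], pi[row["plot"]], yi[int(row["year"])], _STAGE_INDEX[row["stage"]]] = v
        return cls(species=species, plots=plots, years=years, counts=counts, **kw)


# -- file round trips ---------------------------------------------------

def read_counts(path, **kw) -> CountDataset:
    """Parse and validate a long-format counts.csv into a CountDataset."""
    df = pd.read_csv(path, dtype={"plot": str, "species": str, "stage": str}, keep_default_na=False)
    df["count"] = df["count"].replace({"": np.nan, "NA": np.nan, "NaN": np.nan})
    return CountDataset.from_frame(df, **kw)


def write_counts(dataset: CountDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_rainfall(path) -> RainfallSeries:
    df = pd.read_csv(path)
    for col in ("year", "rainfall"):
        if col not in df.columns:
            raise ValidationError(f"rainfall table missing column {col!r}")
    if df["year"].isna().any():
        raise ValidationError("missing year in rainfall table")
    vals = pd.to_numeric(df["rainfall"], errors="coerce")
    if vals.isna().any():
        raise ValidationError("non-numeric rainfall value")
    return RainfallSeries(years=df["year"].astype(int).to_numpy(), values=vals.to_numpy())


def write_rainfall(series: RainfallSeries, path) -> None:
    pd.DataFrame({"year": series.years, "rainfall": series.values}).to_csv(path, index=False)


def read_topology(path, retention: float = 0.9, plots=None, loss: float = 0.0) -> DispersalTopology:
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("topology table needs two plot columns")
    edges = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if plots is None:
        plots = sorted({p for e in edges for p in e}, key=str)
    return DispersalTopology(plots=list(plots), edges=edges, retention=retention, loss=loss)


def write_topology(topology: DispersalTopology, path) -> None:
    pd.DataFrame(topology.edges, columns=["plot_a", "plot_b"]).to_csv(path, index=False)


# -- run configuration ---------------------------------------------------

@dataclass
class RunConfig:
    """All tunables of a pipeline run; one root seed feeds every stage."""

    seed: int = 0
    # MCMC
    chains: int = 2
    warmup: int = 2000
    draws: int = 1100
    target_samples: int = 2100
    # priors
    coef_prior_sd: float = 1.5
    # detection
    detection_enabled: bool = False
    detection_p: float = 1.0
    # dispersal
    retention: float = 0.9
    # scenarios
    p_below: float = 0.8
    horizon: int = 50
    n_runs: int = 100
    # tolerances
    eq_tol: float = 1e-10
    eq_max_iter: int = 20000
    # covariate standardization constants (filled at read/generate time)
    standardization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValidationError("at least 2 chains are required")
        if self.chains * self.draws < self.target_samples:
            raise ValidationError(
                f"chains*draws = {self.chains * self.draws} < target_samples = {self.target_samples}"
            )
        if not 0.0 <= self.p_below <= 1.0:
            raise ValidationError("p_below must be in [0, 1]")
        if self.horizon < 1 or self.n_runs < 1:
            raise ValidationError("horizon and n_runs must be >= 1")
        if self.eq_tol <= 0:
            raise ValidationError("eq_tol must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
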