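"""Synthetic district x age x year mortality data with known structure.

The generator mirrors the model family: smooth age profiles of log death
rates (RW2), a linear national trend plus non-linear period deviations
(RW1), birth-cohort deviations (RW1), and Besag-York-Mollie district
effects (intrinsic CAR + exchangeable noise) on a supplied adjacency graph.
Death counts are Poisson given the cell's population and log rate, so every
generating effect is recoverable by the fitting machinery.

Default magnitudes are chosen to resemble a low-mortality national
population: age effects follow a stylised J-shaped schedule (high infant
mortality, a late-childhood minimum, near-exponential rise into old age,
life expectancy in the high 70s) with smooth random deviations of a few
tenths of a log unit, death rates
decline ~2% a year, cohort and period deviations are a few percent on the
rate scale, and structured spatial variation between districts is ~10%.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .adjacency import AdjacencyGraph, make_grid_adjacency
from .ages import AgeScheme
from .datasets import MortalityDataset
from .models import (
    ModelParameters,
    ModelSpec,
    cumsum0,
    icar_basis,
    linear_predictor_array,
)

TrueParameters = ModelParameters  # generating truth shares the parameter container

#: stylised low-mortality age schedule (deaths per person-year) at the default
#: 19 group midpoints: high infant mortality, a minimum in late childhood, a
#: young-adult bump and near-exponential rise into old age
_BASELINE_RATES = np.array(
    [
        0.006, 0.00025, 0.0001, 0.00012, 0.0005, 0.0007, 0.0008, 0.001,
        0.0013, 0.002, 0.003, 0.005, 0.008, 0.013, 0.022, 0.038, 0.065,
        0.11, 0.20,
    ]
)
_BASELINE_MIDPOINTS = AgeScheme.default().group_midpoints


def baseline_log_rates(age_scheme: AgeScheme) -> np.ndarray:
    """Stylised J-shaped log death-rate schedule at the scheme's midpoints."""
    return np.interp(
        age_scheme.group_midpoints, _BASELINE_MIDPOINTS, np.log(_BASELINE_RATES)
    )


@dataclass
class SimulationConfig:
    """Dimensions, effect scales and seed of one synthetic study.

    SDs are innovation scales of the corresponding random-walk / spatial
    processes, all on the log death-rate scale.
    """

    n_rows: int = 3
    n_cols: int = 4
    first_year: int = 1993
    n_years: int = 20
    alpha0: float = -5.65
    beta0: float = -0.02
    sigma_age_level: float = 0.02
    sigma_age_slope: float = 0.0005
    sigma_period: float = 0.01
    sigma_cohort: float = 0.03
    sigma_spatial_u: float = 0.10
    sigma_spatial_v: float = 0.05
    theta: float = 1.0
    age_baseline_amplitude: float = 1.0  # scale of the J-shaped mean age profile
    w_level: float = 1.0        # logit-scale mean of the cohort age weights
    sigma_w: float = 0.3        # RW1 innovation SD of the logit weights
    sigma_lc_loading: float = 0.01
    seed: int = 0

    @property
    def n_districts(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.n_years)

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if name.startswith("sigma_") and value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_rows < 1 or self.n_cols < 1 or self.n_years < 2:
            raise ValueError("invalid dimensions")
        if self.theta <= 0:
            raise ValueError("theta must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        fields_ = {f: d[f] for f in cls.__dataclass_fields__ if f in d}
        typed = {}
        for k, v in fields_.items():
            target = cls.__dataclass_fields__[k].type
            typed[k] = int(v) if target == "int" else float(v)
        return cls(**typed)


def _rw1_draw(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    path = cumsum0(rng.normal(0.0, sigma, size=n - 1))
    return path - path.mean()


def _detrended_rw1_draw(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """RW1 draw with mean and linear trend removed.

    Period and cohort deviations are only defined up to linear terms (their
    drift is aliased with the explicit linear trend), so the generator keeps
    the identified part: the non-linear wiggles.
    """
    path = _rw1_draw(n, sigma, rng)
    idx = np.arange(n, dtype=float)
    idx -= idx.mean()
    denom = float(idx @ idx)
    if denom > 0:
        path = path - (float(idx @ path) / denom) * idx
    return path - path.mean()


def _rw2_draw(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    second = rng.normal(0.0, sigma, size=n - 2)
    path = cumsum0(cumsum0(second))
    return path - path.mean()


def simulate_true_parameters(
    config: SimulationConfig,
    graph: AdjacencyGraph | None = None,
    age_scheme: AgeScheme | None = None,
) -> TrueParameters:
    """Draw a full set of generating parameters.

    Every deviation block is drawn from its random-walk / BYM process and
    then centred to sum to zero exactly.  Identical config (and seed) gives
    identical output.
    """
    config.validate()
    if age_scheme is None:
        age_scheme = AgeScheme.default()
    if graph is None:
        graph = make_grid_adjacency(config.n_rows, config.n_cols)
    if graph.n_units != config.n_districts:
        raise ValueError("graph does not match the configured grid")
    spec = ModelSpec(3, age_scheme, config.years, graph.n_units)
    n_a, n_t, n_s, n_c = spec.n_ages, spec.n_years, spec.n_districts, spec.n_cohorts
    rng = np.random.default_rng(config.seed)

    baseline = config.age_baseline_amplitude * baseline_log_rates(age_scheme)
    alpha_age = baseline - baseline.mean() + _rw2_draw(n_a, config.sigma_age_level, rng)
    alpha_age -= alpha_age.mean()
    beta_age = _rw2_draw(n_a, config.sigma_age_slope, rng)
    gamma = _detrended_rw1_draw(n_t, config.sigma_period, rng)
    phi = _detrended_rw1_draw(n_c, config.sigma_cohort, rng)

    if n_s > 1:
        u = icar_basis(graph) @ rng.normal(size=n_s - 1) * config.sigma_spatial_u
        u -= u.mean()
        v = rng.normal(0.0, config.sigma_spatial_v, size=n_s) if config.sigma_spatial_v > 0 else np.zeros(n_s)
        v -= v.mean()
    else:
        u = np.zeros(1)
        v = np.zeros(1)

    omega = config.w_level + _rw1_draw(n_a, config.sigma_w, rng)
    w_age = 1.0 / (1.0 + np.exp(-omega))

    # Lee-Carter truth, only used when simulating from model 5
    lc_level = config.alpha0 + (baseline - baseline.mean()) + _rw2_draw(
        n_a, config.sigma_age_level, rng)
    lc_loading = np.full(n_a, 1.0 / n_a) + _rw1_draw(n_a, config.sigma_lc_loading, rng)
    lc_drift = config.beta0 * n_a
    incr = lc_drift + rng.normal(0.0, config.sigma_period, size=n_t - 1)
    lc_period = cumsum0(incr)
    lc_period -= lc_period.mean()

    return TrueParameters(
        alpha0=config.alpha0,
        beta0=config.beta0,
        alpha_age=alpha_age,
        beta_age=beta_age,
        gamma_period=gamma,
        phi_cohort=phi,
        u_spatial=u,
        v_spatial=v,
        theta=config.theta,
        w_age=w_age,
        lc_level=lc_level,
        lc_loading=lc_loading,
        lc_period=lc_period,
        lc_drift=lc_drift,
        sigmas={
            "age_level": config.sigma_age_level,
            "age_slope": config.sigma_age_slope,
            "period": config.sigma_period,
            "cohort": config.sigma_cohort,
            "spatial_u": config.sigma_spatial_u,
            "spatial_v": config.sigma_spatial_v,
            "cohort_weight": config.sigma_w,
            "lc_level": config.sigma_age_level,
            "lc_loading": config.sigma_lc_loading,
            "lc_period": config.sigma_period,
        },
    )


#: stylised person-years per cell by age group (infant, 1-4, 5-79, 80-84, 85+)
def default_populations(
    n_districts: int, age_scheme: AgeScheme, n_years: int
) -> np.ndarray:
    """Stylised district populations, constant over districts and years."""
    per_age = np.full(age_scheme.n_groups, 7500.0)
    per_age[0] = 1500.0
    if age_scheme.n_groups > 2:
        per_age[1] = 6000.0
        per_age[-2] = 4000.0
    per_age[-1] = 3000.0
    return np.broadcast_to(
        per_age[None, :, None], (n_districts, age_scheme.n_groups, n_years)
    ).copy()


def simulate_dataset(
    params: TrueParameters,
    populations: np.ndarray,
    model_id: int,
    seed: int,
    age_scheme: AgeScheme | None = None,
    years: np.ndarray | None = None,
    sex_label: str = "synthetic",
) -> MortalityDataset:
    """Forward-simulate Poisson death counts from one model's linear predictor."""
    if model_id not in (1, 2, 3, 4, 5):
        raise ValueError(f"model_id must be in 1..5, got {model_id}")
    populations = np.asarray(populations, dtype=float)
    if np.any(populations <= 0):
        raise ValueError("populations must be strictly positive")
    if age_scheme is None:
        age_scheme = AgeScheme.default()
    n_s, n_a, n_t = populations.shape
    if years is None:
        years = np.arange(2001 - n_t + 1, 2001 + 1)
    spec = ModelSpec(model_id, age_scheme, years, n_s)
    if params.alpha_age.size != n_a or params.gamma_period.size != n_t:
        raise ValueError("parameter dimensions do not match populations")
    eta = linear_predictor_array(params, spec)
    rng = np.random.default_rng(seed)
    deaths = rng.poisson(populations * np.exp(eta))
    return MortalityDataset(deaths, populations, age_scheme, years, sex_label)


def simulate_study(
    config: SimulationConfig, model_id: int = 3
) -> tuple[MortalityDataset, TrueParameters, AdjacencyGraph]:
    """Convenience wrapper: adjacency + truth + dataset from one config.

    The dataset seed is derived from the config seed so that truth and
    counts are jointly reproducible.
    """
    graph = make_grid_adjacency(config.n_rows, config.n_cols)
    scheme = AgeScheme.default()
    params = simulate_true_parameters(config, graph, scheme)
    pops = default_populations(config.n_districts, scheme, config.n_years)
    data = simulate_dataset(
        params, pops, model_id, seed=config.seed + 1_000_003, age_scheme=scheme,
        years=config.years,
    )
    return data, params, graph


def write_true_parameters(params: TrueParameters, path: str | Path) -> None:
    """Persist a truth object as a long CSV (block, index, value)."""
    rows = []
    for name in (
        "alpha_age", "beta_age", "gamma_period", "phi_cohort", "u_spatial",
        "v_spatial", "w_age", "lc_level", "lc_loading", "lc_period",
    ):
        block = getattr(params, name)
        if block is None:
            continue
        for i, val in enumerate(np.asarray(block, dtype=float)):
            rows.append((name, i, val))
    for name in ("alpha0", "beta0", "theta", "lc_drift"):
        rows.append((name, 0, float(getattr(params, name))))
    for key, val in params.sigmas.items():
        rows.append((f"sigma_{key}", 0, float(val)))
    pd.DataFrame(rows, columns=["block", "index", "value"]).to_csv(path, index=False)
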