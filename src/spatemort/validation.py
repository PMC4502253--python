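"""Holdout validation of mortality forecasts.

Protocol: fit each candidate model on the early years, forecast the withheld
window, and score (i) signed forecast error (systematic bias), (ii) absolute
forecast error, and (iii) 90% interval coverage, for life expectancy and for
age-specific death rates.  The model with the smallest median absolute
life-expectancy error wins.

Conventions (documented, configurable where noted): the central estimate is
the posterior median; forecast error is forecast minus observed; an
observation exactly on an interval bound counts as covered; observed life
expectancy is computed by the same life-table pipeline (including the
old-age extension) applied to raw withheld rates, so forecast and observed
are methodologically commensurate.  Interval coverage is assessed against
posterior-predictive draws (Poisson counts simulated with the withheld
populations), so the comparison includes the sampling noise that the
withheld observations themselves carry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MortalityDataset
from .forecasting import ForecastResult
from .lifetable import life_expectancy_from_rates, national_rate


def holdout_split(
    data: MortalityDataset, last_train_year: int
) -> tuple[MortalityDataset, MortalityDataset]:
    """Split by calendar year into disjoint, exhaustive train/test sets."""
    years = data.years
    if not (years[0] <= last_train_year < years[-1]):
        raise ValueError(
            f"cutoff {last_train_year} must lie inside [{years[0]}, {years[-1] - 1}]"
        )
    train = data.subset_years(years[years <= last_train_year])
    test = data.subset_years(years[years > last_train_year])
    return train, test


def interval_coverage(lower: np.ndarray, upper: np.ndarray, observed: np.ndarray) -> float:
    """Fraction of observations inside closed intervals [lower, upper]."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if lower.shape != upper.shape or lower.shape != observed.shape:
        raise ValueError("bounds and observations must share one shape")
    if np.any(lower > upper):
        raise ValueError("crossed interval bounds")
    inside = (observed >= lower) & (observed <= upper)
    return float(inside.mean())


@dataclass
class ValidationReport:
    """Scores of one model on one withheld window."""

    model_id: int
    e0_errors: pd.DataFrame          # per (district, year): fe, afe
    rate_errors: pd.DataFrame        # per (age_start, year): fe, afe on national rates
    coverage_by_age: pd.DataFrame    # 90% predictive-rate coverage per age group
    coverage_rates: float            # overall cell-level rate coverage
    coverage_e0: float               # district-year life-expectancy coverage
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fe = self.e0_errors["fe"].to_numpy()
        self.summary.setdefault("model_id", self.model_id)
        self.summary.setdefault("mean_fe", float(fe.mean()))
        self.summary.setdefault("median_afe", float(np.median(np.abs(fe))))
        q1, q3 = np.percentile(np.abs(fe), [25, 75])
        self.summary.setdefault("afe_iqr", (float(q1), float(q3)))


def score_forecasts(
    forecast: ForecastResult,
    observed: MortalityDataset,
    model_id: int = 0,
    central: str = "median",
    interval: float = 0.90,
    seed: int = 0,
) -> ValidationReport:
    """Score a rate forecast against withheld data.

    Life expectancies (forecast and observed) run through the same life-table
    pipeline with KT extension; rate errors are on national (population-
    weighted) age-specific rates; coverage uses posterior-predictive counts.
    """
    if not np.array_equal(forecast.years, observed.years):
        raise ValueError("forecast and observed year ranges differ")
    if forecast.rates.shape[1:] != observed.deaths.shape:
        raise ValueError("forecast and observed grids differ")
    scheme = observed.age_scheme
    lo_p, hi_p = (1.0 - interval) / 2.0, 1.0 - (1.0 - interval) / 2.0

    rates = forecast.rates  # (S, n_s, n_a, n_t)
    # posterior-predictive empirical rates: simulate counts with withheld exposures
    rng = np.random.default_rng(seed)
    pred_counts = rng.poisson(rates * observed.population[None])
    pred_rates = pred_counts / observed.population[None]

    # ----- life expectancy, per district-year -----------------------------
    # axes to (S, n_s, n_t, n_a) for the life-table batch
    e0_fc = life_expectancy_from_rates(np.moveaxis(rates, 2, -1), scheme)
    central_fn = np.median if central == "median" else np.mean
    e0_central = central_fn(e0_fc, axis=0)
    obs_rates = observed.rates()
    # zero-death open-group cells get half a death so observed e0 is defined
    obs_rates_lt = obs_rates.copy()
    zero_open_obs = obs_rates_lt[:, -1, :] <= 0
    if np.any(zero_open_obs):
        obs_rates_lt[:, -1, :] = np.where(
            zero_open_obs, 0.5 / observed.population[:, -1, :], obs_rates_lt[:, -1, :]
        )
    obs_e0 = life_expectancy_from_rates(np.moveaxis(obs_rates_lt, 1, -1), scheme)
    fe = e0_central - obs_e0
    n_s, n_t = fe.shape
    d_idx, t_idx = np.meshgrid(np.arange(n_s), np.arange(n_t), indexing="ij")
    e0_errors = pd.DataFrame(
        {
            "district": observed.district_ids[d_idx.ravel()],
            "year": observed.years[t_idx.ravel()],
            "fe": fe.ravel(),
            "afe": np.abs(fe).ravel(),
        }
    )
    # predictive life-expectancy intervals (include withheld sampling noise)
    zero_open = pred_rates[:, :, -1, :] <= 0
    if np.any(zero_open):
        # replace empty predictive open-group cells by half a death
        fill = 0.5 / observed.population[None, :, -1, :]
        pred_rates[:, :, -1, :] = np.where(zero_open, fill, pred_rates[:, :, -1, :])
    e0_pred = life_expectancy_from_rates(np.moveaxis(pred_rates, 2, -1), scheme)
    e0_lo = np.quantile(e0_pred, lo_p, axis=0)
    e0_hi = np.quantile(e0_pred, hi_p, axis=0)
    coverage_e0 = interval_coverage(e0_lo, e0_hi, obs_e0)

    # ----- national age-specific rates ------------------------------------
    pop = observed.population
    nat_fc = (rates * pop[None]).sum(axis=1) / pop.sum(axis=0)[None]
    nat_central = central_fn(nat_fc, axis=0)
    nat_obs = national_rate(observed.rates(), pop)
    rfe = nat_central - nat_obs
    n_a = scheme.n_groups
    a_idx, t_idx = np.meshgrid(np.arange(n_a), np.arange(observed.n_years), indexing="ij")
    rate_errors = pd.DataFrame(
        {
            "age_start": scheme.group_starts[a_idx.ravel()],
            "year": observed.years[t_idx.ravel()],
            "fe": rfe.ravel(),
            "afe": np.abs(rfe).ravel(),
        }
    )

    # ----- coverage of cell-level rates ------------------------------------
    lo = np.quantile(pred_rates, lo_p, axis=0)
    hi = np.quantile(pred_rates, hi_p, axis=0)
    inside = (obs_rates >= lo) & (obs_rates <= hi)
    coverage_rates = float(inside.mean())
    coverage_by_age = pd.DataFrame(
        {
            "age_start": scheme.group_starts,
            "coverage": inside.mean(axis=(0, 2)),
        }
    )
    return ValidationReport(
        model_id=model_id,
        e0_errors=e0_errors,
        rate_errors=rate_errors,
        coverage_by_age=coverage_by_age,
        coverage_rates=coverage_rates,
        coverage_e0=coverage_e0,
    )


def select_best_model(reports: list[ValidationReport]) -> int:
    """Model with the smallest median absolute life-expectancy forecast error.

    Ties break on smallest |mean FE|, then on lowest model id.
    """
    if not reports:
        raise ValueError("no reports to select from")
    if len(reports) == 1:
        warnings.warn("model selection over a single report")
        return reports[0].model_id
    keyed = [
        (r.summary["median_afe"], abs(r.summary["mean_fe"]), r.model_id) for r in reports
    ]
    return min(keyed)[2]
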