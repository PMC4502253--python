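"""Posterior-predictive forecasts of age-specific death rates.

For each posterior draw, deterministic components (linear or exponentiated
trend, age effects, spatial effects, Lee-Carter loadings) are extrapolated
by their formulas, and stochastic random-walk components (period deviations,
new cohorts, the Lee-Carter period index) are forward-simulated once with
that draw's innovation SD — one stochastic path per draw, the standard
posterior-predictive recipe.  Rates are ``exp`` of the extended predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ages import COHORT_BAND_WIDTH
from .inference import PosteriorSamples
from .models import ModelSpec

QUANTILE_PROBS = (0.025, 0.5, 0.975)


@dataclass
class ForecastResult:
    """Rate draws by (posterior draw, district, age, future year)."""

    rates: np.ndarray
    years: np.ndarray
    age_starts: np.ndarray
    district_ids: np.ndarray

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.rates)) or np.any(self.rates <= 0):
            raise ValueError("forecast rates must be strictly positive and finite")

    @property
    def n_draws(self) -> int:
        return self.rates.shape[0]

    def quantiles(self, probs=QUANTILE_PROBS) -> np.ndarray:
        """(n_probs, district, age, year) empirical quantiles (linear interpolation)."""
        return np.quantile(self.rates, probs, axis=0)


def forecast_rates(
    samples: PosteriorSamples,
    spec: ModelSpec | None = None,
    horizon: int = 1,
    seed: int = 0,
    district_ids: np.ndarray | None = None,
) -> ForecastResult:
    """Forward-simulate rates ``horizon`` years past the fitted period."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    spec = spec or samples.spec
    rng = np.random.default_rng(seed)
    n = samples.n_total
    n_s, n_a = spec.n_districts, spec.n_ages
    future_years = np.arange(spec.years[-1] + 1, spec.years[-1] + 1 + horizon)
    t_future = future_years - spec.years.mean()

    u = samples.stacked("u_spatial")
    v = samples.stacked("v_spatial")
    spatial = (u + v)[:, :, None, None]  # (S, n_s, 1, 1)

    if spec.model_id == 5:
        level = samples.stacked("lc_level")        # (S, n_a)
        loading = samples.stacked("lc_loading")
        period = samples.stacked("lc_period")      # (S, n_t)
        drift = samples.stacked("lc_drift")
        sk = samples.sigma_draws["lc_period"].reshape(-1)
        steps = drift[:, None] + sk[:, None] * rng.standard_normal((n, horizon))
        k_future = period[:, -1][:, None] + np.cumsum(steps, axis=1)  # (S, H)
        eta = (
            level[:, None, :, None]
            + loading[:, None, :, None] * k_future[:, None, None, :]
            + spatial
        )
    else:
        alpha0 = samples.stacked("alpha0")
        beta0 = samples.stacked("beta0")
        alpha_a = samples.stacked("alpha_age")
        beta_a = samples.stacked("beta_age")
        gamma = samples.stacked("gamma_period")
        s_gamma = samples.sigma_draws["period"].reshape(-1)
        if spec.model_id == 2:
            theta = samples.stacked("theta")
            g = np.sign(t_future)[None, :] * np.abs(t_future)[None, :] ** theta[:, None]
        else:
            g = np.broadcast_to(t_future, (n, horizon))
        steps = s_gamma[:, None] * rng.standard_normal((n, horizon))
        gamma_future = gamma[:, -1][:, None] + np.cumsum(steps, axis=1)  # (S, H)
        trend = (beta0[:, None] + beta_a)[:, :, None] * g[:, None, :]    # (S, n_a, H)
        eta = (
            alpha0[:, None, None, None]
            + alpha_a[:, None, :, None]
            + trend[:, None, :, :]
            + gamma_future[:, None, None, :]
            + spatial
        )
        if spec.has_cohort:
            phi = samples.stacked("phi_cohort")  # (S, n_c)
            mids = spec.age_scheme.group_midpoints
            raw_all = spec.years[None, :] - mids[:, None]
            origin = np.floor(raw_all / COHORT_BAND_WIDTH).astype(int).min()
            raw_f = future_years[None, :] - mids[:, None]
            cidx_f = np.floor(raw_f / COHORT_BAND_WIDTH).astype(int) - origin  # (n_a, H)
            n_c = spec.n_cohorts
            n_new = int(max(cidx_f.max() - (n_c - 1), 0))
            if n_new > 0:
                s_phi = samples.sigma_draws["cohort"].reshape(-1)
                steps = s_phi[:, None] * rng.standard_normal((n, n_new))
                phi_new = phi[:, -1][:, None] + np.cumsum(steps, axis=1)
                phi_ext = np.concatenate([phi, phi_new], axis=1)
            else:
                phi_ext = phi
            coh = phi_ext[:, cidx_f]  # (S, n_a, H)
            if spec.model_id == 4:
                coh = samples.stacked("w_age")[:, :, None] * coh
            eta = eta + coh[:, None, :, :]

    eta = np.broadcast_to(eta, (n, n_s, n_a, horizon))
    if district_ids is None:
        district_ids = np.arange(n_s)
    return ForecastResult(
        rates=np.exp(eta).copy(),
        years=future_years,
        age_starts=spec.age_scheme.group_starts.copy(),
        district_ids=np.asarray(district_ids),
    )


def summarize_forecast(result: ForecastResult, probs=QUANTILE_PROBS) -> pd.DataFrame:
    """Long quantile table: district, age_start, year, one column per quantile."""
    if result.n_draws < 1:
        raise ValueError("empty forecast")
    q = result.quantiles(probs)
    n_s, n_a, n_h = q.shape[1:]
    d_idx, a_idx, t_idx = np.meshgrid(
        np.arange(n_s), np.arange(n_a), np.arange(n_h), indexing="ij"
    )
    out = pd.DataFrame(
        {
            "district": result.district_ids[d_idx.ravel()],
            "age_start": result.age_starts[a_idx.ravel()],
            "year": result.years[t_idx.ravel()],
        }
    )
    for p, qi in zip(probs, q):
        out[f"q{100 * p:g}"] = qi.transpose(0, 1, 2).ravel()
    return out


def write_forecast_csv(result: ForecastResult, path: str | Path, probs=QUANTILE_PROBS) -> None:
    summarize_forecast(result, probs).to_csv(path, index=False)
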