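"""Scikit-learn-style estimator wrapping model fitting and forecasting."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import inference
from .adjacency import AdjacencyGraph
from .datasets import MortalityDataset
from .forecasting import ForecastResult, forecast_rates
from .models import ModelSpec


class MortalityForecaster(BaseEstimator):
    """Bayesian spatiotemporal mortality model with posterior forecasting.

    Parameters mirror :class:`spatemort.models.ModelSpec` and the MCMC
    configuration; ``fit`` runs HMC and stores the posterior, ``forecast``
    produces posterior-predictive death rates for future years.

    Examples
    --------
    >>> est = MortalityForecaster(model_id=3, draws=200, warmup=200, seed=1)
    >>> est.fit(data, graph)                                # doctest: +SKIP
    >>> fc = est.forecast(horizon=10)                       # doctest: +SKIP
    """

    def __init__(
        self,
        model_id: int = 3,
        rw_order_age: int = 2,
        rw_order_time: int = 1,
        hyper_scale: float = 1.0,
        theta_prior_sd: float = 0.25,
        chains: int = 2,
        draws: int = 500,
        warmup: int = 500,
        target_accept: float = 0.85,
        max_leapfrog: int = 32,
        seed: int = 0,
        psrf_threshold: float = 1.1,
    ):
        self.model_id = model_id
        self.rw_order_age = rw_order_age
        self.rw_order_time = rw_order_time
        self.hyper_scale = hyper_scale
        self.theta_prior_sd = theta_prior_sd
        self.chains = chains
        self.draws = draws
        self.warmup = warmup
        self.target_accept = target_accept
        self.max_leapfrog = max_leapfrog
        self.seed = seed
        self.psrf_threshold = psrf_threshold

    def fit(self, X: MortalityDataset, y=None, graph: AdjacencyGraph | None = None):
        """Fit the model to a mortality dataset on an adjacency graph."""
        if graph is None:
            raise ValueError("an adjacency graph is required (pass graph=...)")
        if not isinstance(X, MortalityDataset):
            raise TypeError("X must be a MortalityDataset")
        spec = ModelSpec(
            self.model_id,
            X.age_scheme,
            X.years,
            X.n_districts,
            rw_order_age=self.rw_order_age,
            rw_order_time=self.rw_order_time,
            hyper_scale=self.hyper_scale,
            theta_prior_sd=self.theta_prior_sd,
        )
        self.spec_ = spec
        self.samples_ = inference.fit(
            spec,
            X,
            graph,
            chains=self.chains,
            draws=self.draws,
            warmup=self.warmup,
            seed=self.seed,
            target_accept=self.target_accept,
            max_leapfrog=self.max_leapfrog,
        )
        self.district_ids_ = np.asarray(X.district_ids)
        self.max_psrf_ = (
            self.samples_.max_psrf() if self.samples_.diagnostics else float("nan")
        )
        self.converged_ = bool(self.max_psrf_ < self.psrf_threshold) if np.isfinite(
            self.max_psrf_
        ) else False
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "samples_"):
            raise RuntimeError("call fit before forecasting")

    def forecast(self, horizon: int, seed: int | None = None) -> ForecastResult:
        """Posterior-predictive rate forecast ``horizon`` years ahead."""
        self._check_fitted()
        return forecast_rates(
            self.samples_,
            self.spec_,
            horizon=horizon,
            seed=self.seed + 1 if seed is None else seed,
            district_ids=self.district_ids_,
        )

    def predict(self, horizon: int, seed: int | None = None) -> np.ndarray:
        """Posterior-median forecast rates, shape (district, age, year)."""
        return np.median(self.forecast(horizon, seed).rates, axis=0)

    def fitted_log_rates(self) -> np.ndarray:
        """Posterior draws of in-sample cell log rates: (n_total, s, a, t)."""
        self._check_fitted()
        return inference.cell_log_rate_draws(self.samples_, self.spec_)
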