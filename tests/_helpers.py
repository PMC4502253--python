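"""Shared builders for degenerate posterior-sample objects used in tests."""

import numpy as np

from spatemort import ModelSpec, PosteriorSamples
from spatemort.models import ModelParameters


def degenerate_samples(default_scheme, n_districts=2, n_years=8, beta0=0.0,
                       sigma_period=0.0, sigma_cohort=0.0, n_draws=1, model_id=3):
    """PosteriorSamples whose draws are all identical, with chosen innovation SDs.

    Useful for exercising the forecast machinery against closed-form answers.
    """
    years = np.arange(2000, 2000 + n_years)
    spec = ModelSpec(model_id, default_scheme, years, n_districts)
    p = ModelParameters.zeros(spec)
    p.alpha0, p.beta0 = -4.0, beta0
    rng = np.random.default_rng(0)
    gamma = rng.normal(0, 0.05, n_years)
    gamma -= gamma.mean()
    idx = np.arange(n_years) - (n_years - 1) / 2
    gamma -= (idx @ gamma) / (idx @ idx) * idx
    p.gamma_period = gamma
    blocks = {
        "alpha0": np.full((1, n_draws), p.alpha0),
        "beta0": np.full((1, n_draws), p.beta0),
        "alpha_age": np.tile(p.alpha_age, (1, n_draws, 1)),
        "beta_age": np.tile(p.beta_age, (1, n_draws, 1)),
        "gamma_period": np.tile(p.gamma_period, (1, n_draws, 1)),
        "phi_cohort": np.tile(p.phi_cohort, (1, n_draws, 1)),
        "u_spatial": np.tile(p.u_spatial, (1, n_draws, 1)),
        "v_spatial": np.tile(p.v_spatial, (1, n_draws, 1)),
    }
    sigma_draws = {
        "period": np.full((1, n_draws), sigma_period),
        "cohort": np.full((1, n_draws), sigma_cohort),
        "age_level": np.full((1, n_draws), 0.1),
        "age_slope": np.full((1, n_draws), 0.01),
        "spatial_u": np.full((1, n_draws), 0.1),
        "spatial_v": np.full((1, n_draws), 0.05),
    }
    samples = PosteriorSamples(spec, blocks, sigma_draws, seed=0)
    return spec, samples, p
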