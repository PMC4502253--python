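"""Posterior sampling, convergence diagnostics and posterior summaries.

The sampler is gradient-based HMC on the non-centred reparameterisation in
:mod:`spatemort._reparam` (the random-walk / ICAR geometry mixes poorly under
centred parameterisations).  Chains are run with over-dispersed data-driven
starting points; convergence is assessed with the (Brooks-)Gelman-Rubin
potential scale reduction factor on every monitored scalar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._hmc import hmc_sample
from ._reparam import InitialisationError, ModelTransform
from .adjacency import AdjacencyGraph
from .datasets import MortalityDataset
from .models import ModelParameters, ModelSpec, linear_predictor_array

#: blocks stored on the natural scale in a PosteriorSamples object
_NATURAL_BLOCKS = (
    "alpha0", "beta0", "alpha_age", "beta_age", "gamma_period", "phi_cohort",
    "u_spatial", "v_spatial", "theta", "w_age",
    "lc_level", "lc_loading", "lc_period", "lc_drift",
)


class DegenerateChainError(ValueError):
    """Within-chain variance is zero; the diagnostic is undefined."""


def potential_scale_reduction(chains: np.ndarray) -> float:
    """(Brooks-)Gelman-Rubin potential scale reduction factor of one scalar.

    ``chains`` has shape (n_chains, n_draws).  The statistic compares the
    between-chain variance of the means with the pooled within-chain
    variance; values near 1 indicate convergence.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    n = chains.shape[1]
    w = float(np.mean(np.var(chains, axis=1, ddof=1)))
    if w == 0.0:
        raise DegenerateChainError("zero within-chain variance")
    b_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


@dataclass
class PosteriorSamples:
    """Post-warmup draws of one model, on the natural parameter scale.

    ``blocks`` maps block names to arrays of shape (n_chains, n_draws, ...);
    ``sigma_draws`` holds innovation-SD draws per component.  Diagnostics are
    potential scale reduction factors per monitored scalar.
    """

    spec: ModelSpec
    blocks: dict[str, np.ndarray]
    sigma_draws: dict[str, np.ndarray]
    seed: int
    diagnostics: dict[str, np.ndarray] = field(default_factory=dict)
    sampler_stats: list[dict] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.blocks.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.blocks.values())).shape[1]

    @property
    def n_total(self) -> int:
        return self.n_chains * self.n_draws

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one block with chains concatenated: (n_total, ...)."""
        arr = self.blocks[name] if name in self.blocks else self.sigma_draws[name]
        return arr.reshape((-1,) + arr.shape[2:])

    def max_psrf(self) -> float:
        if not self.diagnostics:
            raise ValueError("diagnostics unavailable (need >= 2 chains)")
        return float(max(np.max(v) for v in self.diagnostics.values()))

    def parameters_at(self, draw: int) -> ModelParameters:
        """Natural-scale parameters of one flattened draw index."""
        params = ModelParameters.zeros(self.spec)
        for name in _NATURAL_BLOCKS:
            if name in self.blocks:
                value = self.stacked(name)[draw]
                setattr(params, name, value if np.ndim(value) else float(value))
        params.sigmas = {k: float(self.stacked(k)[draw]) for k in self.sigma_draws}
        return params


def _compute_diagnostics(blocks, sigma_draws) -> dict[str, np.ndarray]:
    diags: dict[str, np.ndarray] = {}
    for source in (blocks, sigma_draws):
        for name, arr in source.items():
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            vals = np.empty(flat.shape[2])
            for j in range(flat.shape[2]):
                try:
                    vals[j] = potential_scale_reduction(flat[:, :, j])
                except DegenerateChainError:
                    vals[j] = 1.0  # constant scalar (eg theta fixed at 1)
            diags[name] = vals
    return diags


def fit(
    spec: ModelSpec,
    data: MortalityDataset,
    graph: AdjacencyGraph,
    chains: int = 2,
    draws: int = 500,
    warmup: int = 500,
    seed: int = 0,
    target_accept: float = 0.9,
    max_leapfrog: int = 32,
    init_jitter: float = 0.1,
) -> PosteriorSamples:
    """Fit one model by HMC and return convergence-checked posterior samples.

    Reproducible given ``seed``; chain c uses an independent stream spawned
    from it.  Raises :class:`InitialisationError` if the posterior is not
    finite at a chain's starting point.
    """
    if draws < 1 or warmup < 0 or chains < 1:
        raise ValueError("chains, draws must be >= 1 and warmup >= 0")
    transform = ModelTransform(spec, data, graph)
    psi0 = transform.initial_point()
    lp0, _ = transform.logp_grad(psi0)
    if not np.isfinite(lp0):
        params = transform.natural(psi0)
        offender = "unknown"
        for name in _NATURAL_BLOCKS:
            val = getattr(params, name, None)
            if val is not None and not np.all(np.isfinite(np.atleast_1d(val))):
                offender = name
                break
        raise InitialisationError(f"non-finite posterior at initialisation (block: {offender})")

    mass0 = transform.fisher_matrix(psi0)
    streams = np.random.SeedSequence(seed).spawn(chains + 1)
    split_rng = np.random.default_rng(streams[chains])
    psi_chains = []
    stats_all = []
    for c in range(chains):
        rng = np.random.default_rng(streams[c])
        start = psi0 + init_jitter * rng.standard_normal(transform.dim)
        lp_c, _ = transform.logp_grad(start)
        if not np.isfinite(lp_c):
            start = psi0  # fall back to the unjittered point
        draws_c, stats = hmc_sample(
            transform.logp_grad,
            start,
            n_warmup=warmup,
            n_draws=draws,
            rng=rng,
            target_accept=target_accept,
            max_leapfrog=max_leapfrog,
            init_step=0.1,
            mass_matrix=mass0,
        )
        if stats.accept_rate < 0.6 or stats.n_divergent > max(2, draws // 50):
            # step-size adaptation occasionally locks onto a too-large step;
            # rerun the chain more conservatively (still seed-deterministic)
            rng = np.random.default_rng(streams[c])
            rng.standard_normal(transform.dim)  # consume the jitter draw again
            draws_c, stats = hmc_sample(
                transform.logp_grad,
                start,
                n_warmup=warmup,
                n_draws=draws,
                rng=rng,
                target_accept=0.95,
                max_leapfrog=max_leapfrog,
                init_step=0.02,
                mass_matrix=mass0,
            )
        psi_chains.append(draws_c)
        stats_all.append(
            {
                "chain": c,
                "accept_rate": stats.accept_rate,
                "step_size": stats.step_size,
                "n_divergent": stats.n_divergent,
            }
        )

    blocks: dict[str, np.ndarray] = {}
    sigma_draws: dict[str, np.ndarray] = {}
    for c, psis in enumerate(psi_chains):
        nat = _natural_draws(transform, psis, split_rng)
        for name, arr in nat["blocks"].items():
            blocks.setdefault(name, []).append(arr)  # type: ignore[arg-type]
        for name, arr in nat["sigmas"].items():
            sigma_draws.setdefault(name, []).append(arr)  # type: ignore[arg-type]
    blocks = {k: np.stack(v) for k, v in blocks.items()}
    sigma_draws = {k: np.stack(v) for k, v in sigma_draws.items()}

    diagnostics = _compute_diagnostics(blocks, sigma_draws) if chains >= 2 else {}
    return PosteriorSamples(spec, blocks, sigma_draws, seed, diagnostics, stats_all)


def _natural_draws(
    transform: ModelTransform, psis: np.ndarray, split_rng: np.random.Generator | None = None
) -> dict:
    """Map latent draws (S, dim) to natural-scale block arrays.

    The sampler carries the total spatial effect w = u + v; here each draw's
    (u, v) pair is recovered by sampling u from its exact Gaussian
    conditional given (w, sigma_u, sigma_v) in the Laplacian eigenbasis.
    """
    if split_rng is None:
        split_rng = np.random.default_rng(0)
    spec = transform.spec
    n = psis.shape[0]
    first = transform.natural(psis[0])
    block_names = ["u_spatial", "v_spatial"]
    if spec.model_id == 5:
        block_names += ["lc_level", "lc_loading", "lc_period", "lc_drift"]
    else:
        block_names += ["alpha0", "beta0", "alpha_age", "beta_age", "gamma_period"]
        if spec.model_id == 2:
            block_names += ["theta"]
        if spec.has_cohort:
            block_names += ["phi_cohort"]
        if spec.model_id == 4:
            block_names += ["w_age"]
    blocks = {
        name: np.empty((n,) + np.shape(getattr(first, name))) for name in block_names
    }
    sigmas = {name: np.empty(n) for name in first.sigmas}
    vecs = transform.icar_eigvecs
    lam = transform.icar_eigvals
    for i in range(n):
        p = transform.natural(psis[i])
        if transform.n_s > 1:
            w = p.u_spatial  # sampler stores the total spatial effect here
            su, sv = p.sigmas["spatial_u"], p.sigmas["spatial_v"]
            w_e = vecs.T @ w
            c = (su**2 / lam) / (su**2 / lam + sv**2)
            u_e = c * w_e + np.sqrt(c) * sv * split_rng.standard_normal(lam.size)
            p.u_spatial = vecs @ u_e
            p.v_spatial = w - p.u_spatial
        for name in block_names:
            blocks[name][i] = getattr(p, name)
        for name in sigmas:
            sigmas[name][i] = p.sigmas[name]
    return {"blocks": blocks, "sigmas": sigmas}


def posterior_quantiles(samples: PosteriorSamples, quantity, probs) -> np.ndarray:
    """Empirical quantiles over draws of a derived scalar.

    ``quantity`` maps a :class:`ModelParameters` draw to a scalar; ``probs``
    are probabilities in (0, 1).  Quantiles use linear interpolation of order
    statistics.
    """
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError("probs must lie strictly inside (0, 1)")
    if samples.n_total == 0:
        raise ValueError("empty draw set")
    values = np.array([quantity(samples.parameters_at(i)) for i in range(samples.n_total)])
    return np.quantile(values, probs)


def cell_log_rate_draws(samples: PosteriorSamples, spec: ModelSpec | None = None) -> np.ndarray:
    """Posterior draws of the log death rate on the full grid: (n_total, s, a, t)."""
    spec = spec or samples.spec
    out = np.empty((samples.n_total, spec.n_districts, spec.n_ages, spec.n_years))
    for i in range(samples.n_total):
        out[i] = linear_predictor_array(samples.parameters_at(i), spec)
    return out


# ---------------------------------------------------------------------------
# persistence: a directory of per-block CSV draw tables plus a manifest
# ---------------------------------------------------------------------------

def save_samples(samples: PosteriorSamples, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    shapes = {}
    for group, store in (("block", samples.blocks), ("sigma", samples.sigma_draws)):
        for name, arr in store.items():
            flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
            np.savetxt(directory / f"{group}_{name}.csv", flat, delimiter=",")
            shapes[f"{group}_{name}"] = list(arr.shape)
    manifest = {
        "model_id": samples.spec.model_id,
        "n_chains": samples.n_chains,
        "n_draws": samples.n_draws,
        "seed": samples.seed,
        "n_districts": samples.spec.n_districts,
        "years": samples.spec.years.tolist(),
        "age_starts": samples.spec.age_scheme.group_starts.tolist(),
        "rw_order_age": samples.spec.rw_order_age,
        "rw_order_time": samples.spec.rw_order_time,
        "hyper_scale": samples.spec.hyper_scale,
        "shapes": shapes,
        "sampler_stats": samples.sampler_stats,
        "max_psrf": (samples.max_psrf() if samples.diagnostics else None),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_samples(directory: str | Path) -> PosteriorSamples:
    from .ages import AgeScheme

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    starts = np.asarray(manifest["age_starts"], dtype=float)
    widths = np.concatenate((np.diff(starts), [np.inf]))
    scheme = AgeScheme(starts, widths)
    spec = ModelSpec(
        manifest["model_id"],
        scheme,
        np.asarray(manifest["years"], dtype=int),
        manifest["n_districts"],
        rw_order_age=manifest["rw_order_age"],
        rw_order_time=manifest["rw_order_time"],
        hyper_scale=manifest["hyper_scale"],
    )
    blocks: dict[str, np.ndarray] = {}
    sigma_draws: dict[str, np.ndarray] = {}
    for key, shape in manifest["shapes"].items():
        group, name = key.split("_", 1)
        flat = np.loadtxt(directory / f"{key}.csv", delimiter=",")
        arr = flat.reshape(shape)
        (blocks if group == "block" else sigma_draws)[name] = arr
    samples = PosteriorSamples(spec, blocks, sigma_draws, manifest["seed"])
    samples.sampler_stats = manifest.get("sampler_stats", [])
    if samples.n_chains >= 2:
        samples.diagnostics = _compute_diagnostics(blocks, sigma_draws)
    return samples
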