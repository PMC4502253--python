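"""The five competing mortality-model structures.

All models describe sex-specific death counts ``D[s,a,t]`` in district *s*,
age group *a*, calendar year *t* as Poisson with mean
``population * exp(eta)``, and differ in the linear predictor ``eta``:

* model 1: smooth age-specific levels and linear trends, a non-linear
  period random walk, and a spatial (BYM) district level ::

      eta = alpha0 + alpha_a + (beta0 + beta_a) * t~ + gamma_t + u_s + v_s

* model 2: model 1 with a sign-preserving exponent on the centred time
  covariate, ``t~ -> sign(t~) |t~|**theta``, allowing faster- or
  slower-than-linear trends;
* model 3: model 1 plus a birth-cohort random-walk term ``phi_c``;
* model 4: model 3 with smooth age-specific weights ``w_a in [0,1]`` on the
  cohort term;
* model 5: a Lee-Carter structure (age level ``a_a``, age loading ``b_a``,
  period index ``k_t`` following a random walk with drift) plus the same
  BYM spatial level.

``t~`` is the calendar year centred at the mid-period year, and the cohort
index follows the convention in :mod:`spatemort.ages`.  Age profiles get
second-order random-walk (RW2) priors so levels and trends vary smoothly
with age; period and cohort deviations get RW1 priors; the spatial term is
Besag-York-Mollie: an intrinsic CAR component ``u`` plus an exchangeable
component ``v``.  Identification: every deviation block is centred to sum
to zero (the Lee-Carter loading sums to one, its period index to zero), the
free linear (ramp) coefficient of each RW2 block carries a standard-normal
prior, and innovation scales carry half-normal hyperpriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .adjacency import AdjacencyGraph
from .ages import AgeScheme, cohort_index

#: components present in each model
MODEL_COMPONENTS: dict[int, tuple[str, ...]] = {
    1: ("age_level", "age_slope", "linear_trend", "period_rw", "bym"),
    2: ("age_level", "age_slope", "power_trend", "period_rw", "bym"),
    3: ("age_level", "age_slope", "linear_trend", "period_rw", "cohort_rw", "bym"),
    4: ("age_level", "age_slope", "linear_trend", "period_rw", "weighted_cohort_rw", "bym"),
    5: ("lee_carter", "bym"),
}

SUM_TO_ZERO_TOL = 1e-8


class ConstraintError(ValueError):
    """A parameter block violates its identification constraint."""


# ---------------------------------------------------------------------------
# linear-algebra helpers shared with the generator and the sampler
# ---------------------------------------------------------------------------

def centred_ramp(n: int) -> np.ndarray:
    """Unit-norm, mean-zero linear ramp of length n."""
    r = np.arange(n, dtype=float)
    r -= r.mean()
    return r / np.linalg.norm(r)


def cumsum0(z: np.ndarray) -> np.ndarray:
    """Path with a leading zero: [0, z1, z1+z2, ...]."""
    return np.concatenate(([0.0], np.cumsum(z)))


def rw1_basis(n: int) -> np.ndarray:
    """(n, n-1) map from RW1 increments to a sum-to-zero path.

    Centring leaves first differences untouched, so a standard-normal vector
    of increments maps to a path whose increment density is exactly RW1.
    """
    k = np.zeros((n, n - 1))
    for j in range(n - 1):
        k[j + 1 :, j] = 1.0
    return k - k.mean(axis=0, keepdims=True)

def rw2_basis(n: int) -> np.ndarray:
    """(n, n-2) map from RW2 second differences to a path orthogonal to {1, ramp}.

    Projecting out the affine null space leaves second differences untouched,
    so the implied density on the path is exactly the RW2 increment density;
    the affine part is carried by a separate ramp coefficient.
    """
    if n < 3:
        raise ValueError("RW2 needs at least 3 points")
    k = np.zeros((n, n - 2))
    for j in range(n - 2):
        k[:, j] = cumsum0(cumsum0(np.eye(n - 2)[j]))  # double integration
    ones = np.ones(n) / np.sqrt(n)
    ramp = centred_ramp(n)
    for v in (ones, ramp):
        k -= np.outer(v, v @ k)
    return k


from functools import lru_cache


def _poly_columns(n: int, degree: int) -> list[np.ndarray]:
    """Orthonormal polynomial directions 1, x, ..., x^degree of length n."""
    idx = np.arange(n, dtype=float)
    cols: list[np.ndarray] = []
    for d in range(degree + 1):
        v = idx**d
        for c in cols:
            v = v - (c @ v) * c
        cols.append(v / np.linalg.norm(v))
    return cols


@lru_cache(maxsize=64)
def projected_rw1_basis(n: int, degree: int = 1) -> np.ndarray:
    """(n, n-1-degree) orthogonalised map from iid normals to a
    polynomial-trend-free RW1 path.

    An RW1 path projected orthogonal to the polynomials of degree up to
    ``degree`` (degree 1 removes level and drift; degree 2 additionally the
    quadratic, used for cohort blocks whose quadratic is aliased with the
    age, period and age-trend components).  Columns are ``U @ diag(S)`` from
    the thin SVD of the projected cumulative-sum map, so a standard-normal
    latent vector induces exactly the projected-RW distribution.
    """
    if n < degree + 2:
        raise ValueError("projected RW1 needs at least degree + 2 points")
    m = rw1_basis(n)
    for v in _poly_columns(n, degree):
        m = m - np.outer(v, v @ m)
    k = n - 1 - degree
    u_mat, s_vals, _ = np.linalg.svd(m, full_matrices=False)
    return u_mat[:, :k] * s_vals[:k]


@lru_cache(maxsize=64)
def _restricted_penalty_logdet(n: int, order: int) -> float:
    """log det of the RW penalty restricted to the trend-free subspace."""
    basis = projected_rw1_basis(n, 1)
    u_mat = basis / np.linalg.norm(basis, axis=0)
    m = np.diff(u_mat, n=order, axis=0)
    sign, logdet = np.linalg.slogdet(m.T @ m)
    if sign <= 0:
        raise ValueError("degenerate restricted penalty")
    return float(logdet)


def icar_basis(graph: AdjacencyGraph) -> np.ndarray:
    """(n, n-1) map from iid normals to a unit-scale intrinsic-CAR draw.

    Uses the eigenbasis of the graph Laplacian restricted to its positive
    eigenvalues; draws are automatically sum-to-zero on a connected graph.
    """
    q = graph.laplacian()
    vals, vecs = np.linalg.eigh(q)
    keep = vals > 1e-8 * max(vals.max(), 1.0)
    if keep.sum() < graph.n_units - 1:
        raise ValueError("adjacency graph must be connected for the ICAR prior")
    return vecs[:, keep] / np.sqrt(vals[keep])


# ---------------------------------------------------------------------------
# specs and parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Structure and dimensions of one of the five models.

    ``hyper_scale`` is the scale of the half-normal hyperpriors on all
    innovation SDs (log-rate scale); ``theta_prior_sd`` the SD of the
    log-normal prior on the trend exponent (median 1).
    """

    model_id: int
    age_scheme: AgeScheme
    years: np.ndarray
    n_districts: int
    rw_order_age: int = 2
    rw_order_time: int = 1
    hyper_scale: float = 1.0
    theta_prior_sd: float = 0.25
    #: constrain period and cohort blocks to zero mean *and* zero slope, so the
    #: linear trend is carried by beta0 alone (standard APC identification)
    trend_constrained: bool = True

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_COMPONENTS:
            raise ValueError(f"model_id must be in 1..5, got {self.model_id}")
        if self.rw_order_age not in (1, 2) or self.rw_order_time not in (1, 2):
            raise ValueError("rw_order must be 1 or 2")
        self.years = np.asarray(self.years, dtype=int)
        self._cohort_idx, self._n_cohorts = cohort_index(self.age_scheme, self.years)

    @property
    def n_ages(self) -> int:
        return self.age_scheme.n_groups

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def n_cohorts(self) -> int:
        return self._n_cohorts

    @property
    def cohort_idx(self) -> np.ndarray:
        """(n_ages, n_years) cohort-band index per cell."""
        return self._cohort_idx

    @property
    def t_centred(self) -> np.ndarray:
        """Calendar year minus the mid-period year."""
        return self.years - self.years.mean()

    @property
    def components(self) -> tuple[str, ...]:
        return MODEL_COMPONENTS[self.model_id]

    def to_dict(self) -> dict:
        """Flat key-value form (see :mod:`spatemort.config`)."""
        return {
            "model_id": self.model_id,
            "first_year": int(self.years[0]),
            "n_years": int(self.years.size),
            "n_districts": self.n_districts,
            "age_starts": ",".join(f"{x:g}" for x in self.age_scheme.group_starts),
            "rw_order_age": self.rw_order_age,
            "rw_order_time": self.rw_order_time,
            "hyper_scale": self.hyper_scale,
            "theta_prior_sd": self.theta_prior_sd,
            "trend_constrained": int(self.trend_constrained),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        starts = np.array([float(x) for x in str(d["age_starts"]).split(",")])
        widths = np.concatenate((np.diff(starts), [np.inf]))
        first = int(d["first_year"])
        years = np.arange(first, first + int(d["n_years"]))
        return cls(
            int(d["model_id"]),
            AgeScheme(starts, widths),
            years,
            int(d["n_districts"]),
            rw_order_age=int(d.get("rw_order_age", 2)),
            rw_order_time=int(d.get("rw_order_time", 1)),
            hyper_scale=float(d.get("hyper_scale", 1.0)),
            theta_prior_sd=float(d.get("theta_prior_sd", 0.25)),
            trend_constrained=bool(int(d.get("trend_constrained", 1))),
        )

    @property
    def has_cohort(self) -> bool:
        return self.model_id in (3, 4)


def _zeros(n: int) -> np.ndarray:
    return np.zeros(n)


@dataclass
class ModelParameters:
    """Natural-scale parameter blocks of one model (or generating truth).

    Deviation blocks sum to zero; ``w_age`` lies in [0,1]; for model 5 the
    loading sums to one and the period index to zero.  ``sigmas`` maps
    component names to innovation SDs.
    """

    alpha0: float = 0.0
    beta0: float = 0.0
    alpha_age: np.ndarray = None  # type: ignore[assignment]
    beta_age: np.ndarray = None  # type: ignore[assignment]
    gamma_period: np.ndarray = None  # type: ignore[assignment]
    phi_cohort: np.ndarray = None  # type: ignore[assignment]
    u_spatial: np.ndarray = None  # type: ignore[assignment]
    v_spatial: np.ndarray = None  # type: ignore[assignment]
    theta: float = 1.0
    w_age: np.ndarray = None  # type: ignore[assignment]
    lc_level: np.ndarray = None  # type: ignore[assignment]
    lc_loading: np.ndarray = None  # type: ignore[assignment]
    lc_period: np.ndarray = None  # type: ignore[assignment]
    lc_drift: float = 0.0
    sigmas: dict = field(default_factory=dict)

    @classmethod
    def zeros(cls, spec: ModelSpec) -> "ModelParameters":
        n_a, n_t, n_s, n_c = spec.n_ages, spec.n_years, spec.n_districts, spec.n_cohorts
        return cls(
            alpha_age=_zeros(n_a),
            beta_age=_zeros(n_a),
            gamma_period=_zeros(n_t),
            phi_cohort=_zeros(n_c),
            u_spatial=_zeros(n_s),
            v_spatial=_zeros(n_s),
            w_age=np.ones(n_a),
            lc_level=_zeros(n_a),
            lc_loading=np.full(n_a, 1.0 / n_a),
            lc_period=_zeros(n_t),
            sigmas={},
        )


def trend_covariate(spec: ModelSpec, theta: float, t_centred: np.ndarray | None = None) -> np.ndarray:
    """The model's time covariate: t~ (models 1, 3-5) or sign(t~)|t~|^theta (model 2)."""
    t = spec.t_centred if t_centred is None else np.asarray(t_centred, dtype=float)
    if spec.model_id != 2:
        return t
    return np.sign(t) * np.abs(t) ** theta


def linear_predictor_array(params: ModelParameters, spec: ModelSpec) -> np.ndarray:
    """Log death rate on the full (district, age, year) grid."""
    n_s = spec.n_districts
    spatial = (params.u_spatial + params.v_spatial)[:, None, None]
    if spec.model_id == 5:
        eta = (
            params.lc_level[None, :, None]
            + params.lc_loading[None, :, None] * params.lc_period[None, None, :]
            + spatial
        )
        return np.broadcast_to(eta, (n_s, spec.n_ages, spec.n_years)).copy()
    g = trend_covariate(spec, params.theta)
    eta = (
        params.alpha0
        + params.alpha_age[None, :, None]
        + (params.beta0 + params.beta_age)[None, :, None] * g[None, None, :]
        + params.gamma_period[None, None, :]
        + spatial
    )
    if spec.has_cohort:
        coh = params.phi_cohort[spec.cohort_idx]  # (n_a, n_t)
        if spec.model_id == 4:
            coh = params.w_age[:, None] * coh
        eta = eta + coh[None, :, :]
    return np.broadcast_to(eta, (n_s, spec.n_ages, spec.n_years)).copy()


def linear_predictor(
    params: ModelParameters, spec: ModelSpec, district: int, age: int, year: int
) -> float:
    """Log death rate of a single cell (indices into the spec's grid)."""
    if not (0 <= district < spec.n_districts):
        raise ValueError(f"district index {district} out of range")
    if not (0 <= age < spec.n_ages):
        raise ValueError(f"age index {age} out of range")
    if not (0 <= year < spec.n_years):
        raise ValueError(f"year index {year} out of range")
    if spec.model_id == 5:
        eta = (
            params.lc_level[age]
            + params.lc_loading[age] * params.lc_period[year]
            + params.u_spatial[district]
            + params.v_spatial[district]
        )
        return float(eta)
    g = trend_covariate(spec, params.theta)[year]
    eta = (
        params.alpha0
        + params.alpha_age[age]
        + (params.beta0 + params.beta_age[age]) * g
        + params.gamma_period[year]
        + params.u_spatial[district]
        + params.v_spatial[district]
    )
    if spec.has_cohort:
        coh = params.phi_cohort[spec.cohort_idx[age, year]]
        if spec.model_id == 4:
            coh = params.w_age[age] * coh
        eta += coh
    return float(eta)


def log_likelihood(params: ModelParameters, spec: ModelSpec, data) -> float:
    """Poisson log likelihood over all cells (full log-pmf, constants included).

    Each cell contributes ``D*log(mu) - mu - log(D!)`` with
    ``mu = population * exp(eta)``; a zero-death cell contributes ``-mu``.
    """
    deaths = np.asarray(data.deaths, dtype=float)
    pop = np.asarray(data.population, dtype=float)
    if np.any(deaths < 0):
        raise ValueError("negative death counts")
    if np.any(pop <= 0):
        raise ValueError("non-positive population")
    expected_shape = (spec.n_districts, spec.n_ages, spec.n_years)
    if deaths.shape != expected_shape:
        raise ValueError(f"data shape {deaths.shape} does not match spec {expected_shape}")
    eta = linear_predictor_array(params, spec)
    log_mu = np.log(pop) + eta
    return float(np.sum(deaths * log_mu - np.exp(log_mu) - gammaln(deaths + 1.0)))


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def _norm_logpdf(x: np.ndarray, sigma: float) -> np.ndarray:
    return -0.5 * np.log(2.0 * np.pi) - np.log(sigma) - 0.5 * (np.asarray(x) / sigma) ** 2


def _check_sum_zero(x: np.ndarray, name: str, target: float = 0.0) -> None:
    if abs(float(np.sum(x)) - target) > SUM_TO_ZERO_TOL * max(1.0, np.abs(x).max()):
        raise ConstraintError(f"block {name} violates its sum constraint")


def _rw_logpdf(x: np.ndarray, sigma: float, order: int) -> float:
    """Random-walk smoothness density of a centred block.

    RW1: Gaussian first differences.  RW2: Gaussian second differences plus a
    standard-normal prior on the block's coefficient along the centred unit
    ramp (the linear direction is in the RW2 null space, so it needs its own
    proper prior).
    """
    x = np.asarray(x, dtype=float)
    if order == 1:
        return float(np.sum(_norm_logpdf(np.diff(x), sigma)))
    lp = float(np.sum(_norm_logpdf(np.diff(x, n=2), sigma)))
    slope = float(centred_ramp(x.size) @ x)
    lp += float(_norm_logpdf(slope, 10.0))  # weak: age-profile slopes are O(10)
    return lp


def _driftfree_logpdf(x: np.ndarray, sigma: float, order: int, name: str) -> float:
    """Smoothness density of a period/cohort block with no linear trend.

    These blocks are identified orthogonal to the constant and the linear
    ramp (the drift belongs to the explicit linear-trend parameter), and the
    prior is the RW increment density *conditioned* on that subspace: a
    proper Gaussian with quadratic form |diff(x, order)|^2 / sigma^2 and rank
    n - 2, normalised on the subspace.  The quad form is basis-independent.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    scale = max(1.0, np.abs(x).max())
    for v in _poly_columns(n, 1)[1:]:
        if abs(float(v @ x)) > SUM_TO_ZERO_TOL * scale:
            raise ConstraintError(f"block {name} violates its trend-free constraint")
    quad = float(np.sum(np.diff(x, n=order) ** 2))
    k = n - 2
    return float(
        0.5 * _restricted_penalty_logdet(n, order)
        - 0.5 * k * np.log(2.0 * np.pi)
        - k * np.log(sigma)
        - 0.5 * quad / sigma**2
    )


def _half_normal_logpdf(sigma: float, scale: float) -> float:
    if sigma < 0:
        return -np.inf
    return float(0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (sigma / scale) ** 2)


def icar_logpdf(u: np.ndarray, sigma: float, graph: AdjacencyGraph) -> float:
    """Intrinsic-CAR density of a sum-to-zero block, with its proper
    normalising constant on that subspace (pseudo-determinant of the
    Laplacian).  Invariant to adding a constant to ``u`` before centring."""
    q = graph.laplacian()
    quad = float(u @ q @ u)
    vals = np.linalg.eigvalsh(q)
    pos = vals[vals > 1e-8 * max(vals.max(), 1.0)]
    n_free = pos.size
    return float(
        0.5 * np.sum(np.log(pos))
        - 0.5 * n_free * np.log(2.0 * np.pi)
        - n_free * np.log(sigma)
        - quad / (2.0 * sigma**2)
    )


_MODEL14_SIGMAS = ("age_level", "age_slope", "period", "spatial_u", "spatial_v")


def log_prior(params: ModelParameters, spec: ModelSpec, graph: AdjacencyGraph) -> float:
    """Joint log prior of all blocks and hyperparameters of the model.

    Raises :class:`ConstraintError` when a centred block violates its sum
    constraint beyond tolerance.
    """
    if graph.n_units != spec.n_districts:
        raise ValueError("adjacency graph does not match n_districts")
    sig = params.sigmas
    lp = 0.0
    # spatial BYM, shared by all models
    _check_sum_zero(params.u_spatial, "u_spatial")
    _check_sum_zero(params.v_spatial, "v_spatial")
    lp += icar_logpdf(params.u_spatial, sig["spatial_u"], graph)
    lp += float(np.sum(_norm_logpdf(params.v_spatial, sig["spatial_v"])))
    lp += _half_normal_logpdf(sig["spatial_u"], spec.hyper_scale)
    lp += _half_normal_logpdf(sig["spatial_v"], spec.hyper_scale)

    if spec.model_id == 5:
        lp += _rw_logpdf(params.lc_level - params.lc_level.mean(), sig["lc_level"], 2)
        lp += float(_norm_logpdf(params.lc_level.mean(), 10.0))
        _check_sum_zero(params.lc_loading, "lc_loading", target=1.0)
        _check_sum_zero(params.lc_period, "lc_period")
        lp += float(np.sum(_norm_logpdf(np.diff(params.lc_loading), sig["lc_loading"])))
        incr = np.diff(params.lc_period)
        lp += float(np.sum(_norm_logpdf(incr - params.lc_drift, sig["lc_period"])))
        lp += float(_norm_logpdf(params.lc_drift, 1.0))
        for name in ("lc_level", "lc_loading", "lc_period"):
            lp += _half_normal_logpdf(sig[name], spec.hyper_scale)
        return float(lp)

    _check_sum_zero(params.alpha_age, "alpha_age")
    _check_sum_zero(params.beta_age, "beta_age")
    _check_sum_zero(params.gamma_period, "gamma_period")
    lp += float(_norm_logpdf(params.alpha0, 10.0))
    lp += float(_norm_logpdf(params.beta0, 1.0))
    lp += _rw_logpdf(params.alpha_age, sig["age_level"], spec.rw_order_age)
    lp += _rw_logpdf(params.beta_age, sig["age_slope"], spec.rw_order_age)
    if spec.trend_constrained:
        lp += _driftfree_logpdf(params.gamma_period, sig["period"], spec.rw_order_time,
                                "gamma_period")
    else:
        lp += _rw_logpdf(params.gamma_period, sig["period"], spec.rw_order_time)
    for name in _MODEL14_SIGMAS[:3]:
        lp += _half_normal_logpdf(sig[name], spec.hyper_scale)
    if spec.model_id == 2:
        if params.theta <= 0:
            return -np.inf
        lp += float(_norm_logpdf(np.log(params.theta), spec.theta_prior_sd))
    if spec.has_cohort:
        _check_sum_zero(params.phi_cohort, "phi_cohort")
        if spec.trend_constrained:
            lp += _driftfree_logpdf(params.phi_cohort, sig["cohort"], 1, "phi_cohort")
        else:
            lp += _rw_logpdf(params.phi_cohort, sig["cohort"], 1)
        lp += _half_normal_logpdf(sig["cohort"], spec.hyper_scale)
    if spec.model_id == 4:
        w = np.asarray(params.w_age, dtype=float)
        if np.any(w <= 0) or np.any(w >= 1):
            raise ConstraintError("w_age must lie strictly inside (0, 1)")
        omega = np.log(w / (1.0 - w))
        lp += float(np.sum(_norm_logpdf(np.diff(omega), sig["cohort_weight"])))
        lp += float(_norm_logpdf(omega.mean(), 2.0))
        lp += _half_normal_logpdf(sig["cohort_weight"], spec.hyper_scale)
    return float(lp)


__all__ = [
    "MODEL_COMPONENTS",
    "ConstraintError",
    "ModelParameters",
    "ModelSpec",
    "centred_ramp",
    "cumsum0",
    "icar_basis",
    "icar_logpdf",
    "linear_predictor",
    "linear_predictor_array",
    "log_likelihood",
    "log_prior",
    "rw1_basis",
    "rw2_basis",
    "trend_covariate",
]
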