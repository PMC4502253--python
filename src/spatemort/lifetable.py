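"""Abridged life tables, old-age extension, decomposition and inequality summaries.

Life expectancy is computed from age-specific death rates with standard
abridged life-table recursions.  Because grouped data end in an open 85+
group, rates are first extended to 100+ with the Kannisto-Thatcher logistic
old-age hazard, rescaled so the extended groups reproduce the observed 85+
aggregate rate exactly.  Changes in life expectancy are attributed to age
groups with the discrete (Arriaga) decomposition, which is exactly additive.

Separation-factor conventions
-----------------------------
``standard`` (default): a = 0.1 years in the infant group and n/2 in other
closed groups — the usual low-mortality convention.  ``exponential``:
constant hazard within each interval (q = 1 - exp(-n m), L = d/m), which
makes a constant-hazard population analytically exact (e0 = 1/mu).
The open group always has q = 1 and L = l/m.

All heavy routines accept leading batch dimensions on the rates array, so
life expectancy can be evaluated per posterior draw, per district and per
year in one vectorised call — credible intervals are always formed on life
expectancy itself, never from summarised rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ages import AgeScheme

RADIX = 100_000.0
INFANT_SEPARATION = 0.1  # years lived by infants dying in year one
_Q_CAP = 1.0 - 1e-12

#: lower age bounds used to fit the old-age logistic hazard
KT_FIT_STARTS = (70.0, 75.0, 80.0, 85.0)
#: extension groups replacing 85+: 85-89, 90-94, 95-99, 100+
KT_EXTENSION_STARTS = (85.0, 90.0, 95.0, 100.0)
_KT_MIN_SLOPE = 1e-6


# ---------------------------------------------------------------------------
# core life-table arithmetic (batched over leading axes)
# ---------------------------------------------------------------------------

def _separation_factors(scheme: AgeScheme) -> np.ndarray:
    a = scheme.group_widths / 2.0
    if scheme.group_widths[0] == 1.0:
        a[0] = INFANT_SEPARATION
    return a


def _columns(m: np.ndarray, scheme: AgeScheme, convention: str):
    """q, l, d, L, T, e with batch dims; radix 1."""
    m = np.asarray(m, dtype=float)
    n_groups = scheme.n_groups
    if m.shape[-1] != n_groups:
        raise ValueError("rates do not match the age scheme")
    if np.any(m < 0):
        raise ValueError("death rates must be non-negative")
    if np.any(m[..., -1] <= 0):
        raise ValueError("open-group death rate must be positive (L undefined at m=0)")
    widths = scheme.group_widths
    batch = m.shape[:-1]
    q = np.empty_like(m)
    if convention == "standard":
        a = _separation_factors(scheme)
        for j in range(n_groups - 1):
            n = widths[j]
            q[..., j] = np.minimum(n * m[..., j] / (1.0 + (n - a[j]) * m[..., j]), _Q_CAP)
    elif convention == "exponential":
        for j in range(n_groups - 1):
            q[..., j] = -np.expm1(-widths[j] * m[..., j])
    else:
        raise ValueError(f"unknown a_x convention {convention!r}")
    q[..., -1] = 1.0

    l = np.empty_like(m)
    d = np.empty_like(m)
    big_l = np.empty_like(m)
    l[..., 0] = 1.0
    for j in range(n_groups):
        d[..., j] = l[..., j] * q[..., j]
        if j < n_groups - 1:
            l[..., j + 1] = l[..., j] - d[..., j]
            n = widths[j]
            if convention == "exponential":
                with np.errstate(invalid="ignore", divide="ignore"):
                    big_l[..., j] = np.where(
                        m[..., j] > 0, d[..., j] / np.where(m[..., j] > 0, m[..., j], 1.0),
                        n * l[..., j],
                    )
            else:
                a_j = _separation_factors(scheme)[j]
                big_l[..., j] = n * l[..., j + 1] + a_j * d[..., j]
        else:
            big_l[..., j] = l[..., j] / m[..., j]
    t_col = np.flip(np.cumsum(np.flip(big_l, axis=-1), axis=-1), axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(l > 0, t_col / np.where(l > 0, l, 1.0), 0.0)
    del batch
    return q, l, d, big_l, t_col, e


@dataclass
class LifeTable:
    """Abridged life table for one population-year (radix 100 000)."""

    scheme: AgeScheme
    m: np.ndarray
    q: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray
    a: np.ndarray
    convention: str = "standard"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_start": self.scheme.group_starts,
                "m": self.m,
                "q": self.q,
                "l": self.l,
                "d": self.d,
                "L": self.L,
                "T": self.T,
                "e": self.e,
                "a": self.a,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_life_table(
    m: np.ndarray, scheme: AgeScheme, a_convention: str = "standard"
) -> LifeTable:
    """Build an abridged life table from death rates on one age scheme."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 1:
        raise ValueError("build_life_table expects a 1-D rate vector")
    q, l, d, big_l, t_col, e = _columns(m, scheme, a_convention)
    widths = scheme.group_widths
    with np.errstate(invalid="ignore", divide="ignore"):
        a_eff = np.where(
            d > 1e-300,
            (big_l - np.concatenate((widths[:-1] * l[1:], [0.0]))) / np.where(d > 0, d, 1.0),
            widths / 2.0,
        )
    a_eff[-1] = 1.0 / m[-1]  # mean residual life in the open group
    return LifeTable(
        scheme, m, q, l * RADIX, d * RADIX, big_l * RADIX, t_col * RADIX, e, a_eff,
        a_convention,
    )


def life_expectancy_at(lt: LifeTable, age_start: float) -> float:
    """Remaining life expectancy at a group boundary of the table's scheme."""
    return float(lt.e[lt.scheme.index_of(age_start)])


# ---------------------------------------------------------------------------
# Kannisto-Thatcher old-age extension
# ---------------------------------------------------------------------------

@dataclass
class KTModel:
    """Logistic old-age hazard mu(x) = a*exp(b*x) / (1 + a*exp(b*x)).

    ``fallback`` marks a degenerate fit (slope <= 0), in which case the
    extension uses a flat hazard equal to the open-group rate.
    """

    a_kt: float
    b_kt: float
    fallback: bool = False

    def hazard(self, x: np.ndarray) -> np.ndarray:
        z = self.a_kt * np.exp(self.b_kt * np.asarray(x, dtype=float))
        return z / (1.0 + z)


def fit_kannisto_thatcher(rates: np.ndarray, ages: np.ndarray) -> KTModel:
    """Least-squares fit of the logistic hazard on the logit scale.

    ``rates`` are old-age death rates at group midpoints ``ages``.  Rates are
    clipped just below 1 before the logit.  A non-increasing fit (b <= 0)
    returns a flagged fallback model (flat-hazard extension).
    """
    rates = np.asarray(rates, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if rates.size < 2:
        raise ValueError("need at least two old-age groups")
    if np.any(rates <= 0):
        raise ValueError("old-age rates must be positive")
    clipped = np.minimum(rates, 1.0 - 1e-9)
    y = np.log(clipped / (1.0 - clipped))
    slope, intercept = np.polyfit(ages, y, 1)
    if slope <= _KT_MIN_SLOPE:
        import warnings

        warnings.warn("degenerate Kannisto-Thatcher fit; using flat-hazard extension")
        return KTModel(float(np.exp(intercept)), 0.0, fallback=True)
    return KTModel(float(np.exp(intercept)), float(slope), fallback=False)


def _extension_scheme() -> AgeScheme:
    starts = np.asarray(KT_EXTENSION_STARTS)
    widths = np.concatenate((np.diff(starts), [np.inf]))
    return AgeScheme(starts, widths)


def _stationary_person_years(rates: np.ndarray) -> np.ndarray:
    """Sum of L over the extension groups for a cohort of 1 entering at 85.

    Uses the exponential within-interval convention, which keeps q < 1 (and
    the identity L*r = d exact) for arbitrarily high old-age rates.
    """
    scheme = _extension_scheme()
    _, _, _, big_l, _, _ = _columns(rates, scheme, "exponential")
    return big_l.sum(axis=-1)


def expand_terminal_group(m85plus: float, kt: KTModel) -> np.ndarray:
    """Split an open 85+ rate into 85-89, 90-94, 95-99, 100+ rates.

    The logistic hazard fixes the shape over the new groups; a single scale
    factor is solved so that the life-table-consistent aggregate rate over
    85+ (total deaths / total person-years of the implied stationary
    population, exponential within-interval convention) reproduces
    ``m85plus`` exactly.
    """
    if not m85plus > 0:
        raise ValueError("open-group rate must be positive")
    scheme = _extension_scheme()
    if kt.fallback:
        return np.full(scheme.n_groups, float(m85plus))
    shape = kt.hazard(scheme.group_midpoints)
    # aggregate rate of a stationary cohort = 1 / total person-years;
    # person-years decrease monotonically in the scale, so bisect on log-kappa
    target = 1.0 / m85plus
    lo, hi = -30.0, 12.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _stationary_person_years(np.exp(mid) * shape) > target:
            lo = mid
        else:
            hi = mid
    return np.exp(0.5 * (lo + hi)) * shape


def extend_rates(m: np.ndarray, scheme: AgeScheme) -> tuple[np.ndarray, AgeScheme]:
    """Replace the open group of a rates array with KT-extended old-age groups.

    Accepts leading batch dimensions; the KT fit and rescaling are vectorised
    over the batch.  Returns the extended rates and the extended scheme.
    """
    m = np.asarray(m, dtype=float)
    fit_idx = [scheme.index_of(s) for s in KT_FIT_STARTS if np.any(np.isclose(scheme.group_starts, s))]
    if len(fit_idx) < 2:
        raise ValueError("scheme lacks the old-age groups needed for the KT fit")
    x = scheme.group_midpoints[fit_idx]
    rates_fit = np.clip(m[..., fit_idx], 1e-300, 1.0 - 1e-9)
    y = np.log(rates_fit / (1.0 - rates_fit))
    xc = x - x.mean()
    slope = (y * xc).sum(axis=-1) / (xc**2).sum(axis=-1)
    intercept = y.mean(axis=-1) - slope * x.mean()
    fallback = slope <= _KT_MIN_SLOPE

    ext_scheme = _extension_scheme()
    mids = ext_scheme.group_midpoints
    z = np.exp(intercept[..., None] + slope[..., None] * mids)
    shape = z / (1.0 + z)
    shape = np.where(fallback[..., None], 1.0, shape)

    m85 = m[..., -1]
    target = 1.0 / m85
    lo = np.full(m85.shape, -30.0)
    hi = np.full(m85.shape, 12.0)
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        ext = np.exp(mid)[..., None] * shape
        above = _stationary_person_years(ext) > target
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    kappa = np.exp(0.5 * (lo + hi))
    ext_rates = kappa[..., None] * shape
    ext_rates = np.where(fallback[..., None], m85[..., None], ext_rates)

    full_scheme = AgeScheme(
        np.concatenate((scheme.group_starts[:-1], ext_scheme.group_starts)),
        np.concatenate((scheme.group_widths[:-1], ext_scheme.group_widths)),
    )
    full = np.concatenate((m[..., :-1], ext_rates), axis=-1)
    return full, full_scheme


def life_expectancy_from_rates(
    m: np.ndarray,
    scheme: AgeScheme,
    convention: str = "standard",
    extend: bool = True,
    at_age: float = 0.0,
) -> np.ndarray:
    """Life expectancy from rates, with optional KT extension; batched.

    ``m`` may carry leading batch axes (posterior draws, districts, years);
    the result drops the age axis.
    """
    m = np.asarray(m, dtype=float)
    if extend:
        m, scheme = extend_rates(m, scheme)
    _, l, _, _, t_col, e = _columns(m, scheme, convention)
    return e[..., scheme.index_of(at_age)]


# ---------------------------------------------------------------------------
# decomposition and aggregation
# ---------------------------------------------------------------------------

def decompose_change(lt_ref: LifeTable, lt_new: LifeTable) -> np.ndarray:
    """Discrete (Arriaga) age decomposition of e0(new) - e0(ref).

    Closed groups contribute a direct term (more person-years lived within
    the group) plus an indirect/interaction term (extra survivors exposed to
    the new regime later); the open group contributes only the direct term.
    Contributions sum exactly to the difference in life expectancy at birth.
    """
    if lt_ref.scheme.n_groups != lt_new.scheme.n_groups or not np.allclose(
        lt_ref.scheme.group_starts, lt_new.scheme.group_starts
    ):
        raise ValueError("life tables must share one age scheme")
    l1 = lt_ref.l / lt_ref.l[0]
    l2 = lt_new.l / lt_new.l[0]
    big_l1 = lt_ref.L / lt_ref.l[0]
    big_l2 = lt_new.L / lt_new.l[0]
    t1 = lt_ref.T / lt_ref.l[0]
    t2 = lt_new.T / lt_new.l[0]
    n = lt_ref.scheme.n_groups
    contrib = np.empty(n)
    for j in range(n - 1):
        direct = l1[j] * (big_l2[j] / l2[j] - big_l1[j] / l1[j])
        indirect = t2[j + 1] * (l1[j] / l2[j] - l1[j + 1] / l2[j + 1])
        contrib[j] = direct + indirect
    contrib[-1] = l1[-1] * (t2[-1] / l2[-1] - t1[-1] / l1[-1])
    return contrib


def national_rate(district_rates: np.ndarray, district_populations: np.ndarray) -> np.ndarray:
    """Population-weighted average of district death rates.

    The district axis is the first axis; populations broadcast against the
    rates (a per-district vector or a full per-cell array).
    """
    rates = np.asarray(district_rates, dtype=float)
    pops = np.asarray(district_populations, dtype=float)
    if pops.ndim < rates.ndim:
        pops = pops.reshape(pops.shape + (1,) * (rates.ndim - pops.ndim))
    if np.any(pops <= 0):
        raise ValueError("populations must be positive")
    pops = np.broadcast_to(pops, rates.shape)
    total = pops.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("zero total population")
    return (rates * pops).sum(axis=0) / total


def inequality_spread(
    e0_by_district: np.ndarray, lo_pct: float = 1.0, hi_pct: float = 99.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-district life-expectancy spread, per posterior draw.

    ``e0_by_district`` has shape (n_draws, n_districts) (a single draw may be
    passed as a 1-D vector).  The spread is the difference between the
    ``hi_pct`` and ``lo_pct`` percentiles across districts (linear
    interpolation of order statistics).  Returns the per-draw spreads and
    their posterior (2.5, 50, 97.5)% quantiles.
    """
    e0 = np.atleast_2d(np.asarray(e0_by_district, dtype=float))
    if e0.shape[1] < 2:
        raise ValueError("inequality spread needs at least two districts")
    spreads = np.percentile(e0, hi_pct, axis=1) - np.percentile(e0, lo_pct, axis=1)
    return spreads, np.quantile(spreads, [0.025, 0.5, 0.975])


def quintile_summary(
    e0_by_district: np.ndarray,
    deprivation_index: np.ndarray,
    district_populations: np.ndarray,
) -> pd.DataFrame:
    """Life expectancy by deprivation quintile of districts.

    Districts are ranked by the deprivation index (higher = more deprived)
    and split into five equal-count groups; each quintile reports its
    population-weighted life expectancy and within-quintile min-max range.
    """
    e0 = np.asarray(e0_by_district, dtype=float)
    dep = np.asarray(deprivation_index, dtype=float)
    pops = np.asarray(district_populations, dtype=float)
    if e0.shape != dep.shape or e0.shape != pops.shape:
        raise ValueError("inputs must share one district index")
    if np.any(~np.isfinite(dep)):
        raise ValueError("deprivation index missing (non-finite) for some district")
    order = np.argsort(dep, kind="stable")
    rows = []
    for qi, idx in enumerate(np.array_split(order, 5), start=1):
        w = pops[idx]
        rows.append(
            {
                "quintile": qi,
                "n_districts": idx.size,
                "e0": float(np.sum(w * e0[idx]) / np.sum(w)),
                "e0_min": float(e0[idx].min()),
                "e0_max": float(e0[idx].max()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# small sex-gap arithmetic used when combining male and female results
# ---------------------------------------------------------------------------

def sex_gap(e0_female: float, e0_male: float) -> float:
    """Female minus male life expectancy."""
    return float(e0_female) - float(e0_male)


def gap_after_gains(initial_gap: float, gain_male: float, gain_female: float) -> float:
    """Female-male gap after sex-specific life-expectancy gains."""
    return float(initial_gap) + float(gain_female) - float(gain_male)
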