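"""Mortality datasets: death counts and populations on a district x age x year grid.

One dataset holds one sex.  Counts and populations share a single dense index
space (no missing cells); populations are person-years and must be positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ages import AgeScheme

CSV_COLUMNS = ["district", "age_start", "year", "deaths", "population"]


@dataclass
class MortalityDataset:
    """Dense arrays of deaths and person-years.

    Attributes
    ----------
    deaths, population:
        Arrays of shape (n_districts, n_ages, n_years).
    age_scheme:
        The abridged age grouping of the age axis.
    years:
        Ordered calendar years of the year axis.
    sex_label:
        Free-text label ("male", "female", ...); analyses are sex-specific.
    """

    deaths: np.ndarray
    population: np.ndarray
    age_scheme: AgeScheme
    years: np.ndarray
    sex_label: str = "unspecified"
    district_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths)
        self.population = np.asarray(self.population, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if self.deaths.shape != self.population.shape:
            raise ValueError("deaths and population must share one shape")
        if self.deaths.ndim != 3:
            raise ValueError("expected (district, age, year) arrays")
        n_s, n_a, n_t = self.deaths.shape
        if n_a != self.age_scheme.n_groups:
            raise ValueError("age axis does not match the age scheme")
        if n_t != self.years.size:
            raise ValueError("year axis does not match the year labels")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be consecutive")
        if np.any(self.deaths < 0):
            raise ValueError("negative death counts")
        if np.any(~np.isfinite(self.population)) or np.any(self.population <= 0):
            raise ValueError("population must be positive and finite in every cell")
        if self.district_ids is None:
            self.district_ids = np.arange(n_s)
        else:
            self.district_ids = np.asarray(self.district_ids)
            if self.district_ids.size != n_s:
                raise ValueError("district_ids length does not match district axis")

    @property
    def n_districts(self) -> int:
        return self.deaths.shape[0]

    @property
    def n_ages(self) -> int:
        return self.deaths.shape[1]

    @property
    def n_years(self) -> int:
        return self.deaths.shape[2]

    def rates(self) -> np.ndarray:
        """Empirical death rates deaths/population, cellwise."""
        return self.deaths / self.population

    def subset_years(self, years: np.ndarray) -> "MortalityDataset":
        mask = np.isin(self.years, years)
        return MortalityDataset(
            self.deaths[:, :, mask],
            self.population[:, :, mask],
            self.age_scheme,
            self.years[mask],
            self.sex_label,
            self.district_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns district, age_start, year, deaths, population."""
        n_s, n_a, n_t = self.deaths.shape
        d_idx, a_idx, t_idx = np.meshgrid(
            np.arange(n_s), np.arange(n_a), np.arange(n_t), indexing="ij"
        )
        return pd.DataFrame(
            {
                "district": self.district_ids[d_idx.ravel()],
                "age_start": self.age_scheme.group_starts[a_idx.ravel()],
                "year": self.years[t_idx.ravel()],
                "deaths": self.deaths.ravel(),
                "population": self.population.ravel(),
            }
        )


def write_mortality_csv(data: MortalityDataset, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_mortality_csv(
    path: str | Path,
    age_scheme: AgeScheme | None = None,
    sex_label: str = "unspecified",
) -> MortalityDataset:
    """Read a long-format mortality CSV into a dense dataset.

    The file must have header ``district,age_start,year,deaths,population``,
    exactly one row per (district, age, year) cell, non-negative deaths and
    positive populations.  Violations raise :class:`ValueError` naming the
    offending row (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")

    bad = df.index[df["deaths"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative deaths at data row {bad[0] + 1}")
    bad = df.index[~(df["population"] > 0)]
    if len(bad):
        raise ValueError(f"{path}: non-positive population at data row {bad[0] + 1}")
    dup = df.duplicated(subset=["district", "age_start", "year"])
    if dup.any():
        row = int(np.nonzero(dup.to_numpy())[0][0]) + 1
        raise ValueError(f"{path}: duplicate (district, age_start, year) cell at data row {row}")

    districts = np.sort(df["district"].unique())
    starts = np.sort(df["age_start"].unique())
    years = np.sort(df["year"].unique().astype(int))
    if age_scheme is None:
        if starts.size == 19 and np.allclose(starts, AgeScheme.default().group_starts):
            age_scheme = AgeScheme.default()
        else:
            widths = np.concatenate((np.diff(starts), [np.inf]))
            age_scheme = AgeScheme(starts, widths)
    elif not np.allclose(np.sort(starts), age_scheme.group_starts):
        raise ValueError(f"{path}: age_start values do not match the supplied scheme")

    n_s, n_a, n_t = districts.size, age_scheme.n_groups, years.size
    if len(df) != n_s * n_a * n_t:
        raise ValueError(
            f"{path}: expected {n_s * n_a * n_t} cells "
            f"({n_s} districts x {n_a} ages x {n_t} years), found {len(df)} rows"
        )

    d_pos = np.searchsorted(districts, df["district"].to_numpy())
    a_pos = np.searchsorted(age_scheme.group_starts, df["age_start"].to_numpy())
    t_pos = np.searchsorted(years, df["year"].to_numpy())
    deaths = np.zeros((n_s, n_a, n_t))
    pop = np.zeros((n_s, n_a, n_t))
    deaths[d_pos, a_pos, t_pos] = df["deaths"].to_numpy()
    pop[d_pos, a_pos, t_pos] = df["population"].to_numpy()
    return MortalityDataset(deaths, pop, age_scheme, years, sex_label, districts)
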