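"""Abridged age-group schemes and the cohort-index convention.

Mortality data come grouped into abridged age bands: an infant group (0),
a 1-4 group, five-year groups up to 80-84, and an open-ended terminal group
(85+).  Birth cohorts are indexed from the same scheme: the cohort of a
(year, age group) cell is ``year - midpoint(age group)``, binned into
five-year cohort bands.  The open group's midpoint is fixed at 90 years,
the standard convention for a low-mortality 85+ population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: years past the open group's start taken as its midpoint (85+ -> 90)
OPEN_GROUP_MIDPOINT_OFFSET = 5.0

#: width of a cohort band in years
COHORT_BAND_WIDTH = 5


@dataclass(frozen=True)
class AgeScheme:
    """Contiguous, non-overlapping age groups; the last group is open-ended.

    Parameters
    ----------
    group_starts:
        Ordered lower bounds of each group, in years.
    group_widths:
        Width of each group in years; the final entry is ``np.inf``.
    """

    group_starts: np.ndarray
    group_widths: np.ndarray
    group_midpoints: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        starts = np.asarray(self.group_starts, dtype=float)
        widths = np.asarray(self.group_widths, dtype=float)
        if starts.ndim != 1 or starts.size == 0:
            raise ValueError("group_starts must be a non-empty 1-D sequence")
        if starts.size != widths.size:
            raise ValueError("group_starts and group_widths must have equal length")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("group_starts must be strictly increasing")
        if not np.isinf(widths[-1]):
            raise ValueError("the final group must be open-ended (width inf)")
        if np.any(widths[:-1] <= 0):
            raise ValueError("closed-group widths must be positive")
        # contiguity: start[i] + width[i] == start[i+1]
        if starts.size > 1 and not np.allclose(starts[:-1] + widths[:-1], starts[1:]):
            raise ValueError("age groups must be contiguous and non-overlapping")
        mids = starts + widths / 2.0
        mids[-1] = starts[-1] + OPEN_GROUP_MIDPOINT_OFFSET
        object.__setattr__(self, "group_starts", starts)
        object.__setattr__(self, "group_widths", widths)
        object.__setattr__(self, "group_midpoints", mids)

    @classmethod
    def default(cls) -> "AgeScheme":
        """The 19-group abridged scheme: 0, 1-4, 5-9, ..., 80-84, 85+."""
        starts = np.concatenate(([0.0, 1.0], np.arange(5.0, 90.0, 5.0)))
        widths = np.concatenate(([1.0, 4.0], np.full(16, 5.0), [np.inf]))
        return cls(starts, widths)

    @property
    def n_groups(self) -> int:
        return int(self.group_starts.size)

    def index_of(self, age_start: float) -> int:
        """Index of the group whose lower bound is ``age_start``."""
        hits = np.nonzero(np.isclose(self.group_starts, age_start))[0]
        if hits.size == 0:
            raise ValueError(f"{age_start} is not a group boundary of this scheme")
        return int(hits[0])


def cohort_index(scheme: AgeScheme, years: np.ndarray) -> tuple[np.ndarray, int]:
    """Map every (age group, year) cell to a cohort-band index.

    The raw cohort label of a cell is ``year - midpoint(age group)``; labels
    are binned into 5-year bands and shifted so indices start at zero.

    Returns
    -------
    idx:
        Integer array of shape (n_ages, n_years); index increases with
        birth year (older cohorts have lower indices).
    n_cohorts:
        Number of distinct cohort bands spanned by the grid.
    """
    years = np.asarray(years, dtype=float)
    raw = years[None, :] - scheme.group_midpoints[:, None]
    bands = np.floor(raw / COHORT_BAND_WIDTH).astype(int)
    bands -= bands.min()
    return bands, int(bands.max()) + 1
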