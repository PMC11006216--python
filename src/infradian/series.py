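"""Core containers: one woman's cycle series and a cohort of series.

A :class:`CycleSeries` holds the ordered lengths (whole days) of a woman's
consecutive menstrual cycles, anchored to the calendar date of the first
bleeding onset.  Cycle ``i`` (1-based) starts ``sum(lengths[:i-1])`` days
after ``first_start_date``; the cycle length is the number of days from one
bleeding onset up to and including the day before the next onset.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .errors import ParameterError

__all__ = ["CycleSeries", "Cohort"]


@dataclass(frozen=True)
class CycleSeries:
    """Ordered cycle lengths of one woman, anchored to a first onset date.

    Parameters
    ----------
    woman_id
        Opaque identifier, unique within a cohort.
    first_start_date
        Calendar date of the first day of the first recorded cycle.
    lengths
        Cycle lengths in whole days; every entry must be >= 1.
    """

    woman_id: str
    first_start_date: dt.date
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        lengths = tuple(int(x) for x in self.lengths)
        if len(lengths) == 0:
            raise ParameterError("lengths: series must contain at least one cycle")
        if any(x < 1 for x in lengths):
            raise ParameterError("lengths: every cycle length must be >= 1 day")
        object.__setattr__(self, "lengths", lengths)
        if not isinstance(self.first_start_date, dt.date) or isinstance(
            self.first_start_date, dt.datetime
        ):
            raise ParameterError("first_start_date: must be a calendar date")

    @property
    def n_cycles(self) -> int:
        return len(self.lengths)

    @property
    def lengths_arr(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @property
    def mean_length(self) -> float:
        """Arithmetic mean cycle length — the woman's reference period."""
        return float(np.mean(self.lengths))

    def onset_dates(self) -> list[dt.date]:
        """Calendar date of the first day of every cycle (one per cycle)."""
        starts = np.concatenate([[0], np.cumsum(self.lengths[:-1])])
        return [self.first_start_date + dt.timedelta(days=int(d)) for d in starts]

    def shifted(self, days: int) -> "CycleSeries":
        """A copy whose first start date is moved by ``days`` (lengths kept)."""
        return replace(
            self, first_start_date=self.first_start_date + dt.timedelta(days=int(days))
        )


@dataclass(frozen=True)
class Cohort:
    """A collection of cycle series, one per woman."""

    series: tuple[CycleSeries, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "series", tuple(self.series))
        ids = [s.woman_id for s in self.series]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ParameterError(f"series: duplicate woman_id {dup[0]!r} in cohort")

    def __iter__(self) -> Iterator[CycleSeries]:
        return iter(self.series)

    def __len__(self) -> int:
        return len(self.series)

    @property
    def n_women(self) -> int:
        return len(self.series)

    @property
    def n_cycles(self) -> int:
        return int(sum(s.n_cycles for s in self.series))

    def pooled_lengths(self) -> np.ndarray:
        if not self.series:
            return np.empty(0)
        return np.concatenate([s.lengths_arr for s in self.series])
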