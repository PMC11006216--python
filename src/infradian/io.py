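"""Reading, writing, selecting and summarizing cycle-record tables.

CSV schema (UTF-8, header required):

``woman_id``
    string identifier, unique per woman.
``cycle_index``
    1-based integer, consecutive within each woman.
``start_date``
    ISO 8601 calendar date; required for ``cycle_index`` 1.  When present
    for later cycles it must equal the date derived from the first start
    plus the preceding cycle lengths (whole-day arithmetic, no time zones).
``cycle_length_days``
    positive integer.

Selection rules mirror the cohort-construction conventions of large
cycle-series studies: a series is truncated at the cycle *preceding* the
first cycle longer than 60 days (the offending cycle and everything after
it are dropped), and series falling below a minimum length are removed.
"""

from __future__ import annotations

import datetime as dt
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ParameterError
from .series import Cohort, CycleSeries

__all__ = [
    "read_cohort",
    "write_cohort",
    "apply_selection",
    "subset_by_mean_length",
    "summarize_cohort",
]

_COLUMNS = ("woman_id", "cycle_index", "start_date", "cycle_length_days")


def read_cohort(path: str | Path, label: str | None = None) -> Cohort:
    """Read a schema-conformant CSV into a cohort (one series per woman)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"woman_id": str, "start_date": str})
    for col in _COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")

    series = []
    for woman_id, grp in df.groupby("woman_id", sort=True):
        grp = grp.sort_values("cycle_index")
        idx = grp["cycle_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise FormatError(
                f"woman {woman_id!r}: duplicated cycle_index "
                f"{int(idx[np.argmax(np.diff(idx) == 0)])}"
            )
        if idx[0] != 1 or not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise FormatError(
                f"woman {woman_id!r}: cycle_index must be consecutive from 1"
            )
        lengths = []
        for row, val in zip(grp.index, grp["cycle_length_days"]):
            try:
                length = int(val)
            except (TypeError, ValueError):
                raise FormatError(
                    f"row {row}: cycle_length_days {val!r} is not an integer"
                ) from None
            if length < 1:
                raise FormatError(f"row {row}: cycle_length_days must be positive")
            lengths.append(length)

        first_raw = grp["start_date"].iloc[0]
        if not isinstance(first_raw, str) or not first_raw.strip():
            raise FormatError(
                f"woman {woman_id!r}: start_date required for cycle_index 1"
            )
        first_start = _parse_date(first_raw, grp.index[0])
        # later start dates, when present, must equal the derived calendar dates
        derived = first_start
        for k, (row, raw) in enumerate(zip(grp.index, grp["start_date"])):
            if k > 0 and isinstance(raw, str) and raw.strip():
                if _parse_date(raw, row) != derived:
                    raise FormatError(
                        f"row {row}: start_date {raw} does not equal derived "
                        f"date {derived.isoformat()}"
                    )
            derived += dt.timedelta(days=lengths[k])
        series.append(
            CycleSeries(
                woman_id=str(woman_id),
                first_start_date=first_start,
                lengths=tuple(lengths),
            )
        )
    return Cohort(series=tuple(series), label=label if label is not None else path.stem)


def _parse_date(raw: str, row) -> dt.date:
    try:
        return dt.date.fromisoformat(raw.strip())
    except ValueError:
        raise FormatError(f"row {row}: start_date {raw!r} is not an ISO 8601 date") from None


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to the CSV schema, rows ordered by (woman_id, cycle_index).

    Start dates are written for every cycle (derived dates for indices > 1),
    which read_cohort accepts and re-verifies.
    """
    rows = []
    for series in sorted(cohort, key=lambda s: s.woman_id):
        for k, (onset, length) in enumerate(zip(series.onset_dates(), series.lengths)):
            rows.append(
                {
                    "woman_id": series.woman_id,
                    "cycle_index": k + 1,
                    "start_date": onset.isoformat(),
                    "cycle_length_days": length,
                }
            )
    pd.DataFrame(rows, columns=list(_COLUMNS)).to_csv(path, index=False)


def apply_selection(
    cohort: Cohort, min_series_len: int, max_cycle_len: int = 60
) -> Cohort:
    """Truncate at the cycle preceding the first over-long cycle; drop short series.

    Idempotent; never lengthens a series nor adds a woman.  The input
    cohort is not modified.
    """
    if min_series_len < 1:
        raise ParameterError("min_series_len: must be >= 1")
    kept = []
    for series in cohort:
        lengths = series.lengths
        over = [k for k, x in enumerate(lengths) if x > max_cycle_len]
        if over:
            lengths = lengths[: over[0]]
        if len(lengths) >= min_series_len:
            kept.append(
                CycleSeries(
                    woman_id=series.woman_id,
                    first_start_date=series.first_start_date,
                    lengths=lengths,
                )
            )
    return Cohort(series=tuple(kept), label=cohort.label)


def subset_by_mean_length(cohort: Cohort, low: float = 28, high: float = 30) -> Cohort:
    """Keep series whose mean cycle length lies in the closed interval [low, high].

    The mean is compared as an exact rational (sum/count) against the
    bounds, so boundary series (mean exactly 28.0 or 30.0) are retained.
    """
    if low > high:
        raise ParameterError("low: lower bound exceeds upper bound")
    kept = []
    for series in cohort:
        mean = Fraction(int(sum(series.lengths)), series.n_cycles)
        if Fraction(low) <= mean <= Fraction(high):
            kept.append(series)
    return Cohort(series=tuple(kept), label=cohort.label)


def summarize_cohort(cohort: Cohort) -> dict:
    """Cohort descriptives: sizes, pooled length quartiles, per-woman means.

    Quartiles use linear interpolation between order statistics (the
    default type-7 convention).
    """
    if cohort.n_women == 0:
        raise InsufficientDataError("summarize_cohort: empty cohort")
    pooled = cohort.pooled_lengths()
    per_woman_mean = np.array([s.mean_length for s in cohort])
    q1, med, q3 = np.quantile(pooled, [0.25, 0.5, 0.75])
    return {
        "n_women": cohort.n_women,
        "n_cycles": cohort.n_cycles,
        "pooled_q1": float(q1),
        "pooled_median": float(med),
        "pooled_q3": float(q3),
        "per_woman_mean_min": float(per_woman_mean.min()),
        "per_woman_mean_q1": float(np.quantile(per_woman_mean, 0.25)),
        "per_woman_mean_median": float(np.quantile(per_woman_mean, 0.5)),
        "per_woman_mean_q3": float(np.quantile(per_woman_mean, 0.75)),
        "per_woman_mean_max": float(per_woman_mean.max()),
    }
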