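"""Normalized actograms, trend/band decomposition, and wavelet detection.

The actogram normalizes each woman's series to her own mean cycle length
(her reference infradian period): the cumulative sum of the deviations
``length_i - reference_period`` gives the phase offset of every cycle
onset relative to a perfectly periodic rhythm.  Because the reference is
the sample mean, the final cumulative offset is identically zero.

The offset series is decomposed additively into

* a **trend** — Gaussian kernel regression over cycle index with an
  effective window of 12 cycles (about one year), capturing drifts and
  the displaced baseline after phase jumps; and
* a **band** component — an asymmetric Christiano-Fitzgerald band-pass
  passing oscillations of 3 to 12 cycles' period, isolating the
  relative-coordination "wavelets";

with residual = offsets - trend - band, so the three parts reconstruct
the offsets exactly.

A *wavelet* is one full oscillation of the band component: a pair of
adjacent opposite-sign runs between zero crossings.  Its duration is the
run-pair span in cycles (pairs shorter than 4 cycles are discarded as
irregularities) and its amplitude is the maximum one-sided excursion
``max |band|`` within it, in days.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.tsa.filters.cf_filter import cffilter

from .errors import ConsistencyError, InsufficientDataError, ParameterError
from .series import Cohort, CycleSeries

__all__ = [
    "Actogram",
    "Wavelet",
    "build_actogram",
    "long_trend",
    "bandpass_cf",
    "detect_wavelets",
    "classify_wavelets",
    "flag_large_amplitude",
    "render_actogram",
    "cohort_wavelet_table",
]

#: Labels a wavelet can receive from :func:`classify_wavelets`.
CONTEXTS = ("stable", "after_jump", "with_fluctuations")


@dataclass(frozen=True)
class Actogram:
    """Per-woman normalized actogram and its trend/band decomposition.

    ``trend`` and ``band`` are NaN-filled when the series is too short for
    the corresponding smoother (fewer than 12 / 6 cycles).
    """

    woman_id: str
    reference_period: float  # mean cycle length, days
    offsets: np.ndarray  # cumulative (length - reference), days, one per cycle
    trend: np.ndarray  # 12-cycle kernel smoothing of offsets, days
    band: np.ndarray  # band-pass (3-12 cycle periods) component, days

    @property
    def n_cycles(self) -> int:
        return len(self.offsets)

    @property
    def residual(self) -> np.ndarray:
        return self.offsets - self.trend - self.band

    def implied_lengths(self) -> np.ndarray:
        """Cycle lengths recovered from the offsets (inverse of the cumsum)."""
        return np.diff(np.concatenate([[0.0], self.offsets])) + self.reference_period


@dataclass(frozen=True)
class Wavelet:
    """One full oscillation of the band component.

    Indices are 1-based and inclusive (cycle 1 = first recorded cycle).
    """

    start_index: int
    end_index: int
    amplitude: float  # max one-sided excursion of the band, days
    context: str | None = None  # stable | after_jump | with_fluctuations
    large_amplitude: bool | None = None

    def __post_init__(self) -> None:
        if self.end_index < self.start_index:
            raise ParameterError("end_index: must be >= start_index")
        if self.amplitude < 0:
            raise ParameterError("amplitude: must be >= 0")

    @property
    def duration(self) -> int:
        return self.end_index - self.start_index + 1


def long_trend(offsets: np.ndarray, window: int = 12) -> np.ndarray:
    """Gaussian kernel regression over cycle index, effective window ``window`` cycles.

    The bandwidth is set so the kernel's full width at half maximum equals
    ``window`` (+/- window/2 at half height).  Weights are renormalized at
    the boundaries (Nadaraya-Watson, no padding); the smoother therefore
    preserves constants exactly and straight lines away from the edges.
    """
    offsets = np.asarray(offsets, dtype=float)
    n = len(offsets)
    if n < window:
        raise InsufficientDataError(
            f"long_trend: series of {n} cycles is shorter than the {window}-cycle window"
        )
    sigma = window / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    idx = np.arange(n)
    w = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / sigma) ** 2)
    return (w @ offsets) / w.sum(axis=1)


def bandpass_cf(offsets: np.ndarray, min_period: int = 3, max_period: int = 12) -> np.ndarray:
    """Asymmetric Christiano-Fitzgerald band-pass of the offsets.

    Passes oscillations with period between ``min_period`` and
    ``max_period`` cycles; output has the input's length.
    """
    if not (2 <= min_period < max_period):
        raise ParameterError("min_period: band must satisfy 2 <= min_period < max_period")
    offsets = np.asarray(offsets, dtype=float)
    if len(offsets) < 2 * min_period:
        raise InsufficientDataError(
            f"bandpass_cf: need at least {2 * min_period} cycles, got {len(offsets)}"
        )
    cycle, _trend = cffilter(offsets, low=min_period, high=max_period, drift=False)
    return np.asarray(cycle, dtype=float)


def build_actogram(
    series: CycleSeries,
    trend_window: int = 12,
    band: tuple[int, int] = (3, 12),
) -> Actogram:
    """Actogram of one series: reference period, cumulative offsets, trend, band.

    Needs >= 2 cycles.  For series shorter than the smoothing supports the
    trend/band arrays are NaN-filled (offset construction itself needs
    only the mean).
    """
    if series.n_cycles < 2:
        raise InsufficientDataError(
            f"build_actogram: woman {series.woman_id!r} has fewer than 2 cycles"
        )
    lengths = series.lengths_arr
    reference = float(lengths.mean())
    offsets = np.cumsum(lengths - reference)
    nan = np.full_like(offsets, np.nan)
    trend = long_trend(offsets, trend_window) if len(offsets) >= trend_window else nan
    band_c = (
        bandpass_cf(offsets, band[0], band[1]) if len(offsets) >= 2 * band[0] else nan
    )
    return Actogram(
        woman_id=series.woman_id,
        reference_period=reference,
        offsets=offsets,
        trend=trend,
        band=band_c,
    )


def _sign_runs(band: np.ndarray, tol: float = 1e-12) -> list[tuple[int, int, int]]:
    """Maximal runs of constant nonzero sign: (start, end, sign), 0-based inclusive."""
    sign = np.where(band > tol, 1, np.where(band < -tol, -1, 0))
    runs: list[tuple[int, int, int]] = []
    start = None
    cur = 0
    for k, s in enumerate(sign):
        if s == 0:
            if start is not None:
                runs.append((start, k - 1, cur))
                start = None
            continue
        if start is None:
            start, cur = k, s
        elif s != cur:
            runs.append((start, k - 1, cur))
            start, cur = k, s
    if start is not None:
        runs.append((start, len(sign) - 1, cur))
    return runs


def detect_wavelets(
    trend: np.ndarray, band: np.ndarray, min_duration: int = 4
) -> list[Wavelet]:
    """Pair adjacent opposite-sign runs of the band into full oscillations.

    Each sign run between consecutive zero crossings is one half-oscillation;
    consecutive pairs (first with second, third with fourth, ...) form full
    wavelets, and an unpaired terminal run is dropped.  Wavelets spanning
    fewer than ``min_duration`` cycles are discarded as irregularities.
    """
    trend = np.asarray(trend, dtype=float)
    band = np.asarray(band, dtype=float)
    if len(trend) != len(band):
        raise ConsistencyError("detect_wavelets: trend and band differ in length")
    runs = _sign_runs(band)
    wavelets = []
    for a in range(0, len(runs) - 1, 2):
        start = runs[a][0]
        end = runs[a + 1][1]
        duration = end - start + 1
        if duration < min_duration:
            continue
        amplitude = float(np.max(np.abs(band[start : end + 1])))
        wavelets.append(
            Wavelet(start_index=start + 1, end_index=end + 1, amplitude=amplitude)
        )
    return wavelets


def classify_wavelets(
    wavelets: list[Wavelet],
    series: CycleSeries,
    jump_threshold: float = 5.0,
    actogram: Actogram | None = None,
) -> list[Wavelet]:
    """Label each wavelet stable / after_jump / with_fluctuations.

    ``after_jump``: a jump cycle (length exceeding the reference period by
    more than ``jump_threshold`` days) falls within the two cycles before
    the wavelet or inside its first half.  ``with_fluctuations``: the RMS
    of the decomposition residual inside the wavelet exceeds the wavelet's
    band amplitude.  Otherwise ``stable``.  Labels partition the set.
    """
    acto = actogram if actogram is not None else build_actogram(series)
    if acto.n_cycles != series.n_cycles or acto.woman_id != series.woman_id:
        raise ConsistencyError("classify_wavelets: actogram does not match series")
    lengths = series.lengths_arr
    jump_cycles = np.flatnonzero(lengths > acto.reference_period + jump_threshold) + 1
    residual = acto.residual
    out = []
    for wl in wavelets:
        if wl.end_index > series.n_cycles:
            raise ConsistencyError(
                "classify_wavelets: wavelet indices exceed the series length"
            )
        mid = wl.start_index + (wl.duration - 1) // 2
        lo = wl.start_index - 2
        after_jump = bool(np.any((jump_cycles >= lo) & (jump_cycles <= mid)))
        if after_jump:
            context = "after_jump"
        else:
            seg = residual[wl.start_index - 1 : wl.end_index]
            rms = float(np.sqrt(np.nanmean(seg**2)))
            context = "with_fluctuations" if rms > wl.amplitude else "stable"
        out.append(replace(wl, context=context))
    return out


def flag_large_amplitude(
    wavelets: list[Wavelet], threshold: float = 3.0
) -> tuple[int, list[Wavelet]]:
    """Flag wavelets with amplitude >= threshold days; returns (count, flagged list)."""
    flagged = [replace(w, large_amplitude=bool(w.amplitude >= threshold)) for w in wavelets]
    return sum(w.large_amplitude for w in flagged), flagged


def render_actogram(
    actogram: Actogram,
    path: str | None = None,
    smoothed: bool = True,
    text_width: int | None = None,
) -> list[str]:
    """Raster view: one row per cycle, onset position wrapped modulo the period.

    Returns the plain-text grid (one string per cycle, ``*`` marking the
    wrapped onset position, ``|`` the reference phase); when ``path`` is
    given an image with per-cycle bars and optional trend/band overlays is
    saved alongside.
    """
    period = actogram.reference_period
    width = text_width or max(10, int(round(period)))
    onset_phase = np.mod(np.concatenate([[0.0], actogram.offsets[:-1]]), period)
    grid = []
    for phase in onset_phase:
        col = int(np.floor(phase / period * width)) % width
        row = ["."] * width
        row[0] = "|"
        row[col] = "*"
        grid.append("".join(row))
    if path:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 0.18 * actogram.n_cycles + 1))
        rows = np.arange(1, actogram.n_cycles + 1)
        lengths = actogram.implied_lengths()
        for r, phase, length in zip(rows, onset_phase, lengths):
            ax.hlines(-r, phase, phase + length, color="steelblue", lw=2)
        if smoothed and not np.all(np.isnan(actogram.trend)):
            ax.plot(np.mod(actogram.trend, period), -rows, color="saddlebrown", lw=1.2,
                    label="trend (12-cycle)")
            ax.plot(np.mod(actogram.trend + actogram.band, period), -rows,
                    color="darkorange", lw=1.2, label="trend + band")
            ax.legend(fontsize=7, loc="upper right")
        ax.axvline(0, color="black", lw=0.8)
        ax.set_xlabel(f"days (modulo reference period {period:.1f} d)")
        ax.set_ylabel("cycle (downwards)")
        ax.set_yticks([])
        ax.set_title(f"{actogram.woman_id}")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return grid


def cohort_wavelet_table(
    cohort: Cohort,
    min_series_len: int = 18,
    trend_window: int = 12,
    band: tuple[int, int] = (3, 12),
    min_duration: int = 4,
    jump_threshold: float = 5.0,
    amplitude_flag: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Wavelet table and summary for every woman with a long-enough series.

    Series shorter than ``min_series_len`` cycles (default 18, about 1.5
    years) are excluded: shorter records do not support a stable 12-cycle
    trend plus band decomposition.  Returns the per-wavelet DataFrame and
    a summary dict (counts and percentages by context, mean wavelets per
    woman, large-amplitude counts).
    """
    rows = []
    n_eligible = 0
    for series in cohort:
        if series.n_cycles < min_series_len:
            continue
        n_eligible += 1
        acto = build_actogram(series, trend_window=trend_window, band=band)
        wls = detect_wavelets(acto.trend, acto.band, min_duration=min_duration)
        wls = classify_wavelets(wls, series, jump_threshold=jump_threshold, actogram=acto)
        _, wls = flag_large_amplitude(wls, threshold=amplitude_flag)
        for w in wls:
            rows.append(
                {
                    "woman_id": series.woman_id,
                    "start_index": w.start_index,
                    "end_index": w.end_index,
                    "duration": w.duration,
                    "amplitude": w.amplitude,
                    "context": w.context,
                    "large_amp_flag": w.large_amplitude,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "woman_id", "start_index", "end_index", "duration",
            "amplitude", "context", "large_amp_flag",
        ],
    )
    n_wavelets = len(table)
    by_context = {c: int((table["context"] == c).sum()) for c in CONTEXTS} if n_wavelets else {c: 0 for c in CONTEXTS}
    summary = {
        "n_women_eligible": n_eligible,
        "n_wavelets": n_wavelets,
        "wavelets_per_woman": n_wavelets / n_eligible if n_eligible else float("nan"),
        "by_context": by_context,
        "by_context_pct": {
            c: 100.0 * v / n_wavelets if n_wavelets else float("nan")
            for c, v in by_context.items()
        },
        "n_large_amplitude": int(table["large_amp_flag"].sum()) if n_wavelets else 0,
    }
    return table, summary
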