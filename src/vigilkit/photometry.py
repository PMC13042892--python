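"""Isosbestic-corrected fiber-photometry dF/F and event-aligned analysis.

The 405 nm (isosbestic, calcium-independent) channel is fitted to the
470 nm signal by ordinary least squares over the whole recording; the
fractional fluorescence change is

    dF/F = (F470 - F405_fitted) / F405_fitted,

which cancels bleaching, auto-fluorescence and motion artifacts common to
both channels.  dF/F is block-mean downsampled from 20 to 5 Hz, aligned to
events, and z-scored against a per-trial baseline window ([-10, -3] s
before the event).  Window AUCs follow the "total positive peak area with
a 10% minimum peak height" rule: positive excursions whose peak is at
least the stated fraction of the window's tallest peak contribute their
trapezoidal area above zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import EventTimes, UniformSeries, ValidationError

logger = logging.getLogger(__name__)

BASELINE_WINDOW_S: tuple[float, float] = (-10.0, -3.0)


@dataclass
class PhotometrySession:
    """Paired 470/405 nm channels plus event timestamps."""

    f470: UniformSeries
    f405: UniformSeries
    events: EventTimes = field(default_factory=lambda: EventTimes(np.array([])))

    def __post_init__(self) -> None:
        if len(self.f470) != len(self.f405):
            raise ValidationError("470 and 405 channels must have equal length")
        if self.f470.sampling_rate_hz != self.f405.sampling_rate_hz:
            raise ValidationError("470 and 405 channels must share a sampling rate")


@dataclass
class FitResult:
    """OLS map from the 405 channel onto the 470 channel."""

    slope: float
    intercept: float
    fitted_405: UniformSeries


@dataclass
class AlignedZMatrix:
    """Event-aligned z-scored dF/F: rows are trials, columns the relative
    time grid (event at 0).  ``kept_events`` are the event times retained
    (full window coverage and nonzero baseline sd)."""

    z: np.ndarray
    rel_time_s: np.ndarray
    kept_events: np.ndarray
    baseline_window_s: tuple[float, float]

    @property
    def n_trials(self) -> int:
        return self.z.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.z, columns=np.round(self.rel_time_s, 6))
        df.index.name = "trial"
        return df


def fit_isosbestic(session: PhotometrySession) -> FitResult:
    """Least-squares linear fit of the 405 control onto the 470 signal
    over the whole recording."""
    x = session.f405.values
    y = session.f470.values
    if len(x) < 2:
        raise ValidationError("need at least 2 samples to fit")
    if np.ptp(x) == 0:
        raise ValidationError("405 channel is constant; fit is undefined")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = UniformSeries(
        slope * x + intercept,
        session.f405.sampling_rate_hz,
        session.f405.start_time_s,
        session.f405.units,
    )
    return FitResult(float(slope), float(intercept), fitted)


def compute_dff(
    session: PhotometrySession,
    fit: FitResult | None = None,
    min_fitted: float = 1e-6,
) -> UniformSeries:
    """dF/F = (F470 - F405_fitted) / F405_fitted, elementwise at the
    acquisition rate."""
    if fit is None:
        fit = fit_isosbestic(session)
    f = fit.fitted_405.values
    small = np.abs(f) < min_fitted
    if small.any():
        i = np.flatnonzero(small)
        raise ValidationError(
            f"fitted 405 within {min_fitted} of zero over samples "
            f"{i[0]}..{i[-1]}; dF/F undefined"
        )
    dff = (session.f470.values - f) / f
    return UniformSeries(
        dff, session.f470.sampling_rate_hz, session.f470.start_time_s, "dF/F"
    )


def downsample_dff(dff: UniformSeries, target_rate_hz: float = 5.0) -> UniformSeries:
    """Non-overlapping block-mean downsampling (e.g. 20 -> 5 Hz: mean of
    4); trailing samples that do not fill a block are dropped."""
    factor = dff.sampling_rate_hz / target_rate_hz
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValidationError(
            f"rate {dff.sampling_rate_hz} not an integer multiple of {target_rate_hz}"
        )
    factor = int(round(factor))
    n = (len(dff) // factor) * factor
    blocks = dff.values[:n].reshape(-1, factor)
    return UniformSeries(
        blocks.mean(axis=1), target_rate_hz, dff.start_time_s, dff.units
    )


def align_zscore(
    dff: UniformSeries,
    events: EventTimes,
    window_s: tuple[float, float] = (-10.0, 10.0),
    baseline_s: tuple[float, float] = BASELINE_WINDOW_S,
    sd_ddof: int = 1,
) -> AlignedZMatrix:
    """Event-aligned per-trial z-score of dF/F.

    Each event is snapped to the nearest sample of the (5 Hz) grid; trials
    without full window coverage are dropped and logged, as are trials with
    zero baseline standard deviation.  Per trial,
    z = (x - mean_baseline) / sd_baseline, so every retained trial's
    baseline has mean 0 and sd 1 by construction.
    """
    rate = dff.sampling_rate_hz
    pre = int(round(-window_s[0] * rate))
    post = int(round(window_s[1] * rate))
    rel = np.arange(-pre, post + 1) / rate
    b0, b1 = baseline_s
    base_sel = (rel >= b0 - 1e-9) & (rel <= b1 + 1e-9)
    if not base_sel.any():
        raise ValidationError("baseline window contains no samples")
    rows, kept = [], []
    for ev in np.atleast_1d(events.times):
        center = int(round((ev - dff.start_time_s) * rate))
        lo, hi = center - pre, center + post + 1
        if lo < 0 or hi > len(dff):
            logger.info("align_zscore: event at %.3f s lacks full window; dropped", ev)
            continue
        x = dff.values[lo:hi]
        mu = x[base_sel].mean()
        sd = x[base_sel].std(ddof=sd_ddof)
        if sd == 0:
            warnings.warn(
                f"event at {ev:.3f} s has zero baseline sd; trial dropped",
                stacklevel=2,
            )
            continue
        rows.append((x - mu) / sd)
        kept.append(ev)
    z = np.array(rows) if rows else np.empty((0, rel.size))
    return AlignedZMatrix(z, rel, np.array(kept), baseline_s)


def window_auc(
    matrix: AlignedZMatrix,
    window_s: tuple[float, float],
    peak_height_fraction: float = 0.10,
) -> np.ndarray:
    """Per-trial positive-peak area within a window.

    Positive excursions (contiguous runs with z > 0) whose peak reaches at
    least ``peak_height_fraction`` of the window's tallest peak contribute
    their trapezoidal area above zero; smaller blips are ignored.  An
    all-negative window scores 0.
    """
    sel = (matrix.rel_time_s >= window_s[0] - 1e-9) & (
        matrix.rel_time_s <= window_s[1] + 1e-9
    )
    if not sel.any():
        raise ValidationError(f"window {window_s} contains no grid samples")
    t = matrix.rel_time_s[sel]
    out = np.zeros(matrix.n_trials)
    for i in range(matrix.n_trials):
        z = matrix.z[i, sel]
        pos = z > 0
        if not pos.any():
            continue
        d = np.diff(pos.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if pos[0]:
            starts = np.concatenate([[0], starts])
        if pos[-1]:
            ends = np.concatenate([ends, [len(pos)]])
        peaks = np.array([z[s:e].max() for s, e in zip(starts, ends)])
        cut = peak_height_fraction * peaks.max()
        area = 0.0
        for (s, e), pk in zip(zip(starts, ends), peaks):
            if pk >= cut:
                # include the bounding zero-crossing samples so the
                # excursion's full area above zero is integrated
                s2, e2 = max(s - 1, 0), min(e + 1, len(z))
                area += np.trapezoid(np.clip(z[s2:e2], 0, None), t[s2:e2])
        out[i] = area
    return out


def compare_windows(
    matrix: AlignedZMatrix,
    baseline_window_s: tuple[float, float],
    test_windows_s: list[tuple[float, float]],
    peak_height_fraction: float = 0.10,
) -> pd.DataFrame:
    """Per-trial AUC for the baseline window and each test window, for
    downstream paired comparison.  Overlapping baseline/test windows are
    allowed but warned about."""
    cols = {"baseline": window_auc(matrix, baseline_window_s, peak_height_fraction)}
    for w in test_windows_s:
        if w[0] < baseline_window_s[1] and w[1] > baseline_window_s[0]:
            warnings.warn(f"test window {w} overlaps the baseline window", stacklevel=2)
        cols[f"{w[0]:g}_{w[1]:g}"] = window_auc(matrix, w, peak_height_fraction)
    df = pd.DataFrame(cols)
    df.index.name = "trial"
    return df


def paired_window_test(auc_table: pd.DataFrame, test_column: str) -> dict:
    """Convenience paired comparison of a test window against the baseline
    column (Wilcoxon signed-rank, falling back to the sign of the mean
    difference for degenerate data)."""
    from scipy import stats

    diff = auc_table[test_column] - auc_table["baseline"]
    if np.allclose(diff, 0):
        return {"statistic": 0.0, "p_value": 1.0, "mean_difference": 0.0}
    stat, p = stats.wilcoxon(auc_table[test_column], auc_table["baseline"])
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "mean_difference": float(diff.mean()),
    }
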