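"""Sleep architecture, epoch spectral measures, and spindle detection.

The analysis chain mirrors standard rodent polysomnography practice:

1. EEG is low-pass filtered (zero-phase 4th-order Butterworth, 625 Hz
   cutoff) and decimated to 1250 Hz.
2. Each 10-s epoch gets a Welch power spectral density (1-s Hamming
   segments, no overlap, 1 Hz bins); band powers are normalized by the
   epoch's total power over 1-80 Hz.
3. State time, bout counts and bout durations are computed per circadian
   phase from the manually scored hypnogram, in 1-h clock bins averaged
   over each 12-h phase.
4. Sleep spindles are detected on contiguous NREM segments: sigma-band
   (10-15 Hz) filtering, a 700 ms moving RMS envelope, cubing, and a
   threshold of twice the mean cubed envelope over all NREM samples, with
   a 0.5-5 s duration gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import Hypnogram, PhasePartition, UniformSeries, ValidationError

logger = logging.getLogger(__name__)

#: Canonical EEG frequency bands (Hz).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (6.0, 9.0),
    "sigma": (10.0, 15.0),
    "beta": (16.0, 30.0),
    "gamma": (40.0, 80.0),
}

#: Normalization range for "total power" (union of the defined bands).
TOTAL_RANGE_HZ: tuple[float, float] = (1.0, 80.0)

SIGMA_BAND: tuple[float, float] = (10.0, 15.0)


@dataclass(frozen=True)
class SpindleEvent:
    """One detected sigma-band event.  Times are session seconds; ``peak``
    is the maximum of the cubed RMS envelope within the event."""

    start_s: float
    end_s: float
    peak: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


# ---------------------------------------------------------------------------
# preprocessing and spectra

def preprocess_eeg(
    series: UniformSeries,
    cutoff_hz: float = 625.0,
    target_rate_hz: float = 1250.0,
) -> UniformSeries:
    """Low-pass filter and decimate raw EEG to the analysis rate.

    Zero-phase (forward-backward) 4th-order Butterworth low-pass at
    ``cutoff_hz``, then decimation by an integer factor to
    ``target_rate_hz``.  When the input is already at the target rate the
    signal is filtered only (the cutoff is clipped just below Nyquist).
    """
    rate = series.sampling_rate_hz
    if rate < target_rate_hz:
        raise ValidationError(
            f"cannot downsample upward: rate {rate} Hz < target {target_rate_hz} Hz"
        )
    factor = rate / target_rate_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValidationError(
            f"rate {rate} Hz is not an integer multiple of target {target_rate_hz} Hz"
        )
    factor = int(round(factor))
    nyq = rate / 2.0
    wn = min(cutoff_hz, 0.99 * nyq) / nyq
    sos = sps.butter(4, wn, btype="low", output="sos")
    filtered = sps.sosfiltfilt(sos, series.values)
    return UniformSeries(
        filtered[::factor], target_rate_hz, series.start_time_s, series.units
    )


def epoch_psd(
    series: UniformSeries, epoch_s: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch Welch power spectral density.

    Welch settings: Hamming window, segment length equal to one second of
    samples (1 Hz bins), zero overlap, one-sided.  Returns
    ``(freqs, psd)`` with ``psd`` of shape (n_epochs, n_freqs); a trailing
    partial epoch is dropped and logged.
    """
    rate = series.sampling_rate_hz
    per_epoch = int(round(epoch_s * rate))
    nperseg = int(round(rate))
    if per_epoch < nperseg:
        raise ValidationError("epoch shorter than one Welch segment")
    n_epochs = len(series) // per_epoch
    if n_epochs == 0:
        raise ValidationError("series shorter than one epoch")
    dropped = len(series) - n_epochs * per_epoch
    if dropped:
        logger.info("epoch_psd: dropped trailing partial epoch of %d samples", dropped)
    x = series.values[: n_epochs * per_epoch].reshape(n_epochs, per_epoch)
    freqs, psd = sps.welch(
        x, fs=rate, window="hamming", nperseg=nperseg, noverlap=0, axis=-1
    )
    return freqs, psd


def band_powers(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: dict[str, tuple[float, float]] | None = None,
    total_range_hz: tuple[float, float] = TOTAL_RANGE_HZ,
) -> pd.DataFrame:
    """Normalized band-power fractions per epoch.

    fraction(band) = sum of PSD bins with band_lo <= f <= band_hi, divided
    by the summed PSD over ``total_range_hz``.  Also returns the raw total
    power column.
    """
    bands = dict(bands or DEFAULT_BANDS)
    psd = np.atleast_2d(psd)
    if freqs[-1] < total_range_hz[1]:
        raise ValidationError(
            f"spectrum extends to {freqs[-1]} Hz < total range {total_range_hz}"
        )
    in_total = (freqs >= total_range_hz[0]) & (freqs <= total_range_hz[1])
    total = psd[:, in_total].sum(axis=1)
    out = {"total_power": total}
    safe_total = np.where(total > 0, total, np.nan)
    for name, (lo, hi) in bands.items():
        if lo >= hi:
            raise ValidationError(f"band {name!r} has lower >= upper")
        if hi > freqs[-1]:
            raise ValidationError(f"band {name!r} outside spectral support")
        sel = (freqs >= lo) & (freqs <= hi)
        frac = psd[:, sel].sum(axis=1) / safe_total
        out[name] = np.where(total > 0, frac, 0.0)
    df = pd.DataFrame(out)
    df.index.name = "epoch"
    return df


# ---------------------------------------------------------------------------
# hypnogram architecture

def _retained(hyp: Hypnogram, partition: PhasePartition):
    keep = partition.retained_epochs(hyp)
    phases = partition.epoch_phases(hyp)
    return keep, phases


def state_time_percent(
    hyp: Hypnogram, partition: PhasePartition | None = None
) -> pd.DataFrame:
    """Percent time per state per circadian phase.

    Epochs are grouped into 1-h clock bins; per-bin state percentages are
    averaged over each 12-h phase (bins with no epochs are excluded), so
    the three states sum to 100 within each phase.
    """
    partition = partition or PhasePartition()
    keep, phases = _retained(hyp, partition)
    if not keep.any():
        raise ValidationError("no epochs remain after initial discard")
    labels = hyp.labels[keep]
    phases = phases[keep]
    # 1-h clock bin of each epoch, unwrapped along the session so a bin is
    # a specific hour of the recording, not pooled across days
    session_hour = (hyp.epoch_starts_session_s()[keep] + hyp.start_clock_s) // 3600
    rows = []
    from .types import STATES

    for phase in partition.PHASES:
        sel = phases == phase
        if not sel.any():
            raise ValidationError(f"phase {phase!r} has zero epochs")
        bin_ids = np.unique(session_hour[sel])
        per_bin = np.zeros((len(bin_ids), len(STATES)))
        for i, b in enumerate(bin_ids):
            in_bin = sel & (session_hour == b)
            n = in_bin.sum()
            for j, st in enumerate(STATES):
                per_bin[i, j] = 100.0 * np.sum(labels[in_bin] == st) / n
        means = per_bin.mean(axis=0)
        for st, m in zip(STATES, means):
            rows.append({"phase": phase, "state": st, "percent_time": m})
    return pd.DataFrame(rows)


def bouts(hyp: Hypnogram, partition: PhasePartition | None = None) -> pd.DataFrame:
    """Run-length bout table.

    A bout is a maximal run of identical consecutive epoch labels; runs are
    truncated where the circadian phase changes or at the discard boundary,
    so per-phase bout durations sum exactly to per-phase state time.
    Columns: state, phase, start_epoch, n_epochs, duration_s, session_hour
    (the 1-h bin containing the bout's first epoch).
    """
    partition = partition or PhasePartition()
    keep, phases = _retained(hyp, partition)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValidationError("no epochs remain after initial discard")
    labels = hyp.labels[keep]
    ph = phases[keep]
    # split wherever the label or phase changes (retained epochs are contiguous)
    change = np.flatnonzero((labels[1:] != labels[:-1]) | (ph[1:] != ph[:-1])) + 1
    bounds = np.concatenate([[0], change, [len(labels)]])
    rows = []
    starts_session = hyp.epoch_starts_session_s()[keep]
    for s, e in zip(bounds[:-1], bounds[1:]):
        rows.append(
            {
                "state": labels[s],
                "phase": ph[s],
                "start_epoch": int(idx[s]),
                "n_epochs": int(e - s),
                "duration_s": (e - s) * hyp.epoch_length_s,
                "session_hour": int((starts_session[s] + hyp.start_clock_s) // 3600),
            }
        )
    return pd.DataFrame(rows)


def bout_metrics(
    hyp: Hypnogram,
    state: str,
    partition: PhasePartition | None = None,
) -> pd.DataFrame:
    """Bout count (mean per 1-h bin over the phase) and mean bout duration
    per phase for one state.  Phases with no bouts report NaN duration and
    0 count (never 0 duration for "no bouts")."""
    partition = partition or PhasePartition()
    table = bouts(hyp, partition)
    keep, phases = _retained(hyp, partition)
    session_hour = (hyp.epoch_starts_session_s()[keep] + hyp.start_clock_s) // 3600
    rows = []
    for phase in partition.PHASES:
        bins_with_data = np.unique(session_hour[phases[keep] == phase])
        sub = table[(table["state"] == state) & (table["phase"] == phase)]
        counts = sub.groupby("session_hour").size()
        counts = counts.reindex(bins_with_data, fill_value=0)
        rows.append(
            {
                "phase": phase,
                "state": state,
                "bouts_per_hour": float(counts.mean()) if len(counts) else np.nan,
                "mean_bout_duration_s": float(sub["duration_s"].mean())
                if len(sub)
                else np.nan,
                "n_bouts": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spindles

def moving_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving RMS; the window shrinks at the edges."""
    n = len(x)
    half = window // 2
    c = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(n)
    lo = np.clip(i - half, 0, n)
    hi = np.clip(i + half + 1, 0, n)
    return np.sqrt((c[hi] - c[lo]) / (hi - lo))


def _nrem_segments(hyp: Hypnogram) -> list[tuple[float, float]]:
    """Maximal contiguous NREM intervals in session seconds."""
    is_nrem = hyp.labels == "NREM"
    change = np.flatnonzero(is_nrem[1:] != is_nrem[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(is_nrem)]])
    segs = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if is_nrem[s]:
            segs.append((s * hyp.epoch_length_s, e * hyp.epoch_length_s))
    return segs


def detect_spindles(
    eeg: UniformSeries,
    hyp: Hypnogram,
    sigma_band: tuple[float, float] = SIGMA_BAND,
    rms_window_s: float = 0.7,
    threshold_factor: float = 2.0,
    min_duration_s: float = 0.5,
    max_duration_s: float = 5.0,
) -> list[SpindleEvent]:
    """Detect sigma-band spindle events during NREM sleep.

    Each maximal contiguous NREM segment is band-passed to ``sigma_band``
    (4th-order Butterworth, zero phase), a centered ``rms_window_s`` moving
    RMS envelope is computed and cubed, and events are the supra-threshold
    excursions of the cubed envelope, where the threshold is
    ``threshold_factor`` times the mean cubed envelope over *all* NREM
    samples.  Events outside the duration gate are discarded (never split
    or merged).  Event boundaries are the threshold crossings.
    """
    segs = _nrem_segments(hyp)
    if not segs:
        raise ValidationError("hypnogram contains no NREM epochs")
    rate = eeg.sampling_rate_hz
    sos = sps.butter(4, sigma_band, btype="bandpass", fs=rate, output="sos")
    window = int(round(rms_window_s * rate))
    envelopes = []
    seg_samples = []
    for t0, t1 in segs:
        seg = eeg.slice_time(eeg.start_time_s + t0, eeg.start_time_s + t1)
        if len(seg) < window:
            envelopes.append(np.array([]))
            seg_samples.append((t0, 0))
            continue
        filtered = sps.sosfiltfilt(sos, seg.values)
        env = moving_rms(filtered, window) ** 3
        envelopes.append(env)
        seg_samples.append((t0, len(seg)))
    all_env = np.concatenate([e for e in envelopes if e.size])
    if all_env.size == 0:
        raise ValidationError("NREM segments shorter than the RMS window")
    threshold = threshold_factor * all_env.mean()
    events: list[SpindleEvent] = []
    for (t0, _n), env in zip(seg_samples, envelopes):
        if env.size == 0:
            continue
        above = env > threshold
        d = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if above[0]:
            starts = np.concatenate([[0], starts])
        if above[-1]:
            ends = np.concatenate([ends, [len(env)]])
        for s, e in zip(starts, ends):
            dur = (e - s) / rate
            if min_duration_s <= dur <= max_duration_s:
                events.append(
                    SpindleEvent(
                        start_s=eeg.start_time_s + t0 + s / rate,
                        end_s=eeg.start_time_s + t0 + e / rate,
                        peak=float(env[s:e].max()),
                    )
                )
    return events


def spindle_summary(
    events: list[SpindleEvent],
    hyp: Hypnogram,
    partition: PhasePartition | None = None,
) -> pd.DataFrame:
    """Spindle density (events per NREM minute) and mean duration per
    circadian phase.  An event is assigned to the phase of its midpoint.
    Phases with zero NREM minutes report NaN density."""
    partition = partition or PhasePartition()
    keep, phases = _retained(hyp, partition)
    labels = hyp.labels[keep]
    rows = []
    for phase in partition.PHASES:
        nrem_min = (
            np.sum((phases[keep] == phase) & (labels == "NREM"))
            * hyp.epoch_length_s
            / 60.0
        )
        mids = np.array([ev.midpoint_s for ev in events])
        if mids.size:
            ev_clock = (hyp.start_clock_s + mids) % 86400.0
            ev_keep = mids >= partition.discard_initial_s - 1e-9
            in_phase = (partition.phase_of(ev_clock) == phase) & ev_keep
            durs = np.array([ev.duration_s for ev in events])[in_phase]
        else:
            durs = np.array([])
        rows.append(
            {
                "phase": phase,
                "nrem_minutes": nrem_min,
                "n_spindles": int(durs.size),
                "density_per_min": durs.size / nrem_min if nrem_min > 0 else np.nan,
                "mean_duration_s": float(durs.mean()) if durs.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def architecture_summary(
    hyp: Hypnogram,
    partition: PhasePartition | None = None,
    spindles: list[SpindleEvent] | None = None,
) -> pd.DataFrame:
    """Tidy per-state, per-phase architecture table: percent time, bouts
    per hour, mean bout duration; spindle density/duration merged in when
    events are provided."""
    partition = partition or PhasePartition()
    from .types import STATES

    pct = state_time_percent(hyp, partition)
    frames = [
        bout_metrics(hyp, st, partition) for st in STATES
    ]
    bm = pd.concat(frames, ignore_index=True)
    out = pct.merge(bm, on=["phase", "state"], how="left")
    if spindles is not None:
        sp = spindle_summary(spindles, hyp, partition)
        sp = sp.assign(state="NREM")[
            ["phase", "state", "density_per_min", "mean_duration_s"]
        ].rename(
            columns={
                "density_per_min": "spindle_density_per_min",
                "mean_duration_s": "spindle_mean_duration_s",
            }
        )
        out = out.merge(sp, on=["phase", "state"], how="left")
    return out
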