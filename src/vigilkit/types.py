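"""Shared domain types and time/coordinate conventions.

Conventions used throughout the package:

* Time is in seconds.  Session time runs from a recording origin;
  clock-of-day time is seconds from midnight, with all clock arithmetic
  performed modulo 86400 so that windows may wrap midnight.
* Arena coordinates are 2-D top-down centimetres with the origin at the
  corner of the shelter-end wall and x increasing along the arena's long
  (36 cm) axis toward the trigger zone.
* Hypnogram epochs are half-open intervals [t, t + epoch_length); a frame
  or sample belongs to exactly one epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SECONDS_PER_DAY = 86400.0

#: Vigilance-state alphabet used by every hypnogram.
STATES = ("AWAKE", "NREM", "REM")


class ValidationError(ValueError):
    """Input data violates a structural invariant (non-finite samples,
    unknown state label, non-monotone event times, ...)."""


class ConfigurationError(ValueError):
    """Required configuration is missing or inconsistent (no sampling
    rate, missing body point, ...)."""


@dataclass
class UniformSeries:
    """A uniformly sampled signal (EEG, EMG, velocity or photometry).

    Parameters
    ----------
    values
        Sample values.  Units are carried in ``units`` and passed through
        unchanged by every reader and writer.
    sampling_rate_hz
        Sampling rate, > 0.
    start_time_s
        Time of the first sample, in seconds from the session origin (or
        from clock midnight when the series is clock-anchored).
    units
        Free-text unit label (e.g. ``"uV"``, ``"cm/s"``, ``"au"``).
    """

    values: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("series values must be one-dimensional")
        if not self.sampling_rate_hz > 0:
            raise ValidationError(
                f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}"
            )
        bad = np.flatnonzero(~np.isfinite(self.values))
        if bad.size:
            head = ", ".join(map(str, bad[:10]))
            raise ValidationError(
                f"{bad.size} non-finite sample(s) at indices [{head}"
                + ("...]" if bad.size > 10 else "]")
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        """Exact duration = n_samples / rate (no implicit trimming)."""
        return len(self.values) / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        """Sample times: index i maps to start_time_s + i / rate."""
        return self.start_time_s + np.arange(len(self.values)) / self.sampling_rate_hz

    def slice_time(self, t0: float, t1: float) -> "UniformSeries":
        """Samples with time in the half-open interval [t0, t1)."""
        i0 = int(np.ceil((t0 - self.start_time_s) * self.sampling_rate_hz - 1e-9))
        i1 = int(np.ceil((t1 - self.start_time_s) * self.sampling_rate_hz - 1e-9))
        i0 = max(i0, 0)
        i1 = min(max(i1, i0), len(self.values))
        return UniformSeries(
            self.values[i0:i1],
            self.sampling_rate_hz,
            self.start_time_s + i0 / self.sampling_rate_hz,
            self.units,
        )


@dataclass
class Hypnogram:
    """Sequence of fixed-length vigilance-state epochs anchored to clock time.

    ``labels`` take values in :data:`STATES`; ``start_clock_s`` is the
    clock time (seconds from midnight) of the first epoch's start.
    """

    labels: np.ndarray
    epoch_length_s: float = 10.0
    start_clock_s: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U5")
        if self.labels.size == 0:
            raise ValidationError("hypnogram has no epochs")
        if self.epoch_length_s <= 0:
            raise ValidationError("epoch_length_s must be > 0")
        unknown = set(self.labels.tolist()) - set(STATES)
        if unknown:
            raise ValidationError(
                f"unknown state label(s) {sorted(unknown)}; alphabet is {STATES}"
            )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.epoch_length_s

    def epoch_starts_session_s(self) -> np.ndarray:
        """Epoch start times in session seconds (0 at first epoch)."""
        return np.arange(len(self.labels)) * self.epoch_length_s

    def epoch_starts_clock_s(self) -> np.ndarray:
        """Epoch start clock times, wrapped modulo 24 h."""
        return (self.start_clock_s + self.epoch_starts_session_s()) % SECONDS_PER_DAY


@dataclass
class PhasePartition:
    """Circadian partition of the day into active (lights-off) and
    inactive (lights-on) windows, plus an initial discard interval.

    Defaults: active 19:00->07:00 (wrapping midnight), inactive
    07:00->19:00, first hour of the recording discarded.
    """

    active_start_clock_s: float = 19 * 3600.0
    active_end_clock_s: float = 7 * 3600.0
    discard_initial_s: float = 3600.0

    PHASES = ("active", "inactive")

    def is_active(self, clock_s) -> np.ndarray:
        """True where the (wrapped) clock time falls in the active window."""
        c = np.asarray(clock_s, dtype=float) % SECONDS_PER_DAY
        a, b = self.active_start_clock_s, self.active_end_clock_s
        if a <= b:
            return (c >= a) & (c < b)
        return (c >= a) | (c < b)  # window wraps midnight

    def phase_of(self, clock_s) -> np.ndarray:
        return np.where(self.is_active(clock_s), "active", "inactive")

    def epoch_phases(self, hyp: Hypnogram) -> np.ndarray:
        """Phase label per epoch (by epoch start clock time)."""
        return self.phase_of(hyp.epoch_starts_clock_s())

    def retained_epochs(self, hyp: Hypnogram) -> np.ndarray:
        """Boolean mask of epochs kept after the initial discard."""
        return hyp.epoch_starts_session_s() >= self.discard_initial_s - 1e-9


@dataclass
class ArenaGeometry:
    """Looming-arena geometry: shelter | intermediate | trigger zones laid
    out along x from the shelter-end wall (x = 0)."""

    total_length_cm: float = 36.0
    width_cm: float = 19.7
    shelter_length_cm: float = 12.7
    intermediate_length_cm: float = 13.3
    trigger_length_cm: float = 9.9
    screen_height_cm: float = 30.0

    ZONES = ("shelter", "intermediate", "trigger")

    def __post_init__(self) -> None:
        zone_sum = (
            self.shelter_length_cm
            + self.intermediate_length_cm
            + self.trigger_length_cm
        )
        if zone_sum > self.total_length_cm + 0.2:
            raise ValidationError(
                f"zone lengths sum to {zone_sum} cm > total {self.total_length_cm} cm"
            )

    @property
    def shelter_end_x(self) -> float:
        return self.shelter_length_cm

    @property
    def trigger_start_x(self) -> float:
        return self.shelter_length_cm + self.intermediate_length_cm

    @property
    def shelter_center(self) -> np.ndarray:
        return np.array([self.shelter_length_cm / 2.0, self.width_cm / 2.0])

    def zone_of(self, x) -> np.ndarray:
        """Zone label per x coordinate (cm).  x below 0 maps to shelter and
        x beyond the arena to trigger; out-of-bounds coordinates are the
        caller's to flag."""
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, "intermediate", dtype="U12")
        out[x < self.shelter_end_x] = "shelter"
        out[x >= self.trigger_start_x] = "trigger"
        return out


@dataclass
class PoseTrack:
    """Per-frame 2-D coordinates (cm) of named body points at a fixed
    frame rate, with optional per-point confidence in [0, 1].

    Invalid frames are represented as NaN coordinates; readers flag
    out-of-arena coordinates rather than clamping them.
    """

    frame_rate_hz: float
    points: dict[str, np.ndarray] = field(default_factory=dict)
    confidence: dict[str, np.ndarray] = field(default_factory=dict)
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise ValidationError("frame_rate_hz must be > 0")
        n = None
        for name, xy in self.points.items():
            xy = np.asarray(xy, dtype=float)
            if xy.ndim != 2 or xy.shape[1] != 2:
                raise ValidationError(f"point {name!r} must be an (N, 2) array")
            self.points[name] = xy
            if n is None:
                n = len(xy)
            elif len(xy) != n:
                raise ValidationError("all body points must have equal frame counts")
        for name, c in self.confidence.items():
            self.confidence[name] = np.asarray(c, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.points.values()))) if self.points else 0

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_frames) / self.frame_rate_hz

    def point(self, name: str) -> np.ndarray:
        if name not in self.points:
            raise ConfigurationError(
                f"body point {name!r} not in track (have {sorted(self.points)})"
            )
        return self.points[name]

    def clean(self, min_confidence: float = 0.9, max_gap_s: float = 0.5) -> "PoseTrack":
        """Quality-control pass: frames with confidence below
        ``min_confidence`` are linearly interpolated across gaps of at most
        ``max_gap_s``; longer gaps become NaN (invalid).  Missing confidence
        is treated as 1.0."""
        max_gap = int(round(max_gap_s * self.frame_rate_hz))
        new_points: dict[str, np.ndarray] = {}
        for name, xy in self.points.items():
            conf = self.confidence.get(name)
            if conf is None:
                new_points[name] = xy.copy()
                continue
            good = conf >= min_confidence
            out = xy.astype(float).copy()
            out[~good] = np.nan
            out = _interp_short_gaps(out, good, max_gap)
            new_points[name] = out
        return PoseTrack(
            self.frame_rate_hz,
            new_points,
            {k: v.copy() for k, v in self.confidence.items()},
            self.start_time_s,
        )


def _interp_short_gaps(xy: np.ndarray, good: np.ndarray, max_gap: int) -> np.ndarray:
    """Linear interpolation over interior bad runs of length <= max_gap."""
    n = len(good)
    idx = np.flatnonzero(good)
    if idx.size < 2:
        return xy
    bad = ~good
    edges = np.flatnonzero(np.diff(bad.astype(int)) != 0) + 1
    bounds = np.concatenate([[0], edges, [n]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        if not bad[s]:
            continue
        if s == 0 or e == n or (e - s) > max_gap:
            continue  # edge or long gap stays invalid
        for d in range(2):
            xy[s:e, d] = np.interp(
                np.arange(s, e), [s - 1, e], [xy[s - 1, d], xy[e, d]]
            )
    return xy


@dataclass
class EventTimes:
    """Ordered event timestamps (session seconds) with a kind tag
    (``cue_onset`` or ``escape_onset``)."""

    times: np.ndarray
    kind: str = "cue_onset"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValidationError("event times must be one-dimensional")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("event times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)
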