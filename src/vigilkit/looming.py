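"""Looming-stimulus geometry and pose-based defensive-behavior classification.

The visual looming test presents an expanding dark disc overhead while a
mouse explores a three-zone arena (shelter | intermediate | trigger).  A
trial is an *escape* when, within the response window after cue onset, the
animal (1) exceeds the escape speed threshold, (2) is heading toward the
shelter during that run, and (3) reaches the shelter zone.  Additional
per-trial measures are latency to shelter, peak speed, escape vigor (peak
speed of the shelter-directed return under a relaxed 20 cm/s threshold),
and cumulative immobility (speed < 1 cm/s for >= 1 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ArenaGeometry, PoseTrack, UniformSeries, ValidationError


@dataclass(frozen=True)
class StimulusParams:
    """Looming-cue geometry: a disc growing 0.5 -> 3 cm over 3 s, then two
    fast 3 -> 21 cm expansions of 0.5 s each, the full disc held to 6 s.
    Intensities are 8-bit grayscale (disc 0 on background 127)."""

    start_diameter_cm: float = 0.5
    ramp_end_diameter_cm: float = 3.0
    ramp_duration_s: float = 3.0
    max_diameter_cm: float = 21.0
    expansion_duration_s: float = 0.5
    n_expansions: int = 2
    total_duration_s: float = 6.0
    disc_intensity: int = 0
    background_intensity: int = 127

    def __post_init__(self) -> None:
        used = self.ramp_duration_s + self.n_expansions * self.expansion_duration_s
        if used > self.total_duration_s:
            raise ValidationError(
                f"segment durations ({used} s) exceed total ({self.total_duration_s} s)"
            )


@dataclass(frozen=True)
class EscapeCriteria:
    """Thresholds for the three-part escape definition."""

    speed_threshold_cm_s: float = 35.0
    vigor_threshold_cm_s: float = 20.0
    response_window_s: float = 7.0
    heading_tolerance_deg: float = 60.0
    heading_fraction: float = 0.5
    immobility_speed_cm_s: float = 1.0
    immobility_min_s: float = 1.0
    smoothing_window_s: float = 0.25

    def __post_init__(self) -> None:
        if self.speed_threshold_cm_s <= 0 or self.vigor_threshold_cm_s <= 0:
            raise ValidationError("speed thresholds must be positive")
        if self.vigor_threshold_cm_s >= self.speed_threshold_cm_s:
            raise ValidationError("vigor threshold must be below escape threshold")


@dataclass
class TrialRecord:
    """Outcome of one looming trial."""

    trial: int
    cue_onset_s: float
    performed: bool
    escaped: bool
    speed_ok: bool
    heading_ok: bool
    shelter_ok: bool
    latency_to_shelter_s: float  # NaN when no escape
    max_speed_cm_s: float
    vigor_cm_s: float  # NaN when no qualifying return
    immobile_s: float
    zone_at_onset: str


# ---------------------------------------------------------------------------
# stimulus geometry (closed forms)

def stimulus_profile(
    params: StimulusParams | None = None, frame_rate_hz: float = 60.0
) -> pd.DataFrame:
    """Disc diameter sampled at ``frame_rate_hz`` over the cue duration.

    Timing: slow ramp, then each fast expansion restarts from the ramp-end
    diameter, then the full disc is held until the total duration elapses.
    Columns: ``time_s``, ``diameter_cm``, ``segment``.
    """
    p = params or StimulusParams()
    if frame_rate_hz <= 0:
        raise ValidationError("frame rate must be positive")
    t = np.arange(0.0, p.total_duration_s, 1.0 / frame_rate_hz)
    d = np.empty_like(t)
    seg = np.empty(t.shape, dtype="U12")
    for i, ti in enumerate(t):
        d[i], seg[i] = _diameter_at(p, ti)
    return pd.DataFrame({"time_s": t, "diameter_cm": d, "segment": seg})


def _diameter_at(p: StimulusParams, t: float) -> tuple[float, str]:
    if t < 0 or t > p.total_duration_s:
        raise ValidationError(f"t={t} outside the cue duration [0, {p.total_duration_s}]")
    if t < p.ramp_duration_s:
        frac = t / p.ramp_duration_s
        return (
            p.start_diameter_cm + frac * (p.ramp_end_diameter_cm - p.start_diameter_cm),
            "ramp",
        )
    t2 = t - p.ramp_duration_s
    for k in range(p.n_expansions):
        if t2 < p.expansion_duration_s:
            frac = t2 / p.expansion_duration_s
            return (
                p.ramp_end_diameter_cm
                + frac * (p.max_diameter_cm - p.ramp_end_diameter_cm),
                f"expansion_{k + 1}",
            )
        t2 -= p.expansion_duration_s
    return p.max_diameter_cm, "hold"


def area_expansion_rate(d0_cm: float, d1_cm: float, dt_s: float) -> float:
    """Disc area growth rate in cm^2/s: (pi r1^2 - pi r0^2) / dt."""
    if dt_s <= 0:
        raise ValidationError("dt must be positive")
    return (math.pi * (d1_cm / 2.0) ** 2 - math.pi * (d0_cm / 2.0) ** 2) / dt_s


def visual_angle_deg(diameter_cm: float, distance_cm: float) -> float:
    """Full angular diameter subtended by a disc: 2 atan(d / 2h), degrees."""
    if distance_cm <= 0:
        raise ValidationError("distance must be positive")
    return math.degrees(2.0 * math.atan(diameter_cm / (2.0 * distance_cm)))


def michelson_contrast(i_max: float, i_min: float) -> float:
    """Michelson contrast in percent: (Imax - Imin) / (Imax + Imin) x 100."""
    if i_max + i_min <= 0:
        raise ValidationError("i_max + i_min must be positive")
    return (i_max - i_min) / (i_max + i_min) * 100.0


# ---------------------------------------------------------------------------
# kinematics

def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    n = len(x)
    half = window // 2
    c = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    lo = np.clip(i - half, 0, n)
    hi = np.clip(i + half + 1, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def compute_velocity(
    track: PoseTrack,
    point: str = "body_centroid",
    smoothing_window_s: float = 0.25,
) -> UniformSeries:
    """Central-difference speed magnitude of a body point, smoothed with a
    centered moving average.  Output length equals the frame count."""
    xy = track.point(point)
    valid = np.isfinite(xy).all(axis=1)
    if valid.sum() < 2:
        raise ValidationError("fewer than 2 valid frames")
    dt = 1.0 / track.frame_rate_hz
    vx = np.gradient(xy[:, 0], dt)
    vy = np.gradient(xy[:, 1], dt)
    speed = np.hypot(vx, vy)
    speed[~valid] = np.nan
    window = max(1, int(round(smoothing_window_s * track.frame_rate_hz)))
    finite = np.nan_to_num(speed, nan=0.0)
    smoothed = _moving_average(finite, window)
    smoothed[~valid] = 0.0  # invalid frames cannot trigger thresholds
    return UniformSeries(smoothed, track.frame_rate_hz, track.start_time_s, "cm/s")


def detect_immobility(
    velocity: UniformSeries,
    speed_threshold_cm_s: float = 1.0,
    min_duration_s: float = 1.0,
) -> list[tuple[float, float]]:
    """Maximal runs with speed below threshold lasting >= min duration;
    returned as (start_s, end_s) in session time."""
    below = velocity.values < speed_threshold_cm_s
    d = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if below.size and below[0]:
        starts = np.concatenate([[0], starts])
    if below.size and below[-1]:
        ends = np.concatenate([ends, [len(below)]])
    rate = velocity.sampling_rate_hz
    out = []
    for s, e in zip(starts, ends):
        if (e - s) / rate >= min_duration_s:
            out.append(
                (velocity.start_time_s + s / rate, velocity.start_time_s + e / rate)
            )
    return out


def _runs_above(values: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = values > threshold
    d = np.diff(above.astype(np.int8))
    starts = (np.flatnonzero(d == 1) + 1).tolist()
    ends = (np.flatnonzero(d == -1) + 1).tolist()
    if above.size and above[0]:
        starts.insert(0, 0)
    if above.size and above[-1]:
        ends.append(len(above))
    return list(zip(starts, ends))


def _heading_ok_over(
    track: PoseTrack,
    frames: np.ndarray,
    geometry: ArenaGeometry,
    criteria: EscapeCriteria,
) -> bool:
    """Majority-of-run heading test: the angle between the head-direction
    vector (tail_base -> head, falling back to the centroid motion vector)
    and the bearing to the shelter-zone center must be within tolerance for
    at least ``heading_fraction`` of the frames."""
    if frames.size == 0:
        return False
    centroid = _centroid(track)
    if "head" in track.points and "tail_base" in track.points:
        vec = track.points["head"][frames] - track.points["tail_base"][frames]
    else:
        dt = 1.0 / track.frame_rate_hz
        vec = np.column_stack(
            [np.gradient(centroid[:, 0], dt), np.gradient(centroid[:, 1], dt)]
        )[frames]
    bearing = geometry.shelter_center[None, :] - centroid[frames]
    dot = (vec * bearing).sum(axis=1)
    norms = np.linalg.norm(vec, axis=1) * np.linalg.norm(bearing, axis=1)
    ok = np.zeros(len(frames), dtype=bool)
    nz = norms > 1e-12
    cosang = np.clip(dot[nz] / norms[nz], -1.0, 1.0)
    ok[nz] = np.degrees(np.arccos(cosang)) < criteria.heading_tolerance_deg
    return ok.mean() >= criteria.heading_fraction


def _centroid(track: PoseTrack) -> np.ndarray:
    if "body_centroid" in track.points:
        return track.points["body_centroid"]
    return track.point("centroid")


def classify_escape(
    track: PoseTrack,
    cue_onset_s: float,
    geometry: ArenaGeometry | None = None,
    criteria: EscapeCriteria | None = None,
    trial: int = 0,
) -> TrialRecord:
    """Classify one looming trial.

    A trial is escaped iff within the response window the smoothed speed
    exceeds the escape threshold, the heading criterion holds during the
    first supra-threshold run, and the centroid enters the shelter zone.
    A track not covering the full window yields a not-performed trial.
    When no run exceeds the escape threshold, the heading criterion is
    evaluated on the fastest available run (vigor threshold, then any
    movement) so that all three criteria remain independently defined.
    """
    geometry = geometry or ArenaGeometry()
    criteria = criteria or EscapeCriteria()
    velocity = compute_velocity(
        track, smoothing_window_s=criteria.smoothing_window_s
    )
    t = track.times()
    w0, w1 = cue_onset_s, cue_onset_s + criteria.response_window_s
    if t[0] > w0 + 1e-9 or t[-1] < w1 - 1e-9:
        return TrialRecord(
            trial, cue_onset_s, performed=False, escaped=False, speed_ok=False,
            heading_ok=False, shelter_ok=False, latency_to_shelter_s=np.nan,
            max_speed_cm_s=np.nan, vigor_cm_s=np.nan, immobile_s=np.nan,
            zone_at_onset="",
        )
    in_window = np.flatnonzero((t >= w0 - 1e-9) & (t <= w1 + 1e-9))
    speed_w = velocity.values[in_window]
    centroid = _centroid(track)
    onset_idx = in_window[0]
    zone_at_onset = str(geometry.zone_of(centroid[onset_idx, 0]))

    max_speed = float(np.max(speed_w))
    speed_ok = max_speed > criteria.speed_threshold_cm_s

    # heading over the first supra-threshold run; fallback thresholds keep
    # the criterion defined for slow trials
    heading_ok = False
    for thr in (
        criteria.speed_threshold_cm_s,
        criteria.vigor_threshold_cm_s,
        criteria.immobility_speed_cm_s,
    ):
        runs = _runs_above(speed_w, thr)
        if runs:
            s, e = runs[0]
            heading_ok = _heading_ok_over(track, in_window[s:e], geometry, criteria)
            break

    zones_w = geometry.zone_of(centroid[in_window, 0])
    shelter_frames = np.flatnonzero(zones_w == "shelter")
    # entry means reaching the shelter after onset, not starting there
    entered = shelter_frames[
        shelter_frames > 0
    ] if zone_at_onset == "shelter" else shelter_frames
    shelter_ok = entered.size > 0
    latency = (
        float(t[in_window[entered[0]]] - cue_onset_s) if shelter_ok else np.nan
    )

    escaped = speed_ok and heading_ok and shelter_ok

    immobile = 0.0
    for s0, s1 in detect_immobility(
        velocity, criteria.immobility_speed_cm_s, criteria.immobility_min_s
    ):
        immobile += max(0.0, min(s1, w1) - max(s0, w0))

    vigor = escape_vigor(track, cue_onset_s, geometry, criteria, velocity=velocity)

    return TrialRecord(
        trial=trial, cue_onset_s=cue_onset_s, performed=True, escaped=escaped,
        speed_ok=speed_ok, heading_ok=heading_ok, shelter_ok=shelter_ok,
        latency_to_shelter_s=latency if escaped else (latency if shelter_ok else np.nan),
        max_speed_cm_s=max_speed, vigor_cm_s=vigor, immobile_s=immobile,
        zone_at_onset=zone_at_onset,
    )


def escape_vigor(
    track: PoseTrack,
    cue_onset_s: float,
    geometry: ArenaGeometry | None = None,
    criteria: EscapeCriteria | None = None,
    velocity: UniformSeries | None = None,
) -> float:
    """Peak smoothed speed of the first qualifying shelter-directed return
    under the relaxed (20 cm/s) threshold; NaN when there is no qualifying
    return (speed never above the relaxed threshold, wrong heading, or no
    shelter entry by the end of the window)."""
    geometry = geometry or ArenaGeometry()
    criteria = criteria or EscapeCriteria()
    if velocity is None:
        velocity = compute_velocity(track, smoothing_window_s=criteria.smoothing_window_s)
    t = track.times()
    w0, w1 = cue_onset_s, cue_onset_s + criteria.response_window_s
    in_window = np.flatnonzero((t >= w0 - 1e-9) & (t <= w1 + 1e-9))
    if in_window.size == 0:
        return np.nan
    speed_w = velocity.values[in_window]
    centroid = _centroid(track)
    zones_w = geometry.zone_of(centroid[in_window, 0])
    for s, e in _runs_above(speed_w, criteria.vigor_threshold_cm_s):
        if not _heading_ok_over(track, in_window[s:e], geometry, criteria):
            continue
        if np.any(zones_w[s:] == "shelter"):
            return float(speed_w[s:e].max())
    return np.nan


# ---------------------------------------------------------------------------
# session-level summaries

def escape_probability(trials: list[TrialRecord]) -> float:
    """Escapes divided by completed trials; not-performed trials are
    excluded from the denominator.  NaN when no trial was completed."""
    done = [tr for tr in trials if tr.performed]
    if not done:
        return np.nan
    return sum(tr.escaped for tr in done) / len(done)


def cumulative_immobility(trials: list[TrialRecord]) -> float:
    """Total immobile time within the response window summed over
    completed trials (each trial's value is already clipped)."""
    return float(sum(tr.immobile_s for tr in trials if tr.performed))


def zone_occupancy(
    track: PoseTrack,
    geometry: ArenaGeometry | None = None,
    interval: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Seconds and percent time per zone over the interval (whole track by
    default), by centroid x against the zone extents."""
    geometry = geometry or ArenaGeometry()
    t = track.times()
    sel = (
        np.ones(len(t), dtype=bool)
        if interval is None
        else (t >= interval[0] - 1e-9) & (t < interval[1] - 1e-9)
    )
    zones = geometry.zone_of(_centroid(track)[sel, 0])
    dt = 1.0 / track.frame_rate_hz
    rows = []
    total = zones.size * dt
    for z in geometry.ZONES:
        secs = np.sum(zones == z) * dt
        rows.append(
            {"zone": z, "seconds": secs, "percent": 100.0 * secs / total if total else np.nan}
        )
    return pd.DataFrame(rows)


def distance_moved(
    track: PoseTrack,
    interval: tuple[float, float] | None = None,
    smoothing_window_s: float = 0.25,
) -> float:
    """Total path length (cm) of the smoothed centroid over the interval."""
    xy = _centroid(track)
    t = track.times()
    if interval is not None:
        sel = (t >= interval[0] - 1e-9) & (t < interval[1] - 1e-9)
        xy = xy[sel]
    window = max(1, int(round(smoothing_window_s * track.frame_rate_hz)))
    sm = np.column_stack(
        [_moving_average(xy[:, 0], window), _moving_average(xy[:, 1], window)]
    )
    steps = np.linalg.norm(np.diff(sm, axis=0), axis=1)
    return float(np.nansum(steps))


def session_summary(
    trials: list[TrialRecord],
    track: PoseTrack | None = None,
    geometry: ArenaGeometry | None = None,
    habituation_interval: tuple[float, float] | None = None,
) -> dict:
    """Session-level metrics: escape probability, latency of the first
    escape, cumulative immobility, and (when a track is given) zone
    occupancy and habituation distance."""
    done = [tr for tr in trials if tr.performed]
    first_escape = next((tr for tr in done if tr.escaped), None)
    out = {
        "n_trials": len(trials),
        "n_completed": len(done),
        "escape_probability": escape_probability(trials),
        "first_escape_latency_s": (
            first_escape.latency_to_shelter_s if first_escape else np.nan
        ),
        "cumulative_immobility_s": cumulative_immobility(trials),
        "mean_max_speed_cm_s": (
            float(np.mean([tr.max_speed_cm_s for tr in done])) if done else np.nan
        ),
    }
    if track is not None:
        occ = zone_occupancy(track, geometry, habituation_interval)
        for _, row in occ.iterrows():
            out[f"pct_time_{row['zone']}"] = row["percent"]
        out["distance_moved_cm"] = distance_moved(track, habituation_interval)
    return out


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([tr.__dict__ for tr in trials])
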