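"""Seeded synthetic-data generators with machine-readable ground truth.

Each generator is a pure function of its parameters and seed and emits the
statistical structure its consumer stage assumes, together with ground
truth sufficient to score that stage without re-deriving labels:

* :func:`gen_hypnogram` - semi-Markov vigilance-state sequence with
  exponential dwell times, quantized to 10-s epochs, plus a bout table.
* :func:`gen_eeg_emg` - per-state EEG spectral recipes (1/f broadband,
  NREM delta hump and steady sigma rhythm, REM theta, AWAKE broadband)
  with sigma-band spindle bursts injected only in NREM, plus EMG tone,
  and the injected-spindle table.
* :func:`gen_loom_session` - arena pose tracks in which programmed escapes
  satisfy all three escape criteria by construction and programmed
  non-escapes violate at least one named criterion.
* :func:`gen_photometry` - 470/405 nm channel pair sharing exponential
  bleaching and a multiplicative motion artifact, with calcium transients
  only in the 470 channel, plus the transient table.
* :func:`gen_variable_table` - per-animal behavioral variables with
  control/treated groups and effect sizes in control-sigma units.

The recipes are statistical, not biophysical: filtered noise plus
narrowband components, which is all the downstream analyses assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .composite import DEFAULT_DIRECTIONS
from .types import (
    ArenaGeometry,
    EventTimes,
    Hypnogram,
    PhasePartition,
    PoseTrack,
    UniformSeries,
    ValidationError,
)


def _one_f_noise(n: int, rate: float, rng: np.random.Generator,
                 corner_hz: float = 0.5) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise, flat below the corner frequency."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    amp = 1.0 / np.sqrt(np.maximum(f, corner_hz))
    amp[0] = 0.0
    x = np.fft.irfft(spec * amp, n)
    return x / x.std()


# ---------------------------------------------------------------------------
# sleep

@dataclass
class SleepGenParams:
    """Hypnogram and EEG/EMG generator settings.

    Dwell-time means (s) are per state per phase; bout lengths are
    exponential, quantized to whole 10-s epochs.  ``spindle_amplitude_ratio``
    is the spindle envelope relative to the NREM background sigma-band
    envelope; ``sigma_rhythm_ratio`` sets the steady background sigma
    rhythm relative to the in-band 1/f-noise RMS (a stable-envelope stand-in
    for ongoing background sigma activity).
    """

    total_hours: float = 24.0
    epoch_length_s: float = 10.0
    start_clock_s: float = 18 * 3600.0
    dwell_mean_s: dict = field(
        default_factory=lambda: {
            ("AWAKE", "active"): 600.0,
            ("NREM", "active"): 120.0,
            ("REM", "active"): 60.0,
            ("AWAKE", "inactive"): 180.0,
            ("NREM", "inactive"): 240.0,
            ("REM", "inactive"): 80.0,
        }
    )
    p_nrem_to_rem: float = 0.25
    p_rem_to_wake: float = 0.6
    sampling_rate_hz: float = 1250.0
    spindle_density_per_min: float = 2.0
    spindle_duration_range_s: tuple[float, float] = (0.8, 2.0)
    spindle_amplitude_ratio: float = 4.0
    spindle_freq_hz: float = 12.0
    sigma_rhythm_ratio: float = 5.0
    sigma_rhythm_freq_hz: float = 12.5
    delta_amplitude: float = 2.0
    theta_amplitude: float = 1.5
    emg_tone: dict = field(
        default_factory=lambda: {"AWAKE": 1.0, "NREM": 0.3, "REM": 0.05}
    )

    def __post_init__(self) -> None:
        if self.spindle_density_per_min < 0:
            raise ValidationError("spindle density must be >= 0")
        if any(m < self.epoch_length_s for m in self.dwell_mean_s.values()):
            raise ValidationError("dwell means must be >= one epoch")


def gen_hypnogram(
    params: SleepGenParams | None = None,
    seed: int = 0,
    partition: PhasePartition | None = None,
) -> tuple[Hypnogram, pd.DataFrame]:
    """Semi-Markov state sequence quantized to epochs.

    Returns the hypnogram and a ground-truth bout table (state,
    start_epoch, n_epochs) exactly consistent with the labels.
    """
    p = params or SleepGenParams()
    partition = partition or PhasePartition()
    rng = np.random.default_rng(seed)
    n_epochs = int(round(p.total_hours * 3600.0 / p.epoch_length_s))
    labels: list[str] = []
    truth = []
    state = "AWAKE"
    while len(labels) < n_epochs:
        clock = (p.start_clock_s + len(labels) * p.epoch_length_s) % 86400.0
        phase = "active" if partition.is_active(clock) else "inactive"
        mean = p.dwell_mean_s[(state, phase)]
        n = max(1, int(round(rng.exponential(mean) / p.epoch_length_s)))
        n = min(n, n_epochs - len(labels))
        truth.append({"state": state, "start_epoch": len(labels), "n_epochs": n})
        labels.extend([state] * n)
        if state == "AWAKE":
            state = "NREM"
        elif state == "NREM":
            state = "REM" if rng.random() < p.p_nrem_to_rem else "AWAKE"
        else:
            state = "AWAKE" if rng.random() < p.p_rem_to_wake else "NREM"
    hyp = Hypnogram(np.array(labels), p.epoch_length_s, p.start_clock_s)
    return hyp, pd.DataFrame(truth)


def gen_eeg_emg(
    hyp: Hypnogram,
    params: SleepGenParams | None = None,
    seed: int = 0,
) -> tuple[UniformSeries, UniformSeries, pd.DataFrame]:
    """EEG and EMG realizing the per-state spectral recipes, plus the
    injected-spindle ground truth table (start_s, end_s, duration_s).

    NREM = 1/f + delta-band hump + steady sigma rhythm; REM = 1/f + theta
    oscillation; AWAKE = broadband.  Spindle bursts (Hann-windowed
    ``spindle_freq_hz`` oscillations) are placed only inside contiguous
    NREM segments, non-overlapping, with >= 0.5 s clearance from segment
    edges.
    """
    p = params or SleepGenParams()
    rng = np.random.default_rng(seed)
    rate = p.sampling_rate_hz
    n = int(round(len(hyp) * hyp.epoch_length_s * rate))
    t = np.arange(n) / rate

    eeg = _one_f_noise(n, rate, rng)
    # per-sample state masks
    epoch_of_sample = np.minimum((t / hyp.epoch_length_s).astype(int), len(hyp) - 1)
    sample_state = hyp.labels[epoch_of_sample]
    nrem = sample_state == "NREM"
    rem = sample_state == "REM"

    # in-band sigma noise RMS of the 1/f background fixes the amplitude scale
    sos_sigma = sps.butter(4, (10.0, 15.0), "bandpass", fs=rate, output="sos")
    band_rms = float(sps.sosfiltfilt(sos_sigma, eeg).std())

    # NREM delta hump: 1-4 Hz filtered noise
    if nrem.any():
        sos_d = sps.butter(4, (1.0, 4.0), "bandpass", fs=rate, output="sos")
        delta = sps.sosfiltfilt(sos_d, rng.standard_normal(n))
        delta /= delta.std()
        eeg[nrem] += p.delta_amplitude * delta[nrem]
        tone = (
            p.sigma_rhythm_ratio
            * band_rms
            * np.sqrt(2.0)
            * np.sin(2 * np.pi * p.sigma_rhythm_freq_hz * t + rng.uniform(0, 2 * np.pi))
        )
        eeg[nrem] += tone[nrem]
    # REM theta
    if rem.any():
        theta = np.sin(2 * np.pi * 7.0 * t + rng.uniform(0, 2 * np.pi))
        eeg[rem] += p.theta_amplitude * theta[rem]

    # background sigma envelope (RMS sense) seen by a detector during NREM
    sigma_env = band_rms * np.sqrt(p.sigma_rhythm_ratio**2 + 1.0)

    # spindles inside contiguous NREM segments
    truth_rows = []
    if p.spindle_density_per_min > 0 and nrem.any():
        edges = np.flatnonzero(np.diff(nrem.astype(np.int8)))
        bounds = np.concatenate([[0], edges + 1, [n]])
        margin = 0.5
        for s, e in zip(bounds[:-1], bounds[1:]):
            if not nrem[s]:
                continue
            seg_dur = (e - s) / rate
            n_sp = rng.poisson(p.spindle_density_per_min * seg_dur / 60.0)
            taken = np.zeros(e - s, dtype=bool)
            placed = 0
            attempts = 0
            while placed < n_sp and attempts < 50 * max(n_sp, 1):
                attempts += 1
                dur = rng.uniform(*p.spindle_duration_range_s)
                if seg_dur < dur + 2 * margin:
                    break
                t0 = rng.uniform(margin, seg_dur - margin - dur)
                i0 = int(t0 * rate)
                i1 = i0 + int(dur * rate)
                pad = int(1.0 * rate)
                if taken[max(0, i0 - pad) : min(e - s, i1 + pad)].any():
                    continue
                taken[i0:i1] = True
                tt = np.arange(i1 - i0) / rate
                env = np.sin(np.pi * tt / dur) ** 2
                amp = p.spindle_amplitude_ratio * np.sqrt(2.0) * sigma_env
                eeg[s + i0 : s + i1] += (
                    amp
                    * env
                    * np.sin(2 * np.pi * p.spindle_freq_hz * tt + rng.uniform(0, 2 * np.pi))
                )
                truth_rows.append(
                    {
                        "start_s": (s + i0) / rate,
                        "end_s": (s + i1) / rate,
                        "duration_s": dur,
                    }
                )
                placed += 1
    truth = pd.DataFrame(truth_rows, columns=["start_s", "end_s", "duration_s"])
    truth = truth.sort_values("start_s").reset_index(drop=True)

    emg = rng.standard_normal(n)
    for state, tone_amp in p.emg_tone.items():
        emg[sample_state == state] *= tone_amp

    return (
        UniformSeries(eeg, rate, 0.0, "uV"),
        UniformSeries(emg, rate, 0.0, "uV"),
        truth,
    )


# ---------------------------------------------------------------------------
# looming

@dataclass
class LoomGenParams:
    """Looming-session generator settings.

    ``escape_probability`` is realized exactly: round(p * n_trials) trials
    are programmed escapes (shuffled order), the rest non-escapes split
    between freezing and slow wandering.  Programmed escape peak speeds
    must exceed the 35 cm/s criterion.
    """

    n_trials: int = 10
    escape_probability: float = 0.7
    peak_speed_range_cm_s: tuple[float, float] = (45.0, 70.0)
    reaction_latency_range_s: tuple[float, float] = (0.3, 0.8)
    freeze_fraction: float = 0.6
    wander_speed_cm_s: float = 6.0
    frame_rate_hz: float = 30.0
    trial_slot_s: float = 40.0
    cue_offset_in_slot_s: float = 5.0
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    jitter_cm: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.escape_probability <= 1.0:
            raise ValidationError("escape probability must be in [0, 1]")
        if self.peak_speed_range_cm_s[0] <= 35.0:
            raise ValidationError("programmed escape peak speed must exceed 35 cm/s")


def gen_loom_session(
    params: LoomGenParams | None = None, seed: int = 0
) -> tuple[PoseTrack, EventTimes, pd.DataFrame]:
    """Synthesize a looming session: pose track, cue-onset events, and the
    per-trial ground truth (escape flag, programmed kind, peak speed)."""
    p = params or LoomGenParams()
    rng = np.random.default_rng(seed)
    g = p.arena
    fps = p.frame_rate_hz
    n_frames = int(round(p.n_trials * p.trial_slot_s * fps))
    xy = np.zeros((n_frames, 2))
    y_mid = g.width_cm / 2.0
    trigger_pos = np.array([g.trigger_start_x + g.trigger_length_cm / 2.0, y_mid])
    shelter_pos = g.shelter_center

    n_escapes = int(round(p.escape_probability * p.n_trials))
    kinds = ["escape"] * n_escapes + ["non_escape"] * (p.n_trials - n_escapes)
    rng.shuffle(kinds)

    cue_times = []
    truth_rows = []
    for k, kind in enumerate(kinds):
        slot0 = int(round(k * p.trial_slot_s * fps))
        slot1 = int(round((k + 1) * p.trial_slot_s * fps))
        cue_frame = slot0 + int(round(p.cue_offset_in_slot_s * fps))
        cue_times.append(cue_frame / fps)
        frames = np.arange(slot0, slot1)
        pos = np.tile(trigger_pos, (len(frames), 1))
        if kind == "escape":
            latency = rng.uniform(*p.reaction_latency_range_s)
            peak = rng.uniform(*p.peak_speed_range_cm_s)
            dist = np.linalg.norm(trigger_pos - shelter_pos)
            dash_t = dist / (0.5 * peak)  # mean of a sin^2 profile is half the peak
            t_rel = (frames - cue_frame) / fps
            direction = (shelter_pos - trigger_pos) / dist
            moving = (t_rel >= latency) & (t_rel < latency + dash_t)
            phase = (t_rel[moving] - latency) / dash_t
            # position integral of the sin^2 speed profile
            s_along = dist * (phase - np.sin(2 * np.pi * phase) / (2 * np.pi))
            pos[moving] = trigger_pos + s_along[:, None] * direction[None, :]
            pos[t_rel >= latency + dash_t] = shelter_pos
            # return walk for the next trial, well after the response window
            ret = t_rel >= p.trial_slot_s - p.cue_offset_in_slot_s - 10.0
            if ret.any():
                rt = t_rel[ret] - (p.trial_slot_s - p.cue_offset_in_slot_s - 10.0)
                frac = np.clip(rt * 8.0 / dist, 0.0, 1.0)
                pos[ret] = shelter_pos + frac[:, None] * (trigger_pos - shelter_pos)
            truth_rows.append(
                {"trial": k, "kind": kind, "escape": True, "peak_speed_cm_s": peak,
                 "latency_s": latency + dash_t * 0.5}
            )
        else:
            freeze = rng.random() < p.freeze_fraction
            if freeze:
                truth_rows.append(
                    {"trial": k, "kind": "freeze", "escape": False,
                     "peak_speed_cm_s": 0.0, "latency_s": np.nan}
                )
            else:
                # slow wander inside intermediate/trigger zones
                t_rel = (frames - cue_frame) / fps
                heading = rng.uniform(0, 2 * np.pi)
                cur = trigger_pos.copy()
                for i, tr in enumerate(t_rel):
                    if tr < 0:
                        continue
                    heading += rng.normal(0, 0.15)
                    step = p.wander_speed_cm_s / fps
                    cand = cur + step * np.array([np.cos(heading), np.sin(heading)])
                    if not (g.shelter_end_x + 2.0 < cand[0] < g.total_length_cm - 1.0):
                        heading += np.pi / 2
                        cand = cur
                    cand[1] = np.clip(cand[1], 1.0, g.width_cm - 1.0)
                    cur = cand
                    pos[i] = cur
                truth_rows.append(
                    {"trial": k, "kind": "wander", "escape": False,
                     "peak_speed_cm_s": p.wander_speed_cm_s, "latency_s": np.nan}
                )
        xy[slot0:slot1] = pos
    xy += rng.normal(0, p.jitter_cm, xy.shape)

    # head and tail_base along the motion direction (last direction held)
    vel = np.gradient(xy, 1.0 / fps, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    u = np.zeros_like(xy)
    last = np.array([1.0, 0.0])
    for i in range(len(xy)):
        if speed[i] > 2.0:
            last = vel[i] / speed[i]
        u[i] = last
    track = PoseTrack(
        fps,
        {
            "body_centroid": xy,
            "head": xy + 1.5 * u,
            "tail_base": xy - 1.5 * u,
        },
    )
    events = EventTimes(np.array(cue_times), "cue_onset")
    return track, events, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# photometry

@dataclass
class PhotGenParams:
    """Two-channel photometry generator settings.

    Channel model: F = B(t) * (1 + artifact + transients) + noise, where
    B(t) is an exponential-plus-plateau bleach curve, the multiplicative
    motion artifact is shared between channels, and calcium transients
    enter only the 470 channel.  By default both channels share the same
    bleach time-constant (so the channels differ by a pure scale), with
    470/405 baseline brightnesses of 200/150 counts.
    """

    duration_s: float = 600.0
    sampling_rate_hz: float = 20.0
    base_470: float = 200.0
    base_405: float = 150.0
    bleach_tau_470_s: float = 800.0
    bleach_tau_405_s: float = 800.0
    bleach_plateau: float = 0.7
    artifact_amplitude: float = 0.1
    artifact_bandwidth_hz: float = 0.5
    transient_peak_dff: float = 0.05
    transient_rise_s: float = 0.5
    transient_decay_s: float = 1.5
    transient_latency_s: float = 3.5
    noise_sd: float = 0.05
    event_times_s: tuple = ()

    def __post_init__(self) -> None:
        for tau in (self.bleach_tau_470_s, self.bleach_tau_405_s):
            if tau <= 0:
                raise ValidationError("bleach time-constants must be > 0")


def _transient_kernel(rate: float, rise_s: float, decay_s: float) -> np.ndarray:
    t = np.arange(0, rise_s + 6 * decay_s, 1.0 / rate)
    k = (1 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k / k.max()


def gen_photometry(
    params: PhotGenParams | None = None, seed: int = 0
):
    """Synthesize a photometry session.

    Returns ``(session, truth)`` where ``truth`` lists one row per event
    with the transient onset (event + latency) and programmed peak dF/F.
    Events default to one per minute starting 30 s in.
    """
    from .photometry import PhotometrySession

    p = params or PhotGenParams()
    rng = np.random.default_rng(seed)
    rate = p.sampling_rate_hz
    n = int(round(p.duration_s * rate))
    t = np.arange(n) / rate

    if p.event_times_s:
        ev = np.asarray(p.event_times_s, dtype=float)
    else:
        ev = np.arange(30.0, p.duration_s - 30.0, 60.0)

    bleach_470 = p.base_470 * (
        p.bleach_plateau + (1 - p.bleach_plateau) * np.exp(-t / p.bleach_tau_470_s)
    )
    bleach_405 = p.base_405 * (
        p.bleach_plateau + (1 - p.bleach_plateau) * np.exp(-t / p.bleach_tau_405_s)
    )

    if p.artifact_amplitude > 0:
        raw = rng.standard_normal(n)
        sos = sps.butter(2, p.artifact_bandwidth_hz, "low", fs=rate, output="sos")
        artifact = sps.sosfiltfilt(sos, raw)
        artifact *= p.artifact_amplitude / artifact.std()
    else:
        artifact = np.zeros(n)

    transients = np.zeros(n)
    kernel = _transient_kernel(rate, p.transient_rise_s, p.transient_decay_s)
    truth_rows = []
    for e in ev if p.transient_peak_dff > 0 else []:
        onset = e + p.transient_latency_s
        i0 = int(round(onset * rate))
        if i0 >= n:
            continue
        i1 = min(n, i0 + len(kernel))
        transients[i0:i1] += p.transient_peak_dff * kernel[: i1 - i0]
        truth_rows.append(
            {"event_s": e, "onset_s": onset, "peak_dff": p.transient_peak_dff}
        )
    truth = pd.DataFrame(truth_rows, columns=["event_s", "onset_s", "peak_dff"])

    f405 = bleach_405 * (1 + artifact) + rng.normal(0, p.noise_sd, n)
    f470 = bleach_470 * (1 + artifact + transients) + rng.normal(0, p.noise_sd, n)

    session = PhotometrySession(
        UniformSeries(f470, rate, 0.0, "au"),
        UniformSeries(f405, rate, 0.0, "au"),
        EventTimes(ev, "cue_onset"),
    )
    return session, truth


# ---------------------------------------------------------------------------
# behavioral variable tables

#: Plausible raw-scale (mean, sd) per behavioral variable for the table
#: generator; arbitrary but fixed so z-scoring is exercised on
#: heterogeneous scales.
_VARIABLE_SCALES: dict[str, tuple[float, float]] = {
    name: (50.0 + 13.0 * i, 4.0 + 0.8 * i)
    for i, name in enumerate(sorted(DEFAULT_DIRECTIONS))
}


def gen_variable_table(
    n_per_group: int = 16,
    effects: dict[str, float] | None = None,
    seed: int = 0,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-animal behavioral variable table with control and treated
    groups.  ``effects`` gives the treated-group shift per variable in
    control-sigma units (unlisted variables shift by 0)."""
    rng = np.random.default_rng(seed)
    effects = effects or {}
    variables = variables if variables is not None else sorted(DEFAULT_DIRECTIONS)
    rows = []
    for group in ("control", "treated"):
        for i in range(n_per_group):
            row = {
                "animal_id": f"{group[0]}{i:02d}",
                "group": group,
                "sex": "F" if i % 2 == 0 else "M",
            }
            for v in variables:
                mu, sd = _VARIABLE_SCALES.get(v, (50.0, 5.0))
                shift = effects.get(v, 0.0) * sd if group == "treated" else 0.0
                row[v] = rng.normal(mu + shift, sd)
            rows.append(row)
    return pd.DataFrame(rows).set_index("animal_id")
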