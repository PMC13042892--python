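"""Readers and writers for every file format the pipeline touches.

Delimited UTF-8 CSV is the interchange format for hypnograms, pose tracks
(DeepLabCut header dialect accepted), photometry sessions, event lists and
behavioral variable tables.  Large raw signals may instead use EDF (read
through :mod:`mne`) or a documented ``.npz`` array container.  Every writer
emits a JSON sidecar recording sampling rate, units and origin convention
so a file round-trips without external context.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ConfigurationError,
    EventTimes,
    Hypnogram,
    PoseTrack,
    UniformSeries,
    ValidationError,
)

_TIME_COLUMNS = ("time", "time_s")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_sidecar(path: Path, **meta) -> Path:
    side = _sidecar_path(Path(path))
    side.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return side


def read_sidecar(path: Path) -> dict:
    side = _sidecar_path(Path(path))
    if side.exists():
        return json.loads(side.read_text())
    return {}


# ---------------------------------------------------------------------------
# signals

def infer_format(path: Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix == ".npz":
        return "array_container"
    return "delimited"


def read_signal(
    path,
    format: str | None = None,
    channel: str | None = None,
    sampling_rate_hz: float | None = None,
    start_time_s: float | None = None,
    units: str = "",
) -> UniformSeries:
    """Read one channel as a :class:`UniformSeries`.

    ``channel`` may be omitted when the file holds a single data channel.
    The sampling rate comes from (in order of precedence) the explicit
    argument, the file's own metadata (EDF header, time column, sidecar),
    else a :class:`ConfigurationError` is raised.
    """
    channels = read_signal_channels(
        path, format=format, sampling_rate_hz=sampling_rate_hz,
        start_time_s=start_time_s, units=units,
    )
    if channel is None:
        if len(channels) != 1:
            raise ConfigurationError(
                f"file has channels {sorted(channels)}; pass channel= to pick one"
            )
        return next(iter(channels.values()))
    if channel not in channels:
        raise ConfigurationError(
            f"channel {channel!r} not found; file has {sorted(channels)}"
        )
    return channels[channel]


def read_signal_channels(
    path,
    format: str | None = None,
    sampling_rate_hz: float | None = None,
    start_time_s: float | None = None,
    units: str = "",
) -> dict[str, UniformSeries]:
    """Read every channel in the file, keyed by channel name."""
    path = Path(path)
    fmt = format or infer_format(path)
    if fmt == "edf":
        return _read_edf(path, start_time_s)
    if fmt == "array_container":
        return _read_npz(path, sampling_rate_hz, start_time_s, units)
    return _read_delimited_signal(path, sampling_rate_hz, start_time_s, units)


def _read_delimited_signal(path, sampling_rate_hz, start_time_s, units):
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.empty:
        raise ValidationError(f"{path}: no rows")
    meta = read_sidecar(path)
    time_col = next((c for c in df.columns if c.lower() in _TIME_COLUMNS), None)
    if time_col is not None:
        t = df[time_col].to_numpy(dtype=float)
        if sampling_rate_hz is None:
            dt = np.median(np.diff(t))
            if not dt > 0:
                raise ValidationError(f"{path}: time column is not increasing")
            sampling_rate_hz = 1.0 / dt
        if start_time_s is None:
            start_time_s = float(t[0])
        df = df.drop(columns=[time_col])
    if sampling_rate_hz is None:
        sampling_rate_hz = meta.get("sampling_rate_hz")
    if sampling_rate_hz is None:
        raise ConfigurationError(
            f"{path}: no time column, sidecar, or explicit sampling rate"
        )
    if start_time_s is None:
        start_time_s = meta.get("start_time_s", 0.0)
    units = units or meta.get("units", "")
    out = {}
    for col in df.columns:
        vals = df[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            head = ", ".join(map(str, bad[:10]))
            raise ValidationError(
                f"{path}: channel {col!r} has non-finite values at rows [{head}]"
            )
        out[col] = UniformSeries(vals, float(sampling_rate_hz), float(start_time_s), units)
    return out


def _read_edf(path, start_time_s):
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ConfigurationError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    start = 0.0 if start_time_s is None else start_time_s
    return {
        name: UniformSeries(raw.get_data(picks=[name])[0], raw.info["sfreq"], start, "V")
        for name in raw.ch_names
    }


def _read_npz(path, sampling_rate_hz, start_time_s, units):
    with np.load(path, allow_pickle=False) as z:
        rate = sampling_rate_hz or float(z["sampling_rate_hz"])
        start = start_time_s if start_time_s is not None else float(z.get("start_time_s", 0.0))
        u = units or str(z["units"]) if "units" in z else units
        names = [k for k in z.files if k not in ("sampling_rate_hz", "start_time_s", "units")]
        return {k: UniformSeries(z[k], rate, start, u) for k in names}


def write_signal_container(path, series: dict[str, UniformSeries]) -> Path:
    """Write channels to the package's ``.npz`` array container."""
    path = Path(path)
    first = next(iter(series.values()))
    np.savez(
        path,
        sampling_rate_hz=first.sampling_rate_hz,
        start_time_s=first.start_time_s,
        units=np.str_(first.units),
        **{k: s.values for k, s in series.items()},
    )
    write_sidecar(path, sampling_rate_hz=first.sampling_rate_hz,
                  start_time_s=first.start_time_s, units=first.units,
                  origin="session seconds")
    return path


def write_signal_csv(path, series: dict[str, UniformSeries], time_column: bool = True) -> Path:
    path = Path(path)
    first = next(iter(series.values()))
    cols = {}
    if time_column:
        cols["time_s"] = first.times()
    for k, s in series.items():
        if len(s) != len(first) or s.sampling_rate_hz != first.sampling_rate_hz:
            raise ValidationError("channels must share length and rate")
        cols[k] = s.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    write_sidecar(path, sampling_rate_hz=first.sampling_rate_hz,
                  start_time_s=first.start_time_s, units=first.units,
                  origin="session seconds")
    return path


# ---------------------------------------------------------------------------
# hypnograms

def read_hypnogram(
    path,
    epoch_length_s: float = 10.0,
    start_clock_s: float | None = None,
) -> Hypnogram:
    """Read a hypnogram: one state label per line, or a CSV with a
    ``label`` column.  A ``# start_clock_s=<float>`` header comment (or the
    sidecar) supplies the clock anchor when not given explicitly."""
    path = Path(path)
    labels: list[str] = []
    header_clock = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("start_clock_s"):
                header_clock = float(body.split("=", 1)[1])
            continue
        labels.append(line.split(",")[-1].strip())
    if labels and labels[0].lower() == "label":
        labels = labels[1:]
    if not labels:
        raise ValidationError(f"{path}: empty hypnogram")
    if start_clock_s is None:
        start_clock_s = header_clock
    if start_clock_s is None:
        start_clock_s = read_sidecar(path).get("start_clock_s", 0.0)
    return Hypnogram(np.array(labels), epoch_length_s, float(start_clock_s))


def write_hypnogram(path, hyp: Hypnogram) -> Path:
    path = Path(path)
    lines = [f"# start_clock_s={hyp.start_clock_s:g}", "label", *hyp.labels.tolist()]
    path.write_text("\n".join(lines) + "\n")
    write_sidecar(path, epoch_length_s=hyp.epoch_length_s, start_clock_s=hyp.start_clock_s)
    return path


# ---------------------------------------------------------------------------
# pose tracks

def read_pose_track(
    path,
    dialect: str | None = None,
    frame_rate_hz: float | None = None,
    cm_per_px: float = 1.0,
    start_time_s: float = 0.0,
) -> PoseTrack:
    """Read a pose track.

    ``dlc_csv`` is the DeepLabCut export dialect (three header rows:
    scorer / bodyparts / coords with x, y, likelihood per part);
    ``plain_csv`` is a wide table with ``<part>_x``, ``<part>_y`` and
    optional ``<part>_likelihood`` columns.  Coordinates are multiplied by
    ``cm_per_px``; pass 1.0 when the file is already in cm.
    """
    path = Path(path)
    if dialect is None:
        first = path.open().readline()
        dialect = "dlc_csv" if first.lower().startswith("scorer") else "plain_csv"
    meta = read_sidecar(path)
    if frame_rate_hz is None:
        frame_rate_hz = meta.get("frame_rate_hz")
    if frame_rate_hz is None:
        raise ConfigurationError(f"{path}: frame rate not supplied and no sidecar")

    points: dict[str, np.ndarray] = {}
    confidence: dict[str, np.ndarray] = {}
    if dialect == "dlc_csv":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        parts = list(dict.fromkeys(df.columns.get_level_values(1)))
        for part in parts:
            sub = df.xs(part, axis=1, level=1)
            sub.columns = sub.columns.get_level_values(-1)
            xy = np.column_stack([sub["x"].to_numpy(float), sub["y"].to_numpy(float)])
            points[part] = xy * cm_per_px
            if "likelihood" in sub.columns:
                confidence[part] = sub["likelihood"].to_numpy(float)
    elif dialect == "plain_csv":
        df = pd.read_csv(path, comment="#")
        parts = sorted({c[:-2] for c in df.columns if c.endswith("_x")})
        for part in parts:
            xy = np.column_stack(
                [df[f"{part}_x"].to_numpy(float), df[f"{part}_y"].to_numpy(float)]
            )
            points[part] = xy * cm_per_px
            if f"{part}_likelihood" in df.columns:
                confidence[part] = df[f"{part}_likelihood"].to_numpy(float)
    else:
        raise ConfigurationError(f"unknown pose dialect {dialect!r}")
    if not points:
        raise ValidationError(f"{path}: no body points found")
    return PoseTrack(float(frame_rate_hz), points, confidence, start_time_s)


def write_pose_track(path, track: PoseTrack) -> Path:
    """Write the plain-CSV dialect plus a sidecar with the frame rate."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {}
    for part, xy in track.points.items():
        cols[f"{part}_x"] = xy[:, 0]
        cols[f"{part}_y"] = xy[:, 1]
        if part in track.confidence:
            cols[f"{part}_likelihood"] = track.confidence[part]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    write_sidecar(path, frame_rate_hz=track.frame_rate_hz,
                  start_time_s=track.start_time_s, units="cm",
                  origin="shelter-end wall corner, x toward trigger zone")
    return path


# ---------------------------------------------------------------------------
# events, photometry, variable tables

def read_events(path, kind: str | None = None) -> EventTimes:
    """Events CSV with columns ``time_s`` and optional ``kind``; when
    ``kind`` is given only matching rows are kept."""
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns:
        raise ValidationError(f"{path}: missing time_s column")
    if kind is not None and "kind" in df.columns:
        df = df[df["kind"] == kind]
    return EventTimes(np.sort(df["time_s"].to_numpy(float)), kind or "cue_onset")


def write_events(path, events: EventTimes) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": events.times, "kind": events.kind}).to_csv(
        path, index=False, float_format="%.10g"
    )
    return path


def read_photometry(path) -> tuple[UniformSeries, UniformSeries]:
    """Photometry CSV with columns ``time_s``, ``f470``, ``f405``."""
    channels = read_signal_channels(path, format="delimited")
    for name in ("f470", "f405"):
        if name not in channels:
            raise ValidationError(f"{path}: missing column {name!r}")
    return channels["f470"], channels["f405"]


def write_photometry(path, f470: UniformSeries, f405: UniformSeries) -> Path:
    return write_signal_csv(path, {"f470": f470, "f405": f405})


def read_variable_table(path) -> pd.DataFrame:
    """Per-animal behavioral variable table; must contain a ``group``
    column, optionally ``sex`` and ``animal_id``."""
    df = pd.read_csv(path, comment="#")
    if "group" not in df.columns:
        raise ValidationError(f"{path}: missing 'group' column")
    if "animal_id" in df.columns:
        df = df.set_index("animal_id")
    return df


def write_variable_table(path, df: pd.DataFrame) -> Path:
    path = Path(path)
    df.to_csv(path, index=df.index.name is not None, float_format="%.10g")
    return path
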