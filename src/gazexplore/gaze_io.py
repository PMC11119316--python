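"""Reading, writing, unit conversion and windowing of gaze trajectories.

A trajectory is an ordered sequence of eye-tracker samples (time, gaze x/y,
event label, optional pupil diameter) for a single trial.  Files are
delimited text in the style of an SMI Red-M export; column names and the
label vocabulary vary across firmware, so both are configurable through a
:class:`ColumnDialect`.

Coordinates arrive in screen pixels and are converted to degrees of visual
angle with :func:`pixels_to_degrees` before any kinematic analysis.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Label",
    "Unit",
    "ScreenGeometry",
    "ColumnDialect",
    "GazeTrajectory",
    "ConfigError",
    "DataError",
    "read_trajectory",
    "write_trajectory",
    "pixels_to_degrees",
    "filter_valid",
    "window_first_seconds",
]


class ConfigError(ValueError):
    """Raised when a configuration (dialect, geometry, units) is unusable."""


class DataError(ValueError):
    """Raised when the data itself violates a contract (ordering, emptiness)."""


class Label(enum.IntEnum):
    """Per-sample event label.

    Blinks and missing samples are not distinguished: both carry no usable
    gaze coordinate and both map to ``INVALID``.
    """

    FIXATION = 0
    SACCADE = 1
    INVALID = 2


class Unit(str, enum.Enum):
    PIXELS = "pixels"
    DEGREES = "degrees"


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical description of the stimulus monitor and viewing position.

    The defaults describe a 1280 x 1080 monitor of 47.6 cm x 26.8 cm viewed
    at 60 cm.  The physical panel size is an assumption (a typical 22-inch
    panel); override it when the real monitor dimensions are known, since
    the pixel pitch enters every degree conversion.
    """

    width_px: int = 1280
    height_px: int = 1080
    width_cm: float = 47.6
    height_cm: float = 26.8
    viewing_distance_cm: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "width_px",
            "height_px",
            "width_cm",
            "height_cm",
            "viewing_distance_cm",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ConfigError(f"ScreenGeometry.{name} must be strictly positive, got {value!r}")

    @property
    def pitch_x_cm(self) -> float:
        """Horizontal pixel pitch in cm/px."""
        return self.width_cm / self.width_px

    @property
    def pitch_y_cm(self) -> float:
        return self.height_cm / self.height_px

    def bounds_deg(self) -> tuple[float, float]:
        """Half-width and half-height of the screen in degrees of visual angle."""
        hw = math.degrees(math.atan2(self.width_cm / 2, self.viewing_distance_cm))
        hh = math.degrees(math.atan2(self.height_cm / 2, self.viewing_distance_cm))
        return hw, hh


#: Default mapping from label strings found in files to :class:`Label`.
DEFAULT_LABEL_MAP: dict[str, Label] = {
    "fixation": Label.FIXATION,
    "saccade": Label.SACCADE,
    "blink": Label.INVALID,
    "invalid": Label.INVALID,
    "-": Label.INVALID,
    "": Label.INVALID,
}


@dataclass(frozen=True)
class ColumnDialect:
    """Mapping from the logical columns to the names used in a file.

    ``time_unit`` declares the unit of the time column; timestamps are
    re-based to start at zero and converted to seconds on read.  Unmapped
    label strings raise, so surprising vocabularies fail loudly.
    """

    time: str = "time_ms"
    x: str = "gx_px"
    y: str = "gy_px"
    label: str = "event"
    pupil: str | None = None
    time_unit: str = "ms"  # "ms", "us" or "s"
    delimiter: str = ","
    unit: Unit = Unit.PIXELS
    label_map: dict[str, Label] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def time_scale(self) -> float:
        scales = {"s": 1.0, "ms": 1e-3, "us": 1e-6}
        try:
            return scales[self.time_unit]
        except KeyError:
            raise ConfigError(
                f"unknown time unit {self.time_unit!r}; expected one of {sorted(scales)}"
            ) from None


@dataclass
class GazeTrajectory:
    """Ordered per-trial gaze samples; the common currency between modules.

    Arrays are parallel and share one length.  ``x``/``y`` are NaN exactly
    where ``label`` is :attr:`Label.INVALID`.  Timestamps are seconds since
    trial start and strictly increasing.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    label: np.ndarray
    pupil_mm: np.ndarray | None = None
    trial_id: str = "trial"
    participant_id: str = "participant"
    group: str | None = None
    unit: Unit = Unit.PIXELS
    sampling_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.label = np.asarray(self.label, dtype=np.int8)
        if self.t.size == 0:
            raise DataError(f"trajectory {self.trial_id!r} has no records")
        if not (self.t.size == self.x.size == self.y.size == self.label.size):
            raise DataError("t, x, y and label must have equal length")
        diffs = np.diff(self.t)
        if np.any(diffs <= 0):
            bad = int(np.argmax(diffs <= 0)) + 1
            raise DataError(
                f"timestamps must be strictly increasing; first violation at row {bad}"
            )
        valid = self.label != Label.INVALID
        if not np.all(np.isfinite(self.x[valid])) or not np.all(np.isfinite(self.y[valid])):
            raise DataError("non-finite coordinates on a sample not labeled INVALID")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.label != Label.INVALID))

    def valid_mask(self) -> np.ndarray:
        return self.label != Label.INVALID

    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


def _parse_floats(column: pd.Series) -> np.ndarray:
    """Correctly-rounded string-to-double conversion; non-numeric -> NaN.

    Python's ``float`` is used per cell because fast vectorized parsers can
    be off by one ulp, and half-open time windows sit exactly on sample
    timestamps.
    """

    def conv(s: str) -> float:
        try:
            return float(s)
        except ValueError:
            return math.nan

    return column.map(conv).to_numpy(float)


def read_trajectory(
    path: str | Path,
    dialect: ColumnDialect | None = None,
    *,
    trial_id: str | None = None,
    participant_id: str | None = None,
    group: str | None = None,
    sampling_rate_hz: float = 60.0,
) -> GazeTrajectory:
    """Read one trial file into a :class:`GazeTrajectory`.

    Rows whose gaze coordinates are missing or non-numeric are kept as
    ``INVALID`` records (they still occupy a time slot, which matters for
    the validity filter and for gap handling downstream).  Timestamps are
    re-based so the first record is at t = 0.

    If a JSON sidecar ``<path>.meta.json`` exists (written by
    :func:`write_trajectory`), trial metadata is taken from it unless
    overridden by keyword arguments, and the column layout, time unit and
    coordinate unit recorded there take precedence over the dialect —
    a file this package wrote knows how to read itself back exactly.
    """
    dialect = dialect or ColumnDialect()
    path = Path(path)

    stored: dict = {}
    sidecar = path.with_name(path.name + ".meta.json")
    if sidecar.exists():
        stored = json.loads(sidecar.read_text())
        overrides = {k: stored[k] for k in ("unit", "time_unit") if k in stored}
        overrides.update(stored.get("columns", {}))
        if overrides:
            if "unit" in overrides:
                overrides["unit"] = Unit(overrides["unit"])
            dialect = replace(dialect, **overrides)

    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)

    required = {"time": dialect.time, "x": dialect.x, "y": dialect.y, "label": dialect.label}
    for logical, name in required.items():
        if name not in df.columns:
            raise ConfigError(
                f"required column {name!r} (logical {logical!r}) not found in {path.name}; "
                f"file has columns {list(df.columns)}"
            )

    t_raw = _parse_floats(df[dialect.time])
    if np.any(~np.isfinite(t_raw)):
        bad = int(np.argmax(~np.isfinite(t_raw)))
        raise DataError(f"non-numeric timestamp at row {bad} of {path.name}")
    t = (t_raw - t_raw[0]) * dialect.time_scale()

    x = _parse_floats(df[dialect.x])
    y = _parse_floats(df[dialect.y])

    labels = np.empty(len(df), dtype=np.int8)
    for i, raw in enumerate(df[dialect.label].astype(str)):
        key = raw.strip().lower()
        if key not in dialect.label_map:
            raise ConfigError(f"unmapped label value {raw!r} at row {i} of {path.name}")
        labels[i] = dialect.label_map[key]
    # a row with unusable coordinates is INVALID regardless of its label
    labels[~(np.isfinite(x) & np.isfinite(y))] = Label.INVALID
    x[labels == Label.INVALID] = np.nan
    y[labels == Label.INVALID] = np.nan

    pupil = None
    if dialect.pupil and dialect.pupil in df.columns:
        pupil = _parse_floats(df[dialect.pupil])

    meta = {
        "trial_id": trial_id,
        "participant_id": participant_id,
        "group": group,
        "sampling_rate_hz": sampling_rate_hz,
    }
    for key in meta:
        if meta[key] is None and key in stored:
            meta[key] = stored[key]

    return GazeTrajectory(
        t=t,
        x=x,
        y=y,
        label=labels,
        pupil_mm=pupil,
        trial_id=meta["trial_id"] or path.stem,
        participant_id=meta["participant_id"] or path.stem,
        group=meta["group"],
        unit=dialect.unit,
        sampling_rate_hz=float(meta["sampling_rate_hz"] or sampling_rate_hz),
    )


def write_trajectory(
    traj: GazeTrajectory,
    path: str | Path,
    dialect: ColumnDialect | None = None,
    *,
    sidecar: bool = True,
) -> Path:
    """Write a trajectory using the same CSV schema :func:`read_trajectory` reads.

    INVALID records are written with empty coordinate fields.  A JSON
    sidecar with trial metadata (ids, group, unit, sampling rate) and the
    column layout is written next to the CSV unless ``sidecar=False``, so
    the file reads back without guessing.  Degree trajectories default to
    seconds-based time and ``*_deg`` column names; second-resolution
    timestamps survive the text round trip bit-exactly, which matters
    because analysis windows are half-open in time.
    """
    if dialect is None:
        if traj.unit is Unit.DEGREES:
            dialect = ColumnDialect(
                time="time_s", x="gx_deg", y="gy_deg", time_unit="s", unit=Unit.DEGREES
            )
        else:
            dialect = ColumnDialect()
    path = Path(path)
    inv_label = {Label.FIXATION: "fixation", Label.SACCADE: "saccade", Label.INVALID: "blink"}

    t_out = traj.t / dialect.time_scale()
    cols: dict[str, object] = {
        dialect.time: [repr(float(v)) for v in t_out],
        dialect.x: ["" if not np.isfinite(v) else repr(float(v)) for v in traj.x],
        dialect.y: ["" if not np.isfinite(v) else repr(float(v)) for v in traj.y],
        dialect.label: [inv_label[Label(v)] for v in traj.label],
    }
    if dialect.pupil and traj.pupil_mm is not None:
        cols[dialect.pupil] = ["" if not np.isfinite(v) else repr(float(v)) for v in traj.pupil_mm]
    pd.DataFrame(cols).to_csv(path, sep=dialect.delimiter, index=False)

    if sidecar:
        meta = {
            "trial_id": traj.trial_id,
            "participant_id": traj.participant_id,
            "group": traj.group,
            "unit": traj.unit.value,
            "sampling_rate_hz": traj.sampling_rate_hz,
            "time_unit": dialect.time_unit,
            "columns": {
                "time": dialect.time,
                "x": dialect.x,
                "y": dialect.y,
                "label": dialect.label,
            },
        }
        path.with_name(path.name + ".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def pixels_to_degrees(
    traj: GazeTrajectory,
    geom: ScreenGeometry,
    *,
    linear: bool = False,
) -> GazeTrajectory:
    """Convert a pixel trajectory to degrees of visual angle.

    Each axis is converted independently about the screen center: the pixel
    offset is turned into centimetres via the pixel pitch and then into the
    angle ``atan(offset_cm / viewing_distance_cm)``.  With ``linear=True`` a
    flat small-angle conversion (``offset_cm / distance`` in radians) is
    used instead, for comparability with analyses that assume a constant
    deg/px factor.  INVALID records pass through unchanged (NaN in, NaN out).
    """
    if traj.unit is not Unit.DEGREES and traj.unit is not Unit.PIXELS:
        raise ConfigError(f"unknown unit {traj.unit!r}")
    if traj.unit is Unit.DEGREES:
        raise ConfigError("trajectory is already in degrees")

    cx = geom.width_px / 2.0
    cy = geom.height_px / 2.0
    off_x_cm = (traj.x - cx) * geom.pitch_x_cm
    off_y_cm = (traj.y - cy) * geom.pitch_y_cm
    d = geom.viewing_distance_cm
    if linear:
        x_deg = np.degrees(off_x_cm / d)
        y_deg = np.degrees(off_y_cm / d)
    else:
        x_deg = np.degrees(np.arctan2(off_x_cm, d))
        y_deg = np.degrees(np.arctan2(off_y_cm, d))

    out = replace(traj)
    out.x = x_deg
    out.y = y_deg
    out.unit = Unit.DEGREES
    return out


def filter_valid(traj: GazeTrajectory, min_valid_samples: int = 500) -> tuple[bool, int]:
    """Trial-inclusion decision: enough usable samples excluding blinks?

    Returns ``(accepted, n_valid)`` where a trial is accepted iff the number
    of non-INVALID records is at least ``min_valid_samples`` (default 500).
    """
    n_valid = traj.n_valid
    return n_valid >= min_valid_samples, n_valid


def window_first_seconds(traj: GazeTrajectory, duration_s: float = 5.0) -> GazeTrajectory:
    """Return the prefix of records with ``t < duration_s`` (half-open window).

    The half-open convention makes 5 s at exactly 60 Hz exactly 300 samples.
    A window longer than the trajectory returns the full trajectory.
    """
    if duration_s <= 0:
        raise ConfigError(f"duration_s must be positive, got {duration_s}")
    keep = traj.t < duration_s
    n = int(np.sum(keep))
    if n == 0:
        raise DataError(f"no records in the first {duration_s} s of trial {traj.trial_id!r}")
    out = replace(traj)
    out.t = traj.t[:n].copy()
    out.x = traj.x[:n].copy()
    out.y = traj.y[:n].copy()
    out.label = traj.label[:n].copy()
    if traj.pupil_mm is not None:
        out.pupil_mm = traj.pupil_mm[:n].copy()
    return out
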