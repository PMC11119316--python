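"""Per-sample gaze velocity and its logarithm.

The speed between consecutive samples is the raw first difference

    v(t_i) = sqrt((X_i - X_{i-1})^2 + (Y_i - Y_{i-1})^2) / (t_i - t_{i-1})

in degrees per second, using actual timestamps rather than the nominal
sampling rate.  No smoothing is applied.  Gaze speeds are approximately
log-normal within each eye-movement state, so downstream statistics work on
``log v``; the base is configurable and defaults to base 10, under which
typical fixation speeds sit near 10^1 deg/s and saccades near 10^2 deg/s.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_io import DataError, GazeTrajectory, Label, Unit

__all__ = ["LogBase", "VelocitySeries", "compute_velocity", "log_velocity"]


class LogBase(str, enum.Enum):
    NATURAL = "natural"
    LOG10 = "log10"


@dataclass
class VelocitySeries:
    """Velocity samples derived from one trajectory.

    Each sample i spans the record pair (src_index[i]-1, src_index[i]) and
    inherits the label of the *later* record.  Pairs that straddle an
    INVALID record produce no sample; ``src_index`` keeps enough structure
    to tell which surviving samples are truly consecutive (needed by the
    transition-probability estimator).

    ``log_v`` is NaN until :func:`log_velocity` fills it; samples with
    v = 0 (possible with quantized coordinates) stay NaN there and
    ``n_zero_excluded`` counts them.
    """

    t: np.ndarray
    v: np.ndarray
    label: np.ndarray
    src_index: np.ndarray
    log_v: np.ndarray | None = None
    log_base: LogBase | None = None
    n_zero_excluded: int = 0
    trial_id: str = "trial"

    def __len__(self) -> int:
        return int(self.t.size)

    def consecutive_pairs(self) -> np.ndarray:
        """Boolean mask over pairs (i, i+1) of samples that are adjacent in the
        original record sequence (no INVALID gap between them)."""
        return np.diff(self.src_index) == 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "v": self.v,
                "log_v": self.log_v if self.log_v is not None else np.nan,
                "label": [Label(l).name for l in self.label],
            }
        )


def compute_velocity(traj: GazeTrajectory) -> VelocitySeries:
    """Compute per-sample speed for every consecutive pair of valid records.

    Requires a trajectory in degrees. Raises :class:`DataError` with fewer
    than two valid records.
    """
    if traj.unit is not Unit.DEGREES:
        raise DataError("velocity is defined on trajectories in degrees; convert first")
    valid = traj.valid_mask()
    if int(valid.sum()) < 2:
        raise DataError(f"trial {traj.trial_id!r}: fewer than 2 valid records")

    ok_pair = valid[:-1] & valid[1:]
    idx = np.nonzero(ok_pair)[0] + 1  # index of the later record of each pair
    dt = traj.t[idx] - traj.t[idx - 1]
    dx = traj.x[idx] - traj.x[idx - 1]
    dy = traj.y[idx] - traj.y[idx - 1]
    v = np.hypot(dx, dy) / dt
    return VelocitySeries(
        t=traj.t[idx],
        v=v,
        label=traj.label[idx],
        src_index=idx,
        trial_id=traj.trial_id,
    )


def log_velocity(series: VelocitySeries, base: LogBase = LogBase.LOG10) -> VelocitySeries:
    """Fill ``log_v`` in the requested base.

    Samples with v = 0 have no logarithm; they are excluded from log-domain
    statistics (log_v = NaN) and counted in ``n_zero_excluded`` rather than
    floored to an arbitrary value.
    """
    with np.errstate(divide="ignore"):
        log_v = np.log10(series.v) if base is LogBase.LOG10 else np.log(series.v)
    zero = series.v == 0
    log_v[zero] = np.nan
    series.log_v = log_v
    series.log_base = base
    series.n_zero_excluded = int(zero.sum())
    return series
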