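"""Grid-occupancy exploration metrics: the visited-area curve and Λ.

The screen plane (in degrees of visual angle) is tiled by an unbounded grid
of square cells, 0.5 degrees on a side by default.  The *visited area*
``A(t)`` of a trajectory is the number of distinct cells its valid gaze
samples have entered within the first ``t`` seconds.  The exploration
metric Λ time-averages the visited area per unit time over nested windows:

    Λ(τ, N) = (1/N) · Σ_{k=k_start}^{N}  A(kτ) / (kτ)

with defaults τ = 1/60 s and N = 300, i.e. windows growing sample-by-sample
up to the first 5 s of a 60 Hz recording.  Early windows carry the largest
implicit weight (1/kτ), so Λ emphasises how quickly a viewer starts
exploring.  The k = 0 term of a naive sum is 0/0 and is excluded; the
prefactor stays 1/N regardless of ``k_start``.

Λ has units of cells per second (a time-averaged exploration rate).  Note
that Λ is sensitive to where the grid is anchored: translating a trajectory
by a non-integer number of cells can change cell occupancy.  The anchor is
fixed at the screen's top-left corner (in degree coordinates) by default so
results are comparable across trials; off-screen samples still count, the
grid is unbounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_io import DataError, GazeTrajectory, ScreenGeometry, Unit

__all__ = [
    "GridSpec",
    "LambdaParams",
    "VisitedAreaCurve",
    "visited_cells",
    "area_curve",
    "lambda_metric",
    "lambda_for_trajectory",
]


@dataclass(frozen=True)
class GridSpec:
    """Square grid in degree coordinates.

    ``origin`` is the (x, y) of a cell corner; the default anchors the grid
    at the top-left screen corner of the default geometry.
    """

    cell_deg: float = 0.5
    origin: tuple[float, float] = (
        -ScreenGeometry().bounds_deg()[0],
        -ScreenGeometry().bounds_deg()[1],
    )

    def __post_init__(self) -> None:
        if not self.cell_deg > 0:
            raise DataError(f"cell_deg must be positive, got {self.cell_deg}")

    @classmethod
    def for_geometry(cls, geom: ScreenGeometry, cell_deg: float = 0.5) -> "GridSpec":
        hw, hh = geom.bounds_deg()
        return cls(cell_deg=cell_deg, origin=(-hw, -hh))

    def cell_indices(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """(n, 2) integer cell indices of the given degree coordinates."""
        ix = np.floor((np.asarray(x, float) - self.origin[0]) / self.cell_deg)
        iy = np.floor((np.asarray(y, float) - self.origin[1]) / self.cell_deg)
        return np.stack([ix, iy], axis=1).astype(np.int64)


@dataclass(frozen=True)
class LambdaParams:
    """Window schedule of the Λ sum: windows [0, kτ) for k = k_start..N."""

    tau_s: float = 1.0 / 60.0
    N: int = 300
    k_start: int = 1

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise DataError("tau_s must be positive")
        if self.k_start < 1:
            raise DataError("k_start must be >= 1 (the k = 0 term is 0/0)")
        if self.k_start > self.N:
            raise DataError(f"k_start ({self.k_start}) exceeds N ({self.N})")


@dataclass
class VisitedAreaCurve:
    """A(kτ) for k = k_start..N; non-decreasing by construction."""

    tau_s: float
    k: np.ndarray
    A: np.ndarray
    trial_id: str = "trial"

    @property
    def t(self) -> np.ndarray:
        return self.k * self.tau_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "t": self.t, "A": self.A})


def visited_cells(x: np.ndarray, y: np.ndarray, grid: GridSpec) -> int:
    """Number of distinct grid cells covered by the given points.

    Points must be finite degree coordinates; an empty input visits 0 cells.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0:
        return 0
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("visited_cells requires finite coordinates; drop INVALID samples first")
    cells = grid.cell_indices(x, y)
    return int(np.unique(cells, axis=0).shape[0])


def area_curve(
    traj: GazeTrajectory,
    grid: GridSpec | None = None,
    params: LambdaParams | None = None,
) -> VisitedAreaCurve:
    """Visited-area counts over the nested windows [0, kτ), k = k_start..N.

    INVALID samples contribute nothing; windows are defined by time, not by
    valid-sample count.  Raises :class:`DataError` when the first window
    contains no valid sample.
    """
    if traj.unit is not Unit.DEGREES:
        raise DataError("area_curve requires a trajectory in degrees")
    grid = grid or GridSpec()
    params = params or LambdaParams()

    valid = traj.valid_mask()
    t = traj.t[valid]
    cells = grid.cell_indices(traj.x[valid], traj.y[valid])

    # first-visit flags -> cumulative distinct-cell count, then sample the
    # cumulative curve at each window edge
    n_new = np.zeros(t.size, dtype=np.int64)
    seen: set[tuple[int, int]] = set()
    for i, cell in enumerate(map(tuple, cells)):
        if cell not in seen:
            seen.add(cell)
            n_new[i] = 1
    cum = np.cumsum(n_new)

    k = np.arange(params.k_start, params.N + 1)
    edges = k * params.tau_s
    # number of valid samples with t < edge
    counts = np.searchsorted(t, edges, side="left")
    if counts[0] == 0:
        raise DataError(
            f"trial {traj.trial_id!r}: no valid sample in the first window "
            f"[0, {edges[0]:.4f} s)"
        )
    A = cum[counts - 1]
    return VisitedAreaCurve(tau_s=params.tau_s, k=k, A=A, trial_id=traj.trial_id)


def lambda_metric(curve: VisitedAreaCurve, params: LambdaParams | None = None) -> float:
    """Time-weighted average exploration rate Λ = (1/N)·Σ A(kτ)/(kτ).

    The divisor is N regardless of ``k_start``.
    """
    params = params or LambdaParams(tau_s=curve.tau_s, N=int(curve.k[-1]), k_start=int(curve.k[0]))
    if curve.k[0] != params.k_start or curve.k[-1] != params.N:
        raise DataError(
            f"curve covers k = {curve.k[0]}..{curve.k[-1]} but params request "
            f"{params.k_start}..{params.N}"
        )
    terms = curve.A / (curve.k * curve.tau_s)
    return float(np.sum(terms) / params.N)


def lambda_for_trajectory(
    traj: GazeTrajectory,
    grid: GridSpec | None = None,
    params: LambdaParams | None = None,
) -> float:
    """Convenience: Λ straight from a degree trajectory."""
    params = params or LambdaParams()
    return lambda_metric(area_curve(traj, grid, params), params)
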