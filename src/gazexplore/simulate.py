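"""Synthetic gaze-trajectory generator: a two-state Markov walk.

The generator inverts the descriptive two-state model of eye movement into
a sampler.  Per sample, a hidden state (fixation F or saccade S) evolves as
a two-state Markov chain with switch probabilities ``p_FS`` (F->S) and
``p_SF`` (S->F).  The speed of each sample is drawn log-normally from the
state's (mu, sigma) in the configured log base, so downstream log-velocity
moments recover the inputs by construction.  Spatial dynamics are a
modeling choice the two-state description leaves open:

* during a fixation, the heading is re-drawn isotropically at every sample
  (a drift/tremor proxy), keeping the gaze near one location;
* at saccade onset the heading is drawn once and held for the whole
  saccade episode (a ballistic proxy), producing straight fast sweeps.

Positions live in degrees of visual angle and start at screen center.  A
step that would cross a screen edge bounces by mirroring its heading,
which keeps the gaze on the stimulus while preserving the step length —
and hence the speed a first-difference velocity estimate recovers.  Gaze
direction is physically unbounded, and a step drawn from the extreme
saccade tail can be longer than any on-screen chord; such steps (a small
fraction under the default parameters) overshoot off-screen at full
length and subsequent steps steer back toward the screen, so the planted
velocity distribution is never distorted.  Optional blinks replace runs
of samples with INVALID records, emulating eye-tracker dropout.

Defaults for group-level experiments (:data:`TD_PARAMS`, :data:`ASD_PARAMS`)
are the published group-mean feature values for typically-developed and ASD
children: log10 moments (mu_F, sigma_F, mu_S, sigma_S) = (1.04, 0.437,
2.13, 0.708) for TD and (1.20, 0.429, 2.16, 0.621) for ASD, with switch
rates (p_FS, p_SF) = (0.0502, 0.358) and (0.0617, 0.325) respectively.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .gaze_io import (
    ColumnDialect,
    GazeTrajectory,
    Label,
    ScreenGeometry,
    Unit,
    write_trajectory,
)
from .kinematics import LogBase

__all__ = [
    "SimulationParams",
    "CohortSpec",
    "TD_PARAMS",
    "ASD_PARAMS",
    "simulate_trajectory",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters of one simulated trial.

    Log-velocity moments are in the units of ``log_base`` applied to speed
    in deg/s.  ``blink_rate_hz`` is the Poisson rate of blink onsets; each
    blink invalidates ``blink_duration_s`` of samples.
    """

    mu_F: float = 1.04
    sigma_F: float = 0.437
    mu_S: float = 2.13
    sigma_S: float = 0.708
    p_FS: float = 0.0502
    p_SF: float = 0.358
    duration_s: float = 5.0
    rate_hz: float = 60.0
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    seed: int = 0
    initial_state: Label = Label.FIXATION
    log_base: LogBase = LogBase.LOG10
    blink_rate_hz: float = 0.0
    blink_duration_s: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_FS <= 1.0 and 0.0 <= self.p_SF <= 1.0):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if self.sigma_F < 0 or self.sigma_S < 0:
            raise ValueError("sigmas must be non-negative")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration_s and rate_hz must be positive")
        if self.initial_state is Label.INVALID:
            raise ValueError("initial state must be FIXATION or SACCADE")


#: Published group-mean parameters, usable as generator inputs.
TD_PARAMS = SimulationParams()
ASD_PARAMS = SimulationParams(
    mu_F=1.20, sigma_F=0.429, mu_S=2.16, sigma_S=0.621, p_FS=0.0617, p_SF=0.325
)


@dataclass(frozen=True)
class CohortSpec:
    """Two labeled groups of simulated trials.

    Per-trial seeds are derived by hashing (master seed, group name, trial
    index), so cohorts are reproducible and order-independent.
    """

    group_params: dict[str, SimulationParams]
    n_trials_per_group: int
    master_seed: int = 0

    def trial_seed(self, group: str, index: int) -> int:
        h = zlib.crc32(f"{self.master_seed}:{group}:{index}".encode())
        return int(h % (2**31 - 1))


def _stationary_fixation_fraction(p_fs: float, p_sf: float) -> float:
    """Stationary occupancy of the fixation state, p_SF / (p_FS + p_SF)."""
    if p_fs + p_sf == 0:
        return 1.0
    return p_sf / (p_fs + p_sf)


def simulate_trajectory(params: SimulationParams, *, trial_id: str = "sim") -> GazeTrajectory:
    """Sample one labeled gaze trajectory in degrees.

    5 s at 60 Hz yields exactly 300 samples (sample k at t = k / rate).
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.rate_hz))
    dt = 1.0 / params.rate_hz
    t = np.arange(n) * dt

    # state path of the two-state chain
    states = np.empty(n, dtype=np.int8)
    states[0] = params.initial_state
    u = rng.random(n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        if states[i - 1] == Label.FIXATION:
            states[i] = Label.SACCADE if u[i - 1] < params.p_FS else Label.FIXATION
        else:
            states[i] = Label.FIXATION if u[i - 1] < params.p_SF else Label.SACCADE

    # per-sample speeds: log-normal within state, in the configured base
    z = rng.standard_normal(n)
    log_v = np.where(
        states == Label.FIXATION,
        params.mu_F + params.sigma_F * z,
        params.mu_S + params.sigma_S * z,
    )
    speeds = 10.0**log_v if params.log_base is LogBase.LOG10 else np.exp(log_v)

    # headings: fresh draw per fixation sample; held across a saccade episode.
    # Steps bounce off screen edges by mirroring the heading, which keeps
    # every position on-screen while preserving the drawn step length (and
    # hence the measurable speed); only steps longer than the distance to the
    # farthest screen corner are truncated (they could not fit on any screen).
    hw, hh = params.geometry.bounds_deg()
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = 0.0, 0.0
    steps = speeds * dt
    fresh_angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
    heading = fresh_angles[0]
    for i in range(1, n):
        if not (states[i] == Label.SACCADE and states[i - 1] == Label.SACCADE):
            heading = fresh_angles[i]
        x[i], y[i], heading = _bounded_step(
            x[i - 1], y[i - 1], steps[i], heading, hw, hh, rng
        )

    labels = states.copy()
    if params.blink_rate_hz > 0:
        n_blinks = rng.poisson(params.blink_rate_hz * params.duration_s)
        blink_len = max(1, int(round(params.blink_duration_s * params.rate_hz)))
        for start in rng.integers(0, n, size=n_blinks):
            labels[start : start + blink_len] = Label.INVALID
    xb = x.copy()
    yb = y.copy()
    xb[labels == Label.INVALID] = np.nan
    yb[labels == Label.INVALID] = np.nan

    return GazeTrajectory(
        t=t,
        x=xb,
        y=yb,
        label=labels,
        trial_id=trial_id,
        participant_id=trial_id,
        unit=Unit.DEGREES,
        sampling_rate_hz=params.rate_hz,
    )


def _bounded_step(
    px: float,
    py: float,
    length: float,
    heading: float,
    hw: float,
    hh: float,
    rng: np.random.Generator,
    max_tries: int = 40,
) -> tuple[float, float, float]:
    """One straight step of given length, kept inside [-hw,hw] x [-hh,hh]
    whenever an on-screen endpoint exists.

    The screen box is convex, so a step fits iff its endpoint is in the box.
    Preference order: the current heading, its wall-mirrored images (flip dx,
    flip dy, flip both), then uniformly re-drawn headings, and finally the
    full-length step toward the farthest screen corner (which may land
    off-screen).  The step length is preserved in every case.
    """
    candidates = (heading, np.pi - heading, -heading, np.pi + heading)
    for cand in candidates:
        qx = px + length * np.cos(cand)
        qy = py + length * np.sin(cand)
        if abs(qx) <= hw and abs(qy) <= hh:
            return qx, qy, cand
    for _ in range(max_tries):
        cand = rng.uniform(0.0, 2.0 * np.pi)
        qx = px + length * np.cos(cand)
        qy = py + length * np.sin(cand)
        if abs(qx) <= hw and abs(qy) <= hh:
            return qx, qy, cand
    # no on-screen endpoint exists (or the current point is itself
    # off-screen after such a step): take the full step toward the farthest
    # screen corner, overshooting off-screen if need be, so the step length
    # — and with it the measurable speed — is never distorted
    cx = hw if px <= 0 else -hw
    cy = hh if py <= 0 else -hh
    d = float(np.hypot(cx - px, cy - py))
    qx = px + length * (cx - px) / d
    qy = py + length * (cy - py) / d
    return qx, qy, float(np.arctan2(qy - py, qx - px))


def simulate_cohort(spec: CohortSpec) -> list[GazeTrajectory]:
    """Simulate ``n_trials_per_group`` labeled trials for each group.

    Deterministic given the master seed; trials carry their group label.
    """
    trials: list[GazeTrajectory] = []
    for group in sorted(spec.group_params):
        base = spec.group_params[group]
        for i in range(spec.n_trials_per_group):
            params = replace(base, seed=spec.trial_seed(group, i))
            traj = simulate_trajectory(params, trial_id=f"{group.lower()}_{i:03d}")
            traj.group = group
            trials.append(traj)
    return trials


def write_cohort(
    trials: list[GazeTrajectory],
    out_dir: str | Path,
    dialect: ColumnDialect | None = None,
) -> list[Path]:
    """Write each trial as CSV (+ metadata sidecar) into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for traj in trials:
        paths.append(write_trajectory(traj, out_dir / f"{traj.trial_id}.csv", dialect))
    return paths
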