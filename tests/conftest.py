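import numpy as np
import pytest

from gazexplore import (
    ASD_PARAMS,
    TD_PARAMS,
    CohortSpec,
    GazeTrajectory,
    Label,
    Unit,
    simulate_cohort,
)


def make_trajectory(
    x,
    y,
    labels=None,
    rate_hz: float = 60.0,
    unit: Unit = Unit.DEGREES,
    **kwargs,
) -> GazeTrajectory:
    """Small helper: trajectory from coordinate lists at a fixed rate."""
    x = np.asarray(x, float)
    n = x.size
    if labels is None:
        labels = np.full(n, Label.FIXATION, dtype=np.int8)
    else:
        labels = np.asarray(labels, dtype=np.int8)
    return GazeTrajectory(
        t=np.arange(n) / rate_hz,
        x=x,
        y=np.asarray(y, float),
        label=labels,
        unit=unit,
        sampling_rate_hz=rate_hz,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """30 TD + 30 ASD simulated 5 s trials from the published group parameters."""
    spec = CohortSpec(
        group_params={"TD": TD_PARAMS, "ASD": ASD_PARAMS},
        n_trials_per_group=30,
        master_seed=20240518,
    )
    return simulate_cohort(spec)
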