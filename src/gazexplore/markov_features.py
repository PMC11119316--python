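"""Fixation/saccade summary features of a gaze velocity series.

Six quantities summarise the two-state (fixation F / saccade S) picture of
eye-movement dynamics:

* ``mu_F``, ``sigma_F`` — mean and population standard deviation of the
  log-velocity over fixation-labeled samples;
* ``mu_S``, ``sigma_S`` — the same over saccade-labeled samples;
* ``p_FS`` — probability that a fixation-labeled sample is followed by a
  saccade-labeled one (the F->S switch rate of a two-state Markov chain);
* ``p_SF`` — the S->F switch rate.

Standard deviations divide by N (population form).  Transition
probabilities are maximum-likelihood estimates for the two-state chain:
conditional switch frequencies with all pairs whose first element is in the
source state as denominator.  Pairs interrupted by blink/invalid gaps
contribute to neither numerator nor denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_io import DataError, Label
from .kinematics import VelocitySeries

__all__ = ["MarkovFeatures", "estimate_features", "summarize_group", "FEATURE_NAMES"]

FEATURE_NAMES = ("mu_F", "sigma_F", "mu_S", "sigma_S", "p_FS", "p_SF")


class DegenerateInputError(DataError):
    """A velocity series lacking one of the two states entirely."""


@dataclass(frozen=True)
class MarkovFeatures:
    mu_F: float
    sigma_F: float
    mu_S: float
    sigma_S: float
    p_FS: float
    p_SF: float
    n_F: int
    n_S: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def estimate_features(series: VelocitySeries) -> MarkovFeatures:
    """Estimate the six fixation/saccade quantities from a velocity series.

    ``log_velocity`` must have been applied.  Raises
    :class:`DegenerateInputError` naming the missing state if the series has
    no fixation or no saccade samples.
    """
    if series.log_v is None:
        raise DataError("series has no log-velocity; apply log_velocity first")

    is_f = series.label == Label.FIXATION
    is_s = series.label == Label.SACCADE
    n_f, n_s = int(is_f.sum()), int(is_s.sum())
    if n_f == 0:
        raise DegenerateInputError(f"trial {series.trial_id!r}: no FIXATION samples")
    if n_s == 0:
        raise DegenerateInputError(f"trial {series.trial_id!r}: no SACCADE samples")

    def moments(mask: np.ndarray) -> tuple[float, float]:
        vals = series.log_v[mask]
        vals = vals[np.isfinite(vals)]  # v = 0 samples carry no log
        if vals.size == 0:
            return float("nan"), float("nan")
        mu = float(np.mean(vals))
        sigma = float(np.sqrt(np.mean((vals - mu) ** 2)))  # population SD
        return mu, sigma

    mu_f, sigma_f = moments(is_f)
    mu_s, sigma_s = moments(is_s)

    adjacent = series.consecutive_pairs()
    first = series.label[:-1][adjacent]
    second = series.label[1:][adjacent]
    from_f = first == Label.FIXATION
    from_s = first == Label.SACCADE
    n_from_f = int(from_f.sum())
    n_from_s = int(from_s.sum())
    p_fs = float(np.sum(from_f & (second == Label.SACCADE)) / n_from_f) if n_from_f else float("nan")
    p_sf = float(np.sum(from_s & (second == Label.FIXATION)) / n_from_s) if n_from_s else float("nan")

    return MarkovFeatures(
        mu_F=mu_f,
        sigma_F=sigma_f,
        mu_S=mu_s,
        sigma_S=sigma_s,
        p_FS=p_fs,
        p_SF=p_sf,
        n_F=n_f,
        n_S=n_s,
    )


def summarize_group(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Per-group arithmetic means of the feature table.

    ``table`` is the per-trial feature frame (one row per trial with columns
    mu_F..p_SF and lambda).  Returns one row per group, features as columns,
    in the layout of a group-comparison table.
    """
    cols = [c for c in (*FEATURE_NAMES, "lambda") if c in table.columns]
    if not cols:
        raise DataError("feature table has none of the expected feature columns")
    counts = table.groupby(group_col).size()
    if (counts == 0).any() or counts.empty:
        raise DataError("every group must have at least one member")
    return table.groupby(group_col)[cols].mean()
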