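"""Water-maze behavior summaries and cognitive classification.

Animals are trained on cue and spatial discrimination tasks (five blocks
each) followed by a free-swim probe trial.  Spatial memory is summarised
by the probe-trial discrimination index DI = (G - O) / (G + O), where G
and O are the percent time spent in the goal quadrant and the quadrant
opposite the goal.  Aged animals are classified as aged-impaired (AI) or
aged-unimpaired (AU) relative to the lowest DI observed among young
animals, which anchors the cut-off to the young distribution of the
cohort at hand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import PipelineError


def discrimination_index(goal_pct: float, opposite_pct: float) -> float:
    """Probe-trial discrimination index (G - O)/(G + O), in [-1, 1].

    0 indicates chance performance (equal time in goal and opposite
    quadrants); 1 means all goal-vs-opposite time was spent in the goal
    quadrant.
    """
    if goal_pct < 0 or opposite_pct < 0:
        raise PipelineError("quadrant percentages must be non-negative")
    total = goal_pct + opposite_pct
    if total == 0:
        raise PipelineError("discrimination index undefined when G = O = 0")
    return (goal_pct - opposite_pct) / total


def classify_animals(records: pd.DataFrame) -> pd.DataFrame:
    """Classify animals from probe-trial quadrant times.

    The cut-off is the minimum DI among young animals; aged animals below
    it are labelled AI, all other aged animals AU (a DI exactly at the
    cut-off takes the unimpaired label), and young animals are labelled
    ``young``.  Returns a table (animal_id, di, cognitive_class, cutoff)
    sorted by animal id, so classification is order-invariant.
    """
    di = records.apply(
        lambda r: discrimination_index(r["probe_goal_pct"], r["probe_opposite_pct"]),
        axis=1,
    )
    young = records["age_group"] == "young"
    if not young.any():
        raise PipelineError("cannot classify: no young animals in cohort")
    cutoff = float(di[young].min())
    label = np.where(young, "young", np.where(di < cutoff, "AI", "AU"))
    out = pd.DataFrame(
        {
            "animal_id": records["animal_id"],
            "di": di,
            "cognitive_class": label,
            "cutoff": cutoff,
        }
    )
    return out.sort_values("animal_id", kind="stable").reset_index(drop=True)


def percent_change_from_baseline(block_values) -> np.ndarray:
    """Per-block percent change in path length relative to block 1.

    Block 1 is the baseline, so the first entry is always 0; negative
    values indicate shorter (better) escape paths than baseline.
    """
    values = np.asarray(block_values, dtype=float)
    if values.ndim != 1 or values.size != 5:
        raise PipelineError("expected exactly 5 block values")
    if values[0] <= 0:
        raise PipelineError("baseline (block 1) must be positive")
    return 100.0 * (values - values[0]) / values[0]


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise PipelineError("pearson_r needs two equal-length series of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise PipelineError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def mean_split(values: pd.Series) -> pd.Series:
    """Split animals into performance groups at the mean of ``values``.

    ``values`` are path lengths (larger = worse), so the group at or below
    the mean is labelled ``good`` and the group above the mean ``poor``;
    ties at the mean go to the better-performing group.
    """
    values = pd.Series(values, dtype=float)
    if len(values) < 2:
        raise PipelineError("mean_split needs at least 2 animals")
    return pd.Series(
        np.where(values <= values.mean(), "good", "poor"), index=values.index
    )
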