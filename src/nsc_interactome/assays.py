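"""Small defined computations for the imaging and reporter readouts.

Two quantities from the cell-biology side of the study are reimplemented:
the per-cell Pearson colocalization coefficient between two fluorescence
channels (colocalized when rho >= 0.3), and the dual-sensor luciferase
normalization in which the WT miRNA sensor signal is divided by the
mutated-site sensor signal — a lower ratio means stronger miRNA activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ColocalizationResult:
    cell_id: str
    pearson: float          # NaN when undefined (constant channel)
    colocalized: bool
    threshold: float = 0.3


@dataclass(frozen=True)
class ReporterResult:
    condition: str
    mean_wt: float
    mean_mut: float
    activity: float         # mean_wt / mean_mut, optionally re-referenced


def pearson_colocalization(x: Sequence[float], y: Sequence[float],
                           threshold: float = 0.3,
                           cell_id: str = "") -> ColocalizationResult:
    """Pearson coefficient of paired per-pixel intensities, flagged at >= threshold.

    The threshold is inclusive.  If either channel is constant the
    coefficient is undefined: the result carries NaN and is not
    colocalized.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ColocalizationResult(cell_id, float("nan"), False, threshold)
    rho = float(stats.pearsonr(x, y).statistic)
    return ColocalizationResult(cell_id, rho, rho >= threshold, threshold)


def normalize_reporter(wt_wells: Sequence[float], mut_wells: Sequence[float],
                       condition: str = "",
                       reference: ReporterResult | None = None) -> ReporterResult:
    """Normalized reporter activity A = mean(WT sensor) / mean(mutant sensor).

    Replicate wells are averaged arithmetically.  With a ``reference``
    result, A is additionally divided by the reference activity so the
    reference condition reads 1.
    """
    wt = np.asarray(wt_wells, dtype=float)
    mut = np.asarray(mut_wells, dtype=float)
    if len(wt) < 1 or len(mut) < 1:
        raise ValueError("at least one replicate per sensor is required")
    if (wt <= 0).any() or (mut <= 0).any():
        raise ValueError("luminescence values must be positive")
    activity = float(wt.mean() / mut.mean())
    if reference is not None:
        if not math.isfinite(reference.activity) or reference.activity <= 0:
            raise ValueError("reference activity must be positive")
        activity /= reference.activity
    return ReporterResult(condition, float(wt.mean()), float(mut.mean()), activity)
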