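"""Closed-form statistics for the cell assays around the pipeline.

* Growth doubling time from two confluency/count observations:
  ``t2 = dt * ln(2) / ln(y1 / y0)``.
* qPCR fold change ``2^-ddCq`` with technical-replicate medians and Cq
  quality control (values < 15 or > 40 discarded; the bounds themselves
  are retained).
* Flow-cytometry relative uptake: ratio of geometric mean fluorescence
  (gMFI) between the receptor-positive and receptor-negative populations.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import numpy as np


@dataclasses.dataclass(frozen=True)
class GrowthObservation:
    """Two timepoints of a growth curve (hours, positive confluency)."""

    t0: float
    t1: float
    y0: float
    y1: float

    def __post_init__(self) -> None:
        if self.t1 <= self.t0:
            raise ValueError("t1 must exceed t0")
        if self.y0 <= 0 or self.y1 <= 0:
            raise ValueError("confluency values must be positive")


def doubling_time(obs: GrowthObservation) -> float:
    """Doubling time in hours; +inf when no net growth, negative on decline.

    Scale-invariant in y (only the ratio y1/y0 enters). The measurement
    window is an explicit caller choice — pick a stretch of the growth
    curve free of imaging artifacts.
    """
    if obs.y1 == obs.y0:
        return math.inf
    value = (obs.t1 - obs.t0) * math.log(2.0) / math.log(obs.y1 / obs.y0)
    if value < 0:
        warnings.warn("population declined over the window; doubling time "
                      "is negative", RuntimeWarning)
    return value


@dataclasses.dataclass(frozen=True)
class QpcrWell:
    sample: str
    target: str
    cq: float
    replicate: int = 0


DEFAULT_CQ_BOUNDS = (15.0, 40.0)


def _median_cq(wells: Sequence[QpcrWell], sample: str, target: str,
               bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    # strict discard outside [lo, hi]; boundary values are retained
    cqs = [w.cq for w in wells
           if w.sample == sample and w.target == target and lo <= w.cq <= hi]
    if not cqs:
        warnings.warn(
            f"all Cq replicates for ({sample}, {target}) failed QC",
            RuntimeWarning)
        return math.nan
    if len(cqs) < 2:
        warnings.warn(
            f"only {len(cqs)} Cq replicate(s) for ({sample}, {target}) "
            "survived QC; median of fewer than 2 technical replicates",
            RuntimeWarning)
    return float(np.median(cqs))


def ddcq_fold_change(
    wells: Iterable[QpcrWell],
    target: str,
    reference: str,
    condition: str,
    control: str,
    cq_bounds: tuple[float, float] = DEFAULT_CQ_BOUNDS,
) -> float:
    """Fold change ``2^-ddCq`` of ``target`` vs a housekeeping ``reference``.

    Per sample, dCq = median Cq(target) - median Cq(reference) over the
    QC-passing technical replicates; ddCq = dCq(condition) - dCq(control).
    Returns NaN (with a diagnostic warning) when QC empties any needed
    (sample, gene) cell.
    """
    wells = list(wells)
    d_condition = (_median_cq(wells, condition, target, cq_bounds)
                   - _median_cq(wells, condition, reference, cq_bounds))
    d_control = (_median_cq(wells, control, target, cq_bounds)
                 - _median_cq(wells, control, reference, cq_bounds))
    return float(2.0 ** -(d_condition - d_control))


def relative_uptake(positive_signal: Sequence[float],
                    negative_signal: Sequence[float]) -> float:
    """gMFI(positive population) / gMFI(negative population).

    Non-positive fluorescence values are excluded (counted via warning);
    a population left empty raises.
    """
    ratios = []
    for name, signal in (("positive", positive_signal),
                         ("negative", negative_signal)):
        arr = np.asarray(signal, dtype=float)
        kept = arr[arr > 0]
        if kept.size < arr.size:
            warnings.warn(
                f"excluded {arr.size - kept.size} non-positive value(s) "
                f"from the {name} population", RuntimeWarning)
        if kept.size == 0:
            raise ValueError(f"{name} population has no positive signals")
        ratios.append(float(np.exp(np.mean(np.log(kept)))))
    return ratios[0] / ratios[1]
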