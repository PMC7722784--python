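"""Per-peptide fold changes and significance between genotype groups.

Fold change is the ratio of normalized group means (disease over control,
linear scale); significance is a two-sided unpaired t-test. Regulation
labels use the raw-p thresholds standard in this workflow: a peptide is
*up* when FC > 1.25 and p < 1e-2, *down* when FC < 0.8 and p < 1e-2
(strict inequalities; boundary values are unchanged). No multiple-testing
correction is applied to the per-peptide p-values; downstream set-level
statistics (PSEA) carry their own permutation calibration.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from phosflow.qcnorm import QuantMatrix

_TINY_P = float(np.finfo(float).tiny)


@dataclasses.dataclass(frozen=True)
class RegulationThresholds:
    min_up_fc: float = 1.25
    max_down_fc: float = 0.8
    max_p: float = 1e-2


@dataclasses.dataclass
class SiteStat:
    """Fold change, p-value and regulation label for one peptide row."""

    row_key: str
    fold_change: float
    p_value: float
    n_a: int
    n_b: int
    label: str = "unchanged"
    valid: bool = True

    @property
    def log2_fold_change(self) -> float:
        return math.log2(self.fold_change) if self.fold_change > 0 \
            else math.nan


def _t_test(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: zero variance in both groups
        return 1.0 if a[0] == b[0] else _TINY_P
    p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    if not np.isfinite(p):
        return 1.0 if np.isclose(a.mean(), b.mean()) else _TINY_P
    return float(max(p, _TINY_P))


def fold_change_and_test(
    matrix: QuantMatrix,
    contrast: tuple[str, str],
    equal_var: bool = True,
    thresholds: RegulationThresholds = RegulationThresholds(),
) -> list[SiteStat]:
    """Fold change (group_a mean / group_b mean) and two-sided t-test per row.

    Rows are evaluated complete-case within the contrast: NaN channels are
    dropped per row, and rows left with fewer than two finite values in
    either group (or a non-positive group mean) are flagged invalid and
    excluded from classification. ``equal_var=True`` gives the classical
    pooled-variance Student's t; ``False`` switches to Welch.
    """
    group_a, group_b = contrast
    idx_a = matrix.channel_map.channels_for_group(group_a)
    idx_b = matrix.channel_map.channels_for_group(group_b)

    out: list[SiteStat] = []
    for key, row in zip(matrix.row_keys, matrix.values):
        a = row[idx_a]
        b = row[idx_b]
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size < 2 or b.size < 2 or a.mean() <= 0 or b.mean() <= 0:
            out.append(SiteStat(key, math.nan, math.nan, a.size, b.size,
                                label="unchanged", valid=False))
            continue
        fc = float(a.mean() / b.mean())
        p = _t_test(a, b, equal_var)
        stat = SiteStat(key, fc, p, a.size, b.size)
        stat.label = _label(fc, p, thresholds)
        out.append(stat)
    return out


def _label(fc: float, p: float, th: RegulationThresholds) -> str:
    if p < th.max_p and fc > th.min_up_fc:
        return "up"
    if p < th.max_p and fc < th.max_down_fc:
        return "down"
    return "unchanged"


def classify_regulation(
    stats_list: Sequence[SiteStat],
    thresholds: RegulationThresholds = RegulationThresholds(),
) -> dict[str, list[SiteStat]]:
    """Partition stats into disjoint, exhaustive up/down/unchanged sets.

    Invalid rows (insufficient replication) are reported separately under
    ``"invalid"`` and never classified.
    """
    parts: dict[str, list[SiteStat]] = {
        "up": [], "down": [], "unchanged": [], "invalid": []}
    for s in stats_list:
        if not s.valid:
            parts["invalid"].append(s)
        else:
            parts[_label(s.fold_change, s.p_value, thresholds)].append(s)
    return parts


def merge_run_fold_changes(
    runs: Sequence[Mapping[str, float]],
    policy: str = "median",
) -> dict[str, float]:
    """Combine per-peptide fold changes from replicate multiplexed runs.

    Each element of ``runs`` maps peptide row keys to a linear fold
    change from one TMT plex. Peptides are merged across the runs that
    observed them, on the log scale (so a 2x and a 0.5x observation
    average to 1x), by ``policy`` = ``"median"`` (default) or ``"mean"``;
    the merged value is returned on the linear scale.
    """
    if policy not in ("median", "mean"):
        raise ValueError(f"unknown merge policy {policy!r}")
    pooled: dict[str, list[float]] = {}
    for run in runs:
        for key, fc in run.items():
            if fc > 0 and np.isfinite(fc):
                pooled.setdefault(key, []).append(math.log(fc))
    combine = np.median if policy == "median" else np.mean
    return {key: float(math.exp(combine(values)))
            for key, values in pooled.items()}


def stats_to_frame(stats_list: Sequence[SiteStat]):
    """Tabular view (row_key, fc, log2fc, p, label) for serialization."""
    import pandas as pd
    return pd.DataFrame({
        "row_key": [s.row_key for s in stats_list],
        "fc": [s.fold_change for s in stats_list],
        "log2fc": [s.log2_fold_change for s in stats_list],
        "p": [s.p_value for s in stats_list],
        "label": [s.label for s in stats_list],
    })
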