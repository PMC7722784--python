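"""PSM quality filtering, constrained normalization, duplicate grouping.

Filtering applies the standard multiplexed-quantification quality gates —
search-engine ion score, precursor isolation interference, a raw
median-reporter-signal floor, and Percolator FDR — with transgene-derived
peptides exempt from the FDR gate (they are absent from the canonical
proteome, so decoy-based FDR penalizes them artificially).

Normalization follows a constrained-standardization scheme: the peptide x
channel matrix is iteratively rescaled so each row's mean is 1 (removing
peptide loading) while each column's Gaussian-KDE density mode is 1
(removing channel bias without letting a minority of regulated peptides
drag a mean-based column center).

Duplicate PSMs for one (sequence, localized-site) peptide are combined by
a weighted mean with weight ``1 - isolation_interference/100``, so cleaner
scans dominate the final quantification.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np

from phosflow.io import ChannelMap, PSMRecord


class InsufficientDataError(ValueError):
    """Too few values for the requested estimate."""


@dataclasses.dataclass(frozen=True)
class FilterThresholds:
    """Quality gates for PSM retention; defaults are the standard cutoffs.

    A PSM is retained iff ion_score > min_ion_score AND
    isolation_interference < max_isolation_interference AND
    median(TMT) > min_median_tmt AND (percolator_fdr < max_percolator_fdr
    OR the PSM is transgenic). All comparisons are strict.
    """

    min_ion_score: float = 15.0
    max_isolation_interference: float = 30.0
    min_median_tmt: float = 1500.0
    max_percolator_fdr: float = 1e-2


#: order in which failures are attributed in the report
_CRITERIA = ("ion_score", "isolation_interference", "median_tmt",
             "percolator_fdr")


@dataclasses.dataclass
class FilterReport:
    """Per-criterion removal counts, attributed to the first failing gate."""

    n_input: int = 0
    n_retained: int = 0
    removed: dict[str, int] = dataclasses.field(
        default_factory=lambda: {c: 0 for c in _CRITERIA})

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def _passes(value: float | None, threshold: float, *, above: bool) -> bool:
    # missing quality values count as failing the criterion
    if value is None or not np.isfinite(value):
        return False
    return value > threshold if above else value < threshold


def filter_psms(
    psms: Sequence[PSMRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[PSMRecord], FilterReport]:
    """Apply the quality gates; return retained PSMs and a removal report.

    Removal counts are attributed to the first failing criterion in the
    order ion score, isolation interference, median TMT, Percolator FDR;
    the retained set itself is order-independent.
    """
    report = FilterReport(n_input=len(psms))
    retained: list[PSMRecord] = []
    for psm in psms:
        checks = (
            ("ion_score",
             _passes(psm.ion_score, thresholds.min_ion_score, above=True)),
            ("isolation_interference",
             _passes(psm.isolation_interference,
                     thresholds.max_isolation_interference, above=False)),
            ("median_tmt",
             _passes(float(np.median(psm.tmt_intensities)),
                     thresholds.min_median_tmt, above=True)),
            ("percolator_fdr",
             psm.is_transgenic or _passes(
                 psm.percolator_fdr, thresholds.max_percolator_fdr,
                 above=False)),
        )
        failed = next((name for name, ok in checks if not ok), None)
        if failed is None:
            retained.append(psm)
        else:
            report.removed[failed] += 1
    report.n_retained = len(retained)
    return retained, report


def _kde_density(values: np.ndarray, grid: np.ndarray,
                 bandwidth: float) -> np.ndarray:
    """Exact Gaussian KDE evaluated on a grid (direct sum, chunked)."""
    out = np.zeros(grid.size)
    inv = 1.0 / (2.0 * bandwidth * bandwidth)
    step = max(1, int(2_000_000 / max(grid.size, 1)))
    for start in range(0, values.size, step):
        chunk = values[start:start + step, None]
        out += np.exp(-(grid[None, :] - chunk) ** 2 * inv).sum(axis=0)
    return out / (values.size * bandwidth * np.sqrt(2.0 * np.pi))


def _binned_density(values: np.ndarray, lo: float, hi: float,
                    n_bins: int, bandwidth: float) -> np.ndarray:
    """Gaussian KDE on a uniform grid via histogram + FFT convolution.

    Values are snapped to the nearest grid point; with bin width far
    below the bandwidth the density error is negligible, and the final
    mode is re-located on the exact density anyway.
    """
    from scipy.signal import fftconvolve
    width = (hi - lo) / (n_bins - 1)
    idx = np.clip(np.rint((values - lo) / width).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    half = min(n_bins - 1, int(np.ceil(6.0 * bandwidth / width)))
    offsets = np.arange(-half, half + 1) * width
    kernel = np.exp(-0.5 * (offsets / bandwidth) ** 2)
    dens = fftconvolve(counts, kernel, mode="same")
    return dens  # unnormalized; only the argmax is used


def kde_mode(values, bandwidth_rule: str = "scott",
             grid_size: int = 2048) -> float:
    """Mode of a Gaussian kernel density estimate of ``values``.

    Scott's-rule bandwidth; the mode is located on a dense uniform grid
    over [min, max] (evaluated via a binned convolution of the same
    kernel), then refined by one exact local pass with a parabolic polish
    of the density peak. Deterministic for fixed input, and exactly
    scale-equivariant: kde_mode(c * x) == c * kde_mode(x).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 3 or not np.isfinite(values).all():
        raise InsufficientDataError(
            "kde_mode requires >= 3 finite values")
    lo, hi = values.min(), values.max()
    if lo == hi:
        return float(lo)
    if bandwidth_rule != "scott":
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    sd = values.std(ddof=1)
    if sd == 0.0:
        return float(values[0])
    bandwidth = sd * values.size ** (-1.0 / 5.0)

    n_bins = max(grid_size, 2)
    dens = _binned_density(values, lo, hi, n_bins, bandwidth)
    width = (hi - lo) / (n_bins - 1)
    best = lo + int(np.argmax(dens)) * width

    # one exact local refinement pass around the coarse argmax
    fine = np.linspace(best - width, best + width, 65)
    fdens = _kde_density(values, fine, bandwidth)
    j = int(np.argmax(fdens))
    if 0 < j < fine.size - 1:
        # parabolic interpolation through the peak triplet
        y0, y1, y2 = fdens[j - 1], fdens[j], fdens[j + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        return float(fine[j] + shift * (fine[1] - fine[0]))
    return float(fine[j])


@dataclasses.dataclass
class QuantMatrix:
    """Peptides/phosphosites x channels quantification matrix."""

    row_keys: list[str]
    values: np.ndarray
    channel_map: ChannelMap
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != len(self.row_keys):
            raise ValueError("row_keys length does not match values")
        if self.values.shape[1] != self.channel_map.plex_size:
            raise ValueError("channel count does not match channel map")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(list(self.row_keys), self.values.copy(),
                           self.channel_map, self.normalized)


@dataclasses.dataclass
class NormalizationDiagnostics:
    n_iterations: int
    converged: bool
    max_row_deviation: float
    max_col_deviation: float
    row_factors: np.ndarray  # cumulative per-row divisors
    col_factors: np.ndarray  # cumulative per-column divisors


def normalize_constrained(
    matrix: QuantMatrix,
    tol: float = 1e-6,
    max_iter: int = 200,
    mode_tol: float = 1e-4,
    grid_size: int = 512,
) -> tuple[QuantMatrix, NormalizationDiagnostics]:
    """Iterative constrained standardization of a positive matrix.

    Alternately divides each row by its mean and each column by its
    Gaussian-KDE mode until every row mean is within ``tol`` of 1 and
    every column mode is within ``mode_tol`` of 1, or ``max_iter`` sweeps
    are reached. Non-convergence is reported in the diagnostics, not
    raised. The cumulative column divisors estimate the per-channel
    loading biases.
    """
    vals = np.asarray(matrix.values, dtype=float)
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("matrix must be at least 2 x 2")
    if not np.isfinite(vals).all() or (vals <= 0).any():
        raise ValueError("all entries must be positive and finite")

    vals = vals.copy()
    n_rows, n_cols = vals.shape
    row_factors = np.ones(n_rows)
    col_factors = np.ones(n_cols)
    converged = False
    stalled = False
    max_row_dev = np.inf
    max_col_dev = np.inf
    it = 0
    prev = None
    for it in range(1, max_iter + 1):
        row_means = vals.mean(axis=1)
        max_row_dev = float(np.abs(row_means - 1.0).max())
        vals /= row_means[:, None]
        row_factors *= row_means

        modes = np.array([kde_mode(vals[:, j], grid_size=grid_size)
                          for j in range(n_cols)])
        max_col_dev = float(np.abs(modes - 1.0).max())
        vals /= modes[None, :]
        col_factors *= modes

        if max_row_dev < tol and max_col_dev < mode_tol:
            converged = True
            break
        # the row-mean and column-mode constraints can be mutually
        # inconsistent for skewed noise (the iteration enters an exact
        # cycle); stop once the matrix itself stops changing
        if prev is not None and np.abs(vals - prev).max() < tol:
            stalled = True
            break
        prev = vals.copy()

    if converged:
        # finish on a row pass so the exact row-mean contract holds, then
        # verify the column modes did not drift past their tolerance
        row_means = vals.mean(axis=1)
        vals /= row_means[:, None]
        row_factors *= row_means
        max_row_dev = float(np.abs(vals.mean(axis=1) - 1.0).max())
        modes = np.array([kde_mode(vals[:, j], grid_size=grid_size)
                          for j in range(n_cols)])
        max_col_dev = float(np.abs(modes - 1.0).max())
        converged = max_row_dev < tol and max_col_dev < mode_tol
    if not converged:
        reason = "stalled on inconsistent row/column constraints" \
            if stalled else f"reached max_iter={max_iter}"
        warnings.warn(
            f"constrained normalization did not converge ({reason}; "
            f"row dev {max_row_dev:.2e}, mode dev {max_col_dev:.2e})",
            RuntimeWarning,
        )

    out = QuantMatrix(list(matrix.row_keys), vals, matrix.channel_map,
                      normalized=True)
    diag = NormalizationDiagnostics(
        n_iterations=it, converged=converged,
        max_row_deviation=max_row_dev, max_col_deviation=max_col_dev,
        row_factors=row_factors, col_factors=col_factors,
    )
    return out, diag


def group_duplicate_psms(
    psms: Iterable[PSMRecord],
    vectors: np.ndarray | None = None,
    channel_map: ChannelMap | None = None,
) -> QuantMatrix:
    """Collapse duplicate PSMs into one interference-weighted row each.

    PSMs sharing (sequence, localized phosphosite assignment) are grouped;
    per channel the grouped value is ``sum(w_i * v_i) / sum(w_i)`` with
    ``w_i = 1 - isolation_interference_i / 100``. ``vectors`` may supply
    (e.g. normalized) per-PSM intensity vectors aligned with ``psms``;
    by default the records' raw intensities are used. Groups whose weights
    sum to zero (every scan fully interfered) are dropped with a warning.
    """
    psms = list(psms)
    if vectors is None:
        vectors = np.array([p.tmt_intensities for p in psms], dtype=float) \
            if psms else np.empty((0, 0))
    else:
        vectors = np.asarray(vectors, dtype=float)
        if vectors.shape[0] != len(psms):
            raise ValueError("vectors must align with psms")
    if channel_map is None:
        plex = vectors.shape[1] if vectors.size else (
            psms[0].tmt_intensities.size if psms else 0)
        channel_map = ChannelMap.trivial(plex)

    groups: dict[str, list[int]] = {}
    for i, psm in enumerate(psms):
        groups.setdefault(psm.row_key, []).append(i)

    row_keys: list[str] = []
    rows: list[np.ndarray] = []
    for key in sorted(groups):
        idx = groups[key]
        w = np.array([1.0 - psms[i].isolation_interference / 100.0
                      for i in idx])
        total = w.sum()
        if total <= 0:
            warnings.warn(
                f"dropping group {key!r}: all PSMs fully interfered",
                RuntimeWarning)
            continue
        rows.append((w[:, None] * vectors[idx]).sum(axis=0) / total)
        row_keys.append(key)
    values = np.array(rows) if rows else np.empty((0, channel_map.plex_size))
    return QuantMatrix(row_keys, values, channel_map)
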