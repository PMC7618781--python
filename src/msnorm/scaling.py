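"""Column-wise scaling and element-wise transformation of spectrum matrices.

Scaling makes features (m/z bins) comparable in magnitude across the data
set; transformation reshapes the intensity distribution element-wise.
Scaling statistics are fit separately from their application so that, in a
train/test protocol, test rows never contribute to the statistics.

Note on conventions: the scaling operators follow the printed formulas of
the source methods verbatim, which divide by the per-column mean (or
median) rather than subtracting it.  Pass ``conventional=True`` for the
textbook subtractive variants (I - mean, (I - mean)/sd, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import SpectrumMatrix

__all__ = [
    "SCALING_METHODS",
    "TRANSFORM_METHODS",
    "ColumnStats",
    "fit_column_stats",
    "scale_columns",
    "transform_values",
    "log_offset",
]

SCALING_METHODS = ("none", "meancentre", "mediancentre", "auto", "pareto", "range")
TRANSFORM_METHODS = ("none", "log", "exp", "square", "sqrt", "cube", "cbrt")


@dataclass(frozen=True)
class ColumnStats:
    """Per-column summary statistics of a reference (training) matrix.

    Standard deviations use the sample (n-1) convention.
    """

    bin_mz: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    std: np.ndarray
    min: np.ndarray
    max: np.ndarray

    @property
    def range(self) -> np.ndarray:
        return self.max - self.min


def fit_column_stats(matrix: SpectrumMatrix) -> ColumnStats:
    """Compute per-column mean, median, sample std, min and max."""
    if matrix.n_measurements < 2:
        raise ValueError("column statistics need >= 2 spectra")
    x = matrix.intensities
    return ColumnStats(
        bin_mz=matrix.bin_mz.copy(),
        mean=x.mean(axis=0),
        median=np.median(x, axis=0),
        std=x.std(axis=0, ddof=1),
        min=x.min(axis=0),
        max=x.max(axis=0),
    )


def _check_denominator(denom: np.ndarray, stats: ColumnStats, method: str) -> None:
    bad = np.flatnonzero(denom == 0.0)
    if bad.size:
        mz = stats.bin_mz[bad[0]]
        raise ValueError(
            f"zero denominator for {method!r} scaling at m/z column {mz} "
            f"({bad.size} column(s) affected)"
        )


def scale_columns(
    matrix: SpectrumMatrix,
    stats: ColumnStats,
    method: str,
    conventional: bool = False,
) -> SpectrumMatrix:
    """Scale each column by statistics of a reference matrix.

    Division-based (default, matching the printed formulas):

    meancentre:   N = I / mean_m
    mediancentre: N = I / median_m
    auto:         N = (I / mean_m) / sd_m
    pareto:       N = (I / mean_m) / sqrt(sd_m)
    range:        N = (I / mean_m) / (max_m - min_m)

    With ``conventional=True`` the mean/median are subtracted instead of
    divided (auto/pareto/range then scale the centred values), the usual
    metabolomics convention.
    """
    if method == "none":
        return matrix.with_intensities(matrix.intensities.copy())
    if method not in SCALING_METHODS:
        raise ValueError(f"unknown scaling method {method!r}")
    if not np.array_equal(stats.bin_mz, matrix.bin_mz):
        raise ValueError("column stats are not aligned to the matrix bins")

    x = matrix.intensities
    if conventional:
        centred = x - (stats.median if method == "mediancentre" else stats.mean)
        if method in ("meancentre", "mediancentre"):
            return matrix.with_intensities(centred)
        denom = {"auto": stats.std, "pareto": np.sqrt(stats.std),
                 "range": stats.range}[method]
        _check_denominator(denom, stats, method)
        return matrix.with_intensities(centred / denom)

    if method == "mediancentre":
        _check_denominator(stats.median, stats, method)
        return matrix.with_intensities(x / stats.median)
    _check_denominator(stats.mean, stats, method)
    centred = x / stats.mean
    if method == "meancentre":
        return matrix.with_intensities(centred)
    denom = {"auto": stats.std, "pareto": np.sqrt(stats.std),
             "range": stats.range}[method]
    _check_denominator(denom, stats, method)
    return matrix.with_intensities(centred / denom)


def log_offset(values: np.ndarray) -> float:
    """Pseudo-offset for the log transform of data containing zeros.

    One tenth of the smallest strictly positive value; 0.0 when the data
    are already strictly positive (no offset needed).
    """
    if np.all(values > 0):
        return 0.0
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("log transform undefined: no positive values")
    return float(positive.min()) * 0.1


def transform_values(
    matrix: SpectrumMatrix, method: str, offset: float | None = None
) -> SpectrumMatrix:
    """Element-wise transformation: log, exp, square, sqrt, cube or cbrt.

    The natural log is used; for data containing zeros a pseudo-offset
    (``log_offset``, a tenth of the smallest positive value) is added
    first.  Supply ``offset`` explicitly when transforming a test
    partition with the training partition's offset.  The cube root of a
    negative value is the real root, so transforms compose after the
    subtractive scaling variants.
    """
    if method == "none":
        return matrix.with_intensities(matrix.intensities.copy())
    if method not in TRANSFORM_METHODS:
        raise ValueError(f"unknown transformation {method!r}")
    x = matrix.intensities
    if method == "log":
        eps = log_offset(x) if offset is None else offset
        shifted = x + eps
        if np.any(shifted <= 0):
            raise ValueError(
                "log transform domain violation: non-positive values remain "
                f"after pseudo-offset {eps:g}"
            )
        return matrix.with_intensities(np.log(shifted))
    if method == "exp":
        return matrix.with_intensities(np.exp(x))
    if method == "square":
        return matrix.with_intensities(x * x)
    if method == "cube":
        return matrix.with_intensities(x ** 3)
    if method == "sqrt":
        if np.any(x < 0):
            raise ValueError("sqrt transform domain violation: negative values")
        return matrix.with_intensities(np.sqrt(x))
    # cbrt: numpy's real-root cube root handles negatives
    return matrix.with_intensities(np.cbrt(x))
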