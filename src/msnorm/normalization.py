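"""Per-spectrum and per-set normalisation operators.

Normalisation here means row-wise rescaling of a spectrum so that spectra
become comparable in total signal, mitigating measurement-to-measurement
variation in the amount of sample loaded onto the probe.  Four classical
row-wise operators (AUC, mean, median, vector), two set-level operators
(quantile, minimised-vector) and three intensity-histogram variants are
provided.  The histogram variants rescale each spectrum via a histogram of
its own intensity values, built over five unequal segments whose boundaries
sit at four intensity percentiles -- so the normalisation constant is
driven by the many reproducible mid-intensity peaks rather than by a few
wildly varying dominant ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .matrix import Spectrum, SpectrumMatrix

__all__ = [
    "ROWWISE_METHODS",
    "SET_METHODS",
    "HISTOGRAM_METHODS",
    "NORMALISATION_METHODS",
    "HistogramConfig",
    "IntensityHistogram",
    "normalize_rowwise",
    "normalize_matrix_rowwise",
    "normalize_minimised_vector",
    "normalize_quantile",
    "quantile_reference",
    "build_intensity_histogram",
    "normalize_histogram",
]

ROWWISE_METHODS = ("auc", "mean", "median", "vector")
SET_METHODS = ("quantile", "minvector")
HISTOGRAM_METHODS = ("histbin", "histintensity", "histfunction")
NORMALISATION_METHODS = ("none",) + ROWWISE_METHODS + SET_METHODS + HISTOGRAM_METHODS

_HIST_VARIANT = {"histbin": "bin", "histintensity": "intensity",
                 "histfunction": "function"}


# ---------------------------------------------------------------------------
# row-wise operators


def _rowwise_factor(row: np.ndarray, method: str) -> float:
    if not np.any(row > 0):
        raise ValueError("cannot normalise an all-zero spectrum")
    if method == "auc":
        return float(row.sum())
    if method == "mean":
        return float(row.mean())
    if method == "median":
        med = float(np.median(row))
        if med == 0.0:
            raise ValueError("median normalisation undefined: spectrum median is 0")
        return med
    if method == "vector":
        return float(np.sqrt(np.sum(row * row)))
    raise ValueError(f"unknown row-wise normalisation {method!r}")


def normalize_rowwise(spectrum: Spectrum, method: str) -> Spectrum:
    """Normalise one spectrum by its sum, mean, median or Euclidean norm.

    auc:    N = I / sum(I)
    mean:   N = I / mean(I)
    median: N = I / median(I)
    vector: N = I / sqrt(sum(I^2))
    """
    factor = _rowwise_factor(spectrum.intensities, method)
    return Spectrum(bin_mz=spectrum.bin_mz, intensities=spectrum.intensities / factor)


def normalize_matrix_rowwise(matrix: SpectrumMatrix, method: str) -> SpectrumMatrix:
    """Apply a row-wise normalisation to every row of a matrix."""
    out = np.empty_like(matrix.intensities)
    for i in range(matrix.n_measurements):
        out[i] = matrix.intensities[i] / _rowwise_factor(matrix.intensities[i], method)
    return matrix.with_intensities(out)


# ---------------------------------------------------------------------------
# set-level operators


def normalize_minimised_vector(
    matrix: SpectrumMatrix, centroid: np.ndarray | None = None
) -> SpectrumMatrix:
    """Rescale each spectrum towards the centroid (mean) spectrum.

    Each row I_S is multiplied by the k minimising ||centroid - k I_S||^2,
    which has the closed form k = (centroid . I_S) / (I_S . I_S).  The
    centroid defaults to the column means of ``matrix`` itself; pass a
    training-set centroid to avoid leakage when normalising test rows.
    """
    if centroid is None:
        if matrix.n_measurements < 2:
            raise ValueError("minimised-vector normalisation needs >= 2 spectra")
        centroid = matrix.intensities.mean(axis=0)
    centroid = np.asarray(centroid, dtype=np.float64)
    if centroid.size != matrix.n_bins:
        raise ValueError("centroid length does not match the matrix bins")
    out = np.empty_like(matrix.intensities)
    for i in range(matrix.n_measurements):
        row = matrix.intensities[i]
        denom = float(row @ row)
        if denom == 0.0:
            raise ValueError(f"all-zero spectrum at row {i}")
        out[i] = (float(centroid @ row) / denom) * row
    return matrix.with_intensities(out)


def quantile_reference(matrix: SpectrumMatrix) -> np.ndarray:
    """Rank-wise mean of the sorted rows: the shared target distribution."""
    if matrix.n_measurements < 2:
        raise ValueError("quantile normalisation needs >= 2 spectra")
    return np.sort(matrix.intensities, axis=1).mean(axis=0)


def normalize_quantile(
    matrix: SpectrumMatrix, reference: np.ndarray | None = None
) -> SpectrumMatrix:
    """Force every spectrum to share one intensity distribution.

    Sort each row, average across rows at each rank (or take a supplied
    training-set reference), substitute the averages back at each row's
    sorted positions, then restore the original peak order.  Ties are
    broken by stable sort order, so ranks are positional.
    """
    if reference is None:
        reference = quantile_reference(matrix)
    reference = np.asarray(reference, dtype=np.float64)
    if reference.size != matrix.n_bins:
        raise ValueError("quantile reference length does not match the matrix bins")
    out = np.empty_like(matrix.intensities)
    for i in range(matrix.n_measurements):
        order = np.argsort(matrix.intensities[i], kind="stable")
        out[i, order] = reference
    return matrix.with_intensities(out)


# ---------------------------------------------------------------------------
# intensity-histogram normalisation


@dataclass(frozen=True)
class HistogramConfig:
    """Five-segment intensity-histogram layout.

    P1..P4 are percentile positions of the spectrum's own intensity values,
    splitting it into five segments: a single bin [0, q(P1)) of near-noise
    intensities, three runs of n1/n2/n3 equal-width bins spanning
    [q(P1),q(P2)), [q(P2),q(P3)), [q(P3),q(P4)), and a final single bin
    [q(P4), max] holding the most intense (and least stable) peaks.
    Defaults: P = (20, 40, 60, 80), n = (30, 30, 30).
    """

    P1: float = 20.0
    P2: float = 40.0
    P3: float = 60.0
    P4: float = 80.0
    n1: int = 30
    n2: int = 30
    n3: int = 30

    def __post_init__(self) -> None:
        ps = (self.P1, self.P2, self.P3, self.P4)
        if not all(np.isfinite(ps)):
            raise ValueError("percentiles must be finite")
        if not (0.0 < self.P1 < self.P2 < self.P3 < self.P4 < 100.0):
            raise ValueError(
                f"percentiles must satisfy 0 < P1 < P2 < P3 < P4 < 100, got {ps}"
            )
        for name in ("n1", "n2", "n3"):
            n = getattr(self, name)
            if not isinstance(n, (int, np.integer)) or n < 1:
                raise ValueError(f"{name} must be a positive integer, got {n!r}")

    @property
    def n_hist_bins(self) -> int:
        # two single-bin end segments plus the three flexible segments
        return 2 + self.n1 + self.n2 + self.n3

    def to_json(self) -> str:
        return json.dumps({"P": [self.P1, self.P2, self.P3, self.P4],
                           "n": [self.n1, self.n2, self.n3]})

    @classmethod
    def from_json(cls, text: str) -> "HistogramConfig":
        obj = json.loads(text)
        p, n = obj["P"], obj["n"]
        return cls(P1=p[0], P2=p[1], P3=p[2], P4=p[3],
                   n1=int(n[0]), n2=int(n[1]), n3=int(n[2]))


@dataclass(frozen=True)
class IntensityHistogram:
    """Histogram of one spectrum's intensity values.

    ``edges`` has one more entry than ``counts``; ``bin_of`` maps each m/z
    position of the source spectrum to its 0-based histogram bin.  Bins are
    left-closed right-open except the final bin, which is right-closed.
    """

    edges: np.ndarray
    counts: np.ndarray
    bin_of: np.ndarray


def build_intensity_histogram(
    spectrum: Spectrum | np.ndarray, config: HistogramConfig
) -> IntensityHistogram:
    """Build the five-segment intensity histogram of a single spectrum."""
    values = (spectrum.intensities if isinstance(spectrum, Spectrum)
              else np.asarray(spectrum, dtype=np.float64))
    if values.size == 0:
        raise ValueError("empty spectrum")
    if np.any(values < 0):
        raise ValueError("histogram normalisation expects non-negative raw intensities")
    q1, q2, q3, q4 = np.percentile(
        values, [config.P1, config.P2, config.P3, config.P4], method="linear"
    )
    if q1 == q4:
        raise ValueError(
            "degenerate intensity distribution: "
            f"percentile {config.P1} equals percentile {config.P4} ({q1:g})"
        )
    top = float(values.max())
    edges = np.concatenate([
        [0.0],
        np.linspace(q1, q2, config.n1 + 1),
        np.linspace(q2, q3, config.n2 + 1)[1:],
        np.linspace(q3, q4, config.n3 + 1)[1:],
        [max(top, q4)],
    ])
    n_bins = config.n_hist_bins
    # left-closed right-open assignment; anything >= q(P4) (incl. the max)
    # lands in the final right-closed bin
    idx = np.searchsorted(edges, values, side="right") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return IntensityHistogram(edges=edges, counts=counts, bin_of=idx)


def normalize_histogram(
    matrix: SpectrumMatrix, variant: str, config: HistogramConfig
) -> SpectrumMatrix:
    """Histogram-based normalisation of every spectrum in a matrix.

    variant="bin"       replace each intensity by its histogram bin index
    variant="intensity" replace each spectrum by its histogram counts
                        (the feature axis becomes histogram-bin indices)
    variant="function"  replace each intensity I by bin[I]/I (0 where I=0)

    Histograms are built per spectrum, so no cross-spectrum statistics are
    involved and train/test leakage cannot arise.
    """
    variant = _HIST_VARIANT.get(variant, variant)
    if variant not in ("bin", "intensity", "function"):
        raise ValueError(f"unknown histogram variant {variant!r}")
    if variant == "intensity":
        out = np.empty((matrix.n_measurements, config.n_hist_bins))
        for i in range(matrix.n_measurements):
            out[i] = build_intensity_histogram(matrix.intensities[i], config).counts
        return matrix.with_intensities(
            out, bin_mz=np.arange(config.n_hist_bins), feature_kind="histbin"
        )
    out = np.empty_like(matrix.intensities)
    for i in range(matrix.n_measurements):
        row = matrix.intensities[i]
        hist = build_intensity_histogram(row, config)
        if variant == "bin":
            out[i] = hist.bin_of
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(row > 0, hist.bin_of / np.where(row > 0, row, 1.0), 0.0)
            out[i] = ratio
    return matrix.with_intensities(out)
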