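"""Method-combination enumeration and ordered application.

A preprocessing method combination is an ordered triple: (i) normalisation,
(ii) scaling, (iii) transformation — applied in that fixed order so that
between-repeat variation is reduced first, then between-sample variation
within features, before the intensity distribution is reshaped.  With 10
normalisations, 6 scalings and 7 transformations the full grid holds 420
combinations, including the blank (none, none, none).

Statistics that involve the whole spectrum set (quantile rank-means,
minimised-vector centroid, column scaling statistics, log pseudo-offset)
are always derived from ``fit_matrix`` — the training partition in an ML
protocol — and merely applied to the target matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import clustering_ratio
from .matrix import SpectrumMatrix
from .normalization import (
    HISTOGRAM_METHODS,
    NORMALISATION_METHODS,
    HistogramConfig,
    normalize_histogram,
    normalize_matrix_rowwise,
    normalize_minimised_vector,
    normalize_quantile,
    quantile_reference,
    ROWWISE_METHODS,
)
from .scaling import (
    SCALING_METHODS,
    TRANSFORM_METHODS,
    fit_column_stats,
    log_offset,
    scale_columns,
    transform_values,
)

__all__ = [
    "MethodCombo",
    "GridRecord",
    "GridResult",
    "PipelineError",
    "enumerate_combinations",
    "apply_combo",
    "run_grid",
]


class PipelineError(ValueError):
    """A preprocessing stage failed; carries the stage name and combo."""

    def __init__(self, stage: str, combo: "MethodCombo", cause: Exception):
        self.stage = stage
        self.combo = combo
        super().__init__(f"{stage} stage failed for combo {combo.name}: {cause}")


@dataclass(frozen=True)
class MethodCombo:
    """An ordered (normalisation, scaling, transformation) triple."""

    normalisation: str
    scaling: str
    transformation: str
    histogram_config: HistogramConfig | None = None

    def __post_init__(self) -> None:
        if self.normalisation not in NORMALISATION_METHODS:
            raise ValueError(f"unknown normalisation {self.normalisation!r}")
        if self.scaling not in SCALING_METHODS:
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if self.transformation not in TRANSFORM_METHODS:
            raise ValueError(f"unknown transformation {self.transformation!r}")
        needs_config = self.normalisation in HISTOGRAM_METHODS
        if needs_config and self.histogram_config is None:
            raise ValueError(
                f"normalisation {self.normalisation!r} requires a histogram_config"
            )
        if not needs_config and self.histogram_config is not None:
            raise ValueError(
                f"histogram_config given but normalisation is {self.normalisation!r}"
            )

    @property
    def name(self) -> str:
        return f"{self.normalisation},{self.scaling},{self.transformation}"

    @classmethod
    def parse(
        cls, text: str, histogram_config: HistogramConfig | None = None
    ) -> "MethodCombo":
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != 3:
            raise ValueError(
                f"combo must be 'normalisation,scaling,transformation', got {text!r}"
            )
        if parts[0] in HISTOGRAM_METHODS and histogram_config is None:
            histogram_config = HistogramConfig()
        if parts[0] not in HISTOGRAM_METHODS:
            histogram_config = None
        return cls(parts[0], parts[1], parts[2], histogram_config)


def enumerate_combinations(
    histogram_config: HistogramConfig | None = None,
) -> list[MethodCombo]:
    """All 420 method combinations in deterministic normalisation-major order.

    Histogram-based combinations carry ``histogram_config`` (the default
    five-segment layout if none is given).
    """
    if histogram_config is None:
        histogram_config = HistogramConfig()
    combos = []
    for norm in NORMALISATION_METHODS:
        cfg = histogram_config if norm in HISTOGRAM_METHODS else None
        for scal in SCALING_METHODS:
            for trans in TRANSFORM_METHODS:
                combos.append(MethodCombo(norm, scal, trans, cfg))
    return combos


def _normalise_stage(
    matrix: SpectrumMatrix, combo: MethodCombo, fit_matrix: SpectrumMatrix
) -> SpectrumMatrix:
    norm = combo.normalisation
    if norm == "none":
        return matrix.with_intensities(matrix.intensities.copy())
    if norm in ROWWISE_METHODS:
        return normalize_matrix_rowwise(matrix, norm)
    if norm == "quantile":
        return normalize_quantile(matrix, reference=quantile_reference(fit_matrix))
    if norm == "minvector":
        centroid = fit_matrix.intensities.mean(axis=0)
        return normalize_minimised_vector(matrix, centroid=centroid)
    return normalize_histogram(matrix, norm, combo.histogram_config)


def apply_combo(
    matrix: SpectrumMatrix,
    combo: MethodCombo,
    fit_matrix: SpectrumMatrix | None = None,
) -> SpectrumMatrix:
    """Apply normalisation, then scaling, then transformation.

    ``fit_matrix`` supplies every set-level statistic (quantile reference,
    centroid, column stats, log offset) and defaults to ``matrix`` itself;
    in a train/test protocol pass the training rows so that no test value
    enters a fitted statistic.
    """
    own_fit = fit_matrix is None
    if own_fit:
        fit_matrix = matrix

    try:
        normalised = _normalise_stage(matrix, combo, fit_matrix)
        fit_norm = normalised if own_fit else _normalise_stage(
            fit_matrix, combo, fit_matrix
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("normalisation", combo, exc) from exc

    try:
        if combo.scaling == "none":
            scaled, fit_scaled = normalised, fit_norm
        else:
            stats = fit_column_stats(fit_norm)
            scaled = scale_columns(normalised, stats, combo.scaling)
            fit_scaled = (scaled if own_fit
                          else scale_columns(fit_norm, stats, combo.scaling))
    except Exception as exc:
        raise PipelineError("scaling", combo, exc) from exc

    try:
        offset = (log_offset(fit_scaled.intensities)
                  if combo.transformation == "log" else None)
        return transform_values(scaled, combo.transformation, offset=offset)
    except Exception as exc:
        raise PipelineError("transformation", combo, exc) from exc


@dataclass(frozen=True)
class GridRecord:
    combo: MethodCombo
    C_R: float
    status: str  # "ok" or "failed: <reason>"


@dataclass
class GridResult:
    """One record per enumerated combination; failures kept, never dropped."""

    records: list[GridRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "normalisation": [r.combo.normalisation for r in self.records],
                "scaling": [r.combo.scaling for r in self.records],
                "transformation": [r.combo.transformation for r in self.records],
                "C_R": [r.C_R for r in self.records],
                "status": [r.status for r in self.records],
            }
        )

    def to_pivot(self) -> pd.DataFrame:
        """Colour-map-style table: rows normalisation x scaling, cols transforms."""
        df = self.to_dataframe()
        return df.pivot_table(
            index=["normalisation", "scaling"],
            columns="transformation",
            values="C_R",
            sort=False,
            dropna=False,
        )

    def best(self) -> GridRecord:
        ok = [r for r in self.records if r.status == "ok" and np.isfinite(r.C_R)]
        if not ok:
            raise ValueError("no successful finite-C_R combination in the grid")
        return max(ok, key=lambda r: r.C_R)


def run_grid(
    matrix: SpectrumMatrix,
    histogram_config: HistogramConfig | None = None,
) -> GridResult:
    """Score every method combination on a labelled matrix by C_R.

    Combinations that fail (e.g. a degenerate histogram or a zero scaling
    denominator) are recorded with the failure reason rather than aborting
    the grid.  Deterministic: no randomness is involved.
    """
    matrix.require_binary_labels()
    result = GridResult()
    for combo in enumerate_combinations(histogram_config):
        try:
            # overflow (e.g. exp of large intensities) surfaces as a
            # non-finite C_R below rather than as warning spam
            with np.errstate(over="ignore", invalid="ignore"):
                processed = apply_combo(matrix, combo)
                ratio = clustering_ratio(processed).C_R
            if np.isnan(ratio):
                result.records.append(
                    GridRecord(combo, float("nan"),
                               "failed: non-finite C_R (overflow or degenerate data)")
                )
            else:
                result.records.append(GridRecord(combo, ratio, "ok"))
        except (PipelineError, ValueError) as exc:
            result.records.append(GridRecord(combo, float("nan"), f"failed: {exc}"))
    return result
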