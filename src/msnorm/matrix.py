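"""Core spectrum containers and raw-data plumbing.

Ambient-ionisation (ASAP) mass spectra arrive as centroided peak lists or
as time-resolved acquisitions; downstream preprocessing operates on a
rectangular measurements x unit-mass-bins intensity matrix annotated with
measurement, patient and (optionally) binary class labels.  This module
provides those containers plus unit-mass binning, background subtraction,
replicate averaging and a delimited-text round-trip format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumMatrix",
    "bin_to_unit_mass",
    "subtract_background",
    "average_replicates",
    "read_matrix",
    "write_matrix",
]

#: default unit-mass axis: 10-999 Th inclusive, 990 features
DEFAULT_MZ_MIN = 10
DEFAULT_MZ_MAX = 999

RESERVED_COLUMNS = ("measurement_id", "patient_id", "class_label")


@dataclass(frozen=True)
class Spectrum:
    """A single unit-mass-binned mass spectrum.

    Parameters
    ----------
    bin_mz
        Strictly increasing integer m/z bin centres (Th).
    intensities
        Intensity per bin, aligned to ``bin_mz``.
    """

    bin_mz: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        bin_mz = np.asarray(self.bin_mz, dtype=np.int64)
        intens = np.asarray(self.intensities, dtype=np.float64)
        if bin_mz.ndim != 1 or intens.ndim != 1:
            raise ValueError("bin_mz and intensities must be 1-D")
        if bin_mz.size != intens.size:
            raise ValueError(
                f"bin_mz has {bin_mz.size} entries but intensities has {intens.size}"
            )
        if bin_mz.size and np.any(np.diff(bin_mz) <= 0):
            raise ValueError("bin_mz must be strictly increasing")
        if not np.all(np.isfinite(intens)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "bin_mz", bin_mz)
        object.__setattr__(self, "intensities", intens)

    def __len__(self) -> int:
        return self.bin_mz.size


@dataclass
class SpectrumMatrix:
    """A set of spectra sharing one feature axis, with row annotations.

    ``bin_mz`` is the shared integer feature axis -- unit-mass m/z values
    for raw data, or histogram-bin indices after histogram-intensity
    normalisation (tracked via ``feature_kind``).
    """

    intensities: np.ndarray
    bin_mz: np.ndarray
    measurement_id: np.ndarray
    patient_id: np.ndarray
    class_label: np.ndarray | None = None
    feature_kind: str = "mz"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.bin_mz = np.asarray(self.bin_mz, dtype=np.int64)
        self.measurement_id = np.asarray(self.measurement_id, dtype=object)
        self.patient_id = np.asarray(self.patient_id, dtype=object)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        n, m = self.intensities.shape
        if self.bin_mz.size != m:
            raise ValueError(f"bin_mz length {self.bin_mz.size} != {m} columns")
        if self.measurement_id.size != n or self.patient_id.size != n:
            raise ValueError("row annotations must match the number of rows")
        if len(set(self.measurement_id.tolist())) != n:
            raise ValueError("measurement_id values must be unique")
        if self.class_label is not None:
            self.class_label = np.asarray(self.class_label, dtype=object)
            if self.class_label.size != n:
                raise ValueError("class_label must match the number of rows")

    @property
    def n_measurements(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_bins(self) -> int:
        return self.intensities.shape[1]

    def require_binary_labels(self) -> np.ndarray:
        """Return class labels, validating that exactly two classes exist."""
        if self.class_label is None:
            raise ValueError("matrix carries no class_label")
        labels = self.class_label
        uniq = sorted({str(v) for v in labels.tolist()})
        if len(uniq) != 2:
            raise ValueError(
                f"evaluation needs exactly two classes, found {len(uniq)}: {uniq}"
            )
        return labels

    def with_intensities(
        self, intensities: np.ndarray, bin_mz: np.ndarray | None = None,
        feature_kind: str | None = None,
    ) -> "SpectrumMatrix":
        """Copy of this matrix with new intensity values (same annotations)."""
        return replace(
            self,
            intensities=np.asarray(intensities, dtype=np.float64),
            bin_mz=self.bin_mz if bin_mz is None else np.asarray(bin_mz),
            feature_kind=self.feature_kind if feature_kind is None else feature_kind,
        )

    def rows(self, index: np.ndarray) -> "SpectrumMatrix":
        """Row-subset of the matrix (boolean or integer index)."""
        return SpectrumMatrix(
            intensities=self.intensities[index],
            bin_mz=self.bin_mz,
            measurement_id=self.measurement_id[index],
            patient_id=self.patient_id[index],
            class_label=None if self.class_label is None else self.class_label[index],
            feature_kind=self.feature_kind,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=[str(b) for b in self.bin_mz])
        df.insert(0, "class_label",
                  "" if self.class_label is None else self.class_label)
        df.insert(0, "patient_id", self.patient_id)
        df.insert(0, "measurement_id", self.measurement_id)
        return df


def bin_to_unit_mass(
    peaks: Sequence[tuple[float, float]], mz_min: int, mz_max: int
) -> Spectrum:
    """Bin a centroided peak list to a unit-mass axis.

    Each peak's intensity is added to the nearest-integer bin
    (half rounds away from zero); peaks outside ``[mz_min, mz_max]`` are
    dropped, and every integer bin in the range is present (zero-filled).
    """
    if mz_min >= mz_max:
        raise ValueError(f"mz_min {mz_min} must be < mz_max {mz_max}")
    peak_arr = np.asarray(peaks, dtype=np.float64)
    if peak_arr.size == 0:
        raise ValueError("empty peak list")
    if peak_arr.ndim != 2 or peak_arr.shape[1] != 2:
        raise ValueError("peaks must be (m/z, intensity) pairs")
    mz, intensity = peak_arr[:, 0], peak_arr[:, 1]
    if not np.all(np.isfinite(peak_arr)):
        raise ValueError("non-finite m/z or intensity in peak list")
    if np.any(mz <= 0):
        raise ValueError("m/z values must be strictly positive")
    if np.any(intensity < 0):
        raise ValueError("intensities must be non-negative")

    # round half away from zero; m/z is strictly positive so floor(x + 0.5)
    target = np.floor(mz + 0.5).astype(np.int64)
    in_range = (target >= mz_min) & (target <= mz_max)
    axis = np.arange(mz_min, mz_max + 1, dtype=np.int64)
    binned = np.zeros(axis.size, dtype=np.float64)
    np.add.at(binned, target[in_range] - mz_min, intensity[in_range])
    return Spectrum(bin_mz=axis, intensities=binned)


def subtract_background(sample: Spectrum, background: Spectrum) -> Spectrum:
    """Per-bin background subtraction, clamped below at zero."""
    if not np.array_equal(sample.bin_mz, background.bin_mz):
        raise ValueError("sample and background have mismatched m/z axes")
    diff = np.maximum(sample.intensities - background.intensities, 0.0)
    return Spectrum(bin_mz=sample.bin_mz, intensities=diff)


def average_replicates(matrix: SpectrumMatrix, by: str = "patient_id") -> SpectrumMatrix:
    """Average replicate rows sharing a grouping key into one spectrum each.

    The class label must be constant within each group and is inherited by
    the averaged row; the group key becomes the new measurement_id.
    """
    if by == "patient_id":
        keys = matrix.patient_id
    elif by == "measurement_id":
        keys = matrix.measurement_id
    else:
        raise ValueError(f"unknown grouping key {by!r}")

    order: list[object] = []
    groups: dict[object, list[int]] = {}
    for i, k in enumerate(keys.tolist()):
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(i)

    rows, pids, labels = [], [], []
    for key in order:
        idx = groups[key]
        rows.append(matrix.intensities[idx].mean(axis=0))
        pid = {matrix.patient_id[i] for i in idx}
        if len(pid) != 1:
            raise ValueError(f"group {key!r} spans multiple patients: {sorted(map(str, pid))}")
        pids.append(pid.pop())
        if matrix.class_label is not None:
            lab = {matrix.class_label[i] for i in idx}
            if len(lab) != 1:
                raise ValueError(
                    f"conflicting class labels within group {key!r}: {sorted(map(str, lab))}"
                )
            labels.append(lab.pop())

    return SpectrumMatrix(
        intensities=np.vstack(rows),
        bin_mz=matrix.bin_mz,
        measurement_id=np.array(order, dtype=object),
        patient_id=np.array(pids, dtype=object),
        class_label=np.array(labels, dtype=object) if labels else None,
        feature_kind=matrix.feature_kind,
    )


def read_matrix(path) -> SpectrumMatrix:
    """Read a spectrum matrix from delimited text.

    Expected header: ``measurement_id,patient_id,class_label,<int m/z...>``.
    An all-empty class_label column yields an unlabelled matrix.
    """
    df = pd.read_csv(
        path, dtype={c: str for c in RESERVED_COLUMNS}, float_precision="round_trip"
    )
    for col in ("measurement_id", "patient_id"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if "class_label" not in df.columns:
        df["class_label"] = ""
    if df["measurement_id"].duplicated().any():
        dup = df["measurement_id"][df["measurement_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate measurement_id {dup!r}")

    bin_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    try:
        bin_mz = np.array([int(c) for c in bin_cols], dtype=np.int64)
    except ValueError as exc:
        raise ValueError(f"non-integer m/z column in header: {exc}") from exc
    try:
        values = df[bin_cols].to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric intensity cell: {exc}") from exc

    class_label = df["class_label"].fillna("").to_numpy(dtype=object)
    if all(str(v) == "" for v in class_label):
        class_label = None
    return SpectrumMatrix(
        intensities=values,
        bin_mz=bin_mz,
        measurement_id=df["measurement_id"].to_numpy(dtype=object),
        patient_id=df["patient_id"].to_numpy(dtype=object),
        class_label=class_label,
    )


def write_matrix(matrix: SpectrumMatrix, path) -> None:
    """Write a spectrum matrix as UTF-8 CSV (full float precision)."""
    df = matrix.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")
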