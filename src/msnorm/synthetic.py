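"""Synthetic two-class plasma-like cohorts for testing the toolkit.

The real cohorts behind this kind of study are available only on request,
so the generator emulates the variation structure that motivates
normalisation in ambient-ionisation MS of plasma:

* a shared base intensity profile across unit-mass bins, log-normal with a
  heavy right tail (many weak peaks, a few strong ones);
* a per-measurement multiplicative *loading factor* (log-normal), the
  dominant technical artefact of manual probe loading;
* per-peak, per-patient biological variability (log-normal with a given
  coefficient of variation), so replicates of one patient stay correlated;
* a few dominant, highly unstable peaks whose run-to-run swings distort
  total-signal normalisation of the stable peaks;
* additive baseline noise, truncated at zero;
* optional multiplicative batch factors;
* a two-class effect: class "B" multiplies a subset of signal bins by a
  fold-change.

Log-normal (asymmetric) noise everywhere reflects that intensity errors in
this kind of data are not symmetric or normally distributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import SpectrumMatrix

__all__ = ["SyntheticConfig", "CohortDetails", "generate_cohort", "generate_fig1_pair"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort layout and noise levels.

    Defaults emulate a 20-patients-per-class study with ten replicate
    spectra per patient and 990 unit-mass features.
    """

    n_patients_per_class: int = 20
    replicates_per_patient: int = 10
    n_bins: int = 990
    n_signal_bins: int = 50
    effect_size: float = 2.0
    loading_sigma: float = 0.5
    peak_cv: float = 0.2
    n_dominant_unstable: int = 5
    baseline_noise_sd: float = 1.0
    batch_count: int = 0
    batch_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients_per_class < 1 or self.replicates_per_patient < 1:
            raise ValueError("patient and replicate counts must be >= 1")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.n_signal_bins < 0 or self.n_dominant_unstable < 0:
            raise ValueError("bin counts must be >= 0")
        if self.n_signal_bins + self.n_dominant_unstable > self.n_bins:
            raise ValueError("signal + dominant bins exceed n_bins")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        for name in ("loading_sigma", "peak_cv", "baseline_noise_sd", "batch_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.batch_count < 0:
            raise ValueError("batch_count must be >= 0")


@dataclass(frozen=True)
class CohortDetails:
    """Ground-truth quantities of a generated cohort, for diagnostics."""

    base_profile: np.ndarray
    signal_bins: np.ndarray
    dominant_bins: np.ndarray
    loading_factors: np.ndarray
    batch_of_patient: dict[str, int]


def _lognormal_sigma_from_cv(cv: float) -> float:
    # for X ~ LogNormal, CV^2 = exp(sigma^2) - 1
    return float(np.sqrt(np.log1p(cv * cv)))


def generate_cohort(
    config: SyntheticConfig, return_details: bool = False
) -> SpectrumMatrix | tuple[SpectrumMatrix, CohortDetails]:
    """Generate a labelled synthetic cohort, bit-reproducible from the seed.

    Each measurement is
    ``base x class-effect x patient-peak-noise x dominant-instability x
    loading x batch + truncated baseline noise``.
    """
    rng = np.random.default_rng(config.seed)
    n_bins = config.n_bins

    # heavy-right-tail base profile, median intensity ~ e^3
    base = rng.lognormal(mean=3.0, sigma=1.0, size=n_bins)

    special = rng.choice(
        n_bins, size=config.n_signal_bins + config.n_dominant_unstable, replace=False
    )
    signal_bins = np.sort(special[: config.n_signal_bins])
    dominant_bins = np.sort(special[config.n_signal_bins:])
    if dominant_bins.size:
        stable_max = (
            base[np.setdiff1d(np.arange(n_bins), dominant_bins)].max()
            if dominant_bins.size < n_bins else base.max()
        )
        base[dominant_bins] = 10.0 * stable_max

    sigma_peak = _lognormal_sigma_from_cv(config.peak_cv)
    classes = ("A", "B")
    n_rows = 2 * config.n_patients_per_class * config.replicates_per_patient

    rows = np.empty((n_rows, n_bins))
    measurement_id, patient_id, class_label = [], [], []
    loading_factors = np.empty(n_rows)
    batch_of_patient: dict[str, int] = {}

    row = 0
    patient_no = 0
    for cls in classes:
        class_effect = np.ones(n_bins)
        if cls == "B":
            class_effect[signal_bins] = config.effect_size
        for p in range(config.n_patients_per_class):
            pid = f"{cls}{p + 1:03d}"
            batch = patient_no % config.batch_count if config.batch_count else 0
            batch_of_patient[pid] = batch
            patient_no += 1
            # biological per-peak variability: one draw per patient
            patient_noise = (
                rng.lognormal(mean=0.0, sigma=sigma_peak, size=n_bins)
                if sigma_peak > 0 else np.ones(n_bins)
            )
            profile = base * class_effect * patient_noise
            for r in range(config.replicates_per_patient):
                meas = profile.copy()
                if dominant_bins.size:
                    meas[dominant_bins] *= rng.lognormal(
                        mean=0.0, sigma=1.0, size=dominant_bins.size
                    )
                loading = (
                    rng.lognormal(mean=0.0, sigma=config.loading_sigma)
                    if config.loading_sigma > 0 else 1.0
                )
                meas = meas * loading
                loading_factors[row] = loading
                if config.batch_count and config.batch_sigma > 0:
                    # derive a fixed per-batch factor from the cohort seed
                    batch_rng = np.random.default_rng(config.seed * 1009 + batch)
                    meas = meas * batch_rng.lognormal(0.0, config.batch_sigma)
                if config.baseline_noise_sd > 0:
                    meas = meas + np.maximum(
                        rng.normal(0.0, config.baseline_noise_sd, size=n_bins), 0.0
                    )
                rows[row] = meas
                measurement_id.append(f"{pid}_r{r + 1:02d}")
                patient_id.append(pid)
                class_label.append(cls)
                row += 1

    matrix = SpectrumMatrix(
        intensities=rows,
        bin_mz=np.arange(10, 10 + n_bins),
        measurement_id=np.array(measurement_id, dtype=object),
        patient_id=np.array(patient_id, dtype=object),
        class_label=np.array(class_label, dtype=object),
    )
    if not return_details:
        return matrix
    return matrix, CohortDetails(
        base_profile=base,
        signal_bins=signal_bins,
        dominant_bins=dominant_bins,
        loading_factors=loading_factors,
        batch_of_patient=batch_of_patient,
    )


# fixed two-spectrum fixture illustrating AUC distortion by a dominant peak
_FIG1_STABLE = np.arange(10.0, 29.0)  # 19 stable peaks
_FIG1_A_BIN = 4    # stable peak A, raw intensity 14 in both spectra
_FIG1_B_BIN = 12   # stable peak B, raw intensity 22 in both spectra
_FIG1_C_BIN = 19
_FIG1_C_HIGH = 280.0  # 10x the largest stable peak
_FIG1_C_LOW = 19.0    # near the median of the stable peaks


def generate_fig1_pair() -> SpectrumMatrix:
    """Two spectra demonstrating how one dominant unstable peak breaks AUC.

    Peaks A and B have identical raw intensities in both spectra; peak C is
    dominant (10x the next-largest peak) in spectrum 1 only.  Under AUC
    normalisation the big C inflates spectrum 1's total signal and
    suppresses its A and B values relative to spectrum 2; under median
    normalisation the normalisation constant barely moves, so A and B stay
    within 10% of each other.
    """
    row1 = np.append(_FIG1_STABLE, _FIG1_C_HIGH)
    row2 = np.append(_FIG1_STABLE, _FIG1_C_LOW)
    assert row1[_FIG1_A_BIN] == row2[_FIG1_A_BIN]
    assert row1[_FIG1_B_BIN] == row2[_FIG1_B_BIN]
    return SpectrumMatrix(
        intensities=np.vstack([row1, row2]),
        bin_mz=np.arange(100, 100 + row1.size),
        measurement_id=np.array(["spectrum_1", "spectrum_2"], dtype=object),
        patient_id=np.array(["p1", "p2"], dtype=object),
        class_label=None,
    )
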