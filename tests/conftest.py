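import numpy as np
import pytest

from msnorm import SpectrumMatrix, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> SpectrumMatrix:
    """Labelled synthetic cohort small enough for per-test grid/ML runs."""
    return generate_cohort(
        SyntheticConfig(
            n_patients_per_class=6,
            replicates_per_patient=2,
            n_bins=80,
            n_signal_bins=10,
            n_dominant_unstable=2,
            seed=11,
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_matrix(values, labels=None, patients=None) -> SpectrumMatrix:
    """Shorthand for building a SpectrumMatrix from a plain array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    return SpectrumMatrix(
        intensities=values,
        bin_mz=np.arange(100, 100 + values.shape[1]),
        measurement_id=np.array([f"m{i}" for i in range(n)], dtype=object),
        patient_id=np.array(
            [f"p{i}" for i in range(n)] if patients is None else patients, dtype=object
        ),
        class_label=None if labels is None else np.array(labels, dtype=object),
    )
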