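"""Row-wise, set-level and intensity-histogram normalisation operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msnorm import (
    HistogramConfig,
    Spectrum,
    build_intensity_histogram,
    normalize_histogram,
    normalize_matrix_rowwise,
    normalize_minimised_vector,
    normalize_quantile,
    normalize_rowwise,
)

from conftest import make_matrix


def spectrum(values) -> Spectrum:
    values = np.asarray(values, dtype=float)
    return Spectrum(np.arange(100, 100 + values.size), values)


positive_rows = st.lists(
    st.floats(min_value=1e-3, max_value=1e5, allow_nan=False, allow_infinity=False),
    min_size=2,
    max_size=40,
)


class TestRowwise:
    @pytest.mark.parametrize(
        "values, method, expected",
        [
            ([2, 3, 5], "auc", [0.2, 0.3, 0.5]),
            ([3, 4], "vector", [0.6, 0.8]),
            ([2, 4, 6], "mean", [0.5, 1.0, 1.5]),
            ([1, 2, 9], "median", [0.5, 1.0, 4.5]),
        ],
    )
    def test_worked_examples(self, values, method, expected):
        out = normalize_rowwise(spectrum(values), method)
        np.testing.assert_allclose(out.intensities, expected, rtol=1e-12)

    def test_all_zero_spectrum_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_rowwise(spectrum([0, 0, 0]), "auc")

    def test_zero_median_error_names_method(self):
        with pytest.raises(ValueError, match="median"):
            normalize_rowwise(spectrum([0, 0, 0, 1]), "median")

    @given(positive_rows)
    @settings(deadline=None, max_examples=200)
    def test_identities(self, values):
        """AUC sums to 1, vector has unit norm, mean has mean 1, median has median 1."""
        s = spectrum(values)
        assert np.isclose(normalize_rowwise(s, "auc").intensities.sum(), 1.0, atol=1e-9)
        assert np.isclose(
            np.linalg.norm(normalize_rowwise(s, "vector").intensities), 1.0, atol=1e-9
        )
        assert np.isclose(normalize_rowwise(s, "mean").intensities.mean(), 1.0, atol=1e-9)
        assert np.isclose(
            np.median(normalize_rowwise(s, "median").intensities), 1.0, atol=1e-9
        )

    @given(positive_rows, st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=200)
    def test_loading_factor_invariance(self, values, c):
        """Rescaling a spectrum by any c > 0 leaves the normalised output unchanged."""
        s = spectrum(values)
        scaled = spectrum(np.asarray(values) * c)
        for method in ("auc", "mean", "median", "vector"):
            np.testing.assert_allclose(
                normalize_rowwise(s, method).intensities,
                normalize_rowwise(scaled, method).intensities,
                rtol=1e-9,
                atol=1e-12,
            )


class TestMinimisedVector:
    def test_row_proportional_to_centroid_maps_onto_it(self):
        centroid_row = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        out = normalize_minimised_vector(make_matrix([centroid_row * 7, centroid_row]),
                                         centroid=centroid_row)
        np.testing.assert_allclose(out.intensities[0], centroid_row, rtol=1e-12)

    def test_constant_case(self):
        out = normalize_minimised_vector(make_matrix([[1, 1], [3, 3]]))
        # centroid [2,2]; k for row [1,1] is 2, giving [2,2]
        np.testing.assert_allclose(out.intensities[0], [2, 2], rtol=1e-12)

    def test_closed_form_matches_grid_search(self, rng):
        """k_min from the closed form agrees with a fine brute-force scan."""
        mat = make_matrix(rng.uniform(0.1, 10.0, size=(5, 8)))
        centroid = mat.intensities.mean(axis=0)
        out = normalize_minimised_vector(mat)
        for i in range(5):
            row = mat.intensities[i]
            k_closed = out.intensities[i][0] / row[0]
            ks = np.linspace(0.0, 2.0 * k_closed + 1.0, 100_000)
            dev = (
                centroid @ centroid
                - 2.0 * ks * (centroid @ row)
                + ks * ks * (row @ row)
            )
            k_grid = ks[np.argmin(dev)]
            assert abs(k_closed - k_grid) < 1e-4  # grid resolution bound
            # oracle property: closed-form k beats 100 random k values
            for k in rng.uniform(0.0, 2.0 * k_closed + 1.0, 100):
                assert (
                    np.linalg.norm(centroid - k_closed * row)
                    <= np.linalg.norm(centroid - k * row) + 1e-9
                )

    def test_all_zero_row_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_minimised_vector(make_matrix([[0, 0], [1, 2]]))


class TestQuantile:
    def test_worked_example(self):
        out = normalize_quantile(make_matrix([[1, 3, 2], [4, 6, 5]]))
        np.testing.assert_allclose(out.intensities, [[2.5, 4.5, 3.5], [2.5, 4.5, 3.5]])

    def test_identical_rows_fixed_point(self):
        rows = [[5.0, 1.0, 3.0]] * 3
        out = normalize_quantile(make_matrix(rows))
        np.testing.assert_allclose(out.intensities, rows)

    @given(
        st.integers(min_value=2, max_value=6),
        st.integers(min_value=2, max_value=12),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(deadline=None, max_examples=100)
    def test_rows_share_one_multiset(self, n_rows, n_cols, seed):
        rng = np.random.default_rng(seed)
        out = normalize_quantile(make_matrix(rng.uniform(0, 100, (n_rows, n_cols))))
        ref = np.sort(out.intensities[0])
        for i in range(1, n_rows):
            np.testing.assert_allclose(np.sort(out.intensities[i]), ref, rtol=1e-12)


class TestIntensityHistogram:
    def test_counts_conserve_bins(self):
        config = HistogramConfig(P1=20, P2=40, P3=60, P4=80, n1=1, n2=1, n3=1)
        hist = build_intensity_histogram(spectrum(np.arange(10.0)), config)
        assert hist.counts.sum() == 10
        assert hist.counts.size == 5  # five segments, end segments single bins
        assert hist.edges[0] == 0.0

    def test_constant_spectrum_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_intensity_histogram(spectrum([3.0] * 10), HistogramConfig())

    def test_value_at_p4_falls_in_final_bin(self):
        config = HistogramConfig(P1=20, P2=40, P3=60, P4=80, n1=2, n2=2, n3=2)
        values = np.arange(1.0, 12.0)  # q(80) = 9.0 exactly
        hist = build_intensity_histogram(spectrum(values), config)
        q4 = np.percentile(values, 80)
        at_q4 = np.flatnonzero(values == q4)
        assert (hist.bin_of[at_q4] == hist.counts.size - 1).all()
        # the maximum also lands in the final (right-closed) bin
        assert hist.bin_of[np.argmax(values)] == hist.counts.size - 1

    def test_bin_of_covers_every_mz(self, small_cohort):
        config = HistogramConfig(n1=5, n2=5, n3=5)
        for row in small_cohort.intensities[:4]:
            hist = build_intensity_histogram(row, config)
            assert hist.bin_of.size == row.size
            assert hist.counts.sum() == row.size
            assert ((hist.bin_of >= 0) & (hist.bin_of < hist.counts.size)).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="percentiles"):
            HistogramConfig(P1=50, P2=40, P3=60, P4=80)
        with pytest.raises(ValueError, match="positive integer"):
            HistogramConfig(n1=0)

    def test_json_round_trip(self):
        config = HistogramConfig(P1=15, P2=35, P3=55, P4=85, n1=10, n2=20, n3=30)
        assert HistogramConfig.from_json(config.to_json()) == config


class TestHistogramNormalisation:
    def test_bin_variant_yields_integer_indices(self, small_cohort):
        config = HistogramConfig(n1=4, n2=4, n3=4)
        out = normalize_histogram(small_cohort, "histbin", config)
        assert out.intensities.shape == small_cohort.intensities.shape
        values = out.intensities
        assert np.array_equal(values, np.round(values))
        assert values.min() >= 0 and values.max() <= config.n_hist_bins - 1

    def test_intensity_variant_changes_feature_axis(self, small_cohort):
        config = HistogramConfig(n1=4, n2=4, n3=4)
        out = normalize_histogram(small_cohort, "histintensity", config)
        assert out.n_bins == config.n_hist_bins
        assert out.feature_kind == "histbin"
        # every row sums to the number of m/z bins of the input
        np.testing.assert_array_equal(
            out.intensities.sum(axis=1), small_cohort.n_bins
        )

    def test_function_variant(self):
        config = HistogramConfig(P1=20, P2=40, P3=60, P4=80, n1=1, n2=1, n3=1)
        values = np.array([0.0, 1.0, 2.0, 5.0, 9.0, 4.0, 7.0, 3.0, 8.0, 6.0])
        mat = make_matrix([values])
        out = normalize_histogram(mat, "histfunction", config)
        hist = build_intensity_histogram(values, config)
        expected = np.where(values > 0, hist.bin_of / np.where(values > 0, values, 1), 0)
        np.testing.assert_allclose(out.intensities[0], expected, rtol=1e-12)
        assert out.intensities[0][0] == 0.0  # zero intensity stays absent
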