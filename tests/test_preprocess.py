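import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lakeq.preprocess import (
    SmootherConfig,
    column_normalize,
    communalities,
    fit_pca,
    kmo_and_bartlett,
    ramp_in_mask,
    recursive_average_filter,
    select_n_components,
)
from lakeq.synthetic import SyntheticSpec, generate

from conftest import make_series

# per-component variance-interpretation rates of the worked 12-indicator
# example (percent, descending components)
WORKED_RATES = [44.478, 13.547, 11.156, 10.315, 6.281, 5.466, 4.796,
                2.306, 1.133, 0.489, 0.021, 0.012]


class TestRecursiveAverageFilter:
    @pytest.mark.parametrize(
        "series, l, expected",
        [
            ([5, 5, 5, 5], 2, [2.5, 5, 5, 5]),
            ([1, 2, 3, 4, 5, 6], 3, [1 / 3, 1, 2, 3, 4, 5]),
            ([7, 1, 4], 1, [7, 1, 4]),
        ],
    )
    def test_worked_examples(self, series, l, expected):
        out = recursive_average_filter(make_series(series), SmootherConfig(l))
        np.testing.assert_allclose(out.values[:, 0], expected, atol=1e-12)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            recursive_average_filter(make_series([1, 2, 3]), SmootherConfig(4))

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            SmootherConfig(0)

    @given(
        data=st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=40),
        l=st.integers(1, 4),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_trailing_window_loop_oracle(self, data, l):
        """Positions at or past the window equal an independent loop mean."""
        out = recursive_average_filter(make_series(data), SmootherConfig(l))
        for j in range(l - 1, len(data)):
            expected = sum(data[j - l + 1 : j + 1]) / l
            assert out.values[j, 0] == pytest.approx(expected, abs=1e-6, rel=1e-9)

    def test_constant_series_unchanged_past_ramp_in(self):
        out = recursive_average_filter(make_series([3.7] * 30), SmootherConfig(7))
        np.testing.assert_allclose(out.values[6:, 0], 3.7, atol=1e-12)
        mask = ramp_in_mask(30, 7)
        assert mask.sum() == 6 and mask[:6].all()

    def test_preserves_shape_and_channels(self, small_series):
        out = recursive_average_filter(small_series, SmootherConfig(5))
        assert out.values.shape == small_series.values.shape
        assert out.channel_names == small_series.channel_names


class TestColumnNormalize:
    def test_three_four_five_triangle(self):
        out = column_normalize(make_series([3.0, 4.0]))
        np.testing.assert_allclose(out.values[:, 0], [0.6, 0.8])

    def test_equal_entries(self):
        out = column_normalize(make_series([1.0, 1.0, 1.0, 1.0]))
        np.testing.assert_allclose(out.values[:, 0], 0.5)

    def test_unit_norm_per_channel(self, small_series):
        out = column_normalize(small_series)
        np.testing.assert_allclose(
            np.sqrt((out.values**2).sum(axis=0)), 1.0, atol=1e-12
        )

    def test_zero_column_names_channel(self):
        series = make_series(np.column_stack([[1.0, 2.0], [0.0, 0.0]]),
                             names=["a", "dead"])
        with pytest.raises(ValueError, match="dead"):
            column_normalize(series)


class TestCommunalities:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([0.854, 0.396, -0.032, -0.146, 0.1], 0.918),     # organic demand
            ([0.972, 0.147, 0.109, 0.012, -0.049], 0.981),    # organic carbon
            ([0.211, -0.134, 0.182, 0.73, 0.466], 0.846),     # ammonia
            ([1.0, 0.0, 0.0], 1.0),
        ],
    )
    def test_sum_of_squared_loadings(self, row, expected):
        assert round(float(communalities(np.array(row))[0]), 3) == expected

    def test_requires_a_component(self):
        with pytest.raises(ValueError):
            communalities(np.empty((3, 0)))


class TestRetentionRule:
    def test_worked_example_retains_five(self):
        assert select_n_components(WORKED_RATES, 85.0) == 5

    def test_cumulative_of_first_five(self):
        assert round(sum(WORKED_RATES[:5]), 3) == 85.777

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            select_n_components(WORKED_RATES, 0)
        with pytest.raises(ValueError):
            select_n_components(WORKED_RATES, 101)

    def test_all_components_when_threshold_100(self):
        assert select_n_components([60.0, 30.0, 10.0], 100.0) == 3


class TestFitPCA:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.standard_normal(200)
        series = make_series(np.column_stack([x, 2 * x + 1]))
        report = fit_pca(series)
        np.testing.assert_allclose(report.eigenvalues, [2.0, 0.0], atol=1e-9)
        assert report.contribution_rates[0] == pytest.approx(100.0)
        assert report.n_components == 1

    def test_independent_channels_flat_spectrum(self, rng):
        series = make_series(rng.standard_normal((10000, 4)))
        report = fit_pca(series)
        np.testing.assert_allclose(report.eigenvalues, 1.0, atol=0.1)

    def test_rates_sum_and_cumulative_monotone(self, small_series):
        report = fit_pca(small_series)
        assert report.contribution_rates.sum() == pytest.approx(100.0, abs=1e-6)
        assert (np.diff(report.cumulative_rates) >= -1e-12).all()
        assert report.cumulative_rates[-1] == pytest.approx(100.0, abs=1e-6)

    def test_full_retention_gives_unit_communalities(self, rng):
        series = make_series(rng.standard_normal((300, 5)))
        report = fit_pca(series, retention_threshold=100.0)
        assert report.n_components == 5
        np.testing.assert_allclose(report.communalities, 1.0, atol=1e-6)

    def test_loadings_reconstruct_correlation_matrix(self, rng):
        series, _ = generate(SyntheticSpec(n_steps=400, seed=3), return_truth=True)
        report = fit_pca(series)
        corr = np.corrcoef(series.values, rowvar=False)
        np.testing.assert_allclose(
            report.all_loadings @ report.all_loadings.T, corr, atol=1e-6
        )

    def test_eigenvalues_match_sklearn(self, rng):
        """Independent route: sklearn PCA on z-scored data."""
        from sklearn.decomposition import PCA

        values = rng.standard_normal((500, 6)) @ rng.standard_normal((6, 6))
        series = make_series(values)
        report = fit_pca(series)
        z = (values - values.mean(0)) / values.std(0, ddof=1)
        sk = PCA().fit(z)
        # sklearn normalizes by n-1, matching the ddof=1 correlation matrix
        np.testing.assert_allclose(
            report.eigenvalues, sk.explained_variance_, rtol=1e-8, atol=1e-10
        )

    def test_constant_channel_rejected(self):
        series = make_series(np.column_stack([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]),
                             names=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            fit_pca(series)

    def test_warns_when_underdetermined(self, rng):
        series = make_series(rng.standard_normal((5, 8)))
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_pca(series)

    def test_dominant_loading_sign_positive(self, small_series):
        report = fit_pca(small_series)
        for k in range(report.all_loadings.shape[1]):
            col = report.all_loadings[:, k]
            assert col[np.argmax(np.abs(col))] >= 0


def _kmo_loop_oracle(values):
    """Textbook KMO: pairwise sums over correlations and partials."""
    corr = np.corrcoef(values, rowvar=False)
    inv = np.linalg.inv(corr)
    s = corr.shape[0]
    r2 = p2 = 0.0
    for i in range(s):
        for j in range(s):
            if i == j:
                continue
            r2 += corr[i, j] ** 2
            partial = -inv[i, j] / np.sqrt(inv[i, i] * inv[j, j])
            p2 += partial**2
    return r2 / (r2 + p2)


class TestKMOAndBartlett:
    def test_df_for_twelve_channels(self):
        series = generate(SyntheticSpec(n_steps=300, seed=1))
        _, _, df, _ = kmo_and_bartlett(series)
        assert df == 66  # s(s-1)/2 with s = 12

    def test_sphericity_not_rejected_for_independent_channels(self, rng):
        series = make_series(rng.standard_normal((4000, 5)))
        _, chi2, df, p = kmo_and_bartlett(series)
        assert df == 10
        assert p > 0.05  # the null is true; no evidence of structure

    def test_shared_factor_structure_has_adequate_kmo(self, rng):
        # four channels driven by one latent factor: classic sampling
        # adequacy; duplicated *pairs* sit exactly at the 0.5 boundary
        f = rng.standard_normal(500)
        values = f[:, None] + 0.5 * rng.standard_normal((500, 4))
        kmo, chi2, _, p = kmo_and_bartlett(make_series(values))
        assert kmo > 0.5
        assert p < 1e-6

    def test_matches_loop_oracle(self, rng):
        values = rng.standard_normal((400, 5)) @ rng.standard_normal((5, 5))
        kmo, _, _, _ = kmo_and_bartlett(make_series(values))
        assert kmo == pytest.approx(_kmo_loop_oracle(values), abs=1e-12)

    def test_singular_matrix_rejected(self, rng):
        x = rng.standard_normal(100)
        series = make_series(np.column_stack([x, 2 * x]))
        with pytest.raises(ValueError, match="singular|zero variance"):
            kmo_and_bartlett(series)
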