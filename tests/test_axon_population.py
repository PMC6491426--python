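import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from lhonsim.axon_population import (
    InsufficientDataError,
    MixtureParams,
    RADIUS_SUPPORT,
    RadiusHistogram,
    default_quadrant_params,
    fit_mixture,
    interpolate_region_mixture,
    sample_radii,
    tertile_bounds,
)
from lhonsim.fixtures import pan_like_histograms


def _hist_from_mixture(mp, n_bins=40, lo=0.1, hi=1.0):
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadiusHistogram(centers, mp(centers), region_tag=mp.region_tag)


class TestMixtureParams:
    def test_three_components_required(self):
        with pytest.raises(ValueError):
            MixtureParams(components=((1.0, 0.3, 0.1),))

    def test_positive_sigma_required(self):
        with pytest.raises(ValueError):
            MixtureParams(components=((1.0, 0.3, 0.0), (1.0, 0.4, 0.1), (1.0, 0.5, 0.1)))

    def test_evaluation_finite_nonnegative(self):
        mp = default_quadrant_params()["temporal"]
        r = np.linspace(0.0, 5.0, 501)
        f = mp(r)
        assert np.all(np.isfinite(f)) and np.all(f >= 0)


class TestFitMixture:
    def test_recovers_single_dominant_gaussian(self):
        # histogram generated exactly from one Gaussian plus two near-zero
        # components: the dominant component must come back within 1%
        truth = MixtureParams(
            components=((1e-6, 0.2, 0.05), (100.0, 0.5, 0.1), (1e-6, 0.9, 0.05))
        )
        hist = _hist_from_mixture(truth, n_bins=60)
        params, r2 = fit_mixture(hist, rng_seed=0)
        dominant = max(params.components, key=lambda c: c[0] * c[2])
        assert abs(dominant[1] - 0.5) < 0.005
        assert abs(dominant[2] - 0.1) < 0.001
        assert r2 > 0.999

    def test_recovers_sampled_three_component_mixture(self):
        truth = MixtureParams(
            components=((80.0, 0.25, 0.05), (50.0, 0.5, 0.08), (30.0, 0.8, 0.1))
        )
        radii = sample_radii(truth, 50_000, rng_seed=3)
        edges = np.linspace(0.1, 1.1, 51)
        counts, _ = np.histogram(radii, bins=edges)
        hist = RadiusHistogram(0.5 * (edges[:-1] + edges[1:]), counts.astype(float))
        params, r2 = fit_mixture(hist, rng_seed=1)
        mus = sorted(c[1] for c in params.components)
        # generating means recovered within a few standard errors
        for est, true in zip(mus, (0.25, 0.5, 0.8)):
            assert abs(est - true) < 0.02
        assert r2 >= 0.99

    def test_fixture_histograms_are_mixture_representable(self):
        for tag, hist in pan_like_histograms(seed=0).items():
            _, r2 = fit_mixture(hist, rng_seed=0)
            assert r2 >= 0.99, f"{tag} fit R²={r2:.4f}"

    def test_fit_idempotence(self):
        truth = default_quadrant_params()["nasal"]
        hist = _hist_from_mixture(truth, n_bins=60)
        params, r2 = fit_mixture(hist, rng_seed=0)
        assert r2 > 0.9999
        resid = np.abs(params(hist.bin_centers) - hist.counts)
        assert resid.max() < 1e-2 * hist.counts.max()

    def test_too_few_bins_rejected(self):
        hist = RadiusHistogram(np.linspace(0.2, 0.8, 5), np.ones(5))
        with pytest.raises(InsufficientDataError):
            fit_mixture(hist)


class TestSampleRadii:
    def test_empty_draw(self):
        mp = default_quadrant_params()["temporal"]
        assert sample_radii(mp, 0, rng_seed=0).size == 0

    def test_law_of_large_numbers(self):
        mp = MixtureParams(components=((1e-9, 0.3, 0.05), (100.0, 0.5, 0.05), (1e-9, 0.7, 0.05)))
        r = sample_radii(mp, 100_000, rng_seed=5)
        assert abs(r.mean() - 0.5) < 0.005

    def test_same_seed_identical(self):
        mp = default_quadrant_params()["superior"]
        a = sample_radii(mp, 1000, rng_seed=42)
        b = sample_radii(mp, 1000, rng_seed=42)
        assert np.array_equal(a, b)

    def test_support_respected(self):
        mp = default_quadrant_params()["nasal"]
        r = sample_radii(mp, 20_000, rng_seed=1)
        lo, hi = RADIUS_SUPPORT
        assert r.min() >= lo and r.max() <= hi

    def test_invalid_support_rejected(self):
        mp = default_quadrant_params()["nasal"]
        with pytest.raises(ValueError):
            sample_radii(mp, 10, rng_seed=0, support=(0.5, 0.1))

    def test_sampling_density_normalized(self):
        # quadrature of the truncated, normalized density over the support
        mp = default_quadrant_params()["temporal"]
        lo, hi = RADIUS_SUPPORT
        z, _ = quad(lambda x: mp(np.array(x)), lo, hi, limit=200)
        total, _ = quad(lambda x: mp(np.array(x)) / z, lo, hi, limit=200)
        assert abs(total - 1.0) < 1e-6


class TestTertiles:
    def test_exact_tertiles_nine_values(self):
        b = tertile_bounds(np.arange(1.0, 10.0))
        cls = b.classify(np.arange(1.0, 10.0))
        assert np.array_equal(np.bincount(cls), [3, 3, 3])

    def test_balanced_classes_on_sampled_population(self):
        mp = default_quadrant_params()["inferior"]
        r = sample_radii(mp, 12_000, rng_seed=9)
        cls = tertile_bounds(r).classify(r)
        counts = np.bincount(cls, minlength=3)
        assert counts.sum() == 12_000
        assert max(counts) - min(counts) <= 1

    @given(
        st.lists(
            st.floats(min_value=0.05, max_value=3.0, allow_nan=False),
            min_size=3,
            max_size=500,
        )
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_tertile_balance_property(self, radii):
        # on any distinct-valued population the small and large classes
        # differ by at most one member
        r = np.asarray(radii)
        if np.unique(r).size < 3:
            return
        cls = tertile_bounds(r).classify(r)
        counts = np.bincount(cls, minlength=3)
        if np.unique(r).size == r.size:  # no ties at the cuts
            assert abs(counts[0] - counts[2]) <= 1
        assert counts.sum() == r.size

    def test_ties_go_to_lower_class(self):
        r = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 3.0, 3.0])
        b = tertile_bounds(r)
        assert b.classify([b.lower_cut]).item() == 0
        assert b.classify([b.upper_cut]).item() == 1

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            tertile_bounds([0.3, 0.5])


class TestRegionalInterpolation:
    def test_quadrant_center_identity(self):
        qp = default_quadrant_params()
        got = interpolate_region_mixture(180.0, qp)
        assert np.allclose(got.as_flat(), qp["temporal"].as_flat())

    def test_midpoint_is_arithmetic_mean(self):
        qp = default_quadrant_params()
        got = interpolate_region_mixture(135.0, qp)
        expect = 0.5 * (qp["temporal"].as_flat() + qp["superior"].as_flat())
        assert np.allclose(got.as_flat(), expect)

    def test_mean_radius_monotone_temporal_to_nasal(self):
        # along the superior route, expected caliber grows toward nasal
        qp = default_quadrant_params()
        angles = np.linspace(180.0, 90.0, 19)  # temporal -> superior
        means = [interpolate_region_mixture(a, qp).mean_radius() for a in angles]
        assert all(m2 >= m1 - 1e-9 for m1, m2 in zip(means, means[1:]))

    def test_missing_quadrant_rejected(self):
        qp = default_quadrant_params()
        del qp["nasal"]
        with pytest.raises(KeyError):
            interpolate_region_mixture(10.0, qp)

    def test_blockwise_snaps_to_nearest(self):
        qp = default_quadrant_params()
        got = interpolate_region_mixture(160.0, qp, blockwise=True)
        assert np.allclose(got.as_flat(), qp["temporal"].as_flat())


def test_histogram_text_roundtrip(tmp_path):
    h = pan_like_histograms(seed=1)["temporal"]
    path = tmp_path / "hist.tsv"
    h.to_text(path)
    h2 = RadiusHistogram.from_text(path, region_tag="temporal")
    assert np.allclose(h.bin_centers, h2.bin_centers)
    assert np.allclose(h.counts, h2.counts)
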