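"""LoG filtering and region quantifiers against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage, signal

from logradiomics import volume_io as vio
from logradiomics.log_texture import (
    DEFAULT_SCALES,
    EntropyConfig,
    ScaleSet,
    analytic_log_kernel,
    extract_cohort_features,
    extract_features,
    log_filter,
    quantify,
    scale_sweep,
    sweep_to_feature_tables,
)
from logradiomics.phantom import PhantomRegionSpec, TextureParams, build_label_volume
from logradiomics.volume_io import LabeledVolume


def _effective_discrete_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Independent construction of the discrete operator's kernel: sampled
    1-D Gaussians (outer product) convolved with the 6-neighbour Laplacian
    stencil."""
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1)
    g1 = np.exp(-(x**2) / (2 * sigma**2))
    g1 /= g1.sum()
    g3 = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    lap = np.zeros((3, 3, 3))
    lap[1, 1, 1] = -6.0
    for d in [(0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)]:
        lap[d] = 1.0
    return signal.convolve(g3, lap, mode="full")


class TestLogFilter:
    def test_constant_volume_maps_to_zero(self):
        vol = np.full((16, 16, 16), 7.3)
        for sigma in DEFAULT_SCALES.sigmas_mm:
            resp = log_filter(vol, (1, 1, 1), sigma)
            assert np.abs(resp).max() < 1e-10

    def test_matches_dense_convolution_oracle(self, rng):
        """Discrete path == direct dense convolution with the effective kernel."""
        vol = rng.standard_normal((24, 24, 24))
        for sigma in (0.8, 1.5, 2.0):
            oracle = ndimage.convolve(
                vol, _effective_discrete_kernel(sigma), mode="reflect"
            )
            mine = log_filter(vol, (1, 1, 1), sigma)
            np.testing.assert_allclose(
                mine, oracle, rtol=0, atol=1e-6 * np.abs(oracle).max()
            )

    def test_analytic_impulse_response_is_sampled_log(self):
        """Analytic-kernel path impulse response equals direct evaluation of
        the del^2 G formula at every voxel offset."""
        sigma = 1.5
        n, c = 33, 16
        imp = np.zeros((n, n, n))
        imp[c, c, c] = 1.0
        resp = log_filter(imp, (1, 1, 1), sigma, method="analytic")
        x = np.arange(n, dtype=float) - c
        xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
        r2 = xx**2 + yy**2 + zz**2
        gauss = np.exp(-r2 / (2 * sigma**2)) / (2 * np.pi * sigma**2) ** 1.5
        expected = (r2 / sigma**4 - 3.0 / sigma**2) * gauss
        expected[r2 > (4.0 * sigma) ** 2 * 3] = 0.0  # outside truncation box
        r = analytic_log_kernel(sigma).shape[0] // 2
        sl = slice(c - r, c + r + 1)
        np.testing.assert_allclose(
            resp[sl, sl, sl],
            expected[sl, sl, sl],
            atol=1e-6 * np.abs(expected).max(),
        )

    def test_discrete_approximates_analytic_at_coarse_scale(self, rng):
        # O((h/sigma)^2) discretization error: the two paths agree to a few
        # percent at sigma = 2 voxels, not to machine precision
        vol = rng.standard_normal((20, 20, 20))
        d = log_filter(vol, (1, 1, 1), 2.0)
        a = log_filter(vol, (1, 1, 1), 2.0, method="analytic")
        assert np.abs(d - a).max() < 0.12 * np.abs(d).max()

    def test_linearity(self, rng):
        v1 = rng.standard_normal((12, 12, 12))
        v2 = rng.standard_normal((12, 12, 12))
        lhs = log_filter(2.5 * v1 - 1.5 * v2, (1, 1, 1), 1.2)
        rhs = 2.5 * log_filter(v1, (1, 1, 1), 1.2) - 1.5 * log_filter(
            v2, (1, 1, 1), 1.2
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_translation_equivariance_in_interior(self, rng):
        vol = np.zeros((24, 24, 24))
        vol[8:14, 8:14, 8:14] = rng.standard_normal((6, 6, 6))
        shifted = np.roll(vol, 2, axis=0)
        r1 = log_filter(vol, (1, 1, 1), 1.0)
        r2 = log_filter(shifted, (1, 1, 1), 1.0)
        np.testing.assert_allclose(np.roll(r1, 2, axis=0)[6:-6], r2[6:-6], atol=1e-10)

    def test_anisotropic_spacing_equivalent_to_resampled_sigma(self, rng):
        """sigma in mm is converted per axis: filtering a grid with 2 mm slices
        equals filtering with per-axis voxel sigmas."""
        vol = rng.standard_normal((16, 16, 16))
        resp = log_filter(vol, (1.0, 1.0, 2.0), 2.0)
        sm = ndimage.gaussian_filter(vol, sigma=(2.0, 2.0, 1.0), mode="reflect",
                                     truncate=4.0)
        expected = (
            ndimage.correlate1d(sm, np.array([1.0, -2.0, 1.0]), axis=0, mode="reflect")
            + ndimage.correlate1d(sm, np.array([1.0, -2.0, 1.0]), axis=1, mode="reflect")
            + ndimage.correlate1d(sm, np.array([1.0, -2.0, 1.0]) / 4.0, axis=2,
                                  mode="reflect")
        )
        np.testing.assert_allclose(resp, expected, atol=1e-12)

    def test_blob_scale_selection(self):
        """Scale-normalized center response to a Gaussian blob of width s is
        maximized at sigma near s (classic scale-space blob selection)."""
        s = 2.0
        n, c = 48, 24
        xx, yy, zz = np.indices((n, n, n))
        blob = np.exp(-((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2) / (2 * s * s))
        sigmas = np.arange(0.8, 3.21, 0.2)
        center = [
            abs(log_filter(blob, (1, 1, 1), sg, scale_normalize=True)[c, c, c])
            for sg in sigmas
        ]
        peak = sigmas[int(np.argmax(center))]
        # 3-D theory: argmax at s * sqrt(2/3) ~ 1.63 for s = 2
        assert abs(peak - s * np.sqrt(2.0 / 3.0)) <= 0.21

    def test_non_finite_input_rejected(self):
        vol = np.zeros((8, 8, 8))
        vol[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            log_filter(vol, (1, 1, 1), 1.0)

    def test_under_resolved_sigma_warns(self, caplog):
        with caplog.at_level("WARNING"):
            log_filter(np.zeros((8, 8, 8)), (1, 1, 2.5), 1.0)
        assert "under-resolved" in caplog.text


class TestQuantify:
    def test_worked_example_four_values(self):
        a, sd, e = quantify(np.array([1.0, 2.0, 3.0, 4.0]))
        assert a == pytest.approx(2.5)
        assert sd == pytest.approx(1.1180, abs=1e-4)
        assert e == pytest.approx(2.0)

    def test_two_equally_occupied_bins(self):
        a, sd, e = quantify(np.array([0.0, 0.0, 1.0, 1.0]))
        assert (a, sd, e) == pytest.approx((0.5, 0.5, 1.0))

    def test_degenerate_distribution(self):
        a, sd, e = quantify(np.full(100, 3.7))
        assert (a, sd, e) == pytest.approx((3.7, 0.0, 0.0))

    def test_empty_region_returns_missing_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = quantify(np.array([]))
        assert all(np.isnan(out))
        assert "empty" in caplog.text

    def test_equally_occupied_m_bins_have_entropy_log2_m(self):
        # values placed at bin centers of an m-bin split of [0, 1)
        for m in (2, 4, 8, 32):
            vals = (np.arange(m) + 0.5) / m
            vals = np.concatenate([vals, vals])  # two per bin
            _, _, e = quantify(vals, EntropyConfig(n_bins=m))
            assert e == pytest.approx(np.log2(m))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        data=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=200
        ),
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-1e3, 1e3),
    )
    def test_quantifier_invariants(self, data, scale, offset):
        """A is affine-equivariant, SD scales by |a|, E is invariant under
        increasing affine maps and bounded by log2(n_bins)."""
        x = np.asarray(data)
        a0, sd0, e0 = quantify(x)
        a1, sd1, e1 = quantify(scale * x + offset)
        assert 0.0 <= e0 <= np.log2(256) + 1e-12
        assert sd0 >= 0.0
        assert a1 == pytest.approx(scale * a0 + offset, rel=1e-9, abs=1e-6)
        assert sd1 == pytest.approx(scale * sd0, rel=1e-9, abs=1e-6)
        assert e1 == pytest.approx(e0, abs=1e-9)


class TestExtractFeatures:
    def _volume(self, rng, tau=1.0):
        labels = build_label_volume(
            (24, 24, 24),
            [
                PhantomRegionSpec(1, "a", "sphere", (8, 8, 8), 5),
                PhantomRegionSpec(2, "b", "box", (17, 17, 17), (4, 4, 4)),
            ],
        )
        intensity = np.where(labels > 0, 10.0, 0.0)
        if tau:
            intensity = intensity + tau * rng.standard_normal(labels.shape) * (
                labels > 0
            )
        return LabeledVolume(intensity, labels, (1, 1, 1), "s0")

    def _region_map(self):
        return vio.RegionMap(
            (vio.RegionEntry(1, "a", "left"), vio.RegionEntry(2, "b", "right"))
        )

    def test_default_configuration_yields_279_features(self, rng):
        rm = vio.default_region_map()
        labels = np.zeros((32, 32, 32), dtype=np.int32)
        # one small box per mapped label
        for k, lid in enumerate(rm.label_ids):
            i, j = divmod(k, 8)
            labels[2 + 4 * j : 5 + 4 * j, 2 + 8 * i : 7 + 8 * i, 4:10] = lid
        vol = LabeledVolume(rng.standard_normal(labels.shape), labels, (1, 1, 1), "s")
        row = extract_features(vol, rm)
        assert len(row) == 31 * 3 * 3 == 279
        per_region = {}
        for col in row.index:
            region, _, _ = vio.parse_feature_column(col)
            per_region[region] = per_region.get(region, 0) + 1
        assert set(per_region.values()) == {9}

    def test_piecewise_constant_region_is_all_zero(self, rng):
        # locally constant signal: constant intensity everywhere, so no
        # boundary step leaks edge responses into the regions
        vol = self._volume(rng, tau=0.0)
        vol.intensity[:] = 10.0
        row = extract_features(vol, self._region_map())
        np.testing.assert_allclose(row.to_numpy(), 0.0, atol=1e-9)

    def test_missing_region_yields_missing_cells(self, rng):
        vol = self._volume(rng)
        vol.labels[vol.labels == 2] = 0
        row = extract_features(vol, self._region_map())
        missing = row.isna()
        assert missing.sum() == 9
        assert all("b__" in c for c in row.index[missing])

    def test_no_mapped_region_is_an_error(self, rng):
        vol = self._volume(rng)
        rm = vio.RegionMap((vio.RegionEntry(99, "nope", "midline"),))
        with pytest.raises(ValueError, match="none of the"):
            extract_features(vol, rm)

    def test_sweep_single_sigma_matches_extract(self, rng):
        vol = self._volume(rng)
        rm = self._region_map()
        sweep = scale_sweep([vol], [1.5], rm)
        table = sweep_to_feature_tables(sweep)[1.5]
        row = extract_features(vol, rm, ScaleSet((1.5,), None))
        for col in table.columns:
            assert table.loc["s0", col] == pytest.approx(row[col], rel=1e-12)
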