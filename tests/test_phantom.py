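import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from septinsim.models import (
    ComplexVariant,
    build_lattice,
    default_lattice_spec,
)
from septinsim.phantom import (
    BRIDGE_BASE_MASS,
    DensityVolume,
    GridParams,
    ParticleLabel,
    bin_image,
    generate_particle_mixture,
    low_pass,
    render_projection,
    render_volume,
)

V = ComplexVariant


def _grid(n=96, voxel=7.3):
    return GridParams((n, n, n), voxel)


def _cable(variant=V.WT_GIC1, n_filaments=2, n_repeats=2):
    spec = default_lattice_spec(
        variant, n_filaments=n_filaments, n_repeats=n_repeats
    )
    return build_lattice(spec, variant, seed=0), spec


class TestGridParams:
    def test_rejects_bad_voxel(self):
        with pytest.raises(ValueError):
            GridParams((32, 32, 32), 0.0)

    def test_rejects_tiny_shape(self):
        with pytest.raises(ValueError):
            GridParams((4, 32, 32), 1.0)

    def test_extent(self):
        g = GridParams((10, 20, 30), 2.0)
        assert g.extent == (20.0, 40.0, 60.0)


class TestRenderVolume:
    def test_empty_lattice_renders_zero(self):
        spec = default_lattice_spec(V.WT_GIC1, n_filaments=0, n_repeats=1)
        lat = build_lattice(spec, V.WT_GIC1, seed=0)
        vol = render_volume(lat, _grid())
        assert not vol.values.any()

    def test_integral_matches_component_masses(self):
        # analytic oracle: each subunit integrates to 1, each bridge to
        # BRIDGE_BASE_MASS * mass_scale
        lat, spec = _cable()
        vol = render_volume(lat, _grid(128))
        expected = len(lat.subunits) + BRIDGE_BASE_MASS * sum(
            b.mass_scale for b in lat.bridges
        )
        assert vol.integral() == pytest.approx(expected, rel=1e-3)

    def test_sphere_bridge_integral(self):
        lat, spec = _cable()
        vol = render_volume(lat, _grid(128), which="bridges",
                            bridge_shape="sphere")
        expected = BRIDGE_BASE_MASS * sum(b.mass_scale for b in lat.bridges)
        assert vol.integral() == pytest.approx(expected, rel=1e-3)

    def test_bridge_mass_ratio_is_1_5(self):
        # Gic1+Cdc42-GppNHp bridges carry 1.5x the Gic1 bridge mass
        lat_gtp, _ = _cable(V.WT_GIC1_CDC42GTP)
        lat_gic, _ = _cable(V.WT_GIC1)
        g = _grid(128)
        m_gtp = render_volume(lat_gtp, g, which="bridges").integral()
        m_gic = render_volume(lat_gic, g, which="bridges").integral()
        assert m_gtp / m_gic == pytest.approx(1.5, rel=1e-3)

    def test_rendering_is_linear_in_components(self):
        lat, _ = _cable()
        g = _grid(128)
        full = render_volume(lat, g)
        subs = render_volume(lat, g, which="subunits")
        bridges = render_volume(lat, g, which="bridges")
        np.testing.assert_allclose(
            full.values, subs.values + bridges.values, atol=1e-10
        )

    def test_out_of_bounds_raises(self):
        lat, _ = _cable(n_repeats=4)
        with pytest.raises(ValueError, match="exceeds grid"):
            render_volume(lat, GridParams((32, 32, 32), 7.3))

    def test_nonnegative_and_finite(self):
        lat, _ = _cable()
        vol = render_volume(lat, _grid(128))
        assert np.isfinite(vol.values).all()
        assert (vol.values >= 0).all()

    def test_unknown_selector(self):
        lat, _ = _cable()
        with pytest.raises(ValueError):
            render_volume(lat, _grid(128), which="ligands")


class TestRenderProjection:
    def test_projection_conserves_mass(self):
        lat, _ = _cable()
        g = _grid(128)
        vol = render_volume(lat, g)
        img = render_projection(lat, g, "side")
        assert img.sum() == pytest.approx(
            vol.values.sum() * g.voxel_size, rel=1e-5
        )

    def test_projection_equals_volume_sum(self):
        lat, _ = _cable()
        g = _grid(128)
        vol = render_volume(lat, g)
        side = render_projection(lat, g, "side")
        top = render_projection(lat, g, "top")
        np.testing.assert_allclose(
            side, vol.values.sum(axis=0) * g.voxel_size, rtol=1e-5
        )
        np.testing.assert_allclose(
            top, vol.values.sum(axis=2) * g.voxel_size, rtol=1e-5
        )

    def test_side_view_bridge_peak_spacing(self):
        # peak-finding oracle: bridge humps recur every
        # bridge_period * subunit_diameter along the filament axis
        from scipy import ndimage, signal

        lat, spec = _cable(n_repeats=3)
        g = GridParams((96, 128, 256), 7.3)
        img = render_projection(lat, g, "side")
        col = ndimage.gaussian_filter1d(img.sum(axis=0), 3.0)
        peaks, _ = signal.find_peaks(
            col, prominence=0.3 * (col.max() - col.min())
        )
        expected_px = spec.bridge_period * spec.subunit_diameter * 10 / 7.3
        assert np.diff(peaks) == pytest.approx(expected_px, abs=1.0)

    def test_top_view_two_maxima_at_spacing(self):
        from septinsim.quant import interfilament_spacing

        lat, spec = _cable()
        g = _grid(128)
        img = render_projection(lat, g, "top")
        # top view: (z, y) image, filaments separated along axis 1
        got = interfilament_spacing(img, filament_axis=0,
                                    voxel_size=g.voxel_size)
        assert got == pytest.approx(spec.inter_filament_spacing, abs=0.4)

    def test_unknown_view(self):
        lat, _ = _cable()
        with pytest.raises(ValueError):
            render_projection(lat, _grid(128), "oblique")


class TestParticleMixture:
    def test_degenerate_fraction_all_octamer(self):
        ps = generate_particle_mixture(60, 1.0, snr=np.inf, seed=0)
        assert all(l is ParticleLabel.OCTAMER_CAPPED for l in ps.labels)

    def test_degenerate_fraction_all_hexamer(self):
        ps = generate_particle_mixture(60, 0.0, snr=np.inf, seed=0)
        assert all(l is ParticleLabel.HEXAMER for l in ps.labels)

    def test_binomial_sampling_oracle(self):
        # label fraction within 3 sqrt(p(1-p)/n) of p
        n, p = 1000, 0.9
        ps = generate_particle_mixture(n, p, snr=5.0, seed=11)
        frac = ps.label_fraction(ParticleLabel.OCTAMER_CAPPED)
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_seed_determinism(self):
        a = generate_particle_mixture(20, 0.5, snr=2.0, seed=5)
        b = generate_particle_mixture(20, 0.5, snr=2.0, seed=5)
        np.testing.assert_array_equal(a.images, b.images)
        assert a.labels == b.labels

    def test_seed_sensitivity(self):
        a = generate_particle_mixture(20, 0.5, snr=2.0, seed=5)
        b = generate_particle_mixture(20, 0.5, snr=2.0, seed=6)
        assert not np.array_equal(a.images, b.images)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            generate_particle_mixture(10, 1.5)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            generate_particle_mixture(0, 0.5)

    def test_labels_and_images_aligned(self):
        ps = generate_particle_mixture(25, 0.4, snr=np.inf, seed=3)
        assert len(ps.images) == len(ps.labels) == 25
        # octamer-capped particles carry more total mass (2 extra blobs)
        sums = ps.images.sum(axis=(1, 2))
        oct_mean = sums[
            [l is ParticleLabel.OCTAMER_CAPPED for l in ps.labels]
        ].mean()
        hex_mean = sums[
            [l is ParticleLabel.HEXAMER for l in ps.labels]
        ].mean()
        assert oct_mean > hex_mean


class TestLowPass:
    def test_constant_field_unchanged(self):
        arr = np.full((32, 32), 3.25)
        out = low_pass(arr, 10.0, voxel_size=1.0)
        np.testing.assert_allclose(out, arr, rtol=1e-6)

    def test_mean_preserved(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(48, 48, 48))
        out = low_pass(arr, 8.0, voxel_size=1.0)
        assert out.mean() == pytest.approx(arr.mean(), abs=1e-9)

    def test_white_noise_band_power(self):
        # radial power-spectrum oracle: power beyond the cutoff drops
        # at least 4x relative to the below-cutoff band
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(128, 128))
        res, voxel = 8.0, 1.0
        out = low_pass(arr, res, voxel_size=voxel)
        f_in = np.abs(np.fft.fftn(arr)) ** 2
        f_out = np.abs(np.fft.fftn(out)) ** 2
        ky = np.fft.fftfreq(128, voxel)[:, None]
        kx = np.fft.fftfreq(128, voxel)[None, :]
        k = np.sqrt(ky**2 + kx**2)
        kc = 1.0 / res
        below = k < 0.8 * kc
        above = k > 1.5 * kc
        atten_below = f_out[below].sum() / f_in[below].sum()
        atten_above = f_out[above].sum() / f_in[above].sum()
        assert atten_below >= 4 * atten_above

    def test_filtered_model_self_cc_is_one(self):
        from septinsim.quant import cross_correlation

        lat, _ = _cable()
        vol = render_volume(lat, _grid(128))
        lp = low_pass(vol, 45.0)
        assert cross_correlation(lp, lp) == pytest.approx(1.0)

    def test_sub_nyquist_raises(self):
        arr = np.zeros((32, 32))
        with pytest.raises(ValueError, match="Nyquist"):
            low_pass(arr, 1.5, voxel_size=1.0)

    def test_volume_carries_voxel_size(self):
        g = GridParams((32, 32, 32), 7.3)
        vol = DensityVolume(g, np.ones(g.shape))
        out = low_pass(vol, 45.0)
        assert isinstance(out, DensityVolume)
        assert out.grid == g


class TestBinImage:
    def test_factor4_pixel_size_bookkeeping(self):
        # 4x4 averaging of 1.825 Å pixels gives the working 7.3 Å pixel
        assert 1.825 * 4 == pytest.approx(7.3)
        img = np.arange(64, dtype=float).reshape(8, 8)
        out = bin_image(img, 4)
        assert out.shape == (2, 2)

    def test_constant_preserved(self):
        img = np.full((12, 8), 2.5)
        np.testing.assert_allclose(bin_image(img, 4), np.full((3, 2), 2.5))

    def test_mean_preserved_exactly(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(16, 24))
        assert bin_image(img, 4).mean() == pytest.approx(img.mean())

    def test_non_divisible_raises(self):
        with pytest.raises(ValueError, match="not divisible"):
            bin_image(np.zeros((10, 12)), 4)

    def test_factor_one_identity(self):
        img = np.random.default_rng(3).normal(size=(8, 8))
        np.testing.assert_array_equal(bin_image(img, 1), img)

    @given(
        factor=st.sampled_from([1, 2, 3, 4]),
        rows=st.integers(1, 6),
        cols=st.integers(1, 6),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_block_mean_property(self, factor, rows, cols, seed):
        img = np.random.default_rng(seed).normal(
            size=(rows * factor, cols * factor)
        )
        out = bin_image(img, factor)
        assert out.shape == (rows, cols)
        assert out.mean() == pytest.approx(img.mean())
        # oracle: explicit block loop
        expected = np.array([
            [img[i * factor:(i + 1) * factor,
                 j * factor:(j + 1) * factor].mean()
             for j in range(cols)]
            for i in range(rows)
        ])
        np.testing.assert_allclose(out, expected)
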