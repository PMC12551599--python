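"""Physics simulator: materials, spectra, phantom generation, artifact physics."""

import numpy as np
import pytest
from scipy import ndimage

from ldmar.geometry import Image2D
from ldmar.phantom import (
    AIR,
    BONE,
    METAL,
    SOFT,
    MaterialMap,
    PhantomSpec,
    Spectrum,
    attenuation_image,
    default_geometry,
    default_spectrum,
    effective_mono_energy,
    extract_artifact_map,
    make_dental_phantom,
    mu_of,
    overlay_artifact,
    simulate_polychromatic,
)
from ldmar.projector import fbp_reconstruct, forward_project


@pytest.fixture(scope="module")
def geo():
    return default_geometry()


class TestMaterialsAndSpectrum:
    def test_attenuation_non_increasing_and_ordered(self):
        e = np.linspace(20.0, 95.0, 40)
        curves = {lab: mu_of(lab, e) for lab in (SOFT, BONE, METAL)}
        for mu in curves.values():
            assert np.all(np.diff(mu) < 0) and np.all(mu > 0)
        assert np.all(curves[SOFT] < curves[BONE])
        assert np.all(curves[BONE] < curves[METAL])
        assert np.all(mu_of(AIR, e) == 0.0)

    def test_spectrum_normalized_and_validated(self):
        sp = default_spectrum()
        assert np.isclose(sp.weights.sum(), 1.0)
        assert np.all(np.diff(sp.energies) > 0)
        with pytest.raises(ValueError):
            Spectrum(np.array([30.0, 20.0]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            Spectrum(np.array([20.0, 30.0]), np.array([0.0, 0.0]))

    def test_effective_mono_energy_inside_spectrum_range(self):
        sp = default_spectrum()
        e = effective_mono_energy(sp)
        assert sp.energies[0] < e < sp.energies[-1]


class TestPhantomGeneration:
    def test_deterministic_for_fixed_seed(self):
        spec = PhantomSpec()
        a = make_dental_phantom(spec, 42)
        b = make_dental_phantom(spec, 42)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.soft_texture, b.soft_texture)

    def test_no_metal_spec_gives_empty_mask(self):
        mat = make_dental_phantom(PhantomSpec(n_metal=0), 7)
        assert not mat.metal_mask().any()

    def test_two_cylinders_give_two_components(self):
        mat = make_dental_phantom(PhantomSpec(n_metal=2, metal_shape="cylinder"), 3)
        _, n = ndimage.label(mat.metal_mask())
        assert n == 2

    def test_without_metal_replaces_metal_with_bone(self):
        mat = make_dental_phantom(PhantomSpec(), 5)
        clean = mat.without_metal()
        assert not clean.metal_mask().any()
        assert np.all(clean.labels[mat.metal_mask()] == BONE)

    def test_overgrown_inserts_raise(self):
        with pytest.raises(ValueError):
            make_dental_phantom(PhantomSpec(arch_radius=34.0, tooth_radius=6.0), 0)
        with pytest.raises(ValueError):
            make_dental_phantom(PhantomSpec(metal_radius=5.0), 0)


class TestPolychromaticSimulation:
    def test_single_bin_no_noise_collapses_to_linear_projection(self, geo):
        mat = make_dental_phantom(PhantomSpec(texture_amplitude=0.0), 1)
        sino = simulate_polychromatic(mat, Spectrum.monoenergetic(50.0), geo, None)
        ref = forward_project(attenuation_image(mat, 50.0), geo)
        assert np.abs(sino.values - ref.values).max() < 1e-10

    def test_beam_hardening_produces_cupping(self, geo):
        n, ps = 64, 1.25
        c = (n - 1) / 2.0
        ax = (np.arange(n) - c) * ps
        x = ax[None, :] * np.ones((n, 1))
        y = ax[:, None] * np.ones((1, n))
        lab = np.where(x**2 + y**2 <= 30.0**2, SOFT, AIR).astype(np.int8)
        sp = Spectrum(np.array([30.0, 80.0]), np.array([0.5, 0.5]))
        sino = simulate_polychromatic(MaterialMap(lab, ps), sp, geo, None)
        rec = fbp_reconstruct(sino, Image2D(np.zeros((n, n)), ps), "hann")
        center = rec.values[x**2 + y**2 <= 8.0**2].mean()
        edge = rec.values[(x**2 + y**2 <= 28.0**2) & (x**2 + y**2 >= 22.0**2)].mean()
        assert center < edge

    def test_noise_variance_grows_with_line_integral(self, geo):
        """Variance of -ln(counts) increases with attenuation path length."""
        mat = make_dental_phantom(PhantomSpec(n_metal=0, texture_amplitude=0.0), 1)
        clean = simulate_polychromatic(mat, Spectrum.monoenergetic(50.0), geo, None)
        reps = np.stack(
            [
                simulate_polychromatic(
                    mat, Spectrum.monoenergetic(50.0), geo, 2e4, rng_seed=100 + i
                ).values
                for i in range(12)
            ]
        )
        var = reps.var(axis=0)
        p = clean.values
        pos = p[p > 0.05]
        qs = np.quantile(pos, [0.15, 0.35, 0.55, 0.75, 0.95])
        bins = [(qs[0], qs[1]), (qs[2], qs[3]), (qs[3], qs[4])]
        means = [var[(p > lo) & (p <= hi)].mean() for lo, hi in bins]
        assert means[0] < means[1] < means[2]

    def test_zero_photons_rejected(self, geo):
        mat = make_dental_phantom(PhantomSpec(), 1)
        with pytest.raises(ValueError):
            simulate_polychromatic(mat, default_spectrum(), geo, 0.0)


class TestPairedData:
    def test_dark_band_between_metal_rods(self, holdout_pairs):
        """Mean attenuation between the rods drops in the corrupted image."""
        for pair in holdout_pairs:
            diff = pair.corrupted.values - pair.clean.values
            lbl, n = ndimage.label(pair.metal_mask)
            cents = np.array(ndimage.center_of_mass(pair.metal_mask, lbl, range(1, n + 1)))
            t = np.linspace(0.25, 0.75, 15)
            pts = cents[0][None, :] * (1 - t[:, None]) + cents[1][None, :] * t[:, None]
            band = ndimage.map_coordinates(diff, pts.T, order=1).mean()
            assert band < 0.0

    def test_metal_free_pair_has_lower_residual(self, geo, spectrum):
        """Disabling metal physics shrinks the clean-vs-simulated gap."""
        from ldmar.phantom import make_phantom_pair

        with_metal = make_phantom_pair(PhantomSpec(), geo, spectrum, 11)
        no_metal = make_phantom_pair(PhantomSpec(n_metal=0), geo, spectrum, 11)
        def nm_rmse(p):
            m = ~p.metal_mask
            return np.sqrt(np.mean((p.corrupted.values[m] - p.clean.values[m]) ** 2))
        assert nm_rmse(no_metal) < nm_rmse(with_metal)

    def test_artifact_map_identities(self, holdout_pairs):
        pair = holdout_pairs[0]
        amap = extract_artifact_map(pair.corrupted, pair.clean)
        assert np.allclose(pair.clean.values + amap.values, pair.corrupted.values)
        zero = extract_artifact_map(pair.clean, pair.clean)
        assert np.all(zero.values == 0.0)
        with pytest.raises(ValueError):
            extract_artifact_map(pair.clean, Image2D(np.zeros((8, 8)), 1.0))

    def test_artifact_map_covers_metal_support(self, holdout_pairs):
        pair = holdout_pairs[0]
        amap = extract_artifact_map(pair.corrupted, pair.clean)
        assert np.all(np.abs(amap.values[pair.metal_mask]) > 1e-4)


class TestOverlay:
    def test_zero_map_and_zero_rotation(self, holdout_pairs, rng):
        pair = holdout_pairs[0]
        target = pair.clean
        zero = Image2D(np.zeros_like(target.values), target.pixel_size)
        out, _ = overlay_artifact(zero, target, pair.metal_mask, rotation_deg=123.0)
        assert np.allclose(out.values, target.values)
        amap = extract_artifact_map(pair.corrupted, pair.clean)
        out0, mask0 = overlay_artifact(amap, target, pair.metal_mask, rotation_deg=0.0)
        assert np.allclose(out0.values, target.values + amap.values)
        assert np.array_equal(mask0, pair.metal_mask)

    def test_full_turn_matches_no_rotation(self, holdout_pairs):
        pair = holdout_pairs[0]
        amap = extract_artifact_map(pair.corrupted, pair.clean)
        out0, _ = overlay_artifact(amap, pair.clean, pair.metal_mask, rotation_deg=0.0)
        out360, _ = overlay_artifact(amap, pair.clean, pair.metal_mask, rotation_deg=360.0)
        assert np.abs(out360.values - out0.values).max() < 1e-6

    def test_seeded_rotation_is_deterministic(self, holdout_pairs):
        pair = holdout_pairs[0]
        amap = extract_artifact_map(pair.corrupted, pair.clean)
        a, ma = overlay_artifact(amap, pair.clean, pair.metal_mask, rng_seed=5)
        b, mb = overlay_artifact(amap, pair.clean, pair.metal_mask, rng_seed=5)
        assert np.array_equal(a.values, b.values) and np.array_equal(ma, mb)
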