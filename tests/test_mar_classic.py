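"""Classical MAR: metal trace, LIMAR, threshold prior, NMAR, reinsertion."""

import numpy as np
import pytest

from ldmar.geometry import FanBeamGeometry, Image2D, Sinogram
from ldmar.mar import (
    PriorImage,
    TraceMask,
    build_threshold_prior,
    compute_metal_trace,
    inpaint_trace,
    limar,
    nmar_correct,
    reinsert_metal,
)
from ldmar.projector import forward_project


@pytest.fixture(scope="module")
def geo():
    return FanBeamGeometry.make(500.0, 1000.0, 64, 2.5, 24)


def brute_force_trace(mask, pixel_size, geo, n_samples=4000):
    """Independent oracle: dense sampling along each ray, point-in-pixel test."""
    n = mask.shape[0]
    c = (n - 1) / 2.0
    out = np.zeros((geo.n_views, geo.n_detectors), dtype=bool)
    u = geo.detector_coords()
    half = n * pixel_size * np.sqrt(2) / 2
    for v, beta in enumerate(geo.angles):
        src = geo.source_to_isocenter * np.array([np.cos(beta), np.sin(beta)])
        e_b = np.array([np.cos(beta), np.sin(beta)])
        e_u = np.array([-np.sin(beta), np.cos(beta)])
        for k in range(geo.n_detectors):
            det = src - geo.source_to_detector * e_b + u[k] * e_u
            d = det - src
            d = d / np.linalg.norm(d)
            t = np.linspace(geo.source_to_isocenter - half, geo.source_to_isocenter + half, n_samples)
            pts = src[None, :] + t[:, None] * d[None, :]
            col = np.round(pts[:, 0] / pixel_size + c).astype(int)
            row = np.round(pts[:, 1] / pixel_size + c).astype(int)
            ok = (row >= 0) & (row < n) & (col >= 0) & (col < n)
            out[v, k] = mask[row[ok], col[ok]].any()
    return out


class TestMetalTrace:
    def test_empty_mask_gives_empty_trace(self, geo):
        trace = compute_metal_trace(np.zeros((32, 32), dtype=bool), geo, 1.25, margin=0)
        assert not trace.values.any()

    def test_single_pixel_matches_brute_force_oracle(self, geo):
        mask = np.zeros((32, 32), dtype=bool)
        mask[16, 16] = True  # near-center pixel
        trace = compute_metal_trace(mask, geo, 1.25, margin=0)
        oracle = brute_force_trace(mask, 1.25, geo)
        assert np.array_equal(trace.values, oracle)
        # the central pixel is seen at every view
        assert np.all(trace.values.any(axis=1))

    def test_margin_dilation_is_monotone(self, geo):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:13, 18:21] = True
        t0 = compute_metal_trace(mask, geo, 1.25, margin=0)
        t2 = compute_metal_trace(mask, geo, 1.25, margin=2)
        assert np.all(t0.values <= t2.values)
        assert t2.values.sum() > t0.values.sum()


class TestLimar:
    def test_empty_trace_is_identity(self, geo, rng):
        s = Sinogram(rng.normal(size=(geo.n_views, geo.n_detectors)), geo)
        out = limar(s, TraceMask(np.zeros_like(s.values, dtype=bool)))
        assert np.array_equal(out.values, s.values)

    def test_interior_run_is_linear_interpolation(self, geo):
        vals = np.zeros((geo.n_views, geo.n_detectors))
        vals[0, 10:14] = [4.0, 99.0, 99.0, 8.0]
        tr = np.zeros_like(vals, dtype=bool)
        tr[0, 11:13] = True
        out = limar(Sinogram(vals, geo), TraceMask(tr))
        assert np.allclose(out.values[0, 10:14], [4.0, 16.0 / 3.0, 20.0 / 3.0, 8.0])

    def test_edge_run_extends_single_neighbour(self, geo):
        vals = np.zeros((geo.n_views, geo.n_detectors))
        vals[0, :3] = 99.0
        vals[0, 3] = 7.0
        tr = np.zeros_like(vals, dtype=bool)
        tr[0, :3] = True
        out = limar(Sinogram(vals, geo), TraceMask(tr))
        assert np.allclose(out.values[0, :4], 7.0)

    def test_fully_traced_view_falls_back_with_warning(self, geo):
        vals = np.tile(np.arange(geo.n_detectors, dtype=float), (geo.n_views, 1))
        vals[3] = -50.0
        tr = np.zeros_like(vals, dtype=bool)
        tr[3, :] = True
        with pytest.warns(UserWarning, match="fully traced"):
            out = limar(Sinogram(vals, geo), TraceMask(tr))
        assert np.allclose(out.values[3], out.values[2])

    def test_off_trace_entries_bit_identical(self, geo, rng):
        s = Sinogram(rng.normal(size=(geo.n_views, geo.n_detectors)), geo)
        tr = rng.random(s.values.shape) < 0.2
        out = limar(s, TraceMask(tr))
        assert np.array_equal(out.values[~tr], s.values[~tr])


class TestThresholdPrior:
    def test_piecewise_assignment(self):
        img = Image2D(np.array([[0.0, 0.02], [0.05, 0.002]]), 1.0)
        prior = build_threshold_prior(img, t_soft=0.01, t_bone=0.035, soft_value=0.03)
        assert np.allclose(prior.image.values, [[0.0, 0.03], [0.05, 0.0]])

    def test_uniform_soft_maps_to_constant(self):
        img = Image2D(np.full((8, 8), 0.02), 1.0)
        prior = build_threshold_prior(img, 0.01, 0.035, 0.027)
        assert np.allclose(prior.image.values, 0.027)

    def test_air_maps_to_zero(self):
        img = Image2D(np.zeros((8, 8)), 1.0)
        assert np.all(build_threshold_prior(img).image.values == 0.0)

    def test_inverted_thresholds_raise(self):
        with pytest.raises(ValueError):
            build_threshold_prior(Image2D(np.zeros((4, 4)), 1.0), t_soft=0.05, t_bone=0.01)


class TestNmar:
    @pytest.mark.parametrize("mode", ["harmonic", "linear"])
    def test_empty_trace_identity(self, geo, rng, mode):
        s = Sinogram(np.abs(rng.normal(size=(geo.n_views, geo.n_detectors))) + 0.1, geo)
        prior = PriorImage(Image2D(np.full((32, 32), 0.02), 1.25))
        out = nmar_correct(s, prior, TraceMask(np.zeros_like(s.values, dtype=bool)), inpaint_mode=mode)
        assert np.array_equal(out.values, s.values)

    def test_oracle_prior_gives_global_identity(self, geo):
        """FP(prior) == sino: normalization flattens to 1, inpainting changes nothing."""
        n = 32
        c = (n - 1) / 2.0
        ax = (np.arange(n) - c) * 1.25
        x = ax[None, :] * np.ones((n, 1))
        y = ax[:, None] * np.ones((1, n))
        img = Image2D(((x**2 + y**2) <= 15.0**2) * 0.02 + ((x - 5) ** 2 + y**2 <= 4.0**2) * 0.03, 1.25)
        s = forward_project(img, geo)
        tr = np.zeros_like(s.values, dtype=bool)
        tr[:, 28:34] = True
        out = nmar_correct(s, PriorImage(img, "oracle_clean"), TraceMask(tr))
        assert np.abs(out.values - s.values).max() < 1e-9

    def test_off_trace_preservation_randomized(self, geo, rng):
        prior_img = Image2D(np.abs(rng.normal(0.02, 0.005, size=(32, 32))), 1.25)
        for trial in range(5):
            s = Sinogram(np.abs(rng.normal(size=(geo.n_views, geo.n_detectors))) + 0.05, geo)
            tr = rng.random(s.values.shape) < 0.15
            out = nmar_correct(s, PriorImage(prior_img), TraceMask(tr))
            assert np.array_equal(out.values[~tr], s.values[~tr])

    def test_nonpositive_eps_rejected(self, geo, rng):
        s = Sinogram(np.ones((geo.n_views, geo.n_detectors)), geo)
        tr = np.zeros_like(s.values, dtype=bool)
        tr[0, 5] = True
        with pytest.raises(ValueError):
            nmar_correct(s, PriorImage(Image2D(np.full((32, 32), 0.02), 1.25)), TraceMask(tr), eps=0.0)

    def test_harmonic_inpaint_preserves_constant(self):
        grid = np.full((20, 30), 3.7)
        tr = np.zeros_like(grid, dtype=bool)
        tr[5:12, 8:20] = True
        filled = inpaint_trace(grid, tr, mode="harmonic")
        assert np.abs(filled - 3.7).max() < 1e-9


class TestReinsertMetal:
    def test_identities(self, rng):
        a = Image2D(rng.normal(size=(16, 16)), 1.0)
        b = Image2D(rng.normal(size=(16, 16)), 1.0)
        empty = np.zeros((16, 16), dtype=bool)
        full = np.ones((16, 16), dtype=bool)
        assert np.array_equal(reinsert_metal(a, empty, b).values, a.values)
        assert np.array_equal(reinsert_metal(a, full, b).values, b.values)
        m = rng.random((16, 16)) < 0.3
        out = reinsert_metal(a, m, b)
        assert np.array_equal(out.values[m], b.values[m])
        assert np.array_equal(out.values[~m], a.values[~m])
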