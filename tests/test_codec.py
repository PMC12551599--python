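"""VQ codec: shape contracts, loss algebra, stop-gradient routing, codebook upkeep."""

import numpy as np
import pytest

from ldmar.codec import (
    Codebook,
    VQCodec,
    codec_loss,
    quantize,
    refresh_dead_codes,
    vq_grads,
    window_denormalize,
    window_normalize,
)
from ldmar.geometry import Image2D
from ldmar.perceptual import PerceptualExtractor


@pytest.fixture(scope="module")
def codec():
    return VQCodec(k=16, d=3, channels=(4, 8), seed=7)


class TestShapeContracts:
    def test_roundtrip_preserves_shape(self, codec, rng):
        img = Image2D(rng.normal(0.02, 0.01, size=(32, 32)), 1.0)
        code = codec.encode(img)
        assert code.grid.shape == (3, 8, 8)
        assert code.indices.shape == (8, 8)
        assert code.quantized.shape == (3, 8, 8)
        out = codec.decode(code, img.pixel_size)
        assert out.values.shape == img.values.shape

    def test_quantized_entries_come_from_codebook(self, codec, rng):
        code = codec.encode(Image2D(rng.normal(0.02, 0.01, size=(32, 32)), 1.0))
        flat = code.quantized.reshape(3, -1).T
        idx = code.indices.ravel()
        assert np.array_equal(flat, codec.codebook.vectors[idx])

    def test_non_divisible_size_suggests_padding(self, codec):
        with pytest.raises(ValueError, match="pad to 36"):
            codec.encode(Image2D(np.zeros((34, 34)), 1.0))

    def test_quantize_is_idempotent(self, codec, rng):
        ze = rng.normal(size=(3, 8, 8))
        idx1, zq = quantize(ze, codec.codebook)
        idx2, zq2 = quantize(zq, codec.codebook)
        assert np.array_equal(idx1, idx2)
        assert np.array_equal(zq, zq2)

    def test_window_roundtrip(self, rng):
        v = rng.uniform(-0.02, 0.10, size=(16, 16))
        assert np.allclose(window_denormalize(window_normalize(v)), v)


class TestLossAlgebra:
    def test_zero_loss_when_everything_matches(self, rng):
        f = rng.normal(size=(16, 16))
        z = rng.normal(size=(2, 4, 4))
        parts = codec_loss(f, f.copy(), z, z.copy(), feat=PerceptualExtractor(seed=1))
        assert parts.recon == 0.0
        assert parts.codebook_term == 0.0
        assert parts.commit_term == 0.0
        assert parts.perceptual == 0.0
        assert parts.total == 0.0

    def test_vq_terms_sum_to_one_and_a_quarter_v_squared(self, rng):
        """Stop-gradient changes derivatives, never values: cb + commit = 1.25 |v|^2."""
        ze = rng.normal(size=(2, 4, 4))
        v = rng.normal(size=(2, 4, 4))
        parts = codec_loss(np.zeros((16, 16)), np.zeros((16, 16)), ze, ze - v, beta=0.25)
        assert np.isclose(parts.codebook_term + parts.commit_term, 1.25 * np.sum(v**2))

    def test_total_is_the_weighted_sum_of_parts(self, rng):
        f = rng.normal(size=(16, 16))
        f0 = rng.normal(size=(16, 16))
        ze = rng.normal(size=(2, 4, 4))
        zq = rng.normal(size=(2, 4, 4))
        parts = codec_loss(f, f0, ze, zq, beta=0.5, lambda_p=0.01, feat=PerceptualExtractor(seed=2))
        assert np.isclose(
            parts.total,
            parts.recon + parts.codebook_term + parts.commit_term + 0.01 * parts.perceptual,
        )

    def test_negative_weights_rejected(self, rng):
        z = rng.normal(size=(2, 2, 2))
        with pytest.raises(ValueError):
            codec_loss(np.zeros((8, 8)), np.zeros((8, 8)), z, z, beta=-1.0)

    def test_perceptual_zero_iff_identical_for_any_extractor(self, rng):
        a = rng.normal(size=(1, 1, 16, 16))
        for seed in (1, 2, 3):
            feat = PerceptualExtractor(seed=seed)
            assert feat.distance(a, a.copy()) == 0.0
            assert feat.distance(a, a + 0.1) > 0.0


class TestStopGradientRouting:
    """Finite differences on a 2x2 latent toy, freezing the sg operand."""

    def test_encoder_gradient_is_commitment_only(self, rng):
        ze = rng.normal(size=(2, 2, 2))
        zq = rng.normal(size=(2, 2, 2))
        beta = 0.25
        g_enc, _ = vq_grads(ze, zq, beta)
        eps = 1e-6
        fd = np.zeros_like(ze)
        for idx in np.ndindex(ze.shape):
            zp = ze.copy(); zp[idx] += eps
            zm = ze.copy(); zm[idx] -= eps
            # sg[z_e] frozen at the unperturbed value: the codebook term
            # contributes nothing to the encoder derivative
            lp = np.sum((ze - zq) ** 2) + beta * np.sum((zp - zq) ** 2)
            lm = np.sum((ze - zq) ** 2) + beta * np.sum((zm - zq) ** 2)
            fd[idx] = (lp - lm) / (2 * eps)
        assert np.allclose(g_enc, fd, atol=1e-6)

    def test_codebook_gradient_is_codebook_term_only(self, rng):
        ze = rng.normal(size=(2, 2, 2))
        zq = rng.normal(size=(2, 2, 2))
        beta = 0.25
        _, g_codes = vq_grads(ze, zq, beta)
        eps = 1e-6
        fd = np.zeros_like(zq)
        for idx in np.ndindex(zq.shape):
            qp = zq.copy(); qp[idx] += eps
            qm = zq.copy(); qm[idx] -= eps
            # sg[z_q] frozen: the commitment term contributes nothing
            lp = np.sum((ze - qp) ** 2) + beta * np.sum((ze - zq) ** 2)
            lm = np.sum((ze - qm) ** 2) + beta * np.sum((ze - zq) ** 2)
            fd[idx] = (lp - lm) / (2 * eps)
        assert np.allclose(g_codes, fd, atol=1e-6)


class TestDeadCodeRefresh:
    def test_live_codebook_unchanged(self, rng):
        book = Codebook(rng.normal(size=(8, 3)), usage=np.full(8, 10.0))
        out = refresh_dead_codes(book, rng.normal(size=(32, 3)), threshold=1.0)
        assert np.array_equal(out.vectors, book.vectors)

    def test_dead_code_moves_into_feature_cluster(self, rng):
        vectors = rng.normal(size=(8, 3))
        vectors[5] = 100.0  # dead and far away
        usage = np.full(8, 10.0)
        usage[5] = 0.0
        book = Codebook(vectors, usage)
        feats = rng.normal(loc=(-5.0, 3.0, 0.0), size=(64, 3))
        before = np.min(np.linalg.norm(feats - vectors[5], axis=1))
        out = refresh_dead_codes(book, feats, threshold=1.0, rng_seed=0)
        after = np.min(np.linalg.norm(feats - out.vectors[5], axis=1))
        assert after < before

    def test_refresh_is_deterministic(self, rng):
        vectors = rng.normal(size=(8, 3))
        usage = np.zeros(8)
        feats = rng.normal(size=(64, 3))
        a = refresh_dead_codes(Codebook(vectors.copy(), usage.copy()), feats, rng_seed=3)
        b = refresh_dead_codes(Codebook(vectors.copy(), usage.copy()), feats, rng_seed=3)
        assert np.array_equal(a.vectors, b.vectors)

    def test_empty_buffer_rejected(self, rng):
        book = Codebook(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError):
            refresh_dead_codes(book, np.empty((0, 2)))
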