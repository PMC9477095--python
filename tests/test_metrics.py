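"""Closed-form metric oracles and the FSIM pipeline properties."""

import math

import numpy as np
import pytest

from modalgan.image_io import ImageSlice
from modalgan.metrics import (
    FSIMConstants,
    evaluate_pairs,
    fsim,
    fsim_from_maps,
    gradient_magnitude,
    mse,
    phase_congruency,
    psnr,
    ssim,
)


def _phantom_slice(seed=3, size=64):
    from conftest import toy_phantom_config

    from modalgan import phantom as ph

    cfg = toy_phantom_config(seed=seed, image_size=size)
    m = ph.generate_label_map(cfg, "sub-000", 2)
    return ph.render_modality(m, cfg.modalities[0], 11)


class TestMseAndPsnr:
    def test_identity(self, rng):
        x = ImageSlice(rng.integers(0, 256, (16, 16)).astype(np.uint8))
        assert mse(x, x) == 0.0
        assert psnr(x, x) == math.inf

    def test_constant_offset_closed_form(self):
        a = ImageSlice(np.full((8, 8), 100, dtype=np.uint8))
        b = ImageSlice(np.full((8, 8), 110, dtype=np.uint8))
        assert mse(a, b) == pytest.approx(100.0)
        assert psnr(a, b) == pytest.approx(10 * math.log10(65025 / 100), abs=1e-9)

    def test_symmetry(self, rng):
        a = ImageSlice(rng.integers(0, 256, (8, 8)).astype(np.uint8))
        b = ImageSlice(rng.integers(0, 256, (8, 8)).astype(np.uint8))
        assert mse(a, b) == mse(b, a)
        assert psnr(a, b) == psnr(b, a)

    def test_size_mismatch(self):
        with pytest.raises(ValueError, match="size"):
            mse(ImageSlice(np.zeros((4, 4), np.uint8)), ImageSlice(np.zeros((5, 5), np.uint8)))


class TestSsim:
    def test_self_similarity_is_one(self):
        x = _phantom_slice()
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, rng):
        a = _phantom_slice(seed=1)
        b = _phantom_slice(seed=2)
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_inverted_structure_scores_negative(self, rng):
        x = ImageSlice(rng.integers(0, 256, (64, 64)).astype(np.uint8))
        inv = ImageSlice((255 - x.pixels).astype(np.uint8))
        assert ssim(x, inv) < 0.5

    def test_window_larger_than_image_rejected(self):
        tiny = ImageSlice(np.zeros((8, 8), np.uint8))
        with pytest.raises(ValueError, match="window"):
            ssim(tiny, tiny)


class TestPhaseCongruency:
    def test_edges_beat_flat_regions(self):
        step = np.zeros((64, 64), np.uint8)
        step[:, 32:] = 200
        pc = phase_congruency(ImageSlice(step))
        assert pc[:, 31:33].mean() > 2 * pc[:, 5:15].mean()

    def test_constant_image_is_featureless(self):
        pc = phase_congruency(ImageSlice(np.full((64, 64), 77, np.uint8)))
        assert pc.max() <= 0.05

    def test_affine_intensity_invariance(self):
        x = _phantom_slice().pixels.astype(np.float64)
        pc = phase_congruency(x)
        pc2 = phase_congruency(0.5 * x + 20.0)
        assert np.abs(pc - pc2).mean() / pc.mean() < 0.01

    def test_values_in_unit_interval(self):
        pc = phase_congruency(_phantom_slice())
        assert pc.min() >= 0.0 and pc.max() <= 1.0


class TestGradientMagnitude:
    def test_zero_on_constant(self):
        gm = gradient_magnitude(ImageSlice(np.full((32, 32), 50, np.uint8)))
        assert np.all(gm == 0.0)

    def test_step_response_proportional_to_height(self):
        responses = []
        for h in (50, 100, 200):
            step = np.zeros((32, 32), np.uint8)
            step[:, 16:] = h
            responses.append(gradient_magnitude(ImageSlice(step)).max())
        assert responses[1] == pytest.approx(2 * responses[0])
        assert responses[2] == pytest.approx(4 * responses[0])

    def test_nonnegative(self, rng):
        gm = gradient_magnitude(ImageSlice(rng.integers(0, 256, (16, 16)).astype(np.uint8)))
        assert np.all(gm >= 0.0)


class TestFsim:
    def test_self_similarity_is_one(self):
        x = _phantom_slice()
        assert fsim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_map_injection_oracle(self):
        """Uniform maps with G1 = 3, G2 = 4, T2 = 160: S_G = 184/185."""
        shape = (5, 5)
        val = fsim_from_maps(
            np.full(shape, 0.6), np.full(shape, 0.6),
            np.full(shape, 3.0), np.full(shape, 4.0),
            FSIMConstants(),
        )
        assert val == pytest.approx(184.0 / 185.0, abs=1e-9)

    def test_map_injection_exposes_similarity_maps(self):
        val, maps = fsim_from_maps(
            np.full((2, 2), 0.3), np.full((2, 2), 0.7),
            np.full((2, 2), 5.0), np.full((2, 2), 5.0),
            return_maps=True,
        )
        assert np.all(maps.PCm == 0.7)
        assert np.all(maps.S_G == 1.0)
        assert np.all((maps.S_PC > 0) & (maps.S_PC <= 1))
        assert val == pytest.approx(maps.S_L.mean())

    def test_symmetry(self):
        a, b = _phantom_slice(seed=1), _phantom_slice(seed=2)
        assert fsim(a, b) == pytest.approx(fsim(b, a), abs=1e-12)

    def test_mirror_invariance(self):
        a, b = _phantom_slice(seed=1), _phantom_slice(seed=2)
        am = ImageSlice(a.pixels[:, ::-1].copy())
        bm = ImageSlice(b.pixels[:, ::-1].copy())
        assert fsim(am, bm) == pytest.approx(fsim(a, b), abs=1e-3)

    def test_large_images_downsampled(self):
        big = np.kron(_phantom_slice(size=64).pixels, np.ones((8, 8), dtype=np.uint8))
        sl = ImageSlice(big)  # 512 px -> downsample factor 2
        assert fsim(sl, sl) == pytest.approx(1.0)


def test_monotone_degradation_under_noise():
    """SSIM and FSIM fall monotonically as i.i.d. noise grows."""
    ref = _phantom_slice()
    noise_rng = np.random.default_rng(99)
    ssims, fsims = [], []
    for sigma in (0, 5, 10, 20, 40):
        noisy = np.clip(
            ref.pixels.astype(float) + noise_rng.normal(0, sigma, ref.pixels.shape), 0, 255
        ).astype(np.uint8)
        ssims.append(ssim(ref, ImageSlice(noisy)))
        fsims.append(fsim(ref, ImageSlice(noisy)))
    assert all(a >= b for a, b in zip(ssims, ssims[1:]))
    assert all(a >= b for a, b in zip(fsims, fsims[1:]))


class TestEvaluatePairs:
    def test_identical_pairs_summary(self):
        x = _phantom_slice()
        rep = evaluate_pairs([(x, x)] * 3)
        assert rep.mean["mse"] == 0.0
        assert rep.mean["psnr"] == math.inf
        assert rep.mean["ssim"] == pytest.approx(1.0)
        assert rep.mean["fsim"] == pytest.approx(1.0)
        assert all(rep.sd[m] == 0.0 for m in ("mse", "psnr", "ssim", "fsim"))

    def test_single_pair_flagged(self):
        x = _phantom_slice()
        rep = evaluate_pairs([(x, x)])
        assert rep.single_pair and rep.sd["ssim"] == 0.0

    def test_mean_equals_external_recomputation(self):
        imgs = [_phantom_slice(seed=s) for s in (1, 2, 3, 4)]
        pairs = [(imgs[0], imgs[1]), (imgs[1], imgs[2]), (imgs[2], imgs[3])]
        rep = evaluate_pairs(pairs)
        assert rep.mean["ssim"] == pytest.approx(
            np.mean([ssim(a, b) for a, b in pairs])
        )
        assert rep.mean["mse"] == pytest.approx(np.mean([mse(a, b) for a, b in pairs]))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            evaluate_pairs([])
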