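"""Hand-computed loss oracles and gradient-flow isolation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from modalgan import losses as L
from modalgan.networks import AuxiliaryNet, MaskVector, NetworkConfig, ReconstructionNet


class TestSelfSupervision:
    def test_identical_stacks_give_zero(self, rng):
        f = [rng.standard_normal((2, 4, 4)) for _ in range(3)]
        assert L.self_supervision_loss(f, [x.copy() for x in f]) == 0.0

    def test_single_element_oracle(self):
        # one layer, single feature valued 5 vs 2: (5 - 2)^2 = 9
        assert L.self_supervision_loss(
            [np.array([[[5.0]]])], [np.array([[[2.0]]])]
        ) == pytest.approx(9.0)

    def test_even_under_joint_sign_flip(self, rng):
        a = [rng.standard_normal((1, 3, 3)) for _ in range(2)]
        b = [rng.standard_normal((1, 3, 3)) for _ in range(2)]
        assert L.self_supervision_loss(a, b) == pytest.approx(
            L.self_supervision_loss([-x for x in a], [-x for x in b])
        )

    def test_layer_permutation_invariance(self, rng):
        a = [rng.standard_normal((1, 3, 3)) for _ in range(3)]
        b = [rng.standard_normal((1, 3, 3)) for _ in range(3)]
        assert L.self_supervision_loss(a, b) == pytest.approx(
            L.self_supervision_loss(a[::-1], b[::-1])
        )

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="congruent"):
            L.self_supervision_loss(
                [np.zeros((1, 2, 2))], [np.zeros((1, 3, 3))]
            )

    @given(
        hnp.arrays(np.float64, (2, 3, 3), elements=st.floats(-10, 10)),
        hnp.arrays(np.float64, (2, 3, 3), elements=st.floats(-10, 10)),
    )
    @settings(deadline=None, max_examples=25)
    def test_nonnegative_and_zero_iff_equal(self, a, b):
        val = L.self_supervision_loss([a], [b])
        assert val >= 0.0
        if np.array_equal(a, b):
            assert val == 0.0
        if val == 0.0:  # converse holds up to squared-difference underflow
            assert np.allclose(a, b, atol=1e-150)


class TestDiscriminatorLoss:
    W = L.LossWeights()

    def test_uniform_half_scores_oracle(self):
        s = np.full((3, 3), 0.5)
        assert L.discriminator_loss(s, s, s, self.W) == pytest.approx(
            2 * math.log(0.5), abs=1e-12
        )

    def test_supremum_at_perfect_discrimination(self):
        near1 = np.full((2, 2), 1 - 1e-9)
        near0 = np.full((2, 2), 1e-9)
        val = L.discriminator_loss(near1, near0, near0, self.W)
        assert val == pytest.approx(0.0, abs=1e-4)
        assert val <= 0.0

    def test_lambda1_near_one_reduces_to_two_term_gan(self, rng):
        s_real = rng.uniform(0.1, 0.9, (3, 3))
        s_fr = rng.uniform(0.1, 0.9, (3, 3))
        s_fp = rng.uniform(0.1, 0.9, (3, 3))
        w = L.LossWeights(lambda1=1 - 1e-12)
        two_term = np.mean(np.log(s_real)) + np.mean(np.log(1 - s_fr))
        assert L.discriminator_loss(s_real, s_fr, s_fp, w) == pytest.approx(two_term)

    def test_bounded_above_by_zero(self, rng):
        for _ in range(10):
            args = [rng.uniform(0.01, 0.99, (2, 2)) for _ in range(3)]
            assert L.discriminator_loss(*args, self.W) < 0.0

    def test_out_of_domain_scores_rejected(self):
        ok = np.full((2, 2), 0.5)
        with pytest.raises(ValueError, match="scores"):
            L.discriminator_loss(np.full((2, 2), 1.0), ok, ok, self.W)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            L.LossWeights(lambda1=1.5)
        with pytest.raises(ValueError):
            L.LossWeights(lambda2=-1.0)


class TestPixelLoss:
    def test_identity_gives_zero(self, rng):
        x = rng.standard_normal((4, 4))
        assert L.generator_pixel_loss(x, x) == 0.0

    def test_two_pixel_oracle(self):
        assert L.generator_pixel_loss(
            np.array([[0.0, 1.0]]), np.array([[1.0, 0.0]])
        ) == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        a, b = rng.standard_normal((1, 16)), rng.standard_normal((1, 16))
        perm = rng.permutation(16)
        assert L.generator_pixel_loss(a[:, perm], b[:, perm]) == pytest.approx(
            L.generator_pixel_loss(a, b)
        )

    def test_sum_additivity_of_generator_parts(self, rng):
        """The combined generator loss is exactly the R part plus the P part."""
        y = rng.standard_normal((4, 4))
        rep = L.LossReport(
            l_g_r=L.generator_pixel_loss(rng.standard_normal((4, 4)), y),
            l_g_p=L.generator_pixel_loss(rng.standard_normal((4, 4)), y),
        )
        assert rep.l_g == rep.l_g_r + rep.l_g_p


class TestTotalLoss:
    def test_arithmetic_oracle(self):
        rep = L.LossReport(l_slc=0.2, l_d=-1.0, l_g_r=0.05, l_g_p=0.0)
        assert L.total_loss(rep, L.LossWeights()) == pytest.approx(-0.3)

    def test_zero_components(self):
        assert L.total_loss(L.LossReport(), L.LossWeights()) == 0.0

    def test_linear_in_lambda2(self):
        rep = L.LossReport(l_slc=0.1, l_d=-0.5, l_g_r=0.07, l_g_p=0.03)
        w10 = L.LossWeights(lambda2=10.0)
        w20 = L.LossWeights(lambda2=20.0)
        assert L.total_loss(rep, w20) - L.total_loss(rep, w10) == pytest.approx(
            10.0 * rep.l_g
        )


class TestGradientFlow:
    """Finite-difference checks on 8x8 networks: each loss reaches exactly
    the parameters it is supposed to train."""

    CFG = NetworkConfig(n_input_branches=1, base_channels=2, n_residual_blocks=1)

    def test_self_supervision_reaches_r_not_p(self, rng):
        R = ReconstructionNet(self.CFG, rng)
        P = AuxiliaryNet(self.CFG, rng)
        R.eval(), P.eval()  # freeze BN stats so FD probes are clean
        x = rng.standard_normal((1, 1, 1, 8, 8)).astype(np.float32)
        planes = MaskVector(0, 3, 8, 8).planes()

        def loss():
            _, fr = R.forward(x, planes)
            _, fp, _ = P.forward(x[0])
            return L.self_supervision_loss(fp, fr)

        # analytic gradient into R via the injected feature-gradient path
        _, fr = R.forward(x, planes)
        _, fp, _ = P.forward(x[0])
        R.zero_grad()
        P.zero_grad()
        dummy = np.zeros((1, 1, 8, 8), dtype=np.float32)
        R.backward(dummy, L.self_supervision_grad(fp, fr))
        p = R.decoder_params()[0]
        idx = tuple(int(i) for i in rng.integers(0, np.array(p.data.shape)))
        eps = 1e-2
        orig = float(p.data[idx])
        p.data[idx] = orig + eps
        up = loss()
        p.data[idx] = orig - eps
        dn = loss()
        p.data[idx] = orig
        assert p.grad[idx] == pytest.approx((up - dn) / (2 * eps), rel=0.05, abs=1e-4)
        # the teacher accumulated nothing
        assert all(np.all(q.grad == 0.0) for q in P.params())

    def test_pixel_loss_gradient_matches_finite_differences(self, rng):
        P = AuxiliaryNet(self.CFG, rng)
        P.eval()
        y = rng.standard_normal((1, 1, 8, 8)).astype(np.float32)

        def loss():
            out, _, _ = P.forward(y)
            return L.generator_pixel_loss(out, y)

        out, _, _ = P.forward(y)
        P.zero_grad()
        P.backward(L.generator_pixel_grad(out, y))
        p = P.params()[0]
        idx = tuple(int(i) for i in rng.integers(0, np.array(p.data.shape)))
        eps = 1e-2
        orig = float(p.data[idx])
        p.data[idx] = orig + eps
        up = loss()
        p.data[idx] = orig - eps
        dn = loss()
        p.data[idx] = orig
        assert p.grad[idx] == pytest.approx((up - dn) / (2 * eps), rel=0.05, abs=1e-4)

    def test_adversarial_logit_grad_matches_finite_differences(self, rng):
        z = rng.standard_normal((3, 3))
        g = L.generator_adversarial_logit_grad(z)
        eps = 1e-5
        for idx in [(0, 0), (2, 1)]:
            zp, zm = z.copy(), z.copy()
            zp[idx] += eps
            zm[idx] -= eps
            num = (
                L.generator_adversarial_loss(zp) - L.generator_adversarial_loss(zm)
            ) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-4)

    def test_discriminator_logit_grads_match_finite_differences(self, rng):
        w = L.LossWeights()
        z = [rng.standard_normal((2, 2)) for _ in range(3)]

        def val(zs):
            return L.discriminator_loss(*[L.sigmoid(q) for q in zs], w)

        grads = L.discriminator_logit_grads(*z, w)
        eps = 1e-5
        for which in range(3):
            idx = (1, 0)
            zp = [q.copy() for q in z]
            zm = [q.copy() for q in z]
            zp[which][idx] += eps
            zm[which][idx] -= eps
            num = (val(zp) - val(zm)) / (2 * eps)
            assert grads[which][idx] == pytest.approx(num, rel=1e-3)
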