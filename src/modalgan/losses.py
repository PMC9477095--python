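"""Loss functions: feature-level self-supervision, conditional PatchGAN
discriminator loss, L1 generator losses, and the total objective.

The self-supervision term is the layer-wise l2 discrepancy between the
auxiliary decoder's feature maps (teacher, on the true target) and the
reconstruction decoder's feature maps (student, on the sources), read as
the element-mean of squared differences per layer, summed over layers —
so no layer dominates purely by its size.

The discriminator objective is

    L_D = E[log D(y)] + lambda1 E[log(1 - D(y_hat))]
        + (1 - lambda1) E[log(1 - D(y_prime))]

with y the real target, y_hat the reconstruction network's fake and
y_prime the auxiliary network's reconstruction; D ascends this quantity.
As literally summed the total objective gives the generator no
adversarial gradient, so training alternates: D maximizes L_D while R
descends L_SLC + lambda2 * L_G plus a non-saturating adversarial term
-E[log D(y_hat)].

Patch logit maps are reduced by averaging the log-terms over patches;
probabilities are clamped to [eps, 1-eps] before logs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

EPS = 1e-7

__all__ = [
    "LossWeights",
    "LossReport",
    "self_supervision_loss",
    "self_supervision_grad",
    "discriminator_loss",
    "discriminator_logit_grads",
    "generator_adversarial_loss",
    "generator_adversarial_logit_grad",
    "generator_pixel_loss",
    "generator_pixel_grad",
    "total_loss",
    "sigmoid",
]


@dataclasses.dataclass(frozen=True)
class LossWeights:
    lambda1: float = 0.5  # weight of R's fake vs P's fake in the discriminator loss
    lambda2: float = 10.0  # generator (pixel) loss weight in the total objective
    adversarial_gen_weight: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.lambda1 < 1.0:
            raise ValueError("lambda1 must lie in (0, 1)")
        if self.lambda2 <= 0:
            raise ValueError("lambda2 must be positive")


@dataclasses.dataclass
class LossReport:
    l_slc: float = 0.0
    l_d: float = 0.0
    l_g_r: float = 0.0
    l_g_p: float = 0.0
    l_total: float = 0.0
    per_layer_slc: tuple[float, ...] = ()

    @property
    def l_g(self) -> float:
        return self.l_g_r + self.l_g_p

    def as_dict(self) -> dict:
        return {
            "l_slc": self.l_slc,
            "l_d": self.l_d,
            "l_g_r": self.l_g_r,
            "l_g_p": self.l_g_p,
            "l_total": self.l_total,
        }


def _stack_features(stack) -> list[np.ndarray]:
    return stack.features if hasattr(stack, "features") else list(stack)


def self_supervision_loss(stack_p, stack_r, return_layers: bool = False):
    """Sum over decoder layers of mean((f_P - f_R)^2).

    ``stack_p`` is the frozen teacher; gradients (see
    :func:`self_supervision_grad`) flow only into ``stack_r``'s producer.
    """
    fp, fr = _stack_features(stack_p), _stack_features(stack_r)
    if len(fp) != len(fr):
        raise ValueError(f"stack lengths differ: {len(fp)} vs {len(fr)}")
    layers = []
    for i, (a, b) in enumerate(zip(fp, fr)):
        if a.shape != b.shape:
            raise ValueError(f"layer {i}: shapes {a.shape} vs {b.shape} not congruent")
        d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
        layers.append(float(np.mean(d * d)))
    total = float(sum(layers))
    if return_layers:
        return total, tuple(layers)
    return total


def self_supervision_grad(stack_p, stack_r) -> list[np.ndarray]:
    """d L_SLC / d f_R per layer (teacher features treated as constants)."""
    fp, fr = _stack_features(stack_p), _stack_features(stack_r)
    grads = []
    for a, b in zip(fp, fr):
        grads.append((2.0 / a.size) * (np.asarray(b, np.float32) - np.asarray(a, np.float32)))
    return grads


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30.0, 30.0)))


def _mean_log(p: np.ndarray) -> float:
    return float(np.mean(np.log(np.clip(p, EPS, 1.0 - EPS))))


def discriminator_loss(score_real, score_fake_r, score_fake_p, weights: LossWeights) -> float:
    """Three-term conditional GAN objective; D is trained to maximize it.

    Scores are probabilities in (0, 1) (patch maps are averaged over
    patches in the log domain).
    """
    for s in (score_real, score_fake_r, score_fake_p):
        s = np.asarray(s)
        if s.min() <= 0.0 or s.max() >= 1.0:
            raise ValueError("scores must lie strictly inside (0, 1)")
    l1 = weights.lambda1
    return (
        _mean_log(score_real)
        + l1 * _mean_log(1.0 - np.asarray(score_fake_r))
        + (1.0 - l1) * _mean_log(1.0 - np.asarray(score_fake_p))
    )


def discriminator_logit_grads(z_real, z_fake_r, z_fake_p, weights: LossWeights):
    """Gradients of L_D w.r.t. the patch *logits*, for gradient ascent on D.

    With p = sigmoid(z): d mean log p / dz = (1-p)/n and
    d mean log(1-p) / dz = -p/n.
    """
    l1 = weights.lambda1
    g_real = (1.0 - sigmoid(z_real)) / z_real.size
    g_fr = -l1 * sigmoid(z_fake_r) / z_fake_r.size
    g_fp = -(1.0 - l1) * sigmoid(z_fake_p) / z_fake_p.size
    return g_real.astype(np.float32), g_fr.astype(np.float32), g_fp.astype(np.float32)


def generator_adversarial_loss(z_fake: np.ndarray) -> float:
    """Non-saturating generator term -E[log D(y_hat)] on fake logits."""
    return -_mean_log(sigmoid(z_fake))


def generator_adversarial_logit_grad(z_fake: np.ndarray) -> np.ndarray:
    """d(-mean log sigmoid(z))/dz = (sigmoid(z) - 1)/n."""
    return ((sigmoid(z_fake) - 1.0) / z_fake.size).astype(np.float32)


def generator_pixel_loss(synth, target) -> float:
    """Mean absolute pixel difference (L1), in a shared intensity domain."""
    a = synth.pixels if hasattr(synth, "pixels") else np.asarray(synth)
    b = target.pixels if hasattr(target, "pixels") else np.asarray(target)
    if hasattr(synth, "intensity_domain") and hasattr(target, "intensity_domain"):
        if synth.intensity_domain != target.intensity_domain:
            raise ValueError("images must share one intensity domain")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(np.asarray(a, np.float64) - np.asarray(b, np.float64))))


def generator_pixel_grad(synth: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d mean|a-b| / da = sign(a-b)/n."""
    d = np.sign(np.asarray(synth, np.float32) - np.asarray(target, np.float32))
    return d / d.size


def total_loss(report: LossReport, weights: LossWeights) -> float:
    """L = L_SLC + L_D + lambda2 * L_G (reporting quantity; the training
    loop applies the alternating-update rule, not this scalar)."""
    return report.l_slc + report.l_d + weights.lambda2 * report.l_g
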