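"""Image-quality metrics: MSE, PSNR, SSIM, and FSIM.

FSIM compares two images through two low-level feature maps: phase
congruency (PC), a contrast-invariant measure of how consistently the
local Fourier components agree in phase (high at edges and line
features), and gradient magnitude (GM), which restores sensitivity to
contrast changes.  Pointwise similarities

    S_PC = (2 PC1 PC2 + T1) / (PC1^2 + PC2^2 + T1)
    S_G  = (2 G1  G2  + T2) / (G1^2  + G2^2  + T2)

are combined as S_L = S_PC^alpha * S_G^beta (alpha = beta = 1) and
averaged with the pointwise maximum phase congruency as the weight:

    FSIM = sum(S_L * PCm) / sum(PCm),   PCm = max(PC1, PC2).

PC is computed from a 4-scale, 4-orientation log-Gabor filter bank with
an amplitude-derived noise threshold, GM from the Scharr operator, both
on the uint8 intensity scale (T1 = 0.85, T2 = 160, the 8-bit defaults).
Inputs larger than ~256 px on the short side are average-pool
downsampled by round(min(H, W) / 256) first.

SSIM delegates to scikit-image with the standard 11x11 Gaussian window
(sigma 1.5, K1 = 0.01, K2 = 0.03, L = 255).  All metrics operate in the
uint8 domain; PSNR uses the 255 peak.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.ndimage import correlate, uniform_filter
from skimage.metrics import structural_similarity

__all__ = [
    "FSIMConstants",
    "SimilarityMaps",
    "MetricReport",
    "mse",
    "psnr",
    "ssim",
    "phase_congruency",
    "gradient_magnitude",
    "fsim",
    "fsim_from_maps",
    "evaluate_pairs",
]


@dataclasses.dataclass(frozen=True)
class FSIMConstants:
    T1: float = 0.85
    T2: float = 160.0
    alpha: float = 1.0
    beta: float = 1.0
    pc_scales: int = 4
    pc_orientations: int = 4
    pc_min_wavelength: float = 6.0
    pc_scale_factor: float = 2.0
    pc_sigma_onf: float = 0.55
    pc_noise_k: float = 2.0

    def __post_init__(self):
        if self.T1 <= 0 or self.T2 <= 0:
            raise ValueError("T1 and T2 must be positive")


@dataclasses.dataclass
class SimilarityMaps:
    PC1: np.ndarray
    PC2: np.ndarray
    G1: np.ndarray
    G2: np.ndarray
    PCm: np.ndarray
    S_PC: np.ndarray
    S_G: np.ndarray
    S_L: np.ndarray


def _pixels(a) -> np.ndarray:
    x = a.pixels if hasattr(a, "pixels") else np.asarray(a)
    if hasattr(a, "intensity_domain") and a.intensity_domain != "uint8":
        raise ValueError("metrics operate on uint8-domain slices")
    return np.asarray(x, dtype=np.float64)


def _check_sizes(a, b):
    if a.shape != b.shape:
        raise ValueError(f"size mismatch: {a.shape} vs {b.shape}")


def mse(a, b) -> float:
    x, y = _pixels(a), _pixels(b)
    _check_sizes(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(a, b) -> float:
    """10*log10(255^2 / MSE) in dB; +inf for identical images."""
    m = mse(a, b)
    if m == 0.0:
        return math.inf
    return 10.0 * math.log10(255.0**2 / m)


def ssim(a, b) -> float:
    x, y = _pixels(a), _pixels(b)
    _check_sizes(x, y)
    if min(x.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            x, y, win_size=11, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03, data_range=255.0,
        )
    )


# ---------------------------------------------------------------------------
# phase congruency (log-Gabor bank)

def _filter_grids(h: int, w: int):
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.sqrt(fx**2 + fy**2)
    radius[0, 0] = 1.0  # avoid log(0); DC is zeroed in each filter anyway
    theta = np.arctan2(-fy, fx)
    return radius, theta


def _lowpass(h: int, w: int, cutoff: float = 0.45, order: int = 15) -> np.ndarray:
    radius, _ = _filter_grids(h, w)
    radius[0, 0] = 0.0
    return 1.0 / (1.0 + (radius / cutoff) ** (2 * order))


def phase_congruency(img, constants: FSIMConstants | None = None) -> np.ndarray:
    """Phase-congruency map in [0, 1); high on edges, ~0 on flat regions.

    Relatively invariant to global affine intensity changes: the log-Gabor
    filters have zero DC response (offset invariance) and both the energy
    and the noise threshold scale linearly with amplitude (gain
    invariance).
    """
    c = constants or FSIMConstants()
    x = _pixels(img)
    h, w = x.shape
    if min(h, w) < 32:
        raise ValueError("phase congruency needs images of at least 32 px")
    radius, theta = _filter_grids(h, w)
    lp = _lowpass(h, w)
    sintheta, costheta = np.sin(theta), np.cos(theta)
    xf = np.fft.fft2(x)

    theta_sigma = math.pi / c.pc_orientations / 1.2  # angular spread factor 1.2
    energy_all = np.zeros((h, w))
    an_all = np.zeros((h, w))
    eps = 1e-4

    log_gabors = []
    for s in range(c.pc_scales):
        wavelength = c.pc_min_wavelength * c.pc_scale_factor**s
        f0 = 1.0 / wavelength
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * math.log(c.pc_sigma_onf) ** 2))
        lg *= lp
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    for o in range(c.pc_orientations):
        angle = o * math.pi / c.pc_orientations
        ds = sintheta * math.cos(angle) - costheta * math.sin(angle)
        dc = costheta * math.cos(angle) + sintheta * math.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2.0 * theta_sigma**2))

        responses = [np.fft.ifft2(xf * log_gabors[s] * spread) for s in range(c.pc_scales)]
        sum_e = sum(r.real for r in responses)
        sum_o = sum(r.imag for r in responses)
        sum_an = sum(np.abs(r) for r in responses)
        tau = float(np.median(np.abs(responses[0]))) / math.sqrt(math.log(4.0))
        x_energy = np.sqrt(sum_e**2 + sum_o**2) + eps
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros((h, w))
        for r in responses:
            e, od = r.real, r.imag
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)
        # Rayleigh-statistics noise threshold from the smallest-scale response
        m = 1.0 / c.pc_scale_factor
        total_tau = tau * (1.0 - m**c.pc_scales) / (1.0 - m)
        noise_mean = total_tau * math.sqrt(math.pi / 2.0)
        noise_sigma = total_tau * math.sqrt((4.0 - math.pi) / 2.0)
        t = noise_mean + c.pc_noise_k * noise_sigma
        energy = np.maximum(energy - t, 0.0)
        energy_all += energy
        an_all += sum_an

    return energy_all / (an_all + eps)


_SCHARR_X = np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0
_SCHARR_Y = _SCHARR_X.T


def gradient_magnitude(img) -> np.ndarray:
    """Scharr gradient magnitude; zero on constant images."""
    x = _pixels(img)
    gx = correlate(x, _SCHARR_X, mode="nearest")
    gy = correlate(x, _SCHARR_Y, mode="nearest")
    return np.sqrt(gx**2 + gy**2)


def _downsample_for_fsim(x: np.ndarray) -> np.ndarray:
    f = max(1, round(min(x.shape) / 256))
    if f == 1:
        return x
    y = uniform_filter(x, size=f, mode="nearest")
    return y[::f, ::f]


def fsim_from_maps(pc1, pc2, g1, g2, constants: FSIMConstants | None = None,
                   return_maps: bool = False):
    """Combine precomputed PC and GM maps into the FSIM score.

    This is the analytic core; :func:`fsim` feeds it the filter-bank maps,
    and tests can feed it constant maps with hand-computable values.
    """
    c = constants or FSIMConstants()
    pc1, pc2 = np.asarray(pc1, np.float64), np.asarray(pc2, np.float64)
    g1, g2 = np.asarray(g1, np.float64), np.asarray(g2, np.float64)
    s_pc = (2.0 * pc1 * pc2 + c.T1) / (pc1**2 + pc2**2 + c.T1)
    s_g = (2.0 * g1 * g2 + c.T2) / (g1**2 + g2**2 + c.T2)
    s_l = s_pc**c.alpha * s_g**c.beta
    pcm = np.maximum(pc1, pc2)
    denom = float(pcm.sum())
    if denom <= 0.0:
        # featureless pair (e.g. two constant images): every location is
        # equally (un)informative, so weight uniformly
        value = float(np.mean(s_l))
    else:
        value = float((s_l * pcm).sum() / denom)
    if return_maps:
        return value, SimilarityMaps(pc1, pc2, g1, g2, pcm, s_pc, s_g, s_l)
    return value


def fsim(a, b, constants: FSIMConstants | None = None) -> float:
    c = constants or FSIMConstants()
    x, y = _pixels(a), _pixels(b)
    _check_sizes(x, y)
    x, y = _downsample_for_fsim(x), _downsample_for_fsim(y)
    pc1, pc2 = phase_congruency(x, c), phase_congruency(y, c)
    g1, g2 = gradient_magnitude(x), gradient_magnitude(y)
    return fsim_from_maps(pc1, pc2, g1, g2, c)


# ---------------------------------------------------------------------------
# dataset-level aggregation

METRIC_NAMES = ("mse", "psnr", "ssim", "fsim")


@dataclasses.dataclass
class MetricReport:
    """Per-pair metric table plus mean +/- sd summary."""

    table: "object"  # pandas DataFrame: one row per pair
    mean: dict[str, float]
    sd: dict[str, float]
    n_pairs: int
    single_pair: bool = False

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {m: [self.mean[m], self.sd[m]] for m in METRIC_NAMES},
            index=["mean", "sd"],
        )

    def __str__(self) -> str:
        lines = [f"pairs: {self.n_pairs}"]
        for m in METRIC_NAMES:
            lines.append(f"{m.upper():>5}: {self.mean[m]:.4f} +/- {self.sd[m]:.4f}")
        return "\n".join(lines)


def evaluate_pairs(pairs, constants: FSIMConstants | None = None,
                   metadata: list[dict] | None = None) -> MetricReport:
    """Per-pair MSE/PSNR/SSIM/FSIM for (synthesized, reference) pairs."""
    import pandas as pd

    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_pairs needs at least one image pair")
    rows = []
    for i, (synth, ref) in enumerate(pairs):
        row = dict(metadata[i]) if metadata else {}
        row.update(
            mse=mse(synth, ref),
            psnr=psnr(synth, ref),
            ssim=ssim(synth, ref),
            fsim=fsim(synth, ref, constants),
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    mean, sd = {}, {}
    for m in METRIC_NAMES:
        vals = table[m].to_numpy(dtype=np.float64)
        mean[m] = float(np.mean(vals))
        if len(vals) == 1 or np.all(vals == vals[0]):
            sd[m] = 0.0
        else:
            sd[m] = float(np.std(vals, ddof=1))
    return MetricReport(
        table=table, mean=mean, sd=sd, n_pairs=len(pairs), single_pair=len(pairs) == 1
    )
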