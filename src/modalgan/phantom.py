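"""Synthetic co-registered multimodal brain phantoms.

Emulates the statistical structure of a multi-contrast clinical MR study:
per-subject anatomy shared across modalities, modality-specific tissue
contrast, field-strength-dependent contrast and noise, and a subject-level
train/test split.  Anatomy is a nested set of smoothed random blobs — a
skull ring enclosing CSF, gray matter, white matter and an optional lesion
class — generated from seeded smooth noise so that the whole dataset is a
pure function of its configuration.

Intensity tables are chosen so that no modality is an affine copy of
another and so that resolving the target modality's tissue contrast
genuinely requires more than one source modality (pairs of classes that
are iso-intense in one source are separated in the other).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import ImageSlice, save_slice

MODALITIES = ("T1-FLAIR", "T2-FLAIR", "T2-TRF")
FIELD_STRENGTHS = (1.5, 3.0)

#: tissue classes: 0 background, 1 skull, 2 CSF, 3 gray, 4 white, 5 lesion
N_CLASSES = 5

# Per-modality class mean intensities (uint8), index 0..5.
# Designed contrasts: in T1-FLAIR, CSF and lesion are iso-intense (60) while
# T2-FLAIR separates them (40 vs 230); in T2-FLAIR, gray and white are close
# (150 vs 140) while T1-FLAIR separates them (110 vs 190).  T2-TRF (the usual
# synthesis target) depends on distinctions that no single source carries
# alone.
_BASE_INTENSITY = {
    "T1-FLAIR": (0.0, 210.0, 60.0, 110.0, 190.0, 60.0),
    "T2-FLAIR": (0.0, 120.0, 40.0, 150.0, 140.0, 230.0),
    "T2-TRF": (0.0, 160.0, 220.0, 90.0, 140.0, 200.0),
}


@dataclasses.dataclass(frozen=True)
class ModalityProfile:
    """Rendering recipe for one modality at one field strength."""

    modality_name: str
    field_strength: float
    tissue_intensity: tuple[float, ...]
    contrast_gain: float = 1.0
    noise_sigma: float = 4.0
    bias_field_amplitude: float = 0.05

    def __post_init__(self):
        if self.modality_name not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality_name!r}")
        if len(self.tissue_intensity) != N_CLASSES + 1:
            raise ValueError(
                f"tissue_intensity must cover classes 0..{N_CLASSES}"
            )


def default_profiles(modalities=MODALITIES, field_strengths=FIELD_STRENGTHS):
    """The study conditions: 3 modalities x 2 field strengths.

    3T has higher contrast gain and lower noise than 1.5T for every
    modality.
    """
    profiles = []
    for m in modalities:
        for b in field_strengths:
            if b >= 3.0:
                gain, sigma = 1.25, 2.5
            else:
                gain, sigma = 1.0, 5.0
            profiles.append(
                ModalityProfile(
                    modality_name=m,
                    field_strength=b,
                    tissue_intensity=_BASE_INTENSITY[m],
                    contrast_gain=gain,
                    noise_sigma=sigma,
                    bias_field_amplitude=0.05,
                )
            )
    return profiles


@dataclasses.dataclass(frozen=True)
class PhantomDatasetConfig:
    n_subjects: int = 22
    slices_per_subject: int = 20
    image_size: int = 256
    seed: int = 0
    train_fraction: float = 0.8
    modalities: tuple[ModalityProfile, ...] = tuple(default_profiles())
    lesion_prevalence: float = 0.5  # fraction of subjects carrying a lesion

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_subjects < 1 or self.slices_per_subject < 1:
            raise ValueError("need at least one subject and one slice")


@dataclasses.dataclass
class TissueLabelMap:
    labels: np.ndarray  # 2D int array, values 0..N_CLASSES
    subject_id: str
    slice_index: int

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]


@dataclasses.dataclass
class ManifestRecord:
    subject_id: str
    slice_index: int
    modality_name: str
    field_strength: float
    file_path: str
    split: str


@dataclasses.dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    seed: int
    config: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config": self.config,
                "records": [dataclasses.asdict(r) for r in self.records],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        obj = json.loads(text)
        return cls(
            records=[ManifestRecord(**r) for r in obj["records"]],
            seed=obj["seed"],
            config=obj["config"],
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        return cls.from_json(Path(path).read_text())

    def subjects(self, split: str | None = None) -> list[str]:
        out = []
        for r in self.records:
            if split is not None and r.split != split:
                continue
            if r.subject_id not in out:
                out.append(r.subject_id)
        return out

    def select(self, split=None, modality=None, field_strength=None):
        out = []
        for r in self.records:
            if split is not None and r.split != split:
                continue
            if modality is not None and r.modality_name != modality:
                continue
            if field_strength is not None and r.field_strength != field_strength:
                continue
            out.append(r)
        return out


def _subject_seed(seed: int, subject_id: str, slice_index: int) -> np.random.Generator:
    # stable fan-out of the master seed; SeedSequence keys keep streams independent
    sid_num = int("".join(c for c in subject_id if c.isdigit()) or 0)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(sid_num, slice_index + 1))
    )


def generate_label_map(
    config: PhantomDatasetConfig, subject_id: str, slice_index: int
) -> TissueLabelMap:
    """Deterministic tissue label map for one subject slice.

    Anatomy is an ellipse (skull ring) whose interior is partitioned into
    CSF / gray / white by thresholding subject-specific smooth noise; a
    lesion blob is present in a seeded subset of subjects.  The slice index
    modulates the geometry slowly, so adjacent slices overlap strongly.
    """
    s = config.image_size
    if s < 32:
        raise ValueError("image_size must be >= 32")
    # subject-level shape parameters come from a slice-independent stream
    srng = _subject_seed(config.seed, subject_id, -1)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cy, cx = s / 2.0 + srng.uniform(-s * 0.03, s * 0.03, size=2)
    base_ry = s * srng.uniform(0.33, 0.38)
    base_rx = s * srng.uniform(0.28, 0.33)
    tilt = srng.uniform(-0.2, 0.2)
    # smooth per-subject texture field (shared across slices; the slice index
    # only shifts its threshold slightly -> >80% label overlap between
    # neighbouring slices)
    texture = gaussian_filter(srng.standard_normal((s, s)), sigma=s / 10.0)
    texture = (texture - texture.mean()) / (texture.std() + 1e-12)
    has_lesion = srng.random() < config.lesion_prevalence
    lesion_cy = cy + srng.uniform(-0.15, 0.15) * s
    lesion_cx = cx + srng.uniform(-0.15, 0.15) * s
    lesion_r = s * srng.uniform(0.04, 0.07)

    # slice modulation: radius waxes and wanes through the stack
    n_sl = max(config.slices_per_subject, 1)
    z = (slice_index - (n_sl - 1) / 2.0) / max(n_sl / 2.0, 1.0)  # in ~[-1, 1]
    rscale = np.sqrt(max(1.0 - 0.25 * z * z, 0.05))
    ry, rx = base_ry * rscale, base_rx * rscale

    xr = (xx - cx) + tilt * (yy - cy)
    r2 = ((yy - cy) / ry) ** 2 + (xr / rx) ** 2
    labels = np.zeros((s, s), dtype=np.int64)
    labels[r2 <= 1.0] = 1  # skull ring (outer shell)
    interior = r2 <= 0.88
    # partition interior by texture thresholds; thresholds drift with z so
    # tissue boundaries move smoothly through the stack
    t = texture + 0.1 * z
    labels[interior & (t < -0.55)] = 2  # CSF
    labels[interior & (t >= -0.55) & (t < 0.45)] = 3  # gray
    labels[interior & (t >= 0.45)] = 4  # white
    # ventricle-like central CSF pocket so every slice has >=3 interior classes
    vent = ((yy - cy) / (0.16 * ry)) ** 2 + (xr / (0.30 * rx)) ** 2 <= 1.0
    labels[vent & interior] = 2
    if has_lesion:
        lz = ((yy - lesion_cy) ** 2 + (xx - lesion_cx) ** 2) <= (lesion_r * rscale) ** 2
        labels[lz & interior & (labels > 1)] = 5
    return TissueLabelMap(labels=labels, subject_id=subject_id, slice_index=slice_index)


def render_modality(
    label_map: TissueLabelMap, profile: ModalityProfile, noise_seed: int
) -> ImageSlice:
    """Render a label map under one modality/field-strength profile.

    Pixel model: ``bias_field * contrast_mapped(class mean) + Rician noise``,
    clipped to [0, 255].  The contrast mapping scales class means about the
    mid-gray 128 by ``contrast_gain``, so a higher-field profile of the same
    modality has a wider inter-class intensity range.  Noise is Rician —
    the magnitude of a complex Gaussian around the noiseless signal — as
    appropriate for MR magnitude images.
    """
    labels = label_map.labels
    lut = np.asarray(profile.tissue_intensity, dtype=np.float64)
    if labels.max() >= lut.size:
        raise ValueError(
            f"profile covers classes 0..{lut.size - 1} but map contains {labels.max()}"
        )
    mapped = 128.0 + profile.contrast_gain * (lut - 128.0)
    mapped[0] = 0.0  # background stays air
    img = mapped[labels]

    rng = np.random.default_rng(np.random.SeedSequence(entropy=noise_seed))
    if profile.bias_field_amplitude > 0:
        s = labels.shape[0]
        bias = gaussian_filter(rng.standard_normal(labels.shape), sigma=s / 4.0)
        bias = bias / (np.abs(bias).max() + 1e-12) * profile.bias_field_amplitude
        img = img * (1.0 + bias)
    if profile.noise_sigma > 0:
        n1 = rng.normal(0.0, profile.noise_sigma, labels.shape)
        n2 = rng.normal(0.0, profile.noise_sigma, labels.shape)
        img = np.sqrt((img + n1) ** 2 + n2**2)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ImageSlice(
        pixels=img,
        intensity_domain="uint8",
        modality_name=profile.modality_name,
        field_strength=profile.field_strength,
        subject_id=label_map.subject_id,
        slice_index=label_map.slice_index,
    )


def split_subjects(config: PhantomDatasetConfig) -> tuple[list[str], list[str]]:
    """Subject-level split: round-half-up train count, seeded shuffle."""
    subjects = [f"sub-{i:03d}" for i in range(config.n_subjects)]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(999,)))
    order = rng.permutation(config.n_subjects)
    n_train = int(np.floor(config.train_fraction * config.n_subjects + 0.5))
    if n_train >= config.n_subjects:
        raise ValueError(
            f"train_fraction {config.train_fraction} with {config.n_subjects} "
            "subjects leaves no test subject"
        )
    train = sorted(subjects[i] for i in order[:n_train])
    test = sorted(subjects[i] for i in order[n_train:])
    return train, test


def _noise_seed(config, subject_id, slice_index, modality_name, field_strength) -> int:
    m_idx = MODALITIES.index(modality_name)
    b_idx = 0 if field_strength < 2.0 else 1
    sid = int(subject_id.split("-")[-1])
    # pack into a stable integer < 2**31
    return (
        (config.seed % 1000) * 2_000_000
        + sid * 10_000
        + slice_index * 40
        + m_idx * 4
        + b_idx
    )


def generate_dataset(config: PhantomDatasetConfig, output_dir, fmt: str = "png") -> DatasetManifest:
    """Write every slice of every modality/field-strength plus a manifest.

    Re-running with the same config reproduces the dataset byte for byte.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    train, test = split_subjects(config)
    split_of = {s: "train" for s in train}
    split_of.update({s: "test" for s in test})
    records = []
    for sid in sorted(split_of):
        for k in range(config.slices_per_subject):
            lmap = generate_label_map(config, sid, k)
            for profile in config.modalities:
                img = render_modality(
                    lmap,
                    profile,
                    _noise_seed(config, sid, k, profile.modality_name, profile.field_strength),
                )
                tag = profile.modality_name.replace("-", "")
                fname = f"{sid}_slice{k:02d}_{tag}_{profile.field_strength:g}T.{fmt}"
                save_slice(img, out / fname)
                records.append(
                    ManifestRecord(
                        subject_id=sid,
                        slice_index=k,
                        modality_name=profile.modality_name,
                        field_strength=profile.field_strength,
                        file_path=fname,
                        split=split_of[sid],
                    )
                )
    cfg_echo = dataclasses.asdict(config)
    cfg_echo["modalities"] = [dataclasses.asdict(p) for p in config.modalities]
    manifest = DatasetManifest(records=records, seed=config.seed, config=cfg_echo)
    manifest.save(out / "manifest.json")
    return manifest


def load_bundle(manifest: DatasetManifest, base_dir, subject_id: str, slice_index: int,
                field_strength: float = 1.5) -> dict[str, ImageSlice]:
    """All co-registered modalities of one subject slice at one field strength."""
    from .image_io import load_slice

    out = {}
    for r in manifest.records:
        if (
            r.subject_id == subject_id
            and r.slice_index == slice_index
            and r.field_strength == field_strength
        ):
            out[r.modality_name] = load_slice(Path(base_dir) / r.file_path, r)
    return out
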