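"""Two-phase training: auxiliary pretraining, then joint adversarial
training with feature-level guidance — plus the four experiment scenarios
and inference-time synthesis.

Per joint iteration the updates alternate:

* D ascends the three-term discriminator objective on (real target,
  R's fake weighted lambda1, P's reconstruction weighted 1 - lambda1),
  every input conditioned on the target modality's mask vector;
* R descends  L_SLC + lambda2 * L1(y_hat, y)  plus the non-saturating
  adversarial term -E[log D(y_hat)], where L_SLC compares R's decoder
  features against the frozen auxiliary decoder's features on the true
  target.

The auxiliary network is pretrained as an autoencoder on the target
modality with an L1 loss and is frozen (teacher) during the joint phase
by default.  All randomness — batch sampling, weight init, everything —
fans out from one master seed, so a run is exactly replayable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import losses as L
from .image_io import ImageSlice, denormalize, load_slice, normalize
from .networks import (
    AuxiliaryNet,
    Discriminator,
    MaskVector,
    NetworkConfig,
    ReconstructionNet,
)
from .nn import Adam
from .phantom import MODALITIES, DatasetManifest

__all__ = [
    "TrainConfig",
    "ExperimentResult",
    "SliceDataset",
    "pretrain_auxiliary",
    "train_synthesis",
    "train_missing_modality",
    "synthesize",
    "evaluate_checkpoint",
    "save_checkpoint",
    "load_checkpoint",
    "toy_train_config",
    "paper_train_config",
]

SCENARIOS = (
    "aux_vs_noaux",
    "single_vs_multi_branch",
    "generalization_1p5T_to_3T",
    "missing_modality",
)


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    iterations: int = 300
    batch_size: int = 8
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    weights: L.LossWeights = dataclasses.field(default_factory=L.LossWeights)
    seed: int = 0
    base_channels: int = 8
    n_residual_blocks: int = 2
    use_auxiliary: bool = True
    freeze_auxiliary: bool = True
    #: leading decoder layers whose feature maps enter the guidance loss.
    #: The final decoder layer is the output image itself, which is already
    #: supervised by the pixel loss and the discriminator's y' branch;
    #: including it again would pull the student's output toward the
    #: teacher's own (inferior) reconstruction.
    guidance_layers: int = 2
    pretrain_iterations: int = 400
    log_every: int = 25
    field_strength: float = 1.5

    def __post_init__(self):
        if self.iterations < 0 or self.pretrain_iterations < 0:
            raise ValueError("iteration counts must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")


def toy_train_config(seed: int = 0, **overrides) -> TrainConfig:
    """Desk-scale preset: small images, thin networks, short runs."""
    return TrainConfig(seed=seed, **overrides)


def paper_train_config(seed: int = 0, **overrides) -> TrainConfig:
    """Full-scale preset (256x256, 2e5 iterations); GPU-class hardware
    recommended — provided for completeness, not exercised by the tests."""
    defaults = dict(
        iterations=200_000, batch_size=4, base_channels=32, n_residual_blocks=6,
        pretrain_iterations=20_000,
    )
    defaults.update(overrides)
    return TrainConfig(seed=seed, **defaults)


@dataclasses.dataclass
class ExperimentResult:
    metric_report: object  # MetricReport on the test split
    loss_log: list[dict]
    checkpoint_path: str | None
    config: dict
    seed: int
    access_log: list[tuple[str, str]]  # (subject_id, split) pairs touched in training

    @property
    def mean_ssim(self) -> float:
        return self.metric_report.mean["ssim"]


class SliceDataset:
    """In-memory normalized slices indexed by (subject, slice, modality, field).

    Records every subject whose pixels are handed out for training, so
    test-split isolation is auditable after the fact.
    """

    def __init__(self, manifest: DatasetManifest, base_dir,
                 modalities=None, field_strengths=None):
        self.manifest = manifest
        self.base_dir = Path(base_dir)
        self.arrays: dict[tuple, np.ndarray] = {}
        self.split_of: dict[str, str] = {}
        self.access_log: list[tuple[str, str]] = []
        for r in manifest.records:
            if modalities is not None and r.modality_name not in modalities:
                continue
            if field_strengths is not None and r.field_strength not in field_strengths:
                continue
            sl = load_slice(self.base_dir / r.file_path, r)
            key = (r.subject_id, r.slice_index, r.modality_name, r.field_strength)
            self.arrays[key] = normalize(sl).pixels
            self.split_of[r.subject_id] = r.split

    def keys(self, split: str) -> list[tuple[str, int]]:
        out = sorted(
            {
                (s, i)
                for (s, i, _, _) in self.arrays
                if self.split_of[s] == split
            }
        )
        return out

    def fetch(self, subject: str, slice_index: int, modality: str,
              field_strength: float, log: bool = True) -> np.ndarray:
        if log:
            self.access_log.append((subject, self.split_of[subject]))
        return self.arrays[(subject, slice_index, modality, field_strength)]

    def batch(self, rng, split: str, modalities: list[str], field_strengths: list[float],
              batch_size: int, log: bool = True) -> list[np.ndarray]:
        """One array (N,1,H,W) per requested (modality, field) pair."""
        keys = self.keys(split)
        idx = rng.integers(0, len(keys), size=batch_size)
        out = []
        for m, b in zip(modalities, field_strengths):
            arr = np.stack(
                [self.fetch(*keys[i], m, b, log=log)[None] for i in idx]
            ).astype(np.float32)
            out.append(arr)
        return out


def _net_config(config: TrainConfig, n_branches: int) -> NetworkConfig:
    return NetworkConfig(
        n_input_branches=n_branches,
        base_channels=config.base_channels,
        n_residual_blocks=config.n_residual_blocks,
        n_modalities_total=len(MODALITIES),
    )


def _rng_fanout(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, nets: dict, meta: dict) -> None:
    arrays = {}
    for name, net in nets.items():
        for k, v in net.state_arrays().items():
            arrays[f"{name}/{k}"] = v
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays: dict[str, dict] = {}
        for k in z.files:
            if k == "__meta__":
                continue
            name, sub = k.split("/", 1)
            arrays.setdefault(name, {})[sub] = z[k]
    return meta, arrays


def _restore(net, arrays):
    net.load_state_arrays(arrays)
    return net


# ---------------------------------------------------------------------------
# auxiliary pretraining

def pretrain_auxiliary(manifest: DatasetManifest, base_dir, target_modality: str,
                       config: TrainConfig, out_path=None,
                       dataset: SliceDataset | None = None):
    """Train the auxiliary autoencoder on the target modality (L1 loss).

    Returns (AuxiliaryNet, loss_log); writes a checkpoint when
    ``out_path`` is given.  The target modality's mask vector index is
    registered with the checkpoint as the modality label.
    """
    ds = dataset or SliceDataset(
        manifest, base_dir, modalities=[target_modality],
        field_strengths=[config.field_strength],
    )
    if not any(m == target_modality for (_, _, m, _) in ds.arrays):
        raise ValueError(f"manifest has no {target_modality} slices")
    rng = _rng_fanout(config.seed, 1)
    net = AuxiliaryNet(_net_config(config, 1), rng=_rng_fanout(config.seed, 2))
    opt = Adam(net.params(), lr=config.learning_rate, betas=(config.beta1, config.beta2))
    log = []
    for it in range(config.pretrain_iterations):
        (y,) = ds.batch(rng, "train", [target_modality], [config.field_strength],
                        config.batch_size)
        out, _, _ = net.forward(y)
        l1 = L.generator_pixel_loss(out, y)
        if not np.isfinite(l1):
            raise FloatingPointError(f"auxiliary pretraining diverged at step {it}")
        net.zero_grad()
        net.backward(L.generator_pixel_grad(out, y))
        opt.step()
        if it % config.log_every == 0 or it == config.pretrain_iterations - 1:
            log.append({"iteration": it, "l_g_p": l1})
    meta = {
        "kind": "auxiliary",
        "target_modality": target_modality,
        "mask_index": MODALITIES.index(target_modality),
        "config": dataclasses.asdict(config.weights) | {
            "base_channels": config.base_channels,
            "n_residual_blocks": config.n_residual_blocks,
        },
    }
    if out_path is not None:
        save_checkpoint(out_path, {"P": net}, meta)
    return net, log


# ---------------------------------------------------------------------------
# joint training

def _d_step(D, opt_d, y, y_hat, y_p, mask_planes, weights):
    """Ascend the discriminator objective; returns its current value.

    Without an auxiliary reconstruction (the no-auxiliary ablation) the
    y_prime branch vanishes and R's fake carries full weight — lambda1
    effectively 1.
    """
    l1 = weights.lambda1 if y_p is not None else 1.0 - L.EPS
    # forward+backward one term at a time (each forward overwrites the caches)
    opt_d.zero_grad()
    z_real = D.forward(y, mask_planes)
    g_real = (1.0 - L.sigmoid(z_real)) / z_real.size
    D.backward(-g_real.astype(np.float32))  # Adam descends, so negate for ascent
    z_fr = D.forward(y_hat, mask_planes)
    D.backward((l1 * L.sigmoid(z_fr) / z_fr.size).astype(np.float32))
    z_fp = None
    if y_p is not None:
        z_fp = D.forward(y_p, mask_planes)
        D.backward(((1.0 - l1) * L.sigmoid(z_fp) / z_fp.size).astype(np.float32))
    opt_d.step()
    s_real = np.clip(L.sigmoid(z_real), L.EPS, 1 - L.EPS)
    s_fr = np.clip(L.sigmoid(z_fr), L.EPS, 1 - L.EPS)
    s_fp = s_fr if z_fp is None else np.clip(L.sigmoid(z_fp), L.EPS, 1 - L.EPS)
    return L.discriminator_loss(
        s_real, s_fr, s_fp,
        weights if y_p is not None else dataclasses.replace(weights, lambda1=1.0 - 1e-6),
    )


def _joint_loop(R, P_of, D, ds, directions, config, mask_size):
    """Shared joint-training loop.

    ``directions`` is a list of (source_modalities, source_fs, target_modality,
    target_fs); one is sampled per iteration (a single entry for the fixed
    scenarios, three for missing-modality training).
    """
    w = config.weights
    rng = _rng_fanout(config.seed, 10)
    opt_r = Adam(R.params(), lr=config.learning_rate, betas=(config.beta1, config.beta2))
    opt_d = Adam(D.params(), lr=config.learning_rate, betas=(config.beta1, config.beta2))
    opt_p = None
    if P_of and not config.freeze_auxiliary:
        params = []
        for p_net in P_of.values():
            params.extend(p_net.params())
        opt_p = Adam(params, lr=config.learning_rate, betas=(config.beta1, config.beta2))
    log = []
    for it in range(config.iterations):
        srcs, src_fs, tgt, tgt_fs = directions[rng.integers(0, len(directions))]
        batch = ds.batch(rng, "train", list(srcs) + [tgt], list(src_fs) + [tgt_fs],
                         config.batch_size)
        x = np.stack(batch[:-1])
        y = batch[-1]
        mask = MaskVector(MODALITIES.index(tgt), len(MODALITIES), *mask_size)
        planes = mask.planes()

        report = L.LossReport()
        P = P_of.get(tgt) if P_of else None
        y_p = feats_p = None
        if P is not None:
            if config.freeze_auxiliary:
                P.eval()
            y_p, feats_p, _ = P.forward(y)
            report.l_g_p = L.generator_pixel_loss(y_p, y)

        y_hat, feats_r = R.forward(x, planes)
        report.l_g_r = L.generator_pixel_loss(y_hat, y)

        # --- discriminator ascent ---
        report.l_d = _d_step(D, opt_d, y, y_hat, y_p, planes, w)

        # --- generator (R) descent ---
        dfeats = None
        if feats_p is not None:
            k = config.guidance_layers
            report.l_slc, report.per_layer_slc = L.self_supervision_loss(
                feats_p[:k], feats_r[:k], return_layers=True
            )
            dfeats = L.self_supervision_grad(feats_p[:k], feats_r[:k])
            dfeats += [None] * (len(feats_r) - k)
        z_fake = D.forward(y_hat, planes)
        d_adv = L.generator_adversarial_logit_grad(z_fake)
        dy_hat = w.adversarial_gen_weight * D.backward(d_adv)
        dy_hat = dy_hat + w.lambda2 * L.generator_pixel_grad(y_hat, y)
        opt_r.zero_grad()
        R.backward(dy_hat, dfeats)
        opt_r.step()

        if opt_p is not None and y_p is not None:
            opt_p.zero_grad()
            P.backward(L.generator_pixel_grad(y_p, y))
            opt_p.step()

        report.l_total = L.total_loss(report, w)
        if not np.isfinite(report.l_total):
            raise FloatingPointError(f"training diverged at iteration {it}")
        if it % config.log_every == 0 or it == config.iterations - 1:
            log.append({"iteration": it, **report.as_dict()})
    return log


def _evaluate_directions(R, ds, directions, constants=None, max_pairs=None,
                         instance_stats=False):
    """Test-split metrics for every direction, through pure R inference.

    ``instance_stats`` selects per-sample normalization statistics at
    inference.  A generator trained on one fixed direction has unimodal
    feature statistics, so its running averages are the right (and
    lower-variance) estimator; a direction-switched generator's running
    averages blend the per-direction distributions and misnormalize all
    of them, so per-sample statistics are used instead.
    """
    from .metrics import evaluate_pairs

    R.eval()
    R.use_instance_stats(instance_stats)
    pairs, meta = [], []
    for srcs, src_fs, tgt, tgt_fs in directions:
        h = w = None
        for subject, idx in ds.keys("test"):
            x = np.stack(
                [ds.fetch(subject, idx, m, b, log=False)[None, None]
                 for m, b in zip(srcs, src_fs)]
            ).astype(np.float32)
            h, w = x.shape[-2:]
            mask = MaskVector(MODALITIES.index(tgt), len(MODALITIES), h, w)
            y_hat, _ = R.forward(x, mask.planes())
            synth = denormalize(ImageSlice(np.clip(y_hat[0, 0], -1, 1), "normalized"))
            ref = denormalize(
                ImageSlice(ds.fetch(subject, idx, tgt, tgt_fs, log=False), "normalized")
            )
            pairs.append((synth, ref))
            meta.append({"subject": subject, "slice": idx, "modality": tgt})
            if max_pairs and len(pairs) >= max_pairs:
                break
    R.use_instance_stats(False)
    R.train()
    return evaluate_pairs(pairs, constants, metadata=meta)


def train_synthesis(manifest: DatasetManifest, base_dir, source_modalities, target_modality,
                 config: TrainConfig, aux_net: AuxiliaryNet | None = None,
                 aux_checkpoint=None, target_field_strength: float | None = None,
                 checkpoint_path=None, dataset: SliceDataset | None = None) -> ExperimentResult:
    """Joint adversarial training for one fixed synthesis direction.

    ``source_modalities -> target_modality`` at ``config.field_strength``
    (the target may sit at a different field strength, which is how the
    1.5T -> 3T generalization scenario is run).  Pass a pretrained
    ``aux_net`` (or ``aux_checkpoint``) unless the no-auxiliary ablation
    is wanted (``config.use_auxiliary = False``).
    """
    source_modalities = list(source_modalities)
    tgt_fs = target_field_strength if target_field_strength is not None else config.field_strength
    fs_needed = sorted({config.field_strength, tgt_fs})
    ds = dataset or SliceDataset(
        manifest, base_dir,
        modalities=set(source_modalities) | {target_modality},
        field_strengths=fs_needed,
    )
    if config.use_auxiliary:
        if aux_net is None and aux_checkpoint is not None:
            meta, arrays = load_checkpoint(aux_checkpoint)
            aux_net = _restore(
                AuxiliaryNet(_net_config(config, 1)), arrays["P"]
            )
        if aux_net is None:
            raise ValueError("auxiliary enabled but no pretrained network given")
        P_of = {target_modality: aux_net}
    else:
        P_of = {}

    n_br = len(source_modalities)
    rng_init = _rng_fanout(config.seed, 20)
    R = ReconstructionNet(_net_config(config, n_br), rng=rng_init)
    D = Discriminator(_net_config(config, n_br), rng=_rng_fanout(config.seed, 21))

    some_key = next(iter(ds.arrays))
    h, w = ds.arrays[some_key].shape
    directions = [(tuple(source_modalities), (config.field_strength,) * n_br,
                   target_modality, tgt_fs)]
    log = _joint_loop(R, P_of, D, ds, directions, config, (h, w))
    report = _evaluate_directions(R, ds, directions)
    if checkpoint_path is not None:
        save_checkpoint(
            checkpoint_path, {"R": R},
            {
                "kind": "reconstruction",
                "instance_stats": False,
                "directions": [
                    {"sources": list(source_modalities),
                     "source_fs": [config.field_strength] * n_br,
                     "target": target_modality, "target_fs": tgt_fs}
                ],
                "net": dataclasses.asdict(_net_config(config, n_br)),
            },
        )
    return ExperimentResult(
        metric_report=report,
        loss_log=log,
        checkpoint_path=str(checkpoint_path) if checkpoint_path else None,
        config=dataclasses.asdict(config),
        seed=config.seed,
        access_log=list(ds.access_log),
    )


def _loo_directions(field_strength: float):
    out = []
    for k, tgt in enumerate(MODALITIES):
        srcs = tuple(m for m in MODALITIES if m != tgt)
        out.append((srcs, (field_strength, field_strength), tgt, field_strength))
    return out


def train_missing_modality(manifest: DatasetManifest, base_dir, config: TrainConfig,
                           aux_nets: dict[str, AuxiliaryNet] | None = None,
                           checkpoint_path=None,
                           dataset: SliceDataset | None = None) -> ExperimentResult:
    """One unified model over all three leave-one-out directions.

    Each iteration samples a target modality m_k, feeds the other two as
    sources, and conditions everything on m_k's mask vector; the same
    weights serve all three directions at test time.
    """
    ds = dataset or SliceDataset(
        manifest, base_dir, modalities=set(MODALITIES),
        field_strengths=[config.field_strength],
    )
    present = {m for (_, _, m, _) in ds.arrays}
    if len(present & set(MODALITIES)) < 3:
        raise ValueError("missing-modality training needs all three modalities")
    P_of = dict(aux_nets or {})
    if config.use_auxiliary and not P_of:
        raise ValueError("auxiliary enabled but no pretrained networks given")

    R = ReconstructionNet(_net_config(config, 2), rng=_rng_fanout(config.seed, 20))
    D = Discriminator(_net_config(config, 2), rng=_rng_fanout(config.seed, 21))
    some_key = next(iter(ds.arrays))
    h, w = ds.arrays[some_key].shape
    directions = _loo_directions(config.field_strength)
    log = _joint_loop(R, P_of, D, ds, directions, config, (h, w))
    report = _evaluate_directions(R, ds, directions, instance_stats=True)
    if checkpoint_path is not None:
        save_checkpoint(
            checkpoint_path, {"R": R},
            {
                "kind": "reconstruction",
                "instance_stats": True,
                "directions": [
                    {"sources": list(s), "source_fs": list(sf), "target": t, "target_fs": tf}
                    for s, sf, t, tf in directions
                ],
                "net": dataclasses.asdict(_net_config(config, 2)),
            },
        )
    return ExperimentResult(
        metric_report=report,
        loss_log=log,
        checkpoint_path=str(checkpoint_path) if checkpoint_path else None,
        config=dataclasses.asdict(config),
        seed=config.seed,
        access_log=list(ds.access_log),
    )


def synthesize(checkpoint_path, sources: list[ImageSlice], target_modality: str) -> ImageSlice:
    """Pure inference through R: sources (uint8 or normalized) -> uint8 slice.

    Only the reconstruction network is loaded; the checkpoint need not
    contain P or D at all.
    """
    meta, arrays = load_checkpoint(checkpoint_path)
    if meta.get("kind") != "reconstruction":
        raise ValueError("checkpoint does not contain a reconstruction network")
    src_names = [s.modality_name for s in sources]
    direction = None
    for d in meta["directions"]:
        if d["target"] == target_modality and (
            None in src_names or list(d["sources"]) == src_names
        ):
            direction = d
            break
    if direction is None:
        raise ValueError(
            f"checkpoint does not support synthesizing {target_modality} from {src_names}"
        )
    net = _restore(ReconstructionNet(NetworkConfig(**meta["net"])), arrays["R"])
    net.eval()
    net.use_instance_stats(bool(meta.get("instance_stats", False)))
    prepared = []
    for s in sources:
        if s.intensity_domain == "uint8":
            s = normalize(s)
        prepared.append(s.pixels[None, None].astype(np.float32))
    x = np.stack(prepared)
    h, w = x.shape[-2:]
    mask = MaskVector(MODALITIES.index(target_modality), len(MODALITIES), h, w)
    y, _ = net.forward(x, mask.planes())
    out = denormalize(ImageSlice(np.clip(y[0, 0], -1, 1), "normalized"))
    return dataclasses.replace(out, modality_name=target_modality,
                               subject_id=sources[0].subject_id,
                               slice_index=sources[0].slice_index)


def evaluate_checkpoint(checkpoint_path, manifest: DatasetManifest, base_dir,
                        constants=None, dataset: SliceDataset | None = None):
    """Test-split MetricReport for every direction a checkpoint supports."""
    meta, arrays = load_checkpoint(checkpoint_path)
    net = _restore(ReconstructionNet(NetworkConfig(**meta["net"])), arrays["R"])
    directions = [
        (tuple(d["sources"]), tuple(d["source_fs"]), d["target"], d["target_fs"])
        for d in meta["directions"]
    ]
    mods = set()
    fss = set()
    for s, sf, t, tf in directions:
        mods |= set(s) | {t}
        fss |= set(sf) | {tf}
    ds = dataset or SliceDataset(manifest, base_dir, modalities=mods, field_strengths=fss)
    return _evaluate_directions(
        net, ds, directions, constants,
        instance_stats=bool(meta.get("instance_stats", False)),
    )
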