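"""Shared fixtures: a small phantom dataset and the expensive trained runs.

The trained-run fixtures are session-scoped so the ablation comparisons
and the missing-modality contract reuse the same runs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from modalgan import phantom as ph
from modalgan import training as tr

#: desk-scale study conditions used by every training-based test:
#: 8 subjects x 6 slices at 32 px, 1.5T profiles, subject-level 80/20 split
TOY_PHANTOM = dict(n_subjects=8, slices_per_subject=6, image_size=32, seed=3)
TOY_TRAIN = dict(
    iterations=1200, batch_size=8, base_channels=8, n_residual_blocks=2,
    pretrain_iterations=800, learning_rate=1e-3,
)
ABLATION_SEEDS = (0, 1, 2)


def toy_phantom_config(**overrides):
    kw = dict(TOY_PHANTOM)
    field_strengths = overrides.pop("field_strengths", (1.5,))
    kw.update(overrides)
    return ph.PhantomDatasetConfig(
        modalities=tuple(ph.default_profiles(field_strengths=field_strengths)), **kw
    )


def toy_train_config(seed=0, **overrides):
    kw = dict(TOY_TRAIN)
    kw.update(overrides)
    return tr.TrainConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory):
    """(manifest, base_dir) for the shared 1.5T toy phantom dataset."""
    base = tmp_path_factory.mktemp("phantoms")
    manifest = ph.generate_dataset(toy_phantom_config(), base)
    return manifest, base


@pytest.fixture(scope="session")
def ablation_grid(toy_dataset):
    """Per-seed training runs for the ablation comparisons.

    For each seed: the auxiliary-guided two-source model, the no-auxiliary
    ablation, and the two single-source models, all synthesizing T2-TRF
    from 1.5T inputs on held-out subjects.
    """
    manifest, base = toy_dataset
    grid = {}
    for seed in ABLATION_SEEDS:
        cfg = toy_train_config(seed=seed)
        aux, _ = tr.pretrain_auxiliary(manifest, base, "T2-TRF", cfg)
        grid[seed] = {
            "with_aux": tr.train_synthesis(
                manifest, base, ["T1-FLAIR", "T2-FLAIR"], "T2-TRF", cfg, aux_net=aux
            ),
            "no_aux": tr.train_synthesis(
                manifest, base, ["T1-FLAIR", "T2-FLAIR"], "T2-TRF",
                dataclasses.replace(cfg, use_auxiliary=False),
            ),
            "single_T1": tr.train_synthesis(
                manifest, base, ["T1-FLAIR"], "T2-TRF", cfg, aux_net=aux
            ),
            "single_T2": tr.train_synthesis(
                manifest, base, ["T2-FLAIR"], "T2-TRF", cfg, aux_net=aux
            ),
        }
    return grid


@pytest.fixture(scope="session")
def unified_run(toy_dataset, tmp_path_factory):
    """One missing-modality model over all three leave-one-out directions."""
    manifest, base = toy_dataset
    cfg = toy_train_config(seed=0)
    aux_nets = {}
    for m in ph.MODALITIES:
        aux_nets[m], _ = tr.pretrain_auxiliary(manifest, base, m, cfg)
    ckpt = tmp_path_factory.mktemp("ckpt") / "unified.npz"
    result = tr.train_missing_modality(
        manifest, base, cfg, aux_nets=aux_nets, checkpoint_path=ckpt
    )
    return result, cfg


@pytest.fixture(scope="session")
def pretrained_aux(toy_dataset):
    """A pretrained auxiliary autoencoder on T2-TRF with its config."""
    manifest, base = toy_dataset
    cfg = toy_train_config(seed=0)
    net, log = tr.pretrain_auxiliary(manifest, base, "T2-TRF", cfg)
    return net, log, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
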