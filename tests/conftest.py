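"""Shared fixtures.

Training checkpoints are expensive on 1 CPU, so they are session-scoped and
shared between the unit tests and the acceptance suite. The "desk" fixture
geometry uses a hard-core minimum separation between nuclei so that the
component-centroid detector is not limited by merged discs.
"""

from __future__ import annotations

import numpy as np
import pytest

from tilscope.synthfix import (
    CohortSpec,
    SlideSpec,
    generate_annotated_patches,
    generate_cohort,
)

# geometry for desk-scale detection fixtures: solid-body nuclei (hard-core
# spacing > disc diameter) so centroid extraction has no merging ceiling
DESK_SPEC = SlideSpec(
    lymph_density=4e-4,
    cluster_fraction=0.3,
    cluster_sigma=70.0,
    min_separation=36.0,
    distractor_density=1e-4,
    seed=11,
)


@pytest.fixture(scope="session")
def desk_patch_bank():
    """200 annotated patches split 160/40, mirroring the 80/20 protocol."""
    patches = generate_annotated_patches(200, DESK_SPEC)
    train, test = patches.split(0.8, seed=0)
    return {"all": patches, "train": train, "test": test}


@pytest.fixture(scope="session")
def desk_config():
    from tilscope.lymphseg import SegModelConfig

    return SegModelConfig(
        base_width=8,
        blocks_per_stage=1,
        epochs=8,
        batch_size=8,
        crop_size=64,
        learning_rate=2e-3,
        seed=0,
    )


@pytest.fixture(scope="session")
def desk_checkpoint(desk_patch_bank, desk_config):
    """One reference desk-scale training run (seed 0), reused widely."""
    from tilscope.lymphseg import train_model

    return train_model(desk_config, desk_patch_bank["train"],
                       desk_patch_bank["test"])


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortSpec(n_patients=200, n_genes=60,
                                      n_correlated_genes=5, seed=3))


def pooled_f1(ckpt, patch_set, model=None):
    """Pooled detection F1 of a checkpoint over an annotated patch set."""
    from tilscope.lymphseg import evaluate_detections, extract_detections
    from tilscope.lymphseg.model import predict_mask

    if model is None:
        model = ckpt.build()
    tp = fp = fn = 0
    for img, centers in patch_set.patches:
        _prob, mask = predict_mask(ckpt, img, model=model)
        res = evaluate_detections(extract_detections(mask), centers)
        tp += res.tp
        fp += len(res.fp)
        fn += len(res.fn)
    precision = tp / max(tp + fp, 1)
    recall = tp / max(tp + fn, 1)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
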