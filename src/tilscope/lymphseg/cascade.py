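"""Cascade training: predict on new patch groups, refine the masks, retrain.

The original procedure had pathologists review and correct predicted masks
until they judged accuracy to reach 0.9, with two refinement iterations in
practice. Here the reviewer is a pluggable ``refiner`` callable mapping
``(patch, predicted_mask) -> corrected_mask``; the repo provides a
ground-truth oracle refiner (for fixtures with known centers) and an
identity refiner (self-training). The stopping criterion is the mean
per-patch Dice between predictions and refined masks reaching
``stop_accuracy`` (default 0.9).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .masks import centers_to_mask
from .model import Checkpoint, predict_mask, train_on_masks, _prepare

logger = logging.getLogger(__name__)


def identity_refiner(patch, predicted_mask):
    """Accept predictions unchanged (self-training round)."""
    return predicted_mask


def oracle_refiner(group, diameter: float = 32.0):
    """Refiner that replaces predictions with ground-truth center masks.

    Stands in for expert review on fixtures whose centers are known.
    """
    truth = {id(img): centers for img, centers in group.patches}

    def refine(patch, predicted_mask):
        centers = truth[id(patch)]
        return centers_to_mask(centers, patch.shape[:2], diameter)

    return refine


def _dice(a, b):
    inter = np.logical_and(a, b).sum()
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * inter / denom


def review_group(ckpt: Checkpoint, group, refiner):
    """Predict on a patch group and refine the masks.

    Returns ``(kept_group, refined_masks, mean_dice)`` where ``mean_dice``
    is the accuracy proxy: agreement between the model's predictions and
    the refined masks. Patches whose refinement fails are skipped with a
    log entry.
    """
    model = ckpt.build()
    refined, keep_idx, dices = [], [], []
    for i, (img, _centers) in enumerate(group.patches):
        _prob, pred = predict_mask(ckpt, img, model=model)
        try:
            corrected = refiner(img, pred)
        except Exception as exc:  # refiner failure: skip patch
            logger.warning("refiner failed on patch %d: %s", i, exc)
            continue
        refined.append(corrected.astype(bool))
        keep_idx.append(i)
        dices.append(_dice(pred, corrected))
    if not refined:
        raise RuntimeError("refiner failed on every patch in the group")
    kept = type(group)(
        [group.patches[i] for i in keep_idx],
        role=group.role,
        patch_size=group.patch_size,
    )
    return kept, refined, float(np.mean(dices))


def cascade_round(ckpt: Checkpoint, group, refiner, val_pairs=None,
                  round_index: int = 1, epochs: int | None = None):
    """One review-and-refine round; returns (new checkpoint, mean_dice)."""
    kept, refined, mean_dice = review_group(ckpt, group, refiner)
    config = ckpt.config
    if epochs is not None:
        config = replace(config, epochs=epochs)
    if val_pairs is None:
        val_pairs = _prepare(kept, config.lymph_diameter)
    new_ckpt = train_on_masks(
        config, kept, refined, val_pairs, initial=ckpt,
        stage=f"cascade-{round_index}",
    )
    return new_ckpt, mean_dice


def cascade_train(ckpt: Checkpoint, groups, refiner, stop_accuracy: float = 0.9,
                  max_rounds: int = 2, val_pairs=None, epochs: int | None = None):
    """Run refinement rounds until the accuracy proxy reaches ``stop_accuracy``
    or ``max_rounds`` is exhausted; returns (checkpoint, round_log).

    ``groups`` is a list of patch groups, one per round (the last group is
    reused if fewer groups than rounds are supplied). When a round's
    accuracy proxy already meets the bar, no further retraining happens.
    """
    log = []
    for rnd in range(max_rounds):
        group = groups[min(rnd, len(groups) - 1)]
        kept, refined, mean_dice = review_group(ckpt, group, refiner)
        if mean_dice >= stop_accuracy:
            log.append(
                {"round": rnd + 1, "accuracy_proxy": mean_dice, "stopped": True}
            )
            return ckpt, log
        config = ckpt.config
        if epochs is not None:
            config = replace(config, epochs=epochs)
        vp = val_pairs if val_pairs is not None else _prepare(
            kept, config.lymph_diameter
        )
        ckpt = train_on_masks(
            config, kept, refined, vp, initial=ckpt, stage=f"cascade-{rnd + 1}"
        )
        log.append({"round": rnd + 1, "accuracy_proxy": mean_dice})
    return ckpt, log
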