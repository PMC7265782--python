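"""Training-mask construction from center annotations, and augmentation."""

from __future__ import annotations

import numpy as np

from ..errors import SpecValidationError


def centers_to_mask(centers, shape, diameter: float = 32.0) -> np.ndarray:
    """Dilate each annotated center into a filled disc; overlaps merge.

    A pixel (r, c) belongs to the mask iff ``||(r, c) - center|| <= diameter/2``
    for some center (distances on pixel centers). Discs extending past the
    image border are clipped.
    """
    if diameter < 1:
        raise SpecValidationError("diameter must be >= 1")
    mask = np.zeros(shape, dtype=bool)
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    radius = diameter / 2.0
    for r, c in centers:
        r0 = max(int(np.floor(r - radius)), 0)
        r1 = min(int(np.ceil(r + radius)) + 1, shape[0])
        c0 = max(int(np.floor(c - radius)), 0)
        c1 = min(int(np.ceil(c + radius)) + 1, shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        mask[r0:r1, c0:c1] |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
    return mask


def augment(
    patch: np.ndarray,
    mask: np.ndarray,
    seed=None,
    crop_size: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Random mirror (horizontal/vertical) and random crop, applied jointly.

    The identical geometric transform is applied to patch and mask, so
    annotations stay aligned. Reproducible given ``seed`` (or an explicit
    ``rng``, which is advanced in place).
    """
    if patch.shape[:2] != mask.shape[:2]:
        raise SpecValidationError("patch and mask must be aligned")
    if rng is None:
        rng = np.random.default_rng(seed)
    h, w = patch.shape[:2]
    if crop_size is not None:
        if crop_size > h or crop_size > w:
            raise SpecValidationError("crop size exceeds patch size")
        r0 = int(rng.integers(0, h - crop_size + 1))
        c0 = int(rng.integers(0, w - crop_size + 1))
        patch = patch[r0 : r0 + crop_size, c0 : c0 + crop_size]
        mask = mask[r0 : r0 + crop_size, c0 : c0 + crop_size]
    if rng.random() < 0.5:
        patch, mask = patch[:, ::-1], mask[:, ::-1]
    if rng.random() < 0.5:
        patch, mask = patch[::-1, :], mask[::-1, :]
    return np.ascontiguousarray(patch), np.ascontiguousarray(mask)


def mirror(patch: np.ndarray, axis: int):
    """Deterministic mirror; applying it twice restores the input."""
    return np.ascontiguousarray(np.flip(patch, axis=axis))
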