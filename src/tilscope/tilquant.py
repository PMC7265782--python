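"""FOV tiling, global TIL map assembly, and the slide-level TIL score.

The FOV crop is split into nonoverlapping fixed-size patches (partial edge
patches are dropped); patches with more than 80% background are discarded.
Each valid patch is scored by the segmenter: ``L_i`` counts predicted
lymphocyte pixels within tissue and ``T_i`` counts tissue pixels. The TIL
score is the ratio of sums ``sum(L_i) / sum(T_i)`` — deliberately not the
mean of per-patch ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import NoTissueError, SpecValidationError
from .fovdetect import TissueClusterModel
from .lymphseg.model import Checkpoint, predict_mask

MAX_BACKGROUND_FRACTION = 0.8
PATCH_SIZE = 200
LEVEL_SCALE = 250  # patch_level color scale endpoint ("filled with TILs")


@dataclass(frozen=True)
class PatchGridEntry:
    grid_row: int
    grid_col: int
    offset: tuple  # (row, col) of the patch's top-left corner in the crop
    valid: bool
    background_fraction: float


@dataclass(frozen=True)
class PatchGrid:
    patch_size: int
    entries: tuple  # row-major tuple of PatchGridEntry
    shape: tuple  # (n_rows, n_cols)

    @property
    def K(self) -> int:
        return sum(e.valid for e in self.entries)


@dataclass(frozen=True)
class TILMap:
    """Per-patch lymphocyte/tissue pixel counts plus the stitched mask."""

    grid: PatchGrid
    L: np.ndarray  # int, per entry (row-major, invalid entries 0)
    T: np.ndarray  # int, per entry
    stitched_mask: np.ndarray  # bool, crop-shaped
    patch_size: int = PATCH_SIZE

    @property
    def patch_level(self) -> np.ndarray:
        """Visualization level 0..250 per patch: round(250 * L_i / T_i)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            lvl = np.where(
                self.T > 0, np.round(LEVEL_SCALE * self.L / np.maximum(self.T, 1)), 0
            )
        return lvl.astype(int)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.array([e.valid for e in self.grid.entries], dtype=bool)


@dataclass(frozen=True)
class TILScore:
    value: float  # fraction in [0, 1]


def tile_fov(
    crop: np.ndarray,
    cluster_model: TissueClusterModel,
    patch_size: int = PATCH_SIZE,
    max_background: float = MAX_BACKGROUND_FRACTION,
    background_mask: np.ndarray | None = None,
) -> tuple[PatchGrid, np.ndarray]:
    """Enumerate nonoverlapping patches row-major and flag valid ones.

    Background is decided per pixel by ``cluster_model`` (the K-means color
    model fitted during FOV detection, applied at full resolution), unless an
    explicit ``background_mask`` is given. Returns the grid and the full-
    resolution tissue mask of the crop.
    """
    h, w = crop.shape[:2]
    if background_mask is None:
        background_mask = cluster_model.background_mask(crop)
    if background_mask.shape != (h, w):
        raise SpecValidationError("background mask must match the crop")
    n_rows, n_cols = h // patch_size, w // patch_size
    if n_rows == 0 or n_cols == 0:
        warnings.warn(
            "crop smaller than one patch; using a single clipped patch",
            stacklevel=2,
        )
        n_rows, n_cols = max(n_rows, 1), max(n_cols, 1)
    entries = []
    for gr in range(n_rows):
        for gc in range(n_cols):
            r0, c0 = gr * patch_size, gc * patch_size
            block = background_mask[r0 : r0 + patch_size, c0 : c0 + patch_size]
            bg_frac = float(block.mean())
            entries.append(
                PatchGridEntry(
                    grid_row=gr,
                    grid_col=gc,
                    offset=(r0, c0),
                    valid=bg_frac <= max_background,
                    background_fraction=bg_frac,
                )
            )
    grid = PatchGrid(
        patch_size=patch_size, entries=tuple(entries), shape=(n_rows, n_cols)
    )
    return grid, ~background_mask


def compute_til_map(
    ckpt: Checkpoint,
    grid: PatchGrid,
    crop: np.ndarray,
    tissue_mask: np.ndarray,
) -> TILMap:
    """Run the segmenter over valid patches and assemble the global TIL map.

    ``L_i`` = predicted lymphocyte pixels intersected with tissue;
    ``T_i`` = tissue pixels in the patch. Invalid patches are skipped and
    contribute nothing to the stitched mask or the score.
    """
    model = ckpt.build()
    n = len(grid.entries)
    L = np.zeros(n, dtype=np.int64)
    T = np.zeros(n, dtype=np.int64)
    stitched = np.zeros(crop.shape[:2], dtype=bool)
    ps = grid.patch_size
    for i, e in enumerate(grid.entries):
        r0, c0 = e.offset
        tiss = tissue_mask[r0 : r0 + ps, c0 : c0 + ps]
        if not e.valid:
            continue
        patch = crop[r0 : r0 + ps, c0 : c0 + ps]
        _prob, mask = predict_mask(ckpt, patch, model=model)
        lymph = mask & tiss
        stitched[r0 : r0 + ps, c0 : c0 + ps] = lymph
        L[i] = int(lymph.sum())
        T[i] = int(tiss.sum())
    return TILMap(grid=grid, L=L, T=T, stitched_mask=stitched, patch_size=ps)


def til_score(til_map: TILMap) -> TILScore:
    """Slide-level TIL score: ratio of summed lymphocyte to tissue pixels."""
    valid = til_map.valid_mask
    if til_map.grid.K < 1:
        raise NoTissueError("no valid patches: cannot compute a TIL score")
    total_T = int(til_map.T[valid].sum())
    if total_T == 0:
        raise NoTissueError("no tissue pixels in valid patches")
    total_L = int(til_map.L[valid].sum())
    return TILScore(value=total_L / total_T)
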