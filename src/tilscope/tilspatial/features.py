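"""TIL-patch selection and the per-slide spatial feature vector."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..tilquant import TILMap, til_score
from ..errors import NoTissueError
from .ap import APClustering, affinity_propagation
from .indices import INDEX_NAMES, compute_all_indices

#: Default minimum lymphocyte fraction for a patch to count as a TIL patch.
DEFAULT_MIN_FRACTION = 0.1

FEATURE_NAMES = ["til_pct"] + list(INDEX_NAMES)


@dataclass(frozen=True)
class TILPointSet:
    """Grid coordinates of the patches designated as TIL patches."""

    points: np.ndarray  # (m, 2) of (grid_row, grid_col)
    min_fraction: float

    def __len__(self):
        return len(self.points)


@dataclass(frozen=True)
class SpatialFeatureVector:
    """TIL% plus the 42 validity indices; undefined entries are NaN."""

    values: dict  # name -> float, in FEATURE_NAMES order
    n_points: int = 0
    clustering: APClustering | None = None

    def as_row(self):
        return {name: self.values[name] for name in FEATURE_NAMES}


def select_til_patches(
    til_map: TILMap, min_fraction: float = DEFAULT_MIN_FRACTION
) -> TILPointSet:
    """Valid patches whose lymphocyte fraction L_i/T_i >= min_fraction."""
    pts = []
    for i, e in enumerate(til_map.grid.entries):
        if not e.valid or til_map.T[i] == 0:
            continue
        if til_map.L[i] / til_map.T[i] >= min_fraction:
            pts.append((e.grid_row, e.grid_col))
    return TILPointSet(
        points=np.asarray(pts, dtype=float).reshape(-1, 2),
        min_fraction=min_fraction,
    )


def compute_feature_vector(
    til_map: TILMap,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    preference="median",
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_iter: int = 100,
    seed: int = 0,
) -> SpatialFeatureVector:
    """TIL% plus the 42 validity indices of the AP clustering of TIL patches.

    With fewer than 2 TIL patches (or a single resulting cluster) the
    spatial indices are undefined and reported as NaN; TIL% is always
    computed (0 when the map has no lymphocyte pixels but valid tissue).
    """
    try:
        score = til_score(til_map).value
    except NoTissueError:
        score = np.nan
    values = {name: np.nan for name in FEATURE_NAMES}
    values["til_pct"] = score
    points = select_til_patches(til_map, min_fraction).points
    clustering = None
    if len(points) >= 2:
        clustering = affinity_propagation(
            points,
            preference=preference,
            damping=damping,
            max_iter=max_iter,
            conv_iter=conv_iter,
            seed=seed,
        )
        values.update(compute_all_indices(points, clustering.labels))
    elif len(points) == 1:
        clustering = affinity_propagation(points, preference=preference,
                                          damping=damping, seed=seed)
    return SpatialFeatureVector(
        values=values, n_points=len(points), clustering=clustering
    )
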