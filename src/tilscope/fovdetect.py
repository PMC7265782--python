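"""Field-of-view identification on a slide by low-resolution color clustering.

The slide is downsampled, converted to CIELAB, and its pixels are split into
``k`` color groups by K-means. The group containing the upper-left corner
pixel is treated as background (slide corners are normally unstained); all
remaining groups form the tissue mask. The FOV is the tight bounding box of
the largest connected tissue component, mapped back to full resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab
from skimage.measure import label, regionprops
from sklearn.cluster import KMeans

from .errors import NoTissueError, SpecValidationError
from .synthfix import RasterSlide

EMPTY_BBOX = (0, 0, 0, 0)


@dataclass(frozen=True)
class TissueClusterModel:
    """Fitted color-cluster model: LAB centers plus the background labels.

    ``background_labels`` contains the corner-pixel cluster and any cluster
    whose center is nearly the same color (K-means may split a uniform
    unstained background into several clusters).
    """

    centers_lab: np.ndarray  # (k, 3)
    background_labels: tuple  # corner cluster + near-identical clusters

    @property
    def background_label(self) -> int:
        return self.background_labels[0]

    def classify(self, rgb: np.ndarray) -> np.ndarray:
        """Assign each pixel of an RGB raster to its nearest LAB center."""
        lab = rgb2lab(rgb)
        d2 = ((lab[..., None, :] - self.centers_lab) ** 2).sum(axis=-1)
        return d2.argmin(axis=-1)

    def background_mask(self, rgb: np.ndarray) -> np.ndarray:
        return np.isin(self.classify(rgb), self.background_labels)


@dataclass(frozen=True)
class FOVRegion:
    """The field of view at low and full resolution.

    ``bbox_low`` is the tight half-open box of the largest tissue component
    in downsampled coordinates; ``bbox_full`` is the same box scaled by the
    downsample factor and clipped to the slide bounds.
    """

    bbox_low: tuple
    bbox_full: tuple
    tissue_mask_low: np.ndarray
    factor: int
    cluster_model: TissueClusterModel


def downsample(slide: RasterSlide, factor: int) -> np.ndarray:
    """Downsample by integer striding; output dims are ceil(input/factor)."""
    if factor < 1:
        raise SpecValidationError("downsample factor must be >= 1")
    if factor == 1:
        return slide.pixels
    return slide.pixels[::factor, ::factor]


def cluster_tissue(
    image: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_init: int = 5,
    background_merge_tol: float = 8.0,
) -> tuple[np.ndarray, int, TissueClusterModel]:
    """Cluster pixels in CIELAB space into ``k`` color groups.

    Returns per-pixel labels, the background label (cluster of pixel (0, 0)),
    and the fitted model for re-classifying full-resolution pixels. Clusters
    whose LAB center lies within ``background_merge_tol`` of the corner
    cluster's center are treated as background too (a uniform unstained
    background can be split by K-means when k exceeds the number of true
    color groups).
    """
    if k < 2:
        raise SpecValidationError("k must be >= 2")
    lab = rgb2lab(image)
    flat = lab.reshape(-1, 3)
    uniq = np.unique(flat, axis=0)
    if len(uniq) < k:
        warnings.warn(
            f"only {len(uniq)} distinct colors for k={k}; "
            "assigning one cluster per distinct color",
            stacklevel=2,
        )
        centers = uniq
        d2 = ((flat[:, None, :] - centers) ** 2).sum(axis=-1)
        labels = d2.argmin(axis=1).reshape(image.shape[:2])
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(flat).reshape(image.shape[:2])
        centers = km.cluster_centers_
    background = int(labels[0, 0])
    centers = np.asarray(centers, float)
    close = np.linalg.norm(centers - centers[background], axis=1)
    bg_labels = (background,) + tuple(
        int(i) for i in np.nonzero(close <= background_merge_tol)[0]
        if i != background
    )
    frac_bg = np.isin(labels, bg_labels).mean()
    if frac_bg > 0.95:
        warnings.warn(
            "corner-pixel cluster covers >95% of the image; "
            "slide may be unstained",
            stacklevel=2,
        )
    model = TissueClusterModel(centers_lab=centers,
                               background_labels=bg_labels)
    return labels, background, model


def largest_tissue_bbox(tissue_mask: np.ndarray, connectivity: int = 8) -> tuple:
    """Tight half-open bounding box of the largest connected component.

    Ties in component size are broken by smallest (row, col) of the
    component's top-left bbox corner. An empty mask yields ``EMPTY_BBOX``.
    """
    if connectivity not in (4, 8):
        raise SpecValidationError("connectivity must be 4 or 8")
    lab = label(tissue_mask, connectivity=1 if connectivity == 4 else 2)
    if lab.max() == 0:
        return EMPTY_BBOX
    best = max(regionprops(lab), key=lambda p: (p.area, -p.bbox[0], -p.bbox[1]))
    r0, c0, r1, c1 = best.bbox
    return (r0, r1, c0, c1)


def identify_fov(
    slide: RasterSlide,
    k: int = 3,
    seed: int = 0,
    connectivity: int = 8,
) -> FOVRegion:
    """Locate the FOV: downsample, cluster colors, box the largest component.

    Raises :class:`NoTissueError` when every pixel falls in the background
    cluster.
    """
    factor = slide.downsample_factor
    low = downsample(slide, factor)
    labels, _background, model = cluster_tissue(low, k=k, seed=seed)
    tissue_mask = ~np.isin(labels, model.background_labels)
    if not tissue_mask.any():
        raise NoTissueError("no tissue detected: all pixels are background")
    bbox_low = largest_tissue_bbox(tissue_mask, connectivity=connectivity)
    h, w = slide.shape
    r0, r1, c0, c1 = bbox_low
    bbox_full = (
        min(r0 * factor, h),
        min(r1 * factor, h),
        min(c0 * factor, w),
        min(c1 * factor, w),
    )
    return FOVRegion(
        bbox_low=bbox_low,
        bbox_full=bbox_full,
        tissue_mask_low=tissue_mask,
        factor=factor,
        cluster_model=model,
    )


def crop_fov(slide: RasterSlide, fov: FOVRegion) -> np.ndarray:
    """Return the full-resolution FOV crop."""
    r0, r1, c0, c1 = fov.bbox_full
    if r0 >= r1 or c0 >= c1:
        raise NoTissueError("empty FOV region")
    return slide.pixels[r0:r1, c0:c1]
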