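"""Synthetic slides, annotated patches and cohort tables with known ground truth.

Everything downstream of this module (FOV detection, segmentation, TIL
mapping, spatial features, association analyses) is tested against fixtures
produced here, so generation is fully deterministic for a fixed seed and the
ground truth is exact by construction.

Conventions used throughout the package (stated once, here):

- coordinates are 0-based and row-major: points are ``(row, col)``;
- rectangles are half-open: ``(row_start, row_stop, col_start, col_stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.measure import label, regionprops

from .errors import SpecValidationError

# Hematoxylin-like hue for lymphocyte nuclei; eosin-like default tissue stain.
LYMPH_COLOR = (64, 48, 122)
TISSUE_COLOR = (228, 160, 188)
DISTRACTOR_COLOR = (178, 130, 190)


# ---------------------------------------------------------------------------
# Slide generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlideSpec:
    """Parameters of a synthetic stained-tissue slide at nominal 40x.

    ``lymph_density`` is the expected number of lymphocytes per tissue pixel
    (so the expected count is ``density * tissue_area``).
    ``cluster_fraction`` of the lymphocytes are placed by a parent/offspring
    (Matern-style) clustered process, the rest uniformly over tissue.
    """

    width: int = 1024
    height: int = 1024
    tissue_blobs: tuple = (((512, 512), 400, TISSUE_COLOR),)
    lymph_density: float = 3e-4
    lymph_diameter: int = 32
    cluster_fraction: float = 0.3
    cluster_sigma: float = 60.0
    mean_cluster_size: float = 12.0
    min_separation: float = 0.0  # hard-core thinning distance (Matern II)
    distractor_density: float = 0.0
    background_color: tuple = (246, 244, 246)
    noise_sd: float = 2.0
    magnification: float = 40.0
    seed: int = 0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise SpecValidationError("slide dimensions must be positive")
        if self.lymph_diameter < 4:
            raise SpecValidationError("lymph_diameter must be >= 4")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise SpecValidationError("cluster_fraction must be in [0, 1]")
        if self.lymph_density < 0 or self.distractor_density < 0:
            raise SpecValidationError("densities must be >= 0")
        if not self.tissue_blobs:
            raise SpecValidationError("at least one tissue blob is required")
        for (r, c), radius, _color in self.tissue_blobs:
            if radius <= 0:
                raise SpecValidationError("blob radius must be positive")
            if not (0 <= r < self.height and 0 <= c < self.width):
                raise SpecValidationError(
                    f"blob center ({r}, {c}) lies outside the "
                    f"{self.height}x{self.width} canvas"
                )


@dataclass(frozen=True)
class SlideGroundTruth:
    """Exact ground truth for a generated slide."""

    tissue_mask: np.ndarray  # bool, (H, W)
    tissue_bbox: tuple  # (r0, r1, c0, c1), half-open; largest component
    lymph_centers: np.ndarray  # float, (n, 2) as (row, col)
    distractor_centers: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2))
    )


@dataclass(frozen=True)
class RasterSlide:
    """An RGB raster standing in for a whole-slide image."""

    pixels: np.ndarray  # uint8, (H, W, 3)
    downsample_factor: int = 16
    magnification: float = 40.0

    def __post_init__(self):
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3 or px.size == 0:
            raise SpecValidationError("slide pixels must be a nonempty HxWx3 raster")

    @property
    def shape(self):
        return self.pixels.shape[:2]


def _disc_coords(center, radius, shape):
    """Integer pixel coordinates with ||p - center|| <= radius, clipped."""
    r0 = max(int(np.floor(center[0] - radius)), 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 1, shape[0])
    c0 = max(int(np.floor(center[1] - radius)), 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    keep = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return rr[keep], cc[keep]


def _largest_component_bbox(mask: np.ndarray):
    """Tight half-open bbox of the largest 8-connected component, or None."""
    lab = label(mask, connectivity=2)
    if lab.max() == 0:
        return None
    best = max(
        regionprops(lab), key=lambda p: (p.area, -p.bbox[0], -p.bbox[1])
    )
    r0, c0, r1, c1 = best.bbox
    return (r0, r1, c0, c1)


def _sample_on_mask(rng, mask_coords, n):
    idx = rng.integers(0, len(mask_coords[0]), size=n)
    return np.stack([mask_coords[0][idx], mask_coords[1][idx]], axis=1).astype(float)


def _place_lymphocytes(rng, spec: SlideSpec, tissue_mask: np.ndarray) -> np.ndarray:
    """Poisson-distributed centers, a mix of clustered and uniform placement."""
    coords = np.nonzero(tissue_mask)
    area = len(coords[0])
    if area == 0 or spec.lymph_density == 0:
        return np.empty((0, 2))
    total = rng.poisson(spec.lymph_density * area)
    n_clustered = rng.binomial(total, spec.cluster_fraction)
    centers = [_sample_on_mask(rng, coords, total - n_clustered)]
    placed = total - n_clustered
    # Matern-style: parents uniform on tissue, offspring isotropic Gaussian.
    while placed < total:
        parent = _sample_on_mask(rng, coords, 1)[0]
        k = min(1 + rng.poisson(spec.mean_cluster_size), total - placed)
        off = parent + rng.normal(0.0, spec.cluster_sigma, size=(k, 2))
        off_i = np.round(off).astype(int)
        ok = (
            (off[:, 0] >= 0)
            & (off_i[:, 0] < tissue_mask.shape[0])
            & (off[:, 1] >= 0)
            & (off_i[:, 1] < tissue_mask.shape[1])
        )
        ok &= (off[:, 0] < tissue_mask.shape[0] - 0.5) & (
            off[:, 1] < tissue_mask.shape[1] - 0.5
        )
        ok[ok] &= tissue_mask[off_i[ok, 0], off_i[ok, 1]]
        kept = off[ok]
        centers.append(kept)
        placed += len(kept)
    out = np.concatenate(centers, axis=0) if centers else np.empty((0, 2))
    if spec.min_separation > 0 and len(out) > 1:
        out = _hardcore_thin(rng, out, spec.min_separation)
    return out


def _hardcore_thin(rng, centers, min_sep):
    """Matern II thinning: keep the lower-marked point of any close pair."""
    marks = rng.random(len(centers))
    order = np.argsort(marks)
    kept: list[np.ndarray] = []
    min_sep2 = min_sep**2
    for i in order:
        p = centers[i]
        if all(((p - q) ** 2).sum() >= min_sep2 for q in kept):
            kept.append(p)
    return np.asarray(kept).reshape(-1, 2)


def generate_slide(spec: SlideSpec) -> tuple[RasterSlide, SlideGroundTruth]:
    """Render a synthetic slide and its exact ground truth.

    Deterministic for a fixed ``spec.seed``. Lymphocytes are dark round discs
    of ``spec.lymph_diameter`` whose rendered pixels are always a subset of
    the tissue mask; the background is near-white.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)

    img = np.empty((*shape, 3), dtype=float)
    img[:] = spec.background_color

    tissue_mask = np.zeros(shape, dtype=bool)
    for (r, c), radius, color in spec.tissue_blobs:
        rr, cc = _disc_coords((r, c), radius, shape)
        tissue_mask[rr, cc] = True
        img[rr, cc] = color

    lymph_centers = _place_lymphocytes(rng, spec, tissue_mask)

    n_distract = (
        rng.poisson(spec.distractor_density * tissue_mask.sum())
        if spec.distractor_density > 0
        else 0
    )
    distractor_centers = np.empty((0, 2))
    if n_distract:
        coords = np.nonzero(tissue_mask)
        distractor_centers = _sample_on_mask(rng, coords, n_distract)
        for ctr in distractor_centers:
            # larger, paler, elliptical non-lymphocyte nuclei
            ax_r = spec.lymph_diameter * rng.uniform(0.7, 1.1)
            ax_c = spec.lymph_diameter * rng.uniform(0.45, 0.7)
            rr, cc = _disc_coords(ctr, ax_r, shape)
            keep = ((rr - ctr[0]) / ax_r) ** 2 + ((cc - ctr[1]) / ax_c) ** 2 <= 1.0
            rr, cc = rr[keep], cc[keep]
            inside = tissue_mask[rr, cc]
            img[rr[inside], cc[inside]] = DISTRACTOR_COLOR

    radius = spec.lymph_diameter / 2.0
    for ctr in lymph_centers:
        rr, cc = _disc_coords(ctr, radius, shape)
        inside = tissue_mask[rr, cc]  # keep disc pixels within tissue
        img[rr[inside], cc[inside]] = LYMPH_COLOR

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    bbox = _largest_component_bbox(tissue_mask)
    truth = SlideGroundTruth(
        tissue_mask=tissue_mask,
        tissue_bbox=bbox,
        lymph_centers=lymph_centers,
        distractor_centers=distractor_centers,
    )
    slide = RasterSlide(pixels=pixels, magnification=spec.magnification)
    return slide, truth


# ---------------------------------------------------------------------------
# Annotated patches
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedPatchSet:
    """A set of equally sized RGB patches with lymphocyte-center annotations."""

    patches: list  # list of (uint8 (H, W, 3), float (n, 2) centers)
    role: str = "initial"
    patch_size: int = 200

    def __post_init__(self):
        for img, centers in self.patches:
            if img.shape[:2] != (self.patch_size, self.patch_size):
                raise SpecValidationError("all patches must share patch_size")
            centers = np.asarray(centers, dtype=float).reshape(-1, 2)
            if len(centers) and (
                centers.min() < 0 or centers.max() >= self.patch_size
            ):
                raise SpecValidationError("centers must lie inside the patch")

    def __len__(self):
        return len(self.patches)

    def split(self, train_fraction: float = 0.8, seed: int = 0):
        """Reproducible disjoint train/test split (default 80/20)."""
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(self.patches))
        n_train = int(round(train_fraction * len(self.patches)))
        train = [self.patches[i] for i in order[:n_train]]
        test = [self.patches[i] for i in order[n_train:]]
        return (
            AnnotatedPatchSet(train, role=self.role, patch_size=self.patch_size),
            AnnotatedPatchSet(test, role=self.role, patch_size=self.patch_size),
        )


def generate_annotated_patches(
    n: int, spec: SlideSpec, patch_size: int = 200, role: str = "initial"
) -> AnnotatedPatchSet:
    """Generate ``n`` annotated patches of ``patch_size`` squared pixels.

    Each patch is rendered as a miniature slide whose single tissue blob
    covers most of the patch; geometry (blob extent, densities, clustering)
    comes from ``spec``, with one independent child seed per patch.
    """
    if n <= 0:
        raise SpecValidationError("n must be positive")
    spec.validate()
    seeds = np.random.SeedSequence(spec.seed).generate_state(n)
    patches = []
    half = patch_size // 2
    for i in range(n):
        sub_rng = np.random.default_rng(seeds[i])
        center = (
            half + sub_rng.integers(-patch_size // 8, patch_size // 8 + 1),
            half + sub_rng.integers(-patch_size // 8, patch_size // 8 + 1),
        )
        radius = patch_size * sub_rng.uniform(0.55, 0.9)
        sub = replace(
            spec,
            width=patch_size,
            height=patch_size,
            tissue_blobs=(((int(center[0]), int(center[1])), radius, TISSUE_COLOR),),
            cluster_sigma=min(spec.cluster_sigma, patch_size / 5.0),
            seed=int(seeds[i]),
        )
        slide, truth = generate_slide(sub)
        patches.append((slide.pixels, truth.lymph_centers))
    return AnnotatedPatchSet(patches, role=role, patch_size=patch_size)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic patient cohort with planted associations."""

    n_patients: int = 200
    n_genes: int = 100
    n_correlated_genes: int = 5
    planted_rho: float = 0.6
    n_mut_genes: int = 3
    n_null_mut_genes: int = 10
    mut_effect: float = 1.0
    mut_rate: float = 0.1
    surv_feature: str = "gamma"
    surv_feature_effect: float = 2.0  # hazard ratio per SD of the feature
    baseline_hazard: float = 1e-3
    censoring_rate: float = 0.2
    n_spatial_features: int = 6
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_patients, self.n_genes, self.n_mut_genes + 1) <= 0:
            raise SpecValidationError("counts must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise SpecValidationError("censoring_rate must be in [0, 1)")
        if self.n_correlated_genes > self.n_genes:
            raise SpecValidationError("n_correlated_genes must be <= n_genes")
        if abs(self.planted_rho) >= 1.0:
            raise SpecValidationError("planted Spearman rho must satisfy |rho| < 1")
        if self.surv_feature_effect <= 0:
            raise SpecValidationError("hazard ratio must be positive")


@dataclass
class CohortTable:
    """Per-patient clinical, omics and image-feature records.

    ``clinical`` columns: patient_id, er, pr, her2, time, event, til_score.
    ``expression``/``mutation`` are genes x patients DataFrames; ``features``
    is patients x spatial-feature columns. ``planted`` records the ground
    truth used by recovery tests.
    """

    clinical: pd.DataFrame
    expression: pd.DataFrame
    mutation: pd.DataFrame
    features: pd.DataFrame
    planted: dict = field(default_factory=dict)


def _spearman_to_pearson(rho: float) -> float:
    """Pearson correlation of a bivariate normal with Spearman rho."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Build a cohort with planted gene-TIL correlations, mutation shifts,
    and a proportional-hazards effect of one named spatial feature."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    ids = [f"P{i:04d}" for i in range(n)]

    # -- mutations (planted genes shift the TIL latent; nulls do not) --------
    mut_genes = [f"MUT{i:03d}" for i in range(spec.n_mut_genes)]
    null_mut_genes = [f"NMUT{i:03d}" for i in range(spec.n_null_mut_genes)]
    mut = {}
    for g in mut_genes + null_mut_genes:
        status = rng.random(n) < spec.mut_rate
        while status.sum() < 10:  # guarantee the >=10-patient filter passes
            status[rng.integers(0, n)] = True
        mut[g] = status.astype(np.int8)
    mutation = pd.DataFrame(mut, index=ids).T

    # -- TIL latent and score ------------------------------------------------
    z = rng.normal(size=n)
    for g in mut_genes:
        status = mutation.loc[g].to_numpy().astype(bool)
        z = z + spec.mut_effect * (status - status.mean())
    # strictly monotone squash into (0, 0.5): Spearman structure preserved
    til_score = 0.5 / (1.0 + np.exp(-z))

    # -- expression with planted Spearman correlation ------------------------
    # Gaussian copula: rank-normalize the TIL latent, then mix.
    ranks = pd.Series(z).rank(method="average").to_numpy()
    z_copula = np.asarray(
        np.sqrt(2) * _erfinv_vec(2 * (ranks - 0.5) / n - 1)
    )
    r = _spearman_to_pearson(spec.planted_rho)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    expr = rng.normal(size=(spec.n_genes, n))
    for j in range(spec.n_correlated_genes):
        expr[j] = r * z_copula + np.sqrt(1 - r * r) * rng.normal(size=n)
    expression = pd.DataFrame(expr, index=genes, columns=ids)

    # -- spatial features and survival --------------------------------------
    feat_names = _feature_column_names(spec)
    feats = rng.normal(size=(n, len(feat_names)))
    features = pd.DataFrame(feats, index=ids, columns=feat_names)
    x = features[spec.surv_feature].to_numpy()
    x_std = (x - x.mean()) / x.std()
    beta = np.log(spec.surv_feature_effect)
    rate = spec.baseline_hazard * np.exp(beta * x_std)
    t_event = rng.exponential(1.0 / rate)

    time, event = _apply_censoring(rng, t_event, spec.censoring_rate)

    # -- markers -------------------------------------------------------------
    er = rng.random(n) < 0.65
    pr = np.where(er, rng.random(n) < 0.8, rng.random(n) < 0.3)
    her2 = rng.random(n) < 0.2

    clinical = pd.DataFrame(
        {
            "patient_id": ids,
            "er": np.where(er, "+", "-"),
            "pr": np.where(pr, "+", "-"),
            "her2": np.where(her2, "+", "-"),
            "time": time,
            "event": event,
            "til_score": til_score,
        }
    ).set_index("patient_id", drop=False)

    planted = {
        "correlated_genes": genes[: spec.n_correlated_genes],
        "planted_rho": spec.planted_rho,
        "mut_genes": mut_genes,
        "null_mut_genes": null_mut_genes,
        "surv_feature": spec.surv_feature,
        "hazard_ratio": spec.surv_feature_effect,
    }
    return CohortTable(clinical, expression, mutation, features, planted)


def _feature_column_names(spec: CohortSpec):
    base = ["til_pct", "gamma", "g_plus", "banfeld_raftery", "pbm", "tau"]
    names = [n for n in base]
    if spec.surv_feature not in names:
        names.insert(1, spec.surv_feature)
    i = 0
    while len(names) < spec.n_spatial_features + 1:
        names.append(f"feat{i:02d}")
        i += 1
    return names


def _erfinv_vec(x):
    from scipy.special import erfinv

    return erfinv(np.clip(x, -1 + 1e-12, 1 - 1e-12))


def _apply_censoring(rng, t_event, censoring_rate):
    """Independent exponential censoring calibrated to the requested rate."""
    n = len(t_event)
    if censoring_rate == 0:
        return t_event, np.ones(n, dtype=np.int8)

    # one fixed uniform draw reused across the root-finding scan so the
    # objective is monotone in the rate
    rng_c = np.random.default_rng(rng.integers(2**63))
    u = rng_c.random(n)

    def frac(log_rate):
        c = -np.log(u) * np.exp(-log_rate)
        return (c < t_event).mean() - censoring_rate

    lo, hi = -20.0, 20.0
    try:
        log_rate = brentq(frac, lo, hi, xtol=1e-3)
    except ValueError:
        log_rate = 0.0
    c = -np.log(u) * np.exp(-log_rate)
    event = (t_event <= c).astype(np.int8)
    time = np.minimum(t_event, c)
    return time, event
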