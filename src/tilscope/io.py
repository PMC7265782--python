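"""Reading and writing of pipeline artifacts (CSV/JSON/PNG round trips).

Every CSV written here starts with ``#``-prefixed metadata lines carrying
the package version, the seed, and a hash of the resolved configuration, so
any output file is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .errors import FormatError
from .tilquant import PatchGrid, PatchGridEntry, TILMap
from .tilspatial.features import FEATURE_NAMES, SpatialFeatureVector


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _metadata_lines(seed, config) -> list[str]:
    return [
        f"# tilscope_version={__version__}",
        f"# seed={seed}",
        f"# config_hash={config_hash(config or {})}",
    ]


def _write_csv_with_header(df: pd.DataFrame, path, seed=None, config=None):
    with open(path, "w") as fh:
        for line in _metadata_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def _read_csv_skip_header(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# annotations (lymphocyte centers)
# ---------------------------------------------------------------------------


def write_centers(centers, path, seed=None, config=None):
    df = pd.DataFrame(np.asarray(centers, float).reshape(-1, 2),
                      columns=["row", "col"])
    _write_csv_with_header(df, path, seed=seed, config=config)


def read_centers(path, shape=None) -> np.ndarray:
    """Load a ``row,col`` center table; validates bounds when ``shape`` given."""
    df = _read_csv_skip_header(path)
    if list(df.columns) != ["row", "col"]:
        raise FormatError(f"{path}: expected columns row,col, got {list(df.columns)}")
    centers = df.to_numpy(dtype=float)
    if shape is not None and len(centers):
        bad = np.nonzero(
            (centers[:, 0] < 0)
            | (centers[:, 0] >= shape[0])
            | (centers[:, 1] < 0)
            | (centers[:, 1] >= shape[1])
        )[0]
        if len(bad):
            raise FormatError(
                f"{path}: center out of bounds at data row {bad[0]}: "
                f"{tuple(centers[bad[0]])} for shape {shape}"
            )
    return centers


# ---------------------------------------------------------------------------
# slides and FOV
# ---------------------------------------------------------------------------


def write_image(pixels: np.ndarray, path):
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_fov(fov, path, seed=None, config=None):
    payload = {
        "bbox_low": list(fov.bbox_low),
        "bbox_full": list(fov.bbox_full),
        "factor": fov.factor,
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_fov(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("bbox_low", "bbox_full", "factor"):
        if key not in payload:
            raise FormatError(f"{path}: missing field {key!r}")
    return payload


# ---------------------------------------------------------------------------
# TIL maps
# ---------------------------------------------------------------------------


def write_til_map(tm: TILMap, path_prefix, seed=None, config=None,
                  heatmap=True, stitched=False):
    """Serialize a TIL map: CSV (+ optional PNG heatmap, stitched mask TIFF)."""
    rows = []
    lvl = tm.patch_level
    for i, e in enumerate(tm.grid.entries):
        rows.append(
            {
                "grid_row": e.grid_row,
                "grid_col": e.grid_col,
                "valid": int(e.valid),
                "background_fraction": e.background_fraction,
                "Li": int(tm.L[i]),
                "Ti": int(tm.T[i]),
                "level": int(lvl[i]),
            }
        )
    df = pd.DataFrame(rows)
    _write_csv_with_header(df, f"{path_prefix}.csv", seed=seed, config=config)
    if heatmap:
        _write_heatmap(tm, f"{path_prefix}.png")
    if stitched:
        import tifffile

        tifffile.imwrite(
            f"{path_prefix}_mask.tif", tm.stitched_mask.astype(np.uint8) * 255
        )


def _write_heatmap(tm: TILMap, path):
    from matplotlib import colormaps

    n_rows, n_cols = tm.grid.shape
    lvl = tm.patch_level.reshape(n_rows, n_cols)
    valid = tm.valid_mask.reshape(n_rows, n_cols)
    cmap = colormaps["jet"]
    rgba = cmap(lvl / 250.0)
    rgba[~valid] = (1.0, 1.0, 1.0, 1.0)
    write_image((rgba[..., :3] * 255).round(), path)


def read_til_map(path_prefix) -> TILMap:
    """Rebuild a TILMap from its CSV (stitched mask not reloaded)."""
    df = _read_csv_skip_header(f"{path_prefix}.csv")
    required = {"grid_row", "grid_col", "valid", "Li", "Ti"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path_prefix}.csv: missing columns {sorted(missing)}")
    n_rows = int(df["grid_row"].max()) + 1
    n_cols = int(df["grid_col"].max()) + 1
    entries = []
    for _, r in df.iterrows():
        entries.append(
            PatchGridEntry(
                grid_row=int(r["grid_row"]),
                grid_col=int(r["grid_col"]),
                offset=(int(r["grid_row"]) * 200, int(r["grid_col"]) * 200),
                valid=bool(r["valid"]),
                background_fraction=float(r.get("background_fraction", 0.0)),
            )
        )
    grid = PatchGrid(patch_size=200, entries=tuple(entries), shape=(n_rows, n_cols))
    return TILMap(
        grid=grid,
        L=df["Li"].to_numpy(dtype=np.int64),
        T=df["Ti"].to_numpy(dtype=np.int64),
        stitched_mask=np.zeros((n_rows * 200, n_cols * 200), dtype=bool),
    )


# ---------------------------------------------------------------------------
# feature vectors
# ---------------------------------------------------------------------------


def write_feature_vectors(vectors: dict, path, seed=None, config=None):
    """One CSV row per slide id; missing values stay empty (not zero)."""
    rows = []
    for slide_id, vec in vectors.items():
        row = {"slide_id": slide_id}
        row.update(vec.as_row() if isinstance(vec, SpatialFeatureVector) else vec)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["slide_id"] + FEATURE_NAMES)
    _write_csv_with_header(df, path, seed=seed, config=config)


def read_feature_vectors(path) -> pd.DataFrame:
    df = _read_csv_skip_header(path)
    if "slide_id" not in df.columns:
        raise FormatError(f"{path}: missing slide_id column")
    return df.set_index("slide_id")


# ---------------------------------------------------------------------------
# cluster assignments
# ---------------------------------------------------------------------------


def write_clustering(points, clustering, path, seed=None, config=None):
    pts = np.asarray(points, float).reshape(-1, 2)
    df = pd.DataFrame(
        {
            "point_row": pts[:, 0],
            "point_col": pts[:, 1],
            "cluster": clustering.labels,
            "exemplar": [
                int(i in set(clustering.exemplars)) for i in range(len(pts))
            ],
        }
    )
    _write_csv_with_header(df, path, seed=seed, config=config)
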