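"""Reading and writing the package's on-disk formats.

Images are PNG/TIFF; tabular artifacts are plain CSV; configs and metric
reports are JSON. The manifest convention is a CSV with header
``path,label,group,magnification``; spot tables are CSVs with columns
``spot_id,x,y,gene_*``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .patch_graph import FEATURE_NAMES, TissueGraph
from .st_denoise import SpotTable

MANIFEST_COLUMNS = ("path", "label", "group", "magnification")


def read_image(path) -> np.ndarray:
    """Load a PNG or TIFF patch as HxWx3 uint8."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[..., :3]


def write_image(path, patch: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, patch)
    else:
        Image.fromarray(np.asarray(patch, dtype=np.uint8)).save(path)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("path", "label", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if "magnification" not in df.columns:
        df["magnification"] = ""
    return df


def write_manifest(path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, index=False)


def write_graph_snapshot(graph: TissueGraph, node_path, edge_path) -> None:
    """Debug dump: node CSV (id, grid cell, centre, features) and edge CSV."""
    rows = []
    inv = {v: k for k, v in graph.node_ids.items()}
    for i in range(graph.n_nodes):
        r, c = inv[i]
        rows.append(
            [i, r, c, graph.positions[i, 0], graph.positions[i, 1], *graph.features[i]]
        )
    pd.DataFrame(
        rows, columns=["node_id", "row", "col", "x", "y", *FEATURE_NAMES]
    ).to_csv(node_path, index=False)
    coo = graph.weights.tocoo()
    mask = coo.row < coo.col
    pd.DataFrame(
        {"i": coo.row[mask], "j": coo.col[mask], "weight": coo.data[mask]}
    ).to_csv(edge_path, index=False)


def write_feature_table(path, frame: pd.DataFrame, config: dict | None = None) -> None:
    """Feature CSV plus a JSON sidecar recording the descriptor config."""
    frame.to_csv(path, index=False)
    if config is not None:
        sidecar = Path(path).with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump(config, fh, indent=2, default=str)


def read_spot_table(path) -> SpotTable:
    df = pd.read_csv(path)
    gene_cols = [c for c in df.columns if c.startswith("gene_")]
    if not gene_cols or "x" not in df.columns or "y" not in df.columns:
        raise ValueError("spot CSV needs x, y and gene_* columns")
    return SpotTable(
        positions=df[["x", "y"]].to_numpy(dtype=np.float64),
        expression=df[gene_cols].to_numpy(dtype=np.float64),
        gene_names=tuple(gene_cols),
        spot_ids=df["spot_id"].to_numpy() if "spot_id" in df.columns else None,
    )


def write_spot_table(path, spots: SpotTable) -> None:
    spots.to_frame().to_csv(path, index=False)


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
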