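"""Readers and writers for the package's plain-text formats.

All formats are delimited text and round-trip losslessly at full double
precision (values are written with ``%.17g``):

* atlas CSV: ``node_id,label,network,x,y,z``
* connectome: square whitespace- or comma-delimited ``N x N`` matrix
* edge-feature table: CSV, one row per subject (``subject_id`` + E columns)
* phenotype table: CSV with header
* edge mask: square integer matrix over {-1, 0, 1}
* edge list: CSV ``node_i,node_j,sign`` (1-based node ids)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Atlas,
    ConnectivityMatrix,
    EdgeVector,
    edge_index,
    validate_phenotype,
)

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def read_atlas(path) -> Atlas:
    """Read a node atlas CSV (``node_id,label,network,x,y,z``)."""
    t = pd.read_csv(path)
    required = ["node_id", "label", "network", "x", "y", "z"]
    missing = [c for c in required if c not in t.columns]
    if missing:
        raise ValueError(f"atlas file {path} missing columns: {missing}")
    return Atlas(table=t[required])


def write_atlas(atlas: Atlas, path) -> None:
    atlas.table.to_csv(path, index=False)


def load_dosenbach_atlas() -> Atlas:
    """The 160-node functional atlas with six canonical networks.

    Coordinates and network labels are taken from the copy bundled with
    ``nilearn`` (no download). Networks: default, fronto-parietal,
    cingulo-opercular, sensorimotor, occipital, cerebellum.
    """
    from nilearn.datasets import fetch_coords_dosenbach_2010

    d = fetch_coords_dosenbach_2010()
    rois = pd.DataFrame(d["rois"]).reset_index(drop=True)
    t = pd.DataFrame({
        "node_id": np.arange(1, len(rois) + 1),
        "label": list(d["labels"]),
        "network": np.asarray(d["networks"]).ravel().astype(str),
        "x": rois["x"].to_numpy(float),
        "y": rois["y"].to_numpy(float),
        "z": rois["z"].to_numpy(float),
    })
    return Atlas(table=t)


# ---------------------------------------------------------------------------
# Connectomes and edge vectors
# ---------------------------------------------------------------------------

def _subject_id_from_path(path) -> str:
    return Path(path).stem


def read_connectome(path, subject_id: str | None = None) -> ConnectivityMatrix:
    """Read a square delimited-text Fisher-z matrix."""
    z = np.loadtxt(path, delimiter="," if _is_csv(path) else None)
    z = np.atleast_2d(z)
    if z.shape[0] != z.shape[1]:
        raise ValueError(f"{path}: matrix is {z.shape[0]}x{z.shape[1]}, not square")
    return ConnectivityMatrix(subject_id=subject_id or _subject_id_from_path(path), z=z)


def write_connectome(cm: ConnectivityMatrix, path) -> None:
    np.savetxt(path, cm.z, fmt=_FLOAT_FMT,
               delimiter="," if _is_csv(path) else " ")


def _is_csv(path) -> bool:
    return str(path).lower().endswith(".csv")


def read_edge_table(path) -> tuple[list[str], np.ndarray]:
    """Read a subjects x E edge-feature CSV -> (subject ids, n x E array)."""
    t = pd.read_csv(path, float_precision="round_trip")
    if t.columns[0] != "subject_id":
        raise ValueError(f"{path}: first column must be subject_id")
    ids = t["subject_id"].astype(str).tolist()
    x = t.drop(columns="subject_id").to_numpy(float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{path}: non-finite edge values")
    return ids, x


def write_edge_table(subject_ids, edges: np.ndarray, path) -> None:
    edges = np.asarray(edges, dtype=float)
    cols = [f"e{k}" for k in range(edges.shape[1])]
    t = pd.DataFrame(edges, columns=cols)
    t.insert(0, "subject_id", list(subject_ids))
    t.to_csv(path, index=False, float_format=_FLOAT_FMT)


def edge_vectors_to_table(vectors: list[EdgeVector]) -> tuple[list[str], np.ndarray]:
    """Stack per-subject edge vectors into (ids, n x E matrix)."""
    ids = [v.subject_id for v in vectors]
    return ids, np.vstack([v.values for v in vectors])


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotype(path) -> pd.DataFrame:
    """Read a phenotype CSV; validates unique string subject ids."""
    return validate_phenotype(pd.read_csv(path, float_precision="round_trip"))


def write_phenotype(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Edge masks and edge lists
# ---------------------------------------------------------------------------

def read_edge_mask(path) -> np.ndarray:
    """Read a square {-1, 0, 1} mask matrix from delimited text."""
    m = np.loadtxt(path, delimiter="," if _is_csv(path) else None).astype(int)
    m = np.atleast_2d(m)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: mask is not square")
    if not np.isin(m, [-1, 0, 1]).all():
        raise ValueError(f"{path}: mask entries outside {{-1, 0, 1}}")
    return m


def write_edge_mask(mask: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d",
               delimiter="," if _is_csv(path) else " ")


def write_edge_list(mask: np.ndarray, path) -> None:
    """Write the nonzero edges of a mask as CSV ``node_i,node_j,sign``.

    Node ids are 1-based; one row per undirected edge (i < j), sorted by
    (node_i, node_j).
    """
    mask = np.asarray(mask)
    iu, ju = edge_index(mask.shape[0])
    sign = mask[iu, ju]
    keep = sign != 0
    t = pd.DataFrame({
        "node_i": iu[keep] + 1,
        "node_j": ju[keep] + 1,
        "sign": sign[keep].astype(int),
    }).sort_values(["node_i", "node_j"])
    t.to_csv(path, index=False)


def read_edge_list(path, n_nodes: int) -> np.ndarray:
    """Read an edge-list CSV back into an N x N signed mask matrix."""
    t = pd.read_csv(path)
    m = np.zeros((n_nodes, n_nodes), dtype=int)
    i = t["node_i"].to_numpy(int) - 1
    j = t["node_j"].to_numpy(int) - 1
    m[i, j] = t["sign"].to_numpy(int)
    m[j, i] = t["sign"].to_numpy(int)
    return m
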