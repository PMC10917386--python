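"""Core domain types for connectome-based predictive modelling.

The package works with subject-level resting-state functional connectomes:
Pearson correlations between regional (node) time courses, Fisher
z-transformed into an ``N x N`` symmetric matrix with a zero diagonal.
Everything downstream (site harmonization, edge selection, network
strength) operates on the canonical upper-triangle vectorization of that
matrix, so the edge ordering defined here (:func:`edge_index`) is the
single source of truth for edge identity across the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("cpmconn")

#: Pearson correlations are clipped to +/- (1 - FISHER_CLIP_EPS) before the
#: Fisher transform so that perfectly (anti)correlated node pairs map to a
#: large finite z value instead of +/- inf.
FISHER_CLIP_EPS = 1e-7


# ---------------------------------------------------------------------------
# Fisher transform
# ---------------------------------------------------------------------------

def fisher_z(r):
    """Fisher z-transform ``z = atanh(r)`` with overflow clipping.

    Parameters
    ----------
    r : array_like
        Correlation value(s), each with ``|r| <= 1`` (a tolerance of 1e-12
        is allowed for floating-point round-off).

    Returns
    -------
    ndarray or float
        ``atanh(clip(r))`` where ``r`` is clipped to ``+/-(1 - 1e-7)``.
        Clipped entries are counted and logged.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        bad = float(np.max(np.abs(r)))
        raise ValueError(f"correlation magnitude {bad} exceeds 1")
    lim = 1.0 - FISHER_CLIP_EPS
    n_clipped = int(np.count_nonzero(np.abs(r) > lim))
    if n_clipped:
        logger.info("fisher_z: clipped %d value(s) with |r| > %g", n_clipped, lim)
    out = np.arctanh(np.clip(r, -lim, lim))
    return out if out.ndim else float(out)


def inverse_fisher_z(z):
    """Inverse Fisher transform ``r = tanh(z)``."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atlas:
    """Node atlas: one row per node with a network label and MNI coordinates.

    ``table`` columns: ``node_id`` (1..N, unique and contiguous), ``label``,
    ``network`` (one of K network names), ``x``, ``y``, ``z`` (MNI mm).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = ["node_id", "label", "network", "x", "y", "z"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        ids = t["node_id"].to_numpy()
        dup = t["node_id"][t["node_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate node ids: {sorted(dup.unique().tolist())}")
        if not np.array_equal(np.sort(ids), np.arange(1, len(t) + 1)):
            raise ValueError("node ids must be contiguous 1..N")
        if t["network"].isna().any():
            rows = t.index[t["network"].isna()].tolist()
            raise ValueError(f"missing network label at row(s) {rows}")
        object.__setattr__(self, "table", t.sort_values("node_id").reset_index(drop=True))

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        """Network names in first-appearance order."""
        return list(dict.fromkeys(self.table["network"]))

    @property
    def node_networks(self) -> np.ndarray:
        """Per-node network label, aligned with node_id order."""
        return self.table["network"].to_numpy()


# ---------------------------------------------------------------------------
# Time series and connectomes
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesMatrix:
    """Per-subject node time courses, ``T`` timepoints x ``N`` nodes."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) array")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in time series of {self.subject_id}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric ``N x N`` Fisher-z connectivity matrix, zero diagonal."""

    subject_id: str
    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.z, self.z.T, atol=0, rtol=0, equal_nan=False):
            raise ValueError("connectivity matrix must be exactly symmetric")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("connectivity diagonal must be exactly 0")
        iu = np.triu_indices(n, 1)
        if not np.all(np.isfinite(self.z[iu])):
            raise ValueError("non-finite off-diagonal connectivity values")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class EdgeVector:
    """Canonical upper-triangle vectorization of a connectome.

    ``values`` has length ``E = N(N-1)/2`` in row-major upper-triangle order
    (edge ``(i, j)`` with ``i < j``, 0-based: (0,1), (0,2), ..., (1,2), ...).
    """

    subject_id: str
    values: np.ndarray
    n_nodes: int = field(default=0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.n_nodes == 0:
            self.n_nodes = n_nodes_from_edges(len(self.values))
        if len(self.values) != n_edges(self.n_nodes):
            raise ValueError(
                f"edge vector length {len(self.values)} != N(N-1)/2 for N={self.n_nodes}"
            )


def n_edges(n_nodes: int) -> int:
    """Number of undirected edges between distinct nodes: N(N-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def n_nodes_from_edges(n_edge: int) -> int:
    """Invert E = N(N-1)/2; raises if E is not a triangular number."""
    n = int(round((1 + np.sqrt(1 + 8 * n_edge)) / 2))
    if n_edges(n) != n_edge:
        raise ValueError(f"{n_edge} is not N(N-1)/2 for any integer N")
    return n


def edge_index(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge ordering: row-major upper triangle, i < j (0-based)."""
    return np.triu_indices(n_nodes, 1)


def compute_connectome(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Build a Fisher-z connectome from node time courses.

    Pearson correlation between every pair of node columns, Fisher
    z-transformed (with clipping of ``|r| = 1``), symmetric, zero diagonal.

    Raises
    ------
    ValueError
        If any node column has zero variance (the correlation would be
        undefined); the error lists the offending 1-based node ids.
    """
    x = ts.values
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance node column(s) for subject {ts.subject_id}: "
            f"node ids {[int(i) + 1 for i in dead]}"
        )
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 0.0)
    z = fisher_z(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against round-off
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, z=z)


def vectorize(cm: ConnectivityMatrix) -> EdgeVector:
    """Extract the canonical upper-triangle edge vector of a connectome."""
    iu = edge_index(cm.n_nodes)
    return EdgeVector(subject_id=cm.subject_id, values=cm.z[iu].copy(),
                      n_nodes=cm.n_nodes)


def devectorize(v: EdgeVector, n_nodes: int | None = None) -> ConnectivityMatrix:
    """Rebuild the symmetric connectome from a canonical edge vector."""
    n = v.n_nodes if n_nodes is None else n_nodes
    if len(v.values) != n_edges(n):
        raise ValueError(f"edge vector length {len(v.values)} != N(N-1)/2 for N={n}")
    z = np.zeros((n, n))
    iu = edge_index(n)
    z[iu] = v.values
    z = z + z.T
    return ConnectivityMatrix(subject_id=v.subject_id, z=z)


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

#: Columns a phenotype table may carry; only ``subject_id`` is mandatory.
PHENOTYPE_COLUMNS = [
    "subject_id", "score_total", "score_social", "score_communication",
    "score_rrb", "age", "sex", "mfd", "site", "subtype", "group", "fiq",
    "handedness", "n_timepoints", "max_motion_mm", "max_motion_deg",
]


def validate_phenotype(pheno: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table: unique subject ids, known dtypes.

    Returns the table indexed 0..n-1 with ``subject_id`` as string.
    """
    if "subject_id" not in pheno.columns:
        raise ValueError("phenotype table needs a subject_id column")
    pheno = pheno.copy()
    pheno["subject_id"] = pheno["subject_id"].astype(str)
    dup = pheno["subject_id"][pheno["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject ids: {sorted(dup.unique().tolist())}")
    return pheno.reset_index(drop=True)
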