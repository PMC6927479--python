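"""Canonical connectome containers and elementary transforms.

A connectome is a symmetric P x P matrix of Fisher-z-transformed Pearson
correlations between the resting-state timecourses of P cortical parcels.
The diagonal is stored as 0 in z-space (arctanh(1) is undefined) and is
excluded from every edge statistic.  The canonical edge vector is the
row-major upper triangle (i < j), giving P(P-1)/2 unique edges — 55,278
for a 333-parcel set.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "n_edges",
    "fisher_z",
    "inverse_fisher",
    "vectorize_upper",
    "devectorize",
    "timeseries_to_connectome",
    "group_average",
    "matrix_similarity",
    "edge_index_pairs",
    "centroid_distances",
    "stack_edges",
    "write_connectome_tsv",
    "read_connectome_tsv",
]

_SYM_TOL = 1e-12


def n_edges(n_parcels: int) -> int:
    """Number of unique parcel pairs (upper-triangle edges)."""
    return n_parcels * (n_parcels - 1) // 2


def fisher_z(r):
    """Variance-stabilizing arctanh transform of a correlation.

    Raises ValueError for |r| >= 1 (the transform diverges).
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    return np.arctanh(r)


def inverse_fisher(z):
    """Inverse of :func:`fisher_z` (tanh)."""
    return np.tanh(np.asarray(z, dtype=float))


@dataclass
class Connectome:
    """A per-participant symmetric Fisher-z connectivity matrix.

    Parameters
    ----------
    values : (P, P) ndarray
        Symmetric matrix of z-transformed correlations, zero diagonal.
    parcel_ids : sequence of int, optional
        Parcel order the rows/columns are bound to; defaults to 0..P-1.
    """

    values: np.ndarray
    parcel_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectome must be a square matrix")
        if not np.all(np.isfinite(v[~np.eye(v.shape[0], dtype=bool)])):
            raise ValueError("connectome off-diagonals must be finite")
        if np.max(np.abs(v - v.T)) > _SYM_TOL:
            raise ValueError("connectome must be symmetric to 1e-12")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v
        if self.parcel_ids is None:
            self.parcel_ids = np.arange(v.shape[0])
        else:
            self.parcel_ids = np.asarray(self.parcel_ids)
            if len(self.parcel_ids) != v.shape[0]:
                raise ValueError("parcel_ids length must match matrix dimension")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


def _as_matrix(c) -> np.ndarray:
    return c.values if isinstance(c, Connectome) else np.asarray(c, dtype=float)


def vectorize_upper(c) -> np.ndarray:
    """Row-major upper-triangle (i<j) edge vector of a connectome."""
    m = _as_matrix(c)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def devectorize(edges, n_parcels: int) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from an edge vector."""
    edges = np.asarray(edges, dtype=float)
    expected = n_edges(n_parcels)
    if edges.shape[0] != expected:
        raise ValueError(
            f"edge vector length {edges.shape[0]} does not match "
            f"P={n_parcels} (expected {expected})"
        )
    m = np.zeros((n_parcels, n_parcels))
    iu = np.triu_indices(n_parcels, k=1)
    m[iu] = edges
    m += m.T
    return m


def edge_index_pairs(n_parcels: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) parcel indices for each edge in canonical order."""
    return np.triu_indices(n_parcels, k=1)


def stack_edges(connectomes) -> np.ndarray:
    """Stack a sequence of connectomes into an (n_participants, E) edge matrix."""
    mats = [_as_matrix(c) for c in connectomes]
    if not mats:
        raise ValueError("need at least one connectome")
    p = mats[0].shape[0]
    if any(m.shape != (p, p) for m in mats):
        raise ValueError("connectomes have mixed dimensions")
    iu = np.triu_indices(p, k=1)
    return np.stack([m[iu] for m in mats])


def timeseries_to_connectome(timeseries, censor_mask=None) -> Connectome:
    """Pearson-correlate parcel timecourses and Fisher-z transform.

    Censored frames (mask True = motion-contaminated) are deleted before
    correlation.  Any off-diagonal |r| = 1 (e.g. duplicated parcels) is an
    error, since arctanh diverges there.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be frames x parcels")
    if censor_mask is not None:
        censor_mask = np.asarray(censor_mask, dtype=bool)
        if censor_mask.shape[0] != ts.shape[0]:
            raise ValueError("censor mask length must match frame count")
        ts = ts[~censor_mask]
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 uncensored frames")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant timecourse for parcel(s) {bad.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    # numerical safety: r can overshoot 1 by eps
    r = np.clip(r, -1.0, 1.0)
    if np.any(np.abs(r[off]) >= 1.0 - 1e-15):
        i, j = np.where((np.abs(r) >= 1.0 - 1e-15) & off)
        raise ValueError(f"perfect correlation between parcels {i[0]} and {j[0]}")
    np.fill_diagonal(r, 0.0)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return Connectome(z)


def group_average(connectomes) -> Connectome:
    """Element-wise mean connectome in z-space."""
    mats = [_as_matrix(c) for c in connectomes]
    if not mats:
        raise ValueError("need at least one connectome")
    p = mats[0].shape[0]
    if any(m.shape != (p, p) for m in mats):
        raise ValueError("connectomes have mixed dimensions")
    return Connectome(np.mean(mats, axis=0))


def matrix_similarity(a, b) -> float:
    """Pearson r between two connectomes' edge vectors."""
    va, vb = vectorize_upper(a), vectorize_upper(b)
    if va.shape != vb.shape:
        raise ValueError("connectomes have mixed dimensions")
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero-variance edge vector")
    return float(np.corrcoef(va, vb)[0, 1])


def centroid_distances(parcels: pd.DataFrame) -> np.ndarray:
    """Euclidean inter-centroid distance (mm) per edge, canonical order."""
    xyz = parcels[["x", "y", "z"]].to_numpy(dtype=float)
    i, j = np.triu_indices(len(parcels), k=1)
    return np.linalg.norm(xyz[i] - xyz[j], axis=1)


# ---------------------------------------------------------------------------
# dense TSV I/O with a JSON sidecar carrying the parcel-order hash

def _parcel_hash(parcel_ids) -> str:
    raw = ",".join(str(int(p)) for p in parcel_ids).encode()
    return hashlib.sha256(raw).hexdigest()[:16]


def write_connectome_tsv(c: Connectome, path: str) -> None:
    np.savetxt(path, c.values, fmt="%.6f", delimiter="\t")
    sidecar = {"n_parcels": int(c.n_parcels), "parcel_hash": _parcel_hash(c.parcel_ids)}
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh)


def read_connectome_tsv(path: str, parcel_ids=None) -> Connectome:
    values = np.loadtxt(path, delimiter="\t")
    sidecar_path = path + ".json"
    if os.path.exists(sidecar_path):
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        if sidecar["n_parcels"] != values.shape[0]:
            raise ValueError(
                f"{path}: sidecar declares {sidecar['n_parcels']} parcels, "
                f"matrix has {values.shape[0]}"
            )
        if parcel_ids is not None and _parcel_hash(parcel_ids) != sidecar["parcel_hash"]:
            raise ValueError(f"{path}: parcel order hash mismatch")
    return Connectome(values, parcel_ids=parcel_ids)
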