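"""Functional-connectivity construction, edge vectorization and motion QC.

A subject's connectome is the node-by-node matrix of Pearson correlations
between parcel-mean BOLD time series (AAL-116 by default, giving
E = 116*115/2 = 6670 unique edges).  All downstream modelling operates on
the strict-upper-triangle edge vector; the k <-> (i, j) mapping defined by
:func:`edge_index_pairs` (row-major, 0-based, i < j) is the single canonical
ordering used by every file format and mask in this package.

Motion quality control follows the usual resting-state exclusion rules:
framewise displacement (FD) computed Power-style as the sum of absolute
backward differences of the six rigid-body parameters, rotations converted
to arc length at a configurable head radius (default 50 mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_ROTATION_RADIUS_MM = 50.0

#: exclusion rules applied by :func:`qc_subject`
FD_SPIKE_THRESHOLD_MM = 0.5
MAX_SPIKE_FRACTION = 0.20
MAX_TRANSLATION_MM = 3.0
MAX_ROTATION_DEG = 3.0
MAX_MEAN_FD_MM = 0.2

__all__ = [
    "ConnectivityMatrix",
    "EdgeVector",
    "MotionQCReport",
    "n_edges",
    "edge_index_pairs",
    "edge_ids",
    "build_connectivity",
    "vectorize_upper",
    "devectorize_upper",
    "framewise_displacement",
    "qc_subject",
]


def n_edges(n_nodes: int) -> int:
    """Number of unique edges E = n_nodes*(n_nodes-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def edge_index_pairs(n_nodes: int) -> np.ndarray:
    """Canonical (E, 2) array of node pairs (i, j), i < j, row-major.

    Edge k runs over the strict upper triangle row by row:
    (0,1), (0,2), ..., (0,n-1), (1,2), ...
    """
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu)


def edge_ids(n_nodes: int) -> list[str]:
    """String edge identifiers ``"i_j"`` in canonical order."""
    return [f"{i}_{j}" for i, j in edge_index_pairs(n_nodes)]


@dataclass
class ConnectivityMatrix:
    """One subject's symmetric node x node Pearson correlation matrix."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise ValueError("connectivity matrix must be symmetric within 1e-12")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (np.abs(off) > 1.0 + 1e-12).any():
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeVector:
    """Length-E strict-upper-triangle vectorization of a connectome."""

    subject_id: str
    values: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n_edges(self.n_nodes),):
            raise ValueError(
                f"expected {n_edges(self.n_nodes)} edges for {self.n_nodes} nodes, "
                f"got {self.values.shape}"
            )


@dataclass
class MotionQCReport:
    """Per-subject motion QC summary and pass/fail against the three rules."""

    subject_id: str
    fd_series: np.ndarray
    mean_fd: float
    frac_fd_gt_0p5: float
    max_translation: float
    max_rotation: float  # degrees
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "mean_fd": self.mean_fd,
            "frac_fd_gt_0p5": self.frac_fd_gt_0p5,
            "max_translation": self.max_translation,
            "max_rotation": self.max_rotation,
            "passed": self.passed,
            "reasons": list(self.reasons),
        }


def _as_array(table, min_cols: int | None = None) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D (volumes x columns) table")
    return arr


def build_connectivity(timeseries, subject_id: str = "subject") -> ConnectivityMatrix:
    """Pearson-correlate parcel time series into a connectivity matrix.

    Parameters
    ----------
    timeseries
        Volumes x nodes array or DataFrame of parcel-mean BOLD signals.

    Raises
    ------
    ValueError
        On fewer than 3 volumes, missing values, or a zero-variance node
        (the error names the offending node index).
    """
    ts = _as_array(timeseries)
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 volumes to estimate correlations")
    if not np.isfinite(ts).all():
        raise ValueError("time series contain missing or non-finite values")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance node(s) at index {dead.tolist()}")
    corr = np.corrcoef(ts, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(subject_id=subject_id, values=corr)


def vectorize_upper(matrix: ConnectivityMatrix) -> EdgeVector:
    """Extract the strict upper triangle in canonical edge order."""
    v = matrix.values
    iu = np.triu_indices(matrix.n_nodes, k=1)
    return EdgeVector(
        subject_id=matrix.subject_id, values=v[iu].copy(), n_nodes=matrix.n_nodes
    )


def devectorize_upper(edges: EdgeVector) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_upper`; diagonal restored to 1."""
    n = edges.n_nodes
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = edges.values
    m = m + m.T
    np.fill_diagonal(m, 1.0)
    return ConnectivityMatrix(subject_id=edges.subject_id, values=m)


def framewise_displacement(
    motion,
    rotation_radius_mm: float = DEFAULT_ROTATION_RADIUS_MM,
    rotations_in_degrees: bool = False,
) -> np.ndarray:
    """Power-style framewise displacement from 6 rigid-body parameters.

    FD(t) = sum |delta translation| + radius * sum |delta rotation| for t >= 2,
    FD(1) = 0.  Columns must be ordered as 3 translations (mm) then 3
    rotations (radians, or degrees with ``rotations_in_degrees=True``).
    """
    m = _as_array(motion)
    if m.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got {m.shape[1]}")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 volumes for framewise displacement")
    rot = m[:, 3:6]
    if rotations_in_degrees:
        rot = np.deg2rad(rot)
    d_trans = np.abs(np.diff(m[:, 0:3], axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(rot, axis=0)).sum(axis=1) * rotation_radius_mm
    fd = np.concatenate([[0.0], d_trans + d_rot])
    return fd


def qc_subject(
    motion,
    subject_id: str = "subject",
    rotation_radius_mm: float = DEFAULT_ROTATION_RADIUS_MM,
    rotations_in_degrees: bool = False,
) -> MotionQCReport:
    """Evaluate the three motion exclusion rules for one subject.

    (a) fraction of volumes with FD > 0.5 mm must be < 20%;
    (b) max |translation| <= 3 mm and max |rotation| <= 3 degrees;
    (c) mean FD < 0.2 mm.
    """
    m = _as_array(motion)
    fd = framewise_displacement(
        m, rotation_radius_mm=rotation_radius_mm,
        rotations_in_degrees=rotations_in_degrees,
    )
    rot = m[:, 3:6] if rotations_in_degrees else np.rad2deg(m[:, 3:6])
    max_translation = float(np.abs(m[:, 0:3]).max())
    max_rotation = float(np.abs(rot).max())
    frac = float((fd > FD_SPIKE_THRESHOLD_MM).mean())
    mean_fd = float(fd.mean())

    reasons = []
    if not frac < MAX_SPIKE_FRACTION:
        reasons.append("fd_spike_fraction")
    if not (max_translation <= MAX_TRANSLATION_MM and max_rotation <= MAX_ROTATION_DEG):
        reasons.append("excessive_motion")
    if not mean_fd < MAX_MEAN_FD_MM:
        reasons.append("mean_fd")
    return MotionQCReport(
        subject_id=subject_id,
        fd_series=fd,
        mean_fd=mean_fd,
        frac_fd_gt_0p5=frac,
        max_translation=max_translation,
        max_rotation=max_rotation,
        passed=not reasons,
        reasons=reasons,
    )
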