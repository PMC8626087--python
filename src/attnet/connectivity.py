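"""Seed time-course extraction and functional-connectivity measures.

Connectivity is the Pearson correlation between ROI time courses, Fisher-z
transformed (z = atanh r).  A 10-ROI network yields 45 unique edges; the
network summary is the arithmetic mean of the unique-edge z values, and the
session change is Delta-FC = z(session 2) - z(session 1), elementwise.
Matrices are tagged with their ROI-set label (e.g. DVAN vs DMN) and cross-set
operations raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import RunTimeSeries
from .rois import RoiSpec


def fisher_z(r: np.ndarray, *, clip: bool = False) -> np.ndarray:
    """atanh with an explicit policy for |r| = 1 (error unless ``clip``)."""
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    elif np.any(np.abs(r) >= 1.0 - 1e-15):
        raise ValueError("|r| = 1 gives infinite Fisher z; enable clipping to proceed")
    return np.arctanh(r)


def extract_roi_timeseries(volume4d: np.ndarray, affine: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Unweighted mean time course over voxels whose centers fall in the sphere.

    World coordinates come from the NIfTI-style affine (voxel indices are
    0-based).  An empty sphere is an error naming the ROI.
    """
    volume4d = np.asarray(volume4d)
    if volume4d.ndim != 4:
        raise ValueError("volume must be 4-D (x, y, z, t)")
    shape = volume4d.shape[:3]
    idx = np.indices(shape).reshape(3, -1)
    hom = np.vstack([idx, np.ones((1, idx.shape[1]))])
    world = (np.asarray(affine) @ hom)[:3].T
    dist2 = ((world - np.asarray(roi.center)) ** 2).sum(axis=1)
    mask = (dist2 <= roi.radius_mm**2).reshape(shape)
    if not mask.any():
        raise ValueError(f"ROI {roi.name!r} contains no voxel centers")
    return volume4d[mask].mean(axis=0)


@dataclass
class ConnectivityMatrix:
    """Per-subject, per-session symmetric Fisher-z edge matrix over an ROI set."""

    subject: str
    session: str
    roi_set: str
    roi_names: list[str]
    r_values: np.ndarray
    z_values: np.ndarray

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=float)
        self.z_values = np.asarray(self.z_values, dtype=float)
        p = len(self.roi_names)
        for m in (self.r_values, self.z_values):
            if m.shape != (p, p):
                raise ValueError("matrix shape must match ROI count")
            if not np.allclose(m, m.T, atol=1e-10, equal_nan=True):
                raise ValueError("connectivity matrices must be symmetric")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def n_edges(self) -> int:
        p = self.n_rois
        return p * (p - 1) // 2

    def edge_vector(self, which: str = "z") -> np.ndarray:
        """Upper-triangle unique-edge values (length p(p-1)/2)."""
        m = self.z_values if which == "z" else self.r_values
        iu = np.triu_indices(self.n_rois, k=1)
        return m[iu]

    def edge_table(self) -> pd.DataFrame:
        iu = np.triu_indices(self.n_rois, k=1)
        return pd.DataFrame(
            {
                "subject": self.subject,
                "session": self.session,
                "roi_set": self.roi_set,
                "roi_a": [self.roi_names[i] for i in iu[0]],
                "roi_b": [self.roi_names[j] for j in iu[1]],
                "r": self.r_values[iu],
                "z": self.z_values[iu],
            }
        )


def correlation_matrix(
    series: RunTimeSeries,
    *,
    subject: str = "",
    session: str = "",
    roi_set: str = "",
    clip: bool = False,
) -> ConnectivityMatrix:
    """Pairwise Pearson r over retained frames, Fisher-z transformed."""
    if series.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation matrix")
    sd = series.data.std(axis=0)
    dead = [series.roi_names[i] for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"zero-variance ROI(s): {dead}")
    r = np.corrcoef(series.data, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    z = np.zeros_like(r)
    z[off] = fisher_z(r[off], clip=clip)
    return ConnectivityMatrix(
        subject=subject,
        session=session,
        roi_set=roi_set,
        roi_names=list(series.roi_names),
        r_values=r,
        z_values=z,
    )


@dataclass
class NetworkSummary:
    subject: str
    session: str
    roi_set: str
    mean_z: float
    edge_vector: np.ndarray


def network_mean(matrix: ConnectivityMatrix) -> NetworkSummary:
    """Mean Fisher z over unique edges (no diagonal, no double counting)."""
    edges = matrix.edge_vector("z")
    return NetworkSummary(
        subject=matrix.subject,
        session=matrix.session,
        roi_set=matrix.roi_set,
        mean_z=float(edges.mean()),
        edge_vector=edges,
    )


@dataclass
class DeltaFC:
    subject: str
    roi_set: str
    roi_names: list[str]
    delta: np.ndarray

    @property
    def mean_delta(self) -> float:
        iu = np.triu_indices(len(self.roi_names), k=1)
        return float(self.delta[iu].mean())

    def edge_vector(self) -> np.ndarray:
        iu = np.triu_indices(len(self.roi_names), k=1)
        return self.delta[iu]


def delta_fc(pre: ConnectivityMatrix, post: ConnectivityMatrix) -> DeltaFC:
    """Session-2 minus session-1 Fisher-z matrix, elementwise."""
    if pre.subject != post.subject:
        raise ValueError("delta_fc requires matrices from the same subject")
    if pre.roi_set != post.roi_set or pre.roi_names != post.roi_names:
        raise ValueError("ROI-set mismatch between sessions")
    return DeltaFC(
        subject=pre.subject,
        roi_set=pre.roi_set,
        roi_names=list(pre.roi_names),
        delta=post.z_values - pre.z_values,
    )


def group_average(
    per_subject: pd.DataFrame,
    design: pd.DataFrame,
    *,
    value_col: str = "value",
) -> pd.DataFrame:
    """Average strictly within subject first, then across subjects per group.

    ``per_subject`` is long format with at least (subject, session,
    ``value_col``) and optionally edge identifiers (roi_a, roi_b); ``design``
    maps subject -> group.  Returns group x session means (and per-edge means
    when edge columns are present).
    """
    unknown = set(per_subject["subject"]) - set(design["subject"])
    if unknown:
        raise ValueError(f"subjects missing from design table: {sorted(unknown)}")
    merged = per_subject.merge(design[["subject", "group"]], on="subject", how="left")
    edge_cols = [c for c in ("roi_a", "roi_b") if c in merged.columns]
    keys = ["subject", "group", "session"] + edge_cols
    subject_level = merged.groupby(keys, sort=False, as_index=False)[value_col].mean()
    group_keys = ["group", "session"] + edge_cols
    return (
        subject_level.groupby(group_keys, sort=False, as_index=False)[value_col]
        .mean()
        .rename(columns={value_col: "mean_" + value_col})
    )
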