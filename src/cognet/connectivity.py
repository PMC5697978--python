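"""ROI signal extraction and per-network correlation matrices.

The connectivity strength of a link is the zero-lag Pearson correlation of
the two nodes' region-averaged BOLD signals — one scalar per link, forming a
symmetric unit-diagonal matrix per subject and network.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .networks import NetworkDefinition
from .preprocess import Bold4D
from .synthetic import LabelVolume


class AlignmentError(ValueError):
    """BOLD and label volumes do not share a grid."""


class ConnectivityError(ValueError):
    pass


@dataclass
class RoiTimeSeries:
    """Region-averaged signals, one row per network node."""

    subject_id: str
    signals: np.ndarray  # (nodes, timepoints)
    tr_seconds: float
    node_order: tuple[str, ...]
    degenerate: tuple[str, ...] = field(default=())

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.node_order = tuple(self.node_order)
        self.degenerate = tuple(self.degenerate)
        if self.signals.shape[0] != len(self.node_order):
            raise ConnectivityError("one signal row per node required")


@dataclass
class ConnectivityMatrix:
    """Symmetric unit-diagonal matrix of link correlations for one subject."""

    subject_id: str
    network_name: str
    r: np.ndarray
    node_order: tuple[str, ...]

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.node_order = tuple(self.node_order)
        n = len(self.node_order)
        if self.r.shape != (n, n):
            raise ConnectivityError(f"matrix must be {n}x{n}")

    def link_values(self, links: tuple[tuple[int, int], ...]) -> np.ndarray:
        return np.array([self.r[i, j] for i, j in links])


def extract_roi_signals(
    bold: Bold4D,
    labels: LabelVolume,
    net: NetworkDefinition,
    subject_id: str = "subject",
) -> RoiTimeSeries:
    """Unweighted voxel-mean signal per node of ``net``.

    BOLD and labels must share grid and affine (no implicit resampling); a
    label absent from the volume yields a NaN row flagged degenerate.
    """
    if bold.data.shape[:3] != labels.data.shape:
        raise AlignmentError(
            f"BOLD grid {bold.data.shape[:3]} != label grid {labels.data.shape}"
        )
    if not np.allclose(bold.affine, labels.affine, atol=1e-4):
        raise AlignmentError("BOLD and label affines differ beyond 1e-4")
    n_t = bold.n_timepoints
    flat = bold.data.reshape(-1, n_t)
    labs = labels.data.reshape(-1)
    signals = np.empty((net.n, n_t))
    degenerate = []
    for row, node in enumerate(net.nodes):
        mask = labs == net.label_map[node]
        if not mask.any():
            signals[row] = np.nan
            degenerate.append(node)
            continue
        signals[row] = flat[mask].mean(axis=0)
    if degenerate:
        warnings.warn(
            f"{net.name}: empty label(s) for node(s) {', '.join(degenerate)}",
            stacklevel=2,
        )
    return RoiTimeSeries(
        subject_id=subject_id,
        signals=signals,
        tr_seconds=bold.tr_seconds,
        node_order=net.nodes,
        degenerate=tuple(degenerate),
    )


def correlation_matrix(
    ts: RoiTimeSeries, network_name: str = "", fisher_z: bool = False
) -> ConnectivityMatrix:
    """Zero-lag Pearson correlation between every pair of node signals.

    Degenerate (NaN or zero-variance) rows propagate NaN to their links.
    ``fisher_z`` applies arctanh to the off-diagonal entries.
    """
    x = ts.signals
    if x.shape[1] < 3:
        raise ConnectivityError("need at least 3 timepoints for correlation")
    sd = np.nanstd(x, axis=1)
    bad = ~np.isfinite(x).all(axis=1) | (sd == 0)
    if bad.any():
        warnings.warn(
            "zero-variance or NaN node signal(s); links set to NaN", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.asarray(r, dtype=float)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    good = ~bad
    r[np.ix_(good, good)] = np.clip(r[np.ix_(good, good)], -1.0, 1.0)
    r = (r + r.T) / 2.0
    r[np.diag_indices_from(r)] = np.where(good, 1.0, np.nan)
    if fisher_z:
        off = ~np.eye(len(r), dtype=bool)
        with np.errstate(divide="ignore"):
            r[off] = np.arctanh(r[off])
    return ConnectivityMatrix(
        subject_id=ts.subject_id,
        network_name=network_name,
        r=r,
        node_order=ts.node_order,
    )
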