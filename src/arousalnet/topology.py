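"""Time-resolved network topology: participation coefficient and states.

The participation coefficient of region *i* on a weighted graph with
module partition {s} is

    B_i = 1 - sum_s (K_is / K_i)^2

where K_is is the strength of *positive* connections from *i* to module
*s* and K_i the total positive strength of *i* (self-connections
excluded).  B is 0 when all strength stays inside one module and
approaches 1 - 1/n_M when strength spreads evenly over n_M modules.
Regions with zero positive strength are assigned B = 0.

Module assignments default to a fixed a-priori network table; a seeded
Louvain partition of the static connectivity is offered as an option.
Integrated vs segregated brain states are obtained by k-means (k=2) over
stacked regional PC frames, the higher-mean cluster being "integrated".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .connectivity import DynamicFC, StaticFC
from .preprocess_io import NetworkPartition

__all__ = [
    "PCTimecourse",
    "StateLabels",
    "louvain_partition",
    "participation_frame",
    "participation_timecourse",
    "classify_states",
    "state_occupancy",
]


@dataclass
class PCTimecourse:
    """W x N matrix of per-frame participation coefficients."""

    data: np.ndarray
    region_labels: Sequence[str]
    n_modules: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.region_labels = list(self.region_labels)

    @property
    def global_trace(self) -> np.ndarray:
        """Region-mean PC per frame (the 'global' PC time course)."""
        return self.data.mean(axis=1)


@dataclass
class StateLabels:
    """Binary integrated/segregated labels for stacked PC frames."""

    labels: np.ndarray  # 1 = integrated, 0 = segregated, per row
    cluster_mean_pc: tuple[float, float]  # (segregated, integrated)

    @property
    def is_segregated(self) -> np.ndarray:
        return self.labels == 0


def louvain_partition(
    fc: StaticFC, resolution: float = 1.0, seed: int = 0
) -> tuple[NetworkPartition, float]:
    """Seeded Louvain modules of the positive static connectivity graph.

    Negative edges and self-connections are discarded.  Returns the
    partition and the achieved Newman-Girvan modularity Q.  A partition
    with Q <= 0 (structureless graph) collapses to a single module with
    Q = 0.
    """
    W = np.array(fc.matrix, dtype=float)
    np.fill_diagonal(W, 0.0)
    W[W < 0] = 0.0
    if not np.any(W > 0):
        raise ValueError("no positive edges; cannot run Louvain")
    G = nx.from_numpy_array(W)
    communities = nx.community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=seed
    )
    q = nx.community.modularity(G, communities, weight="weight",
                                resolution=resolution)
    if q <= 1e-12:  # structureless graph (Q at or below zero)
        communities, q = [set(range(W.shape[0]))], 0.0
    # deterministic module numbering: order communities by smallest member
    communities = sorted(communities, key=min)
    ids = np.empty(W.shape[0], dtype=int)
    for m, members in enumerate(communities):
        ids[list(members)] = m
    return NetworkPartition(fc.region_labels, ids), float(q)


def participation_frame(
    coupling: np.ndarray, partition: NetworkPartition
) -> np.ndarray:
    """Participation coefficients of one N x N coupling frame."""
    return _participation(coupling[None, :, :], partition)[0]


def _participation(frames: np.ndarray, partition: NetworkPartition) -> np.ndarray:
    """Vectorised B over a stack of frames (F x N x N -> F x N)."""
    n = frames.shape[1]
    if partition.n_regions != n:
        raise ValueError(
            f"partition covers {partition.n_regions} regions, frames have {n}"
        )
    A = np.clip(frames, 0.0, None).copy()
    idx = np.arange(n)
    A[:, idx, idx] = 0.0  # self-connections excluded
    M = partition.indicator()
    K_s = A @ M                      # F x N x n_M positive module strength
    K = K_s.sum(axis=-1)             # F x N total positive strength
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = K_s / K[..., None]
        B = 1.0 - np.sum(frac * frac, axis=-1)
    B[K == 0] = 0.0
    return B


def participation_timecourse(
    dfc: DynamicFC, partition: NetworkPartition
) -> PCTimecourse:
    """Per-frame, per-region participation coefficient of a coupling tensor."""
    if dfc.seed_label is not None:
        raise ValueError("participation requires the full coupling tensor")
    B = _participation(dfc.data, partition)
    return PCTimecourse(B, dfc.region_labels, partition.n_modules)


def classify_states(
    pc_rows: np.ndarray,
    k: int = 2,
    n_init: int = 100,
    seed: int = 0,
) -> StateLabels:
    """K-means classification of stacked PC frames into two states.

    Rows are (subject, frame) observations of regional PC.  k is fixed at
    2 (integrated vs segregated); k-means++ seeding with ``n_init``
    restarts, keeping the solution with minimum within-cluster sum of
    squares.  Distances are Euclidean on the raw PC values.
    """
    if k != 2:
        raise ValueError("only the two-state (k=2) analysis is supported")
    pc_rows = np.asarray(pc_rows, dtype=float)
    if np.unique(pc_rows, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct rows to cluster")
    km = KMeans(n_clusters=2, init="k-means++", n_init=n_init,
                random_state=seed)
    raw = km.fit_predict(pc_rows)
    means = np.array([pc_rows[raw == c].mean() for c in (0, 1)])
    if means[0] == means[1]:
        warnings.warn("cluster mean PC tie; lower cluster index -> segregated",
                      RuntimeWarning, stacklevel=2)
        integrated = 1
    else:
        integrated = int(np.argmax(means))
    labels = (raw == integrated).astype(int)
    seg_mean = float(means[1 - integrated])
    int_mean = float(means[integrated])
    return StateLabels(labels=labels, cluster_mean_pc=(seg_mean, int_mean))


def state_occupancy(
    states: StateLabels,
    subject_ids: Sequence[str],
    groups: Mapping[str, str],
) -> tuple[pd.Series, pd.DataFrame]:
    """Fraction of frames spent in the segregated state.

    Parameters
    ----------
    states : StateLabels
        Labels for stacked rows.
    subject_ids : sequence
        Subject id of each row (same length as labels).
    groups : mapping
        Subject id -> group label.

    Returns
    -------
    (group_occupancy, subject_occupancy)
        Per-group segregated fraction, and a per-subject table with
        columns ``group`` and ``segregated_fraction``.
    """
    subject_ids = np.asarray(subject_ids, dtype=object)
    if subject_ids.size != states.labels.size:
        raise ValueError("one subject id per labelled frame required")
    seg = states.is_segregated.astype(float)
    df = pd.DataFrame({"subject_id": subject_ids, "segregated": seg})
    per_subject = df.groupby("subject_id", sort=True)["segregated"].mean()
    try:
        subject_group = pd.Series(
            {s: groups[s] for s in per_subject.index}, name="group"
        )
    except KeyError as exc:
        raise ValueError(f"subject {exc.args[0]!r} missing from groups") from exc
    from .preprocess_io import GROUP_LABELS

    bad = set(subject_group.unique()) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    subject_table = pd.DataFrame(
        {"group": subject_group, "segregated_fraction": per_subject}
    )
    group_occupancy = subject_table.groupby("group")["segregated_fraction"].mean()
    return group_occupancy, subject_table
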