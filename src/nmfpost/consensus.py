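"""Cluster assignment, consensus matrices and cophenetic rank selection.

A single NMF run assigns sample j to the metagene with the largest entry in
column j of the (normalized) H matrix.  Stability of that assignment across
random restarts is summarized by the consensus matrix: the average, over many
seeded runs, of the binary connectivity matrix marking co-clustered sample
pairs.  If a rank k captures real structure, assignments barely vary between
restarts and consensus entries concentrate near 0 and 1; the cophenetic
correlation coefficient of the consensus matrix quantifies this, and the k
with the largest coefficient is recommended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .nmf import fit_nmf
from .normalization import normalize_factorization

logger = logging.getLogger("nmfpost")


@dataclass
class ClusterAssignment:
    """Per-sample cluster labels in {1..k}; not every cluster need be occupied."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if self.labels.size and (
            self.labels.min() < 1 or self.labels.max() > self.k
        ):
            raise ValueError(f"labels must lie in 1..{self.k}")

    @property
    def m(self) -> int:
        return self.labels.size


@dataclass
class ConsensusMatrix:
    """Samples x samples co-clustering frequencies averaged over nloop runs."""

    C: np.ndarray
    nloop: int

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)


def assign_clusters(H: np.ndarray) -> ClusterAssignment:
    """Argmax cluster assignment: sample j joins the row maximizing H[:, j].

    Ties break to the smallest row index (np.argmax convention); labels are
    1-based.  An all-zero column has no meaningful maximum and is rejected.
    """
    H = np.asarray(H, dtype=float)
    zero_cols = np.where(~(H > 0).any(axis=0))[0]
    if zero_cols.size:
        raise ValueError(f"all-zero H column for sample index {zero_cols[0]}")
    return ClusterAssignment(np.argmax(H, axis=0) + 1, H.shape[0])


def connectivity_matrix(assignment: ClusterAssignment) -> np.ndarray:
    """Binary m x m matrix with 1 where two samples share a cluster."""
    lab = assignment.labels
    return (lab[:, None] == lab[None, :]).astype(float)


def consensus_matrix(
    A,
    k: int,
    nloop: int,
    base_seed: int,
    scheme: str = "max",
    use_filter: bool = False,
    T: float = 0.5,
) -> ConsensusMatrix:
    """Average connectivity over nloop NMF runs seeded base_seed..base_seed+nloop-1.

    Each run is fit at rank k, normalized by `scheme` (max by default — the
    scheme with the membership interpretation), and argmax-assigned.  With
    ``use_filter`` the full embedded-filter pipeline is run instead of a single
    fit; this is an extension, off by default.
    """
    if nloop < 2:
        raise ValueError("nloop must be at least 2")
    C = None
    for i in range(nloop):
        seed = base_seed + i
        if use_filter:
            from .filtering import post_process_cluster

            _, assignment, _ = post_process_cluster(
                A, k, scheme, seed, use_filter=True, T=T
            )
        else:
            fac = fit_nmf(A, k, seed)
            _, Hn, _ = normalize_factorization(fac.W, fac.H, scheme)
            assignment = assign_clusters(Hn)
        conn = connectivity_matrix(assignment)
        C = conn if C is None else C + conn
    return ConsensusMatrix(C / nloop, nloop)


def cophenetic_coefficient(C: ConsensusMatrix | np.ndarray) -> float:
    """Cophenetic correlation of the consensus matrix.

    Builds the distance matrix 1 - C, clusters it hierarchically with average
    linkage, and returns the Pearson correlation between the original
    distances and the cophenetic distances of the dendrogram, over each
    unordered sample pair once.  A perfectly binary block consensus gives an
    ultrametric 1 - C, reproduced exactly by the tree, hence r = 1.
    """
    Cm = C.C if isinstance(C, ConsensusMatrix) else np.asarray(C, dtype=float)
    m = Cm.shape[0]
    if m < 3:
        raise ValueError("cophenetic coefficient needs at least 3 samples")
    D = 1.0 - Cm
    np.fill_diagonal(D, 0.0)
    y = squareform(D, checks=False)  # condensed: strict upper triangle
    Z = linkage(y, method="average")
    _, coph = cophenet(Z, y)
    if np.std(y) == 0.0 or np.std(coph) == 0.0:
        raise ValueError(
            "undefined correlation: distance vector has zero variance "
            "(all samples always co-cluster or never do)"
        )
    return float(np.corrcoef(y, coph)[0, 1])


def select_k(
    A,
    k_range,
    nloop: int = 50,
    base_seed: int = 0,
    scheme: str = "max",
) -> pd.DataFrame:
    """Cophenetic coefficient r per candidate rank k.

    Returns a DataFrame with columns ``k``, ``r`` and a boolean
    ``recommended`` marking the argmax of r (ties to the smallest k).
    """
    rows = []
    for k in k_range:
        C = consensus_matrix(A, k, nloop, base_seed, scheme)
        r = cophenetic_coefficient(C)
        rows.append({"k": int(k), "r": r})
        logger.info("select_k: k=%d r=%.4f", k, r)
    table = pd.DataFrame(rows)
    best = table.loc[table["r"].idxmax(), "k"]  # idxmax: first max -> smallest k
    table["recommended"] = table["k"] == best
    return table
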