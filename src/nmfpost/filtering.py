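"""Embedded gene filter and the two-pass post-processing pipeline.

Genes whose memberships are nearly flat across all metagenes of the normalized
W cannot separate sample classes.  The embedded filter scores each gene by
u_i = max_j W'_ij - min_j W'_ij, discards every gene whose spread is at or
below the T-quantile of u (default T = 0.5, i.e. the median), and refits NMF
on the reduced matrix.  A factorization-independent alternative keeps the
genes with the highest expression variance across samples and fits once.

`post_process_cluster` runs the whole pipeline: fit, normalize, optionally
filter and refit, normalize again, and assign each sample to the metagene with
the largest normalized H entry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .consensus import ClusterAssignment, assign_clusters
from .nmf import ExpressionMatrix, fit_nmf
from .normalization import normalize_factorization

logger = logging.getLogger("nmfpost")


@dataclass
class FilterReport:
    """Outcome of a gene filter: kept/discarded ids partition all genes."""

    kept_gene_ids: list[str]
    discarded_gene_ids: list[str]
    u: np.ndarray
    threshold: float
    T: float


def embedded_filter(
    W_norm: np.ndarray, gene_ids: list[str], T: float = 0.5
) -> FilterReport:
    """Max-min spread filter on a normalized W.

    Discards gene p when u(p) <= T-quantile of u (inclusive; linear
    interpolation quantile).  With T = 0.5 at least half the genes go.
    """
    if not 0.0 < T < 1.0:
        raise ValueError(f"filter fraction T must be in (0, 1), got {T}")
    W_norm = np.asarray(W_norm, dtype=float)
    u = W_norm.max(axis=1) - W_norm.min(axis=1)
    threshold = float(np.quantile(u, T))
    discard = u <= threshold
    if discard.all():
        warnings.warn(
            "embedded filter discarded every gene (all spreads tie at the "
            "threshold); with k=1 or a degenerate fit this is expected",
            stacklevel=2,
        )
    kept = [g for g, d in zip(gene_ids, discard) if not d]
    gone = [g for g, d in zip(gene_ids, discard) if d]
    return FilterReport(kept, gone, u, threshold, T)


def variance_filter(A: ExpressionMatrix, keep_fraction: float = 0.5) -> FilterReport:
    """Keep the ceil(keep_fraction * n) genes with the largest sample variance.

    Independent of any factorization; ties at the cut break by original index.
    The report's ``u`` holds the per-gene variances (n-1 denominator) and
    ``threshold`` the smallest kept variance.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    var = np.var(A.values, axis=1, ddof=1)
    n_keep = int(np.ceil(keep_fraction * A.n_genes))
    order = np.argsort(-var, kind="stable")
    keep_idx = np.sort(order[:n_keep])
    keep_mask = np.zeros(A.n_genes, dtype=bool)
    keep_mask[keep_idx] = True
    kept = [g for g, kp in zip(A.gene_ids, keep_mask) if kp]
    gone = [g for g, kp in zip(A.gene_ids, keep_mask) if not kp]
    return FilterReport(kept, gone, var, float(var[order[n_keep - 1]]), 1 - keep_fraction)


def post_process_cluster(
    A: ExpressionMatrix,
    k: int,
    scheme: str | None,
    seed: int,
    use_filter: bool = True,
    filter_kind: str = "embedded",
    T: float = 0.5,
) -> tuple[np.ndarray, ClusterAssignment, FilterReport | None]:
    """Full clustering pipeline: NMF, normalization, optional filter, assignment.

    Without a filter: one fit, H2 = normalized H.  With the embedded filter:
    fit, normalize W, score gene spreads, discard the flat half, refit on the
    reduced matrix (seed + 1 so the whole pipeline reproduces from one
    integer), normalize again; H2 comes from the second fit.  With the
    variance filter: reduce A first, then a single fit.

    ``scheme=None`` skips normalization entirely (the unnormalized baseline:
    argmax over raw H); the embedded filter requires a scheme.

    Returns (H2, assignment, FilterReport or None).
    """
    if not isinstance(A, ExpressionMatrix):
        A = ExpressionMatrix(
            np.asarray(A, dtype=float),
            [f"g{i}" for i in range(np.asarray(A).shape[0])],
            [f"s{j}" for j in range(np.asarray(A).shape[1])],
        )

    def _final_H(fac):
        if scheme is None:
            return fac.H
        _, Hn, _ = normalize_factorization(fac.W, fac.H, scheme)
        return Hn

    if not use_filter:
        fac = fit_nmf(A, k, seed)
        H2 = _final_H(fac)
        return H2, assign_clusters(H2), None

    if filter_kind == "embedded":
        if scheme is None:
            raise ValueError("the embedded filter requires a normalization scheme")
        fac0 = fit_nmf(A, k, seed)
        Wn, _, _ = normalize_factorization(fac0.W, fac0.H, scheme)
        report = embedded_filter(Wn, A.gene_ids, T)
        if not report.kept_gene_ids:
            raise ValueError("embedded filter discarded all genes; nothing to refit")
        keep_idx = np.where(~np.isin(A.gene_ids, report.discarded_gene_ids))[0]
        A1 = A.subset_genes(keep_idx)
        fac1 = fit_nmf(A1, k, seed + 1)
        H2 = _final_H(fac1)
        logger.info(
            "embedded filter: kept %d / %d genes (threshold %.4g)",
            len(report.kept_gene_ids), A.n_genes, report.threshold,
        )
        return H2, assign_clusters(H2), report
    if filter_kind == "variance":
        report = variance_filter(A, keep_fraction=1.0 - T)
        keep_idx = np.where(np.isin(A.gene_ids, report.kept_gene_ids))[0]
        A1 = A.subset_genes(keep_idx)
        fac = fit_nmf(A1, k, seed)
        H2 = _final_H(fac)
        return H2, assign_clusters(H2), report
    raise ValueError(f"unknown filter_kind {filter_kind!r}")
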