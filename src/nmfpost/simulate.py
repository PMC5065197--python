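"""Synthetic expression data with the structure the method assumes.

The generator plants a factorization and observes it through Poisson noise:
signal genes belong to one home metagene (membership exactly 1, satisfying
the assumption that each metagene contains at least one fully-on gene) with
small off-home memberships; irrelevant genes have near-flat membership rows
that carry no class information; samples are assigned round-robin to k
clusters, and each sample expresses its home metagene `dominance` times more
strongly than the others.  Entries are A_ij ~ Poisson((W_true H_true)_ij), or
X/c with X ~ Poisson(c (W_true H_true)_ij) for the scaled-Poisson variant.

What this emulates: count-like nonnegative expression with mean-dependent
noise and a planted low-rank class structure, plus a configurable fraction of
uninformative genes.  What it does not: microarray background/saturation,
negative-binomial overdispersion, batch effects, correlated genes beyond the
factor structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consensus import ClusterAssignment
from .nmf import ExpressionMatrix

#: upper bound for off-home memberships of signal genes
OFF_HOME_MAX = 0.2

#: baseline membership range for irrelevant genes; high, like housekeeping
#: genes that are strongly expressed regardless of class
IRRELEVANT_LEVEL = (0.85, 0.95)

_MAX_REDRAWS = 100


@dataclass
class SyntheticDataset:
    """A planted factorization, its Poisson observation, and the ground truth."""

    A: ExpressionMatrix
    true_labels: ClusterAssignment
    W_true: np.ndarray
    H_true: np.ndarray
    irrelevant_gene_ids: list[str]
    seed: int


def _build_truth(
    n_signal: int,
    n_irrelevant: int,
    m: int,
    k: int,
    expression_scale: float,
    dominance: float,
    flatness: float,
    rng: np.random.Generator,
    cluster_weights=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if k < 1 or n_signal < k:
        raise ValueError(f"need at least one signal gene per metagene (k={k})")
    if m < 2 * k:
        raise ValueError(f"need m >= 2k so every cluster gets >= 2 samples (m={m}, k={k})")
    if n_irrelevant < 0:
        raise ValueError("n_irrelevant must be nonnegative")
    if expression_scale <= 0:
        raise ValueError("expression_scale must be positive")
    if dominance <= 1:
        raise ValueError("dominance must exceed 1 (home metagene must dominate)")
    if not 0.0 <= flatness < 1.0:
        raise ValueError("flatness must lie in [0, 1)")

    n = n_signal + n_irrelevant
    W = np.empty((n, k))
    # signal genes: home metagene round-robin, membership 1 there, small elsewhere
    home_gene = np.arange(n_signal) % k
    W[:n_signal] = rng.uniform(0.0, OFF_HOME_MAX, size=(n_signal, k))
    W[np.arange(n_signal), home_gene] = 1.0
    # irrelevant genes: near-constant rows with spread <= flatness
    base = rng.uniform(*IRRELEVANT_LEVEL, size=n_irrelevant)
    W[n_signal:] = base[:, None] + rng.uniform(0.0, flatness, size=(n_irrelevant, k))
    W[n_signal:] = np.clip(W[n_signal:], 0.0, 1.0)

    if cluster_weights is None:
        labels = np.arange(m) % k  # round-robin, balanced
    else:
        w = np.asarray(cluster_weights, dtype=float)
        if w.size != k or (w <= 0).any():
            raise ValueError("cluster_weights must be k positive numbers")
        counts = np.floor(w / w.sum() * m).astype(int)
        counts[0] += m - counts.sum()
        if (counts < 2).any():
            raise ValueError("cluster_weights leave some cluster fewer than 2 samples")
        labels = np.repeat(np.arange(k), counts)
    H = np.full((k, m), expression_scale)
    H[labels, np.arange(m)] = dominance * expression_scale
    return W, H, labels + 1


def _observe(
    WH: np.ndarray, c: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson observation at scale c with bounded redraws of all-zero rows."""
    A = rng.poisson(c * WH).astype(float) / c
    for _ in range(_MAX_REDRAWS):
        zero = ~A.any(axis=1)
        if not zero.any():
            return A
        A[zero] = rng.poisson(c * WH[zero]).astype(float) / c
    raise RuntimeError(
        "could not draw nonzero expression for some genes; "
        "expression_scale is too small"
    )


def generate(
    n_signal: int = 900,
    n_irrelevant: int = 100,
    m: int = 60,
    k: int = 3,
    expression_scale: float = 50.0,
    dominance: float = 5.0,
    flatness: float = 0.05,
    seed: int = 0,
    cluster_weights=None,
) -> SyntheticDataset:
    """Generate a Poisson-noise expression matrix over a planted factorization.

    Defaults give a clearly separable 3-class design with 10% irrelevant
    genes: n = 1000 genes x m = 60 samples, per-entry means of order
    ``expression_scale`` (off-class) to ``dominance * expression_scale``
    (in-class).  ``cluster_weights`` makes cluster sizes unbalanced (balanced
    round-robin by default).  Rows that come out all-zero are redrawn a
    bounded number of times.
    """
    return generate_scaled(
        n_signal, n_irrelevant, m, k, expression_scale, dominance, flatness,
        c=1.0, seed=seed, cluster_weights=cluster_weights,
    )


def generate_scaled(
    n_signal: int = 900,
    n_irrelevant: int = 100,
    m: int = 60,
    k: int = 3,
    expression_scale: float = 50.0,
    dominance: float = 5.0,
    flatness: float = 0.05,
    c: float = 1.0,
    seed: int = 0,
    cluster_weights=None,
) -> SyntheticDataset:
    """Scaled-Poisson variant: A_ij = X / c with X ~ Poisson(c (WH)_ij).

    With c = 1 this is exactly :func:`generate`; larger c reduces the noise
    variance to (WH)_ij / c and makes entries multiples of 1/c.
    """
    if c <= 0:
        raise ValueError("scale factor c must be positive")
    rng = np.random.default_rng(seed)
    W, H, labels = _build_truth(
        n_signal, n_irrelevant, m, k, expression_scale, dominance, flatness,
        rng, cluster_weights,
    )
    A = _observe(W @ H, c, rng)
    n = n_signal + n_irrelevant
    gene_ids = [f"sig{i:04d}" for i in range(n_signal)] + [
        f"irr{i:04d}" for i in range(n_irrelevant)
    ]
    sample_ids = [f"s{j:03d}" for j in range(m)]
    return SyntheticDataset(
        A=ExpressionMatrix(A, gene_ids, sample_ids),
        true_labels=ClusterAssignment(labels, k),
        W_true=W,
        H_true=H,
        irrelevant_gene_ids=gene_ids[n_signal:],
        seed=seed,
    )
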