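"""Basic NMF by multiplicative updates minimizing generalized KL divergence.

Factors a nonnegative genes x samples expression matrix ``A`` into ``W`` (genes
x k metagenes) and ``H`` (k x samples) so that ``A ~ WH``, by the classical
coupled multiplicative update rules for the generalized Kullback-Leibler
divergence

    L(A, WH) = sum_ij [ A_ij log(A_ij / (WH)_ij) - A_ij + (WH)_ij ].

Minimizing L is maximum-likelihood estimation under independent Poisson
observations A_ij ~ Poisson((WH)_ij), which is the noise model this package
assumes throughout.  A Euclidean-loss variant (Gaussian noise) is provided for
comparison.

The stopping rule follows the consensus-clustering convention: iterate until
the sample connectivity matrix derived from argmax over columns of H has not
changed for several consecutive checks, or an iteration cap is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("nmfpost")

#: floor applied to W and H entries after every update, and added inside
#: divisions/logs, to keep the multiplicative updates away from absorbing zeros
EPS = 1e-12

#: lower bound of the uniform initialization range (entries in (INIT_EPS, 1])
INIT_EPS = 1e-4


class DegenerateInputError(ValueError):
    """Raised when an input matrix violates a structural precondition."""


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x samples expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Nonnegative expression values; no missing entries allowed.
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        n, m = self.values.shape
        if n < 1 or m < 2:
            raise DegenerateInputError(
                f"expression matrix must be at least 1 gene x 2 samples, got {n} x {m}"
            )
        if len(self.gene_ids) != n or len(self.sample_ids) != m:
            raise DegenerateInputError("identifier lengths do not match matrix shape")
        if len(set(self.gene_ids)) != n:
            dup = _first_duplicate(self.gene_ids)
            raise DegenerateInputError(f"duplicate gene id: {dup!r}")
        if len(set(self.sample_ids)) != m:
            dup = _first_duplicate(self.sample_ids)
            raise DegenerateInputError(f"duplicate sample id: {dup!r}")
        if np.isnan(self.values).any():
            raise DegenerateInputError("expression matrix contains missing values")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise DegenerateInputError(
                f"negative expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given gene index array."""
        keep = np.asarray(keep)
        return ExpressionMatrix(
            self.values[keep],
            [self.gene_ids[i] for i in keep],
            self.sample_ids,
        )


def _first_duplicate(ids: list[str]) -> str:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return ""


@dataclass
class Factorization:
    """Result of an NMF fit: nonnegative factors plus convergence metadata."""

    W: np.ndarray
    H: np.ndarray
    loss: float
    n_iter: int
    converged: bool
    seed: int
    loss_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def k(self) -> int:
        return self.W.shape[1]


def _as_array(A) -> np.ndarray:
    """Accept an ExpressionMatrix or a plain array-like."""
    if isinstance(A, ExpressionMatrix):
        return A.values
    return np.asarray(A, dtype=float)


def init_factors(
    n: int, m: int, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw strictly positive random starting factors W0 (n x k), H0 (k x m).

    Entries are i.i.d. uniform on ``(INIT_EPS, 1]``; a fixed seed yields
    bitwise-identical factors.
    """
    if n < 1 or m < 1 or k < 1:
        raise ValueError(f"dimensions must be positive, got n={n}, m={m}, k={k}")
    if k > min(n, m):
        raise ValueError(f"rank k={k} exceeds min(n, m)={min(n, m)}")
    rng = np.random.default_rng(seed)
    # 1 - U[0, 1-eps) lies in (eps, 1]
    W0 = 1.0 - rng.random((n, k)) * (1.0 - INIT_EPS)
    H0 = 1.0 - rng.random((k, m)) * (1.0 - INIT_EPS)
    return W0, H0


def kl_divergence(A, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence between A and its model WH.

    Uses the limit convention ``0 * log(0/x) = 0``.  Raises if some A_ij > 0
    sits on a zero model mean (the divergence is infinite there).
    """
    A = _as_array(A)
    WH = W @ H
    if np.any((A > 0) & (WH == 0)):
        raise ZeroDivisionError(
            "infinite divergence: A has positive entries where WH is zero"
        )
    pos = A > 0
    val = float(
        np.sum(A[pos] * np.log(A[pos] / WH[pos])) - A.sum() + WH.sum()
    )
    return val


def update_step(
    A, W: np.ndarray, H: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One coupled multiplicative update: H first, then W using the new H.

    For strictly positive factors the updates preserve positivity and never
    increase the KL loss.  Entries are floored at EPS afterwards.
    """
    A = _as_array(A)
    WH = W @ H + EPS
    H = H * (W.T @ (A / WH)) / (W.sum(axis=0)[:, None] + EPS)
    H = np.maximum(H, EPS)
    WH = W @ H + EPS
    W = W * ((A / WH) @ H.T) / (H.sum(axis=1)[None, :] + EPS)
    W = np.maximum(W, EPS)
    return W, H


def _connectivity_from_H(H: np.ndarray) -> np.ndarray:
    labels = np.argmax(H, axis=0)
    return labels[:, None] == labels[None, :]


def fit_nmf(
    A,
    k: int,
    seed: int,
    max_iter: int = 2000,
    check_every: int = 10,
    stall_checks: int = 4,
) -> Factorization:
    """Fit KL-divergence NMF with random initialization and the stall rule.

    Parameters
    ----------
    A : ExpressionMatrix or array-like
        Nonnegative matrix without all-zero rows.
    k : int
        Factorization rank (number of metagenes), ``1 <= k <= min(n, m)``.
    seed : int
        Seed for the random initialization; fixes the whole trajectory.
    max_iter : int
        Iteration cap.
    check_every, stall_checks : int
        Convergence is declared when the argmax-derived sample connectivity
        matrix of H is unchanged for `stall_checks` consecutive checks spaced
        `check_every` iterations apart.

    Returns
    -------
    Factorization
        Factors, final KL loss, iteration count and convergence flag.
    """
    Aarr = _as_array(A)
    zero_rows = np.where(~Aarr.any(axis=1))[0]
    if zero_rows.size:
        gid = (
            A.gene_ids[zero_rows[0]]
            if isinstance(A, ExpressionMatrix)
            else str(zero_rows[0])
        )
        raise DegenerateInputError(
            f"all-zero gene row (id {gid!r}); drop zero rows before fitting"
        )
    n, m = Aarr.shape
    W, H = init_factors(n, m, k, seed)
    prev_conn = _connectivity_from_H(H)
    stable = 0
    converged = False
    trace: list[float] = []
    it = 0
    while it < max_iter:
        W, H = update_step(Aarr, W, H)
        it += 1
        if it % check_every == 0:
            trace.append(kl_divergence(Aarr, W, H))
            conn = _connectivity_from_H(H)
            if np.array_equal(conn, prev_conn):
                stable += 1
                if stable >= stall_checks:
                    converged = True
                    break
            else:
                stable = 0
                prev_conn = conn
    loss = kl_divergence(Aarr, W, H)
    logger.debug(
        "fit_nmf: k=%d seed=%d iters=%d converged=%s loss=%.6g",
        k, seed, it, converged, loss,
    )
    return Factorization(W, H, loss, it, converged, seed, trace)


def euclidean_loss(A, W: np.ndarray, H: np.ndarray) -> float:
    """Squared Frobenius loss sum_ij (A_ij - (WH)_ij)^2."""
    A = _as_array(A)
    return float(np.sum((A - W @ H) ** 2))


def fit_nmf_eu(
    A,
    k: int,
    seed: int,
    max_iter: int = 2000,
    check_every: int = 10,
    stall_checks: int = 4,
) -> Factorization:
    """Euclidean-loss NMF variant (standard multiplicative updates).

    Same interface and stopping rule as :func:`fit_nmf` but minimizing the
    squared Frobenius norm; ``loss`` holds the Euclidean loss.
    """
    Aarr = _as_array(A)
    if np.any(~Aarr.any(axis=1)):
        raise DegenerateInputError("all-zero gene row; drop zero rows before fitting")
    n, m = Aarr.shape
    W, H = init_factors(n, m, k, seed)
    prev_conn = _connectivity_from_H(H)
    stable = 0
    converged = False
    trace: list[float] = []
    it = 0
    while it < max_iter:
        H = H * (W.T @ Aarr) / (W.T @ W @ H + EPS)
        H = np.maximum(H, EPS)
        W = W * (Aarr @ H.T) / (W @ H @ H.T + EPS)
        W = np.maximum(W, EPS)
        it += 1
        if it % check_every == 0:
            trace.append(euclidean_loss(Aarr, W, H))
            conn = _connectivity_from_H(H)
            if np.array_equal(conn, prev_conn):
                stable += 1
                if stable >= stall_checks:
                    converged = True
                    break
            else:
                stable = 0
                prev_conn = conn
    return Factorization(
        W, H, euclidean_loss(Aarr, W, H), it, converged, seed, trace
    )
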