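"""Factor normalization: resolve the diagonal-rescaling ambiguity of NMF.

Any NMF solution is non-unique: WH = (W D^-1)(D H) for every positive diagonal
D.  Normalization picks a canonical representative by computing a per-column
statistic D_j of W and setting W' = W D^-1, H' = D H.  The product W'H' equals
WH exactly, so the fit to the data is untouched; only the scale split between
the factors changes.  Because every supported statistic is positively
homogeneous of degree 1 (stat(c v) = c stat(v) for c > 0), the normalized pair
— and hence any downstream cluster assignment from H' — is invariant under the
rescaling ambiguity.

Supported schemes: ``max`` (infinity norm; entries of W' land in [0, 1] and
read as gene-in-metagene memberships), p-norms ``norm1``/``norm2``/``norm3``,
sample standard deviation ``sd`` (n-1 denominator), and the linear-interpolation
sample quantiles ``q95``/``q75``/``q50``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SCHEMES = ("max", "norm1", "norm2", "norm3", "sd", "q95", "q75", "q50")


class DegenerateColumnError(ValueError):
    """A W column on which the chosen statistic is zero or undefined."""


@dataclass
class DiagonalScaling:
    """Positive diagonal of the rescaling matrix D (one entry per metagene)."""

    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if (self.d <= 0).any():
            raise ValueError("diagonal scaling must be strictly positive")


def column_statistic(v: np.ndarray, scheme: str) -> float:
    """Map a nonnegative column vector to the positive scalar D_j.

    Raises DegenerateColumnError for an all-zero vector, or a constant vector
    under ``sd`` (zero standard deviation cannot rescale).
    """
    v = np.asarray(v, dtype=float)
    if not (v > 0).any():
        raise DegenerateColumnError("all-zero column")
    if scheme == "max":
        return float(v.max())
    if scheme in ("norm1", "norm2", "norm3"):
        p = float(scheme[-1])
        return float(np.sum(np.abs(v) ** p) ** (1.0 / p))
    if scheme == "sd":
        s = float(np.std(v, ddof=1))
        if s == 0.0:
            raise DegenerateColumnError("constant column has zero standard deviation")
        return s
    if scheme in ("q95", "q75", "q50"):
        q = float(scheme[1:]) / 100.0
        s = float(np.quantile(v, q))  # linear interpolation (default)
        if s == 0.0:
            raise DegenerateColumnError(f"{scheme} of column is zero")
        return s
    raise ValueError(f"unknown normalization scheme {scheme!r}; choose from {SCHEMES}")


def normalize_factorization(
    W: np.ndarray, H: np.ndarray, scheme: str = "max"
) -> tuple[np.ndarray, np.ndarray, DiagonalScaling]:
    """Return (W', H', D) with W' = W D^-1 and H' = D H.

    D_j is `column_statistic` of the j-th column of W; the product W'H' equals
    WH entrywise (exact algebraic cancellation, asserted in tests to 1e-10).
    """
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    d = np.empty(W.shape[1])
    for j in range(W.shape[1]):
        try:
            d[j] = column_statistic(W[:, j], scheme)
        except DegenerateColumnError as e:
            raise DegenerateColumnError(f"metagene {j}: {e}") from None
    Wn = W / d[None, :]
    Hn = H * d[:, None]
    return Wn, Hn, DiagonalScaling(d)


def rescaling_invariance_check(
    W: np.ndarray,
    H: np.ndarray,
    scheme: str,
    d: DiagonalScaling,
    tol: float = 1e-10,
) -> bool:
    """True iff normalizing (W diag(d)^-1, diag(d) H) matches normalizing (W, H).

    Holds for every scheme by degree-1 positive homogeneity of the statistic.
    """
    dv = d.d
    Wn1, Hn1, _ = normalize_factorization(W, H, scheme)
    Wn2, Hn2, _ = normalize_factorization(W / dv[None, :], H * dv[:, None], scheme)
    return bool(
        np.max(np.abs(Wn1 - Wn2)) <= tol and np.max(np.abs(Hn1 - Hn2)) <= tol
    )
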