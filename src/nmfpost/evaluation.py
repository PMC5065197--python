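"""Evaluation protocol: matched accuracy, repeated-seed experiments, t-tests.

Cluster labels are arbitrary, so accuracy is computed after matching predicted
clusters to true classes by optimal one-to-one assignment (Hungarian algorithm
on the contingency table); unmatched predicted clusters contribute no correct
samples.  Experiments repeat the clustering pipeline over consecutive seeds
and report mean accuracy with its standard error; two method configurations
run on the same seeds are compared with a paired two-sided t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .consensus import ClusterAssignment
from .filtering import post_process_cluster
from .nmf import ExpressionMatrix

logger = logging.getLogger("nmfpost")


@dataclass
class ExperimentResult:
    """Per-seed accuracies (percent) of one method configuration."""

    method_id: str
    per_seed_accuracy: np.ndarray
    mean: float
    sem: float
    n_runs: int


def clustering_accuracy(pred: ClusterAssignment, truth: ClusterAssignment) -> float:
    """Percent of samples correctly clustered under the best label matching.

    Maximizes agreement over injective maps from predicted to true labels via
    rectangular Hungarian matching on the contingency table; symmetric under
    relabeling of either argument.
    """
    p = pred.labels if isinstance(pred, ClusterAssignment) else np.asarray(pred)
    t = truth.labels if isinstance(truth, ClusterAssignment) else np.asarray(truth)
    if p.size != t.size:
        raise ValueError(f"length mismatch: {p.size} predictions vs {t.size} truths")
    pu, pi = np.unique(p, return_inverse=True)
    tu, ti = np.unique(t, return_inverse=True)
    cont = np.zeros((pu.size, tu.size))
    np.add.at(cont, (pi, ti), 1)
    rows, cols = linear_sum_assignment(cont, maximize=True)
    return float(cont[rows, cols].sum() / p.size * 100.0)


def run_experiment(
    A: ExpressionMatrix,
    truth: ClusterAssignment,
    method_id: str = "max+embedded",
    scheme: str | None = "max",
    use_filter: bool = True,
    filter_kind: str = "embedded",
    T: float = 0.5,
    k: int | None = None,
    n_runs: int = 100,
    base_seed: int = 0,
) -> ExperimentResult:
    """Repeat the pipeline over seeds base_seed..base_seed+n_runs-1.

    ``k`` defaults to the number of distinct true classes.  SEM is the sample
    standard deviation of the per-seed accuracies divided by sqrt(n_runs);
    with a single run it is reported as 0 with a warning.
    """
    if k is None:
        k = int(np.unique(truth.labels).size)
    acc = np.empty(n_runs)
    for i in range(n_runs):
        _, assignment, _ = post_process_cluster(
            A, k, scheme, base_seed + i,
            use_filter=use_filter, filter_kind=filter_kind, T=T,
        )
        acc[i] = clustering_accuracy(assignment, truth)
    if n_runs == 1:
        warnings.warn("SEM undefined for a single run; reporting 0", stacklevel=2)
        sem = 0.0
    else:
        sem = float(np.std(acc, ddof=1) / np.sqrt(n_runs))
    result = ExperimentResult(method_id, acc, float(acc.mean()), sem, n_runs)
    logger.info("experiment %s: mean %.2f%% +/- %.2f (n=%d)",
                method_id, result.mean, result.sem, n_runs)
    return result


def compare_methods(
    resA: ExperimentResult, resB: ExperimentResult
) -> tuple[float, float]:
    """Paired two-sided t-test on per-seed accuracy differences.

    Returns (mean difference A - B, p-value).  Zero-variance differences are a
    degenerate case: p = 1 when the runs are identical, p = 0 when they differ
    by an exact constant (flagged with a warning).
    """
    if resA.n_runs != resB.n_runs:
        raise ValueError("paired comparison requires equal n_runs")
    diff = resA.per_seed_accuracy - resB.per_seed_accuracy
    mean_diff = float(diff.mean())
    if np.allclose(diff, diff[0]):
        p = 1.0 if mean_diff == 0.0 else 0.0
        warnings.warn(
            "zero-variance paired differences; degenerate p-value convention",
            stacklevel=2,
        )
        return mean_diff, p
    t = stats.ttest_rel(resA.per_seed_accuracy, resB.per_seed_accuracy)
    return mean_diff, float(t.pvalue)


def top_varying_subset(A: ExpressionMatrix, n_genes: int) -> ExpressionMatrix:
    """Restrict to the n_genes rows with the largest sample variance.

    Kept genes retain their original relative order; ties at the cut break by
    original index.
    """
    if n_genes > A.n_genes:
        raise ValueError(f"requested {n_genes} genes but matrix has {A.n_genes}")
    var = np.var(A.values, axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")
    keep = np.sort(order[:n_genes])
    return A.subset_genes(keep)


def noise_perturb(A: ExpressionMatrix, mu: float, seed: int) -> ExpressionMatrix:
    """Add independent uniform noise: A'_ij = A_ij + mu * r_ij.

    r_ij ~ Uniform[0, max(A)] where max(A) is the largest expression value, so
    A <= A' <= A + mu * max(A) entrywise.
    """
    if mu < 0:
        raise ValueError(f"noise magnitude mu must be nonnegative, got {mu}")
    rng = np.random.default_rng(seed)
    r = rng.uniform(0.0, A.values.max(), size=A.values.shape)
    return ExpressionMatrix(A.values + mu * r, A.gene_ids, A.sample_ids)
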