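"""Nonparametric evaluation of pathway predictive power.

A model-free companion to the OPI/PPI detection machinery: samples are
split into two clusters by K-means on the pathway's expression profile,
the two-group logrank test measures whether the clusters differ in
survival, and per-study p-values are pooled with Fisher's method. All
genes in the pathway (noisy ones included) contribute to the clustering,
so this evaluation is less efficient than the penalized detection route
and is used for comparison, not detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, mannwhitneyu
from sklearn.cluster import KMeans

from .datatypes import ExpressionMatrix, StudyDataset, SurvivalData
from .metafdr import fisher_combine
from .power import DegeneratePartitionError, logrank_statistic

__all__ = [
    "ClusterEvalResult",
    "kmeans_two_cluster",
    "cluster_logrank_pvalue",
    "evaluate_pathway",
    "compare_pathway_groups",
]

_KMEANS_SEED = 1729  # fixed multi-start seed: clustering is deterministic


@dataclass
class ClusterEvalResult:
    pathway: str
    per_dataset_logrank_p: np.ndarray
    meta_p: float

    def __post_init__(self) -> None:
        self.per_dataset_logrank_p = np.asarray(self.per_dataset_logrank_p, float)
        if np.any(self.per_dataset_logrank_p <= 0) or np.any(
            self.per_dataset_logrank_p > 1
        ):
            raise ValueError("logrank p-values must lie in (0, 1]")


def kmeans_two_cluster(x) -> np.ndarray:
    """Two-cluster K-means over samples in gene-expression space.

    ``x`` is a pathway submatrix (ExpressionMatrix or genes x samples
    array). Ten seeded restarts, best within-cluster sum of squares kept;
    labels are canonicalized so the cluster containing sample 0 is 0.
    """
    if isinstance(x, ExpressionMatrix):
        x = x.values
    x = np.atleast_2d(np.asarray(x, dtype=float))
    samples = x.T  # samples as rows
    if samples.shape[0] < 2:
        raise ValueError("need at least two samples to cluster")
    if np.allclose(samples, samples[0]):
        raise ValueError("all samples identical; no two-cluster split exists")
    km = KMeans(n_clusters=2, n_init=10, random_state=_KMEANS_SEED)
    labels = km.fit_predict(samples)
    if labels[0] == 1:
        labels = 1 - labels
    return labels


def cluster_logrank_pvalue(labels: np.ndarray, surv: SurvivalData) -> float:
    """Chi-square(1) upper-tail p of the two-group logrank statistic.

    A degenerate statistic (zero variance) yields p = 1 with a warning.
    """
    try:
        stat = logrank_statistic(np.asarray(labels) == 1, surv)
    except DegeneratePartitionError:
        warnings.warn("degenerate logrank statistic; reporting p = 1")
        return 1.0
    return float(chi2.sf(stat, 1))


def evaluate_pathway(
    datasets: list[StudyDataset], pathway: tuple[str, ...], name: str = ""
) -> ClusterEvalResult:
    """Cluster/logrank p-value per study, Fisher-combined across studies."""
    pvals = []
    for ds in datasets:
        genes = [g for g in pathway if g in set(ds.expression.gene_ids)]
        if not genes:
            raise ValueError(
                f"pathway {name!r} not measured in study {ds.label!r}"
            )
        sub = ds.expression.subset_genes(genes)
        labels = kmeans_two_cluster(sub)
        pvals.append(cluster_logrank_pvalue(labels, ds.survival))
    pvals = np.array(pvals)
    _, meta_p = fisher_combine(np.maximum(pvals, 1e-300))
    return ClusterEvalResult(name, pvals, meta_p)


def compare_pathway_groups(
    meta_p_identified: np.ndarray, meta_p_other: np.ndarray
) -> dict:
    """Compare evaluation p-values between two pathway groups.

    Reports the group medians and the two-sided Wilcoxon rank-sum
    p-value, mirroring the identified-vs-not comparisons used to judge
    whether a detection method finds genuinely predictive pathways.
    """
    a = np.asarray(meta_p_identified, dtype=float)
    b = np.asarray(meta_p_other, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return {
        "median_identified": float(np.median(a)),
        "median_other": float(np.median(b)),
        "wilcoxon_p": float(res.pvalue),
        "n_identified": int(a.size),
        "n_other": int(b.size),
    }
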