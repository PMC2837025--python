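"""Fisher meta-analysis across studies and FDR control across pathways.

Per-study pathway p-values p_1..p_D are pooled with Fisher's statistic
s = -2 * sum(log p_d), chi-square with 2D degrees of freedom under the
joint null. Across the N pathways, significance is decided by a step-up
rule at target FDR q whose thresholds are deflated by c(N); under the
``overlap`` correction c(N) is the harmonic sum 1 + 1/2 + ... + 1/N,
valid under arbitrary dependence and appropriate because overlapping
pathways share genes and hence correlate; under ``independence``
c(N) = 1 (the plain Benjamini-Hochberg rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "MetaResult",
    "fisher_combine",
    "fdr_select",
    "rank_pathways",
    "uniformity_report",
    "harmonic_number",
]

P_FLOOR = 1e-300


@dataclass
class MetaResult:
    pathway: str
    per_dataset_p: np.ndarray
    fisher_statistic: float
    meta_p: float
    size: int = 0
    rank: int = 0
    significant: bool = False

    def __post_init__(self) -> None:
        self.per_dataset_p = np.asarray(self.per_dataset_p, dtype=float)


def fisher_combine(pvalues: np.ndarray) -> tuple[float, float]:
    """Fisher's pooled statistic and its chi-square(2D) upper-tail p.

    Zero inputs are clamped to 1e-300 (their log otherwise diverges) with
    a warning. With a single p-value the identity chi2_2.sf(-2 ln p) = p
    returns it unchanged.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("pvalues must be a non-empty 1-D vector")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero p-value clamped to 1e-300 before Fisher pooling")
        p = np.maximum(p, P_FLOOR)
    s = float(-2.0 * np.sum(np.log(p)))
    return s, float(chi2.sf(s, 2 * p.size))


def harmonic_number(n: int) -> float:
    """c(N) = sum_{i=1..N} 1/i, the dependence inflation constant."""
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def fdr_select(
    meta_pvalues: np.ndarray,
    q: float = 0.2,
    correction: str = "overlap",
) -> tuple[np.ndarray, int]:
    """Step-up selection at target FDR q.

    Sorts the N p-values ascending and finds the largest r with
    p_(r) <= r * q / (N * c(N)); the pathways holding the r smallest
    p-values are selected. Returns (selected original indices, r);
    r = 0 with an empty selection is a valid outcome.
    """
    p = np.asarray(meta_pvalues, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    n = p.size
    if n == 0:
        return np.array([], dtype=int), 0
    if correction == "overlap":
        c = harmonic_number(n)
    elif correction == "independence":
        c = 1.0
    else:
        raise ValueError(f"unknown correction {correction!r}")
    order = np.argsort(p, kind="stable")
    thresholds = np.arange(1, n + 1) * q / (n * c)
    passing = np.flatnonzero(p[order] <= thresholds)
    r = int(passing[-1] + 1) if passing.size else 0
    return np.sort(order[:r]), r


def rank_pathways(results: list[MetaResult]) -> list[MetaResult]:
    """Sort ascending by meta p, ties by pathway name; assign ranks 1..N."""
    out = sorted(results, key=lambda r: (r.meta_p, r.pathway))
    for i, r in enumerate(out, start=1):
        r.rank = i
    return out


def uniformity_report(
    per_dataset_p: np.ndarray,
    pathway_names: list[str] | None = None,
    flag_orders: float = 2.0,
) -> pd.DataFrame:
    """Diagnose pathways whose Fisher pooling is driven by one study.

    Fisher's method is sensitive to a single extreme component. For each
    pathway, reports the range and coefficient of variation of -log10 p
    across studies, and flags it when any study's p-value is more than
    ``flag_orders`` orders of magnitude below the median of the others.
    """
    P = np.asarray(per_dataset_p, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValueError("need an N x D matrix with D >= 2")
    P = np.maximum(P, P_FLOOR)
    neglog = -np.log10(P)
    rng_ = neglog.max(axis=1) - neglog.min(axis=1)
    mean = neglog.mean(axis=1)
    sd = neglog.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    n, d = P.shape
    flagged = np.zeros(n, dtype=bool)
    for j in range(d):
        others = np.delete(P, j, axis=1)
        flagged |= P[:, j] < np.median(others, axis=1) * 10.0 ** (-flag_orders)
    if pathway_names is None:
        pathway_names = [f"pathway_{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "pathway": list(pathway_names),
            "neglog10_range": rng_,
            "neglog10_cv": cv,
            "flagged": flagged,
        }
    )
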