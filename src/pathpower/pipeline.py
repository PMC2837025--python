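"""End-to-end orchestration: preprocess -> OPI/PPI -> meta -> FDR -> report.

The in-memory entry point is :func:`analyze`, which takes preprocessed
studies and a pathway collection; :func:`run_pipeline` wraps it with file
IO driven by a :class:`RunConfig`. Pathways are independent work units
with per-pathway seeding, so any execution order yields identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import PathwayCollection, StudyDataset
from .metafdr import (
    MetaResult,
    fdr_select,
    fisher_combine,
    rank_pathways,
    uniformity_report,
)
from .power import PredictiveIndex, ResamplingConfig, pathway_dataset_pvalue
from .preprocess import (
    match_genes,
    preprocess_study,
    read_expression,
    read_gmt,
    read_survival,
    restrict_pathways,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "analyze", "run_pipeline",
           "plot_index_densities", "index_densities"]


@dataclass
class DatasetSpec:
    expression_path: str
    survival_path: str
    label: str


@dataclass
class RunConfig:
    """File-level configuration of a full run.

    Reference defaults pre-filled: B=100 partitions, 2/3 train fraction,
    3-fold CV, gamma=1/2, target FDR q=0.2 with the overlap correction.
    """

    datasets: list[DatasetSpec]
    gmt_path: str
    output_dir: str
    B: int = 100
    train_fraction: float = 2.0 / 3.0
    seed: int = 0
    cv_folds: int = 3
    gamma: float = 0.5
    n_lambda: int = 25
    q: float = 0.2
    correction: str = "overlap"
    knn_k: int = 10
    make_plots: bool = False
    verbosity: str = "INFO"

    def resampling(self) -> ResamplingConfig:
        return ResamplingConfig(
            B=self.B,
            train_fraction=self.train_fraction,
            seed=self.seed,
            cv_folds=self.cv_folds,
            gamma=self.gamma,
            n_lambda=self.n_lambda,
        )

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        datasets = [DatasetSpec(**d) for d in raw.pop("datasets")]
        return cls(datasets=datasets, **raw)


@dataclass
class PipelineResult:
    """Everything a run produced, in memory."""

    results: pd.DataFrame
    per_dataset: pd.DataFrame
    uniformity: pd.DataFrame | None
    meta: list[MetaResult]
    selected: list[str]
    indices: dict[tuple[str, str], tuple[PredictiveIndex, PredictiveIndex]] = field(
        default_factory=dict
    )

    @property
    def n_pathways(self) -> int:
        return len(self.results)


def analyze(
    datasets: list[StudyDataset],
    pathways: PathwayCollection,
    cfg: ResamplingConfig,
    q: float = 0.2,
    correction: str = "overlap",
    keep_indices: bool = False,
) -> PipelineResult:
    """Run every pathway through the OPI/PPI engine in every study.

    Studies must already be preprocessed and gene-matched; pathways are
    restricted to the measured genes here. Per-study p-values are
    Fisher-combined, pathways are ranked by meta p-value, and the
    overlap-corrected step-up rule at target FDR ``q`` decides
    significance.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    measured = set(datasets[0].expression.gene_ids)
    for ds in datasets[1:]:
        measured &= set(ds.expression.gene_ids)
    usable = restrict_pathways(pathways, measured)
    if len(usable) == 0:
        raise ValueError("no pathway overlaps the genes measured in all studies")

    rows = []
    metas = []
    indices: dict[tuple[str, str], tuple[PredictiveIndex, PredictiveIndex]] = {}
    for name, genes in usable:
        per_ds = []
        for ds in datasets:
            try:
                p, opi, ppi = pathway_dataset_pvalue(ds, genes, cfg, name=name)
            except Exception as exc:
                raise RuntimeError(
                    f"pathway {name!r}, study {ds.label!r}: {exc}"
                ) from exc
            per_ds.append(p)
            rows.append(
                {
                    "pathway": name,
                    "size": len(genes),
                    "dataset": ds.label,
                    "pvalue": p,
                    "opi_median": opi.median,
                    "ppi_median": ppi.median,
                    "failed_partitions": opi.failed + ppi.failed,
                }
            )
            if keep_indices:
                indices[(name, ds.label)] = (opi, ppi)
            logger.info(
                "pathway %s | study %s | p=%.4g | failed=%d",
                name, ds.label, p, opi.failed + ppi.failed,
            )
        s, meta_p = fisher_combine(np.array(per_ds))
        metas.append(
            MetaResult(name, np.array(per_ds), s, meta_p, size=len(genes))
        )

    metas = rank_pathways(metas)
    sel_idx, _r = fdr_select(
        np.array([m.meta_p for m in metas]), q=q, correction=correction
    )
    for i in sel_idx:
        metas[i].significant = True
    selected = [metas[i].pathway for i in sel_idx]

    labels = [ds.label for ds in datasets]
    res = pd.DataFrame(
        {
            "pathway": [m.pathway for m in metas],
            "size": [m.size for m in metas],
            "meta_pvalue": [m.meta_p for m in metas],
            "rank": [m.rank for m in metas],
            "significant": [m.significant for m in metas],
            **{
                f"p_{lab}": [m.per_dataset_p[j] for m in metas]
                for j, lab in enumerate(labels)
            },
        }
    )
    per_dataset = pd.DataFrame(rows)
    unif = None
    if len(datasets) >= 2:
        unif = uniformity_report(
            np.vstack([m.per_dataset_p for m in metas]),
            [m.pathway for m in metas],
        )
    return PipelineResult(res, per_dataset, unif, metas, selected, indices)


def load_study(spec: DatasetSpec) -> StudyDataset:
    """Read one study's expression and survival files and align samples."""
    expr = read_expression(spec.expression_path)
    surv = read_survival(spec.survival_path)
    order = {s: i for i, s in enumerate(surv.sample_ids)}
    missing = [s for s in expr.sample_ids if s not in order]
    if missing:
        raise ValueError(
            f"study {spec.label!r}: samples without survival rows: {missing[:5]}"
        )
    idx = np.array([order[s] for s in expr.sample_ids])
    return StudyDataset(spec.label, expr, surv.subset(idx))


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Full file-to-file run; returns the in-memory bundle as well."""
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), logging.INFO))
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    studies = [load_study(d) for d in cfg.datasets]
    studies = [preprocess_study(s, k=cfg.knn_k) for s in studies]
    studies = match_genes(studies)
    pathways = read_gmt(cfg.gmt_path)

    result = analyze(
        studies,
        pathways,
        cfg.resampling(),
        q=cfg.q,
        correction=cfg.correction,
        keep_indices=cfg.make_plots,
    )

    result.results.to_csv(outdir / "results.tsv", sep="\t", index=False)
    result.per_dataset.to_csv(outdir / "per_dataset.tsv", sep="\t", index=False)
    if result.uniformity is not None:
        result.uniformity.to_csv(outdir / "uniformity.tsv", sep="\t", index=False)
    with open(outdir / "run_info.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "seed": cfg.seed,
                "B": cfg.B,
                "gamma": cfg.gamma,
                "cv_folds": cfg.cv_folds,
                "q": cfg.q,
                "correction": cfg.correction,
                "n_pathways": result.n_pathways,
                "n_selected": len(result.selected),
                "failed_partitions": int(
                    result.per_dataset["failed_partitions"].sum()
                ),
            },
            fh,
            indent=2,
        )
    if cfg.make_plots:
        plotdir = outdir / "plots"
        plotdir.mkdir(exist_ok=True)
        for (name, lab), (opi, ppi) in result.indices.items():
            plot_index_densities(opi, ppi, plotdir / f"{name}_{lab}.png")
    return result


def index_densities(opi, ppi, gridsize: int = 256):
    """Gaussian-kernel density estimates of OPI and PPI on a common grid."""
    from scipy.stats import gaussian_kde

    a = np.asarray(getattr(opi, "statistics", opi), dtype=float)
    b = np.asarray(getattr(ppi, "statistics", ppi), dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 statistics per index")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    span = max(hi - lo, 1e-6)
    grid = np.linspace(lo - 0.1 * span, hi + 0.1 * span, gridsize)
    return grid, gaussian_kde(a)(grid), gaussian_kde(b)(grid)


def plot_index_densities(opi, ppi, path) -> None:
    """Overlay OPI and PPI density curves and save to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid, da, db = index_densities(opi, ppi)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(grid, da, color="black", label="OPI")
    ax.plot(grid, db, color="tab:blue", label="PPI")
    ax.set_xlabel("squared standardized logrank statistic")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
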