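"""Reading, imputation, normalization and cross-study alignment.

Each study is processed separately: k-nearest-neighbour imputation of
missing expression values, then per-gene normalization to zero median and
unit variance. Studies are then aligned to the genes measured in every
study, and the pathway collection is restricted to those genes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .datatypes import ExpressionMatrix, PathwayCollection, StudyDataset, SurvivalData

logger = logging.getLogger(__name__)

DEFAULT_NA_TOKENS = ("NA", "NaN", "")


def read_expression(
    path, na_tokens: tuple[str, ...] = DEFAULT_NA_TOKENS
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene id, header sample ids).

    Missing entries may be encoded by any token in ``na_tokens``; they come
    back as NaN. Duplicate gene rows and ragged lines are errors.
    """
    with open(path, newline="") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    sample_ids = [s.strip() for s in header[1:]]
    n_cols = len(sample_ids)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    na = set(na_tokens)
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in ln.split("\t")]
        if len(fields) != n_cols + 1:
            raise ValueError(
                f"{path}:{lineno}: expected {n_cols + 1} fields, got {len(fields)}"
            )
        gene = fields[0]
        if gene in set(gene_ids):
            raise ValueError(f"{path}:{lineno}: duplicate gene identifier {gene!r}")
        gene_ids.append(gene)
        rows.append(
            [np.nan if f in na else float(f) for f in fields[1:]]
        )
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def read_survival(path) -> SurvivalData:
    """Read a TSV with columns sample_id, time, event."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: survival table needs columns {sorted(required)}")
    return SurvivalData(
        [str(s) for s in df["sample_id"]],
        df["time"].to_numpy(float),
        df["event"].to_numpy(int),
    )


def read_gmt(path) -> PathwayCollection:
    """Read a GMT gene-set file: name, description, then member genes.

    Duplicate genes within a set are dropped (order of first occurrence
    kept) with a warning; lines with fewer than three fields are errors.
    """
    entries: dict[str, tuple[str, ...]] = {}
    with open(path, newline="") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\r\n").rstrip()
            if ln == "":
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name = fields[0].strip()
            if name in entries:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    warnings.warn(
                        f"{path}:{lineno}: duplicate gene {g!r} in pathway {name!r}"
                    )
                    continue
                seen.add(g)
                genes.append(g)
            entries[name] = tuple(genes)
    return PathwayCollection(entries, provenance=str(path))


def knn_impute(x: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing entries from the k most similar genes.

    A missing value for gene g at sample s is the unweighted mean, over the
    k genes closest to g, of their values at s. Gene-gene distance is
    Euclidean over mutually observed samples, rescaled by the number of
    shared samples, so genes with different missingness patterns are
    comparable. Complete matrices pass through unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = np.isnan(x.values)
    if not mask.any():
        return x
    all_missing = mask.all(axis=1)
    if all_missing.any():
        bad = x.gene_ids[int(np.argmax(all_missing))]
        raise ValueError(f"gene {bad!r} has no observed values; cannot impute")
    imputer = KNNImputer(n_neighbors=k, weights="uniform", metric="nan_euclidean")
    # genes as rows: neighbours are genes, donors supply the missing sample
    filled = imputer.fit_transform(x.values)
    if filled.shape != x.values.shape:  # pragma: no cover - sklearn drops all-nan cols
        raise RuntimeError("imputation changed matrix shape")
    return ExpressionMatrix(list(x.gene_ids), list(x.sample_ids), filled)


def normalize_median_unit_variance(x: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene at zero median and scale to unit sample variance."""
    v = x.values
    if np.isnan(v).any():
        raise ValueError("normalize requires a complete matrix; impute first")
    med = np.median(v, axis=1, keepdims=True)
    centred = v - med
    sd = np.std(v, axis=1, ddof=1, keepdims=True)
    zero_sd = (sd == 0).ravel()
    if zero_sd.any():
        bad = x.gene_ids[int(np.argmax(zero_sd))]
        raise ValueError(f"gene {bad!r} is constant; cannot scale to unit variance")
    return ExpressionMatrix(list(x.gene_ids), list(x.sample_ids), centred / sd)


def match_genes(datasets: list[StudyDataset]) -> list[StudyDataset]:
    """Restrict every study to the genes measured in all studies.

    Rows come back in the same (sorted) order in every returned dataset so
    that covariate columns align across studies.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    common = set(datasets[0].expression.gene_ids)
    for ds in datasets[1:]:
        common &= set(ds.expression.gene_ids)
    if not common:
        raise ValueError("gene intersection across studies is empty")
    order = sorted(common)
    out = []
    for ds in datasets:
        out.append(
            StudyDataset(ds.label, ds.expression.subset_genes(order), ds.survival,
                         dict(ds.meta))
        )
    logger.info("matched %d genes across %d studies", len(order), len(datasets))
    return out


def restrict_pathways(
    pathways: PathwayCollection, measured: set[str]
) -> PathwayCollection:
    """Intersect each pathway with the measured genes; drop empty pathways."""
    measured = set(measured)
    entries: dict[str, tuple[str, ...]] = {}
    for name, genes in pathways:
        kept = tuple(g for g in genes if g in measured)
        if kept:
            entries[name] = kept
    if entries:
        sizes = np.array([len(v) for v in entries.values()])
        logger.info(
            "restricted %d -> %d pathways; size min/median/max = %d/%g/%d",
            len(pathways), len(entries), sizes.min(), np.median(sizes), sizes.max(),
        )
    else:
        logger.warning("no pathway overlaps the measured genes")
    return PathwayCollection(entries, provenance=pathways.provenance)


def preprocess_study(
    dataset: StudyDataset, k: int = 10
) -> StudyDataset:
    """Impute then normalize one study's expression matrix."""
    expr = knn_impute(dataset.expression, k=k)
    expr = normalize_median_unit_variance(expr)
    return StudyDataset(dataset.label, expr, dataset.survival, dict(dataset.meta))
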