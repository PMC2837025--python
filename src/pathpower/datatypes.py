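"""Core in-memory containers shared across the pipeline.

The unit of analysis is a *study*: a genes x samples expression matrix
together with right-censored survival follow-up for the same samples.
Pathways are named gene sets; after preprocessing they are restricted to
the genes actually measured in every study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SurvivalData",
    "PathwayCollection",
    "StudyDataset",
]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression; NaN marks a missing entry."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Rows restricted to ``genes``, in the order given."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SurvivalData:
    """Right-censored follow-up: T = min(event, censoring), delta = event seen."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length does not match sample_ids")
        if not np.all(self.time > 0):
            raise ValueError("follow-up times must be positive")
        if not np.all(np.isin(self.event, [0, 1])):
            raise ValueError("event indicator must be 0/1")
        if self.event.sum() == 0:
            raise ValueError("survival data contains no events")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx: np.ndarray) -> "SurvivalData":
        idx = np.asarray(idx)
        return SurvivalData(
            [self.sample_ids[i] for i in idx], self.time[idx], self.event[idx]
        )


@dataclass
class PathwayCollection:
    """Named gene sets (e.g. parsed from a GMT file)."""

    entries: dict[str, tuple[str, ...]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.entries.items():
            if len(genes) == 0:
                raise ValueError(f"pathway {name!r} has no genes")
        self.entries = {k: tuple(v) for k, v in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.entries.items()}


@dataclass
class StudyDataset:
    """One study's expression matrix plus survival outcomes, sample-aligned."""

    label: str
    expression: ExpressionMatrix
    survival: SurvivalData
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.survival.sample_ids:
            raise ValueError(
                f"study {self.label!r}: expression and survival sample ids differ"
            )

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples
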