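"""Core in-memory containers shared across the pipeline.

The two objects that travel between almost every stage are the expression
matrix (genes x samples, with an explicit normalization state) and the drug
signature (a named set of genes with projection weights). Both are thin,
validated wrappers around pandas structures so that downstream code can rely
on unique identifiers and finite values without re-checking.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationState",
    "ExpressionMatrix",
    "DrugSignature",
    "ResponseScore",
]


class NormalizationState(str, enum.Enum):
    """Normalization state of an expression matrix."""

    RAW_COUNTS = "raw_counts"
    TMM_LOG2 = "tmm_log2"
    EXTERNAL_NORMALIZED = "external_normalized"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
        if seen[i] == 2:
            dups.append(i)
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {', '.join(map(str, dups))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a normalization state.

    Parameters
    ----------
    data
        DataFrame indexed by gene identifier with one column per sample.
    state
        One of :class:`NormalizationState`. ``raw_counts`` additionally
        requires all values to be non-negative integers.
    """

    data: pd.DataFrame
    state: NormalizationState = NormalizationState.RAW_COUNTS

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.state = NormalizationState(self.state)
        _check_unique(list(self.data.index.astype(str)), "gene")
        _check_unique(list(self.data.columns.astype(str)), "sample")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )
        if self.state is NormalizationState.RAW_COUNTS:
            if (values < 0).any():
                raise ValueError("raw counts must be non-negative")
            if not np.allclose(values, np.round(values)):
                raise ValueError("raw counts must be integral")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        gene_ids: Iterable[str],
        sample_ids: Iterable[str],
        state: NormalizationState | str = NormalizationState.RAW_COUNTS,
    ) -> "ExpressionMatrix":
        df = pd.DataFrame(np.asarray(values), index=list(gene_ids), columns=list(sample_ids))
        return cls(df, NormalizationState(state))

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), self.state)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"state={self.state.value})"
        )


@dataclass
class DrugSignature:
    """A drug name plus signature genes and projection weights.

    Orientation convention: weights are fixed so that a *higher* projection
    score means *more sensitive* (lower viability AUC / POR).
    """

    drug: str
    gene_ids: list[str]
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.gene_ids) == 0:
            raise ValueError("signature must contain at least one gene")
        if self.weights.shape != (len(self.gene_ids),):
            raise ValueError("weights must align one-to-one with gene_ids")
        _check_unique(self.gene_ids, "signature gene")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("signature weights must be finite")
        if np.all(self.weights == 0):
            raise ValueError("signature weights are all zero")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.gene_ids, name=self.drug)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DrugSignature(drug={self.drug!r}, n_genes={self.n_genes})"


@dataclass(frozen=True)
class ResponseScore:
    """Per-model drug sensitivity measurement.

    ``metric`` is ``viability_auc`` for PDC/PDO dose-response panels or
    ``por`` (percentage of resistance, treated/control growth AUC ratio) for
    PDX. For both, lower = more sensitive.
    """

    model_id: str
    drug: str
    metric: str
    value: float

    def __post_init__(self) -> None:
        if self.metric not in ("viability_auc", "por"):
            raise ValueError(f"unknown response metric {self.metric!r}")
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError("response score must be finite and >= 0")


def scores_to_map(scores: Iterable[ResponseScore]) -> dict[str, float]:
    """Collapse a list of ResponseScore to {model_id: value} (single drug)."""
    out: dict[str, float] = {}
    for s in scores:
        if s.model_id in out:
            raise ValueError(f"duplicate response score for model {s.model_id!r}")
        out[s.model_id] = s.value
    return out
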