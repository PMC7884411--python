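"""Core in-memory containers used across the pipeline.

All containers are thin, validated wrappers around numpy/pandas objects:
expression and mutation data live in gene-by-sample matrices, clinical
annotation in a per-sample :class:`pandas.DataFrame`, and gene signatures in
immutable :class:`GeneSet` records. Gene symbols are upper-cased on
construction so that signatures and matrices from different platforms match
at the symbol level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Required columns of a clinical table.
CLINICAL_REQUIRED = ("sample_id", "cohort", "time", "event")

#: Optional covariate columns recognised by the survival models.
CLINICAL_OPTIONAL = ("age", "gender", "stage")


def normalise_symbol(symbol: str) -> str:
    """Upper-case and strip a gene symbol for cross-platform matching."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of unique gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(normalise_symbol(g) for g in self.genes)
        if not genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        seen: set[str] = set()
        deduped = []
        for g in genes:
            if g in seen:
                logger.warning("gene set %s: duplicate gene %s dropped", self.name, g)
                continue
            seen.add(g)
            deduped.append(g)
        object.__setattr__(self, "genes", tuple(deduped))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return normalise_symbol(gene) in set(self.genes)


@dataclass
class ExpressionMatrix:
    """Genes-by-samples numeric expression matrix.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``sample_ids[j]``. Values may be normalised counts (non-negative) or
    log-scale microarray intensities (unrestricted); the pipeline is
    rank-based so the scale only matters for fold-change reporting.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [normalise_symbol(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers after harmonisation")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains missing values")
        if self.n_genes == 0 or self.n_samples == 0:
            raise EmptyInputError("expression matrix has zero genes or samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def sample(self, sample_id: str) -> pd.Series:
        """One sample's expression profile indexed by gene symbol."""
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.values[:, j], index=self.gene_ids, name=sample_id)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])


@dataclass
class MutationMatrix:
    """Binary genes-by-samples somatic mutation indicator matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [normalise_symbol(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("mutation matrix shape does not match id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("mutation matrix values must be 0/1")
        self.values = self.values.astype(np.int8)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers in mutation matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers in mutation matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ClinicalTable:
    """Per-sample survival annotation with optional covariates.

    The underlying frame always has columns ``sample_id``, ``cohort``,
    ``time`` (days), ``event`` (1 = death) and any of ``age``, ``gender``,
    ``stage`` that were supplied. Missing optional covariates are absent
    columns, never sentinel values.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"clinical table missing required columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id values: {dupes[:5]}")
        df["cohort"] = df["cohort"].astype(str)
        if (df["cohort"].str.len() == 0).any():
            raise ValidationError("empty cohort labels")
        df["time"] = pd.to_numeric(df["time"], errors="raise")
        if (df["time"] < 0).any():
            raise ValidationError("survival times must be non-negative")
        df["event"] = pd.to_numeric(df["event"], errors="raise")
        if not df["event"].isin((0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")
        df["event"] = df["event"].astype(int)
        keep = list(CLINICAL_REQUIRED) + [c for c in CLINICAL_OPTIONAL if c in df.columns]
        self.data = df[keep].reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.data["cohort"].unique())

    @property
    def covariates(self) -> list[str]:
        return [c for c in CLINICAL_OPTIONAL if c in self.data.columns]

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, sample_ids: list[str]) -> "ClinicalTable":
        keep = self.data[self.data["sample_id"].isin(set(sample_ids))]
        return ClinicalTable(keep)
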