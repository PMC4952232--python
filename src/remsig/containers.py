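"""Core in-memory containers for the signature-discovery pipeline.

The pipeline's central object is a genes x samples intensity matrix with
optional detection ("present") calls, accompanied by a clinical table keyed
by sample id and GMT-style gene-set collections.  All three are thin,
validated wrappers around pandas structures so that downstream stages can
rely on their invariants (unique ids, finite values, shape agreement)
without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "ClinicalTable",
    "DISCONTINUATION_REASONS",
]

DISCONTINUATION_REASONS = ("none", "insufficient_effect", "adverse_event")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of linear-scale intensities.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by probe or gene identifiers, columns by sample ids.
        Linear-scale, finite, non-negative intensities.
    present : pandas.DataFrame, optional
        Boolean detection calls with the same index/columns as ``values``.
    """

    values: pd.DataFrame
    present: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if self.present is not None:
            if not isinstance(self.present, pd.DataFrame):
                self.present = pd.DataFrame(
                    self.present, index=self.values.index, columns=self.values.columns
                )
            if self.present.shape != self.values.shape:
                raise ValueError(
                    f"present-call shape {self.present.shape} does not match "
                    f"value shape {self.values.shape}"
                )
            self.present = self.present.astype(bool)
            if not self.present.index.equals(self.values.index):
                raise ValueError("present-call row ids do not match value row ids")
            if not self.present.columns.equals(self.values.columns):
                raise ValueError("present-call sample ids do not match value sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        present = self.present[list(sample_ids)] if self.present is not None else None
        return ExpressionMatrix(self.values[list(sample_ids)], present)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing}")
        present = (
            self.present.loc[list(gene_ids)] if self.present is not None else None
        )
        return ExpressionMatrix(self.values.loc[list(gene_ids)], present)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            self.present.copy() if self.present is not None else None,
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        if not self.values.equals(other.values):
            return False
        if (self.present is None) != (other.present is None):
            return False
        return self.present is None or self.present.equals(other.present)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with a free-text description."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if any((not g) or (not isinstance(g, str)) for g in self.genes):
            raise ValueError(f"gene set {self.name!r} contains empty symbols")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


class GeneSetCollection:
    """Ordered mapping of set name -> :class:`GeneSet` (GMT semantics)."""

    def __init__(self, sets: Sequence[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate gene set name: {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection([self._sets[n] for n in names])

    def equals(self, other: "GeneSetCollection") -> bool:
        if self.names != other.names:
            return False
        return all(self._sets[n] == other._sets[n] for n in self.names)


@dataclass
class ClinicalTable:
    """Per-sample clinical data: drug arm, covariates, CDAI time series.

    Backed by a DataFrame indexed by sample id with columns:

    - ``drug_arm`` — arm label, one of ``arms``;
    - ``discontinued_reason`` — one of :data:`DISCONTINUATION_REASONS`;
    - ``cdai_<month>`` — CDAI at each visit month, NaN where unobserved
      (an empty cell is "missing", never 0: a CDAI of 0 is a valid value);
    - anything else — baseline covariates.
    """

    data: pd.DataFrame
    arms: tuple[str, ...] = ("IFX", "TCZ", "ABT")

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if "drug_arm" not in self.data.columns:
            raise ValueError("clinical table requires a drug_arm column")
        bad = set(self.data["drug_arm"]) - set(self.arms)
        if bad:
            raise ValueError(f"unknown drug arm labels: {sorted(bad)}")
        if "discontinued_reason" not in self.data.columns:
            self.data = self.data.assign(discontinued_reason="none")
        bad_reason = set(self.data["discontinued_reason"]) - set(DISCONTINUATION_REASONS)
        if bad_reason:
            raise ValueError(f"unknown discontinuation reasons: {sorted(bad_reason)}")
        cdai = self.data[self.cdai_columns()].to_numpy(dtype=float)
        if np.nanmin(cdai, initial=0.0) < 0:
            raise ValueError("CDAI values must be >= 0")

    def cdai_columns(self) -> list[str]:
        cols = [c for c in self.data.columns if c.startswith("cdai_")]
        return sorted(cols, key=lambda c: int(c.split("_", 1)[1]))

    def cdai_months(self) -> list[int]:
        return [int(c.split("_", 1)[1]) for c in self.cdai_columns()]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def cdai_series(self, sample_id: str) -> list[tuple[int, float]]:
        """Ordered (month, CDAI) pairs, skipping unobserved visits."""
        row = self.data.loc[sample_id]
        out = []
        for col, month in zip(self.cdai_columns(), self.cdai_months()):
            v = row[col]
            if pd.notna(v):
                out.append((month, float(v)))
        return out

    def arm_samples(self, arm: str) -> list[str]:
        if arm not in self.arms:
            raise ValueError(f"unknown arm {arm!r}; expected one of {self.arms}")
        mask = self.data["drug_arm"] == arm
        return [str(s) for s in self.data.index[mask]]

    def check_against(self, matrix: ExpressionMatrix) -> None:
        """Every expression sample must appear exactly once in the table."""
        missing = set(matrix.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValueError(f"samples missing from clinical table: {sorted(missing)}")
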