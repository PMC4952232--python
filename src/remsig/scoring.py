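"""Per-patient signature scores from enrichment core genes.

Each core gene is standardized by a z-score across the full cohort (all
arms pooled), and the per-patient mean of core-gene z-scores is the
patient's "signature score" for that gene set.  Signatures whose score
vectors are near-duplicates (Pearson r at or above a threshold) are
consolidated down to one representative.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix

__all__ = [
    "CohortZScorer",
    "SignatureScorer",
    "zscore_genes",
    "signature_score",
    "consolidate_redundant",
]

logger = logging.getLogger(__name__)


class CohortZScorer(TransformerMixin, BaseEstimator):
    """Standardize each gene across the cohort (sample SD, n-1 denominator).

    Rows are samples, columns genes.  Genes with zero SD carry no
    information for scoring and are dropped at ``transform`` with a
    warning, so the output may have fewer columns than the input.
    """

    def fit(self, X, y=None):
        X = self._to_frame(X)
        if X.shape[0] < 2:
            raise ValueError("z-scoring requires >=2 patients")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        self.keep_ = self.scale_ > 0
        n_dropped = int((~self.keep_).sum())
        if n_dropped:
            logger.warning("dropping %d zero-variance genes from z-matrix", n_dropped)
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = self._to_frame(X)
        kept = self.feature_names_in_[self.keep_.to_numpy()]
        Xk = X[list(kept)]
        return (Xk - self.mean_[kept]) / self.scale_[kept]

    @staticmethod
    def _to_frame(X) -> pd.DataFrame:
        return X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))


def zscore_genes(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene z-scores across all cohort patients (genes x samples).

    Uses the sample SD (n-1).  Zero-SD genes are dropped with a warning.
    The transform is computed on the pooled cohort, never per arm.
    """
    scorer = CohortZScorer().fit(matrix.values.T)
    return scorer.transform(matrix.values.T).T


def signature_score(zmatrix: pd.DataFrame, core_genes: Sequence[str]) -> pd.Series:
    """Per-patient mean of core-gene z-scores.

    ``zmatrix`` is genes x samples.  Core genes absent from the matrix are
    dropped with a logged count; an empty surviving core is an error.
    """
    core = list(dict.fromkeys(core_genes))
    present = [g for g in core if g in zmatrix.index]
    n_missing = len(core) - len(present)
    if not present:
        raise ValueError("no core gene present in the z-matrix")
    if n_missing:
        logger.info("signature score: %d core genes absent from matrix", n_missing)
    return zmatrix.loc[present].mean(axis=0)


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Transform expression profiles into per-signature scores.

    Parameters
    ----------
    signatures : mapping of name -> core gene list.

    ``fit`` learns the cohort-wide per-gene mean and SD (the z-transform);
    ``transform`` returns a samples x signatures frame of mean core-gene
    z-scores.
    """

    def __init__(self, signatures: Mapping[str, Sequence[str]] | None = None) -> None:
        self.signatures = signatures

    def fit(self, X, y=None):
        if not self.signatures:
            raise ValueError("at least one signature is required")
        self.zscorer_ = CohortZScorer().fit(X)
        z_cols = set(
            self.zscorer_.feature_names_in_[self.zscorer_.keep_.to_numpy()]
        )
        self.core_used_: dict[str, list[str]] = {}
        for name, genes in self.signatures.items():
            used = [g for g in dict.fromkeys(genes) if g in z_cols]
            if not used:
                raise ValueError(f"signature {name!r} has no scoreable core gene")
            self.core_used_[name] = used
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "zscorer_")
        z = self.zscorer_.transform(X)
        scores = {
            name: z[genes].mean(axis=1) for name, genes in self.core_used_.items()
        }
        return pd.DataFrame(scores, index=z.index)


def consolidate_redundant(
    scores: pd.DataFrame,
    r_threshold: float = 0.95,
    priority: Sequence[str] = (),
) -> tuple[list[str], dict[str, list[str]]]:
    """Collapse signatures with near-identical score vectors.

    ``scores`` is patients x signatures.  Signatures are grouped by
    single-linkage on pairwise Pearson r >= ``r_threshold``; one
    representative per group is kept, preferring names earlier in
    ``priority`` (e.g. blood-cell sets over pathway sets), then column
    order.  Returns the representative names and the group membership.
    """
    names = list(scores.columns)
    if not names:
        raise ValueError("no signatures to consolidate")
    corr = scores.corr(method="pearson")
    parent = {n: n for n in names}

    def find(n: str) -> str:
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = corr.loc[a, b]
            if pd.notna(r) and r >= r_threshold:
                parent[find(a)] = find(b)

    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)

    rank = {n: i for i, n in enumerate(priority)}
    representatives: list[str] = []
    out_groups: dict[str, list[str]] = {}
    for members in groups.values():
        rep = min(members, key=lambda n: (rank.get(n, len(rank)), names.index(n)))
        representatives.append(rep)
        out_groups[rep] = members
    representatives.sort(key=names.index)
    return representatives, out_groups
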