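"""Array preprocessing: quantile normalization, detection filtering, probe collapse.

The microarray pipeline normalizes raw linear-scale intensities by rank-based
quantile normalization, drops probes detected ("present") in too few samples
or lacking a gene-symbol annotation, and reduces multi-probe genes to the
single probe with the highest mean signal, yielding one row per gene symbol.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import ExpressionMatrix

__all__ = [
    "QuantileNormalizer",
    "quantile_normalize",
    "detection_calls",
    "filter_probes",
    "collapse_probes",
]


def _map_to_reference(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Replace ``x`` by reference order statistics; ties get the mean of the
    reference values at their tied rank positions."""
    n = x.shape[0]
    order = np.argsort(x, kind="mergesort")
    sorted_vals = x[order]
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    sums = np.add.reduceat(ref, starts)
    means = sums / (ends - starts)
    out_sorted = np.repeat(means, ends - starts)
    out = np.empty(n, dtype=float)
    out[order] = out_sorted
    return out


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Rank-based quantile normalization across samples.

    Follows the scikit-learn orientation (rows = samples, columns = genes).
    ``fit`` computes the reference distribution — the across-sample mean of
    order statistics — and ``transform`` replaces each sample's values by
    the reference values at matching ranks, so every transformed sample
    shares an identical sorted vector.  Within-sample ties receive the mean
    of the reference values at their tied rank positions.

    Attributes
    ----------
    reference_ : ndarray of shape (n_features,)
        Sorted reference distribution (mean of order statistics).
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_all_finite=True)
        if X.shape[0] < 2:
            raise ValueError("quantile normalization requires >=2 samples")
        self.n_features_in_ = X.shape[1]
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X, dtype=float, ensure_all_finite=True)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        out = np.empty_like(X, dtype=float)
        for i in range(X.shape[0]):
            out[i] = _map_to_reference(X[i], self.reference_)
        return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize a genes x samples matrix across its samples.

    After normalization every sample column carries the identical sorted
    value vector, equal to the across-sample mean of order statistics.
    """
    normalizer = QuantileNormalizer()
    normed = normalizer.fit_transform(matrix.values.to_numpy(dtype=float).T).T
    values = pd.DataFrame(normed, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.present)


def detection_calls(matrix: ExpressionMatrix, quantile: float = 0.10) -> ExpressionMatrix:
    """Attach threshold-based present calls: a value is "present" when it lies
    strictly above the given quantile of its sample column.

    This explicit rule stands in for scanner-software detection calls when a
    dataset ships without them; the quantile is recorded by the caller's
    provenance.
    """
    if not 0.0 <= quantile < 1.0:
        raise ValueError("detection quantile must be in [0, 1)")
    vals = matrix.values.to_numpy(dtype=float)
    cutoffs = np.quantile(vals, quantile, axis=0)
    present = pd.DataFrame(
        vals > cutoffs[np.newaxis, :],
        index=matrix.values.index,
        columns=matrix.values.columns,
    )
    return ExpressionMatrix(matrix.values, present)


def filter_probes(
    matrix: ExpressionMatrix,
    min_present: int = 50,
    annotation: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Retain probes called present in strictly more than ``min_present``
    samples (pooled over all samples), and, when an annotation map is given,
    drop probes without a gene-symbol annotation."""
    if matrix.present is None:
        raise ValueError(
            "matrix carries no present calls; attach them (e.g. with "
            "detection_calls) or load a present-call file"
        )
    if min_present < 0:
        raise ValueError("min_present must be >= 0")
    counts = matrix.present.sum(axis=1)
    keep = counts > min_present
    if annotation is not None:
        annotated = matrix.values.index.to_series().isin(annotation.keys())
        keep = keep & annotated.to_numpy()
    return ExpressionMatrix(matrix.values.loc[keep], matrix.present.loc[keep])


def collapse_probes(
    matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probes to one row per gene symbol.

    For genes measured by several probes, the probe with the highest mean
    intensity across samples is kept verbatim (no averaging); the surviving
    row is relabeled with the gene symbol.  Output rows are sorted by gene
    symbol, so the result is invariant to input row order; ties in mean
    intensity are broken by probe id.
    """
    missing = [p for p in matrix.values.index if p not in probe_to_gene]
    if missing:
        raise KeyError(f"probes absent from annotation map: {missing[:5]}")
    means = matrix.values.mean(axis=1)
    chosen: dict[str, str] = {}
    for probe in matrix.values.index:
        gene = probe_to_gene[probe]
        best = chosen.get(gene)
        if (
            best is None
            or means[probe] > means[best]
            or (means[probe] == means[best] and str(probe) < str(best))
        ):
            chosen[gene] = probe
    genes = sorted(chosen)
    probes = [chosen[g] for g in genes]
    values = matrix.values.loc[probes].copy()
    values.index = pd.Index(genes, name=matrix.values.index.name)
    present = None
    if matrix.present is not None:
        present = matrix.present.loc[probes].copy()
        present.index = values.index
    return ExpressionMatrix(values, present)
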