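"""Gene set enrichment analysis for two-class cohort comparisons.

Genes are ranked by the signal-to-noise ratio between the non-remission
(NON-REM) and remission (REM) classes, a weighted Kolmogorov–Smirnov
running statistic yields a per-set enrichment score (ES), and phenotype
permutations calibrate the normalized enrichment score (NES), nominal p
value and FDR q value.  The "core" (leading-edge) genes of a set are the
members at or before the running statistic's extremum — the subset that
contributes most to the ES.

Conventions (recorded in output provenance):

- class ordering is fixed as (NON-REM, REM), so a positive ES means the
  set is up-regulated in NON-REM;
- each class standard deviation is floored at ``max(0.2 * |class mean|,
  0.2)`` to keep the ratio stable for near-constant genes;
- the metric is computed on ``log2(intensity + 1)`` by default
  (configurable to the raw linear scale);
- ranking ties are broken lexicographically by gene id;
- nominal p values are floored at 1 / (number of same-sign null scores)
  and flagged as upper bounds when no null score is as extreme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix, GeneSetCollection

__all__ = [
    "GseaParams",
    "RankedList",
    "EnrichmentProfile",
    "GseaResult",
    "GseaEnrichment",
    "signal_to_noise",
    "enrichment_score",
    "leading_edge",
    "permutation_null",
    "nominal_p",
    "normalize_and_fdr",
    "run_gsea",
]

logger = logging.getLogger(__name__)

NONREM, REM = "NON-REM", "REM"
DIRECTION_NONREM_UP = "NON-REM > REM"
DIRECTION_REM_UP = "REM > NON-REM"


@dataclass(frozen=True)
class GseaParams:
    """Tuning knobs of the enrichment analysis."""

    n_perm: int = 1000
    min_size: int = 15
    max_size: int = 500
    weight_exponent: float = 1.0
    alpha_nominal: float = 0.05
    q_threshold: float = 0.1
    log_transform: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_size > self.max_size:
            raise ValueError("min_size must be <= max_size")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")


@dataclass
class RankedList:
    """Genes ordered by descending signal-to-noise metric."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != self.metric.shape[0]:
            raise ValueError("genes and metric lengths differ")
        if np.any(np.diff(self.metric) > 0):
            raise ValueError("metric must be non-increasing along the order")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentProfile:
    """ES with the full running statistic, for leading-edge extraction."""

    es: float
    running: np.ndarray
    hit_positions: np.ndarray  # 0-based positions of set members in the ranking


@dataclass
class GseaResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_nominal: float
    p_is_upper_bound: bool
    q_fdr: float
    direction: str
    core_genes: list[str]
    significant: bool


def _nonrem_mask(labels: Sequence) -> np.ndarray:
    """Boolean mask of NON-REM samples from string or 0/1 labels."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "US" or arr.dtype == object:
        valid = {NONREM, REM}
        bad = set(map(str, arr)) - valid
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
        return np.asarray([str(v) == NONREM for v in arr])
    return arr.astype(bool)


def _snr_metric(
    X: np.ndarray, nonrem: np.ndarray, sd_floor: bool = True
) -> np.ndarray:
    """Signal-to-noise s = (mean_NONREM - mean_REM) / (sd_NONREM + sd_REM)."""
    a, b = X[:, nonrem], X[:, ~nonrem]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    sd_a, sd_b = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    if sd_floor:
        sd_a = np.maximum(sd_a, np.maximum(0.2 * np.abs(mean_a), 0.2))
        sd_b = np.maximum(sd_b, np.maximum(0.2 * np.abs(mean_b), 0.2))
    denom = sd_a + sd_b
    num = mean_a - mean_b
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return s


def _prepare_values(matrix: ExpressionMatrix, log_transform: bool) -> np.ndarray:
    X = matrix.values.to_numpy(dtype=float)
    return np.log2(X + 1.0) if log_transform else X


def signal_to_noise(
    matrix: ExpressionMatrix,
    labels: Sequence,
    log_transform: bool = True,
    sd_floor: bool = True,
) -> RankedList:
    """Rank all genes by the NON-REM-vs-REM signal-to-noise ratio.

    Positive values mean NON-REM-upregulated.  Both classes need at least
    two samples; ties are broken lexicographically by gene id so the
    ranking is deterministic.
    """
    nonrem = _nonrem_mask(labels)
    if nonrem.shape[0] != matrix.n_samples:
        raise ValueError("labels length does not match sample count")
    if nonrem.sum() < 2 or (~nonrem).sum() < 2:
        raise ValueError("each phenotype class needs >=2 samples")
    X = _prepare_values(matrix, log_transform)
    s = _snr_metric(X, nonrem, sd_floor=sd_floor)
    gene_ids = np.asarray(matrix.gene_ids)
    order = np.lexsort((gene_ids, -s))
    return RankedList(genes=list(gene_ids[order]), metric=s[order])


def _es_from_order(
    abs_metric_sorted: np.ndarray, hit_mask: np.ndarray, p: float
) -> tuple[float, np.ndarray]:
    """Weighted KS walk along a ranked list given the hit positions."""
    n = abs_metric_sorted.shape[0]
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit >= n:
        raise ValueError("gene set must hit >=1 and < all ranked genes")
    weights = abs_metric_sorted**p if p != 0 else np.ones(n)
    hit_w = np.where(hit_mask, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit metrics exactly zero: fall back to equal weights
        hit_w = hit_mask.astype(float)
        total = float(n_hit)
    steps = hit_w / total - np.where(hit_mask, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def enrichment_score(
    ranked: RankedList, gene_set: Sequence[str], p: float = 1.0
) -> EnrichmentProfile:
    """Enrichment score of a gene set along a ranked list.

    At each set member the running statistic rises by its weight
    ``|s_i|**p`` (normalized over members); at each non-member it falls by
    ``1/(N - N_H)``.  The ES is the signed maximum deviation from zero.
    """
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in ranked.genes), bool, len(ranked))
    if not hit_mask.any():
        raise ValueError("gene set has empty intersection with the ranked list")
    es, running = _es_from_order(np.abs(ranked.metric), hit_mask, p)
    return EnrichmentProfile(
        es=es, running=running, hit_positions=np.flatnonzero(hit_mask)
    )


def leading_edge(profile: EnrichmentProfile, ranked: RankedList) -> list[str]:
    """Core genes: set members at or before the running-statistic peak
    (positive ES) or at or after the trough (negative ES), in rank order."""
    if profile.es == 0:
        logger.warning("ES is exactly 0; leading edge undefined, returning empty core")
        return []
    if profile.es > 0:
        peak = int(np.argmax(profile.running))
        positions = profile.hit_positions[profile.hit_positions <= peak]
    else:
        trough = int(np.argmin(profile.running))
        positions = profile.hit_positions[profile.hit_positions >= trough]
    return [ranked.genes[i] for i in positions]


def _null_metrics(
    X: np.ndarray, nonrem: np.ndarray, n_perm: int, rng: np.random.Generator,
    sd_floor: bool = True,
) -> np.ndarray:
    """Metric matrix (n_perm x n_genes) under phenotype permutation.

    Class sizes are preserved; sums and sums of squares are shared across
    permutations through two matrix products.
    """
    n = nonrem.shape[0]
    n_a = int(nonrem.sum())
    masks = np.zeros((n_perm, n), dtype=float)
    for k in range(n_perm):
        idx = rng.permutation(n)[:n_a]
        masks[k, idx] = 1.0
    X2 = X * X
    tot1, tot2 = X.sum(axis=1), X2.sum(axis=1)
    s1a = X @ masks.T  # genes x perms
    s2a = X2 @ masks.T
    n_b = n - n_a
    mean_a = s1a / n_a
    mean_b = (tot1[:, None] - s1a) / n_b
    var_a = np.maximum(s2a - n_a * mean_a**2, 0.0) / (n_a - 1)
    var_b = np.maximum((tot2[:, None] - s2a) - n_b * mean_b**2, 0.0) / (n_b - 1)
    sd_a, sd_b = np.sqrt(var_a), np.sqrt(var_b)
    if sd_floor:
        sd_a = np.maximum(sd_a, np.maximum(0.2 * np.abs(mean_a), 0.2))
        sd_b = np.maximum(sd_b, np.maximum(0.2 * np.abs(mean_b), 0.2))
    denom = sd_a + sd_b
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (mean_a - mean_b) / np.where(denom > 0, denom, 1.0), 0.0)
    return s.T


def _batch_es(
    metrics: np.ndarray, member_mask: np.ndarray, p: float
) -> np.ndarray:
    """ES of one gene set for each row of a metric matrix (n_perm x n_genes)."""
    n_perm, n_genes = metrics.shape
    order = np.argsort(-metrics, axis=1, kind="stable")
    abs_sorted = np.abs(np.take_along_axis(metrics, order, axis=1))
    hits = member_mask[order]
    weights = abs_sorted**p if p != 0 else np.ones_like(abs_sorted)
    hit_w = np.where(hits, weights, 0.0)
    totals = hit_w.sum(axis=1, keepdims=True)
    n_hit = int(member_mask.sum())
    degenerate = totals[:, 0] == 0
    if degenerate.any():
        hit_w[degenerate] = hits[degenerate].astype(float)
        totals = hit_w.sum(axis=1, keepdims=True)
    steps = hit_w / totals - np.where(hits, 0.0, 1.0 / (n_genes - n_hit))
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def permutation_null(
    matrix: ExpressionMatrix,
    labels: Sequence,
    gene_sets: Sequence[Sequence[str]],
    params: GseaParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null ES samples by phenotype permutation, shape (n_sets, n_perm).

    The same permutations are shared across all sets, as required for the
    pooled NES null used by the FDR computation.  Reproducible from the
    seed in ``params``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    nonrem = _nonrem_mask(labels)
    X = _prepare_values(matrix, params.log_transform)
    metrics = _null_metrics(X, nonrem, params.n_perm, rng)
    gene_ids = list(matrix.gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    # the ranking and hit weights depend only on the permutation, not the
    # set, so sort once and reuse across sets
    order = np.argsort(-metrics, axis=1, kind="stable")
    abs_sorted = np.abs(np.take_along_axis(metrics, order, axis=1))
    p = params.weight_exponent
    weights = abs_sorted**p if p != 0 else np.ones_like(abs_sorted)
    n_perm, n_genes = metrics.shape
    row_idx = np.arange(n_perm)
    out = np.empty((len(gene_sets), n_perm))
    for j, genes in enumerate(gene_sets):
        mask = np.zeros(len(gene_ids), dtype=bool)
        mask[[gene_pos[g] for g in genes if g in gene_pos]] = True
        hits = mask[order]
        hit_w = np.where(hits, weights, 0.0)
        totals = hit_w.sum(axis=1, keepdims=True)
        n_hit = int(mask.sum())
        degenerate = totals[:, 0] == 0
        if degenerate.any():
            hit_w[degenerate] = hits[degenerate].astype(float)
            totals = hit_w.sum(axis=1, keepdims=True)
        steps = hit_w / totals - np.where(hits, 0.0, 1.0 / (n_genes - n_hit))
        running = np.cumsum(steps, axis=1)
        out[j] = running[row_idx, np.argmax(np.abs(running), axis=1)]
    return out


def nominal_p(observed_es: float, null_es: np.ndarray) -> tuple[float, bool]:
    """One-sided permutation p among null scores sharing the observed sign.

    Returns ``(p, is_upper_bound)``; when no same-sign null is as extreme
    the p value is reported as the floor ``1/n_same_sign`` with the flag
    set (the "< 1/n_perm" convention).
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size == 0:
        raise ValueError("null sample is empty")
    same_sign = null_es > 0 if observed_es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        return 1.0 / null_es.size, True
    k = int((np.abs(null_es[same_sign]) >= abs(observed_es)).sum())
    return max(k, 1) / n_same, k == 0


def _nes_of(es: float | np.ndarray, null_es: np.ndarray) -> float | np.ndarray:
    """Normalize score(s) by the mean same-sign null magnitude of the set."""
    pos = null_es[null_es > 0]
    neg = null_es[null_es < 0]
    mean_pos = pos.mean() if pos.size else np.nan
    mean_neg = np.abs(neg).mean() if neg.size else np.nan
    es = np.asarray(es, dtype=float)
    out = np.where(es >= 0, es / mean_pos, es / mean_neg)
    return float(out) if out.ndim == 0 else out


def normalize_and_fdr(
    observed_es: np.ndarray, null_es: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """NES per set and FDR q per set from shared permutation nulls.

    NES divides each score by the mean magnitude of the set's same-sign
    null scores.  q compares, at each observed NES*, the same-sign tail
    fraction of the pooled null NES with the same-sign tail fraction of
    the observed NES, clipped to [0, 1] and made monotone within each
    sign (a more extreme NES never gets a larger q).
    """
    observed_es = np.asarray(observed_es, dtype=float)
    n_sets = observed_es.shape[0]
    nes = np.empty(n_sets)
    null_nes = np.empty_like(null_es)
    for j in range(n_sets):
        nes[j] = _nes_of(observed_es[j], null_es[j])
        null_nes[j] = _nes_of(null_es[j], null_es[j])
    pooled = null_nes[np.isfinite(null_nes)]
    finite_obs = nes[np.isfinite(nes)]
    q = np.full(n_sets, np.nan)
    for j in range(n_sets):
        star = nes[j]
        if not np.isfinite(star):
            continue
        if star >= 0:
            null_side, obs_side = pooled[pooled >= 0], finite_obs[finite_obs >= 0]
        else:
            null_side, obs_side = pooled[pooled < 0], finite_obs[finite_obs < 0]
        if null_side.size == 0:
            continue
        frac_null = (np.abs(null_side) >= abs(star)).mean()
        frac_obs = max((np.abs(obs_side) >= abs(star)).mean(), 1.0 / max(obs_side.size, 1))
        q[j] = min(frac_null / frac_obs, 1.0)
    # monotone within each sign: sort by |NES| descending, take running min
    for side in (nes >= 0, nes < 0):
        idx = np.flatnonzero(side & np.isfinite(q))
        if idx.size == 0:
            continue
        order = idx[np.argsort(-np.abs(nes[idx]), kind="stable")]
        q[order] = np.minimum.accumulate(q[order][::-1])[::-1]
    return nes, q


def run_gsea(
    matrix: ExpressionMatrix,
    labels: Sequence,
    collection: GeneSetCollection,
    params: GseaParams = GseaParams(),
) -> list[GseaResult]:
    """Full enrichment analysis of a gene-set collection on one cohort arm.

    Sets are restricted to genes present in the matrix; sets smaller than
    ``min_size`` or larger than ``max_size`` after intersection are
    dropped.  A set is flagged significant when nominal p < 0.05 and FDR
    q < 0.1 (both configurable).
    """
    dataset_genes = set(matrix.gene_ids)
    surviving: list[tuple[str, list[str]]] = []
    for gs in collection:
        genes = [g for g in gs.genes if g in dataset_genes]
        if not genes:
            logger.info("set %s skipped: empty intersection with dataset", gs.name)
            continue
        if not params.min_size <= len(genes) <= params.max_size:
            logger.info(
                "set %s skipped: size %d outside [%d, %d]",
                gs.name, len(genes), params.min_size, params.max_size,
            )
            continue
        surviving.append((gs.name, genes))
    if not surviving:
        raise ValueError("no gene set survives the size filters")

    ranked = signal_to_noise(matrix, labels, log_transform=params.log_transform)
    profiles = [
        enrichment_score(ranked, genes, params.weight_exponent)
        for _, genes in surviving
    ]
    observed = np.array([pr.es for pr in profiles])
    null_es = permutation_null(
        matrix, labels, [genes for _, genes in surviving], params
    )
    nes, q = normalize_and_fdr(observed, null_es)
    results = []
    for j, ((name, genes), profile) in enumerate(zip(surviving, profiles)):
        p_val, is_bound = nominal_p(observed[j], null_es[j])
        core = leading_edge(profile, ranked)
        direction = DIRECTION_NONREM_UP if observed[j] >= 0 else DIRECTION_REM_UP
        sig = (
            p_val < params.alpha_nominal
            and np.isfinite(q[j])
            and q[j] < params.q_threshold
        )
        results.append(
            GseaResult(
                set_name=name,
                size=len(genes),
                es=float(observed[j]),
                nes=float(nes[j]),
                p_nominal=float(p_val),
                p_is_upper_bound=is_bound,
                q_fdr=float(q[j]),
                direction=direction,
                core_genes=core,
                significant=bool(sig),
            )
        )
    return results


class GseaEnrichment(BaseEstimator):
    """Estimator-style wrapper around the enrichment analysis.

    ``fit(X, y)`` takes a samples x genes frame (or array plus
    ``gene_names``) and binary phenotype labels (1 or "NON-REM" =
    non-remission) and stores the per-set results in ``results_``.
    """

    def __init__(
        self,
        collection: GeneSetCollection | None = None,
        n_perm: int = 1000,
        min_size: int = 15,
        max_size: int = 500,
        weight_exponent: float = 1.0,
        alpha_nominal: float = 0.05,
        q_threshold: float = 0.1,
        log_transform: bool = True,
        seed: int = 0,
    ) -> None:
        self.collection = collection
        self.n_perm = n_perm
        self.min_size = min_size
        self.max_size = max_size
        self.weight_exponent = weight_exponent
        self.alpha_nominal = alpha_nominal
        self.q_threshold = q_threshold
        self.log_transform = log_transform
        self.seed = seed

    def _params(self) -> GseaParams:
        return GseaParams(
            n_perm=self.n_perm,
            min_size=self.min_size,
            max_size=self.max_size,
            weight_exponent=self.weight_exponent,
            alpha_nominal=self.alpha_nominal,
            q_threshold=self.q_threshold,
            log_transform=self.log_transform,
            seed=self.seed,
        )

    def fit(self, X, y, gene_names: Sequence[str] | None = None):
        if self.collection is None:
            raise ValueError("a GeneSetCollection is required")
        if isinstance(X, pd.DataFrame):
            frame = X.T
        else:
            if gene_names is None:
                raise ValueError("gene_names required for array input")
            frame = pd.DataFrame(np.asarray(X).T, index=list(gene_names))
        matrix = ExpressionMatrix(frame)
        self.results_ = run_gsea(matrix, y, self.collection, self._params())
        self.significant_sets_ = [r.set_name for r in self.results_ if r.significant]
        return self

    def results_frame(self) -> pd.DataFrame:
        from .io import _gsea_results_frame

        return _gsea_results_frame(self.results_)
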