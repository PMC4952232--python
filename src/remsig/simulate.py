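"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a three-arm biologic-therapy cohort: 140/38/31
patients on the three drugs (209 total), per-arm remission rates of
30.0/21.1/22.6 %, ~15k genes, and, optionally, "planted" gene sets whose
members are coordinately shifted by a chosen effect size in one
arm-by-outcome stratum.  Expression is log-normal: a per-gene baseline on
the log2 scale plus Gaussian within-group noise, exponentiated to the
linear scale.  CDAI series are drawn consistently with the outcome labels
(month-6 CDAI <= 2.8 iff remission), with a configurable number of early
discontinuers whose month-6 value is missing, to exercise
last-observation-carried-forward imputation.  Everything is reproducible
from a single integer seed (NumPy PCG64 generator, recorded in the design
echo).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection
from .gsea import DIRECTION_NONREM_UP, DIRECTION_REM_UP, NONREM, REM
from .preprocess import detection_calls

__all__ = ["PlantedSet", "CohortDesign", "generate_cohort", "plant_signal"]


@dataclass(frozen=True)
class PlantedSet:
    """A gene set to shift coordinately in one arm-by-outcome stratum.

    ``delta`` is the mean shift in within-group-SD units on the log2
    scale; ``direction`` states which outcome class is up-regulated.
    """

    name: str
    size: int
    arm: str
    direction: str = DIRECTION_NONREM_UP
    delta: float = 0.8

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.size < 2:
            raise ValueError("planted set size must be >= 2")
        if self.direction not in (DIRECTION_NONREM_UP, DIRECTION_REM_UP):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class CohortDesign:
    """Study design of a synthetic cohort (defaults follow the emulated
    three-arm study: arm sizes 140/38/31, remission rates 30.0/21.1/22.6 %)."""

    arms: tuple[str, ...] = ("IFX", "TCZ", "ABT")
    n_per_arm: tuple[int, ...] = (140, 38, 31)
    remission_rate_per_arm: tuple[float, ...] = (0.300, 0.211, 0.226)
    n_genes: int = 14718
    planted_sets: tuple[PlantedSet, ...] = ()
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 2.0
    noise_sd: float = 1.0
    detection_quantile: float = 0.10
    n_decoy_sets: int = 0
    insufficient_effect_per_arm: tuple[int, ...] = (1, 3, 1)
    adverse_event_per_arm: tuple[int, ...] = (0, 1, 0)
    cdai_baseline_median: float = 21.7
    cdai_baseline_iqr: tuple[float, float] = (14.9, 28.9)
    months: tuple[int, ...] = (0, 3, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if not len(self.arms) == len(self.n_per_arm) == len(self.remission_rate_per_arm):
            raise ValueError("arms, n_per_arm, remission_rate_per_arm lengths differ")
        for r in self.remission_rate_per_arm:
            if not 0.0 < r < 1.0:
                raise ValueError("remission rates must be in (0, 1)")
        for ps in self.planted_sets:
            if ps.arm not in self.arms:
                raise ValueError(f"planted set {ps.name!r} targets unknown arm {ps.arm!r}")
            if ps.size > self.n_genes:
                raise ValueError(f"planted set {ps.name!r} larger than n_genes")
        if sum(ps.size for ps in self.planted_sets) > self.n_genes:
            raise ValueError(
                "planted sets overlap: requested sizes exceed the gene pool "
                "(planted sets are allocated disjoint gene blocks)"
            )

    def rem_count(self, arm_index: int) -> int:
        """REM labels per arm: nearest-integer rounding of rate x n."""
        return int(
            np.floor(self.remission_rate_per_arm[arm_index] * self.n_per_arm[arm_index] + 0.5)
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rng"] = "numpy PCG64 (default_rng)"
        return d


def _draw_cdai_baseline(rng: np.random.Generator, design: CohortDesign, n: int) -> np.ndarray:
    lo, hi = design.cdai_baseline_iqr
    sd = (hi - lo) / 1.349  # normal IQR -> SD
    return np.clip(rng.normal(design.cdai_baseline_median, sd, size=n), 3.0, None)


def generate_cohort(
    design: CohortDesign = CohortDesign(),
) -> tuple[ExpressionMatrix, ClinicalTable, GeneSetCollection]:
    """Generate an expression matrix, clinical table and gene-set collection.

    The returned collection contains the planted sets plus
    ``n_decoy_sets`` decoy sets of matched sizes drawn from non-planted
    genes (decoys never share genes with planted sets).  Present flags are
    true for values strictly above the per-sample detection quantile.
    Bit-identical outputs for identical designs (including the seed).
    """
    rng = np.random.default_rng(design.seed)
    gene_ids = [f"G{i:05d}" for i in range(design.n_genes)]

    sample_ids: list[str] = []
    arm_of: list[str] = []
    labels: list[str] = []
    for ai, arm in enumerate(design.arms):
        n = design.n_per_arm[ai]
        ids = [f"{arm}_{i:03d}" for i in range(n)]
        sample_ids.extend(ids)
        arm_of.extend([arm] * n)
        lab = np.array([NONREM] * n, dtype=object)
        rem_idx = rng.permutation(n)[: design.rem_count(ai)]
        lab[rem_idx] = REM
        labels.extend(lab.tolist())
    arm_of_arr = np.array(arm_of)
    labels_arr = np.array(labels)
    n_samples = len(sample_ids)

    baseline = rng.normal(design.baseline_log_mean, design.baseline_log_sd, design.n_genes)
    log2x = baseline[:, None] + rng.normal(0.0, design.noise_sd, (design.n_genes, n_samples))

    # planted sets get disjoint gene blocks from the front of the gene list
    collection = GeneSetCollection()
    cursor = 0
    planted_genes: set[str] = set()
    planted_sizes: list[int] = []
    for ps in design.planted_sets:
        members = gene_ids[cursor : cursor + ps.size]
        cursor += ps.size
        planted_genes.update(members)
        planted_sizes.append(ps.size)
        up_class = NONREM if ps.direction == DIRECTION_NONREM_UP else REM
        col_mask = (arm_of_arr == ps.arm) & (labels_arr == up_class)
        row_idx = np.arange(cursor - ps.size, cursor)
        log2x[np.ix_(row_idx, np.flatnonzero(col_mask))] += ps.delta * design.noise_sd
        collection.add(GeneSet(ps.name, f"planted {ps.direction} in {ps.arm}", tuple(members)))

    free_pool = np.array([g for g in gene_ids if g not in planted_genes])
    if design.n_decoy_sets:
        sizes = planted_sizes or [30]
        for k in range(design.n_decoy_sets):
            size = sizes[k % len(sizes)]
            members = rng.choice(free_pool, size=size, replace=False)
            collection.add(GeneSet(f"DECOY_{k:03d}", "decoy (no planted signal)", tuple(members)))

    values = pd.DataFrame(
        np.exp2(log2x), index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
    )
    matrix = detection_calls(ExpressionMatrix(values), design.detection_quantile)

    # clinical table: CDAI series consistent with the labels
    cdai0 = _draw_cdai_baseline(rng, design, n_samples)
    cdai3 = np.empty(n_samples)
    cdai6 = np.empty(n_samples)
    rem_mask = labels_arr == REM
    cdai3[rem_mask] = rng.uniform(1.0, 12.0, rem_mask.sum())
    cdai3[~rem_mask] = rng.uniform(3.0, np.maximum(cdai0[~rem_mask], 3.5))
    cdai6[rem_mask] = rng.uniform(0.0, 2.8, rem_mask.sum())
    cdai6[~rem_mask] = rng.uniform(2.9, np.maximum(cdai0[~rem_mask], 3.5))

    reason = np.array(["none"] * n_samples, dtype=object)
    for ai, arm in enumerate(design.arms):
        nonrem_idx = np.flatnonzero((arm_of_arr == arm) & ~rem_mask)
        n_ins = design.insufficient_effect_per_arm[ai]
        n_adv = design.adverse_event_per_arm[ai]
        if n_ins + n_adv > nonrem_idx.size:
            raise ValueError(f"arm {arm}: more discontinuers than NON-REM patients")
        chosen = rng.choice(nonrem_idx, size=n_ins + n_adv, replace=False)
        reason[chosen[:n_ins]] = "insufficient_effect"
        reason[chosen[n_ins:]] = "adverse_event"
        # discontinuers leave before month 6: last observation must exceed 2.8
        cdai3[chosen] = rng.uniform(3.0, np.maximum(cdai0[chosen], 3.5))
        cdai6[chosen] = np.nan

    clin = pd.DataFrame(
        {
            "drug_arm": arm_of_arr,
            "discontinued_reason": reason,
            "age": np.clip(rng.normal(59.0, 12.0, n_samples), 18.0, 90.0).round(0),
            "disease_duration": np.round(rng.gamma(1.5, 4.0, n_samples) + 0.1, 1),
            "mtx_dose": rng.choice([6.0, 8.0, 10.0, 12.0], n_samples, p=[0.2, 0.5, 0.2, 0.1]),
            "cdai_0": cdai0.round(1),
            "cdai_3": cdai3.round(1),
            "cdai_6": np.round(cdai6, 1),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    clinical = ClinicalTable(clin, arms=design.arms)
    return matrix, clinical, collection


def plant_signal(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    samples: Sequence[str],
    delta: float,
    noise_sd: float = 1.0,
) -> ExpressionMatrix:
    """Shift the log2-scale values of a gene/sample block by delta x noise_sd.

    Returns a copy; all other cells are unchanged.  Unknown gene or sample
    ids raise an error.
    """
    out = matrix.copy()
    missing_g = [g for g in genes if g not in out.values.index]
    if missing_g:
        raise KeyError(f"unknown genes: {missing_g[:5]}")
    missing_s = [s for s in samples if s not in out.values.columns]
    if missing_s:
        raise KeyError(f"unknown samples: {missing_s[:5]}")
    factor = float(np.exp2(delta * noise_sd))
    out.values.loc[list(genes), list(samples)] *= factor
    return out
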