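"""End-to-end orchestration: expression matrix -> patient stratification.

Chains the pipeline stages the way the emulated study ran them: label
outcomes (LOCF), run the enrichment analysis per drug arm against
REM/NON-REM, turn each arm's leading signature into per-patient scores
(z-scored over the pooled cohort), consolidate redundant signatures,
associate scores with non-remission by Firth logistic regression, derive
ROC-optimal cutoffs, and stratify all patients into the 2^3 groups from
the three binary signature calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .gsea import GseaParams, GseaResult, run_gsea
from .response import OptimalCutoff, RocResult, firth_logistic, optimal_threshold, roc_curve
from .scoring import consolidate_redundant, signature_score, zscore_genes
from .stratify import assign_group, assign_outcome, binary_call, group_encoding_table, group_summary

__all__ = ["ArmAnalysis", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class ArmAnalysis:
    """Everything computed for one drug arm."""

    arm: str
    gsea: list[GseaResult]
    signature: GseaResult | None  # the arm's focus signature (post-consolidation)
    firth_summary: pd.DataFrame | None
    roc: RocResult | None
    cutoff: OptimalCutoff | None


@dataclass
class PipelineResult:
    outcomes: pd.DataFrame
    scores: pd.DataFrame  # patients x signatures, pooled-cohort z-scoring
    arms: dict[str, ArmAnalysis]
    groups: pd.Series | None
    group_table: pd.DataFrame | None
    group_encoding: pd.DataFrame | None


def _pick_focus(results: list[GseaResult], representatives: Sequence[str]) -> GseaResult | None:
    """Most significant surviving signature (smallest p, then largest |NES|)."""
    pool = [r for r in results if r.set_name in set(representatives)]
    flagged = [r for r in pool if r.significant]
    pool = flagged or pool
    if not pool:
        return None
    return min(
        pool,
        key=lambda r: (
            r.q_fdr if np.isfinite(r.q_fdr) else np.inf,
            r.p_nominal,
            -abs(r.nes) if np.isfinite(r.nes) else 0.0,
        ),
    )


def run_pipeline(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    collection: GeneSetCollection,
    params: GseaParams = GseaParams(),
    r_threshold: float = 0.95,
    priority: Sequence[str] = (),
    log_scores: bool = True,
) -> PipelineResult:
    """Run the full analysis on a preprocessed (one-row-per-gene) matrix.

    Per arm, significant gene sets (nominal p < alpha and FDR q below the
    threshold) become candidate signatures; redundant candidates (score
    Pearson r >= ``r_threshold``) are consolidated, preferring names early
    in ``priority``.  When an arm yields no significant set its
    best-ranked set is carried forward with a warning so downstream stages
    stay exercisable.  Signature scores use core-gene z-scores computed
    over the pooled cohort; per-arm ROC cutoffs then give each patient
    three binary calls and an 8-way group.
    """
    clinical.check_against(matrix)
    outcomes = assign_outcome(clinical)
    labels_all = outcomes["label"]

    score_values = matrix.values
    if log_scores:
        score_values = np.log2(matrix.values + 1.0)
    zmat = zscore_genes(ExpressionMatrix(score_values))

    arm_results: dict[str, ArmAnalysis] = {}
    all_scores: dict[str, pd.Series] = {}
    focus_order: list[tuple[str, str]] = []  # (arm, signature name)

    for arm in clinical.arms:
        samples = clinical.arm_samples(arm)
        sub = matrix.subset_samples(samples)
        y_arm = labels_all.loc[samples]
        gsea_results = run_gsea(sub, y_arm, collection, params)

        candidates = [r for r in gsea_results if r.significant] or gsea_results
        cand_scores = pd.DataFrame(
            {
                r.set_name: signature_score(zmat, r.core_genes)
                for r in candidates
                if r.core_genes
            }
        )
        if cand_scores.empty:
            logger.warning("arm %s: no scoreable signature", arm)
            arm_results[arm] = ArmAnalysis(arm, gsea_results, None, None, None, None)
            continue
        reps, _ = consolidate_redundant(cand_scores, r_threshold, priority)
        focus = _pick_focus(candidates, reps)
        if focus is not None and not focus.significant:
            logger.warning("arm %s: no significant gene set; using best-ranked %s",
                           arm, focus.set_name)

        firth_summary = roc = cutoff = None
        if focus is not None:
            scores_all = cand_scores[focus.set_name]
            all_scores.setdefault(focus.set_name, scores_all)
            focus_order.append((arm, focus.set_name))
            s_arm = scores_all.loc[samples]
            y01 = (y_arm == "NON-REM").astype(int).to_numpy()
            X = pd.DataFrame({focus.set_name: s_arm.to_numpy()})
            fit = firth_logistic(X, y01)
            firth_summary = fit.summary()
            # orient the predictor so that a high value predicts NON-REM:
            # a REM-up signature (negative ES) enters the ROC negated
            sign = 1.0 if focus.es >= 0 else -1.0
            oriented = sign * s_arm.to_numpy()
            roc = roc_curve(oriented, y01)
            cutoff = optimal_threshold(roc, oriented, y01)
            cutoff.orientation = sign  # threshold applies to sign * score
        arm_results[arm] = ArmAnalysis(arm, gsea_results, focus, firth_summary, roc, cutoff)

    groups = group_table = encoding = None
    if len(focus_order) == 3:
        names = [name for _, name in focus_order]
        index = pd.Index(matrix.sample_ids)
        call_cols = []
        for (arm, name) in focus_order:
            cut = arm_results[arm].cutoff
            call_cols.append(
                [binary_call(cut.orientation * v, cut.threshold)
                 for v in all_scores[name].loc[index]]
            )
        call_matrix = np.column_stack(call_cols)
        groups = pd.Series(
            [assign_group(list(row)) for row in call_matrix], index=index
        )
        group_table = group_summary(groups, labels_all.loc[groups.index])
        encoding = group_encoding_table(names)

    return PipelineResult(
        outcomes=outcomes,
        scores=pd.DataFrame(all_scores),
        arms=arm_results,
        groups=groups,
        group_table=group_table,
        group_encoding=encoding,
    )
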