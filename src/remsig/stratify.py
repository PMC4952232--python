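"""Outcome labeling and the three-signature patient stratification.

Remission (REM) is CDAI <= 2.8 at 6 months of therapy; a missing month-6
CDAI (early discontinuation) is resolved by last observation carried
forward (LOCF).  Each patient then receives one binary call per signature
(score strictly above / at-or-below its ROC-derived cutoff), and the three
ordered calls place the patient into one of the 2**3 = 8 groups, for which
per-group non-remission rates are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ClinicalTable
from .gsea import DIRECTION_NONREM_UP, DIRECTION_REM_UP, NONREM, REM

__all__ = [
    "REMISSION_CDAI",
    "assign_outcome",
    "binary_call",
    "predicted_label",
    "assign_group",
    "group_summary",
    "group_encoding_table",
]

REMISSION_CDAI = 2.8


def assign_outcome(clinical: ClinicalTable, target_month: int = 6) -> pd.DataFrame:
    """Label every patient REM/NON-REM from the (LOCF-resolved) month-6 CDAI.

    Returns a frame indexed by sample id with columns ``cdai_resolved``
    (observed month-6 value or the last earlier observation), ``imputed``
    and ``label``.  REM iff the resolved CDAI is <= 2.8.  A patient with no
    CDAI observation at all is an error.
    """
    months = [m for m in clinical.cdai_months() if m <= target_month]
    cols = [f"cdai_{m}" for m in months]
    if not cols:
        raise ValueError(f"no CDAI columns at or before month {target_month}")
    sub = clinical.data[cols]
    resolved = sub.ffill(axis=1).iloc[:, -1]
    if resolved.isna().any():
        bad = list(resolved.index[resolved.isna()])
        raise ValueError(f"patients with no CDAI observations: {bad}")
    target_col = f"cdai_{target_month}"
    observed = (
        clinical.data[target_col].notna()
        if target_col in clinical.data.columns
        else pd.Series(False, index=clinical.data.index)
    )
    labels = np.where(resolved <= REMISSION_CDAI, REM, NONREM)
    return pd.DataFrame(
        {
            "cdai_resolved": resolved.astype(float),
            "imputed": ~observed,
            "label": labels,
        },
        index=clinical.data.index,
    )


def binary_call(score: float, threshold: float) -> bool:
    """True ("above") iff score is strictly above the threshold.

    A score exactly at the threshold is "below" — the strict-inequality
    convention is recorded with results.
    """
    return bool(score > threshold)


def predicted_label(call_above: bool, direction: str) -> str:
    """Map an above/below call to a predicted outcome given the signature
    direction: for a NON-REM-up signature "above" predicts NON-REM; for a
    REM-up signature "above" predicts REM."""
    if direction == DIRECTION_NONREM_UP:
        return NONREM if call_above else REM
    if direction == DIRECTION_REM_UP:
        return REM if call_above else NONREM
    raise ValueError(f"unknown direction {direction!r}")


def assign_group(calls: Sequence[bool]) -> int:
    """Group id (1..8) from three ordered binary calls.

    The encoding is ``1 + 4*c1 + 2*c2 + 1*c3`` with the calls in the fixed
    signature order (first, second, third) and above = 1; it is a bijection
    over the 8 call combinations and is emitted with results via
    :func:`group_encoding_table`.
    """
    calls = list(calls)
    if len(calls) != 3 or any(c is None for c in calls):
        raise ValueError("exactly three binary calls are required")
    return 1 + 4 * int(bool(calls[0])) + 2 * int(bool(calls[1])) + int(bool(calls[2]))


def group_encoding_table(signature_names: Sequence[str] | None = None) -> pd.DataFrame:
    """The documented group-id <-> call-combination mapping."""
    names = list(signature_names or ("signature_1", "signature_2", "signature_3"))
    rows = []
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                rows.append(
                    {
                        "group": assign_group([a, b, c]),
                        names[0]: "above" if a else "below",
                        names[1]: "above" if b else "below",
                        names[2]: "above" if c else "below",
                    }
                )
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)


def group_summary(groups: Mapping[str, int] | pd.Series, labels: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Per-group size, NON-REM count and NON-REM rate (one-decimal percent).

    ``groups`` maps sample id -> group id 1..8; ``labels`` maps sample id
    -> REM/NON-REM.  All 8 groups appear in the output; an empty group has
    n = 0 and an undefined (NaN) rate.  Group sizes sum to the cohort size.
    """
    groups = pd.Series(groups)
    labels = pd.Series(labels)
    if not groups.index.equals(labels.index):
        labels = labels.reindex(groups.index)
        if labels.isna().any():
            raise ValueError("every grouped patient needs an outcome label")
    rows = []
    for gid in range(1, 9):
        members = groups.index[groups == gid]
        n = len(members)
        nonrem = int((labels.loc[members] == NONREM).sum())
        rate = round(100.0 * nonrem / n, 1) if n else np.nan
        rows.append({"group": gid, "n": n, "nonrem": nonrem, "nonrem_rate_pct": rate})
    out = pd.DataFrame(rows)
    assert out["n"].sum() == len(groups)
    return out
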