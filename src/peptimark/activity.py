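"""Per-patient protease activity and case/control group comparison.

A protease's activity in one patient is read out from its substrate
peptides: the ion signals of all marker peptides whose N- or C-terminal
motif was attributed to that protease are integrated (summed; a marker whose
two termini both map to the same protease is counted once). Per-protease
group comparisons report case and control mean +/- SD of those per-patient
activities, the case/control fold change, and a two-sided Mann-Whitney U
p-value, plus a supplementary Benjamini-Hochberg column.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .mapping import ProteaseAssignment
from .profiles import ProfileMatrix

__all__ = ["patient_activity", "mann_whitney_u", "compare_groups"]


def patient_activity(
    matrix: ProfileMatrix,
    assignments: Iterable[ProteaseAssignment],
    aggregate: str = "sum",
) -> pd.DataFrame:
    """Integrate substrate ion signals per patient and protease.

    Returns a tidy DataFrame (sample_id, protease_id, activity) covering
    every sample for every protease with at least one assigned marker; a
    marker absent from a sample contributes 0. ``aggregate`` may be ``"sum"``
    (default) or ``"mean"`` over the protease's distinct assigned markers.
    """
    if aggregate not in ("sum", "mean"):
        raise ValidationError("aggregate must be 'sum' or 'mean'")
    marker_set = set(matrix.marker_ids)
    substrates: dict[str, set[str]] = {}
    for a in assignments:
        if a.marker_id not in marker_set:
            raise ValidationError(f"assignment references unknown marker {a.marker_id!r}")
        substrates.setdefault(a.protease_id, set()).add(a.marker_id)

    rows = []
    for pid in sorted(substrates):
        sub = matrix.intensities.loc[sorted(substrates[pid])]
        agg = sub.sum(axis=0) if aggregate == "sum" else sub.mean(axis=0)
        for sid, val in agg.items():
            rows.append({"sample_id": sid, "protease_id": pid, "activity": float(val)})
    return pd.DataFrame(rows, columns=["sample_id", "protease_id", "activity"])


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for x, p).

    The exact null distribution is enumerated when n_x + n_y <= 12 and there
    are no ties; otherwise the normal approximation with tie and continuity
    corrections is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 12 and not ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups(
    activities: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    case: str = "case",
    control: str = "control",
) -> pd.DataFrame:
    """Case/control comparison of per-patient protease activities.

    ``labels`` maps sample_id to group. Returns one row per protease with
    case/control mean and SD (sample SD, ddof=1), fold change
    (case mean / control mean; NaN with ``fold_undefined=True`` when the
    control mean is 0), direction, the Mann-Whitney p-value, and a
    supplementary Benjamini-Hochberg column ``q``.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    rows = []
    for pid, grp in activities.groupby("protease_id", sort=True):
        lab = grp["sample_id"].map(labels)
        x = grp.loc[lab == case, "activity"].to_numpy()
        y = grp.loc[lab == control, "activity"].to_numpy()
        if x.size < 2 or y.size < 2:
            raise ValidationError(f"protease {pid!r}: need >= 2 samples per group")
        _, p = mann_whitney_u(x, y)
        case_mean, control_mean = float(x.mean()), float(y.mean())
        undefined = control_mean == 0
        fold = np.nan if undefined else case_mean / control_mean
        rows.append({
            "protease_id": pid,
            "case_mean": case_mean, "case_sd": float(x.std(ddof=1)),
            "control_mean": control_mean, "control_sd": float(y.std(ddof=1)),
            "fold_change": fold, "fold_undefined": undefined,
            "direction": "increased" if (not undefined and fold > 1) else "decreased",
            "p": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
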