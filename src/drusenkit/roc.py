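"""ROC analysis for drusen-volume-based AMD discrimination.

Candidate thresholds are the unique observed volumes plus +inf; an eye is
classified positive when its volume is >= the threshold.  AUC is computed
from the Mann–Whitney rank statistic with ties counted 1/2 (identical to
trapezoidal integration of the empirical ROC curve).  The operating
threshold is chosen by minimizing the squared distance to the perfect
corner, min((1 - sensitivity)^2 + (1 - specificity)^2) — the
"closest-to-(0,1)" rule, which is not Youden's J.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

STAGES = ("no_amd", "eamd", "iamd")


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # sorted ascending, last is +inf
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_points(values, labels) -> RocCurve:
    """Empirical ROC curve of volume-based case/control discrimination.

    ``labels`` are truthy for cases.  Sensitivity is non-increasing in the
    threshold; the +inf threshold yields the (0, 1) operating point.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    n_case = int(labels.sum())
    n_ctrl = int((~labels).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("ROC requires at least one case and one control")
    thresholds = np.append(np.unique(values), np.inf)
    pos = values[:, None] >= thresholds[None, :]
    sens = pos[labels].sum(axis=0) / n_case
    spec = (~pos[~labels]).sum(axis=0) / n_ctrl
    # rank (Mann-Whitney) AUC with ties counted 1/2
    ranks = stats.rankdata(values)
    auc = (ranks[labels].sum() - n_case * (n_case + 1) / 2) / (n_case * n_ctrl)
    return RocCurve(thresholds, sens, spec, float(auc))


def optimal_threshold(c: RocCurve) -> tuple[float, float, float]:
    """Threshold minimizing (1 - se)^2 + (1 - sp)^2, ties toward the smaller
    threshold.  Returns (threshold, sensitivity, specificity)."""
    if len(c.thresholds) == 0:
        raise ValueError("empty ROC curve")
    crit = (1 - c.sensitivity) ** 2 + (1 - c.specificity) ** 2
    i = int(np.argmin(crit))  # first minimum = smallest threshold (sorted)
    return float(c.thresholds[i]), float(c.sensitivity[i]), float(c.specificity[i])


def sens_spec_by_stage(values, stages, threshold: float) -> dict[str, float]:
    """Sensitivity overall and per AMD stage, specificity on no-AMD eyes.

    Positive iff value >= threshold.  Empty strata are reported as NaN.
    Returned keys: specificity, sensitivity_overall, sensitivity_eamd,
    sensitivity_iamd (percent).
    """
    values = np.asarray(values, dtype=float)
    stages = np.asarray(stages)
    unknown = set(np.unique(stages)) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage labels: {sorted(unknown)}")
    pos = values >= threshold
    out: dict[str, float] = {}
    ctrl = stages == "no_amd"
    out["specificity"] = (
        float(100 * np.mean(~pos[ctrl])) if ctrl.any() else np.nan
    )
    case = ~ctrl
    out["sensitivity_overall"] = (
        float(100 * np.mean(pos[case])) if case.any() else np.nan
    )
    for stage in ("eamd", "iamd"):
        sel = stages == stage
        out[f"sensitivity_{stage}"] = (
            float(100 * np.mean(pos[sel])) if sel.any() else np.nan
        )
    return out
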