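"""ROC analysis, optimal cut-points and confusion-matrix metrics for DLT.

Each body-composition measurement is scored by how well it separates
patients with dose-limiting toxicity (cases) from those without (controls):
the AUC equals the probability that a random case/control pair is ordered
correctly (ties count one half), with a DeLong nonparametric 95% CI.  The
optimal cut-point maximises Youden's J = sensitivity + specificity - 1
(maximum-accuracy criterion available behind a flag).

The comparison direction is FIXED per analysis rather than auto-oriented
(default: a higher measurement predicts the non-DLT class, the natural
orientation for muscle mass).  A measurement that separates in the opposite
direction therefore shows an AUC below 0.5 instead of being silently
flipped; ``auto_direction=True`` opts into flipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortError, validate_cohort
from .metrics import MEASUREMENT_COLUMNS

HIGHER_CONTROL = "higher-control"  # higher value -> predicted non-DLT (default)
HIGHER_CASE = "higher-case"        # higher value -> predicted DLT
DIRECTIONS = (HIGHER_CONTROL, HIGHER_CASE)

DEFAULT_ROC_VARIABLES = ["bsa_m2"] + MEASUREMENT_COLUMNS


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")


def _scores(values: np.ndarray, direction: str) -> np.ndarray:
    """Map raw values to scores where a higher score predicts the case class."""
    return -values if direction == HIGHER_CONTROL else values


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve with AUC and DeLong 95% CI."""

    thresholds: np.ndarray          # candidate cut-points in measurement units
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    direction: str
    n_cases: int
    n_controls: int
    degenerate: bool = False        # every threshold gives J = 0


@dataclass(frozen=True)
class CutpointEvaluation:
    """Confusion matrix and metrics of a dichotomisation at one threshold."""

    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @classmethod
    def from_counts(cls, tp: int, fn: int, tn: int, fp: int, threshold: float = math.nan):
        return cls(threshold=threshold, tp=tp, fn=fn, tn=tn, fp=fp)


def _as_groups(cases, controls) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(cases, dtype=float)
    y = np.asarray(controls, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CohortError("ROC needs nonempty case and control groups")
    return x, y


def _auc_pair_counting(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """AUC = mean over (case, control) pairs of [case > control] + 0.5*[tie]."""
    cs = np.sort(control_scores)
    greater = np.searchsorted(cs, case_scores, side="left")
    greater_or_equal = np.searchsorted(cs, case_scores, side="right")
    wins = greater + 0.5 * (greater_or_equal - greater)
    return float(wins.sum() / (case_scores.size * control_scores.size))


def _delong_ci(case_scores: np.ndarray, control_scores: np.ndarray, auc: float,
               level: float = 0.95) -> tuple[float, float]:
    """DeLong variance via placement values V10 (cases) and V01 (controls)."""
    m, n = case_scores.size, control_scores.size
    cs = np.sort(control_scores)
    lo = np.searchsorted(cs, case_scores, side="left")
    hi = np.searchsorted(cs, case_scores, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / n
    xs = np.sort(case_scores)
    lo = np.searchsorted(xs, control_scores, side="right")
    hi = np.searchsorted(xs, control_scores, side="left")
    v01 = (m - lo + 0.5 * (lo - hi)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.5 + level / 2)
    return max(0.0, auc - z * se), min(1.0, auc + z * se)


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct observed values, plus +/-inf."""
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _sens_spec(cases: np.ndarray, controls: np.ndarray, thresholds: np.ndarray,
               direction: str) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity/specificity per threshold; value >= threshold is 'higher'."""
    xs, ys = np.sort(cases), np.sort(controls)
    if direction == HIGHER_CONTROL:
        # predicted DLT <=> value < threshold
        sens = np.searchsorted(xs, thresholds, side="left") / xs.size
        spec = 1.0 - np.searchsorted(ys, thresholds, side="left") / ys.size
    else:
        sens = 1.0 - np.searchsorted(xs, thresholds, side="left") / xs.size
        spec = np.searchsorted(ys, thresholds, side="left") / ys.size
    return sens, spec


def roc_auc(cases, controls, direction: str = HIGHER_CONTROL,
            auto_direction: bool = False) -> ROCCurve:
    """Empirical ROC curve of a measurement for case/control discrimination.

    AUC is computed by pair counting (identical to the trapezoidal area under
    the empirical curve, ties included); the CI is DeLong's.  With
    ``auto_direction`` the direction yielding AUC >= 0.5 is chosen.
    """
    _check_direction(direction)
    x, y = _as_groups(cases, controls)
    if auto_direction:
        auc0 = _auc_pair_counting(_scores(x, direction), _scores(y, direction))
        if auc0 < 0.5:
            direction = HIGHER_CASE if direction == HIGHER_CONTROL else HIGHER_CONTROL
    cs, ks = _scores(x, direction), _scores(y, direction)
    auc = _auc_pair_counting(cs, ks)
    ci_low, ci_high = _delong_ci(cs, ks, auc)
    thresholds = _candidate_thresholds(np.concatenate([x, y]))
    sens, spec = _sens_spec(x, y, thresholds, direction)
    degenerate = bool(np.all(sens + spec - 1.0 <= 1e-12))
    return ROCCurve(thresholds=thresholds, sensitivity=sens, specificity=spec,
                    auc=auc, ci_low=ci_low, ci_high=ci_high, direction=direction,
                    n_cases=x.size, n_controls=y.size, degenerate=degenerate)


def optimal_cutpoint(curve: ROCCurve, criterion: str = "youden") -> float:
    """Threshold maximising Youden's J (or accuracy with criterion='accuracy').

    Ties on the objective are broken toward higher specificity, then toward
    the lower threshold; a fully degenerate curve returns its lowest
    candidate.
    """
    if criterion == "youden":
        objective = curve.sensitivity + curve.specificity - 1.0
    elif criterion == "accuracy":
        m, n = curve.n_cases, curve.n_controls
        objective = (curve.sensitivity * m + curve.specificity * n) / (m + n)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    best = np.max(objective)
    tied = np.flatnonzero(objective >= best - 1e-12)
    tied = tied[curve.specificity[tied] >= curve.specificity[tied].max() - 1e-12]
    idx = tied[np.argmin(curve.thresholds[tied])]
    return float(curve.thresholds[idx])


def evaluate_cutpoint(cases, controls, threshold: float,
                      direction: str = HIGHER_CONTROL) -> CutpointEvaluation:
    """Dichotomise at a threshold and count the confusion matrix.

    Boundary rule: a value equal to the threshold goes to the 'higher' class
    (value >= threshold), so under the default direction it is predicted
    non-DLT.
    """
    _check_direction(direction)
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    x, y = _as_groups(cases, controls)
    if direction == HIGHER_CONTROL:
        tp = int(np.sum(x < threshold))
        tn = int(np.sum(y >= threshold))
    else:
        tp = int(np.sum(x >= threshold))
        tn = int(np.sum(y < threshold))
    return CutpointEvaluation(threshold=float(threshold), tp=tp, fn=x.size - tp,
                              tn=tn, fp=y.size - tn)


def _split(cohort: pd.DataFrame, variable: str) -> tuple[np.ndarray, np.ndarray]:
    sub = cohort.dropna(subset=[variable])
    cases = sub.loc[sub.dlt == 1, variable].to_numpy(dtype=float)
    controls = sub.loc[sub.dlt == 0, variable].to_numpy(dtype=float)
    return cases, controls


def threshold_classifier(cohort: pd.DataFrame, variable: str,
                         cutoffs_per_sex: dict[str, float],
                         direction: str = HIGHER_CONTROL) -> dict[str, CutpointEvaluation]:
    """Evaluate published (fixed, not fitted) per-sex cut-offs, e.g. sarcopenia
    SMI thresholds, as classifiers for DLT."""
    cohort = validate_cohort(cohort)
    out = {}
    for sex, block in cohort.groupby("sex"):
        if sex not in cutoffs_per_sex:
            raise CohortError(f"no cut-off supplied for sex={sex}")
        cases, controls = _split(block, variable)
        out[str(sex)] = evaluate_cutpoint(cases, controls, cutoffs_per_sex[sex], direction)
    return out


def evaluate_all(cohort: pd.DataFrame, variables: list[str] | None = None,
                 direction: str = HIGHER_CONTROL, criterion: str = "youden",
                 reference: str = "bsa_m2") -> pd.DataFrame:
    """Per sex, per measurement: AUC (95% CI) and optimal cut-point.

    Rows where the AUC exceeds the reference variable's (BSA by default) are
    flagged, mirroring the convention of highlighting measurements that beat
    body-surface-area dosing.
    """
    cohort = validate_cohort(cohort)
    if variables is None:
        variables = [v for v in DEFAULT_ROC_VARIABLES if v in cohort.columns]
    rows = []
    for sex, block in cohort.groupby("sex"):
        if block.dlt.nunique() < 2:
            raise CohortError(f"sex={sex} lacks both DLT strata")
        aucs = {}
        for var in variables:
            cases, controls = _split(block, var)
            curve = roc_auc(cases, controls, direction=direction)
            cut = optimal_cutpoint(curve, criterion=criterion)
            aucs[var] = curve.auc
            rows.append({
                "sex": str(sex), "variable": var, "auc": curve.auc,
                "ci_low": curve.ci_low, "ci_high": curve.ci_high,
                "cutpoint": cut, "degenerate": curve.degenerate,
                "n_cases": curve.n_cases, "n_controls": curve.n_controls,
            })
        ref_auc = aucs.get(reference)
        for row in rows:
            if row["sex"] == str(sex):
                row["exceeds_reference"] = (
                    ref_auc is not None and row["variable"] != reference
                    and row["auc"] > ref_auc)
    return pd.DataFrame(rows)


def top_variable(report: pd.DataFrame, sex: str, exclude: tuple[str, ...] = ()) -> str:
    """Highest-AUC measurement for one sex from an evaluate_all report."""
    block = report[(report.sex == sex) & ~report.variable.isin(exclude)]
    if block.empty:
        raise CohortError(f"no report rows for sex={sex}")
    return str(block.loc[block.auc.idxmax(), "variable"])
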