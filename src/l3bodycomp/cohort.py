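"""Cohort table handling and DLT vs non-DLT group comparisons.

The analysis substrate is a per-patient table: sex (F/M), age, height, BSA,
a binary dose-limiting-toxicity (DLT) label, and the fifteen body-composition
measurements.  Continuous variables are compared with the Mann-Whitney U test
and summarised as median (IQR); the sex-by-DLT contingency is tested with a
Yates-corrected chi-square.  Quartiles use linear interpolation (the common
statistical-package default) — the convention is fixed so results are
reproducible across environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import MEASUREMENT_COLUMNS

REQUIRED_COLUMNS = ["patient_id", "sex", "dlt"]
DEFAULT_VARIABLES = ["age", "bsa_m2"] + MEASUREMENT_COLUMNS


class CohortError(ValueError):
    """Schema or stratum violations in a cohort table."""


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate CohortTable invariants; returns the frame with dlt as int."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"cohort table missing column(s): {missing}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise CohortError(f"duplicate patient_id(s): {sorted(set(dup))[:5]}")
    bad_sex = set(df["sex"].unique()) - {"F", "M"}
    if bad_sex:
        raise CohortError(f"sex must be F or M, found {sorted(bad_sex)}")
    if not df["dlt"].isin([0, 1]).all():
        bad = df.loc[~df["dlt"].isin([0, 1]), ["patient_id", "dlt"]].head()
        raise CohortError(f"dlt must be 0/1; offending rows:\n{bad}")
    out = df.copy()
    out["dlt"] = out["dlt"].astype(int)
    return out


def read_cohort(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U statistic of group_a, p).

    U counts (a, b) pairs with a > b, half credit for ties.  Exact
    enumeration is used for groups of at most 25 without ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise CohortError("Mann-Whitney needs two nonempty groups")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table, correction: bool = True) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, Yates-corrected by default.

    Returns (statistic, p).  Zero row or column margins are rejected.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise CohortError("need a 2x2 table of nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise CohortError("2x2 table has a zero margin")
    res = stats.chi2_contingency(t, correction=correction)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupSummary:
    """Median (IQR) per DLT stratum plus the between-group p-value."""

    variable: str
    sex: str
    n_dlt: int
    n_no_dlt: int
    median_dlt: float
    q1_dlt: float
    q3_dlt: float
    median_no_dlt: float
    q1_no_dlt: float
    q3_no_dlt: float
    p_value: float


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    return float(med), float(q1), float(q3)


def summarize_groups(
    cohort: pd.DataFrame,
    variables: list[str] | None = None,
    stratify_by_sex: bool = True,
) -> pd.DataFrame:
    """Table-1-style summary: median (IQR) and Mann-Whitney p per variable.

    One block per sex when stratified; both DLT strata must be nonempty
    within every block.
    """
    cohort = validate_cohort(cohort)
    if variables is None:
        variables = [v for v in DEFAULT_VARIABLES if v in cohort.columns]
    blocks = cohort.groupby("sex") if stratify_by_sex else [("all", cohort)]
    rows = []
    for sex, block in blocks:
        dlt = block[block["dlt"] == 1]
        ctrl = block[block["dlt"] == 0]
        if dlt.empty or ctrl.empty:
            stratum = "DLT" if dlt.empty else "no-DLT"
            raise CohortError(f"empty {stratum} stratum in sex={sex}")
        for var in variables:
            x = dlt[var].dropna().to_numpy(dtype=float)
            y = ctrl[var].dropna().to_numpy(dtype=float)
            med1, q11, q31 = _quartiles(x)
            med0, q10, q30 = _quartiles(y)
            if np.ptp(np.concatenate([x, y])) == 0:
                p = 1.0  # constant variable carries no information
            else:
                _, p = mann_whitney(x, y)
            rows.append(GroupSummary(var, str(sex), len(x), len(y),
                                     med1, q11, q31, med0, q10, q30, p))
    return pd.DataFrame([r.__dict__ for r in rows])


def sex_by_dlt_table(cohort: pd.DataFrame) -> np.ndarray:
    """2x2 counts [[F-DLT, F-noDLT], [M-DLT, M-noDLT]]."""
    cohort = validate_cohort(cohort)
    return np.array([
        [int(((cohort.sex == s) & (cohort.dlt == d)).sum()) for d in (1, 0)]
        for s in ("F", "M")
    ])
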