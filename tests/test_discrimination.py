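import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from l3bodycomp.cohort import CohortError, mann_whitney
from l3bodycomp.discrimination import (
    HIGHER_CASE,
    HIGHER_CONTROL,
    CutpointEvaluation,
    evaluate_all,
    evaluate_cutpoint,
    optimal_cutpoint,
    roc_auc,
    threshold_classifier,
    top_variable,
)
from l3bodycomp.synthetic import CohortSimSpec, generate_cohort


def trapezoid_auc(curve):
    """Area under the empirical ROC polygon, as an independent computation."""
    fpr = 1.0 - curve.specificity
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(curve.sensitivity[order], fpr[order]))


class TestAUC:
    def test_perfect_separation(self):
        c = roc_auc([1, 2], [3, 4], direction=HIGHER_CONTROL)
        assert c.auc == 1.0

    def test_all_ties(self):
        c = roc_auc([5, 5, 5], [5, 5], direction=HIGHER_CONTROL)
        assert c.auc == 0.5
        assert c.degenerate

    def test_pair_counting_example(self):
        # controls > cases in 3 of 4 pairs
        c = roc_auc([1, 3], [2, 4], direction=HIGHER_CONTROL)
        assert c.auc == 0.75

    def test_reversal_identity(self, rng):
        x, y = rng.normal(0, 1, 23), rng.normal(0.4, 1.3, 17)
        a1 = roc_auc(x, y, direction=HIGHER_CONTROL).auc
        a2 = roc_auc(x, y, direction=HIGHER_CASE).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_auto_direction_flips_below_half(self, rng):
        x, y = rng.normal(1.0, 1, 50), rng.normal(0, 1, 50)  # cases higher
        c = roc_auc(x, y, direction=HIGHER_CONTROL, auto_direction=True)
        assert c.direction == HIGHER_CASE and c.auc > 0.5

    def test_pair_trapezoid_u_identity_on_random_instances(self, rng):
        """AUC(pairs) = AUC(trapezoid) = U/(n1*n2) on 100 tied instances."""
        for _ in range(100):
            n1, n2 = rng.integers(2, 15, size=2)
            x = rng.integers(0, 6, size=n1).astype(float)
            y = rng.integers(0, 6, size=n2).astype(float)
            c = roc_auc(x, y, direction=HIGHER_CONTROL)
            u_controls, _ = mann_whitney(y, x)  # U counting control > case pairs
            assert c.auc == pytest.approx(trapezoid_auc(c), abs=1e-12)
            assert c.auc == pytest.approx(u_controls / (n1 * n2), abs=1e-12)

    def test_matches_sklearn(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(0.7, 1, 60)
        c = roc_auc(x, y, direction=HIGHER_CONTROL)
        labels = np.r_[np.ones(40), np.zeros(60)]
        assert c.auc == pytest.approx(roc_auc_score(labels, -np.r_[x, y]))

    def test_curve_endpoints(self, rng):
        c = roc_auc(rng.normal(0, 1, 10), rng.normal(0, 1, 10))
        assert (c.sensitivity[0], c.specificity[0]) == (0.0, 1.0)
        assert (c.sensitivity[-1], c.specificity[-1]) == (1.0, 0.0)
        assert c.ci_low <= c.auc <= c.ci_high

    def test_empty_group_rejected(self):
        with pytest.raises(CohortError):
            roc_auc([], [1.0])


class TestDeLong:
    def test_ci_covers_binormal_truth(self):
        """Nominal 95% DeLong CI covers the true AUC in >= 90% of cohorts."""
        rng = np.random.default_rng(42)
        true_auc = float(0.5 * (1 + math.erf((1.0 / math.sqrt(2)) / math.sqrt(2))))
        covered = 0
        n_sim = 500
        for _ in range(n_sim):
            x = rng.normal(0.0, 1.0, 50)   # cases (lower)
            y = rng.normal(1.0, 1.0, 50)   # controls (higher)
            c = roc_auc(x, y, direction=HIGHER_CONTROL)
            covered += c.ci_low <= true_auc <= c.ci_high
        assert covered / n_sim >= 0.90


def exhaustive_best_j(cases, controls, direction):
    """Brute-force search over every dichotomisation threshold."""
    values = np.unique(np.concatenate([cases, controls]))
    mids = np.concatenate(([-np.inf], (values[:-1] + values[1:]) / 2, [np.inf]))
    best = -np.inf
    for t in mids:
        if math.isfinite(t):
            ev = evaluate_cutpoint(cases, controls, t, direction)
            best = max(best, ev.sensitivity + ev.specificity - 1)
        else:
            sens = 1.0 if (t == np.inf) == (direction == HIGHER_CONTROL) else 0.0
            best = max(best, sens + (1.0 - sens) - 1)  # J = 0 at the extremes
    return best


class TestCutpoint:
    def test_perfect_split_midpoint(self):
        c = roc_auc([1, 2], [3, 4], direction=HIGHER_CONTROL)
        t = optimal_cutpoint(c)
        assert t == 2.5
        ev = evaluate_cutpoint([1, 2], [3, 4], t, HIGHER_CONTROL)
        assert ev.sensitivity + ev.specificity - 1 == 1.0

    def test_degenerate_returns_lowest_candidate(self):
        c = roc_auc([5, 5], [5, 5, 5], direction=HIGHER_CONTROL)
        assert c.degenerate
        assert optimal_cutpoint(c) == -np.inf

    def test_matches_exhaustive_search(self, rng):
        """Youden optimum equals brute force on 30 instances of <= 20 points."""
        for _ in range(30):
            n1, n2 = rng.integers(2, 11, size=2)
            x = rng.integers(0, 8, size=n1).astype(float)
            y = rng.integers(0, 8, size=n2).astype(float)
            c = roc_auc(x, y, direction=HIGHER_CONTROL)
            t = optimal_cutpoint(c)
            best = exhaustive_best_j(x, y, HIGHER_CONTROL)
            if math.isfinite(t):
                ev = evaluate_cutpoint(x, y, t, HIGHER_CONTROL)
                j = ev.sensitivity + ev.specificity - 1
            else:
                j = 0.0
            assert j == pytest.approx(best, abs=1e-12)

    def test_accuracy_criterion_flag(self, rng):
        x = np.r_[rng.normal(0, 1, 30), rng.normal(3, 0.1, 3)]
        y = rng.normal(1.5, 1, 60)
        c = roc_auc(x, y, direction=HIGHER_CONTROL)
        t_acc = optimal_cutpoint(c, criterion="accuracy")
        ev = evaluate_cutpoint(x, y, t_acc, HIGHER_CONTROL)
        # no other threshold strictly beats it on accuracy
        for t in c.thresholds[np.isfinite(c.thresholds)]:
            other = evaluate_cutpoint(x, y, float(t), HIGHER_CONTROL)
            assert other.accuracy <= ev.accuracy + 1e-12


class TestEvaluateCutpoint:
    @pytest.mark.parametrize("tp,fn,tn,fp,acc,sens,spec", [
        (53, 20, 20, 13, 0.69, 0.73, 0.61),
        (23, 24, 39, 11, 0.64, 0.49, 0.78),
    ])
    def test_confusion_metrics(self, tp, fn, tn, fp, acc, sens, spec):
        ev = CutpointEvaluation.from_counts(tp, fn, tn, fp)
        assert round(ev.accuracy, 2) == acc
        assert round(ev.sensitivity, 2) == sens
        assert round(ev.specificity, 2) == spec

    def test_perfect_classification(self):
        ev = evaluate_cutpoint([1, 2], [3, 4], 2.5, HIGHER_CONTROL)
        assert (ev.accuracy, ev.sensitivity, ev.specificity) == (1.0, 1.0, 1.0)

    def test_boundary_rule_value_equals_threshold(self):
        # value == threshold goes to the 'higher' class (non-DLT by default)
        ev = evaluate_cutpoint([2.0], [2.0], 2.0, HIGHER_CONTROL)
        assert ev.tp == 0 and ev.tn == 1
        ev = evaluate_cutpoint([2.0], [2.0], 2.0, HIGHER_CASE)
        assert ev.tp == 1 and ev.tn == 0

    def test_counts_partition_groups(self, rng):
        x, y = rng.normal(0, 1, 31), rng.normal(1, 1, 27)
        ev = evaluate_cutpoint(x, y, 0.3, HIGHER_CONTROL)
        assert ev.tp + ev.fn == 31 and ev.tn + ev.fp == 27


class TestThresholdClassifier:
    def make_cohort(self, rng, n=3000, prevalence=0.65):
        dlt = (rng.random(n) < prevalence).astype(int)
        values = rng.normal(40.0, 6.0, size=n)  # independent of the label
        return pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "sex": ["F"] * n, "dlt": dlt, "smi_cm2_m2": values})

    def test_independent_variable_median_cutoff(self, rng):
        """With a label-independent variable, a median split is a coin flip:
        accuracy ~ 0.5 whatever the prevalence."""
        df = self.make_cohort(rng)
        cut = float(np.median(df.smi_cm2_m2))
        out = threshold_classifier(df, "smi_cm2_m2", {"F": cut})
        assert out["F"].accuracy == pytest.approx(0.5, abs=0.04)

    def test_cutoff_below_all_values_degenerate(self, rng):
        df = self.make_cohort(rng, n=50)
        out = threshold_classifier(df, "smi_cm2_m2", {"F": -1e9})
        assert out["F"].sensitivity == 0.0 and out["F"].specificity == 1.0

    def test_missing_sex_cutoff_rejected(self, rng):
        df = self.make_cohort(rng, n=20)
        with pytest.raises(CohortError, match="sex=F"):
            threshold_classifier(df, "smi_cm2_m2", {"M": 40.0})


class TestEvaluateAll:
    def test_report_structure_and_flags(self, default_cohort):
        df, _ = default_cohort
        report = evaluate_all(df)
        assert set(report.sex) == {"F", "M"}
        assert len(report) == 2 * 16  # BSA + 15 measurements per sex
        bsa = report[(report.sex == "F") & (report.variable == "bsa_m2")].iloc[0]
        flagged = report[(report.sex == "F") & report.exceeds_reference]
        assert (flagged.auc > bsa.auc).all()
        assert ((report.ci_low <= report.auc) & (report.auc <= report.ci_high)).all()

    def test_single_sex_cohort(self, default_cohort):
        df, _ = default_cohort
        report = evaluate_all(df[df.sex == "F"])
        assert set(report.sex) == {"F"}

    def test_constant_measurement_degenerate(self, default_cohort):
        df, _ = default_cohort
        df = df.copy()
        df["constant"] = 1.0
        report = evaluate_all(df, variables=["constant"])
        assert (report.auc == 0.5).all()
        assert report.degenerate.all()

    def test_top_variable_recovers_largest_separation(self):
        """With generous n, the highest empirical AUC is the measurement
        generated with the largest true separation (3D SM volume)."""
        df, truth = generate_cohort(CohortSimSpec(
            n_per_sex={"F": 20000, "M": 20000}, seed=5))
        report = evaluate_all(df)
        for sex in ("F", "M"):
            true_best = max(truth["true_auc"][sex], key=truth["true_auc"][sex].get)
            assert true_best == "sm_volume_cm3"
            assert top_variable(report, sex) == "sm_volume_cm3"
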