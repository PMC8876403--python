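"""ROC/AUC machinery, DeLong comparisons, 2x2 metrics and cohort association tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from .cohort import (
    CARRIER_GROUPS,
    GROUPS,
    Cohort,
    FAMILY_CANCERS,
)

__all__ = [
    "TwoByTwo",
    "confusion_metrics",
    "odds_ratio",
    "OddsRatioResult",
    "roc_auc",
    "delong_ci",
    "DelongCI",
    "delong_test",
    "DelongComparison",
    "chi2_or_fisher",
    "association_tests",
    "EvalReport",
    "evaluate_scores",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Counts laid out exposure x outcome.

    ``a`` exposed with outcome, ``b`` exposed without, ``c`` unexposed with,
    ``d`` unexposed without.  For classifier evaluation the exposure is the
    positive call and the outcome the true positive label, so (a, b, c, d)
    reads (TP, FP, FN, TN).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def confusion_metrics(table: TwoByTwo) -> dict:
    """Sensitivity, specificity, accuracy and Youden's J from a (TP, FP, FN, TN) table.

    J = sensitivity + specificity - 1.  Metrics whose denominator is zero are
    returned as None and flagged.
    """
    tp, fp, fn, tn = table.a, table.b, table.c, table.d
    flags = []
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    specificity = tn / (tn + fp) if tn + fp > 0 else None
    if sensitivity is None:
        flags.append("no positives: sensitivity undefined")
    if specificity is None:
        flags.append("no negatives: specificity undefined")
    accuracy = (tp + tn) / table.total
    youden = (
        sensitivity + specificity - 1.0
        if sensitivity is not None and specificity is not None
        else None
    )
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "accuracy": accuracy,
        "youden": youden,
        "flags": flags,
    }


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    lo: float
    hi: float
    corrected: bool


def odds_ratio(table: TwoByTwo, level: float = 0.95) -> OddsRatioResult:
    """OR = ad/bc with a Woolf log-scale CI.

    The Haldane-Anscombe +0.5 correction is applied to every cell iff any
    cell is zero, and flagged in the result.
    """
    a, b, c, d = (float(v) for v in (table.a, table.b, table.c, table.d))
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + level / 2)
    lo = float(np.exp(np.log(or_) - z * se))
    hi = float(np.exp(np.log(or_) + z * se))
    return OddsRatioResult(float(or_), lo, hi, corrected)


# ---------------------------------------------------------------------------
# ROC / AUC and DeLong
# ---------------------------------------------------------------------------

def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must contain both classes 0 and 1, got {classes}")
    return labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC step-function points and trapezoidal AUC (Mann-Whitney with midranks)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), auc


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-observation structural components (Sun & Xu midrank form)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    auc = (np.sum(all_ranks[:m]) - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


@dataclass(frozen=True)
class DelongCI:
    auc: float
    lo: float
    hi: float
    degenerate: bool


def delong_ci(scores: Sequence[float], labels: Sequence[int], level: float = 0.95) -> DelongCI:
    """Normal-approximation AUC CI from the DeLong variance, clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    if np.sum(labels == 1) < 2 or np.sum(labels == 0) < 2:
        raise ValueError("delong_ci requires at least 2 observations per class")
    auc, v10, v01 = _delong_components(scores, labels)
    var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
    if var <= 0:
        return DelongCI(auc, auc, auc, degenerate=True)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return DelongCI(auc, float(max(0.0, auc - half)), float(min(1.0, auc + half)), False)


@dataclass(frozen=True)
class DelongComparison:
    delta_auc: float
    z: float
    p: float


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> DelongComparison:
    """Paired DeLong test for the difference of two correlated AUCs (two-sided)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_binary(np.asarray(labels))
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != labels.shape[0]:
        raise ValueError("scores_a, scores_b and labels must have identical length")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(v10_a, v10_b, ddof=1)
    s01 = np.cov(v01_a, v01_b, ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        if abs(delta) < 1e-15:
            return DelongComparison(0.0, 0.0, 1.0)
        return DelongComparison(float(delta), float(np.sign(delta) * np.inf), 0.0)
    z = delta / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return DelongComparison(float(delta), float(z), float(p))


# ---------------------------------------------------------------------------
# Association tests (Table-1-style)
# ---------------------------------------------------------------------------

def chi2_or_fisher(table: np.ndarray) -> tuple[float, str]:
    """Two-sided p for a 2x2 table: Pearson chi-square, or Fisher's exact test
    when any expected cell is below 5."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("chi2_or_fisher expects a 2x2 table")
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0, "degenerate"
    expected = sps.contingency.expected_freq(table)
    if (expected < 5).any():
        _, p = sps.fisher_exact(table)
        return float(p), "fisher"
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(p), "chi2"


# Feature accessors used for cohort summaries: flags give (known?, positive?),
# categoricals give the observed level or None.
_SUMMARY_FLAGS = (
    ("personal_any_cancer", lambda r: r.personal_any_cancer),
    ("personal_previous_breast", lambda r: r.personal_previous_breast),
    ("personal_ovarian", lambda r: r.personal_ovarian),
    *[
        (f"family_{c}", (lambda c: lambda r: getattr(r, f"family_{c}"))(c))
        for c in FAMILY_CANCERS
    ],
    ("bilateral", lambda r: r.bilateral),
    ("tnbc", lambda r: r.tnbc),
)

_SUMMARY_CATEGORICALS = (
    ("tumor_size_class", lambda r: r.tumor_size_class),
    ("histology", lambda r: r.histology),
    ("grade", lambda r: r.grade),
    ("er", lambda r: r.er),
    ("pr", lambda r: r.pr),
    ("ar", lambda r: r.ar),
    ("her2", lambda r: r.her2),
    ("ki67_class", lambda r: r.ki67_class),
    ("egfr", lambda r: r.egfr),
    ("ck5_6", lambda r: r.ck5_6),
    ("p53_class", lambda r: r.p53_class),
    ("lymph_nodes", lambda r: r.lymph_nodes),
)


def _percent(p: Optional[float]) -> Optional[float]:
    return None if p is None else round(100.0 * p, 1)


def association_tests(cohort: Cohort) -> dict:
    """Per-feature, per-carrier-group summary with group-vs-non-carrier tests.

    Age is compared with Student's (equal-variance) t-test; binary and
    categorical features with Pearson chi-square, switching to Fisher's exact
    test when any expected cell is below 5.  Proportions are computed over
    records whose value is known.
    """
    if not cohort.has_labels:
        raise ValueError("association_tests requires labels")
    groups = cohort.groups()
    by_group = {g: [r for r, gg in zip(cohort.records, groups) if gg == g] for g in GROUPS}
    n_carriers = sum(len(by_group[g]) for g in CARRIER_GROUPS)
    report: dict = {
        "n": len(cohort),
        "group_sizes": {g: len(by_group[g]) for g in GROUPS},
        "carrier_prevalence": n_carriers / len(cohort) if len(cohort) else None,
        "carrier_prevalence_percent": _percent(
            n_carriers / len(cohort) if len(cohort) else None
        ),
        "features": {},
        "notices": [],
    }

    nc_records = by_group["non_carrier"]
    nc_ages = np.array([r.age_at_diagnosis for r in nc_records])

    age_entry: dict = {"kind": "age", "groups": {}}
    for g in GROUPS:
        ages = np.array([r.age_at_diagnosis for r in by_group[g]])
        entry = {
            "n": int(ages.size),
            "mean": float(ages.mean()) if ages.size else None,
            "sd": float(ages.std(ddof=1)) if ages.size > 1 else None,
        }
        if g != "non_carrier":
            if ages.size < 2 or nc_ages.size < 2:
                entry["p"] = None
                report["notices"].append(f"age: group {g} too small for t-test")
            else:
                t, p = sps.ttest_ind(ages, nc_ages, equal_var=True)
                entry["t"] = float(t)
                entry["p"] = float(p)
        age_entry["groups"][g] = entry
    report["features"]["age_at_diagnosis"] = age_entry

    def flag_counts(records, accessor):
        known = [accessor(r) for r in records if accessor(r) is not None]
        return len(known), sum(bool(v) for v in known)

    for name, accessor in _SUMMARY_FLAGS:
        entry = {"kind": "flag", "groups": {}}
        nc_known, nc_pos = flag_counts(nc_records, accessor)
        for g in GROUPS:
            known, pos = flag_counts(by_group[g], accessor)
            prop = pos / known if known else None
            sub = {
                "n_known": known,
                "count": pos,
                "proportion": prop,
                "percent": _percent(prop),
            }
            if g != "non_carrier":
                if known == 0 or nc_known == 0:
                    sub["p"] = None
                    report["notices"].append(f"{name}: group {g} empty, test skipped")
                else:
                    table = np.array([[pos, known - pos], [nc_pos, nc_known - nc_pos]])
                    p, test = chi2_or_fisher(table)
                    sub["p"], sub["test"] = p, test
            entry["groups"][g] = sub
        report["features"][name] = entry

    for name, accessor in _SUMMARY_CATEGORICALS:
        levels = sorted(
            {accessor(r) for r in cohort.records if accessor(r) != "unknown"}
        )
        entry = {"kind": "categorical", "levels": {}}
        for level in levels:
            level_entry: dict = {"groups": {}}
            nc_known = sum(accessor(r) != "unknown" for r in nc_records)
            nc_hit = sum(accessor(r) == level for r in nc_records)
            for g in GROUPS:
                known = sum(accessor(r) != "unknown" for r in by_group[g])
                hit = sum(accessor(r) == level for r in by_group[g])
                prop = hit / known if known else None
                sub = {
                    "n_known": known,
                    "count": hit,
                    "proportion": prop,
                    "percent": _percent(prop),
                }
                if g != "non_carrier":
                    if known == 0 or nc_known == 0:
                        sub["p"] = None
                        report["notices"].append(
                            f"{name}={level}: group {g} empty, test skipped"
                        )
                    else:
                        table = np.array(
                            [[hit, known - hit], [nc_hit, nc_known - nc_hit]]
                        )
                        p, test = chi2_or_fisher(table)
                        sub["p"], sub["test"] = p, test
                level_entry["groups"][g] = sub
            entry["levels"][level] = level_entry
        report["features"][name] = entry
    return report


# ---------------------------------------------------------------------------
# EvalReport
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Evaluation summary for one scoring rule on one labeled set."""

    roc_points: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    confusion: dict = field(default_factory=dict)  # threshold -> metrics dict
    youden: Optional[float] = None
    comparisons: dict = field(default_factory=dict)  # name -> DelongComparison
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "confusion": {str(k): v for k, v in self.confusion.items()},
            "youden": self.youden,
            "comparisons": {
                k: {"delta_auc": v.delta_auc, "z": v.z, "p": v.p}
                for k, v in self.comparisons.items()
            },
            "flags": list(self.flags),
            "roc_points": self.roc_points.tolist(),
        }


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    thresholds: Optional[Sequence[float]] = None,
) -> EvalReport:
    """ROC, DeLong AUC CI and confusion metrics at the supplied thresholds.

    Calls use the rule score >= threshold; Youden's J is reported for the
    first threshold (or the J-maximizing one when none are given).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    points, auc = roc_auc(scores, labels)
    ci = delong_ci(scores, labels)
    report = EvalReport(
        roc_points=points,
        auc=auc,
        auc_ci=(ci.lo, ci.hi),
        flags=(["degenerate CI"] if ci.degenerate else []),
    )
    if thresholds is None:
        fpr, tpr = points[:, 0], points[:, 1]
        report.youden = float(np.max(tpr - fpr))
        return report
    for tau in thresholds:
        calls = scores >= tau
        tp = int(np.sum(calls & (labels == 1)))
        fp = int(np.sum(calls & (labels == 0)))
        fn = int(np.sum(~calls & (labels == 1)))
        tn = int(np.sum(~calls & (labels == 0)))
        report.confusion[float(tau)] = confusion_metrics(TwoByTwo(tp, fp, fn, tn))
    first = report.confusion[float(thresholds[0])]
    report.youden = first["youden"]
    return report
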