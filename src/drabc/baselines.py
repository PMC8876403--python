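"""Comparator methods: genetic-testing eligibility rules and reconstructed
logistic / naive-Bayes risk models.

The default eligibility ruleset approximates the v1.2020 breast-cancer
testing indications that are expressible over the flat phenotype record
(pedigree-level indications such as relative counts cannot be represented
and are omitted).  Rules are data: a ruleset is an ordered list of named
predicates, eligibility is their OR, and each evaluation exposes the list
of fired rules for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .cohort import (
    Cohort,
    EncodingSpec,
    PhenotypeRecord,
    default_encoding_spec,
    encode_cohort,
)
from .model import scenario_labels
from .stats import DelongComparison, delong_ci, delong_test, evaluate_scores, roc_auc

__all__ = [
    "NCCNRule",
    "NCCNRuleSet",
    "default_nccn_rules",
    "nccn_eligible",
    "nccn_expanded",
    "fired_rules",
    "ReconstructedModel",
    "fit_logistic_baseline",
    "fit_naive_bayes_baseline",
    "compare_models",
    "DEFAULT_SUBSETS",
    "age_bin",
]


@dataclass(frozen=True)
class NCCNRule:
    name: str
    text: str
    predicate: Callable[[PhenotypeRecord], bool]


@dataclass
class NCCNRuleSet:
    rules: list[NCCNRule]
    version_tag: str = "reconstruction-v1.2020"


def _true(value) -> bool:
    # unknown (None) counts as not satisfying a rule clause
    return value is True


def default_nccn_rules() -> NCCNRuleSet:
    rules = [
        NCCNRule(
            "early_onset",
            "Breast cancer diagnosed at age <= 45",
            lambda r: r.age_at_diagnosis <= 45,
        ),
        NCCNRule(
            "age_46_50_with_risk",
            "Diagnosis at 46-50 with a second primary, bilateral disease, "
            "relevant family history, or unknown family history",
            lambda r: 45 < r.age_at_diagnosis <= 50
            and (
                _true(r.personal_any_cancer)
                or _true(r.personal_previous_breast)
                or _true(r.bilateral)
                or _true(r.family_breast)
                or _true(r.family_ovarian)
                or _true(r.family_pancreas)
                or _true(r.family_prostate)
                or r.family_any is None
            ),
        ),
        NCCNRule(
            "tnbc_le_60",
            "Triple-negative breast cancer diagnosed at age <= 60",
            lambda r: r.tnbc is True and r.age_at_diagnosis <= 60,
        ),
        NCCNRule(
            "family_high_risk",
            "Any age with a family history of ovarian, pancreatic or male breast cancer",
            lambda r: _true(r.family_ovarian)
            or _true(r.family_pancreas)
            or _true(r.family_male_breast),
        ),
        NCCNRule(
            "personal_ovarian",
            "Personal history of ovarian cancer",
            lambda r: _true(r.personal_ovarian),
        ),
        NCCNRule(
            "bilateral_with_family",
            "Bilateral breast cancer with any family cancer history",
            lambda r: _true(r.bilateral) and _true(r.family_any),
        ),
    ]
    return NCCNRuleSet(rules=rules)


def fired_rules(record: PhenotypeRecord, rules: Optional[NCCNRuleSet] = None) -> list[str]:
    """Names of the rules a record satisfies (unknown fields fail a rule)."""
    if rules is None:
        rules = default_nccn_rules()
    fired = []
    for rule in rules.rules:
        try:
            hit = bool(rule.predicate(record))
        except TypeError:
            hit = False  # unknown field inside a comparison
        if hit:
            fired.append(rule.name)
    return fired


def nccn_eligible(record: PhenotypeRecord, rules: Optional[NCCNRuleSet] = None) -> bool:
    return len(fired_rules(record, rules)) > 0


def nccn_expanded(
    record: PhenotypeRecord,
    rules: Optional[NCCNRuleSet] = None,
    age_cutoff: float = 65.0,
) -> bool:
    """Base eligibility OR diagnosis at or below the expansion age cutoff."""
    return nccn_eligible(record, rules) or record.age_at_diagnosis <= age_cutoff


# ---------------------------------------------------------------------------
# Reconstructed risk models
# ---------------------------------------------------------------------------

AGE_BINS = ((-np.inf, 40.0), (40.0, 50.0), (50.0, 65.0), (65.0, np.inf))


def age_bin(age: float) -> int:
    """Index into the documented age bins (<=40, 41-50, 51-65, >65)."""
    for i, (lo, hi) in enumerate(AGE_BINS):
        if lo < age <= hi:
            return i
    raise ValueError(f"age {age} outside all bins")


# Default variable subsets for the reconstructed model families.  Names refer
# to encoded features; the pseudo-feature "age_bin" is the binned age.
DEFAULT_SUBSETS = {
    "myriad_like": ("age_std", "family_breast", "family_ovarian"),
    "penn2_like": (
        "age_std",
        "family_breast",
        "family_ovarian",
        "bilateral",
        "personal_ovarian",
    ),
    "brcapro_like": (
        "age_bin",
        "family_breast",
        "family_ovarian",
        "family_male_breast",
        "family_any",
    ),
    "boadicea_like": (
        "age_bin",
        "family_breast",
        "family_ovarian",
        "family_male_breast",
        "family_any",
        "er_pos",
        "pr_pos",
        "her2_pos",
        "grade_ii",
        "grade_iii",
    ),
}

_TARGETS = ("any_cpg", "brca12")


def _design_matrix(
    cohort: Cohort, subset: Sequence[str], spec: EncodingSpec
) -> np.ndarray:
    """Columns for the requested features; age_bin becomes its integer index."""
    x_full = encode_cohort(cohort, spec)
    cols = []
    for name in subset:
        if name == "age_bin":
            cols.append(
                np.array([age_bin(r.age_at_diagnosis) for r in cohort.records], dtype=float)
            )
        elif name in spec.feature_order:
            cols.append(x_full[:, spec.feature_order.index(name)])
        else:
            raise ValueError(f"feature {name!r} not available")
    if not cols:
        return np.empty((len(cohort), 0))
    return np.column_stack(cols)


def _target_vector(cohort: Cohort, target: str) -> np.ndarray:
    if target not in _TARGETS:
        raise ValueError(f"target must be one of {_TARGETS}")
    return scenario_labels(cohort, target)


@dataclass
class ReconstructedModel:
    """Fitted in-cohort analogue of an external carrier-risk model."""

    family: str  # "logistic" | "naive_bayes"
    variable_subset: tuple[str, ...]
    target: str
    parameters: dict
    spec: EncodingSpec
    diagnostics: dict = field(default_factory=dict)

    def predict(self, cohort: Cohort) -> np.ndarray:
        x = _design_matrix(cohort, self.variable_subset, self.spec)
        if self.family == "logistic":
            eta = self.parameters["intercept"] + (
                x @ np.asarray(self.parameters["coef"]) if x.shape[1] else 0.0
            )
            return 1.0 / (1.0 + np.exp(-eta))
        return _nb_posterior(x, self.parameters)


def fit_logistic_baseline(
    cohort: Cohort,
    subset: Sequence[str],
    target: str = "any_cpg",
    spec: Optional[EncodingSpec] = None,
    ridge_c: float = 1.0,
) -> ReconstructedModel:
    """Maximum-likelihood logistic fit; ridge (sklearn, C=ridge_c) fallback on
    separation or non-convergence, flagged in the diagnostics."""
    if spec is None:
        spec = default_encoding_spec()
    if not cohort.has_labels:
        raise ValueError("fit_logistic_baseline requires labels")
    x = _design_matrix(cohort, subset, spec)
    y = _target_vector(cohort, target)
    if len(np.unique(y)) < 2:
        raise ValueError("target has a single class")

    diagnostics: dict = {"n": len(cohort)}
    if x.shape[1] == 0:
        prevalence = float(np.mean(y))
        intercept = float(np.log(prevalence / (1 - prevalence)))
        return ReconstructedModel(
            family="logistic",
            variable_subset=tuple(subset),
            target=target,
            parameters={"intercept": intercept, "coef": []},
            spec=spec,
            diagnostics={**diagnostics, "intercept_only": True},
        )

    design = sm.add_constant(x, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            result = sm.Logit(y, design).fit(disp=False, maxiter=200)
        converged = bool(result.mle_retvals.get("converged", False))
        params_finite = np.all(np.isfinite(result.params)) and np.all(
            np.isfinite(result.bse)
        )
        if not (converged and params_finite):
            raise RuntimeError("non-converged or unstable MLE")
        intercept = float(result.params[0])
        coef = [float(v) for v in result.params[1:]]
        diagnostics.update(
            {
                "converged": True,
                "penalized": False,
                "llf": float(result.llf),
                "bse": [float(v) for v in result.bse],
                "conf_int": [[float(a), float(b)] for a, b in result.conf_int()],
            }
        )
    except Exception as exc:  # separation / singular fit
        clf = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=1000)
        clf.fit(x, y)
        intercept = float(clf.intercept_[0])
        coef = [float(v) for v in clf.coef_[0]]
        diagnostics.update(
            {"converged": True, "penalized": True, "fallback_reason": str(exc), "ridge_c": ridge_c}
        )
    return ReconstructedModel(
        family="logistic",
        variable_subset=tuple(subset),
        target=target,
        parameters={"intercept": intercept, "coef": coef},
        spec=spec,
        diagnostics=diagnostics,
    )


def _nb_posterior(x: np.ndarray, params: dict) -> np.ndarray:
    """Posterior P(class 1 | x) under conditional independence (log space)."""
    log_post1 = np.full(x.shape[0], np.log(params["prior"]))
    log_post0 = np.full(x.shape[0], np.log(1.0 - params["prior"]))
    for j, table in enumerate(params["tables"]):
        levels = np.asarray(table["levels"])
        p1 = np.asarray(table["p_given_1"])
        p0 = np.asarray(table["p_given_0"])
        idx = np.searchsorted(levels, x[:, j])
        idx = np.clip(idx, 0, len(levels) - 1)
        log_post1 += np.log(np.maximum(p1[idx], 1e-300))
        log_post0 += np.log(np.maximum(p0[idx], 1e-300))
    m = np.maximum(log_post1, log_post0)
    e1 = np.exp(log_post1 - m)
    e0 = np.exp(log_post0 - m)
    return e1 / (e1 + e0)


def fit_naive_bayes_baseline(
    cohort: Cohort,
    subset: Sequence[str],
    target: str = "any_cpg",
    spec: Optional[EncodingSpec] = None,
    smoothing: float = 1.0,
    prior: Optional[float] = None,
) -> ReconstructedModel:
    """Class prior plus per-feature class-conditional tables (add-``smoothing``)
    combined by Bayes' theorem under conditional independence."""
    if spec is None:
        spec = default_encoding_spec()
    if not cohort.has_labels:
        raise ValueError("fit_naive_bayes_baseline requires labels")
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    x = _design_matrix(cohort, subset, spec)
    y = _target_vector(cohort, target)
    if len(np.unique(y)) < 2:
        raise ValueError("target has a single class")

    tables = []
    for j in range(x.shape[1]):
        levels = np.unique(x[:, j])
        counts1 = np.array([np.sum((x[:, j] == lv) & (y == 1)) for lv in levels], dtype=float)
        counts0 = np.array([np.sum((x[:, j] == lv) & (y == 0)) for lv in levels], dtype=float)
        p1 = (counts1 + smoothing) / (counts1.sum() + smoothing * len(levels))
        p0 = (counts0 + smoothing) / (counts0.sum() + smoothing * len(levels))
        tables.append(
            {
                "levels": levels.tolist(),
                "p_given_1": p1.tolist(),
                "p_given_0": p0.tolist(),
            }
        )
    params = {
        "prior": float(np.mean(y)) if prior is None else float(prior),
        "tables": tables,
    }
    return ReconstructedModel(
        family="naive_bayes",
        variable_subset=tuple(subset),
        target=target,
        parameters=params,
        spec=spec,
        diagnostics={"n": len(cohort), "smoothing": smoothing},
    )


def compare_models(
    model_scores: dict[str, np.ndarray],
    labels: Sequence[int],
    reference: str,
    thresholds: Optional[dict[str, float]] = None,
) -> dict:
    """Per-model AUC with CI, DeLong test against the reference model, and
    confusion metrics at each model's threshold (J-maximizing by default)."""
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("no positive labels in the comparison scenario")
    if reference not in model_scores:
        raise ValueError(f"reference model {reference!r} not among the scored models")
    ref_scores = np.asarray(model_scores[reference], dtype=float)
    thresholds = thresholds or {}
    report: dict = {"reference": reference, "models": {}}
    for name, scores in model_scores.items():
        scores = np.asarray(scores, dtype=float)
        if name in thresholds:
            tau = thresholds[name]
        else:
            pts, _ = roc_auc(scores, labels)
            # J-maximizing threshold among observed scores
            cand = np.unique(scores)
            j_vals = [
                np.mean(scores[labels == 1] >= t) + np.mean(scores[labels == 0] < t) - 1
                for t in cand
            ]
            tau = float(cand[int(np.argmax(j_vals))])
        entry = evaluate_scores(scores, labels, thresholds=[tau]).to_dict()
        entry["threshold"] = tau
        comparison = delong_test(scores, ref_scores, labels)
        entry["vs_reference"] = {
            "delta_auc": comparison.delta_auc,
            "z": comparison.z,
            "p": comparison.p,
        }
        report["models"][name] = entry
    return report
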