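"""Synthetic cohort generation from class-conditional phenotype frequencies.

The default frequency table encodes the per-genotype-group clinical
characteristics of a 2928-patient breast-cancer case series (group sizes
2596 / 131 / 132 / 43 / 26 for non-carriers and BRCA1, BRCA2, other-HRR and
other-CPG carriers).  Counts are stored verbatim; proportions are computed
over each row's known-value denominator.  Features are sampled independently
given the group, with two documented reconciliations:

* ER/PR/HER2 are drawn jointly through a latent triple-negative indicator so
  that the derived TNBC rate matches the per-group target while the three
  marginals are preserved (records all-negative by chance in the non-TNBC
  branch are redrawn);
* the "any personal/family cancer" flags are drawn as OR(specific flags, extra)
  with the extra-probability solved so the printed marginal is matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .cohort import (
    CARRIER_GROUPS,
    GROUPS,
    CarrierLabel,
    Cohort,
    PhenotypeRecord,
)
from . import stats as _stats

__all__ = [
    "GroupFrequencyTable",
    "default_frequency_table",
    "generate_cohort",
    "summarize_cohort",
    "load_frequency_table",
    "save_frequency_table",
]

_TOL = 1e-9

# --- packaged default: per-group counts ------------------------------------
# Group order everywhere: non_carrier, brca1, brca2, other_hrr, other_cpg.
# Flag numerators use the group size as denominator; categorical rows are
# renormalized over their known-category total.

_GROUP_N = (2347, 131, 132, 43, 26)
_PREVALENCE_COUNTS = (2596, 131, 132, 43, 26)  # of 2928 genotyped patients

_AGE_MEAN = (43.4, 39.1, 40.8, 41.2, 40.5)
_AGE_SD = (9.1, 8.4, 8.0, 9.1, 7.6)

_FLAG_COUNTS = {
    "personal_any_cancer": (113, 16, 18, 3, 2),
    "personal_previous_breast": (47, 14, 10, 1, 1),
    "personal_ovarian": (8, 1, 3, 0, 0),
    "family_any": (726, 85, 71, 15, 12),
    "family_breast": (254, 54, 43, 7, 4),
    "family_ovarian": (18, 19, 1, 0, 1),
    "family_pancreas": (34, 4, 2, 4, 1),
    "family_prostate": (10, 0, 0, 0, 0),
    "family_esophageal": (82, 7, 3, 2, 1),
    "family_laryngeal": (12, 2, 2, 0, 1),
    "family_leukemia": (13, 1, 3, 0, 1),
    "family_male_breast": (2, 0, 4, 0, 0),
    "bilateral": (52, 15, 11, 1, 1),
}

_CATEGORICAL_COUNTS = {
    "tumor_size_class": {
        "le2cm": (1099, 51, 62, 18, 15),
        "gt2cm": (899, 60, 56, 20, 7),
    },
    "histology": {
        "idc": (1825, 122, 114, 38, 21),
        "dcis": (184, 0, 7, 2, 2),
        "lobular": (45, 1, 3, 1, 1),
        "mucinous": (45, 0, 2, 1, 0),
        "medullary": (11, 2, 2, 0, 0),
        "other": (34, 2, 1, 0, 1),
    },
    "grade": {
        "I": (139, 0, 2, 0, 0),
        "II": (1004, 26, 67, 26, 10),
        "III": (587, 85, 35, 8, 6),
    },
    "er": {"positive": (1592, 34, 107, 30, 19), "negative": (612, 94, 22, 12, 6)},
    "pr": {"positive": (1571, 35, 107, 32, 18), "negative": (631, 93, 21, 10, 7)},
    "ar": {"positive": (710, 15, 33, 10, 11), "negative": (175, 50, 13, 8, 2)},
    "her2": {
        "positive": (507, 2, 6, 0, 7),
        "negative": (1317, 120, 103, 37, 17),
        "uncertain": (342, 3, 18, 4, 2),
    },
    "ki67_class": {"le30": (1254, 21, 74, 23, 16), "gt30": (852, 98, 52, 17, 8)},
    "egfr": {"positive": (467, 72, 23, 9, 6), "negative": (1026, 24, 75, 22, 11)},
    "ck5_6": {"positive": (309, 61, 16, 10, 3), "negative": (1382, 46, 89, 26, 20)},
    "p53_class": {
        "gain_of_function": (605, 46, 39, 10, 5),
        "loss_of_function": (227, 33, 6, 4, 6),
        "wildtype": (629, 21, 55, 20, 7),
    },
    "lymph_nodes": {"positive": (892, 43, 75, 21, 14), "negative": (1151, 76, 44, 16, 7)},
}

_TNBC_COUNTS = (303, 82, 15, 8, 4)  # numerator over group size


@dataclass
class GroupFrequencyTable:
    """Generative parameters per genotype group.

    ``flag_probs`` maps binary feature -> {group: probability}; ``cat_probs``
    maps categorical feature -> {group: {level: probability}} with each
    per-group simplex summing to 1; ``tnbc_probs`` is the target derived
    triple-negative rate per group.
    """

    prevalences: dict[str, float]
    age_mean: dict[str, float]
    age_sd: dict[str, float]
    flag_probs: dict[str, dict[str, float]]
    cat_probs: dict[str, dict[str, dict[str, float]]]
    tnbc_probs: dict[str, float]

    def validate(self) -> None:
        if set(self.prevalences) != set(GROUPS):
            raise ValueError("prevalences must cover exactly the five groups")
        if abs(sum(self.prevalences.values()) - 1.0) > _TOL:
            raise ValueError("prevalences must sum to 1")
        for g in GROUPS:
            if self.prevalences[g] < 0:
                raise ValueError("prevalences must be non-negative")
            if self.age_sd[g] <= 0:
                raise ValueError("age_sd must be positive")
        for name, per_group in self.flag_probs.items():
            for g, p in per_group.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"flag {name}/{g}: probability {p} outside [0,1]")
        for name, per_group in self.cat_probs.items():
            for g, simplex in per_group.items():
                total = sum(simplex.values())
                if abs(total - 1.0) > _TOL:
                    raise ValueError(f"{name}/{g}: simplex sums to {total}")
                if any(p < 0 for p in simplex.values()):
                    raise ValueError(f"{name}/{g}: negative probability")
        for g, p in self.tnbc_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"tnbc/{g}: probability {p} outside [0,1]")

    def to_dict(self) -> dict:
        return {
            "prevalences": dict(self.prevalences),
            "age_mean": dict(self.age_mean),
            "age_sd": dict(self.age_sd),
            "flag_probs": {k: dict(v) for k, v in self.flag_probs.items()},
            "cat_probs": {
                k: {g: dict(s) for g, s in v.items()} for k, v in self.cat_probs.items()
            },
            "tnbc_probs": dict(self.tnbc_probs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupFrequencyTable":
        table = cls(
            prevalences={k: float(v) for k, v in d["prevalences"].items()},
            age_mean={k: float(v) for k, v in d["age_mean"].items()},
            age_sd={k: float(v) for k, v in d["age_sd"].items()},
            flag_probs={
                k: {g: float(p) for g, p in v.items()} for k, v in d["flag_probs"].items()
            },
            cat_probs={
                k: {g: {lv: float(p) for lv, p in s.items()} for g, s in v.items()}
                for k, v in d["cat_probs"].items()
            },
            tnbc_probs={k: float(v) for k, v in d["tnbc_probs"].items()},
        )
        table.validate()
        return table


def default_frequency_table() -> GroupFrequencyTable:
    """The packaged per-group frequency table (proportions from stored counts)."""
    total = sum(_PREVALENCE_COUNTS)
    prevalences = {g: c / total for g, c in zip(GROUPS, _PREVALENCE_COUNTS)}
    flag_probs = {
        name: {g: counts[i] / _GROUP_N[i] for i, g in enumerate(GROUPS)}
        for name, counts in _FLAG_COUNTS.items()
    }
    cat_probs: dict[str, dict[str, dict[str, float]]] = {}
    for name, level_counts in _CATEGORICAL_COUNTS.items():
        per_group: dict[str, dict[str, float]] = {}
        for i, g in enumerate(GROUPS):
            known = sum(counts[i] for counts in level_counts.values())
            per_group[g] = {
                level: counts[i] / known for level, counts in level_counts.items()
            }
        cat_probs[name] = per_group
    tnbc_probs = {g: _TNBC_COUNTS[i] / _GROUP_N[i] for i, g in enumerate(GROUPS)}
    table = GroupFrequencyTable(
        prevalences=prevalences,
        age_mean=dict(zip(GROUPS, _AGE_MEAN)),
        age_sd=dict(zip(GROUPS, _AGE_SD)),
        flag_probs=flag_probs,
        cat_probs=cat_probs,
        tnbc_probs=tnbc_probs,
    )
    table.validate()
    return table


def load_frequency_table(path: str | Path) -> GroupFrequencyTable:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: not a frequency-table mapping")
    return GroupFrequencyTable.from_dict(data)


def save_frequency_table(table: GroupFrequencyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(table.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_level(rng: np.random.Generator, simplex: dict[str, float]) -> str:
    levels = list(simplex)
    probs = np.array([simplex[lv] for lv in levels], dtype=float)
    probs = probs / probs.sum()
    return levels[rng.choice(len(levels), p=probs)]


def _sample_truncated_age(rng: np.random.Generator, mean: float, sd: float) -> float:
    # redraw until above the adult-age floor
    for _ in range(1000):
        age = rng.normal(mean, sd)
        if age >= 18.0:
            return float(age)
    raise RuntimeError("age sampling failed to satisfy truncation at 18")


def _or_flag_extra_prob(p_any: float, p_none_specific: float) -> float:
    """Probability of the extra Bernoulli so OR(specifics, extra) hits p_any."""
    if p_none_specific <= 0:
        return 0.0
    q = 1.0 - (1.0 - p_any) / p_none_specific
    return float(min(1.0, max(0.0, q)))


def _sample_er_pr_her2(
    rng: np.random.Generator, table: GroupFrequencyTable, group: str
) -> tuple[str, str, str]:
    """Joint draw matching the ER/PR/HER2 marginals and the group TNBC rate."""
    p_t = table.tnbc_probs[group]
    er_m = table.cat_probs["er"][group]
    pr_m = table.cat_probs["pr"][group]
    her2_m = table.cat_probs["her2"][group]
    if rng.random() < p_t:
        return "negative", "negative", "negative"
    denom = 1.0 - p_t
    q_er_neg = max(0.0, min(1.0, (er_m["negative"] - p_t) / denom))
    q_pr_neg = max(0.0, min(1.0, (pr_m["negative"] - p_t) / denom))
    q_h_neg = max(0.0, (her2_m["negative"] - p_t) / denom)
    q_h_unc = her2_m.get("uncertain", 0.0) / denom
    q_h_pos = max(0.0, 1.0 - q_h_neg - q_h_unc)
    her2_simplex = {"positive": q_h_pos, "negative": q_h_neg, "uncertain": q_h_unc}
    for _ in range(1000):
        er = "negative" if rng.random() < q_er_neg else "positive"
        pr = "negative" if rng.random() < q_pr_neg else "positive"
        her2 = _sample_level(rng, her2_simplex)
        if not (er == "negative" and pr == "negative" and her2 == "negative"):
            return er, pr, her2
    # degenerate marginals (all-negative forced): accept the TNBC triple
    return "negative", "negative", "negative"


_SPECIFIC_PERSONAL = ("personal_previous_breast", "personal_ovarian")
_SPECIFIC_FAMILY = (
    "family_breast",
    "family_ovarian",
    "family_pancreas",
    "family_prostate",
    "family_esophageal",
    "family_laryngeal",
    "family_leukemia",
    "family_male_breast",
)


def generate_cohort(
    n: int,
    table: Optional[GroupFrequencyTable] = None,
    seed: int = 0,
    missing_rate: float = 0.0,
    id_prefix: str = "SYN",
) -> Cohort:
    """Draw ``n`` labeled synthetic patients from the group-conditional table.

    ``missing_rate`` optionally blanks each optional field independently with
    the given probability, to exercise the completeness filter downstream.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    if table is None:
        table = default_frequency_table()
    table.validate()
    rng = np.random.default_rng(seed)

    records: list[PhenotypeRecord] = []
    labels: list[CarrierLabel] = []
    prev = np.array([table.prevalences[g] for g in GROUPS])
    prev = prev / prev.sum()
    group_draws = rng.choice(len(GROUPS), size=n, p=prev)

    for i in range(n):
        g = GROUPS[group_draws[i]]
        kwargs: dict = {
            "patient_id": f"{id_prefix}{i:06d}",
            "age_at_diagnosis": _sample_truncated_age(rng, table.age_mean[g], table.age_sd[g]),
        }
        for name in _SPECIFIC_PERSONAL + _SPECIFIC_FAMILY + ("bilateral",):
            kwargs[name] = bool(rng.random() < table.flag_probs[name][g])
        # reconcile the two aggregate flags with their specific components
        p_none_personal = float(
            np.prod([1.0 - table.flag_probs[f][g] for f in _SPECIFIC_PERSONAL])
        )
        q_personal = _or_flag_extra_prob(
            table.flag_probs["personal_any_cancer"][g], p_none_personal
        )
        kwargs["personal_any_cancer"] = bool(
            any(kwargs[f] for f in _SPECIFIC_PERSONAL) or rng.random() < q_personal
        )
        p_none_family = float(
            np.prod([1.0 - table.flag_probs[f][g] for f in _SPECIFIC_FAMILY])
        )
        q_family = _or_flag_extra_prob(table.flag_probs["family_any"][g], p_none_family)
        kwargs["family_any"] = bool(
            any(kwargs[f] for f in _SPECIFIC_FAMILY) or rng.random() < q_family
        )
        for name in ("tumor_size_class", "histology", "grade", "ar", "ki67_class",
                     "egfr", "ck5_6", "p53_class", "lymph_nodes"):
            kwargs[name] = _sample_level(rng, table.cat_probs[name][g])
        kwargs["er"], kwargs["pr"], kwargs["her2"] = _sample_er_pr_her2(rng, table, g)
        kwargs["variant_status"] = "no_variant" if g == "non_carrier" else "pathogenic"

        if missing_rate > 0.0:
            for name in list(kwargs):
                if name in ("patient_id", "age_at_diagnosis", "variant_status"):
                    continue
                if rng.random() < missing_rate:
                    kwargs[name] = None if isinstance(kwargs[name], bool) else "unknown"

        records.append(PhenotypeRecord(**kwargs))
        labels.append(CarrierLabel(g))

    return Cohort(records=records, labels=labels, provenance=f"synthetic(seed={seed})")


def summarize_cohort(cohort: Cohort) -> dict:
    """Per-group frequency report with group-vs-non-carrier tests.

    Thin wrapper over the association-test machinery; see
    :func:`drabc.stats.association_tests` for the exact contract.
    """
    return _stats.association_tests(cohort)
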