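"""Patient records, cohort CSV I/O, completeness filtering and feature encoding.

A cohort is a flat table with one row per patient.  Categorical fields use a
fixed vocabulary with the literal level ``unknown`` for missing values; binary
flags are tri-state (``True``/``False``/``None``) so that incomplete records
can be detected and filtered before model training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeRecord",
    "CarrierLabel",
    "Cohort",
    "EncodingSpec",
    "ExclusionReport",
    "GROUPS",
    "CARRIER_GROUPS",
    "FAMILY_CANCERS",
    "default_encoding_spec",
    "load_cohort",
    "write_cohort",
    "apply_exclusions",
    "encode_features",
    "encode_cohort",
    "stratified_split",
]

GROUPS = ("non_carrier", "brca1", "brca2", "other_hrr", "other_cpg")
CARRIER_GROUPS = GROUPS[1:]

FAMILY_CANCERS = (
    "breast",
    "ovarian",
    "pancreas",
    "prostate",
    "esophageal",
    "laryngeal",
    "leukemia",
    "male_breast",
    "any",
)

TUMOR_SIZE_LEVELS = ("le2cm", "gt2cm", "unknown")
HISTOLOGY_LEVELS = ("idc", "dcis", "lobular", "mucinous", "medullary", "other", "unknown")
GRADE_LEVELS = ("I", "II", "III", "unknown")
RECEPTOR_LEVELS = ("positive", "negative", "unknown")
HER2_LEVELS = ("positive", "negative", "uncertain", "unknown")
KI67_LEVELS = ("le30", "gt30", "unknown")
P53_LEVELS = ("gain_of_function", "loss_of_function", "wildtype", "unknown")
LYMPH_LEVELS = ("positive", "negative", "unknown")
VARIANT_LEVELS = ("no_variant", "pathogenic", "vus_only", "untested")


class SchemaError(ValueError):
    """Raised when a cohort CSV does not match the documented schema."""


class EncodingError(ValueError):
    """Raised when a record cannot be encoded under a given spec."""


@dataclass(frozen=True)
class PhenotypeRecord:
    """One patient's phenotype.  ``None`` in a flag field means unknown."""

    patient_id: str
    age_at_diagnosis: float
    personal_any_cancer: Optional[bool] = None
    personal_previous_breast: Optional[bool] = None
    personal_ovarian: Optional[bool] = None
    family_breast: Optional[bool] = None
    family_ovarian: Optional[bool] = None
    family_pancreas: Optional[bool] = None
    family_prostate: Optional[bool] = None
    family_esophageal: Optional[bool] = None
    family_laryngeal: Optional[bool] = None
    family_leukemia: Optional[bool] = None
    family_male_breast: Optional[bool] = None
    family_any: Optional[bool] = None
    tumor_size_class: str = "unknown"
    histology: str = "unknown"
    grade: str = "unknown"
    er: str = "unknown"
    pr: str = "unknown"
    ar: str = "unknown"
    her2: str = "unknown"
    ki67_class: str = "unknown"
    egfr: str = "unknown"
    ck5_6: str = "unknown"
    p53_class: str = "unknown"
    bilateral: Optional[bool] = None
    lymph_nodes: str = "unknown"
    variant_status: str = "untested"

    def __post_init__(self) -> None:
        if not np.isfinite(self.age_at_diagnosis) or self.age_at_diagnosis <= 0:
            raise ValueError(
                f"age_at_diagnosis must be a positive finite number, got {self.age_at_diagnosis!r}"
            )
        for name, levels in (
            ("tumor_size_class", TUMOR_SIZE_LEVELS),
            ("histology", HISTOLOGY_LEVELS),
            ("grade", GRADE_LEVELS),
            ("er", RECEPTOR_LEVELS),
            ("pr", RECEPTOR_LEVELS),
            ("ar", RECEPTOR_LEVELS),
            ("her2", HER2_LEVELS),
            ("ki67_class", KI67_LEVELS),
            ("egfr", RECEPTOR_LEVELS),
            ("ck5_6", RECEPTOR_LEVELS),
            ("p53_class", P53_LEVELS),
            ("lymph_nodes", LYMPH_LEVELS),
            ("variant_status", VARIANT_LEVELS),
        ):
            value = getattr(self, name)
            if value not in levels:
                raise ValueError(f"{name}={value!r} not in {levels}")

    @property
    def tnbc(self) -> Optional[bool]:
        """Triple-negative status derived from ER/PR/HER2; None if any is unknown."""
        if self.er == "unknown" or self.pr == "unknown" or self.her2 == "unknown":
            return None
        return self.er == "negative" and self.pr == "negative" and self.her2 == "negative"


@dataclass(frozen=True)
class CarrierLabel:
    """Five-group genotype class with its hierarchical binary encoding."""

    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group={self.group!r} not in {GROUPS}")

    @property
    def y_any(self) -> int:
        return int(self.group != "non_carrier")

    @property
    def y_brca(self) -> Optional[int]:
        """1 for BRCA1/2 carriers, 0 for other carriers, None (undefined) for non-carriers."""
        if self.group == "non_carrier":
            return None
        return int(self.group in ("brca1", "brca2"))


@dataclass
class Cohort:
    """Ordered patient records with optional matching carrier labels."""

    records: list[PhenotypeRecord]
    labels: Optional[list[CarrierLabel]] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.records):
            raise ValueError("records and labels must have equal length")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id(s): {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def groups(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("cohort has no labels")
        return np.array([lab.group for lab in self.labels])

    def y_any(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("cohort has no labels")
        return np.array([lab.y_any for lab in self.labels], dtype=int)

    def y_brca(self) -> np.ndarray:
        """BRCA1/2 indicator with -1 where undefined (non-carriers)."""
        if self.labels is None:
            raise ValueError("cohort has no labels")
        return np.array(
            [-1 if lab.y_brca is None else lab.y_brca for lab in self.labels], dtype=int
        )

    def subset(self, index: Sequence[int]) -> "Cohort":
        labels = None if self.labels is None else [self.labels[i] for i in index]
        return Cohort(
            records=[self.records[i] for i in index],
            labels=labels,
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# Feature encoding
# ---------------------------------------------------------------------------

def _flag(value: Optional[bool], name: str) -> float:
    if value is None:
        raise EncodingError(f"flag {name} is unknown")
    return float(value)


def _level(value: str, name: str, positive: str) -> float:
    if value == "unknown":
        raise EncodingError(f"{name} is unknown")
    return float(value == positive)


# Registry mapping encoded-feature names to extractor functions.  Every feature
# is a single real; multi-level categoricals contribute one indicator per
# retained level (grade II/III, histology IDC/DCIS, HER2 positive/uncertain).
_FEATURE_EXTRACTORS = {
    "personal_any_cancer": lambda r: _flag(r.personal_any_cancer, "personal_any_cancer"),
    "personal_previous_breast": lambda r: _flag(
        r.personal_previous_breast, "personal_previous_breast"
    ),
    "personal_ovarian": lambda r: _flag(r.personal_ovarian, "personal_ovarian"),
    "family_breast": lambda r: _flag(r.family_breast, "family_breast"),
    "family_ovarian": lambda r: _flag(r.family_ovarian, "family_ovarian"),
    "family_pancreas": lambda r: _flag(r.family_pancreas, "family_pancreas"),
    "family_male_breast": lambda r: _flag(r.family_male_breast, "family_male_breast"),
    "family_any": lambda r: _flag(r.family_any, "family_any"),
    "bilateral": lambda r: _flag(r.bilateral, "bilateral"),
    "size_gt2cm": lambda r: _level(r.tumor_size_class, "tumor_size_class", "gt2cm"),
    "grade_ii": lambda r: _level(r.grade, "grade", "II"),
    "grade_iii": lambda r: _level(r.grade, "grade", "III"),
    "hist_idc": lambda r: _level(r.histology, "histology", "idc"),
    "hist_dcis": lambda r: _level(r.histology, "histology", "dcis"),
    "er_pos": lambda r: _level(r.er, "er", "positive"),
    "pr_pos": lambda r: _level(r.pr, "pr", "positive"),
    "ar_pos": lambda r: _level(r.ar, "ar", "positive"),
    "egfr_pos": lambda r: _level(r.egfr, "egfr", "positive"),
    "ck56_pos": lambda r: _level(r.ck5_6, "ck5_6", "positive"),
    "her2_pos": lambda r: _level(r.her2, "her2", "positive"),
    "her2_uncertain": lambda r: _level(r.her2, "her2", "uncertain"),
    "ki67_gt30": lambda r: _level(r.ki67_class, "ki67_class", "gt30"),
    "p53_gof": lambda r: _level(r.p53_class, "p53_class", "gain_of_function"),
    "ln_pos": lambda r: _level(r.lymph_nodes, "lymph_nodes", "positive"),
}

# Default 25-feature order: standardized age first, then history flags,
# then tumor/pathology indicators.
DEFAULT_FEATURE_ORDER = ("age_std",) + tuple(_FEATURE_EXTRACTORS)

# Record fields a row must have known for the default encoding to apply.
# All family-history flags are required, including those not encoded.
_REQUIRED_FLAGS = (
    "personal_any_cancer",
    "personal_previous_breast",
    "personal_ovarian",
    "bilateral",
) + tuple(f"family_{c}" for c in FAMILY_CANCERS)
_REQUIRED_LEVELS = (
    "tumor_size_class",
    "histology",
    "grade",
    "er",
    "pr",
    "ar",
    "her2",
    "ki67_class",
    "egfr",
    "ck5_6",
    "p53_class",
    "lymph_nodes",
)


@dataclass(frozen=True)
class EncodingSpec:
    """Names and parameters of the fixed real-vector encoding fed to the net.

    ``age_center``/``age_scale`` standardize age; every other feature is a
    0/1 indicator drawn from the extractor registry.  The default order gives
    the documented reference vector: an all-negative, history-free patient at
    the centering age encodes to the zero vector.
    """

    feature_order: tuple[str, ...] = DEFAULT_FEATURE_ORDER
    age_center: float = 42.9
    age_scale: float = 9.1

    def __post_init__(self) -> None:
        if self.age_scale <= 0:
            raise ValueError("age_scale must be positive")
        for name in self.feature_order:
            if name != "age_std" and name not in _FEATURE_EXTRACTORS:
                raise ValueError(f"unknown encoded feature {name!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_order)

    def to_dict(self) -> dict:
        return {
            "feature_order": list(self.feature_order),
            "age_center": self.age_center,
            "age_scale": self.age_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingSpec":
        return cls(
            feature_order=tuple(d["feature_order"]),
            age_center=float(d["age_center"]),
            age_scale=float(d["age_scale"]),
        )


def default_encoding_spec() -> EncodingSpec:
    return EncodingSpec()


# Named feature blocks used by ablation experiments.
FEATURE_GROUPS = {
    "family_history": (
        "family_breast",
        "family_ovarian",
        "family_pancreas",
        "family_male_breast",
        "family_any",
    ),
    "pathology": (
        "size_gt2cm",
        "grade_ii",
        "grade_iii",
        "hist_idc",
        "hist_dcis",
        "er_pos",
        "pr_pos",
        "ar_pos",
        "egfr_pos",
        "ck56_pos",
        "her2_pos",
        "her2_uncertain",
        "ki67_gt30",
        "p53_gof",
        "ln_pos",
    ),
}


def encode_features(record: PhenotypeRecord, spec: EncodingSpec) -> np.ndarray:
    """Encode one complete record into the spec's real vector."""
    out = np.empty(spec.n_features, dtype=float)
    for i, name in enumerate(spec.feature_order):
        if name == "age_std":
            out[i] = (record.age_at_diagnosis - spec.age_center) / spec.age_scale
        else:
            out[i] = _FEATURE_EXTRACTORS[name](record)
    return out


def encode_cohort(cohort: Cohort, spec: EncodingSpec) -> np.ndarray:
    """Encode every record; raises EncodingError naming the offending patient."""
    rows = []
    for record in cohort.records:
        try:
            rows.append(encode_features(record, spec))
        except EncodingError as exc:
            raise EncodingError(f"patient {record.patient_id}: {exc}") from exc
    if not rows:
        return np.empty((0, spec.n_features), dtype=float)
    return np.vstack(rows)


def is_complete(record: PhenotypeRecord) -> bool:
    """True iff all encoding-required and family-history fields are known."""
    for name in _REQUIRED_FLAGS:
        if getattr(record, name) is None:
            return False
    for name in _REQUIRED_LEVELS:
        if getattr(record, name) == "unknown":
            return False
    return True


@dataclass
class ExclusionReport:
    n_input: int
    n_retained: int
    n_vus: int
    n_incomplete: int

    def as_dict(self) -> dict:
        return {
            "input": self.n_input,
            "retained": self.n_retained,
            "vus": self.n_vus,
            "incomplete": self.n_incomplete,
        }


def apply_exclusions(cohort: Cohort) -> tuple[Cohort, ExclusionReport]:
    """Drop VUS-only carriers and incomplete records.

    A record qualifying for both reasons is counted once, under ``vus``.
    """
    if not cohort.has_labels:
        raise ValueError("apply_exclusions requires a labeled cohort")
    keep, n_vus, n_incomplete = [], 0, 0
    for i, record in enumerate(cohort.records):
        if record.variant_status == "vus_only":
            n_vus += 1
        elif not is_complete(record):
            n_incomplete += 1
        else:
            keep.append(i)
    report = ExclusionReport(
        n_input=len(cohort), n_retained=len(keep), n_vus=n_vus, n_incomplete=n_incomplete
    )
    return cohort.subset(keep), report


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_FLAG_FIELDS = tuple(
    f.name
    for f in fields(PhenotypeRecord)
    if f.name.startswith(("personal_", "family_")) or f.name == "bilateral"
)
_LEVEL_FIELDS = _REQUIRED_LEVELS + ("variant_status",)

CSV_COLUMNS = (
    ("patient_id", "age_at_diagnosis")
    + _FLAG_FIELDS
    + _LEVEL_FIELDS
    + ("carrier_group",)
)


def _format_flag(value: Optional[bool]) -> str:
    if value is None:
        return "unknown"
    return "1" if value else "0"


def _parse_flag(raw, column: str, row: int) -> Optional[bool]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip().lower()
    if text in ("", "unknown", "na", "nan"):
        return None
    if text in ("1", "true", "yes"):
        return True
    if text in ("0", "false", "no"):
        return False
    raise SchemaError(f"row {row}: cannot parse flag {column}={raw!r}")


def _parse_level(raw) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "unknown"
    text = str(raw).strip()
    return text if text else "unknown"


def load_cohort(path: str | Path, label_mode: str = "optional") -> Cohort:
    """Read a cohort CSV (schema documented in the README).

    ``label_mode='required'`` errors when the carrier_group column is absent
    or has blanks; ``'optional'`` returns an unlabeled cohort in that case.
    """
    if label_mode not in ("required", "optional"):
        raise ValueError(f"label_mode={label_mode!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]

    mandatory = [c for c in CSV_COLUMNS if c != "carrier_group"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[PhenotypeRecord] = []
    groups: list[str] = []
    have_label_col = "carrier_group" in df.columns
    for row_idx, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            age = float(row_d["age_at_diagnosis"])
        except (TypeError, ValueError):
            raise SchemaError(
                f"row {row_idx}: unparseable age_at_diagnosis={row_d['age_at_diagnosis']!r}"
            )
        kwargs = {"patient_id": str(row_d["patient_id"]).strip(), "age_at_diagnosis": age}
        for name in _FLAG_FIELDS:
            kwargs[name] = _parse_flag(row_d[name], name, row_idx)
        for name in _LEVEL_FIELDS:
            level = _parse_level(row_d[name])
            kwargs[name] = level if name != "variant_status" or level != "unknown" else "untested"
        try:
            records.append(PhenotypeRecord(**kwargs))
        except ValueError as exc:
            raise SchemaError(f"row {row_idx}: {exc}") from exc
        groups.append(_parse_level(row_d["carrier_group"]) if have_label_col else "unknown")

    labels: Optional[list[CarrierLabel]] = None
    if have_label_col and all(g != "unknown" for g in groups):
        labels = [CarrierLabel(g) for g in groups]
    elif label_mode == "required":
        raise SchemaError("labels required but carrier_group column missing or incomplete")
    return Cohort(records=records, labels=labels, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort CSV; blank carrier_group when unlabeled."""
    rows = []
    for i, record in enumerate(cohort.records):
        row = {"patient_id": record.patient_id, "age_at_diagnosis": repr(record.age_at_diagnosis)}
        for name in _FLAG_FIELDS:
            row[name] = _format_flag(getattr(record, name))
        for name in _LEVEL_FIELDS:
            row[name] = getattr(record, name)
        row["carrier_group"] = cohort.labels[i].group if cohort.labels is not None else ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def stratified_split(cohort: Cohort, fraction: float, seed: int) -> tuple[Cohort, Cohort]:
    """Disjoint split preserving five-group proportions to within one record.

    The first-part total is round(fraction * n), allocated to groups by the
    largest-remainder rule on fraction * n_g.  If rounding would make either
    side empty while 0 < fraction < 1 and the cohort has >= 2 records, one
    record moves from the largest group to restore a non-empty split.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if not cohort.has_labels:
        raise ValueError("stratified_split requires labels")
    rng = np.random.default_rng(seed)
    groups = cohort.groups()
    first: list[int] = []
    second: list[int] = []
    sizes = {g: int(np.sum(groups == g)) for g in GROUPS}
    target_total = int(round(fraction * len(cohort)))
    take = {g: int(np.floor(fraction * sizes[g])) for g in GROUPS}
    remainders = sorted(
        GROUPS, key=lambda g: fraction * sizes[g] - take[g], reverse=True
    )
    for g in remainders:
        if sum(take.values()) >= target_total:
            break
        if take[g] < sizes[g]:
            take[g] += 1
    if len(cohort) >= 2:
        largest = max(GROUPS, key=lambda g: sizes[g])
        if sum(take.values()) == len(cohort):
            take[largest] -= 1
        elif sum(take.values()) == 0:
            take[largest] += 1
    for g in GROUPS:
        idx = np.flatnonzero(groups == g)
        idx = rng.permutation(idx)
        first.extend(idx[: take[g]].tolist())
        second.extend(idx[take[g]:].tolist())
    return cohort.subset(sorted(first)), cohort.subset(sorted(second))
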