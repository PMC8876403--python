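import numpy as np
import pytest

from drabc.cohort import CarrierLabel, Cohort, PhenotypeRecord


def make_record(patient_id="P0", age=45.0, **overrides):
    """A fully known, all-negative, history-free reference record."""
    kwargs = dict(
        patient_id=patient_id,
        age_at_diagnosis=age,
        personal_any_cancer=False,
        personal_previous_breast=False,
        personal_ovarian=False,
        family_breast=False,
        family_ovarian=False,
        family_pancreas=False,
        family_prostate=False,
        family_esophageal=False,
        family_laryngeal=False,
        family_leukemia=False,
        family_male_breast=False,
        family_any=False,
        tumor_size_class="le2cm",
        histology="lobular",
        grade="I",
        er="negative",
        pr="negative",
        ar="negative",
        her2="negative",
        ki67_class="le30",
        egfr="negative",
        ck5_6="negative",
        p53_class="wildtype",
        bilateral=False,
        lymph_nodes="negative",
        variant_status="no_variant",
    )
    kwargs.update(overrides)
    return PhenotypeRecord(**kwargs)


def make_cohort(n=10, n_carriers=2, seed=0):
    """Small complete labeled cohort: carriers alternate brca1/brca2."""
    rng = np.random.default_rng(seed)
    records, labels = [], []
    for i in range(n):
        records.append(make_record(patient_id=f"P{i}", age=float(rng.uniform(25, 70))))
        if i < n_carriers:
            labels.append(CarrierLabel("brca1" if i % 2 == 0 else "brca2"))
        else:
            labels.append(CarrierLabel("non_carrier"))
    return Cohort(records=records, labels=labels)


@pytest.fixture
def reference_record():
    return make_record()


@pytest.fixture
def small_cohort():
    return make_cohort()
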