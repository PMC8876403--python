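# drabc

Phenotype-based germline carrier-risk modelling for breast cancer patients.

The package predicts, from 25 encoded clinical/pathological features, the
probability that a patient carries a pathogenic germline variant in

* **any** cancer-predisposition gene (`P_a`),
* **BRCA1/2** specifically (`P_b`), and
* **another** predisposition gene (`P_c`),

using a hierarchical neural network with two sigmoid outputs `P1` (any
carrier) and `P2` (BRCA1/2 given carrier), combined by the chain rule
`P_a = P1`, `P_b = P1·P2`, `P_c = P1·(1−P2)` (so `P_b + P_c = P_a` always).
Each network is a 25→16→8→2 multilayer perceptron with SELU hidden
activations and 25% dropout during training; the production model is a
101-member bagged ensemble whose per-scenario decision cutoffs are chosen on
the training scores to reach 90% sensitivity (or the maximum attainable).

Also included:

* a **synthetic cohort generator** driven by a per-genotype-group frequency
  table (group prevalences 2596/131/132/43/26 of 2928; per-group age
  distributions and feature frequencies), so the whole pipeline is testable
  without patient data;
* **baseline comparators**: a genetic-testing eligibility rule engine (with an
  age ≤ 65 expansion), and logistic / naive-Bayes reconstructions of classic
  carrier-risk models on configurable variable subsets;
* **evaluation statistics**: ROC/AUC, DeLong confidence intervals and paired
  DeLong tests, confusion metrics with Youden's J, odds ratios
  (Woolf CI, Haldane–Anscombe correction), and per-group association tests
  (Student's t; Pearson χ² with a Fisher's-exact switch when an expected
  cell is below 5).

## Command line

```sh
# simulate a labeled cohort of 2432 patients
drabc simulate --n 2432 --seed 7 --out cohort.csv

# train the 101-member ensemble (writes a JSON model container)
drabc train --cohort cohort.csv --out-model model.json --seed 1

# score a cohort
drabc predict --model model.json --cohort cohort.csv --out predictions.csv

# evaluate the model, rule criteria and reconstructed baselines
drabc evaluate --model model.json --cohort cohort.csv --out-dir report/
```

All commands are deterministic given their seeds, and outputs are written
atomically.

## Cohort CSV schema

One row per patient, comma-separated, UTF-8, `.` decimal. Columns:

| column | values |
|---|---|
| `patient_id` | unique string |
| `age_at_diagnosis` | positive number (years) |
| `personal_any_cancer`, `personal_previous_breast`, `personal_ovarian` | `1`/`0`/`unknown` (blank = unknown) |
| `family_breast`, `family_ovarian`, `family_pancreas`, `family_prostate`, `family_esophageal`, `family_laryngeal`, `family_leukemia`, `family_male_breast`, `family_any` | `1`/`0`/`unknown` |
| `bilateral` | `1`/`0`/`unknown` |
| `tumor_size_class` | `le2cm`, `gt2cm`, `unknown` |
| `histology` | `idc`, `dcis`, `lobular`, `mucinous`, `medullary`, `other`, `unknown` |
| `grade` | `I`, `II`, `III`, `unknown` |
| `er`, `pr`, `ar`, `egfr`, `ck5_6` | `positive`, `negative`, `unknown` |
| `her2` | `positive`, `negative`, `uncertain`, `unknown` |
| `ki67_class` | `le30`, `gt30`, `unknown` |
| `p53_class` | `gain_of_function`, `loss_of_function`, `wildtype`, `unknown` |
| `lymph_nodes` | `positive`, `negative`, `unknown` |
| `variant_status` | `no_variant`, `pathogenic`, `vus_only`, `untested` |
| `carrier_group` | `non_carrier`, `brca1`, `brca2`, `other_hrr`, `other_cpg`; blank when unlabeled |

Triple-negative status is always *derived* from ER/PR/HER2, never stored.
Before training, `apply_exclusions` removes records with `vus_only` variant
status and records with any unknown required field (a record qualifying for
both is counted once, under VUS).

## The 25-feature encoding

The default `EncodingSpec` (serialized as JSON next to every model) encodes,
in order: standardized age `(age − 42.9)/9.1`; personal history any/previous
breast/ovarian; family history breast/ovarian/pancreas/male-breast/any;
bilaterality; tumor size > 2 cm; grade II and III indicators; IDC and DCIS
histology indicators; ER/PR/AR/EGFR/CK5-6 positivity; HER2 positive and
HER2 uncertain indicators; Ki67 > 30%; P53 gain-of-function; lymph-node
positivity. **Reference vector:** an all-negative, history-free patient at
the centering age encodes to the zero vector.

This list is a documented reconstruction (the original model's exact input
list is not public) built from the features that discriminate carrier groups
in the published cohort summary; it is config-overridable.

## Repository layout

```
src/drabc/cohort.py     records, CSV I/O, exclusions, encoding, splits
src/drabc/simulate.py   frequency table, synthetic cohorts, cohort summary
src/drabc/model.py      network, loss, ensemble training, cutoffs, CV, ablation
src/drabc/baselines.py  eligibility rules, logistic/naive-Bayes baselines
src/drabc/stats.py      ROC/AUC, DeLong, 2×2 metrics, association tests
src/drabc/cli.py        command-line interface
tests/                  unit, property and acceptance tests
scripts/acceptance.py   acceptance report generator
```
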