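"""Hierarchical two-output risk network, its ensemble training and prediction.

One network maps the encoded feature vector through two SELU hidden layers
(16 and 8 units, dropout 0.25 during training) to two sigmoid outputs
``P1`` (carrier of a pathogenic variant in any predisposition gene) and
``P2`` (BRCA1/2 given carrier).  Scenario probabilities follow the chain
rule: ``P_a = P1``, ``P_b = P1 * P2``, ``P_c = P1 * (1 - P2)``, so
``P_b + P_c = P_a`` identically.

The loss is hierarchical binary cross-entropy: ``BCE(P1, y_any) +
y_any * BCE(P2, y_brca)`` — the second term is masked out for non-carriers,
whose BRCA status is undefined.  Training is plain minibatch gradient
descent with adaptive moments, implemented directly in numpy (the model is
small enough that an autodiff framework would be overkill).  The ensemble
trains ``n_members`` networks on bootstrap resamples with consecutive seeds
and averages member probabilities; decision cutoffs per scenario are chosen
on the training scores to reach the target sensitivity (default 90%), or
the maximum attainable sensitivity otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cohort import (
    Cohort,
    CarrierLabel,
    EncodingSpec,
    FEATURE_GROUPS,
    default_encoding_spec,
    encode_cohort,
)
from .stats import roc_auc

__all__ = [
    "SELU_ALPHA",
    "SELU_LAMBDA",
    "selu",
    "HierarchicalNet",
    "TrainConfig",
    "EnsembleModel",
    "RiskPrediction",
    "forward",
    "derive_probabilities",
    "hierarchical_loss",
    "train_net",
    "train_ensemble",
    "select_cutoff",
    "predict",
    "cross_validate",
    "ablate_features",
    "scenario_labels",
    "SCENARIOS",
]

SELU_ALPHA = 1.6732632423543772
SELU_LAMBDA = 1.0507009873554805

SCENARIOS = ("any_cpg", "brca12", "other_cpg")

_EPS = 1e-12


def selu(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return SELU_LAMBDA * np.where(x > 0, x, SELU_ALPHA * np.expm1(x))


def _selu_grad(x: np.ndarray) -> np.ndarray:
    return SELU_LAMBDA * np.where(x > 0, 1.0, SELU_ALPHA * np.exp(x))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class HierarchicalNet:
    """Weights of one input->16->8->2 network (SELU hidden, sigmoid outputs)."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: np.ndarray
    dropout_rate: float = 0.25
    seed: int = 0
    history: list = field(default_factory=list)  # per-epoch mean training loss

    @classmethod
    def initialize(
        cls,
        n_inputs: int = 25,
        hidden: tuple[int, int] = (16, 8),
        dropout_rate: float = 0.25,
        seed: int = 0,
    ) -> "HierarchicalNet":
        """LeCun-normal initialization (variance 1/fan_in), suited to SELU."""
        rng = np.random.default_rng(seed)
        h1, h2 = hidden
        return cls(
            w1=rng.normal(0.0, 1.0 / np.sqrt(n_inputs), size=(n_inputs, h1)),
            b1=np.zeros(h1),
            w2=rng.normal(0.0, 1.0 / np.sqrt(h1), size=(h1, h2)),
            b2=np.zeros(h2),
            w3=rng.normal(0.0, 1.0 / np.sqrt(h2), size=(h2, 2)),
            b3=np.zeros(2),
            dropout_rate=dropout_rate,
            seed=seed,
        )

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[0]

    def params(self) -> list[np.ndarray]:
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]

    def forward_batch(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
        cache: bool = False,
    ):
        """Batch forward pass; returns (n, 2) probabilities, optionally a cache."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input")
        if x.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs, got {x.shape[1]}")
        z1 = x @ self.w1 + self.b1
        h1 = selu(z1)
        if train and self.dropout_rate > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            m1 = (rng.random(h1.shape) >= self.dropout_rate) / (1.0 - self.dropout_rate)
            h1 = h1 * m1
        else:
            m1 = None
        z2 = h1 @ self.w2 + self.b2
        h2 = selu(z2)
        if train and self.dropout_rate > 0:
            m2 = (rng.random(h2.shape) >= self.dropout_rate) / (1.0 - self.dropout_rate)
            h2 = h2 * m2
        else:
            m2 = None
        z3 = h2 @ self.w3 + self.b3
        p = _sigmoid(z3)
        if cache:
            return p, (x, z1, h1, m1, z2, h2, m2)
        return p

    def to_dict(self) -> dict:
        return {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "w3": self.w3.tolist(),
            "b3": self.b3.tolist(),
            "dropout_rate": self.dropout_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchicalNet":
        return cls(
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=np.asarray(d["b2"], dtype=float),
            w3=np.asarray(d["w3"], dtype=float),
            b3=np.asarray(d["b3"], dtype=float),
            dropout_rate=float(d["dropout_rate"]),
            seed=int(d["seed"]),
        )


def forward(
    net: HierarchicalNet,
    x: Sequence[float],
    mode: str = "infer",
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Single-record forward pass; dropout only in ``mode='train'``."""
    if mode not in ("train", "infer"):
        raise ValueError(f"mode={mode!r}")
    rng = np.random.default_rng(seed) if mode == "train" else None
    p = net.forward_batch(np.asarray(x, dtype=float).reshape(1, -1), train=(mode == "train"), rng=rng)
    return float(p[0, 0]), float(p[0, 1])


def derive_probabilities(p1: float, p2: float) -> tuple[float, float, float]:
    """Chain-rule scenario probabilities (P_a, P_b, P_c) from (P1, P2)."""
    p1 = float(p1)
    p2 = float(p2)
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError(f"P1={p1}, P2={p2} must lie in [0, 1]")
    return p1, p1 * p2, p1 * (1.0 - p2)


def _bce(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return -(y * np.log(p) + (1.0 - y) * np.log1p(-p))


def hierarchical_loss(p1: float, p2: float, label: CarrierLabel) -> float:
    """BCE(P1, y_any) + y_any * BCE(P2, y_brca); the P2 term is masked for
    non-carriers."""
    y_any = float(label.y_any)
    loss = float(_bce(np.asarray(p1, dtype=float), y_any))
    if label.y_any == 1:
        loss += float(_bce(np.asarray(p2, dtype=float), float(label.y_brca)))
    return loss


@dataclass
class TrainConfig:
    """Hyperparameters for single-net and ensemble training."""

    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 64
    dropout: float = 0.25
    hidden: tuple[int, int] = (16, 8)
    patience: int = 15
    tol: float = 1e-5
    n_members: int = 101
    bootstrap: bool = True
    aggregate: str = "mean"  # or "median"
    target_sensitivity: float = 0.90

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.aggregate not in ("mean", "median"):
            raise ValueError(f"aggregate={self.aggregate!r}")


def _train_arrays(
    x: np.ndarray,
    y_any: np.ndarray,
    y_brca: np.ndarray,
    config: TrainConfig,
    seed: int,
) -> HierarchicalNet:
    """Adam minibatch training on pre-encoded arrays.

    ``y_brca`` uses -1 for undefined (non-carrier) entries; those rows never
    contribute to the second loss term.
    """
    if len(np.unique(y_any)) < 2:
        raise ValueError("training requires both carrier and non-carrier records")
    net = HierarchicalNet.initialize(
        n_inputs=x.shape[1], hidden=config.hidden, dropout_rate=config.dropout, seed=seed
    )
    rng = np.random.default_rng(seed + 1_000_003)
    y1 = y_any.astype(float)
    y2 = np.where(y_brca < 0, 0.0, y_brca.astype(float))  # masked anyway
    mask2 = y1  # second term weighted by y_any

    params = net.params()
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = x.shape[0]
    best = np.inf
    stale = 0

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, y1b, y2b, m2b = x[idx], y1[idx], y2[idx], mask2[idx]
            p, (xc, z1, h1, m1, z2, h2, md2) = net.forward_batch(
                xb, train=True, rng=rng, cache=True
            )
            p1, p2 = p[:, 0], p[:, 1]
            loss = float(np.mean(_bce(p1, y1b) + m2b * _bce(p2, y2b)))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss * idx.size

            b = idx.size
            dz3 = np.column_stack([(p1 - y1b), m2b * (p2 - y2b)]) / b
            g_w3 = h2.T @ dz3
            g_b3 = dz3.sum(axis=0)
            dh2 = dz3 @ net.w3.T
            if md2 is not None:
                dh2 = dh2 * md2
            dz2 = dh2 * _selu_grad(z2)
            g_w2 = h1.T @ dz2
            g_b2 = dz2.sum(axis=0)
            dh1 = dz2 @ net.w2.T
            if m1 is not None:
                dh1 = dh1 * m1
            dz1 = dh1 * _selu_grad(z1)
            g_w1 = xc.T @ dz1
            g_b1 = dz1.sum(axis=0)

            grads = [g_w1, g_b1, g_w2, g_b2, g_w3, g_b3]
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for p_arr, g, m_arr, v_arr in zip(params, grads, m_t, v_t):
                m_arr *= beta1
                m_arr += (1 - beta1) * g
                v_arr *= beta2
                v_arr += (1 - beta2) * g * g
                p_arr -= lr_t * m_arr / (np.sqrt(v_arr) + eps)

        epoch_loss /= n
        net.history.append(epoch_loss)
        if epoch_loss < best - config.tol:
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return net


def train_net(
    cohort: Cohort,
    config: Optional[TrainConfig] = None,
    seed: int = 0,
    spec: Optional[EncodingSpec] = None,
) -> HierarchicalNet:
    """Train one network on an encoded labeled cohort (deterministic per seed)."""
    if config is None:
        config = TrainConfig()
    if spec is None:
        spec = default_encoding_spec()
    if not cohort.has_labels:
        raise ValueError("train_net requires labels")
    x = encode_cohort(cohort, spec)
    return _train_arrays(x, cohort.y_any(), cohort.y_brca(), config, seed)


def select_cutoff(
    scores: Sequence[float], labels: Sequence[int], target_sensitivity: float = 0.90
) -> float:
    """Largest candidate threshold reaching the target sensitivity.

    Candidates are the distinct scores; the call rule is score >= threshold.
    When no candidate reaches the target, the smallest candidate (maximum
    sensitivity) is returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    if pos.size == 0:
        raise ValueError("select_cutoff requires at least one positive label")
    candidates = np.unique(scores)[::-1]  # descending
    for tau in candidates:
        if np.mean(pos >= tau) >= target_sensitivity:
            return float(tau)
    return float(candidates[-1])


@dataclass(frozen=True)
class RiskPrediction:
    patient_id: str
    p_a: float
    p_b: float
    p_c: float
    call_any: bool
    call_brca: bool
    call_other: bool


@dataclass
class EnsembleModel:
    """Bag of trained networks plus thresholds and the feature encoding."""

    members: list[HierarchicalNet]
    encoding: EncodingSpec
    thresholds: dict[str, float]
    aggregate: str = "mean"
    training_meta: dict = field(default_factory=dict)
    input_mask: Optional[np.ndarray] = None  # zeroed-feature mask for ablations

    def member_probs(self, x: np.ndarray) -> np.ndarray:
        """(n_members, n, 2) member inference probabilities."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self.input_mask is not None:
            x = x * self.input_mask
        return np.stack([net.forward_batch(x, train=False) for net in self.members])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """(n, 3) array of (P_a, P_b, P_c) after member aggregation."""
        stacked = self.member_probs(x)
        if self.aggregate == "mean":
            p = stacked.mean(axis=0)
        else:
            p = np.median(stacked, axis=0)
        p1, p2 = p[:, 0], p[:, 1]
        return np.column_stack([p1, p1 * p2, p1 * (1.0 - p2)])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "drabc-ensemble-v1",
            "members": [net.to_dict() for net in self.members],
            "encoding": self.encoding.to_dict(),
            "thresholds": self.thresholds,
            "aggregate": self.aggregate,
            "training_meta": self.training_meta,
            "input_mask": None if self.input_mask is None else self.input_mask.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "drabc-ensemble-v1":
            raise ValueError(f"{path}: not an ensemble model file")
        mask = payload.get("input_mask")
        return cls(
            members=[HierarchicalNet.from_dict(d) for d in payload["members"]],
            encoding=EncodingSpec.from_dict(payload["encoding"]),
            thresholds={k: float(v) for k, v in payload["thresholds"].items()},
            aggregate=payload.get("aggregate", "mean"),
            training_meta=payload.get("training_meta", {}),
            input_mask=None if mask is None else np.asarray(mask, dtype=float),
        )


def scenario_labels(cohort: Cohort, scenario: str) -> np.ndarray:
    """Binary ground truth per scenario: any carrier / BRCA1-2 / other CPG."""
    groups = cohort.groups()
    if scenario == "any_cpg":
        return cohort.y_any()
    if scenario == "brca12":
        return np.isin(groups, ["brca1", "brca2"]).astype(int)
    if scenario == "other_cpg":
        return np.isin(groups, ["other_hrr", "other_cpg"]).astype(int)
    raise ValueError(f"unknown scenario {scenario!r}")


_SCENARIO_COLUMN = {"any_cpg": 0, "brca12": 1, "other_cpg": 2}


def train_ensemble(
    cohort: Cohort,
    config: Optional[TrainConfig] = None,
    seed: int = 0,
    spec: Optional[EncodingSpec] = None,
    input_mask: Optional[np.ndarray] = None,
) -> EnsembleModel:
    """Train the bagged ensemble and fix per-scenario cutoffs on training scores."""
    if config is None:
        config = TrainConfig()
    if spec is None:
        spec = default_encoding_spec()
    if not cohort.has_labels:
        raise ValueError("train_ensemble requires labels")
    x = encode_cohort(cohort, spec)
    if input_mask is not None:
        input_mask = np.asarray(input_mask, dtype=float)
        if input_mask.shape != (x.shape[1],):
            raise ValueError("input_mask length must equal the encoded width")
        x = x * input_mask
    y_any = cohort.y_any()
    y_brca = cohort.y_brca()
    n = x.shape[0]

    members: list[HierarchicalNet] = []
    for i in range(config.n_members):
        member_seed = seed + i
        if config.bootstrap:
            boot_rng = np.random.default_rng(member_seed)
            for _ in range(100):
                idx = boot_rng.integers(0, n, size=n)
                if len(np.unique(y_any[idx])) == 2:
                    break
            else:
                raise RuntimeError("bootstrap failed to include both classes")
        else:
            idx = np.arange(n)
        members.append(_train_arrays(x[idx], y_any[idx], y_brca[idx], config, member_seed))

    model = EnsembleModel(
        members=members,
        encoding=spec,
        thresholds={},
        aggregate=config.aggregate,
        training_meta={
            "seed": seed,
            "n_members": config.n_members,
            "n_train": n,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
            },
        },
        input_mask=input_mask,
    )
    # predict_proba applies the stored mask itself, so score the raw encoding
    probs = model.predict_proba(encode_cohort(cohort, spec))
    for scenario in SCENARIOS:
        labels = scenario_labels(cohort, scenario)
        if labels.sum() == 0:
            model.thresholds[scenario] = 0.5
            model.training_meta.setdefault("warnings", []).append(
                f"no positives for {scenario}; cutoff defaulted to 0.5"
            )
            continue
        model.thresholds[scenario] = select_cutoff(
            probs[:, _SCENARIO_COLUMN[scenario]], labels, config.target_sensitivity
        )
    return model


def predict(model: EnsembleModel, cohort: Cohort) -> list[RiskPrediction]:
    """Score every record; inference mode, calls at the model thresholds."""
    probs = model.predict_proba(encode_cohort(cohort, model.encoding))
    out = []
    for record, (p_a, p_b, p_c) in zip(cohort.records, probs):
        out.append(
            RiskPrediction(
                patient_id=record.patient_id,
                p_a=float(p_a),
                p_b=float(p_b),
                p_c=float(p_c),
                call_any=bool(p_a >= model.thresholds["any_cpg"]),
                call_brca=bool(p_b >= model.thresholds["brca12"]),
                call_other=bool(p_c >= model.thresholds["other_cpg"]),
            )
        )
    return out


def cross_validate(
    cohort: Cohort,
    k: int = 5,
    config: Optional[TrainConfig] = None,
    seed: int = 0,
    spec: Optional[EncodingSpec] = None,
) -> dict:
    """Stratified k-fold ensemble cross-validation; per-fold and mean AUCs."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if not cohort.has_labels:
        raise ValueError("cross_validate requires labels")
    if config is None:
        config = TrainConfig()
    if spec is None:
        spec = default_encoding_spec()
    groups = cohort.groups()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold_idx, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(cohort)), groups)):
        train = cohort.subset(train_idx.tolist())
        test = cohort.subset(test_idx.tolist())
        model = train_ensemble(train, config=config, seed=seed + 10_000 * (fold_idx + 1), spec=spec)
        probs = model.predict_proba(encode_cohort(test, spec))
        fold_report: dict = {"fold": fold_idx, "n_test": len(test), "test_index": test_idx.tolist(), "auc": {}}
        for scenario in SCENARIOS:
            labels = scenario_labels(test, scenario)
            if labels.sum() == 0 or labels.sum() == labels.size:
                fold_report["auc"][scenario] = None
                fold_report.setdefault("flags", []).append(
                    f"{scenario}: single-class fold, AUC undefined"
                )
            else:
                _, auc = roc_auc(probs[:, _SCENARIO_COLUMN[scenario]], labels)
                fold_report["auc"][scenario] = auc
        folds.append(fold_report)
    mean_auc = {}
    for scenario in SCENARIOS:
        vals = [f["auc"][scenario] for f in folds if f["auc"][scenario] is not None]
        mean_auc[scenario] = float(np.mean(vals)) if vals else None
    return {"folds": folds, "mean_auc": mean_auc, "k": k, "seed": seed}


def ablate_features(
    train_cohort: Cohort,
    test_cohort: Cohort,
    feature_groups: Sequence[str] = ("family_history", "pathology"),
    config: Optional[TrainConfig] = None,
    seed: int = 0,
    spec: Optional[EncodingSpec] = None,
    custom_groups: Optional[dict[str, Sequence[str]]] = None,
) -> dict:
    """Retrain with named feature blocks zeroed and report test AUC deltas.

    Group names resolve through ``custom_groups`` first, then the built-in
    registry (``family_history``, ``pathology``); an empty feature tuple is a
    valid no-op ablation.
    """
    if config is None:
        config = TrainConfig()
    if spec is None:
        spec = default_encoding_spec()
    registry = dict(FEATURE_GROUPS)
    if custom_groups:
        registry.update({k: tuple(v) for k, v in custom_groups.items()})
    for name in feature_groups:
        if name not in registry:
            raise ValueError(f"unknown feature group {name!r}")

    x_test = encode_cohort(test_cohort, spec)

    def run(mask: Optional[np.ndarray], run_seed: int) -> dict:
        model = train_ensemble(
            train_cohort, config=config, seed=run_seed, spec=spec, input_mask=mask
        )
        probs = model.predict_proba(x_test)
        aucs = {}
        for scenario in SCENARIOS:
            labels = scenario_labels(test_cohort, scenario)
            if 0 < labels.sum() < labels.size:
                _, aucs[scenario] = roc_auc(probs[:, _SCENARIO_COLUMN[scenario]], labels)
            else:
                aucs[scenario] = None
        return aucs

    baseline = run(None, seed)
    report = {"baseline": baseline, "ablations": {}}
    for name in feature_groups:
        mask = np.ones(spec.n_features)
        for feat in registry[name]:
            if feat not in spec.feature_order:
                raise ValueError(f"feature {feat!r} not in the encoding spec")
            mask[spec.feature_order.index(feat)] = 0.0
        aucs = run(mask, seed)
        deltas = {
            s: (None if aucs[s] is None or baseline[s] is None else aucs[s] - baseline[s])
            for s in SCENARIOS
        }
        report["ablations"][name] = {"auc": aucs, "delta_auc": deltas}
    return report
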