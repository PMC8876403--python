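import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drabc.cohort import CarrierLabel, Cohort, default_encoding_spec, encode_cohort
from drabc.model import (
    SELU_ALPHA,
    SELU_LAMBDA,
    EnsembleModel,
    HierarchicalNet,
    TrainConfig,
    ablate_features,
    cross_validate,
    derive_probabilities,
    forward,
    hierarchical_loss,
    predict,
    select_cutoff,
    selu,
    train_ensemble,
    train_net,
)
from drabc.simulate import generate_cohort

from conftest import make_cohort, make_record


FAST = TrainConfig(epochs=30, n_members=3, patience=30)


def brute_force_cutoff(scores, labels, target):
    """Independent oracle: scan every candidate threshold exhaustively."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    best = None
    for tau in sorted(set(scores.tolist()), reverse=True):
        if np.mean(pos >= tau) >= target:
            return tau
    return min(scores.tolist())


def separable_cohort(n=50):
    """Carriers have every flag set and old age; non-carriers the opposite."""
    records, labels = [], []
    for i in range(n):
        carrier = i % 2 == 0
        overrides = dict(
            age=70.0 if not carrier else 25.0,
            er="positive" if not carrier else "negative",
            grade="I" if not carrier else "III",
            family_breast=carrier,
            family_any=carrier,
            ki67_class="gt30" if carrier else "le30",
        )
        records.append(make_record(f"S{i}", **overrides))
        labels.append(CarrierLabel("brca1" if carrier else "non_carrier"))
    return Cohort(records=records, labels=labels)


class TestSELU:
    def test_selu_zero(self):
        assert selu(0.0) == 0.0

    def test_selu_closed_form_negative(self):
        # lambda * alpha * (exp(-10) - 1)
        expected = SELU_LAMBDA * SELU_ALPHA * (np.exp(-10.0) - 1.0)
        assert selu(-10.0) == pytest.approx(expected, rel=1e-12)
        assert selu(-10.0) == pytest.approx(-1.7580, abs=5e-4)

    def test_selu_positive_linear(self):
        assert selu(3.0) == pytest.approx(SELU_LAMBDA * 3.0)


class TestForward:
    def test_zero_weights_give_half(self):
        net = HierarchicalNet.initialize(seed=0)
        for p in net.params():
            p[...] = 0.0
        p1, p2 = forward(net, np.zeros(25))
        assert p1 == 0.5 and p2 == 0.5

    def test_zero_input_zero_bias_propagates_zero(self):
        net = HierarchicalNet.initialize(seed=1)
        net.b1[...] = 0.0
        net.b2[...] = 0.0
        net.b3[...] = 0.0
        p1, p2 = forward(net, np.zeros(25))
        assert p1 == 0.5 and p2 == 0.5

    def test_layer_shapes(self):
        net = HierarchicalNet.initialize()
        assert net.w1.shape == (25, 16)
        assert net.w2.shape == (16, 8)
        assert net.w3.shape == (8, 2)

    def test_outputs_in_unit_interval(self):
        net = HierarchicalNet.initialize(seed=2)
        rng = np.random.default_rng(0)
        p = net.forward_batch(rng.normal(size=(100, 25)))
        assert np.all((p > 0) & (p < 1))

    def test_infer_deterministic_train_stochastic(self):
        net = HierarchicalNet.initialize(seed=3)
        x = np.ones(25)
        assert forward(net, x) == forward(net, x)
        assert forward(net, x, mode="train", seed=1) != forward(net, x, mode="train", seed=2)

    def test_non_finite_input_rejected(self):
        net = HierarchicalNet.initialize()
        with pytest.raises(ValueError, match="finite"):
            forward(net, np.full(25, np.nan))


class TestDeriveProbabilities:
    def test_midpoint(self):
        assert derive_probabilities(0.5, 0.5) == (0.5, 0.25, 0.25)

    def test_boundary(self):
        assert derive_probabilities(1.0, 1.0) == (1.0, 1.0, 0.0)

    def test_identity_random(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p1, p2 = rng.random(2)
            pa, pb, pc = derive_probabilities(p1, p2)
            assert abs(pb + pc - pa) < 1e-12

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            derive_probabilities(1.2, 0.5)
        with pytest.raises(ValueError):
            derive_probabilities(0.5, -0.1)


class TestHierarchicalLoss:
    def test_perfect_prediction_vanishes(self):
        assert hierarchical_loss(1 - 1e-12, 1 - 1e-12, CarrierLabel("brca1")) < 1e-9
        assert hierarchical_loss(1e-12, 0.3, CarrierLabel("non_carrier")) < 1e-9

    def test_non_carrier_half_is_ln2(self):
        for p2 in (0.1, 0.5, 0.9):
            assert hierarchical_loss(0.5, p2, CarrierLabel("non_carrier")) == pytest.approx(
                np.log(2)
            )

    def test_p2_gradient_masked_for_non_carrier(self):
        # central finite differences in p2 must be ~0 when y_any = 0
        lab = CarrierLabel("non_carrier")
        h = 1e-6
        grad = (hierarchical_loss(0.4, 0.5 + h, lab) - hierarchical_loss(0.4, 0.5 - h, lab)) / (
            2 * h
        )
        assert grad == pytest.approx(0.0, abs=1e-9)

    def test_p2_gradient_active_for_carrier(self):
        lab = CarrierLabel("brca1")
        h = 1e-6
        grad = (hierarchical_loss(0.4, 0.5 + h, lab) - hierarchical_loss(0.4, 0.5 - h, lab)) / (
            2 * h
        )
        # d/dp2 of -log(p2) at 0.5 is -2
        assert grad == pytest.approx(-2.0, rel=1e-4)


class TestSelectCutoff:
    def test_perfectly_separated(self):
        scores = [0.9] * 5 + [0.1] * 5
        labels = [1] * 5 + [0] * 5
        tau = select_cutoff(scores, labels)
        assert tau == 0.9
        assert np.mean(np.array(scores)[np.array(labels) == 1] >= tau) == 1.0

    def test_decile_example(self):
        scores = [(i + 1) / 10 for i in range(10)]
        labels = [1] * 10
        assert select_cutoff(scores, labels, 0.90) == pytest.approx(0.2)

    def test_all_identical(self):
        assert select_cutoff([0.3, 0.3, 0.3], [1, 0, 1]) == 0.3

    def test_no_positives_errors(self):
        with pytest.raises(ValueError):
            select_cutoff([0.1, 0.2], [0, 0])

    @given(
        st.lists(st.floats(0, 1, width=32), min_size=2, max_size=8),
        st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if sum(labels) == 0:
            labels[0] = 1
        target = data.draw(st.sampled_from([0.5, 0.75, 0.9, 1.0]))
        assert select_cutoff(scores, labels, target) == brute_force_cutoff(
            scores, labels, target
        )

    def test_achieves_target_whenever_possible(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            scores = rng.random(8)
            labels = rng.integers(0, 2, 8)
            if labels.sum() == 0:
                labels[0] = 1
            tau = select_cutoff(scores, labels, 0.9)
            attainable = any(
                np.mean(scores[labels == 1] >= t) >= 0.9 for t in np.unique(scores)
            )
            sens = np.mean(scores[labels == 1] >= tau)
            if attainable:
                assert sens >= 0.9


class TestTrainNet:
    def test_deterministic(self):
        cohort = make_cohort(n=30, n_carriers=8)
        cfg = TrainConfig(epochs=5, patience=10)
        n1 = train_net(cohort, cfg, seed=4)
        n2 = train_net(cohort, cfg, seed=4)
        for a, b in zip(n1.params(), n2.params()):
            np.testing.assert_array_equal(a, b)

    def test_single_class_errors(self):
        cohort = make_cohort(n=10, n_carriers=0)
        with pytest.raises(ValueError, match="carrier"):
            train_net(cohort, TrainConfig(epochs=2), seed=0)

    def test_loss_decreases_without_dropout(self):
        # full-batch, no dropout, small lr: loss should trend downward
        cohort = separable_cohort(50)
        cfg = TrainConfig(
            epochs=40, batch_size=50, learning_rate=1e-3, dropout=0.0, patience=100
        )
        net = train_net(cohort, cfg, seed=0)
        assert net.history[-1] < net.history[0]
        diffs = np.diff(net.history)
        assert np.max(diffs) < 1e-2  # near-monotone descent

    def test_separable_cohort_high_auc(self):
        cohort = separable_cohort(60)
        cfg = TrainConfig(epochs=120, dropout=0.0, patience=200, batch_size=16)
        net = train_net(cohort, cfg, seed=1)
        x = encode_cohort(cohort, default_encoding_spec())
        p = net.forward_batch(x)
        from drabc.stats import roc_auc

        _, auc = roc_auc(p[:, 0], cohort.y_any())
        assert auc > 0.99


class TestEnsemble:
    def test_member_count_default_config(self):
        assert TrainConfig().n_members == 101

    def test_members_respected(self):
        cohort = make_cohort(n=30, n_carriers=8)
        model = train_ensemble(cohort, TrainConfig(epochs=3, n_members=4), seed=0)
        assert len(model.members) == 4

    def test_identical_members_equal_single_net(self):
        cohort = make_cohort(n=30, n_carriers=8)
        cfg = TrainConfig(epochs=5, n_members=1, bootstrap=False)
        single = train_ensemble(cohort, cfg, seed=7)
        tripled = EnsembleModel(
            members=[single.members[0]] * 3,
            encoding=single.encoding,
            thresholds=dict(single.thresholds),
        )
        x = encode_cohort(cohort, single.encoding)
        np.testing.assert_allclose(
            single.predict_proba(x), tripled.predict_proba(x), atol=1e-12
        )

    def test_ensemble_pa_is_mean_of_member_p1(self):
        cohort = make_cohort(n=40, n_carriers=10)
        model = train_ensemble(cohort, TrainConfig(epochs=4, n_members=5), seed=1)
        x = encode_cohort(cohort, model.encoding)
        stacked = model.member_probs(x)
        np.testing.assert_allclose(
            model.predict_proba(x)[:, 0], stacked[:, :, 0].mean(axis=0), atol=1e-12
        )

    def test_probability_identity_on_predictions(self):
        cohort = make_cohort(n=25, n_carriers=6)
        model = train_ensemble(cohort, TrainConfig(epochs=4, n_members=3), seed=2)
        for p in predict(model, cohort):
            assert p.p_b + p.p_c == pytest.approx(p.p_a, abs=1e-9)
            assert p.p_b <= p.p_a + 1e-12 and p.p_c <= p.p_a + 1e-12

    def test_prediction_deterministic(self):
        cohort = make_cohort(n=20, n_carriers=5)
        model = train_ensemble(cohort, TrainConfig(epochs=3, n_members=3), seed=3)
        assert predict(model, cohort) == predict(model, cohort)

    def test_threshold_monotonicity(self):
        cohort = generate_cohort(300, seed=21)
        model = train_ensemble(cohort, TrainConfig(epochs=10, n_members=3), seed=4)
        x = encode_cohort(cohort, model.encoding)
        pa = model.predict_proba(x)[:, 0]
        calls = [int(np.sum(pa >= tau)) for tau in (0.8, 0.5, 0.2, 0.05)]
        assert calls == sorted(calls)

    def test_training_sensitivity_reaches_target(self):
        cohort = generate_cohort(800, seed=22)
        cfg = TrainConfig(epochs=25, n_members=5, target_sensitivity=0.90)
        model = train_ensemble(cohort, cfg, seed=5)
        x = encode_cohort(cohort, model.encoding)
        probs = model.predict_proba(x)
        y = cohort.y_any()
        sens = np.mean(probs[y == 1, 0] >= model.thresholds["any_cpg"])
        assert sens >= 0.90

    def test_json_round_trip(self, tmp_path):
        cohort = make_cohort(n=20, n_carriers=5)
        model = train_ensemble(cohort, TrainConfig(epochs=3, n_members=2), seed=6)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = EnsembleModel.from_json(path)
        x = encode_cohort(cohort, model.encoding)
        np.testing.assert_allclose(model.predict_proba(x), back.predict_proba(x), atol=1e-12)
        assert back.thresholds == model.thresholds


class TestCrossValidate:
    def test_partition_and_stratification(self):
        cohort = generate_cohort(300, seed=31)
        rep = cross_validate(cohort, k=3, config=TrainConfig(epochs=4, n_members=2), seed=0)
        all_idx = np.concatenate([f["test_index"] for f in rep["folds"]])
        assert sorted(all_idx.tolist()) == list(range(len(cohort)))
        overall = cohort.y_any().mean()
        for f in rep["folds"]:
            fold_frac = cohort.subset(f["test_index"]).y_any().mean()
            assert abs(fold_frac * f["n_test"] - overall * f["n_test"]) <= 2.0

    def test_same_seed_same_folds(self):
        cohort = generate_cohort(150, seed=32)
        cfg = TrainConfig(epochs=2, n_members=1)
        r1 = cross_validate(cohort, k=3, config=cfg, seed=9)
        r2 = cross_validate(cohort, k=3, config=cfg, seed=9)
        for f1, f2 in zip(r1["folds"], r2["folds"]):
            assert f1["test_index"] == f2["test_index"]

    def test_k_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            cross_validate(make_cohort(), k=1)


class TestAblation:
    def test_unknown_group_errors(self):
        cohort = generate_cohort(100, seed=41)
        with pytest.raises(ValueError, match="unknown feature group"):
            ablate_features(cohort, cohort, feature_groups=("nope",), config=FAST)

    def test_empty_group_is_noop(self):
        train = generate_cohort(250, seed=42)
        test = generate_cohort(150, seed=43)
        rep = ablate_features(
            train,
            test,
            feature_groups=("nothing",),
            custom_groups={"nothing": ()},
            config=TrainConfig(epochs=6, n_members=2),
            seed=0,
        )
        base = rep["baseline"]["any_cpg"]
        assert rep["ablations"]["nothing"]["auc"]["any_cpg"] == pytest.approx(base)

    def test_ablating_everything_kills_signal(self):
        train = generate_cohort(400, seed=44)
        test = generate_cohort(300, seed=45)
        spec = default_encoding_spec()
        rep = ablate_features(
            train,
            test,
            feature_groups=("all",),
            custom_groups={"all": spec.feature_order},
            config=TrainConfig(epochs=8, n_members=2),
            seed=1,
        )
        auc = rep["ablations"]["all"]["auc"]["any_cpg"]
        assert abs(auc - 0.5) < 0.1
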