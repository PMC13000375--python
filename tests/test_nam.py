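import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocalrisk import nam as N
from vocalrisk.errors import DivergenceError, VocalRiskError
from vocalrisk.features import PatientFeatures

from conftest import make_feature_cohort

QUICK = dict(lr_grid=(3e-3,), epoch_grid=(150,), hidden=(16, 16))


def _zeroed_model(panel, b3=None, beta=0.0):
    f = len(panel)
    weights = {"W1": np.zeros((f, 3, 4), np.float32),
               "b1": np.zeros((f, 4), np.float32),
               "W2": np.zeros((f, 4, 4), np.float32),
               "b2": np.zeros((f, 4), np.float32),
               "W3": np.zeros((f, 4), np.float32),
               "b3": np.zeros(f, np.float32) if b3 is None
               else np.asarray(b3, np.float32)}
    return N.NAMModel(panel=panel, weights=weights,
                      feat_mean=np.zeros(f), feat_sd=np.ones(f),
                      age_mean=65.0, age_sd=10.0, beta=beta)


class TestForward:
    def test_all_zero_outputs_give_half(self):
        m = _zeroed_model(["a", "b"])
        assert N.forward_risk(m, {"a": 1.0, "b": -2.0}, 70, "male") == pytest.approx(0.5)

    def test_closed_form_sigmoid(self):
        m = _zeroed_model(["a", "b"], b3=[0.3, -0.1], beta=0.2)
        score = N.forward_risk(m, {"a": 0.0, "b": 0.0}, 65, "female")
        assert score == pytest.approx(1 / (1 + np.exp(-0.4)), abs=1e-6)

    def test_saturation_at_large_offset(self):
        m = _zeroed_model(["a"], beta=50.0)
        assert N.forward_risk(m, {"a": 0.0}, 65, 0) > 0.999999

    def test_missing_feature_named_in_error(self):
        m = _zeroed_model(["a", "b"])
        with pytest.raises(VocalRiskError, match="b"):
            N.forward_risk(m, {"a": 1.0}, 65, 1)


class TestTraining:
    def test_separable_data_high_training_auc(self, rng):
        data = make_feature_cohort(70, 130, rng, shift=3.0, n_features=4)
        model = N.train_nam(data, N.TrainConfig(seed=1, **QUICK))
        feats, age, sex, y = N.design_matrices(data, model.panel)
        assert N.fast_auc(model.score(feats, age, sex), y) >= 0.99

    def test_determinism_same_seed(self, rng):
        data = make_feature_cohort(40, 80, rng, n_features=4)
        cfg = N.TrainConfig(seed=5, **QUICK)
        m1, m2 = N.train_nam(data, cfg), N.train_nam(data, cfg)
        feats, age, sex, _ = N.design_matrices(data, m1.panel)
        assert np.max(np.abs(m1.score(feats, age, sex)
                             - m2.score(feats, age, sex))) < 1e-6

    def test_single_class_rejected(self, rng):
        data = make_feature_cohort(0, 30, rng, n_features=3)
        data = [p for p in data if p.risk_label == "low"]
        with pytest.raises(VocalRiskError):
            N.train_nam(data, N.TrainConfig(seed=0, **QUICK))

    def test_oversampling_balances_counts(self, rng):
        y = np.array([1] * 30 + [0] * 90)
        idx = N.oversample_minority(y, rng)
        assert np.sum(y[idx] == 1) == 90
        assert np.sum(y[idx] == 0) == 90

    def test_nan_input_raises_divergence(self):
        net = N.ParallelNAM(1, 2, hidden=(4, 4), seed=0)
        X = np.full((1, 10, 2, 3), np.nan, np.float32)
        y = np.zeros((1, 10), np.float32)
        with pytest.raises(DivergenceError):
            net.fit(X, y, lr=1e-2, epochs=10)

    def test_save_load_round_trip(self, rng, tmp_path):
        data = make_feature_cohort(30, 60, rng, n_features=3)
        model = N.train_nam(data, N.TrainConfig(seed=2, **QUICK))
        model.save(tmp_path / "m.npz")
        back = N.NAMModel.load(tmp_path / "m.npz")
        feats, age, sex, _ = N.design_matrices(data, model.panel)
        assert np.allclose(back.score(feats, age, sex),
                           model.score(feats, age, sex))
        assert back.metadata["lr"] == model.metadata["lr"]


class TestAdditivity:
    def test_changing_one_feature_moves_only_its_subnetwork(self, rng):
        data = make_feature_cohort(30, 60, rng, n_features=4)
        model = N.train_nam(data, N.TrainConfig(seed=3, **QUICK))
        feats, age, sex, _ = N.design_matrices(data, model.panel)
        g0 = model.contributions(feats, age, sex)
        feats2 = feats.copy()
        feats2[:, 1] += 1.0
        g1 = model.contributions(feats2, age, sex)
        others = [k for k in range(4) if k != 1]
        assert np.allclose(g0[:, others], g1[:, others])
        assert not np.allclose(g0[:, 1], g1[:, 1])

    @settings(max_examples=30, deadline=None)
    @given(vals=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
           age=st.floats(20, 100), sex=st.integers(0, 1))
    def test_score_bounds_property(self, vals, age, sex):
        m = _zeroed_model(["a", "b", "c"], b3=[5.0, -7.0, 2.0], beta=1.0)
        feats = {"a": vals[0], "b": vals[1], "c": vals[2]}
        score = N.forward_risk(m, feats, age, sex)
        assert 0.0 < score < 1.0


class TestImportance:
    def test_zero_weight_subnetwork_zero_importance(self):
        m = _zeroed_model(["a", "b"])
        data = [PatientFeatures("p", 65, "male", "high",
                                {"a": 1.0, "b": 2.0})]
        imp = N.feature_importance(m, data)
        assert imp["a"] == 0.0 and imp["b"] == 0.0

    def test_planted_signal_ranks_first(self, rng):
        data = make_feature_cohort(60, 120, rng, shift=2.5,
                                   signal_features=("f0",), n_features=5)
        model = N.train_nam(data, N.TrainConfig(seed=4, **QUICK))
        imp = N.feature_importance(model, data)
        assert max(imp, key=imp.get) == "f0"

    def test_duplicated_feature_near_equal_importance(self, rng):
        data = make_feature_cohort(60, 120, rng, shift=2.0,
                                   signal_features=("f0",), n_features=2)
        for p in data:
            p.features["f1"] = p.features["f0"]
        model = N.train_nam(data, N.TrainConfig(seed=6, **QUICK))
        imp = N.feature_importance(model, data)
        hi, lo = max(imp["f0"], imp["f1"]), min(imp["f0"], imp["f1"])
        assert hi <= 2.0 * lo


class TestConfoundAdjustment:
    def test_age_only_signal_vanishes_on_matched_pairs(self):
        # age alone drives the label; acoustic features are pure noise
        rng = np.random.default_rng(12)
        data = []
        for i in range(480):
            hi = i < 200
            age = float(rng.normal(72 if hi else 60, 8))
            feats = {f"f{k}": float(rng.normal()) for k in range(4)}
            data.append(PatientFeatures(f"p{i}", age,
                                        "male" if rng.random() < 0.5 else "female",
                                        "high" if hi else "low", feats))
        train, test = data[::2], data[1::2]
        model = N.train_nam(train, N.TrainConfig(seed=0, **QUICK))
        feats, age, sex, y = N.design_matrices(test, model.panel)
        scores = model.score(feats, age, sex)
        unmatched = N.fast_auc(scores, y)
        assert unmatched > 0.6  # the age covariate carries the label

        # age-matched pairs: nearest low-risk patient within 1.5 years
        hi_idx = np.flatnonzero(y == 1)
        lo_idx = np.flatnonzero(y == 0)
        used, pairs = set(), []
        for i in hi_idx:
            diffs = np.abs(age[lo_idx] - age[i])
            order = np.argsort(diffs)
            for j in order:
                cand = lo_idx[j]
                if cand not in used and diffs[j] <= 1.5:
                    used.add(cand)
                    pairs.append((i, cand))
                    break
        assert len(pairs) >= 30
        sel = np.array([i for pair in pairs for i in pair])
        matched = N.fast_auc(scores[sel], y[sel])
        assert 0.4 <= matched <= 0.6
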