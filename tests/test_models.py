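"""Two-branch estimators: sharing, freezing, early stopping, and transfer."""

import numpy as np
import pytest
from sklearn.base import clone

from cliffdti.models import (ActivityCliffClassifier, AffinityRegressor,
                             TransferPlan, ac_design_matrix, dti_design_matrix,
                             encode_target_onehot, load_model, random_search,
                             repeat_train, transfer_encoders)

N_BITS = 32
VOCAB = ["T0", "T1", "T2"]


def _toy_ac_data(n=200, seed=0):
    """Pairs whose label is a simple function of the fingerprints.

    Label 1 iff either member carries the marked bit 0 — a symmetric rule
    a shared encoder can represent and generalize.
    """
    rng = np.random.default_rng(seed)
    X = np.zeros((n, 2 * N_BITS + len(VOCAB)))
    y = np.zeros(n)
    for i in range(n):
        fa = (rng.random(N_BITS) < 0.5).astype(float)
        fb = (rng.random(N_BITS) < 0.5).astype(float)
        y[i] = float(fa[0] + fb[0] >= 1)
        X[i, :N_BITS] = fa
        X[i, N_BITS:2 * N_BITS] = fb
        X[i, 2 * N_BITS + rng.integers(len(VOCAB))] = 1.0
    return X, y


def _toy_dti_data(n=150, seed=0):
    """Affinity = 5 + weighted bit sum + target offset, noiseless."""
    rng = np.random.default_rng(seed)
    w = rng.normal(size=N_BITS)
    offsets = np.array([0.0, 1.0, -1.0])
    X = np.zeros((n, N_BITS + len(VOCAB)))
    y = np.zeros(n)
    for i in range(n):
        fp = (rng.random(N_BITS) < 0.5).astype(float)
        t = rng.integers(len(VOCAB))
        X[i, :N_BITS] = fp
        X[i, N_BITS + t] = 1.0
        y[i] = 5.0 + fp @ w * 0.3 + offsets[t]
    return X, y


FAST = dict(n_bits=N_BITS, encoder_hidden_dims=(16,), embedding_dim=8,
            protein_embedding_dim=4, head_hidden_dims=(8,), max_epochs=30,
            patience=30, batch_size=32, random_state=0)


class TestDesignMatrices:
    def test_onehot_round_trip_and_unseen_target(self):
        v = encode_target_onehot("T1", VOCAB)
        assert v.tolist() == [0.0, 1.0, 0.0]
        with pytest.raises(KeyError):
            encode_target_onehot("T9", VOCAB)

    def test_ac_matrix_layout(self, small_dataset, mined_pairs):
        _, library, records, _ = small_dataset
        vocab = sorted({r.target_id for r in records})
        X, y = ac_design_matrix(mined_pairs[:5], library, vocab)
        n_bits = len(next(iter(library.values())).fingerprint)
        assert X.shape == (5, 2 * n_bits + len(vocab))
        p = mined_pairs[0]
        assert np.array_equal(X[0, :n_bits], library[p.compound_a].fingerprint)
        assert np.array_equal(X[0, n_bits:2 * n_bits],
                              library[p.compound_b].fingerprint)
        assert X[0, 2 * n_bits:].sum() == 1.0
        assert y[0] == p.label

    def test_dti_matrix_layout(self, small_dataset):
        _, library, records, _ = small_dataset
        vocab = sorted({r.target_id for r in records})
        X, y, t = dti_design_matrix(records[:7], library, vocab)
        n_bits = len(next(iter(library.values())).fingerprint)
        assert X.shape == (7, n_bits + len(vocab))
        assert list(t) == [r.target_id for r in records[:7]]
        assert y[3] == records[3].affinity


class TestTransferPlan:
    def test_valid_modes(self):
        TransferPlan("warm_start", "drug_only")
        TransferPlan("freeze", "drug_and_target")
        TransferPlan("freeze_plus_layer", "drug_only", extra_layer_dim=8)

    @pytest.mark.parametrize("kwargs", [
        {"mode": "finetune"},
        {"encoders": "both"},
        {"mode": "freeze", "extra_layer_dim": 8},
        {"mode": "freeze_plus_layer"},
    ])
    def test_invalid_plans(self, kwargs):
        with pytest.raises(ValueError):
            TransferPlan(**{"mode": "warm_start", "encoders": "drug_and_target",
                            **kwargs})


class TestClassifier:
    def test_learns_toy_rule(self):
        X, y = _toy_ac_data()
        clf = ActivityCliffClassifier(
            **{**FAST, "max_epochs": 100, "patience": 100}).fit(X, y)
        Xt, yt = _toy_ac_data(n=100, seed=1)
        acc = np.mean(clf.predict(Xt) == yt)
        assert acc > 0.8

    def test_probabilities_valid_and_consistent(self):
        X, y = _toy_ac_data(n=60)
        clf = ActivityCliffClassifier(**FAST).fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (60, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert np.array_equal(clf.predict(X), (proba[:, 1] >= 0.5).astype(int))

    def test_shared_compound_encoder_is_one_group(self):
        X, y = _toy_ac_data(n=40)
        clf = ActivityCliffClassifier(**FAST).fit(X, y)
        # one parameter group serves both pair members
        assert set(clf._groups()) == {"compound_encoder", "protein_encoder",
                                      "head"}
        # identical fingerprints on both sides produce identical embeddings
        fp = X[0, :N_BITS]
        emb_a, _ = clf.compound_encoder_.forward(fp[None, :])
        emb_b, _ = clf.compound_encoder_.forward(X[0, N_BITS:2 * N_BITS][None, :])
        if np.array_equal(fp, X[0, N_BITS:2 * N_BITS]):
            assert np.array_equal(emb_a, emb_b)

    def test_rejects_nonbinary_labels(self):
        X, y = _toy_ac_data(n=20)
        with pytest.raises(ValueError):
            ActivityCliffClassifier(**FAST).fit(X, y + 1)

    def test_deterministic_given_random_state(self):
        X, y = _toy_ac_data(n=40)
        a = ActivityCliffClassifier(**FAST).fit(X, y)
        b = ActivityCliffClassifier(**FAST).fit(X, y)
        assert a.parameter_digests() == b.parameter_digests()

    def test_sklearn_clone_compatible(self):
        clf = ActivityCliffClassifier(**FAST)
        assert clone(clf).get_params() == clf.get_params()


class TestRegressor:
    def test_fits_noiseless_linear_surface(self):
        X, y = _toy_dti_data()
        reg = AffinityRegressor(**{**FAST, "max_epochs": 300, "patience": 300})
        reg.fit(X, y)
        rmse = np.sqrt(np.mean((reg.predict(X) - y) ** 2))
        assert rmse < 0.35

    def test_predictions_on_original_scale(self):
        X, y = _toy_dti_data(n=80)
        reg = AffinityRegressor(**FAST).fit(X, y)
        pred = reg.predict(X)
        # affinities live around 5; standardization must be undone
        assert 3.0 < np.mean(pred) < 7.0

    def test_feature_count_checked_at_predict(self):
        X, y = _toy_dti_data(n=40)
        reg = AffinityRegressor(**FAST).fit(X, y)
        with pytest.raises(ValueError):
            reg.predict(X[:, :-1])


class TestEarlyStopping:
    def test_stops_before_max_epochs_and_restores_best(self):
        X, y = _toy_ac_data(n=100)
        Xv, yv = _toy_ac_data(n=40, seed=2)
        clf = ActivityCliffClassifier(
            **{**FAST, "max_epochs": 400, "patience": 5})
        clf.fit(X, y, Xv, yv)
        assert clf.n_epochs_run_ < 400
        val = clf.history_["val_loss"]
        assert clf.best_val_loss_ == pytest.approx(min(val))
        assert val[clf.best_epoch_] == pytest.approx(clf.best_val_loss_)
        # stopped exactly `patience` epochs after the best one
        assert clf.n_epochs_run_ == clf.best_epoch_ + 1 + 5

    def test_monitors_train_loss_without_validation(self):
        X, y = _toy_ac_data(n=60)
        clf = ActivityCliffClassifier(**{**FAST, "max_epochs": 50}).fit(X, y)
        assert clf.best_val_loss_ == pytest.approx(
            min(clf.history_["train_loss"]))


@pytest.fixture(scope="module")
def fitted_ac():
    X, y = _toy_ac_data()
    return ActivityCliffClassifier(**FAST).fit(X, y)


class TestTransfer:

    def test_warm_start_copies_weights_then_trains_them(self, fitted_ac):
        reg = transfer_encoders(fitted_ac, TransferPlan("warm_start"),
                                **{k: v for k, v in FAST.items()
                                   if k != "n_bits"})
        X, y = _toy_dti_data(n=60)
        before = fitted_ac.parameter_digests()["compound_encoder"]
        reg.fit(X, y)
        assert reg.frozen_groups == ()
        # source model untouched, transferred copy updated by training
        assert fitted_ac.parameter_digests()["compound_encoder"] == before
        assert reg.parameter_digests()["compound_encoder"] != before

    def test_freeze_keeps_encoders_bit_identical(self, fitted_ac):
        reg = transfer_encoders(fitted_ac,
                                TransferPlan("freeze", "drug_and_target"),
                                **{k: v for k, v in FAST.items()
                                   if k != "n_bits"})
        X, y = _toy_dti_data(n=60)
        reg.fit(X, y)
        got = reg.parameter_digests()
        src = fitted_ac.parameter_digests()
        assert got["compound_encoder"] == src["compound_encoder"]
        assert got["protein_encoder"] == src["protein_encoder"]

    def test_drug_only_scope_leaves_protein_encoder_fresh(self, fitted_ac):
        reg = transfer_encoders(fitted_ac, TransferPlan("freeze", "drug_only"),
                                **{k: v for k, v in FAST.items()
                                   if k != "n_bits"})
        X, y = _toy_dti_data(n=60)
        reg.fit(X, y)
        assert reg.frozen_groups == ("compound_encoder",)
        assert (reg.parameter_digests()["protein_encoder"]
                != fitted_ac.parameter_digests()["protein_encoder"])

    def test_freeze_plus_layer_adds_trainable_adapter(self, fitted_ac):
        plan = TransferPlan("freeze_plus_layer", "drug_and_target",
                            extra_layer_dim=6)
        reg = transfer_encoders(fitted_ac, plan,
                                **{k: v for k, v in FAST.items()
                                   if k != "n_bits"})
        X, y = _toy_dti_data(n=60)
        reg.fit(X, y)
        assert reg.adapter_ is not None
        assert reg.adapter_.out_dim == 6
        assert "adapter" not in reg.frozen_groups
        assert (reg.parameter_digests()["compound_encoder"]
                == fitted_ac.parameter_digests()["compound_encoder"])

    def test_architecture_inherited_from_source(self, fitted_ac):
        reg = transfer_encoders(fitted_ac, TransferPlan("warm_start"))
        assert reg.n_bits == fitted_ac.n_bits
        assert reg.embedding_dim == fitted_ac.embedding_dim
        assert reg.encoder_hidden_dims == fitted_ac.encoder_hidden_dims


class TestSearchAndRepeats:
    def test_random_search_returns_sorted_leaderboard(self):
        X, y = _toy_ac_data(n=80)
        Xv, yv = _toy_ac_data(n=40, seed=3)
        space = {"learning_rate": ("loguniform", 1e-4, 1e-2),
                 "embedding_dim": [4, 8]}
        base = {k: v for k, v in FAST.items()
                if k not in ("embedding_dim", "random_state")}
        base["max_epochs"] = 5
        params, model, board = random_search(
            ActivityCliffClassifier, space, X, y, Xv, yv,
            n_configs=4, seed=0, base_params=base)
        assert len(board) == 4
        assert board["val_loss"].is_monotonic_increasing
        assert model.best_val_loss_ == pytest.approx(board["val_loss"].iloc[0])
        assert params["embedding_dim"] in (4, 8)
        assert 1e-4 <= params["learning_rate"] <= 1e-2

    def test_repeat_train_uses_distinct_seeds(self):
        X, y = _toy_ac_data(n=60)
        proto = ActivityCliffClassifier(**{**FAST, "max_epochs": 3})
        models = repeat_train(proto, X, y, seeds=(0, 1, 2))
        digests = {m.parameter_digests()["compound_encoder"] for m in models}
        assert len(digests) == 3
        with pytest.raises(ValueError):
            repeat_train(proto, X, y, seeds=(0, 0, 1))


class TestSerialization:

    def test_classifier_round_trip_is_bit_identical(self, fitted_ac, tmp_path):
        path = tmp_path / "ac.npz"
        fitted_ac.save(path)
        loaded = load_model(path)
        X, _ = _toy_ac_data(n=40, seed=7)
        assert loaded.parameter_digests() == fitted_ac.parameter_digests()
        assert np.array_equal(loaded.predict_proba(X),
                              fitted_ac.predict_proba(X))
        assert loaded.get_params()["encoder_hidden_dims"] == \
            fitted_ac.encoder_hidden_dims

    def test_regressor_round_trip_restores_standardization(self, tmp_path):
        X, y = _toy_dti_data(n=80)
        reg = AffinityRegressor(**{**FAST, "max_epochs": 5}).fit(X, y)
        path = tmp_path / "dti.npz"
        reg.save(path)
        loaded = load_model(path)
        assert loaded.y_mean_ == reg.y_mean_
        assert loaded.y_scale_ == reg.y_scale_
        assert np.array_equal(loaded.predict(X), reg.predict(X))

    def test_transfer_model_round_trips_with_adapter(self, fitted_ac, tmp_path):
        reg = transfer_encoders(
            fitted_ac, TransferPlan("freeze_plus_layer", extra_layer_dim=4),
            **{k: v for k, v in FAST.items()
               if k not in ("n_bits", "max_epochs")},
            max_epochs=3)
        X, y = _toy_dti_data(n=60)
        reg.fit(X, y)
        path = tmp_path / "tl.npz"
        reg.save(path)
        loaded = load_model(path)
        assert "adapter" in loaded.parameter_digests()
        assert loaded.parameter_digests() == reg.parameter_digests()
        assert np.array_equal(loaded.predict(X), reg.predict(X))

    def test_unfitted_model_refuses_to_save(self, tmp_path):
        with pytest.raises(ValueError, match="unfitted"):
            ActivityCliffClassifier(**FAST).save(tmp_path / "x.npz")
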