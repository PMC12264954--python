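"""Two-branch neural models for AC classification and DTI regression.

Both estimators share one architecture family: a compound encoder (an MLP
over ECFP bit vectors), a protein encoder (a single dense layer mapping the
one-hot target vector to a dense embedding), and a prediction head over the
concatenated embeddings.

* :class:`ActivityCliffClassifier` — the AC model processes *both* compounds
  of a pair through the *same* compound encoder (shared weights), then
  concatenates (emb_a, emb_b, emb_target) and predicts P(activity cliff)
  through a sigmoid head.
* :class:`AffinityRegressor` — the DTI model concatenates (emb_drug,
  emb_target) and predicts a continuous affinity through a linear head.

Transfer learning moves encoder weights from a fitted AC model into a fresh
DTI model under three modes: warm start (copied, all trainable), frozen
(copied, non-trainable), and frozen plus an extra trainable adapter layer in
the drug branch before concatenation. Either the drug encoder alone or both
the drug and target encoders can be transferred.

Estimators follow scikit-learn conventions: ``fit`` / ``predict`` (and
``predict_proba`` for the classifier), ``get_params`` / ``set_params``, and
fitted attributes with a trailing underscore. Design matrices are plain 2-D
arrays: ``[fp_a | fp_b | target one-hot]`` for the AC task and
``[fp | target one-hot]`` for the DTI task, with the fingerprint width given
by ``n_bits``.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from .ac_mining import CompoundPair, InteractionRecord
from .chemio import Molecule
from .nn import (Adam, Sequential, bce_loss_and_grad, mse_loss_and_grad,
                 sigmoid)

PARAM_GROUPS = ("compound_encoder", "protein_encoder", "adapter", "head")
TRANSFER_MODES = ("warm_start", "freeze", "freeze_plus_layer")
TRANSFER_SCOPES = ("drug_only", "drug_and_target")


def encode_target_onehot(target_id: str, target_vocabulary: list[str]) -> np.ndarray:
    """One-hot vector over the target vocabulary; unseen targets are an error.

    One-hot target encoding cannot generalize to proteins outside the
    vocabulary; this is a deliberate, documented limitation of the design.
    """
    try:
        idx = target_vocabulary.index(target_id)
    except ValueError:
        raise KeyError(f"target {target_id!r} not in vocabulary") from None
    vec = np.zeros(len(target_vocabulary))
    vec[idx] = 1.0
    return vec


def ac_design_matrix(pairs: list[CompoundPair], molecules: dict[str, Molecule],
                     target_vocabulary: list[str]):
    """Stack [fp_a | fp_b | target one-hot] rows and 0/1 labels for pairs."""
    index = {t: i for i, t in enumerate(target_vocabulary)}
    n_bits = len(next(iter(molecules.values())).fingerprint)
    X = np.zeros((len(pairs), 2 * n_bits + len(target_vocabulary)))
    y = np.zeros(len(pairs))
    for i, p in enumerate(pairs):
        X[i, :n_bits] = molecules[p.compound_a].fingerprint
        X[i, n_bits:2 * n_bits] = molecules[p.compound_b].fingerprint
        X[i, 2 * n_bits + index[p.target_id]] = 1.0
        y[i] = p.label
    return X, y


def dti_design_matrix(records: list[InteractionRecord],
                      molecules: dict[str, Molecule],
                      target_vocabulary: list[str]):
    """Stack [fp | target one-hot] rows, affinities, and target ids."""
    index = {t: i for i, t in enumerate(target_vocabulary)}
    n_bits = len(next(iter(molecules.values())).fingerprint)
    X = np.zeros((len(records), n_bits + len(target_vocabulary)))
    y = np.zeros(len(records))
    targets = []
    for i, r in enumerate(records):
        X[i, :n_bits] = molecules[r.compound_id].fingerprint
        X[i, n_bits + index[r.target_id]] = 1.0
        y[i] = r.affinity
        targets.append(r.target_id)
    return X, y, np.asarray(targets)


@dataclass(frozen=True)
class TransferPlan:
    """How encoder weights move from the AC model to the DTI model."""

    mode: str = "warm_start"
    encoders: str = "drug_and_target"
    extra_layer_dim: int | None = None

    def __post_init__(self):
        if self.mode not in TRANSFER_MODES:
            raise ValueError(f"mode must be one of {TRANSFER_MODES}")
        if self.encoders not in TRANSFER_SCOPES:
            raise ValueError(f"encoders must be one of {TRANSFER_SCOPES}")
        if (self.mode == "freeze_plus_layer") != (self.extra_layer_dim is not None):
            raise ValueError(
                "extra_layer_dim must be set iff mode='freeze_plus_layer'")


class _TwoBranchBase(BaseEstimator):
    """Shared construction, training loop and early stopping."""

    _task = None  # "AC" or "DTI"

    def __init__(self, n_bits=1024, encoder_hidden_dims=(128,),
                 embedding_dim=32, protein_embedding_dim=16,
                 head_hidden_dims=(64,), activation="relu", dropout=0.0,
                 learning_rate=1e-3, batch_size=64, max_epochs=100,
                 patience=10, random_state=None, pos_weight=1.0,
                 frozen_groups=(), extra_layer_dim=None,
                 pretrained_compound_encoder=None,
                 pretrained_protein_encoder=None, verbose=False):
        self.n_bits = n_bits
        self.encoder_hidden_dims = encoder_hidden_dims
        self.embedding_dim = embedding_dim
        self.protein_embedding_dim = protein_embedding_dim
        self.head_hidden_dims = head_hidden_dims
        self.activation = activation
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state
        self.pos_weight = pos_weight
        self.frozen_groups = frozen_groups
        self.extra_layer_dim = extra_layer_dim
        self.pretrained_compound_encoder = pretrained_compound_encoder
        self.pretrained_protein_encoder = pretrained_protein_encoder
        self.verbose = verbose

    # -- architecture ------------------------------------------------------

    def _n_fp_blocks(self) -> int:
        return 2 if self._task == "AC" else 1

    def _build(self, n_features: int, rng: np.random.Generator) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        unknown = set(self.frozen_groups) - set(PARAM_GROUPS)
        if unknown:
            raise ValueError(f"unknown frozen groups: {sorted(unknown)}")
        k = self._n_fp_blocks()
        n_targets = n_features - k * self.n_bits
        if n_targets < 1:
            raise ValueError(
                f"design matrix has {n_features} columns but needs more than "
                f"{k} x n_bits={self.n_bits} fingerprint columns")
        self.n_targets_ = n_targets
        enc_dims = [self.n_bits, *self.encoder_hidden_dims, self.embedding_dim]
        self.compound_encoder_ = Sequential(
            enc_dims, rng, activation=self.activation, activate_last=True,
            dropout=self.dropout)
        # protein encoder: exactly one dense mapping layer on the one-hot input
        self.protein_encoder_ = Sequential(
            [n_targets, self.protein_embedding_dim], rng,
            activation=self.activation, activate_last=True)
        drug_out = self.embedding_dim
        self.adapter_ = None
        if self.extra_layer_dim is not None:
            self.adapter_ = Sequential(
                [self.embedding_dim, self.extra_layer_dim], rng,
                activation=self.activation, activate_last=True)
            drug_out = self.extra_layer_dim
        head_in = k * drug_out + self.protein_embedding_dim
        self.head_ = Sequential(
            [head_in, *self.head_hidden_dims, 1], rng,
            activation=self.activation, activate_last=False,
            dropout=self.dropout)
        self._load_pretrained()

    def _load_pretrained(self) -> None:
        for name, weights in (("compound_encoder", self.pretrained_compound_encoder),
                              ("protein_encoder", self.pretrained_protein_encoder)):
            if weights is None:
                continue
            group = getattr(self, name + "_")
            try:
                group.set_weights(weights)
            except ValueError as err:
                raise ValueError(f"pretrained {name}: {err}") from err

    def _groups(self) -> dict[str, Sequential]:
        out = {"compound_encoder": self.compound_encoder_,
               "protein_encoder": self.protein_encoder_,
               "head": self.head_}
        if self.adapter_ is not None:
            out["adapter"] = self.adapter_
        return out

    def parameter_digests(self) -> dict[str, str]:
        """SHA-256 digest per parameter group (frozen-group immutability)."""
        return {name: g.digest() for name, g in self._groups().items()}

    # -- forward / backward (task-specific split of the design matrix) ------

    def _split_columns(self, X: np.ndarray):
        k = self._n_fp_blocks()
        blocks = [X[:, i * self.n_bits:(i + 1) * self.n_bits] for i in range(k)]
        onehot = X[:, k * self.n_bits:]
        return blocks, onehot

    def _forward(self, X: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None):
        blocks, onehot = self._split_columns(X)
        enc_caches, adp_caches, embs = [], [], []
        for fp in blocks:
            emb, cache = self.compound_encoder_.forward(fp, train=train, rng=rng)
            enc_caches.append(cache)
            if self.adapter_ is not None:
                emb, acache = self.adapter_.forward(emb, train=train, rng=rng)
                adp_caches.append(acache)
            embs.append(emb)
        emb_t, prot_cache = self.protein_encoder_.forward(onehot, train=train,
                                                          rng=rng)
        h = np.concatenate([*embs, emb_t], axis=1)
        out, head_cache = self.head_.forward(h, train=train, rng=rng)
        caches = {"enc": enc_caches, "adp": adp_caches, "prot": prot_cache,
                  "head": head_cache, "widths": [e.shape[1] for e in embs]}
        return out[:, 0], caches

    def _backward(self, caches, grad_out: np.ndarray):
        """Gradients per group; the shared compound encoder accumulates."""
        g_h, head_grads = self.head_.backward(caches["head"], grad_out[:, None])
        widths = caches["widths"]
        splits = np.cumsum(widths)
        parts = np.split(g_h, splits, axis=1)
        emb_grads, g_prot_emb = parts[:-1], parts[-1]
        _, prot_grads = self.protein_encoder_.backward(caches["prot"], g_prot_emb)
        enc_grads = None
        adp_grads = None
        for i, g_emb in enumerate(emb_grads):
            if self.adapter_ is not None:
                g_emb, ag = self.adapter_.backward(caches["adp"][i], g_emb)
                adp_grads = ag if adp_grads is None else [
                    (a[0] + b[0], a[1] + b[1]) for a, b in zip(adp_grads, ag)]
            _, eg = self.compound_encoder_.backward(caches["enc"][i], g_emb)
            enc_grads = eg if enc_grads is None else [
                (a[0] + b[0], a[1] + b[1]) for a, b in zip(enc_grads, eg)]
        out = {"compound_encoder": enc_grads, "protein_encoder": prot_grads,
               "head": head_grads}
        if self.adapter_ is not None:
            out["adapter"] = adp_grads
        return out

    def _loss_and_grad(self, pred, y):
        if self._task == "AC":
            return bce_loss_and_grad(pred, y, pos_weight=self.pos_weight)
        return mse_loss_and_grad(pred, y)

    def _eval_loss(self, X, y) -> float:
        pred, _ = self._forward(X, train=False)
        loss, _ = self._loss_and_grad(pred, y)
        return loss

    # -- training ----------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train with mini-batch Adam and early stopping on validation loss.

        Without a validation set, early stopping monitors the training loss.
        The parameters of the epoch with the best monitored loss are
        restored at the end. Frozen groups are never updated and are
        verified bit-identical after training.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if len(X) == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.random_state)
        self._build(X.shape[1], rng)
        self.n_features_in_ = X.shape[1]

        frozen = set(self.frozen_groups)
        frozen_before = {name: g.digest() for name, g in self._groups().items()
                         if name in frozen}
        trainable = [(name, g) for name, g in self._groups().items()
                     if name not in frozen]
        flat_params = [p for _, g in trainable for layer in g.layers
                       for p in layer.params()]
        if not flat_params:
            raise ValueError("no trainable parameter groups")
        opt = Adam(flat_params, lr=self.learning_rate)

        has_val = X_val is not None and y_val is not None and len(X_val) > 0
        if has_val:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float)

        history = {"train_loss": [], "val_loss": []}
        best_loss = np.inf
        best_weights = None
        best_epoch = -1
        wait = 0
        n = len(X)
        batch = min(self.batch_size, n)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                pred, caches = self._forward(X[idx], train=True, rng=rng)
                loss, grad = self._loss_and_grad(pred, y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {loss}; "
                        "consider lowering the learning rate")
                epoch_losses.append(loss)
                group_grads = self._backward(caches, grad)
                flat_grads = [g for name, _ in trainable
                              for gr in group_grads[name] for g in gr]
                opt.step(flat_grads)
            train_loss = float(np.mean(epoch_losses))
            monitored = self._eval_loss(X_val, y_val) if has_val else train_loss
            history["train_loss"].append(train_loss)
            history["val_loss"].append(monitored if has_val else np.nan)
            if self.verbose:
                print(f"epoch {epoch}: train {train_loss:.4f} "
                      f"monitored {monitored:.4f}")
            if monitored < best_loss:
                best_loss = monitored
                best_epoch = epoch
                best_weights = {name: g.get_weights()
                                for name, g in self._groups().items()}
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
        if best_weights is not None:
            for name, g in self._groups().items():
                g.set_weights(best_weights[name])
        for name, digest in frozen_before.items():
            if self._groups()[name].digest() != digest:
                raise AssertionError(f"frozen group {name!r} changed during fit")
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_loss)
        self.n_epochs_run_ = len(history["train_loss"])
        return self

    def encoder_weights(self) -> dict[str, list[np.ndarray]]:
        """Copies of the fitted encoder weights, for transfer."""
        return {"compound_encoder": self.compound_encoder_.get_weights(),
                "protein_encoder": self.protein_encoder_.get_weights()}

    def save(self, path) -> None:
        """Serialize a fitted estimator to a single ``.npz`` checkpoint."""
        import json as _json
        if not hasattr(self, "n_features_in_"):
            raise ValueError("cannot save an unfitted model")
        params = {}
        for k, v in self.get_params().items():
            if k in ("pretrained_compound_encoder",
                     "pretrained_protein_encoder"):
                continue  # materialized in the saved weights
            params[k] = list(v) if isinstance(v, tuple) else v
        arrays = {"__meta__": np.frombuffer(_json.dumps({
            "class": type(self).__name__,
            "params": params,
            "n_features_in": int(self.n_features_in_),
            "y_mean": getattr(self, "y_mean_", None),
            "y_scale": getattr(self, "y_scale_", None),
        }).encode(), dtype=np.uint8)}
        for name, group in self._groups().items():
            for i, w in enumerate(group.get_weights()):
                arrays[f"{name}.{i}"] = w
        np.savez(path, **arrays)

    def _decision(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}")
        out, _ = self._forward(X, train=False)
        return out


class ActivityCliffClassifier(_TwoBranchBase, ClassifierMixin):
    """Two-branch AC pair classifier with a shared compound encoder.

    Both pair members pass through the *same* encoder parameters; the head
    sees the concatenation (emb_a, emb_b, emb_target) and outputs the
    probability that the pair is an activity cliff. Trained with binary
    cross-entropy; ``pos_weight`` can up-weight the minority AC class.
    """

    _task = "AC"

    def fit(self, X, y, X_val=None, y_val=None):
        y = np.asarray(y)
        self.classes_ = np.array([0, 1])
        if not np.isin(y, self.classes_).all():
            raise ValueError("labels must be 0 (non-AC) or 1 (AC)")
        return super().fit(X, y.astype(float), X_val, y_val)

    def decision_function(self, X) -> np.ndarray:
        return self._decision(X)

    def predict_proba(self, X) -> np.ndarray:
        p = sigmoid(self._decision(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class AffinityRegressor(_TwoBranchBase, RegressorMixin):
    """Two-branch DTI regressor: linear head over (emb_drug, emb_target).

    Trained with mean squared error on log10-scale affinities. Targets are
    standardized internally during fitting (predictions are returned on the
    original scale); without this, the large initial error signal on
    affinity scales far from zero produces early gradient steps big enough
    to destroy transferred encoder features. Encoders may be initialized
    from a fitted :class:`ActivityCliffClassifier` and optionally frozen —
    see :func:`transfer_encoders`.
    """

    _task = "DTI"

    def fit(self, X, y, X_val=None, y_val=None):
        y = np.asarray(y, dtype=float)
        self.y_mean_ = float(np.mean(y))
        self.y_scale_ = float(np.std(y)) or 1.0
        z = (y - self.y_mean_) / self.y_scale_
        z_val = None
        if y_val is not None:
            z_val = (np.asarray(y_val, dtype=float) - self.y_mean_) / self.y_scale_
        return super().fit(X, z, X_val, z_val)

    def predict(self, X) -> np.ndarray:
        return self._decision(X) * self.y_scale_ + self.y_mean_


def load_model(path):
    """Reload an estimator saved with :meth:`_TwoBranchBase.save`."""
    import json as _json
    with np.load(path) as data:
        meta = _json.loads(bytes(data["__meta__"]).decode())
        weights = {k: data[k] for k in data.files if k != "__meta__"}
    cls = {"ActivityCliffClassifier": ActivityCliffClassifier,
           "AffinityRegressor": AffinityRegressor}.get(meta["class"])
    if cls is None:
        raise ValueError(f"unknown model class {meta['class']!r} in {path}")
    params = {k: tuple(v) if isinstance(v, list) else v
              for k, v in meta["params"].items()}
    model = cls(**params)
    model._build(meta["n_features_in"], np.random.default_rng(0))
    model.n_features_in_ = meta["n_features_in"]
    for name, group in model._groups().items():
        idx = sorted((k for k in weights if k.startswith(name + ".")),
                     key=lambda k: int(k.rsplit(".", 1)[1]))
        group.set_weights([weights[k] for k in idx])
    if cls is ActivityCliffClassifier:
        model.classes_ = np.array([0, 1])
    elif meta["y_mean"] is not None:
        model.y_mean_ = meta["y_mean"]
        model.y_scale_ = meta["y_scale"]
    return model


def transfer_encoders(ac_model: ActivityCliffClassifier, plan: TransferPlan,
                      **dti_params) -> AffinityRegressor:
    """Initialize a DTI regressor from a fitted AC model under a plan.

    Architecture parameters (fingerprint width, encoder dims, embedding
    sizes, activation) are inherited from the AC model so shapes match;
    remaining keyword arguments override training settings of the new
    regressor. The head is always freshly initialized.

    * ``warm_start`` — encoder weights copied, every group trainable.
    * ``freeze`` — encoder weights copied and the transferred group(s)
      excluded from optimization.
    * ``freeze_plus_layer`` — as freeze, plus a new trainable dense adapter
      in the drug branch between the frozen compound encoder and the
      concatenation.

    With ``encoders='drug_only'`` the protein encoder of the DTI model is
    freshly initialized (and trainable) regardless of mode.
    """
    weights = ac_model.encoder_weights()
    inherited = dict(
        n_bits=ac_model.n_bits,
        encoder_hidden_dims=ac_model.encoder_hidden_dims,
        embedding_dim=ac_model.embedding_dim,
        protein_embedding_dim=ac_model.protein_embedding_dim,
        activation=ac_model.activation,
    )
    inherited.update(dti_params)
    inherited["pretrained_compound_encoder"] = weights["compound_encoder"]
    if plan.encoders == "drug_and_target":
        inherited["pretrained_protein_encoder"] = weights["protein_encoder"]
    frozen: tuple = ()
    if plan.mode in ("freeze", "freeze_plus_layer"):
        frozen = ("compound_encoder",)
        if plan.encoders == "drug_and_target":
            frozen = ("compound_encoder", "protein_encoder")
    inherited["frozen_groups"] = frozen
    if plan.mode == "freeze_plus_layer":
        inherited["extra_layer_dim"] = plan.extra_layer_dim
    return AffinityRegressor(**inherited)


def _sample_param(rng: np.random.Generator, space):
    if isinstance(space, (list, tuple)) and not (
            len(space) == 3 and space[0] in ("uniform", "loguniform")):
        return space[int(rng.integers(len(space)))]
    kind, lo, hi = space
    if kind == "uniform":
        return float(rng.uniform(lo, hi))
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def random_search(estimator_cls, space: dict, X, y, X_val, y_val,
                  n_configs: int = 100, seed: int = 0, base_params=None):
    """Random hyperparameter search ranked by best validation loss.

    ``space`` maps a parameter name to either a list of choices or a
    ``("uniform"|"loguniform", low, high)`` range. Each sampled
    configuration is trained with early stopping; the leaderboard is a
    DataFrame sorted by validation loss. Deterministic given the seed.
    """
    if not space:
        raise ValueError("empty search space")
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    rng = np.random.default_rng(seed)
    base_params = dict(base_params or {})
    rows = []
    best = (np.inf, None, None)
    for i in range(n_configs):
        sampled = {k: _sample_param(rng, v) for k, v in space.items()}
        params = {**base_params, **sampled,
                  "random_state": int(rng.integers(2 ** 31))}
        model = estimator_cls(**params).fit(X, y, X_val, y_val)
        rows.append({**sampled, "val_loss": model.best_val_loss_,
                     "n_epochs": model.n_epochs_run_})
        if model.best_val_loss_ < best[0]:
            best = (model.best_val_loss_, params, model)
    leaderboard = pd.DataFrame(rows).sort_values("val_loss").reset_index(drop=True)
    return best[1], best[2], leaderboard


def grid_search_extra_layer(ac_model, base_plan_params: dict, grid: dict,
                            X, y, X_val, y_val, seed: int = 0,
                            base_params=None):
    """Full cross-product grid over the adapter-layer settings.

    Used for the frozen-weights-plus-layer mode, where the already-tuned
    frozen configuration is retained and only parameters of the new layer
    (and training settings affecting it) are varied.
    """
    if not grid:
        raise ValueError("empty grid")
    rng = np.random.default_rng(seed)
    base_params = dict(base_params or {})
    keys = sorted(grid)
    rows = []
    best = (np.inf, None, None)
    for combo in itertools.product(*(grid[k] for k in keys)):
        sampled = dict(zip(keys, combo))
        plan = TransferPlan(mode="freeze_plus_layer",
                            extra_layer_dim=sampled.pop("extra_layer_dim"),
                            **base_plan_params)
        params = {**base_params, **sampled,
                  "random_state": int(rng.integers(2 ** 31))}
        model = transfer_encoders(ac_model, plan, **params).fit(X, y, X_val, y_val)
        rows.append({**dict(zip(keys, combo)), "val_loss": model.best_val_loss_})
        if model.best_val_loss_ < best[0]:
            best = (model.best_val_loss_, dict(zip(keys, combo)), model)
    leaderboard = pd.DataFrame(rows).sort_values("val_loss").reset_index(drop=True)
    return best[1], best[2], leaderboard


def repeat_train(estimator, X, y, X_val=None, y_val=None, seeds=(0, 1, 2)):
    """Train one configuration several times for mean +/- std aggregation."""
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    models = []
    for seed in seeds:
        m = copy.deepcopy(estimator)
        m.set_params(random_state=int(seed))
        models.append(m.fit(X, y, X_val, y_val))
    return models
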