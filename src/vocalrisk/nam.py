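"""Confound-adjusted neural additive model (NAM) for aspiration risk.

The model is a sum of per-feature subnetworks plus a learnable offset,
squashed by a sigmoid:

    risk = sigmoid(beta + sum_k g_k(x_k, age, sex))

Each subnetwork g_k sees one acoustic feature together with the patient's
age and sex, so demographic confounding is absorbed inside every feature's
contribution while the model stays additively interpretable: removing a
subnetwork changes the pre-sigmoid sum by exactly that subnetwork's
output, and feature importance is the mean absolute contribution.

The implementation is a small, fully vectorized numpy network (two tanh
hidden layers by default, trained with Adam on binary cross-entropy plus
light weight decay). An extra leading "model" axis trains many models in
parallel on stacked inputs — the recursive-feature-addition search and
hyperparameter grids train dozens of small models, and batching them into
single einsum calls keeps the whole nested procedure fast on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DivergenceError, VocalRiskError
from .features import PatientFeatures

SEX_ENCODING = {"female": 0.0, "male": 1.0}


@dataclass
class TrainConfig:
    """Training configuration for :func:`train_nam`."""

    lr_grid: tuple = (1e-3, 3e-3, 1e-2)
    epoch_grid: tuple = (100, 300, 1000)
    hidden: tuple = (32, 32)
    seed: int = 0
    oversample: bool = True
    inner_val_fraction: float = 0.2
    weight_decay: float = 1e-4

    def __post_init__(self):
        if not self.lr_grid or not self.epoch_grid:
            raise ConfigurationError("hyperparameter grids must be non-empty")


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def fast_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with half-credit for ties (rank formulation)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise VocalRiskError("AUC needs both classes")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores))
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_pos = np.sum(ranks[labels == 1])
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# parallel trainer


class ParallelNAM:
    """M independent NAMs trained simultaneously via a leading model axis.

    Inputs are stacks ``X`` of shape (M, N, F, 3): per model, N samples,
    F subnetworks, and per subnetwork the triplet (feature, age, sex) in
    standardized units.
    """

    def __init__(self, n_models: int, n_features: int, hidden=(32, 32),
                 seed: int = 0, dtype=np.float32):
        if len(hidden) != 2:
            raise ConfigurationError("ParallelNAM expects exactly 2 hidden layers")
        h1, h2 = hidden
        m, f = n_models, n_features
        rng = np.random.default_rng(seed)
        s = rng.standard_normal
        self.W1 = (s((m, f, 3, h1)) / np.sqrt(3.0)).astype(dtype)
        self.b1 = np.zeros((m, f, h1), dtype)
        self.W2 = (s((m, f, h1, h2)) / np.sqrt(h1)).astype(dtype)
        self.b2 = np.zeros((m, f, h2), dtype)
        self.W3 = (s((m, f, h2)) / np.sqrt(h2)).astype(dtype)
        self.b3 = np.zeros((m, f), dtype)
        self.beta = np.zeros(m, dtype)
        self.dtype = dtype

    def _params(self):
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3, self.beta]

    def _forward(self, Xt: np.ndarray):
        """Xt has layout (M, F, N, 3); returns hidden activations and
        per-subnetwork outputs g with layout (M, F, N)."""
        h1 = np.tanh(Xt @ self.W1 + self.b1[:, :, None, :])
        h2 = np.tanh(h1 @ self.W2 + self.b2[:, :, None, :])
        g = (h2 @ self.W3[..., None])[..., 0] + self.b3[:, :, None]
        return h1, h2, g

    def contributions(self, X: np.ndarray) -> np.ndarray:
        """Per-subnetwork outputs g_k, shape (M, N, F)."""
        Xt = np.ascontiguousarray(X.transpose(0, 2, 1, 3)).astype(self.dtype)
        _, _, g = self._forward(Xt)
        return g.transpose(0, 2, 1)

    def logits(self, X: np.ndarray) -> np.ndarray:
        Xt = np.ascontiguousarray(X.transpose(0, 2, 1, 3)).astype(self.dtype)
        _, _, g = self._forward(Xt)
        return g.sum(axis=1) + self.beta[:, None]

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight=None,
            lr=1e-3, epochs: int = 300, weight_decay: float = 1e-4,
            checkpoints=None, X_val=None, y_val=None):
        """Full-batch Adam on weighted binary cross-entropy.

        ``lr`` may be a scalar or per-model vector. When ``checkpoints``
        (sorted epoch counts) and validation data are given, returns the
        validation AUC per model at each checkpoint.
        """
        m, n, f, _ = X.shape
        Xt = np.ascontiguousarray(X.transpose(0, 2, 1, 3)).astype(self.dtype)
        y = np.broadcast_to(np.asarray(y, self.dtype), (m, n))
        if sample_weight is None:
            w = np.full((m, n), 1.0 / n, self.dtype)
        else:
            w = np.asarray(sample_weight, self.dtype)
            w = np.broadcast_to(w, (m, n))
            w = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-12)
        lr_vec = np.broadcast_to(np.asarray(lr, self.dtype), (m,)).copy()

        params = self._params()
        ms = [np.zeros_like(p) for p in params]
        vs = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        checkpoints = sorted(checkpoints) if checkpoints else [epochs]
        total = checkpoints[-1]
        val_aucs = {}
        XtT = np.ascontiguousarray(Xt.transpose(0, 1, 3, 2))

        for epoch in range(1, total + 1):
            h1, h2, g = self._forward(Xt)              # (M, F, N, ·)
            logit = g.sum(axis=1) + self.beta[:, None]
            p = sigmoid(logit)

            dlogit = w * (p - y)                       # (M, N)
            dg = np.broadcast_to(dlogit[:, None, :], (m, f, n))
            db3 = dg.sum(axis=2)
            dW3 = (h2.transpose(0, 1, 3, 2) @ dg[..., None])[..., 0]
            dh2 = dg[..., None] * self.W3[:, :, None, :]
            dz2 = dh2 * (1.0 - h2 * h2)
            db2 = dz2.sum(axis=2)
            dW2 = h1.transpose(0, 1, 3, 2) @ dz2
            dh1 = dz2 @ self.W2.transpose(0, 1, 3, 2)
            dz1 = dh1 * (1.0 - h1 * h1)
            db1 = dz1.sum(axis=2)
            dW1 = XtT @ dz1
            dbeta = dlogit.sum(axis=1)
            grads = [dW1, db1, dW2, db2, dW3, db3, dbeta]

            t_corr = (np.sqrt(1.0 - beta2 ** epoch) / (1.0 - beta1 ** epoch))
            for pkey, (par, grad, mbuf, vbuf) in enumerate(zip(params, grads, ms, vs)):
                if weight_decay and pkey in (0, 2, 4):   # decay weights only
                    grad = grad + weight_decay * par
                mbuf *= beta1
                mbuf += (1 - beta1) * grad
                vbuf *= beta2
                vbuf += (1 - beta2) * grad * grad
                step = t_corr * mbuf / (np.sqrt(vbuf) + eps)
                shape = (-1,) + (1,) * (par.ndim - 1)
                par -= lr_vec.reshape(shape) * step

            if epoch in checkpoints or epoch == total:
                if not np.all(np.isfinite(self.beta)):
                    raise DivergenceError(
                        "NaN encountered during NAM training; try a smaller lr")
                if X_val is not None and epoch in checkpoints:
                    val_logit = self.logits(X_val.astype(self.dtype))
                    val_aucs[epoch] = np.array([
                        fast_auc(val_logit[i], y_val) for i in range(m)])
        return val_aucs


# ---------------------------------------------------------------------------
# fitted model artifact


@dataclass
class NAMModel:
    """A fitted NAM with its standardization constants and metadata.

    The artifact is self-describing: panel, input standardization, sex
    encoding, training configuration and seed all travel with the weights,
    so a saved model scores new patients without training-time context.
    """

    panel: list
    weights: dict
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    age_mean: float
    age_sd: float
    beta: float
    metadata: dict = field(default_factory=dict)

    def _net(self) -> ParallelNAM:
        h1 = self.weights["W1"].shape[-1]
        h2 = self.weights["W2"].shape[-1]
        net = ParallelNAM(1, len(self.panel), hidden=(h1, h2))
        for key in ("W1", "b1", "W2", "b2", "W3", "b3"):
            setattr(net, key, self.weights[key][None].astype(np.float32))
        net.beta = np.array([self.beta], dtype=np.float32)
        return net

    def _stack(self, feats: np.ndarray, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
        z = (feats - self.feat_mean) / self.feat_sd
        za = (age - self.age_mean) / self.age_sd
        n, f = z.shape
        X = np.empty((1, n, f, 3), dtype=np.float32)
        X[0, :, :, 0] = z
        X[0, :, :, 1] = za[:, None]
        X[0, :, :, 2] = sex[:, None]
        return X

    def contributions(self, feats, age, sex) -> np.ndarray:
        """Subnetwork outputs g_k per patient, shape (N, F)."""
        return self._net().contributions(self._stack(feats, age, sex))[0]

    def score(self, feats, age, sex) -> np.ndarray:
        """Risk scores in (0, 1) for arrays of patients."""
        return sigmoid(self._net().logits(self._stack(feats, age, sex))[0]
                       ).astype(np.float64)

    def save(self, path: str | Path) -> None:
        arrays = {k: v for k, v in self.weights.items()}
        arrays.update(feat_mean=self.feat_mean, feat_sd=self.feat_sd)
        meta = dict(self.metadata)
        meta.update(panel=self.panel, age_mean=self.age_mean,
                    age_sd=self.age_sd, beta=float(self.beta),
                    sex_encoding=SEX_ENCODING)
        np.savez(path, _metadata=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "NAMModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_metadata"]).decode())
            weights = {k: data[k] for k in ("W1", "b1", "W2", "b2", "W3", "b3")}
            feat_mean, feat_sd = data["feat_mean"], data["feat_sd"]
        return cls(panel=list(meta.pop("panel")), weights=weights,
                   feat_mean=feat_mean, feat_sd=feat_sd,
                   age_mean=meta.pop("age_mean"), age_sd=meta.pop("age_sd"),
                   beta=meta.pop("beta"), metadata=meta)


def forward_risk(model: NAMModel, features: dict, age: float, sex) -> float:
    """Score a single patient; ``sex`` is 'female'/'male' or 0/1."""
    missing = [k for k in model.panel if k not in features]
    if missing:
        raise VocalRiskError(f"missing panel feature(s): {missing}")
    feats = np.array([[features[k] for k in model.panel]])
    sex_val = SEX_ENCODING.get(sex, sex)
    return float(model.score(feats, np.array([age]),
                             np.array([float(sex_val)]))[0])


# ---------------------------------------------------------------------------
# training


def design_matrices(data: list[PatientFeatures], panel: list):
    """(features (N,F), age (N,), sex (N,), labels (N,); high=1, low=0,
    moderate=-1)."""
    label_map = {"high": 1, "low": 0, "moderate": -1}
    feats = np.array([[p.features[k] for k in panel] for p in data])
    age = np.array([p.age for p in data], dtype=np.float64)
    sex = np.array([SEX_ENCODING[p.sex] for p in data], dtype=np.float64)
    y = np.array([label_map[p.risk_label] for p in data])
    return feats, age, sex, y


def standardize_inputs(feats, age, feat_mean=None, feat_sd=None,
                       age_mean=None, age_sd=None):
    """Z-score features and age; constants from the supplied (training)
    statistics, or computed when omitted."""
    if feat_mean is None:
        feat_mean = feats.mean(axis=0)
        feat_sd = np.maximum(feats.std(axis=0), 1e-8)
        age_mean = age.mean()
        age_sd = max(age.std(), 1e-8)
    return feat_mean, feat_sd, age_mean, age_sd


def build_stack(feats, age, sex, feat_mean, feat_sd, age_mean, age_sd):
    """Standardized (1, N, F, 3) input stack."""
    z = (feats - feat_mean) / feat_sd
    za = (age - age_mean) / age_sd
    n, f = z.shape
    X = np.empty((1, n, f, 3), dtype=np.float32)
    X[0, :, :, 0] = z
    X[0, :, :, 1] = za[:, None]
    X[0, :, :, 2] = sex[:, None]
    return X


def oversample_minority(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices realizing exact class balance by resampling the minority."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise VocalRiskError("both classes required for oversampling")
    if len(pos) < len(neg):
        extra = rng.choice(pos, size=len(neg) - len(pos), replace=True)
    elif len(neg) < len(pos):
        extra = rng.choice(neg, size=len(pos) - len(neg), replace=True)
    else:
        extra = np.array([], dtype=int)
    return np.concatenate([np.arange(len(y)), extra])


def _stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """(train_idx, val_idx) with the label mix preserved in the held-out part."""
    val = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        k = max(1, int(round(fraction * len(idx))))
        val.extend(idx[:k])
    val = np.sort(np.array(val))
    train = np.setdiff1d(np.arange(len(y)), val)
    return train, val


def train_nam(data: list[PatientFeatures], cfg: TrainConfig,
              panel: list | None = None) -> NAMModel:
    """Fit the NAM on high/low-risk patients.

    Standardization constants come from the training data only; the
    minority class is randomly oversampled to exact balance; the learning
    rate and epoch count are chosen by AUC on a stratified inner
    validation split; the final model is refit on all supplied patients
    with the winning configuration.
    """
    data = [p for p in data if p.risk_label in ("high", "low")]
    if not data:
        raise VocalRiskError("no high/low-risk patients to train on")
    panel = list(panel) if panel is not None else list(data[0].features)
    feats, age, sex, y = design_matrices(data, panel)
    if len(np.unique(y)) < 2:
        raise VocalRiskError("training data contains a single class")

    rng = np.random.default_rng(cfg.seed)
    feat_mean, feat_sd, age_mean, age_sd = standardize_inputs(feats, age)

    # hyperparameter grid: models parallel over lr, epochs via checkpoints
    tr_idx, val_idx = _stratified_split(y, cfg.inner_val_fraction, rng)
    if cfg.oversample:
        os_idx = tr_idx[oversample_minority(y[tr_idx], rng)]
    else:
        os_idx = tr_idx
    X_tr = build_stack(feats[os_idx], age[os_idx], sex[os_idx],
                       feat_mean, feat_sd, age_mean, age_sd)
    X_val = build_stack(feats[val_idx], age[val_idx], sex[val_idx],
                        feat_mean, feat_sd, age_mean, age_sd)
    m = len(cfg.lr_grid)
    X_tr = np.broadcast_to(X_tr, (m,) + X_tr.shape[1:])
    X_val = np.broadcast_to(X_val, (m,) + X_val.shape[1:])
    net = ParallelNAM(m, len(panel), hidden=cfg.hidden, seed=cfg.seed)
    val_aucs = net.fit(X_tr, y[os_idx], lr=np.array(cfg.lr_grid),
                       epochs=max(cfg.epoch_grid),
                       weight_decay=cfg.weight_decay,
                       checkpoints=list(cfg.epoch_grid),
                       X_val=X_val, y_val=y[val_idx])
    best_auc, best_lr, best_epochs = -np.inf, cfg.lr_grid[0], cfg.epoch_grid[0]
    for epochs, aucs in sorted(val_aucs.items()):
        for i, lr in enumerate(cfg.lr_grid):
            if aucs[i] > best_auc:
                best_auc, best_lr, best_epochs = float(aucs[i]), lr, epochs

    # final fit on all training patients with the winning configuration
    if cfg.oversample:
        final_idx = oversample_minority(y, rng)
    else:
        final_idx = np.arange(len(y))
    X_all = build_stack(feats[final_idx], age[final_idx], sex[final_idx],
                        feat_mean, feat_sd, age_mean, age_sd)
    net = ParallelNAM(1, len(panel), hidden=cfg.hidden, seed=cfg.seed)
    net.fit(X_all, y[final_idx], lr=best_lr, epochs=best_epochs,
            weight_decay=cfg.weight_decay)

    weights = {"W1": net.W1[0].copy(), "b1": net.b1[0].copy(),
               "W2": net.W2[0].copy(), "b2": net.b2[0].copy(),
               "W3": net.W3[0].copy(), "b3": net.b3[0].copy()}
    meta = {"seed": cfg.seed, "lr": best_lr, "epochs": best_epochs,
            "inner_val_auc": best_auc, "hidden": list(cfg.hidden),
            "oversample": cfg.oversample, "weight_decay": cfg.weight_decay,
            "n_train": len(data)}
    return NAMModel(panel=panel, weights=weights, feat_mean=feat_mean,
                    feat_sd=feat_sd, age_mean=age_mean, age_sd=age_sd,
                    beta=float(net.beta[0]), metadata=meta)


def feature_importance(model: NAMModel, data: list[PatientFeatures]) -> dict:
    """Mean absolute subnetwork contribution per feature over the data."""
    if not data:
        raise VocalRiskError("empty data for feature importance")
    feats, age, sex, _ = design_matrices(data, model.panel)
    g = model.contributions(feats, age, sex)
    return dict(zip(model.panel, np.mean(np.abs(g), axis=0)))


def mean_absolute_weights(model: NAMModel) -> dict:
    """Secondary diagnostic: mean |parameter| per subnetwork."""
    out = {}
    for i, name in enumerate(model.panel):
        acc = [np.abs(model.weights[k][i]).mean()
               for k in ("W1", "b1", "W2", "b2", "W3", "b3")]
        out[name] = float(np.mean(acc))
    return out
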