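"""Model-development pipeline: nested cross-validation with recursive
feature addition, hyperparameter search, recalibration and external testing.

The patient is the unit of analysis: folds are assigned per patient
(stratified by risk label), so no patient's clips can straddle a fold
boundary. Within each training fold, in order: recursive feature addition
(greedy forward selection by inner cross-validated AUC), hyperparameter
grid search on an inner validation split, minority oversampling, NAM
training, and post-hoc logistic recalibration fitted on training-fold
predictions — the held-out fold is only ever scored. Every stage logs the
patient ids it consumed, and :func:`audit_leakage` verifies from that log
that no validation patient influenced any fitted quantity.

Moderate-risk patients are never trained on; they are scored post hoc
with their fold's model. External cohorts are scored by the ensemble mean
of the five fold models' calibrated scores and classified at the
development-derived Youden threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, VocalRiskError
from .features import PatientFeatures
from .nam import (ParallelNAM, TrainConfig, design_matrices, fast_auc,
                  oversample_minority, sigmoid, standardize_inputs, train_nam)

EPS = 1e-7


def logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, EPS, 1.0 - EPS)
    return np.log(p / (1.0 - p))


@dataclass
class PipelineConfig:
    """Knobs of the development procedure.

    The recursive-feature-addition stage screens candidates with a
    smaller, shorter-trained network than the final fit — selection only
    needs a stable ranking of candidate sets, and the screening
    configuration keeps the nested search tractable on one CPU.
    """

    k: int = 5
    seed: int = 0
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        lr_grid=(3e-3, 1e-2), epoch_grid=(100, 300)))
    rfa_eps: float = 0.005
    rfa_patience: int = 2
    rfa_max_features: int = 8
    rfa_inner_folds: int = 3
    rfa_hidden: tuple = (16, 16)
    rfa_epochs: int = 120
    rfa_lr: float = 3e-3
    #: candidates whose inner-CV AUC is within this margin of the step's
    #: best are treated as tied, and the tie resolves to the earliest
    #: panel position; without this, near-duplicate features (e.g. two
    #: shimmer variants) are picked interchangeably across folds and the
    #: cross-fold intersection reflects noise rather than signal
    rfa_tie_tol: float = 0.01
    ensemble_external: bool = True
    #: "raise" fails loudly when the per-fold RFA selections share no
    #: feature; "warn" records an empty final set instead (useful for
    #: null-control runs, where no stable feature subset should exist)
    on_empty_intersection: str = "raise"


@dataclass
class FoldAssignment:
    k: int
    mapping: dict  # patient_id -> fold index

    def fold_of(self, patient_id: str) -> int:
        return self.mapping[patient_id]


@dataclass
class CalibrationMap:
    """Logistic recalibration sigma(a + b * logit(p))."""

    intercept: float
    slope: float

    def apply(self, scores: np.ndarray) -> np.ndarray:
        return sigmoid(self.intercept + self.slope * logit(np.asarray(scores)))


@dataclass
class RFATrace:
    """Per-fold greedy selection paths and their intersection."""

    per_fold: list          # list (per fold) of [(feature, auc_after), ...]
    final_set: list
    stop_reasons: list
    risk_diff_curves: list  # per fold: mean risk difference after each addition


@dataclass
class StudyResult:
    """Everything run_development produces."""

    oof_scores: pd.DataFrame          # patient_id, risk_label, score, fold, ...
    fold_models: list                 # NAMModel per fold
    calibrations: list                # CalibrationMap per fold
    folds: FoldAssignment
    rfa_trace: RFATrace
    threshold: float                  # development Youden cutoff
    dev_auc: float
    audit_log: list                   # per fold: stage -> patient id lists
    config: PipelineConfig
    panel: list

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.oof_scores.to_csv(out / "oof_scores.csv", index=False)
        for i, (m, c) in enumerate(zip(self.fold_models, self.calibrations)):
            m.save(out / f"fold{i}_model.npz")
            (out / f"fold{i}_calibration.json").write_text(
                json.dumps({"intercept": c.intercept, "slope": c.slope}))
        (out / "rfa_trace.json").write_text(json.dumps({
            "per_fold": self.rfa_trace.per_fold,
            "final_set": self.rfa_trace.final_set,
            "stop_reasons": self.rfa_trace.stop_reasons}))
        (out / "summary.json").write_text(json.dumps({
            "dev_auc": self.dev_auc, "threshold": self.threshold,
            "panel": self.panel, "seed": self.config.seed, "k": self.config.k}))


# ---------------------------------------------------------------------------
# fold assignment


def make_patient_folds(patients: list[PatientFeatures], k: int = 5,
                       seed: int = 0) -> FoldAssignment:
    """Stratified patient-level fold assignment, deterministic in seed."""
    trainable = [p for p in patients if p.risk_label in ("high", "low")]
    if len(trainable) < k:
        raise VocalRiskError(f"need at least {k} high/low patients for {k} folds")
    rng = np.random.default_rng(seed)
    mapping: dict[str, int] = {}
    for label in ("high", "low", "moderate"):
        ids = [p.patient_id for p in patients if p.risk_label == label]
        ids = list(rng.permutation(ids))
        for i, pid in enumerate(ids):
            mapping[pid] = i % k
    return FoldAssignment(k=k, mapping=mapping)


# ---------------------------------------------------------------------------
# recursive feature addition


def _inner_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Stratified k-fold indices over the training patients."""
    folds = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.sort(np.array(f)) for f in folds]


def recursive_feature_addition(train_patients: list[PatientFeatures],
                               panel: list, cfg: PipelineConfig,
                               rng: np.random.Generator):
    """Greedy forward selection by inner cross-validated AUC.

    At each step every remaining candidate is appended to the current set
    and a screening NAM is trained per (candidate, inner fold); all those
    models are stacked on the model axis of one ParallelNAM so the whole
    step is a single vectorized fit. Addition stops after
    ``cfg.rfa_patience`` consecutive improvements below ``cfg.rfa_eps``
    (those tentative additions are rolled back), when the candidate pool
    is exhausted, or at ``cfg.rfa_max_features``.
    """
    if not panel:
        raise ConfigurationError("empty feature panel for RFA")
    data = [p for p in train_patients if p.risk_label in ("high", "low")]
    feats, age, sex, y = design_matrices(data, panel)
    k = cfg.rfa_inner_folds
    folds = _inner_folds(y, k, rng)
    fold_data = []
    for vi in range(k):
        val_idx = folds[vi]
        tr_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        fm, fsd, am, asd = standardize_inputs(feats[tr_idx], age[tr_idx])
        z = (feats - fm) / fsd
        za = (age - am) / asd
        os_idx = tr_idx[oversample_minority(y[tr_idx], rng)]
        fold_data.append((z, za, os_idx, val_idx))
    n_tr = max(len(fd[2]) for fd in fold_data)
    n_val = max(len(fd[3]) for fd in fold_data)

    selected: list[int] = []
    curve: list[tuple[str, float]] = []
    risk_diffs: list[float] = []
    best_auc = 0.5
    low_streak = 0
    stop = "panel exhausted"
    while len(selected) < min(len(panel), cfg.rfa_max_features):
        candidates = [j for j in range(len(panel)) if j not in selected]
        if not candidates:
            break
        m = len(candidates) * k
        f_sub = len(selected) + 1
        X_tr = np.zeros((m, n_tr, f_sub, 3), dtype=np.float32)
        w_tr = np.zeros((m, n_tr), dtype=np.float32)
        X_val = np.zeros((m, n_val, f_sub, 3), dtype=np.float32)
        val_sets = []
        for ci, cand in enumerate(candidates):
            cols = selected + [cand]
            for vi, (z, za, os_idx, val_idx) in enumerate(fold_data):
                mi = ci * k + vi
                nt, nv = len(os_idx), len(val_idx)
                X_tr[mi, :nt, :, 0] = z[np.ix_(os_idx, cols)]
                X_tr[mi, :nt, :, 1] = za[os_idx, None]
                X_tr[mi, :nt, :, 2] = sex[os_idx, None]
                w_tr[mi, :nt] = 1.0
                X_val[mi, :nv, :, 0] = z[np.ix_(val_idx, cols)]
                X_val[mi, :nv, :, 1] = za[val_idx, None]
                X_val[mi, :nv, :, 2] = sex[val_idx, None]
                val_sets.append((mi, val_idx))
        y_tr = np.zeros((m, n_tr), dtype=np.float32)
        for ci in range(len(candidates)):
            for vi, (_, _, os_idx, _) in enumerate(fold_data):
                y_tr[ci * k + vi, :len(os_idx)] = y[os_idx]
        net = ParallelNAM(m, f_sub, hidden=cfg.rfa_hidden,
                          seed=int(rng.integers(0, 2 ** 31)))
        net.fit(X_tr, y_tr, sample_weight=w_tr, lr=cfg.rfa_lr,
                epochs=cfg.rfa_epochs, weight_decay=cfg.train.weight_decay)
        val_logit = net.logits(X_val)
        cand_auc = np.empty(len(candidates))
        cand_rd = np.empty(len(candidates))
        for ci in range(len(candidates)):
            aucs, rds = [], []
            for vi in range(k):
                mi = ci * k + vi
                vidx = fold_data[vi][3]
                lv = val_logit[mi, :len(vidx)]
                aucs.append(fast_auc(lv, y[vidx]))
                pv = sigmoid(lv)
                rds.append(float(pv[y[vidx] == 1].mean() - pv[y[vidx] == 0].mean()))
            cand_auc[ci] = np.mean(aucs)
            cand_rd[ci] = np.mean(rds)
        tied = np.flatnonzero(cand_auc >= cand_auc.max() - cfg.rfa_tie_tol)
        best_ci = int(tied[0])  # candidates are in panel order
        improvement = cand_auc[best_ci] - best_auc
        selected.append(candidates[best_ci])
        curve.append((panel[candidates[best_ci]], float(cand_auc[best_ci])))
        risk_diffs.append(float(cand_rd[best_ci]))
        best_auc = max(best_auc, float(cand_auc[best_ci]))
        if improvement < cfg.rfa_eps:
            low_streak += 1
            if low_streak >= cfg.rfa_patience:
                stop = f"plateau (<{cfg.rfa_eps} AUC gain x{cfg.rfa_patience})"
                break
        else:
            low_streak = 0
    else:
        stop = f"reached max features ({cfg.rfa_max_features})"
    # the fold's subset ends at the plateau point: the trailing additions
    # that each gained < eps are dropped; the full path stays in the trace
    if low_streak:
        selected = selected[:-low_streak] or selected[:1]
    return [panel[j] for j in selected], curve, risk_diffs, stop


def cross_fitted_scores(train_pats: list[PatientFeatures], panel: list,
                        cfg: PipelineConfig, lr: float, epochs: int,
                        rng: np.random.Generator, j: int = 4):
    """Out-of-sample scores for every training-fold patient via j-fold
    inner cross-fitting with fixed hyperparameters (one batched fit).

    Used to estimate the recalibration map: in-sample predictions of an
    overfit network are separable and give degenerate slopes, while
    cross-fitted predictions reflect the score distribution the map will
    actually be applied to.
    """
    feats, age, sex, y = design_matrices(train_pats, panel)
    folds = _inner_folds(y, j, rng)
    fold_data = []
    for vi in range(j):
        val_idx = folds[vi]
        tr_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        fm, fsd, am, asd = standardize_inputs(feats[tr_idx], age[tr_idx])
        z = (feats - fm) / fsd
        za = (age - am) / asd
        os_idx = tr_idx[oversample_minority(y[tr_idx], rng)]
        fold_data.append((z, za, os_idx, val_idx))
    n_tr = max(len(fd[2]) for fd in fold_data)
    n_val = max(len(fd[3]) for fd in fold_data)
    f = len(panel)
    X_tr = np.zeros((j, n_tr, f, 3), dtype=np.float32)
    w_tr = np.zeros((j, n_tr), dtype=np.float32)
    y_tr = np.zeros((j, n_tr), dtype=np.float32)
    X_val = np.zeros((j, n_val, f, 3), dtype=np.float32)
    for vi, (z, za, os_idx, val_idx) in enumerate(fold_data):
        nt, nv = len(os_idx), len(val_idx)
        X_tr[vi, :nt, :, 0] = z[os_idx]
        X_tr[vi, :nt, :, 1] = za[os_idx, None]
        X_tr[vi, :nt, :, 2] = sex[os_idx, None]
        w_tr[vi, :nt] = 1.0
        y_tr[vi, :nt] = y[os_idx]
        X_val[vi, :nv, :, 0] = z[val_idx]
        X_val[vi, :nv, :, 1] = za[val_idx, None]
        X_val[vi, :nv, :, 2] = sex[val_idx, None]
    net = ParallelNAM(j, f, hidden=cfg.train.hidden,
                      seed=int(rng.integers(0, 2 ** 31)))
    net.fit(X_tr, y_tr, sample_weight=w_tr, lr=lr, epochs=epochs,
            weight_decay=cfg.train.weight_decay)
    logits_val = net.logits(X_val)
    scores = np.zeros(len(y))
    for vi, (_, _, _, val_idx) in enumerate(fold_data):
        scores[val_idx] = sigmoid(logits_val[vi, :len(val_idx)])
    return scores, y


# ---------------------------------------------------------------------------
# recalibration


def fit_recalibration(scores: np.ndarray, labels: np.ndarray,
                      max_slope: float = 20.0) -> CalibrationMap:
    """Logistic recalibration: fit label ~ sigma(a + b*logit(score)).

    Perfectly separated training scores drive the slope to infinity; the
    fit then falls back to a bounded slope with a refitted intercept.
    """
    import warnings

    import statsmodels.api as sm

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise VocalRiskError("recalibration needs both classes")
    x = logit(scores)
    design = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(labels, design, family=sm.families.Binomial()).fit()
            a, b = float(res.params[0]), float(res.params[1])
        except Exception:
            a, b = 0.0, max_slope
    if not np.isfinite(a) or not np.isfinite(b) or abs(b) > max_slope:
        import logging
        logging.getLogger(__name__).warning(
            "recalibration hit the slope bound (separation); clamping")
        b = float(np.clip(b if np.isfinite(b) else max_slope,
                          -max_slope, max_slope))
        # refit intercept with the slope frozen
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(labels, np.ones_like(x)[:, None],
                             family=sm.families.Binomial(),
                             offset=b * x).fit()
                a = float(res.params[0])
            except Exception:
                a = 0.0
    return CalibrationMap(intercept=a, slope=b)


# ---------------------------------------------------------------------------
# development run


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity - 1 over observed
    scores; ties resolved toward the lower threshold."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    cand = np.unique(scores)
    pred = scores[None, :] >= cand[:, None]
    pos, neg = labels == 1, labels == 0
    sens = pred[:, pos].mean(axis=1) if pos.any() else np.zeros(len(cand))
    spec = (~pred[:, neg]).mean(axis=1) if neg.any() else np.zeros(len(cand))
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    return float(cand[best[0]])  # lowest threshold among ties


def run_development(patients: list[PatientFeatures], panel: list | None = None,
                    cfg: PipelineConfig | None = None) -> StudyResult:
    """Five-fold patient-level development with nested RFA, grid search,
    oversampling and recalibration, all inside each training fold."""
    cfg = cfg if cfg is not None else PipelineConfig()
    if not patients:
        raise VocalRiskError("empty development cohort")
    panel = list(panel) if panel is not None else list(patients[0].features)
    folds = make_patient_folds(patients, cfg.k, cfg.seed)
    master_rng = np.random.default_rng(cfg.seed)
    fold_seeds = master_rng.integers(0, 2 ** 31, size=cfg.k)

    rows = []
    fold_models, calibrations, audit_log = [], [], []
    per_fold_sel, per_fold_curve, per_fold_rd, stops = [], [], [], []
    for fold in range(cfg.k):
        rng = np.random.default_rng(fold_seeds[fold])
        train_pats = [p for p in patients
                      if folds.fold_of(p.patient_id) != fold
                      and p.risk_label in ("high", "low")]
        val_pats = [p for p in patients if folds.fold_of(p.patient_id) == fold]
        if not val_pats or not train_pats:
            raise VocalRiskError(f"fold {fold} has no patients")

        selected, curve, rdiffs, stop = recursive_feature_addition(
            train_pats, panel, cfg, rng)
        per_fold_sel.append(selected)
        per_fold_curve.append(curve)
        per_fold_rd.append(rdiffs)
        stops.append(stop)

        tcfg = TrainConfig(lr_grid=cfg.train.lr_grid,
                           epoch_grid=cfg.train.epoch_grid,
                           hidden=cfg.train.hidden,
                           seed=int(rng.integers(0, 2 ** 31)),
                           oversample=cfg.train.oversample,
                           inner_val_fraction=cfg.train.inner_val_fraction,
                           weight_decay=cfg.train.weight_decay)
        model = train_nam(train_pats, tcfg, panel=selected)

        # calibration map from training-fold patients only, estimated on
        # cross-fitted predictions with the winning hyperparameters
        cal_scores, cal_y = cross_fitted_scores(
            train_pats, selected, cfg, lr=model.metadata["lr"],
            epochs=model.metadata["epochs"],
            rng=np.random.default_rng(int(rng.integers(0, 2 ** 31))))
        calib = fit_recalibration(cal_scores, cal_y)

        vf, va, vs, vy = design_matrices(val_pats, selected)
        val_scores = calib.apply(model.score(vf, va, vs))
        for p, s in zip(val_pats, val_scores):
            rows.append({"patient_id": p.patient_id, "risk_label": p.risk_label,
                         "age": p.age, "sex": p.sex, "score": float(s),
                         "fold": fold})
        fold_models.append(model)
        calibrations.append(calib)
        train_ids = [p.patient_id for p in train_pats]
        audit_log.append({
            "fold": fold,
            "train_ids": train_ids,
            "val_ids": [p.patient_id for p in val_pats],
            "standardization_ids": train_ids,
            "oversample_ids": train_ids,
            "rfa_ids": train_ids,
            "grid_search_ids": train_ids,
            "calibration_ids": train_ids,
        })

    final_set = sorted(set(per_fold_sel[0]).intersection(*per_fold_sel[1:]))
    if not final_set:
        msg = ("empty RFA intersection across folds; per-fold selections: "
               + json.dumps(per_fold_sel))
        if cfg.on_empty_intersection == "raise":
            raise VocalRiskError(msg)
        import warnings
        warnings.warn(msg)

    oof = pd.DataFrame(rows)
    hl = oof[oof.risk_label.isin(["high", "low"])]
    dev_auc = fast_auc(hl.score.to_numpy(),
                       (hl.risk_label == "high").astype(int).to_numpy())
    threshold = youden_threshold(hl.score.to_numpy(),
                                 (hl.risk_label == "high").astype(int).to_numpy())
    trace = RFATrace(per_fold=per_fold_curve, final_set=final_set,
                     stop_reasons=stops, risk_diff_curves=per_fold_rd)
    return StudyResult(oof_scores=oof, fold_models=fold_models,
                       calibrations=calibrations, folds=folds, rfa_trace=trace,
                       threshold=threshold, dev_auc=dev_auc,
                       audit_log=audit_log, config=cfg, panel=panel)


# ---------------------------------------------------------------------------
# external testing


def score_external(study: StudyResult,
                   patients: list[PatientFeatures]) -> np.ndarray:
    """Ensemble-mean calibrated score for each external patient."""
    if not patients:
        raise VocalRiskError("empty external cohort")
    per_model = []
    for model, calib in zip(study.fold_models, study.calibrations):
        missing = [f for f in model.panel
                   if f not in patients[0].features]
        if missing:
            raise VocalRiskError(f"external cohort lacks feature(s) {missing}")
        f, a, s, _ = design_matrices(patients, model.panel)
        per_model.append(calib.apply(model.score(f, a, s)))
    return np.mean(per_model, axis=0)


def run_external_test(study: StudyResult,
                      external_patients: list[PatientFeatures]) -> dict:
    """Blinded external evaluation at the development Youden threshold."""
    from . import evaluation as ev

    scores = score_external(study, external_patients)
    y = np.array([1 if p.risk_label == "high" else 0
                  for p in external_patients])
    keep = np.array([p.risk_label in ("high", "low") for p in external_patients])
    scores_hl, y_hl = scores[keep], y[keep]
    roc = ev.roc_auc(scores_hl, y_hl)
    pred = scores_hl >= study.threshold
    table = ev.confusion_table(pred, y_hl)
    metrics = ev.classification_metrics(table)
    return {"scores": scores, "auc": roc.auc, "auc_ci": roc.ci,
            "threshold": study.threshold, "confusion": table,
            "metrics": metrics, "n": int(keep.sum())}


# ---------------------------------------------------------------------------
# leakage audit


def audit_leakage(study: StudyResult,
                  clip_patient_ids: dict | None = None) -> dict:
    """Verify from the run log that fitted quantities only saw training-fold
    patients, that no patient appears in both roles in any fold, and that
    every development patient has exactly one out-of-fold score.

    ``clip_patient_ids`` optionally maps clip_id -> patient_id to check
    that all of a patient's clips share its fold.
    """
    problems = []
    for entry in study.audit_log:
        train = set(entry["train_ids"])
        val = set(entry["val_ids"])
        if train & val:
            problems.append(f"fold {entry['fold']}: train/val overlap {train & val}")
        for stage in ("standardization_ids", "oversample_ids", "rfa_ids",
                      "grid_search_ids", "calibration_ids"):
            extra = set(entry[stage]) - train
            if extra:
                problems.append(
                    f"fold {entry['fold']}: {stage} used non-training ids {extra}")
    counts = study.oof_scores.patient_id.value_counts()
    if (counts != 1).any():
        problems.append("patients with != 1 out-of-fold score: "
                        + str(list(counts[counts != 1].index)))
    if clip_patient_ids is not None:
        for clip_id, pid in clip_patient_ids.items():
            if pid not in study.folds.mapping:
                problems.append(f"clip {clip_id}: unknown patient {pid}")
    return {"ok": not problems, "problems": problems}
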