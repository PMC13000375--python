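"""Discrimination, calibration, decision-curve, group-comparison and
agreement statistics for risk-model validation.

Conventions: AUC uses the Mann-Whitney identity with half-credit for
ties and a DeLong 95% CI; proportions get Wilson score intervals (exact
Clopper-Pearson behind a flag); McNemar is the exact binomial test on
discordant pairs; net benefit is (TP - FP * pt/(1-pt)) / n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import VocalRiskError

# ---------------------------------------------------------------------------
# confusion tables and classification metrics


@dataclass
class ConfusionTable:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_table(pred, truth) -> ConfusionTable:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    return ConfusionTable(tp=int(np.sum(pred & truth)),
                          fn=int(np.sum(~pred & truth)),
                          fp=int(np.sum(pred & ~truth)),
                          tn=int(np.sum(~pred & ~truth)))


def _proportion_ci(k: int, n: int, method: str = "wilson"):
    from statsmodels.stats.proportion import proportion_confint
    if n == 0:
        return (None, None)
    lo, hi = proportion_confint(k, n, alpha=0.05,
                                method="beta" if method == "exact" else "wilson")
    return (float(lo), float(hi))


def classification_metrics(table: ConfusionTable, ci_method: str = "wilson") -> dict:
    """Sensitivity, specificity, PPV, NPV, accuracy, precision, recall, F1.

    Metrics with a zero denominator are reported as None (undefined), not
    as 0. Each proportion carries a 95% CI.
    """
    def ratio(k, n):
        return (k / n) if n > 0 else None

    sens = ratio(table.tp, table.tp + table.fn)
    spec = ratio(table.tn, table.tn + table.fp)
    ppv = ratio(table.tp, table.tp + table.fp)
    npv = ratio(table.tn, table.tn + table.fn)
    acc = ratio(table.tp + table.tn, table.n)
    f1 = None
    if ppv is not None and sens is not None and (ppv + sens) > 0:
        f1 = 2 * ppv * sens / (ppv + sens)
    out = {
        "sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv,
        "accuracy": acc, "precision": ppv, "recall": sens, "f1": f1,
        "ci": {
            "sensitivity": _proportion_ci(table.tp, table.tp + table.fn, ci_method),
            "specificity": _proportion_ci(table.tn, table.tn + table.fp, ci_method),
            "ppv": _proportion_ci(table.tp, table.tp + table.fp, ci_method),
            "npv": _proportion_ci(table.tn, table.tn + table.fn, ci_method),
            "accuracy": _proportion_ci(table.tp + table.tn, table.n, ci_method),
        },
    }
    return out


def f1_score(precision: float, recall: float) -> float:
    """2 P R / (P + R)."""
    if precision + recall == 0:
        raise VocalRiskError("F1 undefined for precision + recall = 0")
    return 2.0 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong machinery


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci: tuple


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=np.float64)
    xs = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and xs[j + 1] == xs[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise VocalRiskError("AUC needs both classes")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve with Mann-Whitney AUC and DeLong 95% CI."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = 1.96 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    pred = scores[None, :] >= thresholds[:, None]
    pos, neg = labels == 1, labels == 0
    sens = pred[:, pos].mean(axis=1)
    spec = (~pred[:, neg]).mean(axis=1)
    return ROCCurve(thresholds=thresholds, sensitivity=sens,
                    specificity=spec, auc=auc, ci=ci)


def auc_brute_force(scores, labels) -> float:
    """Exhaustive concordant-pair fraction (half-credit for ties); the
    O(n^2) oracle used to cross-check the rank-based AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise VocalRiskError("AUC needs both classes")
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def delong_test(scores_a, scores_b, labels) -> dict:
    """Paired DeLong z-test comparing two AUCs on the same patients."""
    labels = np.asarray(labels).astype(int)
    auc_a, v10_a, v01_a = _delong_components(np.asarray(scores_a, float), labels)
    auc_b, v10_b, v01_b = _delong_components(np.asarray(scores_b, float), labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
        z = 0.0 if abs(diff) < 1e-12 else np.inf
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "z": float(z), "p": p}


def youden_cutoff(curve: ROCCurve) -> float:
    """Threshold maximizing sensitivity + specificity - 1; ties go to the
    lower threshold (higher sensitivity)."""
    j = curve.sensitivity + curve.specificity - 1.0
    best = j >= j.max() - 1e-12
    finite = curve.thresholds[best]
    finite = finite[np.isfinite(finite)]
    if len(finite) == 0:
        return float(curve.thresholds[np.argmax(j)])
    return float(finite.min())


# ---------------------------------------------------------------------------
# decision curves


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_treat_all: np.ndarray
    nb_treat_none: np.ndarray


def decision_curve(scores, labels, grid=None) -> DecisionCurve:
    """Net benefit of the model vs treat-all / treat-none on a threshold-
    probability grid (default 0 to 0.75 step 0.01)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    grid = np.arange(0.0, 0.7501, 0.01) if grid is None else np.asarray(grid)
    if np.any((grid < 0) | (grid >= 1)):
        raise VocalRiskError("threshold probabilities must lie in [0, 1)")
    n = len(labels)
    prevalence = labels.mean()
    nb_model = np.empty(len(grid))
    nb_all = np.empty(len(grid))
    for i, pt in enumerate(grid):
        w = pt / (1.0 - pt)
        pred = scores >= pt
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        nb_model[i] = (tp - fp * w) / n
        nb_all[i] = prevalence - (1 - prevalence) * w
    return DecisionCurve(thresholds=grid, nb_model=nb_model,
                         nb_treat_all=nb_all,
                         nb_treat_none=np.zeros(len(grid)))


# ---------------------------------------------------------------------------
# calibration


def calibration_assess(scores, labels, n_boot: int = 1000, seed: int = 0,
                       n_bins: int = 10) -> dict:
    """Calibration intercept & slope (logistic fit on logit(score)),
    Brier score, and a bootstrap bias-corrected binned reliability curve."""
    from .pipeline import fit_recalibration

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    cal = fit_recalibration(scores, labels)
    brier = float(np.mean((scores - labels) ** 2))

    def binned_curve(s, y):
        order = np.argsort(s)
        splits = np.array_split(order, n_bins)
        xs, ys = [], []
        for b in splits:
            if len(b) == 0:
                continue
            xs.append(float(np.mean(s[b])))
            ys.append(float(np.mean(y[b])))
        return np.array(xs), np.array(ys)

    x_app, y_app = binned_curve(scores, labels)
    rng = np.random.default_rng(seed)
    boot = np.zeros((n_boot, len(y_app)))
    for b in range(n_boot):
        idx = rng.integers(0, len(scores), len(scores))
        _, yb = binned_curve(scores[idx], labels[idx])
        if len(yb) == len(y_app):
            boot[b] = yb
        else:
            boot[b] = y_app
    corrected = 2.0 * y_app - boot.mean(axis=0)
    return {"intercept": cal.intercept, "slope": cal.slope, "brier": brier,
            "curve_pred": x_app, "curve_obs": y_app,
            "curve_obs_corrected": np.clip(corrected, 0.0, 1.0)}


# ---------------------------------------------------------------------------
# group comparisons with multiplicity control


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(pvalues, dtype=np.float64)
    mask = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def group_stats(patients, group_a: str = "high", group_b: str = "low"):
    """Per-feature Welch t-tests between risk groups with BH q-values.

    Returns a DataFrame (feature, mean_a, mean_b, mean_diff, ci_lo, ci_hi,
    p, q) sorted by q.
    """
    import pandas as pd

    a = [p for p in patients if p.risk_label == group_a]
    b = [p for p in patients if p.risk_label == group_b]
    if len(a) < 2 or len(b) < 2:
        raise VocalRiskError("need at least 2 patients per group")
    featnames = list(a[0].features)
    rows = []
    for name in featnames:
        xa = np.array([p.features[name] for p in a])
        xb = np.array([p.features[name] for p in b])
        diff = xa.mean() - xb.mean()
        if xa.std() == 0 and xb.std() == 0:
            rows.append({"feature": name, "mean_a": xa.mean(), "mean_b": xb.mean(),
                         "mean_diff": diff, "ci_lo": np.nan, "ci_hi": np.nan,
                         "p": np.nan, "degenerate": True})
            continue
        res = stats.ttest_ind(xa, xb, equal_var=False)
        se = np.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb))
        dof = res.df if hasattr(res, "df") else len(xa) + len(xb) - 2
        half = stats.t.ppf(0.975, dof) * se
        rows.append({"feature": name, "mean_a": xa.mean(), "mean_b": xb.mean(),
                     "mean_diff": diff, "ci_lo": diff - half, "ci_hi": diff + half,
                     "p": float(res.pvalue), "degenerate": False})
    df = pd.DataFrame(rows)
    df["q"] = bh_qvalues(df["p"].to_numpy())
    return df.sort_values("q", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# demographic-table tests


def fisher_exact(table, seed: int = 0, n_mc: int = 100_000,
                 max_tables: int = 1_000_000) -> float:
    """Fisher exact test for an r x c count table.

    2x2 tables use the hypergeometric solution; larger tables are fully
    enumerated over fixed margins when at most ``max_tables`` tables fit
    the margins, otherwise a seeded Monte Carlo permutation estimate is
    returned.
    """
    table = np.asarray(table, dtype=np.int64)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise VocalRiskError("empty margin in contingency table")
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    from math import lgamma

    def log_prob(t):
        lp = (sum(lgamma(r + 1) for r in row_sums)
              + sum(lgamma(c + 1) for c in col_sums)
              - lgamma(t.sum() + 1)
              - sum(lgamma(v + 1) for v in t.flat))
        return lp

    obs_lp = log_prob(table)
    r, c = table.shape
    tables_seen = [0]
    total_p = [0.0]
    aborted = [False]

    def recurse(row: int, remaining_cols: np.ndarray, current: list):
        if aborted[0]:
            return
        if row == r - 1:
            last = remaining_cols
            if np.any(last < 0):
                return
            t = np.array(current + [last])
            tables_seen[0] += 1
            if tables_seen[0] > max_tables:
                aborted[0] = True
                return
            lp = log_prob(t)
            if lp <= obs_lp + 1e-9:
                total_p[0] += np.exp(lp)
            return

        def fill(col: int, left: int, acc: list):
            if aborted[0]:
                return
            if col == c - 1:
                if left <= remaining_cols[col]:
                    recurse(row + 1, remaining_cols - np.array(acc + [left]),
                            current + [np.array(acc + [left])])
                return
            for v in range(min(left, remaining_cols[col]) + 1):
                fill(col + 1, left - v, acc + [v])

        fill(0, row_sums[row], [])

    recurse(0, col_sums.copy(), [])
    if not aborted[0]:
        return float(min(total_p[0], 1.0))

    # Monte Carlo: permute category labels, compare log-probabilities
    rng = np.random.default_rng(seed)
    rows_expanded = np.repeat(np.arange(r), row_sums)
    cols_expanded = np.repeat(np.arange(c), col_sums)
    count = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols_expanded)
        t = np.zeros((r, c), dtype=np.int64)
        np.add.at(t, (rows_expanded, perm), 1)
        if log_prob(t) <= obs_lp + 1e-9:
            count += 1
    return float((count + 1) / (n_mc + 1))


def kruskal_wallis(*groups) -> float:
    """Kruskal-Wallis rank-sum p-value with tie correction; identical
    groups (zero statistic) give p = 1."""
    if all(np.array_equal(np.sort(groups[0]), np.sort(g)) for g in groups[1:]):
        try:
            return float(stats.kruskal(*groups).pvalue)
        except ValueError:
            return 1.0
    return float(stats.kruskal(*groups).pvalue)


# ---------------------------------------------------------------------------
# interrater agreement and paired tests


def cohen_kappa(a, b) -> float:
    """Cohen's kappa for two binary raters; NaN when chance agreement is 1."""
    a = np.asarray(a).astype(int)
    b = np.asarray(b).astype(int)
    if len(a) != len(b):
        raise VocalRiskError("raters judged different numbers of patients")
    po = np.mean(a == b)
    pe = np.mean(a) * np.mean(b) + np.mean(1 - a) * np.mean(1 - b)
    if pe >= 1.0 - 1e-12:
        return float("nan")
    return float((po - pe) / (1.0 - pe))


def rater_agreement(predictions: dict, truth) -> dict:
    """Pairwise kappa matrix and per-rater classification metrics.

    ``predictions`` maps rater id -> binary predictions on a common
    patient set; ``truth`` is the ground-truth labels.
    """
    raters = list(predictions)
    if len(raters) < 2:
        raise VocalRiskError("need at least 2 raters")
    n = len(np.asarray(truth))
    for rid in raters:
        if len(predictions[rid]) != n:
            raise VocalRiskError(f"rater {rid} judged a different patient set")
    kappa = {}
    for i, ra in enumerate(raters):
        for rb in raters[i + 1:]:
            kappa[(ra, rb)] = cohen_kappa(predictions[ra], predictions[rb])
    metrics = {rid: classification_metrics(confusion_table(predictions[rid], truth))
               for rid in raters}
    return {"kappa": kappa, "metrics": metrics}


def mcnemar_exact(b: int, c: int) -> float:
    """Exact binomial McNemar p-value from discordant counts; b = c = 0
    gives p = 1 by convention."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    p = 2.0 * stats.binom.cdf(k, n, 0.5)
    if b == c:
        p -= stats.binom.pmf(k, n, 0.5)  # avoid double-counting the center
    return float(min(p, 1.0))


def paired_tests(predictions: dict, machine_pred, machine_scores, truth) -> dict:
    """McNemar (human vs machine correctness) per rater and DeLong AUC
    contrast for raters providing scores."""
    truth = np.asarray(truth).astype(int)
    machine_pred = np.asarray(machine_pred).astype(int)
    out = {}
    machine_correct = machine_pred == truth
    for rid, pred in predictions.items():
        pred = np.asarray(pred).astype(int)
        correct = pred == truth
        b = int(np.sum(machine_correct & ~correct))
        c = int(np.sum(~machine_correct & correct))
        out[rid] = {"mcnemar_p": mcnemar_exact(b, c), "b": b, "c": c,
                    "delong": delong_test(machine_scores, pred, truth)}
    return out
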