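"""Vector-graphic summaries of a study: risk-score distributions, ROC,
decision curves, calibration, and the feature-addition path."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_risk_scores(oof_scores, path: str | Path) -> None:
    """Box plot of out-of-fold risk scores by risk group."""
    order = [g for g in ("high", "moderate", "low")
             if (oof_scores.risk_label == g).any()]
    data = [oof_scores.score[oof_scores.risk_label == g] for g in order]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(data, tick_labels=order, showmeans=True,
               meanprops={"marker": "D", "markerfacecolor": "black",
                          "markeredgecolor": "black"})
    ax.set_ylabel("calibrated risk score")
    ax.set_xlabel("aspiration-risk group")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_roc(curves: dict, path: str | Path) -> None:
    """Overlaid ROC curves; ``curves`` maps label -> ROCCurve."""
    fig, ax = plt.subplots(figsize=(4.2, 4))
    for label, c in curves.items():
        ax.plot(1 - c.specificity, c.sensitivity,
                label=f"{label} (AUC {c.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_decision_curve(dc, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.plot(dc.thresholds, dc.nb_model, label="model")
    ax.plot(dc.thresholds, dc.nb_treat_all, label="treat all")
    ax.plot(dc.thresholds, dc.nb_treat_none, label="treat none")
    ax.set_ylim(bottom=max(-0.05, dc.nb_treat_all.min() - 0.02))
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_calibration(assessment: dict, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="ideal")
    ax.plot(assessment["curve_pred"], assessment["curve_obs"],
            "o-", label="apparent")
    ax.plot(assessment["curve_pred"], assessment["curve_obs_corrected"],
            "s-", label="bias-corrected")
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed proportion")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_rfa_curve(trace, path: str | Path) -> None:
    """Feature-addition paths per fold: inner-CV AUC and the mean
    risk-score difference after each addition."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    for fold, (curve, rd) in enumerate(zip(trace.per_fold,
                                           trace.risk_diff_curves)):
        steps = np.arange(1, len(curve) + 1)
        axes[0].plot(steps, [a for _, a in curve], marker="o",
                     label=f"fold {fold}")
        axes[1].plot(np.arange(1, len(rd) + 1), rd, marker="o")
    axes[0].set_xlabel("features added")
    axes[0].set_ylabel("inner-CV AUC")
    axes[0].legend(fontsize=7)
    axes[1].set_xlabel("features added")
    axes[1].set_ylabel("mean risk-score difference")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
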