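"""Cross-validated model evaluation and randomized-trial statistics.

Model evaluation reports accuracy, macro-F1, one-vs-rest macro AUC and the
4x4 confusion matrix, computed only on original (non-synthetic) validation
rows of a leakage-safe fold plan. Trial analysis covers baseline-adjusted
ANCOVA group effects, paired within-group change with t-based confidence
intervals, Cohen's d on change scores, McNemar's test on the unhealthy-
weight dichotomy, and row-normalized category transition tables. Analysis
is per-protocol (completers only) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score, roc_auc_score

from .cohort import TrialRecord
from .extractor import ExtractorConfig, train_extractor
from .gbm import GBMConfig, fit_gbm, predict_proba
from .preprocess import FoldPlan, tensorize


# ---------------------------------------------------------------------------
# cross-validated classification metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    per_fold: pd.DataFrame
    pooled_accuracy: float
    pooled_macro_f1: float
    pooled_macro_auc: float
    confusion: np.ndarray
    model_id: str = "extractor+gbm"

    def to_markdown(self) -> str:
        lines = [
            f"Model: {self.model_id}",
            f"Pooled accuracy: {self.pooled_accuracy:.3f}",
            f"Pooled macro-F1: {self.pooled_macro_f1:.3f}",
            f"Pooled macro-AUC: {self.pooled_macro_auc:.3f}",
            "Confusion matrix (rows = true):",
            str(self.confusion),
        ]
        return "\n".join(lines)


def _macro_auc_ovr(y_true: np.ndarray, proba: np.ndarray, n_classes: int = 4) -> float:
    """One-vs-rest macro AUC, skipping classes absent from y_true."""
    aucs = []
    for c in range(n_classes):
        pos = y_true == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} absent from evaluation set; AUC skipped",
                          stacklevel=2)
            continue
        aucs.append(roc_auc_score(pos.astype(int), proba[:, c]))
    return float(np.mean(aucs))


def evaluate_predictions(
    y_true: np.ndarray, proba: np.ndarray, n_classes: int = 4
) -> dict[str, float]:
    y_pred = np.argmax(proba, axis=1)
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "macro_f1": float(f1_score(y_true, y_pred, average="macro",
                                   labels=list(range(n_classes)), zero_division=0)),
        "macro_auc": _macro_auc_ovr(y_true, proba, n_classes),
    }


def evaluate_cv(
    X: np.ndarray,
    y: np.ndarray,
    fold_plan: FoldPlan,
    extractor_config: ExtractorConfig,
    gbm_config: GBMConfig,
) -> MetricsReport:
    """Train extractor + GBM per fold and score original validation rows.

    Within each fold the extractor trains on the fold's augmented training
    set (with the fold's validation originals as the early-stopping set),
    the GBM trains on the training embeddings, and all metrics come from
    the original validation subjects only.
    """
    rows = []
    all_true, all_pred, all_proba = [], [], []
    for i, fold in enumerate(fold_plan.folds):
        cfg = ExtractorConfig(**{**extractor_config.__dict__,
                                 "seed": extractor_config.seed + i})
        model, _ = train_extractor(
            tensorize(fold.X_train), fold.y_train,
            tensorize(fold.X_val), fold.y_val, cfg,
        )
        z_train = model.embed_views(tensorize(fold.X_train))
        z_val = model.embed_views(tensorize(fold.X_val))
        gcfg = GBMConfig(**{**gbm_config.__dict__, "seed": gbm_config.seed + i})
        gbm = fit_gbm(z_train, fold.y_train, gcfg)
        proba = predict_proba(gbm, z_val)
        m = evaluate_predictions(fold.y_val, proba)
        m["fold"] = i
        rows.append(m)
        all_true.append(fold.y_val)
        all_pred.append(np.argmax(proba, axis=1))
        all_proba.append(proba)
    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    proba = np.vstack(all_proba)
    return MetricsReport(
        per_fold=pd.DataFrame(rows),
        pooled_accuracy=float(accuracy_score(y_true, y_pred)),
        pooled_macro_f1=float(f1_score(y_true, y_pred, average="macro",
                                       labels=[0, 1, 2, 3], zero_division=0)),
        pooled_macro_auc=_macro_auc_ovr(y_true, proba),
        confusion=confusion_matrix(y_true, y_pred, labels=[0, 1, 2, 3]),
    )


# ---------------------------------------------------------------------------
# trial statistics
# ---------------------------------------------------------------------------

def within_group_change(
    baseline: np.ndarray, post: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Paired mean change with a t-based confidence interval.

    Zero-variance differences give a degenerate interval at the change.
    """
    baseline = np.asarray(baseline, dtype=float)
    post = np.asarray(post, dtype=float)
    if baseline.shape != post.shape:
        raise ValueError("baseline and post must be paired (same length)")
    if len(baseline) < 2:
        raise ValueError("need at least 2 paired observations")
    diff = post - baseline
    mean = float(diff.mean())
    se = float(diff.std(ddof=1) / np.sqrt(len(diff)))
    if se == 0:
        return mean, (mean, mean)
    tcrit = st.t.ppf(1 - alpha / 2, len(diff) - 1)
    return mean, (mean - tcrit * se, mean + tcrit * se)


def ancova_group_effect(
    baseline: np.ndarray,
    post: np.ndarray,
    arm: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float], float]:
    """Baseline-adjusted treatment effect: post ~ arm + baseline (OLS).

    `arm` is 1 for intervention, 0 for control (string labels accepted).
    Returns (tau_hat, Wald CI, p-value) for the arm coefficient.
    """
    baseline = np.asarray(baseline, dtype=float)
    post = np.asarray(post, dtype=float)
    arm = np.asarray(arm)
    if arm.dtype.kind in "UOS":
        arm = (arm == "intervention").astype(float)
    arm = arm.astype(float)
    if len(np.unique(arm)) < 2:
        raise ValueError("both arms must be represented")
    X = sm.add_constant(np.column_stack([arm, baseline]))
    fit = sm.OLS(post, X).fit()
    ci = fit.conf_int(alpha=alpha)[1]
    return float(fit.params[1]), (float(ci[0]), float(ci[1])), float(fit.pvalues[1])


def cohens_d_change(change_a: np.ndarray, change_b: np.ndarray) -> float:
    """Standardized between-group difference of change scores (pooled SD)."""
    a = np.asarray(change_a, dtype=float)
    b = np.asarray(change_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 change scores per group")
    pooled = np.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    if pooled == 0:
        raise ZeroDivisionError("zero pooled SD; d undefined")
    return float((a.mean() - b.mean()) / pooled)


def mcnemar_shift(
    pre_category: np.ndarray, post_category: np.ndarray, exact_below: int = 25
) -> tuple[float, float]:
    """McNemar's test on the unhealthy-weight dichotomy (overweight | obese).

    Continuity-corrected chi-square, chi2 = (max(|b - c| - 1, 0))^2 / (b + c),
    with an exact two-sided binomial fallback when the discordant count
    b + c < exact_below; b + c = 0 gives p = 1 by convention.
    """
    pre = np.asarray(pre_category, dtype=int) >= 2
    post = np.asarray(post_category, dtype=int) >= 2
    if pre.shape != post.shape:
        raise ValueError("paired categories required")
    b = int(np.sum(pre & ~post))   # unhealthy -> healthy
    c = int(np.sum(~pre & post))   # healthy -> unhealthy
    if b + c == 0:
        return 0.0, 1.0
    stat = max(abs(b - c) - 1, 0) ** 2 / (b + c)
    if b + c < exact_below:
        p = min(1.0, 2.0 * st.binom.cdf(min(b, c), b + c, 0.5))
    else:
        p = float(st.chi2.sf(stat, df=1))
    return float(stat), float(p)


def transition_rates(
    pre_category: np.ndarray, post_category: np.ndarray, n_classes: int = 4
) -> np.ndarray:
    """Row-normalized 4x4 category transition matrix (rows = baseline)."""
    pre = np.asarray(pre_category, dtype=int)
    post = np.asarray(post_category, dtype=int)
    if pre.shape != post.shape:
        raise ValueError("paired categories required")
    counts = np.zeros((n_classes, n_classes))
    np.add.at(counts, (pre, post), 1)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(totals > 0, counts / totals, 0.0)
    return rates


def percent_change(baseline_mean: float, post_mean: float, kind: str = "time") -> float:
    """Percent change for reporting, one-decimal rounding.

    Time metrics report decreases as positive (100 * (baseline - post) /
    baseline); count metrics report increases as positive.
    """
    if baseline_mean == 0:
        raise ZeroDivisionError("zero baseline mean")
    if kind == "time":
        value = 100.0 * (baseline_mean - post_mean) / baseline_mean
    elif kind == "count":
        value = 100.0 * (post_mean - baseline_mean) / baseline_mean
    else:
        raise ValueError("kind must be 'time' or 'count'")
    return round(value, 1)


# ---------------------------------------------------------------------------
# full trial outcome table
# ---------------------------------------------------------------------------

TRIAL_METRICS = {
    "pull_ups": ("count", lambda r: r.pull_ups),
    "run_total_s": ("time", lambda r: r.run_total),
    "shuttle_s": ("time", lambda r: r.shuttle_time),
    "sit_ups": ("count", lambda r: r.sit_ups),
}


@dataclass
class TrialOutcome:
    metrics: pd.DataFrame = field(repr=False)
    mcnemar_stat: float = float("nan")
    mcnemar_p: float = float("nan")
    transitions: np.ndarray | None = None

    def to_markdown(self) -> str:
        lines = [self.metrics.to_markdown(index=False)]
        lines.append(
            f"\nMcNemar (unhealthy-weight shift): stat={self.mcnemar_stat:.3f}, "
            f"p={self.mcnemar_p:.3g}"
        )
        return "\n".join(lines)


def analyze_trial(records: list[TrialRecord], completers_only: bool = True) -> TrialOutcome:
    """Per-protocol outcome analysis of a simulated two-arm trial."""
    recs = [r for r in records if r.completed] if completers_only else records
    arms = {"intervention": [r for r in recs if r.arm == "intervention"],
            "control": [r for r in recs if r.arm == "control"]}
    rows = []
    for metric, (kind, get) in TRIAL_METRICS.items():
        values = {
            arm: (np.array([get(r.baseline) for r in group], dtype=float),
                  np.array([get(r.post) for r in group], dtype=float))
            for arm, group in arms.items()
        }
        base_all = np.concatenate([values[a][0] for a in arms])
        post_all = np.concatenate([values[a][1] for a in arms])
        arm_all = np.concatenate(
            [np.repeat(a, len(values[a][0])) for a in arms]
        )
        tau, ci, p = ancova_group_effect(base_all, post_all, arm_all)
        d = cohens_d_change(
            values["intervention"][1] - values["intervention"][0],
            values["control"][1] - values["control"][0],
        )
        for arm in arms:
            base, post = values[arm]
            delta, dci = within_group_change(base, post)
            rows.append(
                {
                    "metric": metric,
                    "group": arm,
                    "baseline_mean": base.mean(),
                    "baseline_sd": base.std(ddof=1),
                    "post_mean": post.mean(),
                    "post_sd": post.std(ddof=1),
                    "within_change": delta,
                    "within_ci_low": dci[0],
                    "within_ci_high": dci[1],
                    "percent_change": percent_change(base.mean(), post.mean(), kind),
                    "ancova_effect": tau if arm == "intervention" else np.nan,
                    "ancova_ci_low": ci[0] if arm == "intervention" else np.nan,
                    "ancova_ci_high": ci[1] if arm == "intervention" else np.nan,
                    "ancova_p": p if arm == "intervention" else np.nan,
                    "cohens_d": d if arm == "intervention" else np.nan,
                }
            )
    # category-shift analyses are reported for the personalized arm
    interv = arms["intervention"]
    pre = np.array([int(r.baseline.category) for r in interv])
    post = np.array([int(r.post.category) for r in interv])
    stat, p = mcnemar_shift(pre, post)
    return TrialOutcome(
        metrics=pd.DataFrame(rows),
        mcnemar_stat=stat,
        mcnemar_p=p,
        transitions=transition_rates(pre, post),
    )
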