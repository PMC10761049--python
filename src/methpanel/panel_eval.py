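"""Clinical-performance evaluation of the marker panel.

Covers the ROC layer (empirical curve, trapezoid AUC = Mann-Whitney
concordance, DeLong 95% CI, Youden-optimal cutoff), the dual-marker
combination (a logistic model on log2 levels, exposed as a scikit-learn
style estimator), cohort splitting (stratified 2:1 training/validation),
subgroup sensitivity/specificity tables, and the AFP comparator analysis
(fixed clinical cutoffs plus a specificity-matched threshold).

Percentages follow the screening convention: sensitivity = TP/(TP+FN)*100,
specificity = TN/(TN+FP)*100; a sample is called positive when its score is
at or above the cutoff.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .containers import RocCurve

__all__ = [
    "split_cohort",
    "roc_analysis",
    "MarkerPanelClassifier",
    "combine_markers",
    "classify",
    "subgroup_performance",
    "compare_afp",
    "group_tests",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Cohort splitting


def split_cohort(
    records: pd.DataFrame, seed: int, group_col: str = "group"
) -> pd.DataFrame:
    """Assign a stratified 2:1 training/validation split.

    Per group, ceil(2n/3) records go to training and the remainder to
    validation; the assignment is a seeded permutation, reproducible for a
    fixed seed. Returns a copy with a ``split`` column.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    out["split"] = ""
    for group, sub in records.groupby(group_col, sort=True):
        if len(sub) == 0:  # pragma: no cover - groupby yields non-empty groups
            logger.warning("group %s is empty; skipped in split", group)
            continue
        order = rng.permutation(len(sub))
        n_train = math.ceil(2 * len(sub) / 3)
        train_idx = sub.index.to_numpy()[order[:n_train]]
        val_idx = sub.index.to_numpy()[order[n_train:]]
        out.loc[train_idx, "split"] = "training"
        out.loc[val_idx, "split"] = "validation"
    return out


# --------------------------------------------------------------------------
# ROC / AUC / DeLong / Youden


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC (probability scale) and its DeLong variance."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(all_scores)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components over positives
    v10 = 1.0 - (tz[m:] - ty) / m  # over negatives
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def roc_analysis(scores, labels) -> RocCurve:
    """Empirical ROC with AUC (percent), DeLong 95% CI and Youden cutoff.

    ``labels`` is boolean/0-1 with True = diseased; larger scores are more
    disease-like. The AUC is the trapezoid over all distinct thresholds,
    identical to the Mann-Whitney concordant-pair fraction (ties counted
    half). The Youden cutoff maximizes J = sensitivity + specificity - 1;
    ties are broken toward the smallest threshold (highest sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("roc_analysis needs both classes present")

    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc01 = float(_trapezoid_auc(fpr, tpr))
    _, var = _delong_auc_variance(scores[labels], scores[~labels])
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    ci_low = max(0.0, auc01 - half)
    ci_high = min(1.0, auc01 + half)

    j = tpr - fpr
    # ties (to float resolution) resolve to the smallest threshold, i.e. the
    # last index since sklearn's thresholds descend
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[-1])
    cutoff = thresholds[best]
    if np.isinf(cutoff):  # degenerate: no finite threshold improves J
        cutoff = float(scores.max()) + 1.0
    return RocCurve(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=100.0 * auc01,
        ci_low=100.0 * ci_low,
        ci_high=100.0 * ci_high,
        youden_cutoff=float(cutoff),
        youden_sens=100.0 * float(tpr[best]),
        youden_spec=100.0 * float(1.0 - fpr[best]),
    )


def classify(scores, cutoff: float) -> np.ndarray:
    """Binary calls: positive iff score >= cutoff (inclusive)."""
    return np.asarray(scores, dtype=float) >= cutoff


# --------------------------------------------------------------------------
# Dual-marker combination


class MarkerPanelClassifier(BaseEstimator, ClassifierMixin):
    """Combine marker methylation levels into one panel score.

    method="logistic" (default) fits a logistic model on log2(level + eps);
    the score is the fitted disease probability, monotone in each marker.
    If the training data are linearly separable the unpenalised fit is
    degenerate and the estimator falls back to a rank-average score (logged).
    method="or" calibrates a per-marker Youden cutoff on the training data
    and scores each sample by its maximum level/cutoff ratio, so the
    either-marker-positive rule is the panel call at score >= 1.

    Attributes set by fit: ``model_`` (logistic mode), ``cutoffs_`` (or
    mode), ``fallback_`` (True when the rank-average fallback was used).
    """

    def __init__(self, method: str = "logistic", eps: float = 1e-6):
        self.method = method
        self.eps = eps

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return np.log2(np.asarray(X, dtype=float) + self.eps)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x markers)")
        if np.isnan(X).any():
            raise ValueError("marker levels must be non-missing (level 0 allowed)")
        if len(np.unique(y)) < 2:
            raise ValueError("fit needs both classes present")
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.unique(y)
        self.fallback_ = False
        if self.method == "or":
            self.cutoffs_ = np.array(
                [
                    roc_analysis(X[:, j], y).youden_cutoff
                    for j in range(X.shape[1])
                ]
            )
            return self
        if self.method != "logistic":
            raise ValueError(f"unknown method {self.method!r}")
        model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(self._transform(X), y)
        scores = model.predict_proba(self._transform(X))[:, 1]
        separable = scores[y == 1].min() > scores[y == 0].max()
        converged = int(np.asarray(model.n_iter_).max()) < model.max_iter
        if separable or not converged:
            # linearly separable training data: unpenalised coefficients
            # diverge and the fit is degenerate
            logger.info(
                "logistic combiner degenerate (separable training data); "
                "falling back to rank-average score"
            )
            self.fallback_ = True
        else:
            self.model_ = model
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.method == "or":
            safe = np.where(self.cutoffs_ != 0, self.cutoffs_, 1.0)
            return (X / safe).max(axis=1)
        if self.fallback_:
            ranks = np.column_stack(
                [stats.rankdata(X[:, j], method="average") for j in range(X.shape[1])]
            )
            return ranks.mean(axis=1) / len(X)
        return self.model_.predict_proba(self._transform(X))[:, 1]

    def predict_proba(self, X) -> np.ndarray:
        score = self.decision_function(X)
        return np.column_stack([1.0 - score, score])

    def predict(self, X) -> np.ndarray:
        threshold = 1.0 if self.method == "or" else 0.5
        return (self.decision_function(X) >= threshold).astype(int)


def combine_markers(
    levels_a, levels_b, labels, method: str = "logistic"
) -> tuple[np.ndarray, MarkerPanelClassifier]:
    """Fit the panel combiner and return per-sample combined scores.

    Fitting must happen on the training split only; apply the returned
    estimator unchanged to validation data via ``decision_function``.
    """
    X = np.column_stack([np.asarray(levels_a, float), np.asarray(levels_b, float)])
    est = MarkerPanelClassifier(method=method).fit(X, np.asarray(labels, int))
    return est.decision_function(X), est


# --------------------------------------------------------------------------
# Performance tables


def _pct(num: int, den: int) -> float | None:
    return round(100.0 * num / den, 2) if den else None


def subgroup_performance(calls, records: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity by HCC subgroup and specificity by control cohort.

    ``calls`` are the binary panel calls aligned to ``records`` rows.
    Sensitivity strata: all HCC, CNLC stage (I / II / III-IV), tumour count
    (single / multiple), and single-tumour size (<=3cm / >3cm). Records
    with an unknown stratum value are excluded from that stratum only.
    Specificity rows cover Normal, CLD and their combination. Each row
    carries its numerator and denominator; an empty stratum reports NA.
    """
    calls = np.asarray(calls, dtype=bool)
    if len(calls) != len(records):
        raise ValueError("calls must align with records")
    rec = records.reset_index(drop=True)
    hcc = rec["group"] == "HCC"

    rows = []

    def sens_row(stratum: str, mask: np.ndarray) -> None:
        den = int(mask.sum())
        num = int(calls[mask].sum())
        rows.append(("sensitivity", stratum, num, den, _pct(num, den)))

    sens_row("all", hcc.to_numpy())
    for stage in ("I", "II", "III-IV"):
        sens_row(f"stage {stage}", (hcc & (rec["cnlc_stage"] == stage)).to_numpy())
    count = pd.to_numeric(rec.get("tumour_count"), errors="coerce")
    sens_row("single tumour", (hcc & (count == 1)).to_numpy())
    sens_row("multiple tumours", (hcc & (count >= 2)).to_numpy())
    size = rec.get("single_tumour_size", pd.Series("", index=rec.index)).astype(str)
    sens_row("single tumour <=3cm", (hcc & (size == "<=3cm")).to_numpy())
    sens_row("single tumour >3cm", (hcc & (size == ">3cm")).to_numpy())

    def spec_row(stratum: str, mask: np.ndarray) -> None:
        den = int(mask.sum())
        num = int((~calls[mask]).sum())  # true negatives
        rows.append(("specificity", stratum, num, den, _pct(num, den)))

    spec_row("Normal", (rec["group"] == "Normal").to_numpy())
    spec_row("CLD", (rec["group"] == "CLD").to_numpy())
    spec_row("non-HCC combined", (~hcc).to_numpy())

    return pd.DataFrame(
        rows, columns=["metric", "stratum", "numerator", "denominator", "percent"]
    )


def compare_afp(
    afp,
    records: pd.DataFrame,
    fixed_cutoffs=(20.0,),
    matched_spec_target: float | None = None,
) -> pd.DataFrame:
    """AFP comparator analysis at fixed and specificity-matched cutoffs.

    For every fixed cutoff (ng/ml, call positive at AFP >= cutoff) the
    per-stage sensitivities and control specificity are tabulated. If
    ``matched_spec_target`` (percent) is given, the smallest AFP threshold
    whose specificity reaches the target is additionally reported (ties
    toward the smallest threshold); when unattainable the threshold is
    +inf with zero sensitivity.
    """
    afp = np.asarray(afp, dtype=float)
    if np.isnan(afp).any():
        raise ValueError("AFP must be present for every included record")
    rec = records.reset_index(drop=True)
    neg = (rec["group"] != "HCC").to_numpy()

    cutoffs = [("fixed", float(c)) for c in fixed_cutoffs]
    if matched_spec_target is not None:
        candidates = np.concatenate([np.unique(afp), [np.inf]])
        matched = np.inf
        for t in candidates:
            spec_calls = classify(afp[neg], t)
            spec = 100.0 * (~spec_calls).mean() if neg.sum() else 100.0
            # compare at the reporting precision (2 decimals)
            if round(spec, 2) >= round(matched_spec_target, 2):
                matched = float(t)
                break
        cutoffs.append(("matched", matched))

    frames = []
    for kind, cutoff in cutoffs:
        calls = classify(afp, cutoff)
        table = subgroup_performance(calls, rec)
        table.insert(0, "cutoff", cutoff)
        table.insert(0, "cutoff_kind", kind)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Group-difference tests


def group_tests(values, groupings, categorical: bool = False) -> float:
    """Dispatch the group-comparison test and return a two-sided p-value.

    Two groups: Wilcoxon rank-sum; more than two: Kruskal-Wallis;
    categorical variables: chi-square on the contingency table.
    """
    values = pd.Series(values).reset_index(drop=True)
    groupings = pd.Series(groupings).reset_index(drop=True)
    samples = [sub.to_numpy() for _, sub in values.groupby(groupings)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if categorical:
        table = pd.crosstab(groupings, values)
        return float(stats.chi2_contingency(table.to_numpy())[1])
    if len(samples) == 2:
        return float(stats.ranksums(samples[0], samples[1]).pvalue)
    return float(stats.kruskal(*samples).pvalue)
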