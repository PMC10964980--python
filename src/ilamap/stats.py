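"""Validation statistics for deceleration-zone vs slow-conduction isthmus.

Confusion-matrix metrics with the F score (class imbalance), ROC/AUC of
isochrones/cm for SC-AI discrimination, Spearman rank correlation with a
seeded permutation p-value, and the group-comparison tests (Wilcoxon rank
sum, Fisher exact).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    f_score: Optional[float]
    auc: Optional[float] = None
    rho: Optional[float] = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "f_score": self.f_score,
            "auc": self.auc, "rho": self.rho,
        }


def _ratio(num: int, den: int) -> Optional[float]:
    """Undefined ratios (zero denominator) are None, never 0."""
    return num / den if den > 0 else None


def confusion_metrics(predicted, truth) -> ClassificationReport:
    """Counts and derived metrics from predicted/true boolean flags."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size == 0:
        raise ValueError("empty inputs")
    tp = int(np.sum(predicted & truth))
    fp = int(np.sum(predicted & ~truth))
    fn = int(np.sum(~predicted & truth))
    tn = int(np.sum(~predicted & ~truth))
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    if prec is not None and sens is not None and (prec + sens) > 0:
        f = 2 * prec * sens / (prec + sens)
    else:
        f = None
    return ClassificationReport(tp, fp, fn, tn, sens, spec, prec, f)


def roc_auc(scores, truth) -> tuple:
    """AUC (trapezoidal over all thresholds; ties as rank-midpoint) + curve.

    Equivalent to the normalized Mann-Whitney U statistic.  Returns
    ``(auc, (fpr, tpr, thresholds))``; raises if one class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present for a ROC curve")
    auc = float(roc_auc_score(truth, scores))
    fpr, tpr, thresholds = roc_curve(truth, scores)
    return auc, (fpr, tpr, thresholds)


def spearman_rho(x, y, n_permutations: int = 10000, seed: int = 0) -> tuple:
    """Spearman rho (Pearson correlation of mid-ranks) + permutation p.

    The two-sided p-value is estimated by permuting one variable's ranks
    ``n_permutations`` times under a fixed seed; an add-one correction keeps
    it strictly positive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors, length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined ranks: constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rho = corr(rx, ry)

    rng = np.random.default_rng(seed)
    perms = np.tile(ry, (n_permutations, 1))
    perms = rng.permuted(perms, axis=1)
    a = rx - rx.mean()
    b = perms - perms.mean(axis=1, keepdims=True)
    rho_perm = (b @ a) / np.sqrt((a @ a) * np.einsum("ij,ij->i", b, b))
    p = (1 + np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12)) / (n_permutations + 1)
    return rho, float(p)


def group_compare(a, b, kind: str = "ranksum") -> tuple:
    """Two-group comparison: Wilcoxon rank sum, or Fisher exact on a 2x2.

    ``ranksum``: exact null for group sizes <= 10, normal approximation
    above.  ``fisher``: ``a`` and ``b`` are the two rows of a 2x2 table.
    Returns (statistic, p) two-sided.
    """
    if kind == "ranksum":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError("empty group")
        method = "exact" if max(a.size, b.size) <= 10 else "asymptotic"
        try:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        except ValueError:
            res = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if kind == "fisher":
        table = np.array([a, b], dtype=int)
        if table.shape != (2, 2):
            raise ValueError("fisher requires a 2x2 table")
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    raise ValueError(f"unknown test kind {kind!r}")


def validation_report(dz_flags, sc_truth, iso_per_cm, cv_est,
                      seed: int = 0) -> ClassificationReport:
    """DZ-vs-SC-AI validation: confusion metrics, AUC, Spearman rho."""
    rep = confusion_metrics(dz_flags, sc_truth)
    truth = np.asarray(sc_truth, dtype=bool)
    if truth.any() and not truth.all():
        rep.auc = roc_auc(np.asarray(iso_per_cm, dtype=float), truth)[0]
    rho, _ = spearman_rho(iso_per_cm, cv_est, seed=seed)
    rep.rho = rho
    return rep
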