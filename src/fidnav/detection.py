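"""Grade-vs-score association and threshold-based detection statistics.

Scans are dichotomized by radiologist grade (1-5): either grades 1-2
("non-diagnostic") against 3-5, or grades 1-3 ("impaired") against 4-5.  A
positive case is a motion-corrupted scan; a scan is called positive when its
integrated motion score is at or above the threshold ``c``.

The module provides the confusion-matrix sensitivity/specificity, the
empirical ROC curve with trapezoidal AUC, the Youden-index optimal threshold,
generalization estimates via the 0.632 bootstrap (a 0.368/0.632 blend of
resubstitution and out-of-bag accuracy), Spearman rank correlation between
scores and grades, and inter-rater weighted kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score

DICHOTOMIZATIONS = ("12v345", "123v45")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def se(self) -> float:
        """Sensitivity TP / (TP + FN)."""
        return self.tp / (self.tp + self.fn)

    @property
    def sp(self) -> float:
        """Specificity TN / (TN + FP)."""
        return self.tn / (self.tn + self.fp)


@dataclass
class RocResult:
    """Empirical ROC over the candidate thresholds (unique scores + +inf)."""

    thresholds: np.ndarray
    se_curve: np.ndarray
    sp_curve: np.ndarray
    auc: float


@dataclass
class BootstrapResult:
    """0.632-bootstrap detection statistics."""

    b: int
    seed: int
    auc_mean: float
    auc_sd: float
    j_mean: float
    j_sd: float
    threshold: float
    se_632: float
    sp_632: float
    n_redrawn: int = 0


def dichotomize(grades: np.ndarray, scheme: str = "12v345") -> np.ndarray:
    """Boolean positive labels (motion-corrupted) from 1-5 grades."""
    grades = np.asarray(grades, dtype=int)
    if np.any((grades < 1) | (grades > 5)):
        raise ValueError("grades must be in 1..5")
    if scheme == "12v345":
        return grades <= 2
    if scheme == "123v45":
        return grades <= 3
    raise ValueError(f"unknown dichotomization {scheme!r}")


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("need at least one positive and one negative label")
    return labels


def confusion(scores: np.ndarray, labels: np.ndarray, threshold: float) -> ConfusionCounts:
    """Counts at threshold ``c``: positive call iff score >= c."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    called = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(called & labels)),
        fp=int(np.sum(called & ~labels)),
        tn=int(np.sum(~called & ~labels)),
        fn=int(np.sum(~called & labels)),
    )


def roc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Empirical ROC curve and trapezoidal AUC.

    Candidate thresholds are the sorted unique scores plus a ``+inf``
    sentinel (nothing called positive).  The AUC is the trapezoidal area
    under (1 - SP, SE) — identical to the tie-corrected Mann-Whitney
    statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    thresholds = np.append(np.unique(scores), np.inf)
    se = np.empty(len(thresholds))
    sp = np.empty(len(thresholds))
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    for k, c in enumerate(thresholds):
        called = scores >= c
        se[k] = np.sum(called & labels) / n_pos
        sp[k] = np.sum(~called & ~labels) / n_neg
    fpr = 1.0 - sp
    order = np.lexsort((se, fpr))  # ties in FPR ordered by SE
    auc = float(np.trapezoid(se[order], fpr[order]))
    return RocResult(thresholds=thresholds, se_curve=se, sp_curve=sp, auc=auc)


def youden_optimal(roc_result: RocResult) -> tuple[float, float]:
    """Maximum Youden index ``J = SE + SP - 1`` and its threshold.

    Ties are broken toward the smaller threshold (higher sensitivity).
    """
    j = roc_result.se_curve + roc_result.sp_curve - 1.0
    best = np.argmax(j >= j.max() - 1e-12)  # first (smallest) threshold at the max
    return float(j[best]), float(roc_result.thresholds[best])


def bootstrap_632(
    scores: np.ndarray,
    labels: np.ndarray,
    b: int = 1000,
    seed: int = 0,
    max_redraws: int = 10_000,
) -> BootstrapResult:
    """0.632-bootstrap estimates of detection accuracy.

    For each of ``b`` replicates, ``N`` subjects are drawn with replacement;
    the ROC, AUC, Youden ``J`` and threshold are computed on the replicate;
    the replicate (resubstitution) and out-of-bag sensitivity/specificity at
    that threshold are blended as ``0.368 * resub + 0.632 * oob`` and
    averaged over replicates.  Replicates whose out-of-bag set misses a class
    are redrawn (counted in ``n_redrawn``).  Replicate random streams are
    spawned from ``seed`` by counter-based splitting, so each replicate is
    independent of execution order.  The reported ``threshold`` is the
    full-sample Youden threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if b < 1:
        raise ValueError("b must be >= 1")
    n = len(scores)
    full_j, full_c = youden_optimal(roc(scores, labels))

    children = np.random.SeedSequence(seed).spawn(b)
    aucs = np.empty(b)
    js = np.empty(b)
    se_blend = np.empty(b)
    sp_blend = np.empty(b)
    n_redrawn = 0
    for i in range(b):
        rng = np.random.default_rng(children[i])
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            both_in = labels[idx].any() and (~labels[idx]).any()
            if both_in and oob.size and labels[oob].any() and (~labels[oob]).any():
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a replicate with a two-class out-of-bag set")
        r = roc(scores[idx], labels[idx])
        j_i, c_i = youden_optimal(r)
        aucs[i] = r.auc
        js[i] = j_i
        resub = confusion(scores[idx], labels[idx], c_i)
        heldout = confusion(scores[oob], labels[oob], c_i)
        se_blend[i] = 0.368 * resub.se + 0.632 * heldout.se
        sp_blend[i] = 0.368 * resub.sp + 0.632 * heldout.sp
    ddof = 1 if b > 1 else 0
    return BootstrapResult(
        b=b,
        seed=seed,
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=ddof)),
        j_mean=float(js.mean()),
        j_sd=float(js.std(ddof=ddof)),
        threshold=full_c,
        se_632=float(se_blend.mean()),
        sp_632=float(sp_blend.mean()),
        n_redrawn=n_redrawn,
    )


def spearman(scores: np.ndarray, grades: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and two-sided p.

    Constant input leaves the correlation undefined; 0 is returned with a
    warning.
    """
    scores = np.asarray(scores, dtype=float)
    grades = np.asarray(grades, dtype=float)
    if len(scores) != len(grades):
        raise ValueError("length mismatch")
    if len(scores) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(scores) == 0 or np.ptp(grades) == 0:
        warnings.warn("spearman: constant input, correlation undefined; returning 0", stacklevel=2)
        return 0.0, float("nan")
    res = stats.spearmanr(scores, grades)
    return float(res.statistic), float(res.pvalue)


def weighted_kappa(
    grades_a: np.ndarray,
    grades_b: np.ndarray,
    weighting: str = "linear",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Cohen's weighted kappa and a 95% subject-level bootstrap CI.

    ``weighting`` is ``"linear"`` or ``"quadratic"`` disagreement weights.
    """
    a = np.asarray(grades_a, dtype=int)
    bb = np.asarray(grades_b, dtype=int)
    if a.shape != bb.shape:
        raise ValueError("rating vectors must have the same length")
    if weighting not in ("linear", "quadratic"):
        raise ValueError("weighting must be 'linear' or 'quadratic'")
    cats = np.union1d(a, bb)
    kappa = float(cohen_kappa_score(a, bb, weights=weighting, labels=cats))
    rng = np.random.default_rng(seed)
    n = len(a)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ra, rb = a[idx], bb[idx]
        if np.ptp(ra) == 0 and np.ptp(rb) == 0 and ra[0] == rb[0]:
            reps.append(1.0)  # single shared category: perfect agreement
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k = cohen_kappa_score(ra, rb, weights=weighting, labels=cats)
        reps.append(1.0 if np.isnan(k) else float(k))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return kappa, (float(lo), min(float(hi), 1.0))
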