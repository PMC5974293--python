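"""SVM training, cross-validation, and FPR-anchored evaluation.

Models are support-vector machines over the assembled per-site feature
vectors, standardised to zero mean / unit variance on the training portion
only.  The hyper-parameter grid spans the linear and rbf kernels with
penalty C in {1, 3, 5, 7, 9}; model selection is by mean AUC under
stratified k-fold cross-validation (10-fold by default).  Thresholds for
Sens/Spec/MCC reporting are anchored at stated false-positive rates on the
negative score distribution: 2/6/10% for S and T sites, 4/9/15% for Y
sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

GRID_C_VALUES = (1.0, 3.0, 5.0, 7.0, 9.0)
GRID_KERNELS = ("linear", "rbf")

# FPR anchor levels (low, medium, high) per acceptor residue class
FPR_LEVELS = {
    "S": (0.02, 0.06, 0.10),
    "T": (0.02, 0.06, 0.10),
    "Y": (0.04, 0.09, 0.15),
}

# Per-task model presets selected in the source study: SVM kernel and C,
# context strategy and total window size (2m+1).
TASK_PRESETS = {
    "general-S": {"kernel": "rbf", "C": 3.0, "strategy": "add", "window_size": 15},
    "general-T": {"kernel": "linear", "C": 7.0, "strategy": "add", "window_size": 15},
    "general-Y": {"kernel": "linear", "C": 7.0, "strategy": "inference", "window_size": 19},
    "kinase:AGC/PKA": {"kernel": "rbf", "C": 5.0, "strategy": "add", "window_size": 19},
    "kinase:AGC/PKC": {"kernel": "rbf", "C": 9.0, "strategy": "add", "window_size": 19},
    "kinase:CMGC/CDK": {"kernel": "rbf", "C": 9.0, "strategy": "inference", "window_size": 7},
    "kinase:CMGC/CK2": {"kernel": "rbf", "C": 3.0, "strategy": "add", "window_size": 19},
    "kinase:TK/SRC": {"kernel": "rbf", "C": 3.0, "strategy": "inference", "window_size": 15},
}


@dataclass(frozen=True)
class SvmConfig:
    kernel: str = "rbf"
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel not in GRID_KERNELS:
            raise ValueError(f"kernel must be one of {GRID_KERNELS}")
        if self.C <= 0:
            raise ValueError("C must be positive")


def default_grid() -> list[SvmConfig]:
    return [SvmConfig(k, c) for k in GRID_KERNELS for c in GRID_C_VALUES]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        return cls(
            TP=int(np.sum(y_true & y_pred)),
            TN=int(np.sum(~y_true & ~y_pred)),
            FP=int(np.sum(~y_true & y_pred)),
            FN=int(np.sum(y_true & ~y_pred)),
        )


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when no positives were evaluated."""
    denom = c.TP + c.FN
    return c.TP / denom if denom else float("nan")


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN when no negatives were evaluated."""
    denom = c.TN + c.FP
    return c.TN / denom if denom else float("nan")


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient, (TP·TN − FP·FN) / √(∏ marginals).

    Defined as 0 when any marginal is zero.  Always in [−1, 1].
    """
    denom2 = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom2 == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / float(np.sqrt(denom2))


@dataclass
class MetricsReport:
    """Threshold metrics at each FPR anchor plus the full ROC curve."""

    auc: float
    roc: np.ndarray  # (n, 2) of (FPR, TPR) points
    thresholds: dict[float, float] = field(default_factory=dict)
    at_threshold: dict[float, dict] = field(default_factory=dict)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """AUC by the midrank (Mann–Whitney) statistic and the ROC polyline."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, np.column_stack([fpr, tpr])


def threshold_at_fpr(negative_scores: np.ndarray, fpr_level: float) -> float:
    """Smallest observed cutoff with strictly-above negative fraction <= level.

    The cutoff is an empirical quantile taken from the observed negative
    scores themselves (no interpolation): a site is called positive when its
    score is strictly greater than the cutoff.
    """
    s = np.sort(np.asarray(negative_scores, dtype=float))
    if s.size == 0:
        raise ValueError("negative score set is empty")
    if not 0 <= fpr_level < 1:
        raise ValueError("fpr_level must lie in [0, 1)")
    n = s.size
    # candidates ascending; fraction strictly above candidate s[j] is
    # (n - searchsorted(s, s[j], 'right')) / n, non-increasing in j
    for j in range(n):
        above = n - np.searchsorted(s, s[j], side="right")
        if above / n <= fpr_level:
            return float(s[j])
    return float(s[-1])


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    residue_class: str = "S",
) -> MetricsReport:
    """Full evaluation: AUC, ROC, and Sens/Spec/MCC at each FPR anchor."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    auc, roc = roc_auc(scores, labels)
    report = MetricsReport(auc=auc, roc=roc)
    neg = scores[labels == 0]
    for level in FPR_LEVELS[residue_class]:
        cut = threshold_at_fpr(neg, level)
        pred = scores > cut
        c = ConfusionCounts.from_predictions(labels == 1, pred)
        report.thresholds[level] = cut
        report.at_threshold[level] = {
            "cutoff": cut,
            "sensitivity": sensitivity(c),
            "specificity": specificity(c),
            "mcc": mcc(c),
            "counts": c,
        }
    return report


def make_svm(cfg: SvmConfig, seed: int = 0) -> Pipeline:
    """Standardiser + SVC pipeline producing decision-function scores."""
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=cfg.kernel, C=cfg.C, gamma="scale", random_state=seed)),
        ]
    )


def train_svm(X: np.ndarray, y: np.ndarray, cfg: SvmConfig, seed: int = 0) -> Pipeline:
    """Fit an SVM scorer on a feature matrix and binary labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = make_svm(cfg, seed)
    clf.fit(X, y)
    return clf


@dataclass
class CrossValResult:
    best_config: "SvmConfig"
    fold_aucs: dict["SvmConfig", np.ndarray]
    mean_auc: dict["SvmConfig", float]
    sd_auc: dict["SvmConfig", float]

    @property
    def best_mean(self) -> float:
        return self.mean_auc[self.best_config]

    @property
    def best_sd(self) -> float:
        return self.sd_auc[self.best_config]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    grid: list[SvmConfig] | None = None,
    seed: int = 0,
) -> CrossValResult:
    """Stratified k-fold CV over the kernel/C grid; select by mean AUC.

    Ties break toward lower C, then linear before rbf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if n_pos < k or n_neg < k:
        raise ValueError(
            f"need >= {k} samples of each class for {k}-fold CV (have {n_pos} pos, {n_neg} neg)"
        )
    grid = grid if grid is not None else default_grid()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    fold_aucs: dict[SvmConfig, np.ndarray] = {}
    for cfg in grid:
        aucs = np.empty(k)
        for f, (tr, va) in enumerate(folds):
            clf = make_svm(cfg, seed)
            clf.fit(X[tr], y[tr])
            scores = clf.decision_function(X[va])
            aucs[f] = roc_auc_score(y[va], scores)
        fold_aucs[cfg] = aucs
    mean_auc = {cfg: float(a.mean()) for cfg, a in fold_aucs.items()}
    sd_auc = {cfg: float(a.std(ddof=1)) for cfg, a in fold_aucs.items()}
    kernel_rank = {"linear": 0, "rbf": 1}
    best = min(grid, key=lambda cfg: (-mean_auc[cfg], cfg.C, kernel_rank[cfg.kernel]))
    return CrossValResult(best, fold_aucs, mean_auc, sd_auc)
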