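"""ROC analysis and the exhaustively grid-searched combined predictor.

Classification direction is fixed: a segment is called disrupted when its
score is at or above the threshold, for every predictor (FER, RR, GdR and any
weighted combination of them).

The empirical ROC curve uses every unique score as a threshold plus a +inf
sentinel; the area under it is computed by the trapezoidal rule, which under
this convention equals the pairwise (Mann-Whitney) statistic with ties
counting one half.  The standard error of the AUC is the Hanley-McNeil
closed form.  A single operating point is chosen by maximizing the Youden
index J = sensitivity + specificity - 1.

The combined predictor min-max scales each predictor to [0, 10] and forms
``sum_i predictor_i * weight_i`` for every weight vector on the 5%-step
simplex lattice (weights in {0, 0.05, ..., 1} summing to 1); the vector with
the largest AUC wins.  Because the lattice contains every unit vector, the
best combined AUC can never fall below the best single predictor's AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import stats

__all__ = [
    "LabeledScores",
    "RocResult",
    "CutoffResult",
    "CombinationResult",
    "roc_curve",
    "optimal_cutoff",
    "minmax_scale",
    "weight_grid",
    "combined_score",
    "optimize_combination",
    "unpaired_t_test",
    "hanley_mcneil_se",
]


@dataclass
class LabeledScores:
    """Predictor values with ground-truth labels (disrupted = positive)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.labels = np.asarray(self.labels, bool)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.labels).sum())


@dataclass
class RocResult:
    thresholds: np.ndarray  # ascending unique scores, then +inf
    sensitivity: np.ndarray  # per threshold (classify positive if score >= t)
    specificity: np.ndarray
    auc: float
    auc_se: float
    n_positive: int
    n_negative: int
    failed: bool = field(init=False)  # AUC < 0.50 defines a test failure

    def __post_init__(self) -> None:
        self.failed = bool(self.auc < 0.50)


@dataclass
class CutoffResult:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass
class CombinationResult:
    predictor_names: list[str]
    step_pct: int
    grid: list[tuple[tuple[float, ...], float]]  # (weights, auc), search order
    best_weights: tuple[float, ...]
    best_auc: float
    best_roc: RocResult


# ---------------------------------------------------------------------------
# ROC curve and AUC
# ---------------------------------------------------------------------------


def hanley_mcneil_se(auc: float, n_positive: int, n_negative: int) -> float:
    """Hanley-McNeil closed-form standard error of an empirical AUC."""
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_positive - 1) * (q1 - a * a)
        + (n_negative - 1) * (q2 - a * a)
    ) / (n_positive * n_negative)
    return float(np.sqrt(max(var, 0.0)))


def roc_curve(data: LabeledScores) -> RocResult:
    """Empirical ROC curve with trapezoidal AUC and Hanley-McNeil SE.

    Thresholds are the unique observed scores (ascending) plus a +inf
    sentinel; at each, sensitivity = P(score >= t | positive) and
    specificity = P(score < t | negative).  The lowest threshold anchors the
    curve at (1, 1) in (1 - specificity, sensitivity) space and the sentinel
    at (0, 0); the trapezoidal area equals the rank-sum AUC with ties
    contributing one half.
    """
    if data.n_positive == 0 or data.n_negative == 0:
        raise ValueError(
            "ROC needs both classes present "
            f"(got {data.n_positive} positive, {data.n_negative} negative)"
        )
    pos = data.scores[data.labels]
    neg = data.scores[~data.labels]
    thresholds = np.append(np.unique(data.scores), np.inf)
    # P(score >= t) via counts of sorted arrays
    sens = 1.0 - np.searchsorted(np.sort(pos), thresholds, side="left") / len(pos)
    spec = np.searchsorted(np.sort(neg), thresholds, side="left") / len(neg)

    fpr = 1.0 - spec  # descending along ascending thresholds
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_se=hanley_mcneil_se(auc, len(pos), len(neg)),
        n_positive=len(pos),
        n_negative=len(neg),
    )


def optimal_cutoff(roc: RocResult) -> CutoffResult:
    """Operating point maximizing Youden J; ties go to the lowest threshold
    (favoring sensitivity)."""
    j = roc.sensitivity + roc.specificity - 1.0
    finite = np.isfinite(roc.thresholds)
    j_finite = np.where(finite, j, -np.inf)  # the +inf sentinel is not a cutoff
    idx = int(np.argmax(j_finite))  # argmax returns the first (lowest) tie
    return CutoffResult(
        threshold=float(roc.thresholds[idx]),
        sensitivity=float(roc.sensitivity[idx]),
        specificity=float(roc.specificity[idx]),
        youden_j=float(j[idx]),
    )


# ---------------------------------------------------------------------------
# Normalization, weight lattice, combined predictor
# ---------------------------------------------------------------------------


def minmax_scale(values, upper: float = 10.0) -> np.ndarray:
    """Affine map of values onto [0, upper] with min -> 0 and max -> upper."""
    v = np.asarray(values, float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("minmax_scale needs at least two distinct values")
    return upper * (v - lo) / (hi - lo)


def weight_grid(n_predictors: int, step_pct: int = 5) -> list[tuple[float, ...]]:
    """All weight vectors on the simplex lattice {0, step, ..., 100%}.

    Vectors are multiples of ``step_pct`` percent summing to exactly 1,
    enumerated in descending lexicographic order (so the first maximum found
    during a scan carries the largest weight on the first predictor).
    Weights are exact (built from integer fractions), not accumulations of
    floating-point steps.
    """
    if n_predictors < 1:
        raise ValueError("need at least one predictor")
    if step_pct <= 0 or 100 % step_pct != 0:
        raise ValueError(f"step must divide 100%, got {step_pct}")
    units = 100 // step_pct

    def compositions(remaining: int, slots: int):
        if slots == 1:
            yield (remaining,)
            return
        for first in range(remaining, -1, -1):
            for rest in compositions(remaining - first, slots - 1):
                yield (first,) + rest

    return [
        tuple(float(Fraction(u, units)) for u in combo)
        for combo in compositions(units, n_predictors)
    ]


def combined_score(scaled_predictors: np.ndarray, weights) -> np.ndarray:
    """Weighted sum over predictors already min-max scaled to [0, 10]."""
    table = np.asarray(scaled_predictors, float)
    w = np.asarray(weights, float)
    if table.ndim != 2 or table.shape[1] != w.shape[0]:
        raise ValueError(
            f"predictor table {table.shape} does not match {w.shape[0]} weights"
        )
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
    return table @ w


def optimize_combination(
    predictors: np.ndarray,
    labels,
    step_pct: int = 5,
    predictor_names: list[str] | None = None,
) -> CombinationResult:
    """Exhaustive AUC maximization over the simplex weight lattice.

    ``predictors`` is (n_samples, n_predictors) of raw values; each column is
    min-max scaled to [0, 10] (pooled over both classes) before weighting.
    Ties on AUC resolve to the vector with the largest weight on the
    first-listed predictor, then lexicographically — i.e. the first maximum
    in the grid's enumeration order.
    """
    table = np.asarray(predictors, float)
    if table.ndim != 2:
        raise ValueError("predictors must be a 2-D (samples x predictors) array")
    labels = np.asarray(labels, bool)
    names = predictor_names or [f"p{i}" for i in range(table.shape[1])]
    if len(names) != table.shape[1]:
        raise ValueError("predictor_names length mismatch")

    scaled = np.column_stack([minmax_scale(table[:, j]) for j in range(table.shape[1])])
    grid_entries: list[tuple[tuple[float, ...], float]] = []
    best_auc = -np.inf
    best_weights: tuple[float, ...] | None = None
    best_roc: RocResult | None = None
    for weights in weight_grid(table.shape[1], step_pct):
        scores = combined_score(scaled, weights)
        roc = roc_curve(LabeledScores(scores, labels))
        grid_entries.append((weights, roc.auc))
        if roc.auc > best_auc:
            best_auc, best_weights, best_roc = roc.auc, weights, roc
    return CombinationResult(
        predictor_names=list(names),
        step_pct=step_pct,
        grid=grid_entries,
        best_weights=best_weights,
        best_auc=float(best_auc),
        best_roc=best_roc,
    )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def unpaired_t_test(group_a, group_b) -> tuple[float, int, float]:
    """Pooled-variance (Student) two-sample t-test, two-sided.

    Returns (t, degrees of freedom, p).  Two identical-variance-free groups
    with equal means yield t = 0, p = 1 rather than a 0/0 indeterminate.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    df = len(a) + len(b) - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, df, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)
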