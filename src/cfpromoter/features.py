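"""Feature engineering for the promoter classifier.

Continuous pTSS coverage is dichotomized at the cutoff whose thresholded
feature attains the largest AUC on the training cohort (a value becomes
1 when strictly above the cutoff).  Features are then ranked by
weight-based SVM recursive feature elimination and correlated pairs
(|Pearson r| > 0.5 on the binary matrix) pruned, keeping the more
important member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

CORR_THRESHOLD_DEFAULT = 0.5


@dataclass(frozen=True)
class DiscretizationRule:
    """AUC-optimal threshold for one region's coverage.

    ``direction`` records whether cases tend to lie above (case_high) or
    below (case_low) the cutoff; the binary encoding itself is always
    value > cutoff.
    """

    region_id: str
    cutoff: float
    auc_at_cutoff: float
    direction: str  # case_high / case_low

    def __post_init__(self) -> None:
        if not (0.5 - 1e-12 <= self.auc_at_cutoff <= 1.0 + 1e-12):
            raise ValueError("auc_at_cutoff must lie in [0.5, 1]")
        if self.direction not in ("case_high", "case_low"):
            raise ValueError(f"bad direction {self.direction!r}")


def optimal_cutoff(values, labels, region_id: str = "") -> DiscretizationRule:
    """Find the dichotomization cutoff with the largest AUC.

    Candidate cutoffs are midpoints between consecutive distinct sorted
    values.  For a thresholded binary feature AUC = (Se + Sp)/2; both
    orientations are considered and the better one recorded as the
    direction.  Ties are broken toward the smallest cutoff.  Constant
    values yield a degenerate rule (AUC 0.5) with a warning.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if v.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    n_case = int(y.sum())
    n_ctrl = int(y.size - n_case)
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both classes must be present")
    distinct = np.unique(v)
    if distinct.size < 2:
        warnings.warn(f"constant feature {region_id!r}: degenerate rule (AUC 0.5)")
        return DiscretizationRule(region_id, float(distinct[0]), 0.5, "case_high")
    cuts = (distinct[:-1] + distinct[1:]) / 2.0
    # case_high AUC at cutoff c: (P(case > c) + P(ctrl <= c)) / 2
    case_sorted = np.sort(v[y == 1])
    ctrl_sorted = np.sort(v[y == 0])
    se = 1.0 - np.searchsorted(case_sorted, cuts, side="right") / n_case
    sp = np.searchsorted(ctrl_sorted, cuts, side="right") / n_ctrl
    auc_high = (se + sp) / 2.0
    auc_best = np.maximum(auc_high, 1.0 - auc_high)
    best = int(np.argmax(auc_best))  # argmax returns first max: smallest cutoff
    direction = "case_high" if auc_high[best] >= 1.0 - auc_high[best] else "case_low"
    return DiscretizationRule(region_id, float(cuts[best]), float(auc_best[best]), direction)


def fit_discretization(matrix: np.ndarray, labels, region_ids) -> list[DiscretizationRule]:
    """One AUC-optimal rule per column."""
    return [optimal_cutoff(matrix[:, j], labels, str(region_ids[j]))
            for j in range(matrix.shape[1])]


def discretize(matrix: np.ndarray, rules: list[DiscretizationRule]) -> np.ndarray:
    """Binary-encode: entry is 1 iff the value is strictly larger than the
    column's cutoff (direction is interpretive metadata only)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] != len(rules):
        raise ValueError(f"need one rule per column: {matrix.shape[1]} columns, {len(rules)} rules")
    cutoffs = np.array([r.cutoff for r in rules])
    return (matrix > cutoffs).astype(int)


@dataclass(frozen=True)
class FeatureRanking:
    """Total importance ordering of features (rank 1 = most important)."""

    region_ids: tuple
    ranks: tuple  # importance rank per region_id position
    scores: tuple  # squared weight at elimination time (0 for constants)

    def rank_of(self, region_id) -> int:
        return self.ranks[self.region_ids.index(region_id)]


def rfe_importance(X: np.ndarray, y, seed: int = 0, C: float = 1.0,
                   region_ids=None) -> FeatureRanking:
    """Weight-based SVM recursive feature elimination.

    Repeatedly fit a linear maximum-margin classifier and drop the
    feature with the smallest squared weight; importance rank is the
    reverse elimination order.  Constant (zero-variance) features carry
    no margin information and are assigned the worst ranks up front with
    a warning.  Deterministic for fixed data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n, p = X.shape
    if p < 2:
        raise ValueError("need >= 2 features to rank")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if region_ids is None:
        region_ids = [str(j) for j in range(p)]
    region_ids = [str(r) for r in region_ids]

    constant = [j for j in range(p) if np.unique(X[:, j]).size < 2]
    if constant:
        warnings.warn(f"{len(constant)} constant feature(s) ranked last")
    active = [j for j in range(p) if j not in set(constant)]
    elimination_order: list[tuple[int, float]] = []  # (col, score) worst first
    for j in sorted(constant, reverse=True):
        elimination_order.append((j, 0.0))

    rng_order = list(active)
    while len(rng_order) > 1:
        clf = SVC(kernel="linear", C=C, random_state=seed)
        clf.fit(X[:, rng_order], y)
        w2 = np.ravel(clf.coef_) ** 2
        # ties: drop the later column for a deterministic, order-stable rule
        worst = int(np.max(np.flatnonzero(w2 == w2.min())))
        elimination_order.append((rng_order[worst], float(w2[worst])))
        rng_order.pop(worst)
    if rng_order:
        elimination_order.append((rng_order[0], float("inf")))

    ranks = np.empty(p, dtype=int)
    scores = np.empty(p)
    for rank_from_worst, (col, score) in enumerate(elimination_order):
        ranks[col] = p - rank_from_worst
        scores[col] = score
    return FeatureRanking(region_ids=tuple(region_ids),
                          ranks=tuple(int(r) for r in ranks),
                          scores=tuple(float(s) for s in scores))


def correlation_prune(X: np.ndarray, ranking: FeatureRanking,
                      r_threshold: float = CORR_THRESHOLD_DEFAULT) -> list[str]:
    """Greedy decorrelation keeping higher-importance features.

    Features are visited best-rank first; a feature is retained only if
    its |Pearson r| with every already-retained feature is <= the
    threshold.  The retained set is maximal: every removed feature
    exceeds the threshold against some retained one.  Constant columns
    have undefined correlation, treated as r = 0.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p != len(ranking.region_ids):
        raise ValueError("ranking must cover every column")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    order = np.argsort(ranking.ranks, kind="mergesort")  # rank 1 first
    retained: list[int] = []
    for j in order:
        if all(abs(corr[j, k]) <= r_threshold for k in retained):
            retained.append(int(j))
    retained_ids = {ranking.region_ids[j] for j in retained}
    return [rid for rid in ranking.region_ids if rid in retained_ids]
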