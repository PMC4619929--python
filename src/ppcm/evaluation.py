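"""ROC construction and AUC-based evaluation.

The receiver operating characteristic plots the true-positive rate
(sensitivity) against the false-positive rate (1 - specificity) as the
decision threshold sweeps the ranked pair list. The area under the curve is
computed with the trapezoidal rule,

    AUC = 1/2 * sum_k (X_k - X_{k-1}) * (Y_k + Y_{k-1}),

where X_k is the FPR and Y_k the TPR after the k-th threshold. Tied scores
advance as a single threshold step (a diagonal segment), which makes the
trapezoidal area identical to the Mann-Whitney pair-ordering statistic with
ties counted one half. Prediction accuracy is summarised as the mean +/- SD
of the AUC over repeated train/test splits (25 repeats by convention), and
an ensemble is compared against the average and the highest-scoring single
classifier with a Welch two-sample t-test on the per-repeat AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass
class ROCPoints:
    """Ordered ROC points from (0,0) to (1,1); one step per distinct score."""

    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def n_thresholds(self) -> int:
        return len(self.fpr) - 1

    def validate(self) -> None:
        x, y = self.fpr, self.tpr
        if x[0] != 0 or y[0] != 0 or x[-1] != 1 or y[-1] != 1:
            raise ValueError("ROC must start at (0,0) and end at (1,1)")
        if np.any(np.diff(x) < 0) or np.any(np.diff(y) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")


@dataclass
class AUCSummary:
    """Per-repeat AUC values with their mean and standard deviation."""

    per_repeat: np.ndarray
    mean: float
    sd: float
    n_repeats: int
    degenerate: bool = field(default=False)

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "AUCSummary":
        arr = np.asarray(values, dtype=float)
        if arr.size < 1:
            raise ValueError("need at least one repeat")
        degenerate = arr.size == 1
        sd = 0.0 if degenerate else float(arr.std(ddof=1))
        return cls(per_repeat=arr, mean=float(arr.mean()), sd=sd,
                   n_repeats=int(arr.size), degenerate=degenerate)

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(self.n_repeats)


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return scores, labels


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCPoints:
    """ROC points for binary ``labels`` scored by ``scores`` (higher = positive).

    Thresholds are the distinct score values in descending order; all pairs
    tied at a score enter in one step, producing a diagonal segment.
    """
    scores, labels = _check_scores_labels(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # indices where a run of tied scores ends
    distinct = np.nonzero(np.diff(s))[0]
    ends = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[ends]
    fp = np.cumsum(1 - y)[ends]
    P = labels.sum()
    N = len(labels) - P
    tpr = np.concatenate([[0.0], tp / P])
    fpr = np.concatenate([[0.0], fp / N])
    roc = ROCPoints(fpr=fpr, tpr=tpr)
    roc.validate()
    return roc


def auc_trapezoid(roc: ROCPoints) -> float:
    """Trapezoidal area under the ROC curve."""
    roc.validate()
    dx = np.diff(roc.fpr)
    ysum = roc.tpr[1:] + roc.tpr[:-1]
    return float(0.5 * np.sum(dx * ysum))


def ranking_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via the Mann-Whitney rank statistic (ties counted 1/2).

    Numerically identical to ``auc_trapezoid(roc_curve(...))``; kept as a
    fast path for inner loops such as taxa-selection fitness evaluation.
    """
    scores, labels = _check_scores_labels(scores, labels)
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC of a score vector, via the explicit ROC trapezoid."""
    return auc_trapezoid(roc_curve(scores, labels))


def repeated_auc(run_repeat, n_repeats: int = 25, base_seed: int = 0) -> AUCSummary:
    """Run a full evaluation repeatedly and summarise the per-repeat AUCs.

    ``run_repeat(repeat_index, seed)`` must perform one complete
    train/evaluate cycle (split, base scoring, meta-learning, AUC) and
    return the test AUC. Seeds are derived from ``base_seed`` so repeats
    differ but the whole protocol is reproducible.
    """
    from .gold_standard import split_seed

    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    values = []
    for i in range(n_repeats):
        try:
            values.append(float(run_repeat(i, split_seed(base_seed, i))))
        except Exception as exc:  # annotate with the failing repeat
            raise RuntimeError(f"repeat {i} failed: {exc}") from exc
    return AUCSummary.from_values(values)


@dataclass
class ComparisonReport:
    """Ensemble vs single-classifier comparison for one evaluation category."""

    average_single: float
    highest_single: float
    highest_single_id: str
    ppcm_mean: float
    ppcm_sd: float
    improvement_pct: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "average": self.average_single,
            "highest": self.highest_single,
            "highest_id": self.highest_single_id,
            "ppcm_mean": self.ppcm_mean,
            "ppcm_sd": self.ppcm_sd,
            "improvement_pct": self.improvement_pct,
            "p_value": self.p_value,
        }


def compare_methods(
    ppcm: AUCSummary,
    singles: Mapping[str, AUCSummary],
) -> ComparisonReport:
    """Compare an ensemble against its constituent single classifiers.

    Reports the mean AUC over all single classifiers, the best single
    classifier, the ensemble mean +/- SD, the percent improvement of the
    ensemble over the best single (rounded to integer percent), and a Welch
    two-sample t-test p-value of the per-repeat AUCs against the best
    single's repeats (Welch handles unequal repeat counts or variances).
    """
    if not singles:
        raise ValueError("need at least one single-classifier summary")
    means = {k: s.mean for k, s in singles.items()}
    best_id = max(means, key=lambda k: means[k])
    best = singles[best_id]
    improvement = (ppcm.mean - best.mean) / best.mean * 100.0
    if np.allclose(ppcm.per_repeat, best.per_repeat):
        p = 1.0
    elif ppcm.sd == 0.0 and best.sd == 0.0:
        # two degenerate (zero-variance) samples: equal means or not at all
        p = 1.0 if ppcm.mean == best.mean else 0.0
    else:
        p = float(stats.ttest_ind(ppcm.per_repeat, best.per_repeat, equal_var=False).pvalue)
    return ComparisonReport(
        average_single=float(np.mean(list(means.values()))),
        highest_single=best.mean,
        highest_single_id=best_id,
        ppcm_mean=ppcm.mean,
        ppcm_sd=ppcm.sd,
        improvement_pct=int(round(improvement)),
        p_value=p,
    )
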