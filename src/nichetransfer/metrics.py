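"""Discrimination metrics and threshold calibration for presence/absence models.

AUC follows the rank (Mann-Whitney) formulation — the probability that a
randomly drawn presence is scored above a randomly drawn absence, with ties
counted one half. The MSS ("maximum sensitivity plus specificity") threshold
binarizes continuous suitability: it scans candidate thresholds — midpoints of
consecutive sorted unique scores plus the extremes — and returns the one
maximizing sensitivity + specificity, with TSS = sensitivity + specificity − 1
at that threshold. A score >= threshold is classified presence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedShuffleSplit


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes (presence and absence) must be present")
    return labels, ~labels


def auc(scores, labels) -> float:
    """Rank-based ROC AUC; ties between classes count 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    ranks = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def mss_threshold(scores, labels) -> tuple[float, float, float, float]:
    """(threshold, sensitivity, specificity, tss) maximizing sens + spec.

    Objective ties are broken toward the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        cands = uniq
    else:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        cands = np.concatenate(([uniq[0]], mids, [uniq[-1]]))
    # sens/spec for rule "score >= t -> presence", vectorized over candidates;
    # the objective is compared on exact integer counts (tp*n_neg + tn*n_pos)
    # so threshold ties are genuine ties, broken toward the lowest threshold
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    pred = scores[None, :] >= cands[:, None]
    tp = (pred & pos[None, :]).sum(axis=1)
    tn = (~pred & neg[None, :]).sum(axis=1)
    best = int(np.argmax(tp * n_neg + tn * n_pos))  # first = lowest maximizer
    t = float(cands[best])
    s, c = tp[best] / n_pos, tn[best] / n_neg
    return t, float(s), float(c), float(s + c - 1.0)


@dataclass
class EvalResult:
    """Held-out discrimination scores of one fitted model on one split."""

    auc: float
    tss: float
    mss_threshold: float
    sensitivity: float
    specificity: float
    split_id: int = 0
    algorithm: str = ""

    def passes(self, tss_min: float, auc_min: float) -> bool:
        return self.tss >= tss_min and self.auc >= auc_min


def evaluate_scores(scores, labels, split_id: int = 0, algorithm: str = "") -> EvalResult:
    t, sens, spec, tss = mss_threshold(scores, labels)
    return EvalResult(
        auc=auc(scores, labels),
        tss=tss,
        mss_threshold=t,
        sensitivity=sens,
        specificity=spec,
        split_id=split_id,
        algorithm=algorithm,
    )


def cv_splits(labels, train_frac: float = 0.7, repeats: int = 5,
              seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated random train/test partitions, stratified by class.

    Each repeat independently assigns ``train_frac`` of every class to the
    training side and the remainder to the test side.
    """
    labels = np.asarray(labels).astype(int)
    if len(labels) < 10:
        raise ValueError("need at least 10 samples to split")
    splitter = StratifiedShuffleSplit(
        n_splits=repeats, train_size=train_frac, random_state=seed
    )
    splits = []
    for train, test in splitter.split(np.zeros((len(labels), 1)), labels):
        for part in (train, test):
            if len(np.unique(labels[part])) < 2:
                raise ValueError("a class is absent from a split")
        splits.append((train, test))
    return splits
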