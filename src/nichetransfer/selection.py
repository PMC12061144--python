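"""Predictor importance scoring and collinearity-driven selection.

A preliminary model fitted to all candidate predictors yields an importance
score per predictor; strongly collinear predictor pairs (|Pearson r| above a
threshold, conventionally 0.7) are then pruned by iteratively dropping the
lower-importance member of the currently worst pair until no pair exceeds the
threshold.

Importance is prediction-permutation importance: permute one column, measure
how much the model's predictions decorrelate from the originals —
``importance(v) = mean over replicates of 1 − max(0, r(p, p_v-permuted))``.
A variable the model ignores scores exactly 0. A leave-one-variable-out
refit delta-AUC variant is available for callers that want importance tied to
held-out discrimination rather than prediction stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .metrics import auc as _auc


@dataclass
class ImportanceTable:
    scores: dict[str, float]
    method: str = "permutation"
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.scores.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"importance score for {k!r} outside [0, 1]: {v}")

    def to_frame(self) -> pd.DataFrame:
        return (
            pd.DataFrame({"predictor": list(self.scores), "importance": list(self.scores.values())})
            .sort_values("importance", ascending=False)
            .reset_index(drop=True)
        )


@dataclass
class SelectionResult:
    retained: list[str]
    removed: list[tuple[str, str, float, str]]  # (name, partner, correlation, reason)
    threshold: float = 0.7

    def removed_names(self) -> list[str]:
        return [r[0] for r in self.removed]


def _predict(model, X: np.ndarray) -> np.ndarray:
    """Score in [0, 1] from either a callable or a predict-bearing object."""
    if callable(model) and not hasattr(model, "predict"):
        return np.asarray(model(X), dtype=float)
    return np.asarray(model.predict(X), dtype=float)


def permutation_importance(
    model, X, replicates: int = 10, seed: int = 0, names: list[str] | None = None
) -> ImportanceTable:
    """Prediction-permutation importance of each column of X.

    ``model`` must map a design matrix to scores in [0, 1] (a callable or an
    object with ``predict``). Constant predictions make every correlation
    undefined; importance is then 0 for all predictors, with a warning.
    """
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(float)
    else:
        Xv = X
        names = names or [f"x{j}" for j in range(Xv.shape[1])]
    rng = np.random.default_rng(seed)
    base = _predict(model, Xv)
    scores: dict[str, float] = {}
    if np.ptp(base) == 0:  # ptp is exact; std of a constant array is not
        warnings.warn("constant model predictions: importance undefined, reporting 0")
        return ImportanceTable({n: 0.0 for n in names}, "permutation", replicates, seed)
    for j, name in enumerate(names):
        vals = []
        for _ in range(replicates):
            Xp = Xv.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            pred = _predict(model, Xp)
            if np.ptp(pred) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(base, pred)[0, 1])
            vals.append(1.0 - max(0.0, r))
        score = float(np.clip(np.mean(vals), 0.0, 1.0))
        # snap floating-point dust so an ignored variable scores exactly 0
        scores[name] = 0.0 if score < 1e-10 else score
    return ImportanceTable(scores, "permutation", replicates, seed)


def loo_auc_importance(
    fit_fn, X: pd.DataFrame, y, replicates: int = 1, seed: int = 0
) -> ImportanceTable:
    """Leave-one-variable-out refit importance: AUC drop when a column is removed.

    ``fit_fn(X, y, seed)`` must return a fitted object whose ``predict`` gives
    scores in [0, 1]. Scores are clipped to [0, 1] (an uninformative variable
    can give a small negative drop by chance).
    """
    y = np.asarray(y)
    full = fit_fn(X, y, seed)
    auc_full = _auc(_predict(full, X.to_numpy(float)), y)
    scores: dict[str, float] = {}
    for name in X.columns:
        Xr = X.drop(columns=[name])
        drops = []
        for rep in range(replicates):
            m = fit_fn(Xr, y, seed + rep)
            drops.append(auc_full - _auc(_predict(m, Xr.to_numpy(float)), y))
        scores[name] = float(np.clip(np.mean(drops), 0.0, 1.0))
    return ImportanceTable(scores, "loo-delta-auc", replicates, seed)


def pearson_matrix(X) -> pd.DataFrame:
    """Pairwise Pearson correlations; constant columns correlate 0 (warned)."""
    df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    if len(df) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    vals = df.to_numpy(float)
    constant = np.ptp(vals, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant columns treated as uncorrelated: {list(df.columns[constant])}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=df.columns, columns=df.columns)


def select_predictors(X, importance: ImportanceTable, threshold: float = 0.7) -> SelectionResult:
    """Iteratively drop the lower-importance member of the worst collinear pair.

    At each step the pair with the largest |r| among surviving columns is
    found; the member with the lower importance is removed (importance tie:
    the lexicographically later name goes); correlations are recomputed on the
    survivors; the loop stops when no pair exceeds the threshold.
    """
    df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    missing = [c for c in df.columns if c not in importance.scores]
    if missing:
        raise KeyError(f"importance table missing predictors: {missing}")
    surviving = sorted(df.columns)
    removed: list[tuple[str, str, float, str]] = []
    while len(surviving) > 1:
        corr = pearson_matrix(df[surviving]).abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        if corr.max() <= threshold:
            break
        # worst pair; ties among pairs broken by sorted name order for determinism
        i, j = np.unravel_index(int(np.argmax(corr)), corr.shape)
        a, b = surviving[i], surviving[j]
        r = float(pearson_matrix(df[[a, b]]).loc[a, b])
        ia, ib = importance.scores[a], importance.scores[b]
        if ia < ib or (ia == ib and a > b):
            victim, partner = a, b
        else:
            victim, partner = b, a
        removed.append(
            (victim, partner, r, f"|r|={abs(r):.3f} > {threshold} with {partner}")
        )
        surviving.remove(victim)
    # preserve the input column order in the retained list
    retained = [c for c in df.columns if c in set(surviving)]
    return SelectionResult(retained=retained, removed=removed, threshold=threshold)


class CollinearityPruner(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping importance-guided collinearity pruning.

    Parameters
    ----------
    importance : mapping predictor name -> score in [0, 1], or None to compute
        prediction-permutation importance of ``model`` at fit time.
    model : object with ``predict`` (or callable), used only when importance
        is not given.
    threshold : |Pearson r| above which a pair counts as strongly collinear.
    """

    def __init__(self, importance: dict[str, float] | None = None, model=None,
                 threshold: float = 0.7, replicates: int = 10, random_state: int = 0):
        self.importance = importance
        self.model = model
        self.threshold = threshold
        self.replicates = replicates
        self.random_state = random_state

    def fit(self, X, y=None):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        if self.importance is not None:
            table = ImportanceTable(dict(self.importance))
        elif self.model is not None:
            table = permutation_importance(
                self.model, df, replicates=self.replicates, seed=self.random_state
            )
        else:
            raise ValueError("provide either an importance mapping or a model")
        self.importance_table_ = table
        self.selection_ = select_predictors(df, table, threshold=self.threshold)
        self.retained_ = self.selection_.retained
        return self

    def transform(self, X):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        return df[self.retained_]
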