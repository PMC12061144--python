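"""Multi-algorithm ensemble species distribution model.

Presence-only occurrence data are complemented with randomly placed
pseudo-absences (1000, or as many as there are occurrences when fewer than
1000). Several algorithm families are fitted on repeated random 70/30
train/test partitions; every (algorithm, split) candidate is evaluated on its
held-out fold and admitted to the committee only if it clears the quality
gates (TSS >= 0.7 and AUC >= 0.8 by default). The ensemble suitability is the
unweighted mean of the surviving members' scores (a TSS-weighted mean is
available), and the ensemble's own MSS threshold — calibrated on the pooled
presence/pseudo-absence set — binarizes predictions into a range map.

The estimator follows scikit-learn conventions: ``fit(X, y)`` /
``predict_suitability(X)`` / ``predict(X)``, ``get_params``/``set_params``,
fitted attributes with a trailing underscore, so it composes with sklearn
model-selection tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .geodata import OccurrenceSet, PredictorStack, RasterGrid
from .metrics import EvalResult, cv_splits, evaluate_scores, mss_threshold


# ---------------------------------------------------------------------------
# Algorithm registry
# ---------------------------------------------------------------------------

def _make_ann(seed: int, **hp):
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", MLPClassifier(
            hidden_layer_sizes=hp.get("hidden_layer_sizes", (16,)),
            max_iter=hp.get("max_iter", 800),
            random_state=seed,
        )),
    ])


def _make_cta(seed: int, **hp):
    return DecisionTreeClassifier(
        max_depth=hp.get("max_depth", 8),
        min_samples_leaf=hp.get("min_samples_leaf", 10),
        random_state=seed,
    )


def _make_fda(seed: int, **hp):
    # flexible discriminant analysis: LDA on a nonlinear (spline) basis
    return Pipeline([
        ("scale", StandardScaler()),
        ("basis", SplineTransformer(n_knots=hp.get("n_knots", 4), degree=2)),
        ("clf", LinearDiscriminantAnalysis()),
    ])


def _make_maxent(seed: int, **hp):
    # maximum-entropy-style model: regularized logistic regression
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(C=hp.get("C", 1.0), max_iter=2000, random_state=seed)),
    ])


def _make_rf(seed: int, **hp):
    return RandomForestClassifier(
        n_estimators=hp.get("n_estimators", 100),
        min_samples_leaf=hp.get("min_samples_leaf", 3),
        random_state=seed,
    )


def _make_gam(seed: int, **hp):
    # generalized additive model: per-feature spline basis + logistic link
    return Pipeline([
        ("scale", StandardScaler()),
        ("basis", SplineTransformer(n_knots=hp.get("n_knots", 6), degree=3)),
        ("clf", LogisticRegression(C=hp.get("C", 1.0), max_iter=2000, random_state=seed)),
    ])


def _make_gbm(seed: int, **hp):
    return GradientBoostingClassifier(
        n_estimators=hp.get("n_estimators", 100),
        max_depth=hp.get("max_depth", 3),
        random_state=seed,
    )


#: the seven registered algorithm families
ALGORITHM_REGISTRY = {
    "ann": _make_ann,
    "cta": _make_cta,
    "fda": _make_fda,
    "maxent": _make_maxent,
    "rf": _make_rf,
    "gam": _make_gam,
    "gbm": _make_gbm,
}


@dataclass
class ModelSpec:
    algorithm_id: str
    hyperparameters: dict | None = None

    def __post_init__(self) -> None:
        if self.algorithm_id not in ALGORITHM_REGISTRY:
            raise ValueError(
                f"unknown algorithm {self.algorithm_id!r}; "
                f"registered: {sorted(ALGORITHM_REGISTRY)}"
            )
        self.hyperparameters = dict(self.hyperparameters or {})

    def build(self, seed: int):
        return ALGORITHM_REGISTRY[self.algorithm_id](seed, **self.hyperparameters)


def fit_member(spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit one algorithm; the result's ``predict_proba``[:, 1] is the score."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = spec.build(seed)
    model.fit(np.asarray(X, float), y)
    return model


def member_scores(model, X: np.ndarray) -> np.ndarray:
    """Suitability scores in [0, 1] from a fitted member."""
    p = model.predict_proba(np.asarray(X, float))
    return np.clip(p[:, list(model.classes_).index(1)], 0.0, 1.0)


# ---------------------------------------------------------------------------
# Pseudo-absences
# ---------------------------------------------------------------------------

@dataclass
class PseudoAbsenceConfig:
    n_rule: str = "1000-or-n-occ"
    seed: int = 0
    exclude_occupied_cells: bool = True

    def resolve_count(self, n_occurrences: int) -> int:
        if self.n_rule != "1000-or-n-occ":
            raise ValueError(f"unknown pseudo-absence rule {self.n_rule!r}")
        n = 1000 if n_occurrences >= 1000 else n_occurrences
        if n < 1:
            raise ValueError("resolved pseudo-absence count must be >= 1")
        return n


def generate_pseudo_absences(
    stack: PredictorStack,
    occurrences: OccurrenceSet | pd.DataFrame,
    config: PseudoAbsenceConfig,
) -> pd.DataFrame:
    """Sample pseudo-absence cell centers uniformly from valid unoccupied cells.

    Returns a DataFrame with lon/lat of the sampled cell centers.
    """
    df = occurrences.records if isinstance(occurrences, OccurrenceSet) else occurrences
    tmpl = stack.template
    valid = ~stack.combined_nodata()
    if config.exclude_occupied_cells and len(df):
        row, col = tmpl.cell_index(df["lon"].to_numpy(float), df["lat"].to_numpy(float))
        inside = (row >= 0) & (row < tmpl.n_rows) & (col >= 0) & (col < tmpl.n_cols)
        valid[row[inside], col[inside]] = False
    n = config.resolve_count(len(df))
    candidates = np.flatnonzero(valid.ravel())
    if len(candidates) < n:
        raise ValueError(
            f"insufficient valid unoccupied cells: need {n}, have {len(candidates)}"
        )
    rng = np.random.default_rng(config.seed)
    chosen = rng.choice(candidates, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, tmpl.shape)
    return pd.DataFrame(
        {
            "lon": tmpl.origin_lon + (cols + 0.5) * tmpl.cell_size,
            "lat": tmpl.origin_lat - (rows + 0.5) * tmpl.cell_size,
        }
    )


# ---------------------------------------------------------------------------
# The ensemble estimator
# ---------------------------------------------------------------------------

class EnsembleSDM(BaseEstimator, ClassifierMixin):
    """Gated committee of SDM algorithms with MSS-threshold binarization.

    Parameters
    ----------
    algorithms : sequence of algorithm ids (keys of ALGORITHM_REGISTRY) or
        ModelSpec instances; at least two distinct families.
    tss_min, auc_min : quality gates applied to each (algorithm, split)
        candidate's held-out evaluation.
    cv_repeats, train_frac : repeated random stratified train/test splits.
    combination : "mean" or "tss-weighted-mean".
    random_state : master seed for splits and member fitting.
    """

    def __init__(
        self,
        algorithms=("maxent", "rf"),
        tss_min: float = 0.7,
        auc_min: float = 0.8,
        cv_repeats: int = 5,
        train_frac: float = 0.7,
        combination: str = "mean",
        random_state: int = 0,
    ):
        self.algorithms = algorithms
        self.tss_min = tss_min
        self.auc_min = auc_min
        self.cv_repeats = cv_repeats
        self.train_frac = train_frac
        self.combination = combination
        self.random_state = random_state

    def _specs(self) -> list[ModelSpec]:
        specs = [
            a if isinstance(a, ModelSpec) else ModelSpec(a) for a in self.algorithms
        ]
        if len({s.algorithm_id for s in specs}) < 2:
            raise ValueError("need at least two distinct algorithm families")
        return specs

    def fit(self, X, y):
        """Fit candidates on CV splits, gate them, calibrate the MSS threshold.

        X : design matrix (DataFrame preserves predictor names); y : 1 for
        presence, 0 for pseudo-absence.
        """
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xv = X.to_numpy(float)
        else:
            Xv = np.asarray(X, float)
            self.feature_names_in_ = np.asarray(
                [f"x{j}" for j in range(Xv.shape[1])], dtype=object
            )
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        specs = self._specs()
        splits = cv_splits(
            y, train_frac=self.train_frac, repeats=self.cv_repeats, seed=self.random_state
        )
        members: list[tuple[ModelSpec, object, EvalResult]] = []
        all_evals: list[EvalResult] = []
        failures: list[str] = []
        for si, spec in enumerate(specs):
            for ki, (train, test) in enumerate(splits):
                seed = self.random_state + 1000 * si + ki
                try:
                    model = fit_member(spec, Xv[train], y[train], seed=seed)
                    scores = member_scores(model, Xv[test])
                except Exception as exc:  # noqa: BLE001 — member failure is data
                    failures.append(f"{spec.algorithm_id}/split{ki}: {exc}")
                    continue
                ev = evaluate_scores(scores, y[test], split_id=ki, algorithm=spec.algorithm_id)
                all_evals.append(ev)
                if ev.passes(self.tss_min, self.auc_min):
                    members.append((spec, model, ev))
        if failures:
            warnings.warn("member fitting failures: " + "; ".join(failures))
        if not members:
            detail = "; ".join(
                f"{e.algorithm}/split{e.split_id}: TSS={e.tss:.3f}, AUC={e.auc:.3f}"
                for e in all_evals
            )
            raise RuntimeError(
                f"no member passed the gates (TSS>={self.tss_min}, AUC>={self.auc_min}): {detail}"
            )
        self.members_ = members
        self.member_evals_ = all_evals
        ens_scores = self._combine(Xv)
        t, sens, spec_, tss = mss_threshold(ens_scores, y)
        self.ensemble_mss_threshold_ = t
        self.ensemble_eval_ = evaluate_scores(ens_scores, y, algorithm="ensemble")
        return self

    def _combine(self, Xv: np.ndarray) -> np.ndarray:
        score_mat = np.stack([member_scores(m, Xv) for _, m, _ in self.members_])
        if self.combination == "tss-weighted-mean":
            w = np.array([ev.tss for _, _, ev in self.members_], dtype=float)
            w = w / w.sum()
            return np.average(score_mat, axis=0, weights=w)
        if self.combination != "mean":
            raise ValueError(f"unknown combination {self.combination!r}")
        return score_mat.mean(axis=0)

    def predict_suitability(self, X) -> np.ndarray:
        """Ensemble suitability score in [0, 1] per row."""
        check_is_fitted(self, "members_")
        Xv = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return self._combine(Xv)

    def predict_proba(self, X) -> np.ndarray:
        s = self.predict_suitability(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        """Binary presence via the ensemble MSS threshold."""
        check_is_fitted(self, "ensemble_mss_threshold_")
        return (self.predict_suitability(X) >= self.ensemble_mss_threshold_).astype(int)

    def evaluation_table(self) -> pd.DataFrame:
        check_is_fitted(self, "member_evals_")
        rows = [
            {
                "algorithm": e.algorithm,
                "split_id": e.split_id,
                "auc": e.auc,
                "tss": e.tss,
                "mss_threshold": e.mss_threshold,
                "sensitivity": e.sensitivity,
                "specificity": e.specificity,
                "passed": e.passes(self.tss_min, self.auc_min),
            }
            for e in self.member_evals_
        ]
        return pd.DataFrame(rows)


def build_ensemble(
    specs, X, y, cv_repeats: int = 5, train_frac: float = 0.7,
    gates: tuple[float, float] = (0.7, 0.8), combination: str = "mean",
    seed: int = 0,
) -> EnsembleSDM:
    """Functional wrapper over :class:`EnsembleSDM`."""
    est = EnsembleSDM(
        algorithms=tuple(specs),
        tss_min=gates[0],
        auc_min=gates[1],
        cv_repeats=cv_repeats,
        train_frac=train_frac,
        combination=combination,
        random_state=seed,
    )
    return est.fit(X, y)


def predict_raster(ensemble: EnsembleSDM, stack: PredictorStack,
                   batch_size: int = 100_000) -> RasterGrid:
    """Project the ensemble onto a predictor stack, cell by cell.

    The stack must contain every predictor the ensemble was fitted on; extra
    layers are ignored. Nodata in any required layer propagates.
    """
    check_is_fitted(ensemble, "members_")
    needed = list(ensemble.feature_names_in_)
    missing = [n for n in needed if n not in stack.grids]
    if missing:
        raise KeyError(f"stack is missing predictors required by the model: {missing}")
    tmpl = stack.template
    mask = np.zeros(tmpl.shape, dtype=bool)
    for n in needed:
        mask |= stack.grids[n].nodata_mask
    valid = np.flatnonzero(~mask.ravel())
    cube = np.stack([stack.grids[n].values.ravel() for n in needed], axis=1)
    out = np.full(tmpl.shape[0] * tmpl.shape[1], np.nan)
    for start in range(0, len(valid), batch_size):
        idx = valid[start : start + batch_size]
        out[idx] = ensemble.predict_suitability(cube[idx])
    return RasterGrid(
        out.reshape(tmpl.shape), mask, tmpl.origin_lon, tmpl.origin_lat, tmpl.cell_size
    )
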