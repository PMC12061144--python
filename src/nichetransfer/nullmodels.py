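"""Null species distribution models and real-vs-null significance testing.

A model fitted to *random* virtual occurrence points has no ecological signal;
its held-out AUC/TSS distribution defines the no-skill baseline for a given
region and sampling design. Per replicate, virtual presences (70 % of the
actual occurrence count, rounded half away from zero) are drawn uniformly
from valid cells, fresh pseudo-absences are generated, the same algorithm
specs are fitted, and the null model is evaluated against a freshly drawn
held-out 30 % of the *real* records (plus pseudo-absences). A one-sided Welch
t-test then asks whether the real models' skill exceeds the null skill.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import (
    ModelSpec,
    PseudoAbsenceConfig,
    fit_member,
    generate_pseudo_absences,
    member_scores,
)
from .geodata import OccurrenceSet, PredictorStack, extract_values
from .metrics import EvalResult, evaluate_scores


@dataclass
class NullModelConfig:
    n_virtual_rule: str = "70%-of-actual"
    replicates: int = 10
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")

    def resolve_virtual_count(self, n_actual: int) -> int:
        if self.n_virtual_rule != "70%-of-actual":
            raise ValueError(f"unknown virtual-record rule {self.n_virtual_rule!r}")
        # round half away from zero, e.g. 445.9 -> 446, 7.5 -> 8
        return int(math.floor(0.7 * n_actual + 0.5))


def _uniform_virtual_records(
    stack: PredictorStack, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    tmpl = stack.template
    valid = np.flatnonzero(~stack.combined_nodata().ravel())
    cells = rng.choice(valid, size=n, replace=n > len(valid))
    rows, cols = np.unravel_index(cells, tmpl.shape)
    return pd.DataFrame(
        {
            "lon": tmpl.origin_lon + (cols + rng.random(n)) * tmpl.cell_size,
            "lat": tmpl.origin_lat - (rows + rng.random(n)) * tmpl.cell_size,
        }
    )


def build_null_models(
    stack: PredictorStack,
    real_occurrences: OccurrenceSet | pd.DataFrame,
    specs: list[ModelSpec | str],
    config: NullModelConfig,
) -> list[EvalResult]:
    """Fit and evaluate null SDMs; one EvalResult per (replicate, spec).

    Each replicate draws its own virtual presences, pseudo-absences, and
    held-out 30 % sample of the real records.
    """
    df = (
        real_occurrences.records
        if isinstance(real_occurrences, OccurrenceSet)
        else real_occurrences
    )
    if len(df) < 10:
        raise ValueError("need at least 10 real occurrence records")
    specs = [s if isinstance(s, ModelSpec) else ModelSpec(s) for s in specs]
    n_virtual = config.resolve_virtual_count(len(df))
    ss = np.random.SeedSequence(config.seed)
    results: list[EvalResult] = []
    for rep, child in enumerate(ss.spawn(config.replicates)):
        rep_seed = int(child.generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(rep_seed)
        virtual = _uniform_virtual_records(stack, n_virtual, rng)
        pas = generate_pseudo_absences(
            stack, virtual.assign(population="virtual"), PseudoAbsenceConfig(seed=rep_seed + 1)
        )
        X_pres, _ = extract_values(virtual.assign(population="virtual"), stack)
        X_abs, _ = extract_values(pas.assign(population="pa"), stack)
        X_train = pd.concat([X_pres, X_abs], ignore_index=True)
        y_train = np.r_[np.ones(len(X_pres), int), np.zeros(len(X_abs), int)]

        # held-out 30% of the real records, redrawn per replicate
        n_test = max(1, int(round(0.3 * len(df))))
        test_idx = rng.choice(len(df), size=n_test, replace=False)
        test_pts = df.iloc[test_idx]
        X_test_pres, _ = extract_values(test_pts, stack)
        test_pas = generate_pseudo_absences(
            stack, test_pts, PseudoAbsenceConfig(seed=rep_seed + 2)
        )
        X_test_abs, _ = extract_values(test_pas.assign(population="pa"), stack)
        X_test = pd.concat([X_test_pres, X_test_abs], ignore_index=True)
        y_test = np.r_[np.ones(len(X_test_pres), int), np.zeros(len(X_test_abs), int)]

        for spec in specs:
            model = fit_member(spec, X_train.to_numpy(float), y_train, seed=rep_seed)
            scores = member_scores(model, X_test.to_numpy(float))
            results.append(
                evaluate_scores(scores, y_test, split_id=rep, algorithm=f"null:{spec.algorithm_id}")
            )
    return results


def welch_t_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch unequal-variance t-test; returns (t, df, two-sided p).

    Both samples zero-variance with equal means -> (0, df, 1) by convention.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            warnings.warn("both samples constant and equal: p = 1 by convention")
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    na, nb = len(a), len(b)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass
class NullComparison:
    """Real-vs-null skill comparison for AUC and TSS."""

    real_auc: list[float]
    null_auc: list[float]
    real_tss: list[float]
    null_tss: list[float]
    alpha: float = 0.05
    t_auc: float = field(init=False)
    p_auc: float = field(init=False)
    t_tss: float = field(init=False)
    p_tss: float = field(init=False)
    verdict_auc: bool = field(init=False)
    verdict_tss: bool = field(init=False)

    def __post_init__(self) -> None:
        for metric in ("auc", "tss"):
            real = getattr(self, f"real_{metric}")
            null = getattr(self, f"null_{metric}")
            t, _, p_two = welch_t_test(real, null)
            # one-sided alternative: real skill exceeds null skill
            p_one = p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
            setattr(self, f"t_{metric}", t)
            setattr(self, f"p_{metric}", float(p_one))
            setattr(self, f"verdict_{metric}", bool(t > 0 and p_one < self.alpha))

    def to_dict(self) -> dict:
        return {
            "t_auc": self.t_auc,
            "p_auc": self.p_auc,
            "verdict_auc": self.verdict_auc,
            "t_tss": self.t_tss,
            "p_tss": self.p_tss,
            "verdict_tss": self.verdict_tss,
            "mean_real_auc": float(np.mean(self.real_auc)),
            "mean_null_auc": float(np.mean(self.null_auc)),
            "mean_real_tss": float(np.mean(self.real_tss)),
            "mean_null_tss": float(np.mean(self.null_tss)),
            "alpha": self.alpha,
        }


def compare_real_vs_null(
    real_evals: list[EvalResult], null_evals: list[EvalResult], alpha: float = 0.05
) -> NullComparison:
    """One-sided verdict per metric: do the real models out-skill the nulls?"""
    if not real_evals or not null_evals:
        raise ValueError("both evaluation lists must be non-empty")
    return NullComparison(
        real_auc=[e.auc for e in real_evals],
        null_auc=[e.auc for e in null_evals],
        real_tss=[e.tss for e in real_evals],
        null_tss=[e.tss for e in null_evals],
        alpha=alpha,
    )
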