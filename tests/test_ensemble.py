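import numpy as np
import pandas as pd
import pytest

from nichetransfer.ensemble import (
    ALGORITHM_REGISTRY,
    EnsembleSDM,
    ModelSpec,
    PseudoAbsenceConfig,
    fit_member,
    generate_pseudo_absences,
    member_scores,
    predict_raster,
)
from nichetransfer.geodata import OccurrenceSet, PredictorStack
from nichetransfer.metrics import auc

from conftest import make_grid


def separable_data(rng, n=500, noise=0.0):
    """Presence iff the single predictor exceeds 0 (plus optional noise)."""
    x = rng.uniform(-1, 1, n)
    y = (x + noise * rng.standard_normal(n) > 0).astype(int)
    return np.column_stack([x]), y


class TestPseudoAbsences:
    def make_occ(self, rng, n, stack):
        tmpl = stack.template
        lon = rng.uniform(tmpl.origin_lon + 0.1, tmpl.origin_lon + 2.0, n)
        lat = rng.uniform(tmpl.origin_lat - 2.0, tmpl.origin_lat - 0.1, n)
        return OccurrenceSet(pd.DataFrame({"population": "p", "lon": lon, "lat": lat}))

    def test_count_equals_occurrences_when_below_1000(self, rng):
        grid = make_grid(np.zeros((70, 70)), cell_size=0.1)
        stack = PredictorStack({"b": grid}, {"b": "climate"})
        occ = self.make_occ(rng, 637, stack)
        pas = generate_pseudo_absences(stack, occ, PseudoAbsenceConfig(seed=0))
        assert len(pas) == 637

    def test_count_capped_at_1000(self, rng):
        grid = make_grid(np.zeros((80, 80)), cell_size=0.1)
        stack = PredictorStack({"b": grid}, {"b": "climate"})
        occ = self.make_occ(rng, 3039, stack)
        pas = generate_pseudo_absences(stack, occ, PseudoAbsenceConfig(seed=0))
        assert len(pas) == 1000

    def test_exhaustion_uses_every_valid_unoccupied_cell(self, rng):
        grid = make_grid(np.zeros((4, 5)), cell_size=1.0, origin_lat=4.0)
        stack = PredictorStack({"b": grid}, {"b": "climate"})
        # occupy 5 cells; 15 remain; 15 occurrences -> every free cell used once
        occ_cells = [(0, j) for j in range(5)]
        lon = [j + 0.5 for _, j in occ_cells] + [0.5] * 10
        lat = [3.5] * 5 + [3.5] * 10
        occ = OccurrenceSet(pd.DataFrame({"population": "p", "lon": lon, "lat": lat}))
        pas = generate_pseudo_absences(stack, occ, PseudoAbsenceConfig(seed=1))
        assert len(pas) == 15
        rows, cols = stack.template.cell_index(pas["lon"].to_numpy(), pas["lat"].to_numpy())
        cells = set(zip(rows.tolist(), cols.tolist()))
        assert len(cells) == 15 and not cells & set(occ_cells)

    def test_insufficient_cells_raises_with_counts(self, rng):
        grid = make_grid(np.zeros((4, 5)), cell_size=1.0, origin_lat=4.0)
        stack = PredictorStack({"b": grid}, {"b": "climate"})
        occ = self.make_occ(rng, 50, stack)
        with pytest.raises(ValueError, match="insufficient"):
            generate_pseudo_absences(stack, occ, PseudoAbsenceConfig(seed=0))

    def test_reproducible(self, rng):
        grid = make_grid(np.zeros((30, 30)), cell_size=0.2)
        stack = PredictorStack({"b": grid}, {"b": "climate"})
        occ = self.make_occ(rng, 40, stack)
        a = generate_pseudo_absences(stack, occ, PseudoAbsenceConfig(seed=3))
        b = generate_pseudo_absences(stack, occ, PseudoAbsenceConfig(seed=3))
        assert a.equals(b)


class TestFitMember:
    @pytest.mark.parametrize("algorithm", sorted(ALGORITHM_REGISTRY))
    def test_separable_problem_high_auc(self, algorithm, rng):
        X, y = separable_data(rng, n=500)
        train, test = np.arange(0, 350), np.arange(350, 500)
        model = fit_member(ModelSpec(algorithm), X[train], y[train], seed=0)
        scores = member_scores(model, X[test])
        assert auc(scores, y[test]) >= 0.95

    def test_constant_predictor_gives_half_auc(self, rng):
        X = np.ones((200, 1))
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        model = fit_member(ModelSpec("cta"), X, y, seed=0)
        scores = member_scores(model, X)
        assert auc(scores, y) == 0.5

    def test_deterministic_given_seed(self, rng):
        X, y = separable_data(rng, n=300, noise=0.3)
        a = member_scores(fit_member(ModelSpec("rf"), X, y, seed=4), X)
        b = member_scores(fit_member(ModelSpec("rf"), X, y, seed=4), X)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_member(ModelSpec("rf"), np.zeros((10, 1)), np.ones(10))

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="registered"):
            ModelSpec("nonesuch")


class TestEnsemble:
    def test_requires_two_distinct_families(self, rng):
        X, y = separable_data(rng)
        with pytest.raises(ValueError, match="two distinct"):
            EnsembleSDM(algorithms=("rf",)).fit(X, y)

    def test_gated_ensemble_on_separable_problem(self, rng):
        X, y = separable_data(rng, n=400)
        est = EnsembleSDM(algorithms=("maxent", "cta"), random_state=0).fit(X, y)
        assert len(est.members_) >= 1
        for _, _, ev in est.members_:
            assert ev.tss >= 0.7 and ev.auc >= 0.8
        assert est.ensemble_eval_.auc >= 0.95
        # tss = sens + spec - 1 identity on every stored evaluation
        for ev in est.member_evals_:
            assert ev.tss == pytest.approx(ev.sensitivity + ev.specificity - 1.0)

    def test_ensemble_score_is_mean_of_members(self, rng):
        X, y = separable_data(rng, n=200)
        est = EnsembleSDM(algorithms=("maxent", "cta"), cv_repeats=2, random_state=1).fit(X, y)
        manual = np.mean([member_scores(m, X) for _, m, _ in est.members_], axis=0)
        assert np.allclose(est.predict_suitability(X), manual)

    def test_no_survivor_reports_metrics(self, rng):
        X = rng.standard_normal((120, 2))
        y = rng.integers(0, 2, 120)  # pure noise: nothing clears the gates
        with pytest.raises(RuntimeError, match="TSS"):
            EnsembleSDM(algorithms=("maxent", "cta"), random_state=0).fit(X, y)

    def test_fit_deterministic(self, rng):
        X, y = separable_data(rng, n=300, noise=0.2)
        Xf = pd.DataFrame(X, columns=["x"])
        a = EnsembleSDM(algorithms=("maxent", "gbm"), random_state=7).fit(Xf, y)
        b = EnsembleSDM(algorithms=("maxent", "gbm"), random_state=7).fit(Xf, y)
        assert a.ensemble_mss_threshold_ == b.ensemble_mss_threshold_
        assert np.array_equal(a.predict_suitability(Xf), b.predict_suitability(Xf))

    def test_sklearn_params_roundtrip(self):
        est = EnsembleSDM(tss_min=0.6)
        assert est.get_params()["tss_min"] == 0.6
        est.set_params(auc_min=0.85)
        assert est.auc_min == 0.85


class TestPredictRaster:
    def _fitted(self, rng, names=("bio1",)):
        n = 400
        X = pd.DataFrame({name: rng.uniform(-1, 1, n) for name in names})
        y = (X.iloc[:, 0] > 0).astype(int).to_numpy()
        return EnsembleSDM(algorithms=("maxent", "cta"), cv_repeats=2, random_state=0).fit(X, y)

    def test_matches_per_cell_brute_force(self, rng):
        est = self._fitted(rng)
        mask = np.zeros((20, 20), dtype=bool)
        mask[2, 3] = True
        vals = rng.uniform(-1, 1, (20, 20))
        vals[mask] = np.nan
        stack = PredictorStack({"bio1": make_grid(vals, mask=mask)}, {"bio1": "climate"})
        out = predict_raster(est, stack)
        for i in range(20):
            for j in range(20):
                if mask[i, j]:
                    assert out.nodata_mask[i, j]
                else:
                    expected = est.predict_suitability(
                        pd.DataFrame({"bio1": [vals[i, j]]})
                    )[0]
                    assert out.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_stack_gives_constant_surface(self, rng):
        est = self._fitted(rng)
        stack = PredictorStack(
            {"bio1": make_grid(np.full((10, 10), 0.4))}, {"bio1": "climate"}
        )
        out = predict_raster(est, stack)
        assert np.ptp(out.values) == 0.0

    def test_missing_predictor_named(self, rng):
        est = self._fitted(rng, names=("bio1", "bio7"))
        stack = PredictorStack({"bio1": make_grid(np.zeros((10, 10)))}, {"bio1": "climate"})
        with pytest.raises(KeyError, match="bio7"):
            predict_raster(est, stack)
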