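"""End-to-end orchestration: simulate/load -> thin -> select -> fit -> null-check
-> project -> range shift.

One master seed deterministically spawns every per-stage seed, so an identical
config reproduces an identical run report and bitwise-identical rasters. Each
native population's model is fitted on its home region and projected onto the
target region before binarization (with the threshold calibrated on its own
source data) and decomposition against the introduced population's range map.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .ensemble import EnsembleSDM, ModelSpec, PseudoAbsenceConfig, generate_pseudo_absences, predict_raster
from .geodata import (
    PredictorStack,
    extract_values,
    read_occurrences,
    read_raster,
    write_raster,
)
from .nullmodels import NullModelConfig, build_null_models, compare_real_vs_null
from .rangeshift import binarize, decompose
from .selection import permutation_importance, select_predictors
from .synthetic import predictor_category
from .thinning import ThinningConfig, thin


@dataclass
class PipelineConfig:
    """All knobs of one analysis run.

    ``mode`` is "synthetic" (generate the bundled virtual-species scenario) or
    "files" (read occurrence CSV + per-region GeoTIFF directories).
    """

    mode: str = "synthetic"
    seed: int = 0
    output_dir: str = "run_output"
    # synthetic mode
    n_occurrences: int = 500
    cell_size: float = 0.3
    # files mode
    occurrences_csv: str | None = None
    predictor_dirs: dict[str, str] = field(default_factory=dict)  # region -> dir
    population_region: dict[str, str] = field(default_factory=dict)
    target_region: str | None = None
    introduced_population: str | None = None
    comparisons: list[tuple[str, str]] = field(default_factory=list)  # (introduced, native)
    # stage settings
    thinning_radius_km: float = 5.0
    collinearity_threshold: float = 0.7
    preliminary_algorithm: str = "rf"
    importance_replicates: int = 5
    algorithms: list[str] = field(default_factory=lambda: ["maxent", "rf", "gbm"])
    cv_repeats: int = 5
    train_frac: float = 0.7
    tss_min: float = 0.7
    auc_min: float = 0.8
    run_null_models: bool = False
    null_replicates: int = 10
    null_alpha: float = 0.05

    def validate(self) -> list[str]:
        """Collect every violation (empty list = valid)."""
        errs: list[str] = []
        if self.mode not in ("synthetic", "files"):
            errs.append(f"mode: must be 'synthetic' or 'files', got {self.mode!r}")
        if not 0 < self.train_frac < 1:
            errs.append(f"train_frac: must lie in (0, 1), got {self.train_frac}")
        if not 0 < self.collinearity_threshold <= 1:
            errs.append(
                f"collinearity_threshold: must lie in (0, 1], got {self.collinearity_threshold}"
            )
        if self.thinning_radius_km <= 0:
            errs.append(f"thinning_radius_km: must be positive, got {self.thinning_radius_km}")
        if not -1 <= self.tss_min <= 1:
            errs.append(f"tss_min: must lie in [-1, 1], got {self.tss_min}")
        if not 0 <= self.auc_min <= 1:
            errs.append(f"auc_min: must lie in [0, 1], got {self.auc_min}")
        if self.cv_repeats < 1:
            errs.append(f"cv_repeats: must be >= 1, got {self.cv_repeats}")
        if len(set(self.algorithms)) < 2:
            errs.append("algorithms: need at least two distinct families")
        if not 0 < self.null_alpha < 1:
            errs.append(f"null_alpha: must lie in (0, 1), got {self.null_alpha}")
        if self.mode == "files":
            if not self.occurrences_csv:
                errs.append("occurrences_csv: required in files mode")
            elif not Path(self.occurrences_csv).exists():
                errs.append(f"occurrences_csv: not found: {self.occurrences_csv}")
            if not self.predictor_dirs:
                errs.append("predictor_dirs: required in files mode")
            for region, d in self.predictor_dirs.items():
                if not Path(d).is_dir():
                    errs.append(f"predictor_dirs[{region}]: not a directory: {d}")
            if self.target_region and self.target_region not in self.predictor_dirs:
                errs.append(f"target_region: {self.target_region!r} has no predictor dir")
        return errs


def validate_config(path) -> PipelineConfig:
    """Load a YAML config; raise ValueError listing *all* violations."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    errs = [f"unknown field: {k}" for k in sorted(unknown)]
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    cfg.comparisons = [tuple(c) for c in cfg.comparisons]
    errs += cfg.validate()
    if errs:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errs))
    return cfg


@dataclass
class PopulationResult:
    population: str
    region: str
    n_raw: int
    n_thinned: int
    n_pseudo_absences: int
    retained_predictors: list[str]
    removed_predictors: list[str]
    member_metrics: list[dict]
    ensemble_auc: float
    ensemble_tss: float
    mss_threshold: float
    null_comparison: dict | None = None


@dataclass
class RunReport:
    seed: int
    config: dict
    populations: list[PopulationResult]
    range_shifts: list[dict]
    stage_seeds: dict[str, int]
    version: str = ""

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "version": self.version,
                "config": self.config,
                "stage_seeds": self.stage_seeds,
                "populations": [asdict(p) for p in self.populations],
                "range_shifts": self.range_shifts,
            },
            indent=2,
            sort_keys=True,
            **kw,
        )


def _spawn_seeds(master: int, labels: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(labels))
    return {lab: int(c.generate_state(1)[0] % 2**31) for lab, c in zip(labels, children)}


def _load_files_inputs(cfg: PipelineConfig):
    occurrences, _ = read_occurrences(cfg.occurrences_csv)
    stacks: dict[str, PredictorStack] = {}
    for region, d in cfg.predictor_dirs.items():
        grids = {}
        category = {}
        for p in sorted(Path(d).glob("*.tif")):
            name = p.stem
            grids[name] = read_raster(p)
            category[name] = predictor_category(name)
        if not grids:
            raise FileNotFoundError(f"no .tif predictors found in {d}")
        stacks[region] = PredictorStack(grids, category)
    return occurrences, stacks, dict(cfg.population_region), cfg.target_region


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> RunReport:
    """Execute the full analysis; returns the run report.

    When ``write_outputs`` is true, suitability and binary-range GeoTIFFs,
    evaluation CSVs, and the JSON report are written under ``output_dir``.
    """
    errs = config.validate()
    if errs:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errs))

    # ------------------------------------------------------------------ inputs
    if config.mode == "synthetic":
        scenario = synthetic.default_scenario(
            seed=config.seed, n_occurrences=config.n_occurrences, cell_size=config.cell_size
        )
        occurrences = scenario.occurrences
        stacks = scenario.stacks
        population_region = dict(scenario.home_region)
        target_region = scenario.target_region.name
        introduced = config.introduced_population or "introduced"
        comparisons = config.comparisons or [
            (introduced, p) for p in sorted(population_region) if p != introduced
        ]
    else:
        occurrences, stacks, population_region, target_region = _load_files_inputs(config)
        introduced = config.introduced_population
        comparisons = config.comparisons
        if introduced is None or target_region is None:
            raise ValueError("files mode requires introduced_population and target_region")

    populations = sorted(population_region)
    stage_seeds = _spawn_seeds(
        config.seed,
        [f"{stage}:{pop}" for pop in populations for stage in ("thin", "pa", "importance", "fit", "null")],
    )

    out = Path(config.output_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    # --------------------------------------------------------- per population
    pop_results: list[PopulationResult] = []
    ensembles: dict[str, EnsembleSDM] = {}
    range_maps: dict[str, "object"] = {}
    target_stack = stacks[target_region]

    for pop in populations:
        region = population_region[pop]
        stack = stacks[region]
        occ = occurrences.subset(pop)
        n_raw = len(occ)

        thinned, _removed = thin(
            occ, ThinningConfig(radius_km=config.thinning_radius_km,
                                seed=stage_seeds[f"thin:{pop}"])
        )

        pas = generate_pseudo_absences(
            stack, thinned, PseudoAbsenceConfig(seed=stage_seeds[f"pa:{pop}"])
        )
        X_pres, _ = extract_values(thinned, stack)
        X_abs, _ = extract_values(pas.assign(population="pa"), stack)
        X = pd.concat([X_pres, X_abs], ignore_index=True)
        y = np.r_[np.ones(len(X_pres), int), np.zeros(len(X_abs), int)]

        # predictor selection on a preliminary all-predictor model
        prelim = ModelSpec(config.preliminary_algorithm).build(
            stage_seeds[f"importance:{pop}"]
        )
        prelim.fit(X.to_numpy(float), y)
        importance = permutation_importance(
            lambda M: prelim.predict_proba(M)[:, 1],
            X,
            replicates=config.importance_replicates,
            seed=stage_seeds[f"importance:{pop}"],
        )
        selection = select_predictors(X, importance, threshold=config.collinearity_threshold)
        X_sel = X[selection.retained]

        est = EnsembleSDM(
            algorithms=tuple(config.algorithms),
            tss_min=config.tss_min,
            auc_min=config.auc_min,
            cv_repeats=config.cv_repeats,
            train_frac=config.train_frac,
            random_state=stage_seeds[f"fit:{pop}"],
        )
        est.fit(X_sel, y)
        ensembles[pop] = est

        null_cmp = None
        if config.run_null_models:
            sub_stack = PredictorStack(
                {n: stack.grids[n] for n in selection.retained},
                {n: stack.category[n] for n in selection.retained},
            )
            null_evals = build_null_models(
                sub_stack,
                thinned,
                [ModelSpec(a) for a in config.algorithms],
                NullModelConfig(
                    replicates=config.null_replicates,
                    seed=stage_seeds[f"null:{pop}"],
                    alpha=config.null_alpha,
                ),
            )
            null_cmp = compare_real_vs_null(
                est.member_evals_, null_evals, alpha=config.null_alpha
            ).to_dict()

        # projection onto the target region and binarization with own threshold
        suit = predict_raster(est, stacks[target_region])
        rmap = binarize(suit, est.ensemble_mss_threshold_, label=pop)
        range_maps[pop] = rmap

        if write_outputs:
            write_raster(suit, out / f"suitability_{pop}_on_{target_region}.tif")
            write_raster(
                suit.with_values(rmap.presence.astype(float), rmap.nodata_mask),
                out / f"range_{pop}_on_{target_region}.tif",
            )
            est.evaluation_table().to_csv(out / f"members_{pop}.csv", index=False)

        pop_results.append(
            PopulationResult(
                population=pop,
                region=region,
                n_raw=n_raw,
                n_thinned=len(thinned),
                n_pseudo_absences=len(pas),
                retained_predictors=selection.retained,
                removed_predictors=selection.removed_names(),
                member_metrics=est.evaluation_table().to_dict("records"),
                ensemble_auc=est.ensemble_eval_.auc,
                ensemble_tss=est.ensemble_eval_.tss,
                mss_threshold=est.ensemble_mss_threshold_,
                null_comparison=null_cmp,
            )
        )

    # ------------------------------------------------------------ range shifts
    shifts = []
    for intro_pop, native_pop in comparisons:
        res = decompose(range_maps[intro_pop], range_maps[native_pop])
        shifts.append(res.to_dict())

    from . import __version__

    report = RunReport(
        seed=config.seed,
        config=asdict(config),
        populations=pop_results,
        range_shifts=shifts,
        stage_seeds=stage_seeds,
        version=__version__,
    )
    if write_outputs:
        (out / "report.json").write_text(report.to_json())
        if shifts:
            pd.DataFrame(shifts).to_csv(out / "range_shifts.csv", index=False)
    return report
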