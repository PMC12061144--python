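"""Virtual-species scenario generator.

Builds paired synthetic "continents" (predictor raster stacks with latitudinal
and longitudinal gradients plus spatially autocorrelated noise), virtual
species whose true habitat suitability is a logistic-linear function of
standardized predictors, and occurrence samples drawn proportionally to
suitability — so every downstream stage of the modelling pipeline can be
tested against a known ground truth.

Cross-continent comparability is deliberate: the deterministic gradient of a
predictor depends only on the predictor's *name* (via a stable hash), never on
the region, so "annual mean temperature" responds to latitude the same way on
every continent and a niche fitted on one region is meaningful on another.
Only the smoothed noise field (the "weather") differs between regions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .geodata import OccurrenceSet, PredictorStack, RasterGrid
from .rangeshift import BinaryRangeMap, binarize

DEFAULT_CELL_SIZE = 2.5 / 60  # degrees; 2.5 arc-minutes

#: default predictor roster: a small climate/land-use/topography mix
DEFAULT_PREDICTORS = ("bio1", "bio4", "bio12", "lu_forest", "elevation")


def predictor_category(name: str) -> str:
    if name.startswith("bio"):
        return "climate"
    if name.startswith("lu_"):
        return "landuse"
    return "topography"


@dataclass
class RegionSpec:
    """Geometry and noise settings of one synthetic region ("continent")."""

    name: str
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float = DEFAULT_CELL_SIZE
    predictor_names: tuple[str, ...] = DEFAULT_PREDICTORS
    noise_smoothing: int = 2
    noise_amplitude: float = 0.3
    nodata_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("region bounds must satisfy lon_min < lon_max, lat_min < lat_max")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError(
                f"degenerate grid {self.n_rows}x{self.n_cols}: need at least 10 cells per side"
            )

    @property
    def n_rows(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @property
    def n_cols(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))


@dataclass
class VirtualSpeciesSpec:
    """A virtual species: logistic niche over standardized predictors."""

    name: str
    coefficients: dict[str, float]
    intercept: float = 0.0
    occupancy_threshold: float = 0.5
    n_occurrences: int = 500
    sampling_bias_strength: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy_threshold <= 1.0:
            raise ValueError("occupancy_threshold must lie in [0, 1]")
        if self.n_occurrences < 1:
            raise ValueError("n_occurrences must be positive")
        if self.sampling_bias_strength < 0:
            raise ValueError("sampling_bias_strength must be >= 0")


#: gradient orientation overrides for the default roster: climate means and
#: precipitation are strongly latitudinal, land-use fractions are not, and
#: topography is a mix. Unlisted predictors get a hash-stable orientation.
GRADIENT_ORIENTATION: dict[str, str] = {
    "bio1": "lat",
    "bio4": "lat",
    "bio12": "lat",
    "lu_forest": "lon",
    "elevation": "mixed",
}


def _gradient_coeffs(name: str) -> tuple[float, float]:
    """Stable per-predictor gradient slopes (lat, lon), independent of region.

    Orientations keep the predictor set from collapsing into one collinear
    cluster: latitudinal layers are near-copies of each other (as bioclim
    variables are in reality), longitudinal and mixed layers decorrelate from
    them. The latitudinal slope is always strictly positive so a noise-free
    layer is strictly monotone in latitude along any column.
    """
    rng = np.random.default_rng(zlib.crc32(name.encode()))
    orientation = GRADIENT_ORIENTATION.get(
        name, ("lat", "lon", "mixed")[int(rng.integers(3))]
    )
    sign = -1.0 if rng.random() < 0.5 else 1.0
    if orientation == "lat":
        a = 0.8 + 0.7 * rng.random()
        b = sign * 0.2 * rng.random()
    elif orientation == "lon":
        a = 0.1 + 0.2 * rng.random()
        b = sign * (1.5 + 1.5 * rng.random())
    else:
        a = 0.4 + 0.4 * rng.random()
        b = sign * (0.7 + 0.7 * rng.random())
    return a, b


def generate_predictor_stack(region: RegionSpec) -> PredictorStack:
    """Synthesize one aligned grid per predictor for a region.

    Each layer is a deterministic lat/lon gradient plus a moving-average
    smoothed white-noise field (radius ``noise_smoothing`` cells, amplitude
    ``noise_amplitude``); land-use layers are squashed to [0, 1]. A random
    ``nodata_fraction`` of cells (shared across layers) is masked to exercise
    nodata handling downstream. Fully reproducible from ``region.seed``.
    """
    rng = np.random.default_rng(region.seed)
    n_rows, n_cols = region.n_rows, region.n_cols
    lat = region.lat_max - (np.arange(n_rows) + 0.5) * region.cell_size
    lon = region.lon_min + (np.arange(n_cols) + 0.5) * region.cell_size
    lon_grid, lat_grid = np.meshgrid(lon, lat)

    nodata = np.zeros((n_rows, n_cols), dtype=bool)
    if region.nodata_fraction > 0:
        n_bad = int(round(region.nodata_fraction * n_rows * n_cols))
        flat = rng.choice(n_rows * n_cols, size=n_bad, replace=False)
        nodata.flat[flat] = True

    grids: dict[str, RasterGrid] = {}
    category: dict[str, str] = {}
    for name in region.predictor_names:
        a, b = _gradient_coeffs(name)
        # longitudinal term is continentality (distance into the region from its
        # west coast), not absolute longitude, so predictor distributions are
        # comparable across continents and a niche fitted on one transfers
        base = a * (lat_grid / 15.0) + b * ((lon_grid - region.lon_min) / 30.0)
        if region.noise_amplitude > 0:
            white = rng.standard_normal((n_rows, n_cols))
            size = 2 * region.noise_smoothing + 1
            noise = ndimage.uniform_filter(white, size=size, mode="nearest") if size > 1 else white
            base = base + region.noise_amplitude * noise
        else:
            # burn the draw so layer k is unchanged by other layers' settings
            rng.standard_normal((n_rows, n_cols))
        cat = predictor_category(name)
        if cat == "landuse":
            base = expit(base)
        vals = base.copy()
        vals[nodata] = np.nan
        grids[name] = RasterGrid(
            vals, nodata.copy(), region.lon_min, region.lat_max, region.cell_size
        )
        category[name] = cat
    return PredictorStack(grids, category)


@dataclass
class StandardizationStats:
    mean: dict[str, float]
    std: dict[str, float]

    @classmethod
    def from_stack(cls, stack: PredictorStack) -> "StandardizationStats":
        mean, std = {}, {}
        for name in stack.names:
            g = stack.grids[name]
            v = g.values[~g.nodata_mask]
            mean[name] = float(np.mean(v))
            s = float(np.std(v))
            std[name] = s if s > 0 else 1.0
        return cls(mean, std)


def true_suitability(
    stack: PredictorStack,
    species: VirtualSpeciesSpec,
    stats: StandardizationStats | None = None,
) -> RasterGrid:
    """Cell-wise logistic(intercept + sum of coefficient * standardized predictor).

    ``stats`` supplies the standardization constants; by default they are the
    stack's own per-layer mean/std over valid cells. Pass the species'
    home-region stats to evaluate the same niche on another region.
    """
    missing = [n for n in species.coefficients if n not in stack.grids]
    if missing:
        raise KeyError(f"coefficients name predictors absent from the stack: {missing}")
    if stats is None:
        stats = StandardizationStats.from_stack(stack)
    tmpl = stack.template
    eta = np.full(tmpl.shape, float(species.intercept))
    for name, coef in species.coefficients.items():
        z = (stack.grids[name].values - stats.mean[name]) / stats.std[name]
        eta = eta + coef * z
    suit = expit(eta)
    mask = stack.combined_nodata()
    suit[mask] = np.nan
    return RasterGrid(suit, mask, tmpl.origin_lon, tmpl.origin_lat, tmpl.cell_size)


def sample_occurrences(
    suitability: RasterGrid, spec: VirtualSpeciesSpec, seed: int
) -> OccurrenceSet:
    """Draw presence points with cell probability proportional to suitability.

    Sampling bias multiplies cell weight by a longitudinal gradient raised to
    ``sampling_bias_strength`` (strength 0 = unbiased). Cells are drawn without
    replacement while enough habitable cells remain, then with replacement;
    each point is placed uniformly within its cell. Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    w = np.where(suitability.nodata_mask, 0.0, np.nan_to_num(suitability.values))
    if spec.sampling_bias_strength > 0:
        bias = (np.arange(suitability.n_cols) + 1) / suitability.n_cols
        w = w * bias[None, :] ** spec.sampling_bias_strength
    flat = w.ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("no habitable cells: suitability is zero everywhere")
    p = flat / total
    n = spec.n_occurrences
    n_support = int((flat > 0).sum())
    if n <= n_support:
        cells = rng.choice(flat.size, size=n, replace=False, p=p)
    else:
        cells = rng.choice(flat.size, size=n, replace=True, p=p)
    rows, cols = np.unravel_index(cells, suitability.shape)
    cs = suitability.cell_size
    lon = suitability.origin_lon + (cols + rng.random(n)) * cs
    lat = suitability.origin_lat - (rows + rng.random(n)) * cs
    df = pd.DataFrame(
        {"population": spec.name, "lon": lon, "lat": lat, "source": "synthetic"}
    )
    return OccurrenceSet(df, provenance=f"virtual species {spec.name} (seed {seed})")


@dataclass
class SyntheticScenario:
    """A complete ground-truthed study system.

    One or more source regions, one target region, at least two virtual
    species with partially shared niches, their true suitability surfaces and
    true binary ranges on every region, and sampled occurrences in each
    species' home region.
    """

    source_regions: dict[str, RegionSpec]
    target_region: RegionSpec
    species: dict[str, VirtualSpeciesSpec]
    home_region: dict[str, str]
    stacks: dict[str, PredictorStack]
    true_suitability: dict[tuple[str, str], RasterGrid]
    true_range: dict[tuple[str, str], BinaryRangeMap]
    occurrences: OccurrenceSet
    seed: int = 0

    @property
    def regions(self) -> dict[str, RegionSpec]:
        out = dict(self.source_regions)
        out[self.target_region.name] = self.target_region
        return out


def build_scenario(
    source_regions: list[RegionSpec],
    target_region: RegionSpec,
    species: list[VirtualSpeciesSpec],
    home_region: dict[str, str],
    seed: int = 0,
) -> SyntheticScenario:
    """Assemble stacks, truth surfaces, ranges, and occurrence samples."""
    if len(species) < 2:
        raise ValueError("a scenario needs at least two virtual species")
    regions = {r.name: r for r in source_regions}
    regions[target_region.name] = target_region
    ss = np.random.SeedSequence(seed)
    region_seeds = {name: int(s.generate_state(1)[0] % 2**31) for name, s in
                    zip(regions, ss.spawn(len(regions)))}
    stacks: dict[str, PredictorStack] = {}
    for name, region in regions.items():
        region.seed = region_seeds[name]
        stacks[name] = generate_predictor_stack(region)

    suit: dict[tuple[str, str], RasterGrid] = {}
    ranges: dict[tuple[str, str], BinaryRangeMap] = {}
    occ_frames = []
    occ_seeds = ss.spawn(len(species))
    for sp, sp_seed in zip(species, occ_seeds):
        home = home_region[sp.name]
        stats = StandardizationStats.from_stack(stacks[home])
        for region_name, stack in stacks.items():
            s = true_suitability(stack, sp, stats=stats)
            suit[(sp.name, region_name)] = s
            ranges[(sp.name, region_name)] = binarize(
                s, sp.occupancy_threshold, label=f"true:{sp.name}@{region_name}"
            )
        occ = sample_occurrences(
            suit[(sp.name, home)], sp, seed=int(sp_seed.generate_state(1)[0] % 2**31)
        )
        occ_frames.append(occ.records)
    occurrences = OccurrenceSet(pd.concat(occ_frames, ignore_index=True), provenance="synthetic")
    return SyntheticScenario(
        source_regions={r.name: r for r in source_regions},
        target_region=target_region,
        species={sp.name: sp for sp in species},
        home_region=dict(home_region),
        stacks=stacks,
        true_suitability=suit,
        true_range=ranges,
        occurrences=occurrences,
        seed=seed,
    )


def default_scenario(seed: int = 0, n_occurrences: int = 500,
                     cell_size: float = 0.3) -> SyntheticScenario:
    """The package's reference study system.

    Mimics an invasion setting: a widely distributed "native" species sampled
    on a source continent and a narrower "introduced" species sampled on the
    target continent, sharing the dominant thermal-niche coefficient but
    diverging in seasonality response and baseline prevalence — so the native
    species' true target-region range strictly exceeds the introduced one's.
    """
    source = RegionSpec(
        "palearctic", lon_min=40, lon_max=70, lat_min=25, lat_max=55, cell_size=cell_size
    )
    target = RegionSpec(
        "nearctic", lon_min=-100, lon_max=-70, lat_min=25, lat_max=55, cell_size=cell_size
    )
    native = VirtualSpeciesSpec(
        "native",
        coefficients={"bio1": 14.0, "bio12": 2.5},
        intercept=-18.5,
        occupancy_threshold=0.5,
        n_occurrences=n_occurrences,
    )
    introduced = VirtualSpeciesSpec(
        "introduced",
        coefficients={"bio1": 16.0, "bio4": -2.5},
        intercept=-17.5,
        occupancy_threshold=0.5,
        n_occurrences=n_occurrences,
    )
    return build_scenario(
        source_regions=[source],
        target_region=target,
        species=[native, introduced],
        home_region={"native": "palearctic", "introduced": "nearctic"},
        seed=seed,
    )
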