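"""Binary range maps and range-shift decomposition.

An introduced-vs-native pair of binary range maps decomposes cell-wise into

* expansion     — cells occupied only by the introduced range,
* stabilization — cells occupied by both (the shared range, RS),
* unfilling     — cells occupied only by the native range,

with areas accumulated from latitude-dependent spherical cell areas. From the
introduced range area IR = expansion + stabilization and native range area
NR = unfilling + stabilization follow two summary indices:

* the range ratio RR = IR / NR (and its inverse NR / IR, the direction in
  which such ratios are usually quoted when the native range is larger), and
* the index of range similarity IRS = 2 RS / (IR + NR), a Sørensen-style
  overlap in [0, 1]; the halved variant RS / (IR + NR) is also reported since
  both conventions circulate.

Both directions/variants are always computed and explicitly labelled; nothing
here silently picks one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geodata import OccurrenceSet, PredictorStack, RasterGrid, cell_area_km2, extract_values


@dataclass
class BinaryRangeMap:
    """Thresholded presence/absence grid with per-cell areas (km^2)."""

    presence: np.ndarray
    nodata_mask: np.ndarray
    area_map: RasterGrid
    threshold_used: float
    label: str = ""

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.presence.shape != self.nodata_mask.shape:
            raise ValueError("presence and nodata_mask shapes differ")
        if self.presence[self.nodata_mask].any():
            raise ValueError("presence must be False on nodata cells")

    @property
    def template(self) -> RasterGrid:
        return self.area_map

    def area_km2(self) -> float:
        """Total area of the range (km^2)."""
        return float(self.area_map.values[self.presence].sum())

    def n_cells(self) -> int:
        return int(self.presence.sum())


def binarize(suitability: RasterGrid, threshold: float, label: str = "") -> BinaryRangeMap:
    """Presence where suitability >= threshold on valid cells; nodata -> absent."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    mask = suitability.nodata_mask
    with np.errstate(invalid="ignore"):
        presence = (suitability.values >= threshold) & ~mask
    return BinaryRangeMap(
        presence=presence,
        nodata_mask=mask.copy(),
        area_map=cell_area_km2(suitability),
        threshold_used=float(threshold),
        label=label,
    )


@dataclass
class RangeShiftResult:
    """Areas (km^2) and indices for one introduced-vs-native comparison."""

    introduced_label: str
    native_label: str
    area_expansion: float
    area_stabilization: float
    area_unfilling: float
    excluded_cells: int
    IR: float = field(init=False)
    NR: float = field(init=False)
    RR: float = field(init=False)
    RR_native_over_introduced: float = field(init=False)
    IRS: float = field(init=False)
    IRS_reported_variant: float = field(init=False)

    def __post_init__(self) -> None:
        self.IR = self.area_expansion + self.area_stabilization
        self.NR = self.area_unfilling + self.area_stabilization
        if self.IR > 0 and self.NR > 0:
            self.RR, self.RR_native_over_introduced = range_ratio(self.IR, self.NR)
        else:  # an empty range: the ratio is undefined, not an error
            self.RR = self.RR_native_over_introduced = float("nan")
        if self.IR + self.NR > 0:
            self.IRS, self.IRS_reported_variant = range_similarity(
                self.area_stabilization, self.IR, self.NR
            )
        else:
            self.IRS = self.IRS_reported_variant = float("nan")

    def to_dict(self) -> dict:
        return {
            "introduced": self.introduced_label,
            "native": self.native_label,
            "area_expansion_km2": self.area_expansion,
            "area_stabilization_km2": self.area_stabilization,
            "area_unfilling_km2": self.area_unfilling,
            "IR_km2": self.IR,
            "NR_km2": self.NR,
            "RR_introduced_over_native": self.RR,
            "RR_native_over_introduced": self.RR_native_over_introduced,
            "IRS": self.IRS,
            "IRS_reported_variant": self.IRS_reported_variant,
            "excluded_cells": self.excluded_cells,
        }


def range_ratio(IR: float, NR: float) -> tuple[float, float]:
    """Both directions of the range ratio (introduced/native, native/introduced)."""
    if IR <= 0 or NR <= 0:
        raise ZeroDivisionError("range ratio needs strictly positive IR and NR")
    return IR / NR, NR / IR


def range_similarity(RS: float, IR: float, NR: float) -> tuple[float, float]:
    """IRS = 2 RS / (IR + NR) and its halved variant RS / (IR + NR)."""
    if IR + NR <= 0:
        raise ZeroDivisionError("range similarity needs IR + NR > 0")
    if RS > min(IR, NR) + 1e-9 * max(IR, NR, 1.0):
        raise ValueError(f"impossible overlap: RS={RS} exceeds min(IR, NR)={min(IR, NR)}")
    irs = 2.0 * RS / (IR + NR)
    return irs, irs / 2.0


def decompose(introduced: BinaryRangeMap, native: BinaryRangeMap) -> RangeShiftResult:
    """Cell-wise expansion / stabilization / unfilling decomposition.

    Cells nodata in either source map are excluded from all three components
    (and counted), preserving the swap symmetry expansion <-> unfilling.
    """
    if introduced.presence.shape != native.presence.shape or not introduced.area_map.same_geometry(
        native.area_map
    ):
        raise ValueError(
            "misaligned range maps: "
            f"{introduced.area_map.geometry()} vs {native.area_map.geometry()}"
        )
    excluded = introduced.nodata_mask | native.nodata_mask
    intro = introduced.presence & ~excluded
    nat = native.presence & ~excluded
    areas = introduced.area_map.values
    return RangeShiftResult(
        introduced_label=introduced.label,
        native_label=native.label,
        area_expansion=float(areas[intro & ~nat].sum()),
        area_stabilization=float(areas[intro & nat].sum()),
        area_unfilling=float(areas[nat & ~intro].sum()),
        excluded_cells=int(excluded.sum()),
    )


def occurrence_summary(
    occurrences: OccurrenceSet, stack: PredictorStack | None = None
) -> pd.DataFrame:
    """Per-population latitudinal extent and (optionally) predictor ranges.

    Returns one row per population with latitude min/max/span; when a stack is
    given, adds per-predictor min/max/IQR at the occurrence cells and, for each
    predictor, Welch two-sample t-tests between every pair of populations.
    """
    rows = []
    values: dict[str, pd.DataFrame] = {}
    for pop in occurrences.populations:
        sub = occurrences.subset(pop)
        lat = sub.records["lat"].to_numpy(float)
        row: dict = {
            "population": pop,
            "n_records": len(sub),
            "lat_min": float(lat.min()),
            "lat_max": float(lat.max()),
            "lat_span": float(lat.max() - lat.min()),
        }
        if stack is not None:
            X, _ = extract_values(sub, stack)
            values[pop] = X
            for name in stack.names:
                v = X[name].to_numpy(float)
                q1, q3 = np.percentile(v, [25, 75])
                row[f"{name}_min"] = float(v.min())
                row[f"{name}_max"] = float(v.max())
                row[f"{name}_iqr"] = float(q3 - q1)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("population")

    if stack is not None and len(values) >= 2:
        pops = sorted(values)
        for i, a in enumerate(pops):
            for b in pops[i + 1 :]:
                for name in stack.names:
                    t, p = stats.ttest_ind(
                        values[a][name], values[b][name], equal_var=False
                    )
                    table.loc[a, f"{name}_t_vs_{b}"] = float(t)
                    table.loc[a, f"{name}_p_vs_{b}"] = float(p)
    return table
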