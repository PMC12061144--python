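"""Spatial rarefaction of occurrence records.

Repeated nearby records (roadside transects, city herbaria, popular parks)
inflate apparent sampling intensity and bias presence models. Thinning keeps a
subset of records such that no two retained records of the same population lie
within a minimum great-circle distance of each other, while discarding as few
records as possible: the classic greedy strategy deletes, at every step, the
record with the most within-radius neighbours (ties broken at random from the
seed). A final re-add pass restores any removed record whose blockers were
themselves later removed, which makes the retained set *maximal*: no removed
record can be re-added without violating the distance constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import EARTH_RADIUS_KM, OccurrenceSet


@dataclass
class ThinningConfig:
    radius_km: float = 5.0
    seed: int = 0
    per_population: bool = True

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (np.asarray(lon1, float),
                                              np.asarray(lat1, float),
                                              np.asarray(lon2, float),
                                              np.asarray(lat2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def _pairwise_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def _thin_group(lon: np.ndarray, lat: np.ndarray, radius_km: float,
                rng: np.random.Generator) -> np.ndarray:
    """Boolean keep-mask for one population."""
    n = len(lon)
    if n <= 1:
        return np.ones(n, dtype=bool)
    dist = _pairwise_km(lon, lat)
    adj = dist < radius_km
    np.fill_diagonal(adj, False)
    keep = np.ones(n, dtype=bool)
    while True:
        counts = adj[np.ix_(keep, keep)].sum(axis=1)
        if counts.size == 0 or counts.max() == 0:
            break
        kept_idx = np.flatnonzero(keep)
        worst = np.flatnonzero(counts == counts.max())
        keep[kept_idx[rng.choice(worst)]] = False
    # re-add pass to a fixpoint: removed records whose neighbours are all gone
    changed = True
    while changed:
        changed = False
        for i in rng.permutation(np.flatnonzero(~keep)):
            if not adj[i, keep].any():
                keep[i] = True
                changed = True
    return keep


def thin(occurrences: OccurrenceSet, config: ThinningConfig) -> tuple[OccurrenceSet, pd.DataFrame]:
    """Thin records so retained same-population pairs are >= radius_km apart.

    Returns the thinned set and a removal report (one row per removed record).
    """
    rng = np.random.default_rng(config.seed)
    df = occurrences.records
    if config.per_population:
        groups = [df[df["population"] == p] for p in occurrences.populations]
    else:
        groups = [df]
    kept_frames, removed_rows = [], []
    for g in groups:
        lon = g["lon"].to_numpy(float)
        lat = g["lat"].to_numpy(float)
        keep = _thin_group(lon, lat, config.radius_km, rng)
        kept_frames.append(g[keep])
        for _, rec in g[~keep].iterrows():
            removed_rows.append(
                {
                    "population": rec["population"],
                    "lon": rec["lon"],
                    "lat": rec["lat"],
                    "reason": f"within {config.radius_km} km of a retained record",
                }
            )
    thinned = OccurrenceSet(
        pd.concat(kept_frames).reset_index(drop=True), provenance=occurrences.provenance
    )
    report = pd.DataFrame(removed_rows, columns=["population", "lon", "lat", "reason"])
    return thinned, report
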