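"""Scenario comparison: difference maps, hotspots, shape-vs-size contrasts.

The simulation experiment crosses three binary factors — dispersal (free vs.
bounded), range structure (coherent vs. patchy) and range sizes (empirical
vs. standardized) — giving up to eight coarse-scale richness maps.  This
module subtracts and averages those maps to isolate the effect of range
linearity (bounded - free) and range patchiness (patchy - coherent), finds
empirical richness hotspots as upper-quantile coarse cells, and compares
scenario means within hotspots using paired per-cell means with a
nonparametric bootstrap over cells for uncertainty (in a balanced
within-cell design these paired means coincide with the marginal means of a
mixed model with a cell random effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .grid import Cell, RichnessMap


class ScenarioKey(NamedTuple):
    dispersal: str  # "free" | "bounded"
    ranges: str  # "coherent" | "patchy"
    sizes: str = "empirical"  # "empirical" | "standardized"


@dataclass
class ScenarioSet:
    """Coarse total-richness maps keyed by scenario flags."""

    maps: dict[ScenarioKey, RichnessMap]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError("scenario maps must share dimensions")
        masks = [np.isnan(m.values) for m in self.maps.values()]
        for m in masks[1:]:
            if not np.array_equal(masks[0], m):
                raise ValueError("scenario maps must share the missing-value mask")

    def __getitem__(self, key: ScenarioKey) -> RichnessMap:
        return self.maps[key]

    def require(self, *keys: ScenarioKey) -> None:
        missing = [k for k in keys if k not in self.maps]
        if missing:
            raise ValueError(f"missing scenarios: {missing}")


@dataclass
class HotspotConfig:
    quantiles: tuple[float, ...] = (0.975, 0.99)
    bootstrap_reps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for q in self.quantiles:
            if not 0 < q < 1:
                raise ValueError("quantiles must lie strictly in (0, 1)")


def difference_map(a: RichnessMap, b: RichnessMap) -> RichnessMap:
    """Per-cell a - b; missing cells propagate missing."""
    if a.shape != b.shape or a.resolution != b.resolution:
        raise ValueError("maps must share shape and resolution")
    diff = a.values - b.values
    out = RichnessMap.__new__(RichnessMap)  # allow negative values
    out.resolution = a.resolution
    out.values = diff
    return out


def shape_effect_maps(s: ScenarioSet) -> tuple[RichnessMap, RichnessMap]:
    """Average two-way contrasts for linearity and patchiness.

    linearity  = mean over range structures of (bounded - free)
    patchiness = mean over dispersal models of (patchy - coherent)
    using the four empirical-size scenarios.
    """
    keys = [ScenarioKey(d, r) for d in ("free", "bounded") for r in ("coherent", "patchy")]
    s.require(*keys)
    m = {k: s[k].values for k in keys}
    linearity = 0.5 * (
        (m[ScenarioKey("bounded", "coherent")] - m[ScenarioKey("free", "coherent")])
        + (m[ScenarioKey("bounded", "patchy")] - m[ScenarioKey("free", "patchy")])
    )
    patchiness = 0.5 * (
        (m[ScenarioKey("free", "patchy")] - m[ScenarioKey("free", "coherent")])
        + (m[ScenarioKey("bounded", "patchy")] - m[ScenarioKey("bounded", "coherent")])
    )
    lin = RichnessMap.__new__(RichnessMap)
    lin.resolution = "coarse"
    lin.values = linearity
    pat = RichnessMap.__new__(RichnessMap)
    pat.resolution = "coarse"
    pat.values = patchiness
    return lin, pat


def hotspot_cells(empirical: RichnessMap, q: float) -> set[Cell]:
    """Coarse cells at or above the q-quantile of land-cell richness.

    The threshold is the lower order statistic at rank floor(q * (n - 1)),
    the natural choice for integer-valued richness: with n distinct values
    and q = 0.99 exactly the top 1% of cells (rounded up) qualify, and ties
    at the threshold are kept.
    """
    if not 0 <= q < 1:
        raise ValueError("q must lie in [0, 1)")
    vals = empirical.values
    land_vals = vals[~np.isnan(vals)]
    if land_vals.size == 0:
        raise ValueError("map has no land cells")
    thresh = np.quantile(land_vals, q, method="lower")
    rows, cols = np.nonzero(~np.isnan(vals) & (vals >= thresh))
    return {(int(r), int(c)) for r, c in zip(rows, cols)}


@dataclass
class HotspotMeans:
    """Per-scenario hotspot mean richness with bootstrap 95% CIs."""

    means: dict[ScenarioKey, float]
    ci_low: dict[ScenarioKey, float]
    ci_high: dict[ScenarioKey, float]
    n_cells: int = 0


def hotspot_model_means(
    s: ScenarioSet,
    hotspots: set[Cell],
    cfg: HotspotConfig,
    rng: np.random.Generator | None = None,
) -> HotspotMeans:
    """Mean scenario richness over hotspot cells, with paired bootstrap CIs.

    The same cell resample is applied to every scenario (paired design), so
    scenario *differences* are estimated within, not across, cells.
    """
    if not hotspots:
        raise ValueError("hotspot set is empty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cells = sorted(hotspots)
    idx = (np.array([c[0] for c in cells]), np.array([c[1] for c in cells]))
    per_cell = {k: m.values[idx] for k, m in s.maps.items()}
    for k, v in per_cell.items():
        if np.any(np.isnan(v)):
            raise ValueError(f"hotspot cell missing in scenario {k}")
    n = len(cells)
    means = {k: float(v.mean()) for k, v in per_cell.items()}
    resamples = rng.integers(n, size=(cfg.bootstrap_reps, n))
    ci_low, ci_high = {}, {}
    for k, v in per_cell.items():
        boot = v[resamples].mean(axis=1)
        ci_low[k] = float(np.quantile(boot, 0.025))
        ci_high[k] = float(np.quantile(boot, 0.975))
    return HotspotMeans(means, ci_low, ci_high, n)


def scatter_table(
    empirical: RichnessMap, s: ScenarioSet, n_bins: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell empirical vs. simulated richness plus binned scenario means.

    Returns (records, bin_means): one record per land coarse cell, and
    per-bin scenario means over ``n_bins`` equal-width bins of empirical
    richness.
    """
    vals = empirical.values
    land = ~np.isnan(vals)
    for m in s.maps.values():
        if m.shape != vals.shape:
            raise ValueError("scenario maps must match the empirical map")
    rows, cols = np.nonzero(land)
    records = pd.DataFrame({"row": rows, "col": cols, "empirical": vals[land]})
    for k, m in s.maps.items():
        records["_".join(k)] = m.values[land]
    lo, hi = records["empirical"].min(), records["empirical"].max()
    edges = np.linspace(lo, hi if hi > lo else lo + 1, n_bins + 1)
    records["bin"] = np.clip(
        np.digitize(records["empirical"], edges[1:-1]), 0, n_bins - 1
    )
    scen_cols = ["_".join(k) for k in s.maps]
    bin_means = records.groupby("bin")[["empirical", *scen_cols]].mean()
    bin_means["bin_center"] = [
        (edges[i] + edges[i + 1]) / 2 for i in bin_means.index
    ]
    return records, bin_means
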