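"""Per-species geographic domains: free vs. bounded dispersal.

Under *free* dispersal a simulated range may occupy any mainland cell — the
only hard boundary is the coastline.  Under *bounded* dispersal the domain is
restricted to cells that (i) contain terrain within the species' elevational
range limits and (ii) fall inside the species' occupied climate volume, which
is characterized by two minimum convex polygons: one over (mean annual
temperature, annual precipitation) and one over (temperature seasonality,
precipitation seasonality), built from the climate values of the occupied
cells.  A cell is climatically suitable only if it is inside-or-on BOTH hulls.

Climate variables are z-scored per layer (over land cells) before hull
construction so that the boundary tolerance eps is meaningful across layers
with very different units.  Empirical range cells are always force-included in
the bounded domain (the spreading dye must be able to start there); forced
inclusions are recorded on the mask.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPoint

from .grid import Cell, GridSpec

logger = logging.getLogger(__name__)

#: boundary tolerance for hull membership, in z-scored climate units
HULL_EPS = 1e-9


@dataclass
class ElevationBands:
    """Per-fine-cell span of terrain elevations (m), from a sub-cell DEM."""

    elev_min: np.ndarray
    elev_max: np.ndarray

    def __post_init__(self) -> None:
        self.elev_min = np.asarray(self.elev_min, dtype=float)
        self.elev_max = np.asarray(self.elev_max, dtype=float)
        if self.elev_min.shape != self.elev_max.shape:
            raise ValueError("elev_min and elev_max shapes differ")
        if np.any(self.elev_min > self.elev_max):
            raise ValueError("elev_min must be <= elev_max everywhere")

    def overlaps(self, limits: tuple[float, float]) -> np.ndarray:
        """Boolean raster: does the cell band overlap [e_lo, e_hi] (closed)?"""
        e_lo, e_hi = limits
        if e_lo > e_hi:
            raise ValueError("elevational limits must satisfy e_lo <= e_hi")
        return (self.elev_max >= e_lo) & (self.elev_min <= e_hi)


@dataclass
class ClimateLayers:
    """Four bioclim-style climate rasters on the fine grid.

    bio1 mean annual temperature (degC), bio12 annual precipitation (mm),
    bio4 temperature seasonality, bio15 precipitation seasonality.
    """

    bio1: np.ndarray
    bio12: np.ndarray
    bio4: np.ndarray
    bio15: np.ndarray

    def __post_init__(self) -> None:
        shapes = {np.asarray(v).shape for v in (self.bio1, self.bio12, self.bio4, self.bio15)}
        if len(shapes) != 1:
            raise ValueError("climate layers must share one shape")
        for name in ("bio1", "bio12", "bio4", "bio15"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def shape(self) -> tuple[int, int]:
        return self.bio1.shape

    def layer_stack(self) -> np.ndarray:
        return np.stack([self.bio1, self.bio12, self.bio4, self.bio15])


@dataclass
class SpeciesRecord:
    """A species' empirical fine-grid range, elevational limits and realms."""

    species_id: str
    empirical_range: frozenset
    elev_limits: tuple[float, float]
    realms: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.empirical_range = frozenset(self.empirical_range)
        if not self.empirical_range:
            raise ValueError(f"{self.species_id}: empirical range is empty")
        e_lo, e_hi = self.elev_limits
        if e_lo > e_hi:
            raise ValueError(f"{self.species_id}: e_lo > e_hi")
        self.realms = frozenset(self.realms)

    @property
    def range_size(self) -> int:
        return len(self.empirical_range)


@dataclass
class ClimateEnvelope:
    """Occupied climate volume: two convex hulls in z-scored climate space.

    Degenerate occupied-climate sets (single point, collinear points) yield
    point or segment hulls; the membership test handles them uniformly via a
    distance-within-eps predicate.
    """

    hull_tp: shapely.Geometry  # (bio1, bio12), z-scored
    hull_seas: shapely.Geometry  # (bio4, bio15), z-scored
    means: np.ndarray  # per-layer z-score means (bio1, bio12, bio4, bio15)
    stds: np.ndarray  # per-layer z-score stds

    def standardize(self, stack: np.ndarray) -> np.ndarray:
        """z-score a (4, ...) stack of raw climate values."""
        shp = (4,) + (1,) * (stack.ndim - 1)
        return (stack - self.means.reshape(shp)) / self.stds.reshape(shp)


@dataclass
class DomainMask:
    """A species' per-scenario geographic domain.

    ``traversable``: cells the spreading dye may pass through (all mainland
    land cells — ocean is a hard boundary).  ``suitable``: the subset that may
    belong to the final range.  Under free dispersal suitable == traversable.
    """

    species_id: str
    traversable: frozenset
    suitable: frozenset
    forced_cells: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.traversable = frozenset(self.traversable)
        self.suitable = frozenset(self.suitable)
        self.forced_cells = frozenset(self.forced_cells)
        if not self.suitable <= self.traversable:
            raise ValueError(f"{self.species_id}: suitable must be within traversable")


def downscale_range(
    coarse_range: set[Cell],
    bands: ElevationBands,
    limits: tuple[float, float],
    spec: GridSpec,
) -> set[Cell]:
    """Project a coarse-grid range onto the fine grid via elevational limits.

    A fine cell is included iff its coarse parent is occupied and the cell's
    elevation band overlaps the species' [e_lo, e_hi] limits (closed-interval
    overlap).  An empty result is legal but signalled with a warning — the
    species' range was lost in downscaling.
    """
    if not coarse_range:
        raise ValueError("coarse_range must be nonempty")
    if bands.elev_min.shape != spec.shape:
        raise ValueError("elevation bands do not match the fine grid")
    ok = bands.overlaps(limits)
    f = spec.agg_factor
    cr, cc = spec.coarse_shape
    out: set[Cell] = set()
    for R, C in coarse_range:
        if not (0 <= R < cr and 0 <= C < cc):
            raise ValueError(f"coarse cell {(R, C)} outside coarse grid {(cr, cc)}")
        for r in range(R * f, (R + 1) * f):
            for c in range(C * f, (C + 1) * f):
                if ok[r, c]:
                    out.add((r, c))
    if not out:
        warnings.warn(
            f"range lost in downscaling: no fine cell within limits {limits}",
            stacklevel=2,
        )
    return out


def build_envelope(
    range_cells: set[Cell],
    climate: ClimateLayers,
    land: set[Cell] | None = None,
) -> ClimateEnvelope:
    """Convex hulls over the climate values of the occupied cells.

    z-scoring statistics are taken over *land* (defaults to the occupied cells
    themselves); constant layers get std 1 so the transform stays finite.
    """
    if not range_cells:
        raise ValueError("range_cells must be nonempty")
    stack = climate.layer_stack()
    ref = sorted(land) if land is not None else sorted(range_cells)
    ridx = np.array([c[0] for c in ref]), np.array([c[1] for c in ref])
    ref_vals = stack[:, ridx[0], ridx[1]]
    if not np.all(np.isfinite(ref_vals)):
        raise ValueError("non-finite climate values on land cells")
    means = ref_vals.mean(axis=1)
    stds = ref_vals.std(axis=1)
    stds[stds == 0] = 1.0

    cells = sorted(range_cells)
    idx = np.array([c[0] for c in cells]), np.array([c[1] for c in cells])
    vals = stack[:, idx[0], idx[1]]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite climate values on range cells")
    z = (vals - means[:, None]) / stds[:, None]
    hull_tp = MultiPoint(list(zip(z[0], z[1]))).convex_hull
    hull_seas = MultiPoint(list(zip(z[2], z[3]))).convex_hull
    return ClimateEnvelope(hull_tp, hull_seas, means, stds)


def climate_suitable(cell: Cell, env: ClimateEnvelope, climate: ClimateLayers) -> bool:
    """Is the cell's climate inside-or-on both hulls (tolerance HULL_EPS)?"""
    r, c = cell
    vals = np.array([climate.bio1[r, c], climate.bio12[r, c],
                     climate.bio4[r, c], climate.bio15[r, c]])
    z = (vals - env.means) / env.stds
    pt_tp = shapely.points(z[0], z[1])
    pt_seas = shapely.points(z[2], z[3])
    return bool(
        shapely.dwithin(env.hull_tp, pt_tp, HULL_EPS)
        and shapely.dwithin(env.hull_seas, pt_seas, HULL_EPS)
    )


def climate_suitability_mask(
    cells: list[Cell], env: ClimateEnvelope, climate: ClimateLayers
) -> np.ndarray:
    """Vectorized climate_suitable over many cells (same semantics)."""
    idx = np.array([c[0] for c in cells]), np.array([c[1] for c in cells])
    z = env.standardize(climate.layer_stack()[:, idx[0], idx[1]])
    pts_tp = shapely.points(z[0], z[1])
    pts_seas = shapely.points(z[2], z[3])
    return shapely.dwithin(env.hull_tp, pts_tp, HULL_EPS) & shapely.dwithin(
        env.hull_seas, pts_seas, HULL_EPS
    )


def build_domain(
    sp: SpeciesRecord,
    bands: ElevationBands,
    climate: ClimateLayers,
    model: str,
    land: set[Cell],
    envelope: ClimateEnvelope | None = None,
) -> DomainMask:
    """The species' geographic domain under the given dispersal model.

    free    -> every mainland cell is suitable.
    bounded -> suitable = land cells whose elevation band overlaps the
               species' limits AND whose climate falls inside the occupied
               climate volume; the empirical range is force-included so the
               dye can always start inside the domain.
    """
    land = frozenset(land)
    if not sp.empirical_range <= land:
        raise ValueError(f"{sp.species_id}: empirical range not on land")
    if model == "free":
        return DomainMask(sp.species_id, land, land)
    if model != "bounded":
        raise ValueError(f"unknown dispersal model {model!r}")

    if envelope is None:
        envelope = build_envelope(set(sp.empirical_range), climate, land)
    elev_ok = bands.overlaps(sp.elev_limits)
    candidates = sorted(c for c in land if elev_ok[c])
    suitable: set[Cell] = set()
    if candidates:
        clim_ok = climate_suitability_mask(candidates, envelope, climate)
        suitable = {c for c, ok in zip(candidates, clim_ok) if ok}
    forced = sp.empirical_range - suitable
    if forced:
        logger.info(
            "%s: force-including %d empirical cells failing the bounded test",
            sp.species_id, len(forced),
        )
    suitable |= sp.empirical_range
    return DomainMask(sp.species_id, land, frozenset(suitable), frozenset(forced))
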