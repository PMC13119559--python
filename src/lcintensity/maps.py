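"""Categorical raster maps, stratum layers, reclassification and
cross-tabulation into area transition matrices.

Maps are plain integer grids with an explicit nodata value and a cell-area
specification. Cross-tabulation is the bridge from pixels to the transition
matrices everything downstream consumes: it counts, per ordered category
pair (i, j), the area of cells classified *i* at the first date and *j* at
the second, optionally restricted to one stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .matrices import ALL_STRATA, TransitionMatrix
from .scheme import CategoryScheme

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


@dataclass(frozen=True)
class GridSpec:
    """Minimal georeferencing: north-west corner and square cell size.

    ``crs`` is an informative tag only; the package never reprojects —
    inputs must share one grid, which :func:`crosstab` enforces.
    """

    west: float = 0.0
    north: float = 0.0
    cell_size: float = 1.0  # degrees for geographic CRS, km otherwise
    crs: str = "local"

    def cell_centers_y(self, nrows: int) -> np.ndarray:
        return self.north - (np.arange(nrows) + 0.5) * self.cell_size

    def cell_centers_x(self, ncols: int) -> np.ndarray:
        return self.west + (np.arange(ncols) + 0.5) * self.cell_size


def geographic_cell_areas(grid: GridSpec, shape: tuple[int, int]) -> np.ndarray:
    """Per-cell spherical footprint (km²) for a lat/lon grid, by latitude row.

    Area of a cell spanning ``cell_size`` degrees in both axes between
    latitudes φ1 and φ2 is R²·Δλ·(sin φ2 − sin φ1).
    """
    nrows, ncols = shape
    d = np.deg2rad(grid.cell_size)
    lat_top = np.deg2rad(grid.north - np.arange(nrows) * grid.cell_size)
    lat_bot = lat_top - d
    row_area = EARTH_RADIUS_KM**2 * d * (np.sin(lat_top) - np.sin(lat_bot))
    return np.repeat(row_area[:, None], ncols, axis=1)


@dataclass
class CategoricalMap:
    """A single-date categorical map.

    Parameters
    ----------
    grid
        2-D integer array of category ids.
    year
        Acquisition year of the classification.
    nodata
        Id marking unclassified/masked cells.
    cell_area
        Constant km² per cell, or a per-cell area array of the same shape
        (use :func:`geographic_cell_areas` for lat/lon grids).
    gridspec
        Georeferencing descriptor; crosstab requires it to match between dates.
    """

    grid: np.ndarray
    year: int
    nodata: int = -1
    cell_area: float | np.ndarray = 1.0
    gridspec: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if isinstance(self.cell_area, np.ndarray):
            if self.cell_area.shape != self.grid.shape:
                raise ValueError("per-cell area grid must match map shape")
            if np.any(self.cell_area <= 0):
                raise ValueError("cell areas must be strictly positive")
        elif self.cell_area <= 0:
            raise ValueError("cell area must be strictly positive")

    @property
    def valid(self) -> np.ndarray:
        return self.grid != self.nodata

    def areas(self) -> np.ndarray:
        """Per-cell areas as a full array."""
        if isinstance(self.cell_area, np.ndarray):
            return self.cell_area
        return np.full(self.grid.shape, float(self.cell_area))


@dataclass
class StratumSet:
    """Mutually exclusive spatial strata aligned to the analysis maps.

    ``membership`` holds, per cell, an index into ``labels`` (or -1 for
    cells outside every stratum).
    """

    labels: list[str]
    membership: np.ndarray

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("stratum labels must be unique")
        if self.membership.max(initial=-1) >= len(self.labels):
            raise ValueError("membership index exceeds label count")

    def mask(self, label: str) -> np.ndarray:
        return self.membership == self.labels.index(label)

    @classmethod
    def from_polygons(
        cls, labels: list[str], polygons: list, gridspec: GridSpec, shape: tuple[int, int]
    ) -> "StratumSet":
        """Assign cells to strata by cell-center containment (shapely polygons)."""
        from shapely import contains_xy  # deferred: shapely optional at runtime

        ys = gridspec.cell_centers_y(shape[0])
        xs = gridspec.cell_centers_x(shape[1])
        xx, yy = np.meshgrid(xs, ys)
        membership = np.full(shape, -1, dtype=int)
        for k, poly in enumerate(polygons):
            inside = contains_xy(poly, xx.ravel(), yy.ravel()).reshape(shape)
            membership[inside & (membership == -1)] = k
        return cls(list(labels), membership)


def reclassify_map(cmap: CategoricalMap, scheme: CategoryScheme) -> CategoricalMap:
    """Map fine source codes to scheme category ids, preserving nodata.

    Raises with the offending code and its cell count if any non-nodata
    code lacks a mapping.
    """
    grid = cmap.grid
    valid = cmap.valid
    codes = np.unique(grid[valid])
    missing = [int(c) for c in codes if int(c) not in scheme.reclass_map]
    if missing:
        counts = {c: int(np.sum(grid[valid] == c)) for c in missing}
        raise ValueError(
            f"unmapped source code(s) {missing} "
            f"({sum(counts.values())} cells: {counts})"
        )
    out = np.full_like(grid, cmap.nodata)
    for code in codes:
        out[valid & (grid == code)] = scheme.reclass_map[int(code)]
    return replace(cmap, grid=out)


def crosstab(
    map_t0: CategoricalMap,
    map_t1: CategoricalMap,
    scheme: CategoryScheme,
    stratum_mask: np.ndarray | None = None,
    stratum: str = ALL_STRATA,
) -> TransitionMatrix:
    """Cross-tabulate two dates of one landscape into a transition matrix.

    Cells nodata at either date are excluded entirely, so row sums remain
    the start-date category areas of the analyzable domain and column sums
    the end-date areas. Areas are taken from ``map_t0``.
    """
    if map_t0.grid.shape != map_t1.grid.shape:
        raise ValueError(
            f"grid shape mismatch: {map_t0.grid.shape} vs {map_t1.grid.shape}"
        )
    if map_t0.gridspec != map_t1.gridspec:
        raise ValueError("georeferencing mismatch between dates")
    if map_t0.year >= map_t1.year:
        raise ValueError(f"dates out of order: {map_t0.year} !< {map_t1.year}")

    valid = map_t0.valid & map_t1.valid
    if stratum_mask is not None:
        valid &= stratum_mask
    if not valid.any():
        raise ValueError(f"no analyzable cells in stratum {stratum!r}")

    ids = np.asarray(scheme.ids)
    index = np.full(ids.max() + 1, -1, dtype=int)
    index[ids] = np.arange(len(ids))
    a = map_t0.grid[valid]
    b = map_t1.grid[valid]
    for name, arr in (("first", a), ("second", b)):
        bad = np.setdiff1d(np.unique(arr), ids)
        if bad.size:
            raise ValueError(f"{name} map holds ids outside the scheme: {bad.tolist()}")

    j = len(ids)
    flat = index[a] * j + index[b]
    weights = map_t0.areas()[valid]
    counts = np.bincount(flat, weights=weights, minlength=j * j).reshape(j, j)
    return TransitionMatrix(counts, scheme.abbrevs, map_t0.year, map_t1.year, stratum)


def crosstab_by_stratum(
    map_t0: CategoricalMap,
    map_t1: CategoricalMap,
    scheme: CategoryScheme,
    strata: StratumSet,
) -> dict[str, TransitionMatrix]:
    """One transition matrix per stratum (strata with no valid cells omitted)."""
    out: dict[str, TransitionMatrix] = {}
    for label in strata.labels:
        try:
            out[label] = crosstab(map_t0, map_t1, scheme, strata.mask(label), label)
        except ValueError as exc:
            if "no analyzable cells" not in str(exc):
                raise
    return out
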