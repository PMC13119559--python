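"""Text raster I/O for categorical maps: ESRI ASCII grid plus JSON sidecar.

The ASCII grid (.asc) format is plain text, readable by every desktop GIS,
and carries the grid, cell size, origin and nodata in-band. The package
keeps year/CRS/cell-area metadata in a ``.json`` sidecar next to the grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .maps import CategoricalMap, GridSpec


def write_ascii_grid(cmap: CategoricalMap, path: str | Path) -> None:
    path = Path(path)
    nrows, ncols = cmap.grid.shape
    gs = cmap.gridspec
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {gs.west}\n"
        f"yllcorner {gs.north - nrows * gs.cell_size}\n"
        f"cellsize {gs.cell_size}\n"
        f"NODATA_value {cmap.nodata}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, cmap.grid, fmt="%d")
    meta = {"year": cmap.year, "crs": gs.crs}
    if not isinstance(cmap.cell_area, np.ndarray):
        meta["cell_area_km2"] = float(cmap.cell_area)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_ascii_grid(path: str | Path, year: int | None = None) -> CategoricalMap:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        grid = np.loadtxt(fh, dtype=int, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key!r}")
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: grid shape {grid.shape} disagrees with header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if year is None:
        year = meta.get("year")
    if year is None:
        raise ValueError(f"{path}: year not in sidecar nor argument")
    gs = GridSpec(
        west=header.get("xllcorner", 0.0),
        north=header.get("yllcorner", 0.0) + header["nrows"] * header["cellsize"],
        cell_size=header["cellsize"],
        crs=meta.get("crs", "local"),
    )
    return CategoricalMap(
        grid,
        year=int(year),
        nodata=int(header.get("nodata_value", -1)),
        cell_area=float(meta.get("cell_area_km2", 1.0)),
        gridspec=gs,
    )
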