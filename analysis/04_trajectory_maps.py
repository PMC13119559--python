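"""Map first-to-last trajectories and budget the six conversion pathways.

Labels every cell of the simulated landscape by the pathway its
(1985, 2022) category pair belongs to — deforestation, forest degradation,
agricultural expansion, wetland expansion, shrub degradation,
desertification — and reconciles the mapped areas with the first-to-last
transition matrices, reporting each pathway's continental area and the
regional shares behind it.

Run:  python analysis/04_trajectory_maps.py [seed]
"""

import sys
from pathlib import Path

from lcintensity import (
    crosstab_by_stratum,
    default_config,
    default_pathways,
    label_trajectories,
    pathway_budget,
    simulate_series,
)
from lcintensity.raster_io import write_ascii_grid
from lcintensity.maps import CategoricalMap

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
config = default_config(shape=(100, 100), seed=seed)
result = simulate_series(config)

first, last = result.maps[0], result.maps[-1]
pathways = default_pathways()
traj = label_trajectories(first, last, config.scheme, pathways)
fl = crosstab_by_stratum(first, last, config.scheme, result.strata)
budget = pathway_budget(fl, pathways)

areas = traj.areas_km2()
total = sum(areas.values())
print(f"1985-2022 trajectory budget over {total:.0f} km2:")
print(f"  persistence: {areas.get('persistence', 0):.0f} km2")
for p in pathways:
    a = areas.get(p.name, 0.0)
    if a == 0:
        continue
    rows = budget[budget["pathway"] == p.name].sort_values("share_pct", ascending=False)
    lead = rows.iloc[0]
    print(f"  {p.name}: {a:.0f} km2 (leading stratum {lead['stratum']}, {lead['share_pct']:.0f}%)")
print(f"  other change: {areas.get('other-change', 0):.0f} km2")

out = Path("results/trajectories")
out.mkdir(parents=True, exist_ok=True)
budget.to_csv(out / "pathway_budget.csv", index=False)
write_ascii_grid(
    CategoricalMap(traj.grid, year=last.year, nodata=-1, cell_area=first.cell_area),
    out / "trajectories.asc",
)
print(f"budget and trajectory raster written to {out}")
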