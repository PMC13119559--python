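"""Generate the synthetic stratified landscape used by the downstream steps.

Realizes the default study design — ten Level-1 land-cover classes, five
regional strata (EAF, MED, SAF, SAH, WAF) with annual change tempos from
0.16 to 1.45 %/yr, nine time points 1985-2022 (last interval 2 years) —
and writes the per-(stratum, interval) transition matrices plus the first
and last date maps under results/data/.

Run:  python analysis/01_simulate_landscape.py [seed]
"""

import sys
from pathlib import Path

from lcintensity import default_config, simulate_series, validate_series, write_matrix_table
from lcintensity.raster_io import write_ascii_grid

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
out = Path("results/data")
out.mkdir(parents=True, exist_ok=True)

config = default_config(shape=(100, 100), seed=seed)
result = simulate_series(config)

issues = validate_series(result.series)
print(f"simulated {len(config.strata)} strata x {result.series.n_intervals} intervals, seed={seed}")
print(f"validation issues: {len(issues)} (closed landscape: totals exactly constant)")

n = 0
for stratum in result.series.strata:
    for mat in result.series.matrices[stratum]:
        write_matrix_table(mat, out / f"matrix_{stratum}_{mat.from_year}_{mat.to_year}.csv")
        n += 1
write_ascii_grid(result.maps[0], out / "lc_1985.asc")
write_ascii_grid(result.maps[-1], out / "lc_2022.asc")
write_ascii_grid(
    type(result.maps[0])(result.strata.membership, year=result.maps[0].year),
    out / "strata.asc",
)
print(f"wrote {n} matrix tables and 3 rasters to {out}")
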