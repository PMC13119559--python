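# Methods

## Model and assumptions

The package implements gain-perspective Intensity Analysis over square
area cross-tabulation matrices. All statistics are pure functions of the
matrices: the spatial arrangement of cells matters only while
cross-tabulating, never afterwards. The framework assumes categories are
discrete and mutually exclusive, strata are mutually exclusive and fixed
over time, and a cell that is nodata at either end of an interval is
excluded from that interval entirely — so row sums remain interpretable
as start-date sizes and column sums as end-date sizes of the analyzable
domain.

Three levels are computed per interval `t`:

- interval: `S_t = gross_t / (ΔY_t · total_t) × 100`, compared to the
  uniform intensity `U`;
- category: `G_tj` (gain over end size) and `L_ti` (loss over start
  size), compared to `S_t`;
- transition: `R_tmn` (gain of `n` from `m` over `m`'s start size),
  compared to `W_tn` (gain of `n` over all non-`n` start area).

Only the gain perspective is implemented; the loss-perspective
transition statistics of the broader framework are out of scope.

The algebraic backbone, which the test suite verifies to 1e-10 relative
tolerance on random matrices, is that each uniform baseline is the
size-weighted mean of the statistics it is compared against: `S_t` of the
defined `L_ti` (start-size weights) and of the defined `G_tj` (end-size
weights), and `W_tn` of the defined `R_tmn` (availability weights). Hence
for any gainer with positive gains at least one donor is
targeted-or-equal and one avoided-or-equal.

## Statuses and degenerate inputs

Strict inequalities define fast/slow, active/dormant and
targeted/avoided. Exact ties get their own `equal` status rather than
being forced into either side; the tie test uses a relative band of
1e-12 so that statuses are invariant under rescaling all areas (a ratio
computed at a different scale may differ in the last bit). Zero
denominators — a category absent at the relevant date — yield `NaN`
intensity and an `undefined` status; undefined entries are excluded from
the weighted-mean identities and from classification, rather than being
treated as zeros.

`U` is computed with per-interval totals in the denominator,
`U = Σ_t gross_t / Σ_t (ΔY_t · total_t) × 100`, which reduces to the
textbook constant-area form when totals are constant and stays meaningful
under mild nodata drift. When per-interval totals are equal, `U` is the
duration-weighted mean of `S_t` (tested).

Gross change, gains and losses sum off-diagonal entries directly instead
of subtracting the trace from the total, so no-change matrices give
exactly zero. `sum_strata` adds matrices in label-sorted order, making
the aggregate bit-identical under any permutation of its inputs.

## Stratified decomposition

Contributions are defined on areas: a stratum's share of the continental
gross change, of a category's gross gain/loss, or of a single transition
flow is `A_k / Σ_k A_k × 100`. When the continental denominator is zero
the whole row set is undefined (`NaN`), not 100%. The dominant stratum is
the strict argmax; exact ties resolve to the first-declared stratum, so
stratum declaration order is the only order-dependent behavior.

## Pathway selection, trajectories, network

Dominant transitions are pairs that were (i) targeted in at least
`ceil(min_targeted_frac × n_intervals)` intervals and (ii) at least
`min_area_km2` in cumulative first-to-last area, ranked by area. Defaults:
`min_targeted_frac = 0.5`, and the area cutoff at the top decile of
positive off-diagonal first-to-last areas — both are thresholds a user
should treat as starting points and override to suit their landscape.
Selection is monotone: raising either threshold never adds a pair.

Trajectory maps compare first and last dates only; intermediate
reversals are invisible by design. Cells map to the pathway containing
their (first, last) pair, to `persistence` on the diagonal, and to
`other-change` for changed pairs outside every pathway, so mapped areas
reconcile exactly with the first-to-last matrix. Pathway definitions ship
as an editable six-pathway default (deforestation, forest degradation,
agricultural expansion, wetland expansion, shrub degradation,
desertification) and can be loaded from YAML; a pair may belong to at
most one pathway.

When no maps are available (matrices-only input), first-to-last matrices
are reconstructed by chaining the row-normalized interval flows
(`T = Π_t P_t` scaled by start sizes) — exact when cell-level dynamics
are Markovian (tested against the direct product), an approximation
otherwise; with maps the direct endpoint cross-tabulation is used.

Network edges connect losing to gaining categories for pairs targeted in
at least one interval; edge area sums the pair's flow over its targeted
intervals only (the `targeted_only=False` flag sums all intervals
instead, since either reading of "cumulative targeted area" is
defensible). Node size is the mean class area over all time points.

## Synthetic landscape generator

The generator realizes a stratified annual Markov model: stratum `s` has
a row-stochastic annual kernel `K_s`, and over an interval of `ΔY` years
every cell transitions independently by `K_s^ΔY`. Using the matrix power
of an annual kernel makes the unequal interval schedule (seven 5-year
steps plus one 2-year step) genuinely exercise the duration
normalization. The analytic expected matrix,
`diag(start areas) · K^ΔY` with the composition propagated from the
first date, is exposed alongside the realization, so convergence tests
compare means over seeds against an exact target.

Defaults encode the emulated study design: ten Level-1 land-cover
classes, five regional strata (EAF, MED, SAF, SAH, WAF) with annual
change tempos of 1.05, 0.54, 1.45, 0.16 and 0.77 %/yr — a spread whose
domain-wide mean sits near 0.75 %/yr — per-stratum initial compositions
ranging from forest/shrub-rich (SAF) to bare-dominated (SAH), nine time
points 1985–2022, 100×100 cells of 1 km² per stratum. One global seed
drives everything; each stratum consumes its own deterministic substream,
so runs are bit-reproducible and adding a stratum leaves others
unchanged.

The neutral kernel (`availability_kernel`) gives every donor the same
per-destination annual probability `rate · s_n / (1 − Σ s²)`, so each
gainer draws from all donors at exactly its uniform transition intensity:
`R = W` in expectation and targeted/avoided statuses are coin flips. The
normalization constant calibrates the landscape-wide tempo to the
nominal rate at the initial composition. Note that renormalizing each
row by its available area instead (`rate · s_n / (1 − s_m)`) is *not*
neutral — it systematically targets large donors — which is why the
neutral null is defined this way. Ground truth for recovery experiments
is injected by multiplying one kernel entry and re-balancing that row's
diagonal (rejected as infeasible if the diagonal would go negative).

What the generator does *not* emulate: spatial autocorrelation (cells
are independent, fine for matrix-based statistics but unrealistic for
map pattern), classification noise and inter-annual "flicker" of real
remote-sensing products, nodata/ocean masking drift, and
non-Markovian land-use memory. Passing tests therefore demonstrate the
statistics, decomposition and recovery machinery — not robustness to
classification error in real archives.

## Raster handling

Maps are plain integer grids with explicit nodata, a cell-area
specification and a minimal georeferencing descriptor; file I/O uses the
ESRI ASCII grid text format with a JSON sidecar for year/CRS/cell-area.
The package never reprojects or resamples — inputs must share one grid,
which cross-tabulation enforces. For geographic (lat/lon) grids, per-cell
areas follow the spherical cell footprint by latitude
(`R²·Δλ·(sin φ₂ − sin φ₁)`); for projected equal-area grids a constant
cell area suffices. Polygon strata are assigned by cell-center
containment. Areas are km² throughout; intensities %/yr; intensities are
carried at full double precision and rounded only at presentation.

## Problem sizes

Tests and the acceptance script use sizes chosen to make every check
statistically decisive at interactive runtimes: oracle and identity
checks on 100–120 random matrices with 2–6 categories; the neutral-
targeting and boost-recovery experiments on three strata of 200×200
cells (the boost experiment flags the injected pair in all eight
intervals with a dominant-stratum share near 84%); expectation
convergence on 110 seeds of a 10×10 grid with a 3-SE bound. The full
five-stratum pipeline runs at 100×100 cells per stratum.

## Known limitations

- Loss-perspective transition statistics are not implemented.
- The matrices-only first-to-last reconstruction assumes Markovian cell
  dynamics; real landscapes with land-use memory will deviate.
- Contributions are area-based only; intensity-based regional shares are
  not provided.
- Validation treats per-stratum area drift across intervals as a warning,
  not an error, since masking in real products rarely conserves totals
  exactly; the drift tolerance is configurable.
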