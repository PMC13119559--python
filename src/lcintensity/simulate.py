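"""Synthetic stratified Markov landscapes.

Generates multi-temporal categorical maps whose statistical structure
matches what the analysis assumes: each stratum evolves by an annual
row-stochastic transition kernel K, compounded to K^ΔY over an interval of
ΔY years (so a trailing 2-year interval genuinely exercises the duration
normalization), with cells evolving independently. "Targeted" ground truth
is injected by multiplying one kernel entry and re-balancing its diagonal.
The analytic expected transition matrix is available alongside the
realization, which makes parameter-recovery tests exact rather than
eyeballed.

Defaults emulate the continental study design: ten Level-1 categories,
five regional strata with annual change tempos spanning roughly 0.2-1.5
%/yr around a ~0.7 %/yr domain mean, and nine time points 1985-2022 whose
last interval is two years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .maps import CategoricalMap, StratumSet, crosstab_by_stratum
from .matrices import MatrixSeries, TransitionMatrix
from .scheme import CategoryScheme, level1_scheme

DEFAULT_YEARS = (1985, 1990, 1995, 2000, 2005, 2010, 2015, 2020, 2022)

#: Per-stratum mean annual change tempo (fraction of the stratum per year).
DEFAULT_RATES = {"EAF": 0.0105, "MED": 0.0054, "SAF": 0.0145, "SAH": 0.0016, "WAF": 0.0077}

#: Initial composition per stratum, in scheme order
#: (CRP, FST, SHR, GRS, TUD, WET, IMP, BAL, WTR, PSI); normalized on use.
DEFAULT_COMPOSITION = {
    "EAF": (0.18, 0.16, 0.22, 0.25, 0.010, 0.040, 0.010, 0.080, 0.045, 0.005),
    "MED": (0.12, 0.03, 0.05, 0.08, 0.005, 0.005, 0.020, 0.670, 0.020, 0.000),
    "SAF": (0.12, 0.30, 0.30, 0.18, 0.005, 0.020, 0.010, 0.030, 0.030, 0.005),
    "SAH": (0.03, 0.005, 0.02, 0.06, 0.005, 0.005, 0.005, 0.860, 0.010, 0.000),
    "WAF": (0.25, 0.22, 0.20, 0.22, 0.005, 0.050, 0.015, 0.020, 0.020, 0.000),
}


def _check_kernel(k: np.ndarray, label: str = "") -> None:
    k = np.asarray(k)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError(f"kernel {label} must be square")
    if np.any(k < 0) or np.any(k > 1):
        raise ValueError(f"kernel {label} has probabilities outside [0, 1]")
    if not np.allclose(k.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError(f"kernel {label} rows do not sum to 1")


def availability_kernel(shares: np.ndarray, annual_rate: float) -> np.ndarray:
    """Annual kernel under which no transition is targeted or avoided.

    The per-destination probability k[m, n] = rate · s_n / c is identical
    for every donor m, so each gainer draws from all donors at exactly the
    uniform transition intensity (R = W in expectation) — the null model of
    the transition-level test. The constant c = 1 − Σ s² calibrates the
    landscape-wide change tempo to ``annual_rate`` per year at the initial
    composition. Categories with zero share receive nothing.
    """
    shares = np.asarray(shares, dtype=float)
    shares = shares / shares.sum()
    j = len(shares)
    c = 1.0 - float(shares @ shares)
    if c <= 0:  # single-category landscape: nothing can move
        return np.eye(j)
    k = np.tile(annual_rate * shares / c, (j, 1))
    np.fill_diagonal(k, 0.0)
    np.fill_diagonal(k, 1.0 - k.sum(axis=1))
    _check_kernel(k)
    return k


@dataclass
class SimConfig:
    """Full specification of a synthetic stratified landscape.

    ``kernels[s]`` is the annual row-stochastic transition kernel of
    stratum ``s`` (in scheme category order); ``initial[s]`` its starting
    composition. All strata share one grid shape; cells are
    ``cell_area_km2`` each. One global ``seed`` drives everything, with
    per-stratum substreams derived deterministically from it.
    """

    scheme: CategoryScheme
    strata: list[str]
    kernels: dict[str, np.ndarray]
    initial: dict[str, np.ndarray]
    years: tuple[int, ...] = DEFAULT_YEARS
    shape: tuple[int, int] = (100, 100)
    cell_area_km2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        j = len(self.scheme)
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        if len(self.years) < 2:
            raise ValueError("need at least two time points")
        for s in self.strata:
            k = np.asarray(self.kernels[s], dtype=float)
            if k.shape != (j, j):
                raise ValueError(f"kernel for {s!r} is {k.shape}, expected ({j}, {j})")
            _check_kernel(k, s)
            self.kernels[s] = k
            p = np.asarray(self.initial[s], dtype=float)
            if p.shape != (j,) or np.any(p < 0) or p.sum() <= 0:
                raise ValueError(f"invalid initial composition for {s!r}")
            self.initial[s] = p / p.sum()

    @property
    def intervals(self) -> list[tuple[int, int]]:
        return list(zip(self.years, self.years[1:]))

    @property
    def stratum_area_km2(self) -> float:
        return self.shape[0] * self.shape[1] * self.cell_area_km2


def default_config(
    shape: tuple[int, int] = (100, 100), seed: int = 0, years: tuple[int, ...] = DEFAULT_YEARS
) -> SimConfig:
    """The emulated continental study design (see module docstring)."""
    scheme = level1_scheme()
    strata = sorted(DEFAULT_RATES)
    initial = {s: np.asarray(DEFAULT_COMPOSITION[s], dtype=float) for s in strata}
    kernels = {
        s: availability_kernel(initial[s], DEFAULT_RATES[s]) for s in strata
    }
    return SimConfig(scheme, strata, kernels, initial, years=years, shape=shape, seed=seed)


def inject_target(
    config: SimConfig, stratum: str, pair: tuple[str, str], factor: float
) -> SimConfig:
    """Boost one kernel entry ×factor, re-balancing that row's diagonal.

    Creates ground truth for targeted-transition recovery: the (m, n)
    annual probability is multiplied and the persistence probability
    (m, m) absorbs the difference. Raises when the adjusted diagonal would
    go negative ("boost infeasible") or the boosted entry exceed 1.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    m = config.scheme.index_of(config.scheme.id_of(pair[0]))
    n = config.scheme.index_of(config.scheme.id_of(pair[1]))
    if m == n:
        raise ValueError("cannot boost a diagonal (persistence) entry")
    k = config.kernels[stratum].copy()
    delta = k[m, n] * (factor - 1.0)
    if k[m, n] + delta > 1.0:
        raise ValueError("boost infeasible: boosted probability exceeds 1")
    if k[m, m] - delta < 0.0:
        raise ValueError("boost infeasible: adjusted diagonal below 0")
    k[m, n] += delta
    k[m, m] -= delta
    kernels = {s: (k if s == stratum else v.copy()) for s, v in config.kernels.items()}
    return replace(config, kernels=kernels, initial={s: v.copy() for s, v in config.initial.items()})


# ---------------------------------------------------------------------------
# Analytic expectation
# ---------------------------------------------------------------------------


def expected_matrix(config: SimConfig, interval: tuple[int, int], stratum: str) -> TransitionMatrix:
    """Exact expected transition matrix diag(start areas) · K^ΔY.

    Start areas propagate the initial composition through the kernel over
    the years elapsed since the first time point.
    """
    k = config.kernels[stratum]
    _check_kernel(k, stratum)
    if interval not in config.intervals:
        raise ValueError(f"interval {interval} not in schedule {config.intervals}")
    y0 = config.years[0]
    comp = config.initial[stratum] @ np.linalg.matrix_power(k, interval[0] - y0)
    start = comp * config.stratum_area_km2
    c = start[:, None] * np.linalg.matrix_power(k, interval[1] - interval[0])
    return TransitionMatrix(c, config.scheme.abbrevs, interval[0], interval[1], stratum)


def expected_series(config: SimConfig) -> MatrixSeries:
    """Expected matrices for every (stratum, interval) of the schedule."""
    mats = {
        s: [expected_matrix(config, iv, s) for iv in config.intervals]
        for s in config.strata
    }
    return MatrixSeries(config.scheme, config.intervals, mats)


# ---------------------------------------------------------------------------
# Realization
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """A realized landscape: one combined map per time point, the stratum
    layer, and the cross-tabulated per-stratum matrix series."""

    config: SimConfig
    maps: list[CategoricalMap]
    strata: StratumSet
    series: MatrixSeries = field(repr=False, default=None)


def simulate_series(config: SimConfig) -> SimResult:
    """Realize the landscape cell-by-cell and cross-tabulate it.

    Strata are stacked as horizontal bands of one combined grid. Each
    stratum uses its own RNG substream spawned from the global seed, so a
    run is bit-reproducible and adding a stratum does not perturb others.
    The per-stratum total area is exactly constant over time (closed
    landscape: cells change label, never disappear).
    """
    ny, nx = config.shape
    n_cells = ny * nx
    j = len(config.scheme)
    ids = np.asarray(config.scheme.ids)
    streams = np.random.SeedSequence(config.seed).spawn(len(config.strata))

    full_shape = (ny * len(config.strata), nx)
    membership = np.repeat(np.arange(len(config.strata)), n_cells).reshape(full_shape)
    strata = StratumSet(list(config.strata), membership)

    grids = [np.empty(full_shape, dtype=int) for _ in config.years]
    for si, stratum in enumerate(config.strata):
        rng = np.random.default_rng(streams[si])
        state = rng.choice(j, size=n_cells, p=config.initial[stratum])
        rows = slice(si * ny, (si + 1) * ny)
        grids[0][rows] = ids[state].reshape(ny, nx)
        for ti, (y0, y1) in enumerate(config.intervals):
            step = np.linalg.matrix_power(config.kernels[stratum], y1 - y0)
            new_state = np.empty_like(state)
            for cat in range(j):
                sel = state == cat
                cnt = int(sel.sum())
                if cnt:
                    new_state[sel] = rng.choice(j, size=cnt, p=step[cat])
            state = new_state
            grids[ti + 1][rows] = ids[state].reshape(ny, nx)

    maps = [
        CategoricalMap(g, year=y, nodata=-1, cell_area=config.cell_area_km2)
        for g, y in zip(grids, config.years)
    ]
    flat: list[TransitionMatrix] = []
    for m0, m1 in zip(maps, maps[1:]):
        flat.extend(crosstab_by_stratum(m0, m1, config.scheme, strata).values())
    series = MatrixSeries.from_matrices(config.scheme, flat)
    return SimResult(config, maps, strata, series)
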