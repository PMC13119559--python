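"""The three hierarchical levels of Intensity Analysis (gain perspective).

Interval level: how fast did the whole landscape change in each interval,
relative to the uniform rate implied by the full study span? Category
level: which classes gained or lost faster than the landscape changed
overall (active) and which slower (dormant)? Transition level: when a
category gained, did it draw disproportionately from particular donors
(targeted) or below the uniform expectation (avoided)?

All intensities are annualized percentages (%/yr), which keeps intervals of
unequal duration — e.g. a trailing 2-year interval after a run of 5-year
ones — directly comparable. Statuses come from strict comparisons; exact
equality is reported as its own "equal" status, and zero-denominator cases
(a category absent at the relevant date) as "undefined" with NaN intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import ALL_STRATA, MatrixSeries, TransitionMatrix

FAST, SLOW = "fast", "slow"
ACTIVE, DORMANT = "active", "dormant"
TARGETED, AVOIDED = "targeted", "avoided"
EQUAL, UNDEFINED = "equal", "undefined"


#: Relative width of the "equal" band. Strict comparisons define the
#: fast/active/targeted statuses; ties get their own status, and the band
#: absorbs last-bit rounding so statuses are invariant under rescaling areas.
EQUAL_RTOL = 1e-12


def _compare(value: float, reference: float, above: str, below: str) -> str:
    if math.isnan(value) or math.isnan(reference):
        return UNDEFINED
    if math.isclose(value, reference, rel_tol=EQUAL_RTOL, abs_tol=0.0):
        return EQUAL
    if value > reference:
        return above
    return below


# ---------------------------------------------------------------------------
# Interval level
# ---------------------------------------------------------------------------


@dataclass
class IntervalIntensity:
    """Overall change tempo of one interval.

    ``annual_intensity`` is S_t = (gross change / duration) / total area ×
    100; ``tempo`` compares it with the series-level uniform intensity U
    and is filled in by :func:`uniform_intensity`.
    """

    interval: tuple[int, int]
    stratum: str
    gross_change_km2: float
    gross_change_pct: float
    annual_intensity: float  # S_t, %/yr
    uniform_intensity: float = float("nan")  # U, %/yr
    tempo: str = UNDEFINED  # fast | slow | equal

    @property
    def interval_label(self) -> str:
        return f"{self.interval[0]}-{self.interval[1]}"


def interval_intensity(matrix: TransitionMatrix) -> IntervalIntensity:
    """Gross change area, its map fraction, and the annual intensity S_t."""
    total = matrix.total_area
    if total <= 0:
        raise ValueError("zero total area")
    gross = matrix.gross_change
    return IntervalIntensity(
        interval=matrix.interval,
        stratum=matrix.stratum,
        gross_change_km2=gross,
        gross_change_pct=gross / total * 100.0,
        annual_intensity=gross / matrix.duration / total * 100.0,
    )


def uniform_intensity(
    series: MatrixSeries, stratum: str = ALL_STRATA
) -> tuple[float, list[IntervalIntensity]]:
    """Uniform annual intensity U and tempo-flagged per-interval records.

    U spreads the summed gross change evenly over the study span:
    U = Σ_t gross_t / Σ_t (ΔY_t · total_t) × 100. With constant total area
    the denominator factors into (study duration × area), the textbook
    form; computing it per interval keeps U meaningful under mild nodata
    drift. Intervals with S_t > U are "fast", < U "slow".
    """
    mats = series.stratum_series(stratum)
    if not mats:
        raise ValueError("empty series")
    records = [interval_intensity(m) for m in mats]
    denom = sum(m.duration * m.total_area for m in mats)
    u = sum(m.gross_change for m in mats) / denom * 100.0
    for rec in records:
        rec.uniform_intensity = u
        rec.tempo = _compare(rec.annual_intensity, u, FAST, SLOW)
    return u, records


# ---------------------------------------------------------------------------
# Category level
# ---------------------------------------------------------------------------


@dataclass
class CategoryIntensity:
    """Annual gross gain/loss of one category in one interval.

    Gain intensity G_tj divides the category's gross gain rate by its
    end-of-interval size; loss intensity L_ti divides the gross loss rate
    by the start size. A category is an active gainer (loser) when its
    intensity exceeds the interval's overall S_t.
    """

    interval: tuple[int, int]
    stratum: str
    category: str
    gain_km2: float
    loss_km2: float
    start_size_km2: float
    end_size_km2: float
    gain_intensity: float  # G_tj, %/yr; NaN when end size is 0
    loss_intensity: float  # L_ti, %/yr; NaN when start size is 0
    gain_status: str = UNDEFINED
    loss_status: str = UNDEFINED


def category_intensities(
    matrix: TransitionMatrix, annual_intensity: float | None = None
) -> list[CategoryIntensity]:
    """Per-category gain/loss areas, intensities and active/dormant flags.

    ``annual_intensity`` (S_t) defaults to the matrix's own interval
    intensity; pass it explicitly when comparing against another baseline.
    """
    if annual_intensity is None:
        annual_intensity = interval_intensity(matrix).annual_intensity
    dt = matrix.duration
    start, end = matrix.start_sizes, matrix.end_sizes
    gains, losses = matrix.gains(), matrix.losses()
    out = []
    for k, label in enumerate(matrix.labels):
        g = gains[k] / dt / end[k] * 100.0 if end[k] > 0 else float("nan")
        lo = losses[k] / dt / start[k] * 100.0 if start[k] > 0 else float("nan")
        out.append(
            CategoryIntensity(
                interval=matrix.interval,
                stratum=matrix.stratum,
                category=label,
                gain_km2=float(gains[k]),
                loss_km2=float(losses[k]),
                start_size_km2=float(start[k]),
                end_size_km2=float(end[k]),
                gain_intensity=g,
                loss_intensity=lo,
                gain_status=_compare(g, annual_intensity, ACTIVE, DORMANT),
                loss_status=_compare(lo, annual_intensity, ACTIVE, DORMANT),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Transition level
# ---------------------------------------------------------------------------


@dataclass
class TransitionIntensity:
    """Gain profile of one gaining category n within one interval.

    For each potential donor m ≠ n, R_tmn = C_tmn / (ΔY · C_tm·) × 100 asks
    how intensively n gained from m relative to m's availability; the
    uniform intensity W_tn is the rate n would show had it gained evenly
    from all non-n area. R > W marks a targeted transition, R < W avoided.
    W_tn equals the availability-weighted mean of the defined R_tmn.
    """

    interval: tuple[int, int]
    stratum: str
    gaining: str
    uniform_transition_intensity: float  # W_tn, %/yr
    donors: dict[str, dict] = field(default_factory=dict)
    # donors[m] = {area_km2, start_size_km2, intensity, status}


def transition_profile(matrix: TransitionMatrix, gaining: str) -> TransitionIntensity:
    """Transition intensities R_tmn and W_tn for one gaining category."""
    if gaining not in matrix.labels:
        raise KeyError(gaining)
    n = matrix.labels.index(gaining)
    dt = matrix.duration
    start = matrix.start_sizes
    col = matrix.values[:, n]

    others = [i for i in range(len(matrix.labels)) if i != n]
    avail = float(start[others].sum())
    gain = float(col[others].sum())
    w = gain / dt / avail * 100.0 if avail > 0 else float("nan")

    donors: dict[str, dict] = {}
    for m in others:
        label = matrix.labels[m]
        if start[m] > 0:
            r = float(col[m]) / dt / float(start[m]) * 100.0
        else:
            r = float("nan")
        donors[label] = {
            "area_km2": float(col[m]),
            "start_size_km2": float(start[m]),
            "intensity": r,
            "status": _compare(r, w, TARGETED, AVOIDED),
        }
    return TransitionIntensity(matrix.interval, matrix.stratum, gaining, w, donors)


# ---------------------------------------------------------------------------
# Stationarity across intervals
# ---------------------------------------------------------------------------


@dataclass
class StationarityTable:
    """Per ordered pair (from, to): targeted/avoided status in each interval.

    A transition is stationary when its status persists across intervals;
    the targeted-interval count over the total quantifies that persistence.
    """

    labels: list[str]
    intervals: list[tuple[int, int]]
    stratum: str
    statuses: dict[tuple[str, str], list[str]]

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def count(self, frm: str, to: str, status: str = TARGETED) -> int:
        return sum(s == status for s in self.statuses[(frm, to)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (m, n), ss in self.statuses.items():
            row = {"from": m, "to": n}
            row.update({f"{a}-{b}": s for (a, b), s in zip(self.intervals, ss)})
            row["targeted_count"] = self.count(m, n)
            row["n_intervals"] = self.n_intervals
            rows.append(row)
        return pd.DataFrame(rows)


def stationarity_table(series: MatrixSeries, stratum: str = ALL_STRATA) -> StationarityTable:
    """Transition statuses for every ordered pair across all intervals."""
    mats = series.stratum_series(stratum)
    labels = series.scheme.abbrevs
    statuses: dict[tuple[str, str], list[str]] = {
        (m, n): [] for n in labels for m in labels if m != n
    }
    for mat in mats:
        for n in labels:
            prof = transition_profile(mat, n)
            for m, d in prof.donors.items():
                statuses[(m, n)].append(d["status"])
    return StationarityTable(labels, list(series.intervals), stratum, statuses)


# ---------------------------------------------------------------------------
# Tidy exports
# ---------------------------------------------------------------------------


def intervals_frame(records: list[IntervalIntensity]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "interval": r.interval_label,
            "from_year": r.interval[0],
            "to_year": r.interval[1],
            "stratum": r.stratum,
            "gross_change_km2": r.gross_change_km2,
            "gross_change_pct": r.gross_change_pct,
            "annual_intensity_pct_yr": r.annual_intensity,
            "uniform_intensity_pct_yr": r.uniform_intensity,
            "tempo": r.tempo,
        }
        for r in records
    )


def categories_frame(records: list[CategoryIntensity]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "interval": f"{r.interval[0]}-{r.interval[1]}",
            "stratum": r.stratum,
            "category": r.category,
            "gain_km2": r.gain_km2,
            "loss_km2": r.loss_km2,
            "start_size_km2": r.start_size_km2,
            "end_size_km2": r.end_size_km2,
            "gain_intensity_pct_yr": r.gain_intensity,
            "loss_intensity_pct_yr": r.loss_intensity,
            "gain_status": r.gain_status,
            "loss_status": r.loss_status,
        }
        for r in records
    )


def transitions_frame(profiles: list[TransitionIntensity]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for m, d in p.donors.items():
            rows.append(
                {
                    "interval": f"{p.interval[0]}-{p.interval[1]}",
                    "stratum": p.stratum,
                    "from": m,
                    "to": p.gaining,
                    "area_km2": d["area_km2"],
                    "transition_intensity_pct_yr": d["intensity"],
                    "uniform_transition_intensity_pct_yr": p.uniform_transition_intensity,
                    "status": d["status"],
                }
            )
    return pd.DataFrame(rows)
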