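"""Stratified decomposition: attributing continental change to sub-regions.

Each level of Intensity Analysis has a companion decomposition that splits
an area total across strata as percentages: the interval-level gross
change, a category's gross gain or loss, or a single (from, to) transition
flow. Shares are defined on areas — P_k = A_k / Σ_k A_k × 100 — so defined
rows always sum to 100% and absolute areas to the continental value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .intensity import interval_intensity
from .matrices import TransitionMatrix

INTERVAL, GAIN, LOSS, TRANSITION = "interval", "gain", "loss", "transition"


@dataclass
class ContributionTable:
    """Per-stratum shares of one continental quantity.

    ``shares`` are percentages (NaN throughout when the continental total
    is zero — the decomposition is then undefined, not 0/0 = 100%).
    Stratum order is declaration order and decides argmax ties.
    """

    level: str  # interval | gain | loss | transition
    interval: tuple[int, int]
    target: str  # "" | category | "m->n"
    strata: list[str]
    areas_km2: list[float]
    shares_pct: list[float]

    @property
    def defined(self) -> bool:
        return not any(math.isnan(s) for s in self.shares_pct)

    @property
    def total_km2(self) -> float:
        return float(sum(self.areas_km2))

    def share(self, stratum: str) -> float:
        return self.shares_pct[self.strata.index(stratum)]

    def area(self, stratum: str) -> float:
        return self.areas_km2[self.strata.index(stratum)]


def _table(
    level: str, interval: tuple[int, int], target: str, strata: list[str], areas: list[float]
) -> ContributionTable:
    total = sum(areas)
    if total > 0:
        shares = [a / total * 100.0 for a in areas]
    else:
        shares = [float("nan")] * len(areas)
    return ContributionTable(level, interval, target, list(strata), list(map(float, areas)), shares)


def _check_same_interval(matrices: list[TransitionMatrix]) -> tuple[int, int]:
    if not matrices:
        raise ValueError("no per-stratum matrices")
    iv = matrices[0].interval
    for m in matrices[1:]:
        if m.interval != iv:
            raise ValueError(f"interval mismatch: {m.interval_label} vs {iv[0]}-{iv[1]}")
    return iv


def interval_contributions(matrices: list[TransitionMatrix]) -> ContributionTable:
    """Stratum shares of the interval's continental gross change area."""
    iv = _check_same_interval(matrices)
    areas = [m.gross_change for m in matrices]
    return _table(INTERVAL, iv, "", [m.stratum for m in matrices], areas)


def category_contributions(
    matrices: list[TransitionMatrix], category: str, side: str
) -> ContributionTable:
    """Stratum shares of one category's continental gross gain or loss."""
    iv = _check_same_interval(matrices)
    if side not in (GAIN, LOSS):
        raise ValueError(f"side must be {GAIN!r} or {LOSS!r}, got {side!r}")
    areas = []
    for m in matrices:
        k = m.labels.index(category)
        areas.append(float(m.gains()[k] if side == GAIN else m.losses()[k]))
    return _table(side, iv, category, [m.stratum for m in matrices], areas)


def transition_contributions(
    matrices: list[TransitionMatrix], frm: str, to: str
) -> ContributionTable:
    """Stratum shares of one (from, to) transition's continental area."""
    iv = _check_same_interval(matrices)
    areas = [m.entry(frm, to) for m in matrices]
    return _table(TRANSITION, iv, f"{frm}->{to}", [m.stratum for m in matrices], areas)


def dominant_stratum(table: ContributionTable) -> tuple[str, float]:
    """Stratum with the largest share; ties go to the first-declared one."""
    if not table.defined:
        raise ValueError("all contributions undefined (zero continental total)")
    best = max(range(len(table.strata)), key=lambda k: (table.shares_pct[k], -k))
    return table.strata[best], table.shares_pct[best]


def decomposition_consistency(
    matrices: list[TransitionMatrix], aggregate: TransitionMatrix
) -> float:
    """Max |stratum-sum − aggregate| interval intensity residual (diagnostic)."""
    s_from_strata = interval_intensity(aggregate).annual_intensity
    total_gross = sum(m.gross_change for m in matrices)
    total_area = sum(m.total_area for m in matrices)
    s_direct = total_gross / aggregate.duration / total_area * 100.0
    return abs(s_from_strata - s_direct)


def contributions_frame(tables: list[ContributionTable]) -> pd.DataFrame:
    """Tidy long frame: one row per (table, stratum), with a dominant flag."""
    rows = []
    for t in tables:
        dom = dominant_stratum(t)[0] if t.defined else None
        for s, a, p in zip(t.strata, t.areas_km2, t.shares_pct):
            rows.append(
                {
                    "level": t.level,
                    "interval": f"{t.interval[0]}-{t.interval[1]}",
                    "target": t.target,
                    "stratum": s,
                    "area_km2": a,
                    "share_pct": p,
                    "dominant": s == dom,
                }
            )
    return pd.DataFrame(rows)
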