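"""Dominant transition pathways, trajectory maps and transition networks.

A pathway is a named set of ordered (from, to) category pairs — e.g.
deforestation is forest→cropland, agricultural expansion pools shrubland/
grassland/bare→cropland. Pathways are selected from the stationarity table
(how often a pair was targeted) together with its cumulative first-to-last
area, mapped cell-by-cell from the first and last dates, budgeted per
stratum, and summarized as a directed network of targeted transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .decomposition import ContributionTable, dominant_stratum
from .intensity import TARGETED, StationarityTable, stationarity_table
from .maps import CategoricalMap
from .matrices import ALL_STRATA, MatrixSeries, TransitionMatrix
from .scheme import CategoryScheme

#: Reserved trajectory-map codes.
NODATA_CODE = -1
PERSISTENCE_CODE = 0
OTHER_CHANGE_CODE = 99


@dataclass(frozen=True)
class PathwayDef:
    """A named set of (from, to) category pairs with a map display code."""

    name: str
    pairs: tuple[tuple[str, str], ...]
    code: int

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError(f"pathway {self.name!r} has no pairs")
        if self.code in (NODATA_CODE, PERSISTENCE_CODE) or self.code >= OTHER_CHANGE_CODE:
            raise ValueError(f"pathway {self.name!r}: code {self.code} is reserved")


def default_pathways() -> list[PathwayDef]:
    """The six dominant land-cover conversion pathways.

    Deforestation (FST→CRP), Forest Degradation (FST→SHR), Agricultural
    Expansion (SHR/GRS/BAL→CRP), Wetland Expansion (FST→WET), Shrub
    Degradation (SHR→GRS) and Desertification (GRS→BAL).
    """
    return [
        PathwayDef("Deforestation", (("FST", "CRP"),), 1),
        PathwayDef("Forest Degradation", (("FST", "SHR"),), 2),
        PathwayDef(
            "Agricultural Expansion",
            (("SHR", "CRP"), ("GRS", "CRP"), ("BAL", "CRP")),
            3,
        ),
        PathwayDef("Wetland Expansion", (("FST", "WET"),), 4),
        PathwayDef("Shrub Degradation", (("SHR", "GRS"),), 5),
        PathwayDef("Desertification", (("GRS", "BAL"),), 6),
    ]


def check_pathways(pathways: list[PathwayDef]) -> dict[tuple[str, str], PathwayDef]:
    """Validate no pair belongs to two pathways; return pair -> pathway map."""
    seen: dict[tuple[str, str], PathwayDef] = {}
    for p in pathways:
        for pair in p.pairs:
            if pair in seen:
                raise ValueError(
                    f"pair {pair[0]}->{pair[1]} appears in both "
                    f"{seen[pair].name!r} and {p.name!r}"
                )
            seen[pair] = p
    return seen


def pathways_to_yaml(pathways: list[PathwayDef], path: str | Path) -> None:
    data = [
        {"name": p.name, "code": p.code, "pairs": [list(pair) for pair in p.pairs]}
        for p in pathways
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def pathways_from_yaml(path: str | Path) -> list[PathwayDef]:
    data = yaml.safe_load(Path(path).read_text())
    pathways = [
        PathwayDef(d["name"], tuple(tuple(pair) for pair in d["pairs"]), int(d["code"]))
        for d in data
    ]
    check_pathways(pathways)
    return pathways


# ---------------------------------------------------------------------------
# Pathway selection
# ---------------------------------------------------------------------------


def select_dominant_transitions(
    stationarity: StationarityTable,
    first_last: TransitionMatrix,
    min_targeted_frac: float = 0.5,
    min_area_km2: float | None = None,
) -> pd.DataFrame:
    """Rank (from, to) pairs that were frequently targeted AND large.

    A pair qualifies when its targeted-interval count reaches
    ``ceil(min_targeted_frac × n_intervals)`` and its first-to-last
    cumulative area reaches ``min_area_km2``; by default the area cutoff is
    the top decile of positive off-diagonal first-to-last areas. Result is
    sorted by area descending.
    """
    if not 0.0 <= min_targeted_frac <= 1.0:
        raise ValueError("min_targeted_frac must be in [0, 1]")
    labels = first_last.labels
    off = [
        first_last.entry(m, n) for m in labels for n in labels if m != n
    ]
    if min_area_km2 is None:
        positive = [a for a in off if a > 0]
        min_area_km2 = float(np.quantile(positive, 0.9)) if positive else float("inf")
    need = math.ceil(min_targeted_frac * stationarity.n_intervals)

    rows = []
    for (m, n), statuses in stationarity.statuses.items():
        count = sum(s == TARGETED for s in statuses)
        area = first_last.entry(m, n)
        if count >= need and area >= min_area_km2:
            rows.append(
                {
                    "from": m,
                    "to": n,
                    "targeted_count": count,
                    "n_intervals": stationarity.n_intervals,
                    "area_km2": area,
                }
            )
    df = pd.DataFrame(rows, columns=["from", "to", "targeted_count", "n_intervals", "area_km2"])
    return df.sort_values("area_km2", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# Trajectory map
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryMap:
    """Grid of pathway codes derived from a first-vs-last date comparison."""

    grid: np.ndarray
    legend: dict[int, str]
    cell_area: float | np.ndarray = 1.0

    def counts(self) -> dict[str, int]:
        vals, cnt = np.unique(self.grid, return_counts=True)
        return {
            self.legend.get(int(v), str(int(v))): int(c)
            for v, c in zip(vals, cnt)
            if int(v) != NODATA_CODE
        }

    def areas_km2(self) -> dict[str, float]:
        area = (
            self.cell_area
            if isinstance(self.cell_area, np.ndarray)
            else np.full(self.grid.shape, float(self.cell_area))
        )
        out: dict[str, float] = {}
        for code, name in self.legend.items():
            if code == NODATA_CODE:
                continue
            out[name] = float(area[self.grid == code].sum())
        return out


def label_trajectories(
    map_first: CategoricalMap,
    map_last: CategoricalMap,
    scheme: CategoryScheme,
    pathways: list[PathwayDef],
) -> TrajectoryMap:
    """Label each cell by the pathway its (first, last) pair belongs to.

    Unchanged cells are persistence; changed pairs outside every pathway
    are other-change. Intermediate reversals between the two dates are
    invisible by construction — the comparison is endpoint-only.
    """
    if map_first.grid.shape != map_last.grid.shape:
        raise ValueError("grid shape mismatch")
    pair_map = check_pathways(pathways)
    code_of = {
        (scheme.id_of(m), scheme.id_of(n)): p.code for (m, n), p in pair_map.items()
    }
    a, b = map_first.grid, map_last.grid
    valid = map_first.valid & map_last.valid
    out = np.full(a.shape, NODATA_CODE, dtype=int)
    out[valid] = OTHER_CHANGE_CODE
    out[valid & (a == b)] = PERSISTENCE_CODE
    for (i, j), code in code_of.items():
        out[valid & (a == i) & (b == j)] = code
    legend = {NODATA_CODE: "nodata", PERSISTENCE_CODE: "persistence", OTHER_CHANGE_CODE: "other-change"}
    legend.update({p.code: p.name for p in pathways})
    return TrajectoryMap(out, legend, map_first.cell_area)


# ---------------------------------------------------------------------------
# Pathway budget
# ---------------------------------------------------------------------------


def pathway_budget(
    first_last_by_stratum: dict[str, TransitionMatrix],
    pathways: list[PathwayDef],
) -> pd.DataFrame:
    """Continental and per-stratum area (and share) of each pathway.

    Pools member-pair areas of the first-to-last matrices; shares follow
    the transition-level decomposition applied to the pooled areas.
    Pathways with zero continental area are omitted.
    """
    check_pathways(pathways)
    strata = list(first_last_by_stratum.keys())
    rows = []
    for p in pathways:
        per_stratum = {
            s: sum(m.entry(a, b) for a, b in p.pairs)
            for s, m in first_last_by_stratum.items()
        }
        total = sum(per_stratum.values())
        if total <= 0:
            continue
        for s in strata:
            rows.append(
                {
                    "pathway": p.name,
                    "stratum": s,
                    "area_km2": per_stratum[s],
                    "share_pct": per_stratum[s] / total * 100.0,
                    "total_km2": total,
                }
            )
    return pd.DataFrame(
        rows, columns=["pathway", "stratum", "area_km2", "share_pct", "total_km2"]
    )


def first_last_matrices(
    series: MatrixSeries,
    map_first: CategoricalMap | None = None,
    map_last: CategoricalMap | None = None,
) -> dict[str, TransitionMatrix]:
    """First-to-last matrices per stratum.

    With maps available these come from a direct endpoint cross-tabulation;
    otherwise (matrices-only input) from chaining each stratum's interval
    flows under a cell-level Markov assumption: T = Π_t (row-normalized
    C_t), scaled by start sizes. The direct reading is exact; the chained
    one is the best reconstruction the matrices alone support.
    """
    if map_first is not None and map_last is not None:
        raise ValueError("use crosstab_by_stratum for map-based first-last matrices")
    y0, y1 = series.years[0], series.years[-1]
    out: dict[str, TransitionMatrix] = {}
    for stratum in series.strata:
        mats = series.matrices[stratum]
        start = mats[0].start_sizes
        trans = np.eye(len(start))
        for m in mats:
            rs = m.start_sizes
            p = np.divide(
                m.values, rs[:, None], out=np.zeros_like(m.values), where=rs[:, None] > 0
            )
            # absent categories keep identity rows so the chain stays stochastic
            p[rs == 0] = np.eye(len(start))[rs == 0]
            trans = trans @ p
        out[stratum] = TransitionMatrix(
            start[:, None] * trans, mats[0].labels, y0, y1, stratum
        )
    return out


# ---------------------------------------------------------------------------
# Targeted-transition network
# ---------------------------------------------------------------------------


@dataclass
class TransitionNetwork:
    """Directed network of targeted transitions over the full study period.

    Nodes carry the mean class area over all time points; edges run from
    the losing to the gaining category with the cumulative transition area
    and the dominant contributing stratum.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def nodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": n, "mean_area_km2": d["mean_area_km2"]}
            for n, d in self.graph.nodes(data=True)
        )

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "from": u,
                "to": v,
                "area_km2": d["area_km2"],
                "n_targeted_intervals": d["n_targeted_intervals"],
                "dominant_stratum": d.get("dominant_stratum"),
                "dominant_share_pct": d.get("dominant_share_pct"),
            }
            for u, v, d in self.graph.edges(data=True)
        )

    def write(self, nodes_path: str | Path, edges_path: str | Path) -> None:
        self.nodes_frame().to_csv(nodes_path, index=False)
        self.edges_frame().to_csv(edges_path, index=False)

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _, _, d in g.edges(data=True):  # GraphML cannot hold None
            for k, v in list(d.items()):
                if v is None:
                    d[k] = ""
        nx.write_graphml(g, str(path))


def build_network(
    series: MatrixSeries,
    stationarity: StationarityTable | None = None,
    targeted_only: bool = True,
) -> TransitionNetwork:
    """Aggregate targeted transitions into a directed network summary.

    Edges appear for pairs targeted (at the whole-domain level) in at least
    one interval. With ``targeted_only`` (default) the edge area sums the
    pair's flow over its targeted intervals only; otherwise over all
    intervals. Dominant stratum per edge comes from the per-stratum flows
    pooled over the same intervals (absent when the series has one stratum).
    """
    agg = series.aggregate() if series.strata != [ALL_STRATA] else series.matrices[ALL_STRATA]
    if stationarity is None:
        stationarity = stationarity_table(series)
    labels = series.scheme.abbrevs

    net = TransitionNetwork()
    # mean class area over the T time points (start sizes + final end sizes)
    sizes = np.array([m.start_sizes for m in agg] + [agg[-1].end_sizes])
    for k, lab in enumerate(labels):
        net.graph.add_node(lab, mean_area_km2=float(sizes[:, k].mean()))

    multi_strata = series.strata != [ALL_STRATA] and len(series.strata) > 1
    for (m, n), statuses in stationarity.statuses.items():
        targeted_idx = [t for t, s in enumerate(statuses) if s == TARGETED]
        if not targeted_idx:
            continue
        use_idx = targeted_idx if targeted_only else range(series.n_intervals)
        area = sum(agg[t].entry(m, n) for t in use_idx)
        attrs: dict = {"area_km2": float(area), "n_targeted_intervals": len(targeted_idx)}
        if multi_strata:
            pooled = [
                sum(series.matrices[s][t].entry(m, n) for t in use_idx)
                for s in series.strata
            ]
            table = ContributionTable(
                "transition", (series.years[0], series.years[-1]), f"{m}->{n}",
                list(series.strata), pooled,
                [a / sum(pooled) * 100.0 for a in pooled] if sum(pooled) > 0
                else [float("nan")] * len(pooled),
            )
            if table.defined:
                dom, share = dominant_stratum(table)
                attrs["dominant_stratum"] = dom
                attrs["dominant_share_pct"] = share
        net.graph.add_edge(m, n, **attrs)
    return net
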