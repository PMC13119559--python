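"""Three-stage pipeline: cross-tabulate -> analyze -> decompose/report.

`run_pipeline` takes a :class:`RunConfig`, acquires a matrix series (from
rasters, from pre-computed matrix tables, or from the synthetic
generator), runs all three levels of Intensity Analysis with stratified
decomposition, selects dominant pathways, and writes a complete result
bundle of tidy CSVs plus a JSON run manifest. `render_report` turns a
bundle into summary figures. Both are deterministic for identical inputs.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decomposition import (
    GAIN,
    LOSS,
    category_contributions,
    contributions_frame,
    interval_contributions,
    transition_contributions,
)
from .intensity import (
    categories_frame,
    category_intensities,
    intervals_frame,
    stationarity_table,
    transition_profile,
    transitions_frame,
    uniform_intensity,
)
from .maps import CategoricalMap, StratumSet, crosstab_by_stratum, reclassify_map
from .matrices import ALL_STRATA, MatrixSeries, read_matrix_table, validate_series
from .raster_io import read_ascii_grid, write_ascii_grid
from .scheme import CategoryScheme, level1_scheme
from .simulate import default_config, inject_target, simulate_series
from .trajectories import (
    PathwayDef,
    TrajectoryMap,
    build_network,
    default_pathways,
    first_last_matrices,
    label_trajectories,
    pathway_budget,
    pathways_from_yaml,
    select_dominant_transitions,
)

REQUIRED_ARTIFACTS = [
    "intervals.csv",
    "categories.csv",
    "transitions.csv",
    "stationarity.csv",
    "contributions.csv",
    "pathway_budget.csv",
    "dominant_transitions.csv",
    "network_nodes.csv",
    "network_edges.csv",
    "manifest.json",
]


class PipelineError(RuntimeError):
    """Module error surfaced with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    ``mode`` selects the input path: "matrices" reads pre-computed matrix
    CSVs (with JSON sidecars) from ``matrices_dir``; "rasters" cross-
    tabulates ASCII-grid maps listed in ``raster_paths`` using
    ``strata_path``; "simulate" generates the default synthetic landscape
    with ``seed``. Thresholds feed dominant-pathway selection.
    """

    mode: str = "simulate"  # rasters | matrices | simulate
    out_dir: Path = Path("results")
    matrices_dir: Path | None = None
    raster_paths: list[Path] = field(default_factory=list)
    strata_path: Path | None = None
    pathways_path: Path | None = None
    scheme: CategoryScheme | None = None
    min_targeted_frac: float = 0.5
    min_area_km2: float | None = None
    area_drift_rtol: float = 0.01
    seed: int = 0
    sim_shape: tuple[int, int] = (100, 100)
    sim_boost: tuple[str, str, str, float] | None = None  # (stratum, from, to, factor)

    def __post_init__(self) -> None:
        if self.mode not in ("rasters", "matrices", "simulate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.min_targeted_frac <= 1.0:
            raise ValueError("min_targeted_frac must be in [0, 1]")
        self.out_dir = Path(self.out_dir)


def _load_matrices(config: RunConfig) -> tuple[MatrixSeries, CategoryScheme]:
    if config.matrices_dir is None or not Path(config.matrices_dir).is_dir():
        raise FileNotFoundError(f"matrices directory not found: {config.matrices_dir}")
    scheme = config.scheme or level1_scheme()
    paths = sorted(Path(config.matrices_dir).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no matrix CSVs in {config.matrices_dir}")
    mats = [read_matrix_table(p, scheme) for p in paths]
    return MatrixSeries.from_matrices(scheme, mats), scheme


def _load_rasters(
    config: RunConfig,
) -> tuple[MatrixSeries, CategoryScheme, list[CategoricalMap], StratumSet]:
    scheme = config.scheme or level1_scheme()
    if not config.raster_paths:
        raise FileNotFoundError("no raster paths configured")
    maps = sorted((read_ascii_grid(p) for p in config.raster_paths), key=lambda m: m.year)
    needs_reclass = any(
        v not in scheme.ids for m in maps for v in np.unique(m.grid[m.valid])
    )
    if needs_reclass:
        maps = [reclassify_map(m, scheme) for m in maps]
    if config.strata_path is not None:
        stratum_map = read_ascii_grid(config.strata_path, year=maps[0].year)
        labels = [str(v) for v in np.unique(stratum_map.grid[stratum_map.valid])]
        index = np.full(stratum_map.grid.shape, -1, dtype=int)
        for k, lab in enumerate(labels):
            index[stratum_map.grid == int(lab)] = k
        strata = StratumSet(labels, index)
    else:
        strata = StratumSet([ALL_STRATA], np.zeros(maps[0].grid.shape, dtype=int))
    flat = []
    for m0, m1 in zip(maps, maps[1:]):
        flat.extend(crosstab_by_stratum(m0, m1, scheme, strata).values())
    return MatrixSeries.from_matrices(scheme, flat), scheme, maps, strata


def run_pipeline(config: RunConfig, verbose: int = 0) -> dict:
    """Execute the full workflow and write the result bundle.

    Returns a bundle dict holding every result table (DataFrames), the
    series, and the output paths. Raises :class:`PipelineError` tagged
    with the failing stage.
    """

    def log(msg: str) -> None:
        if verbose:
            print(msg, file=sys.stderr)

    maps = None
    strata = None
    # -- stage 1: acquire matrices -----------------------------------------
    try:
        if config.mode == "matrices":
            series, scheme = _load_matrices(config)
        elif config.mode == "rasters":
            series, scheme, maps, strata = _load_rasters(config)
        else:
            sim_config = default_config(shape=config.sim_shape, seed=config.seed)
            if config.sim_boost is not None:
                s, frm, to, factor = config.sim_boost
                sim_config = inject_target(sim_config, s, (frm, to), float(factor))
            result = simulate_series(sim_config)
            series, scheme, maps, strata = result.series, sim_config.scheme, result.maps, result.strata
        log(f"stage 1: {len(series.strata)} strata x {series.n_intervals} intervals")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("cross-tabulation", exc) from exc

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    # -- stage 2: intensity metrics -----------------------------------------
    try:
        issues = validate_series(series, config.area_drift_rtol)
        for issue in issues:
            log(f"validate: {issue.kind}: {issue.message}")
        agg = series.aggregate() if len(series.strata) > 1 else series.stratum_series(series.strata[0])

        interval_records = []
        for stratum in [ALL_STRATA] + (series.strata if len(series.strata) > 1 else []):
            _, recs = uniform_intensity(series, stratum)
            interval_records.extend(recs)
        intervals_df = intervals_frame(interval_records)

        category_records = []
        profiles = []
        for stratum in [ALL_STRATA] + (series.strata if len(series.strata) > 1 else []):
            for mat in series.stratum_series(stratum):
                category_records.extend(category_intensities(mat))
                profiles.extend(transition_profile(mat, n) for n in scheme.abbrevs)
        categories_df = categories_frame(category_records)
        transitions_df = transitions_frame(profiles)

        stat = stationarity_table(series)
        stationarity_df = stat.to_frame()
        log(f"stage 2: {len(transitions_df)} transition records")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("intensity-analysis", exc) from exc

    # -- stage 3: decomposition, pathways, network ---------------------------
    try:
        tables = []
        multi = len(series.strata) > 1
        if multi:
            for t in range(series.n_intervals):
                per_stratum = [series.matrices[s][t] for s in series.strata]
                tables.append(interval_contributions(per_stratum))
                for cat in scheme.abbrevs:
                    tables.append(category_contributions(per_stratum, cat, GAIN))
                    tables.append(category_contributions(per_stratum, cat, LOSS))
                for m in scheme.abbrevs:
                    for n in scheme.abbrevs:
                        if m != n:
                            tables.append(transition_contributions(per_stratum, m, n))
        contributions_df = contributions_frame(tables)

        if maps is not None and strata is not None and multi:
            fl = crosstab_by_stratum(maps[0], maps[-1], scheme, strata)
        elif maps is not None:
            fl = crosstab_by_stratum(
                maps[0], maps[-1], scheme,
                StratumSet([ALL_STRATA], np.zeros(maps[0].grid.shape, dtype=int)),
            )
        else:
            fl = first_last_matrices(series)
        from .matrices import sum_strata

        fl_all = sum_strata(list(fl.values())) if len(fl) > 1 else next(iter(fl.values()))

        dominant_df = select_dominant_transitions(
            stat, fl_all, config.min_targeted_frac, config.min_area_km2
        )
        if config.pathways_path is not None:
            pathways = pathways_from_yaml(config.pathways_path)
        else:
            pathways = default_pathways()
            known = set(scheme.abbrevs)
            pathways = [
                p for p in pathways if all(a in known and b in known for a, b in p.pairs)
            ]
        budget_df = pathway_budget(fl, pathways)
        network = build_network(series, stat)

        trajectory = None
        if maps is not None:
            trajectory = label_trajectories(maps[0], maps[-1], scheme, pathways)
        log(f"stage 3: {len(dominant_df)} dominant pairs, {network.graph.number_of_edges()} network edges")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("decomposition", exc) from exc

    # -- write bundle --------------------------------------------------------
    try:
        intervals_df.to_csv(out / "intervals.csv", index=False)
        categories_df.to_csv(out / "categories.csv", index=False)
        transitions_df.to_csv(out / "transitions.csv", index=False)
        stationarity_df.to_csv(out / "stationarity.csv", index=False)
        contributions_df.to_csv(out / "contributions.csv", index=False)
        dominant_df.to_csv(out / "dominant_transitions.csv", index=False)
        budget_df.to_csv(out / "pathway_budget.csv", index=False)
        network.write(out / "network_nodes.csv", out / "network_edges.csv")
        network.write_graphml(out / "network.graphml")
        if trajectory is not None:
            traj_map = CategoricalMap(
                trajectory.grid, year=series.years[-1], nodata=-1,
                cell_area=maps[0].cell_area, gridspec=maps[0].gridspec,
            )
            write_ascii_grid(traj_map, out / "trajectories.asc")
            (out / "trajectories_legend.json").write_text(
                json.dumps({str(k): v for k, v in trajectory.legend.items()}, indent=1)
            )
        manifest = {
            "version": __version__,
            "mode": config.mode,
            "seed": config.seed,
            "strata": series.strata,
            "intervals": [f"{a}-{b}" for a, b in series.intervals],
            "categories": scheme.abbrevs,
            "min_targeted_frac": config.min_targeted_frac,
            "min_area_km2": config.min_area_km2,
            "validation_issues": [f"{i.kind}: {i.message}" for i in issues],
            "artifacts": REQUIRED_ARTIFACTS,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("write-bundle", exc) from exc

    return {
        "series": series,
        "scheme": scheme,
        "intervals": intervals_df,
        "categories": categories_df,
        "transitions": transitions_df,
        "stationarity": stationarity_df,
        "contributions": contributions_df,
        "dominant_transitions": dominant_df,
        "pathway_budget": budget_df,
        "network": network,
        "trajectory": trajectory,
        "first_last": fl,
        "out_dir": out,
        "manifest": manifest,
    }


def render_report(bundle: dict, out_dir: str | Path | None = None) -> list[Path]:
    """Render the standard figure set from a complete bundle.

    Writes an interval-level panel (gross change, S_t vs U, stacked
    regional contributions), category gain/loss panels, a stationarity
    grid and a network diagram. Deterministic for a given bundle.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    missing = [
        k
        for k in ("intervals", "categories", "stationarity", "network")
        if k not in bundle or bundle[k] is None
    ]
    if missing:
        raise ValueError(f"incomplete bundle, missing: {missing}")
    out = Path(out_dir) if out_dir is not None else Path(bundle["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    iv = bundle["intervals"]
    iv_all = iv[iv["stratum"] == ALL_STRATA]
    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    axes[0].bar(iv_all["interval"], iv_all["gross_change_pct"], color="#777")
    axes[0].set_ylabel("gross change (% of map)")
    axes[1].plot(iv_all["interval"], iv_all["annual_intensity_pct_yr"], "o-", label="S_t")
    axes[1].axhline(iv_all["uniform_intensity_pct_yr"].iloc[0], ls="--", color="k", label="U")
    axes[1].set_ylabel("annual intensity (%/yr)")
    axes[1].legend()
    contrib = bundle.get("contributions")
    if contrib is not None and len(contrib):
        piv = (
            contrib[contrib["level"] == "interval"]
            .pivot(index="interval", columns="stratum", values="share_pct")
            .fillna(0.0)
        )
        bottom = np.zeros(len(piv))
        for stratum in piv.columns:
            axes[2].bar(piv.index, piv[stratum], bottom=bottom, label=stratum)
            bottom += piv[stratum].to_numpy()
        axes[2].set_ylabel("regional share of gross change (%)")
        axes[2].legend(fontsize=7)
    for ax in axes:
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    p = out / "fig_intervals.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    cat = bundle["categories"]
    cat_all = cat[cat["stratum"] == ALL_STRATA]
    fig, axes = plt.subplots(1, 2, figsize=(12, 4), sharey=True)
    for ax, side in zip(axes, ("gain", "loss")):
        piv = cat_all.pivot(index="interval", columns="category", values=f"{side}_km2")
        piv.plot.bar(stacked=True, ax=ax, legend=side == "gain")
        ax.set_ylabel(f"annualized {side} area (km²)" if side == "gain" else "")
        ax.set_title(f"gross {side}")
    fig.tight_layout()
    p = out / "fig_categories.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    stat = bundle["stationarity"]
    interval_cols = [c for c in stat.columns if "-" in c]
    mat = (stat[interval_cols] == "targeted").astype(int)
    fig, ax = plt.subplots(figsize=(8, max(3, 0.18 * len(stat))))
    ax.imshow(mat.to_numpy(), aspect="auto", cmap="Greens", vmin=0, vmax=1)
    ax.set_yticks(range(len(stat)), (stat["from"] + "→" + stat["to"]).tolist(), fontsize=5)
    ax.set_xticks(range(len(interval_cols)), interval_cols, rotation=60, fontsize=6)
    ax.set_title("targeted (green) vs not, per interval")
    fig.tight_layout()
    p = out / "fig_stationarity.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    import networkx as nx

    net = bundle["network"]
    fig, ax = plt.subplots(figsize=(7, 7))
    g = net.graph
    pos = nx.circular_layout(g)
    sizes = [max(30.0, 3000.0 * d["mean_area_km2"] / max(
        1e-12, max(dd["mean_area_km2"] for _, dd in g.nodes(data=True)))) for _, d in g.nodes(data=True)]
    widths = [0.5 + 4.0 * d["area_km2"] / max(
        1e-12, max((dd["area_km2"] for _, _, dd in g.edges(data=True)), default=1.0))
        for _, _, d in g.edges(data=True)]
    nx.draw_networkx(g, pos, ax=ax, node_size=sizes, width=widths, font_size=8,
                     node_color="#9ecae1", edge_color="#636363", arrows=True)
    ax.set_axis_off()
    p = out / "fig_network.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
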