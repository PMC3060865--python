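"""Experiment-grid orchestration and figure-equivalent summary tables.

``run_grid`` drives the full analysis over a grid of environmental demands S
and network sizes N, with the replicate protocol used throughout the
analysis: ``n_demand_sets`` random source sets per S, and per demand set
either ``n_minimal`` minimal networks or ``n_replicates`` walks/populations.
Every cell derives its own RNG from (base_seed, stage, S, demand set,
replicate), so the grid is deterministic and resumable: completed cells are
stored as per-cell TSV files and skipped on re-run, and the summary tables
are always recomputed from the per-replicate rows on disk.

Outputs (tidy TSVs, one per figure-equivalent):

    minimal_stats.tsv     S, metric in {n_min, r_se, d_avg}, mean, sd, n
    dmax_vs_n.tsv         S, N, mean D_max of forced walks, sd, n
    robustness_vs_n.tsv   S, N, mean robustness of random networks, sd, n
    essential_vs_n.tsv    S, N, mean essential-reaction count, sd, n
    viable_sources.tsv    S, N, mean realized number of viable sources, sd, n
    unique_fraction.tsv   S, k (mutations), mean unique fraction, sd, n
    cumulative_novel.tsv  S, N, mean cumulative novel phenotypes, sd, n
    neighborhood_novel.tsv S, N, mean novel phenotypes per neighborhood, sd, n
    pop_diversity.tsv     S, N, mean final pairwise distance, sd, n
    pop_cum_novel.tsv     S, N, mean population cumulative novelty, sd, n

``overlay_predictions`` joins measured D_max / robustness values with the
closed-form predictions 1 - R_SE/N and 1 + m - (N_min/N)(1+m) and flags
cells where the prediction overestimates by more than 10%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .fba import Genotype, get_model
from .genotype_space import (Demand, essential_reactions, fit_essential_decline,
                             minimal_network, predicted_dmax,
                             predicted_robustness, random_demand,
                             random_viable_network, superessential_reactions)
from .population import (evolve_population, population_cumulative_novel)
from .universe import ReactionUniverse
from .walks import cumulative_novel, neighborhood_phenotypes, neutral_walk

__all__ = ["ExperimentGrid", "run_grid", "overlay_predictions", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("minimal", "walks", "neighborhoods", "populations")
_STAGE_CODE = {s: i + 1 for i, s in enumerate(STAGES)}


@dataclass
class ExperimentGrid:
    """The grid of study conditions and replicate counts."""

    s_values: tuple[int, ...] = (1, 5, 10, 20, 40, 60)
    n_values: tuple[int, ...] = (50, 100, 150, 200, 250, 300)
    n_demand_sets: int = 10
    n_replicates: int = 20   # walks / populations / random nets per demand set
    n_minimal: int = 100     # minimal networks per demand set
    walk_steps: int = 10_000
    neighborhood_stride: int = 50
    population_size: int = 100
    generations: int = 2000
    pop_neighborhood_stride: int = 10
    base_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentGrid":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("s_values", "n_values"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _cell_rng(grid: ExperimentGrid, stage: str, s: int, d: int,
              rep: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        [grid.base_seed, _STAGE_CODE[stage], s, d, rep])


def _demand_for(grid: ExperimentGrid, universe: ReactionUniverse,
                s: int, d: int) -> Demand:
    # demand sets are shared across stages for a given (base_seed, S, d)
    return random_demand(universe, s, np.random.default_rng(
        [grid.base_seed, 0, s, d]))


def _summary(rows: pd.DataFrame, by: list[str], value: str) -> pd.DataFrame:
    g = rows.groupby(by)[value]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out


class _CellStore:
    """Per-cell TSV persistence making grid runs resumable."""

    def __init__(self, out_dir: Path):
        self.dir = out_dir / "cells"
        self.dir.mkdir(parents=True, exist_ok=True)

    def get_or_run(self, name: str, fn) -> pd.DataFrame:
        path = self.dir / f"{name}.tsv"
        if path.exists():
            return pd.read_csv(path, sep="\t", float_precision="round_trip")
        df = fn()
        df.to_csv(path, sep="\t", index=False)
        return df


def _clip_n(universe: ReactionUniverse, n_values: Iterable[int],
            n_min: float) -> list[int]:
    lo = int(np.ceil(n_min))
    return sorted({min(max(n, lo), universe.size) for n in n_values})


def run_grid(universe: ReactionUniverse, grid: ExperimentGrid,
             stages: Iterable[str] = STAGES,
             out_dir: str | Path = "results") -> dict[str, pd.DataFrame]:
    """Run the requested stages over the grid and write summary TSVs."""
    stages = list(stages)
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    if any(s in stages for s in ("walks", "neighborhoods", "populations")) \
            and "minimal" not in stages:
        raise ValueError("stages 'walks', 'neighborhoods' and 'populations' "
                         "need the 'minimal' stage for N_min/R_SE")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    store = _CellStore(out)
    model = get_model(universe)
    s_values = [s for s in grid.s_values if s <= len(universe.sources)]
    results: dict[str, pd.DataFrame] = {}
    stats_per_s: dict[int, dict[str, float]] = {}

    # ---- minimal networks: N_min, R_SE, D_avg ----------------------------
    if "minimal" in stages:
        rows = []
        for s in s_values:
            for d in range(grid.n_demand_sets):
                demand = _demand_for(grid, universe, s, d)

                def run_cell(s=s, d=d, demand=demand) -> pd.DataFrame:
                    log.info("minimal stage: S=%d demand-set=%d", s, d)
                    st = superessential_reactions(
                        universe, demand, grid.n_minimal,
                        _cell_rng(grid, "minimal", s, d))
                    return pd.DataFrame({
                        "S": s, "demand_set": d,
                        "replicate": range(grid.n_minimal),
                        "size": st.sizes,
                        "r_se": len(st.superessential),
                        "d_avg": st.d_avg,
                    })

                rows.append(store.get_or_run(f"minimal_S{s}_d{d}", run_cell))
        reps = pd.concat(rows, ignore_index=True)
        per_set = reps.groupby(["S", "demand_set"]).agg(
            n_min=("size", "mean"), r_se=("r_se", "first"),
            d_avg=("d_avg", "first")).reset_index()
        tidy = per_set.melt(id_vars=["S", "demand_set"], var_name="metric")
        results["minimal_stats"] = _summary(tidy, ["S", "metric"], "value")
        for s in s_values:
            sub = per_set[per_set.S == s]
            stats_per_s[s] = {"n_min": sub.n_min.mean(), "r_se": sub.r_se.mean()}

    # ---- forced walks (D_max) and random-network robustness --------------
    if "walks" in stages:
        rows = []
        for s in s_values:
            n_vals = _clip_n(universe, grid.n_values, stats_per_s[s]["n_min"])
            for d in range(grid.n_demand_sets):
                demand = _demand_for(grid, universe, s, d)
                for n in n_vals:
                    def run_cell(s=s, d=d, n=n, demand=demand) -> pd.DataFrame:
                        log.info("walks stage: S=%d demand-set=%d N=%d", s, d, n)
                        recs = []
                        for rep in range(grid.n_replicates):
                            rng = _cell_rng(grid, "walks", s, d, rep * 1000 + n)
                            start = random_viable_network(universe, demand, n, rng)
                            ess = len(essential_reactions(start, universe, demand))
                            realized = int(model.phenotype(start).sum())
                            walk = neutral_walk(start, universe, demand,
                                                grid.walk_steps, rng, forced=True)
                            recs.append({"S": s, "demand_set": d, "N": n,
                                         "replicate": rep, "d_max": walk.d_max,
                                         "r_ess": ess,
                                         "robustness": 1 - ess / n,
                                         "viable_sources": realized})
                        return pd.DataFrame(recs)

                    rows.append(store.get_or_run(f"walks_S{s}_d{d}_N{n}", run_cell))
        reps = pd.concat(rows, ignore_index=True)
        results["dmax_vs_n"] = _summary(reps, ["S", "N"], "d_max")
        results["robustness_vs_n"] = _summary(reps, ["S", "N"], "robustness")
        results["essential_vs_n"] = _summary(reps, ["S", "N"], "r_ess")
        results["viable_sources"] = _summary(reps, ["S", "N"], "viable_sources")
        for s in s_values:
            sub = reps[reps.S == s]
            if sub.N.nunique() >= 2:
                stats_per_s[s]["m"] = fit_essential_decline(
                    list(zip(sub.N, sub.r_ess))).m

    # ---- neighborhood novelty along walks --------------------------------
    if "neighborhoods" in stages:
        n_ref = max(int(np.ceil(max(st["n_min"] for st in stats_per_s.values()))),
                    min(grid.n_values))
        n_ref = min(n_ref, universe.size)
        rows = []
        for s in s_values:
            for d in range(grid.n_demand_sets):
                demand = _demand_for(grid, universe, s, d)

                def run_cell(s=s, d=d, demand=demand) -> pd.DataFrame:
                    log.info("neighborhoods stage: S=%d demand-set=%d", s, d)
                    recs = []
                    for rep in range(grid.n_replicates):
                        rng = _cell_rng(grid, "neighborhoods", s, d, rep)
                        start = random_viable_network(universe, demand, n_ref, rng)
                        walk = neutral_walk(
                            start, universe, demand, grid.walk_steps, rng,
                            log_neighborhoods_every=grid.neighborhood_stride)
                        cum = cumulative_novel(walk)
                        nb0 = neighborhood_phenotypes(start, universe, demand)
                        for k, uf in zip(walk.logged_steps, walk.unique_fractions):
                            recs.append({"S": s, "demand_set": d, "N": n_ref,
                                         "replicate": rep, "k": k,
                                         "unique_fraction": uf,
                                         "cum_novel": np.nan,
                                         "novel_in_neighborhood": np.nan})
                        recs.append({"S": s, "demand_set": d, "N": n_ref,
                                     "replicate": rep, "k": -1,
                                     "unique_fraction": np.nan,
                                     "cum_novel": int(cum[-1]) if len(cum) else 0,
                                     "novel_in_neighborhood": len(nb0.novel)})
                    return pd.DataFrame(recs)

                rows.append(store.get_or_run(f"neigh_S{s}_d{d}", run_cell))
        reps = pd.concat(rows, ignore_index=True)
        uf = reps[reps.k >= 0]
        results["unique_fraction"] = _summary(uf, ["S", "k"], "unique_fraction")
        totals = reps[reps.k < 0]
        results["cumulative_novel"] = _summary(totals, ["S", "N"], "cum_novel")
        results["neighborhood_novel"] = _summary(
            totals, ["S", "N"], "novel_in_neighborhood")

    # ---- Fisher-Wright populations ---------------------------------------
    if "populations" in stages:
        rows = []
        for s in s_values:
            n_vals = _clip_n(universe, grid.n_values, stats_per_s[s]["n_min"])
            for d in range(grid.n_demand_sets):
                demand = _demand_for(grid, universe, s, d)
                for n in n_vals:
                    def run_cell(s=s, d=d, n=n, demand=demand) -> pd.DataFrame:
                        log.info("populations stage: S=%d demand-set=%d N=%d",
                                 s, d, n)
                        recs = []
                        for rep in range(grid.n_replicates):
                            rng = _cell_rng(grid, "populations", s, d,
                                            rep * 1000 + n)
                            founder = random_viable_network(
                                universe, demand, n, rng)
                            series = evolve_population(
                                founder, universe, demand,
                                grid.population_size, grid.generations, rng,
                                neighborhood_stride=grid.pop_neighborhood_stride)
                            cum = population_cumulative_novel(series)
                            recs.append({
                                "S": s, "demand_set": d, "N": n,
                                "replicate": rep,
                                "diversity": series.states[-1].diversity,
                                "cum_novel": int(cum[-1]) if len(cum) else 0})
                        return pd.DataFrame(recs)

                    rows.append(store.get_or_run(f"pop_S{s}_d{d}_N{n}", run_cell))
        reps = pd.concat(rows, ignore_index=True)
        results["pop_diversity"] = _summary(reps, ["S", "N"], "diversity")
        results["pop_cum_novel"] = _summary(reps, ["S", "N"], "cum_novel")

    for name, df in results.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    return results


def overlay_predictions(results: Mapping[str, pd.DataFrame],
                        stats_per_s: Mapping[int, Mapping[str, float]]
                        ) -> pd.DataFrame:
    """Join measured D_max / robustness with the closed-form predictions.

    ``stats_per_s`` maps S to {"n_min", "r_se", "m"}.  The returned table has
    one row per (metric, S, N) with measured value, prediction, residual and
    a flag for predictions overestimating the measurement by more than 10%.
    """
    frames = []
    for metric, table, predict in (
            ("d_max", results.get("dmax_vs_n"),
             lambda n, st: predicted_dmax(n, st["r_se"])),
            ("robustness", results.get("robustness_vs_n"),
             lambda n, st: predicted_robustness(n, st["n_min"], st.get("m", 0.0)))):
        if table is None:
            continue
        rows = []
        for _, row in table.iterrows():
            st = stats_per_s[int(row.S)]
            pred = predict(row.N, st)
            rows.append({"metric": metric, "S": int(row.S), "N": int(row.N),
                         "measured": row["mean"], "predicted": pred,
                         "residual": row["mean"] - pred,
                         "overestimates_10pct": pred > row["mean"] * 1.10})
        frames.append(pd.DataFrame(rows))
    if not frames:
        raise ValueError("no D_max or robustness results to overlay")
    return pd.concat(frames, ignore_index=True)
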