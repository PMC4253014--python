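"""The simulate-and-test experimental-design engine.

Sweeps a grid of candidate designs (replicates NR x sequencing depth ND x
test), runs repeated simulate -> normalize -> test -> evaluate pipelines in
each cell, and summarizes where performance saturates and which affordable
design meets a target.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dat import run_dat
from .evaluation import evaluate_result
from .generators import SimConfig, simulate
from .profiles import AbundanceProfile, PerturbationSpec, apply_perturbation

__all__ = ["DesignGrid", "DesignReport", "grid_evaluate", "saturation_point", "recommend"]


@dataclass
class DesignGrid:
    """Candidate designs plus the fixed simulation template."""

    profile: AbundanceProfile
    perturbation: PerturbationSpec
    sim_template: SimConfig
    nr_values: list[int] = field(default_factory=lambda: [2, 5])
    nd_values: list[float] = field(default_factory=lambda: [100.0, 500.0])
    dat_names: list[str] = field(default_factory=lambda: ["nb_exact"])
    normalization: str = "mode"
    n_sims: int = 10
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        if not self.nr_values or not self.nd_values or not self.dat_names:
            raise ValueError("grids must be non-empty")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


@dataclass
class DesignReport:
    """Per-cell metric summaries plus saturation points and cell failures."""

    table: pd.DataFrame  # one row per (NR, ND, DAT)
    saturation_nr: dict  # (ND, DAT) -> saturating NR
    saturation_nd: dict  # (NR, DAT) -> saturating ND
    failed_cells: list = field(default_factory=list)


def derive_seed(*parts) -> int:
    """Deterministic 31-bit seed from heterogeneous parts (CRC32 of their repr)."""
    text = ":".join(repr(p) for p in parts)
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def run_cell(grid: DesignGrid, nr: int, nd: float, dat: str, seed: int) -> dict:
    """One simulate -> normalize -> test -> evaluate pipeline."""
    pair = apply_perturbation(grid.profile, grid.perturbation, seed=derive_seed(seed, "pert"))
    cfg = replace(grid.sim_template, NR=nr, ND=nd, seed=derive_seed(seed, "sim"))
    cm = simulate(pair, cfg)
    options = {}
    if dat == "nb_exact" and nr < 2:
        # single replicates cannot yield a dispersion estimate; fall back to
        # the design's own simulation dispersion
        options["dispersion"] = float(np.mean(grid.sim_template.SV))
    res = run_dat(dat, cm, normalization=grid.normalization, **options)
    ev = evaluate_result(res, pair, q=grid.fdr_q)
    return {
        "auc": ev.auc,
        "sensitivity": ev.sensitivity_at[grid.fdr_q],
        "actual_fdr": ev.actual_fdr_at[grid.fdr_q],
    }


def grid_evaluate(grid: DesignGrid, seed: int = 0) -> DesignReport:
    """Run every (NR, ND, DAT) cell ``n_sims`` times with independently derived seeds."""
    rows = []
    failed = []
    for nr in grid.nr_values:
        for nd in grid.nd_values:
            for dat in grid.dat_names:
                metrics = []
                for k in range(grid.n_sims):
                    cell_seed = derive_seed(seed, nr, nd, dat, k)
                    try:
                        metrics.append(run_cell(grid, nr, nd, dat, cell_seed))
                    except Exception as exc:  # noqa: BLE001 - cell isolation
                        failed.append((nr, nd, dat, k, str(exc)))
                if not metrics:
                    continue
                df = pd.DataFrame(metrics)
                row = {"NR": nr, "ND": nd, "DAT": dat, "n_sims": len(metrics)}
                for m in ("auc", "sensitivity", "actual_fdr"):
                    row[f"{m}_mean"] = float(df[m].mean())
                    row[f"{m}_sd"] = float(df[m].std(ddof=1)) if len(metrics) > 1 else float("nan")
                rows.append(row)
    table = pd.DataFrame(rows)
    sat_nr, sat_nd = {}, {}
    if not table.empty:
        for (nd, dat), sub in table.groupby(["ND", "DAT"]):
            series = list(zip(sub["NR"], sub["auc_mean"]))
            sat_nr[(nd, dat)] = saturation_point(series)
        for (nr, dat), sub in table.groupby(["NR", "DAT"]):
            series = list(zip(sub["ND"], sub["auc_mean"]))
            sat_nd[(nr, dat)] = saturation_point(series)
    return DesignReport(table=table, saturation_nr=sat_nr, saturation_nd=sat_nd,
                        failed_cells=failed)


def saturation_point(metric_series) -> float:
    """Smallest x whose metric value is within 5% of the maximum observed.

    ``metric_series`` is an iterable of (x, value) pairs; returns the
    smallest x with value >= 0.95 * max(values).
    """
    pairs = sorted(metric_series)
    if not pairs:
        raise ValueError("metric series must be non-empty")
    cutoff = 0.95 * max(v for _, v in pairs)
    for x, v in pairs:
        if v >= cutoff:
            return x
    return pairs[-1][0]  # unreachable: the argmax always qualifies


def recommend(report: DesignReport, target_auc: float = 0.95, cost=None):
    """Cheapest design cell whose mean AUC meets the target.

    Cost defaults to NR * ND (total data generated); ties prefer smaller
    NR, then smaller ND, then the lexicographically first test name.
    """
    if cost is None:
        cost = lambda nr, nd: nr * nd  # noqa: E731
    table = report.table
    ok = table[table["auc_mean"] >= target_auc]
    if ok.empty:
        best = table["auc_mean"].max() if not table.empty else float("nan")
        raise ValueError(f"no design meets AUC target {target_auc}; best achieved {best:.4f}")
    ranked = sorted(
        ok.itertuples(index=False),
        key=lambda r: (cost(r.NR, r.ND), r.NR, r.ND, r.DAT),
    )
    top = ranked[0]
    return int(top.NR), float(top.ND), str(top.DAT)
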