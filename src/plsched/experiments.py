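"""Experiment drivers: trade-off curves, heatmap validation, convergence.

These regenerate the headline analyses around the core method: metric
trade-off curves comparing GA-optimised against time-uniform schedules over
a range of sample counts, a parameter-grid heatmap validating that the
optimised schedule outperforms the uniform one in the neighbourhood of the
design scenarios, and convergence summaries of GA histories.  Every driver
is a pure function of (configuration, seed); CSV/JSON tables are the tested
interface and plotting is an optional extra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ga import GAConfig, GAResult, GenerationRecord, T_MAX, repair, run
from .model import CASE_NS_MIN, NS_MAX, ParameterScenario, scenario
from .profiles import plb_crit_noise_free


def case_ns_range(case: int) -> range:
    """Sample counts explored per case: 3..20, 4..20 and 5..20 for cases 1-3."""
    return range(CASE_NS_MIN[case], NS_MAX + 1)


def uniform_schedule(n_s: int) -> np.ndarray:
    """The naive comparator: n_s equi-distant samples on [0, 600], repaired
    so none falls in the post-bolus exclusion window."""
    if n_s < 2:
        raise ValueError("a uniform schedule needs at least 2 samples")
    return repair(np.linspace(0.0, T_MAX, n_s))


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % 2**31)


def worst_case_metric(scenarios, times, **kw) -> float:
    """Max PLB_crit of a schedule across scenarios (minimax comparator)."""
    return max(plb_crit_noise_free(s, times, **kw) for s in scenarios)


def tradeoff(case: int, *, policy: str = "minimax",
             scenario_numbers=(1, 2, 3), ns_values=None,
             n_generations: int = 150, n_organisms: int = 100,
             mutation_sigma: float = 16.0, seed: int = 0,
             keep_results: bool = False) -> pd.DataFrame | tuple:
    """Optimised-vs-uniform metric trade-off across sample counts.

    ``policy`` is "minimax" (one GA over all scenarios, worst-case metric)
    or "single" (one GA per scenario; rows carry the scenario number).
    Returns a DataFrame with columns (case, policy, scenario, n_s,
    plb_uniform, plb_optimised, percent_reduction); with
    ``keep_results=True`` also the list of GAResult objects.
    """
    if policy not in ("minimax", "single"):
        raise ValueError("policy must be 'minimax' or 'single'")
    ns_values = list(case_ns_range(case)) if ns_values is None else list(ns_values)
    scens = [scenario(case, n) for n in scenario_numbers]
    rows, results = [], []
    groups = ([("minimax", scens)] if policy == "minimax"
              else [(str(n), [scenario(case, n)]) for n in scenario_numbers])
    for label, group in groups:
        for n_s in ns_values:
            cfg = GAConfig(scenarios=tuple(group), n_s=n_s,
                           n_organisms=n_organisms,
                           n_generations=n_generations,
                           mutation_sigma=mutation_sigma,
                           seed=_derived_seed(seed, case, n_s,
                                              0 if label == "minimax"
                                              else int(label)))
            res = run(cfg)
            uni = worst_case_metric(group, uniform_schedule(n_s))
            opt = res.best_metric
            red = (100.0 * (uni - opt) / uni
                   if math.isfinite(uni) and uni > 0 and math.isfinite(opt)
                   else float("nan"))
            rows.append(dict(case=case, policy=policy, scenario=label,
                             n_s=n_s, plb_uniform=uni, plb_optimised=opt,
                             percent_reduction=red))
            if keep_results:
                results.append(res)
    df = pd.DataFrame(rows)
    return (df, results) if keep_results else df


@dataclass
class HeatmapGrid:
    """Optimised/uniform metric ratio over a (k, U_N) parameter grid."""

    k_values: np.ndarray
    u_n_values: np.ndarray
    ratio: np.ndarray            # (len(k), len(u_n)); NaN where non-finite
    scenario_points: list[tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, k in enumerate(self.k_values):
            for j, u in enumerate(self.u_n_values):
                recs.append(dict(k=k, u_n=u, ratio=self.ratio[i, j]))
        return pd.DataFrame(recs)


def heatmap_validation(case: int, optimised: np.ndarray,
                       uniform: np.ndarray, *, n_grid: int = 15,
                       k_range: tuple[float, float] | None = None,
                       u_n_range: tuple[float, float] | None = None,
                       v: float = 400.0) -> HeatmapGrid:
    """Ratio of optimised to uniform PLB_crit over a (k, U_N) grid.

    Defaults: a log-spaced n_grid x n_grid lattice spanning half the
    smallest to twice the largest scenario value of each parameter, with V
    (and beta, per case) at the scenario values.  Ratios below 1 mean the
    optimised schedule outperforms the comparator at that parameter point.
    """
    from .model import CASE_BETA, CASE_FREE, PARAM_NAMES, SCENARIO_TABLE

    ks = [row[0] for row in SCENARIO_TABLE.values()]
    us = [row[1] for row in SCENARIO_TABLE.values()]
    k_range = k_range or (0.5 * min(ks), 2.0 * max(ks))
    u_n_range = u_n_range or (0.5 * min(us), 2.0 * max(us))
    k_values = np.geomspace(*k_range, n_grid)
    u_n_values = np.geomspace(*u_n_range, n_grid)
    mask = tuple(name in CASE_FREE[case] for name in PARAM_NAMES)
    ratio = np.full((n_grid, n_grid), np.nan)
    for i, k in enumerate(k_values):
        for j, u in enumerate(u_n_values):
            try:
                scen = ParameterScenario(k=k, u_n=u, v=v,
                                         beta=CASE_BETA[case], free_mask=mask)
            except ValueError:
                continue
            m_opt = plb_crit_noise_free(scen, optimised)
            m_uni = plb_crit_noise_free(scen, uniform)
            if math.isfinite(m_opt) and math.isfinite(m_uni) and m_uni > 0:
                ratio[i, j] = m_opt / m_uni
    return HeatmapGrid(k_values=k_values, u_n_values=u_n_values, ratio=ratio,
                       scenario_points=[(r[0], r[1])
                                        for r in SCENARIO_TABLE.values()])


def convergence_report(history: list[GenerationRecord]) -> pd.DataFrame:
    """Per-generation best/median/worst metrics and the settling point.

    The ``converged_after`` attribute on the returned frame gives the first
    generation from which the best schedule no longer changes.
    """
    if not history:
        raise ValueError("history must be non-empty")
    rows = []
    for g, rec in enumerate(history):
        finite = rec.worst_case_metrics[np.isfinite(rec.worst_case_metrics)]
        rows.append(dict(
            generation=g,
            best_metric=rec.best_metric,
            median_metric=float(np.median(finite)) if finite.size else np.nan,
            worst_finite_metric=float(finite.max()) if finite.size else np.nan,
            n_nonfinite=int(np.sum(~np.isfinite(rec.worst_case_metrics)))))
    df = pd.DataFrame(rows)
    last = history[-1].best_schedule
    converged_after = len(history) - 1
    for g in range(len(history) - 1, -1, -1):
        if history[g].best_schedule.shape == last.shape and \
                np.allclose(history[g].best_schedule, last):
            converged_after = g
        else:
            break
    df.attrs["converged_after"] = converged_after
    return df


def history_frame(result: GAResult) -> pd.DataFrame:
    """Flat per-(generation, rank) table of a GA history, for CSV export."""
    rows = []
    for g, rec in enumerate(result.history):
        for rank, (times, worst) in enumerate(
                zip(rec.ranked_schedules, rec.worst_case_metrics), start=1):
            row = dict(generation=g, organism_rank=rank,
                       worst_case_metric=worst)
            row.update({f"t{i}": t for i, t in enumerate(times)})
            rows.append(row)
    return pd.DataFrame(rows)


def plot_convergence(report: pd.DataFrame, path) -> None:
    """Best-metric trace over generations (optional matplotlib artifact)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(report["generation"], report["best_metric"], "-o", ms=3,
            label="best organism")
    ax.plot(report["generation"], report["median_metric"], color="grey",
            lw=1, label="population median")
    ax.set_xlabel("generation")
    ax.set_ylabel("worst-case PLB$_{crit}$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tradeoff(df: pd.DataFrame, path) -> None:
    """Optimised vs uniform metric against sample count."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, sub in df.groupby("scenario"):
        ax.plot(sub["n_s"], sub["plb_uniform"], "--", label=f"{label} uniform")
        ax.plot(sub["n_s"], sub["plb_optimised"], "-", label=f"{label} optimised")
    ax.set_xlabel("number of samples $N_s$")
    ax.set_ylabel("PLB$_{crit}$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(grid: HeatmapGrid, path) -> None:
    """Ratio heatmap with scenario markers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    pc = ax.pcolormesh(grid.u_n_values, grid.k_values, grid.ratio,
                       shading="nearest", cmap="viridis")
    for k, u in grid.scenario_points:
        ax.plot(u, k, "ko")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("$U_N$")
    ax.set_ylabel("$k$")
    fig.colorbar(pc, ax=ax, label="optimised / uniform PLB$_{crit}$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
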