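"""Stress-sweep simulation experiments.

Reproduces the central in-silico experiment: draw a population of 1000
individuals (500 per sex) under a stress scenario, randomly partition it
into disjoint mating groups of two females and two males, resolve
reproduction in every group, and compute the opportunity for selection per
sex from the fitness of all individuals pooled across groups.  Sweeps vary
the condition SD ("stress") over a grid for the scenarios both / female
only / male only and average I_f, I_m and log(I_m/I_f) over replicates.

Group formation is a uniform random partition, re-drawn each replicate.
In sex-limited sweeps the unstressed sex keeps a small nonzero baseline SD
(default 0.05) so its opportunity for selection stays defined and positive
on the log-ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from opsel.condition import Population, StressScenario, draw_conditions, make_population
from opsel.metrics import opportunity_for_selection
from opsel.reproduction import GroupFitness, MatingGroup, ReproductionParams, group_reproduction

DEFAULT_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))
DEFAULT_BASELINE_SIGMA = 0.05


@dataclass
class SweepResult:
    """Replicate-averaged outcome at one (scenario, stress) grid point."""

    scenario: str
    stress: float
    mean_I_f: float
    mean_I_m: float
    mean_log_ratio: float
    replicates: int
    I_f_values: np.ndarray = field(repr=False)
    I_m_values: np.ndarray = field(repr=False)
    log_ratio_values: np.ndarray = field(repr=False)


def _group_fitness_vectors(
    pop: Population, params: ReproductionParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a population into random 2+2 groups and resolve them.

    Returns per-individual fitness vectors (females, males) aligned with
    the population's condition arrays.
    """
    n = pop.n_per_sex
    f_order = rng.permutation(n)
    m_order = rng.permutation(n)
    wf = np.empty(n)
    wm = np.empty(n)
    for k in range(n // 2):
        fi, fj = f_order[2 * k], f_order[2 * k + 1]
        mi, mj = m_order[2 * k], m_order[2 * k + 1]
        g = MatingGroup(
            cf1=pop.female_conditions[fi],
            cf2=pop.female_conditions[fj],
            cm1=pop.male_conditions[mi],
            cm2=pop.male_conditions[mj],
        )
        fit: GroupFitness = group_reproduction(g, params)
        wf[fi], wf[fj] = fit.wf1, fit.wf2
        wm[mi], wm[mj] = fit.wm1, fit.wm2
    return wf, wm


def simulate_replicate(
    scenario: StressScenario,
    params: ReproductionParams,
    n_per_sex: int,
    seed,
) -> tuple[float, float]:
    """One replicate: population draw, random grouping, (I_f, I_m).

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.
    """
    if not isinstance(n_per_sex, (int, np.integer)) or n_per_sex < 2 or n_per_sex % 2:
        raise ValueError(f"n_per_sex must be a positive even integer, got {n_per_sex!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    f_ss, m_ss, part_ss = ss.spawn(3)
    females = draw_conditions(n_per_sex, scenario.sigma_f, np.random.default_rng(f_ss))
    males = draw_conditions(n_per_sex, scenario.sigma_m, np.random.default_rng(m_ss))
    pop = Population(females, males, seed=0, scenario=scenario)
    rng = np.random.default_rng(part_ss)
    wf, wm = _group_fitness_vectors(pop, params, rng)
    if np.all(wf == wf[0]) and np.all(wm == wm[0]):
        return 0.0, 0.0  # fully degenerate population (e.g. zero stress)
    return opportunity_for_selection(wf), opportunity_for_selection(wm)


def _scenario_at(label: str, stress: float, baseline_sigma: float) -> StressScenario:
    if label == "both":
        return StressScenario("both", sigma_f=stress, sigma_m=stress)
    if label == "female_only":
        return StressScenario("female_only", sigma_f=stress, sigma_m=baseline_sigma)
    if label == "male_only":
        return StressScenario("male_only", sigma_f=baseline_sigma, sigma_m=stress)
    if label == "none":
        return StressScenario("none", sigma_f=baseline_sigma, sigma_m=baseline_sigma)
    raise ValueError(f"unknown scenario label {label!r}")


def run_sweep(
    scenarios,
    stress_grid,
    params: ReproductionParams | None = None,
    n_per_sex: int = 500,
    replicates: int = 20,
    seed: int = 0,
    baseline_sigma: float = DEFAULT_BASELINE_SIGMA,
) -> list[SweepResult]:
    """Sweep stress scenarios over a grid of condition SDs.

    For scenario ``both`` the stress value sets both sigmas; for
    ``female_only`` / ``male_only`` it sets one sigma while the other sex
    keeps ``baseline_sigma``.  Each (scenario, stress, replicate) cell
    gets an independent sub-seed derived from ``seed``.
    """
    if params is None:
        params = ReproductionParams()
    stress_grid = list(stress_grid)
    scenarios = list(scenarios)
    if not stress_grid or not scenarios:
        raise ValueError("scenarios and stress_grid must be nonempty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    root = np.random.SeedSequence(seed)
    results: list[SweepResult] = []
    for label in scenarios:
        for stress in stress_grid:
            scen = _scenario_at(label, float(stress), baseline_sigma)
            cell_ss = np.random.SeedSequence(
                entropy=root.entropy,
                spawn_key=(scenarios.index(label), stress_grid.index(stress)),
            )
            rep_seeds = cell_ss.spawn(replicates)
            I_f = np.empty(replicates)
            I_m = np.empty(replicates)
            for r, rs in enumerate(rep_seeds):
                I_f[r], I_m[r] = simulate_replicate(scen, params, n_per_sex, rs)
            with np.errstate(divide="ignore", invalid="ignore"):
                log_ratio = np.log(I_m / I_f)
            results.append(
                SweepResult(
                    scenario=label,
                    stress=float(stress),
                    mean_I_f=float(I_f.mean()),
                    mean_I_m=float(I_m.mean()),
                    mean_log_ratio=float(np.mean(log_ratio)),
                    replicates=replicates,
                    I_f_values=I_f,
                    I_m_values=I_m,
                    log_ratio_values=log_ratio,
                )
            )
    return results


def summarize_sweep(results) -> pd.DataFrame:
    """Tidy per-replicate table: scenario, stress, rep, I_f, I_m, log_ratio."""
    rows = []
    for res in results:
        for r in range(res.replicates):
            rows.append(
                {
                    "scenario": res.scenario,
                    "stress": res.stress,
                    "rep": r,
                    "I_f": res.I_f_values[r],
                    "I_m": res.I_m_values[r],
                    "log_ratio": res.log_ratio_values[r],
                }
            )
    return pd.DataFrame(rows)


def plot_sweep(results, path) -> None:
    """Two-panel summary: per-sex I and the logged sex ratio vs stress."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summarize_sweep(results)
    agg = df.groupby(["scenario", "stress"], as_index=False).mean(numeric_only=True)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for label, sub in agg.groupby("scenario"):
        ax1.plot(sub["stress"], sub["I_f"], "o-", label=f"{label} I_f")
        ax1.plot(sub["stress"], sub["I_m"], "s--", label=f"{label} I_m")
        ax2.plot(sub["stress"], sub["log_ratio"], "o-", label=label)
    ax1.set_xlabel("stress (condition SD)")
    ax1.set_ylabel("opportunity for selection")
    ax2.set_xlabel("stress (condition SD)")
    ax2.set_ylabel("log(I_m / I_f)")
    ax2.axhline(0.0, color="grey", lw=0.8)
    ax1.legend(fontsize=7)
    ax2.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
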