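"""Batch simulation studies: recovery of simulated trees by the ILP.

Each run draws seeded instances from the generator, solves them with
:func:`cnphylo.cnt_ilp.solve_cnt`, and records the inferred cost, the
simulated cost, the solve status and the normalized Robinson–Foulds
distance between the inferred and generating topologies. Summaries follow
the two headline readouts of such studies: the median topology distance,
and the fraction of instances whose inferred (maximum-parsimony) cost does
not exceed the cost of the events actually drawn.

Instance seeds are derived from one base seed through
``numpy.random.SeedSequence`` so a whole study is reproducible from a
single integer.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from statistics import median

import numpy as np

from .cnt_ilp import solve_cnt
from .evaluate import normalized_rf, topology_from_tree
from .simulate import SimulationConfig, generate_instance

__all__ = ["InstanceResult", "run_batch", "median_rf", "cost_recovery_percent"]


@dataclass
class InstanceResult:
    config: SimulationConfig
    e: int
    simulated_cost: int
    inferred_cost: int
    status: str
    rf: float


def _instance_seed(base_seed: int, idx: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(idx)])
    return int(ss.generate_state(1)[0] % 2**31)


def run_batch(grid: list[tuple[int, int, int, float]], reps: int, seed: int,
              time_limit: float = 60.0, budget_s: float | None = None,
              min_instances: int = 0) -> list[InstanceResult]:
    """Simulate and solve one instance per (k, n, m, rho) combination and rep.

    ``time_limit`` bounds each of the two MILP solves per instance. When a
    wall-clock ``budget_s`` is given, no new instance is started after it is
    exhausted (but at least ``min_instances`` are always run); results
    report whichever instances completed.
    """
    t0 = time.monotonic()
    results: list[InstanceResult] = []
    idx = 0
    for rep in range(reps):
        for (k, n, m, rho) in grid:
            idx += 1
            if (
                budget_s is not None
                and len(results) >= min_instances
                and time.monotonic() - t0 > budget_s
            ):
                continue
            cfg = SimulationConfig(k, n, m, rho, _instance_seed(seed, idx))
            sim = generate_instance(cfg)
            sol = solve_cnt(sim.instance, time_limit=time_limit)
            rf = normalized_rf(
                topology_from_tree(sol.tree), topology_from_tree(sim.truth)
            )
            results.append(
                InstanceResult(cfg, sim.instance.e, sim.simulated_cost,
                               sol.cost, sol.status, rf)
            )
    return results


def median_rf(results: list[InstanceResult], optimal_only: bool = True) -> float:
    """Median normalized RF distance, by default over proven-optimal solves."""
    vals = [r.rf for r in results if r.status == "optimal" or not optimal_only]
    if not vals:
        raise ValueError("no instances to summarize")
    return float(median(vals))


def cost_recovery_percent(results: list[InstanceResult],
                          optimal_only: bool = True) -> float:
    """Percent of instances whose inferred cost is at most the simulated cost."""
    use = [r for r in results if r.status == "optimal" or not optimal_only]
    if not use:
        raise ValueError("no instances to summarize")
    good = sum(1 for r in use if r.inferred_cost <= r.simulated_cost)
    return 100.0 * good / len(use)
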