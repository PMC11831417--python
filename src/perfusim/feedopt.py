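"""Dynamic media-exchange optimization.

The decision variable is the exchange-rate (VVD) value at six fixed knot
times; candidate schedules are simulated with the PID bleed controller in
the loop and a qp predictor driving the titer state, and scored by the
product captured in the harvest stream over the production window,
``integral of IgG * Fh dt``.  A soft constraint keeps the viable density
from sagging more than 15% below the setpoint once the culture has reached
it — an "optimal" schedule that starves the culture is not a schedule a
process engineer would run.

Candidates are evaluated in vectorized blocks (one simulation pass per
swarm iteration), which makes the exhaustive coarse-grid oracle used in
testing affordable as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .kinetics import KineticParams
from .pso import PsoConfig, pso_minimize
from .simulate import (
    BleedController,
    FeedSchedule,
    ProcessRecipe,
    SolverSettings,
    Trajectory,
    simulate_batch,
)

__all__ = [
    "DEFAULT_KNOTS",
    "ScheduleProblem",
    "ScheduleReport",
    "evaluate_schedules",
    "optimize_schedule",
    "coarse_grid_search",
]

#: default knot times (days): initial growth-phase rate plus five
#: production-phase adjustment points
DEFAULT_KNOTS = (0.0, 4.0, 6.0, 9.0, 13.0, 17.0)

_INFEASIBLE = -1e12


@dataclass(frozen=True)
class ScheduleProblem:
    """Feed-optimization problem description."""

    params: KineticParams
    recipe: ProcessRecipe
    qp_model: object  # callable (..., 7) features -> qp
    controller: BleedController | None = None
    knot_times: tuple[float, ...] = DEFAULT_KNOTS
    bounds: tuple[float, float] = (0.5, 2.5)
    window: tuple[float, float] = (4.0, 21.0)
    interpolation: str = "piecewise_linear"
    vcd_band: float = 0.15
    penalty_weight: float = 1e3
    settings: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not 0 <= lo < hi:
            raise ValueError("bounds must satisfy 0 <= lower < upper")
        t0, t1 = self.window
        if not (t0 < t1 <= self.recipe.t_end):
            raise ValueError("window must fit inside the recipe horizon")

    def schedule_recipe(self) -> ProcessRecipe:
        feed = FeedSchedule(
            mode="vvd_knots",
            knot_times=self.knot_times,
            knot_values=tuple([1.0] * len(self.knot_times)),
            interpolation=self.interpolation,
        )
        return replace(self.recipe, feed=feed)


@dataclass
class ScheduleReport:
    """Outcome of a schedule optimization."""

    knot_times: tuple[float, ...]
    best_values: np.ndarray
    best_objective: float
    baselines: dict[float, float]
    trajectory: Trajectory
    minimal_bleeding: bool
    constraint_ok: bool
    trace: np.ndarray
    seed: int

    def summary(self) -> str:
        knots = "  ".join(
            f"d{t:g}:{v:.2f}" for t, v in zip(self.knot_times,
                                              self.best_values)
        )
        base = "  ".join(
            f"{k:g} VVD -> {v:.1f}" for k, v in self.baselines.items()
        )
        return "\n".join(
            [
                "Feed-schedule optimization",
                f"  best harvested product : {self.best_objective:.2f}",
                f"  schedule (VVD)         : {knots}",
                f"  constant baselines     : {base}",
                f"  minimal bleeding       : {self.minimal_bleeding}",
                f"  VCD band respected     : {self.constraint_ok}",
            ]
        )


def _window_mask(t: np.ndarray, window) -> np.ndarray:
    return (t >= window[0]) & (t <= window[1])


def _harvest_and_violation(problem: ScheduleProblem, traj: Trajectory):
    """Windowed harvested product and VCD-band violation per candidate."""
    t = traj.t
    mask = _window_mask(t, problem.window)
    xv = traj.states[..., 0]
    igg = traj.states[..., 6]
    rate = igg * traj.fh
    if rate.ndim == 1:
        rate = rate[:, None]
        xv = xv[:, None]
    harvested = np.trapezoid(rate[mask], t[mask], axis=0)

    floor = (1.0 - problem.vcd_band) * problem.recipe.vcd_setpoint
    reached = np.cumsum(xv >= floor, axis=0) > 0
    active = reached & mask[:, None]
    sag = np.where(active, np.maximum(floor - xv, 0.0), 0.0)
    violation = np.trapezoid(sag, t, axis=0)

    bad = ~np.isfinite(harvested) | (np.min(xv, axis=0) < 0)
    return harvested, violation, bad


def evaluate_schedules(
    problem: ScheduleProblem, values: np.ndarray
) -> np.ndarray:
    """Penalized harvested product for candidate knot values (C, n_knots).

    Infeasible candidates (non-finite simulation) score ``-1e12``; VCD-band
    violations are charged ``penalty_weight`` per 1e6 cells/mL/day of sag.
    Returns an array of shape ``(C,)`` (scalar input allowed).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    lo, hi = problem.bounds
    if np.any(values < lo - 1e-9) or np.any(values > hi + 1e-9):
        raise ValueError("candidate schedule outside bounds")
    recipe = problem.schedule_recipe()
    ctrl = problem.controller or BleedController(
        setpoint=recipe.vcd_setpoint
    )
    traj = simulate_batch(
        problem.params, recipe, controller=ctrl,
        qp_model=problem.qp_model, settings=problem.settings,
        feed_values=values,
    )
    harvested, violation, bad = _harvest_and_violation(problem, traj)
    score = harvested - problem.penalty_weight * violation
    return np.where(bad, _INFEASIBLE, score)


def _constant_baselines(
    problem: ScheduleProblem, rates: Sequence[float]
) -> dict[float, float]:
    values = np.array(
        [[r] * len(problem.knot_times) for r in rates], dtype=float
    )
    scores = evaluate_schedules(problem, values)
    return {float(r): float(s) for r, s in zip(rates, scores)}


def optimize_schedule(
    problem: ScheduleProblem,
    pso: PsoConfig | None = None,
    baseline_rates: Sequence[float] = (1.0, 1.5, 2.0),
) -> ScheduleReport:
    """Search knot values maximizing windowed harvested product.

    The swarm is warm-started with the constant-rate baselines, so the
    returned schedule can never score below the best of them.
    """
    pso = pso or PsoConfig(n_particles=20, n_iter=(30, 10))
    n = len(problem.knot_times)
    lo, hi = problem.bounds
    lb, ub = np.full(n, lo), np.full(n, hi)

    baselines = _constant_baselines(problem, baseline_rates)
    feasible_rates = [
        r for r in baseline_rates
        if np.clip(r, lo, hi) == r
    ]
    warm = np.array([[r] * n for r in feasible_rates], dtype=float)

    def neg(values):
        return -evaluate_schedules(problem, values)

    x_best, f_best, trace = pso_minimize(
        neg, lb, ub, pso, x0=warm if warm.size else None
    )
    if -f_best <= _INFEASIBLE:
        raise RuntimeError("every evaluated schedule was infeasible")

    recipe = problem.schedule_recipe()
    ctrl = problem.controller or BleedController(
        setpoint=recipe.vcd_setpoint
    )
    traj = simulate_batch(
        problem.params, recipe, controller=ctrl,
        qp_model=problem.qp_model, settings=problem.settings,
        feed_values=x_best[None, :],
    ).select(0)
    _, violation, _ = _harvest_and_violation(problem, traj)
    mask = _window_mask(traj.t, problem.window)
    minimal_bleed = bool(
        np.max(traj.fb[mask]) < 0.01 * np.mean(traj.ff[mask])
    )
    return ScheduleReport(
        knot_times=problem.knot_times,
        best_values=x_best,
        best_objective=float(-f_best),
        baselines=baselines,
        trajectory=traj,
        minimal_bleeding=minimal_bleed,
        constraint_ok=bool(violation[0] == 0.0),
        trace=trace,
        seed=pso.seed,
    )


def coarse_grid_search(
    problem: ScheduleProblem,
    levels: Sequence[float] | None = None,
    block: int = 128,
):
    """Exhaustively score a full factorial grid of knot values.

    Default levels are the bound edges and midpoint (3^n_knots candidates).
    Returns ``(best_values, best_score, all_scores)``; used as an oracle
    lower bound for the swarm optimizer.
    """
    lo, hi = problem.bounds
    if levels is None:
        levels = (lo, 0.5 * (lo + hi), hi)
    n = len(problem.knot_times)
    grids = np.meshgrid(*([np.asarray(levels, dtype=float)] * n),
                        indexing="ij")
    candidates = np.stack([g.ravel() for g in grids], axis=-1)
    scores = np.empty(candidates.shape[0])
    for start in range(0, candidates.shape[0], block):
        chunk = candidates[start : start + block]
        scores[start : start + chunk.shape[0]] = evaluate_schedules(
            problem, chunk
        )
    best = int(np.argmax(scores))
    return candidates[best], float(scores[best]), scores
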