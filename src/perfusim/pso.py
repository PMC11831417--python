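"""Two-stage global-best particle swarm optimizer.

A plain constricted PSO with per-dimension velocity clamping, run in two
stages: a coarse stage with a large velocity cap explores the box, then a
fine stage re-seeded around the coarse optimum hones in with a reduced cap.
The objective is evaluated on the whole swarm at once (``fn`` receives an
``(n_particles, n_dim)`` array and returns ``(n_particles,)``), which lets
callers vectorize expensive simulations across particles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PsoConfig", "pso_minimize"]


@dataclass(frozen=True)
class PsoConfig:
    n_particles: int = 40
    n_iter: tuple[int, int] = (60, 60)
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    vel_frac: tuple[float, float] = (0.2, 0.05)
    #: independent coarse-stage swarms; the best feeds the fine stage.
    #: cheap insurance against a single swarm collapsing into a local basin
    restarts: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if min(self.n_iter) < 1 or min(self.vel_frac) <= 0:
            raise ValueError("invalid PSO stage settings")
        if self.restarts < 1:
            raise ValueError("need at least one coarse-stage swarm")


def _run_stage(
    fn, lb, ub, config, rng, n_iter, vel_cap, init_x, trace
):
    n, d = init_x.shape
    span = ub - lb
    x = init_x.copy()
    v = rng.uniform(-1.0, 1.0, size=(n, d)) * vel_cap
    f = np.asarray(fn(x), dtype=float)
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
    trace.append(gbest_f)

    for _ in range(n_iter):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        v = (
            config.inertia * v
            + config.cognitive * r1 * (pbest_x - x)
            + config.social * r2 * (gbest_x[None, :] - x)
        )
        v = np.clip(v, -vel_cap, vel_cap)
        x = np.clip(x + v, lb, ub)
        f = np.asarray(fn(x), dtype=float)
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
        trace.append(gbest_f)
    return gbest_x, gbest_f


def pso_minimize(
    fn,
    lower,
    upper,
    config: PsoConfig | None = None,
    x0: np.ndarray | None = None,
):
    """Minimize ``fn`` over a box with two-stage PSO.

    ``x0`` optionally supplies warm-start particles (rows) injected into the
    initial swarm of stage 1.  Returns ``(x_best, f_best, trace)`` where
    ``trace`` is the best objective after every iteration of both stages.
    """
    config = config or PsoConfig()
    lb = np.asarray(lower, dtype=float)
    ub = np.asarray(upper, dtype=float)
    if lb.shape != ub.shape or np.any(lb >= ub):
        raise ValueError("bounds must satisfy lower < upper elementwise")
    d = lb.size
    rng = np.random.default_rng(config.seed)
    span = ub - lb
    trace: list[float] = []

    best_x, best_f = None, np.inf
    for start in range(config.restarts):
        init = lb + rng.random((config.n_particles, d)) * span
        if x0 is not None and start == 0:
            warm = np.atleast_2d(np.asarray(x0, dtype=float))
            k = min(warm.shape[0], config.n_particles)
            init[:k] = np.clip(warm[:k], lb, ub)
        sx, sf = _run_stage(
            fn, lb, ub, config, rng, config.n_iter[0],
            config.vel_frac[0] * span, init, trace,
        )
        if sf < best_f:
            best_x, best_f = sx, sf

    # stage 2: local swarm around the coarse optimum, reduced velocity cap
    init2 = best_x[None, :] + 0.05 * span * rng.standard_normal(
        (config.n_particles, d)
    )
    init2 = np.clip(init2, lb, ub)
    init2[0] = best_x
    x2, f2 = _run_stage(
        fn, lb, ub, config, rng, config.n_iter[1],
        config.vel_frac[1] * span, init2, trace,
    )
    if f2 < best_f:
        best_x, best_f = x2, f2
    # running best across restarts and stages: monotone by construction
    return best_x, best_f, np.minimum.accumulate(np.asarray(trace))
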