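"""Kinetic parameter estimation from batch records.

Calibration runs the model in *tracking* configuration: measured feed,
temperature and pH are replayed, and the bleed controller's setpoint
follows the measured VCD, so the bleed flow the model needs in order to
stay on the data can be compared with the bleed the plant actually used.
Residuals of VCD, viability and bleed (each normalized by its measured
range) enter a squared-autocovariance objective over lags 0..L: the lag-0
term penalizes raw error magnitude while the positive lags penalize
structured (autocorrelated) misfit that white measurement noise cannot
explain.  The objective is minimized by two-stage particle swarm
optimization inside box bounds.

The VCD residual is included alongside bleed and viability because the
bleed stream only carries growth information while the controller is
actively bleeding; in operating regimes where the model holds the culture
below setpoint (bleed at zero), VCD misfit is the only signal that can
identify the growth parameters.

A scale-transfer refit (`fit_sieving`) re-estimates only the inhibition
threshold, toxicity factor and the two CRD retention fractions on data from
a different reactor scale, with all growth/lysis parameters frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import BatchRecord
from .kinetics import KineticParams, QuadraticEffect
from .pso import PsoConfig, pso_minimize
from .simulate import BleedController, SolverSettings, simulate_tracking
from .synth import PARAM_BOUNDS, SIEVING_BOUNDS

__all__ = [
    "FitResult",
    "nmse",
    "r_squared",
    "residual_objective",
    "track_record",
    "pso_fit",
    "fit_sieving",
]

#: order of the free parameters in the default calibration vector
FREE_PARAMS = (
    "mu_max", "kd", "kt", "kl", "K_I_phib", "theta_temp", "theta_ph",
)
SIEVING_FREE = ("K_I_phib", "kt", "kls", "kbh")

_PENALTY = 1e6
_AUTOCOV_LAGS = 5
_DEFAULT_WEIGHTS = {"xv": 1.0, "viability": 1.0, "bleed": 1.0}


# --------------------------------------------------------------------------
# fit metrics
# --------------------------------------------------------------------------

def r_squared(measured, predicted) -> float:
    """Coefficient of determination; 1 for a perfect fit, can be negative."""
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("measured signal is constant; R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2) / ss_tot)


def nmse(records_signals: dict[str, tuple[np.ndarray, np.ndarray]]) -> float:
    """Range-normalized MSE summed over signals.

    ``records_signals`` maps a signal name to ``(measured, simulated)``
    arrays; each signal contributes ``MSE / range(measured)**2``.
    """
    total = 0.0
    for name, (y, yhat) in records_signals.items():
        y = np.asarray(y, dtype=float)
        yhat = np.asarray(yhat, dtype=float)
        rng = np.ptp(y)
        if rng == 0:
            raise ValueError(f"signal {name!r} is constant; NMSE undefined")
        total += float(np.mean((y - yhat) ** 2)) / rng**2
    return total


# --------------------------------------------------------------------------
# tracking simulation and residuals
# --------------------------------------------------------------------------

def track_record(
    p: KineticParams,
    record: BatchRecord,
    ctrl: BleedController | None = None,
    settings: SolverSettings | None = None,
):
    """Simulate a record in tracking configuration (see module docstring)."""
    return _track(
        p, record, ctrl, settings or SolverSettings()
    )


def _track(p, record: BatchRecord, ctrl, settings):
    return simulate_tracking(
        p,
        times=record.time_d,
        xv_meas=record.xv,
        feed_meas=record.feed_ml_d,
        temp_meas=record.temp_c,
        ph_meas=record.ph,
        V=record.volume_ml,
        controller=ctrl,
        settings=settings,
    )


def _sample(traj, times):
    """Simulated xv, viability, bleed at the record's sample times."""
    idx = np.clip(
        np.round((times - traj.t[0]) / (traj.t[1] - traj.t[0])).astype(int),
        0, traj.t.size - 1,
    )
    xv = traj.states[idx, ..., 0]
    xd = traj.states[idx, ..., 1]
    viab = xv / np.maximum(xv + xd, 1e-12)
    fb = traj.fb[idx]
    return xv, viab, fb


#: assumed measurement scales used to studentize residuals: relative for
#: VCD (cell-counter CV), absolute for viability, and a fraction of the
#: mean feed rate for bleed (pump resolution); a residual of 1 means
#: "one measurement-noise standard deviation"
MEASUREMENT_SCALES = {
    "xv_rel": 0.03,
    "viability_abs": 0.01,
    "bleed_rel_feed": 0.01,
}


def _residuals(p, record, ctrl, settings, scales=None):
    """Studentized residual arrays (meas - sim) keyed by signal.

    Each residual may carry a trailing particle axis.  Residuals are
    divided by the assumed measurement scale of their signal
    (heteroscedastic for VCD, whose counting error is relative), so every
    signal contributes in units of its own noise standard deviation.  This
    is what keeps the early growth phase — the only window where the
    maximum growth rate is cleanly identifiable — from being drowned by
    plateau-scale normalization.
    """
    sc = scales or MEASUREMENT_SCALES
    traj = _track(p, record, ctrl, settings)
    xv_s, viab_s, fb_s = _sample(traj, record.time_d)

    def shape(meas, sim):
        meas = np.asarray(meas, dtype=float)
        if sim.ndim > meas.ndim:
            meas = meas[:, None]
        return meas, sim

    m, s = shape(record.xv, xv_s)
    r_xv = (m - s) / (sc["xv_rel"] * np.maximum(m, 1.0))
    m, s = shape(record.viability, viab_s)
    r_viab = (m - s) / sc["viability_abs"]
    m, s = shape(record.bleed_ml_d, fb_s)
    r_bleed = (m - s) / (
        sc["bleed_rel_feed"] * max(float(np.mean(record.feed_ml_d)), 1e-9)
    )
    return {"xv": r_xv, "viability": r_viab, "bleed": r_bleed}


def _autocov_score(r: np.ndarray, lags: int) -> np.ndarray:
    """Sum over lags 0..L of the squared biased autocovariance."""
    n = r.shape[0]
    score = 0.0
    for lag in range(min(lags, n - 1) + 1):
        c = np.mean(r[: n - lag] * r[lag:], axis=0) if lag else np.mean(
            r * r, axis=0
        )
        score = score + c * c
    return score


def residual_objective(
    p: KineticParams,
    records: Sequence[BatchRecord],
    ctrl: BleedController | None = None,
    weights: dict[str, float] | None = None,
    lags: int = _AUTOCOV_LAGS,
    settings: SolverSettings | None = None,
):
    """Controller-in-the-loop calibration objective (0 = perfect fit).

    Supports vectorized parameters (array-valued fields), in which case an
    array of objective values is returned.  Simulation failures (non-finite
    states) map to a large finite penalty rather than an exception so a
    swarm can keep moving.
    """
    if not records:
        raise ValueError("need at least one batch record")
    weights = weights or _DEFAULT_WEIGHTS
    settings = settings or SolverSettings()
    total = 0.0
    for record in records:
        res = _residuals(p, record, ctrl, settings)
        for name, w in weights.items():
            if w == 0:
                continue
            r = res[name]
            bad = ~np.isfinite(r).all(axis=0)
            r = np.where(np.isfinite(r), r, 0.0)
            score = _autocov_score(r, lags)
            total = total + w * np.where(bad, _PENALTY, score)
    return total


# --------------------------------------------------------------------------
# fit drivers
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a swarm calibration."""

    params: KineticParams
    objective: float
    bounds: dict[str, tuple[float, float]]
    free_names: tuple[str, ...]
    trace: np.ndarray
    seed: int
    nmse_per_batch: dict[str, float] = field(default_factory=dict)
    r2_per_batch: dict[str, dict[str, float]] = field(default_factory=dict)
    residuals: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        from .io import params_to_dict

        return {
            "params": params_to_dict(self.params),
            "objective": self.objective,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "free_names": list(self.free_names),
            "seed": self.seed,
            "nmse_per_batch": self.nmse_per_batch,
            "r2_per_batch": self.r2_per_batch,
            "trace": self.trace.tolist(),
        }


def _params_from_vector(
    x: np.ndarray, base: KineticParams, names: Sequence[str]
) -> KineticParams:
    """Build (possibly vectorized) params from free-parameter columns."""
    cols = {name: x[..., i] for i, name in enumerate(names)}
    quads = []
    for q in base.quad_effects:
        key = (
            "theta_temp" if q.input_name == "temp_c"
            else "theta_ph" if q.input_name == "ph"
            else None
        )
        if key in cols:
            quads.append(replace(q, theta=cols.pop(key)))
        else:
            quads.append(q)
    return replace(base, quad_effects=tuple(quads), **cols)


def _diagnostics(result: FitResult, records, ctrl, settings) -> None:
    for record in records:
        traj = _track(result.params, record, ctrl, settings)
        xv_s, viab_s, fb_s = _sample(traj, record.time_d)
        result.nmse_per_batch[record.batch_id] = nmse(
            {"xv": (record.xv, xv_s), "viability": (record.viability, viab_s)}
        )
        r2 = {"xv": r_squared(record.xv, xv_s),
              "viability": r_squared(record.viability, viab_s)}
        if np.ptp(record.bleed_ml_d) > 0:
            r2["bleed"] = r_squared(record.bleed_ml_d, fb_s)
        result.r2_per_batch[record.batch_id] = r2
        result.residuals[record.batch_id] = {
            "xv": record.xv - xv_s,
            "viability": record.viability - viab_s,
            "bleed": record.bleed_ml_d - fb_s,
        }


def pso_fit(
    records: Sequence[BatchRecord],
    config: PsoConfig | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    base_params: KineticParams | None = None,
    ctrl: BleedController | None = None,
    weights: dict[str, float] | None = None,
    settings: SolverSettings | None = None,
) -> FitResult:
    """Estimate kinetic parameters by two-stage PSO.

    All parameters in ``bounds`` (default: the packaged search box over
    ``mu_max, kd, kt, kl, K_I_phib, theta_temp, theta_ph``) are free; the
    remainder is taken from ``base_params``.  Reproducible given
    ``config.seed``.
    """
    config = config or PsoConfig()
    bounds = dict(bounds or PARAM_BOUNDS)
    base = base_params or KineticParams()
    settings = settings or SolverSettings()
    names = tuple(bounds)
    lb = np.array([bounds[n][0] for n in names])
    ub = np.array([bounds[n][1] for n in names])

    def fn(x):
        p = _params_from_vector(x, base, names)
        return residual_objective(
            p, records, ctrl, weights=weights, settings=settings
        )

    x_best, f_best, trace = pso_minimize(fn, lb, ub, config)
    if not np.isfinite(f_best) or f_best >= _PENALTY:
        raise RuntimeError(
            "no feasible simulation found for any particle; check bounds "
            "and record units"
        )
    params = _params_from_vector(x_best, base, names)
    params.validate()
    result = FitResult(
        params=params,
        objective=float(f_best),
        bounds=bounds,
        free_names=names,
        trace=trace,
        seed=config.seed,
    )
    _diagnostics(result, records, ctrl, settings)
    return result


def fit_sieving(
    records: Sequence[BatchRecord],
    base_params: KineticParams,
    config: PsoConfig | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    ctrl: BleedController | None = None,
    settings: SolverSettings | None = None,
) -> FitResult:
    """Scale-transfer refit: estimate K_I_phib, kt, kls, kbh only.

    Growth, death-base, lysis and input-effect parameters stay frozen at
    ``base_params`` (the small-scale calibration); the objective uses VCD
    and viability residuals.
    """
    bounds = dict(bounds or SIEVING_BOUNDS)
    unknown = set(bounds) - set(SIEVING_FREE)
    if unknown:
        raise ValueError(f"fit_sieving cannot free {sorted(unknown)}")
    return pso_fit(
        records,
        config=config,
        bounds=bounds,
        base_params=base_params,
        ctrl=ctrl,
        weights={"xv": 1.0, "viability": 1.0},
        settings=settings,
    )
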