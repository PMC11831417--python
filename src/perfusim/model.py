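"""Model/Results facade over calibration, in the spirit of statsmodels.

``PerfusionGrowthModel`` is constructed from measured batch records and its
``fit()`` returns a ``PerfusionFitResults`` carrying the estimated kinetic
parameters, fit diagnostics (range-normalized MSE and R-squared per batch),
the optimizer trace and a ``summary()`` table; forward simulation under new
recipes hangs off the results object.  ``SievingModel`` is the companion
for scale transfer: it freezes the growth parameters of an existing fit and
re-estimates only the inhibition threshold, toxicity factor and the CRD
retention fractions on data from the larger reactor.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .calibrate import FitResult, fit_sieving, pso_fit
from .io import BatchRecord, read_batch_records, save_params
from .kinetics import KineticParams
from .pso import PsoConfig
from .simulate import (
    BleedController,
    ProcessRecipe,
    SolverSettings,
    Trajectory,
    simulate_batch,
)

__all__ = ["PerfusionGrowthModel", "SievingModel", "PerfusionFitResults"]


class PerfusionFitResults:
    """Estimates, diagnostics and simulation access for a calibrated model."""

    def __init__(self, model, fit: FitResult):
        self.model = model
        self._fit = fit

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> KineticParams:
        return self._fit.params

    @property
    def objective(self) -> float:
        return self._fit.objective

    @property
    def trace(self) -> np.ndarray:
        return self._fit.trace

    @property
    def nmse(self) -> dict[str, float]:
        return self._fit.nmse_per_batch

    @property
    def rsquared(self) -> dict[str, dict[str, float]]:
        return self._fit.r2_per_batch

    @property
    def residuals(self) -> dict[str, dict[str, np.ndarray]]:
        return self._fit.residuals

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        f = self._fit
        p = f.params
        lines = [
            "Perfusion growth model calibration",
            "=" * 54,
            f"{'batches':<22}{len(self.model.records)}",
            f"{'free parameters':<22}{', '.join(f.free_names)}",
            f"{'objective':<22}{f.objective:.6g}",
            f"{'swarm seed':<22}{f.seed}",
            "-" * 54,
            f"{'parameter':<14}{'estimate':>12}{'lower':>12}{'upper':>12}",
        ]
        values = {
            "mu_max": p.mu_max, "kd": p.kd, "kt": p.kt, "kl": p.kl,
            "K_I_phib": p.K_I_phib, "kls": p.kls, "kbh": p.kbh,
        }
        for q in p.quad_effects:
            key = "theta_temp" if q.input_name == "temp_c" else "theta_ph"
            values[key] = q.theta
        for name in f.free_names:
            lo, hi = f.bounds[name]
            lines.append(
                f"{name:<14}{float(np.asarray(values[name])):>12.5g}"
                f"{lo:>12.5g}{hi:>12.5g}"
            )
        lines.append("-" * 54)
        for bid, v in f.nmse_per_batch.items():
            r2 = f.r2_per_batch[bid]
            r2s = ", ".join(f"{k} {val:.3f}" for k, val in r2.items())
            lines.append(f"{bid:<22}NMSE {v:.4f}  R2: {r2s}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PerfusionFitResults objective={self.objective:.4g}>"

    # -- downstream use ----------------------------------------------------
    def simulate(
        self,
        recipe: ProcessRecipe,
        controller: BleedController | None = None,
        qp_model=None,
        settings: SolverSettings | None = None,
    ) -> Trajectory:
        """Forward-simulate the fitted kinetics under a new recipe."""
        return simulate_batch(
            self.params, recipe, controller=controller, qp_model=qp_model,
            settings=settings,
        )

    def save(self, path: str) -> None:
        """Write the estimated parameters plus fit metadata (seed, bounds,
        convergence trace, per-batch diagnostics) to JSON."""
        save_params(
            self.params, path,
            objective=self.objective, seed=self._fit.seed,
            free_names=list(self._fit.free_names),
            bounds={k: list(v) for k, v in self._fit.bounds.items()},
            trace=self._fit.trace.tolist(),
            nmse_per_batch=self._fit.nmse_per_batch,
        )


class PerfusionGrowthModel:
    """Kinetic growth model to be calibrated against perfusion batches."""

    def __init__(
        self,
        records: Sequence[BatchRecord],
        bounds: dict[str, tuple[float, float]] | None = None,
        base_params: KineticParams | None = None,
        controller: BleedController | None = None,
        weights: dict[str, float] | None = None,
        settings: SolverSettings | None = None,
    ):
        if not records:
            raise ValueError("need at least one batch record")
        self.records = list(records)
        self.bounds = bounds
        self.base_params = base_params
        self.controller = controller
        self.weights = weights
        self.settings = settings

    @classmethod
    def from_csv(cls, path_or_glob, **kwargs) -> "PerfusionGrowthModel":
        return cls(read_batch_records(path_or_glob), **kwargs)

    def fit(self, pso: PsoConfig | None = None) -> PerfusionFitResults:
        fit = pso_fit(
            self.records,
            config=pso,
            bounds=self.bounds,
            base_params=self.base_params,
            ctrl=self.controller,
            weights=self.weights,
            settings=self.settings,
        )
        return PerfusionFitResults(self, fit)


class SievingModel:
    """Scale-transfer model: sieving refit with frozen growth parameters."""

    def __init__(
        self,
        records: Sequence[BatchRecord],
        base_params: KineticParams,
        bounds: dict[str, tuple[float, float]] | None = None,
        controller: BleedController | None = None,
        settings: SolverSettings | None = None,
    ):
        if not records:
            raise ValueError("need at least one batch record")
        self.records = list(records)
        self.base_params = base_params
        self.bounds = bounds
        self.controller = controller
        self.settings = settings

    def fit(self, pso: PsoConfig | None = None) -> PerfusionFitResults:
        fit = fit_sieving(
            self.records,
            self.base_params,
            config=pso,
            bounds=self.bounds,
            ctrl=self.controller,
            settings=self.settings,
        )
        return PerfusionFitResults(self, fit)
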