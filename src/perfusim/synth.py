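"""Synthetic perfusion batches with the statistical structure of real runs.

The generator simulates the mechanistic model under a recipe, samples the
trajectory on a measurement grid and corrupts it with white Gaussian noise,
returning both the noisy batch record and the clean ground-truth trajectory
so recovery experiments can be scored.  The design presets reproduce the
published study layout of an intensified CHO perfusion campaign: 20-25-day
runs inoculated at 2.5e6 cells/mL, media exchange between 1 and 2 vessel
volumes per day, a 37->34 degC shift triggered by VCD, production density
targets of 60-65e6 cells/mL held (where dynamically possible) by bleed
control, and a pair of 5 L-scale runs whose retention filter holds back part
of the lysed-cell material and biomaterial (nonzero sieving fractions).

The default specific-productivity surrogate increases with lysed-cell
density and decreases with feed rate, planting the feature ranking that the
productivity and optimization modules are designed to uncover.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import BatchRecord
from .kinetics import KineticParams, QuadraticEffect
from .simulate import (
    BleedController,
    FeedSchedule,
    ProcessRecipe,
    SolverSettings,
    Trajectory,
    simulate_batch,
)

__all__ = [
    "REFERENCE_KINETICS",
    "SIEVING_RUN1",
    "SIEVING_RUN2",
    "PARAM_BOUNDS",
    "SIEVING_BOUNDS",
    "NoiseModel",
    "SurrogateQp",
    "make_design",
    "generate_record",
    "generate_design_records",
    "planted_qp_samples",
]

#: reference kinetic parameter set for an intensified small-scale CHO
#: perfusion process; the default ground truth for synthetic data
REFERENCE_KINETICS = KineticParams(
    mu_max=0.848, kd=0.00921, kt=0.03514, kl=1.58991, K_I_phib=12.7205
)

#: 5 L-scale parameter sets with CRD sieving (retention) of lysed material
#: and biomaterial; growth/lysis parameters inherited from the reference set
SIEVING_RUN1 = replace(
    REFERENCE_KINETICS, K_I_phib=12.139, kt=0.049, kls=0.023, kbh=0.014
)
SIEVING_RUN2 = replace(
    REFERENCE_KINETICS, K_I_phib=12.70, kt=0.035, kls=0.010, kbh=0.010
)

#: calibration search box (lower, upper) per free parameter
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "mu_max": (0.05, 1.2),
    "kd": (0.001, 0.05),
    "kt": (1e-6, 0.1),
    "kl": (0.8, 2.0),
    "K_I_phib": (10.0, 250.0),
    "theta_temp": (0.011, 0.081),
    "theta_ph": (0.000271, 3.301),
}

#: search box for the scale-transfer refit (growth parameters frozen)
SIEVING_BOUNDS: dict[str, tuple[float, float]] = {
    "K_I_phib": (10.0, 250.0),
    "kt": (1e-6, 0.1),
    "kls": (0.0, 0.2),
    "kbh": (0.0, 0.2),
}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise levels per signal (white Gaussian).

    Relative levels for VCD, bleed, titer and diameter; absolute for
    viability (which is clipped back into (0, 1]).  Defaults are typical
    instrument coefficients of variation for cell counters, balances and
    protein-A HPLC.
    """

    vcd_rel: float = 0.03
    viability_abs: float = 0.01
    bleed_rel: float = 0.05
    titer_rel: float = 0.05
    diameter_rel: float = 0.01
    interval_d: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        levels = (
            self.vcd_rel, self.viability_abs, self.bleed_rel,
            self.titer_rel, self.diameter_rel,
        )
        if min(levels) < 0 or self.interval_d <= 0:
            raise ValueError("noise levels must be >= 0, interval positive")


@dataclass(frozen=True)
class SurrogateQp:
    """Smooth specific-productivity surrogate with a planted mechanism.

    qp rises with the lysed-cell pool (saturating Michaelis form, echoing
    the cell-size/productivity shift that accompanies accumulation of cell
    debris) and falls linearly with the volumetric exchange rate, so lower
    perfusion means higher specific productivity.  Units are normalized
    product units per 1e6 cells per day.
    """

    q0: float = 0.03
    xl_floor: float = 0.3
    xl_half: float = 1.0
    feed_slope: float = 0.45
    feed_ref_vvd: float = 1.5

    def __call__(self, features: np.ndarray) -> np.ndarray:
        f = np.asarray(features, dtype=float)
        xl = f[..., 1]
        volume = f[..., 5]
        vvd = f[..., 6] / volume
        g = self.xl_floor + (1.0 - self.xl_floor) * xl / (xl + self.xl_half)
        h = 1.0 + self.feed_slope * (self.feed_ref_vvd - vvd)
        return self.q0 * g * np.maximum(h, 0.0)


def planted_qp_samples(
    n: int = 400,
    qp_truth: SurrogateQp | None = None,
    noise_rel: float = 0.0,
    seed: int = 0,
):
    """Feature-decorrelated qp samples with a planted dependency.

    Feature vectors are drawn independently within realistic marginal
    ranges for an intensified perfusion process, and the target is the
    surrogate qp (which depends only on lysed cells and feed rate).
    Trajectory-derived samples leave the mechanistic states collinear with
    the inputs (biomaterial is a low-pass image of Xv over exchange rate),
    which is exactly the regime where permutation importance splits credit
    between proxies; this generator supplies the decorrelated design needed
    to probe whether a trained network relies on the right features.
    """
    import pandas as pd

    qp_truth = qp_truth or SurrogateQp()
    rng = np.random.default_rng(seed)
    V = 200.0
    feats = np.column_stack(
        [
            rng.uniform(20.0, 65.0, n),          # xv
            rng.uniform(0.0, 3.5, n),            # xl
            rng.uniform(10.0, 35.0, n),          # phib
            rng.choice([34.0, 37.0], n),         # temp_c
            rng.choice([6.95, 7.05], n),         # ph
            np.full(n, V),                       # volume_ml
            rng.uniform(0.8, 2.2, n) * V,        # feed_ml_d
        ]
    )
    qp = qp_truth(feats)
    if noise_rel > 0:
        qp = qp * (1.0 + noise_rel * rng.standard_normal(n))
    df = pd.DataFrame(
        feats,
        columns=["xv", "xl", "phib", "temp_c", "ph", "volume_ml",
                 "feed_ml_d"],
    )
    df["qp"] = qp
    df["batch_id"] = "planted"
    df["time_d"] = np.arange(n, dtype=float)
    return df


_PRESETS = ("training_3batch", "validation_3batch", "V01V02", "fiveL")


def _recipe(vvd, t_end, shift, setpoint, V=200.0):
    # the shift decision is taken when a daily at-line VCD count arrives,
    # so the emulated plant and a calibration replay of the recorded
    # temperature series see identical input timing
    return ProcessRecipe(
        V=V,
        X0=2.5,
        shift_threshold=shift,
        vcd_setpoint=setpoint,
        feed=FeedSchedule(mode="constant_vvd", knot_values=(vvd,)),
        t_end=t_end,
        shift_decision_interval_d=1.0,
    )


def make_design(preset: str) -> list[tuple[KineticParams, ProcessRecipe]]:
    """Truth parameters and recipes for a named study design.

    ``training_3batch`` / ``validation_3batch``
        three runs at ~1, ~1.5 and ~2 vessel volumes/day, shift at 50,
        setpoint 60, terminated at day 25/20/25;
    ``V01V02``
        two runs with a later shift (60) and a higher density target (65),
        terminated at day 17, at the top of the explored exchange range;
    ``fiveL``
        two 5 L runs generated with the sieving parameter sets.
    """
    if preset not in _PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available: {', '.join(_PRESETS)}"
        )
    p = REFERENCE_KINETICS
    if preset in ("training_3batch", "validation_3batch"):
        return [
            (p, _recipe(1.0, 25.0, 50.0, 60.0)),
            (p, _recipe(1.5, 20.0, 50.0, 60.0)),
            (p, _recipe(2.0, 25.0, 50.0, 60.0)),
        ]
    if preset == "V01V02":
        return [
            (p, _recipe(2.0, 17.0, 60.0, 65.0)),
            (p, _recipe(2.0, 17.0, 60.0, 65.0)),
        ]
    return [
        (SIEVING_RUN1, _recipe(2.0, 20.0, 50.0, 60.0, V=5000.0)),
        (SIEVING_RUN2, _recipe(1.5, 20.0, 50.0, 60.0, V=5000.0)),
    ]


def generate_record(
    truth: KineticParams,
    recipe: ProcessRecipe,
    qp_truth=None,
    noise: NoiseModel | None = None,
    batch_id: str = "synthetic",
    controller: BleedController | None = None,
    settings: SolverSettings | None = None,
) -> tuple[BatchRecord, Trajectory]:
    """Simulate a batch and corrupt it into a measured-looking record.

    Returns the noisy :class:`BatchRecord` and the clean ground-truth
    :class:`Trajectory`.  The synthetic mean cell diameter is an affine
    function of the true lysed-cell density (cell swelling tracks debris
    accumulation) plus noise.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    traj = simulate_batch(
        truth, recipe, controller=controller, qp_model=qp_truth,
        settings=settings,
    )
    t_samp = np.arange(0.0, recipe.t_end + 1e-9, noise.interval_d)

    xv = traj.at(t_samp, "Xv")
    viab = traj.at(t_samp, "viability")
    bleed = traj.at(t_samp, "fb")
    feed = traj.at(t_samp, "ff")
    temp = traj.at(t_samp, "temp")
    ph = traj.at(t_samp, "ph")
    xl = traj.at(t_samp, "xl_total")

    xv_n = np.maximum(xv * (1.0 + noise.vcd_rel * rng.standard_normal(
        xv.shape)), 0.0)
    viab_n = np.clip(
        viab + noise.viability_abs * rng.standard_normal(viab.shape),
        1e-6, 1.0,
    )
    bleed_n = np.maximum(
        bleed * (1.0 + noise.bleed_rel * rng.standard_normal(bleed.shape)),
        0.0,
    )
    diam = 14.0 + 1.5 * xl
    diam_n = diam * (1.0 + noise.diameter_rel * rng.standard_normal(
        diam.shape))

    titer_n = None
    if qp_truth is not None:
        igg = traj.at(t_samp, "IgG")
        titer_n = np.maximum(
            igg * (1.0 + noise.titer_rel * rng.standard_normal(igg.shape)),
            0.0,
        )

    record = BatchRecord(
        batch_id=batch_id,
        time_d=t_samp,
        xv=xv_n,
        viability=viab_n,
        bleed_ml_d=bleed_n,
        feed_ml_d=feed,
        temp_c=temp,
        ph=ph,
        volume_ml=recipe.V,
        titer_norm=titer_n,
        diameter_um=diam_n,
    )
    return record, traj


def generate_design_records(
    preset: str,
    noise: NoiseModel | None = None,
    qp_truth=None,
    seed: int = 0,
) -> tuple[list[BatchRecord], list[Trajectory]]:
    """Generate a full design preset with per-batch derived seeds."""
    noise = noise or NoiseModel()
    design = make_design(preset)
    records, trajs = [], []
    for i, (truth, recipe) in enumerate(design):
        nm = replace(noise, seed=(seed * 1000 + i) % (2**31 - 1))
        rec, traj = generate_record(
            truth, recipe, qp_truth=qp_truth, noise=nm,
            batch_id=f"{preset}_{i:02d}",
        )
        records.append(rec)
        trajs.append(traj)
    return records, trajs
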