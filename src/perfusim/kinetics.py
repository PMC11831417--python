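"""Kinetic core of the perfusion cell-culture model.

The culture is described by three cell sub-populations -- viable (``Xv``),
dead (``Xd``) and lysed (``Xl``) cells -- plus a catch-all "biomaterial"
state (``Phib``) that lumps the unmeasured growth-inhibiting byproducts
secreted by viable cells.  The effective specific growth rate is the maximum
rate attenuated by a cubic Hill term in total biomaterial and by bell-shaped
("quadratic") effects of process inputs such as temperature and pH; the
effective specific death rate rises linearly with the lysed-cell pool
(toxicity).  Dead cells lyse with first-order kinetics.

Stream conventions follow perfusion practice: a feed ``Ff``, a cell-free
harvest ``Fh`` drawn through the cell retention device (CRD), and a bleed
``Fb`` with reactor composition.  Lysed material and biomaterial pass through
the CRD, so they are washed out at ``(Fh+Fb)/V``; cells are retained and only
leave through the bleed.  A sieving extension splits lysed cells and
biomaterial into a pass-through part and a retained part (``Xlh``,
``Phibh``, governed by retention fractions ``kls`` and ``kbh``) to describe
filters that hold part of that material inside the reactor; the retained
species leave only through the bleed.  With ``kls = kbh = 0`` the extension
reduces exactly to the base model.

All functions in this module are pure and broadcast over NumPy arrays: every
kinetic parameter may be a scalar or an array of particle/candidate values,
which is what makes swarm calibration cheap.

Units: time in days, cell densities in 1e6 cells/mL, biomaterial in
1e6 cells/mL*day (unit specific production rate, see ``rhs``), flows in
mL/day, volume in mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "STATE_NAMES",
    "IDX",
    "QuadraticEffect",
    "KineticParams",
    "CultureState",
    "Flows",
    "quadratic_effect",
    "inhibition_factor",
    "effective_growth_rate",
    "effective_death_rate",
    "viability",
    "rhs",
]

#: order of the state vector used throughout the package
STATE_NAMES = ("Xv", "Xd", "Xl", "Phib", "Xlh", "Phibh", "IgG")
IDX = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)


@dataclass(frozen=True)
class QuadraticEffect:
    """Bell-shaped effect of a process input on growth.

    The factor equals 1 at the optimum ``target`` and decays like a Gaussian
    with distance from it.  Two parameterizations are supported:

    * ``"sensitivity"`` (default): ``exp(-c * (theta*(z-target))**2)`` --
      larger ``theta`` means a *stronger* effect,
    * ``"spread"``: ``exp(-c * ((z-target)/theta)**2)`` -- ``theta`` is the
      width of the bell.

    The sensitivity form is the package default because the calibration
    bounds shipped with the package (``synth.PARAM_BOUNDS``) are only
    numerically sensible under it: a width of 0.08 degC would annihilate
    growth for a routine 3 degC temperature shift.
    """

    input_name: str
    target: float
    theta: float | np.ndarray
    scale_c: float = 0.5
    parameterization: str = "sensitivity"

    def __post_init__(self) -> None:
        if self.scale_c <= 0:
            raise ValueError("scale_c must be positive")
        if self.parameterization not in ("sensitivity", "spread"):
            raise ValueError(
                f"unknown parameterization {self.parameterization!r}"
            )


def quadratic_effect(effect: QuadraticEffect, z):
    """Evaluate a quadratic input effect at input value ``z``; in (0, 1]."""
    dev = np.asarray(z, dtype=float) - effect.target
    if effect.parameterization == "sensitivity":
        d = effect.theta * dev
    else:
        theta = np.asarray(effect.theta, dtype=float)
        if np.any(theta == 0):
            raise ZeroDivisionError(
                f"spread parameterization of {effect.input_name!r} "
                "requires theta != 0"
            )
        d = dev / theta
    return np.exp(-effect.scale_c * d * d)


def _default_quads() -> tuple[QuadraticEffect, ...]:
    # defaults for an intensified CHO process: growth at 37 degC / pH 7.05;
    # theta midway between the packaged calibration bounds
    return (
        QuadraticEffect("temp_c", target=37.0, theta=0.046),
        QuadraticEffect("ph", target=7.05, theta=1.6506),
    )


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the growth/death/lysis/biomaterial model.

    Attributes
    ----------
    mu_max : maximum specific growth rate (1/day)
    kd : base (primary) specific death rate (1/day)
    kt : lysed-cell toxicity factor (mL/1e6 cells/day)
    kl : first-order lysing rate of dead cells (1/day)
    K_I_phib : biomaterial level at which growth inhibition is half-maximal
        (1e6 cells/mL*day)
    quad_effects : bell-shaped input effects entering the growth rate
    kls, kbh : sieving retention fractions in [0, 1] for lysed cells and
        biomaterial (0 = everything passes the CRD, the base model)
    """

    mu_max: float | np.ndarray = 0.848
    kd: float | np.ndarray = 0.00921
    kt: float | np.ndarray = 0.03514
    kl: float | np.ndarray = 1.58991
    K_I_phib: float | np.ndarray = 12.7205
    quad_effects: tuple[QuadraticEffect, ...] = field(
        default_factory=_default_quads
    )
    kls: float | np.ndarray = 0.0
    kbh: float | np.ndarray = 0.0

    def validate(self) -> None:
        """Raise ValueError on any violated invariant (scalar or array)."""
        for name in ("mu_max", "kd", "kt", "kl"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")
        if np.any(np.asarray(self.K_I_phib) <= 0):
            raise ValueError("K_I_phib must be positive")
        for name in ("kls", "kbh"):
            v = np.asarray(getattr(self, name))
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        for q in self.quad_effects:
            if np.any(np.asarray(q.theta) < 0):
                raise ValueError(f"theta of {q.input_name!r} must be >= 0")

    def take(self, index) -> "KineticParams":
        """Select a subset along the particle axis of vectorized fields."""

        def pick(x):
            x = np.asarray(x)
            return x if x.ndim == 0 else x[index]

        return replace(
            self,
            mu_max=pick(self.mu_max),
            kd=pick(self.kd),
            kt=pick(self.kt),
            kl=pick(self.kl),
            K_I_phib=pick(self.K_I_phib),
            kls=pick(self.kls),
            kbh=pick(self.kbh),
            quad_effects=tuple(
                replace(q, theta=pick(q.theta)) for q in self.quad_effects
            ),
        )


@dataclass(frozen=True)
class CultureState:
    """Instantaneous culture state (densities plus working volume)."""

    Xv: float
    Xd: float = 0.0
    Xl: float = 0.0
    Phib: float = 0.0
    Xlh: float = 0.0
    Phibh: float = 0.0
    IgG: float = 0.0
    V: float = 200.0

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.V <= 0:
            raise ValueError("V must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, V: float) -> "CultureState":
        return cls(*(float(v) for v in np.asarray(y, dtype=float)), V=V)


@dataclass(frozen=True)
class Flows:
    """Feed, bleed and harvest rates (mL/day); Fh = Ff - Fb at constant V."""

    Ff: float
    Fb: float

    def __post_init__(self) -> None:
        if self.Ff < 0 or self.Fb < 0:
            raise ValueError("flows must be non-negative")
        if self.Fb > self.Ff + 1e-12:
            raise ValueError("bleed cannot exceed feed at constant volume")

    @property
    def Fh(self) -> float:
        return self.Ff - self.Fb


def inhibition_factor(phib_total, K_I_phib):
    """Cubic Hill attenuation of growth by total biomaterial; in (0, 1].

    Equals exactly 1/2 when ``phib_total == K_I_phib`` and 1 with no
    biomaterial present.
    """
    phib_total = np.asarray(phib_total, dtype=float)
    if np.any(phib_total < 0):
        raise ValueError("biomaterial concentration must be non-negative")
    if np.any(np.asarray(K_I_phib) <= 0):
        raise ValueError("K_I_phib must be positive")
    r = phib_total / K_I_phib
    return 1.0 / (r * r * r + 1.0)


def effective_growth_rate(
    p: KineticParams,
    phib_total,
    inputs: Mapping[str, float],
    eta_substrate=1.0,
    eta_inhibitor=1.0,
):
    """Effective specific growth rate (1/day).

    ``mu_max`` times the biomaterial Hill attenuation and every registered
    quadratic input effect.  ``eta_substrate`` / ``eta_inhibitor`` are
    multiplicative hooks for Monod-type substrate limitation and inhibitor
    terms; they default to 1 because no metabolite was limiting or inhibiting
    in the process this package models.
    """
    mu = p.mu_max * inhibition_factor(phib_total, p.K_I_phib)
    for q in p.quad_effects:
        if q.input_name not in inputs:
            raise KeyError(
                f"no value supplied for input {q.input_name!r} "
                "required by a quadratic growth effect"
            )
        mu = mu * quadratic_effect(q, inputs[q.input_name])
    return mu * eta_substrate * eta_inhibitor


def effective_death_rate(p: KineticParams, xl_total):
    """Effective specific death rate kd + kt * (Xl + Xlh) (1/day)."""
    return p.kd + p.kt * np.asarray(xl_total, dtype=float)


def viability(xv, xd):
    """Viable fraction Xv / (Xv + Xd)."""
    xv = np.asarray(xv, dtype=float)
    xd = np.asarray(xd, dtype=float)
    total = xv + xd
    if np.any(total <= 0):
        raise ZeroDivisionError("viability undefined for Xv + Xd == 0")
    return xv / total


def rhs(
    p: KineticParams,
    y: np.ndarray,
    ff,
    fb,
    V: float,
    inputs: Mapping[str, float],
    qp=0.0,
    eta_substrate=1.0,
    eta_inhibitor=1.0,
) -> np.ndarray:
    """Time derivative of the state vector at constant working volume.

    ``y`` has shape ``(..., 7)`` ordered as ``STATE_NAMES``; parameters and
    flows broadcast against the leading axes.  Biomaterial is produced at a
    unit specific rate (``dPhib/dt`` carries ``Xv`` directly), which fixes
    its unit to 1e6 cells/mL*day; the inhibition threshold absorbs the scale.
    """
    y = np.asarray(y, dtype=float)
    xv, xd, xl = y[..., 0], y[..., 1], y[..., 2]
    phib, xlh, phibh = y[..., 3], y[..., 4], y[..., 5]
    igg = y[..., 6]
    fh = ff - fb
    d_pass = (fh + fb) / V  # pass-through washout = Ff/V at constant volume
    d_bleed = fb / V

    # clip transient sub-zero biomaterial from an unstable integration step
    # so a bad swarm particle degrades to a penalized (non-finite or huge)
    # objective instead of an exception killing the whole evaluation
    mu_eff = effective_growth_rate(
        p, np.maximum(phib + phibh, 0.0), inputs, eta_substrate,
        eta_inhibitor,
    )
    mu_d = effective_death_rate(p, xl + xlh)

    dy = np.empty_like(y)
    dy[..., 0] = (mu_eff - mu_d - d_bleed) * xv
    dy[..., 1] = mu_d * xv - (p.kl + d_bleed) * xd
    dy[..., 2] = (1.0 - p.kls) * p.kl * xd - d_pass * xl
    dy[..., 3] = (1.0 - p.kbh) * xv - d_pass * phib
    dy[..., 4] = p.kls * p.kl * xd - d_bleed * xlh
    dy[..., 5] = p.kbh * xv - d_bleed * phibh
    dy[..., 6] = qp * xv - d_pass * igg
    return dy
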