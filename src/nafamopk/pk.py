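"""Two-compartment constant-infusion kinetics in closed form.

The drug enters the central compartment (volume ``v1``, concentration
``Cp``) as a piecewise-constant infusion, distributes to a peripheral
compartment (``v2``) via intercompartmental clearance ``q`` and is
eliminated from the central compartment with clearance ``cl``.  Micro rate
constants::

    k10 = cl/v1      k12 = q/v1      k21 = q/v2

The central concentration is biexponential with macro exponents alpha and
beta, the roots of ``x^2 - (k10+k12+k21) x + k10*k21 = 0``.  For a constant
infusion of rate R (μg/h) started at time 0 from a drug-free state,

    Cp(t) = (R/v1) * [ A (1-exp(-alpha t))/alpha + B (1-exp(-beta t))/beta ]

with ``A = (alpha-k21)/(alpha-beta)`` and ``B = (k21-beta)/(alpha-beta)``.
Because the kinetics are linear, arbitrary piecewise-constant dosing is
handled by superposing one such term per rate *step change* (+R at a
segment start, -R at its end).  This analytic path is exact at machine
precision and is the primary engine for estimation and Monte Carlo
simulation; an adaptive ODE integration serves as an independent oracle in
the test suite only.

Units: clearances L/h, volumes L, rates mg/h at the interface (converted
to μg/h internally so concentrations are natively μg/L), times in hours,
half-lives reported in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .dataset import DoseEvent, ValidationError

__all__ = [
    "PKParameters",
    "MacroConstants",
    "apply_pk_covariates",
    "macro_constants",
    "concentration",
    "concentration_profile",
    "dose_steps",
    "GASFLOW_REFERENCE",
]

#: Centering constant for the gas-flow covariate models (L/min); equals the
#: study-population median gas flow rate.
GASFLOW_REFERENCE = 3.75

MG_TO_UG = 1000.0


@dataclass(frozen=True)
class PKParameters:
    """Structural PK parameters for one sampling-site model.

    ``cov_gasflow_cl`` / ``cov_gasflow_v2`` are the exponential covariate
    coefficients (per L/min) applied as
    ``param * exp(coef * (gas_flow_rate - gasflow_ref))``.
    """

    cl: float
    v1: float
    q: float
    v2: float
    cov_gasflow_cl: float = 0.0
    cov_gasflow_v2: float = 0.0
    gasflow_ref: float = GASFLOW_REFERENCE

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "v2"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.q < 0:
            raise ValidationError("q must be >= 0")
        if not self.gasflow_ref > 0:
            raise ValidationError("gasflow_ref must be > 0")


@dataclass(frozen=True)
class MacroConstants:
    """Macro (hybrid) constants derived from the micro rate constants."""

    alpha: float  # 1/h, fast (distribution) exponent
    beta: float  # 1/h, slow (terminal) exponent
    t_half_alpha: float  # min
    t_half_beta: float  # min
    vss: float  # L
    k10: float
    k12: float
    k21: float


def apply_pk_covariates(theta: PKParameters, gas_flow_rate: float) -> PKParameters:
    """Individualize typical parameters for a subject's gas flow rate.

    Affected parameters are scaled by ``exp(coef * (gas_flow - ref))``;
    the returned parameter set has its coefficients zeroed so the
    operation is idempotent.
    """
    if not gas_flow_rate > 0:
        raise ValidationError(f"gas_flow_rate must be > 0, got {gas_flow_rate}")
    delta = gas_flow_rate - theta.gasflow_ref
    return replace(
        theta,
        cl=theta.cl * math.exp(theta.cov_gasflow_cl * delta),
        v2=theta.v2 * math.exp(theta.cov_gasflow_v2 * delta),
        cov_gasflow_cl=0.0,
        cov_gasflow_v2=0.0,
    )


def macro_exponents(k10, k12, k21):
    """Vectorized alpha/beta from micro constants (alpha >= beta)."""
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    root = np.sqrt(np.maximum(disc, 0.0))
    alpha = 0.5 * (s + root)
    # beta via the product alpha*beta = k10*k21 avoids the catastrophic
    # cancellation of (s - root)/2 when the roots are widely separated
    beta = k10 * k21 / alpha
    return alpha, beta


def macro_constants(pk: PKParameters) -> MacroConstants:
    """Macro exponents, half-lives (min) and steady-state volume.

    Raises for ``q == 0`` (a degenerate one-compartment model: refit with a
    reduced structure instead) and for the coincident-root edge case.
    """
    if pk.q == 0:
        raise ValidationError(
            "q = 0 collapses the model to one compartment; use a reduced model"
        )
    k10 = pk.cl / pk.v1
    k12 = pk.q / pk.v1
    k21 = pk.q / pk.v2
    alpha, beta = macro_exponents(k10, k12, k21)
    if not beta > 0 or (alpha - beta) < 1e-10 * alpha:
        raise ValidationError("degenerate macro exponents (alpha ~= beta)")
    return MacroConstants(
        alpha=float(alpha),
        beta=float(beta),
        t_half_alpha=60.0 * math.log(2.0) / float(alpha),
        t_half_beta=60.0 * math.log(2.0) / float(beta),
        vss=pk.v1 + pk.v2,
        k10=k10,
        k12=k12,
        k21=k21,
    )


def dose_steps(doses: list[DoseEvent]) -> tuple[np.ndarray, np.ndarray]:
    """Collapse dose events to rate step changes.

    Returns ``(times, deltas)`` where ``deltas`` are signed rate changes in
    μg/h: +rate at each segment start, -rate at each finite segment end.
    """
    times: list[float] = []
    deltas: list[float] = []
    for d in doses:
        if d.rate == 0:
            continue
        times.append(d.start_time)
        deltas.append(d.rate * MG_TO_UG)
        if math.isfinite(d.end_time):
            times.append(d.end_time)
            deltas.append(-d.rate * MG_TO_UG)
    if not times:
        return np.zeros(0), np.zeros(0)
    order = np.argsort(times, kind="stable")
    return np.asarray(times, float)[order], np.asarray(deltas, float)[order]


def _profile(pk: PKParameters, doses: list[DoseEvent], t: np.ndarray) -> np.ndarray:
    mc = macro_constants(pk)
    denom = mc.alpha - mc.beta
    A = (mc.alpha - mc.k21) / denom
    B = (mc.k21 - mc.beta) / denom
    st, dr = dose_steps(doses)
    out = np.zeros_like(t, dtype=float)
    for s, d in zip(st, dr):
        tau = t - s
        active = tau > 0
        tau = np.where(active, tau, 0.0)
        term = A * -np.expm1(-mc.alpha * tau) / mc.alpha + B * -np.expm1(
            -mc.beta * tau
        ) / mc.beta
        out += np.where(active, (d / pk.v1) * term, 0.0)
    return out


def concentration(pk: PKParameters, doses: list[DoseEvent], t: float) -> float:
    """Central-compartment concentration (μg/L) at time ``t`` (hours)."""
    if t < 0:
        raise ValidationError(f"t must be >= 0, got {t}")
    return float(_profile(pk, doses, np.asarray([t], float))[0])


def concentration_profile(
    pk: PKParameters, doses: list[DoseEvent], grid
) -> np.ndarray:
    """Elementwise :func:`concentration` over a sorted time grid."""
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1:
        raise ValidationError("grid must be one-dimensional")
    if g.size and (np.any(np.diff(g) < 0) or g[0] < 0):
        raise ValidationError("grid must be sorted and non-negative")
    return _profile(pk, doses, g)
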