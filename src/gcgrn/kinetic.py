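"""Kinetic ODE reference model of BCL6/IRF4/BLIMP1 protein dynamics.

A deterministic three-protein system in which each protein has a basal
production rate mu, a maximum induced rate sigma shaped by Hill terms with
dissociation constants k, and linear degradation lambda; BCR adds to the
decay of BCL6 and CD40 adds to the production of IRF4:

    dp/dt = mu_p + sigma_p kb^2/(kb^2+b^2) + sigma_p r^2/(kr^2+r^2) - lambda_p p
    db/dt = mu_b + sigma_b [kp^2/(kp^2+p^2)][kb^2/(kb^2+b^2)][kr^2/(kr^2+r^2)]
            - (lambda_b + BCR(t)) b
    dr/dt = mu_r + sigma_r r^2/(kr^2+r^2) + CD40(t) - lambda_r r

with p = BLIMP1, b = BCL6, r = IRF4.  Parameter values are user-supplied
configuration (no defaults are claimed); the module exists as the
deterministic reference against which the reduced stochastic model is
compared when choosing initial promoter rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Tuple

import numpy as np
from scipy.integrate import solve_ivp

StimulusFn = Callable[[float], float]


def _zero(_: float) -> float:
    return 0.0


@dataclass(frozen=True)
class KineticParameters:
    """Per-protein constants (p = BLIMP1, b = BCL6, r = IRF4) and stimulus
    time courses BCR(t), CD40(t) (callables, default identically zero)."""

    mu_p: float
    mu_b: float
    mu_r: float
    sigma_p: float
    sigma_b: float
    sigma_r: float
    k_p: float
    k_b: float
    k_r: float
    lambda_p: float
    lambda_b: float
    lambda_r: float
    bcr: StimulusFn = field(default=_zero)
    cd40: StimulusFn = field(default=_zero)

    def __post_init__(self) -> None:
        for name in (
            "mu_p", "mu_b", "mu_r", "sigma_p", "sigma_b", "sigma_r",
            "k_p", "k_b", "k_r", "lambda_p", "lambda_b", "lambda_r",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("k_p", "k_b", "k_r", "lambda_p", "lambda_b", "lambda_r"):
            if getattr(self, name) == 0:
                raise ValueError(f"{name} must be strictly positive")


def kinetic_rhs(t: float, y: np.ndarray, params: KineticParameters) -> np.ndarray:
    p, b, r = np.maximum(y, 0.0)
    kp2, kb2, kr2 = params.k_p**2, params.k_b**2, params.k_r**2
    hill_b = kb2 / (kb2 + b**2)
    hill_p = kp2 / (kp2 + p**2)
    hill_r_rep = kr2 / (kr2 + r**2)
    hill_r_act = r**2 / (kr2 + r**2)
    dp = params.mu_p + params.sigma_p * hill_b + params.sigma_p * hill_r_act - params.lambda_p * p
    db = params.mu_b + params.sigma_b * hill_p * hill_b * hill_r_rep - (params.lambda_b + params.bcr(t)) * b
    dr = params.mu_r + params.sigma_r * hill_r_act + params.cd40(t) - params.lambda_r * r
    return np.array([dp, db, dr])


def simulate_kinetic(
    params: KineticParameters,
    t_span: Tuple[float, float],
    initial: Tuple[float, float, float],
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
):
    """Integrate the kinetic system; returns the scipy result object with
    rows of ``.y`` ordered (p, b, r).  Integrator failures are surfaced with
    the solver's diagnostic message."""
    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (3,) or np.any(y0 < 0):
        raise ValueError("initial must be a nonnegative (p, b, r) triple")
    sol = solve_ivp(
        kinetic_rhs, t_span, y0, args=(params,), method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"kinetic-model integration failed: {sol.message}")
    return sol
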