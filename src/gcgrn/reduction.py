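"""Mean-field ODE reduction of the stochastic network and steady-state
analysis.

Replacing each telegraph promoter by its stationary mean
``<E> = k_on/(k_on + k_off)`` turns the PDMP into the deterministic system

    dM/dt = s0 <E>(P, Q) - d0 M,      dP/dt = s1 M - d1 P,

with the rates evaluated continuously at the current protein levels and
stimulus intensities.  This is the fast-switching limit of the stochastic
model and is used to locate steady states, to test whether the stimulus
protocol moves the network between two distinct stable states (the GC and
PB_PC expression patterns), and to back out a promoter activation rate from
a target mean mRNA level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .network import CompiledNetwork, DegenerateRatesError, NetworkModel
from .simulate import StimulusSchedule, _stimulus_vector


def mean_promoter(kon: float, koff: float) -> float:
    """Stationary mean promoter occupancy kon/(kon+koff)."""
    if kon < 0 or koff < 0:
        raise ValueError("rates must be >= 0")
    if kon + koff == 0:
        raise DegenerateRatesError("kon and koff cannot both be zero")
    return kon / (kon + koff)


def _rhs(t: float, y: np.ndarray, net: CompiledNetwork, schedules) -> np.ndarray:
    m, p = y[:3], y[3:]
    x = np.maximum(p, 0.0)[None, :] / net.protein_max[None, :]
    q = _stimulus_vector(schedules, t) if schedules else np.zeros(2)
    kon, koff = net.rates(x, q)
    e_mean = kon[0] / (kon[0] + koff[0])
    dm = net.s0 * e_mean - net.d0 * np.maximum(m, 0.0)
    dp = net.s1 * np.maximum(m, 0.0) - net.d1 * np.maximum(p, 0.0)
    return np.concatenate([dm, dp])


def simulate_reduced(
    model: NetworkModel,
    schedules: Sequence[StimulusSchedule] | None,
    t_span: Tuple[float, float],
    initial: np.ndarray | None = None,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
):
    """Integrate the reduced system over ``t_span``.

    ``initial`` is the concatenated (M, P) 6-vector; ``None`` means the
    empty state.  Returns the scipy integration result (``.t``, ``.y``).
    """
    if not model.calibrated:
        model = model.calibrate()
    net = model.compile()
    y0 = np.zeros(6) if initial is None else np.asarray(initial, dtype=float)
    if y0.shape != (6,):
        raise ValueError("initial must be a 6-vector (M then P)")
    sol = solve_ivp(
        _rhs,
        t_span,
        y0,
        args=(net, schedules),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover - surfaced with diagnostics
        raise RuntimeError(f"reduced-model integration failed: {sol.message}")
    return sol


def _relax(
    model: NetworkModel,
    y0: np.ndarray,
    window: float = 50.0,
    rel_tol: float = 1e-6,
    max_horizon: float = 5000.0,
) -> Tuple[np.ndarray, bool]:
    """Integrate the stimulus-free system window by window until the relative
    state change over one window drops below ``rel_tol``."""
    if not model.calibrated:
        model = model.calibrate()
    net = model.compile()
    scale = np.concatenate([net.s0 / net.d0, net.s0 * net.s1 / (net.d0 * net.d1)])
    t = 0.0
    y = np.asarray(y0, dtype=float)
    while t < max_horizon:
        sol = simulate_reduced(model, None, (0.0, window), y)
        y_new = sol.y[:, -1]
        denom = np.maximum(np.abs(y_new), 1e-9)
        change = np.max(np.abs(y_new - y) / denom)
        # near a saddle-node the window-change criterion can stall; a tiny
        # scaled vector-field residual is equally conclusive
        residual = np.max(np.abs(_rhs(0.0, y_new, net, None)) / scale)
        y = y_new
        t += window
        if change < rel_tol or residual < 1e-9:
            return y, True
    return y, False


@dataclass(frozen=True)
class SteadyStateReport:
    """Pre- and post-stimulus steady states of the reduced model.

    ``pre_M``/``post_M`` are per-gene mRNA levels (BCL6, IRF4, BLIMP1 order),
    ``bistable`` is True when the stimulus protocol left the system in a
    second stimulus-free fixed point distinct from the first.
    """

    pre_M: np.ndarray
    post_M: np.ndarray
    pre_P: np.ndarray
    post_P: np.ndarray
    bistable: bool
    converged: bool
    residual_pre: float
    residual_post: float


def detect_bistability(
    model: NetworkModel,
    schedules: Sequence[StimulusSchedule],
    tolerance: float = 0.05,
    residual_tol: float = 1e-6,
) -> SteadyStateReport:
    """Relax to the pre-stimulus steady state from the empty state, run the
    full stimulus protocol, relax again without stimuli, and compare.

    The system is declared bistable when the two relaxed states differ in
    relative norm by more than ``tolerance`` *and* both are genuine fixed
    points of the stimulus-free vector field (scaled residual below
    ``residual_tol``).  Non-convergence within the horizon is reported via
    ``converged`` rather than raised.
    """
    if not model.calibrated:
        model = model.calibrate()
    net = model.compile()
    pre, ok_pre = _relax(model, np.zeros(6))
    t_end = max(s.ramp_down_end for s in schedules) + 20.0
    sol = simulate_reduced(model, schedules, (0.0, t_end), pre)
    post, ok_post = _relax(model, sol.y[:, -1])

    def scaled_residual(y: np.ndarray) -> float:
        f = _rhs(0.0, y, net, None)
        scale = np.concatenate([net.s0 / net.d0, net.s0 * net.s1 / (net.d0 * net.d1)])
        return float(np.max(np.abs(f) / scale))

    res_pre, res_post = scaled_residual(pre), scaled_residual(post)
    rel_diff = np.linalg.norm(post - pre) / max(np.linalg.norm(pre), 1e-12)
    bistable = bool(
        ok_pre
        and ok_post
        and rel_diff > tolerance
        and res_pre < residual_tol
        and res_post < residual_tol
    )
    return SteadyStateReport(
        pre_M=pre[:3],
        post_M=post[:3],
        pre_P=pre[3:],
        post_P=post[3:],
        bistable=bistable,
        converged=ok_pre and ok_post,
        residual_pre=res_pre,
        residual_post=res_post,
    )


def estimate_kon_init(
    target_mean_mrna: float, s0: float, d0: float, koff_init: float
) -> float:
    """Promoter activation rate at which the reduced model's steady mRNA
    equals ``target_mean_mrna``.

    At a fixed point  M* = s0 <E>/d0  with  <E> = kon/(kon+koff), so the
    required occupancy is eps = d0*M*/s0 and  kon = koff * eps/(1-eps).
    Raises when the target exceeds the s0/d0 expression ceiling.
    """
    if target_mean_mrna < 0:
        raise ValueError("target mean mRNA must be >= 0")
    if s0 <= 0 or d0 <= 0 or koff_init <= 0:
        raise ValueError("s0, d0 and koff_init must be > 0")
    eps = d0 * target_mean_mrna / s0
    if eps >= 1.0:
        raise ValueError(
            f"target mRNA {target_mean_mrna} exceeds the ceiling s0/d0 = {s0 / d0}"
        )
    return koff_init * eps / (1.0 - eps)
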