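"""Piecewise-deterministic simulation of the network.

Between promoter switches the mRNA/protein pair of each gene follows the
linear ODEs  M' = s0*E - d0*M,  P' = s1*M - d1*P.  The simulator advances in
fixed steps ``dt``: the switching rates are evaluated at the current protein
levels and stimulus intensities and frozen over the step, each promoter is
redrawn from the exact two-state master-equation probability

    pi = E * exp(-dt (kon+koff)) + kon/(kon+koff) * (1 - exp(-dt (kon+koff)))

and M, P are then advanced by the closed-form solution of the linear system
with the freshly drawn promoter state held constant.  The per-step update is
therefore exact; only the rate freezing introduces an O(dt) error.

A simulation runs a 500 h stimulus-free burn-in from the empty state, takes
the germinal-center (GC) snapshot at t = 0- (just before the stimuli), then
applies the BCR and CD40 ramp-plateau-ramp protocols and takes the
plasmablast/plasma-cell (PB_PC) snapshot at the end of the post-stimulus
window.  Cells are independent: each draws its promoter noise from its own
RNG substream spawned deterministically from the master seed, so cell ``i``
of a given seed is identical no matter how many cells are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .datasets import SCDataset
from .network import STIMULI, CompiledNetwork, DegenerateRatesError, NetworkModel


@dataclass(frozen=True)
class StimulusSchedule:
    """Piecewise-linear intensity profile of one stimulus.

    Zero before ``ramp_up[0]``, linear rise to ``amplitude`` over
    ``ramp_up``, constant until ``plateau_end``, linear fall back to zero at
    ``ramp_down_end``, zero afterwards.  Times in hours, amplitude
    dimensionless (the thresholds H_{s,i} carry the scale).
    """

    stimulus_id: str
    ramp_up: Tuple[float, float] = (0.5, 1.5)
    plateau_end: float = 24.0
    ramp_down_end: float = 25.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.stimulus_id not in STIMULI:
            raise ValueError(f"unknown stimulus {self.stimulus_id!r}")
        t0, t1 = self.ramp_up
        if not (t0 < t1 <= self.plateau_end < self.ramp_down_end):
            raise ValueError(
                "schedule must satisfy ramp start < ramp end <= plateau end < ramp-down end"
            )
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def value(self, t: float) -> float:
        """Intensity at time t (total function; zero outside the window)."""
        t0, t1 = self.ramp_up
        return float(
            np.interp(
                t,
                [t0, t1, self.plateau_end, self.ramp_down_end],
                [0.0, self.amplitude, self.amplitude, 0.0],
                left=0.0,
                right=0.0,
            )
        )


def default_schedules() -> Tuple[StimulusSchedule, StimulusSchedule]:
    """The BCR/CD40 protocol used throughout: BCR acts on [0.5, 25] h with
    plateau [1.5, 24] h, CD40 on [35, 61] h with plateau [36, 60] h."""
    return (
        StimulusSchedule("BCR", (0.5, 1.5), 24.0, 25.0, 1.0),
        StimulusSchedule("CD40", (35.0, 36.0), 60.0, 61.0, 1.0),
    )


def stimulus_value(schedule: StimulusSchedule, t: float) -> float:
    return schedule.value(t)


def _stimulus_vector(schedules: Iterable[StimulusSchedule], t: float) -> np.ndarray:
    q = np.zeros(len(STIMULI))
    for sched in schedules:
        q[STIMULI.index(sched.stimulus_id)] += sched.value(t)
    return q


@dataclass(frozen=True)
class SimulationProtocol:
    """Timing and size of a simulation run (hours)."""

    burn_in: float = 500.0
    post_stimulus: float = 500.0
    dt: float = 0.1
    sample_every: float = 0.5
    n_cells: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in <= 0 or self.post_stimulus <= 0:
            raise ValueError("burn_in and post_stimulus must be > 0")
        if self.dt <= 0 or self.dt > self.sample_every:
            raise ValueError("need 0 < dt <= sample_every")
        if abs(self.sample_every / self.dt - round(self.sample_every / self.dt)) > 1e-9:
            raise ValueError("sample_every must be an integer multiple of dt")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round((self.burn_in + self.post_stimulus) / self.dt))

    @property
    def steps_per_sample(self) -> int:
        return int(round(self.sample_every / self.dt))


@dataclass
class CellState:
    """State of one cell: time, binary promoter states, mRNA and protein."""

    t: float
    E: np.ndarray
    M: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=int)
        self.M = np.asarray(self.M, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if not np.all((self.E == 0) | (self.E == 1)):
            raise ValueError("promoter states must be binary")
        if np.any(self.M < 0) or np.any(self.P < 0):
            raise ValueError("molecule counts must be >= 0")

    @classmethod
    def empty(cls, t: float = 0.0) -> "CellState":
        return cls(t=t, E=np.zeros(3, dtype=int), M=np.zeros(3), P=np.zeros(3))


def promoter_transition_prob(E, kon, koff, dt) -> np.ndarray | float:
    """P(promoter on at t+dt | state E at t) for the two-state chain with
    constant rates, from the master-equation solution."""
    kon = np.asarray(kon, dtype=float)
    koff = np.asarray(koff, dtype=float)
    if np.any(kon < 0) or np.any(koff < 0):
        raise ValueError("rates must be >= 0")
    s = kon + koff
    if np.any(s == 0):
        raise DegenerateRatesError("kon and koff cannot both be zero")
    if np.any(np.asarray(dt) < 0):
        raise ValueError("dt must be >= 0")
    decay = np.exp(-np.asarray(dt, dtype=float) * s)
    pi = np.asarray(E, dtype=float) * decay + kon / s * (1.0 - decay)
    if pi.ndim == 0:
        return float(pi)
    return pi


class _Engine:
    """Vectorised stepping core shared by all simulation entry points."""

    def __init__(self, net: CompiledNetwork, dt: float):
        self.net = net
        self.dt = dt
        d0, d1 = net.d0, net.d1
        self.a0 = np.exp(-d0 * dt)
        self.a1 = np.exp(-d1 * dt)
        # M(t+dt) = Msat + (M - Msat) a0 with Msat = s0 E / d0
        # P(t+dt) = P a1 + Msat c_sat + (M - Msat) c_tr
        self.c_sat = net.s1 * (1.0 - self.a1) / d1
        with np.errstate(divide="ignore", invalid="ignore"):
            c_tr = net.s1 * (self.a0 - self.a1) / (d1 - d0)
        self.c_tr = np.where(np.isclose(d0, d1), net.s1 * dt * self.a1, c_tr)

    def step(
        self,
        E: np.ndarray,
        M: np.ndarray,
        P: np.ndarray,
        q: np.ndarray,
        u: np.ndarray,
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """One dt step for a batch; ``u`` are the (n, 3) uniform draws."""
        net = self.net
        x = P / net.protein_max[None, :]
        kon, koff = net.rates(x, q)
        pi = promoter_transition_prob(E, kon, koff, self.dt)
        E_new = (u < pi).astype(np.int8)
        m_sat = net.s0 * E_new / net.d0
        trans = M - m_sat
        P_new = P * self.a1 + m_sat * self.c_sat + trans * self.c_tr
        M_new = m_sat + trans * self.a0
        return E_new, np.maximum(M_new, 0.0), np.maximum(P_new, 0.0)


def step_cell(
    state: CellState,
    model: NetworkModel,
    schedules: Sequence[StimulusSchedule],
    dt: float,
    rng: np.random.Generator,
) -> CellState:
    """Advance one cell by one step (rates frozen over [t, t+dt], promoters
    redrawn, then mRNA/protein advanced exactly with the new promoter)."""
    engine = _Engine(model.compile(), dt)
    q = _stimulus_vector(schedules, state.t)
    u = rng.random((1, 3))
    e, m, p = engine.step(
        state.E[None, :].astype(np.int8), state.M[None, :], state.P[None, :], q, u
    )
    return CellState(t=state.t + dt, E=e[0], M=m[0], P=p[0])


def _cell_rngs(seed: int, n_cells: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_cells)]


def _run_batch(
    model: NetworkModel,
    schedules: Sequence[StimulusSchedule],
    protocol: SimulationProtocol,
    cell_indices: Sequence[int],
    record_trajectory: bool,
):
    """Simulate the requested cells in lockstep.  Returns (times, samples,
    gc, pb) where ``samples`` is (n_samples, n, 3) mRNA if recording was
    requested else None, and gc/pb are the (n, 3) stage snapshots."""
    if not model.calibrated:
        model = model.calibrate()
    net = model.compile()
    engine = _Engine(net, protocol.dt)
    n = len(cell_indices)
    rngs = _cell_rngs(protocol.seed, max(cell_indices) + 1)
    n_steps = protocol.n_steps
    # pre-draw each cell's promoter noise from its own substream
    u_all = np.empty((n, n_steps, 3))
    for row, ci in enumerate(cell_indices):
        u_all[row] = rngs[ci].random((n_steps, 3))

    E = np.zeros((n, 3), dtype=np.int8)
    M = np.zeros((n, 3))
    P = np.zeros((n, 3))
    burn_steps = int(round(protocol.burn_in / protocol.dt))
    k_sample = protocol.steps_per_sample

    times = [-protocol.burn_in]
    samples = [M.copy()] if record_trajectory else None
    gc = None
    t = -protocol.burn_in
    for step in range(n_steps):
        if step == burn_steps:
            gc = M.copy()  # state at t = 0-, before any stimulus acts
        q = _stimulus_vector(schedules, t) if step >= burn_steps else np.zeros(2)
        E, M, P = engine.step(E, M, P, q, u_all[:, step, :])
        t = -protocol.burn_in + (step + 1) * protocol.dt
        if record_trajectory and (step + 1) % k_sample == 0:
            times.append(t)
            samples.append(M.copy())
    if gc is None:  # burn_in equals the whole run (not reachable via protocol)
        gc = M.copy()
    pb = M.copy()
    sample_arr = np.stack(samples) if record_trajectory else None
    return np.array(times), sample_arr, gc, pb


def simulate_cell(
    model: NetworkModel,
    schedules: Sequence[StimulusSchedule],
    protocol: SimulationProtocol,
    cell_index: int = 0,
):
    """Trajectory of a single cell plus its stage snapshots.

    Returns ``(trajectory, snapshots)`` where ``trajectory`` is a DataFrame
    with columns time, BCL6, IRF4, BLIMP1 (mRNA sampled every
    ``sample_every``) and ``snapshots`` maps 'GC' / 'PB_PC' to length-3 mRNA
    vectors (GC at t = 0-, PB_PC at t = post_stimulus).
    """
    times, samples, gc, pb = _run_batch(model, schedules, protocol, [cell_index], True)
    traj = pd.DataFrame(samples[:, 0, :], columns=["BCL6", "IRF4", "BLIMP1"])
    traj.insert(0, "time", times)
    return traj, {"GC": gc[0], "PB_PC": pb[0]}


def simulate_dataset(
    model: NetworkModel,
    schedules: Sequence[StimulusSchedule],
    protocol: SimulationProtocol,
) -> SCDataset:
    """Simulate ``protocol.n_cells`` independent cells and return their GC
    and PB_PC mRNA snapshots as a stage-labelled single-cell dataset
    (molecule scale, continuous values)."""
    _, _, gc, pb = _run_batch(
        model, schedules, protocol, list(range(protocol.n_cells)), False
    )
    frames = []
    for stage, snap in (("GC", gc), ("PB_PC", pb)):
        df = pd.DataFrame(snap, columns=["BCL6", "IRF4", "BLIMP1"])
        df.insert(0, "stage", stage)
        df.insert(0, "cell_id", [f"cell_{i:04d}" for i in range(len(snap))])
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return SCDataset(table, scale="molecules")
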