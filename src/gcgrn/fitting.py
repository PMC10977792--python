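"""Grid-search and one-dimensional-sweep calibration of the stochastic
network against stage-wise mean expression.

The objective compares, node by node over the six (gene, stage) pairs, the
mean expression of a simulated dataset (Upsilon) with the mean of the
reference dataset (Omega):

    OF = sum over nodes |Omega - Upsilon| / |Omega|

Because the run-to-run variability of the simulator is small relative to
between-parameter-set differences (see :func:`gcgrn.metrics.mtm_variability`),
each candidate parameter set is scored from a single simulated dataset.
Model output means are taken on the log2(x+1) scale; reference data on the
Et scale are treated as directly comparable (both are bounded log-like
scales), and raw-scale comparison is available via ``comparison_scale``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .datasets import GENE_COLUMNS, STAGES, SCDataset
from .network import NetworkModel
from .qpcr import dataset_means
from .simulate import SimulationProtocol, StimulusSchedule, simulate_dataset

NODES: Tuple[Tuple[str, str], ...] = tuple(
    (gene, stage) for gene in GENE_COLUMNS for stage in STAGES
)

#: candidate sets of the full automatized screen: theta values scaled by a
#: factor f_theta in {1,5} for five gene-gene edges and {1,10} for the IRF4
#: autoactivation and the two stimulus edges; H replaced outright from
#: {0.01,0.1,1} (gene-gene) or {0.0001,0.001,0.1,1,100} (autoactivation and
#: stimuli).  2^5 * 2^3 * 3^5 * 5^3 = 7,776,000 combinations.
FULL_GRID_THETA_MULTIPLIERS: Dict[str, Tuple[float, ...]] = {
    "theta.BCL6.BCL6": (1.0, 5.0),
    "theta.BCL6.BLIMP1": (1.0, 5.0),
    "theta.IRF4.BCL6": (1.0, 5.0),
    "theta.IRF4.BLIMP1": (1.0, 5.0),
    "theta.BLIMP1.BCL6": (1.0, 5.0),
    "theta.IRF4.IRF4": (1.0, 10.0),
    "theta.BCR.BCL6": (1.0, 10.0),
    "theta.CD40.IRF4": (1.0, 10.0),
}
FULL_GRID_H_CANDIDATES: Dict[str, Tuple[float, ...]] = {
    "H.BCL6.BCL6": (0.01, 0.1, 1.0),
    "H.BCL6.BLIMP1": (0.01, 0.1, 1.0),
    "H.IRF4.BCL6": (0.01, 0.1, 1.0),
    "H.IRF4.BLIMP1": (0.01, 0.1, 1.0),
    "H.BLIMP1.BCL6": (0.01, 0.1, 1.0),
    "H.IRF4.IRF4": (0.0001, 0.001, 0.1, 1.0, 100.0),
    "H.BCR.BCL6": (0.0001, 0.001, 0.1, 1.0, 100.0),
    "H.CD40.IRF4": (0.0001, 0.001, 0.1, 1.0, 100.0),
}


def objective_function(
    model_means: Mapping[Tuple[str, str], float],
    data_means: Mapping[Tuple[str, str], float],
) -> float:
    """Sum of relative absolute mean errors over the six (gene, stage) nodes."""
    total = 0.0
    for node in NODES:
        if node not in model_means or node not in data_means:
            raise KeyError(f"means are missing node {node}")
        omega = data_means[node]
        if omega == 0:
            raise ZeroDivisionError(
                f"reference mean for node {node} is zero; the relative objective is undefined"
            )
        total += abs(omega - model_means[node]) / abs(omega)
    return total


@dataclass(frozen=True)
class ParameterGrid:
    """Cartesian candidate grid around a base model.

    ``theta_multipliers`` maps a theta parameter name to the multiplicative
    factors applied to its base value; ``H_candidates`` maps an H parameter
    name to the replacement values.  Parameters not listed stay at base.
    """

    base: NetworkModel
    theta_multipliers: Mapping[str, Sequence[float]] = field(default_factory=dict)
    H_candidates: Mapping[str, Sequence[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        from .network import InteractionParams

        for name, values in {**dict(self.theta_multipliers), **dict(self.H_candidates)}.items():
            parts = name.split(".")
            if len(parts) != 3 or parts[0] not in ("theta", "H"):
                raise KeyError(f"unknown parameter name {name!r}")
            try:
                InteractionParams._check_pair(parts[1], parts[2])
            except ValueError as exc:
                raise KeyError(str(exc)) from exc
            if len(values) == 0:
                raise ValueError(f"empty candidate set for {name!r}")

    @classmethod
    def full_screen(cls, base: NetworkModel) -> "ParameterGrid":
        """The complete automatized screen (7,776,000 candidates)."""
        return cls(
            base=base,
            theta_multipliers=FULL_GRID_THETA_MULTIPLIERS,
            H_candidates=FULL_GRID_H_CANDIDATES,
        )

    def axes(self) -> list[Tuple[str, Tuple[float, ...]]]:
        """(name, candidate values) in fixed lexicographic name order, with
        theta multipliers resolved against the base value."""
        out: list[Tuple[str, Tuple[float, ...]]] = []
        base_theta = self.base.interactions.theta
        for name in sorted(set(self.theta_multipliers) | set(self.H_candidates)):
            if name in self.theta_multipliers:
                _, w, i = name.split(".")
                base_value = base_theta.get((w, i), 0.0)
                values = tuple(base_value * m for m in self.theta_multipliers[name])
            else:
                values = tuple(float(v) for v in self.H_candidates[name])
            out.append((name, values))
        return out


def grid_size(grid: ParameterGrid) -> int:
    """Exact number of candidates (product of candidate-set sizes)."""
    return math.prod(len(values) for _, values in grid.axes()) if grid.axes() else 1


def _iter_overrides(grid: ParameterGrid) -> Iterator[Dict[str, float]]:
    axes = grid.axes()
    if not axes:
        yield {}
        return
    names = [name for name, _ in axes]
    value_sets = [values for _, values in axes]
    idx = [0] * len(axes)
    while True:
        yield {name: values[i] for name, values, i in zip(names, value_sets, idx)}
        for pos in reversed(range(len(axes))):  # odometer: last axis fastest
            idx[pos] += 1
            if idx[pos] < len(value_sets[pos]):
                break
            idx[pos] = 0
        else:
            return


def build_grid(grid: ParameterGrid) -> Iterator[NetworkModel]:
    """Deterministic iterator over candidate models (lexicographic parameter
    order, last axis fastest).  Use :func:`grid_size` for the exact count
    without materialising anything."""
    for overrides in _iter_overrides(grid):
        yield grid.base.with_overrides(overrides)


@dataclass(frozen=True)
class FitResult:
    """One scored candidate: the model, its overrides and the objective."""

    model: NetworkModel
    overrides: Dict[str, float]
    of: float
    seed: int
    index: int


def _comparison_means(
    dataset: SCDataset, comparison_scale: str
) -> Dict[Tuple[str, str], float]:
    if comparison_scale == "log2p1" and dataset.scale == "molecules":
        dataset = dataset.to_log2p1()
    return dataset_means(dataset)


def _score_candidate(
    model: NetworkModel,
    schedules: Sequence[StimulusSchedule],
    protocol: SimulationProtocol,
    data_means: Mapping[Tuple[str, str], float],
    comparison_scale: str,
) -> float:
    simulated = simulate_dataset(model.calibrate(), schedules, protocol)
    return objective_function(_comparison_means(simulated, comparison_scale), data_means)


def run_grid_search(
    grid: ParameterGrid,
    reference_data: SCDataset,
    schedules: Sequence[StimulusSchedule],
    protocol: SimulationProtocol,
    subsample: Tuple[int, int] | None = None,
    comparison_scale: str = "log2p1",
) -> Tuple[FitResult, pd.DataFrame]:
    """Score every candidate (or a seeded random subsample ``(count, seed)``)
    with a single simulated dataset each and return the argmin plus the
    ranked table.

    Candidates whose simulation fails are recorded with OF = inf and the
    search continues.  Ties are broken by iteration order; everything is
    deterministic under fixed seeds.
    """
    data_means = _comparison_means(reference_data, comparison_scale)
    for node in NODES:
        if data_means.get(node, 0.0) == 0.0:
            raise ZeroDivisionError(f"reference data mean for node {node} is zero")
    n_total = grid_size(grid)
    keep: set[int] | None = None
    if subsample is not None:
        count, sub_seed = subsample
        count = min(count, n_total)
        rng = np.random.default_rng(sub_seed)
        keep = set(rng.choice(n_total, size=count, replace=False).tolist())
    rows = []
    best: FitResult | None = None
    for index, overrides in enumerate(_iter_overrides(grid)):
        if keep is not None and index not in keep:
            continue
        try:
            model = grid.base.with_overrides(overrides)
            of = _score_candidate(model, schedules, protocol, data_means, comparison_scale)
        except Exception:
            model, of = grid.base, float("inf")
        rows.append({"index": index, "of": of, **overrides})
        if best is None or of < best.of:
            best = FitResult(
                model=model, overrides=overrides, of=of, seed=protocol.seed, index=index
            )
    if best is None:
        raise ValueError("grid produced no candidates")
    ranked = pd.DataFrame(rows).sort_values(["of", "index"], kind="stable").reset_index(drop=True)
    return best, ranked


@dataclass(frozen=True)
class SweepSpec:
    """A one-dimensional sweep of a single parameter over [lo, hi]."""

    parameter: str
    lo: float
    hi: float
    points: int
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("need lo < hi")
        if self.points < 1:
            raise ValueError("points must be >= 1")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")
        if self.scale == "log" and self.lo * self.hi <= 0:
            raise ValueError("log scale requires lo and hi of the same sign, nonzero")

    def values(self) -> np.ndarray:
        if self.points == 1:
            return np.array([self.lo])
        if self.scale == "linear":
            return np.linspace(self.lo, self.hi, self.points)
        if self.lo > 0:
            return np.geomspace(self.lo, self.hi, self.points)
        # negative interval: sweep magnitudes log-wise, keep the sign/order
        return -np.geomspace(-self.lo, -self.hi, self.points)


def sweep_parameter(
    spec: SweepSpec,
    base: NetworkModel,
    reference_data: SCDataset,
    schedules: Sequence[StimulusSchedule],
    protocol: SimulationProtocol,
    comparison_scale: str = "log2p1",
) -> pd.DataFrame:
    """Perturb one parameter at a time and score each value; returns a
    (value, of) table sorted by value."""
    data_means = _comparison_means(reference_data, comparison_scale)
    rows = []
    for value in spec.values():
        try:
            model = base.with_overrides({spec.parameter: float(value)})
            of = _score_candidate(model, schedules, protocol, data_means, comparison_scale)
        except Exception:
            of = float("inf")
        rows.append({"value": float(value), "of": of})
    return pd.DataFrame(rows).sort_values("value").reset_index(drop=True)
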