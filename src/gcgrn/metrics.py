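"""Binned Kantorovich distance and the model-to-model variability study.

The Kantorovich distance (KD) between two samples is computed on a shared
equal-width binning spanning the pooled range:

    KD = sum_{n=1..N} | CDF_p(n) - CDF_q(n) |

i.e. the discrete 1-D Wasserstein distance in units of one bin width.  By
default samples are compared on the log2(x+1) scale, the scale on which the
expression histograms are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .datasets import GENE_COLUMNS, STAGES, SCDataset
from .network import NetworkModel
from .simulate import SimulationProtocol, StimulusSchedule, simulate_dataset

DEFAULT_BINS = 30


@dataclass(frozen=True)
class BinnedDistribution:
    """A discrete distribution on equal-width bins."""

    edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        prob = np.asarray(self.probabilities, dtype=float)
        if edges.ndim != 1 or len(edges) != len(prob) + 1:
            raise ValueError("need len(edges) == len(probabilities) + 1")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-12):
            raise ValueError("bins must have equal widths")
        if np.any(prob < 0) or abs(prob.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be >= 0 and sum to 1")

    @property
    def centers(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return 0.5 * (e[:-1] + e[1:])


def _shared_binning(a: np.ndarray, b: np.ndarray, n_bins: int) -> np.ndarray | None:
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return None  # zero pooled range
    return np.linspace(lo, hi, n_bins + 1)


def kantorovich_distance(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    n_bins: int = DEFAULT_BINS,
    log2p1: bool = True,
    edges: np.ndarray | None = None,
) -> float:
    """KD between two samples binned on a common equal-width grid.

    Symmetric, nonnegative, zero iff the binned distributions coincide.  A
    zero pooled range (all values identical) yields 0 by convention.  By
    default the grid spans the pooled min-max of the two samples; pass
    ``edges`` to fix one grid across several comparisons (KD is a metric
    only on a fixed binning).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if log2p1:
        a = np.log2(a + 1.0)
        b = np.log2(b + 1.0)
    if edges is None:
        edges = _shared_binning(a, b, n_bins)
    if edges is None:
        return 0.0
    p, _ = np.histogram(a, bins=edges)
    q, _ = np.histogram(b, bins=edges)
    cdf_p = np.cumsum(p / p.sum())
    cdf_q = np.cumsum(q / q.sum())
    return float(np.abs(cdf_p - cdf_q).sum())


def histogram_log2p1(
    dataset: SCDataset, gene: str, stage: str, n_bins: int = DEFAULT_BINS
) -> BinnedDistribution:
    """Relative-frequency histogram of log2(x+1)-transformed expression for
    one (gene, stage) slice."""
    values = np.log2(dataset.stage_values(gene, stage) + 1.0)
    lo, hi = values.min(), values.max()
    if hi == lo:  # single occupied bin around the common value
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return BinnedDistribution(edges=edges, probabilities=counts / counts.sum())


@dataclass(frozen=True)
class KDResult:
    """Pairwise KD values per (gene, stage) node plus summary statistics.

    ``stage_contrast`` holds, per gene, the within-dataset KD between the GC
    and PB_PC distributions of each replicate: the biological stage signal
    against which the model-to-model sampling noise is judged.
    """

    distances: Dict[Tuple[str, str], np.ndarray]
    n_datasets: int
    stage_contrast: Dict[str, np.ndarray]

    def summary(self) -> pd.DataFrame:
        rows = []
        for (gene, stage), kd in self.distances.items():
            q1, med, q3 = np.percentile(kd, [25, 50, 75])
            rows.append(
                {"gene": gene, "stage": stage, "median": med, "iqr": q3 - q1,
                 "mean": kd.mean(), "n_pairs": len(kd)}
            )
        return pd.DataFrame(rows)

    def median(self, gene: str, stage: str) -> float:
        return float(np.median(self.distances[(gene, stage)]))

    def median_stage_contrast(self, gene: str) -> float:
        return float(np.median(self.stage_contrast[gene]))


def mtm_variability(
    model: NetworkModel,
    schedules: Sequence[StimulusSchedule],
    protocol: SimulationProtocol,
    n_datasets: int,
    n_bins: int = DEFAULT_BINS,
) -> KDResult:
    """Model-to-model variability: simulate ``n_datasets`` independent
    datasets from one parameter set and collect the KD between every
    unordered pair, per gene and stage (6 nodes).

    Dataset ``k`` uses seed ``protocol.seed + k`` so replicates are
    independent but the whole study is reproducible.
    """
    if n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    if not model.calibrated:
        model = model.calibrate()
    from dataclasses import replace as _replace

    datasets = [
        simulate_dataset(model, schedules, _replace(protocol, seed=protocol.seed + k))
        for k in range(n_datasets)
    ]
    slices = {
        (gene, stage): [d.stage_values(gene, stage) for d in datasets]
        for gene in GENE_COLUMNS
        for stage in STAGES
    }
    distances = {
        node: np.array(
            [
                kantorovich_distance(vals[i], vals[j], n_bins)
                for i, j in combinations(range(n_datasets), 2)
            ]
        )
        for node, vals in slices.items()
    }
    stage_contrast = {
        gene: np.array(
            [
                kantorovich_distance(
                    d.stage_values(gene, "GC"), d.stage_values(gene, "PB_PC"), n_bins
                )
                for d in datasets
            ]
        )
        for gene in GENE_COLUMNS
    }
    return KDResult(distances=distances, n_datasets=n_datasets, stage_contrast=stage_contrast)
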