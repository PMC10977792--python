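"""Generator of experiment-like single-cell qPCR datasets.

Single-cell RT-qPCR reports a cycle threshold Ct per gene and cell; the
expression threshold transform Et = 30 - Ct maps it to a bounded positive
scale, with undetected expression (Ct > 30) recorded as an exact zero
("dropout").  The generator reproduces the *structure* of such data - stage
sizes, per-gene exact dropout counts, positive values bounded in (0, 30] -
without claiming the real positive-value distributions: positives are drawn
from a truncated normal whose defaults merely exercise the pipeline.

The default profiles encode two differentiation stages of germinal-center
B cells: GC (317 cells; 30/292/292 zeros for BCL6/IRF4/BLIMP1) and PB_PC
(104 cells; 25/79/5 zeros).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .datasets import ET_MAX, GENE_COLUMNS, SCDataset


@dataclass(frozen=True)
class StageProfile:
    """Dropout counts and positive-value law for one stage.

    ``n_zero`` maps gene -> exact number of zero cells; ``positive_law``
    maps gene -> (mu, sd) of a normal truncated to (0, 30] from which the
    non-zero Et values are drawn.
    """

    stage: str
    n_cells: int
    n_zero: Mapping[str, int]
    positive_law: Mapping[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in ("GC", "PB_PC"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for gene in GENE_COLUMNS:
            nz = self.n_zero.get(gene, 0)
            if not 0 <= nz <= self.n_cells:
                raise ValueError(f"{self.stage}/{gene}: n_zero={nz} outside [0, {self.n_cells}]")
            mu, sd = self.positive_law.get(gene, DEFAULT_POSITIVE_LAW)
            if not 0 < mu < ET_MAX:
                raise ValueError(f"{self.stage}/{gene}: mu must lie in (0, {ET_MAX})")
            if sd <= 0:
                raise ValueError(f"{self.stage}/{gene}: sd must be > 0")


#: default (mu, sd) of the truncated normal for positive Et values; chosen
#: only to give plausible unimodal bounded values, not derived from data.
DEFAULT_POSITIVE_LAW: Tuple[float, float] = (8.0, 2.5)


def default_profiles() -> Tuple[StageProfile, StageProfile]:
    """Stage sizes and per-gene dropout counts of the reference experiment."""
    return (
        StageProfile(
            stage="GC",
            n_cells=317,
            n_zero={"BCL6": 30, "IRF4": 292, "BLIMP1": 292},
        ),
        StageProfile(
            stage="PB_PC",
            n_cells=104,
            n_zero={"BCL6": 25, "IRF4": 79, "BLIMP1": 5},
        ),
    )


def et_from_ct(ct: float) -> float:
    """Expression threshold Et = 30 - Ct, clamped to 0 for undetected
    expression (Ct > 30)."""
    if ct < 0:
        raise ValueError("Ct must be >= 0")
    return 0.0 if ct >= ET_MAX else ET_MAX - ct


def generate_experimental_like(
    profiles: Sequence[StageProfile] | None = None,
    seed: int = 0,
) -> SCDataset:
    """Draw an Et-scale dataset with *exactly* the profiled dropout counts.

    Within each stage and gene the zero cells are chosen by an independent
    seeded shuffle, and the remaining cells draw from the stage/gene
    truncated normal on (0, 30].
    """
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for profile in profiles:
        data: Dict[str, np.ndarray] = {}
        for gene in GENE_COLUMNS:
            mu, sd = profile.positive_law.get(gene, DEFAULT_POSITIVE_LAW)
            a, b = (0.0 - mu) / sd, (ET_MAX - mu) / sd
            values = truncnorm.rvs(a, b, loc=mu, scale=sd, size=profile.n_cells, random_state=rng)
            # truncnorm includes the lower bound; exact zeros are set below
            values = np.maximum(values, np.finfo(float).tiny)
            zero_idx = rng.permutation(profile.n_cells)[: profile.n_zero.get(gene, 0)]
            values[zero_idx] = 0.0
            data[gene] = values
        df = pd.DataFrame(data)
        df.insert(0, "stage", profile.stage)
        df.insert(0, "cell_id", [f"cell_{offset + i:04d}" for i in range(profile.n_cells)])
        offset += profile.n_cells
        frames.append(df)
    return SCDataset(pd.concat(frames, ignore_index=True), scale="Et")


def dataset_means(dataset: SCDataset) -> Dict[Tuple[str, str], float]:
    """Arithmetic mean per (gene, stage) node, zeros included, on the
    dataset's own scale.  Raises when a node has no cells."""
    out: Dict[Tuple[str, str], float] = {}
    for stage in dataset.frame["stage"].unique():
        for gene in GENE_COLUMNS:
            out[(gene, stage)] = float(dataset.stage_values(gene, stage).mean())
    return out
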