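"""Stage-labelled single-cell expression tables and their CSV dialect.

A dataset is a cells x genes table with columns ``cell_id``, ``stage``
(GC or PB_PC) and one column per gene (BCL6, IRF4, BLIMP1), plus a scale
tag: ``molecules`` (simulator output, continuous), ``Et`` (qPCR expression
threshold, bounded by 30) or ``log2p1`` (log2(x+1)-transformed molecules).
On disk the scale travels in a ``# scale: <tag>`` comment line above the
header; write -> read round-trips values, labels and the tag.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from os import PathLike
from typing import Tuple

import numpy as np
import pandas as pd

GENE_COLUMNS = ["BCL6", "IRF4", "BLIMP1"]
STAGES: Tuple[str, str] = ("GC", "PB_PC")
SCALES = ("molecules", "Et", "log2p1")
ET_MAX = 30.0


class DatasetFormatError(ValueError):
    """Raised on malformed dataset files or invalid in-memory tables."""


@dataclass
class SCDataset:
    """A single-cell expression matrix with stage labels and a scale tag."""

    frame: pd.DataFrame
    scale: str = "molecules"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise DatasetFormatError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        missing = [c for c in ["cell_id", "stage", *GENE_COLUMNS] if c not in self.frame.columns]
        if missing:
            raise DatasetFormatError(f"dataset is missing column(s) {missing}")
        bad_stages = set(self.frame["stage"]) - set(STAGES)
        if bad_stages:
            raise DatasetFormatError(f"unknown stage label(s) {sorted(bad_stages)}")
        values = self.frame[GENE_COLUMNS].to_numpy(dtype=float)
        if np.any(values < 0):
            raise DatasetFormatError("expression values must be >= 0")
        if self.scale == "Et" and np.any(values > ET_MAX):
            raise DatasetFormatError(f"Et-scale values must be <= {ET_MAX}")

    def stage_values(self, gene: str, stage: str) -> np.ndarray:
        """Expression of one gene in one stage (1-D array)."""
        if gene not in GENE_COLUMNS:
            raise KeyError(f"unknown gene {gene!r}")
        if stage not in STAGES:
            raise KeyError(f"unknown stage {stage!r}")
        sub = self.frame.loc[self.frame["stage"] == stage, gene]
        if sub.empty:
            raise KeyError(f"dataset has no cells for stage {stage!r}")
        return sub.to_numpy(dtype=float)

    def n_cells(self, stage: str | None = None) -> int:
        if stage is None:
            return len(self.frame)
        return int((self.frame["stage"] == stage).sum())

    def to_log2p1(self) -> "SCDataset":
        """log2(x+1)-transformed copy (the reporting/comparison scale)."""
        if self.scale == "log2p1":
            return self
        out = self.frame.copy()
        out[GENE_COLUMNS] = np.log2(out[GENE_COLUMNS].to_numpy(dtype=float) + 1.0)
        return SCDataset(out, scale="log2p1")


def write_dataset(dataset: SCDataset, path: str | PathLike) -> None:
    """Write to CSV with the scale tag in a leading comment line."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# scale: {dataset.scale}\n")
        dataset.frame.to_csv(fh, index=False)


def read_dataset(path: str | PathLike) -> SCDataset:
    """Read a dataset CSV, validating header, stages, value ranges and the
    scale comment (defaults to ``molecules`` when the comment is absent)."""
    with open(path) as fh:
        first = fh.readline()
        scale = "molecules"
        if first.startswith("#"):
            if "scale:" not in first:
                raise DatasetFormatError(f"{path}: line 1: unrecognised comment {first.strip()!r}")
            scale = first.split("scale:", 1)[1].strip()
            body = fh.read()
        else:
            body = first + fh.read()
    try:
        frame = pd.read_csv(io.StringIO(body))
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DatasetFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    for required in ("cell_id", "stage"):
        if required not in frame.columns:
            raise DatasetFormatError(f"{path}: line 2: missing required column {required!r}")
    try:
        return SCDataset(frame, scale=scale)
    except DatasetFormatError as exc:
        raise DatasetFormatError(f"{path}: {exc}") from exc
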