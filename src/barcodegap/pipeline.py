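"""Orchestrate the full alignment x distance-model x prior comparison.

``run_comparison`` takes any number of labelled alignments (e.g. the same
sequences aligned by different programs) and distance corrections, builds each
distance matrix, sweeps the prior grid, and collates OTU counts together with
per-alignment site statistics.  Failures (a saturated matrix, too few defined
pairs) are confined to their grid cell so one bad combination never loses the
rest of the run.  Output tables are deterministic given the inputs.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence, Union

import numpy as np
import pandas as pd

from .alignment import MultipleAlignment, SiteSummary, site_summary
from .distances import DistanceMatrix, DistanceModelSpec, build_distance_matrix
from .gap import (
    DEFAULT_PRIOR_GRID,
    DEFAULT_X,
    PriorSweepRow,
    prior_sweep,
)

__all__ = [
    "ComparisonCell",
    "ComparisonGrid",
    "MetadataSummary",
    "run_comparison",
    "summarize_metadata",
]

log = logging.getLogger("barcodegap")


@dataclass(frozen=True)
class ComparisonCell:
    """One (alignment, model) combination: the sweep rows, or the error."""

    alignment_label: str
    model: str
    sweep: tuple[PriorSweepRow, ...] = ()
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None

    def modal_initial_count(self) -> int | None:
        """The modal initial-partition count across the prior grid — the
        single headline OTU number for this alignment/model combination
        (initial partitions are typically stable across priors)."""
        if self.failed or not self.sweep:
            return None
        counts = pd.Series([r.n_initial for r in self.sweep])
        return int(counts.mode().iloc[0])


@dataclass(frozen=True)
class ComparisonGrid:
    """Complete grid of sweep results plus per-alignment site summaries."""

    cells: tuple[ComparisonCell, ...]
    site_summaries: dict[str, SiteSummary] = field(default_factory=dict)

    @property
    def any_failed(self) -> bool:
        return any(c.failed for c in self.cells)

    def cell(self, alignment_label: str, model: str) -> ComparisonCell:
        for c in self.cells:
            if c.alignment_label == alignment_label and c.model == model:
                return c
        raise KeyError((alignment_label, model))

    def sweep_table(self) -> pd.DataFrame:
        """Rows = priors, column blocks = alignment x model (recursive counts),
        mirroring the classic ABGD summary layout."""
        frames = {}
        priors = None
        for c in self.cells:
            if c.failed:
                continue
            col = f"{c.alignment_label}:{c.model}"
            frames[col] = [r.n_recursive for r in c.sweep]
            priors = [r.prior for r in c.sweep]
        out = pd.DataFrame(frames)
        out.insert(0, "prior", priors if priors is not None else [])
        return out

    def otu_table(self) -> pd.DataFrame:
        """Rows = alignments, columns = models: modal initial OTU counts."""
        labels = list(dict.fromkeys(c.alignment_label for c in self.cells))
        models = list(dict.fromkeys(c.model for c in self.cells))
        data = {
            m: [self.cell(lab, m).modal_initial_count() for lab in labels]
            for m in models
        }
        return pd.DataFrame(data, index=labels)

    def site_table(self) -> pd.DataFrame:
        rows = {lab: s.as_dict() for lab, s in self.site_summaries.items()}
        return pd.DataFrame.from_dict(rows, orient="index")


def run_comparison(
    alignments: Sequence[tuple[str, MultipleAlignment]],
    models: Sequence[Union[str, DistanceModelSpec]],
    p_min: float = DEFAULT_PRIOR_GRID[0],
    p_max: float = DEFAULT_PRIOR_GRID[1],
    steps: int = DEFAULT_PRIOR_GRID[2],
    x: float = DEFAULT_X,
    window: int | None = None,
) -> ComparisonGrid:
    """Sweep every alignment under every distance model.

    Each cell equals a direct :func:`~barcodegap.gap.prior_sweep` call on the
    same inputs; cell-level errors are captured in the cell, not raised.
    """
    if not alignments or not models:
        raise ValueError("need at least one alignment and one model")
    specs = [DistanceModelSpec(m) if isinstance(m, str) else m for m in models]
    cells: list[ComparisonCell] = []
    summaries: dict[str, SiteSummary] = {}
    for label, aln in alignments:
        summaries[label] = site_summary(aln)
        for spec in specs:
            try:
                dm = build_distance_matrix(aln, spec)
                rows = prior_sweep(dm, p_min, p_max, steps, x, window)
                cells.append(ComparisonCell(label, spec.model, tuple(rows)))
            except Exception as exc:  # per-cell failure policy
                log.warning("cell (%s, %s) failed: %s", label, spec.model, exc)
                cells.append(ComparisonCell(label, spec.model, (), error=str(exc)))
    return ComparisonGrid(tuple(cells), summaries)


@dataclass(frozen=True)
class MetadataSummary:
    """Frequency table of one categorical metadata column."""

    column: str
    counts: pd.Series
    n_rows: int

    def as_frame(self) -> pd.DataFrame:
        return self.counts.rename("count").rename_axis(self.column).reset_index()


def summarize_metadata(
    table: Union[str, Path, IO[str], pd.DataFrame],
    column: str,
    sep: str = "\t",
) -> MetadataSummary:
    """Count category frequencies in a delimited metadata table.

    Empty cells are grouped as ``(missing)``; counts are returned in
    descending order and always sum to the number of rows.
    """
    if isinstance(table, pd.DataFrame):
        frame = table
    else:
        frame = pd.read_csv(table, sep=sep, dtype=str)
    if column not in frame.columns:
        raise KeyError(f"column {column!r} not in table (has {list(frame.columns)})")
    values = frame[column].fillna("(missing)").replace("", "(missing)")
    counts = values.value_counts(sort=True)
    return MetadataSummary(column=column, counts=counts, n_rows=len(frame))
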