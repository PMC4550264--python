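"""Automatic barcode-gap discovery and OTU partitioning.

The barcode-gap principle: pairwise distances within a species are small,
distances between species are large, and the empty interval between the two
distributions — the *barcode gap* — can be used as a clustering threshold.
Given a prior upper bound ``P`` on intraspecific divergence, the scan ranks
all defined pairwise distances, looks for the first conspicuously wide jump at
or above the prior, and single-links sequences below the gap midpoint into
hypothetical species (OTUs).  Re-applying the scan inside each group until
nothing splits yields the *recursive* partition, always a refinement of the
*initial* one.  Sweeping the prior over a geometric grid reproduces the
classic prior-vs-group-count diagnostic tables.

Gap-significance criterion (this package's concretisation, tunable): with
ranked distances d(1..N) and consecutive gaps g_i = d(i+1) - d(i), a gap at
rank i qualifies iff it reaches above the prior (d(i+1) >= prior; distances
below the prior are intraspecific by assumption, but the gap itself may start
below it) and g_i > X * m_i, where m_i is the mean of the (up to) w gaps
preceding i and w = max(10, ceil(0.01 N)).  The first qualifying rank wins;
the threshold is the gap midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix

__all__ = [
    "GapScanResult",
    "SpeciesPartition",
    "PriorSweepRow",
    "InsufficientDataError",
    "DEFAULT_X",
    "DEFAULT_PRIOR_GRID",
    "detect_barcode_gap",
    "partition_at_threshold",
    "abgd_initial",
    "abgd_recursive",
    "prior_sweep",
    "prior_grid",
]

#: Default relative gap width (how much wider than the local gap scale a jump
#: must be to count as the barcode gap).
DEFAULT_X = 1.5

#: Default prior sweep: geometric from 0.001 to 0.12 in 10 steps
#: (consecutive ratio ~1.70).
DEFAULT_PRIOR_GRID = (0.001, 0.12, 10)


class InsufficientDataError(ValueError):
    """Fewer than 3 defined pairwise distances: no gap can be estimated."""


@dataclass(frozen=True)
class GapScanResult:
    """Outcome of one ranked-distance scan at one prior.

    ``gap_index`` is the 0-based rank i of the detected gap within ``ranked``
    (None when no gap qualifies); ``threshold`` the partition threshold
    (midpoint of the gap) or None.
    """

    prior: float
    x_relative_gap: float
    ranked: np.ndarray
    gap_index: int | None
    threshold: float | None
    window: int

    def diagnostics_frame(self) -> pd.DataFrame:
        """Ranked distances with per-rank gap statistics (for gap-zone plots)."""
        n = len(self.ranked)
        gaps = np.diff(self.ranked)
        return pd.DataFrame(
            {
                "rank": np.arange(1, n + 1),
                "distance": self.ranked,
                "gap_after": np.append(gaps, np.nan),
                "is_detected_gap": [
                    self.gap_index is not None and k == self.gap_index for k in range(n)
                ],
            }
        )


@dataclass(frozen=True)
class SpeciesPartition:
    """Assignment of sequence ids to hypothetical OTUs.

    ``kind`` records whether this is the single-pass (*initial*) or fixed-point
    (*recursive*) partition; the simulator tags its generating truth ``true``.
    """

    assignment: dict[str, int]
    kind: str = "initial"

    def __post_init__(self) -> None:
        if self.kind not in ("initial", "recursive", "true"):
            raise ValueError("kind must be 'initial', 'recursive' or 'true'")
        if not self.assignment:
            raise ValueError("empty partition")

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, g in self.assignment.items():
            out.setdefault(g, []).append(sid)
        return out

    def relabel_canonical(self) -> "SpeciesPartition":
        """Labels renumbered 0..k-1 in order of first appearance."""
        mapping: dict[int, int] = {}
        new = {}
        for sid, g in self.assignment.items():
            if g not in mapping:
                mapping[g] = len(mapping)
            new[sid] = mapping[g]
        return SpeciesPartition(new, self.kind)

    def refines(self, other: "SpeciesPartition") -> bool:
        """True iff every group of ``self`` lies inside one group of ``other``."""
        for members in self.groups().values():
            parents = {other.assignment[m] for m in members}
            if len(parents) != 1:
                return False
        return True

    def to_tsv(self, dest: Union[str, Path, IO[str]]) -> None:
        frame = pd.DataFrame(
            {"id": list(self.assignment), "group": list(self.assignment.values())}
        )
        if isinstance(dest, (str, Path)):
            frame.to_csv(dest, sep="\t", index=False)
        else:
            frame.to_csv(dest, sep="\t", index=False)


@dataclass(frozen=True)
class PriorSweepRow:
    """One row of the prior sweep: group counts at one prior value."""

    prior: float
    n_initial: int
    n_recursive: int


def _window_size(n_pairs: int) -> int:
    return max(10, ceil(0.01 * n_pairs))


def detect_barcode_gap(
    dm: DistanceMatrix,
    prior: float,
    x_relative_gap: float = DEFAULT_X,
    window: int | None = None,
) -> GapScanResult:
    """Scan the ranked defined distances for the first significant gap at or
    above the prior intraspecific divergence.

    Raises :class:`InsufficientDataError` with fewer than 3 defined pairs.
    """
    if prior < 0:
        raise ValueError("prior must be >= 0")
    if x_relative_gap <= 0:
        raise ValueError("x_relative_gap must be > 0")
    ranked = np.sort(dm.condensed())
    n = len(ranked)
    if n < 3:
        raise InsufficientDataError(f"only {n} defined pairs; need at least 3")
    w = window if window is not None else _window_size(n)
    gaps = np.diff(ranked)
    gap_index = None
    threshold = None
    # rank i (0-based) has gap g_i = ranked[i+1] - ranked[i]; the local scale
    # m_i is the mean of up to w gaps preceding i (at least one, so the first
    # assessable rank is i = 1).  A gap is eligible when it reaches above the
    # prior: d(i+1) >= prior (its lower edge may sit below the prior).
    csum = np.concatenate([[0.0], np.cumsum(gaps)])
    for i in range(1, n - 1):
        if ranked[i + 1] < prior:
            continue
        lo = max(0, i - w)
        m_i = (csum[i] - csum[lo]) / (i - lo)
        if gaps[i] > x_relative_gap * m_i:
            gap_index = i
            threshold = 0.5 * (ranked[i] + ranked[i + 1])
            break
    return GapScanResult(
        prior=prior,
        x_relative_gap=x_relative_gap,
        ranked=ranked,
        gap_index=gap_index,
        threshold=threshold,
        window=w,
    )


def partition_at_threshold(dm: DistanceMatrix, threshold: float) -> SpeciesPartition:
    """Single-linkage grouping: connected components of the graph with an edge
    between i and j iff their distance is defined and strictly below the
    threshold.  Undefined (saturated / no-overlap) entries contribute no edge.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    adj = dm.defined & (dm.d < threshold)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False, return_labels=True
    )
    part = SpeciesPartition(
        {sid: int(lab) for sid, lab in zip(dm.ids, labels)}, kind="initial"
    )
    return part.relabel_canonical()


def abgd_initial(
    dm: DistanceMatrix,
    prior: float,
    x: float = DEFAULT_X,
    window: int | None = None,
) -> SpeciesPartition:
    """One pass of gap detection + single-linkage partitioning.

    Returns a single group when no gap qualifies at this prior.
    """
    scan = detect_barcode_gap(dm, prior, x, window)
    if scan.threshold is None:
        return SpeciesPartition({sid: 0 for sid in dm.ids}, kind="initial")
    return partition_at_threshold(dm, scan.threshold)


def abgd_recursive(
    dm: DistanceMatrix,
    prior: float,
    x: float = DEFAULT_X,
    window: int | None = None,
) -> SpeciesPartition:
    """Fixed point of re-applying the gap scan within each group.

    Starting from the initial partition, every group of size >= 3 is re-scanned
    on its own sub-matrix with the same prior and X, until no group splits.
    Groups of fewer than 3 sequences are never split (a gap cannot be
    estimated from fewer than 3 pairwise distances).  The result always
    refines the initial partition.
    """
    initial = abgd_initial(dm, prior, x, window)
    assignment = dict(initial.assignment)
    next_label = max(assignment.values()) + 1
    stack = list(initial.groups().values())
    while stack:
        members = stack.pop()
        if len(members) < 3:
            continue
        sub = dm.submatrix(members)
        try:
            scan = detect_barcode_gap(sub, prior, x, window)
        except InsufficientDataError:
            continue
        if scan.threshold is None:
            continue
        subpart = partition_at_threshold(sub, scan.threshold)
        if subpart.n_groups <= 1:
            continue
        for group_members in subpart.groups().values():
            for m in group_members:
                assignment[m] = next_label
            next_label += 1
            stack.append(group_members)
    return SpeciesPartition(assignment, kind="recursive").relabel_canonical()


def prior_grid(p_min: float, p_max: float, steps: int) -> np.ndarray:
    """Geometrically spaced priors p_min * (p_max/p_min)^(k/(steps-1))."""
    if not (0 < p_min < p_max):
        raise ValueError("require 0 < p_min < p_max")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    k = np.arange(steps)
    return p_min * (p_max / p_min) ** (k / (steps - 1))


def prior_sweep(
    dm: DistanceMatrix,
    p_min: float = DEFAULT_PRIOR_GRID[0],
    p_max: float = DEFAULT_PRIOR_GRID[1],
    steps: int = DEFAULT_PRIOR_GRID[2],
    x: float = DEFAULT_X,
    window: int | None = None,
) -> list[PriorSweepRow]:
    """Initial and recursive group counts across a geometric prior grid."""
    rows = []
    for prior in prior_grid(p_min, p_max, steps):
        ini = abgd_initial(dm, prior, x, window)
        rec = abgd_recursive(dm, prior, x, window)
        rows.append(
            PriorSweepRow(prior=float(prior), n_initial=ini.n_groups, n_recursive=rec.n_groups)
        )
    return rows


def sweep_frame(rows: list[PriorSweepRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "prior": [r.prior for r in rows],
            "n_initial": [r.n_initial for r in rows],
            "n_recursive": [r.n_recursive for r in rows],
        }
    )
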