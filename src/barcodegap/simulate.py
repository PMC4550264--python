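"""Truth-known simulator of ITS-like barcode datasets.

Generates aligned nucleotide sequences organised into species clusters with
directly controlled within- and between-species divergence — the two scales
whose separation (the barcode gap) the delimitation machinery assumes.  The
design is deliberately transparent rather than realistic:

* a star phylogeny between species and a star within each species, so every
  within-species pair sits at the same expected divergence ``intra_d`` and
  every between-species pair at ``inter_d``;
* an HKY substitution process (transition/transversion ratio ``kappa``,
  equilibrium composition ``base_freqs``), with branch lengths numerically
  calibrated so the *expected observed p-distance* between tips hits the
  requested targets (multiple hits are accounted for);
* an indel process (events Poisson in sequence length, geometric lengths,
  mean 3) applied along nonzero branches with exact homology bookkeeping, so
  the emitted alignment is the true alignment and degapping recovers the raw
  simulated sequences exactly.

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Union

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .alignment import MultipleAlignment
from .distances import build_distance_matrix
from .gap import SpeciesPartition

__all__ = [
    "SimulationSpec",
    "SyntheticDataset",
    "simulate_dataset",
    "study_emulation_preset",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated dataset.

    ``intra_d`` / ``inter_d`` are target *mean observed p-distances* within and
    between species; ``indel_rate`` is the expected number of indel events per
    site per (nonzero) branch; ``n_per_species`` may be a single count or a
    per-species tuple.
    """

    n_species: int
    n_per_species: Union[int, tuple[int, ...]]
    seq_len: int
    intra_d: float
    inter_d: float
    kappa: float = 2.0
    indel_rate: float = 0.0
    indel_mean_len: float = 3.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.seq_len <= 0:
            raise ValueError("seq_len must be > 0")
        if not (0 <= self.intra_d < self.inter_d):
            raise ValueError("require 0 <= intra_d < inter_d")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not (0 <= self.indel_rate <= 0.2):
            raise ValueError("indel_rate must be in [0, 0.2]")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9 or min(self.base_freqs) <= 0:
            raise ValueError("base_freqs must be positive and sum to 1")
        sizes = self.sizes()
        if len(sizes) != self.n_species or min(sizes) < 1:
            raise ValueError("n_per_species inconsistent with n_species")

    def sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_per_species, int):
            return (self.n_per_species,) * self.n_species
        return tuple(self.n_per_species)

    @property
    def n_sequences(self) -> int:
        return sum(self.sizes())


@dataclass(frozen=True)
class SyntheticDataset:
    """A simulated alignment, its generating truth, and realized divergences."""

    alignment: MultipleAlignment
    true_partition: SpeciesPartition
    spec: SimulationSpec
    realized_intra_p: float
    realized_inter_p: float

    def within_between(self, model: str = "p") -> tuple[np.ndarray, np.ndarray]:
        """Defined within- and between-species distances under ``model``."""
        dm = build_distance_matrix(self.alignment, model)
        lab = np.array([self.true_partition.assignment[i] for i in dm.ids])
        iu = np.triu_indices(dm.n, k=1)
        same = lab[iu[0]] == lab[iu[1]]
        ok = dm.defined[iu]
        vals = dm.d[iu]
        return vals[same & ok], vals[~same & ok]


# ---------------------------------------------------------------------------
# substitution process
# ---------------------------------------------------------------------------

def _hky_rate_matrix(kappa: float, pi: np.ndarray) -> np.ndarray:
    """HKY85 generator scaled to one expected substitution per unit time."""
    # state order A, C, G, T; transitions: A<->G, C<->T
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for a in range(4):
        for b in range(4):
            if a == b:
                continue
            Q[a, b] = pi[b] * (kappa if (a, b) in transitions else 1.0)
    Q[np.diag_indices(4)] = -Q.sum(axis=1)
    rate = -np.sum(pi * np.diagonal(Q))
    return Q / rate


def _expected_p(t: float, Q: np.ndarray, pi: np.ndarray) -> float:
    """Expected p-distance between two tips separated by total path length t."""
    if t <= 0:
        return 0.0
    P_half = expm(Q * (t / 2.0))
    same = float(np.einsum("a,as,as->", pi, P_half, P_half))
    return 1.0 - same


def _invert_p(target: float, Q: np.ndarray, pi: np.ndarray) -> float:
    """Total path length whose expected p-distance equals ``target``."""
    if target <= 0:
        return 0.0
    pmax = 1.0 - float(pi @ pi)  # saturation plateau
    if target >= 0.98 * pmax:
        raise ValueError(f"target p-distance {target} too close to saturation ({pmax:.3f})")
    return brentq(lambda t: _expected_p(t, Q, pi) - target, 1e-9, 50.0)


def _evolve(seq: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One multinomial draw per site from the transition matrix rows."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(seq.shape[0])
    return (u[:, None] > cum[seq]).sum(axis=1).astype(np.int8)


# ---------------------------------------------------------------------------
# indel process with exact homology bookkeeping
# ---------------------------------------------------------------------------

class _Lineage:
    """A sequence as parallel lists of homology keys and states.

    Keys are ``(position, uid)`` tuples: ancestral columns carry positions
    0..L-1 with uid 0; an insertion creates fresh columns at fractional
    positions between its neighbours with a globally unique uid, so columns
    inserted independently in different lineages are never treated as
    homologous.  Sorting all keys that survive to the tips yields the true
    alignment.
    """

    __slots__ = ("keys", "states")

    def __init__(self, keys: list[tuple[float, int]], states: list[int]):
        self.keys = keys
        self.states = states

    def copy(self) -> "_Lineage":
        return _Lineage(list(self.keys), list(self.states))


def _apply_indels(
    lin: _Lineage,
    rate: float,
    mean_len: float,
    base_cum: np.ndarray,
    rng: np.random.Generator,
    uid_counter: list[int],
) -> None:
    if rate <= 0 or not lin.keys:
        return
    n_events = rng.poisson(rate * len(lin.keys))
    for _ in range(n_events):
        if not lin.keys:
            return
        length = int(rng.geometric(1.0 / mean_len))
        if rng.random() < 0.5:  # deletion
            start = int(rng.integers(len(lin.keys)))
            del lin.keys[start : start + length]
            del lin.states[start : start + length]
        else:  # insertion
            at = int(rng.integers(len(lin.keys) + 1))
            left = lin.keys[at - 1][0] if at > 0 else lin.keys[0][0] - 1.0
            right = lin.keys[at][0] if at < len(lin.keys) else lin.keys[-1][0] + 1.0
            span = right - left
            new_keys = []
            for k in range(length):
                pos = left + span * (k + 1) / (length + 1)
                uid_counter[0] += 1
                new_keys.append((pos, uid_counter[0]))
            new_states = list((rng.random(length)[:, None] > base_cum).sum(axis=1))
            lin.keys[at:at] = new_keys
            lin.states[at:at] = [int(s) for s in new_states]


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def simulate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Simulate one dataset; bit-identical under identical spec (incl. seed).

    A self-check asserts that for ``seq_len >= 500`` the realized mean within-
    and between-species p-distances land within 25% of the targets.
    """
    rng = np.random.default_rng(spec.seed)
    pi = np.asarray(spec.base_freqs)
    Q = _hky_rate_matrix(spec.kappa, pi)
    t_intra = _invert_p(spec.intra_d, Q, pi)  # total tip-to-tip within species
    t_inter = _invert_p(spec.inter_d, Q, pi)  # total tip-to-tip across species
    b_tip = t_intra / 2.0
    b_species = max(0.0, (t_inter - t_intra) / 2.0)
    P_tip = expm(Q * b_tip) if b_tip > 0 else np.eye(4)
    P_species = expm(Q * b_species) if b_species > 0 else np.eye(4)
    base_cum = np.cumsum(pi)[None, :]

    root_states = (rng.random(spec.seq_len)[:, None] > base_cum).sum(axis=1).astype(np.int8)
    root = _Lineage([(float(i), 0) for i in range(spec.seq_len)], [int(s) for s in root_states])
    uid_counter = [0]

    ids: list[str] = []
    tips: list[_Lineage] = []
    labels: dict[str, int] = {}
    for g, size in enumerate(spec.sizes()):
        anc = root.copy()
        if b_species > 0:
            anc.states = list(_evolve(np.array(anc.states, dtype=np.int8), P_species, rng))
            _apply_indels(anc, spec.indel_rate, spec.indel_mean_len, base_cum, rng, uid_counter)
        for k in range(size):
            tip = anc.copy()
            if b_tip > 0:
                tip.states = list(_evolve(np.array(tip.states, dtype=np.int8), P_tip, rng))
                _apply_indels(tip, spec.indel_rate, spec.indel_mean_len, base_cum, rng, uid_counter)
            sid = f"sp{g:03d}_t{k:03d}"
            ids.append(sid)
            tips.append(tip)
            labels[sid] = g

    all_keys = sorted({key for tip in tips for key in tip.keys})
    col_index = {key: c for c, key in enumerate(all_keys)}
    ncol = len(all_keys)
    rows = []
    for tip in tips:
        row = ["-"] * ncol
        for key, s in zip(tip.keys, tip.states):
            row[col_index[key]] = _BASES[int(s)]
        rows.append("".join(row))

    aln = MultipleAlignment(tuple(ids), tuple(rows))
    truth = SpeciesPartition(labels, kind="true")
    ds_intra, ds_inter = _realized_p(aln, labels)
    ds = SyntheticDataset(aln, truth, spec, ds_intra, ds_inter)
    if spec.seq_len >= 500:
        _self_check(ds)
    return ds


def _realized_p(aln: MultipleAlignment, labels: dict[str, int]) -> tuple[float, float]:
    dm = build_distance_matrix(aln, "p")
    lab = np.array([labels[i] for i in dm.ids])
    iu = np.triu_indices(dm.n, k=1)
    same = lab[iu[0]] == lab[iu[1]]
    ok = dm.defined[iu]
    vals = dm.d[iu]
    within = vals[same & ok]
    between = vals[~same & ok]
    return (
        float(within.mean()) if within.size else 0.0,
        float(between.mean()) if between.size else 0.0,
    )


def _self_check(ds: SyntheticDataset) -> None:
    spec = ds.spec
    if spec.intra_d > 0 and not (
        0.75 * spec.intra_d <= ds.realized_intra_p <= 1.25 * spec.intra_d
    ):
        raise AssertionError(
            f"realized within-species p {ds.realized_intra_p:.4f} outside 25% of target {spec.intra_d}"
        )
    if ds.realized_inter_p and not (
        0.75 * spec.inter_d <= ds.realized_inter_p <= 1.25 * spec.inter_d
    ):
        raise AssertionError(
            f"realized between-species p {ds.realized_inter_p:.4f} outside 25% of target {spec.inter_d}"
        )


def study_emulation_preset() -> SimulationSpec:
    """A fixed spec at the scale of the study system this package targets:
    290 ITS-like barcodes in 75 species of uneven size, raw length 550 nt,
    within-species divergence ~0.012, between-species ~0.15, with indels.

    The per-species sizes are drawn once from a fixed internal seed (uniform
    multinomial over the 215 non-singleton slots plus one guaranteed sequence
    per species) and are therefore a constant of the package.
    """
    size_rng = np.random.default_rng(75290)
    extra = size_rng.multinomial(290 - 75, np.full(75, 1.0 / 75))
    sizes = tuple(int(1 + e) for e in extra)
    return SimulationSpec(
        n_species=75,
        n_per_species=sizes,
        seq_len=550,
        intra_d=0.012,
        inter_d=0.15,
        kappa=2.0,
        indel_rate=0.02,
        seed=0,
    )


def write_dataset(ds: SyntheticDataset, out_dir: Union[str, Path]) -> None:
    """Write aligned FASTA, a two-column truth TSV (id, species) and the spec
    as JSON next to each other."""
    from .alignment import write_fasta_alignment

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta_alignment(ds.alignment, out / "alignment.fasta")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("id\tspecies\n")
        for sid in ds.alignment.ids:
            fh.write(f"{sid}\t{ds.true_partition.assignment[sid]}\n")
    spec_dict = asdict(ds.spec)
    with open(out / "spec.json", "w") as fh:
        json.dump(spec_dict, fh, indent=2)
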