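import numpy as np
import pytest

from barcodegap import (
    MultipleAlignment,
    SimulationSpec,
    simulate_dataset,
    study_emulation_preset,
)


@pytest.fixture(scope="session")
def clean_dataset():
    """5 well-separated species x 6 sequences: intra ~0.01, inter ~0.2."""
    spec = SimulationSpec(
        n_species=5, n_per_species=6, seq_len=600, intra_d=0.01, inter_d=0.2,
        indel_rate=0.02, seed=1,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def preset_dataset():
    """The 290-sequence / 75-species study-scale emulation."""
    return simulate_dataset(study_emulation_preset())


@pytest.fixture()
def toy_alignment():
    """4 rows, 4 columns (AAAA / AAAC / AACC / A--C as *columns*): one
    constant, two uninformative, one informative."""
    columns = ["AAAA", "AAAC", "AACC", "A--C"]
    rows = ["".join(col[i] for col in columns) for i in range(4)]
    return MultipleAlignment.from_records(
        [(f"r{i+1}", row) for i, row in enumerate(rows)]
    )


def random_additive_matrix(n_leaves: int, rng: np.random.Generator):
    """A random additive distance matrix plus its generating tree structure.

    Builds a random unrooted binary tree with positive branch lengths by
    sequential leaf addition and returns (ids, matrix, total_branch_length).
    """
    edges = {(0, n_leaves), (1, n_leaves), (2, n_leaves)}
    lengths = {}
    next_internal = n_leaves + 1
    for e in list(edges):
        lengths[e] = rng.uniform(0.05, 0.5)
    for leaf in range(3, n_leaves):
        e = list(edges)[rng.integers(len(edges))]
        edges.remove(e)
        u, v = e
        w = next_internal
        next_internal += 1
        half = lengths.pop(e)
        for ne in [(u, w), (w, v), (w, leaf)]:
            edges.add(ne)
            lengths[ne] = rng.uniform(0.05, 0.5)
    adj = {}
    for (u, v), wlen in lengths.items():
        adj.setdefault(u, []).append((v, wlen))
        adj.setdefault(v, []).append((u, wlen))
    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, wlen in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + wlen
                    stack.append(nb)
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]
    D = (D + D.T) / 2.0  # exact symmetry despite float summation order
    ids = tuple(f"t{i}" for i in range(n_leaves))
    return ids, D, sum(lengths.values())
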