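# barcodegap

Species delimitation from DNA barcodes is only as good as the two steps that
precede it: the multiple sequence alignment and the evolutionary distance
correction. For indel-rich markers such as the fungal ITS region
(ITS1–5.8S–ITS2), different alignment programs produce alignments of very
different length and informativeness, and the operational taxonomic units
(OTUs) delimited downstream can differ accordingly — the algorithm matters.

`barcodegap` is a library for quantifying exactly that sensitivity. It
implements, as tested reusable components:

- **Alignment ingestion and site statistics** — aligned FASTA in/out,
  constant / parsimony-uninformative / parsimony-informative / missing column
  classification under the gaps-as-missing convention, unique-barcode counts.
- **Pairwise evolutionary distances** — p-distance, Kimura 2-parameter (K2P),
  Tamura–Nei (TN93) and a general-time-reversible (GTR) pairwise estimator,
  all under pairwise deletion, with optional Γ rate heterogeneity and
  invariant-site adjustments; saturated pairs are flagged, never silently
  zeroed.
- **Automatic barcode-gap discovery** — ranked-distance gap detection given a
  prior intraspecific divergence `P` and relative gap width `X`,
  single-linkage partitioning at the gap midpoint, recursive refinement to a
  fixed point, and prior sweeps over a geometric grid.
- **Tree diagnostics** — neighbor joining with deterministic tie-breaking,
  Fitch parsimony tree length with consistency (CI) and retention (RI)
  indices, minimum-evolution score, and the g1 tree-length skewness statistic
  (signal vs noise).
- **A truth-known simulator** of ITS-like barcode datasets with controlled
  within/between-species divergence and an indel process with exact homology
  bookkeeping — so every stage of the pipeline can be validated against a
  known answer.

## The method in brief

For aligned barcodes, all pairwise distances `d_ij` are computed under a
chosen correction. Within-species distances are expected to be small,
between-species distances large; the empty interval between the two
distributions is the *barcode gap*. Given a prior `P` on intraspecific
divergence, the ranked distances `d(1) ≤ … ≤ d(N)` are scanned for the first
gap `g_i = d(i+1) − d(i)` that reaches above `P` and exceeds `X` times the
local mean gap (window `max(10, 0.01·N)` preceding gaps). Sequences are then
single-linked below the gap midpoint into OTUs; the scan is re-applied inside
each OTU until nothing splits (the *recursive* partition, always a refinement
of the *initial* one). Sweeping `P` over a geometric grid exposes how stable
the delimitation is.

The distance corrections are the standard closed forms, e.g. K2P
`d = −½·ln[(1−2P−Q)·√(1−2Q)]` with transition/transversion proportions `P, Q`,
TN93 with separate purine/pyrimidine transition classes and unequal base
frequencies, and the GTR pairwise estimator
`d = −tr(Π·log(Π⁻¹·F̂))` on the symmetrised divergence matrix `F̂`.

## Worked example

```python
from barcodegap import (SimulationSpec, simulate_dataset,
                        build_distance_matrix, detect_barcode_gap,
                        abgd_initial, abgd_recursive)

ds = simulate_dataset(SimulationSpec(
    n_species=8, n_per_species=5, seq_len=600,
    intra_d=0.01, inter_d=0.18, indel_rate=0.02, seed=21))
dm = build_distance_matrix(ds.alignment, "k2p")
scan = detect_barcode_gap(dm, prior=0.04)
print(scan.threshold)
print(abgd_initial(dm, 0.04).n_groups, abgd_recursive(dm, 0.04).n_groups)
```

Running `python examples/03_barcode_gap.py` (the same computation with
narration) prints:

```
defined pairs: 780  smoothing window: 10
detected gap after rank 79: 0.0270 -> 0.1502
partition threshold (gap midpoint): 0.0886
initial partition:   8 OTUs
recursive partition: 8 OTUs (true species: 8)
```

i.e. the scan finds the empty interval between the within-species distances
(≤ 0.027) and the between-species distances (≥ 0.150), cuts at its midpoint
0.0886, and recovers exactly the 8 simulated species — both in a single pass
and at the recursive fixed point. The other scripts in `examples/` walk
through site statistics, the four distance corrections, tree diagnostics and
the full alignment × model comparison grid.

A thin CLI mirrors the library:

```sh
barcodegap simulate --preset study --seed 1 --out-dir sim/
barcodegap stats sim/alignment.fasta
barcodegap sweep sim/alignment.fasta --model k2p
barcodegap compare --alignments a.fasta --alignments b.fasta --models p --models gtr
```

## Layout

- `src/barcodegap/` — `alignment`, `distances`, `gap`, `trees`, `simulate`,
  `pipeline`, `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, conventions, numerical choices, limitations
- `tests/` — unit, property and acceptance suites
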