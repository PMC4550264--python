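# Methods

This note documents the models, conventions and numerical choices behind
`barcodegap`, in the order data flows through the pipeline.

## Alignment handling

Alignments are rectangular character matrices over `{A,C,G,T,U,N}` plus IUPAC
ambiguity codes, `-` and `?`. Input is upper-cased and `U` is normalised to
`T`; the record identifier is the FASTA header token before the first
whitespace (the full header is kept as a description). For **all**
site classification and distance counting, only `A,C,G,T` are determinate;
gaps, `N`, `?` and ambiguity codes are missing data. This is the
PAUP*/MEGA-style convention and is the one under which the reference
benchmark's site statistics were produced.

Column classification: a column is *parsimony-informative* iff at least two
distinct determinate states each occur in at least two rows; *constant* iff
exactly one determinate state occurs (necessarily in ≥ 2 rows); columns with
fewer than two determinate characters are tallied separately as
`n_all_missing` rather than as constant (a deliberate choice — such columns
carry no signal of either kind); everything else is variable-uninformative.
The four counts always sum to the column count, and raw columns are counted
(a column that is gap-only still contributes to `length`).

## Pairwise distances

All distances share one counting step under **pairwise deletion**: for each
pair, only sites determinate in both sequences enter `n_valid`; from these we
take the divergence matrix `F̂[x,y]` (fraction of valid sites with `x` in one
sequence, `y` in the other), the purine-transition proportion `P1` (A↔G),
pyrimidine-transition proportion `P2` (C↔T), transversion proportion `Q`, and
per-pair base frequencies (average of the two marginals of `F̂`). Complete
deletion is deliberately not offered: on indel-rich ITS alignments it would
discard most columns.

- **p**: `n_diff / n_valid`.
- **K2P**: `d = −½·ln[(1−2P−Q)·√(1−2Q)]` with `P = P1+P2`. With gamma shape
  `α`: each `−ln x` term becomes `α(x^(−1/α) − 1)` (the `α→∞` limit recovers
  the log form; verified to 1e−6 at `α = 10⁶`). With invariable-site
  proportion `I`: `P, Q` are rescaled by `1/(1−I)` and the result multiplied
  by `(1−I)`.
- **TN93**: with `πR = πA+πG`, `πY = πC+πT`, `k1 = 2πAπG/πR`,
  `k2 = 2πTπC/πY`, `k3 = 2(πRπY − πAπGπY/πR − πTπCπR/πY)`:
  `d = −k1·ln(1 − P1/k1 − Q/2πR) − k2·ln(1 − P2/k2 − Q/2πY)
  − k3·ln(1 − Q/2πRπY)`; Γ and I applied as for K2P, per log term. Base
  frequencies come from the pair's valid sites by default (consistent with
  pairwise deletion); an alignment-wide `frequency_mode="global"` switch is
  provided. The per-pair convention differs from e.g. `ape::dist.dna`, which
  uses each sequence's full-site frequencies — the numerical difference is
  O(1e−4) on typical pairs and the test suite pins both a frozen `ape` value
  (loose tolerance) and an independent transliteration of the closed form
  (1e−12).
- **GTR**: the standard tree-free pairwise estimator. Symmetrise
  `F̂ ← (F̂+F̂ᵀ)/2`, let `Π = diag(marginals)`; then
  `d = −tr(Π·log(Π⁻¹F̂))`, evaluated through the symmetric similar matrix
  `S = Π^(−1/2) F̂ Π^(−1/2)` (batched `eigh`), so
  `d = −Σᵢ πᵢ (log S)ᵢᵢ`. Eigenvalues ≤ 0, a base absent from the pair, or a
  singular `Π` mean the log does not exist: the entry is *undefined*. No Γ/I
  variant is offered for GTR. Γ and I are always user-supplied (typically
  from a prior model-selection run); the package never estimates them.

**Missing-entry policy.** Saturation (log/eigen domain violations) and
zero-overlap pairs yield entries flagged in `DistanceMatrix.defined` and
holding NaN — never an exception, never a silent zero and never +∞, so a
single saturated pair cannot abort a 290-sequence analysis. Downstream gap
discovery simply excludes undefined pairs from the ranking and gives them no
clustering edge.

Matrix construction is vectorised (16 indicator matrix products give all
pairwise `F̂` counts at once); building one 290-sequence matrix takes well
under a second, and per-pair scalar functions evaluate the identical kernels
(asserted in tests).

## Barcode-gap discovery

With ranked defined distances `d(1) ≤ … ≤ d(N)` and consecutive gaps
`g_i = d(i+1) − d(i)`:

- smoothing window `w = max(10, ⌈0.01·N⌉)`;
- local scale `m_i` = mean of the up-to-`w` gaps preceding rank `i` (at least
  one, so the first assessable rank is the second);
- the detected gap is the **first** `i` whose gap *reaches above the prior*
  (`d(i+1) ≥ P`; its lower edge may sit below `P` — distances under the prior
  are intraspecific by assumption) with `g_i > X·m_i`;
- the partition threshold is the gap midpoint `(d(i) + d(i+1))/2`.

The relative-width test against a windowed local scale, the window constant
and the first-qualifying-gap rule are this package's concretisation of the
barcode-gap principle; both the window and `X` (default 1.5) are exposed as
parameters precisely because other implementations' gap statistics differ in
these details. Using the gap's *upper* edge for prior eligibility is the only
reading consistent with the required behaviours: a prior inside the gap must
find it, a prior above the gap's upper edge must not, and on distributions
whose gap sits low a large prior therefore collapses everything to one OTU.

Partitioning is single linkage: connected components of the graph with an
edge wherever a defined distance is strictly below the threshold. Strict
inequality is safe because the threshold is a gap midpoint — no distance can
tie with it — and makes the result deterministic. The recursive partition
re-runs scan+partition inside every group of ≥ 3 members (fewer than 3
sequences give fewer than 3 pairwise distances, too few to place a gap) with
the same `P` and `X` until no group splits; by construction it refines the
initial partition, and both are invariant to input order up to label
renaming.

The prior sweep uses a geometric grid `p_min·(p_max/p_min)^(k/(steps−1))`,
default `0.001 → 0.12` in 10 steps (consecutive ratio ≈ 1.70). The headline
OTU number for an alignment × model cell is the modal initial-partition count
across the grid, initial counts being typically stable over priors inside the
gap.

## Tree diagnostics

**NJ** follows Saitou–Nei agglomeration with the Studier–Keppler `Q`
criterion; ties in `Q` break to the lowest `(i, j)` index pair, so the
topology is deterministic. Negative branch-length estimates (expected on
non-additive inputs) are clamped to zero with the count recorded; the
minimum-evolution score is the clamped branch-length sum. On additive
matrices NJ provably recovers the generating tree; the suite checks exact
recovery (1e−9) of random additive 5–12-taxon trees and cross-checks
topologies against scikit-bio's independent implementation. Undefined matrix
entries are a hard error for NJ (unlike gap discovery, which tolerates them).

**Fitch parsimony** is computed on the NJ (or any) unrooted binary topology,
rooted for the pass by subdividing an arbitrary edge (the score is
root-invariant). Leaves with missing data carry the full state set and
contribute no constraint. Per site, `s` = Fitch steps, `m` = distinct
determinate states − 1 (the best achievable on any tree), `g` = determinate
taxa − most-frequent-state count (the worst, a star). Sums give
`CI = M/S` (1.0 when `S = 0`) and `RI = (G−S)/(G−M)` (1.0 when `G = M`).
CI/RI include parsimony-uninformative sites by default (the common default in
mainstream parsimony software); `include_uninformative=False` restricts all
three sums to informative sites, since conventions differ between programs.

**g1** samples `n_trees` unrooted binary topologies uniformly at random
(random sequential leaf addition — each of the `(2k−5)!!` topologies equally
probable), scores each with Fitch, and reports the sample skewness (third
central moment / cubed SD) of the length distribution. Default
`n_trees = 10,000`; the test and acceptance runs use a few hundred to ~1,200
trees, enough to separate the strongly negative skew of clustered data from
the near-zero skew of structure-free data. A zero-variance distribution is
flagged degenerate with `g1 = 0`. Everything is seeded and bit-reproducible.

## The simulator

The generator is built for *transparent control of the two divergence
scales*, not realism:

- **Topology**: a star between species and a star within each species. Every
  within-species pair then has the same expected divergence and likewise every
  between-species pair — the idealised two-scale world in which the barcode
  gap is well defined.
- **Substitutions**: HKY process (`kappa`, default 2.0, typical for ITS;
  `base_freqs` default uniform), generator scaled to one expected substitution
  per site per unit branch length. Branch lengths are calibrated numerically
  (Brent root-finding on the closed-form expected observed p-distance) so that
  realized tip-to-tip *p*-distances match `intra_d` and `inter_d` in
  expectation, multiple hits included.
- **Indels**: per branch of nonzero length, `Poisson(indel_rate · L)` events;
  each is an insertion or deletion with equal probability, of geometric
  length (mean 3). Homology is tracked exactly — every residue carries a
  column key, insertions mint fresh keys at fractional positions — so the
  emitted alignment is the *true* alignment, degapping reproduces the raw
  simulated sequences, and independently inserted columns are never spuriously
  homologous. Tying indels to nonzero branches keeps `intra_d = 0` meaning
  "conspecific sequences identical", which the test suite relies on.
- **Self-check**: for `seq_len ≥ 500` the generator asserts realized mean
  within/between p-distances within 25% of targets.

The **study-scale preset** fixes 75 species over 290 sequences (sizes drawn
once from a frozen internal seed, so they are package constants), raw length
550 nt, `intra_d = 0.012`, `inter_d = 0.15`, `kappa = 2`, `indel_rate = 0.02`
— chosen to emulate a realistic fungal ITS barcoding campaign: within-species
K2P divergence realized around 0.012 (inside the 0.007–0.018 band typical of
conspecific fungal ITS), between-species divergence an order of magnitude
higher, and enough indels that the aligned length (~6 kb across 290 gappy
sequences of the *true* alignment) far exceeds the raw length.

What the simulator does **not** emulate — and hence what passing tests do not
show about real data: overlapping intra/inter distance distributions (real
gaps can be narrow or absent), rate variation among lineages and sites,
alignment *error* (the true alignment is emitted; real aligners disagree,
which is precisely the sensitivity the comparison grid measures on real
inputs), duplicated barcodes from resampled isolates (every simulated
sequence is distinct, so unique-degapped equals the sequence count), and ITS
secondary-structure constraints. Recovery of exactly 75/75 OTUs by all four
corrections on the preset validates the machinery on well-separated scales;
it is not a claim about noisy empirical gaps.

## Numerical choices and degenerate inputs

- Histogram binning uses half-open bins `[k·w, (k+1)·w)` with a 1e−9 nudge
  before flooring so that values like 0.30/0.1 land in their own bin.
- TN93 terms with an empty substitution class (`k_j = 0` and matching
  proportion 0) contribute 0; `k_j = 0` with a nonzero proportion is
  degenerate and yields NaN (or a composition error in the scalar API).
- Distance matrices are exactly symmetrised after construction (the
  vectorised kernels are symmetric up to float evaluation order).
- GTR values that are tiny negatives at zero divergence are clamped to 0.
- The gap scan needs ≥ 3 defined pairs (`InsufficientDataError` otherwise);
  `partition_at_threshold` on an empty edge set returns all singletons; a
  sweep cell that fails is recorded as failed without aborting the grid.

## Problem sizes

Default test and acceptance runs use the 290-sequence preset (41,905 pairs)
for matrix-level checks, 5–8-species simulations for delimitation oracles,
≤ 12 taxa for NJ/Fitch oracles and 400–1,200 random topologies for g1 — sizes
at which every oracle (brute force, closed form, independent implementation)
is exact or statistically unambiguous while the whole suite runs in seconds.

## Known limitations

- The gap-significance statistic is one principled concretisation; other
  implementations use different slope/window rules, so OTU counts on real
  borderline datasets can differ by a few units. The window and `X` are
  parameters for exactly this reason.
- The GTR pairwise estimator is the eigendecomposition closed form; programs
  that fit GTR distances by ML on trees will differ slightly.
- CI/RI depend on the tree supplied; NJ topologies from different distance
  corrections give different indices. Tree statistics here diagnose
  alignments, they are not a phylogenetic inference.
- `me_score` is the NJ branch-length sum, not a minimum-evolution criterion
  optimum over topologies.
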