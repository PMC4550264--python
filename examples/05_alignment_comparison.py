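"""Does the algorithm matter?  Alignment x model comparison grid.

Runs the full grid — several alignments of the same sequences under several
distance corrections — and reports the modal initial OTU count per cell plus
the recursive counts per prior.  On clean synthetic data with a wide gap the
count is invariant to the distance model within each alignment; on real data
aligned by different programs the counts differ between alignments, which is
exactly the sensitivity this grid is built to expose.
"""

from barcodegap import SimulationSpec, run_comparison, simulate_dataset

# two datasets standing in for two alignment variants of the same isolates
variants = []
for label, seed in [("variant_a", 41), ("variant_b", 42)]:
    ds = simulate_dataset(
        SimulationSpec(
            n_species=7, n_per_species=5, seq_len=600,
            intra_d=0.01, inter_d=0.2, indel_rate=0.03, seed=seed,
        )
    )
    variants.append((label, ds.alignment))

grid = run_comparison(variants, ["p", "k2p", "tn93", "gtr"])

print("modal initial OTU counts (rows = alignment, cols = model):")
print(grid.otu_table().to_string())
print("\nper-alignment site statistics:")
print(grid.site_table().to_string())
print("\nrecursive counts across the prior grid:")
print(grid.sweep_table().to_string(index=False))
print("\nwith a clean gap every correction agrees within an alignment;")
print("disagreement between rows is alignment-induced, not model-induced.")
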