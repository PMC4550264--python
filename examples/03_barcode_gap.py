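"""Automatic barcode-gap discovery and the prior sweep.

Scans the ranked pairwise distances for the gap, partitions at its midpoint,
refines recursively, and sweeps the prior intraspecific divergence across the
default geometric grid.  On clean two-scale data the recovered OTU count
equals the number of simulated species for every prior inside the gap and
collapses to one once the prior exceeds it.
"""

from barcodegap import (
    SimulationSpec,
    abgd_initial,
    abgd_recursive,
    build_distance_matrix,
    detect_barcode_gap,
    prior_sweep,
    simulate_dataset,
)

ds = simulate_dataset(
    SimulationSpec(
        n_species=8, n_per_species=5, seq_len=600,
        intra_d=0.01, inter_d=0.18, indel_rate=0.02, seed=21,
    )
)
dm = build_distance_matrix(ds.alignment, "k2p")

scan = detect_barcode_gap(dm, prior=0.04)
print(f"defined pairs: {len(scan.ranked)}  smoothing window: {scan.window}")
print(f"detected gap after rank {scan.gap_index}: "
      f"{scan.ranked[scan.gap_index]:.4f} -> {scan.ranked[scan.gap_index + 1]:.4f}")
print(f"partition threshold (gap midpoint): {scan.threshold:.4f}")

ini = abgd_initial(dm, 0.04)
rec = abgd_recursive(dm, 0.04)
print(f"initial partition:   {ini.n_groups} OTUs")
print(f"recursive partition: {rec.n_groups} OTUs (true species: "
      f"{ds.true_partition.n_groups})")

print("\nprior sweep (geometric 0.001 .. 0.12):")
print("prior     initial  recursive")
for row in prior_sweep(dm):
    print(f"{row.prior:<8.4f}  {row.n_initial:<7d}  {row.n_recursive}")
print("\ncounts are stable across priors inside the gap; a prior above the")
print("between-species scale would find no gap and return a single OTU.")
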