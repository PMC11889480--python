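#!/usr/bin/env python
"""End-to-end pipeline validation on synthetic phantoms.

Twenty random binary vascular trees (branch radii >= 2 voxels, lengths >=
5x radius, Gaussian sensor noise SD 300 on a 28 000 gray-level contrast)
are rasterized at 10 um voxels, segmented by seeded region growing
(tolerance 1100), skeletonized, pruned, rooted, and summarized; the
recovered (median, maximum, count) triple is compared with the known
ground truth.

Writes results/phantom_recovery.csv.
"""

import time
from pathlib import Path

from vascmorph.recovery import recovery_experiment

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0
N_RUNS = 20


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    df = recovery_experiment(n_runs=N_RUNS, seed=SEED)
    df.to_csv(RESULTS / "phantom_recovery.csv", index=False)
    n_exact = int(df["exact_match"].sum())
    worst = int(df["count_error"].max())
    print(df[["run", "max_generation", "truth_count", "recovered_count",
              "exact_match", "count_error", "qc_pruned_spurs",
              "qc_removed_cycle_edges"]].to_string(index=False))
    print(f"\n{n_exact}/{N_RUNS} phantoms recovered their ground-truth "
          f"statistics exactly (largest vessel-count error {worst}); "
          f"{time.time() - t0:.0f} s total.")


if __name__ == "__main__":
    main()
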