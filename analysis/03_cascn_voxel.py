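#!/usr/bin/env python
"""Seed-based voxel-wise causal mapping over the pseudo-time-ordered cohort.

Seed-to-map: which regions' volumes the seed's earlier volume predicts.
Map-to-seed: which regions' earlier volumes predict the seed.  Surviving
clusters (joint |Z| > 3.75 and |GC| > 0.39) are reported with signs.
"""

from _study import RESULTS, ensure_dataset
from cascnet import io as cio
from cascnet.pipeline import run_pipeline


def main() -> None:
    config = ensure_dataset()
    run_pipeline(config, "vbm", RESULTS)  # seed selection must precede mapping
    manifest = run_pipeline(config, "cascn-voxel", RESULTS)
    info = manifest["stages"]["cascn-voxel"]
    for direction in ("seed_to_map", "map_to_seed"):
        table = cio.read_table(RESULTS / f"{direction}_clusters.tsv")
        print(f"\n{direction} ({info[f'n_clusters_{direction}']} cluster(s)):")
        if len(table):
            print(table.round(3).to_string(index=False))
        else:
            print("  none surviving the joint criterion")
    print(f"\nregions carried into the ROI-wise analysis: {info['rois']}")


if __name__ == "__main__":
    main()
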