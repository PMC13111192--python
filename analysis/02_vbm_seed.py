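#!/usr/bin/env python
"""Group-difference mapping: identify the seed region and relate it to cognition.

Runs the voxel-wise patient-vs-control contrast (permutation cluster-extent
FWE) and the Spearman/FDR cognition correlation of the seed's volume.
"""

from _study import RESULTS, ensure_dataset
from cascnet import io as cio
from cascnet.pipeline import run_pipeline


def main() -> None:
    config = ensure_dataset()
    manifest = run_pipeline(config, "vbm", RESULTS)
    info = manifest["stages"]["vbm"]
    print(f"seed region from the group contrast: {info['seed_region']} "
          f"({info['n_clusters']} surviving cluster(s), "
          f"extent threshold {info['cluster_extent_threshold']:.0f} voxels)")
    clusters = cio.read_table(RESULTS / "vbm_clusters.tsv")
    if len(clusters):
        print(clusters.to_string(index=False))
    corr = cio.read_table(RESULTS / "cognition_correlations.tsv")
    print("\nseed volume vs cognition (Spearman, BH-FDR):")
    print(corr.round(4).to_string(index=False))
    sig = corr[corr["significant"] == True]  # noqa: E712
    print(f"\n{len(sig)} of {len(corr)} tests significant at q < 0.05")


if __name__ == "__main__":
    main()
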