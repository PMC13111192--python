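"""Shared study configuration for the numbered analysis drivers.

One synthetic cohort emulating the target design: 38 post-RT patients and
23 controls, a fine 216-parcel grid, a group deficit plus a mild atrophy
slope on TPOmid.L (so the group contrast selects it as seed), and a
planted causal chain PHG.R -> TPOmid.L -> ITG.L (source -> transition
point -> sink) with negative couplings, matching the direction semantics
the pipeline is meant to expose.

Volumes (binary NIfTI) go under scratch/; every table the drivers report
lands under results/.
"""

from pathlib import Path

from cascnet.pipeline import PipelineConfig, VBMConfig, run_pipeline
from cascnet.sim import DEFAULT_ROI_NAMES, SimConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "study"
DATASET = ROOT / "scratch" / "study_dataset"

N_FILLERS = 206  # 10 named regions + fillers = 216 parcels
SEED = 20260927


def study_config(seed: int = SEED) -> PipelineConfig:
    roi_names = DEFAULT_ROI_NAMES + tuple(f"F{i:03d}" for i in range(N_FILLERS))
    sim = SimConfig(
        roi_names=roi_names,
        planted_edges=(
            ("PHG.R", "TPOmid.L", -3.0),
            ("TPOmid.L", "ITG.L", -2.5),
        ),
        noise_sd=0.3,
        persistence={"PHG.R": 0.95},  # slowly evolving source region
        atrophy_profile={"TPOmid.L": -0.006},
        group_deficit={"TPOmid.L": 2.0},
        rng_seed=seed,
    )
    return PipelineConfig(
        sim=sim,
        rng_seed=seed,
        vbm=VBMConfig(n_permutations=300),
        grid_shape=(30, 30, 30),
        voxel_noise_sd=0.25,
        data_dir=str(DATASET),
    )


def ensure_dataset() -> PipelineConfig:
    config = study_config()
    if not (DATASET / "metadata.tsv").exists():
        run_pipeline(config, "simulate", RESULTS)
    return config
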