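# Methods

## Model

The analysis treats a cross-sectional cohort as one trajectory. Patients
(each scanned once, at months 0.5–108 after radiotherapy) are sorted
ascending by time post-RT, ties broken by subject id so the ordering is a
pure function of the data. Regional or voxel gray-matter volumes along this
order form a pseudo-time series; the working assumption — inherited from the
causal-structural-covariance literature, and the central caveat of the
method — is that between-subject differences along the progression axis
stand in for within-subject change over time.

Directed association is the lag-1 signed path coefficient: for source *x*
and target *y*,

    y_t = b0 + b1*y_{t-1} + b2*x_{t-1} + e_t ,   t = 2..T

fit by OLS; the GC value is b2 with its sign. The model order is hard-fixed
at 1 (config rejects anything else). Before fitting, every series is
residualized once, over the full T-length sequence, against an intercept,
sex (F=0/M=1), age, education, total intracranial volume, and the interval
between consecutive pseudo-time points (assigned to the later observation,
first entry 0 — the interval modifies the transition *into* that
observation). Residualization precedes lagging so the seed and every map
feature share one residual basis. Series are then z-scored (population sd,
divisor T), making b2 a unitless standardized path coefficient; this is what
renders a fixed magnitude threshold meaningful across features, and it is
exposed as a switch (`GCConfig.standardize_series`). With standardization
off, b2 estimates the raw coupling, which is how the generator's planted
coefficients are checked for unbiasedness.

The multivariate variant fits one joint regression per target, conditioning
on all other regions' lagged values; it requires K < T − 5 regressors and is
the robustness check against indirect paths and common drivers, to which the
bivariate fit is deliberately sensitive.

## Significance

A GC map is converted to z by *global standardization over the analysis
mask* — not a per-coefficient t statistic. This reading is forced by the
paired criterion (a z cutoff alongside a raw-GC cutoff only makes sense if z
is a map-level rescaling) and is the main interpretive choice of the
implementation. Voxels survive jointly when |Z| > 3.75 and |GC| > 0.39
(strict inequalities); magnitudes are used because strong negative paths are
reported alongside positive ones, with the sign carried separately. Two
consequences worth knowing:

- a z sign can in principle disagree with its gc sign when the map mean is
  far from zero; with edges at |gc| > 0.39 and near-centred maps this does
  not occur in practice, but it is a property of the conversion, not an
  enforced invariant;
- a planted target region is only detectable when signal regions occupy a
  small fraction of the mask: the signal itself inflates the map sd, and
  with equal-size parcels a target larger than ~3% of the mask saturates
  below z = 3.75. The voxel-level experiments therefore use fine (216-
  parcel) grids; maps with few, large parcels are reported descriptively
  and the ROI stage carries the analysis.

ROI networks keep edges with |GC| > 0.39 (the same magnitude threshold, no z
gate); edge z standardizes the coefficients over all R(R−1) ordered pairs,
configurable conceptually but fixed here. Maps or networks with fewer than
10 features/pairs leave z as NaN rather than failing, so degenerate
reductions (two regions) still produce their edge set. Degree bookkeeping is
binarized: out-degree, in-degree, out−in; strict sign of out−in assigns
source-like / sink-like / balanced. The transition flag is a documented
heuristic — a node that both sends and receives and has the maximum
in-degree among senders — and is never used in quantitative claims.

The seed region's own voxels are excluded from the voxel-wise analysis mask:
a seed voxel's series nearly duplicates the seed mean, so its lagged
regressors are collinear and the resulting coefficients are unstable enough
to dominate map standardization. Voxels with zero temporal variance are
likewise dropped (logged) before standardization.

## Seed identification (group contrast)

The simplified morphometry stage fits, per voxel, volume ~ group + sex +
age + education + TIV + months-post-RT (0 for controls); the group t-map is
thresholded at voxel p < 0.001 and clusters (26-connectivity) are kept when
their extent exceeds the 95th percentile of a Freedman–Lane permutation
null: the nuisance-only residuals are row-permuted, added back to the
nuisance fit, and the maximum suprathreshold cluster extent recorded per
permutation. This replaces random-field-theory FWE with an assumption-light
equivalent at desk scale. Constant covariate columns (e.g. an all-male
subsample) are dropped rather than fatal. Months-post-RT is structurally
collinear with group (controls sit at 0), which genuinely inflates the group
term's standard error — a property of the design being emulated, not a bug.
Cognition is related to the seed's volume by Spearman correlation with
Benjamini–Hochberg FDR across the battery (q < 0.05).

## Synthetic cohorts

`cascnet.sim` emulates the study design: default 38 patients and 23
controls; post-RT times log-uniform on (0.5, 108) months as a stand-in for
the observed right-skew (the true empirical distribution is characterized
only by median and range; explicit times may be supplied); ages, sex ratio
(33:5 patients, 16:7 controls), education and TIV drawn at realistic
magnitudes; a ten-test cognitive battery with group-shifted means.

Volumes decompose as baseline + atrophy-slope × months − group deficit
(patients only) + covariate effects + a latent deviation d, where d follows
a lag-1 linear system over the time-sorted patient sequence:

    d[t, roi] = sum_edges c * d[t-1, src] + rho_roi * d[t-1, roi] + eps,
    eps ~ N(0, noise_sd)  for every ROI.

Couplings act on the source's *deviation*, not the raw volume: coupling a
raw volume would only shift intercepts and leak covariate effects that
residualization removes again, whereas deviations make c directly the
planted lag-1 path. Per-ROI persistence rho is available because without an
autocorrelated driver no lag-1 indirect-path or common-driver confound
exists at all — the phenomenon the multivariate analysis exists to suppress.
Controls receive baseline + covariate effects + noise only. All randomness
derives from one seed through SeedSequence spawning; identical configs
reproduce bit-identical cohorts.

What the generator does *not* emulate: MRI physics, segmentation error,
smoothing, spatial autocorrelation beyond parcel structure, realistic
parcel geometry, and any feedback from volumes to covariates. Passing tests
therefore demonstrate that the estimator recovers the model it assumes under
the stated conditions — not that the pseudo-time assumption holds in real
cohorts.

## Study conditions used by the experiments

- **Recovery** (`roi_recovery_experiment`): T = 38 patients, 9 regions,
  innovation sd 0.3, three planted edges forming a source → relay → sink
  motif (+2.0, −1.5, +1.2), 200 replicate cohorts, full nuisance pipeline.
  The motif gives the evaluated source and sink two planted paths each: at
  this T and threshold, ~2% of null ordered pairs exceed |GC| > 0.39, so a
  degree-1 node's out−in sign flips in ~15% of replicates no matter how
  strong its single edge — an intrinsic ceiling of the published threshold
  at this sample size, which the motif sidesteps rather than hides (the
  per-node rates are reported alongside).
- **Null calibration**: identical cohorts with zero planted structure, 500
  replicates; the reference expectation is an *independent* Monte-Carlo that
  simulates white-noise pairs directly (with the same nuisance projection)
  rather than reusing the cohort machinery. Comparison uses replicate-level
  standard errors because the 72 pairs within one cohort share series.
- **Sign semantics / direction separation** (`voxel_sign_experiment`):
  216-parcel grids; a seed with one positive and one negative planted
  out-coupling (±3.0) and one in-driver; seed-to-map must recover the
  targets with matching signs, map-to-seed the driver, and neither
  direction may leak into the other at lag 1.
- **Chain robustness**: A→B→C (0.9, 0.9) with driver persistence 0.6;
  the bivariate A→C rate (~0.15–0.2) versus the conditional rate (~0).
- **Determinism**: the full pipeline (simulate → contrast → voxel maps →
  network) on a 20³ grid, 9 regions, T = 38, run twice per seed and
  byte-compared on its degree table.

Replicate counts and grid sizes are the package's chosen desk-scale study
conditions; all experiments complete in well under a minute each on one CPU.

## Numerical choices and edge cases

- All OLS through `numpy.linalg.lstsq`; the voxel stages solve per-voxel
  3×3 normal equations vectorized, verified against the scalar path to
  1e-8. Test oracles use explicit (X'X)⁻¹X'y solves as an independent route.
- Population (divisor-T) convention for every sd, including z-conversion;
  no small-sample correction, documented rather than patched.
- Identical source/target series, rank-deficient designs, zero-variance
  features, constant GC maps, and sub-minimum series (T < 8) are errors
  naming the offending feature or column; constant nuisance columns are
  dropped silently only where a retained intercept makes them redundant.
- Atlas parcels are axis-aligned blocks with a one-voxel margin; cluster
  connectivity is 26-neighbour everywhere.
- Pipeline artifacts are TSVs with a comment header carrying the config
  hash and seed; the run manifest records versions and stage timings.

## Known limitations

Pseudo-time ordering cannot distinguish progression from cohort effects;
the generator's linear lag-1 world matches the estimator's assumptions by
construction, so recovery results are a consistency check, not clinical
validation; blocky synthetic parcels make permutation cluster-extent nulls
coarse (near-noise-free parcels fire as wholes — the demo adds voxel noise
0.25 so voxels decorrelate); and the voxel-level joint criterion is
conservative whenever signal regions are a non-trivial fraction of the
analysis mask.
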