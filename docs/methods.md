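# Methods

This note documents the models behind `cardioprofiler`: what the synthetic
screen generator simulates, how each analysis stage is defined, the
numerical conventions, and what the recovery experiments do and do not
demonstrate.

## Synthetic screen generator

The generator emulates a 17-compound cardiotoxicity screen in hiPSC-derived
cardiomyocytes: a 7-point semi-logarithmic concentration series per compound
(spanning each compound's clinical exposure window), three cell lines, six
replicate wells per condition plus six vehicle (0.1% DMSO) wells per plate,
~2,000 cells per imaging well, 205 morphological features partitioned into
10 organelle blocks (nuclei, DNA damage, nucleoli, sarcomere/cytoplasm, gap
junctions, mitochondria, lysosomes, peroxisomes, Golgi, ER), and 8-electrode
MEA wells recorded for 5 minutes.

### Imaging model

A cell's feature vector is multiplicative on four levels:

    value = line baseline × exp(effect) × exp(g · w) × lognormal noise

- **Line baselines** are per-line, per-feature lognormal draws (σ = 0.3)
  around feature-type scales (areas ~10²–10³ µm², intensities ~10³ a.u.,
  counts ~10). Cytoplasmic area (the outlier-filter feature) has baseline
  2,500 µm².
- **Compound effects** follow a Hill curve on concentration (coefficient 2,
  per-compound EC50, per-line EC50 shift of ±0.5 log₁₀ units) applied to the
  organelle blocks in the compound's mechanism profile; within a block,
  per-feature weights are drawn once per compound from U(0.5, 1). All
  compounds additionally share a mild nonspecific stress signature
  (ER +0.08, Golgi +0.06, lysosomes +0.04 log-fold at maximal effect):
  dose-correlated secretory/lysosomal drift exists even for compounds
  without a specific mechanism.
- **Well factor**: every well draws a global nuisance factor g ~ N(0, 0.1)
  that loads on all features with fixed positive weights w ~ U(0.2, 1).
  This reproduces the dominant feature–feature correlation structure of real
  imaging plates (confluence, staining intensity); without it, inactive
  compounds would have arbitrary PCA fingerprints, which real screens do not
  show.
- **Cell-level noise** is lognormal with σ = 0.25.
- **Viability**: well cell counts are Poisson with mean
  2,000 × (1 − viability_effect × Hill(c)); the doxorubicin-like default
  (maximal loss 0.67, viability EC50 1 µM) reproduces a −67% nuclei-count
  change at 10 µM.
- **Artifacts**: 1% of cells per well get a 6× cytoplasmic area (planted
  outliers, far beyond 3 raw MADs); two acquisition-gain columns are exactly
  constant; one peroxisomal feature is missing in the amiodarone top-dose
  condition (undetectable signal).

### MEA model

Per well: a mean beat period (baseline 30 BPM, ±5% well noise) shifted by
the compound's fractional `bpm_shift`; per electrode, a mean period drawn
with across-electrode CV = 0.01 + `bri_inflation` × Hill(c) (this CV *is*
the planted beat-rate irregularity), beat-to-beat noise of 2%, and an FPD
(baseline 400 ms, shifted by `fpd_shift`) detected with probability 0.9 per
electrode. 5% of electrodes fall below the 300 µV detection threshold and
contribute no beats; at or above a compound's `quiescence_dose` the whole
well is silent. Electrophysiology effects use the nominal compound EC50
(no line shift): the emulated screen acquires electrophysiology in a
single well-characterized line.

### Planted structure

Each compound carries an FDA-label toxicity group (arrhythmia: amiodarone,
bupivacaine, dofetilide, digoxin, chlorpromazine; ischemia: cisplatin,
fluorouracil, ponatinib, erlotinib; structural: doxorubicin, dasatinib,
lapatinib, methotrexate; none: aspirin, empagliflozin, omecamtiv, propofol)
and a planted morphological mechanism class:

1. genotoxic — doxorubicin alone (DNA damage, nucleoli, nuclei dominant);
2. no specific phenotype — the inactive/ephys-only compounds;
3. ion-channel blockers — mitochondrial gain with lysosomal loss;
4. mixed multi-organelle toxicity — a shared gap-junction/sarcomere/Golgi
   core with signed group extras: ischemia-associated members +ER/−nuclei,
   structural members +nuclei/−ER (lapatinib additionally −peroxisomes).

The signed extras are deliberate: absolute PC1 loadings are sign-blind, so
k-means sees one homogeneous mixed cluster, while the supervised analysis
receives a bipolar ER-vs-nuclei contrast that separates the ischemia and
structural groups. Chlorpromazine is planted with no usable signal in either
modality — mirroring its behaviour in the study this design emulates — and
is therefore the expected systematic misclassification of the supervised
branch. Two deliberate departures from the emulated study's cluster listing:
omecamtiv and propofol are planted as morphologically quiet (keeping them in
the mixed cluster would make the "none" class bimodal), and erlotinib
carries the ischemia-class signature rather than a null one.

## Analysis definitions and numerical conventions

- **SD convention**: sample standard deviation (n−1) everywhere.
- **MAD rule**: raw MAD without the 1.4826 consistency constant; threshold
  3; MAD = 0 ⇒ no outliers; undefined ratios (0/0) are non-outliers; applied
  per dataset (cell line/batch).
- **FPDc** divides milliseconds by a dimensionless power (0.192) of the
  period in seconds — the instrument formula is followed literally even
  though it is not dimensionally homogeneous.
- **Undefined propagation**: quiescent wells and wells with < 2 active
  electrodes yield NaN parameters and are excluded from plate CVs, never
  imputed.
- **Vehicle matching**: the reference is the feature-wise median of the
  vehicle replicate profiles of the same (line, plate) stratum; features
  with a zero reference are dropped (`zero_vehicle`), not divided.
- **Near-zero variance** is assessed on the whole normalized replicate-level
  matrix; values are compared after rounding to 8 significant digits
  (replicate medians are continuous; exact float uniqueness would defeat the
  frequency-ratio test). Ties among most-common values use the two largest
  counts regardless of value identity.
- **Fingerprint PCA** centers the pooled (7 concentrations + vehicle)
  line-level profiles and takes PC1 from an SVD of the centered matrix.
  Unit-variance feature scaling is available but **off by default**:
  vehicle-normalized fold changes are already commensurate across features,
  and standardization erases the effect-size contrast between a compound's
  affected organelles and incidentally dose-correlated noise — with scaling
  on, strong and weak compounds collapse onto similar |loading| patterns and
  the planted cluster structure is not recoverable.
- **k-means** uses k-means++ with 50 restarts at fixed seed, Euclidean
  distance on the raw fingerprint weights; k is fixed at 4 by default, with
  mean-silhouette selection over k = 2..8 available (and used by the
  recovery experiments).
- **Sparse PLS-DA**: columns of X centered (and scaled unless the input is
  a pre-standardized block combination — re-scaling would undo the
  per-datatype weighting); Y is the centered one-hot class indicator. Per
  component, the weight vector is the dominant left singular vector of the
  cross-covariance XᵀY, soft-thresholded to at most keepX nonzeros (λ = the
  (keep+1)-th largest |w|; ties at λ resolved by first-index priority) and
  renormalized; scores deflate both X and Y in regression mode, which makes
  them mutually orthogonal. Defaults: 2 components, keepX = 50, no internal
  tuning. Prediction assigns samples to the nearest class centroid in score
  space (Euclidean); compounds by majority vote over replicate wells, ties
  broken toward the alphabetically first group.
- **Block fusion**: each block is standardized column-wise and scaled by
  w_b/√p_b so that at equal weights the morphology (~200 columns) and
  electrophysiology (6 columns: BPM, BRI, FPD, FPDc, active %, FPD success
  %) blocks contribute equal total variance.
- **Exposure-dose selection** (supervised branch): the highest-magnitude
  electrophysiological effect among doses with expected viability ≥ 80% and
  below any quiescence dose; compounds without electrophysiological activity
  default to the highest tolerated dose.

## Recovery experiments and problem sizes

Simulations in the test suite and the acceptance script are run at reduced
per-well cell counts — replicate medians converge like σ/√n, so a few
hundred cells per well already pin the profile medians while keeping runs on
one CPU in minutes:

- **Unsupervised recovery**: full 3-line × 6-replicate design at 120
  cells/well, 20 seeds; silhouette-selected k must equal 4 with assignments
  exactly matching the planted classes (up to permutation) in ≥ 19/20.
- **Supervised recovery**: single-line design at the selected exposure doses,
  200 cells/well, 6 replicates, 20 seeds; per-compound accuracy must reach
  76% in ≥ 18/20. Typical accuracies are 82–94% with chlorpromazine as the
  standing error; residual seed-to-seed variation comes from the ±0.5 log₁₀
  per-line EC50 shifts and the per-compound feature-weight draws, not from
  cell-count noise (raising the density further does not reduce it).
- **Viability calibration** runs at the study-scale 2,000 cells/well
  (doxorubicin-only design) and recovers −67% ± sampling error at 10 µM.

## What passing these tests shows — and what it does not

The generator shares with real screens the hierarchy (cells → wells →
plates → lines), positive right-skewed features with a dominant common
variance factor, Hill-type dose responses, viability loss, quiescent and
irregular beating regimes, and contaminated/constant/missing features. It
does not simulate images or segmentation error, plate-position gradients,
staining-batch effects beyond the line baseline, multi-nucleation, or
temporal drift of the monolayer; feature noise beyond the rank-1 factor is
independent across features. Passing recovery therefore validates the
pipeline's statistical machinery — the QC chain, the parameter algebra, the
fingerprint/cluster geometry and the classifier — under the planted
conditions; it does not certify classification accuracy on real screens,
where group separability is an empirical property of the compounds chosen.

## Known limitations

- With two latent components and four classes, the score space cannot carry
  three independent contrasts; class geometries that need them (e.g. two
  groups separated only in a third direction) will fold together. The
  component count is configurable.
- The centroid prediction rule is sensitive to strongly heterogeneous
  classes (one extreme member drags the centroid); the per-compound majority
  vote mitigates but does not remove this.
- The NZV frequency-ratio test is designed for discretized/constant
  features; on continuous data it acts only through the constant-column
  path, which is the intended behaviour here.
- `block_combine` currently supports exactly two blocks; a multiblock
  (DIABLO-style) extension is out of scope.
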