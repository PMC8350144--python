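# Methods

`netreconfig` implements a dynamic functional-connectivity (FC) analysis for
parcellated fMRI time series recorded during naturalistic (movie) viewing:
sliding-window signed connectomes, per-window consensus community
structure, reconfiguration indices at two timescales, coupling of FC
reconfiguration with movie semantic annotations, and a subject-level
inference layer (cross-validated CCA, behavioral PLS, robust regression).
Because suitable naturalistic cohorts are access-restricted, the package
ships a first-class synthetic-cohort generator with planted ground truth;
every downstream stage is validated against that ground truth.

## Denoising

Input is a volumes x nodes matrix of ROI-averaged BOLD. The chain is:

1. **Confound regression** — least-squares removal of nuisance columns:
   10 aCompCor-style component regressors plus 24 motion-derived regressors
   (6 rigid-body parameters, their backward-difference derivatives with a
   zero first row, and the squares of both). Residuals are orthogonal to
   every regressor (checked to 1e-10 on correlations). Global signal
   regression is deliberately absent.
2. **Bandpass** 0.008–0.09 Hz, realized as a zero-phase forward–backward
   4th-order Butterworth (the band, not the filter family, is the
   specification; zero-phase avoids temporal shifts that would smear
   window boundaries).
3. **Linear detrend** (kept after the bandpass for fidelity to the stated
   order even though it is partially redundant).
4. **Tanh despike** — per column, with robust scale
   s = multiplier · 1.4826 · MAD (multiplier default 3): output =
   median + s·tanh((x − median)/s). This is odd-symmetric about the median,
   non-expanding, and bounds every value within median ± s. Zero-variance
   columns pass through unchanged.

Task regressors for event designs are a boxcar convolved with a canonical
double-gamma HRF (peak delay 6 s, undershoot delay 16 s, dispersions 1,
ratio 6, 32 s support) sampled at volume times, plus its backward-difference
temporal derivative.

## Windowed connectomes

Windows are `floor(length_s / tr)` volumes long (40 s default; the 30 s /
TR 2.47 s worked example gives 12 volumes) advanced by
`max(1, round(step_s / tr))` volumes (~2 s default), 0-based half-open.
Within a window, connectivity is the Hann-tapered weighted Pearson
correlation between every node pair — weights sin²(π(k+1)/(n+1)),
normalized, strictly positive so every scan contributes while the window
center dominates — Fisher z-transformed with |r| clipped at 1−1e-7.
Matrices keep both signs, are exactly symmetrized, and the diagonal is set
to 0 (not +inf). Scans with excluded rest periods are windowed per segment
so no window straddles an exclusion.

## Community structure

Partitions maximize the asymmetric signed modularity

    Q* = (1/v+) Σij (w+ij − γ s+i s+j / v+) δ(ci,cj)
       − (1/(v+ + v−)) Σij (w−ij − γ s−i s−j / v−) δ(ci,cj)

with w± the positive/negative parts, s± node strengths, v± total weights,
and the resolution γ multiplying both configuration-model expectation
terms (resolution applied symmetrically — the single most consequential
formulation choice). Positive weights are thus unaffected by negative ones,
while the negative term shrinks as positive connectivity grows.

Optimization is a two-phase Louvain (greedy local moves accepting only
strict Q* gains, then community aggregation with self-loops), with the node
sweep order drawn from the seed; ties go to the first-best candidate in
label order. On 7-node signed graphs the best of 100 restarts matches
exhaustive search over all 877 partitions in ≥95% of seeds.

Per window and per γ ∈ {0.95, 1.00, 1.05}, 100 seeded restarts (default)
feed an agreement matrix (pairwise co-assignment frequencies), which is
thresholded at τ = 0, re-clustered 100 times, and iterated to a fixed point
(Lancichinetti–Fortunato consensus). Windows are treated independently
(single-layer); agreement matrices are kept per γ, and subject-level
indices are averaged over the three γ values afterwards.

The local-move sweep is JIT-compiled with numba; a full 30-subject cohort
(60 nodes, ~121 windows, 3 γ, 25 restarts — the scale used by the
determinism check) runs in a few minutes on one CPU.

## Reconfiguration indices

Partition similarity is the adjusted mutual information with the exact
permutation-model (hypergeometric) expectation and the arithmetic-mean
entropy normalizer: AMI = (MI − E[MI]) / (mean(H(p), H(q)) − E[MI]).
Degenerate conventions: both partitions single-cluster → 1; exactly one
single-cluster → 0. The implementation is cross-checked in the tests
against an independent scipy-based oracle and scikit-learn.

* **Window-to-window reconfiguration** = 1 − mean AMI over temporally
  adjacent window pairs, per γ then γ-averaged.
* **Event-boundary reconfiguration** = 1 − mean AMI over window pairs
  straddling narrative event boundaries. For each boundary the pre-window
  is the latest window ending at or before the boundary and the post-window
  the earliest starting at least gap_min (default 5 s) after the
  pre-window's end; pairs whose gap exceeds gap_max (default 7 s) or that
  fall off the scan edges are skipped. The gap range is configurable; this
  is one admissible reading of a "~5–7 s" separation rule, chosen because a
  symmetric half-gap rule cannot realize any admissible gap on a 2 s grid.
* **Temporal participation coefficient** P_i = 1 − Σ_m (k_i(m)/k_i)², where
  k_i(m) counts node i's cross-window co-assignments with nodes of atlas
  community m. P_i = 0 for isolated nodes (k_i = 0). Network-level values
  are unweighted means over each atlas network's nodes.

## Semantic coupling

Binary per-frame movie features (nouns = entities, verbs = actions; the
single adjective feature is ignored) are averaged within each window's
volume-time span. Averages are kept as exact integer counts over a common
denominator, so the "unique value defines a cluster label" step is immune
to floating-point equality artifacts. Window-to-window semantic similarity
is the AMI of adjacent windows' label vectors, separately for nouns and
verbs; brain–movie coupling is the Spearman correlation between the FC
similarity series (γ-averaged) and each semantic series. At cohort level,
overall window-to-window reconfiguration is regressed out of the couplings
(least squares across subjects). Reliability of repeated per-movie values
uses Cronbach's α with optional per-item covariate residualization.

## Inference

* **CV-CCA**: 10 folds (sizes within ±1). Per fold, both blocks are
  standardized with training-fold statistics, a classical CCA (whitening +
  SVD of the cross-product; rank-deficient blocks reduced with a warning)
  is fit on the training folds, and the held-out fold is projected; fold
  weight signs are aligned to the first fold. The pooled predicted variates
  are correlated (partial Pearson, covariates removed). The permutation
  test re-runs the complete CV loop on each row-permuted Y block
  (100,000 permutations by default, add-one p): a simple shuffle of the
  pooled variates is anticonservative because fold models share training
  data, and the full-refit scheme restores nominal type-I error
  (verified at 0.02–0.09 over 200 simulated nulls). Per-variable loadings
  (partial correlations with the predicted variate) and standardized
  coefficients (joint regression of the z-scored variate on all z-scored
  variables plus covariates) carry BCa bootstrap CIs (percentile fallback).
* **Behavioral PLS**: SVD of the behavior x ROI cross-correlation matrix.
  LV significance permutes ROI-block rows and compares singular values
  position-wise. Salience SEs come from a subject bootstrap with Procrustes
  rotation of each resample's LVs onto the originals; saliences are scaled
  by their singular values, so with one behavior column the first LV's
  saliences equal the behavior–ROI correlation vector up to sign. Bootstrap
  ratio BSR = salience/SE; |BSR| ≥ 3 marks reliable ROIs. The behavior–LV
  correlation gets a 99% percentile bootstrap CI.
* **Robust regression**: statsmodels RLM with the Tukey bisquare norm,
  tuning constant 4.685, MAD scale, tolerance 1e-8 (95% Gaussian efficiency;
  matches ordinary least squares to 1e-6 on clean data while bounding slope
  error under 10% gross contamination).
* **Partial Spearman**: rank-transform everything, residualize the ranked
  x and y on ranked covariates, Pearson on the residuals; permutation p.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
fMRI physics:

* **Planted dynamics**: a sequence of balanced partitions over
  n_communities (default 4) switching between adjacent windows with
  probability switch_rate; on a switch, reassign_fraction of nodes move
  (fraction 1 redraws a fresh partition). Change points are exported in
  windows, volumes and seconds.
* **BOLD-like signal**: within a window, node signal =
  √(snr/(1+snr))·community latent + √(1/(1+snr))·node noise, giving
  closed-form within-community correlation snr/(1+snr) and zero between
  communities. At snr 3 (within-community r = 0.75) consensus partitions
  recover the planted labels with median AMI > 0.9 using 40-volume
  windows; at snr 0.01 recovery collapses to chance. No hemodynamic
  forward model or head-motion physics is simulated.
* **Semantic streams**: binary features flip between frames with
  probability base_flip_rate (default 0.01), boosted by
  coupling_strength × 0.25 at planted change-point frames. Default class
  sizes follow the 629-noun / 229-verb / 1-adjective coding of the movie
  annotation set.
* **Behavior**: scored columns are linear loadings on per-subject brain
  indices plus Gaussian noise; demographic/covariate columns (age, gender,
  handedness, education, motion, ROI homogeneity) are generated
  independently unless an explicit confounding knob (default 0) is turned.
* **Nuisance**: 6 Gaussian random-walk motion traces expanded to 24
  columns by the denoise module's own expansion rule, plus 10 smoothed
  Gaussian component regressors.

All generators are deterministic given their seed; the pipeline derives
every stream from one cohort seed, and two identically seeded end-to-end
runs produce byte-identical CSV/JSON outputs.

Because the generator plants block-covariance switches, passing tests show
that the pipeline recovers this class of structure under calibrated noise;
they do not certify behavior on real BOLD, whose FC transitions need not be
block-like, whose noise is autocorrelated, and whose semantic annotations
are not synchronized to connectivity by construction.

## Problem sizes and numerical choices

The test-suite and example runs use scaled problem sizes chosen to keep the
statistical properties measurable: cohorts of 12–30 subjects, 20–60 nodes,
12–121 windows, 8–50 Louvain restarts, and 100–999 permutations/bootstraps
(the production defaults remain 100 restarts and 100,000 resamples). Other
numerical conventions: Fisher z clipping at |r| = 1 − 1e-7; Louvain move
acceptance threshold 1e-12; consensus iteration cap 50 with a modal-partition
fallback (warned); weighted-correlation zero-variance guard at a relative
1e-8 scale; AMI snapped to exactly 1 for partitions identical up to
relabeling. File formats write 17 significant digits so write→read round
trips are exact.

## Known limitations

* The signed-modularity resolution parameter multiplies both expectation
  terms; formulations that scale only the positive term exist and would
  shift Q* values.
* The event-boundary window-selection rule is one admissible reading of a
  loosely specified "~5–7 s" separation; alternatives change which pairs
  enter the boundary index (the gap range is exposed in configuration).
* CV-CCA covariate control residualizes the pooled predicted variates
  rather than the raw inputs; with covariates strongly correlated with the
  Y block the permutation null ignores the Y–covariate link.
* Multilayer (temporally coupled) community detection, connectome
  thresholding, and voxel-level processing are out of scope.
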