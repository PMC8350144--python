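# netreconfig

Dynamic functional-connectivity (FC) community reconfiguration for
parcellated fMRI recorded during naturalistic (movie) viewing — for network
neuroscientists who want the full chain from denoised ROI time series to
subject-level inference as one tested, seeded, reproducible pipeline.

## What it computes

1. **Denoising** — confound regression (10 aCompCor-style components + 24
   motion-derived regressors), 0.008–0.09 Hz zero-phase Butterworth
   bandpass, linear detrend, tanh despiking.
2. **Windowed connectomes** — 40 s Hann-tapered sliding windows (~2 s
   step), weighted Pearson correlation per node pair, Fisher z, both signs
   retained, no thresholding.
3. **Community structure** — signed-modularity Louvain maximizing

   `Q* = (1/v⁺) Σᵢⱼ (w⁺ᵢⱼ − γ e⁺ᵢⱼ) δ(cᵢ,cⱼ) − (1/(v⁺+v⁻)) Σᵢⱼ (w⁻ᵢⱼ − γ e⁻ᵢⱼ) δ(cᵢ,cⱼ)`

   with 100 seeded restarts per window at γ ∈ {0.95, 1.00, 1.05}, followed
   by agreement-matrix consensus clustering (τ = 0, 100 repetitions,
   iterated to a fixed point).
4. **Reconfiguration indices** — adjusted mutual information (AMI, exact
   hypergeometric chance correction) between window partitions;
   window-to-window reconfiguration = 1 − mean adjacent-window AMI;
   event-boundary reconfiguration over non-overlapping window pairs
   separated by a 5–7 s gap around narrative boundaries; temporal
   participation coefficient `Pᵢ = 1 − Σₘ (kᵢ(m)/kᵢ)²` over cross-window
   co-assignments, summarized per atlas network.
5. **Brain–movie coupling** — per-window averages of binary semantic
   features (nouns/verbs), unique averaged values as cluster labels,
   AMI-based semantic similarity series, Spearman coupling with the FC
   similarity series, cohort-level residualization, Cronbach-α reliability.
6. **Inference** — cross-validated CCA (10 folds, pooled test-fold
   variates, full-refit permutation test, BCa bootstrap CIs for loadings
   and standardized coefficients), behavioral PLS (SVD of the
   behavior × ROI correlation matrix, permutation p per latent variable,
   bootstrap ratios with |BSR| ≥ 3 marking reliable ROIs), bisquare robust
   regression (tuning 4.685) and partial Spearman correlations.

Raw naturalistic cohorts with these properties are access-restricted, so
the package includes a synthetic-cohort generator with planted community
dynamics, semantic streams coupled to the planted change points, and
behavior loading on the planted brain indices — every stage is validated
by parameter recovery against that ground truth (see `docs/methods.md`).

## Worked example

Simulate a 20-subject cohort (40 nodes, 4 planted communities, 240 volumes
at TR 1 s, snr 3) and run the full pipeline:

```python
from netreconfig.pipeline import PipelineConfig, simulate_cohort, run_pipeline
from netreconfig.dynfc import WindowSpec
from netreconfig.communities import ModularityConfig, ConsensusConfig
from netreconfig.stats import StatsConfig

cfg = PipelineConfig(
    n_subjects=20, n_nodes=40, n_communities=4, n_planted_windows=12,
    vols_per_window=20, tr=1.0, snr=3.0,
    window=WindowSpec(length_s=20.0, step_s=2.0),
    modularity=ModularityConfig(gammas=(0.95, 1.0, 1.05), n_init=20),
    consensus=ConsensusConfig(reps=20),
    stats=StatsConfig(n_folds=5, n_perm=999, n_boot=499, seed=0),
    seed=7,
)
simulate_cohort(cfg, "cohort/")
run_pipeline(cfg, "cohort/", "results/")
```

`results/subject_indices.csv` then holds one row per subject:

```
subject_id  w2w_reconfig  boundary_reconfig  noun_coupling  verb_coupling  participation_mean
  sub-0000        0.1083             1.0167         0.0973         0.0980              0.8940
  sub-0001        0.0456             1.0816        -0.0295        -0.1124              0.8770
  sub-0002        0.1420             0.9931        -0.0668        -0.0852              0.8943
  sub-0003        0.1341             0.9867        -0.0600         0.0257              0.8948
```

`w2w_reconfig` is 1 − mean adjacent-window AMI (sub-0001 reconfigures
least; across the cohort it correlates r ≈ 0.79 with the planted switch
rates). `boundary_reconfig` near 1 means partitions on either side of a
planted event boundary share no more community structure than chance.
`participation_mean` near 0.9 reflects co-assignments spread across the 10
atlas networks. `results/cca.json` and `results/pls.json` carry the
inference layer — this run prints pooled CV-CCA r = 0.477 (permutation
p = 0.148; 20 subjects is far below the scale such tests need) and a
first PLS singular value of 1.167 (p = 0.087).

The same stages are available from the shell:

```bash
netreconfig simulate --config cfg.yaml --out cohort/
netreconfig run --config cfg.yaml --data cohort/ --out results/
netreconfig fc cohort/sub-0000_ts.tsv --window-s 40 --step-s 2 --out fc.npz
netreconfig communities fc.npz --gammas 0.95,1.0,1.05 --out parts.json
netreconfig metrics parts.json fc.npz --events cohort/sub-0000_events.tsv
```

## Layout

```
src/netreconfig/
  synthdata.py    synthetic cohorts with planted ground truth
  denoise.py      confound regression, bandpass, detrend, despike, HRF
  dynfc.py        sliding-window tapered Fisher-z connectomes
  communities.py  signed Louvain Q*, agreement, consensus partitions
  reconfig.py     AMI, reconfiguration indices, participation coefficient
  semalign.py     semantic profiles, coupling, residualization, Cronbach α
  stats.py        CV-CCA, behavioral PLS, robust regression, partial Spearman
  io.py           TSV/CSV/JSON dialects with validation
  pipeline.py     end-to-end orchestration, deterministic under one seed
  cli.py          click command-line interface
```
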