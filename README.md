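# arousalnet

Preoperative resting-state fMRI analysis linking whole-brain network
segregation and ascending-arousal nucleus connectivity to postoperative
delirium — as a tested, reproducible Python pipeline.

Postoperative delirium disproportionately affects older surgical
patients, and one candidate mechanism is a pre-existing imbalance of
the ascending arousal system: the noradrenergic locus coeruleus (LC),
which pushes cortical networks toward integration, and the cholinergic
nucleus basalis of Meynert (nbM), which pushes them toward segregation.
This package implements the full analysis a study of that hypothesis
needs, for researchers working with parcellated BOLD time series:

* **static connectivity** — Pearson correlation between parcel series;
* **dynamic connectivity** — multiplication of temporal derivatives
  (MTD): `MTD_ijt = (1/w) Σ_t dt_i(t)·dt_j(t) / (σ_dti·σ_dtj)` with a
  trailing `w = 5` TR window over z-scored first differences;
* **time-resolved topology** — the participation coefficient
  `B_i = 1 − Σ_s (K_is/K_i)²` per coupling frame over a 17-network
  partition (or a seeded Louvain partition), with k-means (k = 2)
  classification of integrated vs segregated brain states;
* **discriminant analysis** — an eigen-mode two-class Fisher LDA with
  balanced priors over concatenated seed-coupling frames, selection of
  the top 5% discriminating time points and back-projected
  group-contrast maps;
* **phasic coupling** — detection of nucleus BOLD peaks (≥ mean + 2 SD,
  edge-trimmed) and peak-locked profiles of the z-scored global
  participation coefficient at lags −5..+5 TRs, with per-lag
  permutation Welch t-tests;
* **group inference** — edge-wise permutation t-tests (1000 shuffles,
  optional max-statistic FWE), logistic outcome models `D ~ PC × C`
  ranked by AIC, Benjamini–Hochberg FDR, biomarker correlations;
* **gene association** — robust-sigmoid normalisation and PCA (80%
  variance) of a cholinergic expression panel, spin-permutation spatial
  null tests on the sphere, and Williams–Hotelling comparisons of the
  dependent correlations.

Because the clinical data such studies use are ethics-restricted, the
package includes a first-class **synthetic cohort generator**
(`arousalnet.synthetic_cohort`) that plants every effect the pipeline
is meant to detect — group-dependent between-module coupling,
seed-coupling shifts, phasic bursts with lagged topology responses, an
outcome with a PC × covariate interaction, and spatially autocorrelated
gene maps — so the entire analysis runs end-to-end from a single seed.
See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
from arousalnet import pipeline
from arousalnet.synthetic_cohort import CohortConfig

results = pipeline.run_pipeline(config=CohortConfig(seed=1), seed=1)
print(results["mean_pc"]["delirious"], results["mean_pc"]["non_delirious"])
print(results["logistic"]["aic_ranking"])
```

On the default cohort (60 delirious + 60 non-delirious subjects,
210 TRs × 402 regions, seed 1) this prints a mean participation
coefficient of 0.9112 for the delirious group against 0.9166 for the
non-delirious group — the planted segregation of the delirious brains,
small against the between-subject spread but recovered from the
generated data (group permutation p = 0.001) — and the AIC table

```
             form         aic  ...  delta_aic
0     interaction  134.85      ...   0.00
1  predictor_only  150.84      ...  15.99
2        additive  152.80      ...  17.95
3  covariate_only  170.31      ...  35.46
```

ranking the PC × slow-wave-change interaction model first, the model
ordering this analysis design predicts.  The delirious group also
spends more time in the segregated state (occupancy 0.588 vs 0.341),
and the phasic stage shows the mirrored arousal signature: the mean
peak-locked global-PC profile at lag +1 is positive for LC (+0.49,
integration after noradrenergic peaks) and negative for nbM (−0.70,
segregation after cholinergic peaks).

A command-line interface mirrors the library
(`arousalnet simulate | denoise | fc | dfc | topology | lda | phasic |
edgetest | outcome | genes | run`); `arousalnet run --out results/`
executes the whole pipeline on a synthetic cohort.

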