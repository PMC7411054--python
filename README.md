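# phenoprofiler

Phenomic profiling of multi-plate compound screens: from per-cell imaging
features to per-mechanism-of-action (MoA) distinguishability scores.

High-content screens image reporter cell lines treated with compound
libraries at several concentrations and extract hundreds of morphological
features per cell. `phenoprofiler` implements the downstream analysis as a
tested, reusable pipeline:

1. **Preprocess** — filter to live cells, aggregate each well to mean /
   median per feature plus cell count (~2F+1 descriptors), and z-score
   against DMSO vehicle controls (plate-wise centering, batch-wise scaling).
2. **Signature selection** — a modified minimum-redundancy-maximum-relevance
   (mRMR) ranking with treatment ID as the class variable: greedy
   maximization of `relevance · (1 − redundancy)`, where relevance is the
   scaled ANOVA F-statistic and redundancy the maximum |Pearson r| to the
   selected set; the signature size k is the smallest prefix whose
   replicate-vs-non-replicate discrimination AUC is within one SD of the
   best mean AUC.
3. **Active calling** — a treatment is phenotypically active when (i)
   strictly more than half of its replicate wells deviate from vehicle
   beyond τ, the 95th percentile of the control-well distance null, and
   (ii) its median replicate correlation exceeds the 95th percentile of a
   non-replicate (different-compound) correlation null.
4. **MoA evaluation** — every active treatment queries the others (own
   compound excluded, one entry per compound at its best-correlated
   concentration); ranking co-MoA compounds above the rest gives an
   AUC-ROC, aggregated per MoA as the median of per-compound maxima, with
   permutation p-values (annotation sets permuted as blocks) and
   Benjamini–Hochberg FDR. MoAs with aggregated AUC-ROC ≥ 0.9 are
   *distinguishable*.
5. **Auxiliary rules** — expressed/absent gene calls from a two-component
   Gaussian mixture per microarray replicate, core-fitness gene calling
   (defects in ≥ 2/3 of cell lines), activity-association tests, cell-line
   coverage ranking, and concentration / fluorescence-channel subset
   analyses.

A synthetic screen generator (`phenoprofiler.synthgen`) produces screens
with known ground truth — 384-well plates with 28 DMSO and 280 sample
wells, 4 concentrations, 2 technical replicates × 2 batches, plate/batch
nuisance offsets, MoA-coherent effect directions with Hill-curve potencies,
redundant feature blocks, noise features, and dead/mis-segmented cells — so
every stage is testable end to end without downloads. See
`docs/methods.md` for the model and all conventions.

## Worked example

```python
from phenoprofiler import ScreenConfig
from phenoprofiler.pipeline import run_pipeline

result = run_pipeline(ScreenConfig(seed=1), n_perm=1000)
print("signature size k =", result.signature.k)
print("tau = %.3f  rho_null = %.3f" % (result.thresholds.tau, result.thresholds.rho_null))
print("active treatments:", int(result.calls["active"].sum()), "/", len(result.calls))
print(result.moa_results[["moa", "n_compounds", "auc", "p_adj", "significant"]])
```

prints (seed 1):

```
signature size k = 23
tau = 5.641  rho_null = 0.672
active treatments: 140 / 240
     moa  n_compounds       auc     p_adj  significant
0  MOA00            7  1.000000  0.001332         True
1  MOA01            8  1.000000  0.001332         True
2  MOA02            7  1.000000  0.001332         True
3  MOA03            5  1.000000  0.001332         True
4  MOA04            5  1.000000  0.001332         True
5  MOA05            7  0.944444  0.001332         True
6  MOA06            5  0.643617  0.198658        False
7  MOA07            7  0.500000  0.611389        False
```

The default `ScreenConfig` simulates a 60-compound screen with 8 planted
MoAs of 5 compounds each: the six MoAs whose members share an effect
direction (MOA00–MOA05) are recovered as distinguishable (aggregated
AUC-ROC ≥ 0.9, FDR < 0.05), while the two incoherent MoAs (MOA06–MOA07,
members with independent random directions) stay near chance and
non-significant. `k = 23` selected descriptors out of 193, τ is the
Euclidean activity threshold in control-SD units, and `rho_null` the
replicate-reproducibility threshold.

The same stages are available from the shell:

```sh
phenoprofiler run --out out/ --seed 1 --n-perm 1000
phenoprofiler simulate --out sim/ --seed 1
phenoprofiler preprocess --cells sim/cells.parquet --platemap sim/plate_maps.csv --out wells.parquet
phenoprofiler select-features --wells wells.parquet --out signature.json
phenoprofiler call-active --wells wells.parquet --signature signature.json --out activity.csv
phenoprofiler moa-auc --activity activity.csv --annotations sim/annotations.csv \
    --signature signature.json --out results.csv --n-perm 10000
```

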