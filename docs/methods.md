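# Methods

This note describes the statistical procedures implemented in
`phenoprofiler`, the assumptions behind the synthetic screen generator, and
the design choices made where the procedure definitions left room.

## The analysis problem

High-content imaging screens treat cells with a library of compounds at
several concentrations, extract hundreds of morphological features per cell,
and ask two questions: *which treatments produce a phenotype at all*, and
*do compounds sharing a mechanism of action (MoA) produce similar
phenotypes*? The pipeline answers them in five stages: well aggregation,
control-based normalization, unsupervised signature (feature) selection,
two-criterion active calling, and nearest-reference MoA scoring.

## Preprocessing

Cells labelled dead or mis-segmented by the upstream QC classifier are
dropped. Per well, each raw feature contributes its mean and median over the
live cells, and the live-cell count is appended, giving `2·F + 1`
descriptors for `F` raw features. Descriptors are z-scored against vehicle:
subtract the mean of the 28 DMSO control wells of the well's plate, then
divide by the sample SD (n−1) of the *plate-centered* control values pooled
over the well's batch. Centering before pooling makes the batch SD a proper
residual scale estimate; computing it on raw control values instead would
mix plate offsets into the denominator. Descriptors with zero control SD
cannot be standardized and are dropped with a warning. Empty wells keep a
row with missing descriptors; missingness propagates and is never imputed.

## Signature selection (modified mRMR)

Feature selection is unsupervised with respect to MoA: the class variable is
the treatment ID. Three prefilters precede it: wells whose Euclidean
distance (over all descriptors) to the mean control profile falls below the
95th percentile of the control-distance null are removed; wells with fewer
than 100 live cells are removed; each descriptor is winsorized at its 1st
and 99th percentiles. Winsorization (clipping) rather than row removal
keeps treatment class sizes intact for the F-statistic.

Relevance of a descriptor is its one-way ANOVA F over treatments, scaled by
the maximum F so relevance ∈ (0, 1]. Ranking is greedy: starting from the
most relevant descriptor, each step picks the descriptor maximizing
`relevance · (1 − redundancy)`, where redundancy is the maximum *absolute*
Pearson correlation with any already-selected descriptor — an
anti-correlated copy carries no new information. Ties break toward the lower
descriptor index, making the ranking deterministic. The cell count and both
mean and median variants are ordinary candidates.

The signature size `k` comes from a replicate-discrimination criterion: for
increasing prefixes of the ranking, score well pairs by the Pearson
correlation of their prefix-restricted profiles and measure the AUC for
separating replicate pairs (same compound and concentration) from
non-replicate pairs (any other pair of treatments). Up to 10,000 pairs per
class are sampled per repeat, 10 repeats; `k` is the smallest size whose
mean AUC is within one SD (the SD at the argmax) of the best mean AUC. The
evaluation grid is every size up to 40 and every 5th size up to 120 — a
compromise between fidelity and runtime, configurable. Prefixes of size 1
have undefined correlations and can never be chosen.

## Active calling

A treatment is phenotypically active when both hold:

1. **Deviation.** A well is flagged when the Euclidean norm of its signature
   (the mean control signature is the zero vector after normalization)
   exceeds `tau`, the empirical 95th percentile of control-well norms
   (linear-interpolation quantile; by construction 5% of control wells are
   flagged). The treatment passes when strictly more than half of its
   replicate wells are flagged — ≥3 of 4 in the standard design, 2 of 3
   when a well was lost to the cell-count filter.
2. **Reproducibility.** The median Pearson correlation over all replicate
   pairs (6 pairs for 4 wells) must exceed the 95th percentile of a null of
   non-replicate correlations, built from all well pairs of
   Euclidean-active treatments belonging to *different compounds* — pairs
   of the same compound at different concentrations are excluded because a
   compound's concentrations often share a phenotype. Pairs are enumerated
   exactly up to a cap (default 2·10⁶) and subsampled beyond it, seeded.

The treatment-level signature is the component-wise median over replicate
wells; a compound is active if any concentration is. On screens where fewer
than two distinct compounds are Euclidean-active (e.g. effect-free null
screens) the reproducibility null is not estimable and nothing is called
active, which is the conservative limit of the rule.

## MoA distinguishability (nearest-reference AUC-ROC)

Each active treatment is used once as a query. All other active treatments —
excluding every concentration of the query's own compound — are ranked by
Pearson correlation of treatment signatures and collapsed to one entry per
compound (its best-correlated concentration). With membership of the query's
MoA as the binary label, the ranking yields a Mann–Whitney AUC (midranks for
ties). Per compound the maximum AUC over its concentrations is kept, and the
MoA aggregate is the median of per-compound maxima; multi-MoA compounds are
evaluated independently per MoA. Aggregates are computed only for MoAs with
≥ 3 active compounds, and an aggregate ≥ 0.9 marks the MoA distinguishable.

Significance: the compound→annotation-set mapping is permuted among active
compounds (sets move as blocks, preserving MoA sizes and the multi-MoA
structure), aggregates are recomputed per iteration, and
`p = (1 + #{null ≥ observed}) / (1 + n_perm)` — the +1 correction avoids
zero p-values. BH-FDR is applied jointly across all tested (MoA, cell line)
pairs.

**A known property, not a bug:** the max-then-median aggregation is
deliberately optimistic, and this carries into the permutation null — the
mean of the permuted *aggregated* AUC sits a few hundredths above 0.5
(≈ 0.535 on the reference screen) even though each per-query AUC is
mean-0.5 by rank symmetry. The bias grows with per-query AUC noise, i.e.
with few candidate compounds, and shrinks as the active set grows. The
p-values are valid regardless, because observed and null aggregates share
the bias.

Ancillary analyses: a greedy set-cover ranking of cell lines by how many
additional distinguishable MoAs each contributes; concentration-subset
re-aggregation (active set restricted, nothing recomputed upstream); and
channel-subset analysis, where mRMR is *re-run* on the channel-restricted
descriptors for an unbiased comparison while the active set of the
full-channel run is kept.

## Auxiliary calling rules

*Expression calls*: per microarray replicate, a two-component Gaussian
mixture is fitted (EM; deterministic initialization at the 25th/75th
percentile, k-means retry on non-convergence) to the probe-set-level log2
intensity distribution; the threshold is the 95th percentile of the
lower-mean component, `μ₁ + 1.645·σ₁` ("first mode" = lower mean, not lower
weight). A gene is expressed only if every probe set exceeds the threshold
in every replicate. *Core-fitness genes*: fitness defects in at least two
thirds of tested cell lines (≥ 6 of 9). *Association tests* (Fisher exact,
Wilcoxon rank-sum) are thin wrappers over scipy; the bespoke content is the
calling rules.

## The synthetic screen generator

The generator emulates the screening design the analysis assumes: 384-well
plates with 28 DMSO control and 280 sample wells (controls interleaved every
11th used position), four concentrations (0.3, 1, 3, 9 µM), two technical
replicates in each of two batches. Per live cell and feature,

```
x = baseline + plate_offset + batch_offset + effect + noise
```

with Gaussian nuisance offsets per (plate, feature) and (batch, feature) and
i.i.d. per-cell noise. The treatment effect is
`effect_size · jitter_c · potency_c(conc) · direction · σ_well` on
informative features: each coherent MoA draws one unit-RMS direction shared
by its members (multi-MoA compounds blend their MoAs' directions);
incoherent MoAs give each member its own direction; `potency` is a Hill
function with per-compound lognormal EC50 (median 1 µM) so some compounds
are active only at high concentrations, exercising the
concentration-collapsing logic; `jitter` is a lognormal per-compound
magnitude spread; `σ_well` is the expected well-level control SD, so
`effect_size` is a z-score-scale magnitude (default 3). Redundant features
are affine copies of informative parents plus small noise (|r| ≥ 0.9 with
the parent); noise features carry no effect; every feature carries a
BFP/GFP/RFP channel tag (round-robin) so channel subsets are testable.
Per-well cell counts are negative-binomial (mean 200, size 10 — low enough
dispersion that most wells survive the 100-cell filter, enough that some do
not); dead and mis-segmented cells (5% each) are shifted ±3 in feature
space and labelled. A single master seed spawns independent per-stage
streams, so every artifact is bit-reproducible.

The **reference screen** used by the tests and `scripts/acceptance.py` has
60 compounds: 8 main MoAs of 5 compounds (6 coherent, 2 incoherent) plus 20
singleton-MoA compounds, of which 53% are active — the main-MoA members are
always active so the planted MoAs remain testable with ≥ 3 active members.
18% of compounds carry a second MoA descriptor, and 96 raw features give 193
well descriptors. These sizes keep a full run (including 1,000 permutation
iterations) near ten seconds on one CPU while preserving all the structure
the stages consume; they are the package's chosen desk-scale study
conditions, not tuning knobs.

**What the generator does not emulate:** optics and illumination artifacts,
spatial plate gradients (edge effects), cell-level phenotype heterogeneity
within a well beyond i.i.d. noise, classifier errors in the QC labels, and
feature distributions with heavy tails. Passing tests therefore demonstrate
that the procedures recover the structure they assume — not that real
screens satisfy those assumptions.

## Numerical conventions

Quantiles use linear interpolation between order statistics (numpy default)
everywhere a percentile threshold is defined. SDs use the n−1 denominator.
Correlations of zero-variance vectors are undefined: such features get
redundancy 0 (and relevance 0, so they rank last); such wells are excluded
from rankings with a warning. Greedy and sorting ties break by index or
identifier, never by hash order. Empirical p-values use the +1 correction.

## Known limitations

- The permutation-null bias of the aggregated AUC described above.
- Euclidean-active calibration holds for *control* wells by construction;
  the false-positive rate of the full two-criterion call on real screens
  depends on the reproducibility null being representative.
- `choose_k` inherits the Monte-Carlo noise of the replicate AUC; with few
  treatments the chosen k can vary by a few features across seeds.
- The expression-mixture fit assumes two reasonably separated modes; on
  unimodal inputs EM converges to an arbitrary split and the threshold is
  not meaningful.
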