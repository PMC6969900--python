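# Methods

## Model and assumptions

The pipeline treats a repositioning experiment as a set of case/control
expression studies ("layers") measured on a shared gene universe: a
drug-action layer (treated vs baseline/placebo, optionally stratified into
responder / non-responder / dose subgroups), the drug's approved target
disease (disease vs healthy), and one or more candidate repositioning
diseases. The core assumptions are (i) a disease dysregulates functional
gene modules relative to its healthy reference; (ii) an effective drug
compensates that dysregulation; (iii) a second disease sharing the
pathomechanism dysregulates largely the same modules, so the drug is a
candidate for it as well. The unit of evidence is therefore not a gene but
a *spot* — a connected cluster of co-expressed metagenes — and the decision
rule is the existence of a spot regulated antagonistically between a
disease contrast and the drug contrast.

Input matrices are taken as already normalized log2 intensities (RMA-like);
the package performs no background correction, probe summarization, or gene
identifier mapping. Genes present in only some layers are dropped to the
shared intersection before training (counts logged).

## Preprocessing

Fixed order: per-layer quantile normalization → global per-gene centering →
layer harmonization → re-centering.

* Quantile normalization equalizes each layer's sample distributions; ties
  receive the mean of the tied ranks' reference values, so the result is
  order-independent.
* Centering subtracts each gene's mean over *all* samples of *all* layers,
  giving the Δe scale used by portraits, spot profiles, and GSZ.
* Harmonization rescales each layer by one scalar so the layer's mean
  per-gene SD equals the across-layer median of those means, then
  re-centers. This keeps any single layer from dominating the Euclidean
  distances that drive SOM training and is idempotent. The statistic (mean
  per-gene SD, median target) is this package's concrete choice for a step
  that is usually described only as "harmonization".
* All quantiles/percentiles use linear interpolation between order
  statistics (the "type 7" convention), everywhere.

## Joint SOM training

Genes are objects; their Δe profile across all samples (all layers
concatenated) is the feature vector. Training is batch Kohonen on a K×K
grid (default 45×45; tests and the synthetic studies use 20×20 — ~5 genes
per unit at 2,000 genes, matching the production ratio of ~10 genes/unit at
~20k genes):

* **Initialization:** prototypes laid out on the plane spanned by the first
  two principal components of the gene cloud (±2 SD per component). With
  batch updates this makes training fully deterministic — the seed is kept
  in the model for provenance but no step draws random numbers.
* **Schedule:** rough phase, neighborhood radius max(K)/2 → 3 over 20
  epochs; fine phase, 3 → 0.5 over 30 epochs. Gaussian neighborhood
  h = exp(−d²/2σ²) truncated at grid distance d > σ, so the last fine
  epochs reduce exactly to Lloyd (k-means) iterations — this is what makes
  the two-separated-clusters limit recover the 2-means solution, and the
  quantization error (mean squared distance of genes to their
  best-matching unit, logged per epoch) monotone late in training.
* Empty units keep their last prototype; they carry interpolated expression
  and may join spots. The population map exposes them.

A *portrait* is one sample's K×K image of prototype entries; a group
portrait is the mean over member samples. Support maps summarize the grid:
population (genes/unit), variance (prototype variance across samples), and
overexpression frequency (how often a unit falls inside a spot mask).

## Spot segmentation and calling

A unit is overexpressed in a portrait when its value strictly exceeds the
portrait's own 95th-percentile (configurable). Masks are computed per
(layer × group × subgroup) group portrait; their union is segmented into
8-connected components (4-connectivity available), labelled A, B, …
row-major by centroid.

Spot profiles — the per-sample expression of a spot — are the mean Δe of
the spot's *member genes* from the joint matrix. The alternative (mean of
the spot units' prototype entries) is available via
`PipelineConfig(profile_source="prototypes")` but is biased toward zero:
empty units and sparsely populated border units enter the unit average with
full weight, which measurably shrinks spot fold changes by 25–45% on
synthetic studies and costs real calls at the fold-change gate. Gene-based
profiles weight each metagene by the genes it actually holds.

Two callers per spot × contrast:

* **Presence/absence:** with σ the SD of all spot-unit prototype entries
  across the layer's samples, vote up/down when the target−reference
  difference of mean spot expression exceeds ±`sd_multiplier`·σ (default
  1). The criterion thresholds the *difference* between the two states;
  σ = 0 yields vote none with a warning.
* **t-test:** Welch's t (pooled-variance variant behind `welch=False`) on
  per-sample spot means; vote requires p < α (default 0.05, raw — no
  correction across spots, though BH-adjusted p values are reported
  alongside) *and* a two-sided linear fold-change gate
  2^(Δ mean) > 1.5 or < 1/1.5. `fc_threshold=None` disables the gate.

The joint direction is the conservative AND (votes must agree; `vote="any"`
fires when exactly one caller fires). The perturbation matrix collects all
calls; the verdict for a (drug contrast, disease contrast) pair is
*candidate* iff some spot has directions {up, down} across the pair.
Disease-dysregulated spots with no drug response are reported as
"unopposed" — candidate adverse-effect or non-response markers.

Contrasts are enumerated from the sample sheet (disease layers: target vs
reference; treatment layers: each target subgroup vs each reference
subgroup plus target-subgroup pairs) or declared explicitly in the run
config, since contrast choice is a study-design decision.

## Enrichment, GSZ, PSF

* **Spot annotation:** right-tailed Fisher exact test = hypergeometric tail
  P(X ≥ overlap) on the in-spot/in-set 2×2 table, universe = the shared
  gene set of the run; BH FDR across the queried sets within each spot.
* **GSZ:** z = √n_S · (mean Δe over set genes − mean over all genes) / SD
  over all genes, per sample. This is the simplified standardized-mean
  form (tagged `gsz-simplified` in outputs); variants with hypergeometric
  variance corrections exist but are not reproduced here. On null data the
  score is approximately standard normal for sets of ≥ 20 genes.
* **PSF:** input nodes start at their linear fold change; node j with
  parents i has S_j = fc_j · Π contribution(i), where an activating edge
  contributes S_i and an inhibiting edge 1/S_i. Product aggregation is the
  minimal consistent extension of the pairwise multiply/reduce rule
  (`aggregation="mean"` available); inhibition-as-division quantifies
  "reduces the signal" reciprocally so a sign flip maps a contribution to
  its exact reciprocal. Cycles are iterated from the fold-change
  initialization with damped (geometric, factor 0.5) updates — undamped
  sweeps oscillate on negative feedback loops — until the max |Δ log S| <
  1e-6 or 100 sweeps (then the last state is reported with a warning).

## Synthetic studies

The generator emulates the multi-layer design: per-gene baselines drawn
once from Normal(7, 1.5) log2 units (RMA-like intensity range), i.i.d.
Gaussian noise with SD 0.5, and planted co-regulated modules. A module's
genes share a per-sample latent factor with loading 0.8 in the standardized
sense: the residual is noise_sd·(0.8·f + √(1−0.8²)·ε), so the marginal
noise SD stays at the stated level while module genes correlate at 0.64 —
without this shared factor the genes would not co-cluster into a spot, only
shift in mean. Directional effects (default 1.0 log2) are added to the
target samples ("up") or reference samples ("down" — a treatment layer's
diseased baseline is elevated and the drug returns it toward normal). The
canonical scenario has 2,000 genes, one 100-gene module, n=10 per group,
four layers (drug + two affected diseases + one null disease).

What the generator does *not* emulate: platform-specific probe effects,
batch structure within a layer, non-Gaussian heavy tails, correlated
background modules, or realistic pathway-level covariance. Passing tests
therefore demonstrate the machinery's correctness and its operating
characteristics under clean conditions, not performance on real microarray
data.

## Measured operating characteristics

Computed by `scripts/acceptance.py` and the test suite (100 replicate
studies, grid 20×20, default calling):

* Null calibration: the t-vote fires at ~6% of 500 independent null
  contrasts at α = 0.05 (fc gate off); the presence/absence vote is far
  more conservative on null data, and the AND vote never exceeds either
  component by construction.
* A planted 1-log2-unit module lands in a single connected spot in
  essentially every replicate, and is called in the correct direction in
  ~93% of replicates.
* The full repositioning pattern (candidate, candidate, not_supported)
  reproduces in ~59% of replicates.

The gap to perfection is a detection-boundary effect, not noise in the
machinery: the shared latent factor makes each layer's *realized* module
effect fluctuate around 1.0 with SD ≈ 0.18, and spot profiles carry a
further ~10% dilution from background genes that the union-of-masks
segmentation merges into the spot. The fold-change gate needs
2^Δ > 1.5, i.e. Δ > 0.585 — roughly two latent-factor SDs below the mean
realized effect — so each of the three required layer calls succeeds with
probability ~0.8–0.95 and the three-way conjunction correspondingly less
often. Planted effects of ≥ 1.5 log2 units, larger groups, or the `any`
vote move the chain well above 95%; at effect 1.0 and n=10 the default
conservative rules sit deliberately at the boundary between sensitivity
and the strict false-positive control shown by the null calibration.

## Numerical and degenerate-input choices

* Type-7 quantiles everywhere; strict inequality at the overexpression
  threshold (a constant portrait yields an empty mask).
* Welch p = NaN (both groups constant and equal) is treated as p = 1.
* Fewer than 2 samples per side: t-vote none with a warning.
* A layer with zero total variance fails harmonization loudly.
* Spots made entirely of empty units fall back to prototype-entry profiles.
* An empty overexpression union is a valid result: zero spots, all
  verdicts not_supported.
* Floating-point round trips: all TSV writers serialize with round-trip
  repr and all readers parse with `float_precision="round_trip"`, so
  staged CLI runs are byte-identical to single `run` invocations.

## Known limitations

* The presence/absence σ conflates within-group noise with between-group
  separation; at ±1 SD this makes the caller conservative for moderate
  effects (it is the difference criterion that keeps it usable at effect
  ~1 log2).
* Joint SOM training assumes the layers share a gene universe and a
  roughly comparable correlation structure; a layer from a very different
  tissue can claim disproportionate map area even after harmonization.
* PSF semantics (product aggregation, reciprocal inhibition, damped cyclic
  iteration) are one consistent reading of signed-topology propagation;
  rule-based (AND/OR gate) pathway logics are out of scope.
* Verdicts are qualitative (candidate / not_supported); no effect-size
  ranking across candidate diseases is attempted.
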