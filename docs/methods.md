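# Methods

`hipptox` implements a high-content phenotypic-profiling analysis for
predicting chemical pulmonotoxicity from imaging-derived features of
cultured human lung cells. The pipeline takes per-well median feature
values measured across a concentration series, summarises each
(chemical, feature) pair by a fitted maximum response (Δmax), and feeds
the resulting Δmax matrix into a cascade classifier whose performance is
estimated by stratified cross-validation. Plate-level QC statistics
(autofluorescence FBR, viability CoV rejection) and effect-size
statistics (log2-ratio t-tests with BH correction, comet-assay
aggregation) round out the analysis.

## Concentration–response model

For a chemical at concentration *x* (µM) the control-normalised
response is

    Δ(x) = log2( r̃(x) / r̃(0) )

where r̃(x) is the median of the feature over all wells treated at *x*
(replicates pooled before the median) and r̃(0) the median over the
chemical's solvent-control wells. Cell count and viability are kept as
untransformed fractions Δ(x) = r̃(x)/r̃(0), because their natural scale
is "fraction of control cells surviving".

Three candidate models are fit to the 7 points (one per tested
concentration) by least squares:

* **up-sigmoid** Δ(x) = α − α / (1 + exp(β(log x − log γ))), plateau
  α ≥ 0 — a log-logistic curve rising from 0 to α;
* **down-sigmoid** Δ(x) = α′ / (1 + exp(−β′(log x − log γ′))), plateau
  α′ ≤ 0 — the mirrored falling curve. For fraction features (where the
  up model is not offered) this becomes a decay from plateau α′ ≥ 0
  toward 0, i.e. a kill curve;
* **null** Δ(x) = 0 for log-ratio features, replaced by the **constant**
  model Δ(x) = α″ for fraction features.

The two sigmoids are the same three-parameter family algebraically; the
sign constraint on the plateau is what distinguishes "up" from "down"
and makes model kind meaningful. Logs are natural; the log-logistic
family is scale-covariant in γ, so the base only reparameterises β.

**Fitting.** Parameters are optimised as (plateau, β, log γ): the log-γ
parameterisation keeps the problem conditioned when the inflection point
falls outside the tested range. Because the model is linear in the
plateau for fixed (β, γ), a deterministic 6 × 12 grid over
(β, log γ) with the analytic plateau provides starting points; the two
best grid points are refined with bounded trust-region least squares
using the analytic Jacobian. Bounds: β ∈ (0, 50],
γ ∈ [min dose / 20, max dose × 20], plateau bounded away from absurd
magnitudes (|plateau| ≤ 5·max|Δ| + 10). Fits that exhaust their
iteration budget while still improving materially (flat-valley curves
heading to near-zero residual) receive extra rounds; fits polishing the
last fraction of a percent of a noisy residual do not. On noiseless
data the generating parameters are recovered to ~1e-6 relative.

**Model selection.** Models are compared by AIC with
D = number of fitted parameters (3 / 3 / 0 / 1):

    AIC = m · ln(rss / m) + 2D

with rss/m floored at 1e-300 so perfect fits stay finite. A printed
variant `2(D − ln(rss/m))` is retained behind `variant="as_printed"`
for audit; minimising it would reward *worse* fits, so it is never used
for selection. Ties — including numerical ties, where rss/m below 1e-24
counts as a perfect fit (a plateau-saturated sigmoid can reproduce a
constant to exactly zero residual while the constant's own mean leaves
~1e-32 of float noise) — resolve toward the model with fewer
parameters, then toward the null/constant model.

**Δmax.** The selected model is evaluated at 2000 µM, the highest
sampled concentration. Chemicals titrated only up to 1000 µM are
evaluated at 2000 µM by model extrapolation and flagged in the fit
report; whether to trust those cells is left to the analyst.

## Bioactivity, MAD filter, clustering

A feature counts as *changed* for a chemical when the fold change is at
least 30%: treated/control ratio ≥ 1.3 or ≤ 0.7, i.e. Δmax ≥ log2(1.3)
or ≤ log2(0.7) (each direction uses its own ratio bound; a symmetric
log-scale variant |Δmax| ≥ 0.3 is available behind `scale="log2"` for
sensitivity analysis). Fraction features use |Δmax − 1| ≥ 0.3. A
chemical is *bioactive* when at least 5% of the measured features
changed; the denominator is the full panel (phenotypic features plus
cell count), and NC chemicals are excluded from the assessment set.

Feature filtering before clustering uses the unscaled median absolute
deviation across chemicals (no 1.4826 consistency constant) with the
conventional 0.05 cut on the raw Δ scale. Clustering is Ward linkage on
Euclidean distances (scipy's implementation); items are presented in
sorted-id order so ties break deterministically and the dendrogram is
invariant to input ordering.

## Cascade classifier and evaluation protocol

The cascade applies two rules in order:

1. **NC rule.** A chemical with relative cell count below 30% of the
   solvent control at *every* tested concentration ≥ 125 µM ("no cell")
   is called positive outright — massive early cell loss is treated as
   sufficient evidence of toxicity.
2. **Maximum-margin rule.** Remaining chemicals are classified by a
   linear SVM on the selected feature(s). Each feature is linearly
   mapped so the training minimum/maximum land on [−1, 1] (test values
   are not clamped; a constant training feature maps everything to 0).
   The cost C is chosen from {10⁰ … 10⁵} by an inner stratified 5-fold
   cross-validation on the training chemicals, scoring pooled balanced
   accuracy, ties to the smallest C; the winner is refit on all non-NC
   training chemicals. The margin machine is liblinear
   (`sklearn.svm.LinearSVC`) with an L2-regularised bias term
   (bias-as-augmented-feature semantics), which is deterministic. A
   decision value of exactly 0 is called positive: at the boundary a
   toxicity screen should favour sensitivity.

Performance is estimated by stratified tenfold cross-validation:
chemicals are shuffled within class by the seed and dealt round-robin to
folds. NC chemicals participate as unconditional positive predictions in
whatever fold they land in and never enter margin training, so the
cascade's overall operating characteristics — not just the SVM's — are
what cross-validation measures. Sensitivity is TP/(TP+FN) over the
pulmonotoxic class, specificity TN/(TN+FP) over the non-pulmonotoxic
class, balanced accuracy their mean. Scalers and C are functions of
training folds only; corrupting a held-out value cannot change the
trained models. An optional `repeats` argument averages the three
metrics over independent fold partitions, since a single 13/20-chemical
partition makes the metrics coarse-grained. Multi-feature selection uses
recursive feature elimination: refit, drop the feature with the smallest
absolute weight, record the cross-validated score per nested set.

## QC procedures

**Autofluorescence.** FBR = log2(P99.9 of foreground pixels / median of
background pixels), reported per chemical × channel as the median over
replicate images. The acceptance threshold is one third of the
positive-control FBR for the channel; a value exactly at the threshold
passes ("maximally acceptable"). Segmentation into
foreground/background is upstream of this package; the statistic
consumes pixel-value pools.

**Viability plates.** The mean of the no-cell control wells is
subtracted from every well. Per control or treated group, if the CoV
(sample SD over mean, in %) exceeds 30%, the well whose removal most
reduces the CoV is dropped, at most twice — a greedy deterministic
reading of "discard the wells contributing most to the CoV". A treated
group may keep CoV > 30% when its median is below 20% of the control
median (cell-death responses are heterogeneous). A chemical with fewer
than six passing concentrations (at most one failure tolerated) is
flagged `repeat_required`.

## Statistics

Treatment effects are tested on the log2 scale: the log2-ratio of group
means equals the difference of log2-transformed means, so a standard
two-sample t-test (pooled variance; Welch behind a flag) on
log2-transformed values tests Δ = 0 and yields the 95% CI of the log2
fold change. Families of p-values passed in one call are adjusted with
Benjamini–Hochberg step-up (via `statsmodels`; an independently coded
step-up serves as the oracle in the tests). Comet-assay conditions are
summarised as the mean of per-replicate median % tail DNA; replicate
exclusions are an explicit input list, never automatic. % tail DNA is
floored at 0.1% before the log transform — values at zero are below the
assay's quantitation limit and would otherwise dominate the log-scale
variance. Significance tiers: *** adjusted p ≤ 0.01, ** ≤ 0.05,
* ≤ 0.10.

## Synthetic-data generator

`simulate_study` reproduces the study design: 7 two-fold dilutions
(2000 → 31.3 µM; optionally 1000 → 15.7 µM for designated chemicals), 4
technical replicates, solvent controls per chemical, 13 pulmonotoxic /
20 non-pulmonotoxic / 17 unannotated test chemicals, ~2500 cells per
control well. Per (chemical, feature) a ground-truth model is drawn —
60% null, the rest up/down sigmoids with plateau magnitude 0.4–1.5 log2
units, slope 1–5, inflection log-uniform inside the tested range — and
well values are generated as baseline · 2^(Δ_model(x) + ε) with
ε ~ Normal(0, noise_sd = 0.15 log2 units by default). One planted
feature carries the class signal: an up-sigmoid with plateau 1.5 for
pulmonotoxic (and every other test) chemical versus 0.1 for
non-pulmonotoxic, β = 2, γ = 250 µM. NC chemicals get a steep kill
curve (γ = 30 µM, β = 6) keeping relative counts far below 30% at every
dose ≥ 125 µM. Cell counts are Poisson around the model-implied mean
when noise is on; with `noise_sd = 0` the generator emits exact model
means so noiseless recovery checks are exact. Each (chemical, feature)
consumes its own hash-derived RNG substream, so adding a chemical never
perturbs another's draws.

What the generator does **not** emulate: correlated features, plate
spatial effects (edge wells, drift), heteroscedastic noise across the
dose range, feature-specific response directions tied to biology, or a
realistic prevalence of non-bioactive chemicals (most simulated
chemicals perturb at least one feature, so the synthetic bioactive
fraction is near 100%). Passing tests therefore demonstrate the
correctness of the computations under the declared statistical
structure, not performance on real imaging data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: the synthetic
studies use 6–12 features × 33–50 chemicals (a few hundred fitted
dose–response curves per run) rather than the full 166-feature panel,
and the permutation null uses 50–100 label permutations. The fitted
pipeline is identical at any panel width; the sizes were chosen so a
complete run finishes in minutes on one core. Other numerical
conventions: concentrations are matched to the nominal dilution series
with 1% tolerance (31.3 vs 31.25 µM both occur in practice); chemical
and feature identifiers are NFC-normalised with typographic primes and
dashes mapped to ASCII at import; CSV floats are written with the
shortest lossless representation so read∘write is the identity.

## Known limitations

* The up/down sigmoid split is a convention over one algebraic family;
  data equally consistent with both (e.g. a flat curve at the plateau)
  resolve by the fewer-parameters tie-break, not by biology.
* Δmax extrapolation to 2000 µM for chemicals titrated to 1000 µM
  trusts the fitted curve one dilution beyond the data.
* The greedy CoV well-drop is one deterministic reading of an
  under-specified procedure; other drop orders could retain different
  wells in pathological groups.
* With 13/20 training chemicals, single-partition cross-validation
  metrics move in steps of ~7.7%/5% per flipped chemical; use
  `repeats` for stabler estimates.
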