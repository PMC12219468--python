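# Methods

This note documents the generative model behind the synthetic worlds, the
estimation choices in the analysis pipeline, and the limitations we know
about — including places where the method itself (not the implementation)
behaves imperfectly at desk scale.

## The simulated world

Stimuli are abstract rows shared by every generated object; `n_stim_fit`
rows form the fit split (basis estimation only) and `n_stim_eval` rows the
evaluation split (all metrics), split deterministically by index.

**Latents.** All latent matrices have iid standard-normal entries:

- `Z_shared` (stimuli × `n_universal`): dimensions available to *every*
  network — the planted "universal" structure;
- `Z_idio[i]` (stimuli × `n_idio`): private to network *i*;
- `Z_brain`: the latents the simulated brain mixes.  Policy `all` copies
  `Z_shared`, `subset:k` its first *k* columns, and `disjoint` draws fresh
  independent latents (the null world, obtainable via `make_null_world`).

**Networks.** Layer *l* of network *i* is the linear readout
`[Z_shared | Z_idio[i]] · W[i,l] + ε`, with `W` standard normal scaled by
`universal_scale` (default 1.0) on the shared block and `idio_scale`
(default 0.3) on the private block, and `ε ~ N(0, noise_sd²)` (default 0.1).
The scale ordering makes shared structure dominate the top of each layer's
variance spectrum, which is the regime the analysis presumes; real networks'
idiosyncratic/universal variance spectra are not characterized anywhere we
can borrow from, so these scales are a modeling convenience (set once in the
config, not tuned).  An optional rectification `max(0, ·)` (off by default)
produces ReLU-distorted activations for probing nonlinear regimes; layers may
carry a spatial axis (`n_spatial`), but the default of 1 keeps the pooled
activations an exact linear image of the latents so that generator-side
ground truth (per-direction shared-variance fractions) stays exact.

**Subjects.** Voxel responses are `Z_brain · B[s] + noise`, then each voxel
is z-scored across stimuli — the analog of session-standardized response
amplitudes.  Subjects share latents and differ in mixing and noise
(`brain_noise_sd`, default 0.3).

Every random draw comes from a `SeedSequence` spawned from the config seed
and a component key, so identical configurations reproduce all matrices
bit-identically.

**What a green test on this world does and does not establish.**  The
simulator produces Gaussian, linear(-izable), stationary data with additive
noise.  Passing tests establish that the pipeline recovers planted shared
structure, stays null when nothing is shared, and is internally consistent —
not that real networks' universal dimensions have these statistics.  In
particular the simulator has no nonlinear feature reuse, no heavy-tailed
activations, no voxel correlation structure beyond the shared latents, and no
stimulus-level dependence.

## Dimension extraction

Global max pooling removes the spatial axis.  PCA is fit on the pooled
fit-split activations, centered on fit-split channel means ("no peeking":
those means are the only statistic carried to the evaluation split; PCA
without centering would conflate mean with variance).  All components up to
the numerical matrix rank are retained, with the conventional tolerance
`max(n, p) · eps · s_max`; channels are not variance-standardized first.
PC ranks are 1-based variance-order indices.  PC scores are not standardized
before regression — Pearson-r scoring is scale-invariant, so it would change
nothing.

## Cross-validated mapping

The prediction backbone is ridge regression with an unpenalized intercept
(handled by centering on training means), evaluated in a nested design: five
outer folds (random near-equal assignment with a recorded seed, to avoid
stimulus-order artifacts), and, within each outer training set, leave-one-out
selection of the penalty from {0} ∪ {10⁻³, 10⁻², …, 10⁴} — the smallest grid
with those endpoints and equal logarithmic spacing.

LOO residuals use the hat-matrix identity `e_loo = e / (1 − h)` computed from
one SVD of the centered training matrix, which equals explicit refitting to
floating-point precision.  When λ = 0 and the centered predictors exactly
interpolate the training rows (more columns than rows), the identity's
analytic λ→0 limit — the kernel form `e_loo,i = [K⁺y]ᵢ / [K⁺]ᵢᵢ` on the
centered Gram matrix — is used instead, again equal to the minimum-norm
refit.  λ = 0 always means least squares, minimum-norm under rank deficiency.

The inner selection criterion maximizes the LOO Pearson correlation, matching
the outer evaluation metric; minimizing LOO MSE is available as a switch.
The choice matters: the Pearson criterion is scale-blind and does *not*
systematically prefer shrinkage on pure-noise targets (a 100-seed simulation
gives λ* > 0 only ~27% of the time at 12×20), whereas the MSE criterion does
(~87%).  For the scoring use-case the distinction is immaterial because
performance is itself measured by Pearson r.

Degenerate cases score 0, never NaN: zero-variance predictions or targets
contribute r = 0 to fold averages, and a zero-variance target selects the
smallest grid penalty with a warning.

Two alternative mappings mirror the robustness analyses: cross-validated OLS
(λ fixed at 0, no inner loop) and one-to-one matching (per fold, the
predictor column with the highest signed training Pearson correlation; its
test-fold correlation is the score; constant training columns are excluded).

A `FoldedRidgeDesign` caches the per-fold SVDs of a predictor matrix so that
many targets — in particular the thousands of rescorings a permutation test
needs — cost only matrix products.

## Metrics and inference

Universality is the **median** over predictor networks (robust to a few
extreme predictors); brain similarity the **mean** over subjects.  The
permutation test shuffles evaluation-stimulus labels *before* recomputing
universality, one shared permutation per target network per iteration so the
dependence among a network's dimensions is preserved, and compares the
observed Spearman against the null with the add-one convention
`p = (1 + #{ρ_null ≥ ρ_obs}) / (n_perm + 1)`, one-sided for a positive
association (the directional claim under test).  The desk-scale default is
199 permutations with a config override.

Between-subject reliability of a dimension is the mean pairwise Pearson
correlation of the subjects' cross-validated predicted series, clamped to
[0, 1] — a prediction-consistency definition chosen because it upper-bounds
attainable brain similarity; adjusted brain similarity divides by
√reliability (the attenuation-correction convention; plain division is a
switch), and records at or below a reliability floor (default 0.1) are
excluded rather than divided by a noisy small number.  Quantile summaries
bin dimensions by universality in groups of exactly 100, dropping a partial
final bin so all bins are equally sized.

Partial Spearman midrank-transforms all three variables, residualizes the
ranked pair on the ranked control by least squares, and correlates residuals
— equivalent to the classical closed form on rank correlations.

## RSA with universal-subspace reduction

Evaluation stimuli are split into random disjoint halves (odd counts put the
extra stimulus in train).  RDMs use Pearson correlation distances; rows with
zero variance get distance 1 (chance) with a warning.  RDM similarity is the
Spearman correlation over strictly-lower-triangle entries.  Per network, the
layer with the best subject-averaged train-half similarity is selected (ties
to the shallower layer, deterministically), and the reported similarity comes
from the held-out half.  The reduction keeps the k most universal dimensions
*within the selected layer* (k clamped to the layer rank with a warning);
ranking the top-k across all of a network's layers is a defensible
alternative — RDMs are computed per layer, which is why layer-local is the
default.  Subject averaging happens after the per-subject Spearman.

## Pipeline

`run_all` persists every stage (activations and brain data as HDF5, the score
table as CSV with a JSON config sidecar, inference/RSA/summary as JSON) and
records a config hash per stage in a manifest, so a rerun recomputes only
missing artifacts — deleting the report reassembles it without re-running any
mapping.  All component seeds derive from the global seed through SHA-256 of
`"<seed>:<label>"`, keeping runs bit-reproducible and components decoupled.

## Known limitations

- **Unregularized OLS near the interpolation threshold.**  With layers
  concatenated, the default world gives 180 predictor columns against 160
  training rows per outer fold — almost exactly the n ≈ p peak where
  minimum-norm OLS has maximal variance.  OLS universality scores are
  therefore noise-dominated for dimensions without strong shared signal, and
  their per-dimension rank agreement with ridge is only moderate (~0.5) at
  this scale, even though all mappings agree on which dimensions are strongly
  universal.  At production scale (thousands of channels versus hundreds of
  training rows) ridgeless interpolation is far from the peak and behaves
  benignly.
- **The permutation test is slightly anti-conservative under the null.**
  Shuffling stimulus labels destroys not only any universality–brain coupling
  but also row-alignment effects — fold difficulty, sample outliers in a
  dimension's evaluation series — that are *common* to the two metrics,
  because both predict the same target series over the same evaluation rows.
  Under a fully null world the observed Spearman is therefore slightly
  positive on average (~+0.1 at a reduced scale of 36 dimensions), and
  repeated end-to-end p-values skew small rather than uniform.  Using
  independent fold plans for the two metrics shrinks but does not remove the
  effect.  Conclusions should rest on effect sizes well above this bias, as
  the aligned-world ρ ≈ 0.58 comfortably is.
- **Tail behavior of null universality.**  The nested-CV score of a truly
  unshared dimension has null spread ~0.10 (SD) with wide concatenated
  predictors and 200 evaluation stimuli, and PCA noise eigendirections leak a
  small fraction (≲2%) of shared variance at a 600-stimulus fit set.  Among
  ~1,000 such dimensions the extreme tail of universality reaches ~0.25–0.30.
  Universality near zero is therefore meaningful in aggregate, but individual
  scores below ~0.3 should not be read as evidence that a dimension carries
  any shared structure.
- Reliability uses a prediction-consistency definition; other noise-ceiling
  conventions exist and would scale the adjusted scores differently.
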