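# Methods

`vqnorm` implements a normative model of structural gray-matter maps
built from two learned components: a vector-quantized autoencoder that
compresses a 3-D density volume into a grid of discrete codebook indices,
and a causal (autoregressive) transformer trained on the token sentences
of *typical* subjects only. At evaluation the transformer emits, for
every token position, the probability it assigned to the token actually
observed there — the *likelihood of typicality* of the corresponding
brain segment. Likelihoods are replicated back onto the voxel grid,
averaged within atlas regions and over the whole brain, and screened for
associations with dimensional symptom scores (Pearson r with Bonferroni
correction) and binary diagnoses (AUC with a permutation p-value).

## Model and assumptions

**Tokenizer.** The encoder maps each non-overlapping `factor`^3 voxel
patch (default 4^3) through a small MLP to a D-dimensional vector — a
strided convolution in all but name. Quantization snaps each vector to
the nearest codebook entry (Euclidean; ties to the lowest index, for
determinism). The decoder mirrors the encoder and clamps its output to be
non-negative, since gray-matter density maps are non-negative. Training
minimizes reconstruction MSE plus a commitment term (weight 0.25, the
conventional value in the VQ lineage), with straight-through gradients;
the codebook itself is maintained by exponential-moving-average cluster
updates (decay 0.95) with dead-code reseeding from current encoder
outputs. Models are plain NumPy with hand-written gradients and an Adam
optimizer; at the package's working scale (32^3 volumes, K=32 codes,
D=16) this trains in seconds on one CPU.

**Autoregressor.** The latent grid is serialized by a recorded raster
ordering (slowest-varying axis first, ascending; configurable and stored
in every checkpoint, since any fixed bijection works but it must be
reproducible). A learned start token is prepended; there is no
demographic conditioning. The model is a pre-norm transformer (token +
learned position embeddings, causal multi-head attention, GELU MLP)
trained by next-token cross-entropy with teacher forcing. Likelihood
scoring is a single teacher-forced forward pass; no sampling. The
reported likelihood is the raw probability (not log), and downstream
averaging uses raw probabilities.

**Input-token corruption.** During training, a fraction (default 10%) of
*input* tokens is replaced by uniform random codes; targets are
untouched. This is a deliberate robustness choice addressing exposure
bias: a model fit only on clean typical context otherwise assigns
degraded likelihoods to *every* position downstream of an anomalous
token, which smears an injected regional effect across the whole brain.
With corruption the model's predictions lean on position and robust
context, and likelihood drops localize at the anomalous positions
themselves. Set `input_corruption=0` to recover plain teacher forcing.

**Normative training set.** Following standard practice for normative
models, only "typical" subjects train both components: those at or below
the cohort's lower quartile (configurable) of the total symptom score,
ties kept (`<=`). Evaluation uses the held-out test split only, and the
train/evaluation subject intersection is asserted empty on every run.

## Scoring

Each token's likelihood fills its `factor`^3 voxel block
(nearest-neighbor replication, no interpolation), so the block mean of
the voxel map recovers the token likelihood exactly. The atlas is applied
at voxel resolution *after* upscaling; a token straddling two regions
contributes to each in proportion to voxel overlap. Region scores are
arithmetic means; the whole-brain score is the mean over all labelled
voxels, which equals the voxel-count-weighted mean of region scores when
regions partition the brain mask. Background blocks are excluded: they
are trivially predictable and would inflate typicality.

## Association battery

Numeric targets (symptom scales, age) use the sample Pearson correlation
with the two-sided t-transform p-value (n-2 df). Binary targets use AUC
with the orientation fixed so that AUC > 0.5 means atypicality is
detectable (cases are expected to have *lower* typicality); significance
comes from a label-permutation test with the add-one estimator
p = (1 + #{permuted AUC >= observed}) / (B + 1), B = 1,000 by default, so
p is never 0 and never below 1/(B+1). All raw p-values in one dataset
evaluation form a single Bonferroni family by default
(p_corr = min(1, m p) with m = #regions+1 times #targets); a per-target
family rule is available. This is the most conservative defensible
reading; the correction is implemented directly because the family size
may legitimately exceed the number of p-values in hand. A constant score
column (no variance) is recorded as a null result with a warning rather
than aborting the screen. No covariate adjustment is performed; age is
screened as a separate target, mirroring how structural normative studies
report aging as a potential confound.

## Synthetic cohorts

The phantom generator supplies everything the analysis consumes, with
the statistical structure the method assumes:

- **Atlas**: geodesic Voronoi parcellation of an ellipsoidal mask —
  regions grow from uniformly seeded cells at equal speed, so they are
  connected by construction and irregular. By default boundaries are
  drawn on a 4^3-voxel lattice aligned with the tokenizer factor
  (`atlas_block=4`), so each token belongs to exactly one region and an
  injected regional effect is exactly attributable in token space. Real
  parcellations do not align with any latent grid; with a non-aligned
  atlas (`block=1`) boundary tokens mix regional signals and localization
  degrades — a genuine property of the method, not of the phantom.
- **Phenotypes**: each symptom scale is an independent zero-inflated
  gamma (point mass at zero + gamma tail), matching the floor-heavy,
  right-skewed shape of caregiver-report scales. Defaults calibrate the
  total score to a general-population pediatric cohort (mean ~18,
  sd ~19, 30% exact zeros; ages uniform 8.9–10.9 y; 52% male).
  Scale independence is a simplification (real subscales correlate with
  the total); it buys exactly-null pairs for calibration tests.
  Diagnosis, when enabled, marks the top-`prevalence` fraction of a
  liability equal to the total score plus Gaussian noise (sd 10), so
  diagnosis co-occurs with elevated symptoms as in clinical cohorts and
  lower-quartile selection excludes most cases from training. Default
  prevalence 0.3 mirrors a high-risk pediatric cohort.
- **Volumes**: intensity = per-region baseline (uniform 0.3–0.8)
  + per-region age slope x (age − age0) (slopes ~ N(0, 0.005/yr))
  + injected effects + a *subject-invariant* smooth "anatomical texture"
  field (sd 0.08, FWHM 6 mm) + spatially smoothed Gaussian noise
  (sd 0.02, FWHM 4 mm, brain-masked), clipped to be non-negative.
  The texture emulates the stable anatomical structure real maps share
  across subjects and gives every patch a distinctive signature, so code
  assignment rests on anatomy rather than on a knife-edge scalar
  intensity. Only the *noise* is smoothed; the deterministic signal is
  piecewise-defined per region. This keeps two identities exact and
  testable: the pre-noise mean intensity difference per unit score inside
  affected regions equals gamma, and group differences vanish identically
  outside affected regions. Smoothing the signal would trade those exact
  identities for boundary blur without changing what the tests can show.
- **Effects**: additive intensity shifts per unit of a named scale, or
  per diagnosis, in a chosen region set. An optional per-site additive
  offset (off by default) stands in for scanner effects without modeling
  the physics.

**What the phantom does not emulate**: acquisition physics, registration
error, bias fields, within-region anatomical variability across subjects,
correlated symptom scales, and comorbidity structure. Passing tests on
phantoms therefore demonstrates the pipeline's internal correctness and
its sensitivity/specificity under the stated generative model — not
performance on real VBM data.

## Reference experiments and the detectability window

The packaged experiments (`vqnorm.experiments`) use a 240-subject cohort
on a 32^3 grid with 10 regions (latent 8^3 = 512 tokens), split
50/20/30 into train/validation/test; the typical lower quartile of the
train split (~30 subjects) trains both models (tokenizer 30 epochs,
transformer 12 epochs — enough for the per-position code distributions
to sharpen while keeping a full run around a minute on one CPU).
Atypicality is injected as a density *reduction* — the usual direction of
structural gray-matter findings — of 0.012 units per point of the total
score (so a subject 1 sd above the mean loses ~0.23, one to three
codebook cluster spacings: a moderate, clearly detectable effect), or a
flat 0.35 for diagnosis, in the two regions with the *highest* baseline
density.

High-baseline regions are chosen because of a structural property of VQ
normative models worth stating plainly: the codebook is fitted to typical
data, so intensity excursions *beyond* the typical range collapse into
the nearest extreme code and become invisible — only shifts that cross
into other clusters' territory flip tokens. A downward shift from a
high-baseline region traverses the full span of typical clusters and is
detectable at any moderate magnitude; an upward shift from the same
region, or a large downward shift from the lowest-baseline region,
saturates. The detectability window is the intensity range spanned by
the learned codebook.

## Numerical choices

- Quantizer ties break to the lowest code index; serialization ordering
  is recorded in checkpoints; all stochastic stages take explicit seeds
  and are reproducible to the byte on one platform.
- Transformer attention masks use -inf logits, so masked positions carry
  exactly zero weight and past likelihoods are bit-identical under any
  change of future tokens.
- Training raises on non-finite loss, naming the epoch; sequences longer
  than the model context raise rather than truncate.
- Permutation p-values use the add-one estimator; Bonferroni caps at 1.
- Empty atlas regions are reported as absent (with a warning), never as
  zero scores.

## Known limitations

- The NumPy models are toy-scale by design; full-resolution geometry
  (24x28x24 latents, 16,128-token contexts) is supported by the
  serialization and scoring layers but not practical to train here.
- Raw-probability averaging weights every token equally; a
  likelihood-ratio variant is out of scope.
- With `atlas_block=1` (non-aligned boundaries) regional attribution is
  diluted by boundary tokens; quantitative localization claims hold for
  the aligned phantom only.
- Single-site defaults: the site-effect knob exists but no harmonization
  is provided.
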