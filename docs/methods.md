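# Methods

This note documents the models implemented by `gaze-priority`, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical decisions taken where the constructions were
genuinely open.

## Detection preprocessing

Proposals are axis-aligned boxes `[x, y, w, h]` under a 0-based, half-open
pixel convention (`[x, x+w) × [y, y+h)`, origin top-left); IoU is computed
under the same convention, so on integer boxes it equals the ratio of
overlapping to covered pixel counts. The pipeline is confidence filtering
(`Th_conf`, default 0.02: a proposal survives iff its best category score
reaches the threshold, and sub-threshold category entries within survivors
are pruned) followed by greedy non-maximum suppression (`Th_NMS`, default
0.30). NMS is class-agnostic by default — the goal is one surviving box
per physical object, not per category — with a per-class mode behind a
flag. Suppression uses strict inequality (`IoU > Th_NMS` suppresses; a box
at exactly the threshold is kept), and score ties are broken by input
order, so the reduction is deterministic without any seed. Boxes are
clipped to image bounds on read; proposals entirely outside the image are
dropped with a warning. The competing-category count `f_b` is the number
of score entries `≥ Th_conf` in a surviving proposal; counting after the
within-box pruning is the convention adopted throughout (the alternative —
counting sub-threshold entries toward `f_b` — is rejected because the
threshold is precisely what defines "competing").

## Priority maps

**Recognition uncertainty (UC).** Each surviving proposal contributes an
isotropic Gaussian centered at its box center (pixel-center coordinates,
so center = `(x + w/2 − 0.5, y + h/2 − 0.5)`), scaled by `f_b / max_B f_b`,
summed over proposals. Two constructions were open:

- *Per-proposal σ.* Defined here as one quarter of the box height
  (`σ = h_b/4`), consistent with the target-map construction below; a
  global fixed σ is available via `sigma_rule`.
- *Gaussian normalization.* Per-box Gaussians are peak-normalized
  (amplitude 1 before weighting) rather than mass-normalized, so the
  weight `f_b / max f_b` is directly the peak priority of the box; the
  box with the maximal competing count peaks at exactly 1 before any
  overlap. Mass normalization would instead privilege small boxes; the
  choice is configurable at the `gaussian_blob` level.

Gaussians are evaluated over the full image; mass falling outside the
borders is simply lost (no renormalization). Images with no surviving
proposal yield an all-zero map with a logged warning so batch evaluation
proceeds.

The information-theoretic reading: `P_unique(b) = 1 − f_b / Σ f` and
`SI_unique = −log10 P_unique`. Base 10 is fixed by the worked
four-box example (counts 3, 2, 1, 4 → probabilities 0.70/0.80/0.90/0.60 →
self-information 0.155/0.097/0.046/0.222, which print as
0.154/0.096/0.045/0.221 when truncated to three decimals).

**Label entropy (UC_E).** The per-box weight is the Shannon entropy of
the above-threshold confidences. Raw detector scores need not sum to 1,
so they are renormalized to a distribution before `−Σ w log10 w`
(configurable); log base 10 matches the self-information convention, and
makes `k` uniform categories give weight `log10 k` exactly. A single
above-threshold category gives weight 0 — the box is certain.

**Pixel-wise uncertainty (UC_P).** Applied to confidence-filtered
proposals *without* NMS, since counting overlapping proposals per pixel is
the point of the variant. A pixel `j` is inside `[x, x+w)` iff
`x ≤ j < x+w`. The count raster is smoothed with a truncated Gaussian
kernel whose window is one quarter of the image height (forced odd for a
well-defined center), σ = window/4, normalized to unit sum, applied with
zero padding.

**Center bias (CB).** Isotropic Gaussian at the image center
`((w−1)/2, (h−1)/2)` with the one-dimensional normal amplitude
`1/(σ_c√(2π))` retained as written even though min-max normalization later
cancels it. `σ_c` defaults to one third of the image height (a broad,
task-independent bias); no canonical value exists, so it is configurable.

**Target maps.** The per-box bump is a Gaussian with σ = `h_im/4` built
on an `h_im × h_im` square and bilinearly resampled to the box's pixel
footprint (half-pixel-center convention, edges clamped), so its
anisotropy follows the box aspect ratio; bumps are placed at the box
position with border clipping and summed. Target-present maps use only
boxes whose target-category confidence exceeds 0.9 (usually exactly the
true target); target-absent maps apply the same construction at every box
with target confidence above 0.02.

**Post-processing.** Min-max normalization maps to [0, 1]; a constant map
becomes all-zero with a warning. Histogram matching is exact monotone
empirical-quantile specification (rank order preserved up to ties),
applied per image against that image's fixation-density map — not a
pooled task-level reference.

## Evaluation

**FDM.** Delta masses at fixation pixels convolved with an isotropic
Gaussian (σ default = image height / 24, roughly one degree of visual
angle at typical eye-tracking geometry) and renormalized to unit mass.

**NSS.** The map is standardized by its own mean and *population*
standard deviation; the score is the mean standardized value at fixated
pixels (coordinates rounded to the nearest pixel). Constancy is detected
by `max == min` (a `std() == 0` test is unreliable under summation
round-off) and scores 0 with a warning. NSS is invariant to positive
affine transforms of the map.

**Patch-grid GLMM.** Each image is partitioned into an 8-across × 6-down
grid (48 patches; remainder pixels fold into the last row/column). The
fixed processing order is: histogram-match each map to its image FDM →
patch means → min-max normalize each feature column across the whole
table. Fixation indices are 1-based scanpath ordinals ("new fixations"),
counted whether or not a location was previously visited. The table keeps
the exact `n_images × n_subjects × 48` row structure, flagging
(subject, image) pairs that lack the n-th fixation as non-contributing;
models are fit on contributing rows only, which is what makes the
per-index instance proportions meaningful.

One logistic mixed model per fixation index, all features entered jointly
(so each z is a unique contribution given the others); a per-feature
separate-models mode exists behind a flag. Random intercepts are
specified per grouping column (scene type for free viewing; scene type
plus target category for search). The mixed fit is a Laplace
(posterior-mode) approximation with diffuse priors
(`statsmodels.BinomialBayesMixedGLM.fit_map`; prior sd 10 on fixed
effects, 3 on log random-effect sd); its fixed-effect standard errors
were cross-validated against `lme4::glmer` on simulated data (slope SEs
agree to <1%, and a variational-Bayes alternative was rejected for
underestimating SEs severalfold — see `tests/test_glmm_crosscheck.py`).
With no random terms (or `re_variance=0`) the model reduces to an
ordinary logistic GLM, which matches a direct likelihood-maximization
oracle to 1e-3. Degenerate designs (constant or collinear feature
columns) raise; suspiciously large coefficients are flagged as possible
separation. p-values are two-sided normal on z, reported raw and
Bonferroni-adjusted across features × fixation indices.

**Weight table.** Per fixation index, weights are `max(z, 0)`
row-normalized to sum 1 — a negative z carries no positive evidence that
a factor attracts gaze, so it clamps to zero (raw z values are always
retained); a row with no positive z falls back to uniform with a warning.
The instance column is the per-index contributing count normalized to sum
1 down the column.

## Synthetic data

The generators define the simulated study conditions:

- **Scenes**: 240 × 320 px rasters (a scaled-down eye-tracking stimulus;
  constructors are resolution-agnostic), boxes 24-64 px, placed by
  rejection sampling under an overlap policy, categories drawn from a
  global pool of 18 everyday object labels.
- **Detections**: one proposal per object whose above-threshold category
  count *equals* the requested competition level — the true category near
  0.9, `k−1` distractors in [0.05, 0.4], remaining pool categories
  sub-threshold — so `gen_detections → filter → NMS → competing_count` is
  the identity on the requested competition vector.
- **Fixations**: sampled i.i.d. from
  `(1−ε)·Σ wᵢ mᵢ/Σmᵢ + ε·uniform` with ε = 0.05; the floor keeps the
  density strictly positive so the logistic model never sees separable
  data. No saccade-length prior, no inhibition of return, no center-start:
  the GLMM treats fixation indices independently, so sequential structure
  is unnecessary for validating it — but passing tests say nothing about
  temporal scanpath realism, and every subject contributes all nine
  indices (uniform instance column), unlike real cohorts whose trials end
  early.

**Weight recovery.** The end-to-end harness builds, per image, three
spatially separated maps — recognition uncertainty from three cluttered
objects on one side, a center-bias bump, and a target map from one
high-confidence detection on the opposite side — samples 10 subjects × 9
fixations per image from a known mixture, and runs the full
table-plus-GLMM pipeline with scene type as a random intercept. One
design point matters: a GLMM z-statistic scales with a map's spatial
discriminability as well as its mixture weight, so the three components
must be comparably concentrated for the z-ordering to track the weights.
The harness therefore uses σ_c = h/8 for its center-bias component
(the broad h/3 default would flatten its patch contrast and confound the
comparison). At 200 images × 10 subjects, mixture (0.6, 0.3, 0.1)
separates cleanly (z roughly 55 / 29 / 5).

## Numerical notes and limitations

- All map constructors match brute-force per-pixel evaluation of their
  defining sums to 1e-9 relative tolerance (`tests/test_acceptance.py`).
- Map rasters serialize as 16-bit grayscale PNG with min/max recorded in
  a JSON sidecar (quantization ≈ 1.5e-5 of the value range), or as exact
  plain-text matrices.
- Problem sizes in tests (64×64 oracle scenes, 200-image recovery runs)
  are deliberate desk-scale choices; constructors are linear in pixels ×
  boxes and the GLMM in rows, so larger corpora scale predictably.
- The package consumes detector outputs; it does not run a detector, and
  the bundled center-surround "saliency" is a test stand-in, not a
  published saliency model.
- Dataset-scale empirical findings (which factor dominates which task)
  are properties of real data; this package reproduces the machinery and
  validates it on synthetic ground truth only.
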