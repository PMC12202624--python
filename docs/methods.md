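# Methods

This note documents the models, conventions and numerical choices behind
`reefcover`, in the order the pipeline runs them.

## Cover extraction

Six benthic categories are tracked: branching *Acropora*, plating
*Acropora*, massive-form corals, other coral, reef substrate, and
water/sand/shadow. All covers are floats on the 0–100 percent scale,
never proportions.

**Masks.** Percent cover from a segmentation mask is the per-category
pixel count divided by the count of non-missing pixels. A mask with every
pixel missing has no defined cover and raises an error rather than
returning NaNs.

**Polygons.** Cover is the summed polygon area per category divided by
the image area. Area covered by no polygon — including "I don't know"
labels — is reported as an explicit `unannotated` residual, not silently
merged into reef substrate; `fold_residual` performs that merge only when
the caller asserts the annotation protocol was exhaustive. Overlap
resolution is geometric, not arithmetic: the rasterisation helper paints
shapes in input order so the later-drawn polygon wins, a deterministic
z-order chosen because colonies rarely overlap but a rule must exist.

**3×3 visual grid.** Each cell is scored 0–100 per category by eye; each
cell covers exactly **1/9** of the image, so the image cover is the mean
of the nine cell scores. The weight is the exact fraction 1/9 — the
rounded presentation 0.111 would make nine full cells sum to 99.9 — and
the implementation divides the summed cell scores once at the end so nine
full cells give exactly 100.0 in floating point. Per-cell category sums
may exceed 100 by ≤ 0.5 (data-entry slack); more is an error.

**Colonisable basis.** Coral covers are reported as percent of
colonisable substrate: remaining categories are divided by
(100 − water_sand_shadow)/100. An image with ≥ 99.999% water/sand/shadow
has no meaningful denominator; it raises a dedicated error and propagates
downstream as an absent record, never as zeros. Both expert protocols are
normalised identically.

**Analyst averaging.** Multiple analyses of one image are combined by an
unweighted per-category mean; the contributing analyst count is retained
because it drives the analyst-resampling simulation.

## Accuracy against experts

Accuracy is the signed difference *method − expert* in percentage points,
per image and coral category, computed only for images present in both
tables and only on the colonisable basis (a basis mismatch is an error,
not a warning). Method summaries report per-category means with standard
errors, plus a `total_coral` row: the per-image sum of the four coral
differences, averaged over images.

The **best method** maps each coral category to whichever of AI-alone or
AI+Citizen has the smaller absolute mean difference; ties go to AI
because it needs no analyst effort. Applying the map row-wise can leave
missing cells where the chosen method did not analyse an image, so
per-category *n* may differ — the summaries report their own counts.

**Reef-state bins** are [0,10), [10,20), …, [90,100] (last bin closed; the
boundary convention is ours, left-closed so a 10.0 expert cover lands in
the second bin). Images are re-assigned to bins per category using the
*expert* cover of that category, and only bins with at least
`min_bin_images` (default 80) images are reported.

**Offset correction.** A known systematic bias can be subtracted as a
constant per-category offset; results are clamped to [0,100] and the
number of clamped cells is reported, since clamping near the bounds
partially undoes the correction.

**Protocol comparison.** The detailed (polygon) and visual (grid) expert
protocols are compared on per-image total coral cover with a two-sided
Wilcoxon signed-rank test (scipy's implementation; this is plumbing, not
a contribution of the package).

## Site-sampling simulation

The per-image accuracy values of the best method form a pooled library
per category. One run draws *n* images and records their mean accuracy;
with analyst resampling, each drawn image first receives *m* of its
individual analyst differences drawn **with replacement**, mirroring the
fact that an image can be served repeatedly to the online crowd. Images
are drawn **without replacement** within a run — a site is photographed
at n distinct spots — with a config flag for the with-replacement
variant. Threshold comparison is inclusive (|mean| ≤ 5).

Each (category, n, m) cell reports the mean of run means, the central 95%
band and the fraction of runs within threshold; the minimum image count
is the smallest simulated *n* whose fraction meets the target (default
0.95), with no smoothing — at the default 10,000 runs the fraction
carries Monte-Carlo noise of order 0.005, which can move the crossing by
about one image. Some categories plateau below the target no matter how
many images are drawn; these are reported as not reached rather than
extrapolated.

Randomness uses one master seed with per-(category, n, m) substreams
derived through `SeedSequence`, so a grid is bit-reproducible even when
recomputed cell by cell. Tests run at 2,000 runs with widened tolerances;
the acceptance checks run at 10,000.

Under an iid Gaussian accuracy pool the simulation must agree with the
closed form P(|mean| ≤ t) = Φ(t√n/σ) − Φ(−t√n/σ), and with analyst
resampling the run-mean variance follows (σ²ᵢ + σ²ₐ/m)/n; both are
asserted in the acceptance suite (±0.015 on fractions, 10% on variances
at 10,000 runs).

## Power analysis

Within-site SDs of best-method cover (sample SD, n−1 denominator) are
computed per site and category; sites with fewer than 10 analysed images
are dropped, and images are never mixed across sites. Each site is binned
by the *expert* site mean (mean, not median — the choice is ours). Per
(category, bin) the **unweighted** mean of site SDs is reported with its
standard error; a single-site bin reports SE 0 and a low-confidence flag
rather than disappearing.

Required images per site solve: smallest equal group size *n* such that a
two-sample, two-sided, pooled-variance t test with Cohen's
d = effect/sd reaches the target power (defaults: effect 10 pp, power
0.8, α 0.05). Power is evaluated exactly through the noncentral-t
distribution (df = 2n−2, noncentrality d√(n/2)) and inverted by doubling
plus bisection, so the returned *n* satisfies the exact argmin contract
power(n−1) < target ≤ power(n). The two-sample two-sided family mirrors
the convention of standard power packages; a one-sided option exists. A
degenerate sd ≤ 0 returns the search floor of 2 with a flag. The solver
is cross-checked in tests against statsmodels' independent solver and a
seeded Monte-Carlo rejection-rate oracle (the Monte-Carlo inversion is
stabilised by a probit-scale regression on √n, since raw 20,000-rep
rejection rates move the crossing by more than one image for small d).

## Synthetic surveys

The generator emulates the structure of a large reef-census validation
set: reefs → sites → images → analysts, defaulting to 210 reefs × 7
sites × 20 images (29,400 images), six categories with realistic mean
covers, within-site heterogeneity of ~8 pp, an AI that under-calls
plating by ~9 pp, citizens who over-call branching by ~9.5 pp, and 1–6
citizen analyses per image from a 200-analyst pool in which each analyst
carries a persistent personal offset.

**Compositional noise.** Site and image covers are drawn on the logit
scale, which keeps covers inside [0,100]. The logit-scale SD is seeded by
the delta method and then calibrated by a short fixed-point iteration so
the realised within-group sample SD matches the requested
percentage-point SD at the configured means (the raw delta-method value
realises ~15% short at mid covers because of expit curvature and row
renormalisation). Near the 0/100 bounds realised SDs still shrink; this
residual compression is inherent to bounded covers and is why recovery
tests place covers mid-range.

**Observations.** Expert, AI and citizen observations perturb the four
coral categories (bias + Gaussian noise, per-analyst offset for
citizens) and let reef substrate close each composition to 100. Closure
in the substrate rather than renormalisation is deliberate: it preserves
the configured coral biases exactly, except where clamping at the bounds
intervenes. Each image's citizen analyses come from distinct analysts.
Grid annotations likewise add cell-level noise to non-water categories
(absent categories stay pinned at 0) and close each cell with
water/sand/shadow. Mask pixels are allocated by largest-remainder
rounding (deterministic, conserves the pixel total) so a mask
round-trips through pixel counting within one pixel quantum.

**What the generator does not emulate:** spatial autocorrelation between
neighbouring images, image-quality variation, analyst learning over
time, and cover-dependent method bias (bin-level behaviour is instead
tested with directly constructed tables). Passing tests therefore
demonstrate the pipeline's arithmetic and statistical machinery, not the
field accuracy of any particular survey program.

## Problem sizes and determinism

The default test suite runs the simulation engine at 2,000 runs and the
pipeline at a few hundred images; the acceptance suite uses 10,000 runs,
200,000-value Gaussian pools, 20,000-rep power oracles and a
5,000-image recovery survey (25 reefs × 5 sites × 40 images) — sizes at
which the asserted tolerances (±0.015 on fractions, ±0.3 pp on recovered
biases, ±1 image on sample sizes) hold with comfortable margin. The
recovery survey places mean covers mid-range (total coral 55%) with
moderate noise so the configured biases are identifiable; at the
generator's field-realistic defaults (coral categories near 6–8% cover)
clamping at zero visibly compresses recovered biases, which is a property
of bounded cover data worth knowing about, not an artifact of the
implementation.

The entire pipeline is a pure function of (inputs, config, seed):
reruns produce byte-identical CSVs (floats serialised to 4 decimals),
and the manifest records the seed and a config hash that excludes the
output directory.
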