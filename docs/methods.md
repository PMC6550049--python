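# Methods

## The model

`edma` analyzes samples of 3D anatomical landmark configurations under
the classical perturbation model of landmark-based morphometrics: an
observed configuration is a population mean form plus independent
random displacement of each landmark. All inference is carried out in
*distance space*. A configuration of K landmarks is reduced to its
**form matrix** — the vector of all K(K−1)/2 unique inter-landmark
Euclidean distances — which is invariant to translation, rotation, and
reflection. This sidesteps superimposition entirely: no registration
step is needed, and mirrored structures (left vs right sides) are
directly commensurable.

Two groups are compared through the **form difference matrix** (FDM):
element-wise ratios of like distances between the two groups' mean
forms, test group over reference group, so a ratio above 1 means that
distance is longer in the test group. A localized difference between
the groups appears as a coherent cluster of ratios away from 1 on the
distances incident to the affected landmarks.

## Mean-form estimation

Two per-distance estimators are provided:

* **arithmetic** (default): the mean of the observed distances for that
  landmark pair. Simple and robust; under landmark noise it is biased
  upward, because a distance is a convex functional of the noisy
  coordinates (for true distance δ and isotropic coordinate noise σ per
  landmark, E[d²] = δ² + 6σ² in 3D).
* **moment**: sqrt(mean(d²) − var̂(d)) per pair, with var̂ the ddof-1
  sample variance of that distance, falling back to the arithmetic mean
  (recorded on the result) whenever the correction would be
  non-positive. Because E[d]² = E[d²] − Var(d) identically, this
  correction coincides with the arithmetic mean in the large-sample
  limit; at finite n it equals sqrt(mean(d)² − var₀(d)/(n−1)), an
  always-slightly-smaller value that moves the upward-biased estimate
  toward the truth by an O(1/n) term. It is documented as exactly
  that — a small finite-sample shrinkage, not a full noise correction.
  Removing the entire 6σ² inflation would require an estimate of the
  landmark-noise variance itself (e.g. from replicate digitizations),
  which this estimator deliberately does not attempt.

## Bootstrap inference

**Confidence intervals.** For each FDM element, a nonparametric
bootstrap resamples specimens with replacement independently within
each group (original group sizes), recomputes both mean forms and
their ratio, and takes marginal percentile bounds. Defaults: 100,000
resamples, 90% two-sided intervals. A distance is flagged significant
when its interval excludes 1.0. Intervals are marginal — no
multiple-testing adjustment across the K(K−1)/2 pairs — matching the
per-distance reading of the results tables this package produces.

A known property worth stating plainly: percentile intervals at n≈25
per group undercover slightly. The bootstrap variance of a group mean
underestimates the sampling variance by the factor (n−1)/n, so the
realized marginal error rate of a nominal 90% interval is ≈11–12%
rather than 10% (we verified this with a standalone scalar simulation
of a ratio of group means). Users who need tighter marginal control
should raise `confidence_level`; the default remains the conventional
90%.

**Mean-form test.** The null hypothesis that two samples share a mean
form is tested with the statistic T = max(FDM)/min(FDM), which equals
1 exactly when the two mean forms are proportional. The null
distribution is built by pooling all specimens and drawing both
pseudo-groups, at their observed sizes, with replacement from the
pool; the p-value uses the add-one estimator
p = (1 + #{T\* ≥ T_obs}) / (1 + n_boot), so it is never exactly zero.
Note that T is insensitive to a *uniform* scaling contrast (all ratios
shift together), by construction: it is a test of proportionality of
forms, and pure size differences are detected by the confidence
intervals instead. At the package's standard simulation conditions
(16 landmarks, n=25/group, noise at 1% of mean distance, 500
resamples) the measured type-I rate at α=0.05 is ≈0.06, and power
against a 12% regional expansion of 4 landmarks is ≈1.0 — both
recomputed by the test suite and `scripts/acceptance.py`, not quoted
from anywhere.

**Randomness contract.** Every bootstrap call derives all resample
indices from a single `numpy.random.default_rng(seed)` — all group-A
indices in one draw of shape (n_boot, n_A), then group-B — and the
chunked vectorized evaluation never touches the RNG stream. Results
are therefore bit-reproducible across runs, chunk sizes, and the naive
reference loop used in the tests.

## Effect bands

Significant distances are classified by the point-estimate ratio r
into the reporting bands used for distance-map figures: increases of
5–10% (1.05 ≤ r < 1.10) or >10% (r ≥ 1.10), with decreases mirrored
multiplicatively (r ≤ 1/1.05, r ≤ 1/1.10) because FDM ratios are
multiplicative — a 10% decrease is the reciprocal of a 10% increase.
Additive mirroring (r ≤ 0.95, r ≤ 0.90) is available behind a flag.
Significance (from the CI) and effect size (from the point estimate)
are deliberately separated: a significant distance below the 5% band
is reported as `significant_lt5` rather than suppressed, and a large
but non-significant ratio stays `not_significant`.

## PCA of ln-distances

Form variation is summarized by PCA of the per-specimen table of
ln-transformed inter-landmark distances, using the column
variance-covariance matrix (not correlations). With
`scale_free=True`, each specimen's distances are first divided by
their geometric mean — equivalently each log-row is centered by its
row mean — giving scale-free *shape* variation; both modes are exposed
because size-and-shape and shape-only analyses answer different
questions and neither is privileged here. The decomposition runs
through the SVD of the column-centered table, which yields the
covariance eigenstructure without forming the pairs × pairs matrix
(pairs usually far exceed specimens). Components are oriented so the
largest-magnitude loading is positive, making outputs deterministic
across platforms. Group separation is summarized as the distance
between group centroids in a chosen score subspace divided by the
pooled within-group dispersion sqrt(Σ_g Σ_i ||s_i − c_g||² / (N − G)).

## Replicate digitization QC

Manual landmark placement is replicated: each specimen is digitized
twice and the trials averaged coordinate-wise, which halves the
placement-error variance. The QC report lists the Euclidean
inter-trial displacement of every (specimen, landmark) and flags those
exceeding `max_error` (default 0.05 mm, the conventional acceptance
threshold for µCT landmarking at this scale). Flagging is advisory:
averaging is still performed, and exclusion or re-digitization is left
to the analyst, since an automatic drop would silently change the
landmark set.

## Synthetic data

The generator emulates a two-group µCT landmark study of newborn
mouse hemimandibles: a fixed template mean form (16 pseudo-random
landmarks in a 10×4×3 mm box for `mandible_16`; a 3-4-5 triangle and a
10×4×3 mm box corner set as toy fixtures), isotropic Gaussian landmark
perturbation, optional localized effects (radial expansion of a
landmark subset about its centroid, or fixed displacement), and
optional replicate-digitization noise. Defaults are 25 specimens per
group and a perturbation SD of ~1–2% of the mean inter-landmark
distance, reflecting typical group sizes (≈20–40) and the small
within-group dispersion of inbred neonatal samples relative to
mutation effects.

What the generator does **not** emulate: realistic mandible geometry
and landmark covariance structure (real landmark noise is anisotropic
and spatially correlated through the digitizing surface), allometry,
asymmetric directional effects, missing or misidentified landmarks,
and group-specific variances. Passing the simulation suite therefore
shows the estimators and resampling machinery behave correctly under
the stated perturbation model — not that any particular biological
dataset satisfies that model.

## Numerical choices and degenerate inputs

* Distances below 1e−9 mm are treated as coincident landmarks and are
  a hard error (identifying the pair); genuinely tiny separations at
  the µCT scale are orders of magnitude larger.
* Missing or non-finite coordinates are hard errors naming the
  specimen and landmark; imputation is out of scope.
* Percentile bounds use `numpy.quantile` with linear interpolation.
* Two identical zero-variance groups give T = 1 and p = 1.
* PCA requires n_components ≤ min(specimens − 1, pairs); explained
  fractions are reported against the total variance (trace), so they
  sum to ≤ 1 even when components are truncated.
* Simulation problem sizes used by the test suite and acceptance
  script (200 null replicates, 50 effect replicates, 500 resamples)
  were chosen as the smallest sizes at which the binomial envelopes
  are meaningful; all contracts hold identically at larger sizes.

## Known limitations

* Percentile CIs only (no BCa or studentized intervals) — chosen for
  transparency and exact testability against a reference loop; see
  the undercoverage note above.
* No multiple-testing correction across distances; the per-distance
  intervals answer "where is the difference", not a familywise claim.
* The pooled-resampling null for the mean-form test is the standard
  nonparametric construction, but other null constructions exist; the
  choice is recorded in every report's provenance block.
* Landmark correspondence across specimens is assumed perfect; there
  is no outlier detection beyond the replicate-digitization QC.
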