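# edma

Euclidean Distance Matrix Analysis (EDMA) and ln-distance PCA for 3D
anatomical landmark data, with nonparametric bootstrap inference and a
synthetic two-group data generator.

## What this is for

Landmark-based phenotyping studies — e.g. µCT landmarking of mouse
mandibles in craniofacial-dysmorphology models — compare the 3D form
of a structure between a test group (animals carrying a mutation) and
a reference group (unaffected littermates). `edma` implements the
coordinate-system-free side of that workflow:

* **Form matrix** — a K-landmark configuration is represented by its
  K(K−1)/2 unique inter-landmark distances, invariant to translation,
  rotation, and reflection, so no superimposition is needed and left
  vs right sides can be compared directly.
* **Form difference matrix (FDM)** — ratios of like distances between
  two group mean forms (test/reference; ratio > 1 ⇔ longer in the
  test group), localizing *where* the forms differ.
* **Bootstrap inference** — percentile confidence intervals for every
  FDM element (specimens resampled within groups; 100,000 resamples
  by default) and a pooled-resampling test of the null hypothesis
  that the two mean forms are the same, using
  T = max(FDM)/min(FDM) and p = (1 + #{T\* ≥ T}) / (1 + n_boot).
* **Effect bands** — significant distances classified as increases or
  decreases of 5–10% or >10% for distance-map style reporting.
* **PCA of ln-distances** — principal components of the
  variance-covariance matrix of ln-transformed distances, in form
  (size + shape) or scale-free shape mode, with a group-separation
  summary.
* **Study plumbing** — tidy-CSV landmark I/O, landmark subsets,
  replicate-digitization averaging with a 0.05 mm placement-error QC,
  bilateral (left/right) matching, an end-to-end analysis runner with
  JSON/CSV reports, and a synthetic-data generator with known ground
  truth.

See `docs/methods.md` for the statistical details and limitations.

## Worked example

Simulate a study at typical conditions — 16 landmarks, 25 specimens
per group, landmark noise 0.04 mm, and a 12% expansion of a
4-landmark region in the test group — then test and localize the
difference:

```python
import edma

template = edma.make_template_form("mandible_16", seed=11)
affected = ("md01", "md02", "md03", "md04")
mutant_form = edma.apply_regional_effect(template, affected, "radial_scale", 0.12)
mutant = edma.simulate_group(mutant_form, 25, 0.04, "mutant", seed=1)
unaffected = edma.simulate_group(template, 25, 0.04, "unaffected", seed=2)

res = edma.test_mean_form_difference(mutant, unaffected, n_boot=10_000, seed=7)
print(f"T = {res.statistic_observed:.3f}, p = {res.p_value:.5f}")

ci = edma.bootstrap_fdm_intervals(mutant, unaffected, n_boot=10_000, seed=7)
bands = edma.classify_fdm_effects(ci)
for cat, n in bands.counts().items():
    print(f"{cat:16s} {n}")
```

prints

```
T = 2.109, p = 0.00010
increase_gt10    15
increase_5_10    21
decrease_5_10    4
decrease_gt10    4
significant_lt5  10
not_significant  66
```

The mean forms differ (the observed max/min ratio spread T = 2.109 is
never reached in 10,000 null resamples, so p is at its add-one floor
1/10001), and the significant increases concentrate on distances
involving the four truly expanded landmarks — e.g. the first rows of
the per-distance table:

```
landmark_i landmark_j    ratio    lower    upper  significant      category
      md01       md02 1.115609 1.100796 1.130790         True increase_gt10
      md01       md03 1.122176 1.117273 1.127111         True increase_gt10
      md01       md04 1.123295 1.118002 1.128441         True increase_gt10
```

The 66 `not_significant` pairs are dominated by distances among the
12 unaffected landmarks. The same analysis runs from the shell:

```sh
edma compare --group-a mutant.csv --group-b unaffected.csv \
     --n-boot 100000 --confidence 0.90 --seed 17 -o fdm.csv \
     --test --report report.json
```

and `edma run --config analysis.yaml` executes the whole-set +
regional-subset workflow (mean-form tests, FDM CIs, effect bands,
PCA) in one pass; `edma asymmetry` compares left vs right sides
within each group via bilateral landmark matching.

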