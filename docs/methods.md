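# Methods

## Model and procedure

`jackmap` operates on the inputs of a second-level random-effects fMRI
analysis: one contrast (parameter-estimate) volume per subject, aligned on
a common voxel grid, optionally with per-subject nuisance covariates and an
analysis mask.

**Second-level GLM.** Per voxel, subject values y are regressed on
X = [1 | C̃], where C̃ are the selected covariates mean-centered *within
the analyzed subset* — every reduced design is treated as a self-contained
group analysis, so covariate centering never leaks information from
excluded subjects. The test statistic is t = c'β̂ / √(σ̂² c'(X'X)⁻¹c) with
σ̂² = RSS/df, df = m − rank(X) for subset size m; the default contrast
tests the intercept (group mean activation), one-sided. Two-sided
inference is available by flag.

**Thresholding.** Voxelwise over the mask, closed at p ≤ α:

- `uncorrected` — p ≤ α;
- `fwe_bonferroni` — p ≤ α / n_voxels. Bonferroni was chosen as the FWE
  default because it is assumption-free and valid under any dependence;
  it is conservative relative to random-field-theory thresholds, so voxel
  counts will differ from SPM-style analyses of the same data;
- `fwe_permutation` — sign-flip max-t null with B seeded flips (default
  1000), voxel significant when t reaches the (1−α) quantile of the max-t
  distribution; the exchangeable less conservative FWE alternative;
- `fdr_bh` — Benjamini–Hochberg step-up over mask voxels (voxelwise, per
  the classical FDR formulation for neuroimaging).

**Degenerate voxels.** Voxels whose residual sum of squares is zero up to
float round-off (RSS ≤ 1e-24 × total SS) are flagged rather than allowed
to produce infinite t. They are assigned p = 0 when the contrast effect is
strictly positive (a noise-free effect is detected with certainty) and
p = 1 otherwise (an identically zero voxel can never be significant). This
keeps noise-free synthetic cohorts fully consistent: every reduced design
reproduces the original map, and noise-free blobs are detected at every
group size.

**Jackknife planning.** Removing r of n subjects admits C(n, r) unique
designs. When C(n, r) ≤ cap all are enumerated in lexicographic order of
the removed set; otherwise cap combination *ranks* are sampled uniformly
without replacement (Python's `random.Random(seed).sample` over the full
integer range, exact for arbitrarily large C(n, r)) and unranked through
the combinatorial number system. Nothing larger than the cap is ever
materialized, sampling is reproducible under the seed, and every subject
has an even chance of removal. The default cap of 100 makes each reduced
analysis contribute exactly 1% to the overlap map; each removal depth is
planned independently.

**Reliability summaries.** Dice similarity DSI = 2|A∩B|/(|A|+|B|) between
each reduced and the original thresholded map, with the convention DSI = 0
when either map is empty (a reduced design losing all significant voxels
is zero overlap, not undefined). The group percent overlap map stores
round-half-up integer percentages; raw counts are kept alongside for
exactness. Reliability classes: 100% very reliable, 50–99% reliable,
0–50% (exclusive) unreliable. The boundary at exactly 50% is classed
"reliable" by default with a switch for strict majority, since the two
conventions in circulation disagree at that single value. "Very reliable"
is a statement about the designs actually computed: under a capped sample
it is sampling-based, not exhaustive.

**Sampling-depth comparison.** DSI distributions from different caps
(e.g. 100 vs 1000 designs per step) are compared with a two-sided
Mann–Whitney U test, Bonferroni-corrected across comparisons; exact
enumeration for tie-free samples of at most 20, otherwise the normal
approximation with mid-rank tie correction.

**Power scan.** Group sizes m = n−1 … floor are each given an
independently planned (per-size child seed) capped design sample and a
per-size detection-fraction map. A voxel is *safely detected* at m when
its detection fraction reaches the safe threshold (default 100%; 80% is
offered as the customary laxer power convention) at m **and at every
evaluated size above m**. This monotone closure is a deliberate choice:
sampled detection fractions need not be monotone in m, and the closure
makes the minimum detecting size well-defined without detection gaps.
min_n is only defined for voxels significant in the full-group design
(post-hoc power for null results is meaningless — the power-approach
paradox); the sentinel 0 marks all other voxels, and min_n = n marks
voxels only the full design detects. Cluster-level min_n defaults to the
minimum over member voxels (the size at which the cluster first contains a
safely detected voxel); peak-voxel and all-voxel semantics are available,
as the cluster-level granularity is genuinely underdetermined. Cluster
connectivity defaults to 26 (configurable 6/18/26). A stride option
evaluates every k-th size for speed at the cost of min_n granularity.

## Synthetic cohorts

The generator emulates the *inputs* of a second-level analysis, not the
acquisition: subject map = Σ Gaussian blobs + i.i.d. N(0, noise_sd²) noise
per voxel. Blobs are isotropic, truncated at 4 s.d., mimicking smoothed
activation foci. With i.i.d. noise the one-sample t at a blob peak has
noncentrality a√n/s, so closed-form oracles hold exactly; an optional
smoothing of the noise field (off by default) provides spatial
autocorrelation at the cost of those oracles. Covariates, when requested
by name, are independent standard normals — nuisance-only, like age,
gender, or handedness in a typical design. "Deviant" subjects are
sign-inverted *after* construction (the finished map is negated), placed
last in subject order and flagged in the manifest; this models the
maximally inhomogeneous outlier whose activation pattern opposes the
group's.

What the generator does **not** model: spatially varying noise, the
spatial autocorrelation structure of real BOLD residuals, inter-subject
anatomical variability, or realistic activation geometry. Passing the
scenario tests therefore shows that the machinery behaves as the method
predicts under its idealized assumptions, not that any particular real
dataset would show the same DSI levels.

## Study-scale test conditions

The scenario suites run cohorts on a 20×24×20 voxel grid with three foci
of graded peak amplitude (1.6, 1.2, 0.8 contrast units; σ = 2, 2, 1.5
voxels), unit noise, group sizes 19/29/39, removal depths 1–3 at cap 100,
and 20 seeds, with properties asserted on across-seed medians. Amplitudes
were chosen so the smallest group, including the one-deviant variant,
still yields a rich supra-threshold map — mirroring a well-powered
language/visuospatial paradigm — while leaving headroom for overlap to
degrade. The FWE-vs-FDR steepness comparison uses removal depths up to 17
at n = 39, where the differential elimination of voxels expresses itself;
at depths 1–3 the two controls decline almost identically. The power
ranking check uses n = 30, floor 12, cap 40, FDR α = .05; blob-core median
min_n recovers the amplitude ordering in ≥ 90% of seeds. On one CPU the
full test suite runs in about five minutes.

## Numerical choices

- Binomial counts in exact integer arithmetic (no float overflow at any
  depth).
- gPOM rounding is half-up (1/3 → 33, 1/8 → 13); counts carried alongside.
- Affine agreement between input volumes is required to 1e-4 per entry;
  float volumes round-trip through NIfTI-1 at ≤ 1e-6 relative error,
  integer volumes exactly.
- Cluster labels are ordered by descending size, ties broken by
  lexicographically smallest member voxel, for platform-independent
  output.
- All seeding flows through a single integer; child seeds for per-design
  permutation nulls and per-size plans are derived via `SeedSequence`
  spawning, so identical configurations are bit-reproducible and
  exhaustive plans are seed-independent.

## Known limitations

- No random-field-theory FWE and no cluster-extent inference: cluster-level
  reliability under non-stationary smoothness is out of scope.
- OLS only at the second level; no weighted/mixed-effects variance
  modeling.
- The jackknife is systematic removal without replacement; there is
  deliberately no bootstrap-with-replacement mode.
- Reliability statements are conditional on the computed (possibly capped)
  design sample and on the chosen threshold; they are descriptive, not a
  formal conjunction inference.
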