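# jackmap

Iterative jackknife reliability and post-hoc power analysis for fMRI group
activation maps.

## The problem

Second-level (random-effects) fMRI analyses fit a group GLM over per-subject
contrast images and are meant to generalize to the population — but a map
from one particular group of *n* subjects says nothing about how that map
would change if the group were slightly smaller or differently composed.
Two equally legitimate analyses (say, *n* and *n*−1 subjects) can disagree,
especially in small or inhomogeneous groups. `jackmap` makes that
variability visible instead of hiding it: it systematically removes
subjects, re-fits the group analysis on every (or a capped random sample
of) reduced designs, and summarizes how reliably each voxel survives.

The same machinery, pushed further down in group size, yields a post-hoc
power analysis: the smallest group size at which a voxel or cluster is
still detected is its *observable effect size*, a readily interpretable
alternative to comparing t-values across designs with different degrees of
freedom.

It is aimed at neuroimaging researchers working with groups that cannot
easily be enlarged — pediatric cohorts, rare patient populations — who need
to know which of their activations are robust and which hang on one or two
subjects.

## The method

For a group of *n* subjects and removal depth *r* there are

&nbsp;&nbsp;&nbsp;&nbsp;C(n, r) = n! / (r!(n−r)!)

unique reduced designs. `jackmap` computes all of them when C(n, r) is at
most the cap (default 100), otherwise a uniform without-replacement sample
of `cap` designs. Each reduced design is a self-contained second-level
GLM: ordinary least squares per voxel of subject values on
[intercept | mean-centered nuisance covariates], one-sided t-test on the
intercept, thresholded voxelwise at p ≤ α with no correction, Bonferroni
FWE, sign-flip max-t permutation FWE, or Benjamini–Hochberg FDR.

Each reduced thresholded map A is compared with the original map B by the
Dice similarity index

&nbsp;&nbsp;&nbsp;&nbsp;DSI = 2|A∩B| / (|A| + |B|) ∈ [0, 1],

and all reduced maps of one step are combined into a **group percent
overlap map** (gPOM): the voxel value is the percentage of reduced designs
in which the voxel was significant (with 100 designs, each contributes
exactly 1%). Voxels are classed *very reliable* (100%), *reliable*
(50–99%), or *unreliable* (<50%).

The power scan sweeps group sizes m = n−1 … floor (default 12), builds a
capped design sample and detection-fraction map per size, and assigns every
voxel that is significant in the full design the minimum m at which its
detection fraction still reaches the safe threshold (default 100%) at m and
every larger evaluated size. Clusters (26-connected by default) are ranked
by the minimum over their member voxels.

## Worked example

Simulate a 19-subject cohort with three activation foci of graded strength
(peak amplitudes 1.6, 1.2, 0.8 in contrast units, unit between-subject
noise) on a 20×24×20 voxel grid, then run the jackknife at removal depths
1–3 with BH-FDR thresholding at α = .05:

```sh
jackmap simulate --config cohort.yaml --out data
jackmap l3 --maps data/sub-001.nii.gz ... --maps data/sub-019.nii.gz \
    --covariates data/manifest.tsv --use-covariates age,handedness \
    --remove 1 --remove 2 --remove 3 --cap 100 --seed 7 \
    --threshold fdr:0.05 --out l3_out
```

```
 step  n_designs   median       q1       q3
    1         19 0.866667 0.851351 0.874586
    2        100 0.767020 0.748174 0.783385
    3        100 0.686141 0.655669 0.713716
```

Removing one subject still leaves a median Dice overlap of 0.87 with the
full-group map (values of .7–.8 are conventionally "high"); overlap decays
as more subjects are removed, exactly the group-composition sensitivity the
method is designed to expose. Per-step outputs include the gPOM and the
3-class reliability volume (`L3p19-1_gpom.nii.gz`, …) plus per-design DSI
tables naming the removed subjects.

The power scan on the same cohort:

```sh
jackmap power --maps ... --covariates data/manifest.tsv \
    --use-covariates age,handedness --floor 12 --cap 50 --seed 7 \
    --threshold fdr:0.05 --out power_out
```

```
 cluster_id  n_voxels    peak_t  min_n
          1        48 11.827381     14
          2        25  6.564421     16
          3         2  4.489875     19
```

The strongest focus is safely detected from 14 subjects on, the middle one
needs 16, and the weak foci only appear with the full group of 19 — the
clusters are ranked by observable effect size. `min_n.nii.gz` carries the
voxelwise minimum group sizes.

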