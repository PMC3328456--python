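"""Shared scenario battery for reliability/power property tests.

Reproduces the study conditions at desk scale: cohorts on a 20x24x20 voxel
grid with three activation foci of graded amplitude (1.2, 0.9, 0.6 contrast
units, sigma 2 voxels), unit between-subject noise, group sizes 19/29/39,
removal depths 1-3, and up to 100 reduced designs per step.  Each planned
subset is fitted once and thresholded under both Bonferroni-FWE and BH-FDR,
so FWE-vs-FDR comparisons share the identical designs.
"""

from __future__ import annotations

import numpy as np

from jackmap import CohortSpec, dice, simulate_cohort
from jackmap.glm import fit_second_level, p_values, threshold_map
from jackmap.jackknife import plan_reduced_designs

GRID = (20, 24, 20)
BLOBS = [((5, 12, 10), 1.6, 2.0), ((14, 6, 8), 1.2, 2.0), ((10, 18, 12), 0.8, 1.5)]
NOISE_SD = 1.0
GROUP_SIZES = (19, 29, 39)
DEPTHS = (1, 2, 3)
CAP = 100
ALPHA = 0.05
METHODS = ("fwe_bonferroni", "fdr_bh")


def make_cohort(n, seed, n_deviants=0):
    return simulate_cohort(CohortSpec(
        grid_shape=GRID, n_subjects=n, blobs=BLOBS, noise_sd=NOISE_SD,
        n_deviants=n_deviants, seed=seed))


def _threshold_both(pvals, mask):
    return {m: threshold_map(pvals, mask, method=m, alpha=ALPHA).significant
            for m in METHODS}


def median_dsi_by_depth(cohort, seed, depths=DEPTHS, cap=CAP):
    """Median DSI per (method, depth), fitting each reduced design once."""
    n = cohort.n_subjects
    full_t = fit_second_level(cohort)
    full_sig = _threshold_both(p_values(full_t), cohort.mask)
    out = {m: {} for m in METHODS}
    for r in depths:
        plan = plan_reduced_designs(n, r, cap=cap, seed=seed)
        dsis = {m: [] for m in METHODS}
        for subset in plan.subsets:
            tm = fit_second_level(cohort, list(subset))
            sig = _threshold_both(p_values(tm), cohort.mask)
            for m in METHODS:
                dsis[m].append(dice(full_sig[m], sig[m]))
        for m in METHODS:
            vals = np.asarray(dsis[m])
            out[m][r] = {
                "median": float(np.median(vals)),
                "iqr": float(np.percentile(vals, 75) - np.percentile(vals, 25)),
            }
    return out


def run_battery(seeds, group_sizes=GROUP_SIZES):
    """Per-seed median/IQR DSI for plain and one-deviant cohorts.

    Returns nested dict: stats[scenario][n][method][r][stat] = list over seeds.
    """
    stats = {
        scen: {n: {m: {r: {"median": [], "iqr": []} for r in DEPTHS}
                   for m in METHODS} for n in group_sizes}
        for scen in ("plain", "deviant")
    }
    for seed in seeds:
        for n in group_sizes:
            for scen, ndev in (("plain", 0), ("deviant", 1)):
                cohort = make_cohort(n, 100 + seed, n_deviants=ndev)
                res = median_dsi_by_depth(cohort, seed)
                for m in METHODS:
                    for r in DEPTHS:
                        stats[scen][n][m][r]["median"].append(res[m][r]["median"])
                        stats[scen][n][m][r]["iqr"].append(res[m][r]["iqr"])
    return stats
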