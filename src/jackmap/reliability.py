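"""Spatial-reliability metrics over collections of thresholded maps.

Two complementary summaries are computed from the reduced analyses of a
jackknife step:

* the Dice similarity index (DSI) between the original and each reduced
  thresholded map, ``2|A∩B| / (|A| + |B|)`` — one value per reduced design;
* the group percent overlap map (gPOM), whose voxel value is the percentage
  of reduced designs in which that voxel is significant (with 100 designs,
  each contributes exactly 1%).

gPOM values map onto reliability classes: a voxel significant in all
computed reduced designs (100%) is "very reliable", in at least half
(50–99%) "reliable", in fewer than half "unreliable".  The 100% convention
is a statement about the designs actually computed — under a capped sample
it is a sampling-based claim, not an exhaustive one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glm import ThresholdedMap
from .jackknife import L3Result

__all__ = [
    "dice",
    "build_gpom",
    "classify_reliability",
    "compare_sampling_depth",
    "dsi_table",
    "OverlapMap",
    "CLASS_NOT_SIGNIFICANT",
    "CLASS_UNRELIABLE",
    "CLASS_RELIABLE",
    "CLASS_VERY_RELIABLE",
]

CLASS_NOT_SIGNIFICANT = 0
CLASS_UNRELIABLE = 1
CLASS_RELIABLE = 2
CLASS_VERY_RELIABLE = 3


def _as_bool(a) -> np.ndarray:
    if isinstance(a, ThresholdedMap):
        a = a.significant
    return np.asarray(a, dtype=bool)


def dice(a, b) -> float:
    """Dice similarity index between two binary maps.

    Returns 1 for perfect overlap and 0 for none; by convention 0 when
    either map is empty (a reduced design without significant voxels counts
    as zero overlap).
    """
    a = _as_bool(a)
    b = _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na = int(a.sum())
    nb = int(b.sum())
    if na == 0 or nb == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / (na + nb)


@dataclass
class OverlapMap:
    """Group percent overlap map (gPOM) for one jackknife step.

    ``gpom`` holds integer percentages (round-half-up); ``counts`` the raw
    per-voxel number of significant designs, for exactness.
    """

    gpom: np.ndarray
    counts: np.ndarray
    n_designs: int
    step: Optional[int] = None


def build_gpom(maps: Sequence, step: Optional[int] = None) -> OverlapMap:
    """Combine thresholded maps into a group percent overlap map."""
    vols = [_as_bool(m) for m in maps]
    if not vols:
        raise ValueError("need at least one thresholded map")
    shape = vols[0].shape
    for v in vols[1:]:
        if v.shape != shape:
            raise ValueError(f"shape mismatch: {shape} vs {v.shape}")
    counts = np.sum(vols, axis=0).astype(np.int64)
    # round half up so e.g. 1/3 of designs -> 33 and 50.5 -> 51
    gpom = np.floor(100.0 * counts / len(vols) + 0.5).astype(np.int32)
    return OverlapMap(gpom=gpom, counts=counts, n_designs=len(vols), step=step)


def classify_reliability(gpom: OverlapMap | np.ndarray,
                         reliable_includes_50: bool = True) -> np.ndarray:
    """Map gPOM percentages onto reliability classes.

    100 -> very reliable (3); [50, 100) -> reliable (2); (0, 50) ->
    unreliable (1); 0 -> not significant anywhere (0).  Whether exactly 50%
    counts as "reliable" is convention; the default includes it, and
    ``reliable_includes_50=False`` switches to a strict majority.
    """
    pct = gpom.gpom if isinstance(gpom, OverlapMap) else np.asarray(gpom)
    out = np.full(pct.shape, CLASS_NOT_SIGNIFICANT, dtype=np.int32)
    lo = 50 if reliable_includes_50 else 51
    out[(pct > 0) & (pct < lo)] = CLASS_UNRELIABLE
    out[(pct >= lo) & (pct < 100)] = CLASS_RELIABLE
    out[pct >= 100] = CLASS_VERY_RELIABLE
    return out


def dsi_table(result: L3Result) -> pd.DataFrame:
    """Per-design Dice similarity of reduced vs original thresholded maps."""
    rows = []
    for i, (thr, removed) in enumerate(zip(result.reduced_maps,
                                           result.plan.removed)):
        rows.append({
            "step": result.plan.r,
            "design_id": i,
            "removed_subjects": ",".join(str(s) for s in removed),
            "dsi": dice(result.original_map, thr),
        })
    return pd.DataFrame(rows)


def summarize_dsi(table: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of DSI per jackknife step."""
    return (
        table.groupby("step")["dsi"]
        .agg(n_designs="count", median="median",
             q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
        .reset_index()
    )


class DepthComparison(NamedTuple):
    u_statistic: float
    p_corrected: float
    median_difference: float
    significant: bool


def compare_sampling_depth(
    dsi_a: Sequence[float],
    dsi_b: Sequence[float],
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> DepthComparison:
    """Mann–Whitney U comparison of two DSI samples, Bonferroni-corrected.

    Used to check whether a cheaper sampling depth (e.g. 100 designs per
    step) differs from a denser one (e.g. 1000).  Exact enumeration is used
    for small tie-free samples (both n <= 20), otherwise the normal
    approximation with mid-rank tie correction.
    """
    a = np.asarray(dsi_a, dtype=np.float64)
    b = np.asarray(dsi_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both DSI samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    pval = float(res.pvalue)
    if not np.isfinite(pval):  # degenerate case, e.g. every value tied
        pval = 1.0
    p_corr = min(1.0, pval * n_comparisons)
    med_diff = abs(float(np.median(a)) - float(np.median(b)))
    return DepthComparison(
        u_statistic=float(res.statistic),
        p_corrected=p_corr,
        median_difference=med_diff,
        significant=p_corr <= alpha,
    )
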