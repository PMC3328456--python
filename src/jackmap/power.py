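"""Post-hoc power scan: minimum group size for safe detection.

When subjects are removed, activation foci shrink and eventually disappear
as detection power falls.  Sweeping the group size m from n-1 down to a
floor (default 12, the classical minimum for a random-effects group
analysis) and recording, for each voxel, the smallest m at which it is
still detected in (by default) all sampled size-m designs, assigns every
significant voxel a minimum detecting group size — its observable effect
size.  Clusters are then ranked by the minimum over their member voxels.

The scan is only meaningful for voxels significant in the full-group map in
the first place, which also sidesteps the "power approach paradox" of
post-hoc power computed for null results.  Because detection fractions are
estimated from a capped sample of designs per size, they need not be
monotone in m; ``min_n`` uses a monotone closure (a voxel is safely
detected at m only if it is also safely detected at every evaluated size
above m), which makes the minimum well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .glm import ThresholdConfig, ThresholdedMap, TMap, fit_and_threshold
from .io import SubjectMapSet
from .jackknife import DEFAULT_CAP, plan_reduced_designs, _design_seed

__all__ = [
    "PowerMap",
    "power_scan",
    "label_clusters",
    "cluster_power_table",
]

#: classical minimum group size for a random-effects fMRI analysis
DEFAULT_FLOOR = 12

#: min_n sentinel for voxels not significant in the full-group design
NOT_SIGNIFICANT = 0


@dataclass
class PowerMap:
    """Per-voxel minimum detecting group size and supporting detail.

    ``min_n`` is 0 (:data:`NOT_SIGNIFICANT`) outside the full-group
    significant set; elsewhere it is the smallest evaluated size at which
    the voxel is safely detected, or ``n`` when only the full design
    detects it.  ``detection_pct`` stacks the per-size overlap percentages
    (one gPOM layer per entry of ``sizes``, descending).
    """

    min_n: np.ndarray
    sizes: list[int]
    detection_pct: np.ndarray
    full_map: ThresholdedMap
    full_t: TMap
    n: int
    floor: int
    safe_threshold: float
    cap: int
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def power_scan(
    maps: SubjectMapSet,
    config: ThresholdConfig = ThresholdConfig(),
    floor: int = DEFAULT_FLOOR,
    cap: int = DEFAULT_CAP,
    seed: Optional[int] = None,
    safe_threshold: float = 100.0,
    stride: int = 1,
    covariate_names: Sequence[str] = (),
    contrast: Optional[Sequence[float]] = None,
) -> PowerMap:
    """Sweep group sizes n-1 .. floor and assign per-voxel minimum sizes.

    For each size m a capped plan of size-m subsets is drawn (independently
    per size, with a per-size child seed) and the fraction of designs
    detecting each voxel recorded.  A voxel is *safely detected* at m when
    its detection fraction reaches ``safe_threshold`` percent at m and at
    every evaluated size above m.  ``safe_threshold=100`` is the strict
    all-designs convention; 80 is the customary laxer power threshold.

    ``stride`` > 1 evaluates every stride-th size (always including n-1)
    for speed; min_n granularity coarsens accordingly.
    """
    n = maps.n_subjects
    min_size = max(2, len(covariate_names) + 2)
    if floor < min_size:
        raise ValueError(f"floor {floor} below minimum design size {min_size}")
    if floor > n:
        raise ValueError(f"floor {floor} exceeds group size {n}")
    if not 0 < safe_threshold <= 100:
        raise ValueError(f"safe_threshold must be in (0, 100], got {safe_threshold}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")

    full_t, full_thr = fit_and_threshold(
        maps, None, config, covariate_names, contrast,
        seed=_design_seed(seed, 0),
    )

    sizes = list(range(n - 1, floor - 1, -stride))
    detection_pct = np.zeros((len(sizes),) + maps.grid_shape, dtype=np.float64)

    min_n = np.zeros(maps.grid_shape, dtype=np.int32)
    min_n[full_thr.significant] = n  # full design always detects its own set
    chain = full_thr.significant.copy()  # voxels still safely detected so far

    for si, m in enumerate(sizes):
        r = n - m
        plan = plan_reduced_designs(n, r, cap=cap, seed=_design_seed(seed, 1000 + m))
        counts = np.zeros(maps.grid_shape, dtype=np.int64)
        for di, subset in enumerate(plan.subsets):
            _, thr = fit_and_threshold(
                maps, list(subset), config, covariate_names, contrast,
                seed=_design_seed(seed, (1000 + m) * 10_000 + di),
            )
            counts += thr.significant
        pct = 100.0 * counts / len(plan.subsets)
        detection_pct[si] = pct
        safe_here = pct >= safe_threshold - 1e-9
        chain &= safe_here
        min_n[chain] = m

    return PowerMap(
        min_n=min_n, sizes=sizes, detection_pct=detection_pct,
        full_map=full_thr, full_t=full_t, n=n, floor=floor,
        safe_threshold=safe_threshold, cap=cap, affine=maps.affine,
    )


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_clusters(significant: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Connected-component labels of a binary volume, deterministically ordered.

    Labels are assigned 1, 2, ... by descending cluster size, ties broken by
    the lexicographically smallest member voxel index, so the labeling is
    platform-independent.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    sig = np.asarray(significant, dtype=bool)
    if sig.ndim != 3:
        raise ValueError(f"expected a 3-D binary volume, got {sig.ndim}-D")
    raw, n_lab = ndimage.label(sig, structure=_STRUCTURES[connectivity])
    if n_lab == 0:
        return raw.astype(np.int32)

    order = []
    for lab in range(1, n_lab + 1):
        vox = np.argwhere(raw == lab)
        order.append((-len(vox), tuple(vox.min(axis=0)), lab))
    order.sort()
    relabel = np.zeros(n_lab + 1, dtype=np.int32)
    for new, (_, _, old) in enumerate(order, start=1):
        relabel[old] = new
    return relabel[raw]


def cluster_power_table(
    powermap: PowerMap,
    labels: np.ndarray,
    tmap: Optional[TMap] = None,
    min_n_rule: str = "any",
) -> pd.DataFrame:
    """Summarize clusters of the full-group map by minimum detecting size.

    ``min_n_rule`` chooses the cluster-level semantics: ``any`` (default) is
    the minimum over member voxels — the size at which the cluster first
    contains a safely detected voxel; ``peak`` uses the peak-t voxel;
    ``all`` the maximum over members (whole cluster safely detected).

    The table carries, per cluster, the voxel count, peak t and its location
    (voxel indices and world mm), the cluster min-n, and per-size counts of
    safely detected voxels inside the cluster footprint (the voxel-count vs
    group-size curves used to rank clusters by observable effect size).
    """
    if min_n_rule not in ("any", "peak", "all"):
        raise ValueError(f"min_n_rule must be any|peak|all, got {min_n_rule!r}")
    labels = np.asarray(labels)
    if labels.shape != powermap.min_n.shape:
        raise ValueError(
            f"label shape {labels.shape} != power map shape {powermap.min_n.shape}"
        )
    tmap = tmap or powermap.full_t
    safe = powermap.detection_pct >= powermap.safe_threshold - 1e-9

    rows = []
    for lab in range(1, int(labels.max()) + 1):
        member = labels == lab
        vox = np.argwhere(member)
        tvals = tmap.t[member]
        peak_flat = int(np.argmax(tvals))
        peak_vox = tuple(int(v) for v in vox[peak_flat])
        peak_mm = (powermap.affine @ np.array([*peak_vox, 1.0]))[:3]
        member_minn = powermap.min_n[member]
        defined = member_minn[member_minn > 0]
        if defined.size == 0:
            cluster_minn = NOT_SIGNIFICANT
        elif min_n_rule == "any":
            cluster_minn = int(defined.min())
        elif min_n_rule == "all":
            cluster_minn = int(member_minn.max())
        else:
            cluster_minn = int(powermap.min_n[peak_vox])
        row = {
            "cluster_id": lab,
            "n_voxels": int(member.sum()),
            "peak_t": float(tvals[peak_flat]),
            "peak_i": peak_vox[0],
            "peak_j": peak_vox[1],
            "peak_k": peak_vox[2],
            "peak_x_mm": float(peak_mm[0]),
            "peak_y_mm": float(peak_mm[1]),
            "peak_z_mm": float(peak_mm[2]),
            "min_n": cluster_minn,
        }
        for si, m in enumerate(powermap.sizes):
            row[f"n_detected_at_{m}"] = int((safe[si] & member).sum())
        rows.append(row)
    return pd.DataFrame(rows)
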