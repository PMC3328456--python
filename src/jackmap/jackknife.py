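"""Jackknife planning and orchestration of reduced second-level designs.

Removing r of n subjects admits C(n, r) unique reduced designs — a number
that explodes quickly (leave-one-out of 39 gives 39 analyses; removing 5
gives over half a million).  Plans therefore cap the number of designs per
removal depth (default 100, so each reduced analysis contributes exactly 1%
to the overlap map) and sample combinations uniformly without replacement.
Sampling works on combination ranks in the combinatorial number system, so
astronomically large combination spaces are never materialized and every
subject has an even chance of being removed.

The collection of reduced analyses at one depth is the "third level" of a
group analysis, denoted L3^{n-r}: reliability of each voxel is read off the
overlap of the reduced thresholded maps.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np

from .glm import ThresholdConfig, ThresholdedMap, fit_and_threshold, fit_second_level
from .io import SubjectMapSet

__all__ = [
    "CombinationPlan",
    "L3Result",
    "count_combinations",
    "plan_reduced_designs",
    "run_l3",
]

DEFAULT_CAP = 100


def count_combinations(n: int, r: int) -> int:
    """Exact number of unique ways to remove r of n subjects, C(n, r).

    Computed in arbitrary precision; safe for any depth (e.g. C(39, 9) =
    211,915,132).
    """
    if n < 0 or r < 0 or r > n:
        raise ValueError(f"need 0 <= r <= n, got n={n}, r={r}")
    return comb(n, r)


def _unrank_combination(rank: int, n: int, r: int) -> tuple[int, ...]:
    """The rank-th r-combination of range(n) in lexicographic order."""
    out = []
    x = 0
    for i in range(r):
        while comb(n - 1 - x, r - 1 - i) <= rank:
            rank -= comb(n - 1 - x, r - 1 - i)
            x += 1
        out.append(x)
        x += 1
    return tuple(out)


@dataclass
class CombinationPlan:
    """The reduced designs to compute at one removal depth.

    ``subsets`` holds retained-subject index tuples (size n - r each);
    ``removed`` the complementary removed sets, in the same order.  When
    ``exhaustive`` the subsets are every combination exactly once, in
    lexicographic order of the removed set; otherwise they are ``cap``
    distinct combinations sampled uniformly without replacement under
    ``seed``.
    """

    n: int
    r: int
    c_max: int
    cap: int
    subsets: list[tuple[int, ...]]
    removed: list[tuple[int, ...]]
    seed: Optional[int]
    exhaustive: bool

    def __len__(self) -> int:
        return len(self.subsets)


def plan_reduced_designs(n: int, r: int, cap: int = DEFAULT_CAP,
                         seed: Optional[int] = None) -> CombinationPlan:
    """Enumerate or sample the reduced designs for removal depth r."""
    if not 1 <= r <= n - 2:
        raise ValueError(
            f"removal depth must satisfy 1 <= r <= n - 2 "
            f"(reduced designs need >= 2 subjects); got n={n}, r={r}"
        )
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")

    c_max = count_combinations(n, r)
    all_idx = frozenset(range(n))
    if c_max <= cap:
        removed = [tuple(c) for c in combinations(range(n), r)]
        exhaustive = True
    else:
        ranks = random.Random(seed).sample(range(c_max), cap)
        removed = [_unrank_combination(rk, n, r) for rk in ranks]
        exhaustive = False
    subsets = [tuple(sorted(all_idx - set(rm))) for rm in removed]
    return CombinationPlan(n=n, r=r, c_max=c_max, cap=cap, subsets=subsets,
                           removed=removed, seed=seed, exhaustive=exhaustive)


@dataclass
class L3Result:
    """Original plus reduced thresholded maps at one removal depth."""

    plan: CombinationPlan
    original_map: ThresholdedMap
    original_t: "np.ndarray"
    reduced_maps: list[ThresholdedMap] = field(default_factory=list)
    notation: str = ""

    def __post_init__(self):
        if not self.notation:
            self.notation = f"L3^{self.plan.n}-{self.plan.r}"
        if len(self.reduced_maps) != len(self.plan.subsets):
            raise ValueError(
                f"{len(self.reduced_maps)} reduced maps for "
                f"{len(self.plan.subsets)} planned subsets"
            )


def _design_seed(seed: Optional[int], tag: int) -> Optional[int]:
    """Stable per-design child seed (only used by permutation thresholding)."""
    if seed is None:
        return None
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2 ** 31))


def run_l3(
    maps: SubjectMapSet,
    r: int,
    config: ThresholdConfig = ThresholdConfig(),
    cap: int = DEFAULT_CAP,
    seed: Optional[int] = None,
    covariate_names: Sequence[str] = (),
    contrast: Optional[Sequence[float]] = None,
) -> L3Result:
    """Fit and threshold the original design and every planned reduced design.

    All designs use identical settings (contrast, covariates, threshold);
    covariates are re-centered within each retained subset.
    """
    n = maps.n_subjects
    min_size = max(2, len(covariate_names) + 2)
    if n - r < min_size:
        raise ValueError(
            f"removing {r} of {n} subjects leaves {n - r}, below the minimum "
            f"design size {min_size}"
        )
    plan = plan_reduced_designs(n, r, cap=cap, seed=seed)

    full = list(range(n))
    tmap, original = fit_and_threshold(
        maps, full, config, covariate_names, contrast,
        seed=_design_seed(seed, 0),
    )

    reduced = []
    for i, subset in enumerate(plan.subsets):
        try:
            _, thr = fit_and_threshold(
                maps, list(subset), config, covariate_names, contrast,
                seed=_design_seed(seed, i + 1),
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"reduced design {i} (removed subjects "
                f"{plan.removed[i]}) failed: {exc}"
            ) from exc
        reduced.append(thr)

    return L3Result(plan=plan, original_map=original, original_t=tmap.t,
                    reduced_maps=reduced)
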