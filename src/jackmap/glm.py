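"""Second-level mass-univariate GLM and voxelwise thresholding.

The group model is ordinary least squares per voxel of subject contrast
values on a design matrix ``X = [intercept | mean-centered nuisance
covariates]``, with the default contrast testing the intercept (group mean
activation > 0).  Covariates are re-centered within each analyzed subset:
every reduced design is a self-contained second-level analysis.

Inference is one-sided (activation) by default; thresholding offers no
correction, Bonferroni FWE, sign-flip max-t permutation FWE, or
Benjamini–Hochberg FDR over the mask voxels.  Bonferroni is a conservative
but assumption-free family-wise control; voxel counts will differ from
random-field-theory thresholds, and the permutation option is the less
conservative alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.stats import false_discovery_control

from .io import SubjectMapSet

__all__ = [
    "TMap",
    "ThresholdedMap",
    "ThresholdConfig",
    "fit_second_level",
    "p_values",
    "threshold_map",
]

THRESHOLD_METHODS = ("uncorrected", "fwe_bonferroni", "fwe_permutation", "fdr_bh")


@dataclass
class TMap:
    """Voxelwise t-statistics from one second-level fit.

    ``t`` is defined over the mask; voxels with zero residual variance are
    flagged in ``zero_variance`` (their t is +/-inf or nan, never silently
    propagated into p-values).  ``effect`` holds the contrast of the fitted
    coefficients (c'beta), used to resolve the sign of degenerate voxels.
    """

    t: np.ndarray
    df: int
    mask: np.ndarray
    contrast: np.ndarray
    zero_variance: np.ndarray
    effect: np.ndarray
    n: int
    covariate_names: tuple[str, ...] = ()
    design_rank: int = 1
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        if self.df <= 0:
            raise ValueError(f"degrees of freedom must be positive, got {self.df}")


@dataclass
class ThresholdedMap:
    """Binary significance map from one thresholded second-level analysis."""

    significant: np.ndarray
    method: str
    alpha: float
    n_tests: int
    mask: np.ndarray

    def __post_init__(self):
        self.significant = np.asarray(self.significant, dtype=bool)
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.method not in THRESHOLD_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if np.any(self.significant & ~self.mask):
            raise ValueError("significant voxels outside the mask")


@dataclass(frozen=True)
class ThresholdConfig:
    """How reduced designs are thresholded: method, alpha, permutation count."""

    method: str = "fwe_bonferroni"
    alpha: float = 0.05
    permutations: int = 1000
    two_sided: bool = False

    def __post_init__(self):
        if self.method not in THRESHOLD_METHODS:
            raise ValueError(
                f"method must be one of {THRESHOLD_METHODS}, got {self.method!r}"
            )
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


def _design_matrix(maps: SubjectMapSet, subset: Sequence[int],
                   covariate_names: Sequence[str]) -> np.ndarray:
    cov = maps.covariate_matrix(covariate_names)[list(subset)]
    if cov.shape[1]:
        cov = cov - cov.mean(axis=0, keepdims=True)
    return np.column_stack([np.ones(len(subset)), cov])


def fit_second_level(
    maps: SubjectMapSet,
    subset: Optional[Sequence[int]] = None,
    covariate_names: Sequence[str] = (),
    contrast: Optional[Sequence[float]] = None,
) -> TMap:
    """Fit the voxelwise one-sample GLM on a subject subset.

    Parameters
    ----------
    maps:
        The full map set.
    subset:
        Subject indices retained in this (possibly reduced) design;
        ``None`` keeps everyone.
    covariate_names:
        Nuisance covariate columns, mean-centered within the subset.
    contrast:
        Row vector over design columns; default tests the intercept.

    Returns
    -------
    TMap with ``t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c)`` and
    ``df = m - rank(X)`` for subset size m.
    """
    if subset is None:
        subset = list(range(maps.n_subjects))
    subset = list(subset)
    if len(set(subset)) != len(subset):
        raise ValueError("duplicate subject indices in subset")
    m = len(subset)
    n_cols = 1 + len(covariate_names)
    if m < n_cols + 1:
        raise ValueError(
            f"subset size {m} too small for design with {n_cols} columns"
        )

    X = _design_matrix(maps, subset, covariate_names)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns linearly dependent on the preceding ones
        dep = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                dep.append(covariate_names[j - 1])
        raise ValueError(f"rank-deficient design; dependent columns: {dep}")

    if contrast is None:
        c = np.zeros(X.shape[1])
        c[0] = 1.0
    else:
        c = np.asarray(contrast, dtype=np.float64)
        if c.shape != (X.shape[1],):
            raise ValueError(
                f"contrast length {c.size} != {X.shape[1]} design columns"
            )

    df = m - rank
    mask = maps.mask
    Y = maps.data[subset][:, mask]  # (m, n_vox)

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    ss_res = (resid ** 2).sum(axis=0)
    cvar = float(c @ xtx_inv @ c)
    effect_m = c @ beta

    # zero residual variance up to float round-off of the fit itself
    ss_tot = (Y ** 2).sum(axis=0)
    zero_var = ss_res <= 1e-24 * ss_tot
    sigma2 = ss_res / df
    se = np.sqrt(sigma2 * cvar)
    t_m = np.full(Y.shape[1], np.nan)
    np.divide(effect_m, se, out=t_m, where=~zero_var)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} mask voxels with zero residual variance",
            RuntimeWarning,
            stacklevel=2,
        )

    shape = maps.grid_shape
    t = np.zeros(shape)
    t[mask] = t_m
    effect = np.zeros(shape)
    effect[mask] = effect_m
    zv = np.zeros(shape, dtype=bool)
    zv[mask] = zero_var

    return TMap(
        t=t, df=df, mask=mask, contrast=c, zero_variance=zv, effect=effect,
        n=m, covariate_names=tuple(covariate_names), design_rank=rank,
        affine=maps.affine,
    )


def p_values(tmap: TMap, two_sided: bool = False) -> np.ndarray:
    """Student-t p-values per mask voxel (upper-tail by default).

    Zero-residual-variance voxels are degenerate: a strictly positive
    contrast effect there is detected with certainty (p = 0), anything else
    gets p = 1 (never significant), so noise-free inputs behave sensibly
    instead of producing spurious infinite t-values.
    """
    p = np.ones(tmap.t.shape)
    ok = tmap.mask & ~tmap.zero_variance
    if two_sided:
        p[ok] = 2.0 * stats.t.sf(np.abs(tmap.t[ok]), tmap.df)
    else:
        p[ok] = stats.t.sf(tmap.t[ok], tmap.df)
    degen = tmap.mask & tmap.zero_variance
    if two_sided:
        p[degen] = np.where(tmap.effect[degen] != 0, 0.0, 1.0)
    else:
        p[degen] = np.where(tmap.effect[degen] > 0, 0.0, 1.0)
    return p


def _permutation_fwe(tmap: TMap, maps: SubjectMapSet, subset: Sequence[int],
                     config: ThresholdConfig, seed: Optional[int]) -> np.ndarray:
    """Sign-flip max-t null distribution for one-sample FWE control.

    Subject maps in the subset are randomly multiplied by +/-1 and the
    design refit; the observed t is compared with the (1-alpha) quantile of
    the max statistic over the mask (max |t| when two-sided).
    """
    subset = list(subset)
    X = _design_matrix(maps, subset, tmap.covariate_names)
    xtx_inv = np.linalg.inv(X.T @ X)
    c = tmap.contrast
    cvar = float(c @ xtx_inv @ c)
    Y = maps.data[subset][:, maps.mask]
    df = tmap.df
    rng = np.random.default_rng(seed)

    max_t = np.empty(config.permutations)
    for b in range(config.permutations):
        signs = rng.choice([-1.0, 1.0], size=len(subset))
        Yb = Y * signs[:, None]
        beta = xtx_inv @ (X.T @ Yb)
        resid = Yb - X @ beta
        sigma2 = (resid ** 2).sum(axis=0) / df
        se = np.sqrt(sigma2 * cvar)
        with np.errstate(divide="ignore", invalid="ignore"):
            tb = (c @ beta) / se
        tb = tb[np.isfinite(tb)]
        if config.two_sided:
            tb = np.abs(tb)
        max_t[b] = tb.max() if tb.size else -np.inf

    crit = np.quantile(max_t, 1.0 - config.alpha, method="higher")
    obs = np.abs(tmap.t) if config.two_sided else tmap.t
    sig = np.zeros(tmap.t.shape, dtype=bool)
    ok = tmap.mask & ~tmap.zero_variance
    sig[ok] = obs[ok] >= crit
    # degenerate voxels: certain detection iff effect has the tested sign
    degen = tmap.mask & tmap.zero_variance
    if config.two_sided:
        sig[degen] = tmap.effect[degen] != 0
    else:
        sig[degen] = tmap.effect[degen] > 0
    return sig


def threshold_map(
    pvals: np.ndarray,
    mask: np.ndarray,
    method: str = "fwe_bonferroni",
    alpha: float = 0.05,
    tmap: Optional[TMap] = None,
    maps: Optional[SubjectMapSet] = None,
    subset: Optional[Sequence[int]] = None,
    permutations: int = 1000,
    seed: Optional[int] = None,
    two_sided: bool = False,
) -> ThresholdedMap:
    """Threshold a p-value volume with the chosen multiplicity control.

    Significance is the closed condition p <= alpha (after correction).
    ``fwe_permutation`` ignores ``pvals`` and needs ``tmap``, ``maps`` and
    ``subset`` to rebuild the sign-flip null.
    """
    if method not in THRESHOLD_METHODS:
        raise ValueError(f"method must be one of {THRESHOLD_METHODS}, got {method!r}")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    mask = np.asarray(mask, dtype=bool)
    n_tests = int(mask.sum())
    sig = np.zeros(mask.shape, dtype=bool)

    if method == "fwe_permutation":
        if tmap is None or maps is None or subset is None:
            raise ValueError(
                "fwe_permutation requires the fitted TMap, the SubjectMapSet "
                "and the subject subset"
            )
        cfg = ThresholdConfig(method=method, alpha=alpha,
                              permutations=permutations, two_sided=two_sided)
        sig = _permutation_fwe(tmap, maps, subset, cfg, seed)
    else:
        pm = pvals[mask]
        if method == "uncorrected":
            sig[mask] = pm <= alpha
        elif method == "fwe_bonferroni":
            sig[mask] = pm <= alpha / n_tests
        elif method == "fdr_bh":
            adj = false_discovery_control(np.clip(pm, 0.0, 1.0), method="bh")
            sig[mask] = adj <= alpha

    return ThresholdedMap(significant=sig, method=method, alpha=alpha,
                          n_tests=n_tests, mask=mask)


def fit_and_threshold(
    maps: SubjectMapSet,
    subset: Optional[Sequence[int]],
    config: ThresholdConfig,
    covariate_names: Sequence[str] = (),
    contrast: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
) -> tuple[TMap, ThresholdedMap]:
    """Convenience: fit one (reduced) design and threshold it."""
    tmap = fit_second_level(maps, subset, covariate_names, contrast)
    pvals = p_values(tmap, two_sided=config.two_sided)
    thr = threshold_map(
        pvals, maps.mask, method=config.method, alpha=config.alpha,
        tmap=tmap, maps=maps,
        subset=subset if subset is not None else list(range(maps.n_subjects)),
        permutations=config.permutations, seed=seed, two_sided=config.two_sided,
    )
    return tmap, thr
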