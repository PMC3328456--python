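"""Seeded synthetic cohorts of subject-level contrast volumes.

Each simulated subject map is a shared spatial activation pattern (a sum of
isotropic Gaussian blobs of graded amplitude) plus independent per-subject
Gaussian noise, optionally with nuisance covariates and with "deviant"
subjects whose finished maps are sign-inverted — the classic way of planting
a maximally inhomogeneous outlier in a group, since the inverted subject
activates where the group deactivates and vice versa.

With i.i.d. noise and no smoothing, the voxelwise one-sample t-statistic at
a blob center has noncentrality a*sqrt(n)/s for peak amplitude ``a``, noise
s.d. ``s`` and group size ``n``, so closed-form oracles hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import SubjectMapSet, write_volume

__all__ = ["Blob", "CohortSpec", "blob_template", "simulate_cohort", "write_cohort"]

#: blobs are truncated at this many s.d. from their center
BLOB_TRUNCATION_SD = 4.0


@dataclass(frozen=True)
class Blob:
    """One isotropic Gaussian activation focus.

    ``center`` in 0-based voxel indices, ``amplitude`` in arbitrary contrast
    units (the peak value), ``sigma`` the isotropic spatial s.d. in voxels.
    """

    center: tuple[int, int, int]
    amplitude: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"blob sigma must be positive, got {self.sigma}")


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort; identical specs regenerate identical data.

    Parameters
    ----------
    grid_shape:
        3-D voxel extents of the simulated volumes.
    n_subjects:
        Group size (>= 2).
    blobs:
        Activation foci shared by all subjects; each entry is a
        :class:`Blob` or a ``(center, amplitude, sigma)`` triple.
    noise_sd:
        Per-voxel between-subject standard deviation, same units as blob
        amplitude.
    covariates:
        ``None`` (no covariates), a list of column names (independent
        standard-normal nuisance columns are drawn), or a DataFrame with one
        row per subject.
    n_deviants:
        Number of subjects whose finished maps are multiplied by -1; they
        occupy the last positions of the subject order and are flagged in
        the manifest so tests can locate them deterministically.
    seed:
        Seed for all randomness in the cohort.
    noise_fwhm:
        Optional Gaussian smoothing (FWHM in voxels) of each subject's noise
        field for spatially correlated noise; off (0) by default so that
        closed-form t oracles hold.
    """

    grid_shape: tuple[int, int, int]
    n_subjects: int
    blobs: Sequence[Union[Blob, tuple]] = field(default_factory=list)
    noise_sd: float = 1.0
    covariates: Union[None, Sequence[str], pd.DataFrame] = None
    n_deviants: int = 0
    seed: int = 0
    noise_fwhm: float = 0.0

    def __post_init__(self):
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if len(self.grid_shape) != 3 or any(g < 1 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive extents, got {self.grid_shape}")
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if not 0 <= self.n_deviants < self.n_subjects:
            raise ValueError(
                f"n_deviants must satisfy 0 <= n_deviants < n_subjects, "
                f"got n_deviants={self.n_deviants}, n_subjects={self.n_subjects}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        self.blobs = [b if isinstance(b, Blob) else Blob(*b) for b in self.blobs]
        for b in self.blobs:
            if any(not 0 <= c < g for c, g in zip(b.center, self.grid_shape)):
                raise ValueError(
                    f"blob center {b.center} outside grid {self.grid_shape}"
                )
        if isinstance(self.covariates, pd.DataFrame):
            if len(self.covariates) != self.n_subjects:
                raise ValueError(
                    f"covariates table has {len(self.covariates)} rows for "
                    f"{self.n_subjects} subjects"
                )


def blob_template(grid_shape: Sequence[int],
                  blobs: Sequence[Blob]) -> np.ndarray:
    """Noise-free activation template: sum of truncated Gaussian kernels."""
    template = np.zeros(tuple(grid_shape))
    ii, jj, kk = np.meshgrid(*[np.arange(g) for g in grid_shape], indexing="ij")
    for b in blobs:
        d2 = ((ii - b.center[0]) ** 2
              + (jj - b.center[1]) ** 2
              + (kk - b.center[2]) ** 2)
        kernel = b.amplitude * np.exp(-d2 / (2.0 * b.sigma ** 2))
        kernel[d2 > (BLOB_TRUNCATION_SD * b.sigma) ** 2] = 0.0
        template += kernel
    return template


def simulate_cohort(spec: CohortSpec) -> SubjectMapSet:
    """Generate a seeded cohort of per-subject contrast volumes.

    Subject maps are the blob template plus i.i.d. Gaussian noise; the last
    ``n_deviants`` maps are sign-inverted *after* construction, so a deviant
    is the exact element-wise negation of the map the same seed would have
    produced without inversion.
    """
    rng = np.random.default_rng(spec.seed)
    template = blob_template(spec.grid_shape, spec.blobs)

    data = np.empty((spec.n_subjects,) + spec.grid_shape)
    for i in range(spec.n_subjects):
        noise = rng.standard_normal(spec.grid_shape)
        if spec.noise_fwhm > 0:
            sigma = spec.noise_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            noise = gaussian_filter(noise, sigma)
            sd = noise.std()
            if sd > 0:
                noise /= sd
        data[i] = template + spec.noise_sd * noise
    if spec.n_deviants:
        data[-spec.n_deviants:] *= -1.0

    subject_ids = [f"sub-{i + 1:03d}" for i in range(spec.n_subjects)]
    is_deviant = np.zeros(spec.n_subjects, dtype=bool)
    if spec.n_deviants:
        is_deviant[-spec.n_deviants:] = True

    cov = pd.DataFrame({"subject_id": subject_ids, "is_deviant": is_deviant})
    if isinstance(spec.covariates, pd.DataFrame):
        cov = pd.concat([cov, spec.covariates.reset_index(drop=True)], axis=1)
    elif spec.covariates is not None:
        for name in spec.covariates:
            cov[name] = rng.standard_normal(spec.n_subjects)

    return SubjectMapSet(
        data=data,
        subject_ids=subject_ids,
        mask=np.ones(spec.grid_shape, dtype=bool),
        affine=np.eye(4),
        covariates=cov,
    )


def write_cohort(maps: SubjectMapSet, out_dir: str | Path) -> pd.DataFrame:
    """Write one NIfTI volume per subject plus a TSV manifest.

    The manifest has columns subject_id, filename, is_deviant and any
    covariates; it round-trips through :func:`jackmap.io.load_map_set`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(maps.subject_ids):
        fname = f"{sid}.nii.gz"
        write_volume(maps.data[i], maps.affine, out / fname)
        rows.append({"subject_id": sid, "filename": fname})
    manifest = pd.DataFrame(rows)
    if maps.covariates is not None:
        extra = maps.covariates.drop(
            columns=[c for c in ("subject_id",) if c in maps.covariates],
        )
        manifest = pd.concat([manifest, extra.reset_index(drop=True)], axis=1)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False,
                    float_format="%.17g")
    return manifest
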