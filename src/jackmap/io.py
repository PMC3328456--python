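"""NIfTI volume and covariate-table I/O, and the aligned subject map stack.

Second-level (random-effects) fMRI analyses operate on one contrast
(parameter-estimate) image per subject, all resampled to a common voxel
grid.  :class:`SubjectMapSet` is the validated in-memory container for that
stack: an ``(n_subjects, x, y, z)`` array, subject identifiers, a boolean
analysis mask, the shared affine, and an optional per-subject covariate
table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SubjectMapSet",
    "AlignmentError",
    "load_map_set",
    "write_volume",
    "default_mask",
]

#: tolerance on affine entries when checking grid alignment
AFFINE_ATOL = 1e-4


class AlignmentError(ValueError):
    """Input volumes do not share a common voxel grid."""


@dataclass
class SubjectMapSet:
    """Aligned stack of per-subject contrast volumes.

    Parameters
    ----------
    data:
        Array of shape ``(n_subjects, x, y, z)`` holding the contrast values.
    subject_ids:
        Unique identifier per subject, in stack order.
    mask:
        Boolean volume of shape ``(x, y, z)``; analysis is restricted to
        mask-true voxels.
    affine:
        4x4 voxel-to-world matrix shared by all volumes.
    covariates:
        Optional table with one row per subject (nuisance regressors such as
        age, gender, handedness, plus bookkeeping columns).
    """

    data: np.ndarray
    subject_ids: list[str]
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(
                f"data must be 4-D (n_subjects, x, y, z); got shape {self.data.shape}"
            )
        n = self.data.shape[0]
        if n < 2:
            raise ValueError(f"need at least 2 subjects, got {n}")
        if len(self.subject_ids) != n:
            raise ValueError(
                f"{len(self.subject_ids)} subject_ids for {n} volumes"
            )
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid_shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != volume shape {self.grid_shape}"
            )
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.covariates is not None:
            if len(self.covariates) != n:
                raise ValueError(
                    f"covariate table has {len(self.covariates)} rows "
                    f"for {n} subjects"
                )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Return the named covariate columns as a float matrix (n x k)."""
        if not names:
            return np.empty((self.n_subjects, 0))
        if self.covariates is None:
            raise ValueError("map set has no covariate table")
        missing = [c for c in names if c not in self.covariates.columns]
        if missing:
            raise ValueError(f"covariates not found: {missing}")
        sub = self.covariates.loc[:, list(names)]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise ValueError(f"missing values in covariate columns: {bad}")
        return sub.to_numpy(dtype=np.float64)

    def subset(self, indices: Sequence[int]) -> "SubjectMapSet":
        """Return the map set restricted to the given subject indices."""
        idx = list(indices)
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate subject indices in subset")
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[idx].reset_index(drop=True)
        return SubjectMapSet(
            data=self.data[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            mask=self.mask,
            affine=self.affine,
            covariates=cov,
        )


def default_mask(data: np.ndarray) -> np.ndarray:
    """Voxels with finite values in every subject and non-zero variance.

    Stands in for the implicit analysis mask of a packaged second-level
    pipeline, which is otherwise analysis-dependent.
    """
    finite = np.isfinite(data).all(axis=0)
    var = np.zeros(data.shape[1:])
    var[finite] = data[:, finite].var(axis=0)
    return finite & (var > 0)


def _load_volumes(paths: Sequence[str | os.PathLike]):
    """Load volumes, splitting any 4-D file along its 4th axis."""
    vols: list[np.ndarray] = []
    ids: list[str] = []
    affines: list[tuple[str, np.ndarray, tuple]] = []
    for p in paths:
        img = nib.load(str(p))
        arr = np.asanyarray(img.dataobj, dtype=np.float64)
        base = os.path.basename(str(p))
        for suf in (".nii.gz", ".nii"):
            if base.endswith(suf):
                base = base[: -len(suf)]
                break
        if arr.ndim == 4:
            for j in range(arr.shape[3]):
                vols.append(arr[..., j])
                ids.append(f"{base}_{j:03d}")
                affines.append((str(p), img.affine, arr.shape[:3]))
        elif arr.ndim == 3:
            vols.append(arr)
            ids.append(base)
            affines.append((str(p), img.affine, arr.shape))
        else:
            raise AlignmentError(f"{p}: expected a 3-D or 4-D volume, got {arr.ndim}-D")
    return vols, ids, affines


def load_map_set(
    volume_paths: Sequence[str | os.PathLike],
    covariate_path: Optional[str | os.PathLike] = None,
    mask_path: Optional[str | os.PathLike] = None,
) -> SubjectMapSet:
    """Load per-subject contrast volumes into a validated :class:`SubjectMapSet`.

    Subject order follows the input list.  Covariates are matched by a
    ``subject_id`` column when present, otherwise by row order.  Without an
    explicit mask, voxels with finite values and non-zero between-subject
    variance form the analysis mask.
    """
    vols, ids, meta = _load_volumes(volume_paths)
    if len(vols) < 2:
        raise ValueError(f"need at least 2 volumes, got {len(vols)}")

    ref_path, ref_affine, ref_shape = meta[0]
    for path, affine, shape in meta[1:]:
        if tuple(shape) != tuple(ref_shape):
            raise AlignmentError(
                f"shape mismatch: {ref_path} has {tuple(ref_shape)}, "
                f"{path} has {tuple(shape)}"
            )
        if not np.allclose(affine, ref_affine, atol=AFFINE_ATOL):
            raise AlignmentError(
                f"affine mismatch between {ref_path} and {path} "
                f"(tolerance {AFFINE_ATOL})"
            )

    data = np.stack(vols, axis=0)

    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asanyarray(mimg.dataobj) > 0
        if mask.shape != data.shape[1:]:
            raise AlignmentError(
                f"mask shape {mask.shape} != volume shape {data.shape[1:]}"
            )
    else:
        mask = default_mask(data)

    cov = None
    if covariate_path is not None:
        sep = "\t" if str(covariate_path).endswith((".tsv", ".txt")) else ","
        cov = pd.read_csv(covariate_path, sep=sep, float_precision="round_trip")
        if "subject_id" in cov.columns:
            cov = (
                cov.set_index("subject_id")
                .reindex(ids)
                .reset_index()
            )
            if cov.drop(columns=["subject_id"]).isna().all(axis=1).any():
                unmatched = [
                    i for i, row in cov.iterrows()
                    if row.drop("subject_id").isna().all()
                ]
                raise ValueError(
                    f"covariate table rows could not be matched for subjects "
                    f"{[ids[i] for i in unmatched]}"
                )
        elif len(cov) != len(ids):
            raise ValueError(
                f"covariate table has {len(cov)} rows for {len(ids)} subjects"
            )

    return SubjectMapSet(data=data, subject_ids=ids, mask=mask,
                         affine=ref_affine, covariates=cov)


def write_volume(
    volume: np.ndarray,
    affine: np.ndarray,
    path: str | os.PathLike,
    reference_shape: Optional[tuple[int, ...]] = None,
) -> None:
    """Write a 3-D volume as NIfTI-1 with the reference affine.

    Integer-valued inputs (gPOM, reliability classes, cluster labels,
    minimum-n maps) are written as int32; everything else as float64.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {volume.ndim}-D")
    if reference_shape is not None and tuple(volume.shape) != tuple(reference_shape):
        raise ValueError(
            f"volume shape {volume.shape} does not match reference grid "
            f"{tuple(reference_shape)}"
        )
    if volume.dtype == bool or np.issubdtype(volume.dtype, np.integer):
        out = volume.astype(np.int32)
    else:
        out = volume.astype(np.float64)
    img = nib.Nifti1Image(out, np.asarray(affine, dtype=np.float64))
    nib.save(img, str(path))
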