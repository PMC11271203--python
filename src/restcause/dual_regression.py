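"""Two-stage dual regression of group spatial maps onto subject data.

Stage 1 regresses each time point's voxel vector on the group maps to get
subject-specific component time courses (T x K); stage 2 regresses each
voxel's time series on those (variance-normalized) time courses to get
subject-specific spatial maps (V x K).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10


@dataclass
class GroupMaps:
    """Group-level spatial maps (V voxels x K components) with a voxel mask."""

    maps: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be a voxels x components matrix")
        v, k = self.maps.shape
        if k >= v:
            raise ValueError(f"need more voxels than components (V={v}, K={k})")
        if self.mask is None:
            self.mask = np.ones(v, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (v,):
                raise ValueError("mask length must equal the number of voxels")
        zero_cols = np.flatnonzero(np.all(self.maps[self.mask] == 0, axis=0))
        if zero_cols.size:
            raise ValueError(f"all-zero map columns within mask: {zero_cols.tolist()}")

    @property
    def n_components(self) -> int:
        return self.maps.shape[1]


@dataclass
class SubjectMaps:
    """Subject-specific spatial maps (V x K), output of stage 2."""

    maps: np.ndarray
    subject_id: str | None = None


def _collinear_columns(design: np.ndarray) -> list[int]:
    """Identify columns made redundant by earlier ones (QR pivot diagnostic)."""
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.max() > 0 else 1.0
    return np.flatnonzero(diag < _RANK_TOL * scale).tolist()


def spatial_regression(
    subject_data: np.ndarray,
    group_maps: GroupMaps,
    demean: bool = True,
) -> np.ndarray:
    """Stage 1: project group maps onto a subject's data (V x T) -> T x K.

    Solves, for every time point, the least-squares regression of the voxel
    vector on the K map columns within the mask.  Map columns are demeaned
    over mask voxels by default, which absorbs an intercept.
    """
    subject_data = np.asarray(subject_data, dtype=float)
    if subject_data.ndim != 2:
        raise ValueError("subject_data must be a voxels x time matrix")
    if subject_data.shape[0] != group_maps.maps.shape[0]:
        raise ValueError(
            f"voxel mismatch: data has {subject_data.shape[0]} voxels, "
            f"maps have {group_maps.maps.shape[0]}"
        )
    design = group_maps.maps[group_maps.mask]
    data = subject_data[group_maps.mask]
    if demean:
        design = design - design.mean(axis=0)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValueError(f"group map matrix is rank deficient; collinear columns: {bad}")
    coeffs, *_ = np.linalg.lstsq(design, data, rcond=None)
    return coeffs.T  # T x K


def temporal_regression(
    subject_data: np.ndarray,
    timecourses: np.ndarray,
    variance_normalize: bool = True,
    subject_id: str | None = None,
) -> SubjectMaps:
    """Stage 2: regress each voxel's series on the component time courses.

    Time courses are demeaned and (by default) scaled to unit variance first,
    so the resulting map values are on a comparable scale across components.
    """
    subject_data = np.asarray(subject_data, dtype=float)
    timecourses = np.asarray(timecourses, dtype=float)
    if subject_data.shape[1] != timecourses.shape[0]:
        raise ValueError(
            f"time mismatch: data has {subject_data.shape[1]} volumes, "
            f"time courses have {timecourses.shape[0]}"
        )
    design = timecourses - timecourses.mean(axis=0)
    sd = design.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance time course for component index {zero.tolist()}")
    if variance_normalize:
        design = design / sd
    coeffs, *_ = np.linalg.lstsq(design, subject_data.T, rcond=None)
    return SubjectMaps(maps=coeffs.T, subject_id=subject_id)
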