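"""Dual regression: group templates -> subject time courses -> subject maps.

Stage 1 regresses the K group spatial templates into each timepoint's voxel
vector (templates as spatial regressors), yielding a T x K matrix of
subject-specific time courses.  Stage 2 uses those time courses (variance-
normalized by default, so the resulting maps encode both network shape and
amplitude) as temporal regressors for every voxel's series, yielding K
subject-specific spatial maps.  Both regressions demean data and design
instead of fitting an intercept, the standard formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import (
    BrainMask, CollinearityError, DegenerateInputError, DimensionError,
    InputError, VolumeSeries, pad_to_shape,
)

__all__ = [
    "SubjectTimeCourses", "SubjectMaps", "stage1_spatial_regression",
    "normalize_timecourses", "stage2_temporal_regression",
    "assemble_subject_stack", "dual_regress_subject",
]

_RCOND = 1e-10


@dataclass
class SubjectTimeCourses:
    """T x K subject-specific network time courses, in template order."""

    tcs: np.ndarray
    subject_id: str = ""
    normalized: bool = False
    scale_factors: np.ndarray | None = None   # per column, set by normalization


@dataclass
class SubjectMaps:
    """Padded per-subject stack of selected network maps: (C, H, W, D)."""

    maps: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.maps.ndim != 4:
            raise DimensionError("SubjectMaps.maps must be (C, H, W, D)")
        if not np.all(np.isfinite(self.maps)):
            raise DegenerateInputError("non-finite values in subject maps")


def _demean_cols(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=0, keepdims=True)


def _check_rank(design: np.ndarray, what: str) -> None:
    K = design.shape[1]
    rank = np.linalg.matrix_rank(design, tol=_RCOND * max(design.shape))
    if rank < K:
        # name the most collinear pairs to help the caller
        r = np.corrcoef(design.T)
        np.fill_diagonal(r, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(r)), r.shape)
        raise CollinearityError(
            f"{what} design is rank-deficient (rank {rank} < {K}); "
            f"components {i} and {j} are collinear (|r| = {abs(r[i, j]):.4f})",
            components=[int(i), int(j)])


def stage1_spatial_regression(templates: np.ndarray, subject: VolumeSeries,
                              mask: BrainMask) -> SubjectTimeCourses:
    """Stage 1: regress templates into the subject's data over space.

    ``templates`` is (K, V) on the mask.  For each timepoint the V-vector of
    voxel values is regressed on the K demeaned template maps; the OLS
    coefficients form the T x K time-course matrix.
    """
    K, V = templates.shape
    if K >= V:
        raise DimensionError(f"need K < V, got K = {K}, V = {V}")
    data = subject.flatten(mask).astype(float)      # (V, T)
    design = _demean_cols(templates.T)              # (V, K)
    _check_rank(design, "stage-1 (spatial)")
    Y = _demean_cols(data)                          # demean over voxels
    beta, *_ = np.linalg.lstsq(design, Y, rcond=_RCOND)   # (K, T)
    return SubjectTimeCourses(tcs=beta.T, subject_id=subject.subject_id)


def normalize_timecourses(stc: SubjectTimeCourses) -> SubjectTimeCourses:
    """Scale each column to unit variance, keeping the factors for reporting."""
    sd = stc.tcs.std(axis=0)
    if np.any(sd == 0):
        bad = list(np.where(sd == 0)[0])
        raise DegenerateInputError(f"zero-variance time course column(s): {bad}")
    return SubjectTimeCourses(tcs=stc.tcs / sd, subject_id=stc.subject_id,
                              normalized=True, scale_factors=sd.copy())


def stage2_temporal_regression(stc: SubjectTimeCourses, subject: VolumeSeries,
                               mask: BrainMask) -> np.ndarray:
    """Stage 2: per-voxel multiple regression on all K time courses jointly.

    Returns the (K, V) coefficient maps.
    """
    T, K = stc.tcs.shape
    if T <= K:
        raise InputError(f"need T > K time points, got T = {T}, K = {K}")
    if subject.n_timepoints != T:
        raise DimensionError("time courses and subject disagree on T")
    design = _demean_cols(stc.tcs)                  # (T, K)
    _check_rank(design, "stage-2 (temporal)")
    data = subject.flatten(mask).astype(float)      # (V, T)
    Y = data.T - data.mean(axis=1)                  # (T, V), demeaned per voxel
    beta, *_ = np.linalg.lstsq(design, Y, rcond=_RCOND)   # (K, V)
    return beta


def assemble_subject_stack(maps: np.ndarray, selected: list[int],
                           mask: BrainMask, pad_shape: tuple[int, int, int],
                           channel_names: list[str] | None = None,
                           subject_id: str = "") -> SubjectMaps:
    """Un-flatten selected maps to the grid, pad, and stack as CNN channels."""
    K = maps.shape[0]
    for i in selected:
        if not 0 <= i < K:
            raise InputError(f"selected component index {i} out of range 0..{K - 1}")
    grids = []
    for i in selected:
        vol = np.zeros(mask.mask.shape, dtype=float)
        vol[mask.mask] = maps[i]
        grids.append(pad_to_shape(vol, pad_shape))
    names = channel_names or [f"IC{i}" for i in selected]
    return SubjectMaps(maps=np.stack(grids), channel_names=list(names),
                       subject_id=subject_id)


def dual_regress_subject(templates: np.ndarray, subject: VolumeSeries,
                         mask: BrainMask, des_norm: bool = True,
                         ) -> tuple[SubjectTimeCourses, np.ndarray]:
    """Run both stages for one subject; ``des_norm`` toggles the stage-2
    variance normalization of the time courses (on by default, so stage-2
    maps encode shape and amplitude together)."""
    stc = stage1_spatial_regression(templates, subject, mask)
    stc2 = normalize_timecourses(stc) if des_norm else stc
    maps = stage2_temporal_regression(stc2, subject, mask)
    return stc, maps


def save_timecourses(stc: SubjectTimeCourses, path: str | Path) -> None:
    """Plain-text T x K matrix (rows = time, columns = components)."""
    np.savetxt(path, stc.tcs)


def load_timecourses(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, ndmin=2)
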