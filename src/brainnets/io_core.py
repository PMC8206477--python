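"""Core data model and I/O for the rs-fMRI network pipeline.

Defines the in-memory containers shared by every stage (4-D volume series,
brain masks, subject tables, study configuration), NIfTI reading/writing via
nibabel, grid padding, and the run manifest.  All spatial maps live in the
input image's native orientation; no reorientation is performed because the
pipeline assumes a single registered space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("brainnets")

__all__ = [
    "BrainnetsError", "InputError", "FormatError", "DimensionError",
    "DegenerateInputError", "ParameterError", "ConvergenceError",
    "CollinearityError", "ArchitectureError", "TrainingError", "NumericError",
    "VolumeSeries", "BrainMask", "SubjectTable", "StudyConfig",
    "read_volume_series", "write_volume_series", "pad_to_shape",
    "crop_to_shape", "compute_mask", "read_subject_table",
    "write_subject_table", "write_manifest",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class BrainnetsError(Exception):
    """Base class for all pipeline errors."""


class InputError(BrainnetsError):
    """Missing file, bad label, empty set — caller-supplied input is wrong."""


class FormatError(BrainnetsError):
    """File exists but is not a readable NIfTI / CSV of the expected layout."""


class DimensionError(BrainnetsError):
    """Shape or grid mismatch between objects that must share geometry."""


class DegenerateInputError(BrainnetsError):
    """Input is structurally valid but carries no usable signal."""


class ParameterError(BrainnetsError):
    """A numeric parameter is outside its valid range."""


class ConvergenceError(BrainnetsError):
    """Iterative algorithm failed to converge."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter


class CollinearityError(BrainnetsError):
    """Rank-deficient design matrix; carries the offending column indices."""

    def __init__(self, message: str, components: list[int] | None = None):
        super().__init__(message)
        self.components = components or []


class ArchitectureError(BrainnetsError):
    """Model spec and input geometry are incompatible."""


class TrainingError(BrainnetsError):
    """Non-finite loss or other optimization failure."""


class NumericError(BrainnetsError):
    """Singular matrix or other numerical breakdown."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VolumeSeries:
    """One subject's 4-D scan: 3-D voxel grid x time.

    ``data`` has shape (X, Y, Z, T); a 3-D image is stored with T = 1.
    ``n_nonfinite_zeroed`` counts voxels whose values were non-finite on
    load and were replaced by zero.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_seconds: float
    affine: np.ndarray
    subject_id: str = ""
    n_nonfinite_zeroed: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise DimensionError(
                f"VolumeSeries requires 3-D or 4-D data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise DimensionError(f"empty axis in shape {self.data.shape}")
        nonfinite = ~np.isfinite(self.data)
        n_bad = int(nonfinite.sum())
        if n_bad:
            self.data = np.where(nonfinite, 0.0, self.data)
            self.n_nonfinite_zeroed += n_bad
            logger.warning("zeroed %d non-finite voxel values in subject %r",
                           n_bad, self.subject_id)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def flatten(self, mask: "BrainMask | None" = None) -> np.ndarray:
        """Return a (V, T) matrix of in-mask voxel time series."""
        if mask is None:
            return self.data.reshape(-1, self.n_timepoints)
        if mask.mask.shape != self.spatial_shape:
            raise DimensionError(
                f"mask shape {mask.mask.shape} != spatial shape {self.spatial_shape}")
        return self.data[mask.mask, :]

    def unflatten(self, flat: np.ndarray, mask: "BrainMask | None" = None) -> np.ndarray:
        """Inverse of :meth:`flatten` for one or more flattened volumes.

        ``flat`` may be (V,) or (K, V); returns the corresponding 3-D or
        (K, X, Y, Z) grid with out-of-mask voxels set to zero.
        """
        flat = np.asarray(flat)
        single = flat.ndim == 1
        rows = flat[np.newaxis, :] if single else flat
        if mask is None:
            out = rows.reshape(rows.shape[0], *self.spatial_shape)
        else:
            out = np.zeros((rows.shape[0], *self.spatial_shape), dtype=rows.dtype)
            out[:, mask.mask] = rows
        return out[0] if single else out


@dataclass
class BrainMask:
    """Boolean voxel-inclusion grid shared by a cohort."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise DimensionError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SubjectTable:
    """Cohort listing: one row per subject (id, group label, file path)."""

    frame: pd.DataFrame

    GROUPS = ("case", "control")

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "path"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"subject table missing columns {sorted(missing)}")
        if self.frame["subject_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["subject_id"].duplicated(), "subject_id"]
            raise InputError(f"duplicate subject ids: {sorted(set(dupes))}")
        bad = set(self.frame["group"]) - set(self.GROUPS)
        if bad:
            raise InputError(f"unknown group labels {sorted(bad)}; expected {self.GROUPS}")
        for g in self.GROUPS:
            if (self.frame["group"] == g).sum() == 0:
                raise InputError(f"group {g!r} is empty")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame["subject_id"])

    @property
    def labels(self) -> np.ndarray:
        """Binary labels: 1 = case, 0 = control, in table order."""
        return (self.frame["group"] == "case").to_numpy().astype(int)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class StudyConfig:
    """All tunable parameters of the pipeline, YAML round-trippable.

    Defaults follow the published recipe: 30 ICA components, 8 selected
    networks, 48x56x48 padded grid, Adam at 5e-4 with 0.1 decay after a
    10-epoch validation-loss plateau, batch 12, LeakyReLU slope 0.01,
    L2 1e-5, dropout 0.7, SE reduction ratio 16, ridge rho 0.1,
    5000 permutations at alpha 0.05.
    """

    n_ica_components: int = 30
    n_selected_networks: int = 8
    grid_pad_shape: tuple[int, int, int] = (48, 56, 48)
    seed: int = 0
    # training
    lr: float = 5e-4
    lr_decay_factor: float = 0.1
    lr_patience_epochs: int = 10
    batch_size: int = 12
    leaky_slope: float = 0.01
    l2_weight: float = 1e-5
    dropout: float = 0.7
    max_epochs: int = 150
    early_stop_patience: int = 30
    n_folds: int = 10
    width_multiplier: float = 1.0
    se_reduction: int = 16
    # netmats
    rho: float = 0.1
    n_perm: int = 5000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.grid_pad_shape = tuple(int(v) for v in self.grid_pad_shape)
        for name in ("n_ica_components", "n_selected_networks", "batch_size",
                     "max_epochs", "n_folds", "n_perm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ParameterError("dropout must be in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["grid_pad_shape"] = list(self.grid_pad_shape)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume_series(path: str | Path, subject_id: str | None = None) -> VolumeSeries:
    """Load a 3-D or 4-D NIfTI-1 file into a :class:`VolumeSeries`.

    3-D images come back with a degenerate time axis (T = 1).  Non-finite
    voxel values are zeroed and counted (logged).  Voxel sizes and TR are
    taken from the header zooms.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    try:
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises various types on corrupt input
        raise FormatError(f"cannot read {p} as NIfTI: {exc}") from exc
    if data.ndim not in (3, 4):
        raise FormatError(f"{p}: expected 3-D or 4-D image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if data.ndim == 4 and len(zooms) > 3 else 0.0
    sid = subject_id if subject_id is not None else p.name.split(".")[0]
    return VolumeSeries(data=data, voxel_size_mm=voxel_size, tr_seconds=tr,
                        affine=np.asarray(img.affine, dtype=float), subject_id=sid)


def write_volume_series(series: VolumeSeries, path: str | Path) -> None:
    """Write a VolumeSeries to NIfTI-1, preserving affine, zooms and TR."""
    data = series.data
    if data.shape[3] == 1:
        data = data[..., 0]
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), series.affine)
    zooms = list(series.voxel_size_mm)
    if data.ndim == 4:
        zooms.append(series.tr_seconds)
    img.header.set_zooms(tuple(zooms))
    nib.save(img, str(path))


def write_maps_nifti(maps: np.ndarray, mask: BrainMask, affine: np.ndarray,
                     path: str | Path) -> None:
    """Write K flattened maps (K, V) as one 4-D NIfTI with K volumes."""
    K = maps.shape[0]
    grid = np.zeros((*mask.mask.shape, K), dtype=np.float32)
    for k in range(K):
        grid[mask.mask, k] = maps[k]
    nib.save(nib.Nifti1Image(grid, affine), str(path))


# ---------------------------------------------------------------------------
# Grid padding
# ---------------------------------------------------------------------------

def _pad_widths(src: tuple[int, ...], target: tuple[int, ...]) -> list[tuple[int, int]]:
    widths = []
    for s, t in zip(src, target):
        if t < s:
            raise DimensionError(f"target {target} smaller than source {src}")
        total = t - s
        lo = total // 2          # odd split favors the low-index side
        widths.append((lo, total - lo))
    return widths


def pad_to_shape(volume: np.ndarray, target: tuple[int, int, int]) -> np.ndarray:
    """Center a 3-D map in a zero-filled grid of shape ``target``.

    The value sum is preserved; an odd padding amount puts the smaller pad
    on the low-index side.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise DimensionError("pad_to_shape expects a 3-D grid")
    widths = _pad_widths(volume.shape, tuple(target))
    return np.pad(volume, widths, mode="constant")


def crop_to_shape(volume: np.ndarray, source: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`pad_to_shape`: recover the centered source grid."""
    widths = _pad_widths(tuple(source), volume.shape)
    sl = tuple(slice(lo, lo + s) for (lo, _), s in zip(widths, source))
    return volume[sl]


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def compute_mask(series_list: list[VolumeSeries], method: str = "nonzero-intersection") -> BrainMask:
    """Common-voxel mask: in-mask iff temporal std > 0 in *every* subject."""
    if method != "nonzero-intersection":
        raise ParameterError(f"unknown mask method {method!r}")
    if not series_list:
        raise InputError("compute_mask needs at least one VolumeSeries")
    shape = series_list[0].spatial_shape
    mask = np.ones(shape, dtype=bool)
    for s in series_list:
        if s.spatial_shape != shape:
            raise DimensionError(
                f"subject {s.subject_id!r} shape {s.spatial_shape} != {shape}")
        mask &= s.data.std(axis=3) > 0
    if not mask.any():
        raise DegenerateInputError("empty brain mask: no voxel is active in all subjects")
    return BrainMask(mask=mask)


# ---------------------------------------------------------------------------
# Subject table + manifest
# ---------------------------------------------------------------------------

def read_subject_table(path: str | Path) -> SubjectTable:
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    try:
        frame = pd.read_csv(p, dtype={"subject_id": str})
    except Exception as exc:
        raise FormatError(f"cannot parse subject table {p}: {exc}") from exc
    return SubjectTable(frame=frame)


def write_subject_table(table: SubjectTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def write_manifest(out_dir: str | Path, config: StudyConfig, seed: int,
                   extra: dict | None = None) -> Path:
    """Write a run manifest (config + seed + package versions) next to outputs."""
    import brainnets
    manifest = {
        "config": {**asdict(config), "grid_pad_shape": list(config.grid_pad_shape)},
        "seed": int(seed),
        "versions": {
            "brainnets": brainnets.__version__,
            "numpy": np.__version__,
            "nibabel": nib.__version__,
        },
    }
    if extra:
        manifest["extra"] = extra
    path = Path(out_dir) / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
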