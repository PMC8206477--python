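"""Synthetic rs-fMRI cohort generator.

Emulates the structure of a single-site resting-state study: K latent
spatial networks (smooth Gaussian blobs on a small MNI-like grid), each
driven by a band-limited (0.01-0.1 Hz) time course with a prescribed
inter-network correlation structure, mixed bilinearly into voxel space and
degraded by AR(1) Gaussian voxel noise.  Group differences are injected as
(a) per-network amplitude multipliers, (b) integer-voxel spatial shifts of
the case-group maps, and (c) different inter-network coupling matrices.

The generated ground truth is exact: with ``noise_sigma = 0`` every voxel
series equals sum_k a_k * map_k(v) * tc_k(t) bitwise on the stored
precision, which is what dual regression assumes and what the recovery
tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .io_core import (
    DimensionError, InputError, NumericError, ParameterError, SubjectTable,
    VolumeSeries, write_subject_table, write_volume_series,
)

__all__ = [
    "SourceSpec", "EffectSpec", "CohortGroundTruth", "make_source_maps",
    "make_coupling", "make_time_courses", "synthesize_subject",
    "generate_cohort", "DEFAULT_GRID", "DEFAULT_T", "DEFAULT_TR",
]

# Desk-scale defaults: half-resolution analogue of the 48x56x48 padded grid,
# 180 volumes at TR = 2 s (a 6-minute scan).
DEFAULT_GRID = (24, 28, 24)
DEFAULT_T = 180
DEFAULT_TR = 2.0
BAND_HZ = (0.01, 0.1)

# Canonical network names, in the fixed channel order used downstream.
NETWORK_NAMES = ["PVN", "dDMN", "vDMN", "PCUN", "SMN", "SN", "LCEN", "RCEN"]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SourceSpec:
    """Geometry of the K latent networks."""

    K: int = 8
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    centers: np.ndarray | None = None   # (K, 3) voxel coordinates
    radii: np.ndarray | None = None     # (K,) gaussian sd in voxels
    overlap: bool = False

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ParameterError("SourceSpec.K must be >= 2")
        self.grid_shape = tuple(int(v) for v in self.grid_shape)

    def resolved_centers(self) -> np.ndarray:
        """Default centers: K points on an interior lattice, well separated."""
        if self.centers is not None:
            c = np.asarray(self.centers, dtype=float)
            if c.shape != (self.K, 3):
                raise ParameterError(f"centers must be ({self.K}, 3)")
            return c
        # lattice of m^3 candidate sites at fractions evenly inside [0.27, 0.73]
        m = int(np.ceil(self.K ** (1 / 3)))
        fracs = np.linspace(0.27, 0.73, m) if m > 1 else np.array([0.5])
        sites = np.array([(fx, fy, fz) for fx in fracs for fy in fracs for fz in fracs])
        sites = sites[: self.K]
        return sites * (np.asarray(self.grid_shape) - 1)

    def resolved_radii(self) -> np.ndarray:
        if self.radii is not None:
            r = np.broadcast_to(np.asarray(self.radii, dtype=float), (self.K,)).copy()
        else:
            r = np.full(self.K, min(self.grid_shape) / 10.0)
        if np.any(r <= 0):
            raise ParameterError("radii must be positive")
        return r


def _default_amplitude(K: int) -> np.ndarray:
    return np.ones(K)


@dataclass
class EffectSpec:
    """Group-difference injection parameters.

    ``amplitude_delta`` multiplies the case group's network amplitudes
    (1.0 = no change); ``shape_shift_voxels`` translates the case group's
    maps by an integer number of voxels along the first axis;
    ``coupling_case`` / ``coupling_control`` set the target inter-network
    time-course correlation matrices per group.
    """

    K: int = 8
    amplitude_delta: np.ndarray = None  # type: ignore[assignment]
    shape_shift_voxels: np.ndarray = None  # type: ignore[assignment]
    coupling_case: np.ndarray = None  # type: ignore[assignment]
    coupling_control: np.ndarray = None  # type: ignore[assignment]
    noise_sigma: float = 0.5
    ar1_coefficient: float = 0.3

    def __post_init__(self) -> None:
        K = self.K
        if self.amplitude_delta is None:
            self.amplitude_delta = np.ones(K)
        self.amplitude_delta = np.broadcast_to(
            np.asarray(self.amplitude_delta, dtype=float), (K,)).copy()
        if self.shape_shift_voxels is None:
            self.shape_shift_voxels = np.zeros(K, dtype=int)
        self.shape_shift_voxels = np.broadcast_to(
            np.asarray(self.shape_shift_voxels, dtype=int), (K,)).copy()
        if self.coupling_control is None:
            self.coupling_control = np.eye(K)
        if self.coupling_case is None:
            self.coupling_case = self.coupling_control.copy()
        for name in ("coupling_case", "coupling_control"):
            C = np.asarray(getattr(self, name), dtype=float)
            if C.shape != (K, K):
                raise ParameterError(f"{name} must be {K}x{K}")
            if not np.allclose(C, C.T, atol=1e-12):
                raise ParameterError(f"{name} must be symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-12):
                raise ParameterError(f"{name} must have a unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise NumericError(f"{name} is not positive semi-definite")
            setattr(self, name, C)
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ParameterError("ar1_coefficient must be in [0, 1)")

    @classmethod
    def strong(cls, K: int = 8, noise_sigma: float = 0.3) -> "EffectSpec":
        """The strong-effect study condition used for separability checks.

        Amplitude is doubled on three networks (the dDMN / PCUN / SN
        analogues, channels 1, 3, 5) and three coupling edges differ by
        +/-0.4 between groups, mirroring the hyper-/hypo-connectivity
        pattern the analysis stage is meant to detect.
        """
        amp = np.ones(K)
        for k in (1, 3, 5):
            if k < K:
                amp[k] = 2.0
        ctrl_edges = {(i, j): r for (i, j), r in {(1, 3): 0.4}.items()
                      if max(i, j) < K}
        case_edges = {(i, j): r
                      for (i, j), r in {(1, 5): 0.4, (5, 6): 0.4}.items()
                      if max(i, j) < K}
        return cls(K=K,
                   amplitude_delta=amp,
                   coupling_control=make_coupling(K, ctrl_edges),
                   coupling_case=make_coupling(K, case_edges),
                   noise_sigma=noise_sigma)

    @classmethod
    def null(cls, K: int = 8, noise_sigma: float = 0.5) -> "EffectSpec":
        """No group difference at all (for calibration runs)."""
        return cls(K=K, noise_sigma=noise_sigma)


def signal_sd(maps: np.ndarray, amplitudes: np.ndarray | None = None) -> float:
    """Standard deviation of the noiseless signal over voxels and time.

    With unit-variance, (near-)uncorrelated time courses the signal variance
    at voxel v is sum_k (a_k m_k(v))^2; averaging over the grid gives the
    global signal power, so ``noise_sigma = signal_sd(maps)`` puts the
    whole-volume SNR at 1.
    """
    a = np.ones(maps.shape[0]) if amplitudes is None else np.asarray(amplitudes)
    return float(np.sqrt(np.mean(np.sum((a[:, None] * maps) ** 2, axis=0))))


def make_coupling(K: int, edges: dict[tuple[int, int], float]) -> np.ndarray:
    """Build a PSD correlation matrix: identity plus the given off-diagonal
    entries, shrunk toward identity if needed to restore PSD."""
    C = np.eye(K)
    for (i, j), r in edges.items():
        C[i, j] = C[j, i] = r
    lam = np.linalg.eigvalsh(C).min()
    if lam < 1e-8:
        # shrink off-diagonals until the smallest eigenvalue clears zero
        t = (1e-6 - lam) / (1.0 - lam)
        C = (1 - t) * C + t * np.eye(K)
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return C


# ---------------------------------------------------------------------------
# Source maps
# ---------------------------------------------------------------------------

def make_source_maps(spec: SourceSpec, seed: int) -> np.ndarray:
    """K Gaussian-profile blobs on the grid, flattened to a (K, V_full) matrix.

    Values lie in [0, 1]; profiles are truncated at 3 sd so each network is
    compact.  Centers are jittered by <= 1 voxel from the spec layout using
    the seed, keeping distinct networks nearly uncorrelated when overlap is
    disallowed.
    """
    rng = np.random.default_rng(seed)
    centers = spec.resolved_centers()
    radii = spec.resolved_radii()
    centers = centers + rng.uniform(-1.0, 1.0, size=centers.shape)
    shape = spec.grid_shape
    coords = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    maps = np.zeros((spec.K, int(np.prod(shape))))
    for k in range(spec.K):
        d2 = ((coords - centers[k]) ** 2).sum(axis=-1)
        blob = np.exp(-d2 / (2.0 * radii[k] ** 2))
        blob[d2 > (3.0 * radii[k]) ** 2] = 0.0
        if blob.max() <= 0:
            raise ParameterError(f"network {k}: blob does not fit the grid")
        maps[k] = (blob / blob.max()).ravel()
    if not spec.overlap:
        cc = np.corrcoef(maps)
        off = cc[~np.eye(spec.K, dtype=bool)]
        if np.abs(off).max() >= 0.3:
            raise ParameterError(
                "network blobs overlap too much for overlap=False; "
                "spread centers or shrink radii")
    return maps


# ---------------------------------------------------------------------------
# Time courses
# ---------------------------------------------------------------------------

def make_time_courses(T: int, tr_seconds: float, coupling: np.ndarray,
                      band: tuple[float, float] = BAND_HZ, seed: int = 0) -> np.ndarray:
    """Band-limited time courses with an exact target correlation matrix.

    White Gaussian noise is filtered in the frequency domain to the pass
    band, the empirical covariance is whitened exactly, and the target
    correlation is imposed through its symmetric matrix square root; columns
    are therefore zero-mean, unit-variance, band-limited, and carry exactly
    the requested sample correlation.
    """
    coupling = np.asarray(coupling, dtype=float)
    K = coupling.shape[0]
    if T < 2 * K:
        raise ParameterError(f"T = {T} too short for K = {K} (need T >= 2K)")
    evals, evecs = np.linalg.eigh(coupling)
    if evals.min() < -1e-10:
        raise NumericError("coupling matrix is not positive semi-definite")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((T, K))
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ParameterError("pass band contains no DFT frequency at this T/TR")
    X = np.fft.irfft(np.fft.rfft(x, axis=0) * keep[:, None], n=T, axis=0)
    X -= X.mean(axis=0)
    # exact whitening of the sample covariance
    cov = X.T @ X / T
    w, U = np.linalg.eigh(cov)
    if w.min() <= 1e-12:
        raise NumericError("degenerate filtered noise; increase T")
    X = X @ (U / np.sqrt(w)) @ U.T
    # color with the target correlation's symmetric square root
    L = (evecs * np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    Y = X @ L.T
    sd = Y.std(axis=0)
    sd[sd == 0] = 1.0
    return Y / sd


# ---------------------------------------------------------------------------
# Subject synthesis
# ---------------------------------------------------------------------------

def _apply_shape_shift(maps: np.ndarray, grid_shape: tuple[int, int, int],
                       shifts: np.ndarray) -> np.ndarray:
    """Translate each network's 3-D map by an integer voxel count along the
    first axis, zero-filling (no wrap-around)."""
    out = maps.copy()
    for k, s in enumerate(shifts):
        s = int(s)
        if s == 0:
            continue
        vol = maps[k].reshape(grid_shape)
        shifted = np.zeros_like(vol)
        if s > 0:
            shifted[s:] = vol[:-s]
        else:
            shifted[:s] = vol[-s:]
        out[k] = shifted.ravel()
    return out


def effective_maps(maps: np.ndarray, effect: EffectSpec, group: str,
                   grid_shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Return (shape-adjusted maps, amplitude vector) for a group."""
    if group == "case":
        return (_apply_shape_shift(maps, grid_shape, effect.shape_shift_voxels),
                effect.amplitude_delta.copy())
    if group == "control":
        return maps.copy(), np.ones(maps.shape[0])
    raise InputError(f"unknown group label {group!r}")


def synthesize_subject(maps: np.ndarray, tcs: np.ndarray, effect: EffectSpec,
                       group: str, grid_shape: tuple[int, int, int],
                       seed: int, tr_seconds: float = DEFAULT_TR,
                       subject_id: str = "") -> tuple[VolumeSeries, dict]:
    """Mix networks into a 4-D volume and add AR(1) voxel noise.

    Returns the VolumeSeries and a per-subject ground-truth record
    (effective maps, amplitudes, time courses, label) sufficient to
    recompute the noiseless signal exactly.
    """
    K, V = maps.shape
    T = tcs.shape[0]
    if tcs.shape[1] != K:
        raise DimensionError("maps and time courses disagree on K")
    if V != int(np.prod(grid_shape)):
        raise DimensionError("maps do not match grid_shape")
    eff_maps, amps = effective_maps(maps, effect, group, grid_shape)
    signal = (eff_maps.T * amps) @ tcs.T            # (V, T)
    if effect.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        phi = effect.ar1_coefficient
        if phi > 0:
            # stationary AR(1): x_0 ~ N(0, sigma^2), x_t = phi x_{t-1} + e_t
            innov_sd = effect.noise_sigma * np.sqrt(1.0 - phi ** 2)
            x0 = rng.standard_normal(V) * effect.noise_sigma
            eps = rng.standard_normal((V, T - 1)) * innov_sd
            rest, _ = lfilter([1.0], [1.0, -phi], eps, axis=1,
                              zi=(phi * x0)[:, None])
            noise = np.concatenate([x0[:, None], rest], axis=1)
        else:
            noise = rng.standard_normal((V, T)) * effect.noise_sigma
        data = signal + noise
    else:
        data = signal
    series = VolumeSeries(
        data=data.reshape(*grid_shape, T),
        voxel_size_mm=(4.0, 4.0, 4.0),
        tr_seconds=tr_seconds,
        affine=np.diag([4.0, 4.0, 4.0, 1.0]),
        subject_id=subject_id,
    )
    truth = {"maps": eff_maps, "amplitudes": amps, "tcs": tcs, "group": group}
    return series, truth


# ---------------------------------------------------------------------------
# Cohort ground truth
# ---------------------------------------------------------------------------

@dataclass
class CohortGroundTruth:
    """Exact generative record for a synthetic cohort.

    Per-subject true maps and time courses are recoverable through
    :meth:`true_maps` / :meth:`true_tcs`; the noiseless bilinear signal of
    any subject can be rebuilt exactly from these fields.
    """

    subject_ids: list[str]
    groups: list[str]
    grid_shape: tuple[int, int, int]
    tr_seconds: float
    maps_control: np.ndarray        # (K, V)
    maps_case: np.ndarray           # (K, V) after shape shift
    amplitudes_case: np.ndarray     # (K,)
    tcs: np.ndarray                 # (N, T, K)
    network_names: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.maps_control.shape[0]

    def true_maps(self, i: int) -> np.ndarray:
        return self.maps_case if self.groups[i] == "case" else self.maps_control

    def true_amplitudes(self, i: int) -> np.ndarray:
        return (self.amplitudes_case if self.groups[i] == "case"
                else np.ones(self.K))

    def true_tcs(self, i: int) -> np.ndarray:
        return self.tcs[i]

    def noiseless_signal(self, i: int) -> np.ndarray:
        """(V, T) noiseless data for subject i."""
        return (self.true_maps(i).T * self.true_amplitudes(i)) @ self.tcs[i].T

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "maps_control.npy", self.maps_control)
        np.save(d / "maps_case.npy", self.maps_case)
        np.save(d / "amplitudes_case.npy", self.amplitudes_case)
        np.save(d / "tcs.npy", self.tcs)
        meta = {
            "subject_ids": self.subject_ids,
            "groups": self.groups,
            "grid_shape": list(self.grid_shape),
            "tr_seconds": float(self.tr_seconds),
            "network_names": self.network_names,
        }
        (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "CohortGroundTruth":
        d = Path(directory)
        meta = yaml.safe_load((d / "meta.yaml").read_text())
        return cls(
            subject_ids=meta["subject_ids"],
            groups=meta["groups"],
            grid_shape=tuple(meta["grid_shape"]),
            tr_seconds=meta["tr_seconds"],
            maps_control=np.load(d / "maps_control.npy"),
            maps_case=np.load(d / "maps_case.npy"),
            amplitudes_case=np.load(d / "amplitudes_case.npy"),
            tcs=np.load(d / "tcs.npy"),
            network_names=meta.get("network_names", []),
        )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(n_case: int, n_control: int, spec: SourceSpec,
                    effect: EffectSpec, seed: int, out_dir: str | Path,
                    T: int = DEFAULT_T, tr_seconds: float = DEFAULT_TR,
                    write_files: bool = True,
                    ) -> tuple[SubjectTable, CohortGroundTruth, list[VolumeSeries]]:
    """Generate a labeled cohort of 4-D volumes plus its exact ground truth.

    Writes one NIfTI per subject, ``subjects.csv`` and a ``ground_truth/``
    archive under ``out_dir`` (unless ``write_files`` is False, in which
    case everything stays in memory).  Per-subject seeds are spawned
    deterministically from the master seed.
    """
    if n_case < 1 or n_control < 1:
        raise InputError("both groups need at least one subject")
    if spec.K != effect.K:
        raise DimensionError("SourceSpec.K != EffectSpec.K")
    out = Path(out_dir)
    if write_files:
        try:
            out.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise InputError(f"cannot create output directory {out}: {exc}") from exc

    ss = np.random.SeedSequence(seed)
    map_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    maps = make_source_maps(spec, seed=map_seed)
    maps_case = _apply_shape_shift(maps, spec.grid_shape, effect.shape_shift_voxels)

    groups = ["case"] * n_case + ["control"] * n_control
    n = len(groups)
    subject_ids = [f"sub-{i:03d}" for i in range(n)]
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2 * n)]
    tc_seeds, noise_seeds = child_seeds[:n], child_seeds[n:]

    names = (NETWORK_NAMES[: spec.K] if spec.K <= len(NETWORK_NAMES)
             else [f"NET{k}" for k in range(spec.K)])

    all_tcs = np.empty((n, T, spec.K))
    series_list: list[VolumeSeries] = []
    rows = []
    for i, (sid, group) in enumerate(zip(subject_ids, groups)):
        coupling = (effect.coupling_case if group == "case"
                    else effect.coupling_control)
        tcs = make_time_courses(T, tr_seconds, coupling, seed=tc_seeds[i])
        all_tcs[i] = tcs
        series, _ = synthesize_subject(maps, tcs, effect, group,
                                       spec.grid_shape, seed=noise_seeds[i],
                                       tr_seconds=tr_seconds, subject_id=sid)
        path = out / f"{sid}.nii.gz"
        if write_files:
            write_volume_series(series, path)
        series_list.append(series)
        rows.append({"subject_id": sid, "group": group, "path": str(path)})

    table = SubjectTable(frame=pd.DataFrame(rows))
    truth = CohortGroundTruth(
        subject_ids=subject_ids, groups=groups, grid_shape=spec.grid_shape,
        tr_seconds=tr_seconds, maps_control=maps, maps_case=maps_case,
        amplitudes_case=effect.amplitude_delta.copy(), tcs=all_tcs,
        network_names=names,
    )
    if write_files:
        write_subject_table(table, out / "subjects.csv")
        truth.save(out / "ground_truth")
    return table, truth, series_list
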