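"""Temporal-concatenation group ICA.

Each subject's masked voxel series is demeaned and variance-normalized,
stacked in time, reduced to K dimensions by PCA, and unmixed with
fixed-point ICA (logcosh contrast, symmetric decorrelation) into K group
spatial maps.  Maps are z-scored over in-mask voxels and thresholded by a
Gaussian + two-Gamma mixture fit to the intensity histogram: a voxel
survives when its posterior probability of belonging to one of the Gamma
(signal) classes exceeds 1 - p, the local false-discovery-rate rule at
p < 0.5.

Sign/permutation ambiguity is fixed by forcing positive skewness on every
spatial map, so two runs with the same seed produce identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.special import digamma, polygamma, logsumexp
from scipy.stats import gamma as gamma_dist, norm, skew

from .io_core import (
    BrainMask, ConvergenceError, DegenerateInputError, DimensionError,
    InputError, ParameterError, VolumeSeries,
)

__all__ = [
    "ComponentSet", "MixtureFit", "temporal_concat", "pca_reduce",
    "ica_decompose", "z_transform_maps", "fit_gauss_gamma_mixture",
    "threshold_map",
]

# Gamma tails with shape <= 1 have non-vanishing density at zero, which
# would let the origin be called signal; MELODIC-style fits keep the
# signal classes strictly tail-like.
_MIN_GAMMA_SHAPE = 1.05
_MAX_GAMMA_SHAPE = 1e4


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ComponentSet:
    """K group-level spatial components with matching group time courses."""

    maps: np.ndarray                     # (K, V) raw spatial maps
    group_tcs: np.ndarray                # (sum_T, K) concatenated time courses
    zmaps: np.ndarray | None = None      # (K, V) z-scored maps
    threshold_masks: np.ndarray | None = None  # (K, V) boolean
    labels: list[str] | None = None      # per-component {"good", "artifact"}
    mixture_fits: list["MixtureFit"] | None = None

    def __post_init__(self) -> None:
        if self.maps.ndim != 2:
            raise DimensionError("maps must be (K, V)")
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(norms == 0):
            raise DegenerateInputError("a component map has zero norm")
        if self.group_tcs.shape[1] != self.maps.shape[0]:
            raise DimensionError("group_tcs columns must match number of maps")

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.maps.shape[1]


@dataclass
class MixtureFit:
    """Gaussian + two-Gamma mixture fit to a z-map histogram.

    The Gaussian models background noise around zero; the positive Gamma
    models the activation tail and the negative Gamma its mirror image.
    Weights sum to one; a class whose weight collapses during EM is dropped
    (weight pinned at 0) and listed in ``dropped``.
    """

    gauss_mean: float
    gauss_sd: float
    gauss_weight: float
    gamma_pos_shape: float
    gamma_pos_scale: float
    gamma_pos_weight: float
    gamma_neg_shape: float
    gamma_neg_scale: float
    gamma_neg_weight: float
    log_likelihood: list[float] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    n_iter: int = 0

    def _log_components(self, x: np.ndarray) -> np.ndarray:
        """(3, n) log of weight * class density at x; -inf where unsupported."""
        x = np.asarray(x, dtype=float)
        out = np.full((3, x.size), -np.inf)
        if self.gauss_weight > 0:
            out[0] = np.log(self.gauss_weight) + norm.logpdf(
                x, self.gauss_mean, self.gauss_sd)
        if self.gamma_pos_weight > 0:
            pos = x > 0
            out[1, pos] = np.log(self.gamma_pos_weight) + gamma_dist.logpdf(
                x[pos], self.gamma_pos_shape, scale=self.gamma_pos_scale)
        if self.gamma_neg_weight > 0:
            neg = x < 0
            out[2, neg] = np.log(self.gamma_neg_weight) + gamma_dist.logpdf(
                -x[neg], self.gamma_neg_shape, scale=self.gamma_neg_scale)
        return out

    def signal_posterior(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability that each value belongs to a Gamma class."""
        logc = self._log_components(x)
        logtot = logsumexp(logc, axis=0)
        with np.errstate(invalid="ignore"):
            post = np.exp(logsumexp(logc[1:], axis=0) - logtot)
        return np.where(np.isfinite(logtot), post, 0.0)

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.gauss_weight, self.gamma_pos_weight,
                         self.gamma_neg_weight])


# ---------------------------------------------------------------------------
# Concatenation and PCA
# ---------------------------------------------------------------------------

def temporal_concat(series_list: list[VolumeSeries], mask: BrainMask,
                    return_scales: bool = False,
                    ) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Stack subjects in time: (sum_T, V) with each subject's voxel series
    demeaned and variance-normalized within its own block.

    With ``return_scales`` the cohort-mean per-voxel standard deviation is
    also returned; multiplying component maps by it re-expresses them in
    data units (undoing the per-voxel normalization).
    """
    if not series_list:
        raise InputError("temporal_concat needs at least one subject")
    blocks = []
    scales = np.zeros(mask.n_voxels)
    for s in series_list:
        if s.spatial_shape != mask.mask.shape:
            raise DimensionError(
                f"subject {s.subject_id!r} does not match the mask grid")
        x = s.flatten(mask)                          # (V, T)
        x = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1)
        if np.any(sd == 0):
            raise DegenerateInputError(
                f"subject {s.subject_id!r} has flat voxels inside the mask")
        scales += sd / len(series_list)
        blocks.append((x / sd[:, None]).T)           # (T, V)
    concat = np.concatenate(blocks, axis=0)
    return (concat, scales) if return_scales else concat


def pca_reduce(concat: np.ndarray, K: int, seed: int = 0,
               exact_threshold: int = 800) -> tuple[np.ndarray, np.ndarray]:
    """Top-K spatial principal directions of the concatenated data.

    Returns (components (K, V) with orthonormal rows, singular values).
    Uses an exact SVD when the smaller matrix dimension is modest and a
    seeded randomized SVD otherwise.
    """
    n, V = concat.shape
    if K > min(n, V):
        raise ParameterError(f"K = {K} exceeds matrix rank bound {min(n, V)}")
    if min(n, V) <= exact_threshold:
        _, s, Vt = np.linalg.svd(concat, full_matrices=False)
        return Vt[:K], s[:K]
    from sklearn.utils.extmath import randomized_svd
    _, s, Vt = randomized_svd(concat, n_components=K, n_iter=7,
                              random_state=seed)
    return Vt, s


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

def ica_decompose(concat: np.ndarray, K: int, seed: int = 0,
                  max_iter: int = 1000, tol: float = 1e-6,
                  voxel_scales: np.ndarray | None = None) -> ComponentSet:
    """Spatial ICA on the concatenated data: K independent spatial maps.

    PCA-whitens to K dimensions, runs fixed-point ICA with symmetric
    decorrelation and the logcosh contrast over voxels, fixes each map's
    sign so its skewness is positive, and recovers group time courses by
    projecting the data onto the maps (pseudo-inverse).  ``voxel_scales``
    (from :func:`temporal_concat`) re-expresses the maps in data units
    before they are standardized, undoing the per-voxel variance
    normalization's compression of strong-signal voxels.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    if K < 2:
        raise ParameterError("K must be >= 2")
    n, V = concat.shape
    if n < K:
        raise ParameterError(f"need at least K = {K} rows, got {n}")

    Vt, _ = pca_reduce(concat, K, seed=seed)
    Z = Vt * np.sqrt(V)                       # rows: unit-variance over voxels

    ica = FastICA(algorithm="parallel", fun="logcosh", whiten=False,
                  max_iter=max_iter, tol=tol, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            sources = ica.fit_transform(Z.T)  # (V, K)
        except ConvergenceWarning as exc:
            raise ConvergenceError(
                f"fixed-point ICA did not converge within {max_iter} iterations",
                n_iter=max_iter) from exc

    maps = sources.T                          # (K, V)
    if voxel_scales is not None:
        maps = maps * voxel_scales[None, :]
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = maps / sd
    flip = np.where(skew(maps, axis=1) < 0, -1.0, 1.0)
    maps = maps * flip[:, None]
    group_tcs = concat @ np.linalg.pinv(maps)  # (sum_T, K)
    return ComponentSet(maps=maps, group_tcs=group_tcs)


def z_transform_maps(cset: ComponentSet) -> ComponentSet:
    """Standardize each spatial map to mean 0, sd 1 over in-mask voxels.

    Idempotent: re-applying to an already standardized set changes nothing.
    """
    mu = cset.maps.mean(axis=1, keepdims=True)
    sd = cset.maps.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = list(np.where(sd[:, 0] == 0)[0])
        raise DegenerateInputError(f"zero-variance component map(s): {bad}")
    cset.zmaps = (cset.maps - mu) / sd
    return cset


# ---------------------------------------------------------------------------
# Gaussian + 2 Gamma mixture
# ---------------------------------------------------------------------------

def _gamma_mle_shape(log_ratio: float) -> float:
    """Solve log(a) - digamma(a) = log_ratio for the Gamma shape a."""
    s = max(log_ratio, 1e-8)
    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(40):
        f = np.log(a) - digamma(a) - s
        fp = 1.0 / a - polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < 1e-12 * max(1.0, a):
            a = a_new
            break
        a = a_new
    return float(np.clip(a, _MIN_GAMMA_SHAPE, _MAX_GAMMA_SHAPE))


def _weighted_gamma_mle(x: np.ndarray, r: np.ndarray,
                        prev: tuple[float, float]) -> tuple[float, float]:
    """Weighted Gamma MLE (shape, scale); falls back to ``prev`` when the
    responsibility mass is too thin to estimate anything."""
    w = r.sum()
    if w < 1e-8:
        return prev
    m = float((r * x).sum() / w)
    mlog = float((r * np.log(x)).sum() / w)
    if m <= 0 or not np.isfinite(mlog):
        return prev
    log_ratio = np.log(m) - mlog
    if log_ratio <= 0:
        return prev
    a = _gamma_mle_shape(log_ratio)
    return a, m / a


def _init_fit(x: np.ndarray, tail_mult: float) -> MixtureFit:
    """Moment-based initialization: Gaussian from the interquartile core,
    Gammas from the tails beyond ``tail_mult`` robust standard deviations."""
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    core_sd = max((q75 - q25) / 1.349, 1e-3)

    def tail_init(vals: np.ndarray) -> tuple[float, float, float]:
        if vals.size < 10:
            return 2.0, core_sd, 0.02
        m, v = float(vals.mean()), float(max(vals.var(), 1e-6))
        a = np.clip(m * m / v, _MIN_GAMMA_SHAPE, _MAX_GAMMA_SHAPE)
        return float(a), m / a, max(vals.size / x.size, 0.01)

    cut = tail_mult * core_sd
    a_p, th_p, w_p = tail_init(x[x > q50 + cut] - 0.0)
    a_n, th_n, w_n = tail_init(-(x[x < q50 - cut]) - 0.0)
    w_g = max(1.0 - w_p - w_n, 0.5)
    tot = w_g + w_p + w_n
    return MixtureFit(
        gauss_mean=float(q50), gauss_sd=float(core_sd), gauss_weight=w_g / tot,
        gamma_pos_shape=a_p, gamma_pos_scale=max(th_p, 1e-3),
        gamma_pos_weight=w_p / tot,
        gamma_neg_shape=a_n, gamma_neg_scale=max(th_n, 1e-3),
        gamma_neg_weight=w_n / tot,
    )


def _em(x: np.ndarray, fit: MixtureFit, max_iter: int, tol: float,
        collapse_at: float = 1e-4) -> MixtureFit:
    n = x.size
    prev_ll = -np.inf
    for it in range(max_iter):
        logc = fit._log_components(x)
        logtot = logsumexp(logc, axis=0)
        ll = float(logtot.mean())
        fit.log_likelihood.append(ll)
        fit.n_iter = it + 1
        resp = np.exp(logc - logtot)          # (3, n)
        resp[~np.isfinite(resp)] = 0.0

        w = resp.sum(axis=1) / n
        # drop collapsed signal classes and keep going with the rest
        for idx, name in ((1, "gamma_pos"), (2, "gamma_neg")):
            if 0 < w[idx] < collapse_at:
                setattr(fit, f"{name}_weight", 0.0)
                fit.dropped.append(name)
                w[idx] = 0.0
        w = w / w.sum()
        fit.gauss_weight, fit.gamma_pos_weight, fit.gamma_neg_weight = map(float, w)

        wg = resp[0].sum()
        if wg > 1e-8:
            mu = float((resp[0] * x).sum() / wg)
            var = float((resp[0] * (x - mu) ** 2).sum() / wg)
            fit.gauss_mean, fit.gauss_sd = mu, float(np.sqrt(max(var, 1e-10)))
        if fit.gamma_pos_weight > 0:
            pos = x > 0
            fit.gamma_pos_shape, fit.gamma_pos_scale = _weighted_gamma_mle(
                x[pos], resp[1, pos],
                (fit.gamma_pos_shape, fit.gamma_pos_scale))
        if fit.gamma_neg_weight > 0:
            neg = x < 0
            fit.gamma_neg_shape, fit.gamma_neg_scale = _weighted_gamma_mle(
                -x[neg], resp[2, neg],
                (fit.gamma_neg_shape, fit.gamma_neg_scale))

        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return fit


def fit_gauss_gamma_mixture(zvalues: np.ndarray, max_iter: int = 200,
                            tol: float = 1e-7) -> MixtureFit:
    """Fit the Gaussian + two-Gamma mixture to z-map intensities by EM.

    Three moment-based restarts with increasingly strict tail cuts are run
    and the fit with the best final log-likelihood is kept.  The M-step
    uses exact weighted maximum likelihood (Newton on the Gamma shape), so
    the log-likelihood trace is non-decreasing.
    """
    x = np.asarray(zvalues, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise InputError("z values must be finite")
    if x.size < 50:
        raise InputError("too few values to fit a 3-class mixture")
    best: MixtureFit | None = None
    for tail_mult in (1.0, 1.5, 2.0):
        fit = _em(x, _init_fit(x, tail_mult), max_iter=max_iter, tol=tol)
        if best is None or fit.log_likelihood[-1] > best.log_likelihood[-1]:
            best = fit
    assert best is not None
    return best


def threshold_map(zmap: np.ndarray, fit: MixtureFit,
                  p_threshold: float = 0.5) -> np.ndarray:
    """Boolean signal mask: posterior P(Gamma class | z) > 1 - p_threshold,
    i.e. local false-discovery rate < p_threshold."""
    if not 0.0 < p_threshold < 1.0:
        raise ParameterError("p_threshold must lie in (0, 1)")
    return fit.signal_posterior(np.asarray(zmap, dtype=float)) > 1.0 - p_threshold


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_component_outputs(cset: ComponentSet, mask: BrainMask,
                           affine: np.ndarray, out_dir: str | Path) -> None:
    """Write maps and z-maps as 4-D NIfTI, time courses as plain text, and
    mixture fits as YAML."""
    from .io_core import write_maps_nifti
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_maps_nifti(cset.maps, mask, affine, out / "group_components.nii.gz")
    if cset.zmaps is not None:
        write_maps_nifti(cset.zmaps, mask, affine, out / "group_zmaps.nii.gz")
    np.savetxt(out / "group_timecourses.txt", cset.group_tcs)
    if cset.mixture_fits:
        fits = []
        for f in cset.mixture_fits:
            fits.append({
                "gaussian": {"mean": f.gauss_mean, "sd": f.gauss_sd,
                             "weight": f.gauss_weight},
                "gamma_pos": {"shape": f.gamma_pos_shape,
                              "scale": f.gamma_pos_scale,
                              "weight": f.gamma_pos_weight},
                "gamma_neg": {"shape": f.gamma_neg_shape,
                              "scale": f.gamma_neg_scale,
                              "weight": f.gamma_neg_weight},
                "n_iter": f.n_iter, "dropped": f.dropped,
            })
        (out / "mixture_fits.yaml").write_text(yaml.safe_dump(fits))
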