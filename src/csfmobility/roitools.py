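"""ROI construction and statistics for CSF-mobility maps.

Covers the CSF masking rules (signal threshold, excessive-change exclusion,
lonely-voxel removal), multiscale ridge filtering for perivascular-space
selection, distance-rim profiles around a segmented vessel, ROI descriptive
statistics with normal-theory confidence intervals, the nonparametric group
tests, and the visual-stimulation response metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import friedmanchisquare, mannwhitneyu, wilcoxon
from skimage.filters import frangi, meijering

from .errors import ConfigurationError

__all__ = ["MaskConfig", "RidgeConfig", "RimProfile", "csf_mask",
           "ridge_filter", "dilation_rims", "roi_stats", "nonparam_tests",
           "stim_response", "largest_cluster"]


@dataclass
class MaskConfig:
    csf_threshold: float = 150.0  # a.u.
    max_change: float = 50.0  # %
    remove_lonely: bool = True
    connectivity: int = 26  # 6 | 18 | 26

    def __post_init__(self) -> None:
        if self.csf_threshold <= 0 or self.max_change <= 0:
            raise ConfigurationError("thresholds must be > 0")
        if self.connectivity not in (6, 18, 26):
            raise ConfigurationError("connectivity must be 6, 18 or 26")


@dataclass
class RidgeConfig:
    mode: str = "frangi"  # or "meijering"
    sigmas: tuple[float, ...] = (0.6, 0.8, 1.0)  # mm
    vesselness_constant: float = 0.5
    threshold: float = 0.05  # response cutoff for the segmented mask

    def __post_init__(self) -> None:
        if self.mode not in ("frangi", "meijering"):
            raise ConfigurationError(f"unknown ridge mode {self.mode!r}")
        if any(s <= 0 for s in self.sigmas):
            raise ConfigurationError("sigmas must be > 0")


_CONN_RANK = {6: 1, 18: 2, 26: 3}


def _neighbor_counts(mask: np.ndarray, connectivity: int) -> np.ndarray:
    struct = ndimage.generate_binary_structure(3, _CONN_RANK[connectivity])
    struct = struct.copy()
    struct[1, 1, 1] = False
    return ndimage.convolve(mask.astype(np.uint8), struct.astype(np.uint8),
                            mode="constant", cval=0)


def csf_mask(reference: np.ndarray, change_volumes: list[np.ndarray] | None,
             cfg: MaskConfig) -> np.ndarray:
    """CSF inclusion mask from the non-motion-sensitized reference volume.

    Keeps voxels at or above the signal threshold, drops voxels whose
    percent change exceeds ``max_change`` in any provided change volume, and
    finally removes voxels with no included neighbor ("lonely" voxels) under
    the configured connectivity.  The threshold and change rules commute;
    lonely-voxel removal is a single final pass.
    """
    mask = np.asarray(reference, dtype=float) >= cfg.csf_threshold
    for cv in change_volumes or []:
        mask &= ~(np.abs(np.asarray(cv, dtype=float)) > cfg.max_change)
    if cfg.remove_lonely:
        mask &= _neighbor_counts(mask, cfg.connectivity) > 0
    return mask


def ridge_filter(volume: np.ndarray, cfg: RidgeConfig,
                 voxel_size: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Multiscale Hessian vesselness and its thresholded mask.

    Sigmas are given in mm and converted to voxels; the volume must be
    isotropic (resample anisotropic data first).  Frangi mode uses the
    plate/blob deviation terms with alpha = beta = ``vesselness_constant``;
    meijering mode is the neuriteness variant used for perivascular-space
    segmentation.
    """
    volume = np.asarray(volume, dtype=float)
    if np.isscalar(voxel_size):
        vs = float(voxel_size)
    else:
        vs = np.asarray(voxel_size, dtype=float)
        if not np.allclose(vs, vs.flat[0]):
            raise ConfigurationError("anisotropic voxels: resample first")
        vs = float(vs.flat[0])
    sigmas_vox = [s / vs for s in cfg.sigmas]
    if cfg.mode == "frangi":
        resp = frangi(volume, sigmas=sigmas_vox, alpha=cfg.vesselness_constant,
                      beta=cfg.vesselness_constant, black_ridges=False)
    else:
        resp = meijering(volume, sigmas=sigmas_vox, black_ridges=False)
    return resp, resp > cfg.threshold


def largest_cluster(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Largest connected component of a boolean volume."""
    struct = ndimage.generate_binary_structure(3, _CONN_RANK[connectivity])
    labels, n = ndimage.label(mask, structure=struct)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


@dataclass
class RimProfile:
    """Concentric distance rims around a vessel with per-rim map means."""

    distances: np.ndarray  # outer edge of each rim, mm
    mobility_mean: np.ndarray
    fa_mean: np.ndarray
    voxel_count: np.ndarray
    rims: list[np.ndarray] = field(default_factory=list)  # bool volumes


def dilation_rims(vessel_mask: np.ndarray, voxel_size: float,
                  csf: np.ndarray, mobility: np.ndarray,
                  fa: np.ndarray | None = None, step: float = 0.17,
                  max_dist: float = 3.00) -> RimProfile:
    """Per-rim mobility/FA means at increasing distance from a vessel.

    Rim k collects CSF voxels whose Euclidean distance to the vessel lies in
    ((k-1)*step, k*step], for k = 1..floor(max_dist/step).  The Euclidean
    distance transform implements the "inflation" (avoids the Chebyshev
    distortion of iterated structuring-element dilation at sub-voxel steps).
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not vessel_mask.any():
        raise ConfigurationError("empty vessel mask")
    if step < voxel_size:
        warnings.warn("rim step below the voxel size: rims may be empty",
                      stacklevel=2)
    dist = ndimage.distance_transform_edt(~vessel_mask,
                                          sampling=[voxel_size] * 3)
    n_rims = int(np.floor(max_dist / step))
    csf = np.asarray(csf, dtype=bool)
    distances = step * np.arange(1, n_rims + 1)
    mob_mean = np.full(n_rims, np.nan)
    fa_mean = np.full(n_rims, np.nan)
    counts = np.zeros(n_rims, dtype=int)
    rims: list[np.ndarray] = []
    for k in range(1, n_rims + 1):
        rim = (dist > (k - 1) * step) & (dist <= k * step) & csf & ~vessel_mask
        rims.append(rim)
        counts[k - 1] = int(rim.sum())
        if counts[k - 1]:
            mob_mean[k - 1] = float(np.mean(mobility[rim]))
            if fa is not None:
                fa_mean[k - 1] = float(np.mean(fa[rim]))
    return RimProfile(distances=distances, mobility_mean=mob_mean,
                      fa_mean=fa_mean, voxel_count=counts, rims=rims)


def roi_stats(values: np.ndarray, mask: np.ndarray | None = None) -> dict:
    """Mean, sample s.d. and CI half-width 1.96 * s.d. / sqrt(n).

    With a single observation the s.d. and CI are undefined and flagged.
    """
    values = np.asarray(values, dtype=float)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    values = values.ravel()
    n = len(values)
    if n == 0:
        raise ConfigurationError("empty mask")
    mean = float(np.mean(values))
    if n == 1:
        return {"mean": mean, "sd": np.nan, "ci_half_width": np.nan, "n": 1,
                "degenerate": True}
    sd = float(np.std(values, ddof=1))
    return {"mean": mean, "sd": sd,
            "ci_half_width": 1.96 * sd / np.sqrt(n), "n": n,
            "degenerate": False}


def nonparam_tests(samples: list[np.ndarray], design: str,
                   correction: int = 1) -> dict:
    """Nonparametric group comparison with optional Bonferroni correction.

    design:
        ``paired_multi``     Friedman test across >= 3 paired conditions.
        ``paired_two``       Two-sided Wilcoxon signed-rank (exact, n <= 25).
        ``independent_two``  Two-sided Mann-Whitney U (exact for small n).

    The Bonferroni-corrected p multiplies by ``correction``, capped at 1.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if any(len(s) < 3 for s in samples):
        raise ConfigurationError("need >= 3 observations per group")
    if design == "paired_multi":
        if len(samples) < 3:
            raise ConfigurationError("paired_multi needs >= 3 conditions")
        res = friedmanchisquare(*samples)
        stat, p = float(res.statistic), float(res.pvalue)
    elif design == "paired_two":
        a, b = samples
        d = a - b
        if np.all(d == 0):
            warnings.warn("all paired differences are zero", stacklevel=2)
            stat, p = 0.0, 1.0
        else:
            method = "exact" if len(d) <= 25 else "auto"
            res = wilcoxon(a, b, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
    elif design == "independent_two":
        a, b = samples
        method = "exact" if max(len(a), len(b)) <= 25 else "auto"
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ConfigurationError(f"unknown design {design!r}")
    return {"statistic": stat, "p_value": p,
            "p_corrected": min(1.0, p * correction)}


def stim_response(mobility_on: np.ndarray, mobility_off: np.ndarray,
                  roi_active: np.ndarray, roi_control: np.ndarray,
                  bold_timeseries: np.ndarray | None = None,
                  n_blocks: int = 3, n_dynamics: int = 20) -> dict:
    """Stimulation-induced mobility change and BOLD amplitude.

    Mobility change per ROI: 100 * (mean_on - mean_off) / mean_off.
    BOLD amplitude: after averaging the blocks, 100 * (mean of dynamics
    15-20 - mean of dynamics 5-10) / mean of dynamics 5-10 (1-based,
    inclusive).
    """
    out = {}
    for name, roi in (("active", roi_active), ("control", roi_control)):
        roi = np.asarray(roi, dtype=bool)
        if not roi.any():
            raise ConfigurationError(f"empty {name} ROI")
        on = float(np.mean(mobility_on[roi]))
        off = float(np.mean(mobility_off[roi]))
        out[f"{name}_change_pct"] = 100.0 * (on - off) / off
    if bold_timeseries is not None:
        ts = np.asarray(bold_timeseries, dtype=float).ravel()
        if len(ts) != n_blocks * n_dynamics:
            raise ConfigurationError(
                f"expected {n_blocks * n_dynamics} BOLD time points")
        block = ts.reshape(n_blocks, n_dynamics).mean(axis=0)
        baseline = float(np.mean(block[4:10]))  # dynamics 5-10, 1-based
        plateau = float(np.mean(block[14:20]))  # dynamics 15-20
        out["bold_amplitude_pct"] = 100.0 * (plateau - baseline) / baseline
    return out
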