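"""Reconstruction of per-phase magnitude volumes from binned k-space.

Two modes:

``zero_fill``
    Inverse centered Fourier transform of the mask-filled k-space (unsampled
    points set to zero), magnitude taken.  Baseline and initialization.

``tv``
    Joint reconstruction of the six phase images with total variation along
    the (cyclic) phase axis:

        min_x  sum_p || M_p o F x_p - y_p ||^2  +  lambda sum_v sum_p |x_{p+1,v} - x_{p,v}|

    solved by proximal gradient (ISTA): a gradient step on the data term
    (step size 1 = the inverse Lipschitz bound of the orthonormal masked
    Fourier operator) followed by the exact proximal map of the cyclic 1D TV,
    computed per voxel by a projected-gradient solve of its dual.  The
    iterate is kept real (single coil, real-valued object model), the
    iteration count is fixed, and the solve is fully deterministic.

    lambda is interpreted relative to the peak magnitude of the zero-filled
    initialization, so the default 0.005 is meaningful regardless of the
    arbitrary signal units (k-space is normalized internally and the result
    scaled back).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .binning import BinnedKSpace, N_PHASES
from .sampling import centered_fftn, centered_ifftn

__all__ = ["ReconConfig", "ImageSeries", "reconstruct", "cyclic_tv_prox"]


@dataclass
class ReconConfig:
    mode: str = "zero_fill"  # or "tv"
    lam: float = 0.005  # TV regularization weight (relative units, see above)
    iterations: int = 30
    step: float = 1.0  # gradient step; 1 = 1/Lipschitz for orthonormal F

    def __post_init__(self) -> None:
        if self.mode not in ("zero_fill", "tv"):
            raise ConfigurationError(f"unknown recon mode {self.mode!r}")
        if self.lam < 0:
            raise ConfigurationError("lambda must be >= 0")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")


@dataclass
class ImageSeries:
    """Magnitude volumes indexed along the first axis (phases or conditions)."""

    volumes: np.ndarray  # (n, X, Y, Z), non-negative
    voxel_size: float
    provenance: dict = field(default_factory=dict)
    objective: np.ndarray | None = None  # per-iteration objective (tv mode)

    def __post_init__(self) -> None:
        if np.any(self.volumes < 0):
            raise ConfigurationError("magnitudes must be non-negative")


def _zero_fill(kspace: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.empty(kspace.shape, dtype=complex)
    for p in range(kspace.shape[0]):
        out[p] = centered_ifftn(kspace[p] * mask[p][None, :, :])
    return out


def cyclic_tv_prox(z: np.ndarray, gamma: float, inner: int = 60,
                   p0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Proximal map of gamma * sum_p |x_{p+1} - x_p| (cyclic) along axis 0.

    Solved through the dual:  prox(z) = z - D^T p*,  with
    p* = argmin_{||p||_inf <= gamma} 1/2 ||z - D^T p||^2,
    by projected gradient with step 1/4 (||D||^2 = 4 for cyclic differences).
    Returns (prox, p*) so the dual variable can be warm-started.
    """
    if gamma <= 0:
        return z, np.zeros_like(z)
    p = np.zeros_like(z) if p0 is None else p0.copy()
    for _ in range(inner):
        x = z - (np.roll(p, 1, axis=0) - p)  # z - D^T p
        g = np.roll(x, -1, axis=0) - x  # D x
        p = np.clip(p + 0.25 * g, -gamma, gamma)
    return z - (np.roll(p, 1, axis=0) - p), p


def _tv_objective(x: np.ndarray, y: np.ndarray, mask: np.ndarray,
                  lam: float) -> float:
    data = 0.0
    for p in range(x.shape[0]):
        resid = mask[p][None, :, :] * centered_fftn(x[p]) - y[p]
        data += float(np.sum(np.abs(resid) ** 2))
    tv = float(np.sum(np.abs(np.roll(x, -1, axis=0) - x)))
    return data + lam * tv


def reconstruct(binned: BinnedKSpace, cfg: ReconConfig,
                voxel_size: float = 1.0) -> ImageSeries:
    """Reconstruct the six per-phase magnitude volumes of one subscan."""
    empty = [p + 1 for p in range(N_PHASES) if not binned.mask[p].any()]
    if empty:
        raise ConfigurationError(f"empty phase dataset(s): {empty}")

    y = binned.kspace * binned.mask[:, None, :, :]
    x0 = _zero_fill(y, binned.mask)

    if cfg.mode == "zero_fill":
        return ImageSeries(volumes=np.abs(x0), voxel_size=voxel_size,
                           provenance={"mode": "zero_fill"})

    scale = float(np.max(np.abs(x0)))
    if scale == 0:
        scale = 1.0
    lam = cfg.lam * scale
    x = x0.real.copy()
    tau = cfg.step
    obj = np.empty(cfg.iterations + 1)
    obj[0] = _tv_objective(x, y, binned.mask, lam)
    pdual = None
    for it in range(cfg.iterations):
        grad = np.empty_like(x)
        for p in range(N_PHASES):
            resid = binned.mask[p][None, :, :] * centered_fftn(x[p]) - y[p]
            grad[p] = centered_ifftn(binned.mask[p][None, :, :] * resid).real
        z = x - tau * grad
        x, pdual = cyclic_tv_prox(z, 0.5 * tau * lam, p0=pdual)
        obj[it + 1] = _tv_objective(x, y, binned.mask, lam)
    return ImageSeries(volumes=np.abs(x), voxel_size=voxel_size,
                       provenance={"mode": "tv", "lambda": cfg.lam,
                                   "iterations": cfg.iterations},
                       objective=obj)
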