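"""Oscillation analysis over the six physiological phases.

Per-phase mobility (or FA) maps are converted to percent-change profiles
relative to the across-phase mean, fitted voxel-wise to a single-cycle
sinusoid, gated on fit quality (R² >= 0.5), and summarized per ROI:
realigned mean profiles, the coherent-voxel fraction and the driving-force
amplitude (max - min of the profile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["PhaseProfile", "SineFitResult", "percent_change", "sine_fit",
           "phase_summaries"]

N_PHASES = 6
R2_GATE = 0.5

_K = np.arange(N_PHASES)
_SIN = np.sin(2 * np.pi * _K / N_PHASES)
_COS = np.cos(2 * np.pi * _K / N_PHASES)
# sum of sin² = sum of cos² = 3 over k = 0..5; the two regressors are orthogonal
_NORM = N_PHASES / 2.0


@dataclass
class PhaseProfile:
    """Per-voxel 6-vector of % change relative to the across-phase mean."""

    values: np.ndarray  # (6, X, Y, Z) or (6, n)
    valid: np.ndarray  # spatial mask


@dataclass
class SineFitResult:
    amplitude: np.ndarray  # % (>= 0)
    phase: np.ndarray  # radians
    r2: np.ndarray
    gated_amplitude: np.ndarray  # amplitude where r2 >= 0.5, else 0
    valid: np.ndarray


def percent_change(maps: np.ndarray, valid: np.ndarray | None = None) -> PhaseProfile:
    """100 * (m_k - mean) / mean per voxel; invalid where the mean is <= 0."""
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] != N_PHASES:
        raise ConfigurationError(f"expected {N_PHASES} phase maps")
    mean = maps.mean(axis=0)
    ok = mean > 0
    if valid is not None:
        ok = ok & valid
    safe = np.where(ok, mean, 1.0)
    values = np.where(ok[None], 100.0 * (maps - mean[None]) / safe[None], np.nan)
    return PhaseProfile(values=values, valid=ok)


def sine_fit(profile: PhaseProfile) -> SineFitResult:
    """Closed-form least-squares fit of y_k = a sin(2πk/6) + b cos(2πk/6).

    The data are zero-mean by construction, so no offset term is fitted.
    Amplitude A = sqrt(a² + b²), phase θ = atan2(b, a),
    R² = 1 - SS_res / SS_tot (defined 0 when SS_tot = 0).  Voxels with any
    non-finite input are invalid.
    """
    y = profile.values
    finite = np.all(np.isfinite(y), axis=0)
    valid = profile.valid & finite
    ys = np.where(finite[None], y, 0.0)
    shape_tail = (1,) * (ys.ndim - 1)
    s = _SIN.reshape((N_PHASES,) + shape_tail)
    c = _COS.reshape((N_PHASES,) + shape_tail)
    a = np.sum(ys * s, axis=0) / _NORM
    b = np.sum(ys * c, axis=0) / _NORM
    fit = a[None] * s + b[None] * c
    ss_res = np.sum((ys - fit) ** 2, axis=0)
    ss_tot = np.sum(ys**2, axis=0)  # data are zero-mean
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.where(ss_tot > 0, r2, 0.0)
    amp = np.hypot(a, b)
    theta = np.arctan2(b, a)
    gated = np.where(r2 >= R2_GATE, amp, 0.0)
    for arr in (amp, theta, r2, gated):
        arr[~valid] = 0.0
    return SineFitResult(amplitude=amp, phase=theta, r2=r2,
                         gated_amplitude=gated, valid=valid)


def phase_summaries(profile: PhaseProfile, fits: SineFitResult,
                    roi: np.ndarray) -> dict:
    """ROI summary of phase-resolved behavior.

    Returns the voxel-wise realigned mean profile (each voxel circularly
    shifted so its maximum lands at array index 0 = phase 1, whose value is
    flagged as discarded for plotting), the coherent-voxel fraction
    (R² > 0.5) and the ROI-mean driving amplitude (max - min per voxel).
    """
    roi = np.asarray(roi, dtype=bool)
    roi = roi & profile.valid
    if not roi.any():
        raise ConfigurationError("empty ROI")
    y = profile.values[:, roi]  # (6, n)
    n = y.shape[1]
    shift = np.argmax(y, axis=0)
    realigned = np.empty_like(y)
    for k in range(N_PHASES):
        sel = shift == k
        realigned[:, sel] = np.roll(y[:, sel], -k, axis=0)
    mean_profile = realigned.mean(axis=1)
    coherent = float(np.count_nonzero(fits.r2[roi] > R2_GATE)) / n
    driving = float(np.mean(y.max(axis=0) - y.min(axis=0)))
    return {
        "realigned_mean_profile": mean_profile,
        "discard_index": 0,  # phase 1 holds each voxel's maximum by construction
        "coherent_fraction": coherent,
        "driving_amplitude": driving,
        "n_voxels": n,
    }
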