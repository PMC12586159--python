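"""Mobility-tensor estimation from the seven subscans.

Per voxel, each encoded subscan i satisfies (noiselessly)

    -ln(S_i / S_0) / b = g_i^T D g_i,

a linear system in the six independent components of the symmetric tensor D.
With six well-chosen directions the 6x6 system is exactly determined and
solved by (unweighted) log-linear least squares.  The derived maps follow the
usual diffusion-tensor conventions: mobility = mean eigenvalue, fractional
anisotropy from the normalized eigenvalue dispersion, principal orientation =
leading eigenvector with a fixed sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .phantom import tensor6_to_mat, mat_to_tensor6

__all__ = ["TensorField", "design_matrix", "fit_tensor", "tensor_metrics",
           "fa_from_eigenvalues"]


def design_matrix(directions: np.ndarray) -> np.ndarray:
    """Per direction, the row mapping the (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)
    component vector to g^T D g: [gx², 2 gx gy, 2 gx gz, gy², 2 gy gz, gz²]."""
    g = np.asarray(directions, dtype=float)
    return np.stack(
        [g[:, 0] ** 2, 2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2],
         g[:, 1] ** 2, 2 * g[:, 1] * g[:, 2], g[:, 2] ** 2],
        axis=1,
    )


@dataclass
class TensorField:
    """Fitted per-voxel tensors plus derived scalar/vector maps."""

    tensor: np.ndarray  # (X, Y, Z, 6) mm²/s, after eigenvalue clamping
    eigenvalues: np.ndarray  # (X, Y, Z, 3), descending
    mobility: np.ndarray  # mean eigenvalue, mm²/s
    fa: np.ndarray
    e1: np.ndarray  # (X, Y, Z, 3) principal orientation, unit where valid
    valid: np.ndarray  # bool
    clamped: np.ndarray  # bool: negative eigenvalue was clamped to 0


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lam - mean|| / ||lam|| (0 for all-zero tensors)."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((evals - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(evals**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def _orient_sign(e1: np.ndarray) -> np.ndarray:
    """Fix eigenvector signs: non-negative z; ties broken by y, then x."""
    z = e1[..., 2]
    y = e1[..., 1]
    x = e1[..., 0]
    flip = (z < 0) | ((z == 0) & (y < 0)) | ((z == 0) & (y == 0) & (x < 0))
    return np.where(flip[..., None], -e1, e1)


def fit_tensor(volumes: np.ndarray, directions: np.ndarray, b: float,
               s0_threshold: float = 150.0) -> TensorField:
    """Fit the mobility tensor from 7 aligned volumes (reference first).

    Voxels whose reference signal falls below ``s0_threshold`` (or with
    non-positive signals anywhere) are marked invalid.  Negative eigenvalues
    are clamped to zero and flagged; the stored tensor is rebuilt from the
    clamped spectrum.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.shape[0] != 7:
        raise ConfigurationError("expected 7 volumes: reference + 6 encoded")
    if b <= 0:
        raise ConfigurationError("b must be > 0")
    B = design_matrix(directions)
    if B.shape[0] != 6 or np.linalg.matrix_rank(B) < 6:
        raise ConfigurationError("direction set is rank deficient")
    Binv = np.linalg.inv(B)

    s0 = volumes[0]
    enc = volumes[1:]
    valid = (s0 >= s0_threshold) & np.all(enc > 0, axis=0) & (s0 > 0)
    ratio = np.where(valid[None], enc / np.where(s0 > 0, s0, 1.0)[None], 1.0)
    yv = -np.log(np.clip(ratio, 1e-300, None)) / b  # (6, X, Y, Z)
    d6 = np.einsum("ij,j...->...i", Binv, yv)  # (X, Y, Z, 6)

    mats = tensor6_to_mat(d6)
    evals, evecs = np.linalg.eigh(mats)  # ascending
    clamped = np.any(evals < 0, axis=-1) & valid
    evals_cl = np.clip(evals, 0.0, None)
    tensor = mat_to_tensor6(
        np.einsum("...ij,...j,...kj->...ik", evecs, evals_cl, evecs))
    evals_desc = evals_cl[..., ::-1]
    e1 = _orient_sign(evecs[..., :, 2])  # eigenvector of the largest eigenvalue
    mobility = evals_desc.mean(axis=-1)
    fa = fa_from_eigenvalues(evals_desc)

    zero = ~valid
    for arr in (tensor, e1):
        arr[zero] = 0.0
    mobility[zero] = 0.0
    fa[zero] = 0.0
    evals_desc[zero] = 0.0
    return TensorField(tensor=tensor, eigenvalues=evals_desc, mobility=mobility,
                       fa=fa, e1=e1, valid=valid, clamped=clamped)


def tensor_metrics(field: TensorField, cutoff: float = 0.15) -> dict:
    """Mobility/FA/orientation maps with the high-mobility noise cutoff.

    Voxels with mobility above ``cutoff`` (mm²/s) are unphysiologically high
    (noise) and removed from the validity mask.
    """
    valid = field.valid & (field.mobility <= cutoff)
    return {
        "mobility": field.mobility,
        "fa": field.fa,
        "orientation": field.e1,
        "valid": valid,
        "clamped": field.clamped,
    }
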