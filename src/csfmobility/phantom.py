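"""Synthetic CSF-mobility phantoms and physiological traces.

The phantom emulates the contrast of a long-echo-time, CSF-selective
acquisition: bright CSF compartments (ventricle-like blobs, subarachnoid and
perivascular tubes) on a fully suppressed tissue/blood background.  Each
structure carries a ground-truth mobility tensor D0 (mm²/s) whose magnitude
oscillates sinusoidally with the cardiac and respiratory cycles,

    D(phi_c, phi_r) = D0 * [1 + A_c sin(2*pi*phi_c + psi)
                              + A_r sin(2*pi*phi_r + psi)],

a multiplicative, shape-preserving modulation: the eigenvectors and the
fractional anisotropy stay fixed while the mean eigenvalue (the "mobility")
oscillates by a few percent, the effect the downstream analysis must recover.

Coordinates are 0-based voxel indices; world coordinates are obtained through
a diagonal RAS affine with the isotropic voxel size.  All geometry is in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._rng import substream
from .errors import ConfigurationError, GeometryError

__all__ = [
    "StructureSpec",
    "PhantomSpec",
    "PhysioTraces",
    "PhantomTruth",
    "axial_eigenvalues",
    "make_phantom",
    "make_physio_traces",
    "modulation_scale",
    "modulate_tensors",
    "tensor6_to_mat",
    "mat_to_tensor6",
]

# Symmetric-tensor component order used throughout: Dxx, Dxy, Dxz, Dyy, Dyz, Dzz
TENSOR6_ORDER = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")


def tensor6_to_mat(t6: np.ndarray) -> np.ndarray:
    """(..., 6) component vector -> (..., 3, 3) symmetric matrix."""
    t6 = np.asarray(t6)
    m = np.empty(t6.shape[:-1] + (3, 3), dtype=t6.dtype)
    m[..., 0, 0] = t6[..., 0]
    m[..., 0, 1] = m[..., 1, 0] = t6[..., 1]
    m[..., 0, 2] = m[..., 2, 0] = t6[..., 2]
    m[..., 1, 1] = t6[..., 3]
    m[..., 1, 2] = m[..., 2, 1] = t6[..., 4]
    m[..., 2, 2] = t6[..., 5]
    return m


def mat_to_tensor6(m: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrix -> (..., 6) component vector."""
    m = np.asarray(m)
    return np.stack(
        [m[..., 0, 0], m[..., 0, 1], m[..., 0, 2],
         m[..., 1, 1], m[..., 1, 2], m[..., 2, 2]],
        axis=-1,
    )


@dataclass
class StructureSpec:
    """One CSF compartment: an ellipsoid blob or a cylindrical tube.

    ``base_mobility`` is the mean eigenvalue of the ground-truth tensor
    (mm²/s); ``fa`` the target fractional anisotropy in [0, 1); ``axis`` the
    principal mobility direction (unit vector, required for anisotropic
    structures); ``cardiac_amp``/``resp_amp`` the fractional oscillation
    amplitudes; ``spatial_phase`` a per-structure phase offset (rad).
    """

    kind: str  # "ellipsoid" | "tube"
    base_mobility: float
    fa: float = 0.0
    center: Sequence[float] | None = None  # mm, ellipsoid
    axes: Sequence[float] | None = None  # mm semi-axes, ellipsoid
    endpoints: Sequence[Sequence[float]] | None = None  # mm, tube
    radius: float | None = None  # mm, tube
    axis: Sequence[float] | None = None
    cardiac_amp: float = 0.0
    resp_amp: float = 0.0
    spatial_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ellipsoid", "tube"):
            raise ConfigurationError(f"unknown structure kind {self.kind!r}")
        if self.base_mobility < 0:
            raise ConfigurationError("base_mobility must be >= 0")
        if not 0.0 <= self.fa < 1.0:
            raise ConfigurationError("fa must be in [0, 1)")
        for a in (self.cardiac_amp, self.resp_amp):
            if not 0.0 <= a <= 0.5:
                raise ConfigurationError("modulation amplitudes must be in [0, 0.5]")
        if self.kind == "ellipsoid":
            if self.center is None or self.axes is None:
                raise ConfigurationError("ellipsoid needs center and axes")
        else:
            if self.endpoints is None or self.radius is None:
                raise ConfigurationError("tube needs endpoints and radius")
        if self.axis is not None:
            ax = np.asarray(self.axis, dtype=float)
            n = np.linalg.norm(ax)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise ConfigurationError("axis must have unit norm")
            self.axis = ax / n
        elif self.kind == "tube":
            p0, p1 = (np.asarray(p, dtype=float) for p in self.endpoints)
            d = p1 - p0
            self.axis = d / np.linalg.norm(d)
        elif self.fa > 0:
            raise ConfigurationError("anisotropic ellipsoid needs an explicit axis")


@dataclass
class PhantomSpec:
    """Grid geometry, contrast and noise level of a synthetic phantom."""

    grid_shape: tuple[int, int, int]
    voxel_size: float  # mm, isotropic
    structures: list[StructureSpec] = field(default_factory=list)
    csf_signal: float = 1000.0  # a.u.
    noise_sd: float | None = None  # complex-channel s.d.; default csf_signal/50
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n < 8 for n in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 integers, each >= 8")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be > 0")
        if self.csf_signal <= 0:
            raise ConfigurationError("csf_signal must be > 0")
        if self.noise_sd is None:
            self.noise_sd = self.csf_signal / 50.0
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        return aff


@dataclass
class PhysioTraces:
    """Surrogate cardiac/respiratory recordings with ground-truth peak times."""

    sample_rate: float  # Hz
    time: np.ndarray  # s
    cardiac: np.ndarray
    respiratory: np.ndarray
    cardiac_peaks: np.ndarray  # s, ground truth
    resp_peaks: np.ndarray  # s, ground truth

    @property
    def duration(self) -> float:
        return float(self.time[-1])


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom."""

    spec: PhantomSpec
    tensor0: np.ndarray  # (X, Y, Z, 6) mm²/s
    structure_masks: list[np.ndarray]  # per-structure bool volumes (disjoint)
    signal: np.ndarray  # (X, Y, Z) a.u., noiseless
    cardiac_amp: np.ndarray  # (X, Y, Z) fraction
    resp_amp: np.ndarray
    spatial_phase: np.ndarray  # rad

    @property
    def mask(self) -> np.ndarray:
        """Union of all structure masks."""
        out = np.zeros(self.signal.shape, dtype=bool)
        for m in self.structure_masks:
            out |= m
        return out


def axial_eigenvalues(mean_mobility: float, fa: float) -> tuple[float, float, float]:
    """Eigenvalues of the axially symmetric spectrum with given mean and FA.

    The (mean, FA) pair does not determine three eigenvalues uniquely; the
    generator uses the axially symmetric solution lam2 = lam3:

        lam1 = m (1 + 2 d),  lam2 = lam3 = m (1 - d),  d = FA / sqrt(3 - 2 FA²),

    which inverts the FA formula exactly for FA in [0, 1).
    """
    if not 0.0 <= fa < 1.0:
        raise ConfigurationError("fa must be in [0, 1)")
    d = fa / np.sqrt(3.0 - 2.0 * fa * fa)
    return (mean_mobility * (1 + 2 * d),
            mean_mobility * (1 - d),
            mean_mobility * (1 - d))


def _structure_tensor(s: StructureSpec) -> np.ndarray:
    """3x3 ground-truth tensor for one structure."""
    lam1, lam2, _ = axial_eigenvalues(s.base_mobility, s.fa)
    if s.fa == 0 or s.axis is None:
        return s.base_mobility * np.eye(3)
    n = np.asarray(s.axis, dtype=float)
    return lam2 * np.eye(3) + (lam1 - lam2) * np.outer(n, n)


def _voxel_grid_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = [np.arange(n) * spec.voxel_size for n in spec.grid_shape]
    return np.meshgrid(*ax, indexing="ij")


def _structure_mask(s: StructureSpec, spec: PhantomSpec) -> np.ndarray:
    X, Y, Z = _voxel_grid_mm(spec)
    extent = np.array([(n - 1) * spec.voxel_size for n in spec.grid_shape])
    if s.kind == "ellipsoid":
        c = np.asarray(s.center, dtype=float)
        a = np.asarray(s.axes, dtype=float)
        if np.any(c - a < -1e-9) or np.any(c + a > extent + 1e-9):
            raise GeometryError("ellipsoid extends outside the grid")
        r2 = (((X - c[0]) / a[0]) ** 2
              + ((Y - c[1]) / a[1]) ** 2
              + ((Z - c[2]) / a[2]) ** 2)
        return r2 <= 1.0
    p0, p1 = (np.asarray(p, dtype=float) for p in s.endpoints)
    for p in (p0, p1):
        if np.any(p - s.radius < -1e-9) or np.any(p + s.radius > extent + 1e-9):
            raise GeometryError("tube extends outside the grid")
    d = p1 - p0
    L2 = float(d @ d)
    px = X - p0[0]
    py = Y - p0[1]
    pz = Z - p0[2]
    t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / L2, 0.0, 1.0)
    dx = px - t * d[0]
    dy = py - t * d[1]
    dz = pz - t * d[2]
    return dx * dx + dy * dy + dz * dz <= s.radius**2


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Rasterize a phantom spec into ground-truth volumes.

    Overlapping structures are resolved in list order: a later structure
    overwrites earlier ones, and the stored per-structure masks are the
    post-resolution (disjoint) masks.  The noiseless signal is ``csf_signal``
    inside structures and exactly 0 outside (tissue and blood suppressed).
    """
    shape = spec.grid_shape
    tensor0 = np.zeros(shape + (6,), dtype=float)
    signal = np.zeros(shape, dtype=float)
    a_c = np.zeros(shape, dtype=float)
    a_r = np.zeros(shape, dtype=float)
    psi = np.zeros(shape, dtype=float)

    raw_masks = [_structure_mask(s, spec) for s in spec.structures]
    masks: list[np.ndarray] = []
    claimed = np.zeros(shape, dtype=bool)
    # later structure wins: walk in reverse, keep only unclaimed voxels
    for m in reversed(raw_masks):
        mm = m & ~claimed
        claimed |= mm
        masks.append(mm)
    masks.reverse()

    for s, m in zip(spec.structures, masks):
        D = _structure_tensor(s)
        tensor0[m] = mat_to_tensor6(D)
        signal[m] = spec.csf_signal
        a_c[m] = s.cardiac_amp
        a_r[m] = s.resp_amp
        psi[m] = s.spatial_phase

    return PhantomTruth(spec=spec, tensor0=tensor0, structure_masks=masks,
                        signal=signal, cardiac_amp=a_c, resp_amp=a_r,
                        spatial_phase=psi)


def _quasi_periodic_peaks(duration: float, rate: float, jitter: float,
                          rng: np.random.Generator) -> np.ndarray:
    period = 1.0 / rate
    n = int(np.ceil(duration * rate)) + 8
    # clip at 3 sigma so intervals stay positive for jitter < 1/3
    z = np.clip(rng.standard_normal(n), -3.0, 3.0)
    intervals = period * (1.0 + jitter * z)
    peaks = np.concatenate([[0.0], np.cumsum(intervals)])
    return peaks[peaks <= duration + period]


def _phase_from_peaks(peaks: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Linear intra-cycle phase in [0, 1); periodic extrapolation outside."""
    peaks = np.asarray(peaks, dtype=float)
    t = np.asarray(t, dtype=float)
    mean_T = float(np.mean(np.diff(peaks))) if len(peaks) > 1 else 1.0
    idx = np.searchsorted(peaks, t, side="right") - 1
    inside = (idx >= 0) & (idx < len(peaks) - 1)
    phi = np.empty_like(t)
    i = np.clip(idx, 0, len(peaks) - 2)
    phi_in = (t - peaks[i]) / (peaks[i + 1] - peaks[i])
    phi[:] = phi_in
    before = idx < 0
    after = idx >= len(peaks) - 1
    phi[before] = ((t[before] - peaks[0]) / mean_T) % 1.0
    phi[after] = ((t[after] - peaks[-1]) / mean_T) % 1.0
    phi[inside] = phi_in[inside] % 1.0
    return phi % 1.0


def make_physio_traces(duration: float, cardiac_rate: float = 1.0,
                       resp_rate: float = 0.25, jitter: float = 0.05,
                       seed: int = 0, sample_rate: float = 50.0) -> PhysioTraces:
    """Quasi-periodic cardiac/respiratory traces with known peak times.

    Inter-peak intervals are ``period * (1 + jitter * z)`` with z a clipped
    standard normal, so their coefficient of variation is approximately
    ``jitter``.  The traces themselves are cosines of the intra-cycle phase,
    peaking exactly at the stored ground-truth peak times.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    if cardiac_rate <= 0 or resp_rate <= 0:
        raise ConfigurationError("rates must be > 0")
    if not 0.0 <= jitter < 0.5:
        raise ConfigurationError("jitter must be in [0, 0.5)")
    if resp_rate >= cardiac_rate:
        raise ConfigurationError("resp_rate must be below cardiac_rate")

    rng = substream(seed, "traces")
    c_peaks = _quasi_periodic_peaks(duration, cardiac_rate, jitter, rng)
    r_peaks = _quasi_periodic_peaks(duration, resp_rate, jitter, rng)
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    cardiac = np.cos(2 * np.pi * _phase_from_peaks(c_peaks, t))
    respiratory = np.cos(2 * np.pi * _phase_from_peaks(r_peaks, t))
    return PhysioTraces(sample_rate=sample_rate, time=t, cardiac=cardiac,
                        respiratory=respiratory, cardiac_peaks=c_peaks,
                        resp_peaks=r_peaks)


def modulation_scale(truth: PhantomTruth, cardiac_phase: float,
                     resp_phase: float) -> np.ndarray:
    """Per-voxel multiplicative tensor scaling at the given phases."""
    for phi in (cardiac_phase, resp_phase):
        if not 0.0 <= phi < 1.0:
            raise ConfigurationError("phases must be in [0, 1)")
    s = (1.0
         + truth.cardiac_amp * np.sin(2 * np.pi * cardiac_phase + truth.spatial_phase)
         + truth.resp_amp * np.sin(2 * np.pi * resp_phase + truth.spatial_phase))
    if np.any(s[truth.mask] <= 0):
        raise ConfigurationError("modulation amplitudes too large: scale <= 0")
    return s


def modulate_tensors(truth: PhantomTruth, cardiac_phase: float,
                     resp_phase: float) -> np.ndarray:
    """Ground-truth tensor volume (X, Y, Z, 6) at the given physiological phases."""
    s = modulation_scale(truth, cardiac_phase, resp_phase)
    return truth.tensor0 * s[..., None]
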