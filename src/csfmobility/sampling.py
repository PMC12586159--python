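"""Acquisition geometry: motion-encoding directions, undersampled ky-kz
patterns, turbo-spin-echo (TSE) shot scheduling and the forward k-space
simulation of the seven subscans (1 reference + 6 motion-encoded).

Signal model
------------
Motion-sensitizing gradients attenuate the CSF signal like a low-b-value
apparent-diffusion measurement: for encoding direction g (unit vector) and
effective weighting b (s/mm²), the voxel signal of subscan i is

    S_i(v) = S(v) * exp(-b * g_i^T D(v) g_i),          S_0 = S (reference).

The readout direction (x) is fully sampled; undersampling happens on the
ky-kz phase-encode plane only.  k-space uses the centered (fft-shifted)
convention with the DC sample at floor(N/2) and an orthonormal FFT, so
Parseval's identity holds exactly between image and fully sampled k-space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from ._rng import substream
from .errors import ConfigurationError
from .phantom import PhantomTruth, PhysioTraces, _phase_from_peaks, modulation_scale

__all__ = [
    "AcquisitionConfig",
    "SamplingPattern",
    "ShotSchedule",
    "EncodedData",
    "encoding_directions",
    "b_from_venc",
    "make_pattern",
    "make_shot_schedule",
    "simulate_subscan",
    "simulate_acquisition",
    "centered_fftn",
    "centered_ifftn",
]

# Six dual-axis encoding directions: per-axis gradients played on two axes
# simultaneously, giving diagonal unit vectors.  Their outer products span
# the 6-dimensional space of symmetric tensors (full-rank design).
_DIRECTIONS = np.array(
    [[1, 1, 0], [1, -1, 0], [0, 1, 1], [0, 1, -1], [1, 0, 1], [-1, 0, 1]],
    dtype=float,
) / np.sqrt(2.0)


def encoding_directions(venc_axis: float = 5.0) -> tuple[np.ndarray, float]:
    """The dual-axis direction scheme and the effective encoding velocity.

    Playing a per-axis venc on two axes simultaneously shortens the
    effective venc by sqrt(2); the returned value is rounded to one decimal
    for reporting (5 -> 3.5 mm/s, 5.6 -> 4.0 mm/s).
    """
    eff = round(venc_axis / np.sqrt(2.0), 1)
    return _DIRECTIONS.copy(), eff


def b_from_venc(venc: float, kappa: float = 122.5) -> float:
    """Map an encoding velocity (mm/s) to an effective b-value (s/mm²).

    For a bipolar gradient pair, b scales with the inverse square of venc;
    the proportionality constant kappa depends on gradient timing and is
    exposed rather than asserted.  The default gives b = 10 s/mm² at the
    3.5 mm/s effective venc, which puts the 0.012-0.041 mm²/s mobility range
    at 10-35% signal attenuation.
    """
    if venc <= 0:
        raise ConfigurationError("venc must be > 0")
    return kappa / venc**2


@dataclass
class AcquisitionConfig:
    """Protocol parameters of a motion-encoded TSE acquisition."""

    grid: tuple[int, int] = (64, 64)  # (ky, kz)
    TR: float = 3.4  # s
    tse_factor: int = 146  # profiles per shot
    venc_axis: float = 5.0  # mm/s per-axis
    b_value: float = 10.0  # s/mm² effective encoding weight
    n_directions: int = 6
    pattern_mode: str = "pseudoradial"  # or "poisson"
    density_decay: float = 0.5
    acs_size: int = 29  # fully sampled square at k-space center
    accel_target: float = 17.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = tuple(int(n) for n in self.grid)
        if self.TR <= 0:
            raise ConfigurationError("TR must be > 0")
        if self.tse_factor < 1:
            raise ConfigurationError("tse_factor must be >= 1")
        if self.b_value <= 0:
            raise ConfigurationError("b_value must be > 0")
        if self.pattern_mode not in ("pseudoradial", "poisson"):
            raise ConfigurationError(f"unknown pattern_mode {self.pattern_mode!r}")
        if self.acs_size % 2 == 0 or self.acs_size > min(self.grid):
            raise ConfigurationError("acs_size must be odd and <= min(grid)")
        if self.accel_target < 1:
            raise ConfigurationError("accel_target must be >= 1")

    @property
    def directions(self) -> np.ndarray:
        return _DIRECTIONS.copy()


@dataclass
class SamplingPattern:
    """A set of unique (ky, kz) profiles on an integer grid."""

    profiles: np.ndarray  # (n, 2) int
    grid: tuple[int, int]
    acs_size: int

    @property
    def n_profiles(self) -> int:
        return len(self.profiles)

    @property
    def acceleration(self) -> float:
        return self.grid[0] * self.grid[1] / len(self.profiles)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid, dtype=bool)
        m[self.profiles[:, 0], self.profiles[:, 1]] = True
        return m


@dataclass
class ShotSchedule:
    """Profiles grouped into TSE shots; shot k starts at k * TR.

    The physiological state of a shot is evaluated at its start time, the
    instant of the magnetization preparation that encodes mobility for the
    whole echo train.
    """

    shot_profiles: list[np.ndarray]  # per shot, (m, 2) int profiles
    start_times: np.ndarray  # s
    TR: float
    grid: tuple[int, int]
    repeats: int = 1

    @property
    def n_shots(self) -> int:
        return len(self.shot_profiles)

    @property
    def duration(self) -> float:
        return float(self.start_times[-1]) + self.TR


def _acs_profiles(grid: tuple[int, int], acs_size: int) -> np.ndarray:
    cy, cz = grid[0] // 2, grid[1] // 2
    h = acs_size // 2
    ky, kz = np.meshgrid(np.arange(cy - h, cy + h + 1),
                         np.arange(cz - h, cz + h + 1), indexing="ij")
    return np.stack([ky.ravel(), kz.ravel()], axis=1)


def _norm_radius(grid: tuple[int, int]) -> np.ndarray:
    """Elliptically normalized k-space radius per grid point, capped at 1."""
    cy, cz = grid[0] // 2, grid[1] // 2
    ky, kz = np.meshgrid(np.arange(grid[0]), np.arange(grid[1]), indexing="ij")
    r = np.sqrt(((ky - cy) / max(cy, 1)) ** 2 + ((kz - cz) / max(cz, 1)) ** 2)
    return np.minimum(r, 1.0)


def _pseudoradial_pattern(cfg: AcquisitionConfig, target: int) -> np.ndarray:
    """Variable-density random pattern, inclusion probability ~ r^-decay.

    One uniform draw per grid point is fixed up front; the proportionality
    constant is then bisected so the included count hits the target, making
    the pattern deterministic for a given seed and monotone in the constant.
    """
    rng = substream(cfg.seed, "pattern")
    grid = cfg.grid
    u = rng.random(grid)
    r = _norm_radius(grid)
    with np.errstate(divide="ignore"):
        w = np.where(r > 0, r**(-cfg.density_decay), np.inf)
    acs = np.zeros(grid, dtype=bool)
    a = _acs_profiles(grid, cfg.acs_size)
    acs[a[:, 0], a[:, 1]] = True

    def count(c: float) -> int:
        inc = (u < np.minimum(1.0, c * w)) | acs
        return int(inc.sum())

    lo, hi = 0.0, 1.0
    while count(hi) < target:
        hi *= 2.0
        if hi > 1e6:
            break
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if count(mid) < target:
            lo = mid
        else:
            hi = mid
    inc = (u < np.minimum(1.0, hi * w)) | acs
    ky, kz = np.nonzero(inc)
    return np.stack([ky, kz], axis=1)


def _poisson_pattern(cfg: AcquisitionConfig, target: int) -> np.ndarray:
    """Poisson-disk pattern: minimum pairwise distance scaled to the target.

    The disk radius (in normalized units) is bisected until the number of
    kept grid points matches the target count; the ACS block is added on top.
    """
    grid = cfg.grid
    acs = _acs_profiles(grid, cfg.acs_size)
    base = int(substream(cfg.seed, "pattern").integers(2**31))

    def sample(radius: float) -> np.ndarray:
        eng = qmc.PoissonDisk(d=2, radius=radius,
                              seed=np.random.default_rng(base))
        pts = eng.fill_space()
        ij = np.unique(
            np.clip((pts * np.array(grid)).astype(int),
                    0, np.array(grid) - 1), axis=0)
        both = np.unique(np.concatenate([ij, acs], axis=0), axis=0)
        return both

    # initial guess from maximal-packing density in the unit square
    lo = 0.25 / np.sqrt(target)
    hi = 4.0 / np.sqrt(target)
    best = None
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        pts = sample(mid)
        if best is None or abs(len(pts) - target) < abs(len(best) - target):
            best = pts
        if abs(len(pts) - target) <= 0.01 * target:
            break
        if len(pts) > target:
            lo = mid  # too dense -> larger radius
        else:
            hi = mid
    return best


def make_pattern(cfg: AcquisitionConfig) -> SamplingPattern:
    """Generate the undersampled ky-kz profile set for one subscan."""
    area = cfg.grid[0] * cfg.grid[1]
    target = int(round(area / cfg.accel_target))
    if target < cfg.acs_size**2:
        raise ConfigurationError(
            "accel_target infeasible: fewer profiles than the ACS block")
    if cfg.accel_target == 1.0:
        ky, kz = np.meshgrid(np.arange(cfg.grid[0]), np.arange(cfg.grid[1]),
                             indexing="ij")
        profiles = np.stack([ky.ravel(), kz.ravel()], axis=1)
    elif cfg.pattern_mode == "pseudoradial":
        profiles = _pseudoradial_pattern(cfg, target)
    else:
        profiles = _poisson_pattern(cfg, target)
    return SamplingPattern(profiles=profiles, grid=cfg.grid, acs_size=cfg.acs_size)


def make_shot_schedule(pattern: SamplingPattern, cfg: AcquisitionConfig,
                       repeats: int = 1) -> ShotSchedule:
    """Group profiles into TSE shots ordered like pseudoradial spokes.

    Profiles are sorted by (azimuth, radius) about the k-space center, ties
    broken lexicographically on (ky, kz), then chunked into contiguous groups
    of at most ``tse_factor``.  With ``repeats`` > 1 the whole pattern is
    acquired that many times back to back (longer scan, same profile order),
    which is how the simulator reaches near-complete per-phase-bin coverage
    after retrospective binning.
    """
    if pattern.n_profiles == 0:
        raise ConfigurationError("pattern is empty")
    if repeats < 1:
        raise ConfigurationError("repeats must be >= 1")
    cy, cz = pattern.grid[0] // 2, pattern.grid[1] // 2
    p = pattern.profiles
    ang = np.arctan2(p[:, 1] - cz, p[:, 0] - cy)
    rad = np.hypot(p[:, 0] - cy, p[:, 1] - cz)
    order = np.lexsort((p[:, 1], p[:, 0], rad, ang))
    sorted_p = p[order]
    chunks = [sorted_p[i:i + cfg.tse_factor]
              for i in range(0, len(sorted_p), cfg.tse_factor)]
    shot_profiles = [c for _ in range(repeats) for c in chunks]
    start_times = np.arange(len(shot_profiles)) * cfg.TR
    return ShotSchedule(shot_profiles=shot_profiles, start_times=start_times,
                        TR=cfg.TR, grid=pattern.grid, repeats=repeats)


@dataclass
class EncodedData:
    """Complex k-space samples of one subscan, keyed by shot.

    ``samples[k]`` has shape (Nx, m_k): the full readout (kx) line for each
    of the shot's m_k (ky, kz) profiles.
    """

    samples: list[np.ndarray]
    schedule: ShotSchedule
    direction_index: int
    image_shape: tuple[int, int, int]

    @property
    def n_samples(self) -> int:
        return sum(s.shape[1] for s in self.samples)


def centered_fftn(x: np.ndarray) -> np.ndarray:
    """Orthonormal 3D FFT with DC at floor(N/2)."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x), norm="ortho"))


def centered_ifftn(k: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(k), norm="ortho"))


def simulate_subscan(truth: PhantomTruth, traces: PhysioTraces,
                     schedule: ShotSchedule, direction_index: int,
                     cfg: AcquisitionConfig) -> EncodedData:
    """Forward-simulate one subscan, shot by shot.

    For every shot the phantom image is attenuated according to the
    physiological phases at the shot start time, Fourier transformed, and
    sampled at the shot's profiles; complex Gaussian noise of s.d.
    ``truth.spec.noise_sd`` is added per k-space sample.
    """
    if not 0 <= direction_index <= 6:
        raise ConfigurationError("direction_index must be in 0..6")
    if schedule.duration > traces.duration + traces.sample_rate**-1 + schedule.TR:
        warnings.warn("schedule extends beyond the physiological traces; "
                      "phases are extrapolated periodically", stacklevel=2)

    shape = truth.signal.shape
    if direction_index == 0:
        q = np.zeros(shape)
    else:
        g = _DIRECTIONS[direction_index - 1]
        D = truth.tensor0
        # g^T D g expanded over the 6 symmetric components
        q = (D[..., 0] * g[0] * g[0] + D[..., 3] * g[1] * g[1]
             + D[..., 5] * g[2] * g[2] + 2 * D[..., 1] * g[0] * g[1]
             + 2 * D[..., 2] * g[0] * g[2] + 2 * D[..., 4] * g[1] * g[2])

    phi_c = _phase_from_peaks(traces.cardiac_peaks, schedule.start_times)
    phi_r = _phase_from_peaks(traces.resp_peaks, schedule.start_times)
    rng = substream(truth.spec.seed, "noise", child=direction_index)
    sd = truth.spec.noise_sd

    samples: list[np.ndarray] = []
    for k in range(schedule.n_shots):
        s = modulation_scale(truth, float(phi_c[k]), float(phi_r[k]))
        img = truth.signal * np.exp(-cfg.b_value * q * s)
        ksp = centered_fftn(img)
        prof = schedule.shot_profiles[k]
        vals = ksp[:, prof[:, 0], prof[:, 1]]
        if sd > 0:
            vals = vals + sd * (rng.standard_normal(vals.shape)
                                + 1j * rng.standard_normal(vals.shape))
        samples.append(vals)
    return EncodedData(samples=samples, schedule=schedule,
                       direction_index=direction_index, image_shape=shape)


def simulate_acquisition(truth: PhantomTruth, traces: PhysioTraces,
                         schedule: ShotSchedule,
                         cfg: AcquisitionConfig) -> list[EncodedData]:
    """All seven subscans (reference + 6 encoded) of one scan session."""
    return [simulate_subscan(truth, traces, schedule, i, cfg)
            for i in range(cfg.n_directions + 1)]
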