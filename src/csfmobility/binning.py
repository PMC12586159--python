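"""Retrospective physiological binning of k-space shots.

Each TSE shot is stamped with a cardiac, respiratory or random phase in
[0, 1), taken at the shot's preparation instant.  The six phase datasets come
from a two-step procedure: k-space is binned twice into three phases, with a
one-sixth phase shift between the two steps, and the results interleaved.
Equivalently, dataset d_k (k = 1..6) collects shots whose phase lies in the
half-open window of width 1/3 centered at (k-1)/6, wrapped modulo 1 — so every
shot lands in exactly two (adjacent) of the six datasets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from ._rng import substream
from .errors import ConfigurationError, SignalQualityError
from .phantom import PhysioTraces, _phase_from_peaks
from .sampling import EncodedData, ShotSchedule

__all__ = ["PhaseAssignment", "BinnedKSpace", "detect_peaks", "assign_bins",
           "bin_kspace", "phase_memberships"]

logger = logging.getLogger(__name__)

N_PHASES = 6
FORCES = ("cardiac", "respiratory", "random")


def detect_peaks(time: np.ndarray, trace: np.ndarray) -> np.ndarray:
    """Detect quasi-periodic peaks in a physiological trace.

    Two passes of local-maximum detection: a first pass with an adaptive
    prominence threshold (half the trace's standard deviation) estimates the
    median period; the second pass additionally enforces a minimum inter-peak
    distance of 0.4 x that period.  The start of the trace is padded so a
    maximum at the first sample is found; a rising edge cut off by the end of
    the recording is not a peak (no subsequent decline confirms it).

    Raises :class:`SignalQualityError` when fewer than two peaks are found.
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if len(time) != len(trace) or len(time) < 3:
        raise ConfigurationError("time and trace must be equal length >= 3")
    prominence = 0.5 * float(np.std(trace))
    padded = np.concatenate([[-np.inf], trace])
    idx, _ = find_peaks(padded, prominence=prominence if prominence > 0 else None)
    idx = idx - 1
    if len(idx) < 2:
        raise SignalQualityError("fewer than 2 peaks detected")
    dt = float(np.median(np.diff(time)))
    period = float(np.median(np.diff(time[idx])))
    distance = max(1, int(round(0.4 * period / dt)))
    idx, _ = find_peaks(padded, prominence=prominence if prominence > 0 else None,
                        distance=distance)
    idx = idx - 1
    if len(idx) < 2:
        raise SignalQualityError("fewer than 2 peaks detected")
    return time[idx]


def phase_memberships(phi: np.ndarray) -> np.ndarray:
    """Map phases in [0, 1) to their two (1-based) phase-dataset indices.

    The half-open windows [c - 1/6, c + 1/6) centered at c = (k-1)/6 overlap
    pairwise; a phase with floor(6 phi) = j belongs to datasets j+1 and j+2
    (cyclically).  Returns an (n, 2) integer array.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any((phi < 0) | (phi >= 1)):
        raise ConfigurationError("phases must be in [0, 1)")
    j = np.floor(phi * N_PHASES).astype(int)
    return np.stack([j % N_PHASES + 1, (j + 1) % N_PHASES + 1], axis=1)


@dataclass
class PhaseAssignment:
    """Per-shot phase and phase-dataset membership for one driving force."""

    force: str
    phases: np.ndarray  # (n_shots,), NaN for dropped shots
    memberships: np.ndarray  # (n_shots, 2) int, 1-based; 0 rows for dropped
    kept: np.ndarray  # (n_shots,) bool
    n_dropped: int = 0


def assign_bins(peaks: np.ndarray | None, schedule: ShotSchedule, force: str,
                seed: int = 0) -> PhaseAssignment:
    """Assign every shot a phase and its two phase-dataset memberships.

    For the physiological forces the phase is the linear interpolation
    between the two peaks bracketing the shot start time; shots before the
    first or after the last peak are dropped (with a warning / logged count).
    ``force='random'`` draws uniform phases from a seeded substream and
    applies the identical windowing.
    """
    if force not in FORCES:
        raise ConfigurationError(f"force must be one of {FORCES}")
    t = schedule.start_times
    n = len(t)
    kept = np.ones(n, dtype=bool)
    if force == "random":
        rng = substream(seed, "random_binning")
        phi = rng.random(n)
    else:
        peaks = np.asarray(peaks, dtype=float)
        if len(peaks) < 2:
            raise SignalQualityError("need at least 2 peaks to assign phases")
        kept = (t >= peaks[0]) & (t < peaks[-1])
        if not kept[0] and t[0] < peaks[0]:
            warnings.warn(f"{int((t < peaks[0]).sum())} shot(s) before the "
                          "first peak dropped", stacklevel=2)
        n_after = int((t >= peaks[-1]).sum())
        if n_after:
            logger.info("%d shot(s) beyond the last peak dropped", n_after)
        phi = np.full(n, np.nan)
        phi[kept] = _phase_from_peaks(peaks, t[kept])

    memberships = np.zeros((n, 2), dtype=int)
    memberships[kept] = phase_memberships(phi[kept])
    return PhaseAssignment(force=force, phases=phi, memberships=memberships,
                           kept=kept, n_dropped=int((~kept).sum()))


@dataclass
class BinnedKSpace:
    """Six per-phase k-space datasets for one subscan.

    ``kspace[p]`` holds the accumulated (duplicate-averaged) complex samples,
    ``mask[p]`` the binary ky-kz sampling mask and ``multiplicity[p]`` the
    per-profile sample count of phase dataset p+1.
    """

    kspace: np.ndarray  # (6, Nx, Nky, Nkz) complex
    mask: np.ndarray  # (6, Nky, Nkz) bool
    multiplicity: np.ndarray  # (6, Nky, Nkz) int
    direction_index: int


def bin_kspace(data: EncodedData, assignment: PhaseAssignment) -> BinnedKSpace:
    """Split one subscan's shots into the six phase datasets.

    A (ky, kz) profile sampled by several member shots of the same dataset is
    averaged (equal-noise samples; variance-optimal combination).
    """
    sched = data.schedule
    if len(assignment.phases) != sched.n_shots:
        raise ConfigurationError("assignment does not cover all shots")
    nx = data.samples[0].shape[0]
    ny, nz = sched.grid
    acc = np.zeros((N_PHASES, nx, ny, nz), dtype=complex)
    count = np.zeros((N_PHASES, ny, nz), dtype=int)
    for k in range(sched.n_shots):
        if not assignment.kept[k]:
            continue
        prof = sched.shot_profiles[k]
        vals = data.samples[k]
        for d in assignment.memberships[k]:
            p = d - 1
            # profiles are unique within a shot, so fancy-indexed += is exact
            acc[p][:, prof[:, 0], prof[:, 1]] += vals
            count[p][prof[:, 0], prof[:, 1]] += 1
    mask = count > 0
    safe = np.maximum(count, 1)
    kspace = acc / safe[:, None, :, :]
    return BinnedKSpace(kspace=kspace, mask=mask, multiplicity=count,
                        direction_index=data.direction_index)
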