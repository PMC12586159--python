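"""Shared fixtures: small phantoms and a module-scoped end-to-end run.

The end-to-end fixture simulates a full scan session once (48³ phantom,
12 acquisition passes, cardiac + random binning, zero-fill reconstruction,
tensor fit, phase-cycle analysis) and is shared by the amplitude-recovery
and binning-specificity tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import csfmobility as cm
from csfmobility.binning import assign_bins, bin_kspace, detect_peaks
from csfmobility.phasecycle import percent_change, sine_fit
from csfmobility.recon import ReconConfig, reconstruct
from csfmobility.sampling import (AcquisitionConfig, make_pattern,
                                  make_shot_schedule, simulate_subscan)
from csfmobility.tensorfit import fit_tensor, tensor_metrics


def small_phantom(n: int = 16, noise_sd: float = 0.0, seed: int = 0,
                  **tube_kwargs) -> cm.PhantomTruth:
    """A 2-structure phantom (anisotropic tube + isotropic blob)."""
    spec = cm.PhantomSpec(
        grid_shape=(n, n, n), voxel_size=0.5, noise_sd=noise_sd, seed=seed,
        structures=[
            cm.StructureSpec(kind="tube", endpoints=[(2, 3, 1), (2, 3, 6)],
                             radius=0.8, base_mobility=0.015, fa=0.716,
                             **tube_kwargs),
            cm.StructureSpec(kind="ellipsoid", center=(5, 1.8, 1.8),
                             axes=(1.2, 1.2, 1.2), base_mobility=0.02),
        ])
    return cm.make_phantom(spec)


def full_sampling_volumes(truth, cfg, traces, schedule):
    """Assemble all 7 subscan magnitude images from fully sampled k-space."""
    from csfmobility.sampling import centered_ifftn, simulate_subscan

    vols = []
    for i in range(7):
        sub = simulate_subscan(truth, traces, schedule, i, cfg)
        full = np.zeros(truth.signal.shape, dtype=complex)
        for k in range(schedule.n_shots):
            p = schedule.shot_profiles[k]
            full[:, p[:, 0], p[:, 1]] = sub.samples[k]
        vols.append(np.abs(centered_ifftn(full)))
    return np.stack(vols)


def run_phase_chain(truth, cfg, schedule, traces, subscans, assignment):
    """bin -> recon (zero-fill) -> fit -> percent change -> sine fit."""
    rcfg = ReconConfig(mode="zero_fill")
    vols = np.stack([reconstruct(bin_kspace(s, assignment), rcfg).volumes
                     for s in subscans])
    mob, valid = [], []
    for p in range(6):
        f = fit_tensor(vols[:, p], cfg.directions, cfg.b_value)
        m = tensor_metrics(f)
        mob.append(m["mobility"])
        valid.append(m["valid"])
    mob = np.stack(mob)
    valid = np.stack(valid).all(axis=0)
    prof = percent_change(mob, valid=valid)
    return prof, sine_fit(prof), valid


@pytest.fixture(scope="session")
def end_to_end():
    """Full simulated session at the study conditions (A_c = 3.2%)."""
    seed = 11
    n = 48
    spec = cm.PhantomSpec(
        grid_shape=(n, n, n), voxel_size=0.45, seed=seed,
        structures=[
            cm.StructureSpec(kind="tube", endpoints=[(6, 10, 2), (6, 10, 19)],
                             radius=1.4, base_mobility=0.041, fa=0.7,
                             cardiac_amp=0.032, resp_amp=0.012),
            cm.StructureSpec(kind="ellipsoid", center=(14, 6, 6), axes=(3, 3, 3),
                             base_mobility=0.02),
        ])
    truth = cm.make_phantom(spec)
    cfg = AcquisitionConfig(grid=(n, n), accel_target=1.0, acs_size=9,
                            tse_factor=146, seed=seed)
    pattern = make_pattern(cfg)
    schedule = make_shot_schedule(pattern, cfg, repeats=12)
    traces = cm.make_physio_traces(schedule.duration + 30.0, cardiac_rate=1.0,
                                   resp_rate=0.25, jitter=0.05, seed=seed)
    subscans = [simulate_subscan(truth, traces, schedule, i, cfg)
                for i in range(7)]
    peaks = detect_peaks(traces.time, traces.cardiac)
    results = {}
    for force, asg in (
            ("cardiac", assign_bins(peaks, schedule, "cardiac")),
            ("random", assign_bins(None, schedule, "random", seed=seed))):
        prof, fits, valid = run_phase_chain(truth, cfg, schedule, traces,
                                            subscans, asg)
        roi = truth.structure_masks[0] & valid
        results[force] = {
            "profile": prof, "fits": fits, "roi": roi,
            "coherent_fraction": float((fits.r2[roi] > 0.5).mean()),
            "gated_amplitude": float(fits.gated_amplitude[roi].mean()),
        }
    return {"truth": truth, "cfg": cfg, "cardiac_amp_pct": 3.2, **results}
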