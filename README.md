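# csfmobility

Simulation and analysis of **motion-encoded CSF-mobility MRI** — the class of
ultra-high-field acquisitions that isolate the cerebrospinal-fluid signal with
a long-echo-time T₂ preparation, attenuate it with motion-sensitizing
gradients, and fit a mobility tensor per voxel, down to the scale of
perivascular spaces.

## Who this is for

Researchers developing or validating CSF-mobility pipelines: retrospective
cardiac/respiratory k-space binning, compressed-sensing-style undersampling,
tensor estimation and the oscillation analytics that quantify which
physiological force drives CSF motion.  Because raw 7 T scanner data is rarely
at hand, the package ships a first-class synthetic phantom generator whose
ground truth (tensors, modulation amplitudes, physiological peak times) makes
every downstream stage testable.

## The model

Each of 7 subscans (1 reference + 6 motion-encoded) measures, per voxel `v`
with tensor `D(v)` (mm²/s) and unit encoding direction `gᵢ`,

```
Sᵢ(v) = S(v) · exp(−b · gᵢᵀ D(v) gᵢ),      S₀ = S  (reference),
```

the attenuation model of an apparent-diffusion measurement at a very low
b-value — "mobility" rather than diffusion, since slow flow, laminar flow and
back-and-forth motion all dephase the signal.  The six dual-axis directions
`{(1,1,0),(1,−1,0),(0,1,1),(0,1,−1),(1,0,1),(−1,0,1)}/√2` make the 6×6
log-linear system exactly determined; playing a per-axis venc on two axes
gives an effective venc of `venc/√2` (5 → 3.5 mm/s).  From the fitted tensor:
mobility `λ̄ = (λ₁+λ₂+λ₃)/3`, fractional anisotropy
`FA = √(3/2)·‖λ−λ̄‖/‖λ‖`, and the principal orientation `ê₁`.

Physiological oscillations are analyzed by stamping every turbo-spin-echo
shot with its cardiac/respiratory phase (taken at the preparation instant),
binning k-space twice into three phases with a one-sixth phase shift — six
overlapping datasets, every shot in exactly two — reconstructing per phase,
and fitting the voxel-wise percent-change profile to a single-cycle sinusoid
`y_k = a·sin(2πk/6) + b·cos(2πk/6)`.  Amplitudes with fit quality R² < 0.5
are gated to zero; the fraction of voxels above the gate is the
coherent-voxel fraction.  A random-phase binning of the same data serves as
negative control.

## Worked example

Simulate a perivascular tube (mobility 0.041 mm²/s, FA 0.7) whose mobility
oscillates by 3.2 % with the cardiac cycle, then recover the oscillation
through the full chain:

```python
import numpy as np
import csfmobility as cm
from csfmobility.binning import assign_bins, bin_kspace, detect_peaks
from csfmobility.phasecycle import percent_change, phase_summaries, sine_fit
from csfmobility.recon import ReconConfig, reconstruct
from csfmobility.sampling import (AcquisitionConfig, make_pattern,
                                  make_shot_schedule, simulate_subscan)
from csfmobility.tensorfit import fit_tensor, tensor_metrics

spec = cm.PhantomSpec(grid_shape=(32, 32, 32), voxel_size=0.45, seed=0,
                      structures=[cm.StructureSpec(
                          kind="tube", endpoints=[(4, 8, 2), (4, 8, 12)],
                          radius=1.2, base_mobility=0.041, fa=0.7,
                          cardiac_amp=0.032)])
truth = cm.make_phantom(spec)

acq = AcquisitionConfig(grid=(32, 32), accel_target=1.0, acs_size=9,
                        tse_factor=146, seed=0)
schedule = make_shot_schedule(make_pattern(acq), acq, repeats=12)
traces = cm.make_physio_traces(schedule.duration + 30, cardiac_rate=1.0,
                               resp_rate=0.25, jitter=0.05, seed=0)
subscans = [simulate_subscan(truth, traces, schedule, i, acq)
            for i in range(7)]

peaks = detect_peaks(traces.time, traces.cardiac)
assignment = assign_bins(peaks, schedule, "cardiac")
volumes = np.stack([reconstruct(bin_kspace(s, assignment),
                                ReconConfig(mode="zero_fill")).volumes
                    for s in subscans])       # (7 subscans, 6 phases, ...)

mobility, valid = [], []
for p in range(6):
    field = fit_tensor(volumes[:, p], acq.directions, acq.b_value)
    metrics = tensor_metrics(field)
    mobility.append(metrics["mobility"])
    valid.append(metrics["valid"])
profile = percent_change(np.stack(mobility),
                         valid=np.stack(valid).all(axis=0))
fits = sine_fit(profile)
roi = truth.structure_masks[0] & profile.valid
summary = phase_summaries(profile, fits, roi)

print(f"ROI mobility      : {np.stack(mobility).mean(axis=0)[roi].mean():.4f} mm²/s")
print(f"gated amplitude   : {fits.gated_amplitude[roi].mean():.2f} %")
print(f"coherent fraction : {summary['coherent_fraction']:.2f}")
print(f"driving amplitude : {summary['driving_amplitude']:.2f} % (max - min)")
```

Output:

```
ROI mobility      : 0.0409 mm²/s
gated amplitude   : 3.45 %
coherent fraction : 0.83
driving amplitude : 8.49 % (max - min)
```

The fitted ROI mobility matches the configured 0.041 mm²/s; the gated sine
amplitude recovers the injected 3.2 % cardiac modulation (phase-window
averaging and estimator noise account for the residual difference); most ROI
voxels fit the single-cycle sinusoid coherently.

A command-line pipeline wraps the same stages
(`csfmob simulate|bin|recon|fit|phasecycle|roi|report --config cfg.yaml`),
writing NIfTI volumes, TSV traces/patterns and a seeded, byte-reproducible
JSON report.

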