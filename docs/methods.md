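# Methods

## Signal model and tensor estimation

The forward model treats each voxel's CSF signal as
`Sᵢ = S·exp(−b·gᵢᵀDgᵢ)` for encoding direction `gᵢ` and effective weighting
`b` (s/mm²), with the non-encoded reference `S₀ = S`.  The inverse problem is
the unweighted log-linear least-squares solve of the 6×6 system
`gᵢᵀDgᵢ = −ln(Sᵢ/S₀)/b`; with the dual-axis direction scheme the design
matrix is full rank and the noiseless solve is exact.  Scanners specify the
motion sensitization as an encoding velocity (venc) rather than a b-value;
the mapping `b = κ/venc²` depends on gradient timing, so `b` is a direct
configuration parameter (default 10 s/mm², which places the physiological
mobility range 0.012–0.041 mm²/s at roughly 10–35 % attenuation — partial
attenuation, as required for a sensitive fit) and the helper `b_from_venc`
exposes κ instead of asserting a scanner value.

Negative eigenvalues — possible under noise since nothing constrains the
linear solve — are clamped to zero and flagged; the tensor is rebuilt from
the clamped spectrum.  The principal eigenvector's sign is fixed (non-negative
z, ties broken by y then x) so orientation maps are reproducible.  Voxels
with reference signal below the CSF threshold (150 a.u. at the default signal
scaling) are invalid, and mobilities above 0.15 mm²/s are treated as noise
and excluded.

## Phantom

The phantom emulates a CSF-selective contrast: compartments (ellipsoid blobs
for ventricle-like spaces, tubes for subarachnoid and perivascular channels)
carry signal `csf_signal` (default 1000 a.u.) on an exactly-zero background —
tissue and blood suppression is idealized as perfect, which matches
measurements placing suppressed-tissue signal at the noise level.  Noise is
Rician: complex Gaussian of s.d. `noise_sd` (default `csf_signal/50`) enters
k-space, and magnitudes are taken after reconstruction.

Each structure's ground-truth tensor is built from a requested mean mobility
λ̄ and FA.  The (λ̄, FA) pair does not fix three eigenvalues; the generator
uses the axially symmetric solution λ₂ = λ₃ (λ₁ = λ̄(1+2δ),
λ₂ = λ̄(1−δ), δ = FA/√(3−2FA²)), with the principal axis along the tube.
Mobility oscillates multiplicatively,

```
D(φc, φr) = D₀·[1 + A_c·sin(2πφc + ψ) + A_r·sin(2πφr + ψ)],
```

a shape-preserving scaling: eigenvectors and FA stay constant while the mean
eigenvalue oscillates.  Measured data suggest FA itself also fluctuates; the
shape-preserving choice is a deliberate simplification — the analysis chain
only claims to recover mobility-magnitude oscillations, and a passing test
says nothing about FA dynamics.  Defaults mirror the physiological regime:
cardiac amplitudes of a few percent (3.2 % for the subarachnoid space around
the middle cerebral artery), respiratory amplitudes smaller, ~1 Hz cardiac
and ~0.25 Hz respiratory rates with 5 % inter-beat jitter.

Physiological traces are cosines of a piecewise-linear intra-cycle phase with
quasi-periodic peaks (interval CV ≈ the jitter parameter); ground-truth peak
times are stored so peak detection can be validated against truth.

## Acquisition simulation

Undersampling acts on the ky–kz phase-encode plane (the readout is fully
sampled and absorbed into the image axis).  Two pattern modes:

* **pseudoradial** — variable-density random sampling with inclusion
  probability ∝ r^(−decay) (r = elliptically normalized radius, default decay
  0.5, probability capped at 1).  The vendor's exact "pseudoradial variable
  density" law is not public; this power-law reconstruction keeps the
  documented decay parameter and is bisected (with a single fixed uniform
  draw per grid point) so the achieved acceleration lands within 5 % of the
  target.  Deterministic per seed.
* **poisson** — Poisson-disk sampling (scipy's maximal-fill engine), the
  disk radius bisected to the target count; used by the patient-protocol
  configuration (12×).

Both modes force a fully sampled autocalibration block (default 29×29).
Profiles are sorted by (azimuth, radius) about the k-space center — ties
broken lexicographically — and chunked into TSE shots of at most
`tse_factor` profiles (146 by default); shot k starts at k·TR (TR = 3.4 s).
A shot's physiological state is evaluated at its start, the preparation
instant that encodes mobility for the entire echo train.  The centered,
orthonormal FFT convention puts DC at floor(N/2) and preserves Parseval's
identity exactly.

With one pass over the pattern, retrospective binning leaves each of the six
phase datasets with ~1/3 k-space coverage.  The `repeats` parameter acquires
the pattern R times back to back (a longer scan); duplicates landing in the
same phase dataset are averaged, so per-bin coverage reaches 1−(2/3)^R and
the averaging emulates integration over the 1/3-cycle phase window.  The
end-to-end analyses here use R = 12 (99.2 % per-bin coverage).  Single-coil
simulation, magnitude images; no sensitivity maps, no echo-train relaxation.

## Binning

Peaks are detected by two-pass local-maximum search: an adaptive prominence
threshold (half the trace s.d.) estimates the median period, then a minimum
inter-peak distance of 0.4×period is enforced.  A rising edge cut off by the
end of the recording is not counted (no subsequent decline confirms it).

The intra-cycle phase of a shot is the linear interpolation between its
bracketing peaks.  Six half-open windows of width 1/3 centered at (k−1)/6
(k = 1..6), wrapped modulo 1, implement the two-step three-phase binning with
a one-sixth shift: every phase belongs to exactly two adjacent windows
(floor(6φ) = j → datasets j+1, j+2 cyclically).  Random control phases are
uniform per shot from a dedicated seeded substream, windowed identically.
Duplicate samples within a dataset are averaged (variance-optimal for
equal-noise observations).

## Reconstruction

`zero_fill` is the inverse centered FFT of mask-filled k-space.  `tv`
minimizes `Σ_p ‖M_p∘F x_p − y_p‖² + λ Σ_v Σ_p |x_{p+1,v} − x_{p,v}|`
(cyclic in the phase index) by proximal gradient: step size 1/L of the
orthonormal masked-Fourier data term, the exact per-voxel proximal map of
cyclic 1D TV computed by a warm-started projected-gradient dual solve, fixed
iteration count (default 30), zero-fill initialization, real-valued iterate
(single-coil, real object model).  λ is interpreted relative to the peak
magnitude of the zero-fill initialization — regularization weights are only
meaningful against normalized data — with default 0.005.  The objective is
monotonically non-increasing; the solve is deterministic.

## Oscillation analytics

Per-phase mobility maps are normalized voxel-wise to their across-phase mean
(percent change; zero-mean by construction), then fitted in closed form to
`a·sin(2πk/6) + b·cos(2πk/6)` — no offset term, frequency fixed at one cycle
per physiological period.  Amplitude √(a²+b²), phase atan2(b, a),
R² = 1−SS_res/SS_tot (0 when SS_tot = 0); amplitudes with R² < 0.5 are gated
to zero.  ROI summaries: the voxel-wise realigned mean profile (each voxel
circularly shifted so its maximum sits at phase 1, whose value is flagged as
discarded for plotting — a shift, not a deletion, so no data are lost), the
coherent-voxel fraction (R² > 0.5), and the driving amplitude (per-voxel
max − min, ROI-averaged).

## ROI tools

CSF masks keep voxels at/above the 150 a.u. threshold, drop voxels whose
percent change exceeds 50 % in any provided change volume, and finally remove
voxels without an included neighbor; the first two rules commute, the lonely
rule is a single last pass.  Perivascular structures are selected with
multiscale Hessian ridge filters (Frangi with α = β = 0.5 at σ = 0.6, 0.8,
1.0 mm, or the Meijering neuriteness variant), requiring isotropic voxels.
Vessel "inflation" uses the Euclidean distance transform rather than iterated
morphological dilation — at 0.17-mm steps a structuring element would impose
Chebyshev geometry — partitioning the perivascular shell into 17 disjoint
rims out to 3.00 mm.  Descriptive statistics report mean, sample s.d., and
the normal-theory CI half-width 1.96·s.d./√n (undefined and flagged at
n = 1).  Group comparisons: Friedman across paired conditions, two-sided
Wilcoxon signed-rank (exact for n ≤ 25), two-sided Mann–Whitney U (exact for
small n), Bonferroni by multiplication capped at 1.  The
visual-stimulation metric is 100·(mean_on − mean_off)/mean_off per ROI, and
the BOLD amplitude averages three 20-dynamic blocks before comparing
dynamics 15–20 against the 5–10 baseline (1-based, inclusive).

## Problem sizes and determinism

All randomness descends from one top-level seed through named substreams
(phantom traces, sampling pattern, measurement noise per subscan, random
binning, cohort draws), so pipeline reports are byte-identical across runs.
The shipped analyses use desk-scale problems: 16³–48³ grids, 32²–48²
phase-encode planes, 12 acquisition passes for near-complete per-bin
coverage, 200 cohort draws for the group-test power estimate.  The protocol
arithmetic (556×422 encode plane, 17×, 146-profile shots) runs at full size
since only the pattern and schedule are built.

## Known limitations

* **Random-binning coherence floor.**  The two-step overlapped binning puts
  every shot in two *adjacent* phase datasets, so any shot-level
  perturbation — thermal noise, modulation leakage, even undersampling
  artifacts — reaches the six-point profile as a cyclic moving average of
  independent sub-window aggregates.  That kernel concentrates ~75 % of
  noise power at the single-cycle fundamental: pure noise fits the sinusoid
  with E[R²] ≈ 0.68, and the random control's coherent-voxel fraction floors
  near 0.7 rather than near the independent-noise value 0.35.  The random
  control therefore shows *reduced* coherence and amplitude relative to
  physiological binning (tested directionally), but not the large specificity
  factors achievable with strongly nonlinear multi-coil reconstructions,
  which are out of scope here.
* **Group-test power.**  At the observed patient/control effect size
  (0.042 ± 0.006 vs 0.035 ± 0.005 mm²/s, n = 8 + 8, Cohen's d ≈ 1.27) the
  exact two-sided Mann–Whitney test has ≈ 60 % power at α = 0.05 — a single
  significant study outcome at these sizes is unremarkable, but a
  per-repetition detection rate much above that is not achievable and the
  power analysis here reports the honest value.
* Shape-preserving modulation keeps FA constant over the cycle; FA dynamics
  are not modeled.
* No anatomical geometry, partial-volume effects, relaxation along the echo
  train, coil sensitivities, eddy currents or subject motion.
* The pseudoradial density law is a documented reconstruction of an
  under-specified vendor pattern; only its decay parameter is carried over.
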