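# Methods

## The measurement being modeled

T1ρ (spin-lattice relaxation in the rotating frame) is the decay constant of
magnetization held along a continuous radio-frequency "spin-lock" field of
amplitude B1sl. In articular cartilage T1ρ is sensitive to proteoglycan
content, which makes voxel-wise T1ρ maps a marker of early cartilage
degeneration before morphological change. The toolkit models the complete
measurement chain for a high-resolution knee protocol at 7 T: a T1ρ
preparation pulse cluster followed by a gradient-echo readout, repeated over
a series of spin-lock times TSL ∈ {0, 10, 20, 30, 40} ms at B1sl = 500 Hz,
then voxel-wise fitting of

    S(TSL) = S0 · exp(−TSL / T1ρ).

At 7 T the static (B0) and transmit (B1) fields are inhomogeneous enough
over the knee that an uncompensated lock produces banding artifacts and
biased maps, so the pipeline also covers the calibration steps that tame
them: WASSR B0 mapping, double-angle B1 mapping, and STEAM-based reference
voltage (flip-angle) calibration over a small volume around the cartilage.

## Rotating-frame Bloch model

Hard pulses are instantaneous rotations; a pulse of nominal flip α executed
at relative transmit field b1rel rotates the magnetization by α·b1rel about
the transverse axis at the pulse phase (right-handed; a 90° pulse about +x
takes equilibrium (0,0,1) to (0,−1,0)). During a lock of duration t the
magnetization evolves about the effective field

    ω_eff = 2π·(B1sl·b1rel)·(cos φ, sin φ, 0) + 2π·Δf·(0,0,1),

with Δf the B0 offset in Hz: the component of **m** parallel to ω_eff decays
as exp(−t/T1ρ), the perpendicular component precesses at |ω_eff| and decays
as exp(−t/T2ρ). Approximations, all standard for preparation-cluster
analysis and documented here as model assumptions:

- relaxation during the hard pulses is neglected;
- equilibrium regrowth (T1 recovery) during the ≤40 ms lock is neglected;
- T2ρ defaults to T1ρ. Under that default relaxation is isotropic, so an
  off-resonance tilt of the lock axis does not change the observed decay
  rate by itself — residual artifacts come only from uncompensated
  rotations. The on-resonance behavior is insensitive to the choice; T2ρ is
  configurable for studies of the anisotropic case.
- the readout is modeled as proportional sampling of the prepared
  longitudinal magnetization: no k-space/encoding simulation, no fat signal,
  no coil model. T1-recovery mixing across the segmented readout is out of
  scope.

### Preparation cluster

Two modes:

- `simple`: 90° tip-down, lock at one phase for TSL, 90° tip-up. This is
  the uncompensated reference whose off-resonance failure (banding, biased
  deep/middle-zone T1ρ under a bulk frequency offset) the compensated
  cluster removes.
- `compensated`: 90° tip-down about x, lock TSL/2 along +y, 180° refocusing
  pulse about the lock axis, lock TSL/2 along −y (rotary echo), 90° tip-up
  about x. The tip-up deliberately shares the tip-down phase: the prepared
  magnetization returns along −z, an overall sign that the crusher gradient
  plus magnitude readout discards. During design the cluster family
  (refocusing-pulse axis × tip-up phase) was evaluated on a grid of
  Δf ∈ ±100 Hz, b1rel ∈ [0.7, 1.3]: this variant keeps the worst-case
  noiseless R² of the 5-point exponential fit at 0.97, whereas a
  phase-inverted tip-up drops to 0.64. Published schematics of such
  clusters rarely pin down phases; the scheme implemented here is declared,
  not asserted as any scanner's.

Crushers are modeled by zeroing transverse components after tip-up; the
retained signal is |m_z|. Both modes reduce exactly to exp(−TSL/T1ρ) at
Δf = 0, b1rel = 1.

The closed-form evolution (rotation plus anisotropic decay about a constant
effective field) is cross-checked in the tests against an independent RK4
integration of the full Bloch ODE at 1 µs steps; agreement is required to
1e−4.

## Synthetic phantom

`PhantomSpec` describes a patellar-like scene: a half-annular cartilage
band (default inner radius 28, outer 37 voxels on a 96×96×8 grid, in-plane
voxel 0.3125 mm — the protocol's frequency-encode resolution — and 3 mm
slices), bone inside the band, a synovial-fluid arc outside. The band is
split radially into deep/middle/superficial zones with fractions
0.5/0.3/0.2 (the deep zone is anatomically the thickest). Default zone T1ρ
values 35/45/55 ms follow the healthy ordering (superficial > deep, all
below 60 ms); they are configuration values, not measured ground truth.
Fluid gets a long T1ρ (500 ms) and lower amplitude; bone a short one and
low amplitude.

Field models are bulk + smooth in-plane ramp + per-voxel Gaussian jitter:

- B0: bulk 0 Hz with jitter s.d. 30 Hz by default — the residual
  inhomogeneity measured after volume-localized frequency calibration; a
  bulk offset of ~139 Hz reproduces the patellar scanner-prescan condition.
- B1rel: mean 1.0, jitter s.d. 0.1.

Noise is Rician: independent Gaussian noise of σ = cartilage amplitude /
base SNR added to two quadrature channels, then magnitude. Base SNR
defaults to 240 (the protocol's TSL = 0 cartilage SNR); 90 is the
worst-case (TSL = 40 ms) figure used in the fit-quality simulations. All
randomness derives from a single integer seed; outputs are bit-identical
for a fixed spec.

What the phantom does *not* emulate: realistic knee anatomy and partial
voluming, spatially correlated (shim-harmonic) field structure beyond a
linear ramp, magic-angle T1ρ modulation (only a per-region T1ρ value is
available), fat, motion between TSLs (injected explicitly in registration
tests). Passing simulations therefore demonstrate correctness of the
measurement model and the pipeline's inversions, not clinical performance.

## Calibration

- **WASSR B0**: the direct-saturation dip of each voxel's z-spectrum
  (sampled −0.8…0.8 ppm in 0.1 ppm steps ≈ 29.8 Hz at 7 T) is upsampled by
  cubic interpolation onto a 1 Hz grid and located at the interpolated
  minimum. Simpler than symmetry-center algorithms and sub-Hz accurate for
  noiseless dips anywhere in the inner 80% of the sweep (tested). Minima on
  the sweep boundary are censored to NaN.
- **Double-angle B1**: actual flip = arccos(S₂α/(2·Sα)); b1rel =
  actual/nominal. Assumes full relaxation between excitations (the
  protocol's 5 s shot TR); no T1 correction term. Out-of-domain ratios give
  NaN rather than an error.
- **STEAM voltage**: with three identical pulses the stimulated-echo signal
  is ∝ sin³α, so two spectra at voltages x and 2x give
  α = arccos((S₂/(8S₁))^⅓) and, with flip angle linear in voltage,
  V_ref = x·90/α. The ratio cancels all proportionality constants, so the
  calibration is scale-invariant in signal units; Monte-Carlo with 1%
  signal noise keeps the recovered voltage within 6% of truth across
  α ∈ [40°, 90°].

## Fitting and quality control

Registration aligns each TSL volume to the TSL = 0 volume by the
integer-voxel translation maximizing circular cross-correlation of
mean-subtracted volumes (FFT-computed, search window ±5 voxels by default).
Integer shifts are exact for the simulated motion model; sub-voxel motion
is out of scope.

The linearized fit is unweighted least squares on log-signal (the
whole-volume default, for speed); the nonlinear fit is Levenberg–Marquardt
on the exponential initialized from it. Both are exposed because at this
protocol's SNR they agree to well under 1% — the comparison is reproduced
in the tests rather than a winner declared. R² is always computed on the
native signal scale, so the display floor (R² < 0.8 hidden) means the same
thing for both methods. Voxels with any nonpositive sample are flagged
invalid (NaN), never zeroed in stored maps; the display ceiling (T1ρ >
300 ms → 0) is a separate presentation step.

## Zone and side segmentation

Normalized depth is computed from Euclidean distance transforms: d_in to
the bone-facing surface (an adjacent bone label or a user-marked boundary)
and d_out to the articular surface (outside voxels adjacent to cartilage —
restricting to adjacency keeps far-side background from shortcutting the
estimate). Depth = (d_in − 0.5)/(d_in + d_out − 1) reproduces the exact
(i + 0.5)/n layer rule on flat slabs and is the isotropic limit of
layer-peeling by erosion, which showed a pronounced city-block bias on
curved bands. Zones are cumulative-fraction bins of depth (defaults
0.5/0.3/0.2, configurable — any fixed split is an approximation to real
zonal anatomy). Side assignment is a user-supplied plane, as in the
semi-automatic workflow this mirrors. Known limitation: at open band ends
(rim faces) the articular distance collapses and rim voxels skew
superficial; rim-free geometry recovers volume fractions to within a few
percent of total volume.

## Statistics

- SNR = 0.655 × ROI mean / background-ROI s.d., averaged over (by protocol
  convention four) background ROIs. The 0.655 = √(2 − π/2) factor converts
  the Rayleigh s.d. of background magnitude noise to the per-channel
  Gaussian σ; the package recomputes it by Monte-Carlo rather than
  hard-coding trust in it.
- ICC: two-way random effects, absolute agreement, single measures, with
  F-based 95% CI and p-value (computed via pingouin; verified against a
  brute-force variance-components oracle to 1e−10 in tests). Absolute
  agreement is the standard test-retest form; a perfectly linear but
  rescaled retest has Pearson r = 1 yet ICC < 1, a contrast the tests pin
  down.
- CV per subject = s.d. of the two measurements (ddof = 1) over their mean,
  ×100; summarized as mean ± s.d. over subjects.
- Group comparison from published summary statistics uses Welch's
  unequal-variance t with Satterthwaite df — a re-check of reported
  significance from means/s.d./n, not a replication of a per-subject
  paired analysis (pairing information is not available in summaries).

## Problem sizes and numerical choices

Simulations use the 96×96×8 phantom (~7,400 cartilage voxels) and 10⁶
draws for the Rician Monte-Carlo; both run in seconds and are the
package's chosen desk-scale study conditions. Degenerate inputs are
handled explicitly: constant volumes register with zero shift and a
warning; all-constant z-spectra, zero double-angle signals and
out-of-domain ratios map to NaN; zero total variance makes the ICC error
out; two identical zero-variance groups compare with t = 0, p = 1 by
convention. Seeds: every stochastic routine takes an explicit seed and is
reproducible bit-for-bit.
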