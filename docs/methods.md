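# Methods

`oftflow` reconstructs a beating-tube geometry from non-gated
cross-sectional image sequences, runs quasi-steady viscous flow
simulations with inverse inlet-traction fitting to measured vertical
velocities, and maps wall shear stress (WSS) and the oscillatory shear
index (OSI) on the endocardial surface. The pipeline targets the
embryonic chick outflow tract (OFT) during cardiac looping stages
(HH14–HH18), imaged by structural + Doppler optical coherence
tomography; since no real scans ship with the package, a synthetic
phantom generator provides inputs with full ground truth.

## The phantom

The phantom emulates the acquisition geometry: one longitudinal b-mode
sequence along the tube plus a stack of cross-sectional sequences at
20 µm increments, 200 frames each at 140 frames/s, every sequence
starting at an unknown cardiac phase drawn uniformly from [0, 1)
(no gating). The lumen radius field is

    R(s, φ) = R0(s) · [1 + a sin 2π(φ − s/w)] · [1 − d·bump(s)·g(φ)]

with normalized axial position `s`, cycle phase `φ`, baseline profile
`R0`, pulsation amplitude `a` (default 0.25), wave speed `w` in tube
lengths per cycle (default 2, giving the inlet→outlet phase lag seen
in area-motion plots), and a cushion-like constriction of depth `d`
(default 0.85) that approaches closure once per cycle: `bump` is a
Gaussian in `s` (center 0.65, width 0.12) and `g` a smooth periodic
pulse peaking at phase 0.75. Defaults were chosen once to reproduce
the qualitative features the algorithms depend on — periodicity, a
longitudinal phase lag, near-closure with backflow restriction — at
the measured stage scales (periods 400–507 ms, tube lengths
0.54–0.78 mm, peak velocities 35–90 mm/s, which the `HH14`–`HH18`
presets encode).

Blood velocity is quasi-Poiseuille: axial, parabolic, no-slip at
R(s, φ), with the local flow rate obtained from mass conservation in
the deforming tube (inlet waveform minus the analytic phase derivative
of the upstream lumen volume). Wall-motion-induced radial velocity is
neglected; it is O(wall speed), far below axial speeds except at
near-closure, and those phases are excluded from simulation anyway.
Images render the wall as a bright annulus of configurable thickness
around a dark lumen with sub-pixel sigmoid edges and additive Gaussian
speckle; there is no OCT physics (attenuation, refraction,
shadowing). Doppler planes store cos(beam tilt) times the axial
velocity — the beam-axis projection — zeroed outside the lumen, with a
default 45° tilt so the projection is non-degenerate.

What passing tests on this phantom do *not* show: robustness to bulk
embryo motion (real scans with motion are discarded, and the phantom
has none), to genuine OCT speckle statistics, to non-star-convex
(crescent) lumen shapes during partial cushion coaptation, or to
torsion of the tube axis.

## Synchronization

Each sequence is folded onto one normalized cycle:

1. **Period.** The string-length method: candidate periods `p` map
   column `i` of an m-mode to phase `(i mod p)/p`; the phase-ordered
   polyline through the (phase, column-vector) points is shortest when
   `p` is the true period. Grid search (0.1-frame step) with parabolic
   refinement; the search range must sit within (2, n/2) so at least
   two cycles fold and the 2T harmonic is excluded. M-modes are
   normalized to zero mean and unit variance first, making the
   estimator invariant to affine intensity transforms. The median over
   all longitudinal and cross-sectional m-modes is the consensus
   period. Measured accuracy on the phantom: ±0.03 frames noiseless,
   within ±1 frame at 15% speckle.
2. **Pooling.** Columns are averaged into 200 phase bins; empty bins
   are filled by circular linear interpolation (the folding of ~3.5
   cycles leaves gaps whenever the period nearly divides the frame
   count).
3. **Alignment.** The circular shift between each cross-sectional
   pooled m-mode and the longitudinal m-mode at the corresponding
   column maximizes normalized cross-correlation, with parabolic
   sub-bin refinement and ties broken toward the smallest shift.
   `phase_shift(a, b)` returns `s` such that `b` advanced by `s` bins
   matches `a`; if the sequences started at cycle phases `o_a`, `o_b`,
   then `s ≈ (o_a − o_b)` cycles.
4. **Cumulative-phase refinement.** Horizontal center-line m-modes of
   the coarsely aligned stack are compared neighbor-to-neighbor and
   the wrapped shifts accumulated along the slice axis. This curve
   mixes the *physical* traveling-wave lag (smooth in slice index)
   with residual per-slice jitter, so the smooth part must not be
   "corrected" away: a robust low-order polynomial fit (after a
   running-median de-spiking pass) models the smooth component, and
   only residuals exceeding an outlier threshold (default 5 pooled
   bins) are applied as corrections. Neighbor shifts within 10% of a
   half cycle are flagged unwrap-ambiguous. A manual-override table
   stands in for the interactive correction step of the original
   workflow.
5. **Resequencing.** Images and Doppler planes are pooled and
   circularly re-sampled to 100 output frames by linear interpolation
   between phase bins (higher-order splines were rejected: they ring
   at the sharp wall edges).

Cross-validation extracts vertical-velocity-vs-phase curves at four
corresponding points from the longitudinal Doppler data and the
synchronized stack and reports peak circular correlation, lag, and RMS
difference. End-to-end on seeded phantoms the median slice-phase error
is ~0.02 pooled frames noiseless and well under 2 pooled frames (1% of
the cycle) with speckle.

## Segmentation

A deliberately simple radial edge detector replaces the original
double-line maximum-likelihood/active-contour segmenter, which is not
specified in this work's sources: ≥64 rays cast from a seed in the
dark lumen, the inner wall edge at the maximum positive intensity
gradient per ray (sub-pixel parabolic refinement), circular median
filtering and boxcar smoothing over angle, resampling to 64 vertices
with vertex 0 anchored at the image +x axis (this fixed angular
anchoring is what makes surfaces correspond across phases and slices —
a convention of ours, with no twist minimization; adequate for the
torsion-free phantom, a documented limitation for real data). A
lumen whose median detected radius falls below 3 pixels — or whose
seed neighborhood contains no dark tissue at all — is flagged fully
coapted (`is_closed_lumen`) and carries zero area. The myocardial
(outer) boundary is found by a second pass locating the strongest
negative gradient beyond the inner edge, so wall-area maps can be
produced. The scheme handles star-convex lumens only.

## Geometry and meshing

Cross-section areas use the shoelace formula; lumen volume at a phase
is the slab sum Σ areaₖ·gapₖ with half-gaps at the ends, which works
even for phases with closed (unmeshable) slices; centerline length is
the centroid polyline length, by convention at the phase of minimum
lumen volume (a closed configuration). Area-motion matrices (slice ×
phase) carry a diagnostic fit of the per-slice phase of maximum area;
its slope against normalized length recovers the traveling-wave lag
(1/w) within 5% on the phantom.

Meshes are structured all-hex O-grids: a square core mapped onto half
the local radius by the smooth elliptical mapping
(x', y') = (u√(1−v²/2), v√(1−u²/2)), plus radial ring layers out to
the wall, lofted along the centerline. Ring layers are geometrically
graded toward the wall (ratio 0.7) to sharpen near-wall gradients.
Sampled boundary radii are rescaled per station so the polygonal
cross-section preserves the contour area — without this an n=16
circumferential discretization undershoots volume by the
inscribed-polygon deficit (~2.5%), which would swamp the ≤2%
slab-vs-mesh consistency check. Inlet and outlet are extended by 3
local diameters (default) of straight tube, the end contour tapering
smoothly (cubic smoothstep) to its area-preserving circle over the
first diameter; extension stations use twice the body's axial spacing
and extension cells are tagged and excluded from all analyses. Cell
quality is guarded by an explicit positive-Jacobian check at all Gauss
points; closed slices refuse meshing.

## Flow solver

Each of the 100 phases is an independent steady problem — justified
at Re < 5 (radius × mean-velocity convention) and Womersley ≈ 0.16
(f = 1/T convention); with these conventions the stage presets
reproduce the regime the method assumes. The discretization is
equal-order trilinear velocity/pressure (Q1–Q1) on the hex mesh with
Brezzi–Pitkäranta pressure stabilization (τₑ = α h²/μ, α = 0.05,
h = cell-volume^{1/3}); the viscous term uses the symmetric-gradient
(stress-divergence) form so the natural boundary condition is the true
traction σ·n. Boundary conditions: no-slip on the wall, uniform
normal traction −P·n at the inlet, zero traction at the outlet; P > 0
drives inlet→outlet flow. Taking the constant pressure test function
in the stabilized continuity equation shows the discrete solution
conserves mass globally without error, and the inlet/outlet flux
balance is indeed at machine precision in the tests. The linear
systems are solved by sparse LU (MMD ordering); the convective term is
available by Picard iteration but defaults off in the Stokes limit.
Benchmarks on a traction-driven cylinder: centerline velocity within
~1%, flow rate within ~1–2%, wall shear within ~2–4% of the Poiseuille
closed forms at the refined default resolutions, with monotone error
decay under refinement and <5% observable shift under mesh doubling.

**Inverse fit.** The inlet traction is updated by a secant iteration
until the computed axial velocity at the monitor point (default: the
lumen-center node of the mid-tube station) matches the Doppler-derived
target within 1%. The zero-traction solution is identically zero, so
(0, 0) is a free secant point; in the Stokes limit the response is
exactly linear and convergence takes at most two solves from any
nonzero warm start. Each phase warm-starts from the previous phase's
fitted traction. Doppler targets are angle-corrected by cos(beam
tilt) by default (the phantom's geometry is known; the flag is
exposed). Phases with a closed slice or a failed mesh are skipped and
reported; the coverage fraction is checked against the 0.6 floor.

## Hemodynamic metrics

WSS is τ = σ·n − [(σ·n)·n]n with σ = −pI + μ(∇v + ∇vᵀ), evaluated per
wall face from the one-sided trilinear gradient of the adjacent cell
at the face centroid; tangency τ·n = 0 holds by construction.
OSI = ½(1 − |∫τ dt| / ∫|τ| dt) uses rectangle weights of 1/100 cycle
per *simulated* phase only, i.e. T in the normalization is the
simulated portion of the cycle; gaps from skipped phases carry no
weight (trapezoids across non-contiguous gaps would fabricate shear
there). Flow rate is the velocity flux through a transverse station
inside the analysis region (default mid-tube); V_F = ∫max(Q,0)dt,
V_B = ∫max(−Q,0)dt by trapezoid on the sampled waveform without
sub-interval crossing resolution, SV = V_F − V_B, η = 1 − V_B/V_F
(flagged undefined when V_F = 0). "Mean WSS" is the pooled
space-and-time area-weighted mean; the time-then-space variant is also
computed since the original reports do not specify the order.
Unrolled endocardial maps cut the wall at θ = π and flatten it with
the inlet at the bottom row, resampling the structured face grid
bilinearly (periodic in θ); area-weighted means survive the resampling
within 2%.

## Numerical choices and degenerate inputs

- Phase arithmetic is circular everywhere; shifts are reported in
  [0, 1) cycles and compared via wrapped differences.
- Phase-bin assignment adds a 1e-9 epsilon before flooring (guards
  against `i/p·p` landing just below an integer).
- Flat m-modes, constant correlation inputs, seeds on bright tissue,
  featureless images, closed slices at meshing, zero-target inverse
  fits, and all-zero shear histories are all explicit, tested paths —
  flagged or refused rather than returning numbers.
- OSI is clipped to [0, 0.5] against float noise; the analytic bound
  |∫τ| ≤ ∫|τ| guarantees the range.
- Problem sizes in the shipped tests and the acceptance script are
  deliberately compact (phantoms of 8–51 slices, meshes of ~1–10 k
  cells, 50–100 phases); every resolution knob reaches the
  tens-of-thousands-of-cells scale of the original organ-scale runs,
  and the mesh-independence checks bound what the coarser defaults
  give up (<5%).

## Known limitations

- The radial segmenter cannot represent crescent (partially coapted)
  lumens; such shapes fall back to star-convex approximations.
- No fluid–structure interaction, moving-mesh/ALE transport, or
  transient inertia: each phase is steady, so phenomena on the scale
  of the wall velocity are absent by design.
- The loft has no torsion handling; angular correspondence is anchored
  to the image axes.
- Doppler emulation projects the axial velocity only; in-plane
  components of real flow do not appear in the phantom's Doppler
  channel.
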