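# Methods

This note documents the models behind `mukiss`, the conventions and
defaults that matter, and what the synthetic fixtures do and do not
establish about real recordings.

## Reduced-order flow model

The aperture pair is modelled as a point source of volumetric strength
Q_inj and a point sink of strength Q_asp in Stokes flow, each
contributing radially with |v| = Q/(4πr²). Coordinates: the substrate
plane is z = 0 with z up; the source–sink axis runs along x; the
opening centers sit at height `tip_height` (default: the injection
inner radius, i.e. the tip resting at the surface). All lengths are in
μm, flows in nl/s, volumes in fl (1 fl = 1 μm³); SI conversions are
internal. With `substrate_present`, an image source and sink mirrored
across z = 0 cancel the normal velocity on the substrate. This enforces
**no-penetration, not no-slip** — a stated limitation: near-wall speeds
are overestimated relative to a viscous boundary layer.

Confinement requires Q_inj < Q_asp; a configuration with
Q_inj ≥ Q_asp > 0 is rejected outright ("no confinement possible").
Pure-source (Q_asp = 0) and no-flow fields are allowed so that escape
behaviour and degenerate cases can be exercised.

Default geometry closes the remaining free parameters: the
center-to-center tip separation defaults to
(⌀_inj + ⌀_asp)/2 + 2·wall_thickness (outer rims touching), because the
physical devices are assembled in near-touching contact; the in-plane
angle between the pipettes does not enter the field itself (openings
are points) and only documents the build.

### Streamlines and the envelope

Streamlines integrate the unit-speed ODE dx/ds = v/|v| (adaptive RK45,
relative tolerance 1e-6). The arc-length parameterization makes paths
— and therefore the envelope — exactly invariant under joint scaling of
both flow rates: the envelope is a function of Q_ratio and geometry
only, which the tests check at voxel identity.

Termination: capture within the aspiration inner radius; escape beyond
R_max = 50 × the largest aperture diameter; exhaustion when the local
speed falls below 1e-9 of the characteristic speed (stagnation). An
exclusion sphere of radius 0.1 × the inner radius around each opening
bounds evaluations near the singularities.

The **envelope** is rasterized from n streamlines launched isotropically
(seeded RNG) from the source exclusion sphere: the integrator's visited
points are binned onto a voxel grid (default voxel: ⌀_inj/50). Volume =
occupied voxels × voxel volume; extent = the maximum in-plane caliper
width of the occupied set (computed from the convex hull); boundary
points are the surface voxels. Because the voxelization samples
streamline points rather than filling the separatrix interior, the
volume is an *operational, streamline-sampled* estimate tied to the
stated launch count and voxel size (2000 streamlines, 20 nm voxels for
the 1 μm device). It concentrates where the flow actually carries
injected fluid and is meant for order-of-magnitude comparison; the
filled separatrix interior of the point-source model is substantially
larger, dominated by a slow back lobe behind the source that the real,
wall-collimated aperture flow does not produce.

Shear stress is μ‖(∇v + ∇vᵀ)/2‖_F with the analytic velocity gradient.
Within about one aperture diameter of an opening the point singularity
makes the strain rate diverge (the real flow is bounded by the glass
there), so shear summaries exclude that zone.

## Transport numbers

Diffusivities are carried in m²/s (a 1–500 nm particle size range in
water at 22 °C corresponds to ≈ 4.5×10⁻¹⁰…9×10⁻¹³ m²/s by
Stokes–Einstein D = k_B·T/(3πμd); the printed μm²/s variant of that
range is dimensionally inconsistent with those sizes, and we adopt
m²/s). Default fluid: water at 22 °C, μ = 0.9544 mPa·s, ρ = 997.8 kg/m³.

Conventions, recorded in every report:

* characteristic length L = envelope extent;
* characteristic speed v = mean |v| over envelope boundary voxels;
* Pe = vL/D, reported as the minimum over the diffusivity grid;
* Da = k_on·b_m·δ_s/D with the Lévêque depletion-layer thickness
  δ_s = L·Pe^(−1/3), k_on converted from M⁻¹s⁻¹ to a per-molecule
  volumetric rate via Avogadro's number, and the worst (largest) value
  over the grid reported. The source analysis only names the framework
  for this number, so the exact δ_s and L conventions are a package
  choice; we verify the reaction-limited *flag* (Da ≪ 1, threshold
  0.1), not the printed magnitude range.
* Re = ρvL/μ. With the mean-boundary-speed convention Re stays ≪ 1 at
  the 0.03–0.3 nl/s operating conditions (~10⁻²–10⁻¹) and approaches
  unity only at the extreme 3 nl/s injection rate, where the near-
  aperture speeds dominate the mean; the Stokes assumption is anchored
  to the 1–2 mm/s envelope speeds of the standard condition.

Thresholds for the flags: advection-dominated at Pe ≥ 10,
reaction-limited at Da < 0.1.

## Tracers and deposition

Particles are overdamped points (no inertia — justified by Re ≪ 1 — and
no hydrodynamic wall corrections): x ← x + v(x)·dt + √(2D·dt)·ξ per
axis. The default dt = 1e-5 s matches a 10 kHz localization cadence. A
dt whose advective step at the seeding radius exceeds half the aperture
radius is rejected as too coarse. Particles seed isotropically on the
injection-opening sphere, are absorbed at the aspiration capture
radius, and reflect specularly at the substrate; substrate contact
means z < particle radius (default 0.1 μm, a 200 nm bead). Sticking
probability defaults to 1 (carboxylate beads adhere readily);
the sticking model for beads on glass is otherwise unspecified, so it
is exposed as a parameter.

Deposition strokes translate the whole device along a waypoint path at
constant speed under a quasi-static field (the flow adjusts much faster
than the ~μm/s tip motion). Stroke width bins deposits transverse to
the local path direction at equally spaced stations (default bin
0.5 μm) and interpolates each station histogram's FWHM at half maximum;
stations with fewer than 5 deposits are skipped.

A note on velocimetry statistics: a tracer's step velocity carries
Brownian noise of standard deviation √(2D/dt) per axis (≈ 1 mm/s for an
80 nm particle at 10 kHz), which only averages out over many steps per
bin. Agreement with the analytic field is therefore asserted in bins
whose predicted speed resolves above that noise floor (≥ 0.5 mm/s at
the test bin occupancies); slower bins are statistically uninformative
at desk scale, not evidence of model error.

## Synthetic imaging

σ² always denotes per-axis Gaussian variance; free 2D diffusion grows
it as σ²(t) = σ0² + 2Dt (equivalently width² ≡ 2σ² grows as 4Dt). The
PSF is the standard Gaussian approximation σ_psf = 0.21·λ/NA (λ = 488 nm,
NA = 1.0 by default, from the confocal described in the source
methods). Gaussian⊛Gaussian is evaluated analytically, so rendering
adds σ_psf² to the variance; amplitudes follow
A(t) = A0·σ0²/(σ0² + 2Dt + σ_psf²), conserving the spatial integral.
Pixels sample intensity at their centers, 0-based indices, x right /
y down; Poisson shot noise acts on expected counts plus background and
Gaussian read noise adds on top. Photobleaching during imaging is off —
the delivery-based analysis does not model it.

The initial punctual spot is a Gaussian whose FWHM equals the 1 μm
aperture footprint (σ0 = 0.425 μm); the true post-pulse profile shape
is unknown, and any smooth compact profile converges to this one after
a frame of diffusion. The first frame is recorded half a frame after
the pulse ends (exposure-midpoint convention); the estimator only uses
slopes, so this offset does not bias D̂.

Fixture ground truths are the reported estimates for each system:
supported-bilayer GM1 (0.048 μm²/s punctual / 0.045 FRAP, 30
replicates, 130 ms frames) and live-cell membrane GM1 (0.32 punctual at
0.7 s labeling frames, 8 replicates / 0.35 FRAP). For the live-cell
FRAP fixture the recovery is rendered at 130 ms frames: at
0.35 μm²/s a 1 μm hole refills within ~1 s, so a 0.7 s cadence would
leave fewer than three usable frames; late frames falling below the
noise floor are flagged "flat" and excluded rather than treated as
failures. The punctual amplitude is set ~5× below the FRAP plateau
signal, mirroring the shorter exposure of the delivery modality and
reproducing its larger ensemble spread.

What the generator does *not* emulate: membrane topography and
projection effects, immobile fractions and binding during recovery,
anomalous diffusion, detector pixel-integration, optical sectioning,
sample drift. Passing recovery tests therefore establishes estimator
correctness under the stated noise model, not robustness to those
real-data effects.

The two-channel colocalization design solves the amplitudes of the
channel-exclusive spots by fixed-point iteration — first against
noiseless renders, then against noisy renders drawn from a
seed-derived solver RNG — so that the measured Mander's coefficients
under the design's own convention (fixed absolute threshold,
background subtraction at background + ~3 sd, floor at zero) equal the
designed M1/M2; residual seed-to-seed deviation is ≲ 0.005.

## Diffusion estimation

Each frame is fitted with a symmetric 2D Gaussian plus constant
background. Initialization is robust to pedestals: a median/MAD noise
scale, moments over pixels above 4 MAD. The least-squares fit runs
twice: an unweighted pass, then a pass weighted by the *model's*
predicted shot noise — weighting by the observed counts would bias the
width low (high pixels get down-weighted exactly where they carry the
width information). Frames whose feature sits below the noise floor
are flagged flat; only convergence failures on more than half the
frames abort.

`punctual_width` (default): weighted linear regression of fitted
variance on time; D̂ = slope/2, SE from the regression. A negative
slope clips to D̂ = 0 with a warning. `punctual_amplitude`: hyperbolic
fit A(t) = A0·s0²/(s0² + 2D̂(t−t0)) with s0² the first usable frame's
fitted variance. If the two methods disagree by more than 3 joint
standard errors both are reported and flagged. FRAP series are averaged
over the prebleach frames, inverted (plateau − frame, plus a pedestal
of ~6 noise sd so the noise floor is not clipped — clipping the wings
systematically narrows the apparent hole and was the largest bias we
found), and then fitted identically; using one estimator for both
modalities makes their agreement testable by construction. A hole
shallower than 5 sd of the differenced noise aborts ("no detectable
bleach hole"); a hole gone by the second frame flags D̂ as a lower
bound. No immobile-fraction term is fitted by default.

Ensembles report mean ± sample sd over replicates, matching the
reporting convention of replicate measurements.

## Image quantification

Detection: difference-of-Gaussians band-pass, local maxima above an
absolute threshold, intensity-weighted centroid refinement (~0.1 px).
Linking: gated nearest neighbor, candidates assigned greedily by
increasing distance (which breaks ties by minimal total displacement);
an exact tie rejects all parties and the orphaned localization starts a
new trajectory; `memory` frames of disappearance may be bridged. Global
optimization is unnecessary at fixture densities.

Kymographs sample the image at pixel pitch along a polyline, averaging
across the line width with bilinear interpolation. Ridge speed comes
from an intensity-weighted centroid per time column inside a tracking
window, truncated when SNR < 2, followed by weighted linear regression
of position on time (reported in nm/s).

Mander's coefficients: M1 = Σ A·[B > T_B]/Σ A over the ROI with
background-subtracted intensities floored at zero, M2 symmetric.
The thresholding convention of the source analysis is unstated; default
is per-channel Otsu within the ROI with a fixed-threshold override, and
the convention used is stored in the result. Cluster timecourses
threshold per frame (Otsu or fixed), label 8-connected components, and
convert integrated intensity to copy numbers via a user-supplied unit
intensity (single-fluorophore calibration is instrument-specific and
out of scope). MSD analysis is in-plane, time-averaged per track and
ensemble-averaged, with the anomalous exponent from a log-log fit.

## Problem sizes and numerical choices

Envelope comparisons use 2000 streamlines at 20 nm voxels for the 1 μm
device and 300–400 streamlines at 120 nm voxels for the 6 μm device;
recovery ensembles use 30 replicates (8 for the live-cell punctual
condition, matching its reported replicate count); deposition strokes
release 1200 beads along a 40 μm path at 2 μm/s with dt = 2e-5 s; the
end-to-end velocimetry check tracks 30 particles over 300 frames at
10 kHz. These sizes reproduce the reported quantities with comfortable
statistical margins on a single core.

Tie-breaks and degenerate inputs are handled explicitly throughout:
zero-flow fields evaluate to zero velocity and zero shear; flat frames
yield amplitude ≈ 0 with unconstrained variance; all-background frames
yield empty cluster tables; empty velocity-map bins are masked NaN, not
zero. Every stochastic operation takes an explicit seed and is
bit-reproducible given (parameters, seed).

## Known limitations

* The point-source model ignores wall collimation; envelope volume is
  order-of-magnitude, near-aperture shear and speeds are inflated, and
  the rear lobe behind the source is an artifact of the idealization.
* No-slip at the substrate is not enforced (potential-flow image
  system).
* The synthetic fixtures inherit the reported values as ground truth;
  recovery demonstrates pipeline fidelity, not independent measurement.
* Nearest-neighbor linking degrades at densities or speeds where gates
  overlap; the packaged fixtures stay below that regime.
* Microtubule-length and gap-size readouts are exposed only as generic
  kymograph ridge analysis; their exact edge conventions in the source
  are unspecified.
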