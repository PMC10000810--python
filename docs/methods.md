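# Methods

This note documents the models behind `helict`, the conventions the
implementation fixes where several were possible, the parameters that
matter, and what the synthetic test bed does and does not demonstrate.

## Acquisition geometry and index conventions

All indices are 0-based. A standard scan records `N_p/2` projections over
exactly 180°, projection `k` at angle `2πk/N_p`. A helical scan records
`N_R·N_p` projections over `N_R` full revolutions at the same angular
spacing while the stage translates at constant speed; the dimensionless
pitch is `p = s_v·t/h_FOV` with `h_FOV = M·d`, and the per-projection row
advance is `v = p·M/N_p`. Global (virtual) row 0 coincides with detector
row 0 of projection 0, and the continuous global row of local row `i` in
frame `k` is `g = i + k·v`. "Down" is the reference stage direction; an
"up" scan is handled by reversing detector row order, which maps it onto
the down-scan algebra (the virtual rows then enumerate the object in the
opposite sense).

The virtual stack height is fixed as `M′ = M + ⌈v·(N_R·N_p − 1)⌉`. This is
a package convention: it is the smallest integer row count containing
every sample the scan acquired.

## The helical→standard conversion

Routing: `k′ = k mod (N_p/2)`; a frame is column-reversed
(`j → N−1−j`) when `⌊k/(N_p/2)⌋` is odd, which is exact for parallel beams
because the projector's rotation centre is the in-plane grid centre
`(N−1)/2` — the same centre the backprojector uses, so no sub-pixel
registration exists anywhere in the chain.

Row interpolation: virtual row `r` takes
`(1−w)·I[i₀] + w·I[i₀+1]`, `i₀ = ⌊r − k·v⌋`. We *define* `w` as the
fractional part of `r − k·v` (equivalently `frac(−k·v)`, independent of
`r`), which makes the expression exact linear interpolation of the sampled
field and preserves `w = 0` at integral `k·v`. Other sign/offset
conventions for `w` circulate; this one is self-consistent with the
deposit formula and is what the exhaustive window-enumeration oracle in
the tests checks. Contributions that would need the nonexistent row `M`
are accepted only when `w = 0`; otherwise the frame simply does not serve
that row (the next rotation does) — no extrapolation ever happens.

Redundancy (`p < 2`): the default policy keeps the contribution from the
earliest rotation (smallest `k`) and discards later duplicates; an
`average` policy exists but is non-default, because averaging mixes
rotations and re-introduces a coherence path for fixed-pattern errors.
Gaps (`p > 2`): rows no rotation covered are NaN, flagged in the stack
mask, reported in provenance, and skipped by the reconstructor. Rows near
the scan start/end are intrinsically incomplete for some `k′` (the helix
ramps onto and off the object); these "edge rows" are flagged separately
from true inter-rotation gaps, which exist iff `p > 2`.

## Forward model (simulator)

The projector computes parallel-beam line integrals of δ and β by bilinear
resampling (`grid-constant` boundary, so values are continuous across the
grid edge) and summing along rays on a unit-spaced lattice; projections at
`θ` and `θ+π` are mirror-exact by construction. Propagation is the
*linearized TIE* operator

    I = exp(−(4π/λ)∫β ds) · (1 + z·∇²∫δ ds),

i.e. absorption times a defocus term proportional to the transverse
Laplacian of the phase-thickness (5-point finite-difference Laplacian,
edge-replicated). The sign is the one that makes a convex object produce
bright fringes outside its edge and that the Paganin filter (below)
inverts; the pair is tested by inversion. Full Fresnel diffraction,
polychromaticity, scatter and detector blur are *not* modelled: fringe
shapes far from the weak-defocus regime, and any resolution claims beyond
the sampling limit, are outside what the simulator can support.

Contrast is computed once per distinct rotation angle on the full phantom
height and then windowed to the detector rows of each frame (propagation
happens upstream of the detector crop — also the reason the defect-free
helical↔standard round trip closes to machine precision for integer `v`).
Fractional window offsets are linearly interpolated in z, mirroring the
conversion's row interpolation; for non-integer `v` the round trip is then
a one-row linear blur, which is the physically honest statement of what
the conversion can recover.

Detector model: mean counts × transmission × per-row flux profile ×
per-pixel gain, Poisson-sampled, stuck pixels overwritten, quantized to
16 bit. Flats share the gain/dead defects (so flat correction removes gain
rings up to flat noise but cannot fix stuck pixels); darks are zero-beam
frames. One master seed spawns independent streams for projections, flats
and darks. With no defects and `counts=None` the simulation is
deterministic, noise-free and stays floating point.

Default defect amplitudes (nowhere calibrated against a specific
instrument; chosen once as typical of scintillator-coupled CMOS
detectors): gain std 1.5 %, 3 stuck pixels, 4 flats/darks, 2×10⁴ counts.

Default materials pin water to δ = 2.56·10⁻⁷, β = 1.28·10⁻¹⁰ at 30 keV
(δ ∝ E⁻², µ ∝ E⁻³ scaling elsewhere) and give the printed strand a δ/β of
exactly 2000 with ~1–2 % transmission contrast over a 0.5 mm strand — the
low-density regime the chain is designed for.

## Phase retrieval

Single-distance homogeneous-object filter

    T = −ln( F⁻¹[ F[I] / (1 + πλz(δ/β)|q|²) ] ),   |q| in cycles/m,

with unit DC gain (uniform `c` → `−ln c`; δ/β → 0 → plain `−ln`). Output
is the attenuation line integral `µ·thickness = (4π/λ)∫β ds`. Frames are
edge-padded to twice their size before the FFT; the beam is parallel so
magnification is 1 and the effective pixel is `d·binning`. Default order
of operations is flat/dark → convert → retrieve on the full-height virtual
frames (taller frames push the padding boundary away from the object; a
per-helical-frame mode is available by calling `tie_filter_stack` before
`convert`). Nonpositive pixels are masked up to a 1 % budget and floored
at the smallest positive value; beyond that the frame is rejected.

## Reconstruction

FBP with frequency-domain ramp (default) or Shepp-Logan filtering and
linear-interpolation backprojection; 4× zero-padding keeps the ramp
filter's DC leakage below ~1 % on a uniform disk. Rotation centre is
`(N−1)/2`, matching the projector; there is deliberately no
auto-centering. With sinogram values in attenuation·mm and the pixel size
supplied, a disk of attenuation µ reconstructs to µ per mm (verified to
2 % interior mean / 3 % RMSE, and cross-checked against
`skimage.transform.iradon` as an independent implementation). Angles must
be uniform over a half turn; a constant offset is allowed so odd/even
half-stacks reconstruct directly.

## Ring removal baselines

*Low-pass Fourier (Raven)*: a detector stripe is constant along angle, so
its energy sits on the zero-angular-frequency line of the 2D sinogram
spectrum. The filter is `H = 1 − (1 − e^{−u²/2σ_u²})·e^{−v²/2σ_v²}`
(σ_u = 10, σ_v = 1 in frequency-index units): a Gaussian low-pass along
the stripe line that leaves `H(0,0) = 1`, so the global mean is preserved
— a notch that also killed DC would shift every reconstruction value.

*Sorting-based*: each column is sorted along angle, a horizontal median of
window 10 (forced odd) removes the stripe from the sorted image, and the
permutation is inverted. An optional SNR gate (recommended 1.1–3.0)
detects large/unresponsive stripes from the median column profile
(deviation > SNR × 1.4826·MAD from a median-smoothed baseline) and
replaces flagged columns by linear interpolation across columns — the
exact interpolation used is a documented package choice. Isolated dead
columns are removed by the plain median already; the gate matters for
wide or partially responsive defect regions.

## Quality metrics

SNR = mean(fg)/σ and CNR = |mean(fg) − mean(bg)|/σ_bg from disjoint
foreground (object) and background ROIs of ≥ 25 samples. Whether σ in the
SNR should be the background's or the foreground's is ambiguous in common
usage; both are available (`noise_roi=`), background is the default.

Bar-pattern MTF: per group, modulation `(P − T)/(P + T)` from the
peak/trough of the profile averaged along the bars, normalized to the
lowest-frequency group (square-wave modulation without Coltman
correction — adequate because the cutoff is *defined* on the same bar
phantom it is measured on); cutoff = linear interpolation of the 10 %
crossing; groups beyond the sampling Nyquist are excluded with a warning.
Linewidth = 1000/(2f) µm.

FSC: unit-width shells of the 3D DFT,
`Re Σ F_a F_b* / √(Σ|F_a|² Σ|F_b|²)`, smoothed by a 5-shell moving
average (window a package default). FIRE is the reciprocal of the
smoothed curve's first 1/7 crossing, floored at 2 voxels (Nyquist); the
odd/even projection split (`split_half`) provides the two independent
reconstructions.

Ring residual: the slice is resampled to polar coordinates about the
rotation centre; rings are azimuthally coherent, so the score is the RMS
of (azimuthal mean − its radial Gaussian trend, σ = 4 px) over radii
inside the object support. It is rotation-invariant, near zero for smooth
phantoms, and ≈ A/√2 for a sinusoidal radial ripple of amplitude A. It is
*blind* to azimuthally incoherent noise only up to the 1/√(2πr)
averaging, so comparisons must be made at matched noise (dose).

## Dosimetry

`D = Ḋ·Δt·N_eff` with `N_eff = N_p/p` (helical; one pitch of travel) or
`N_p/2` (standard). Because the rate is measured at the beam centre, D is
the approximate *maximum* surface entry dose. The absolute full-flux rate
of any given beamline is never assumed: planned configurations are scaled
from a measured reference by `D_t = D_r·(Δt_t/Δt_r)·(N_eff,t/N_eff,r)`,
which reproduces an entire measured pitch series from any one row to
printed precision (two published entries are truncated rather than
rounded; the scaled values agree within ±0.01). A separate
`dose_as_published` computes the alternative low-dose convention
`Ḋ·Δt·N_p` (all acquired projections, no pitch division) — the two differ
by the factor p and are never silently mixed.

## The ring-comparison experiment (study conditions)

One water-equivalent cylinder is scanned helically (M = 32, N = 96,
N_p = 128, N_R = 2, p = 1.5) and in standard mode (M′ = 128 rows, 64
projections over 180°) with shared defects and matched surface dose
(helical counts scaled by p/2). Design choices, made once:

- **Attenuation-matched phantom.** The scaled-down cylinder (1.2 mm
  diameter at 13 µm voxels) would be nearly transparent; its material
  constants are raised ×9 so the path attenuation (T ≈ 0.7) matches a
  centimetre-scale water sample — defect-induced errors then have the
  realistic size relative to signal.
- **Band-limited phantom.** The material interface is Gaussian-smoothed by
  1.5 voxels; a voxel-sharp edge produces azimuthally symmetric FBP
  ringing that the ring metric would (correctly) count but that has
  nothing to do with detector defects.
- **Defects.** 1.5 % gain + 3 stuck pixels + one 2×7-pixel stuck patch
  (a damaged scintillator area) in the detector band both modes share.
  The patch is wide across columns — a width-10 median cannot bridge
  it — and shallow in rows, so the helix disperses it. Reconstruction
  rows sit on the defects: the worst case for the standard scan.
- **Filters as benchmarked.** Raven at σ = (10, 1); sorting at window 10
  without the SNR gate (the gate is a separate, tested feature).

Across seeds the helical reconstruction scores 6–12× below the raw
standard scan and below both filter outputs. What this shows: dispersal
beats filtering *for fixed-pattern defects* under matched dose. What it
does not show: performance on beam-instability rings, on defects taller
than the detector travel per half-turn (which helical acquisition cannot
disperse), or on real scintillator physics, none of which are modelled.

## Scaled-down problem sizes

All shipped experiments and tests run on reduced geometries (tens of
detector rows, ≤ 128 projections/revolution, ≤ 96-pixel slices) chosen so
the full suite completes in about two minutes on one core while every
mechanism — row interpolation, flip parity, redundancy discard, gap
flagging, ring dispersal — is exercised at full fidelity. The algebra of
the conversion is size-free; only noise floors and resolution limits
scale, and the tests state their tolerances accordingly.

## Known limitations

- Linearized TIE forward model only; no Fresnel propagator.
- No detector point-spread/optical blur; MTF calibrations use synthetic
  Gaussian blur with a known σ.
- No centre-of-rotation estimation, tilt, or fan/cone geometry.
- The flux-drop statistic depends on where the profile edges fall on a
  real beam; published per-instrument drop percentages are not
  reproducible without that instrument's flats (the closed-form Gaussian
  calibration is what the package certifies).
- Helical artifacts of real fly-scans (angular blur within a frame) are
  not modelled; frames are instantaneous.
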