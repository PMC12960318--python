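# Methods

This note documents the models, estimators and numerical choices
behind `maglevpiv`, and what the synthetic test rig does and does not
emulate.

## Coordinate conventions

Lengths are in mm, angles in degrees at every API boundary (radians
only inside trigonometric kernels), time in seconds. The global frame
(X, Y, Z) is fixed to the pump housing with Z from the volute mid-plane
toward the inlet; the rotor reference plane sits at Z = −5.15 mm and
the laser sheet at Z = −2.25 mm (0.5 mm thick) in the default rig. The
rotor-local frame has z along the spin axis and x along the leading
edge of the first main blade. A local point maps to the global frame
as `P = OR + R_z(α)·R_ψ(θ)·p`, where ψ = R_Z(φ)·Ŷ is the tilt axis,
R_ψ(θ) tilts Z onto the spin axis (azimuth φ, polar angle θ ∈ [0°,
90°), sign chosen so the axis has positive Z), and R_z(α) spins about
the tilted axis. Positive α is counterclockwise viewed from +Z; the
physical rotation sense of a given pump is not derivable from the
model and is a configuration choice.

## Forward model (synthetic rig)

The generator produces every input the inverse chain consumes, with
exact ground truth:

* **Motion.** Three modes applied to an ideal rotation: a centre shift
  (ΔX, ΔY), a mean tilt (θ_mean at azimuth φ_mean), and a synchronous
  precession — the instantaneous axis is the mean-tilt rotation
  applied to an axis inclined by θ_prec at azimuth α + φ_prec. The
  default parameters are the studied pump's measured decomposition:
  shift (−0.13, +0.04) mm, tilt 0.65° at 273°, precession 0.45° at
  275°, 2350 rpm. An optional pivot offset along the axis lets the
  wobble hinge below the reference plane. Tilt magnitudes are
  restricted to ≤ 5°: the inverse assumes the small-tilt regime.
* **Markers.** Each of the four blades carries an inner and an outer
  straight channel, `(x, y)(z) = (x0 + a z, y0 + b z)`; blades 2–4 are
  blade 1 rotated by 90° (base points *and* slope vectors). The
  default layout — inner base (11.5, 0) mm with slopes (0.20, 0.05),
  outer base (16.0, 0.8) mm with slopes (−0.15, 0.10) — is synthetic:
  it has the structure of the real part but not its proprietary
  dimensions. Channel/laser intersections are solved exactly per
  channel (the global Z of the transformed line is affine in the local
  height, so the intersection is one linear solve); each channel gets
  its own height. Intersections outside the physical height range
  [0, 6] mm are dropped with a warning.
* **Frames.** Dots are rendered as anisotropic Gaussian blobs
  (σ = 2.2 × 1.6 px, major axis along the dot's azimuth, mimicking the
  elliptical section of a slanted channel) on a 16-bit 896×848 px
  frame at 60 µm/px. Noiseless blob centroids reproduce the projected
  points to well under 0.05 px; dots closer than 3 px are flagged as
  overlapping.
* **Fields.** A solid-body-like swirl decaying outward plus four
  blade-locked Gaussian wake bumps rotated to the phase angle, with
  i.i.d. Gaussian noise amplified ×3 inside the wake so the
  phase-conditioned variance map flags the wake region.
* **Signals.** Pressure-head / rotor-moment traces as sums of
  sinusoids at integer multiples of the rotation frequency plus white
  noise; requesting an aliased harmonic is an error.

Default marker noise, when enabled, is σ = 30 µm (half a pixel); the
default seed is 20250 and every stochastic operation takes an explicit
seed or generator.

What the rig does **not** emulate: lens distortion and refraction,
ray-traced blob photometry, realistic pump hydrodynamics (the wake
bumps are phenomenological), marker manufacturing errors, or occlusion
physics. Passing tests therefore demonstrate the correctness and
noise behaviour of the estimators under the stated observation model,
not the accuracy of a particular laboratory rig.

## Inverse chain

1. **Detection** — threshold at background mean + 5σ, connected
   components of ≥ 4 px, intensity-weighted centroids.
2. **Calibration** — least-squares affine map px→mm from ≥ 3
   non-collinear reference points (the 4×4 drilled grid by default);
   collinear sets are rejected; the RMS residual is reported.
3. **Pairing** — centres are clustered by azimuth about a provisional
   centre (first frame: centroid of all dots; then the previous
   frame's centre), split at circular gaps > 30°; within a cluster the
   inner/outer roles follow the radial rank. Blade labels come from
   the expected azimuths at the hinted blade angle; a consistent
   cyclic mislabelling is harmless because relabelling by +90° in
   blade index is exactly compensated by −90° in α.
4. **Blade angle** — circular mean (on the 90° torus) of observed
   inner-dot azimuths minus the base-point azimuth at the observation
   height; unwrapped across frames by continuity with the expected
   per-frame advance `360·rpm/(60·fps)`.
5. **Heights** — the quadratic in `z_n` from the dot spacing. With the
   default geometry the linear coefficient `B = Δx0Δa + Δy0Δb` is
   negative, so *both* roots can be positive; the physical height
   range [0, 6] mm disambiguates, preferring the principal (+√δ) root
   when both are admissible. The discriminant tolerance is propagated
   from the configured marker noise (`2 σ d (Δa²+Δb²)`): slightly
   negative discriminants are clamped to zero, anything worse is
   rejected as a measurement inconsistency, as are negative or
   out-of-range heights.
6. **Reference points and pose** — `P_n` by back-projecting the inner
   dot along its channel by `z_n`. By default the full pose operator
   (tilt from the previous iterate) is applied; the fully simplified
   form (rotation about global Z only) is available via
   `tilt_correction=False` but carries a first-order in-tilt error of
   ~50 µm per point at 1°. The axis is the plane normal of the `P_n`
   (cross product for 3 points, total-least-squares SVD normal for 4,
   which reduces to the cross product at zero residual), the centre
   the mean of opposing-pair midpoints. α, heights, `P_n` and
   axis/centre are iterated to a fixed point (centre step < 1 µm and
   α step < 0.01°, max 10 iterations; non-convergence is flagged, not
   fatal).
7. **Exact refinement (default in the track pipeline)** — all six pose
   parameters fitted by Levenberg–Marquardt least squares against
   every observed dot coordinate, with each channel/laser intersection
   solved exactly under the candidate pose; the closed form seeds the
   fit. The axis is parameterised by its (x, y) components so the
   fit stays smooth through θ = 0. On noiseless data the refinement
   reproduces the generating pose to < 1e-9 mm/deg.

### Error budget of the closed form

The equal-height approximation (`z_in ≈ z_out`) is geometry-limited:
the default inner/outer channels are ~4.6 mm apart radially, so their
intersection heights differ to first order in the tilt (~80 µm/°). The
measured consequences over the default fixture motion (peak tilt
~1.1°): height error up to ~28 µm, centre error < 15 µm, blade-angle
error < 0.001°, and an axis error of ~0.11° per degree of tilt. Since
the recovered mean tilt and precession amplitudes would inherit part
of this as bias (~+0.07° on θ_mean), the track pipeline defaults to
the exact refinement and keeps the closed form for quantifying the
approximation — a dual-route design that the tests exercise against
each other.

## Motion decomposition

* **Motion centre** — `C(s, t) = OR(t) + s·axis(t)`; the projection
  distance s* minimises var_X + var_Y (the sum, a documented choice)
  over s ∈ [−20, 20] mm by bounded golden-section search (1 µm
  tolerance). A flat objective (ideal rotation) returns s* = 0 with a
  flag.
* **Mean axis** — spherical angles of the normalized arithmetic mean
  of the unit axes; ill-defined (error) if the mean vector's norm is
  < 0.5. A full revolution of data is needed for the precession to
  cancel out of the mean.
* **Precession** — the de-tilted axis is written as a small 2D tilt
  vector t = θ·(cos φ_dev, sin φ_dev); demodulation at the rotation
  frequency, `d = mean(t_k e^{−iα_k})`, gives θ_prec = |d| and
  φ_prec = arg d. This is the matched estimator for the slope-1
  synchronous model and is noise-unbiased to first order, unlike the
  plain mean inclination angle (reported separately as
  `mean_inclination_deg`), which is Rician-biased upward by ~0.14° at
  the default 30 µm marker noise. Samples with inclination < 0.05°
  are excluded from the azimuth-based synchrony diagnostic
  (`sync_slope`, a linear fit of unwrapped deviating azimuth vs
  unwrapped α) because a near-vertical axis has no defined azimuth.
* **Blade-Z prediction** — the fitted model applied to each blade's
  inner base point; for tilt-only motion the curves are sinusoids of
  peak-to-peak 2·r·sin θ.

Circular quantities use circular means throughout.

## Field statistics

Phase bins are 1° wide, bin k = floor(α mod 90) + 1, exploiting the
fourfold blade symmetry. Components are averaged before the magnitude
(so opposing vectors cancel — the defining property separating Ū from
a mean of magnitudes). `E_rel` normalises by the single scalar maximum
of the reference field over the jointly valid nodes, per phase angle;
RMS is reported in percent over the joint validity mask (boundary
handling of invalid nodes is by mask intersection, a documented
choice). Pressures are inlet-referenced and reported in mmHg
(133.322 Pa). σ_U is, as its source prints it, the *mean squared
deviation* of instantaneous magnitudes about Ū — dimensionally a
variance despite its name; a `sqrt=True` switch yields the proper
standard deviation and the printed form remains the default.
Regridding is linear in-plane (exact on affine fields, error ≤ h²/8
per direction times the curvature) with an unweighted mean over Z
levels inside the laser-sheet window (−2.5 to −2.0 mm by default);
nodes outside the source hull are masked. The out-of-plane check flags
nodes where |w|·Δt exceeds 25% of the sheet thickness (Δt = 100 µs at
10,000 fps).

## Flow metrics and spectra

Viscosity is the linear rheometer fit μ = μ0 + C_T·T (μ0 = 5.975e-3
Pa·s, C_T = −8.55e-5 Pa·s/°C), valid for 24–31 °C and warning outside.
Reynolds numbers: `Re = ρuD/μ` with the mean inlet velocity
u = Q/(πD²/4), and `Re_pump = ρω̇D²_rotor/μ` with ω̇ in rad/s (rpm
accepted at the API). Note the default operating point (ρ = 1164
kg/m³, μ = 0.0039 Pa·s, 4.4 L/min, 2350 rpm, D_inlet = 9.2 mm,
D_rotor = 44.9 mm) yields Re_inlet ≈ 3.0e3 and Re_pump ≈ 1.48e5 —
self-consistent values computed from the stated inputs; published
tabulations for this condition quote slightly different numbers
(2804; 137,100) that are mutually consistent only for μ ≈ 0.0042 Pa·s,
so the package reports only what the stated inputs imply.

PSDs use Welch's method (Hann window, segments of 4 rotor revolutions,
50% overlap, constant detrend); the frequency axis is normalized by
the rotation frequency and the estimate conserves variance to within
~2%. Mode detection takes local maxima of the dB spectrum at least
10 dB above a local median (window of 4 rotation orders, so a tone's
leakage skirt cannot inflate its own baseline) and within 100 dB of
the spectrum maximum (ripples of the numerical noise floor of a
noiseless synthetic signal are not physical modes). Peaks are matched
to the nearest integer rotation harmonic within ±2%; multiples of 4
are ordinary blade-passage harmonics (8 covers the secondary blades),
any other integer flags non-ideal rotation — the spectral signature by
which precession shows up in integral signals without any optical
tracking.

## Problem sizes and determinism

The test suite and the acceptance script run the recovery chain on one
revolution (256 frames at 2350 rpm / 10,000 fps, ~6 s including
rendering and detection), the noise study on five seeds of a full
revolution each, and Monte-Carlo fits on 400–1000 draws — sizes chosen
so the whole suite completes in well under a minute of numerics plus
the image chain. All randomness flows through explicit
`numpy.random.default_rng` seeds; noiseless chains are bit-stable
across seeds.

## Known limitations

* The closed-form inverse's axis accuracy is limited to ~0.11° per
  degree of tilt by the channel geometry (see error budget); use the
  default exact refinement when absolute axis accuracy matters.
* The blade-angle estimator ignores the tilt's azimuthal distortion
  (bounded < 0.2° at ≤ 1.1° tilt over a revolution); the exact
  refinement removes this too.
* Blade identity is only defined modulo 90° within a single frame;
  absolute labels rely on track continuity from the first frame.
* The synthetic wake/swirl fields are structural stand-ins, not
  hydrodynamics; comparison statistics validated on them say nothing
  about any real pump's flow.
* No temporal smoothing of pose tracks is applied — estimates are raw
  per-frame, by design.
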