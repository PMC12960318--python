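# maglevpiv

Single-camera 3D pose tracking for magnetically levitated blood-pump
impellers, with the phase-averaged PIV statistics used to compare
measured and simulated flow fields.

## The problem

Magnetically levitated (MagLev) centrifugal blood pumps suspend the
impeller without shafts or bearings, so the rotor is free to shift,
tilt and precess while it spins. CFD models of such pumps almost always
assume an ideal rotation; checking that assumption requires measuring
the full 3D rigid-body motion of the rotor — normally a stereoscopic
(two-camera) problem. This package implements a single-camera
alternative: each main blade carries two counter-angled fluorescent
marker channels, and where a channel pierces the PIV laser sheet it
appears as a bright dot. Because the two channels of a blade converge
with height, the *in-plane spacing* `d_n` of the dot pair encodes the
local blade height — the depth cue that makes full 3D pose recovery
from one camera view possible.

The package is aimed at experimentalists and CFD engineers working on
rotary blood pumps (or any small rotor in a light sheet) who want to

* quantify non-rotatory rotor motion from high-speed camera footage,
* generate synthetic, ground-truthed test data for such a rig, and
* compare phase-averaged velocity/pressure fields between modalities
  (PIV vs simulation, or two simulations) with the standard error
  statistics.

## The method

**Pose from dot pairs.** With rotor-local channel lines
`x(z) = x0 + a z`, `y(z) = y0 + b z`, the spacing of a blade's dot pair
obeys (neglecting the small height difference between the two
channels' intersections)

    d_n² = (Δa_n z_n + Δx_n0)² + (Δb_n z_n + Δy_n0)²,

a quadratic whose admissible root gives the local height `z_n` at the
laser sheet. Back-projecting the inner dot along its channel by `z_n`
yields a reference point `P_n` on the rotor reference plane; three or
more `P_n` give the spin axis (plane normal, `z⃗ = P_nP_m × P_nP_l`)
and the rotor centre (mean of opposing-pair midpoints). The blade
angle α follows from the dot azimuths modulo the fourfold blade
symmetry. An exact variant solves all six pose parameters by nonlinear
least squares against every dot coordinate using the exact
channel/laser intersection; it serves as the oracle that quantifies
the closed form's approximation error.

**Motion decomposition.** A pose track is summarised by three modes:
a shift of the motion centre (found by projecting the centre along the
instantaneous axis to the distance of minimal scatter), a mean tilt
(θ_mean, φ_mean), and a synchronous precession of the instantaneous
axis about the mean axis (θ_prec at azimuth α + φ_prec), estimated by
demodulating the de-tilted tilt vector at the rotation frequency.

**Field statistics.** Velocity snapshots are phase-binned in 1° bins
modulo 90°, components averaged first (`Ū = √(ū_X² + ū_Y²)`), and two
fields are compared via `E_rel,i = (Ū_i − Ū_ref,i)/max(Ū_ref)`, its
RMS in percent, nodewise pressure errors in mmHg, the
phase-conditioned variability σ_U, and an out-of-plane displacement
check against 25% of the laser-sheet thickness. Flow regimes use
`Re = ρuD/μ`, `Re_pump = ρω̇D_rotor²/μ`, and pipe-flow turbulence
boundary conditions `I = 0.16 Re^(−1/8)`, `l = 0.07 D_h`. Power
spectra of integral signals (pressure head, rotor moment) flag
non-ideal rotation: an ideal fourfold impeller only excites multiples
of 4 of the rotation frequency, so any other rotation harmonic is a
wobble signature.

## Worked example

Recover the three-mode motion of the built-in synthetic rig (2350 rpm,
10,000 fps, 896×848 px at 60 µm/px) through the full image chain —
render frames, detect dots, calibrate, pair, reconstruct, decompose:

```python
from maglevpiv.workbench import run_fixture_recovery

summary = run_fixture_recovery(seed=20250, from_images=True)
print(summary.to_yaml())
```

```
center_x_mm: -0.1299413855607601
center_y_mm: 0.039914108453543
theta_mean_deg: 0.6489675204978866
phi_mean_deg: 272.98525128820944
theta_prec_deg: 0.4490384112826806
phi_prec_deg: 274.91429925863275
sync_slope: 0.998417602052981
blade_z_range_mm: 0.44003974536514256
```

The generator's ground truth is a centre shift of (−0.13, +0.04) mm, a
mean tilt of 0.65° at azimuth 273°, and a synchronous precession of
0.45° at 275° from the first main blade — all recovered to within the
detection noise of the rendered images. `sync_slope ≈ 1` confirms the
precession is locked to the rotation; `blade_z_range_mm` is the
resulting vertical travel of the blade reference points.

Flow-regime numbers for the studied operating point (4.4 L/min,
2350 rpm, blood analog at 24.3 °C):

```bash
$ maglevpiv regimes
{
  "mu_pa_s": 0.003897,
  "re_inlet": 3031.1,
  "re_pump": 148174.2,
  "i_turb": 0.058738,
  "l_turb_mm": 0.644
}
```

i.e. transitional pipe flow in the inlet cannula and a fully turbulent
pump Reynolds number. Other CLI commands: `simulate` (synthetic fixture
bundles), `reconstruct` (tracks → pose CSV + motion summary),
`compare` (two field bundles → per-phase RMS and error PDFs), `psd`
(integral signals → spectra and the non-ideal-rotation flag).

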