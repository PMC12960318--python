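"""Forward model of the optical rig: marker tracks, frames, fields, signals.

This module is the ground-truth generator for the whole package.  It
emulates the measurement chain of a single-camera impeller tracker:

* a rotor whose motion deviates from ideal rotation by three small
  modes — a lateral shift of the motion centre, a constant tilt of the
  mean spin axis, and a synchronous precession of the instantaneous
  axis about the mean axis;
* four blades, each carrying an inner and an outer straight fluorescent
  channel; where a channel pierces the laser sheet it shows up as a
  bright dot in the camera image.  The in-plane spacing of the two dots
  of a blade encodes the local blade height — the depth cue that makes
  single-camera 3D pose recovery possible;
* gridded velocity snapshots with a smooth swirling base flow plus
  blade-locked wake perturbations, for exercising the phase-averaging
  statistics;
* integral signals (pressure head, rotor Z-moment) as sums of harmonics
  of the rotation frequency, for the spectral mode diagnostic.

The channel-laser intersections are solved **exactly** (per-channel
line/plane intersection, no equal-height approximation), so downstream
inverse operators can be tested against an exact oracle.

The default motion model and optical layout mirror the studied
operating condition of a clinical centrifugal pump: 2350 rpm imaged at
10,000 fps with about 60 µm/px, a 0.5 mm laser sheet 2.25 mm below the
housing mid-plane and the rotor reference plane at Z = −5.15 mm.  The
channel base positions and slopes are synthetic placeholders with the
same structure as the real part, not the manufacturer's geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateGeometryError
from .geometry import (
    RotationSpec,
    RotorPose,
    Z_HAT,
    axis_from_angles,
    angles_from_axis,
    local_to_global,
    pose_matrix,
    rotation_matrix,
    tilt_axis,
)

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20250

__all__ = [
    "ChannelGeometry",
    "MotionModel",
    "LaserPlane",
    "MarkerObservation",
    "ImageSpec",
    "GridSpec",
    "FieldSnapshot",
    "default_channel_geometry",
    "default_motion_model",
    "default_laser_plane",
    "default_image_spec",
    "reference_grid_mm",
    "pose_at",
    "synth_trajectory",
    "project_channels",
    "render_frame",
    "synth_field",
    "synth_signals",
    "observations_to_frame",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_fields_h5",
    "read_fields_h5",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class ChannelGeometry:
    """Inner/outer marker-channel lines of the four main blades.

    A channel centreline of blade ``n`` is the straight line

        x(z) = x0 + a * z,   y(z) = y0 + b * z

    in rotor-local coordinates, where ``z`` is the height above the
    rotor reference plane.  ``base`` holds the base points (x0, y0) and
    ``slope`` the lateral slopes (a, b), both indexed ``[blade, channel,
    xy]`` with blade 0..3 and channel 0 = inner, 1 = outer.  Blade n+1
    is blade n rotated by 90 degrees about the local z axis (fourfold
    symmetry of the impeller).
    """

    base: np.ndarray   # (4, 2, 2) mm
    slope: np.ndarray  # (4, 2, 2) mm per mm height

    def __post_init__(self) -> None:
        base = np.asarray(self.base, dtype=float)
        slope = np.asarray(self.slope, dtype=float)
        if base.shape != (4, 2, 2) or slope.shape != (4, 2, 2):
            raise ConfigError("channel geometry arrays must have shape (4, 2, 2)")
        dslope = slope[:, 1, :] - slope[:, 0, :]
        if np.any(np.linalg.norm(dslope, axis=1) == 0.0):
            raise ConfigError(
                "inner and outer channel slopes must differ for every blade "
                "(otherwise the dot spacing carries no height information)")
        object.__setattr__(self, "base", base)
        object.__setattr__(self, "slope", slope)

    @classmethod
    def fourfold(cls,
                 inner_base: tuple[float, float],
                 inner_slope: tuple[float, float],
                 outer_base: tuple[float, float],
                 outer_slope: tuple[float, float]) -> "ChannelGeometry":
        """Build the full geometry from blade 1 by successive 90° rotations
        of base points *and* slope vectors about the local z axis."""
        base = np.empty((4, 2, 2))
        slope = np.empty((4, 2, 2))
        b1 = np.array([inner_base, outer_base], dtype=float)
        s1 = np.array([inner_slope, outer_slope], dtype=float)
        for n in range(4):
            ang = np.deg2rad(90.0 * n)
            rot = np.array([[np.cos(ang), -np.sin(ang)],
                            [np.sin(ang), np.cos(ang)]])
            base[n] = b1 @ rot.T
            slope[n] = s1 @ rot.T
        return cls(base=base, slope=slope)

    # Per-blade differences entering the height solver.  The scalar
    # combinations B = dx0*da + dy0*db, |dslope|^2 and d0 are invariant
    # under the fourfold rotation, so all blades share one quadratic.
    def deltas(self, blade: int) -> tuple[float, float, float, float]:
        """(dx0, dy0, da, db) of ``blade`` (1-based)."""
        i = blade - 1
        dx0, dy0 = self.base[i, 1] - self.base[i, 0]
        da, db = self.slope[i, 1] - self.slope[i, 0]
        return float(dx0), float(dy0), float(da), float(db)

    def d0(self, blade: int) -> float:
        """Dot spacing when the laser lies in the reference plane (z=0)."""
        dx0, dy0, _, _ = self.deltas(blade)
        return float(np.hypot(dx0, dy0))

    def channel_line(self, blade: int, channel: str) -> tuple[np.ndarray, np.ndarray]:
        """Local 3D line ``p0 + u*z`` of a channel; ``u = (a, b, 1)``."""
        c = {"in": 0, "out": 1}[channel]
        i = blade - 1
        p0 = np.array([self.base[i, c, 0], self.base[i, c, 1], 0.0])
        u = np.array([self.slope[i, c, 0], self.slope[i, c, 1], 1.0])
        return p0, u


@dataclass(frozen=True)
class MotionModel:
    """Three-mode departure from ideal rotation plus the rotation rate.

    The modes are applied to an ideal rotation in order:

    1. *shift*: the motion centre sits at (shift_x, shift_y) instead of
       the housing origin;
    2. *mean tilt*: the mean spin axis is tilted by ``theta_mean_deg``
       at azimuth ``phi_mean_deg``;
    3. *synchronous precession*: the instantaneous axis is further
       inclined by ``theta_prec_deg`` at azimuth ``alpha +
       phi_prec_deg`` measured about the mean axis, i.e. the tilt
       rotates once per revolution, locked to the first main blade.

    ``pivot_distance_mm`` places the fixed pivot of the wobble at a
    signed distance along the axis from the rotor reference plane
    (0 keeps the centre OR itself fixed).
    """

    shift_x_mm: float = 0.0
    shift_y_mm: float = 0.0
    rotor_plane_z_mm: float = -5.15
    theta_mean_deg: float = 0.0
    phi_mean_deg: float = 0.0
    theta_prec_deg: float = 0.0
    phi_prec_deg: float = 0.0
    rotation_rate_rpm: float = 2350.0
    pivot_distance_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.rotation_rate_rpm <= 0:
            raise ConfigError("rotation rate must be positive")
        for name in ("theta_mean_deg", "theta_prec_deg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 5.0):
                raise ConfigError(
                    f"{name}={v}: the reconstruction assumes the small-tilt "
                    "regime (0 to 5 degrees)")


@dataclass(frozen=True)
class LaserPlane:
    """Horizontal laser sheet ``Z = z_mm`` of finite thickness."""

    z_mm: float = -2.25
    thickness_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ConfigError("laser sheet thickness must be positive")


@dataclass
class MarkerObservation:
    """One channel/laser intersection dot.

    Global coordinates are in mm on the laser plane (Z implied); pixel
    coordinates are present when the observation came from an image.
    """

    frame_index: int
    blade: int | None
    channel: str
    x_mm: float
    y_mm: float
    x_px: float | None = None
    y_px: float | None = None


@dataclass(frozen=True)
class ImageSpec:
    """Camera/image model: pixel grid, scale and blob appearance.

    Pixel (0, 0) is the top-left sample; the global (X, Y) origin maps
    to the image centre.  ``scale_um_per_px`` is the uniform optical
    magnification.
    """

    width_px: int = 896
    height_px: int = 848
    scale_um_per_px: float = 60.0
    center_mm: tuple[float, float] = (0.0, 0.0)
    blob_sigma_px: tuple[float, float] = (2.2, 1.6)
    intensity: float = 20000.0
    background: float = 400.0
    noise_sd: float = 0.0

    @property
    def scale_mm(self) -> float:
        return self.scale_um_per_px / 1000.0

    def mm_to_px(self, xy_mm: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy_mm, dtype=float))
        c = np.array([(self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0])
        return (xy - np.asarray(self.center_mm)) / self.scale_mm + c

    def px_to_mm(self, xy_px: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy_px, dtype=float))
        c = np.array([(self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0])
        return (xy - c) * self.scale_mm + np.asarray(self.center_mm)


# ---------------------------------------------------------------------------
# Default fixtures (the study conditions)


def default_motion_model() -> MotionModel:
    """Measured motion decomposition of the studied pump: centre shifted
    by (−0.13, +0.04) mm, mean axis tilted 0.65° at azimuth 273°,
    synchronous precession of 0.45° at 275° from the first main blade,
    at 2350 rpm with the reference plane at Z = −5.15 mm."""
    return MotionModel(
        shift_x_mm=-0.13, shift_y_mm=0.04, rotor_plane_z_mm=-5.15,
        theta_mean_deg=0.65, phi_mean_deg=273.0,
        theta_prec_deg=0.45, phi_prec_deg=275.0,
        rotation_rate_rpm=2350.0)


def default_channel_geometry() -> ChannelGeometry:
    """Synthetic channel layout (same structure as, but not identical to,
    any manufactured impeller): blade 1 inner channel based at
    (11.5, 0) mm with slopes (0.20, 0.05), outer at (16.0, 0.8) mm with
    slopes (−0.15, 0.10); blades 2–4 by 90° rotations."""
    return ChannelGeometry.fourfold(
        inner_base=(11.5, 0.0), inner_slope=(0.20, 0.05),
        outer_base=(16.0, 0.8), outer_slope=(-0.15, 0.10))


def default_laser_plane() -> LaserPlane:
    return LaserPlane(z_mm=-2.25, thickness_mm=0.5)


def default_image_spec() -> ImageSpec:
    return ImageSpec()


DEFAULT_FPS = 10000.0

#: Default physical height range of the marker channels above the
#: reference plane, mm.  Intersections outside it are dropped.
DEFAULT_Z_RANGE = (0.0, 6.0)


def reference_grid_mm(pitch_mm: float = 5.0) -> np.ndarray:
    """A 4x4 calibration grid of hole positions (mm), centred on the
    global origin — the drilled reference pattern used to map pixels to
    millimetres."""
    line = (np.arange(4) - 1.5) * pitch_mm
    gx, gy = np.meshgrid(line, line, indexing="xy")
    return np.column_stack([gx.ravel(), gy.ravel()])


# ---------------------------------------------------------------------------
# Trajectory synthesis


def pose_at(model: MotionModel, alpha_deg: float,
            frame_index: int = 0, time_s: float = 0.0) -> RotorPose:
    """Rotor pose implied by the three-mode model at blade angle alpha.

    The instantaneous axis is the mean-tilt rotation applied to an axis
    inclined by ``theta_prec`` at azimuth ``alpha + phi_prec``; the
    centre follows from the fixed pivot.
    """
    r_mean = rotation_matrix(RotationSpec(tilt_axis(model.phi_mean_deg),
                                          model.theta_mean_deg))
    axis = r_mean @ axis_from_angles(alpha_deg + model.phi_prec_deg,
                                     model.theta_prec_deg)
    phi, theta = angles_from_axis(axis)
    pivot = np.array([model.shift_x_mm, model.shift_y_mm,
                      model.rotor_plane_z_mm + model.pivot_distance_mm])
    center = pivot - model.pivot_distance_mm * axis
    return RotorPose(center=center, phi_deg=phi, theta_deg=theta,
                     alpha_deg=alpha_deg % 360.0,
                     frame_index=frame_index, time_s=time_s)


def synth_trajectory(model: MotionModel, n_frames: int,
                     fps: float = DEFAULT_FPS,
                     alpha0_deg: float = 0.0,
                     noise_mm: float = 0.0,
                     noise_deg: float = 0.0,
                     seed: int | None = None) -> list[RotorPose]:
    """Pose track of ``n_frames`` frames at ``fps``.

    The blade angle advances by ``360 * rpm / (60 * fps)`` per frame.
    Optional Gaussian noise perturbs the centre (``noise_mm``, per axis
    in X and Y) and the angles (``noise_deg`` on alpha, and on the axis
    as a random small additional tilt).
    """
    if fps <= 0:
        raise ConfigError("fps must be positive")
    if n_frames < 1:
        raise ConfigError("need at least one frame")
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    step = 360.0 * model.rotation_rate_rpm / (60.0 * fps)
    poses = []
    for i in range(n_frames):
        t = i / fps
        pose = pose_at(model, alpha0_deg + step * i, frame_index=i, time_s=t)
        if noise_mm > 0.0:
            pose.center = pose.center + np.array(
                [rng.normal(0, noise_mm), rng.normal(0, noise_mm), 0.0])
        if noise_deg > 0.0:
            jitter = rotation_matrix(RotationSpec(
                tilt_axis(rng.uniform(0, 360)), abs(rng.normal(0, noise_deg))))
            phi, theta = angles_from_axis(jitter @ pose.axis)
            pose = RotorPose(center=pose.center, phi_deg=phi, theta_deg=theta,
                             alpha_deg=pose.alpha_deg + rng.normal(0, noise_deg),
                             frame_index=i, time_s=t)
        poses.append(pose)
    return poses


# ---------------------------------------------------------------------------
# Exact channel projection (the forward oracle)


def project_channels(pose: RotorPose, geom: ChannelGeometry,
                     plane: LaserPlane,
                     z_range: tuple[float, float] = DEFAULT_Z_RANGE,
                     noise_mm: float = 0.0,
                     rng: np.random.Generator | None = None) -> list[MarkerObservation]:
    """Exact intersections of every channel centreline with the laser plane.

    Each channel is the local line ``p0 + u*z`` mapped to the global
    frame by the pose; its intersection with ``Z = Z_L`` is a linear
    solve in the local height ``z`` (each channel gets its own height —
    no equal-height approximation).  This is the oracle the inverse
    pipeline is validated against.
    """
    m = pose_matrix(pose)
    obs: list[MarkerObservation] = []
    if noise_mm > 0.0 and rng is None:
        rng = np.random.default_rng(DEFAULT_SEED)
    for blade in (1, 2, 3, 4):
        for channel in ("in", "out"):
            p0, u = geom.channel_line(blade, channel)
            base_g = pose.center + m @ p0
            dir_g = m @ u
            if abs(dir_g[2]) < 1e-12:
                raise DegenerateGeometryError(
                    f"channel {channel} of blade {blade} is parallel to the laser plane")
            z = (plane.z_mm - base_g[2]) / dir_g[2]
            if not (z_range[0] <= z <= z_range[1]):
                logger.warning(
                    "blade %d %s channel: intersection height %.3f mm outside "
                    "physical range %s; observation dropped", blade, channel, z, z_range)
                continue
            p = base_g + z * dir_g
            x, y = float(p[0]), float(p[1])
            if noise_mm > 0.0:
                x += rng.normal(0.0, noise_mm)
                y += rng.normal(0.0, noise_mm)
            obs.append(MarkerObservation(frame_index=pose.frame_index,
                                         blade=blade, channel=channel,
                                         x_mm=x, y_mm=y))
    return obs


# ---------------------------------------------------------------------------
# Frame rendering


def render_frame(observations: Sequence[MarkerObservation], spec: ImageSpec,
                 seed: int | None = None,
                 extra_points_mm: np.ndarray | None = None) -> np.ndarray:
    """Render marker dots as anisotropic Gaussian blobs on a 16-bit frame.

    Each dot's major blob axis is aligned with its azimuth about the
    image centre (mimicking the elliptical cross-section of a slanted
    channel).  In the noiseless case the intensity-weighted centroid of
    a rendered blob reproduces the projected point to well under 0.05 px.
    ``extra_points_mm`` adds isotropic dots (e.g. a calibration grid).
    """
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    img = np.full((spec.height_px, spec.width_px), float(spec.background))
    if spec.noise_sd > 0.0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)

    pts_mm = [np.array([o.x_mm, o.y_mm]) for o in observations]
    if extra_points_mm is not None:
        pts_mm += [np.asarray(p, dtype=float) for p in np.atleast_2d(extra_points_mm)]
    if not pts_mm:
        return np.clip(img, 0, 65535).astype(np.uint16)

    centers_px = spec.mm_to_px(np.array(pts_mm))
    # flag dots closer than 3 px: their blobs overlap and bias centroids
    for i in range(len(centers_px)):
        for j in range(i + 1, len(centers_px)):
            dist = np.linalg.norm(centers_px[i] - centers_px[j])
            if dist < 3.0:
                logger.warning("markers %d and %d only %.2f px apart: "
                               "blob overlap likely", i, j, dist)

    sx, sy = spec.blob_sigma_px
    half = int(np.ceil(5.0 * max(sx, sy)))
    for (cx, cy) in centers_px:
        if not (0 <= cx < spec.width_px and 0 <= cy < spec.height_px):
            logger.info("marker at (%.1f, %.1f) px outside field of view, skipped",
                        cx, cy)
            continue
        ang = np.arctan2(cy - (spec.height_px - 1) / 2.0,
                         cx - (spec.width_px - 1) / 2.0)
        ca, sa = np.cos(ang), np.sin(ang)
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        xs = np.arange(max(x0, 0), min(x1, spec.width_px))
        ys = np.arange(max(y0, 0), min(y1, spec.height_px))
        gx, gy = np.meshgrid(xs - cx, ys - cy)
        u = ca * gx + sa * gy
        v = -sa * gx + ca * gy
        img[np.ix_(ys, xs)] += spec.intensity * np.exp(
            -0.5 * (u / sx) ** 2 - 0.5 * (v / sy) ** 2)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# Velocity-field synthesis


@dataclass(frozen=True)
class GridSpec:
    """Uniform in-plane Eulerian grid, mm."""

    x_min: float = 0.0
    x_max: float = 30.0
    y_min: float = -30.0
    y_max: float = 0.0
    dx: float = 0.5

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        if self.dx <= 0:
            raise ConfigError("grid resolution must be positive")
        x = np.arange(self.x_min, self.x_max + 0.5 * self.dx, self.dx)
        y = np.arange(self.y_min, self.y_max + 0.5 * self.dx, self.dx)
        return x, y

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        x, y = self.axes()
        return np.meshgrid(x, y, indexing="xy")


@dataclass
class FieldSnapshot:
    """One velocity (and optionally pressure) snapshot on a grid.

    Velocities in m/s, pressure in Pa, coordinates in mm; ``alpha_deg``
    is the rotor phase the snapshot belongs to.
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray | None = None
    p: np.ndarray | None = None
    z_mm: np.ndarray | None = None
    alpha_deg: float = 0.0
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.u.shape != self.x_mm.shape or self.v.shape != self.x_mm.shape:
            raise ConfigError("field component arrays must match the grid shape")
        self.alpha_deg = float(self.alpha_deg) % 360.0


@dataclass(frozen=True)
class SwirlParams:
    """Solid-body-like swirl decaying outward: at radius r from the
    rotor axis the tangential speed is ``omega * r * exp(-(r/r_core)^2)``."""

    omega: float = 30.0       # 1/s equivalent angular scale
    r_core_mm: float = 20.0


@dataclass(frozen=True)
class WakeParams:
    """Four blade-locked Gaussian wake bumps, rotated to the phase angle."""

    amplitude: float = 0.8        # m/s tangential excess at bump centre
    radius_mm: float = 16.0       # radial location of the bumps
    sigma_mm: float = 2.0         # bump width
    noise_ratio: float = 3.0      # fluctuation amplification inside the wake


def _wake_weight(x: np.ndarray, y: np.ndarray, alpha_deg: float,
                 wake: WakeParams) -> np.ndarray:
    r = np.hypot(x, y)
    az = np.arctan2(y, x)
    weight = np.zeros_like(x, dtype=float)
    for k in range(4):
        blade_az = np.deg2rad(alpha_deg + 90.0 * k)
        dar = (az - blade_az + np.pi) % (2 * np.pi) - np.pi
        ds2 = ((r - wake.radius_mm) ** 2 + (r * dar) ** 2) / wake.sigma_mm ** 2
        weight += np.exp(-0.5 * ds2)
    return weight


def synth_field(grid: GridSpec, alpha_deg: float,
                swirl: SwirlParams = SwirlParams(),
                wake: WakeParams = WakeParams(),
                noise_sd: float = 0.0,
                with_w: bool = False,
                with_p: bool = False,
                rho_kg_m3: float = 1164.0,
                seed: int | None = None) -> FieldSnapshot:
    """Deterministic swirl + phase-locked wakes + i.i.d. Gaussian noise.

    With ``noise_sd = 0`` the snapshot is a pure function of the phase
    angle; ensemble means of noisy snapshots at fixed phase converge to
    that noiseless field.  The noise is amplified inside the wake bumps
    by ``wake.noise_ratio`` so that the phase-conditioned variance map
    flags the wake, as it does in a real turbulent blade wake.
    """
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    x, y = grid.mesh()
    r = np.hypot(x, y)
    az = np.arctan2(y, x)
    ut = swirl.omega * (r / 1000.0) * np.exp(-(r / swirl.r_core_mm) ** 2)
    weight = _wake_weight(x, y, alpha_deg, wake)
    ut = ut + wake.amplitude * weight
    u = -ut * np.sin(az)
    v = ut * np.cos(az)
    if noise_sd > 0.0:
        sigma = noise_sd * (1.0 + (wake.noise_ratio - 1.0) * weight)
        u = u + rng.normal(0.0, 1.0, u.shape) * sigma
        v = v + rng.normal(0.0, 1.0, v.shape) * sigma
    w = None
    if with_w:
        w = 0.3 * wake.amplitude * weight
        if noise_sd > 0.0:
            w = w + rng.normal(0.0, noise_sd, w.shape)
    p = None
    if with_p:
        # centrifugal pressure rise of the swirl, relative to the centre
        p = 0.5 * rho_kg_m3 * ut ** 2
    return FieldSnapshot(x_mm=x, y_mm=y, u=u, v=v, w=w, p=p,
                         alpha_deg=alpha_deg, source="synthetic")


# ---------------------------------------------------------------------------
# Integral signals


def synth_signals(f_rot_hz: float, harmonics: dict[int, float],
                  duration_s: float, fs_hz: float,
                  noise_sd: float = 0.0,
                  phases_deg: dict[int, float] | None = None,
                  seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sum of sinusoids at integer multiples of the rotation frequency.

    Returns ``(t, x)``.  Raises if any harmonic would alias
    (``fs <= 2 * k * f_rot``).
    """
    if harmonics and fs_hz <= 2.0 * max(harmonics) * f_rot_hz:
        raise ConfigError(
            f"sampling rate {fs_hz} Hz aliases harmonic k={max(harmonics)} "
            f"of f_rot={f_rot_hz} Hz")
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    t = np.arange(0.0, duration_s, 1.0 / fs_hz)
    x = np.zeros_like(t)
    phases_deg = phases_deg or {}
    for k, amp in harmonics.items():
        ph = np.deg2rad(phases_deg.get(k, 0.0))
        x += amp * np.sin(2 * np.pi * k * f_rot_hz * t + ph)
    if noise_sd > 0.0:
        x += rng.normal(0.0, noise_sd, t.shape)
    return t, x


# ---------------------------------------------------------------------------
# Serialization of fixture bundles

TRACK_COLUMNS = ["frame", "blade", "channel", "X_mm", "Y_mm", "x_px", "y_px"]


def observations_to_frame(obs: Sequence[MarkerObservation]) -> pd.DataFrame:
    rows = [(o.frame_index, -1 if o.blade is None else o.blade, o.channel,
             o.x_mm, o.y_mm,
             np.nan if o.x_px is None else o.x_px,
             np.nan if o.y_px is None else o.y_px) for o in obs]
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def write_tracks_csv(path: str | Path, obs: Sequence[MarkerObservation]) -> None:
    observations_to_frame(obs).to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> list[MarkerObservation]:
    df = pd.read_csv(path)
    return [MarkerObservation(
        frame_index=int(r.frame),
        blade=None if r.blade < 0 else int(r.blade),
        channel=str(r.channel), x_mm=float(r.X_mm), y_mm=float(r.Y_mm),
        x_px=None if pd.isna(r.x_px) else float(r.x_px),
        y_px=None if pd.isna(r.y_px) else float(r.y_px))
        for r in df.itertuples(index=False)]


def write_fields_h5(path: str | Path, snapshots: Sequence[FieldSnapshot]) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        grp = h5.create_group("snapshots")
        for i, s in enumerate(snapshots):
            g = grp.create_group(str(i))
            g.create_dataset("X", data=s.x_mm)
            g.create_dataset("Y", data=s.y_mm)
            g.create_dataset("u", data=s.u)
            g.create_dataset("v", data=s.v)
            if s.w is not None:
                g.create_dataset("w", data=s.w)
            if s.p is not None:
                g.create_dataset("p", data=s.p)
            g.attrs["alpha_deg"] = s.alpha_deg
            g.attrs["source"] = s.source


def read_fields_h5(path: str | Path) -> list[FieldSnapshot]:
    import h5py

    out = []
    with h5py.File(path, "r") as h5:
        grp = h5["snapshots"]
        for key in sorted(grp, key=int):
            g = grp[key]
            out.append(FieldSnapshot(
                x_mm=g["X"][...], y_mm=g["Y"][...],
                u=g["u"][...], v=g["v"][...],
                w=g["w"][...] if "w" in g else None,
                p=g["p"][...] if "p" in g else None,
                alpha_deg=float(g.attrs["alpha_deg"]),
                source=str(g.attrs.get("source", "unknown"))))
    return out
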