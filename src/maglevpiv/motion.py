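"""Decomposition of a rotor pose track into the three motion modes.

A levitated impeller's departure from ideal rotation is summarised by
three modes, fitted here in sequence:

1. **Shift** — the fixed motion centre.  The per-frame centre OR wanders
   in a torus when the rotor wobbles, but projecting it along the
   instantaneous axis by the right distance collapses the cloud to a
   single cluster; the projection distance is found by minimising the
   summed X/Y variance of the projected centre.
2. **Mean tilt** — spherical angles of the normalized mean of the
   instantaneous axis directions.
3. **Synchronous precession** — inclination of the instantaneous axis
   to the mean axis, and the phase offset of its azimuth (the
   *deviating azimuth*, i.e. the axis azimuth after removing the mean
   tilt) relative to the blade angle.  The model fixes the precession
   to be synchronous with the rotation (slope one); the fitted slope is
   reported only as a diagnostic.

Circular quantities use circular means throughout; plain averages
would be wrong near the 0/360 wrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.optimize import minimize_scalar

from .errors import InsufficientDataError
from .geometry import (RotationSpec, RotorPose, angles_from_axis,
                       axis_from_angles, local_to_global, rotation_matrix,
                       tilt_axis)
from .synthetic import ChannelGeometry, MotionModel, pose_at

logger = logging.getLogger(__name__)

__all__ = [
    "MotionCenter",
    "PrecessionFit",
    "MotionSummary",
    "find_motion_center",
    "mean_axis",
    "deviating_azimuth",
    "fit_precession",
    "predict_blade_z",
    "decompose",
]

#: Axis samples closer than this to the mean axis carry almost no
#: azimuth information and are down-weighted in circular fits.
MIN_AZIMUTH_TILT_DEG = 0.05


@dataclass
class MotionCenter:
    """Motion-centre search result."""

    s_star_mm: float
    mean_mm: np.ndarray          # (3,) cluster mean at s*
    std_mm: np.ndarray           # (2,) per-axis std in X, Y
    flat_objective: bool = False


@dataclass
class PrecessionFit:
    theta_prec_deg: float
    phi_prec_deg: float | None
    sync_slope: float | None
    mean_inclination_deg: float = 0.0
    low_confidence: bool = False


@dataclass
class MotionSummary:
    """Fitted three-mode motion of the rotor."""

    center_x_mm: float
    center_y_mm: float
    center_std_x_mm: float
    center_std_y_mm: float
    s_star_mm: float
    rotor_plane_z_mm: float
    theta_mean_deg: float
    phi_mean_deg: float
    theta_prec_deg: float
    phi_prec_deg: float | None
    sync_slope: float | None
    blade_z_range_mm: float
    rotation_rate_rpm: float | None = None

    def to_motion_model(self) -> MotionModel:
        return MotionModel(
            shift_x_mm=self.center_x_mm, shift_y_mm=self.center_y_mm,
            rotor_plane_z_mm=self.rotor_plane_z_mm,
            theta_mean_deg=self.theta_mean_deg, phi_mean_deg=self.phi_mean_deg,
            theta_prec_deg=self.theta_prec_deg,
            phi_prec_deg=self.phi_prec_deg or 0.0,
            rotation_rate_rpm=self.rotation_rate_rpm or 1.0,
            pivot_distance_mm=self.s_star_mm)

    def to_yaml(self) -> str:
        d = {k: (None if v is None else float(v))
             for k, v in self.__dict__.items()}
        return yaml.safe_dump(d, sort_keys=False)


def _axes(poses: list[RotorPose]) -> np.ndarray:
    return np.array([p.axis for p in poses])


def _centers(poses: list[RotorPose]) -> np.ndarray:
    return np.array([p.center for p in poses])


def find_motion_center(poses: list[RotorPose],
                       s_range: tuple[float, float] = (-20.0, 20.0),
                       tol_mm: float = 1e-3) -> MotionCenter:
    """Projection distance along the axis that minimises centre scatter.

    Evaluates ``C(s, t) = OR(t) + s * axis(t)`` and minimises
    ``var_X + var_Y`` over ``s`` with a bounded golden-section search.
    A flat objective (ideal rotation: the centre never moves) returns
    ``s* = 0`` by convention, flagged.
    """
    if len(poses) < 10:
        raise InsufficientDataError("need >= 10 poses for the motion-centre search")
    centers = _centers(poses)
    axes = _axes(poses)

    def objective(s: float) -> float:
        c = centers + s * axes
        return float(c[:, 0].var() + c[:, 1].var())

    probe = [objective(s) for s in np.linspace(*s_range, 9)]
    flat = (max(probe) - min(probe)) < 1e-18
    if flat:
        s_star = 0.0
    else:
        res = minimize_scalar(objective, bounds=s_range, method="bounded",
                              options={"xatol": tol_mm})
        s_star = float(res.x)
    c = centers + s_star * axes
    return MotionCenter(s_star_mm=s_star, mean_mm=c.mean(axis=0),
                        std_mm=c[:, :2].std(axis=0), flat_objective=flat)


def mean_axis(poses: list[RotorPose]) -> tuple[float, float]:
    """Azimuth and polar angle (deg) of the normalized mean axis."""
    if len(poses) < 2:
        raise InsufficientDataError("need >= 2 poses for a mean axis")
    m = _axes(poses).mean(axis=0)
    if np.linalg.norm(m) < 0.5:
        raise InsufficientDataError("mean axis ill-defined (axes nearly cancel)")
    return angles_from_axis(m)


def deviating_azimuth(axis: np.ndarray, phi_mean_deg: float,
                      theta_mean_deg: float) -> float | None:
    """Azimuth of the axis after removing the mean tilt.

    Applies the inverse of the rotation that tilts Z onto the mean axis
    and reads off the residual azimuth.  Returns None (undefined) when
    the de-tilted axis is within 1e-6 degrees of Z.
    """
    detilt = rotation_matrix(RotationSpec(tilt_axis(phi_mean_deg),
                                          -theta_mean_deg))
    a = detilt @ np.asarray(axis, dtype=float)
    phi, theta = angles_from_axis(a)
    if theta < 1e-6:
        return None
    return phi


def _circular_mean_deg(angles_deg: np.ndarray,
                       weights: np.ndarray | None = None) -> float:
    rad = np.deg2rad(angles_deg)
    w = np.ones_like(rad) if weights is None else weights
    return float(np.rad2deg(np.arctan2(
        np.average(np.sin(rad), weights=w),
        np.average(np.cos(rad), weights=w))) % 360.0)


def fit_precession(poses: list[RotorPose],
                   phi_mean_deg: float, theta_mean_deg: float) -> PrecessionFit:
    """Precession inclination, phase offset and synchrony diagnostic.

    Each instantaneous axis is expressed, after removing the mean tilt,
    as a small 2D tilt vector ``t = theta * (cos phi_dev, sin phi_dev)``.
    For a precession locked to the rotation, ``t`` rotates with the
    blade angle, so demodulating at the rotation frequency,

        d = mean( t_k * exp(-i * alpha_k) ),

    gives the precession as amplitude ``theta_prec = |d|`` and phase
    offset ``phi_prec = arg(d)``.  Measurement noise enters this
    average vectorially and cancels, unlike the plain mean inclination
    angle (also reported, as ``mean_inclination_deg``), which is biased
    upward by noise.  ``sync_slope`` — the slope of the unwrapped
    deviating azimuth against the unwrapped blade angle — is a pure
    diagnostic; the model fixes it at one.
    """
    axes = _axes(poses)
    m_axis = rotation_matrix(RotationSpec(tilt_axis(phi_mean_deg),
                                          theta_mean_deg)) @ np.array([0.0, 0.0, 1.0])
    cosang = np.clip(axes @ m_axis, -1.0, 1.0)
    mean_incl = float(np.rad2deg(np.arccos(cosang)).mean())

    alphas = np.array([p.alpha_deg for p in poses])
    alpha_cov = np.ptp(np.unwrap(np.deg2rad(alphas)))
    low_conf = alpha_cov < np.pi

    detilt = rotation_matrix(RotationSpec(tilt_axis(phi_mean_deg),
                                          -theta_mean_deg))
    detilted = axes @ detilt.T
    theta_i = np.rad2deg(np.arccos(np.clip(detilted[:, 2], -1.0, 1.0)))
    phi_dev = np.arctan2(detilted[:, 1], detilted[:, 0])
    tilt_vec = theta_i * np.exp(1j * phi_dev)
    demod = np.mean(tilt_vec * np.exp(-1j * np.deg2rad(alphas)))
    theta_prec = float(np.abs(demod))

    if theta_prec < MIN_AZIMUTH_TILT_DEG:
        return PrecessionFit(theta_prec_deg=theta_prec, phi_prec_deg=None,
                             sync_slope=None, mean_inclination_deg=mean_incl,
                             low_confidence=True)
    phi_prec = float(np.rad2deg(np.angle(demod)) % 360.0)

    # synchrony diagnostic on samples with a defined deviating azimuth
    defined = theta_i > MIN_AZIMUTH_TILT_DEG
    slope = None
    if defined.sum() >= 2:
        au = np.rad2deg(np.unwrap(np.deg2rad(alphas[defined])))
        pu = np.rad2deg(np.unwrap(phi_dev[defined]))
        if np.ptp(au) > 0:
            slope = float(np.polyfit(au, pu, 1)[0])
    return PrecessionFit(theta_prec_deg=theta_prec, phi_prec_deg=phi_prec,
                         sync_slope=slope, mean_inclination_deg=mean_incl,
                         low_confidence=low_conf)


def predict_blade_z(model: MotionModel, geom: ChannelGeometry,
                    alpha_grid_deg: np.ndarray) -> dict[int, np.ndarray]:
    """Global Z of each blade's reference point over a revolution.

    Applies the fitted three-step transform to the inner-channel base
    point of each blade.  For a tilt-only motion the curves are
    sinusoids of amplitude ``r_n * sin(theta_mean)``.
    """
    out: dict[int, np.ndarray] = {}
    grid = np.asarray(alpha_grid_deg, dtype=float)
    locals_ = {n: np.array([geom.base[n - 1, 0, 0], geom.base[n - 1, 0, 1], 0.0])
               for n in (1, 2, 3, 4)}
    for n in (1, 2, 3, 4):
        z = np.empty_like(grid)
        for i, a in enumerate(grid):
            pose = pose_at(model, a)
            z[i] = local_to_global(pose, locals_[n])[2]
        out[n] = z
    return out


def plot_motion_diagnostics(poses: list[RotorPose], summary: MotionSummary,
                            geom: ChannelGeometry | None = None,
                            path: str | None = None):
    """Four-panel diagnostic figure of a pose track.

    Centre scatter, axis-tip scatter (the precession cone seen from
    +Z), deviating azimuth vs blade angle (identity line = synchronous
    precession), and predicted blade reference-point Z vs blade angle.
    Saves to ``path`` when given, else returns the figure.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    centers = _centers(poses)
    axes = _axes(poses)
    alphas = np.array([p.alpha_deg for p in poses])

    fig, ax = plt.subplots(2, 2, figsize=(9, 8))
    ax[0, 0].scatter(centers[:, 0], centers[:, 1], s=4)
    ax[0, 0].plot(summary.center_x_mm, summary.center_y_mm, "r+", ms=12)
    ax[0, 0].set_xlabel("X (mm)")
    ax[0, 0].set_ylabel("Y (mm)")
    ax[0, 0].set_title("centre OR and motion centre")

    ax[0, 1].scatter(axes[:, 0], axes[:, 1], s=4)
    mean_ax = axis_from_angles(summary.phi_mean_deg, summary.theta_mean_deg)
    ax[0, 1].plot(mean_ax[0], mean_ax[1], "r+", ms=12)
    ax[0, 1].set_xlabel("axis X component")
    ax[0, 1].set_ylabel("axis Y component")
    ax[0, 1].set_title("axis orientations (cone from +Z)")

    phis = [deviating_azimuth(a, summary.phi_mean_deg, summary.theta_mean_deg)
            for a in axes]
    ok = [i for i, p in enumerate(phis) if p is not None]
    ax[1, 0].scatter(alphas[ok], np.array(phis, dtype=object)[ok].astype(float),
                     s=4)
    ax[1, 0].plot([0, 360], [0, 360], "k--", lw=0.8)
    ax[1, 0].set_xlabel("blade angle α (deg)")
    ax[1, 0].set_ylabel("deviating azimuth φ (deg)")
    ax[1, 0].set_title("precession synchrony")

    if geom is not None:
        grid = np.arange(0.0, 360.0, 2.0)
        zs = predict_blade_z(summary.to_motion_model(), geom, grid)
        for n, z in zs.items():
            ax[1, 1].plot(grid, z, label=f"blade {n}")
        ax[1, 1].legend(fontsize=7)
    ax[1, 1].set_xlabel("blade angle α (deg)")
    ax[1, 1].set_ylabel("Z of P$_n$ (mm)")
    ax[1, 1].set_title("predicted blade Z travel")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def decompose(poses: list[RotorPose], geom: ChannelGeometry | None = None,
              rotation_rate_rpm: float | None = None) -> MotionSummary:
    """Full three-mode summary of a pose track."""
    mc = find_motion_center(poses)
    phi_mean, theta_mean = mean_axis(poses)
    prec = fit_precession(poses, phi_mean, theta_mean)
    rotor_plane_z = float(_centers(poses)[:, 2].mean())

    summary = MotionSummary(
        center_x_mm=float(mc.mean_mm[0]), center_y_mm=float(mc.mean_mm[1]),
        center_std_x_mm=float(mc.std_mm[0]), center_std_y_mm=float(mc.std_mm[1]),
        s_star_mm=mc.s_star_mm, rotor_plane_z_mm=rotor_plane_z,
        theta_mean_deg=theta_mean, phi_mean_deg=phi_mean,
        theta_prec_deg=prec.theta_prec_deg, phi_prec_deg=prec.phi_prec_deg,
        sync_slope=prec.sync_slope, blade_z_range_mm=0.0,
        rotation_rate_rpm=rotation_rate_rpm)
    if geom is not None:
        grid = np.arange(0.0, 360.0, 2.0)
        zs = predict_blade_z(summary.to_motion_model(), geom, grid)
        allz = np.concatenate(list(zs.values()))
        summary.blade_z_range_mm = float(allz.max() - allz.min())
    return summary
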