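"""Coordinate systems and rigid transforms for impeller pose tracking.

Two frames are used throughout the package (lengths in mm, angles in
degrees at the API, seconds for time):

* the **global** frame (X, Y, Z), fixed to the pump housing.  Z points
  from the volute mid-plane toward the inlet, so the rotor reference
  plane sits below the mid-plane at negative Z and the laser sheet lies
  at a (negative) plane ``Z = Z_L``;
* the **local** frame (x, y, z), anchored to the rotor centre ``OR``
  with z along the instantaneous spin axis and x along the leading edge
  of the first main blade.

The axis direction is parameterised by spherical angles: azimuth ``phi``
of its projection onto the (X, Y) plane and polar angle ``theta`` from
Z.  A point transforms between frames as

    P_global = OR + R_z(alpha) . R_psi(theta) . p_local

where ``psi = R_Z(phi) . Y`` is the tilt axis (normal to the projection
of the spin axis on the housing plane), ``R_psi(theta)`` tilts Z onto
the spin axis and ``R_z(alpha)`` spins the rotor about that axis by the
blade angle ``alpha``.  Positive ``alpha`` is counterclockwise when
viewed from +Z (a configuration choice; the physical sense of rotation
is set by the caller).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Z_HAT",
    "Y_HAT",
    "X_HAT",
    "RotorPose",
    "RotationSpec",
    "rotation_matrix",
    "axis_from_angles",
    "angles_from_axis",
    "tilt_axis",
    "pose_matrix",
    "local_to_global",
    "global_to_local",
    "poses_to_frame",
    "frame_to_poses",
    "write_pose_csv",
    "read_pose_csv",
]

X_HAT = np.array([1.0, 0.0, 0.0])
Y_HAT = np.array([0.0, 1.0, 0.0])
Z_HAT = np.array([0.0, 0.0, 1.0])

#: Columns of the on-disk pose table.
POSE_COLUMNS = ["frame", "time_s", "X_mm", "Y_mm", "Z_mm",
                "phi_deg", "theta_deg", "alpha_deg"]


@dataclass(frozen=True)
class RotationSpec:
    """A rotation of ``angle_deg`` degrees about a (non-zero) axis."""

    axis: np.ndarray
    angle_deg: float

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        if axis.shape != (3,) or not np.all(np.isfinite(axis)):
            raise ValueError("rotation axis must be a finite 3-vector")
        if np.linalg.norm(axis) == 0.0:
            raise ValueError("rotation axis must be non-zero")
        object.__setattr__(self, "axis", axis)


@dataclass
class RotorPose:
    """Centre, axis orientation and blade angle of the rotor for one frame.

    ``center`` is the point OR where the spin axis pierces the rotor
    reference plane (the plane aligned with the bottom of the blades).
    """

    center: np.ndarray
    phi_deg: float
    theta_deg: float
    alpha_deg: float
    frame_index: int = 0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("pose center must be a 3-vector")
        if not (0.0 <= self.theta_deg < 90.0):
            raise ValueError(f"polar angle must lie in [0, 90), got {self.theta_deg}")
        self.phi_deg = float(self.phi_deg) % 360.0
        self.alpha_deg = float(self.alpha_deg) % 360.0

    @property
    def axis(self) -> np.ndarray:
        """Unit vector of the spin axis in global coordinates."""
        return axis_from_angles(self.phi_deg, self.theta_deg)


def rotation_matrix(spec: RotationSpec) -> np.ndarray:
    """Rodrigues rotation matrix for a rotation about an arbitrary axis.

    Returns a proper orthogonal 3x3 matrix (det = +1) satisfying
    ``R @ axis = axis``.
    """
    n = spec.axis / np.linalg.norm(spec.axis)
    ang = np.deg2rad(spec.angle_deg)
    k = np.array([[0.0, -n[2], n[1]],
                  [n[2], 0.0, -n[0]],
                  [-n[1], n[0], 0.0]])
    return np.eye(3) + np.sin(ang) * k + (1.0 - np.cos(ang)) * (k @ k)


def tilt_axis(phi_deg: float) -> np.ndarray:
    """Tilt axis ``psi = R_Z(phi) . Y`` for an axis azimuth ``phi``."""
    return rotation_matrix(RotationSpec(Z_HAT, phi_deg)) @ Y_HAT


def axis_from_angles(phi_deg: float, theta_deg: float) -> np.ndarray:
    """Unit spin-axis vector from azimuth and polar angle.

    Tilting Z by ``theta`` about ``psi = R_Z(phi) . Y`` lands the axis at

        (sin(theta) cos(phi), sin(theta) sin(phi), cos(theta)),

    i.e. the usual spherical parameterisation.
    """
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    return np.array([np.sin(th) * np.cos(ph),
                     np.sin(th) * np.sin(ph),
                     np.cos(th)])


def angles_from_axis(axis: np.ndarray) -> tuple[float, float]:
    """Spherical angles ``(phi, theta)`` in degrees of a unit axis.

    The axis sign is chosen so that the returned direction has a
    positive Z component (polar angle in [0, 90)).  For an axis exactly
    along Z the azimuth is reported as 0 by convention.
    """
    v = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm == 0.0:
        raise ValueError("zero axis has no direction angles")
    v = v / nrm
    if v[2] < 0.0:
        v = -v
    theta = np.rad2deg(np.arccos(np.clip(v[2], -1.0, 1.0)))
    phi = np.rad2deg(np.arctan2(v[1], v[0])) % 360.0 if theta > 0.0 else 0.0
    return float(phi), float(theta)


def pose_matrix(pose: RotorPose) -> np.ndarray:
    """Full local->global rotation ``R_z(alpha) . R_psi(theta)``.

    ``R_psi(theta)`` tilts the global Z onto the spin axis and
    ``R_z(alpha)`` rotates about that (already tilted) axis.
    """
    r_tilt = rotation_matrix(RotationSpec(tilt_axis(pose.phi_deg), pose.theta_deg))
    spin_axis = r_tilt @ Z_HAT
    r_spin = rotation_matrix(RotationSpec(spin_axis, pose.alpha_deg))
    return r_spin @ r_tilt


def local_to_global(pose: RotorPose, p_local: np.ndarray) -> np.ndarray:
    """Map a rotor-fixed point to the global frame."""
    return pose.center + pose_matrix(pose) @ np.asarray(p_local, dtype=float)


def global_to_local(pose: RotorPose, p_global: np.ndarray) -> np.ndarray:
    """Inverse of :func:`local_to_global`."""
    return pose_matrix(pose).T @ (np.asarray(p_global, dtype=float) - pose.center)


# ---------------------------------------------------------------------------
# Pose-track serialization


def poses_to_frame(poses: Iterable[RotorPose]) -> pd.DataFrame:
    rows = [
        (p.frame_index, p.time_s, p.center[0], p.center[1], p.center[2],
         p.phi_deg, p.theta_deg, p.alpha_deg)
        for p in poses
    ]
    return pd.DataFrame(rows, columns=POSE_COLUMNS)


def frame_to_poses(df: pd.DataFrame) -> list[RotorPose]:
    return [
        RotorPose(center=np.array([r.X_mm, r.Y_mm, r.Z_mm]),
                  phi_deg=r.phi_deg, theta_deg=r.theta_deg, alpha_deg=r.alpha_deg,
                  frame_index=int(r.frame), time_s=float(r.time_s))
        for r in df.itertuples(index=False)
    ]


def write_pose_csv(path: str | Path, poses: Sequence[RotorPose]) -> None:
    poses_to_frame(poses).to_csv(path, index=False)


def read_pose_csv(path: str | Path | io.IOBase) -> list[RotorPose]:
    return frame_to_poses(pd.read_csv(path))
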