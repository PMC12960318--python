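"""Image-side pipeline: blob detection, spatial calibration, blade pairing.

Takes raw camera frames (or pre-detected pixel centres) to calibrated,
blade-assigned inner/outer marker pairs with their in-plane spacings
``d_n`` and a provisional blade angle ``alpha``.  The blade angle is
only determined modulo 90 degrees here — the impeller has fourfold
symmetry — and is unwrapped across frames by continuity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import InsufficientDataError
from .synthetic import ChannelGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "Calibration",
    "BladePair",
    "BladePairing",
    "detect_markers",
    "fit_calibration",
    "pair_and_assign",
    "estimate_alpha",
    "unwrap_alpha",
]


# ---------------------------------------------------------------------------
# Detection


def detect_markers(image: np.ndarray,
                   threshold: float | None = None,
                   min_area_px: int = 4,
                   max_area_px: int | None = None) -> np.ndarray:
    """Sub-pixel centres of bright blobs in a grayscale frame.

    Pixels above ``threshold`` (default: image mean + 5 image standard
    deviations, a background-dominated statistic for sparse markers)
    are grouped into connected components; each component of admissible
    area yields one intensity-weighted centroid.  Returns an (N, 2)
    array of (x_px, y_px); empty with a warning when nothing is found.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if threshold is None:
        threshold = img.mean() + 5.0 * img.std()
    mask = img > threshold
    labels = measure.label(mask)
    centers = []
    for region in measure.regionprops(labels, intensity_image=img):
        if region.area < min_area_px:
            continue
        if max_area_px is not None and region.area > max_area_px:
            continue
        cy, cx = region.centroid_weighted
        centers.append((cx, cy))
    if not centers:
        warnings.warn("no markers detected in frame", stacklevel=2)
        return np.empty((0, 2))
    return np.array(centers)


# ---------------------------------------------------------------------------
# Calibration


@dataclass(frozen=True)
class Calibration:
    """Affine pixel-to-millimetre map ``mm = A @ px + offset``."""

    matrix: np.ndarray       # (2, 2)
    offset: np.ndarray       # (2,)
    residual_rms_mm: float = 0.0

    def px_to_mm(self, pts_px: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_px, dtype=float))
        return pts @ self.matrix.T + self.offset

    def mm_to_px(self, pts_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        return (pts - self.offset) @ np.linalg.inv(self.matrix).T

    @property
    def scale_um_per_px(self) -> float:
        """Mean isotropic scale implied by the affine map."""
        return float(np.sqrt(abs(np.linalg.det(self.matrix))) * 1000.0)


def fit_calibration(points_px: np.ndarray, points_mm: np.ndarray) -> Calibration:
    """Least-squares affine fit of pixel to physical grid coordinates.

    Requires at least three non-collinear correspondences (e.g. the
    drilled reference grid in the housing).  Noise-free inputs are
    recovered exactly; the RMS residual is reported in mm.
    """
    px = np.atleast_2d(np.asarray(points_px, dtype=float))
    mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    if px.shape != mm.shape or px.shape[0] < 3:
        raise InsufficientDataError("need >= 3 point correspondences")
    centered = px - px.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise InsufficientDataError("calibration points are collinear")
    design = np.column_stack([px, np.ones(len(px))])
    coef, *_ = np.linalg.lstsq(design, mm, rcond=None)
    matrix = coef[:2].T
    offset = coef[2]
    resid = mm - design @ coef
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return Calibration(matrix=matrix, offset=offset, residual_rms_mm=rms)


# ---------------------------------------------------------------------------
# Pairing and blade assignment


@dataclass
class BladePair:
    """Inner/outer dot pair of one blade with its in-plane spacing."""

    blade: int
    inner_mm: np.ndarray
    outer_mm: np.ndarray
    d_mm: float


@dataclass
class BladePairing:
    """Per-frame pairing result: assigned pairs plus leftovers."""

    pairs: dict[int, BladePair] = field(default_factory=dict)
    unassigned: list[np.ndarray] = field(default_factory=list)
    frame_index: int = 0

    @property
    def n_blades(self) -> int:
        return len(self.pairs)


def _circular_gap_groups(azimuths: np.ndarray, gap_deg: float) -> list[np.ndarray]:
    """Indices grouped by splitting the sorted azimuths at circular gaps
    larger than ``gap_deg``."""
    order = np.argsort(azimuths)
    az_sorted = azimuths[order]
    gaps = np.diff(np.concatenate([az_sorted, [az_sorted[0] + 360.0]]))
    cut_after = np.where(gaps > gap_deg)[0]
    if len(cut_after) == 0:
        return [order]
    # rotate so the list starts right after the last circular cut
    start = (cut_after[-1] + 1) % len(order)
    idx = np.concatenate([order[start:], order[:start]])
    rotated = np.concatenate([az_sorted[start:], az_sorted[:start] + 360.0])
    groups, current = [], [idx[0]]
    for i in range(1, len(idx)):
        if rotated[i] - rotated[i - 1] > gap_deg:
            groups.append(np.array(current))
            current = []
        current.append(idx[i])
    groups.append(np.array(current))
    return groups


def pair_and_assign(centers_mm: np.ndarray,
                    provisional_center: np.ndarray,
                    geom: ChannelGeometry,
                    expected_alpha_deg: float | None = None,
                    z_height_mm: float = 0.0,
                    gap_deg: float = 30.0,
                    frame_index: int = 0) -> BladePairing:
    """Group detected centres into per-blade inner/outer pairs.

    Centres are clustered by azimuth about the provisional rotor centre
    (the two dots of a blade sit within a few degrees of each other,
    blades are 90 degrees apart); within a cluster the inner/outer
    roles follow from the radial rank.  Clusters without exactly two
    members are left unassigned.  When ``expected_alpha_deg`` is given,
    blade numbers are assigned by proximity to each blade's expected
    azimuth; otherwise blades are numbered 1..4 in azimuth order.
    """
    pts = np.atleast_2d(np.asarray(centers_mm, dtype=float))
    if len(pts) < 2:
        raise InsufficientDataError("need at least two marker centres to pair")
    c = np.asarray(provisional_center, dtype=float)[:2]
    rel = pts - c
    azimuths = np.rad2deg(np.arctan2(rel[:, 1], rel[:, 0])) % 360.0
    radii = np.linalg.norm(rel, axis=1)

    pairing = BladePairing(frame_index=frame_index)
    groups = _circular_gap_groups(azimuths, gap_deg)

    # expected azimuth of each blade's inner dot (at height z above the
    # reference plane), used for labelling when an alpha hint exists
    inner0 = geom.base[0, 0] + geom.slope[0, 0] * z_height_mm
    ref_az = np.rad2deg(np.arctan2(inner0[1], inner0[0]))

    used_labels: set[int] = set()
    for g in groups:
        if len(g) != 2:
            for i in g:
                pairing.unassigned.append(pts[i])
            continue
        i, j = (g[0], g[1]) if radii[g[0]] <= radii[g[1]] else (g[1], g[0])
        d = float(np.linalg.norm(pts[g[0]] - pts[g[1]]))
        group_az = np.rad2deg(np.arctan2(rel[i, 1], rel[i, 0])) % 360.0
        if expected_alpha_deg is not None:
            offsets = (group_az - ref_az - expected_alpha_deg - 90.0 *
                       np.arange(4)) % 360.0
            offsets = np.minimum(offsets, 360.0 - offsets)
            blade = int(np.argmin(offsets)) + 1
        else:
            blade = len(pairing.pairs) + 1
        if blade in used_labels:
            logger.warning("duplicate blade label %d in frame %d; extra pair "
                           "left unassigned", blade, frame_index)
            pairing.unassigned.extend([pts[i], pts[j]])
            continue
        used_labels.add(blade)
        pairing.pairs[blade] = BladePair(blade=blade, inner_mm=pts[i],
                                         outer_mm=pts[j], d_mm=d)
    return pairing


# ---------------------------------------------------------------------------
# Blade-angle estimation


def estimate_alpha(pairing: BladePairing,
                   center_mm: np.ndarray,
                   geom: ChannelGeometry,
                   z_height_mm: float | dict[int, float] = 0.0) -> float:
    """Blade angle modulo 90 degrees from the inner-dot azimuths.

    For each assigned blade the observed azimuth of the inner dot about
    the rotor centre is compared with the azimuth the blade-1 inner
    channel would have at the observation height; because of the
    fourfold symmetry the per-blade differences agree modulo 90 and are
    combined with a circular mean.  ``z_height_mm`` is the local
    channel height at the laser plane (scalar or per-blade).
    """
    if pairing.n_blades < 1:
        raise InsufficientDataError("no assigned inner markers")
    c = np.asarray(center_mm, dtype=float)[:2]
    angles = []
    for blade, pair in pairing.pairs.items():
        z = z_height_mm[blade] if isinstance(z_height_mm, dict) else z_height_mm
        inner_local = geom.base[0, 0] + geom.slope[0, 0] * z
        ref_az = np.rad2deg(np.arctan2(inner_local[1], inner_local[0]))
        rel = pair.inner_mm - c
        obs_az = np.rad2deg(np.arctan2(rel[1], rel[0]))
        angles.append((obs_az - ref_az) % 90.0)
    # circular mean on the 90-degree torus
    rad = np.deg2rad(np.asarray(angles) * 4.0)
    mean = np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) / 4.0
    return float(mean % 90.0)


def unwrap_alpha(alpha_mod90_deg: float, hint_deg: float) -> float:
    """Lift a modulo-90 blade angle to the full circle near a hint."""
    k = np.round((hint_deg - alpha_mod90_deg) / 90.0)
    return float(alpha_mod90_deg + 90.0 * k)
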