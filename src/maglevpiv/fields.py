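"""Phase-binned field averaging and comparison statistics.

Velocity snapshots are conditioned on the rotor phase modulo 90
degrees (fourfold blade symmetry) in 1-degree bins.  Components are
averaged first and the in-plane magnitude is taken of the means,

    U_bar = sqrt(mean(u_X)^2 + mean(u_Y)^2),

which differs from the mean of magnitudes whenever directions vary
(opposite vectors cancel to zero).  Two phase-averaged fields are
compared through the nodewise relative error normalized by the single
scalar maximum of the reference field,

    E_rel_i = (U_i - U_ref_i) / max(U_ref),

its root mean square in percent, and — for pressures referenced to the
inlet — the nodewise absolute error in mmHg.  The phase-conditioned
variability map sigma_U is reported, as printed in its source, as the
mean squared deviation of the instantaneous magnitudes about U_bar; a
switch provides its square root for readers who want a proper standard
deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import griddata

from .errors import ConfigError, InsufficientDataError
from .synthetic import FieldSnapshot, GridSpec

__all__ = [
    "PhaseAveragedField",
    "MMHG_PA",
    "bin_phases",
    "regrid",
    "phase_average",
    "relative_error",
    "rms_error",
    "abs_pressure_error",
    "field_std",
    "error_pdf",
    "out_of_plane_check",
]

#: 1 mmHg in Pa.
MMHG_PA = 133.322

#: Default laser-sheet Z-averaging window, mm.
DEFAULT_Z_WINDOW = (-2.5, -2.0)


@dataclass
class PhaseAveragedField:
    """Per-phase-bin ensemble statistics on a common grid."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    mean_u: np.ndarray
    mean_v: np.ndarray
    magnitude: np.ndarray
    count: int
    sigma_u: np.ndarray | None = None
    mean_p: np.ndarray | None = None
    alpha_bin: int | None = None

    @property
    def mask(self) -> np.ndarray:
        """True on valid (finite) nodes."""
        return np.isfinite(self.magnitude)


def bin_phases(alpha_deg: np.ndarray) -> np.ndarray:
    """1-degree phase bins 1..90, modulo the fourfold symmetry.

    Bin ``k`` collects angles with ``alpha mod 90`` in ``[k-1, k)``.
    """
    a = np.mod(np.asarray(alpha_deg, dtype=float), 90.0)
    return np.floor(a).astype(int) + 1


def regrid(snapshot: FieldSnapshot, grid: GridSpec,
           z_window: tuple[float, float] | None = None) -> FieldSnapshot:
    """Linear in-plane interpolation onto a uniform Eulerian grid.

    When the snapshot carries multiple Z levels, each level inside
    ``z_window`` is interpolated separately and the levels are averaged
    with equal weight (the unweighted mean over the laser-sheet
    thickness).  Target nodes outside the source's convex hull are
    masked (NaN).
    """
    gx, gy = grid.mesh()

    def interp_level(xs, ys, vals):
        pts = np.column_stack([np.ravel(xs), np.ravel(ys)])
        return griddata(pts, np.ravel(vals), (gx, gy), method="linear")

    fields = {"u": snapshot.u, "v": snapshot.v}
    if snapshot.w is not None:
        fields["w"] = snapshot.w
    if snapshot.p is not None:
        fields["p"] = snapshot.p

    out: dict[str, np.ndarray] = {}
    if snapshot.z_mm is not None:
        z = np.asarray(snapshot.z_mm)
        levels = np.unique(np.round(z, 9))
        if z_window is not None:
            levels = levels[(levels >= z_window[0]) & (levels <= z_window[1])]
            if len(levels) == 0:
                raise ConfigError(f"no Z levels inside window {z_window}")
        for name, vals in fields.items():
            stack = []
            for lv in levels:
                sel = np.isclose(z, lv)
                stack.append(interp_level(snapshot.x_mm[sel], snapshot.y_mm[sel],
                                          np.asarray(vals)[sel]))
            out[name] = np.mean(stack, axis=0)
    else:
        for name, vals in fields.items():
            out[name] = interp_level(snapshot.x_mm, snapshot.y_mm, vals)

    return FieldSnapshot(x_mm=gx, y_mm=gy, u=out["u"], v=out["v"],
                         w=out.get("w"), p=out.get("p"),
                         alpha_deg=snapshot.alpha_deg, source=snapshot.source)


def phase_average(snapshots: list[FieldSnapshot],
                  with_sigma: bool = False,
                  sigma_sqrt: bool = False,
                  alpha_bin: int | None = None) -> PhaseAveragedField:
    """Ensemble statistics of congruent snapshots in one phase bin.

    Components are averaged before the magnitude is formed.  With
    ``with_sigma`` the phase-conditioned variability of the
    instantaneous magnitudes is attached (mean squared deviation, or
    its root when ``sigma_sqrt``).
    """
    if not snapshots:
        raise InsufficientDataError("phase bin is empty")
    shape = snapshots[0].u.shape
    for s in snapshots:
        if s.u.shape != shape:
            raise ConfigError("snapshots in a bin must share one grid")
    mean_u = np.mean([s.u for s in snapshots], axis=0)
    mean_v = np.mean([s.v for s in snapshots], axis=0)
    magnitude = np.hypot(mean_u, mean_v)
    sigma = None
    if with_sigma:
        sigma = field_std(snapshots, magnitude, sqrt=sigma_sqrt)
    mean_p = None
    if all(s.p is not None for s in snapshots):
        mean_p = np.mean([s.p for s in snapshots], axis=0)
    return PhaseAveragedField(
        x_mm=snapshots[0].x_mm, y_mm=snapshots[0].y_mm,
        mean_u=mean_u, mean_v=mean_v, magnitude=magnitude,
        count=len(snapshots), sigma_u=sigma, mean_p=mean_p,
        alpha_bin=alpha_bin)


def field_std(snapshots: list[FieldSnapshot], magnitude: np.ndarray,
              sqrt: bool = False) -> np.ndarray:
    """Phase-conditioned variability of the velocity magnitude.

    ``(1/N) * sum_n (U_n - U_bar)^2`` per node — reported without the
    square root by default, with it when ``sqrt`` is set.  A single
    snapshot yields zeros (flagged with a warning).
    """
    if len(snapshots) < 2:
        warnings.warn("sigma_U of a single snapshot is identically zero",
                      stacklevel=2)
        return np.zeros_like(magnitude)
    inst = np.array([np.hypot(s.u, s.v) for s in snapshots])
    msd = np.mean((inst - magnitude) ** 2, axis=0)
    return np.sqrt(msd) if sqrt else msd


def _joint_mask(*masks: np.ndarray | None) -> np.ndarray:
    out = None
    for m in masks:
        if m is None:
            continue
        out = m if out is None else (out & m)
    if out is None:
        raise ConfigError("no validity information available")
    return out


def relative_error(magnitude: np.ndarray, reference: np.ndarray,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Nodewise error normalized by the reference-field maximum.

    The denominator is the single scalar max of the reference over the
    valid nodes of the compared pair.
    """
    if magnitude.shape != reference.shape:
        raise ConfigError("fields must be congruent")
    m = _joint_mask(np.isfinite(magnitude), np.isfinite(reference), mask)
    denom = np.nanmax(np.where(m, reference, np.nan))
    if not np.isfinite(denom) or denom == 0.0:
        raise ConfigError("reference field is all-zero or empty; "
                          "normalization undefined")
    out = np.full(magnitude.shape, np.nan)
    out[m] = (magnitude[m] - reference[m]) / denom
    return out


def rms_error(e_rel: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Root mean square of the relative error over valid nodes, percent."""
    m = _joint_mask(np.isfinite(e_rel), mask)
    if m.sum() == 0:
        raise InsufficientDataError("no valid nodes for the RMS")
    return float(100.0 * np.sqrt(np.mean(e_rel[m] ** 2)))


def abs_pressure_error(p_pa: np.ndarray, p_ref_pa: np.ndarray,
                       inlet_p_pa: float = 0.0, inlet_p_ref_pa: float = 0.0,
                       mask: np.ndarray | None = None
                       ) -> tuple[np.ndarray, float, float]:
    """Nodewise pressure error between inlet-referenced fields, in mmHg.

    Each field is first referenced to its own inlet pressure; the
    return is ``(E_abs_mmHg, mean_mmHg, rms_mmHg)``.
    """
    if p_pa is None or p_ref_pa is None:
        raise ConfigError("both pressure fields are required")
    rel = p_pa - inlet_p_pa
    rel_ref = p_ref_pa - inlet_p_ref_pa
    m = _joint_mask(np.isfinite(rel), np.isfinite(rel_ref), mask)
    e = np.full(rel.shape, np.nan)
    e[m] = (rel[m] - rel_ref[m]) / MMHG_PA
    return e, float(np.mean(e[m])), float(np.sqrt(np.mean(e[m] ** 2)))


def error_pdf(e_rel: np.ndarray, bin_width: float = 0.005,
              mask: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Density-normalized histogram of the relative error.

    Returns ``(bin_centers, density)``; the density integrates to one.
    """
    m = _joint_mask(np.isfinite(e_rel), mask)
    vals = e_rel[m]
    if vals.size == 0:
        raise InsufficientDataError("no valid nodes for the error PDF")
    if vals.size < 100:
        warnings.warn(f"error PDF from only {vals.size} nodes", stacklevel=2)
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    density, edges = np.histogram(vals, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def out_of_plane_check(w_m_s: np.ndarray, dt_s: float = 1e-4,
                       sheet_thickness_mm: float = 0.5,
                       threshold_fraction: float = 0.25,
                       mask: np.ndarray | None = None) -> float:
    """Fraction of nodes whose out-of-plane displacement between two
    frames exceeds the accepted fraction of the laser-sheet thickness.

    Displacement is ``|w| * dt`` (converted to mm); the conventional
    limit is 25% of the sheet thickness.
    """
    if dt_s <= 0:
        raise ConfigError("frame interval must be positive")
    m = _joint_mask(np.isfinite(w_m_s), mask)
    disp_mm = np.abs(w_m_s[m]) * dt_s * 1000.0
    return float(np.mean(disp_mm > threshold_fraction * sheet_thickness_mm))
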