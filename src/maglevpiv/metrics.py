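"""Fluid properties, flow-regime numbers and the spectral mode diagnostic.

The blood-analog viscosity follows a linear temperature model
``mu = mu0 + C_T * T`` fitted on a rheometer between 24 and 31 °C.
Flow regimes are characterised by the pipe Reynolds number of the
inlet (``Re = rho * u * D / mu`` with the mean inlet velocity) and the
pump Reynolds number ``Re_pump = rho * omega * D_rotor^2 / mu`` with
the angular velocity in rad/s.  Inlet turbulence boundary conditions
for fully developed pipe flow use the standard correlations
``I = 0.16 * Re^(-1/8)`` and ``l = 0.07 * D_h``.

Integral signals (pressure head, rotor Z-moment) are screened for
non-ideal rotation: an ideally rotating fourfold impeller only excites
blade-passage harmonics (multiples of 4 of the rotation frequency, 8
with the secondary blades); any spectral line at the rotation frequency
itself or a non-multiple-of-4 harmonic flags a non-rotatory motion mode
such as precession.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks, welch

from .errors import ConfigError

__all__ = [
    "FluidProperties",
    "PumpOperatingPoint",
    "IntegralSignal",
    "SpectralMode",
    "ModeReport",
    "viscosity",
    "turbulence_bc",
    "reynolds_inlet",
    "reynolds_pump",
    "percent_deviation",
    "psd",
    "detect_modes",
]

#: Temperature validity range of the viscosity model, °C.
VISCOSITY_T_RANGE = (24.0, 31.0)

#: Default viscosity-model parameters of the blood-analog mixture.
MU0_PA_S = 5.975e-3
C_T_PA_S_PER_C = -8.55e-5


@dataclass(frozen=True)
class FluidProperties:
    """Density and linear viscosity model of the working fluid."""

    rho_kg_m3: float = 1164.0
    mu0_pa_s: float = MU0_PA_S
    c_t_pa_s_per_c: float = C_T_PA_S_PER_C
    temperature_c: float = 24.3

    @property
    def mu_pa_s(self) -> float:
        return viscosity(self.temperature_c, self.mu0_pa_s, self.c_t_pa_s_per_c)


@dataclass(frozen=True)
class PumpOperatingPoint:
    """Operating condition of a centrifugal pump."""

    flow_l_min: float = 4.4
    rotation_rate_rpm: float = 2350.0
    d_inlet_mm: float = 9.2
    d_rotor_mm: float = 44.9
    d_hydraulic_mm: float = 9.2

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")


@dataclass
class IntegralSignal:
    """Uniformly sampled pressure-head and rotor-moment traces."""

    time_s: np.ndarray
    dp_mmhg: np.ndarray
    mz_nmm: np.ndarray
    fs_hz: float
    f_rot_hz: float

    def __post_init__(self) -> None:
        if self.f_rot_hz <= 0:
            raise ConfigError("rotation frequency must be positive")
        dt = np.diff(self.time_s)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ConfigError("signal must be uniformly sampled")


def viscosity(temperature_c: float,
              mu0_pa_s: float = MU0_PA_S,
              c_t_pa_s_per_c: float = C_T_PA_S_PER_C) -> float:
    """Dynamic viscosity of the blood-analog from the linear model, Pa·s.

    Warns outside the 24–31 °C range the model was fitted on; values
    are kept at full precision (round only at reporting).
    """
    if not (VISCOSITY_T_RANGE[0] <= temperature_c <= VISCOSITY_T_RANGE[1]):
        warnings.warn(
            f"temperature {temperature_c} °C outside the model validity "
            f"range {VISCOSITY_T_RANGE}", stacklevel=2)
    mu = mu0_pa_s + c_t_pa_s_per_c * temperature_c
    if mu <= 0:
        raise ConfigError(f"non-physical viscosity {mu:.2e} Pa·s at "
                          f"{temperature_c} °C")
    return mu


def turbulence_bc(reynolds: float, d_h_mm: float) -> tuple[float, float]:
    """Turbulence intensity and length scale for fully developed pipe flow.

    ``I = 0.16 * Re^(-1/8)`` (dimensionless) and ``l = 0.07 * D_h`` in
    the unit of ``D_h``.
    """
    if reynolds <= 0 or d_h_mm <= 0:
        raise ConfigError("Reynolds number and hydraulic diameter must be positive")
    return 0.16 * reynolds ** (-1.0 / 8.0), 0.07 * d_h_mm


def reynolds_inlet(rho_kg_m3: float, mu_pa_s: float,
                   flow_l_min: float, d_mm: float) -> float:
    """Pipe Reynolds number of the inlet cannula.

    Uses the mean velocity ``u = Q / (pi D^2 / 4)`` and the inlet
    diameter as the length scale.
    """
    d_m = d_mm / 1000.0
    q_m3_s = flow_l_min / 1000.0 / 60.0
    u = q_m3_s / (np.pi * d_m ** 2 / 4.0)
    return rho_kg_m3 * u * d_m / mu_pa_s


def reynolds_pump(rho_kg_m3: float, mu_pa_s: float,
                  rotation_rate_rpm: float, d_rotor_mm: float) -> float:
    """Rotary-pump Reynolds number ``rho * omega * D_rotor^2 / mu``.

    The rotation rate is accepted in rpm and converted to rad/s.
    """
    omega = rotation_rate_rpm * 2.0 * np.pi / 60.0
    d_m = d_rotor_mm / 1000.0
    return rho_kg_m3 * omega * d_m ** 2 / mu_pa_s


def percent_deviation(value: float, reference: float) -> float:
    """Signed relative deviation of ``value`` from ``reference``, percent."""
    if reference == 0:
        raise ConfigError("reference must be non-zero")
    return 100.0 * (value - reference) / reference


# ---------------------------------------------------------------------------
# Spectral diagnostics


def psd(x: np.ndarray, fs_hz: float, f_rot_hz: float,
        rotations_per_segment: float = 4.0,
        overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density on a rotation-normalized axis.

    Hann window, segments spanning ``rotations_per_segment`` rotor
    revolutions, 50% overlap by default.  Returns ``(f / f_rot, PSD)``.
    The estimate conserves variance (Parseval) to within a few percent
    at the default settings.
    """
    x = np.asarray(x, dtype=float)
    n_per_rot = fs_hz / f_rot_hz
    nperseg = int(round(rotations_per_segment * n_per_rot))
    if x.size < nperseg:
        raise ConfigError(
            f"signal too short: need >= {rotations_per_segment} rotations "
            f"({nperseg} samples), got {x.size}")
    f, pxx = welch(x, fs=fs_hz, window="hann", nperseg=nperseg,
                   noverlap=int(overlap * nperseg), detrend="constant")
    return f / f_rot_hz, pxx


@dataclass
class SpectralMode:
    f_norm: float
    power_db: float
    excess_db: float
    harmonic: int | None
    kind: str  # "blade_passage" | "rotational" | "non_harmonic"


@dataclass
class ModeReport:
    modes: list[SpectralMode] = field(default_factory=list)
    non_ideal: bool = False

    @property
    def rotational(self) -> list[SpectralMode]:
        return [m for m in self.modes if m.kind == "rotational"]

    @property
    def blade_passage(self) -> list[SpectralMode]:
        return [m for m in self.modes if m.kind == "blade_passage"]


def detect_modes(f_norm: np.ndarray, pxx: np.ndarray,
                 min_excess_db: float = 10.0,
                 harmonic_tol: float = 0.02,
                 median_window_orders: float = 4.0,
                 dynamic_range_db: float = 100.0) -> ModeReport:
    """Classify spectral peaks against the rotation harmonics.

    Peaks are local maxima rising at least ``min_excess_db`` above the
    local median of the dB spectrum.  The median window spans a few
    rotation orders so that a tone's spectral-leakage skirt cannot
    dominate its own baseline.  Each peak is matched to the nearest
    integer multiple of
    the rotation frequency within a ±2% tolerance and classified:
    multiples of 4 are ordinary blade-passage harmonics; any other
    integer multiple is a rotational harmonic and flags non-ideal
    rotation; unmatched peaks are non-harmonic.
    """
    f_norm = np.asarray(f_norm, dtype=float)
    pxx = np.asarray(pxx, dtype=float)
    db = 10.0 * np.log10(np.maximum(pxx, np.finfo(float).tiny))
    df = np.median(np.diff(f_norm)) if f_norm.size > 1 else 1.0
    win = max(5, int(round(median_window_orders / df)) | 1)
    local_med = median_filter(db, size=win, mode="nearest")
    excess = db - local_med
    peaks, _ = find_peaks(excess, height=min_excess_db)
    # ripples of the numerical noise floor are not physical modes
    peaks = [i for i in peaks if db[i] >= db.max() - dynamic_range_db]

    report = ModeReport()
    for i in peaks:
        f = f_norm[i]
        k = int(round(f))
        matched = k >= 1 and abs(f - k) <= harmonic_tol * max(k, 1)
        if not matched:
            kind, harm = "non_harmonic", None
        elif k % 4 == 0:
            kind, harm = "blade_passage", k
        else:
            kind, harm = "rotational", k
        report.modes.append(SpectralMode(
            f_norm=float(f), power_db=float(db[i]),
            excess_db=float(excess[i]), harmonic=harm, kind=kind))
    report.non_ideal = any(m.kind == "rotational" for m in report.modes)
    return report
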