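"""Configuration, end-to-end pipelines and the command-line interface.

The workbench chains the library modules into the runs a bench
scientist actually performs:

* ``simulate``     — generate a fixture bundle (marker tracks, rendered
                     frames, velocity fields, integral signals) from a
                     motion model;
* ``reconstruct``  — marker tracks (or frames) -> pose track + motion
                     summary;
* ``compare``      — two field bundles -> per-phase RMS, error maps and
                     PDFs;
* ``psd``          — integral signals -> rotation-normalized spectra and
                     the non-ideal-rotation mode report;
* ``regimes``      — fluid properties + operating point -> viscosity,
                     Reynolds numbers, turbulence boundary conditions.

Configuration is a YAML file; every run writes back a resolved copy of
the configuration it actually used, so results are reproducible from
the output directory alone.  Exit codes: 0 ok, 2 configuration error,
3 data error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, MaglevPivError
from .fields import bin_phases, error_pdf, phase_average, relative_error, rms_error
from .geometry import write_pose_csv
from .markers import pair_and_assign
from .metrics import (FluidProperties, PumpOperatingPoint, detect_modes, psd,
                      reynolds_inlet, reynolds_pump, turbulence_bc)
from .motion import decompose
from .reconstruct import reconstruct_track
from .synthetic import (DEFAULT_FPS, DEFAULT_SEED, ChannelGeometry, GridSpec,
                        LaserPlane, MotionModel, default_channel_geometry,
                        default_laser_plane, default_motion_model,
                        project_channels, read_fields_h5, read_tracks_csv,
                        synth_field, synth_signals, synth_trajectory,
                        write_fields_h5, write_tracks_csv)

logger = logging.getLogger(__name__)

EXIT_CONFIG = 2
EXIT_DATA = 3


# ---------------------------------------------------------------------------
# Configuration


def load_config(path: str | Path | None) -> dict:
    """Load a YAML run configuration; defaults when no file is given."""
    cfg: dict = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if not isinstance(cfg, dict):
            raise ConfigError("configuration root must be a mapping")
    return cfg


def build_motion_model(cfg: dict) -> MotionModel:
    section = cfg.get("motion")
    if section is None:
        return default_motion_model()
    try:
        return MotionModel(**section)
    except TypeError as exc:
        raise ConfigError(f"invalid motion section: {exc}") from exc


def build_geometry(cfg: dict) -> ChannelGeometry:
    section = cfg.get("geometry")
    if section is None:
        return default_channel_geometry()
    try:
        return ChannelGeometry.fourfold(
            inner_base=tuple(section["inner_base"]),
            inner_slope=tuple(section["inner_slope"]),
            outer_base=tuple(section["outer_base"]),
            outer_slope=tuple(section["outer_slope"]))
    except KeyError as exc:
        raise ConfigError(f"geometry section missing field {exc}") from exc


def build_laser(cfg: dict) -> LaserPlane:
    section = cfg.get("laser", {})
    return LaserPlane(**section) if section else default_laser_plane()


def write_resolved_config(outdir: Path, resolved: dict) -> None:
    resolved = dict(resolved)
    resolved["package_version"] = __version__
    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(resolved, sort_keys=False))


# ---------------------------------------------------------------------------
# Pipelines (importable; the CLI wraps these)


def run_simulate(cfg: dict, outdir: Path, seed: int = DEFAULT_SEED) -> dict:
    """Generate a fixture bundle: tracks CSV, fields HDF5, signals CSV."""
    outdir.mkdir(parents=True, exist_ok=True)
    model = build_motion_model(cfg)
    geom = build_geometry(cfg)
    plane = build_laser(cfg)
    n_frames = int(cfg.get("n_frames", 256))
    fps = float(cfg.get("fps", DEFAULT_FPS))
    noise_mm = float(cfg.get("marker_noise_mm", 0.0))

    rng = np.random.default_rng(seed)
    poses = synth_trajectory(model, n_frames, fps=fps, seed=seed)
    obs = []
    for pose in poses:
        obs.extend(project_channels(pose, geom, plane,
                                    noise_mm=noise_mm, rng=rng))
    write_tracks_csv(outdir / "tracks.csv", obs)
    write_pose_csv(outdir / "poses_true.csv", poses)

    n_snap = int(cfg.get("n_field_snapshots", 20))
    snaps = [synth_field(GridSpec(), alpha_deg=p.alpha_deg,
                         noise_sd=float(cfg.get("field_noise", 0.05)),
                         seed=int(rng.integers(2 ** 31)))
             for p in poses[:n_snap]]
    write_fields_h5(outdir / "fields.h5", snaps)

    f_rot = model.rotation_rate_rpm / 60.0
    fs = float(cfg.get("signal_fs_hz", 40.0 * f_rot))
    dur = float(cfg.get("signal_duration_s", 40.0 / f_rot))
    harmonics = {int(k): float(v)
                 for k, v in cfg.get("signal_harmonics", {4: 1.0, 8: 0.5}).items()}
    t, dp = synth_signals(f_rot, harmonics, dur, fs,
                          noise_sd=float(cfg.get("signal_noise", 0.0)),
                          seed=int(rng.integers(2 ** 31)))
    _, mz = synth_signals(f_rot, harmonics, dur, fs,
                          noise_sd=float(cfg.get("signal_noise", 0.0)),
                          seed=int(rng.integers(2 ** 31)))
    pd.DataFrame({"t_s": t, "dp_mmHg": dp, "Mz_Nmm": mz}).to_csv(
        outdir / "signals.csv", index=False)

    resolved = {"command": "simulate", "seed": seed,
                "motion": dataclasses.asdict(model),
                "n_frames": n_frames, "fps": fps,
                "marker_noise_mm": noise_mm}
    write_resolved_config(outdir, resolved)
    return {"n_frames": n_frames, "n_observations": len(obs)}


def run_reconstruct(tracks_csv: Path, cfg: dict, outdir: Path) -> dict:
    """Marker tracks -> pose track CSV, diagnostics CSV, motion summary."""
    outdir.mkdir(parents=True, exist_ok=True)
    geom = build_geometry(cfg)
    plane = build_laser(cfg)
    fps = float(cfg.get("fps", DEFAULT_FPS))
    rpm = float(cfg.get("motion", {}).get("rotation_rate_rpm",
                                          default_motion_model().rotation_rate_rpm))
    alpha_step = 360.0 * rpm / (60.0 * fps)

    obs = read_tracks_csv(tracks_csv)
    frames: dict[int, list] = {}
    for o in obs:
        frames.setdefault(o.frame_index, []).append(o)

    pairings = []
    center = np.zeros(2)
    alpha_hint = float(cfg.get("alpha_start_deg", 0.0))
    for fi in sorted(frames):
        pts = np.array([[o.x_mm, o.y_mm] for o in frames[fi]])
        pairing = pair_and_assign(pts, center, geom,
                                  expected_alpha_deg=alpha_hint, frame_index=fi)
        pairings.append(pairing)
        alpha_hint += alpha_step
    poses, diags = reconstruct_track(
        pairings, geom, plane,
        alpha_start_deg=float(cfg.get("alpha_start_deg", 0.0)),
        alpha_step_deg=alpha_step,
        sigma_marker_mm=float(cfg.get("marker_noise_mm", 0.0)),
        exact=bool(cfg.get("exact_solver", True)), fps=fps)

    write_pose_csv(outdir / "poses.csv", poses)
    pd.DataFrame([dataclasses.asdict(d) for d in diags]).to_csv(
        outdir / "diagnostics.csv", index=False)
    summary = decompose(poses, geom, rotation_rate_rpm=rpm)
    (outdir / "motion_summary.yaml").write_text(summary.to_yaml())
    write_resolved_config(outdir, {"command": "reconstruct",
                                   "tracks": str(tracks_csv),
                                   "alpha_step_deg": alpha_step})
    return {"n_poses": len(poses), "summary": summary}


def run_fixture_recovery(seed: int = DEFAULT_SEED,
                         n_frames: int | None = None,
                         fps: float = DEFAULT_FPS,
                         from_images: bool = True,
                         exact: bool = True,
                         marker_noise_mm: float = 0.0):
    """End-to-end motion recovery on the default synthetic fixture.

    Generates one revolution (unless ``n_frames`` is given) of the
    default motion model, renders and detects the marker dots (or uses
    the projected positions directly when ``from_images`` is False),
    calibrates pixels to millimetres from a rendered reference grid,
    pairs and labels the dots, reconstructs the pose track and
    decomposes it into the three motion modes.  Returns the
    :class:`~maglevpiv.motion.MotionSummary`.
    """
    from .markers import detect_markers, fit_calibration
    from .synthetic import (default_image_spec, project_channels,
                            reference_grid_mm, render_frame)

    model = default_motion_model()
    geom = build_geometry({})
    plane = build_laser({})
    spec = default_image_spec()
    step = 360.0 * model.rotation_rate_rpm / (60.0 * fps)
    if n_frames is None:
        n_frames = int(np.ceil(360.0 / step))
    rng = np.random.default_rng(seed)

    calibration = None
    if from_images:
        grid_mm = reference_grid_mm()
        cal_img = render_frame([], spec, extra_points_mm=grid_mm)
        detected = detect_markers(cal_img)
        predicted = spec.mm_to_px(grid_mm)
        order = [int(np.argmin(np.linalg.norm(detected - p, axis=1)))
                 for p in predicted]
        calibration = fit_calibration(detected[order], grid_mm)

    poses_true = synth_trajectory(model, n_frames, fps=fps, seed=seed)
    pairings = []
    for pose in poses_true:
        obs = project_channels(pose, geom, plane,
                               noise_mm=marker_noise_mm, rng=rng)
        if from_images:
            img = render_frame(obs, spec)
            centers_mm = calibration.px_to_mm(detect_markers(img))
        else:
            centers_mm = np.array([[o.x_mm, o.y_mm] for o in obs])
        pairings.append(pair_and_assign(
            centers_mm, np.zeros(2), geom,
            expected_alpha_deg=pose.alpha_deg, frame_index=pose.frame_index))
    poses, _ = reconstruct_track(pairings, geom, plane, alpha_start_deg=0.0,
                                 alpha_step_deg=step,
                                 sigma_marker_mm=marker_noise_mm,
                                 exact=exact, fps=fps)
    return decompose(poses, geom,
                     rotation_rate_rpm=model.rotation_rate_rpm)


def run_compare(fields_a: Path, fields_b: Path, outdir: Path) -> dict:
    """Phase-matched comparison of two HDF5 field bundles."""
    outdir.mkdir(parents=True, exist_ok=True)
    snaps_a = read_fields_h5(fields_a)
    snaps_b = read_fields_h5(fields_b)
    if not snaps_a or not snaps_b:
        raise MaglevPivError("empty field bundle")
    bins_a = bin_phases(np.array([s.alpha_deg for s in snaps_a]))
    bins_b = bin_phases(np.array([s.alpha_deg for s in snaps_b]))
    rows = []
    for b in sorted(set(bins_a) & set(bins_b)):
        pa = phase_average([s for s, k in zip(snaps_a, bins_a) if k == b],
                           alpha_bin=b)
        pb = phase_average([s for s, k in zip(snaps_b, bins_b) if k == b],
                           alpha_bin=b)
        e = relative_error(pa.magnitude, pb.magnitude)
        rows.append({"bin": int(b), "rms_percent": rms_error(e),
                     "n_a": pa.count, "n_b": pb.count})
        centers, density = error_pdf(e)
        np.savetxt(outdir / f"error_pdf_bin{b:02d}.csv",
                   np.column_stack([centers, density]), delimiter=",",
                   header="e_rel,density", comments="")
    report = {"per_bin": rows}
    (outdir / "comparison.yaml").write_text(yaml.safe_dump(report))
    write_resolved_config(outdir, {"command": "compare",
                                   "fields_a": str(fields_a),
                                   "fields_b": str(fields_b)})
    return report


def run_psd(signals_csv: Path, f_rot_hz: float, outdir: Path) -> dict:
    """Spectra + mode classification of the integral signals."""
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(signals_csv)
    fs = 1.0 / float(np.median(np.diff(df["t_s"])))
    out_rows = {}
    report = {}
    for col in ("dp_mmHg", "Mz_Nmm"):
        if col not in df:
            continue
        f_norm, pxx = psd(df[col].to_numpy(), fs, f_rot_hz)
        out_rows[col] = (f_norm, pxx)
        modes = detect_modes(f_norm, pxx)
        report[col] = {
            "non_ideal": bool(modes.non_ideal),
            "modes": [{"f_norm": m.f_norm, "kind": m.kind,
                       "harmonic": m.harmonic} for m in modes.modes]}
    if out_rows:
        first = next(iter(out_rows.values()))[0]
        table = {"f_norm": first}
        for col, (f_norm, pxx) in out_rows.items():
            table[f"psd_{col}"] = pxx
        pd.DataFrame(table).to_csv(outdir / "spectra.csv", index=False)
    (outdir / "modes.yaml").write_text(yaml.safe_dump(report))
    write_resolved_config(outdir, {"command": "psd", "f_rot_hz": f_rot_hz})
    return report


def run_regimes(fluid: FluidProperties, op: PumpOperatingPoint) -> dict:
    mu = fluid.mu_pa_s
    re_in = reynolds_inlet(fluid.rho_kg_m3, mu, op.flow_l_min, op.d_inlet_mm)
    re_pump = reynolds_pump(fluid.rho_kg_m3, mu, op.rotation_rate_rpm,
                            op.d_rotor_mm)
    i_turb, l_turb = turbulence_bc(re_in, op.d_hydraulic_mm)
    return {"mu_pa_s": mu, "re_inlet": re_in, "re_pump": re_pump,
            "i_turb": i_turb, "l_turb_mm": l_turb}


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Impeller-motion tracking and flow-field comparison workbench."""
    logging.basicConfig(level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


def _fail(exc: Exception, code: int) -> None:
    click.echo(f"error: {exc}", err=True)
    sys.exit(code)


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), required=True)
@click.option("--seed", type=int, default=DEFAULT_SEED, show_default=True)
def simulate(config: str | None, out: str, seed: int) -> None:
    """Generate a synthetic fixture bundle."""
    try:
        cfg = load_config(config)
        info = run_simulate(cfg, Path(out), seed=seed)
    except ConfigError as exc:
        _fail(exc, EXIT_CONFIG)
    except MaglevPivError as exc:
        _fail(exc, EXIT_DATA)
    else:
        click.echo(json.dumps(info))


@cli.command()
@click.argument("tracks", type=click.Path(exists=True))
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), required=True)
def reconstruct(tracks: str, config: str | None, out: str) -> None:
    """Reconstruct poses and motion modes from a marker-track CSV."""
    try:
        cfg = load_config(config)
        info = run_reconstruct(Path(tracks), cfg, Path(out))
    except ConfigError as exc:
        _fail(exc, EXIT_CONFIG)
    except (MaglevPivError, OSError) as exc:
        _fail(exc, EXIT_DATA)
    else:
        click.echo(info["summary"].to_yaml())


@cli.command()
@click.argument("fields_a", type=click.Path(exists=True))
@click.argument("fields_b", type=click.Path(exists=True))
@click.option("--out", type=click.Path(), required=True)
def compare(fields_a: str, fields_b: str, out: str) -> None:
    """Compare two phase-labelled field bundles."""
    try:
        report = run_compare(Path(fields_a), Path(fields_b), Path(out))
    except ConfigError as exc:
        _fail(exc, EXIT_CONFIG)
    except (MaglevPivError, OSError) as exc:
        _fail(exc, EXIT_DATA)
    else:
        click.echo(yaml.safe_dump(report))


@cli.command("psd")
@click.argument("signals", type=click.Path(exists=True))
@click.option("--f-rot", type=float, required=True,
              help="rotation frequency, Hz")
@click.option("--out", type=click.Path(), required=True)
def psd_cmd(signals: str, f_rot: float, out: str) -> None:
    """Spectral non-ideal-rotation diagnostic of integral signals."""
    try:
        report = run_psd(Path(signals), f_rot, Path(out))
    except ConfigError as exc:
        _fail(exc, EXIT_CONFIG)
    except (MaglevPivError, OSError) as exc:
        _fail(exc, EXIT_DATA)
    else:
        click.echo(yaml.safe_dump(report))


@cli.command()
@click.option("--temperature", type=float, default=24.3, show_default=True)
@click.option("--flow", type=float, default=4.4, show_default=True,
              help="flow rate, L/min")
@click.option("--rpm", type=float, default=2350.0, show_default=True)
def regimes(temperature: float, flow: float, rpm: float) -> None:
    """Viscosity, Reynolds numbers and turbulence boundary conditions."""
    try:
        fluid = FluidProperties(temperature_c=temperature)
        op = PumpOperatingPoint(flow_l_min=flow, rotation_rate_rpm=rpm)
        out = run_regimes(fluid, op)
    except ConfigError as exc:
        _fail(exc, EXIT_CONFIG)
    else:
        click.echo(json.dumps(out, indent=2))


if __name__ == "__main__":
    cli()
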