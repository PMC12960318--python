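"""Phase binning, regridding and the field-comparison statistics."""

import numpy as np
import pytest

from maglevpiv.errors import ConfigError
from maglevpiv.fields import (MMHG_PA, abs_pressure_error, bin_phases,
                              error_pdf, field_std, out_of_plane_check,
                              phase_average, regrid, relative_error, rms_error)
from maglevpiv.synthetic import FieldSnapshot, GridSpec, synth_field

GRID = GridSpec(x_min=0.0, x_max=10.0, y_min=-10.0, y_max=0.0, dx=0.5)


def _snapshot(u, v, **kw):
    x, y = GRID.mesh()
    return FieldSnapshot(x_mm=x, y_mm=y, u=np.broadcast_to(u, x.shape).copy(),
                         v=np.broadcast_to(v, x.shape).copy(), **kw)


class TestBinPhases:
    @pytest.mark.parametrize("alpha, expected",
                             [(0.0, 1), (0.5, 1), (89.999, 90), (90.0, 1),
                              (91.4, 2), (359.0, 90), (271.0, 2)])
    def test_boundary_convention(self, alpha, expected):
        assert bin_phases(np.array([alpha]))[0] == expected

    def test_counts_conserved_and_uniform(self, rng):
        alphas = rng.uniform(0.0, 360.0, 90000)
        bins = bin_phases(alphas)
        assert bins.min() >= 1 and bins.max() <= 90
        counts = np.bincount(bins, minlength=91)[1:]
        assert counts.sum() == len(alphas)
        # multinomial fluctuation around 1000 per bin, ~5 sigma bound
        assert np.all(np.abs(counts - 1000) < 5 * np.sqrt(1000))


class TestRegrid:
    def test_identity_on_matching_grid(self):
        snap = synth_field(GRID, 30.0)
        out = regrid(snap, GRID)
        assert np.allclose(out.u, snap.u, atol=1e-12)
        assert np.allclose(out.v, snap.v, atol=1e-12)

    def test_affine_field_reproduced_exactly(self):
        """Linear interpolation is exact on affine functions."""
        src = GridSpec(x_min=-1.0, x_max=11.0, y_min=-11.0, y_max=1.0, dx=0.7)
        x, y = src.mesh()
        snap = FieldSnapshot(x_mm=x, y_mm=y, u=2.0 * x - 3.0 * y + 1.0,
                             v=0.5 * x + 0.25 * y)
        out = regrid(snap, GRID)
        gx, gy = GRID.mesh()
        assert np.allclose(out.u, 2.0 * gx - 3.0 * gy + 1.0, atol=1e-10)
        assert np.allclose(out.v, 0.5 * gx + 0.25 * gy, atol=1e-10)

    def test_refinement_error_bounded_by_curvature(self):
        """Taylor bound: linear interpolation error <= h^2/8 * max |f''|
        per direction (use a quadratic with known second derivative)."""
        src = GridSpec(x_min=-1.0, x_max=11.0, y_min=-11.0, y_max=1.0, dx=1.0)
        x, y = src.mesh()
        snap = FieldSnapshot(x_mm=x, y_mm=y, u=x ** 2 + y ** 2, v=0.0 * x)
        out = regrid(snap, GRID)
        gx, gy = GRID.mesh()
        err = np.nanmax(np.abs(out.u - (gx ** 2 + gy ** 2)))
        # d2f/dx2 = d2f/dy2 = 2, h = 1 mm -> bound 2 * (1/8) * 2
        assert err <= 2.0 * (1.0 / 8.0) * 2.0 + 1e-9

    def test_outside_hull_masked(self):
        small = GridSpec(x_min=2.0, x_max=8.0, y_min=-8.0, y_max=-2.0, dx=0.5)
        x, y = small.mesh()
        snap = FieldSnapshot(x_mm=x, y_mm=y, u=np.ones_like(x),
                             v=np.zeros_like(x))
        out = regrid(snap, GRID)
        assert np.isnan(out.u).any()
        assert np.isfinite(out.u[(GRID.mesh()[0] == 5.0)
                                 & (GRID.mesh()[1] == -5.0)]).all()

    def test_z_levels_averaged_in_window(self):
        """Multi-level snapshots are averaged with equal weight over the
        laser-sheet window only."""
        xs, ys, zs, us = [], [], [], []
        for z, val in [(-2.5, 1.0), (-2.25, 2.0), (-2.0, 3.0), (-1.0, 100.0)]:
            x, y = GRID.mesh()
            xs.append(x.ravel())
            ys.append(y.ravel())
            zs.append(np.full(x.size, z))
            us.append(np.full(x.size, val))
        snap = FieldSnapshot(x_mm=np.concatenate(xs), y_mm=np.concatenate(ys),
                             u=np.concatenate(us),
                             v=np.zeros(sum(len(a) for a in xs)),
                             z_mm=np.concatenate(zs))
        out = regrid(snap, GRID, z_window=(-2.5, -2.0))
        assert np.allclose(out.u[np.isfinite(out.u)], 2.0)

    def test_empty_z_window_rejected(self):
        x, y = GRID.mesh()
        snap = FieldSnapshot(x_mm=x.ravel(), y_mm=y.ravel(),
                             u=np.zeros(x.size), v=np.zeros(x.size),
                             z_mm=np.full(x.size, -2.25))
        with pytest.raises(ConfigError):
            regrid(snap, GRID, z_window=(5.0, 6.0))


class TestPhaseAverage:
    def test_single_snapshot_is_its_own_magnitude(self):
        snap = synth_field(GRID, 30.0)
        pa = phase_average([snap])
        assert np.allclose(pa.magnitude, np.hypot(snap.u, snap.v))
        assert pa.count == 1

    def test_opposite_vectors_cancel(self):
        """Components are averaged before the magnitude: two snapshots
        with opposite velocities average to exactly zero, which
        distinguishes this from a mean of magnitudes."""
        a = _snapshot(1.3, -0.7)
        b = _snapshot(-1.3, 0.7)
        pa = phase_average([a, b])
        assert np.all(pa.magnitude == 0.0)

    def test_magnitude_never_exceeds_mean_of_magnitudes(self, rng):
        """Triangle inequality, strict when directions differ."""
        snaps = [synth_field(GRID, 30.0, noise_sd=0.3, seed=s)
                 for s in range(8)]
        pa = phase_average(snaps)
        mean_of_mags = np.mean([np.hypot(s.u, s.v) for s in snaps], axis=0)
        assert np.all(pa.magnitude <= mean_of_mags + 1e-12)
        assert (pa.magnitude < mean_of_mags - 1e-9).any()

    def test_noisy_ensemble_within_clt_bound(self):
        clean = synth_field(GRID, 30.0)
        n, sd = 200, 0.05
        snaps = [synth_field(GRID, 30.0, noise_sd=sd, seed=s) for s in range(n)]
        pa = phase_average(snaps)
        from maglevpiv.synthetic import WakeParams

        bound = 4.0 * sd * WakeParams().noise_ratio / np.sqrt(n)
        ok = np.abs(pa.magnitude - np.hypot(clean.u, clean.v)) < bound
        assert ok.mean() > 0.99


class TestErrorStatistics:
    def test_relative_error_direct_oracle(self, rng):
        ref = np.abs(rng.normal(1.0, 0.3, (20, 20)))
        fld = ref + rng.normal(0.0, 0.1, ref.shape)
        e = relative_error(fld, ref)
        expected = (fld - ref) / ref.max()
        assert np.allclose(e, expected, atol=1e-15)

    def test_identical_fields_zero(self):
        ref = np.ones((5, 5))
        assert np.all(relative_error(ref, ref) == 0.0)

    def test_constant_offset_fraction_of_max(self):
        ref = np.linspace(0.0, 2.0, 100).reshape(10, 10)
        e = relative_error(ref + 0.1 * ref.max(), ref)
        assert np.allclose(e, 0.1, atol=1e-14)

    def test_zero_reference_rejected(self):
        with pytest.raises(ConfigError):
            relative_error(np.ones((3, 3)), np.zeros((3, 3)))

    def test_rms_known_values_and_oracle(self, rng):
        assert rms_error(np.full((7, 7), 0.05)) == pytest.approx(5.0)
        assert rms_error(np.zeros((4, 4))) == 0.0
        e = rng.normal(0.0, 0.1, (30, 30))
        brute = 100.0 * np.sqrt(np.sum(e ** 2) / e.size)
        assert rms_error(e) == pytest.approx(brute, abs=1e-12)

    def test_rms_permutation_invariant_and_monotone(self, rng):
        e = rng.normal(0.0, 0.1, (10, 10))
        shuffled = e.ravel()[rng.permutation(e.size)].reshape(e.shape)
        assert rms_error(e) == pytest.approx(rms_error(shuffled))
        e2 = e.copy()
        e2[3, 3] *= 2.0
        assert rms_error(e2) > rms_error(e)

    def test_pressure_error_constant_offset(self):
        ref = np.zeros((10, 10))
        fld = ref + 4.0 * MMHG_PA
        e, mean, rms = abs_pressure_error(fld, ref)
        assert np.allclose(e, 4.0)
        assert mean == pytest.approx(4.0) and rms == pytest.approx(4.0)

    def test_pressure_error_bimodal_mixture(self, rng):
        """Two-population offsets (0 and -4 mmHg) show up as two peaks in
        the error histogram, the outlet-offset signature."""
        ref = np.zeros(2000)
        offsets = np.where(rng.random(2000) < 0.5, 0.0, -4.0)
        fld = ref + offsets * MMHG_PA + rng.normal(0, 0.2 * MMHG_PA, 2000)
        e, mean, _ = abs_pressure_error(fld, ref)
        hist, edges = np.histogram(e, bins=40)
        centers = 0.5 * (edges[:-1] + edges[1:])
        peak_lo = hist[np.abs(centers + 4.0) < 1.0].max()
        peak_hi = hist[np.abs(centers) < 1.0].max()
        trough = hist[np.abs(centers + 2.0) < 0.6].min()
        assert peak_lo > 3 * trough and peak_hi > 3 * trough

    def test_inlet_referencing(self):
        p = np.array([[10.0, 20.0]])
        p_ref = np.array([[5.0, 15.0]])
        e, mean, _ = abs_pressure_error(p, p_ref, inlet_p_pa=10.0,
                                        inlet_p_ref_pa=5.0)
        assert np.allclose(e, 0.0)


class TestFieldStd:
    def test_identical_snapshots_zero(self):
        snaps = [_snapshot(1.0, 2.0) for _ in range(5)]
        pa = phase_average(snaps, with_sigma=True)
        assert np.all(pa.sigma_u == 0.0)

    def test_symmetric_spread_gives_squared_deviation(self):
        """Magnitudes U +/- c about the mean give exactly c^2 in the
        printed (no square root) form, and c with the root applied."""
        a = _snapshot(3.0, 0.0)
        b = _snapshot(5.0, 0.0)
        mean_mag = phase_average([a, b]).magnitude
        printed = field_std([a, b], mean_mag)
        assert np.allclose(printed, 1.0)  # c = 1 -> c^2 = 1
        rooted = field_std([a, b], mean_mag, sqrt=True)
        assert np.allclose(rooted, 1.0)
        c = _snapshot(2.0, 0.0)
        d = _snapshot(6.0, 0.0)
        mean2 = phase_average([c, d]).magnitude
        assert np.allclose(field_std([c, d], mean2), 4.0)  # c = 2 -> 4

    def test_monte_carlo_matches_direct_summation(self, rng):
        snaps = [synth_field(GRID, 10.0, noise_sd=0.1, seed=s)
                 for s in range(20)]
        pa = phase_average(snaps, with_sigma=True)
        mags = np.array([np.hypot(s.u, s.v) for s in snaps])
        direct = np.mean((mags - pa.magnitude) ** 2, axis=0)
        assert np.allclose(pa.sigma_u, direct, atol=1e-14)

    def test_single_snapshot_flagged(self):
        with pytest.warns(UserWarning):
            out = field_std([_snapshot(1.0, 0.0)], np.hypot(1.0, 0.0)
                            * np.ones_like(GRID.mesh()[0]))
        assert np.all(out == 0.0)


class TestErrorPdf:
    def test_density_integrates_to_one(self, rng):
        e = rng.normal(0.0, 0.03, (50, 50))
        centers, density = error_pdf(e)
        width = centers[1] - centers[0]
        assert np.sum(density) * width == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_distribution_single_bin(self):
        centers, density = error_pdf(np.zeros((20, 20)))
        assert (density > 0).sum() == 1

    def test_gaussian_errors_match_density(self, rng):
        from scipy import stats

        e = rng.normal(0.0, 0.05, 100000)
        centers, density = error_pdf(e, bin_width=0.005)
        expected = stats.norm.pdf(centers, 0.0, 0.05)
        # Kolmogorov-Smirnov style sup bound on the binned CDFs
        width = centers[1] - centers[0]
        sup = np.max(np.abs(np.cumsum(density) - np.cumsum(expected)) * width)
        assert sup < 0.01

    def test_positive_mean_shifts_mode_right(self, rng):
        e = rng.normal(0.04, 0.02, 20000)
        centers, density = error_pdf(e)
        assert centers[np.argmax(density)] > 0.0


class TestOutOfPlane:
    def test_zero_velocity_no_flags(self):
        assert out_of_plane_check(np.zeros((10, 10))) == 0.0

    def test_arithmetic_threshold(self):
        """1.3 m/s for 0.1 ms travels 0.13 mm — over a quarter of the
        0.5 mm sheet; 1.2 m/s (0.12 mm) stays under."""
        assert out_of_plane_check(np.array([[1.3]]), dt_s=1e-4) == 1.0
        assert out_of_plane_check(np.array([[1.2]]), dt_s=1e-4) == 0.0

    def test_fraction_counts_nodes(self):
        w = np.array([[1.3, 1.2, 0.0, 2.0]])
        assert out_of_plane_check(w, dt_s=1e-4) == pytest.approx(0.5)
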