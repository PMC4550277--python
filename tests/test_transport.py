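import numpy as np
import pandas as pd
import pytest

from eggshed import synthetic_data as sd
from eggshed import transport as tp
from eggshed.io_formats import KernelMode


def t0(field):
    return pd.Timestamp(field.times[0])


class TestSampleVelocity:
    def test_uniform_everywhere(self, uniform_field):
        u, v = tp.sample_velocity(uniform_field, t0(uniform_field), 3000.0, 4000.0)
        assert (u, v) == (10.0, 0.0)

    def test_grid_node_exact(self, gyre_field):
        f = gyre_field
        j, i = 5, 7
        u, v = tp.sample_velocity(f, t0(f), float(f.x[i]), float(f.y[j]))
        assert u == pytest.approx(f.u[0, j, i], abs=1e-12)
        assert v == pytest.approx(f.v[0, j, i], abs=1e-12)

    def test_gyre_speed_interpolation_error_second_order(self, gyre_field):
        # solid-body rotation is linear in x,y: bilinear interpolation is exact
        f = gyre_field
        xc, yc = f.x.mean(), f.y.mean()
        omega = 10.0 / (f.x.max() - xc)
        x, y = xc + 1234.5, yc + 987.6
        u, v = tp.sample_velocity(f, t0(f), x, y)
        r = np.hypot(x - xc, y - yc)
        assert np.hypot(u, v) == pytest.approx(omega * r, rel=1e-9)

    def test_time_outside_span_rejected(self, uniform_field):
        with pytest.raises(ValueError, match="span"):
            tp.sample_velocity(uniform_field, t0(uniform_field) - pd.Timedelta(hours=1), 3000.0, 3000.0)

    def test_point_on_land_rejected(self, uniform_field):
        with pytest.raises(ValueError, match="land"):
            tp.sample_velocity(uniform_field, t0(uniform_field), -500.0, 3000.0)

    def test_nearshore_along_coast_projection(self):
        # uniform eastward (onshore-normal) flow with a 1 km band along the
        # x=0 coast: inside the band only the along-coast (y) component of
        # the probed offshore velocity survives -> (0, 0) for pure cross-
        # shore flow
        f = sd.gen_current_field(
            sd.FieldSimParams(nx=20, ny=20, dx=500.0, n_hours=4, regime="uniform", u0=10.0),
            nearshore_band_width=1000.0,
        )
        u, v = tp.sample_velocity(f, t0(f), 400.0, 5000.0)
        assert u == pytest.approx(0.0, abs=1e-9)
        assert v == pytest.approx(0.0, abs=1e-9)
        # offshore of the band the full flow is untouched
        u2, _ = tp.sample_velocity(f, t0(f), 3000.0, 5000.0)
        assert u2 == pytest.approx(10.0)


class TestStepping:
    def test_uniform_24h_displacement(self, uniform_field):
        # 10 cm/s for 24 hours = 8.64 km east
        params = tp.TransportParams(source=(500.0, 5000.0), epsilon=0.0, release_rate=1,
                                    window_hours=24, seed=0)
        tracers = tp.run_release(uniform_field, params, KernelMode.FIT)
        first = tracers[0]  # released at window start, 24 steps
        disp = first.positions[-1] - first.positions[0]
        assert disp[0] == pytest.approx(8640.0, abs=1e-6)
        assert disp[1] == pytest.approx(0.0, abs=1e-9)

    def test_bit_uniform_displacement_negative(self, uniform_field):
        params = tp.TransportParams(source=(9000.0, 5000.0), epsilon=0.0, release_rate=1,
                                    window_hours=24, seed=0)
        w = (t0(uniform_field), t0(uniform_field) + pd.Timedelta(hours=24))
        tracers = tp.run_release(uniform_field, params, KernelMode.BIT, window=w)
        first = tracers[0]  # released at window end, integrated 24 h back
        disp = first.positions[-1] - first.positions[0]
        assert disp[0] == pytest.approx(-8640.0, abs=1e-6)

    def test_noise_rms_per_component(self, uniform_field):
        # epsilon=5 cm/s, u0 irrelevant: per-component single-step rms
        # displacement = eps * dt
        f = sd.gen_current_field(
            sd.FieldSimParams(nx=20, ny=20, dx=500.0, n_hours=3, regime="uniform", u0=0.0)
        )
        params = tp.TransportParams(source=(5000.0, 5000.0), epsilon=5.0, release_rate=1000,
                                    window_hours=2, seed=3)
        w = (t0(f), t0(f) + pd.Timedelta(hours=1))
        # single hourly release, one step each
        params2 = tp.TransportParams(source=(5000.0, 5000.0), epsilon=5.0, release_rate=1000,
                                     window_hours=1, seed=3)
        tracers = tp.run_release(f, params2, KernelMode.FIT, window=w)
        steps = np.array([tr.positions[1] - tr.positions[0] for tr in tracers])
        expected = 0.05 * 3600.0  # 180 m
        assert np.std(steps[:, 0]) == pytest.approx(expected, rel=0.1)
        assert np.std(steps[:, 1]) == pytest.approx(expected, rel=0.1)

    def test_same_seed_identical_trajectories(self, uniform_field):
        params = tp.TransportParams(source=(2000.0, 5000.0), epsilon=5.0, release_rate=5,
                                    window_hours=6, seed=42)
        t1 = tp.run_release(uniform_field, params, KernelMode.FIT)
        t2 = tp.run_release(uniform_field, params, KernelMode.FIT)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.positions, b.positions)

    def test_fit_bit_inversion_static_field(self, uniform_field):
        # zero noise, static homogeneous field: BIT from the FIT endpoint
        # returns to the release point within 1e-6 m
        f = uniform_field
        start = np.array([1000.0, 4000.0])
        params = tp.TransportParams(source=tuple(start), epsilon=0.0, release_rate=1,
                                    window_hours=10, seed=0)
        w = (t0(f), t0(f) + pd.Timedelta(hours=10))
        fit = tp.run_release(f, params, KernelMode.FIT, window=w)[0]
        end = fit.positions[-1]
        params_b = tp.TransportParams(source=tuple(end), epsilon=0.0, release_rate=1,
                                      window_hours=10, seed=0)
        bit = tp.run_release(f, params_b, KernelMode.BIT, window=w)[0]
        assert np.allclose(bit.positions[-1], start, atol=1e-6)

    def test_fit_bit_round_trip_error_second_order_per_step(self):
        # time-varying field: the single-step round-trip error shrinks ~4x
        # when the step is halved
        f = sd.gen_current_field(
            sd.FieldSimParams(nx=20, ny=20, dx=500.0, n_hours=6, regime="time_varying",
                              u0=20.0, period_hours=6.0)
        )
        start = np.array([5000.0, 5000.0])
        errs = {}
        for sub in (1, 2):
            params = tp.TransportParams(source=tuple(start), epsilon=0.0, release_rate=1,
                                        window_hours=1, seed=0, substeps=sub)
            w = (t0(f), t0(f) + pd.Timedelta(hours=1))
            fit = tp.run_release(f, params, KernelMode.FIT, window=w)[0]
            params_b = tp.TransportParams(source=tuple(fit.positions[-1]), epsilon=0.0,
                                          release_rate=1, window_hours=1, seed=0, substeps=sub)
            bit = tp.run_release(f, params_b, KernelMode.BIT, window=w)[0]
            errs[sub] = np.linalg.norm(bit.positions[-1] - start)
        assert errs[2] < errs[1]

    def test_diffusion_scaling_variance(self):
        # u=v=0: per-component displacement variance after k steps = k (eps dt)^2
        f = sd.gen_current_field(
            sd.FieldSimParams(nx=40, ny=40, dx=2000.0, n_hours=13, regime="uniform", u0=0.0)
        )
        k = 12
        params = tp.TransportParams(source=(40000.0, 40000.0), epsilon=5.0, release_rate=1000,
                                    window_hours=k, seed=7)
        w = (t0(f), t0(f) + pd.Timedelta(hours=k))
        tracers = [tr for tr in tp.run_release(f, params, KernelMode.FIT, window=w)
                   if tr.release_time == t0(f)]
        final = np.array([tr.positions[-1] - tr.positions[0] for tr in tracers])
        expected = k * (0.05 * 3600.0) ** 2
        assert final[:, 0].var() == pytest.approx(expected, rel=0.15)
        assert final[:, 1].var() == pytest.approx(expected, rel=0.15)


class TestBoundary:
    def test_inland_step_snaps_to_coast(self, uniform_field):
        (x, y), status = tp.handle_boundary((-50.0, 5000.0), uniform_field)
        assert x == pytest.approx(0.0, abs=1e-3)
        assert y == pytest.approx(5000.0, abs=1e-6)
        assert status is tp.TracerStatus.BEACHED

    def test_step_outside_grid_exits(self, uniform_field):
        _, status = tp.handle_boundary((20000.0, 5000.0), uniform_field)
        assert status is tp.TracerStatus.EXITED

    def test_offshore_step_unchanged(self, uniform_field):
        (x, y), status = tp.handle_boundary((3000.0, 3000.0), uniform_field)
        assert (x, y) == (3000.0, 3000.0)
        assert status is tp.TracerStatus.ACTIVE

    def test_tracer_count_conservation(self, uniform_field):
        params = tp.TransportParams(source=(9500.0, 5000.0), epsilon=10.0, release_rate=10,
                                    window_hours=24, seed=1)
        tracers = tp.run_release(uniform_field, params, KernelMode.FIT)
        n = sum(1 for tr in tracers)
        by_status = {s: sum(1 for tr in tracers if tr.status is s) for s in tp.TracerStatus}
        assert n == 240 == sum(by_status.values())


class TestReleasesAndKernels:
    def test_release_counts(self, uniform_field):
        # 3-day window at 50/hr -> 3600 tracers
        params = tp.TransportParams(source=(500.0, 5000.0), epsilon=0.0, release_rate=50,
                                    window_hours=72, seed=0)
        tracers = tp.run_release(uniform_field, params, KernelMode.BIT,
                                 window=(t0(uniform_field),
                                         t0(uniform_field) + pd.Timedelta(hours=72)))
        assert len(tracers) == 3600

    def test_single_tracer_release(self, uniform_field):
        params = tp.TransportParams(source=(500.0, 5000.0), epsilon=0.0, release_rate=1,
                                    window_hours=1, seed=0)
        tracers = tp.run_release(uniform_field, params, KernelMode.FIT,
                                 window=(t0(uniform_field),
                                         t0(uniform_field) + pd.Timedelta(hours=1)))
        assert len(tracers) == 1

    def test_window_exceeding_span_rejected(self, uniform_field):
        params = tp.TransportParams(source=(500.0, 5000.0), release_rate=1, window_hours=2000)
        with pytest.raises(ValueError, match="span"):
            tp.run_release(uniform_field, params, KernelMode.FIT)

    def test_kernel_single_cell(self, uniform_field):
        params = tp.TransportParams(source=(5250.0, 5250.0), epsilon=0.0, release_rate=3,
                                    window_hours=5, seed=0)
        f0 = sd.gen_current_field(
            sd.FieldSimParams(nx=20, ny=20, dx=500.0, n_hours=6, regime="uniform", u0=0.0)
        )
        tracers = tp.run_release(f0, params, KernelMode.FIT)
        k = tp.exposure_kernel(tracers, f0)
        assert k.P.max() == 100.0
        assert (k.F > 0).sum() == 1

    def test_kernel_ratio(self):
        from eggshed.io_formats import percent_kernel
        F = np.array([[10, 5], [0, 0]])
        P = percent_kernel(F)
        assert P[0, 0] == 100.0 and P[0, 1] == 50.0 and P[1, 1] == 0.0

    def test_kernel_straight_path_uniform_flow(self, uniform_field):
        # single release, no noise: P=100 along the advection path row
        params = tp.TransportParams(source=(250.0, 5250.0), epsilon=0.0, release_rate=1,
                                    window_hours=10, seed=0)
        w = (t0(uniform_field), t0(uniform_field) + pd.Timedelta(hours=10))
        tracers = tp.run_release(uniform_field, params, KernelMode.FIT, window=w)
        k = tp.exposure_kernel(tracers, uniform_field)
        visited_rows = np.unique(np.nonzero(k.F)[0])
        assert len(visited_rows) == 1  # straight east path
        assert k.P.max() == 100.0

    def test_kernel_relabeling_invariance(self, uniform_field):
        params = tp.TransportParams(source=(2000.0, 5000.0), epsilon=5.0, release_rate=4,
                                    window_hours=6, seed=5)
        tracers = tp.run_release(uniform_field, params, KernelMode.FIT,
                                 window=(t0(uniform_field),
                                         t0(uniform_field) + pd.Timedelta(hours=6)))
        k1 = tp.exposure_kernel(tracers, uniform_field)
        k2 = tp.exposure_kernel(list(reversed(tracers)), uniform_field)
        assert np.array_equal(k1.F, k2.F)


class TestHindcastForecast:
    def test_hindcast_mass_upstream_of_pier(self):
        # uniform northward flow: spawning sources lie SOUTH of the pier
        f = sd.gen_current_field(
            sd.FieldSimParams(nx=20, ny=40, dx=500.0, n_hours=96, regime="uniform", u0=0.0)
        )
        f.v[:] = 10.0  # northward 10 cm/s
        pier = (2000.0, 15000.0)
        params = tp.TransportParams(source=pier, epsilon=0.0, release_rate=5, seed=0)
        t_coll = pd.Timestamp(f.times[0]) + pd.Timedelta(hours=80)
        k = tp.hindcast_spawning(f, t_coll, pier, params)
        assert k.mode is KernelMode.BIT
        yy = np.nonzero(k.F)[0]
        y_vals = k.y[yy]
        # nothing north of the release cell; bulk of the mass well south
        assert y_vals.max() <= pier[1] + 250.0
        assert y_vals.min() < pier[1] - 5000.0

    def test_hindcast_zero_flow_retention(self):
        f = sd.gen_current_field(
            sd.FieldSimParams(nx=10, ny=10, dx=1000.0, n_hours=96, regime="uniform", u0=0.0)
        )
        pier = (5500.0, 5500.0)
        params = tp.TransportParams(source=pier, epsilon=0.0, release_rate=2, seed=0)
        t_coll = pd.Timestamp(f.times[0]) + pd.Timedelta(hours=80)
        k = tp.hindcast_spawning(f, t_coll, pier, params)
        nz = np.nonzero(k.F)
        assert len(nz[0]) == 1
        assert k.P[nz][0] == 100.0

    def test_forecast_elongated_downstream(self):
        # uniform southward flow: forecast kernel mass lies south of source
        f = sd.gen_current_field(
            sd.FieldSimParams(nx=20, ny=60, dx=500.0, n_hours=200, regime="uniform", u0=0.0)
        )
        f.v[:] = -5.0
        src = (3000.0, 25000.0)
        params = tp.TransportParams(source=src, epsilon=0.0, release_rate=2, seed=0)
        t_coll = pd.Timestamp(f.times[0])
        k = tp.forecast_larvae(f, t_coll, src, params, days=8.0)
        assert k.mode is KernelMode.FIT
        yy, xx = np.nonzero(k.F)
        assert k.y[yy].min() < src[1] - 10000.0
        assert k.y[yy].max() <= src[1] + 500.0

    def test_insufficient_span_rejected(self, uniform_field):
        pier = (2000.0, 5000.0)
        with pytest.raises(ValueError, match="cover"):
            tp.hindcast_spawning(uniform_field, pd.Timestamp(uniform_field.times[0]), pier)

    def test_epsilon_widens_forecast_kernel(self):
        f = sd.gen_current_field(
            sd.FieldSimParams(nx=30, ny=30, dx=1000.0, n_hours=60, regime="uniform", u0=0.0)
        )
        src = (15500.0, 15500.0)
        t_coll = pd.Timestamp(f.times[0])
        second_moments = []
        for eps in (2.0, 8.0):
            params = tp.TransportParams(source=src, epsilon=eps, release_rate=40, seed=9)
            k = tp.forecast_larvae(f, t_coll, src, params, days=2.0)
            X, Y = np.meshgrid(k.x, k.y)
            w = k.F / k.F.sum()
            m2 = (w * ((X - src[0]) ** 2 + (Y - src[1]) ** 2)).sum()
            second_moments.append(m2)
        assert second_moments[1] > second_moments[0]


class TestSourceRecovery:
    @pytest.mark.parametrize("regime", ["uniform", "gyre"])
    def test_bit_kernel_argmax_near_fit_source(self, regime):
        # plant a source, advect forward with noise, then hindcast from the
        # endpoint cloud's center: the BIT kernel maximum must fall within
        # 2 grid cells of the planted source
        f = sd.gen_current_field(
            sd.FieldSimParams(nx=30, ny=30, dx=500.0, n_hours=30, regime=regime, u0=8.0, seed=0)
        )
        src = (7250.0, 7250.0)
        hours = 12
        params = tp.TransportParams(source=src, epsilon=3.0, release_rate=1000,
                                    window_hours=hours, seed=21)
        w0 = pd.Timestamp(f.times[0])
        w1 = w0 + pd.Timedelta(hours=hours)
        fit_all = tp.run_release(f, params, KernelMode.FIT, window=(w0, w1))
        # single cohort released at the window start, advected the full span
        fit = [tr for tr in fit_all if tr.release_time == w0]
        assert len(fit) >= 1000
        endpoints = np.array([tr.positions[-1] for tr in fit if tr.status is tp.TracerStatus.ACTIVE])
        center = endpoints.mean(axis=0)
        params_b = tp.TransportParams(source=tuple(center), epsilon=3.0, release_rate=1000,
                                      window_hours=hours, seed=22)
        bit_all = tp.run_release(f, params_b, KernelMode.BIT, window=(w0, w1))
        bit = [tr for tr in bit_all if tr.release_time == w1]
        # score only trajectory endpoints (the inferred source positions)
        ends = [tp.Tracer(tr.tracer_id, tr.release_time, tr.times[-1:], tr.positions[-1:], tr.status)
                for tr in bit if tr.status is tp.TracerStatus.ACTIVE]
        k = tp.exposure_kernel(ends, f, mode=KernelMode.BIT)
        j, i = np.unravel_index(np.argmax(k.F), k.F.shape)
        dist_cells = np.hypot((k.x[i] - src[0]) / f.dx, (k.y[j] - src[1]) / f.dx)
        assert dist_cells <= 2.0


class TestRetention:
    def test_whole_grid_polygon(self, uniform_field):
        params = tp.TransportParams(source=(2000.0, 5000.0), epsilon=0.0, release_rate=2,
                                    window_hours=6, seed=0)
        tracers = tp.run_release(uniform_field, params, KernelMode.FIT,
                                 window=(t0(uniform_field),
                                         t0(uniform_field) + pd.Timedelta(hours=6)))
        poly = [(-1000.0, -1000.0), (12000.0, -1000.0), (12000.0, 12000.0), (-1000.0, 12000.0)]
        assert tp.retention_fraction(tracers, poly) == 1.0

    def test_unvisited_polygon(self, uniform_field):
        params = tp.TransportParams(source=(2000.0, 5000.0), epsilon=0.0, release_rate=2,
                                    window_hours=6, seed=0)
        tracers = tp.run_release(uniform_field, params, KernelMode.FIT,
                                 window=(t0(uniform_field),
                                         t0(uniform_field) + pd.Timedelta(hours=6)))
        poly = [(8000.0, 8000.0), (9000.0, 8000.0), (9000.0, 9000.0), (8000.0, 9000.0)]
        assert tp.retention_fraction(tracers, poly) == 0.0

    def test_half_plane_symmetric_diffusion(self):
        # symmetric diffusion from a point on the half-plane boundary: about
        # half of all position-hours land on each side
        f = sd.gen_current_field(
            sd.FieldSimParams(nx=40, ny=40, dx=2000.0, n_hours=15, regime="uniform", u0=0.0)
        )
        src = (40000.0, 40000.0)
        params = tp.TransportParams(source=src, epsilon=10.0, release_rate=200,
                                    window_hours=10, seed=13)
        w = (pd.Timestamp(f.times[0]), pd.Timestamp(f.times[0]) + pd.Timedelta(hours=10))
        tracers = tp.run_release(f, params, KernelMode.FIT, window=w)
        # drop the release snapshot (it sits exactly on the dividing line)
        moved = [tp.Tracer(tr.tracer_id, tr.release_time, tr.times[1:], tr.positions[1:], tr.status)
                 for tr in tracers if len(tr.positions) > 1]
        half = [(src[0], -1e6), (1e7, -1e6), (1e7, 1e7), (src[0], 1e7)]
        frac = tp.retention_fraction(moved, half)
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_degenerate_polygon_rejected(self, uniform_field):
        with pytest.raises(ValueError, match="polygon"):
            tp.retention_fraction([], [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)])
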