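"""Hemodynamic indices, separation detection, regions, streamlines."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from anastoflow import hemodynamics as hd
from anastoflow import solver as sv
from anastoflow.geometry import StenosisSpec, make_channel_geometry, make_geometry


def _uniform_times(n, T=1.0):
    return np.arange(n) / n * T


class TestOSI:
    def test_steady_shear_gives_zero(self):
        assert hd.compute_osi(np.ones(64)) == pytest.approx(0.0)

    def test_zero_mean_sinusoid_gives_half(self):
        t = _uniform_times(4096)
        assert hd.compute_osi(np.sin(2 * np.pi * t)) == pytest.approx(0.5, abs=1e-12)

    def test_offset_sinusoid_matches_dense_quadrature_oracle(self):
        # tau(t) = 1 + 2 sin(2 pi t): analysis value vs 1e6-point midpoint rule
        t = _uniform_times(20000)
        osi = float(hd.compute_osi(1.0 + 2.0 * np.sin(2 * np.pi * t)))
        td = (np.arange(1_000_000) + 0.5) / 1_000_000
        taud = 1.0 + 2.0 * np.sin(2 * np.pi * td)
        oracle = 0.5 * (1.0 - abs(taud.mean()) / np.abs(taud).mean())
        assert osi == pytest.approx(oracle, abs=1e-6)

    def test_zero_signal_defined_as_zero(self):
        assert hd.compute_osi(np.zeros(16)) == 0.0

    @given(hst.lists(hst.floats(-10, 10), min_size=2, max_size=64))
    @settings(max_examples=100, deadline=None)
    def test_bounds_on_arbitrary_series(self, vals):
        osi = float(hd.compute_osi(np.asarray(vals)))
        assert 0.0 <= osi <= 0.5 + 1e-12


class TestRRT:
    def test_identity_case(self):
        # steady tau = 1 Pa: TAWSS = 1, OSI = 0, RRT = 1
        tau = np.ones(32)
        tawss = hd.compute_tawss(tau)
        osi = hd.compute_osi(tau)
        rrt, capped = hd.compute_rrt(tawss, osi)
        assert rrt == pytest.approx(1.0)
        assert not capped

    def test_pure_oscillation_flagged_unbounded(self):
        t = _uniform_times(512)
        tau = np.sin(2 * np.pi * t)
        rrt, capped = hd.compute_rrt(hd.compute_tawss(tau), hd.compute_osi(tau))
        assert capped
        assert rrt == pytest.approx(1e6)

    def test_biased_sinusoid_against_dense_oracle(self):
        t = _uniform_times(20000)
        tau = 1.0 + 0.5 * np.sin(2 * np.pi * t)
        tawss, osi = hd.compute_tawss(tau), hd.compute_osi(tau)
        rrt, capped = hd.compute_rrt(tawss, osi)
        assert not capped
        assert osi == pytest.approx(0.0, abs=1e-12)   # never reverses
        td = (np.arange(1_000_000) + 0.5) / 1_000_000
        oracle = 1.0 / np.abs(1.0 + 0.5 * np.sin(2 * np.pi * td)).mean()
        assert rrt == pytest.approx(oracle, abs=1e-6)

    @given(hst.floats(0.1, 5.0), hst.floats(0.0, 0.49))
    @settings(max_examples=50, deadline=None)
    def test_internal_identity_where_uncapped(self, tawss, osi):
        rrt, capped = hd.compute_rrt(tawss, osi)
        if not capped:
            assert rrt * (1 - 2 * osi) * tawss == pytest.approx(1.0, rel=1e-12)


@pytest.fixture(scope="module")
def poiseuille_frames():
    """Steady channel flow frames for wall-shear plumbing tests."""
    geom = make_channel_geometry(4.0, 1.0, 0.05)
    props = sv.FluidProperties()
    bcs = {"host_inlet": sv.FixedPressure(6.4), "host_outlet": sv.FixedPressure(0.0)}
    cfg = sv.SolverConfig(umax_est=0.2, dt_max=1e-3)
    grid, state = sv.initialize(geom, props, bcs, cfg)
    dt = sv._timestep(grid, 0.2)
    for _ in range(5):
        state, _, _ = sv.advance_cycle(grid, state, bcs, 400, period=400 * dt)
    frames = [sv.Frame(k * 0.25, state.u, state.v, state.p) for k in range(4)]
    return geom, props, frames, grid


class TestWallShearExtraction:
    def test_poiseuille_wall_shear_accuracy(self, poiseuille_frames):
        geom, props, frames, grid = poiseuille_frames
        series = hd.extract_wss(frames, geom, props.mu)
        q = float(np.sum(frames[0].u[:, grid.nx // 2][geom.fluid_mask[:, grid.nx // 2]])
                  * grid.h)
        tau_th = 6 * props.mu * q / (1.0e-3) ** 2
        tau = series.walls["floor"]["tau"][0]
        mid = slice(tau.size // 3, 2 * tau.size // 3)
        assert np.abs(tau[mid] - tau_th).max() / tau_th < 0.02

    def test_zero_velocity_gives_zero_shear(self, poiseuille_frames):
        geom, props, frames, _ = poiseuille_frames
        zero = sv.Frame(0.0, np.zeros_like(frames[0].u),
                        np.zeros_like(frames[0].v), np.zeros_like(frames[0].p))
        series = hd.extract_wss([zero], geom, props.mu)
        for w in series.walls.values():
            assert np.all(w["tau"] == 0.0)

    def test_flow_reversal_flips_sign_only(self, poiseuille_frames):
        geom, props, frames, _ = poiseuille_frames
        fwd = hd.extract_wss(frames[:1], geom, props.mu)
        rev_frame = sv.Frame(0.0, -frames[0].u, -frames[0].v, frames[0].p)
        rev = hd.extract_wss([rev_frame], geom, props.mu)
        for wall in fwd.walls:
            np.testing.assert_allclose(rev.walls[wall]["tau"],
                                       -fwd.walls[wall]["tau"], atol=1e-12)

    def test_attached_flow_has_no_separation_zones(self, poiseuille_frames):
        geom, props, frames, _ = poiseuille_frames
        series = hd.extract_wss(frames, geom, props.mu)
        maps = hd.compute_maps(series, geom, frames=frames)
        assert hd.detect_recirculation(maps) == []

    def test_region_summaries_stable_under_time_resampling(self, poiseuille_frames):
        # doubling the number of phase samples must not move the reductions
        geom, props, frames, _ = poiseuille_frames
        s1 = hd.extract_wss(frames[:2], geom, props.mu)
        s2 = hd.extract_wss(frames, geom, props.mu)
        m1 = hd.compute_maps(s1, geom)
        m2 = hd.compute_maps(s2, geom)
        for wall in m1.walls:
            np.testing.assert_allclose(m1.walls[wall]["tawss"],
                                       m2.walls[wall]["tawss"], rtol=0.02)


@pytest.fixture(scope="module")
def anastomosis_setup():
    geom = make_geometry(StenosisSpec(), h=0.1)
    sampler = hd.WallSampler(geom)
    return geom, sampler


class TestRegions:
    def test_windows_are_disjoint(self, anastomosis_setup):
        geom, sampler = anastomosis_setup
        wins = hd.region_windows(geom, sampler)
        per_wall = {}
        for region, window in wins.items():
            for wall, mask in window:
                acc = per_wall.setdefault(wall, np.zeros_like(mask, dtype=int))
                acc += mask.astype(int)
        for wall, acc in per_wall.items():
            assert acc.max() <= 1, f"overlapping regions on {wall}"

    def test_all_regions_populated_on_all_patterns(self):
        import warnings
        for spec in (StenosisSpec(), StenosisSpec("longitudinal", 0.75, 0.90),
                     StenosisSpec("bilateral", 0.75, 1.00)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                geom = make_geometry(spec, h=0.1)
            sampler = hd.WallSampler(geom)
            wins = hd.region_windows(geom, sampler)
            assert set(wins) == set(hd.REGION_LABELS)
            for region, window in wins.items():
                assert sum(int(m.sum()) for _, m in window) > 0, region

    def test_constant_shear_summary(self, anastomosis_setup):
        geom, sampler = anastomosis_setup
        times = _uniform_times(8)
        walls = {w: {"s": sampler.walls[w]["s"],
                     "tau": np.ones((8, sampler.walls[w]["s"].size))}
                 for w in sampler.walls}
        series = hd.WallShearSeries(times=times, walls=walls, sampler=sampler)
        maps = hd.compute_maps(series, geom)
        rows = hd.summarize_regions(maps, geom)
        assert len(rows) == len(hd.REGION_LABELS)
        for r in rows:
            assert r.min_tawss == pytest.approx(1.0)
            assert r.max_osi == pytest.approx(0.0)
            assert r.max_rrt == pytest.approx(1.0)


class TestStreamlines:
    def test_uniform_flow_gives_straight_lines(self):
        geom = make_channel_geometry(4.0, 1.0, 0.05)
        ny, nx = geom.fluid_mask.shape
        frame = sv.Frame(0.0, np.full((ny, nx + 1), 0.1),
                         np.zeros((ny + 1, nx)), np.zeros((ny, nx)))
        lines = hd.compute_streamlines(frame, geom, [(0.2, 0.5)], max_length=3.0)
        assert len(lines) == 1
        assert np.abs(lines[0][:, 1] - 0.5).max() < 1e-6
        assert lines[0][-1, 0] > 3.0

    def test_solid_body_rotation_gives_circles(self):
        geom = make_channel_geometry(10.0, 10.0, 0.1)
        ny, nx = geom.fluid_mask.shape
        x0, y0 = geom.origin
        xu, yu = np.meshgrid(x0 + np.arange(nx + 1) * 0.1,
                             y0 + (np.arange(ny) + 0.5) * 0.1)
        xv, yv = np.meshgrid(x0 + (np.arange(nx) + 0.5) * 0.1,
                             y0 + np.arange(ny + 1) * 0.1)
        cx, cy = 5.0, 5.0
        frame = sv.Frame(0.0, -(yu - cy), xv - cx, np.zeros((ny, nx)))
        seed = (7.0, 5.0)   # radius 2 about the centre
        lines = hd.compute_streamlines(frame, geom, [seed], max_length=15.0,
                                       step=0.05)
        r = np.hypot(lines[0][:, 0] - cx, lines[0][:, 1] - cy)
        assert np.abs(r - 2.0).max() < 0.1   # radius error below one cell

    def test_seed_outside_fluid_is_skipped_with_warning(self):
        geom = make_channel_geometry(4.0, 1.0, 0.05)
        ny, nx = geom.fluid_mask.shape
        frame = sv.Frame(0.0, np.zeros((ny, nx + 1)), np.zeros((ny + 1, nx)),
                         np.zeros((ny, nx)))
        with pytest.warns(UserWarning, match="outside fluid"):
            lines = hd.compute_streamlines(frame, geom, [(2.0, -5.0)])
        assert lines == []

    def test_streamlines_stay_inside_fluid(self):
        geom = make_channel_geometry(4.0, 1.0, 0.05)
        ny, nx = geom.fluid_mask.shape
        frame = sv.Frame(0.0, np.full((ny, nx + 1), 0.1),
                         np.full((ny + 1, nx), 0.05), np.zeros((ny, nx)))
        lines = hd.compute_streamlines(frame, geom, [(0.2, 0.5), (0.2, 0.9)])
        import shapely
        for ln in lines:
            assert shapely.contains_xy(geom.polygon, ln[:, 0], ln[:, 1]).all()


class TestExceedanceMonotonicity:
    def test_threshold_sweep_is_monotone(self):
        rng = np.random.default_rng(3)
        rrt = rng.lognormal(1.0, 1.5, size=500)
        fracs = [np.mean(rrt > thr) for thr in (1.0, 5.0, 10.0, 50.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
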