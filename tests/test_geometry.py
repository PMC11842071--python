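"""Parametric anastomosis geometry: study matrix, dimensions, rasterization."""
import numpy as np
import pytest
from scipy import ndimage

from anastoflow import geometry as gm


@pytest.fixture(scope="module")
def matrix_geoms():
    """All 14 model geometries at the study grid spacing."""
    import warnings
    out = {}
    for spec in gm.enumerate_study_matrix():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", gm.ResolutionWarning)
            out[spec.model_id] = gm.make_geometry(spec, h=0.1)
    return out


class TestStudyMatrix:
    def test_fourteen_models(self):
        specs = gm.enumerate_study_matrix()
        assert len(specs) == 14
        assert len({s.model_id for s in specs}) == 14

    def test_reference_paired_with_both_native_grades(self):
        specs = gm.enumerate_study_matrix()
        assert sum(s.pattern == "none" for s in specs) == 2

    def test_six_stenotic_models_per_native_grade(self):
        specs = gm.enumerate_study_matrix()
        assert sum(s.native_grade == 0.90 and s.pattern != "none"
                   for s in specs) == 6

    def test_deterministic_ordering(self):
        specs = gm.enumerate_study_matrix()
        keys = [(s.native_grade, gm.PATTERNS.index(s.pattern), s.grade)
                for s in specs]
        assert keys == sorted(keys)

    @pytest.mark.parametrize("pattern,grade,native", [
        ("none", 0.25, 0.90),        # pattern none requires grade 0
        ("longitudinal", 0.0, 0.90),  # stenotic pattern requires grade > 0
        ("longitudinal", 0.6, 0.90),  # grade outside allowed set
        ("longitudinal", 0.5, 0.5),   # native grade outside allowed set
        ("oblique", 0.5, 0.9),        # unknown pattern
    ])
    def test_invalid_specs_rejected(self, pattern, grade, native):
        with pytest.raises(ValueError):
            gm.StenosisSpec(pattern, grade, native)


class TestDimensions:
    def test_reference_prints_ex_vivo_dimensions(self, matrix_geoms):
        g = matrix_geoms["ref00_n090"]
        assert g.orifice_length == pytest.approx(10.0)
        # host inlet/outlet gaps measured from the rasterized mask
        h = g.h
        inlet_gap = g.fluid_mask[:, 0].sum() * h
        outlet_gap = g.fluid_mask[:, -1].sum() * h
        assert inlet_gap == pytest.approx(2.8, abs=h)
        assert outlet_gap == pytest.approx(3.2, abs=h)

    @pytest.mark.parametrize("grade,expected", [(0.25, 7.5), (0.5, 5.0), (0.75, 2.5)])
    def test_longitudinal_orifice_shortening(self, matrix_geoms, grade, expected):
        g = matrix_geoms[f"long{int(grade*100)}_n090"]
        # heel-toe landmark separation equals arteriotomy * (1 - grade)
        assert g.landmarks["toe"][0] - g.landmarks["heel"][0] == pytest.approx(expected)
        assert g.orifice_length == pytest.approx(expected)

    def test_bilateral_passage_scales_with_grade(self, matrix_geoms):
        ref = matrix_geoms["ref00_n090"].min_passage
        g50 = matrix_geoms["bila50_n090"]
        assert g50.min_passage == pytest.approx(0.5 * ref, abs=0.02)
        assert g50.orifice_length == pytest.approx(10.0)

    def test_bilateral_passage_measured_on_mask(self, matrix_geoms):
        # cross-check the polygon measurement against the rasterized throat
        g = matrix_geoms["bila50_n090"]
        lab, n = ndimage.label(g.fluid_mask)
        assert n == 1
        d = g.metadata["graft_direction"]
        # narrowest fluid column count along the tube, sampled mid-constriction
        # (coarse check: mask min passage within one cell of the polygon value)
        from shapely.geometry import LineString
        import shapely
        M = np.array([15.0, 3.0])
        widths = []
        for s in np.linspace(4.6, 7.0, 13):
            c = M + s * d
            nvec = np.array([d[1], -d[0]])
            probe_t = np.linspace(-2.2, 2.2, 89)
            px = c[0] + probe_t * nvec[0]
            py = c[1] + probe_t * nvec[1]
            ii = ((px - g.origin[0]) / g.h).astype(int)
            jj = ((py - g.origin[1]) / g.h).astype(int)
            ok = (ii >= 0) & (ii < g.fluid_mask.shape[1]) & (jj >= 0) & (jj < g.fluid_mask.shape[0])
            inside = np.zeros_like(px, dtype=bool)
            inside[ok] = g.fluid_mask[jj[ok], ii[ok]]
            widths.append(inside.sum() * (probe_t[1] - probe_t[0]))
        assert min(widths) == pytest.approx(g.min_passage, abs=2 * g.h)

    def test_longitudinal_graft_axis_steepens_with_grade(self, matrix_geoms):
        # gathering the graft onto a shorter arteriotomy rotates its axis
        angles = [matrix_geoms["ref00_n090"].metadata["graft_angle_eff_deg"]]
        angles += [matrix_geoms[f"long{g}_n090"].metadata["graft_angle_eff_deg"]
                   for g in (25, 50, 75)]
        assert all(a < b for a, b in zip(angles, angles[1:]))
        assert angles[0] == pytest.approx(30.0)
        bil = matrix_geoms["bila75_n090"].metadata["graft_angle_eff_deg"]
        assert bil == pytest.approx(30.0)   # bilateral keeps the take-off

    def test_monotone_passage_and_orifice_in_grade(self, matrix_geoms):
        for pattern, short in (("longitudinal", "long"), ("bilateral", "bila")):
            passages = [matrix_geoms["ref00_n090"].min_passage]
            orifices = [matrix_geoms["ref00_n090"].orifice_length]
            for grade in (25, 50, 75):
                g = matrix_geoms[f"{short}{grade}_n090"]
                passages.append(g.min_passage)
                orifices.append(g.orifice_length)
            assert all(a >= b - 1e-9 for a, b in zip(passages, passages[1:]))
            if pattern == "longitudinal":
                assert all(a > b for a, b in zip(orifices, orifices[1:]))
            else:
                assert all(a == pytest.approx(b) for a, b in zip(orifices, orifices[1:]))


class TestMaskTopology:
    def test_single_component_with_open_boundaries(self, matrix_geoms):
        for g in matrix_geoms.values():
            lab, n = ndimage.label(g.fluid_mask)
            assert n == 1
            assert "graft_inlet" in g.open_boundaries
            assert "host_outlet" in g.open_boundaries

    def test_total_occlusion_seals_host_inlet(self, matrix_geoms):
        g = matrix_geoms["ref00_n100"]
        assert "host_inlet" not in g.open_boundaries
        assert not g.fluid_mask[:, 0].any()
        # flood fill from the graft inlet must still reach the outlet
        lab, _ = ndimage.label(g.fluid_mask)
        top = g.open_boundaries["graft_inlet"]["index"]
        right = g.open_boundaries["host_outlet"]["index"]
        assert lab[-1, top[0]] == lab[right[0], -1]

    def test_graft_to_outlet_connectivity_all_models(self, matrix_geoms):
        for g in matrix_geoms.values():
            lab, _ = ndimage.label(g.fluid_mask)
            top = g.open_boundaries["graft_inlet"]["index"]
            right = g.open_boundaries["host_outlet"]["index"]
            assert lab[-1, top[0]] == lab[right[0], -1]

    def test_boundary_cells_lie_near_walls(self, matrix_geoms):
        import shapely
        g = matrix_geoms["ref00_n090"]
        m = g.fluid_mask
        interior = (np.roll(m, 1, 0) & np.roll(m, -1, 0)
                    & np.roll(m, 1, 1) & np.roll(m, -1, 1) & m)
        boundary = m & ~interior
        jj, ii = np.nonzero(boundary)
        # skip cells on the open edges (they border open boundary, not walls)
        keep = (ii > 0) & (ii < m.shape[1] - 1) & (jj < m.shape[0] - 1)
        x = g.origin[0] + (ii[keep] + 0.5) * g.h
        y = g.origin[1] + (jj[keep] + 0.5) * g.h
        d = shapely.distance(shapely.points(np.column_stack([x, y])),
                             g.polygon.exterior)
        assert d.max() <= g.h + 1e-9


class TestResolutionPolicy:
    def test_refinement_stability_of_reported_metrics(self):
        spec = gm.StenosisSpec("longitudinal", 0.5, 0.90)
        g1 = gm.make_geometry(spec, h=0.2)
        g2 = gm.make_geometry(spec, h=0.1)
        assert abs(g1.orifice_length - g2.orifice_length) < 0.2
        assert abs(g1.min_passage - g2.min_passage) < 0.2

    def test_coarse_grid_rejected_for_tight_throat(self):
        spec = gm.StenosisSpec("bilateral", 0.75, 0.90)
        with pytest.raises(gm.GeometryResolutionError):
            gm.make_geometry(spec, h=0.2)   # 0.75 mm throat < 6 cells

    def test_marginal_resolution_warns(self):
        spec = gm.StenosisSpec("bilateral", 0.75, 0.90)
        with pytest.warns(gm.ResolutionWarning):
            gm.make_geometry(spec, h=0.1)   # 7.5 cells across the throat


class TestReport:
    def test_reference_report_values(self, matrix_geoms):
        rep = gm.geometry_report(matrix_geoms["ref00_n090"])
        assert rep["open_orifice_fraction"] == 1.0
        assert rep["orifice_length_mm"] == pytest.approx(10.0)
        assert rep["native_passage_mm"] == pytest.approx(0.28)

    def test_longitudinal_25_report(self, matrix_geoms):
        rep = gm.geometry_report(matrix_geoms["long25_n090"])
        assert rep["orifice_length_mm"] == pytest.approx(7.5)
        assert rep["open_orifice_fraction"] == 0.75

    def test_one_row_per_model(self, matrix_geoms):
        ids = {gm.geometry_report(g)["model_id"] for g in matrix_geoms.values()}
        assert len(ids) == 14
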