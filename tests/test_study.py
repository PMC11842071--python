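"""Study driver: subset runs, aggregation tables, determinism of writers."""
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from anastoflow import hemodynamics as hd
from anastoflow import study as st
from anastoflow.config import RunConfig, parse_config_text
from anastoflow.geometry import StenosisSpec


@pytest.fixture(scope="module")
def coarse_cfg():
    """Desk-smoke configuration: coarse grid, single cycle."""
    return parse_config_text(
        "[geometry]\ngrid_h_mm = 0.2\n"
        "[solver]\nmax_cycles = 1\nframes_per_cycle = 20\n"
        "[study]\nmax_cycles = 1\n")


@pytest.fixture(scope="module")
def coarse_reference_study(coarse_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return st.run_study(coarse_cfg, specs=[StenosisSpec("none", 0.0, 0.90)])


class TestSubsetRun:
    def test_single_row_summary(self, coarse_reference_study):
        s = coarse_reference_study.summary
        assert len(s) == 1
        assert s.model_id[0] == "ref00_n090"
        assert not s.failed[0]

    def test_mass_balance_within_one_percent(self, coarse_reference_study):
        r = coarse_reference_study.summary.iloc[0]
        total_in = r.mean_graft_flow_mlmin + r.mean_native_inflow_mlmin
        assert r.mean_outlet_flow_mlmin == pytest.approx(total_in, rel=0.01)

    def test_flow_split_is_graft_dominant(self, coarse_reference_study):
        # 90% native stenosis leaves only a trickle of proximal inflow
        r = coarse_reference_study.summary.iloc[0]
        assert r.mean_graft_flow_mlmin > 3 * r.mean_native_inflow_mlmin
        assert r.mean_graft_flow_mlmin > 10.0

    def test_region_table_has_all_regions(self, coarse_reference_study):
        reg = coarse_reference_study.region_table
        assert set(reg.region) == set(hd.REGION_LABELS)

    def test_table_writers_are_deterministic(self, coarse_reference_study, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        st.write_study_tables(coarse_reference_study, d1)
        st.write_study_tables(coarse_reference_study, d2)
        for name in ("study_summary.csv", "region_summary.csv",
                     "geometry_report.csv", "wallmap_ref00_n090.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_effective_config_snapshot_written(self, coarse_reference_study,
                                               tmp_path):
        st.write_study_tables(coarse_reference_study, tmp_path / "out")
        text = (tmp_path / "out" / "effective_config.cfg").read_text()
        assert "grid_h_mm = 0.2" in text


class TestSelection:
    def test_all_selects_full_matrix(self):
        assert len(st.select_models(RunConfig())) == 14

    def test_named_subset(self):
        cfg = parse_config_text("[study]\nmodels = ref00_n090, long75_n090\n")
        specs = st.select_models(cfg)
        assert [s.model_id for s in specs] == ["ref00_n090", "long75_n090"]

    def test_unknown_id_rejected(self):
        cfg = parse_config_text("[study]\nmodels = nosuch_model\n")
        with pytest.raises(ValueError, match="nosuch_model"):
            st.select_models(cfg)


class TestNativeOcclusionContrast:
    def test_identical_maps_give_zero_contrast(self, coarse_reference_study):
        base = coarse_reference_study.models["ref00_n090"]
        twin = st.ModelResult(
            spec=StenosisSpec("none", 0.0, 1.00), geom=base.geom,
            maps=base.maps, regions=base.regions, zones=base.zones,
            fluxes=base.fluxes, residuals=base.residuals,
            jet_angle_deg=base.jet_angle_deg,
            heel_circulation=base.heel_circulation)
        result = st.StudyResult(
            config=coarse_reference_study.config,
            models={"ref00_n090": base, "ref00_n100": twin},
            summary=pd.DataFrame(), region_table=pd.DataFrame(),
            geometry_table=pd.DataFrame(), config_hash="x")
        con = st.compare_native_occlusion(result)
        assert len(con) == 1
        row = con.iloc[0]
        assert row.max_RRT_n100 == pytest.approx(row.max_RRT_n090)
        assert row.mean_RRT_n100 == pytest.approx(row.mean_RRT_n090)

    def test_unpaired_models_are_skipped(self, coarse_reference_study):
        con = st.compare_native_occlusion(coarse_reference_study)
        assert con.empty


class TestFailurePolicy:
    def test_failed_model_recorded_and_study_continues(self, coarse_cfg):
        # bilateral 75% at h = 0.2 mm under-resolves the throat -> resolution
        # error must be recorded as a failed row, not abort the study
        specs = [StenosisSpec("bilateral", 0.75, 0.90),
                 StenosisSpec("none", 0.0, 0.90)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = st.run_study(coarse_cfg, specs=specs)
        assert list(res.summary.failed) == [True, False]
        assert "GeometryResolutionError" in res.summary.error[0]


class TestMatrixTrends:
    """Cross-model orderings at the study resolution (shared fixtures)."""

    def test_flow_stability_with_anastomotic_grade(self, long_grades):
        # the anastomotic resistance is tiny against the lumped impedances,
        # so graft flow falls only marginally with grade and the total
        # perfusion stays stable (within a few percent across the sweep)
        grades = sorted(long_grades)
        graft = [long_grades[g].mean_flux_mlmin("graft_inlet") for g in grades]
        native = [long_grades[g].mean_flux_mlmin("host_inlet") for g in grades]
        assert all(b <= a * 1.005 for a, b in zip(graft, graft[1:])), graft
        assert max(native) - min(native) < 0.03 * max(native), native
        assert max(graft) - min(graft) < 0.03 * max(graft), graft

    def test_bilateral_raises_inferior_distal_toe_wss(self, ref_n090,
                                                      bila75_n090):
        # the concentrated bilateral jet washes the floor opposite the toe
        ref_e = {r.region: r for r in ref_n090.regions}["E_distal_toe_inferior"]
        bil_e = {r.region: r for r in bila75_n090.regions}["E_distal_toe_inferior"]
        assert bil_e.min_tawss >= ref_e.min_tawss * 0.98

    def test_total_occlusion_zeroes_native_inflow(self, ref_n100):
        assert ref_n100.mean_flux_mlmin("host_inlet") == 0.0
        assert "host_inlet" not in ref_n100.geom.open_boundaries


def test_jet_angle_requires_graft_inlet(coarse_reference_study):
    r = coarse_reference_study.summary.iloc[0]
    assert math.isfinite(r.jet_angle_deg)
    assert 0.0 < r.jet_angle_deg < 90.0
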