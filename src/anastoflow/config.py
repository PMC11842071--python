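"""Run configuration: plain-text (INI-style) parsing, validation, defaults.

The config file has one section per pipeline stage; every key has a typed
default, unknown keys are rejected by name, and a parsed config serializes
back to identical text (lossless round-trip). User-facing units are
clinical (mm, l/min, ml/min, mmHg, seconds); key names carry the unit.
"""
from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, field

from .geometry import GRADES, NATIVE_GRADES, PATTERNS, GeometryParams, StenosisSpec

__all__ = ["RunConfig", "ConfigError", "parse_config", "parse_config_text",
           "serialize_config", "SCHEMA"]


class ConfigError(ValueError):
    """Schema violation: names the offending section/key."""


def _bool(x: str) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("1", "true", "yes", "on"):
        return True
    if s in ("0", "false", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {x!r}")


def _in_set(allowed):
    def check(v):
        if v not in allowed:
            raise ValueError(f"{v!r} not in allowed set {sorted(allowed)}")
    return check


def _positive(v):
    if not v > 0:
        raise ValueError(f"must be positive, got {v}")


def _fraction(v):
    if not (0.0 < v < 1.0):
        raise ValueError(f"must lie in (0, 1), got {v}")


# section -> key -> (type, default, validator-or-None)
SCHEMA = {
    "geometry": {
        "pattern": (str, "none", _in_set(set(PATTERNS))),
        "grade": (float, 0.0, _in_set(set(GRADES))),
        "native_grade": (float, 0.90, _in_set(set(NATIVE_GRADES))),
        "host_diam_proximal_mm": (float, 2.8, _positive),
        "host_diam_distal_mm": (float, 3.2, _positive),
        "arteriotomy_mm": (float, 10.0, _positive),
        "graft_diam_mm": (float, 3.0, _positive),
        "graft_angle_deg": (float, 30.0, None),
        "grid_h_mm": (float, 0.1, _positive),
        "host_length_proximal_mm": (float, 10.0, _positive),
        "host_length_distal_mm": (float, 10.0, _positive),
        "native_stenosis_length_mm": (float, 2.0, _positive),
        "native_stenosis_offset_mm": (float, 7.5, _positive),
        "junction_length_mm": (float, 4.0, _positive),
        "domain_top_mm": (float, 8.0, _positive),
    },
    "boundary_conditions": {
        "mean_aortic_flow_lmin": (float, 5.0, _positive),
        "mean_aortic_pressure_mmhg": (float, 96.0, _positive),
        "period_s": (float, 1.0, _positive),
        "systole_fraction": (float, 0.35, _fraction),
        "wk_compliance_l_mmhg": (float, 0.0015, None),
        "z_sys_mmhg_min_l": (float, 4500.0, _positive),
        "z_dia_mmhg_min_l": (float, 900.0, _positive),
        "z_transition_s": (float, 0.05, _positive),
        "p_distal_mmhg": (float, 0.0, None),
        "r_graft_mmhg_min_l": (float, 300.0, _positive),
        "r_native_mmhg_min_l": (float, 2000.0, _positive),
        "node_compliance_m3_pa": (float, 2.0e-12, _positive),
        "target_graft_flow_mlmin": (float, 60.0, _positive),
        "n_samples": (int, 1000, _positive),
        "notch_depth": (float, 0.15, None),
        "notch_width_fraction": (float, 0.08, _fraction),
        "diastolic_level": (float, 0.04, None),
    },
    "solver": {
        "cfl": (float, 0.4, _fraction),
        "dt_max_s": (float, 5.0e-5, _positive),
        "advection_order": (int, 2, _in_set({1, 2})),
        "frames_per_cycle": (int, 50, _positive),
        "max_cycles": (int, 5, _positive),
        "periodicity_tol": (float, 1.0e-3, _positive),
        "single_cycle": (bool, False, None),
        "umax_est_ms": (float, 1.5, _positive),
    },
    "hemodynamics": {
        "wall_sample_ds_mm": (float, 0.0, None),   # 0 -> use grid_h_mm
        "rrt_eps_pa": (float, 1.0e-6, _positive),
        "rrt_threshold_inv_pa": (float, 10.0, _positive),
        "separation_threshold": (float, 0.5, _fraction),
        "min_zone_samples": (int, 4, _positive),
        "region_a_half_mm": (float, 1.0, _positive),
        "region_b_lo_mm": (float, 1.0, None),
        "region_b_hi_mm": (float, 4.0, _positive),
        "region_c_half_mm": (float, 1.0, _positive),
        "region_d_lo_mm": (float, 1.0, None),
        "region_d_hi_mm": (float, 5.0, _positive),
        "region_f_half_mm": (float, 1.5, _positive),
        "region_g_lo_mm": (float, 1.5, None),
        "region_g_hi_mm": (float, 6.0, _positive),
    },
    "study": {
        "models": (str, "all", None),
        "out_dir": (str, "results", None),
        "max_cycles": (int, 3, _positive),
        "write_vtk": (bool, False, None),
        "schema_version": (str, "1", None),
    },
}


@dataclass
class RunConfig:
    """Validated configuration with defaults applied."""

    sections: dict = field(default_factory=dict)

    def __post_init__(self):
        full = {s: {k: v[1] for k, v in keys.items()} for s, keys in SCHEMA.items()}
        for sec, kv in self.sections.items():
            if sec not in SCHEMA:
                raise ConfigError(f"unknown config section [{sec}]")
            for key, val in kv.items():
                if key not in SCHEMA[sec]:
                    raise ConfigError(f"unknown key {key!r} in section [{sec}]")
                typ, _, validator = SCHEMA[sec][key]
                try:
                    cast = _bool(val) if typ is bool else typ(val)
                except (TypeError, ValueError) as e:
                    raise ConfigError(f"[{sec}] {key}: {e}") from None
                if validator is not None:
                    try:
                        validator(cast)
                    except ValueError as e:
                        raise ConfigError(f"[{sec}] {key}: {e}") from None
                full[sec][key] = cast
        self.sections = full

    def __getitem__(self, section: str) -> dict:
        return self.sections[section]

    def __eq__(self, other):
        return isinstance(other, RunConfig) and self.sections == other.sections

    # -- stage-object builders ----------------------------------------------
    def stenosis_spec(self) -> StenosisSpec:
        g = self["geometry"]
        return StenosisSpec(g["pattern"], g["grade"], g["native_grade"])

    def geometry_params(self) -> GeometryParams:
        g = self["geometry"]
        return GeometryParams(
            host_diam_proximal=g["host_diam_proximal_mm"],
            host_diam_distal=g["host_diam_distal_mm"],
            arteriotomy_length=g["arteriotomy_mm"],
            graft_diam=g["graft_diam_mm"],
            graft_angle=g["graft_angle_deg"],
            host_length_proximal=g["host_length_proximal_mm"],
            host_length_distal=g["host_length_distal_mm"],
            native_stenosis_length=g["native_stenosis_length_mm"],
            native_stenosis_offset=g["native_stenosis_offset_mm"],
            junction_length=g["junction_length_mm"],
            domain_top=g["domain_top_mm"],
        )

    def region_widths(self) -> dict:
        h = self["hemodynamics"]
        return {
            "A_half": h["region_a_half_mm"], "B_lo": h["region_b_lo_mm"],
            "B_hi": h["region_b_hi_mm"], "C_half": h["region_c_half_mm"],
            "D_lo": h["region_d_lo_mm"], "D_hi": h["region_d_hi_mm"],
            "F_half": h["region_f_half_mm"], "G_lo": h["region_g_lo_mm"],
            "G_hi": h["region_g_hi_mm"],
        }


def parse_config_text(text: str) -> RunConfig:
    cp = configparser.ConfigParser()
    cp.read_string(text)
    sections = {s: dict(cp.items(s)) for s in cp.sections()}
    return RunConfig(sections)


def parse_config(path) -> RunConfig:
    """Parse and validate a config file; missing keys take defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_config_text(fh.read())


def serialize_config(cfg: RunConfig) -> str:
    """Deterministic text form of the effective (fully defaulted) config."""
    cp = configparser.ConfigParser()
    for sec in SCHEMA:
        cp.add_section(sec)
        for key in SCHEMA[sec]:
            val = cfg[sec][key]
            cp.set(sec, key, repr(val) if isinstance(val, float) else str(val))
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()
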