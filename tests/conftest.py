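"""Shared fixtures: study-condition simulations reused across acceptance tests.

The full-pipeline runs at the study grid spacing (h = 0.1 mm) are expensive,
so each model is simulated once per test session and its results shared by
every test that inspects it.
"""
import warnings

import pytest
from hypothesis import settings

from anastoflow import study as st
from anastoflow.config import RunConfig
from anastoflow.geometry import StenosisSpec

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# cardiac cycles per model: one warm-up cycle plus the analysis cycle
CYCLES_PRIMARY = 2
CYCLES_SECONDARY = 2


@pytest.fixture(scope="session")
def study_cfg() -> RunConfig:
    """The default study conditions (h = 0.1 mm, physiological BCs)."""
    return RunConfig()


def _simulate(spec: StenosisSpec, cfg: RunConfig, cycles: int) -> st.ModelResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return st.run_model(spec, cfg, max_cycles=cycles)


@pytest.fixture(scope="session")
def ref_n090(study_cfg):
    """Reference anastomosis (0% stenosis), 90% native stenosis."""
    return _simulate(StenosisSpec("none", 0.0, 0.90), study_cfg, CYCLES_PRIMARY)


@pytest.fixture(scope="session")
def ref_n100(study_cfg):
    """Reference anastomosis with total native occlusion.

    A single cycle suffices here: the sealed proximal segment turns into a
    stagnant pocket immediately, and the occlusion contrast it feeds is an
    order-of-magnitude effect.
    """
    return _simulate(StenosisSpec("none", 0.0, 1.00), study_cfg, 1)


@pytest.fixture(scope="session")
def long75_n090(study_cfg):
    """75% longitudinal shortening, 90% native stenosis."""
    return _simulate(StenosisSpec("longitudinal", 0.75, 0.90), study_cfg,
                     CYCLES_PRIMARY)


@pytest.fixture(scope="session")
def bila75_n090(study_cfg):
    """75% bilateral narrowing, 90% native stenosis."""
    return _simulate(StenosisSpec("bilateral", 0.75, 0.90), study_cfg,
                     CYCLES_PRIMARY)


@pytest.fixture(scope="session")
def long_grades(study_cfg, ref_n090, long75_n090):
    """Longitudinal grade sweep 0 -> 0.75 (jet-angle steepening check)."""
    out = {0.0: ref_n090, 0.75: long75_n090}
    for grade in (0.25, 0.50):
        out[grade] = _simulate(StenosisSpec("longitudinal", grade, 0.90),
                               study_cfg, CYCLES_SECONDARY)
    return out
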