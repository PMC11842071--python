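"""Physiological boundary conditions for the anastomosis simulation.

The simulation domain starts at the graft and the proximal native coronary
artery; the aorta is represented as a lumped pressure source. Three pieces
are synthesized here:

* a pulsatile aortic inflow waveform with a prescribed cycle-mean flow
  (raised-cosine systolic ejection, end-systolic reverse notch, low
  diastolic baseline),
* the aortic pressure over one cycle from a two-element Windkessel
  (resistance-compliance) model driven by that inflow, calibrated so the
  periodic mean pressure matches the target (96 mmHg at 5.0 l/min), and
* a time-varying coronary outlet impedance: peripheral resistance elevated
  during systole by intramyocardial compression, which is what makes
  coronary flow diastolic-dominant.

All quantities here are in clinical units (l/min, mmHg, seconds); the
solver converts to SI at its boundary closures.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "Waveform",
    "WindkesselParams",
    "ImpedanceModel",
    "synthesize_aortic_inflow",
    "windkessel_pressure",
    "calibrate_wk_resistance",
    "coronary_impedance",
    "diastolic_flow_fraction",
    "calibrate_graft_resistance",
    "CalibrationError",
]


@dataclass
class Waveform:
    """Periodic scalar time series over one cardiac cycle.

    ``times`` spans [0, period] inclusive with uniform spacing; the first and
    last values are equal (periodic closure). ``unit`` tags the physical unit
    of ``values`` (e.g. ``"l/min"`` or ``"mmHg"``).
    """

    times: np.ndarray
    values: np.ndarray
    period: float
    unit: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times/values must be matching 1-D arrays")
        if self.times.size < 3:
            raise ValueError("waveform needs at least 3 samples")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("waveform requires uniform time spacing")
        if not np.isclose(self.values[0], self.values[-1], rtol=1e-9, atol=1e-12):
            raise ValueError("waveform must close periodically (first == last value)")

    @property
    def n_samples(self) -> int:
        """Number of distinct samples per period (closure point excluded)."""
        return self.times.size - 1

    def mean(self) -> float:
        """Cycle mean by trapezoidal quadrature (exact for the periodic grid)."""
        return float(np.mean(self.values[:-1]))

    def sample(self, t) -> np.ndarray:
        """Periodic linear interpolation at arbitrary times."""
        tp = np.mod(t, self.period)
        return np.interp(tp, self.times, self.values)

    def scaled(self, factor: float) -> "Waveform":
        return Waveform(self.times.copy(), self.values * factor, self.period, self.unit)


@dataclass
class WindkesselParams:
    """Two-element Windkessel: total resistance, compliance, distal pressure.

    R_total in mmHg.min/l, C in l/mmHg, p_distal in mmHg.
    """

    R_total: float
    C: float
    p_distal: float = 0.0

    def __post_init__(self):
        if self.R_total <= 0:
            raise ValueError("R_total must be positive")
        if self.C < 0:
            raise ValueError("C must be non-negative")


def synthesize_aortic_inflow(
    period: float = 1.0,
    mean_flow: float = 5.0,
    systole_fraction: float = 0.35,
    n_samples: int = 1000,
    notch_depth: float = 0.15,
    notch_width_fraction: float = 0.08,
    diastolic_level: float = 0.04,
) -> Waveform:
    """Pulsatile aortic inflow with an exact prescribed cycle mean (l/min).

    Shape: raised-cosine ejection burst over the systolic interval, a small
    negative end-systolic notch (valve closure backflow), and a low smooth
    diastolic bump returning to zero at end-cycle.  The waveform is rescaled
    analytically so its discrete cycle mean equals ``mean_flow`` exactly.
    """
    if mean_flow <= 0:
        raise ValueError("mean_flow must be positive")
    if not (0.0 < systole_fraction < 1.0):
        raise ValueError("systole_fraction must lie in (0, 1)")
    t = np.linspace(0.0, period, n_samples + 1)
    ts = systole_fraction * period
    wn = notch_width_fraction * period
    if ts + wn >= period:
        raise ValueError("systole plus notch exceeds the period")
    shape = np.zeros_like(t)
    sys_m = t < ts
    shape[sys_m] = np.sin(np.pi * t[sys_m] / ts) ** 2
    notch_m = (t >= ts) & (t < ts + wn)
    shape[notch_m] = -notch_depth * np.sin(np.pi * (t[notch_m] - ts) / wn) ** 2
    dia_m = t >= ts + wn
    span = period - ts - wn
    shape[dia_m] = diastolic_level * np.sin(np.pi * (t[dia_m] - ts - wn) / span) ** 2
    shape[-1] = shape[0]  # exact periodic closure
    m = np.mean(shape[:-1])
    values = shape * (mean_flow / m)
    return Waveform(t, values, period, unit="l/min")


def windkessel_pressure(
    inflow: Waveform,
    wk: WindkesselParams,
    p_init: float | None = None,
    max_cycles: int = 200,
    tol: float = 1e-8,
) -> Waveform:
    """Periodic pressure (mmHg) from the Windkessel driven by ``inflow``.

    Integrates dp/dt = (Q - (p - p_distal)/R)/C with the trapezoidal
    (Crank-Nicolson) rule, repeating cycles until the solution is periodic.
    With that scheme the discrete identity mean(p) = p_distal + R * mean(Q)
    holds exactly for the converged cycle.  C = 0 reduces to the algebraic
    relation p = p_distal + R * Q pointwise.
    """
    t = inflow.times
    q_ls = inflow.values / 60.0          # l/min -> l/s
    R_s = wk.R_total * 60.0              # mmHg.min/l -> mmHg.s/l
    if wk.C == 0.0:
        p = wk.p_distal + R_s * q_ls
        return Waveform(t, p, inflow.period, unit="mmHg")
    dt = t[1] - t[0]
    a = dt / (2.0 * R_s * wk.C)
    p = np.empty_like(q_ls)
    p0 = wk.p_distal if p_init is None else p_init
    mean_scale = max(abs(wk.p_distal + R_s * np.mean(q_ls)), 1.0)
    for _ in range(max_cycles):
        p[0] = p0
        for n in range(len(t) - 1):
            p[n + 1] = (
                p[n] * (1.0 - a)
                + (dt / (2.0 * wk.C)) * (q_ls[n] + q_ls[n + 1])
                + 2.0 * a * wk.p_distal
            ) / (1.0 + a)
        if abs(p[-1] - p0) < tol * mean_scale:
            p0 = p[-1]
            break
        p0 = p[-1]
    p[0] = p[-1] = p0
    return Waveform(t, p, inflow.period, unit="mmHg")


def calibrate_wk_resistance(mean_flow: float, target_mean_pressure: float,
                            p_distal: float = 0.0) -> float:
    """R_total (mmHg.min/l) so the periodic mean pressure hits the target.

    For the two-element Windkessel the periodic mean obeys
    mean(p) = p_distal + R_total * mean(Q), so calibration is closed-form.
    """
    if mean_flow <= 0:
        raise ValueError("mean_flow must be positive")
    if target_mean_pressure <= p_distal:
        raise ValueError("target mean pressure must exceed p_distal")
    return (target_mean_pressure - p_distal) / mean_flow


@dataclass
class ImpedanceModel:
    """Time-varying coronary outlet impedance (mmHg.min/l).

    A smooth two-level periodic switch: ``Z_sys`` during systole (myocardial
    compression throttles perfusion), ``Z_dia`` during diastole, blended with
    half-cosine transitions of width ``transition_width`` seconds centred on
    the systole/diastole boundaries.
    """

    Z_sys: float = 4500.0
    Z_dia: float = 900.0
    systole_fraction: float = 0.35
    transition_width: float = 0.05
    period: float = 1.0

    def __post_init__(self):
        if self.Z_sys <= 0 or self.Z_dia <= 0:
            raise ValueError("impedance levels must be positive")
        if self.Z_sys <= self.Z_dia:
            raise ValueError("Z_sys must exceed Z_dia")
        if not (0 < self.systole_fraction < 1):
            raise ValueError("systole_fraction must lie in (0, 1)")

    def systolic_weight(self, t) -> np.ndarray:
        """Smooth indicator of systole in [0, 1], periodic and continuous.

        The rising edge spans [0, w] just after cycle start and the falling
        edge is centred on end-systole, so the weight is zero at both t = 0
        and t = period (exact periodic closure, C1-smooth everywhere).
        """
        tp = np.mod(np.asarray(t, dtype=float), self.period)
        w = self.transition_width
        ts = self.systole_fraction * self.period

        def edge(x):
            # smooth step 0 -> 1 over [-w/2, w/2]
            return 0.5 * (1.0 + np.sin(np.pi * np.clip(x, -w / 2, w / 2) / w))

        rise = edge(tp - 0.5 * w)
        fall = 1.0 - edge(tp - ts)
        return rise * fall

    def __call__(self, t) -> np.ndarray:
        return self.Z_dia + (self.Z_sys - self.Z_dia) * self.systolic_weight(t)


def coronary_impedance(model: ImpedanceModel, t) -> np.ndarray:
    """Outlet resistance Z(t) (mmHg.min/l) at time(s) ``t``."""
    return model(t)


def diastolic_flow_fraction(
    p_ao: Waveform,
    impedance: ImpedanceModel,
    upstream_resistance: float,
    p_distal: float = 0.0,
) -> float:
    """Fraction of cycle coronary flow occurring in diastole (lumped model).

    Drives a single resistive path (upstream resistance in series with the
    time-varying outlet impedance) with the aortic pressure waveform and
    integrates the resulting flow over the diastolic interval. Used as the
    calibration criterion for diastolic-dominant coronary flow.
    """
    t = p_ao.times
    z = impedance(t)
    q = (p_ao.values - p_distal) / (upstream_resistance + z)
    q = np.clip(q, 0.0, None)
    ts = impedance.systole_fraction * impedance.period
    w_dia = (t[:-1] >= ts).astype(float)
    total = np.sum(q[:-1])
    if total <= 0:
        return 0.0
    return float(np.sum(q[:-1] * w_dia) / total)


class CalibrationError(RuntimeError):
    """Bisection failed to bracket or converge; carries diagnostics."""


def calibrate_graft_resistance(
    target_mean_graft_flow: float,
    evaluate_flow: Callable[[float], float],
    r_lo: float = 10.0,
    r_hi: float = 20000.0,
    rel_tol: float = 0.05,
    max_iter: int = 60,
) -> float:
    """Upstream graft resistance (mmHg.min/l) hitting a target mean flow.

    ``evaluate_flow(R)`` must return the simulated mean graft flow (ml/min)
    for a candidate upstream resistance; it is monotonically decreasing in R.
    Bisection stops when the evaluated flow is within ``rel_tol`` of target.

    Raises :class:`CalibrationError` with diagnostics if [r_lo, r_hi] does
    not bracket the target.
    """
    if target_mean_graft_flow <= 0:
        raise ValueError("target mean graft flow must be positive")
    q_lo = evaluate_flow(r_lo)   # high flow end
    q_hi = evaluate_flow(r_hi)   # low flow end
    if not (q_hi <= target_mean_graft_flow <= q_lo):
        raise CalibrationError(
            f"target {target_mean_graft_flow} ml/min not bracketed: "
            f"flow({r_lo})={q_lo:.3g}, flow({r_hi})={q_hi:.3g}"
        )
    lo, hi = r_lo, r_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        q = evaluate_flow(mid)
        if abs(q - target_mean_graft_flow) <= rel_tol * target_mean_graft_flow:
            return mid
        if q > target_mean_graft_flow:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not converge in {max_iter} iterations "
        f"(last interval [{lo:.4g}, {hi:.4g}])"
    )
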