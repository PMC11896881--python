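"""Heat-up trace summaries: truncation, heat-up speed, equilibrium temperature.

A trace is a regularly sampled temperature series for one individual and one
channel (``internal`` thermocouple at 5 s, ``external`` thermal camera at
20 s).  Both channels flow through the same code path; the only difference is
the sampling interval carried by the input series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ThermalTrace",
    "PhysiologySummary",
    "truncate_trace",
    "heatup_speed",
    "equilibrium_temperature",
    "summarise_trace",
    "newton_backbone",
    "fit_newton",
]

_TIME_TOL = 1e-6


@dataclass
class ThermalTrace:
    """Uniformly sampled temperature series, time origin 0 s at lamp-on."""

    individual_id: str
    channel: str  # "internal" or "external"
    times_s: np.ndarray
    temperatures_c: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.temperatures_c = np.asarray(self.temperatures_c, dtype=float)
        if self.times_s.shape != self.temperatures_c.shape:
            raise ValueError("times and temperatures must have equal length")
        if self.times_s.size >= 2:
            steps = np.diff(self.times_s)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if np.ptp(steps) > _TIME_TOL:
                raise ValueError("trace sampling is not uniform")

    @property
    def interval_s(self) -> float:
        if self.times_s.size < 2:
            return float("nan")
        return float(self.times_s[1] - self.times_s[0])

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1]) if self.times_s.size else 0.0

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass
class PhysiologySummary:
    individual_id: str
    channel: str
    heatup_speed_c_per_min: float
    equilibrium_c: float  # NaN when missing
    flags: list = field(default_factory=list)

    @property
    def equilibrium_missing(self) -> bool:
        return bool(np.isnan(self.equilibrium_c))


def truncate_trace(trace: ThermalTrace, cutoff_s: float = 20.0) -> ThermalTrace:
    """Drop samples with time < ``cutoff_s``; time stamps are preserved.

    The sample at exactly ``cutoff_s`` is retained.  Raises ``ValueError``
    when the trace does not extend beyond the cutoff.
    """
    if trace.duration_s <= cutoff_s:
        raise ValueError(
            f"trace duration {trace.duration_s} s does not exceed cutoff {cutoff_s} s"
        )
    keep = trace.times_s >= cutoff_s - _TIME_TOL
    return replace(
        trace, times_s=trace.times_s[keep], temperatures_c=trace.temperatures_c[keep]
    )


def _sample_at(trace: ThermalTrace, t: float) -> float:
    """Nearest-grid-point lookup; errors when no sample lies on the grid point."""
    idx = int(np.argmin(np.abs(trace.times_s - t)))
    if abs(trace.times_s[idx] - t) > _TIME_TOL:
        raise ValueError(f"no sample at t = {t} s (nearest: {trace.times_s[idx]} s)")
    return float(trace.temperatures_c[idx])


def heatup_speed(
    trace: ThermalTrace,
    window_s: tuple[float, float] = (20.0, 240.0),
    method: str = "endpoint",
) -> float:
    """Rate of temperature change over ``window_s``, in degC per minute.

    ``endpoint`` (default): (T(end) - T(start)) / (end - start).
    ``ols``: slope of an ordinary least-squares line fitted to all samples
    inside the window (both endpoints inclusive).
    """
    start, end = window_s
    if end <= start:
        raise ValueError("window end must exceed window start")
    if method == "endpoint":
        slope_per_s = (_sample_at(trace, end) - _sample_at(trace, start)) / (end - start)
    elif method == "ols":
        mask = (trace.times_s >= start - _TIME_TOL) & (trace.times_s <= end + _TIME_TOL)
        if mask.sum() < 2:
            raise ValueError("fewer than two samples inside the heat-up window")
        slope_per_s = np.polyfit(trace.times_s[mask], trace.temperatures_c[mask], 1)[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(slope_per_s * 60.0)


def equilibrium_temperature(
    trace: ThermalTrace,
    window_s: tuple[float, float] = (660.0, 760.0),
    not_reached: bool = False,
) -> float:
    """Mean temperature over ``window_s`` (inclusive); NaN when missing.

    Missing when the trace ends before the window does or when the
    individual's group is flagged as never reaching equilibrium.
    """
    if not_reached:
        return float("nan")
    start, end = window_s
    if trace.duration_s < end - _TIME_TOL:
        return float("nan")
    mask = (trace.times_s >= start - _TIME_TOL) & (trace.times_s <= end + _TIME_TOL)
    if not mask.any():
        return float("nan")
    return float(np.mean(trace.temperatures_c[mask]))


def summarise_trace(
    trace: ThermalTrace,
    truncate_s: float = 20.0,
    heatup_window_s: tuple[float, float] = (20.0, 240.0),
    equilibrium_window_s: tuple[float, float] = (660.0, 760.0),
    heatup_method: str = "endpoint",
    equilibrium_not_reached: bool = False,
) -> PhysiologySummary:
    """Truncate a raw trace and derive both summary statistics."""
    truncated = truncate_trace(trace, cutoff_s=truncate_s)
    speed = heatup_speed(truncated, window_s=heatup_window_s, method=heatup_method)
    equilibrium = equilibrium_temperature(
        truncated, window_s=equilibrium_window_s, not_reached=equilibrium_not_reached
    )
    flags = []
    if equilibrium_not_reached:
        flags.append("equilibrium_not_reached")
    elif np.isnan(equilibrium):
        flags.append("trace_too_short")
    return PhysiologySummary(
        individual_id=trace.individual_id,
        channel=trace.channel,
        heatup_speed_c_per_min=speed,
        equilibrium_c=equilibrium,
        flags=flags,
    )


def newton_backbone(t, t0: float, t_eq: float, k: float):
    """Lumped-capacitance heating curve T(t) = T_eq - (T_eq - T0) exp(-k t)."""
    t = np.asarray(t, dtype=float)
    return t_eq - (t_eq - t0) * np.exp(-k * t)


def fit_newton(
    times_s: np.ndarray, temperatures_c: np.ndarray
) -> tuple[float, float, float]:
    """Fit (T0, T_eq, k) of the Newton heating model by nonlinear least squares.

    Test/validation utility (parameter recovery), not a pipeline stage.
    """
    times_s = np.asarray(times_s, dtype=float)
    temperatures_c = np.asarray(temperatures_c, dtype=float)
    if times_s.size < 4:
        raise ValueError("need at least 4 samples to fit three parameters")
    t0_guess = float(temperatures_c[0])
    teq_guess = float(temperatures_c[-1])
    span = max(teq_guess - t0_guess, 1e-6)
    # crude rate guess from the time to reach ~63% of the span
    frac = (temperatures_c - t0_guess) / span
    above = np.nonzero(frac >= 0.632)[0]
    k_guess = 1.0 / float(times_s[above[0]]) if above.size and times_s[above[0]] > 0 else 0.01
    popt, _ = curve_fit(
        newton_backbone,
        times_s,
        temperatures_c,
        p0=(t0_guess, teq_guess, k_guess),
        maxfev=20000,
    )
    t0, t_eq, k = (float(v) for v in popt)
    return t0, t_eq, k
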