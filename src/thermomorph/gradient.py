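"""Thermal-gradient calibration and preferred-temperature extraction.

Each runway's position -> temperature map is a least-squares cubic fitted to
five calibration readings (0, 20, 40, 60, 80 cm from the cold edge).
Occupancy tracks (six sightings, one per 10 minutes) are converted to
substrate temperatures through the calibration; the preferred temperature is
the available-case mean over sightings from minute 30 onwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as P

__all__ = [
    "GradientCalibration",
    "GradientTrack",
    "fit_calibration",
    "position_to_temperature",
    "temperature_to_position",
    "attach_temperatures",
    "preferred_temperature",
]


@dataclass
class GradientCalibration:
    """Cubic position->temperature map for one runway."""

    runway_id: str
    positions_cm: np.ndarray
    temperatures_c: np.ndarray
    coefficients: np.ndarray  # power basis, ascending order (c0..c3)
    residual_rms_c: float

    @property
    def position_range_cm(self) -> tuple[float, float]:
        return float(np.min(self.positions_cm)), float(np.max(self.positions_cm))

    @property
    def temperature_range_c(self) -> tuple[float, float]:
        lo, hi = self.position_range_cm
        grid = np.linspace(lo, hi, 161)
        temps = P.polyval(grid, self.coefficients)
        return float(temps.min()), float(temps.max())


@dataclass
class GradientTrack:
    """Timed runway positions for one individual; NaN marks a missing sighting."""

    individual_id: str
    runway_id: str
    times_min: np.ndarray
    positions_cm: np.ndarray
    substrate_c: np.ndarray | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        if self.times_min.shape != self.positions_cm.shape:
            raise ValueError("times and positions must have equal length")
        present = self.positions_cm[~np.isnan(self.positions_cm)]
        if present.size and (present.min() < 0 or present.max() > 80):
            raise ValueError("positions outside the 0-80 cm runway")


def fit_calibration(
    positions_cm,
    temperatures_c,
    runway_id: str = "",
) -> GradientCalibration:
    """Least-squares cubic through the calibration readings.

    Requires at least four distinct positions (the cubic is underdetermined
    otherwise); with exactly five readings and four parameters the residuals
    are reported for drift/plausibility checks.
    """
    positions_cm = np.asarray(positions_cm, dtype=float)
    temperatures_c = np.asarray(temperatures_c, dtype=float)
    if positions_cm.shape != temperatures_c.shape:
        raise ValueError("positions and temperatures must have equal length")
    if np.unique(positions_cm).size < 4:
        raise ValueError("need >= 4 distinct positions to fit a cubic")
    if not np.all(np.isfinite(temperatures_c)):
        raise ValueError("calibration temperatures must be finite")
    coeffs = P.polyfit(positions_cm, temperatures_c, 3)
    residuals = temperatures_c - P.polyval(positions_cm, coeffs)
    return GradientCalibration(
        runway_id=runway_id,
        positions_cm=positions_cm,
        temperatures_c=temperatures_c,
        coefficients=coeffs,
        residual_rms_c=float(np.sqrt(np.mean(residuals**2))),
    )


def position_to_temperature(calibration: GradientCalibration, position_cm):
    """Evaluate the calibration cubic; no extrapolation beyond the runway."""
    position_cm = np.asarray(position_cm, dtype=float)
    lo, hi = calibration.position_range_cm
    finite = position_cm[np.isfinite(position_cm)]
    if finite.size and (finite.min() < lo - 1e-9 or finite.max() > hi + 1e-9):
        raise ValueError(f"position outside calibrated range [{lo}, {hi}] cm")
    temps = P.polyval(position_cm, calibration.coefficients)
    if position_cm.ndim == 0:
        return float(temps)
    return temps


def temperature_to_position(
    calibration: GradientCalibration, temperature_c: float
) -> tuple[float, bool]:
    """Invert the calibration: position whose temperature equals the target.

    Returns ``(position, clamped)``.  When the target lies outside the
    achievable range the nearest runway end is returned with ``clamped=True``.
    When several in-range roots exist (non-monotone cubic) the one closest to
    the runway centre is chosen.
    """
    lo, hi = calibration.position_range_cm
    coeffs = calibration.coefficients.copy()
    coeffs[0] -= temperature_c
    roots = P.polyroots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-8].real
    in_range = real[(real >= lo - 1e-9) & (real <= hi + 1e-9)]
    if in_range.size:
        centre = 0.5 * (lo + hi)
        pos = float(in_range[np.argmin(np.abs(in_range - centre))])
        return min(max(pos, lo), hi), False
    # outside achievable range: clamp to the end with the nearest temperature
    t_lo = position_to_temperature(calibration, lo)
    t_hi = position_to_temperature(calibration, hi)
    pos = lo if abs(t_lo - temperature_c) <= abs(t_hi - temperature_c) else hi
    return float(pos), True


def attach_temperatures(
    track: GradientTrack, calibration: GradientCalibration
) -> GradientTrack:
    """Derive substrate temperatures at every non-missing sighting."""
    if track.runway_id and calibration.runway_id and track.runway_id != calibration.runway_id:
        raise ValueError(
            f"track runway {track.runway_id!r} != calibration runway "
            f"{calibration.runway_id!r}"
        )
    substrate = np.full_like(track.positions_cm, np.nan)
    present = ~np.isnan(track.positions_cm)
    if present.any():
        substrate[present] = position_to_temperature(
            calibration, track.positions_cm[present]
        )
    track.substrate_c = substrate
    return track


def preferred_temperature(
    track: GradientTrack, window_min: tuple[float, float] = (30.0, 60.0)
) -> tuple[float, int]:
    """Mean substrate temperature over sightings inside ``window_min``.

    Both window endpoints are inclusive.  Missing sightings are skipped
    (available-case mean); returns ``(nan, 0)`` when no sighting in the
    window has a temperature.
    """
    if track.substrate_c is None:
        raise ValueError("substrate temperatures not derived; call attach_temperatures")
    lo, hi = window_min
    in_window = (track.times_min >= lo - 1e-9) & (track.times_min <= hi + 1e-9)
    temps = track.substrate_c[in_window]
    temps = temps[~np.isnan(temps)]
    if temps.size == 0:
        return float("nan"), 0
    return float(temps.mean()), int(temps.size)
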