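"""Synthetic cohort generator emulating the study's measurement design.

Per individual the generator produces:

* an internal (5 s) and an external (20 s) heat-up trace following a
  lumped-capacitance (Newton) heating backbone with the rate constant
  scaling as mass**beta (beta = -1/3 by default, surface-to-volume scaling),
  Gaussian observation noise, and — with configurable probability — an
  initial dip over the first 20 s mimicking haemolymph homogenisation;
* a gradient occupancy track (six sightings, 10 min apart) relaxing from
  the release point towards the position whose calibrated temperature
  matches the individual's preferred temperature, with positional noise and
  independently missing sightings;
* ten raw reflectance spectra (five dorsal + five lateral) whose processed
  mean brightness is centred on the configured group target, including the
  654-659 nm instrument-artefact spike.

Randomness is hierarchical: each individual draws from a stream keyed by the
cohort seed and a stable hash of its id, so adding individuals to a config
does not perturb the data of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .config import EXTERNAL, INTERNAL, MORPHS_BY_SPECIES, SimConfig
from .gradient import (
    GradientCalibration,
    GradientTrack,
    fit_calibration,
    temperature_to_position,
)
from .physiology import ThermalTrace, newton_backbone
from .spectra import (
    ARTEFACT_BAND_NM,
    BODY_PARTS,
    WAVELENGTH_GRID,
    ReflectanceSpectrum,
)

__all__ = [
    "Individual",
    "ThermalParams",
    "Cohort",
    "generate_cohort",
    "simulate_heatup_trace",
    "simulate_gradient_track",
    "simulate_reflectance",
    "time_grid",
]

_RUNWAY_STREAM_TAG = 0x52554E57  # cohort-level stream for runway calibrations


@dataclass
class Individual:
    id: str
    species: str
    sex: str
    morph: str
    mass_g: float
    brightness_pct: float | None = None  # set after spectra processing

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("mass must be > 0")
        allowed = MORPHS_BY_SPECIES.get(self.species)
        if allowed is None:
            raise ValueError(f"unknown species {self.species!r}")
        if self.morph not in allowed:
            raise ValueError(
                f"morph {self.morph!r} not permitted for species {self.species!r}"
            )


@dataclass
class ThermalParams:
    """True generator parameters of one individual (for recovery tests)."""

    t0_c: float
    t_eq_c: float
    k_per_s: float
    has_dip: bool
    preferred_c: float
    brightness_target_pct: float
    runway_id: str


@dataclass
class Cohort:
    individuals: list = field(default_factory=list)
    traces: dict = field(default_factory=dict)  # (individual_id, channel) -> ThermalTrace
    tracks: dict = field(default_factory=dict)  # individual_id -> GradientTrack
    spectra: dict = field(default_factory=dict)  # individual_id -> [ReflectanceSpectrum]
    calibrations: dict = field(default_factory=dict)  # runway_id -> GradientCalibration
    true_params: dict = field(default_factory=dict)  # individual_id -> ThermalParams

    def __len__(self) -> int:
        return len(self.individuals)


def _individual_rng(seed: int, individual_id: str) -> np.random.Generator:
    """Stream keyed by (cohort seed, stable hash of the id)."""
    key = zlib.crc32(individual_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def time_grid(duration_s: float, dt_s: float) -> np.ndarray:
    """All multiples of ``dt_s`` in [0, duration_s]."""
    n = int(np.floor(duration_s / dt_s + 1e-9))
    return np.arange(n + 1) * dt_s


def _draw_mass(config: SimConfig, species: str, sex: str, rng) -> float:
    dist = config.mass[species][sex]
    for _ in range(1000):
        m = float(dist.sample(rng))
        if m >= config.mass_min_g:
            return m
    return config.mass_min_g


def _thermal_params(
    individual: Individual, config: SimConfig, rng: np.random.Generator,
    brightness_target: float,
) -> tuple[float, float, float, bool]:
    t0 = float(config.t0.sample(rng))
    t_eq = (
        float(config.t_eq[individual.species][individual.sex])
        + float(config.morph_teq_offset_c.get(individual.morph, 0.0))
    )
    group_mean_brightness = config.brightness[individual.species][individual.sex][
        individual.morph
    ].mean
    k = (
        config.k0_per_s
        * (individual.mass_g / config.m_ref_g) ** config.beta
        * float(config.k_scale[individual.species][individual.sex])
        * float(config.morph_k_scale.get(individual.morph, 1.0))
        * (1.0 + config.brightness_k_slope * (brightness_target - group_mean_brightness))
    )
    if k <= 0:
        raise ValueError("derived rate constant must be > 0")
    has_dip = bool(rng.random() < config.dip_prob)
    return t0, t_eq, k, has_dip


def simulate_heatup_trace(
    individual: Individual,
    config: SimConfig,
    channel: str = INTERNAL,
    rng: np.random.Generator | None = None,
    params: ThermalParams | None = None,
) -> ThermalTrace:
    """One noisy heat-up trace on the channel's sampling grid.

    The noiseless backbone is ``T(t) = T_eq - (T_eq - T0) exp(-k t)`` with
    ``k = k0 (m / m_ref)**beta`` (scaled further by group/morph factors).
    With probability ``dip_prob`` the internal channel's first
    ``dip_duration_s`` seconds are replaced by a linear decline from
    ``T0 + dip_depth_c`` to the backbone value at the end of the dip.
    """
    if individual.mass_g <= 0:
        raise ValueError("mass must be > 0")
    if config.k0_per_s <= 0:
        raise ValueError("k0 must be > 0")
    if rng is None:
        rng = _individual_rng(config.seed, individual.id)
    if params is None:
        t0, t_eq, k, has_dip = _thermal_params(
            individual, config, rng,
            brightness_target=config.brightness[individual.species][individual.sex][
                individual.morph
            ].mean,
        )
    else:
        t0, t_eq, k, has_dip = params.t0_c, params.t_eq_c, params.k_per_s, params.has_dip

    dt = config.internal_dt_s if channel == INTERNAL else config.external_dt_s
    times = time_grid(config.duration_s, dt)
    temps = newton_backbone(times, t0, t_eq, k)
    if has_dip and channel == INTERNAL and config.dip_duration_s > 0:
        end = newton_backbone(config.dip_duration_s, t0, t_eq, k)
        start = t0 + config.dip_depth_c
        in_dip = times < config.dip_duration_s - 1e-9
        temps[in_dip] = start + (end - start) * times[in_dip] / config.dip_duration_s
    if config.noise_sd_c > 0:
        temps = temps + rng.normal(0.0, config.noise_sd_c, size=temps.shape)
    return ThermalTrace(
        individual_id=individual.id, channel=channel, times_s=times,
        temperatures_c=temps,
    )


def simulate_gradient_track(
    individual: Individual,
    calibration: GradientCalibration,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    preferred_c: float | None = None,
) -> GradientTrack:
    """Occupancy track relaxing from the release point to the preferred spot.

    The target position is the calibration inverse of the preferred
    temperature (clamped to the nearest runway end and flagged when the
    preference is outside the achievable range).  Approach is linear in time
    and complete after ``settle_time_min``; each sighting is independently
    missing with ``missing_prob``.
    """
    if rng is None:
        rng = _individual_rng(config.seed, individual.id + "/track")
    if preferred_c is None:
        preferred_c = (
            float(config.preferred[individual.species][individual.sex].sample(rng))
            + float(config.morph_preferred_offset_c.get(individual.morph, 0.0))
        )
    target_cm, clamped = temperature_to_position(calibration, preferred_c)
    times = np.asarray(config.sighting_times_min, dtype=float)
    progress = np.minimum(1.0, times / max(config.settle_time_min, 1e-9))
    positions = config.release_cm + (target_cm - config.release_cm) * progress
    if config.position_noise_cm > 0:
        positions = positions + rng.normal(0.0, config.position_noise_cm, times.shape)
    positions = np.clip(positions, 0.0, config.runway_length_cm)
    missing = rng.random(times.shape) < config.missing_prob
    positions[missing] = np.nan
    flags = ["preference_clamped"] if clamped else []
    return GradientTrack(
        individual_id=individual.id,
        runway_id=calibration.runway_id,
        times_min=times,
        positions_cm=positions,
        flags=flags,
    )


def _base_shape(morph: str) -> np.ndarray:
    """Unit-mean spectral shape: green morphs peak near 550 nm, brown rise gently."""
    lam = WAVELENGTH_GRID.astype(float)
    if "green" in morph:  # green, dorsal-green, lateral-green
        shape = 1.0 + 1.2 * np.exp(-0.5 * ((lam - 550.0) / 45.0) ** 2)
        shape += 0.3 * (lam - 300.0) / 700.0
    else:
        shape = 1.0 + 0.8 * (lam - 300.0) / 700.0
    return shape / shape.mean()


def simulate_reflectance(
    individual: Individual,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    brightness_target_pct: float | None = None,
) -> list[ReflectanceSpectrum]:
    """Ten raw spectra (5 per body part) with artefact spike injected.

    The expected processed brightness (artefact-corrected, averaged over the
    10 replicates) equals ``brightness_target_pct``.
    """
    if rng is None:
        rng = _individual_rng(config.seed, individual.id + "/spectra")
    if brightness_target_pct is None:
        brightness_target_pct = float(
            config.brightness[individual.species][individual.sex][
                individual.morph
            ].sample(rng)
        )
    brightness_target_pct = max(brightness_target_pct, 0.5)
    shape = _base_shape(individual.morph)
    spike_idx = np.nonzero(
        (WAVELENGTH_GRID >= ARTEFACT_BAND_NM[0])
        & (WAVELENGTH_GRID <= ARTEFACT_BAND_NM[1])
    )[0]
    spectra: list[ReflectanceSpectrum] = []
    for part_i, part in enumerate(BODY_PARTS):
        # body parts differ deterministically but symmetrically around the target
        part_factor = 1.0 + config.body_part_delta * (1 if part_i == 0 else -1)
        for rep in range(1, 6):
            jitter = 1.0 + config.jitter_sd * float(rng.standard_normal())
            jitter = max(jitter, 0.05)
            refl = brightness_target_pct * shape * part_factor * jitter
            refl[spike_idx] += config.spike_magnitude_pct
            refl = np.clip(refl, 0.0, None)
            spectra.append(
                ReflectanceSpectrum(
                    individual_id=individual.id,
                    body_part=part,
                    replicate=rep,
                    reflectance_pct=refl,
                )
            )
    return spectra


def _make_calibrations(config: SimConfig) -> dict:
    """Four runway calibrations from a bowed, noisy cold-to-hot profile."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _RUNWAY_STREAM_TAG])
    )
    calibrations = {}
    positions = np.asarray(config.calibration_positions_cm, dtype=float)
    length = config.runway_length_cm
    for r in range(1, config.n_runways + 1):
        base = config.cold_end_c + (config.hot_end_c - config.cold_end_c) * (
            positions / length
        )
        bow = config.calibration_bow_c * np.sin(np.pi * positions / length)
        noise = (
            rng.normal(0.0, config.calibration_noise_c, positions.shape)
            if config.calibration_noise_c > 0
            else 0.0
        )
        runway_id = f"runway-{r}"
        calibrations[runway_id] = fit_calibration(
            positions, base + bow + noise, runway_id=runway_id
        )
    return calibrations


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate the complete cohort: individuals, traces, tracks, spectra.

    Deterministic under a fixed config seed; per-group counts match the
    config exactly.  A zero total count yields an empty cohort (with its
    runway calibrations still fitted).
    """
    config.validate()
    cohort = Cohort()
    cohort.calibrations = _make_calibrations(config)
    runway_ids = sorted(cohort.calibrations)
    index = 0
    for species, sex, morph, count in config.iter_groups():
        for i in range(1, count + 1):
            ind_id = f"{species}-{sex}-{morph}-{i:03d}"
            rng = _individual_rng(config.seed, ind_id)
            mass = _draw_mass(config, species, sex, rng)
            individual = Individual(
                id=ind_id, species=species, sex=sex, morph=morph, mass_g=mass
            )
            brightness_target = max(
                float(config.brightness[species][sex][morph].sample(rng)), 0.5
            )
            t0, t_eq, k, has_dip = _thermal_params(
                individual, config, rng, brightness_target
            )
            runway_id = runway_ids[index % len(runway_ids)]
            calibration = cohort.calibrations[runway_id]
            preferred = (
                float(config.preferred[species][sex].sample(rng))
                + float(config.morph_preferred_offset_c.get(morph, 0.0))
            )
            params = ThermalParams(
                t0_c=t0, t_eq_c=t_eq, k_per_s=k, has_dip=has_dip,
                preferred_c=preferred, brightness_target_pct=brightness_target,
                runway_id=runway_id,
            )
            for channel in (INTERNAL, EXTERNAL):
                cohort.traces[(ind_id, channel)] = simulate_heatup_trace(
                    individual, config, channel=channel, rng=rng, params=params
                )
            cohort.tracks[ind_id] = simulate_gradient_track(
                individual, calibration, config, rng=rng, preferred_c=preferred
            )
            cohort.spectra[ind_id] = simulate_reflectance(
                individual, config, rng=rng, brightness_target_pct=brightness_target
            )
            cohort.individuals.append(individual)
            cohort.true_params[ind_id] = params
            index += 1
    return cohort
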