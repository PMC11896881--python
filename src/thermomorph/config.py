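"""Configuration objects for the simulator and the analysis pipeline.

Two configuration layers exist:

* :class:`SimConfig` — every knob of the synthetic cohort generator
  (sample sizes, mass/brightness distributions, heating model constants,
  gradient geometry, spectral artefact magnitude, effect sizes).
* :class:`AnalysisConfig` — analysis constants (summary windows, bootstrap
  size and CI level, assumption-check alpha, groups flagged as never
  reaching equilibrium).

Both serialise to plain dictionaries (and therefore YAML/JSON)
field-for-field via :meth:`to_dict` / :meth:`from_dict`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np
import yaml

SPECIES: tuple[str, ...] = ("ungarica", "sibiricus", "parallelus")
SEXES: tuple[str, ...] = ("F", "M")

#: Morphs permitted per species; only parallelus has the two intermediate morphs.
MORPHS_BY_SPECIES: dict[str, tuple[str, ...]] = {
    "ungarica": ("green", "brown"),
    "sibiricus": ("green", "brown"),
    "parallelus": ("green", "dorsal-green", "lateral-green", "brown"),
}

ALL_MORPHS: tuple[str, ...] = ("green", "dorsal-green", "lateral-green", "brown")

INTERNAL = "internal"
EXTERNAL = "external"
CHANNELS: tuple[str, ...] = (INTERNAL, EXTERNAL)


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class Normal:
    """Mean/SD pair describing a univariate normal distribution."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError(f"SD must be >= 0, got {self.sd}")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.normal(self.mean, self.sd, size=size)

    def to_dict(self) -> dict[str, float]:
        return {"mean": self.mean, "sd": self.sd}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "Normal":
        return cls(mean=float(d["mean"]), sd=float(d["sd"]))


def _study_counts() -> dict:
    # Per-morph replicate counts of the study design: 30/30 F + 34/34 M
    # (ungarica), 19/19 F + 13/13 M (sibiricus), 30 per morph and sex
    # (parallelus) -> 432 individuals in total.
    return {
        "ungarica": {
            "F": {"green": 30, "brown": 30},
            "M": {"green": 34, "brown": 34},
        },
        "sibiricus": {
            "F": {"green": 19, "brown": 19},
            "M": {"green": 13, "brown": 13},
        },
        "parallelus": {
            "F": {m: 30 for m in MORPHS_BY_SPECIES["parallelus"]},
            "M": {m: 30 for m in MORPHS_BY_SPECIES["parallelus"]},
        },
    }


def _study_mass() -> dict:
    return {
        "ungarica": {"F": Normal(1.12, 0.27), "M": Normal(0.21, 0.02)},
        "sibiricus": {"F": Normal(0.36, 0.07), "M": Normal(0.19, 0.03)},
        "parallelus": {"F": Normal(0.22, 0.04), "M": Normal(0.10, 0.01)},
    }


def _study_brightness() -> dict:
    # Identical across morphs within a species x sex group: the generator's
    # default is the null of no morph effect.
    per_group = {
        "ungarica": {"F": Normal(18.9, 3.6), "M": Normal(20.5, 2.7)},
        "sibiricus": {"F": Normal(5.1, 1.3), "M": Normal(2.8, 1.1)},
        "parallelus": {"F": Normal(13.2, 2.7), "M": Normal(8.6, 2.2)},
    }
    return {
        sp: {
            sex: {m: per_group[sp][sex] for m in MORPHS_BY_SPECIES[sp]}
            for sex in SEXES
        }
        for sp in SPECIES
    }


def _t_eq_default() -> dict:
    return {sp: {sex: 40.0 for sex in SEXES} for sp in SPECIES}


def _k_scale_default() -> dict:
    # Ungarica females get a strongly reduced rate constant so that, like in
    # the study, they do not plateau within the trace duration.
    d = {sp: {sex: 1.0 for sex in SEXES} for sp in SPECIES}
    d["ungarica"]["F"] = 0.18
    return d


def _preferred_default() -> dict:
    return {sp: {sex: Normal(32.0, 3.0) for sex in SEXES} for sp in SPECIES}


def _morph_zero() -> dict:
    return {m: 0.0 for m in ALL_MORPHS}


def _morph_one() -> dict:
    return {m: 1.0 for m in ALL_MORPHS}


@dataclass
class SimConfig:
    """All parameters of the synthetic cohort generator."""

    # cohort composition: species -> sex -> morph -> count
    counts: dict = field(default_factory=_study_counts)
    # body mass distribution (g): species -> sex -> Normal
    mass: dict = field(default_factory=_study_mass)
    mass_min_g: float = 0.005

    # heating model
    t0: Normal = field(default_factory=lambda: Normal(5.8, 3.0))
    t_eq: dict = field(default_factory=_t_eq_default)  # species -> sex -> degC
    k0_per_s: float = 0.012
    m_ref_g: float = 0.2
    beta: float = -1.0 / 3.0
    k_scale: dict = field(default_factory=_k_scale_default)  # species -> sex -> factor
    noise_sd_c: float = 0.3
    dip_prob: float = 0.24
    dip_depth_c: float = 8.0
    dip_duration_s: float = 20.0
    duration_s: float = 792.0
    internal_dt_s: float = 5.0
    external_dt_s: float = 20.0

    # gradient / preference assay
    cold_end_c: float = 10.0
    hot_end_c: float = 51.0
    runway_length_cm: float = 80.0
    release_cm: float = 40.0
    sighting_times_min: tuple = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    missing_prob: float = 0.016
    settle_time_min: float = 10.0
    position_noise_cm: float = 2.0
    n_runways: int = 4
    calibration_positions_cm: tuple = (0.0, 20.0, 40.0, 60.0, 80.0)
    calibration_bow_c: float = 2.0
    calibration_noise_c: float = 0.5
    preferred: dict = field(default_factory=_preferred_default)  # sp -> sex -> Normal

    # reflectance spectra
    brightness: dict = field(default_factory=_study_brightness)  # sp->sex->morph->Normal
    jitter_sd: float = 0.03
    spike_magnitude_pct: float = 15.0
    body_part_delta: float = 0.08

    # effect sizes on thermal parameters (defaults: the null)
    morph_k_scale: dict = field(default_factory=_morph_one)
    morph_teq_offset_c: dict = field(default_factory=_morph_zero)
    morph_preferred_offset_c: dict = field(default_factory=_morph_zero)
    brightness_k_slope: float = 0.0  # per % brightness deviation from group mean
    seed: int = 0

    def validate(self) -> None:
        for sp, by_sex in self.counts.items():
            if sp not in SPECIES:
                raise ConfigError(f"unknown species {sp!r}")
            for sex, by_morph in by_sex.items():
                if sex not in SEXES:
                    raise ConfigError(f"unknown sex {sex!r}")
                for morph, n in by_morph.items():
                    if morph not in MORPHS_BY_SPECIES[sp]:
                        raise ConfigError(
                            f"morph {morph!r} not permitted for species {sp!r}"
                        )
                    if int(n) < 0:
                        raise ConfigError("counts must be >= 0")
        for p in (self.dip_prob, self.missing_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        for sd in (self.noise_sd_c, self.jitter_sd, self.position_noise_cm,
                   self.calibration_noise_c):
            if sd < 0:
                raise ConfigError("noise SDs must be >= 0")
        if self.k0_per_s <= 0 or self.m_ref_g <= 0:
            raise ConfigError("k0 and reference mass must be > 0")
        for dt in (self.internal_dt_s, self.external_dt_s):
            if dt <= 0:
                raise ConfigError("sampling intervals must be > 0")
        if self.duration_s <= 0:
            raise ConfigError("trace duration must be > 0")
        if not 0 <= self.release_cm <= self.runway_length_cm:
            raise ConfigError("release position outside runway")
        if self.n_runways < 1:
            raise ConfigError("need at least one runway")

    def total_count(self) -> int:
        return sum(
            int(n)
            for by_sex in self.counts.values()
            for by_morph in by_sex.values()
            for n in by_morph.values()
        )

    def iter_groups(self) -> Iterator[tuple[str, str, str, int]]:
        """Yield (species, sex, morph, count) in canonical order."""
        for sp in SPECIES:
            by_sex = self.counts.get(sp, {})
            for sex in SEXES:
                by_morph = by_sex.get(sex, {})
                for morph in MORPHS_BY_SPECIES[sp]:
                    if morph in by_morph:
                        yield sp, sex, morph, int(by_morph[morph])

    def to_dict(self) -> dict:
        return _to_plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "t0" in d and isinstance(d["t0"], dict):
            d["t0"] = Normal.from_dict(d["t0"])
        for key in ("mass", "preferred", "brightness"):
            if key in d:
                d[key] = _nested_normals(d[key])
        if "sighting_times_min" in d:
            d["sighting_times_min"] = tuple(d["sighting_times_min"])
        if "calibration_positions_cm" in d:
            d["calibration_positions_cm"] = tuple(d["calibration_positions_cm"])
        return cls(**d)


@dataclass
class AnalysisConfig:
    """Constants of the downstream analysis."""

    n_bootstrap: int = 1000
    ci_level: float = 0.95
    truncate_s: float = 20.0
    heatup_window_s: tuple = (20.0, 240.0)
    equilibrium_window_s: tuple = (660.0, 760.0)
    preferred_window_min: tuple = (30.0, 60.0)
    heatup_method: str = "endpoint"  # or "ols"
    quantile_method: str = "linear"  # numpy quantile method ("type 7")
    alpha: float = 0.05
    max_missing_frac: float = 0.5
    # species x sex groups for which the equilibrium window is not trusted
    equilibrium_not_reached: list = field(
        default_factory=lambda: [["ungarica", "F"]]
    )
    all_pairwise_contrasts: bool = False
    calibration_max_rms_c: float = 1.5

    def validate(self) -> None:
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError("ci_level must be in (0, 1)")
        if self.heatup_method not in ("endpoint", "ols"):
            raise ConfigError(f"unknown heatup_method {self.heatup_method!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return _to_plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for key in ("heatup_window_s", "equilibrium_window_s", "preferred_window_min"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineConfig:
    """Top-level configuration: simulation + analysis."""

    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self) -> None:
        self.sim.validate()
        self.analysis.validate()

    def to_dict(self) -> dict:
        return {"sim": self.sim.to_dict(), "analysis": self.analysis.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            sim=SimConfig.from_dict(d.get("sim", {})),
            analysis=AnalysisConfig.from_dict(d.get("analysis", {})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def study_config(seed: int = 0) -> PipelineConfig:
    """Configuration matching the study design (432 individuals)."""
    cfg = PipelineConfig()
    cfg.sim.seed = seed
    return cfg


def _to_plain(obj: Any) -> Any:
    """Recursively convert dataclass-asdict output into YAML-safe primitives."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _nested_normals(d: dict) -> dict:
    """Convert {..: {mean, sd}} leaves (arbitrary nesting) back into Normal."""
    out = {}
    for k, v in d.items():
        if isinstance(v, Normal):
            out[k] = v
        elif isinstance(v, dict) and set(v) == {"mean", "sd"}:
            out[k] = Normal.from_dict(v)
        elif isinstance(v, dict):
            out[k] = _nested_normals(v)
        else:
            out[k] = v
    return out
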