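"""Schema and consistency validation of the input CSVs.

Produces a machine-readable report instead of raising: every violation
carries the offending file, an identifying key and a message, so callers
can fail fast with precise diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CHANNELS, MORPHS_BY_SPECIES, SEXES, SPECIES
from .io import INPUT_FILES
from .spectra import WAVELENGTH_GRID

__all__ = ["Violation", "ValidationReport", "validate_inputs"]


@dataclass
class Violation:
    file: str
    key: str
    message: str


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)
    checked_files: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, file: str, key: str, message: str) -> None:
        self.violations.append(Violation(file=file, key=key, message=message))

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "checked_files": self.checked_files,
            "violations": [vars(v) for v in self.violations],
        }


def validate_inputs(in_dir) -> ValidationReport:
    """Check grids, value ranges, id consistency and species/morph rules."""
    in_dir = Path(in_dir)
    report = ValidationReport()

    ind_path = in_dir / INPUT_FILES["individuals"]
    individuals = _read(ind_path, report)
    known_ids: set = set()
    if individuals is not None:
        f = ind_path.name
        dup = individuals["individual_id"][individuals["individual_id"].duplicated()]
        for ind_id in dup.unique():
            report.add(f, str(ind_id), "duplicate individual_id")
        for row in individuals.itertuples(index=False):
            if row.species not in SPECIES:
                report.add(f, row.individual_id, f"unknown species {row.species!r}")
            elif row.morph not in MORPHS_BY_SPECIES[row.species]:
                report.add(
                    f,
                    row.individual_id,
                    f"morph {row.morph!r} not permitted for species {row.species!r}",
                )
            if row.sex not in SEXES:
                report.add(f, row.individual_id, f"unknown sex {row.sex!r}")
            if not np.isfinite(row.mass_g) or row.mass_g <= 0:
                report.add(f, row.individual_id, f"non-positive mass {row.mass_g}")
        known_ids = set(individuals["individual_id"])

    traces_path = in_dir / INPUT_FILES["traces"]
    traces = _read(traces_path, report)
    if traces is not None:
        f = traces_path.name
        for (ind_id, channel), grp in traces.groupby(
            ["individual_id", "channel"], sort=False
        ):
            key = f"{ind_id}/{channel}"
            if channel not in CHANNELS:
                report.add(f, key, f"unknown channel {channel!r}")
            if known_ids and ind_id not in known_ids:
                report.add(f, key, "individual_id not in individuals table")
            times = np.sort(grp["time_s"].to_numpy(dtype=float))
            if times.size >= 2:
                steps = np.diff(times)
                if np.any(steps <= 0):
                    report.add(f, key, "duplicate time stamps")
                elif np.ptp(steps) > 1e-6:
                    report.add(f, key, "non-uniform sampling")
            if not np.all(np.isfinite(grp["temperature_c"].to_numpy(dtype=float))):
                report.add(f, key, "non-finite temperature")

    tracks_path = in_dir / INPUT_FILES["tracks"]
    tracks = _read(tracks_path, report)
    runway_ids: set = set()
    cal_path = in_dir / INPUT_FILES["calibrations"]
    calibrations = _read(cal_path, report)
    if calibrations is not None:
        f = cal_path.name
        for runway_id, grp in calibrations.groupby("runway_id"):
            runway_ids.add(runway_id)
            if grp["position_cm"].nunique() < 4:
                report.add(
                    f, str(runway_id), "fewer than 4 distinct calibration positions"
                )
            if not np.all(np.isfinite(grp["temperature_c"].to_numpy(dtype=float))):
                report.add(f, str(runway_id), "non-finite calibration temperature")
    if tracks is not None:
        f = tracks_path.name
        for ind_id, grp in tracks.groupby("individual_id", sort=False):
            if known_ids and ind_id not in known_ids:
                report.add(f, str(ind_id), "individual_id not in individuals table")
            if runway_ids and not set(grp["runway_id"]).issubset(runway_ids):
                report.add(f, str(ind_id), "unknown runway_id")
            pos = grp["position_cm"].to_numpy(dtype=float)
            pos = pos[~np.isnan(pos)]
            if pos.size and (pos.min() < 0 or pos.max() > 80):
                report.add(f, str(ind_id), "position outside 0-80 cm")

    spectra_path = in_dir / INPUT_FILES["spectra"]
    if spectra_path.exists():
        spectra = _read(spectra_path, report)
        if spectra is not None:
            f = spectra_path.name
            keys = ["individual_id", "body_part", "replicate"]
            for (ind_id, part, rep), grp in spectra.groupby(keys, sort=False):
                key = f"{ind_id}/{part}/{rep}"
                if known_ids and ind_id not in known_ids:
                    report.add(f, key, "individual_id not in individuals table")
                wl = np.sort(grp["wavelength_nm"].to_numpy())
                if wl.size != WAVELENGTH_GRID.size or not np.array_equal(
                    wl, WAVELENGTH_GRID
                ):
                    report.add(f, key, "wavelength grid is not 300-1000 nm at 1 nm")
                refl = grp["reflectance_pct"].to_numpy(dtype=float)
                if not np.all(np.isfinite(refl)) or np.any(refl < 0):
                    report.add(f, key, "invalid reflectance values")

    return report


def _read(path: Path, report: ValidationReport):
    if not path.exists():
        report.add(path.name, "-", "file missing")
        return None
    try:
        df = pd.read_csv(path, dtype={"individual_id": str, "runway_id": str})
    except Exception as exc:  # surface parse failures as violations
        report.add(path.name, "-", f"unreadable: {exc}")
        return None
    report.checked_files.append(str(path))
    return df
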