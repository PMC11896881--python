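"""CSV readers and writers for all inter-stage files.

Conventions: tidy long format, UTF-8, "." decimal, empty cell = missing.

Input schemas (produced by the generator, consumed by the pipeline):

* ``individuals.csv``  — individual_id, species, sex, morph, mass_g
* ``traces.csv``       — individual_id, channel, time_s, temperature_c
* ``tracks.csv``       — individual_id, runway_id, time_min, position_cm
* ``calibrations.csv`` — runway_id, position_cm, temperature_c
* ``spectra.csv``      — individual_id, body_part, replicate, wavelength_nm,
  reflectance_pct
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gradient import GradientTrack
from .physiology import ThermalTrace
from .spectra import WAVELENGTH_GRID, ReflectanceSpectrum
from .synthetic import Cohort, Individual

INPUT_FILES = {
    "individuals": "individuals.csv",
    "traces": "traces.csv",
    "tracks": "tracks.csv",
    "calibrations": "calibrations.csv",
    "spectra": "spectra.csv",
}


def individuals_frame(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [i.id for i in cohort.individuals],
            "species": [i.species for i in cohort.individuals],
            "sex": [i.sex for i in cohort.individuals],
            "morph": [i.morph for i in cohort.individuals],
            "mass_g": [i.mass_g for i in cohort.individuals],
        }
    )


def traces_frame(cohort: Cohort) -> pd.DataFrame:
    parts = []
    for (ind_id, channel), trace in cohort.traces.items():
        parts.append(
            pd.DataFrame(
                {
                    "individual_id": ind_id,
                    "channel": channel,
                    "time_s": trace.times_s,
                    "temperature_c": trace.temperatures_c,
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=["individual_id", "channel", "time_s", "temperature_c"]
        )
    return pd.concat(parts, ignore_index=True)


def tracks_frame(cohort: Cohort) -> pd.DataFrame:
    parts = []
    for ind_id, track in cohort.tracks.items():
        parts.append(
            pd.DataFrame(
                {
                    "individual_id": ind_id,
                    "runway_id": track.runway_id,
                    "time_min": track.times_min,
                    "position_cm": track.positions_cm,
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=["individual_id", "runway_id", "time_min", "position_cm"]
        )
    return pd.concat(parts, ignore_index=True)


def calibrations_frame(cohort: Cohort) -> pd.DataFrame:
    parts = []
    for runway_id in sorted(cohort.calibrations):
        cal = cohort.calibrations[runway_id]
        parts.append(
            pd.DataFrame(
                {
                    "runway_id": runway_id,
                    "position_cm": cal.positions_cm,
                    "temperature_c": cal.temperatures_c,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=["runway_id", "position_cm", "temperature_c"])
    return pd.concat(parts, ignore_index=True)


def spectra_frame(cohort: Cohort) -> pd.DataFrame:
    parts = []
    for ind_id in sorted(cohort.spectra):
        for spec in cohort.spectra[ind_id]:
            parts.append(
                pd.DataFrame(
                    {
                        "individual_id": ind_id,
                        "body_part": spec.body_part,
                        "replicate": spec.replicate,
                        "wavelength_nm": WAVELENGTH_GRID,
                        "reflectance_pct": spec.reflectance_pct,
                    }
                )
            )
    if not parts:
        return pd.DataFrame(
            columns=[
                "individual_id",
                "body_part",
                "replicate",
                "wavelength_nm",
                "reflectance_pct",
            ]
        )
    return pd.concat(parts, ignore_index=True)


def write_cohort(cohort: Cohort, out_dir, write_spectra: bool = True) -> dict:
    """Write the four/five input CSVs plus the true-parameter JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    frames = {
        "individuals": individuals_frame(cohort),
        "traces": traces_frame(cohort),
        "tracks": tracks_frame(cohort),
        "calibrations": calibrations_frame(cohort),
    }
    if write_spectra:
        frames["spectra"] = spectra_frame(cohort)
    for key, frame in frames.items():
        path = out_dir / INPUT_FILES[key]
        frame.to_csv(path, index=False)
        written[key] = str(path)
    sidecar = {
        ind_id: dataclasses.asdict(params)
        for ind_id, params in cohort.true_params.items()
    }
    sidecar_path = out_dir / "true_params.json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)
    written["true_params"] = str(sidecar_path)
    return written


def read_individuals(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str})
    required = {"individual_id", "species", "sex", "morph", "mass_g"}
    _require_columns(df, required, path)
    return df


def read_traces(path) -> dict:
    """Return {(individual_id, channel): ThermalTrace}."""
    df = pd.read_csv(path, dtype={"individual_id": str})
    _require_columns(df, {"individual_id", "channel", "time_s", "temperature_c"}, path)
    traces = {}
    for (ind_id, channel), grp in df.groupby(["individual_id", "channel"], sort=False):
        grp = grp.sort_values("time_s")
        traces[(ind_id, channel)] = ThermalTrace(
            individual_id=ind_id,
            channel=channel,
            times_s=grp["time_s"].to_numpy(),
            temperatures_c=grp["temperature_c"].to_numpy(),
        )
    return traces


def read_tracks(path) -> dict:
    """Return {individual_id: GradientTrack} (empty position cell = missing)."""
    df = pd.read_csv(path, dtype={"individual_id": str, "runway_id": str})
    _require_columns(df, {"individual_id", "runway_id", "time_min", "position_cm"}, path)
    tracks = {}
    for ind_id, grp in df.groupby("individual_id", sort=False):
        grp = grp.sort_values("time_min")
        runways = grp["runway_id"].unique()
        if len(runways) != 1:
            raise ValueError(f"individual {ind_id} spans multiple runways: {runways}")
        tracks[ind_id] = GradientTrack(
            individual_id=ind_id,
            runway_id=runways[0],
            times_min=grp["time_min"].to_numpy(),
            positions_cm=grp["position_cm"].to_numpy(dtype=float),
        )
    return tracks


def read_calibration_points(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"runway_id": str})
    _require_columns(df, {"runway_id", "position_cm", "temperature_c"}, path)
    return df


def read_spectra(path) -> dict:
    """Return {individual_id: [ReflectanceSpectrum]}; validates the 1 nm grid."""
    df = pd.read_csv(path, dtype={"individual_id": str})
    _require_columns(
        df,
        {"individual_id", "body_part", "replicate", "wavelength_nm", "reflectance_pct"},
        path,
    )
    spectra: dict = {}
    keys = ["individual_id", "body_part", "replicate"]
    for (ind_id, part, rep), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("wavelength_nm")
        wl = grp["wavelength_nm"].to_numpy()
        if wl.size != WAVELENGTH_GRID.size or not np.array_equal(wl, WAVELENGTH_GRID):
            raise ValueError(
                f"spectrum ({ind_id}, {part}, {rep}) is not on the 300-1000 nm grid"
            )
        spectra.setdefault(ind_id, []).append(
            ReflectanceSpectrum(
                individual_id=ind_id,
                body_part=part,
                replicate=int(rep),
                reflectance_pct=grp["reflectance_pct"].to_numpy(),
            )
        )
    return spectra


def load_cohort(in_dir) -> Cohort:
    """Rebuild a Cohort from the input CSV directory (spectra optional)."""
    from .gradient import fit_calibration

    in_dir = Path(in_dir)
    cohort = Cohort()
    inds = read_individuals(in_dir / INPUT_FILES["individuals"])
    for row in inds.itertuples(index=False):
        cohort.individuals.append(
            Individual(
                id=row.individual_id,
                species=row.species,
                sex=row.sex,
                morph=row.morph,
                mass_g=float(row.mass_g),
            )
        )
    cohort.traces = read_traces(in_dir / INPUT_FILES["traces"])
    cohort.tracks = read_tracks(in_dir / INPUT_FILES["tracks"])
    cal_points = read_calibration_points(in_dir / INPUT_FILES["calibrations"])
    for runway_id, grp in cal_points.groupby("runway_id"):
        cohort.calibrations[runway_id] = fit_calibration(
            grp["position_cm"].to_numpy(),
            grp["temperature_c"].to_numpy(),
            runway_id=runway_id,
        )
    spectra_path = in_dir / INPUT_FILES["spectra"]
    if spectra_path.exists():
        cohort.spectra = read_spectra(spectra_path)
    return cohort


def _require_columns(df: pd.DataFrame, required: set, path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
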