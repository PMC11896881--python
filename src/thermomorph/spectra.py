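"""Reflectance spectra processing.

Raw spectra (five dorsal + five lateral replicates per individual, percent
reflectance relative to a white standard on a fixed 1 nm grid from 300 to
1000 nm) are artefact-corrected, averaged into one mean spectrum per
individual, and summarised as mean brightness over the whole grid.

The spectrometer artefact is a narrow positive spike between 654 and 659 nm;
samples strictly inside that band (655-658 nm) are replaced by the mean of
the flanking bands 650-654 and 659-664 nm (all inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "WAVELENGTH_GRID",
    "ARTEFACT_BAND_NM",
    "FLANK_BANDS_NM",
    "ReflectanceSpectrum",
    "MeanSpectrum",
    "BrightnessSummary",
    "resample_to_grid",
    "correct_artefact",
    "aggregate_spectra",
    "mean_brightness",
    "process_individual",
]

WAVELENGTH_GRID = np.arange(300, 1001)  # 701 samples, 1 nm step
ARTEFACT_BAND_NM = (655, 658)  # replaced samples (inclusive)
FLANK_BANDS_NM = ((650, 654), (659, 664))  # trusted flank samples (inclusive)

DORSAL = "dorsal_pronotum"
LATERAL = "lateral_lobe"
BODY_PARTS = (DORSAL, LATERAL)


def _band_indices(lo: int, hi: int) -> np.ndarray:
    idx = np.nonzero((WAVELENGTH_GRID >= lo) & (WAVELENGTH_GRID <= hi))[0]
    if idx.size != hi - lo + 1:
        raise ValueError(f"grid does not cover the {lo}-{hi} nm band")
    return idx


@dataclass
class ReflectanceSpectrum:
    """One raw reflectance measurement on the fixed wavelength grid."""

    individual_id: str
    body_part: str
    replicate: int
    reflectance_pct: np.ndarray

    def __post_init__(self) -> None:
        self.reflectance_pct = np.asarray(self.reflectance_pct, dtype=float)
        if self.reflectance_pct.shape != WAVELENGTH_GRID.shape:
            raise ValueError(
                f"expected {WAVELENGTH_GRID.size} samples, got "
                f"{self.reflectance_pct.size}"
            )
        if not np.all(np.isfinite(self.reflectance_pct)):
            raise ValueError("reflectance must be finite")
        if np.any(self.reflectance_pct < 0):
            raise ValueError("reflectance must be >= 0")

    @property
    def wavelength_nm(self) -> np.ndarray:
        return WAVELENGTH_GRID


@dataclass
class MeanSpectrum:
    """Per-individual mean of artefact-corrected replicates."""

    individual_id: str
    reflectance_pct: np.ndarray
    n_spectra: int

    @property
    def wavelength_nm(self) -> np.ndarray:
        return WAVELENGTH_GRID


@dataclass
class BrightnessSummary:
    individual_id: str
    brightness_pct: float
    n_spectra_used: int


def resample_to_grid(wavelength_nm: np.ndarray, reflectance_pct: np.ndarray) -> np.ndarray:
    """Linearly interpolate an arbitrary-grid spectrum onto the 1 nm grid.

    The input grid must cover 300-1000 nm (no extrapolation).
    """
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    reflectance_pct = np.asarray(reflectance_pct, dtype=float)
    order = np.argsort(wavelength_nm)
    wavelength_nm, reflectance_pct = wavelength_nm[order], reflectance_pct[order]
    if wavelength_nm[0] > WAVELENGTH_GRID[0] or wavelength_nm[-1] < WAVELENGTH_GRID[-1]:
        raise ValueError("input grid does not cover 300-1000 nm")
    return np.interp(WAVELENGTH_GRID, wavelength_nm, reflectance_pct)


def correct_artefact(spectrum: ReflectanceSpectrum) -> ReflectanceSpectrum:
    """Replace the 655-658 nm samples by the scalar mean of the flank bands.

    Idempotent: the flank samples themselves are never modified.
    """
    artefact_idx = _band_indices(*ARTEFACT_BAND_NM)
    flank_idx = np.concatenate([_band_indices(lo, hi) for lo, hi in FLANK_BANDS_NM])
    corrected = spectrum.reflectance_pct.copy()
    corrected[artefact_idx] = corrected[flank_idx].mean()
    return replace(spectrum, reflectance_pct=corrected)


def aggregate_spectra(spectra: list[ReflectanceSpectrum]) -> MeanSpectrum:
    """Pointwise mean across all replicates (both body parts) of one individual."""
    if not spectra:
        raise ValueError("cannot aggregate an empty list of spectra")
    ids = {s.individual_id for s in spectra}
    if len(ids) != 1:
        raise ValueError(f"spectra from multiple individuals: {sorted(ids)}")
    stack = np.stack([s.reflectance_pct for s in spectra])
    return MeanSpectrum(
        individual_id=spectra[0].individual_id,
        reflectance_pct=stack.mean(axis=0),
        n_spectra=len(spectra),
    )


def mean_brightness(spectrum) -> float:
    """Arithmetic mean reflectance over the full 300-1000 nm grid (percent)."""
    values = np.asarray(
        getattr(spectrum, "reflectance_pct", spectrum), dtype=float
    )
    if values.shape != WAVELENGTH_GRID.shape:
        raise ValueError("spectrum is not on the 300-1000 nm grid")
    if not np.all(np.isfinite(values)):
        raise ValueError("reflectance must be finite")
    return float(values.mean())


def process_individual(
    spectra: list[ReflectanceSpectrum],
) -> tuple[MeanSpectrum, BrightnessSummary]:
    """Artefact-correct every replicate, average, and summarise brightness."""
    corrected = [correct_artefact(s) for s in spectra]
    mean_spec = aggregate_spectra(corrected)
    summary = BrightnessSummary(
        individual_id=mean_spec.individual_id,
        brightness_pct=mean_brightness(mean_spec),
        n_spectra_used=mean_spec.n_spectra,
    )
    return mean_spec, summary
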