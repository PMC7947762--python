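"""Core spectral containers and tabular I/O.

Every downstream stage (binding analysis, photoconversion kinetics,
melting-curve extraction) consumes :class:`Spectrum`, :class:`TitrationSeries`
or :class:`TimeCourse` objects built here.  Units are fixed package-wide:
wavelengths in nm, concentrations in µM, temperatures in °C, path lengths in
cm, times in s.  Absorbance is in AU; fluorescence channels are in arbitrary
units.

The on-disk format is a wide matrix: first column ``wavelength_nm``, one
column per sample (header row = sample ids), comma- or tab-delimited with
``.`` as decimal point.  Per-sample metadata (concentration, pH, temperature,
time) travels in a JSON sidecar keyed by sample id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SpectralParseError, ValidationError

__all__ = [
    "SpectrumKind",
    "Spectrum",
    "TitrationSeries",
    "TimeCourse",
    "read_spectral_table",
    "write_spectral_table",
    "read_metadata_sidecar",
    "resample_to_common_grid",
]


class SpectrumKind(str, Enum):
    ABSORBANCE = "absorbance"
    FLUORESCENCE_RATIO = "fluorescence_ratio"
    WHOLE_CELL = "whole_cell"


@dataclass
class Spectrum:
    """A single spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths
        Grid in nm, strictly increasing, length >= 2.
    values
        Absorbance (AU) or fluorescence (a.u.); same length as the grid.
    kind
        What the values represent.
    meta
        Free-form metadata (sample id, conc_uM, pH, temp_C, time_s, ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = SpectrumKind.ABSORBANCE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if isinstance(self.kind, str):
            self.kind = SpectrumKind(self.kind)
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ValidationError("wavelengths and values must be 1-D")
        if self.wavelengths.size != self.values.size:
            raise ValidationError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.values.size} values"
            )
        if self.wavelengths.size < 2:
            raise ValidationError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.wavelengths)) or not np.all(
            np.isfinite(self.values)
        ):
            raise ValidationError("non-finite entries in spectrum")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.wavelengths.size

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated value at ``wavelength`` (no extrapolation)."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength <= hi):
            raise ValidationError(
                f"{wavelength} nm outside measured range [{lo}, {hi}] nm"
            )
        return float(np.interp(wavelength, self.wavelengths, self.values))

    def copy_with(self, values: np.ndarray, **meta) -> "Spectrum":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Spectrum(self.wavelengths.copy(), np.asarray(values, float),
                        self.kind, new_meta)


@dataclass
class TitrationSeries:
    """Spectral titration: one spectrum per apo-protein concentration at a
    fixed pigment concentration.

    ``protein_conc`` is [A] in µM (the binding partner is the NADPH-saturated
    apo-protein), ``pigment_conc`` is the fixed [B] in µM.
    """

    spectra: list[Spectrum]
    protein_conc: np.ndarray
    pigment_conc: float
    path_length: float = 1.0

    def __post_init__(self) -> None:
        self.protein_conc = np.asarray(self.protein_conc, dtype=float)
        if len(self.spectra) != self.protein_conc.size:
            raise ValidationError("one protein concentration per spectrum required")
        if np.any(self.protein_conc < 0):
            raise ValidationError("protein concentrations must be >= 0")
        if self.pigment_conc <= 0:
            raise ValidationError("pigment concentration must be > 0")
        if self.path_length <= 0:
            raise ValidationError("path length must be > 0")
        grids = [s.wavelengths for s in self.spectra]
        if not all(np.array_equal(grids[0], g) for g in grids[1:]):
            self.spectra = resample_to_common_grid(self.spectra)

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    def sorted_by_concentration(self) -> "TitrationSeries":
        order = np.argsort(self.protein_conc, kind="stable")
        return TitrationSeries(
            [self.spectra[i] for i in order],
            self.protein_conc[order],
            self.pigment_conc,
            self.path_length,
        )


@dataclass
class TimeCourse:
    """Pulsed-illumination photoconversion time course.

    ``a672`` is the absorbance of the chlorophyllide product band; frames
    recorded during (or adjacent to) a light pulse are flagged in
    ``illumination_mask`` and typically carry a broadband artifact.
    """

    times: np.ndarray
    a672: np.ndarray
    illumination_mask: np.ndarray
    spectra: list[Spectrum] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a672 = np.asarray(self.a672, dtype=float)
        self.illumination_mask = np.asarray(self.illumination_mask, dtype=bool)
        n = self.times.size
        if self.a672.size != n or self.illumination_mask.size != n:
            raise ValidationError("times, a672 and illumination_mask must align")
        if self.spectra is not None and len(self.spectra) != n:
            raise ValidationError("one spectrum per frame required")
        if n and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def subset(self, keep: np.ndarray) -> "TimeCourse":
        keep = np.asarray(keep)
        return TimeCourse(
            self.times[keep],
            self.a672[keep],
            self.illumination_mask[keep],
            [s for s, k in zip(self.spectra, keep) if k] if self.spectra else None,
        )


# ---------------------------------------------------------------------------
# tabular I/O


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_spectral_table(path, kind: SpectrumKind | str = SpectrumKind.ABSORBANCE,
                        layout: str = "wide") -> list[Spectrum]:
    """Read a wide spectral matrix (first column wavelength in nm, one
    column per sample) into a list of :class:`Spectrum`.

    Delimiter is auto-detected among comma and tab.  Non-numeric cells and
    non-monotone wavelength grids are rejected with a located error.
    """
    if layout != "wide":
        raise ValidationError(f"unsupported layout {layout!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.shape[1] < 2:
        raise SpectralParseError(f"{path}: need a wavelength column plus >=1 sample")
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise SpectralParseError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at data row {r + 1}, "
            f"column {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise SpectralParseError(
            f"{path}: missing value at data row {r + 1}, column {raw.columns[c]!r}"
        )
    wl = numeric.iloc[:, 0].to_numpy()
    if not np.all(np.diff(wl) > 0):
        raise ValidationError(f"{path}: wavelength column not strictly increasing")
    out = []
    for col in numeric.columns[1:]:
        out.append(
            Spectrum(wl, numeric[col].to_numpy(), kind, {"sample_id": str(col)})
        )
    return out


def write_spectral_table(path, spectra: Sequence[Spectrum], sep: str = ",") -> None:
    """Write spectra sharing a grid as a wide matrix (inverse of the reader)."""
    spectra = list(spectra)
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, grid):
            raise ValidationError("all spectra must share one grid; resample first")
    data = {"wavelength_nm": grid}
    for i, s in enumerate(spectra):
        data[str(s.meta.get("sample_id", f"sample_{i}"))] = s.values
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_metadata_sidecar(path) -> dict:
    """Read the JSON sidecar {sample_id: {conc_uM, pH, temp_C, time_s, ...}}."""
    with open(path) as fh:
        meta = json.load(fh)
    if not isinstance(meta, dict):
        raise SpectralParseError(f"{path}: sidecar must be a JSON object")
    return meta


def resample_to_common_grid(spectra: Sequence[Spectrum]) -> list[Spectrum]:
    """Linearly interpolate all spectra onto the intersection of their ranges,
    sampled on the first spectrum's grid.  Extrapolation is forbidden; disjoint
    ranges raise.
    """
    spectra = list(spectra)
    lo = max(s.wavelengths[0] for s in spectra)
    hi = min(s.wavelengths[-1] for s in spectra)
    if lo > hi:
        raise ValidationError("spectra cover disjoint wavelength ranges")
    base = spectra[0].wavelengths
    grid = base[(base >= lo) & (base <= hi)]
    if grid.size < 2:
        raise ValidationError("wavelength overlap too small to resample")
    out = []
    for s in spectra:
        if np.array_equal(s.wavelengths, grid):
            out.append(s)
        else:
            out.append(
                Spectrum(grid, np.interp(grid, s.wavelengths, s.values),
                         s.kind, dict(s.meta))
            )
    return out
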