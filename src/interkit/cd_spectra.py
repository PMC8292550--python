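"""Conversion of raw circular-dichroism signal to molar ellipticity per residue.

theta = CD_signal / (10 * n * p * c)

with the CD signal in mdeg, ``n`` the number of residues, ``p`` the cell
path length in cm and ``c`` the molar protein concentration in mol/L; theta
is reported in deg*cm²/dmol per residue.  The formula is applied to the
instrument signal in mdeg as is; note that some conventions insert an
additional factor of 1000 (mdeg→deg) — results differ accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = ["CDSpectrum", "molar_ellipticity", "convert_spectrum"]


def molar_ellipticity(raw_cd, n: float, p: float, c: float):
    """theta = raw_cd / (10 * n * p * c), elementwise over a spectrum.

    Parameters
    ----------
    raw_cd : float or array
        Instrument CD signal, mdeg.
    n : int
        Number of residues.
    p : float
        Path length, cm.
    c : float
        Molar concentration, mol/L.

    Raises
    ------
    InvalidParameterError
        If n, p or c is not positive.
    """
    if not (n > 0):
        raise InvalidParameterError(f"n_residues must be > 0, got {n}")
    if not (p > 0):
        raise InvalidParameterError(f"path_length must be > 0, got {p}")
    if not (c > 0):
        raise InvalidParameterError(f"concentration must be > 0, got {c}")
    return np.asarray(raw_cd, dtype=float) / (10.0 * n * p * c) if np.ndim(
        raw_cd
    ) else float(raw_cd) / (10.0 * n * p * c)


@dataclass
class CDSpectrum:
    """Wavelength-indexed raw and converted CD data."""

    wavelength: np.ndarray  # nm
    raw_cd: np.ndarray  # mdeg
    n_residues: int
    path_length: float  # cm
    concentration: float  # mol/L
    theta: np.ndarray | None = None  # deg*cm²/dmol per residue

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.raw_cd = np.asarray(self.raw_cd, dtype=float)
        if self.wavelength.shape != self.raw_cd.shape:
            raise InvalidParameterError("wavelength and raw_cd must share length")
        if not (self.n_residues > 0 and self.path_length > 0 and self.concentration > 0):
            raise InvalidParameterError(
                "n_residues, path_length and concentration must be positive"
            )

    def convert(self) -> "CDSpectrum":
        self.theta = molar_ellipticity(
            self.raw_cd, self.n_residues, self.path_length, self.concentration
        )
        return self


def convert_spectrum(spectrum: CDSpectrum) -> CDSpectrum:
    """Populate ``spectrum.theta`` from its raw signal and metadata."""
    return spectrum.convert()
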