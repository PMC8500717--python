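"""Spectral computations: quantum yield, overlap integral and Forster distance.

The Forster distance of a donor-acceptor pair follows from the donor emission
spectrum F_D(lambda), the acceptor molar absorptivity eps_A(lambda), the donor
quantum yield Q, the refractive index eta and the orientation factor kappa^2:

    J  = Int F_D(l) eps_A(l) l^4 dl / Int F_D(l) dl      [M^-1 cm^-1 nm^4]
    R0 = (C * J * Q * eta^-4 * kappa^2)**(1/6)           [Angstrom]

with the standard scaling constant C = 8.79e-5 A^6 M cm nm^-4 for J in these
units.  Relative quantum yields are measured against a reference standard from
the slopes of integrated emission versus absorbance dilution series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Spectrum",
    "OverlapResult",
    "relative_quantum_yield",
    "overlap_integral",
    "forster_radius",
    "FORSTER_CONSTANT",
]

#: Scaling constant C in R0^6 = C * J * Q * eta^-4 * kappa^2, for J in
#: M^-1 cm^-1 nm^4 and R0 in Angstrom.
FORSTER_CONSTANT = 8.79e-5

DEFAULT_REFRACTIVE_INDEX = 1.33   # aqueous buffer
DEFAULT_KAPPA2 = 2.0 / 3.0        # isotropic orientation average


@dataclass(frozen=True)
class Spectrum:
    """Wavelength-resolved values: emission (a.u.) or absorptivity (1/M/cm)."""

    wavelength: np.ndarray    # nm, strictly increasing
    values: np.ndarray        # >= 0
    kind: str = "emission"    # "emission" | "absorption"

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelength", np.asarray(self.wavelength, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.wavelength) != len(self.values):
            raise ValueError("wavelength and values must be equally long")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("spectral values must be nonnegative")

    def interpolated(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``grid``; zero outside the support."""
        return np.interp(grid, self.wavelength, self.values, left=0.0, right=0.0)


@dataclass(frozen=True)
class OverlapResult:
    """Overlap integral with the inputs that produced a Forster distance."""

    j_overlap: float          # M^-1 cm^-1 nm^4
    r0: float                 # Angstrom
    quantum_yield: float
    refractive_index: float
    kappa2: float


def relative_quantum_yield(sample_slope: float, ref_slope: float,
                           eta_sample: float, eta_ref: float,
                           q_ref: float) -> float:
    """Quantum yield relative to a reference standard.

    ``Q = Q_ref * (slope / slope_ref) * (eta^2 / eta_ref^2)`` where each slope
    is that of integrated emission intensity versus absorbance across a
    dilution series.
    """
    if sample_slope <= 0 or ref_slope <= 0:
        raise ValueError("slopes must be positive")
    return q_ref * (sample_slope / ref_slope) * (eta_sample ** 2 / eta_ref ** 2)


def overlap_integral(donor_emission: Spectrum, acceptor_absorption: Spectrum
                     ) -> float:
    """Normalized spectral overlap J in M^-1 cm^-1 nm^4.

    Both spectra are linearly interpolated onto the finer of the two grids
    restricted to the common support (no extrapolation); the numerator is
    integrated there and the normalization over the full donor emission, both
    by the trapezoid rule.  Disjoint supports give J = 0 with a warning.
    """
    lo = max(donor_emission.wavelength[0], acceptor_absorption.wavelength[0])
    hi = min(donor_emission.wavelength[-1], acceptor_absorption.wavelength[-1])
    denom = np.trapezoid(donor_emission.values, donor_emission.wavelength)
    if denom <= 0:
        raise ValueError("donor emission spectrum integrates to zero")
    if lo >= hi:
        warnings.warn("donor emission and acceptor absorption do not overlap; J = 0")
        return 0.0
    step = min(float(np.min(np.diff(donor_emission.wavelength))),
               float(np.min(np.diff(acceptor_absorption.wavelength))))
    grid = np.arange(lo, hi + 0.5 * step, step)
    f_d = donor_emission.interpolated(grid)
    eps = acceptor_absorption.interpolated(grid)
    num = np.trapezoid(f_d * eps * grid ** 4, grid)
    return float(num / denom)


def forster_radius(j: float, q: float, eta: float = DEFAULT_REFRACTIVE_INDEX,
                   kappa2: float = DEFAULT_KAPPA2) -> float:
    """Forster distance R0 = (C * J * Q * eta^-4 * kappa^2)**(1/6) in Angstrom.

    An uncertainty of kappa^2 over [1/3, 4/3] (mixed-polarization bound when
    one probe is immobile) moves R0 by at most about +/-11%.
    """
    if min(j, q, eta, kappa2) <= 0:
        raise ValueError("all inputs must be positive")
    return (FORSTER_CONSTANT * j * q * kappa2 / eta ** 4) ** (1.0 / 6.0)


def overlap_and_radius(donor_emission: Spectrum, acceptor_absorption: Spectrum,
                       q: float, eta: float = DEFAULT_REFRACTIVE_INDEX,
                       kappa2: float = DEFAULT_KAPPA2) -> OverlapResult:
    """Convenience wrapper computing J and R0 in one call."""
    j = overlap_integral(donor_emission, acceptor_absorption)
    r0 = forster_radius(j, q, eta, kappa2) if j > 0 else 0.0
    return OverlapResult(j, r0, q, eta, kappa2)
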