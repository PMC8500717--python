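"""Model-independent phasor analysis of fluorescence lifetime data.

A response at one modulation frequency maps to the Cartesian point
``(D, N) = (m cos(phi), m sin(phi))``.  Single-exponential decays fall on the
"universal circle" of radius 1/2 centered at (1/2, 0); any intensity-weighted
mixture of two lifetime signatures falls on the straight chord between the two
parent points, and its fractional position along that chord is the intensity
fraction of the second parent.  This gives a two-state occupancy estimate that
needs no assumption about the decay model or distance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fd_model import FrequencyResponse

__all__ = [
    "PhasorPoint",
    "to_phasor",
    "universal_circle_residual",
    "chord_fraction",
    "centroid",
    "population_from_intensity_fraction",
]

#: Phasor analysis frequency used throughout unless stated otherwise (MHz),
#: matching the fundamental repetition rate of pulsed FLIM instruments.
DEFAULT_PHASOR_FREQUENCY = 10.0


@dataclass(frozen=True)
class PhasorPoint:
    """(D, N) coordinates at one modulation frequency."""

    frequency: float     # MHz
    d: float             # real component, m*cos(phi)
    n: float             # imaginary component, m*sin(phi)
    group: str | None = None

    @classmethod
    def from_polar(cls, frequency: float, phase_deg: float, modulation: float,
                   group: str | None = None) -> "PhasorPoint":
        phi = np.radians(phase_deg)
        return cls(frequency, float(modulation * np.cos(phi)),
                   float(modulation * np.sin(phi)), group)

    @classmethod
    def from_lifetime(cls, frequency: float, tau_ns: float,
                      group: str | None = None) -> "PhasorPoint":
        """Phasor of a single-exponential decay (always on the universal circle)."""
        w = 2.0 * np.pi * frequency * 1e-3
        wt = w * tau_ns
        return cls(frequency, 1.0 / (1.0 + wt ** 2), wt / (1.0 + wt ** 2), group)


def to_phasor(response: FrequencyResponse, frequency: float = DEFAULT_PHASOR_FREQUENCY,
              group: str | None = None) -> PhasorPoint:
    """Phasor coordinates of a (corrected) response at one frequency."""
    phase_deg, modulation = response.at(frequency)
    return PhasorPoint.from_polar(frequency, phase_deg, modulation, group)


def universal_circle_residual(point: PhasorPoint) -> float:
    """Signed distance from the universal circle.

    Zero for single-exponential decays, negative (inside the circle) for
    multi- or non-exponential decays.
    """
    return float(np.hypot(point.d - 0.5, point.n) - 0.5)


def chord_fraction(point: PhasorPoint, parent_a: PhasorPoint,
                   parent_b: PhasorPoint) -> tuple[float, float]:
    """Fractional position of ``point`` along the chord parent_a -> parent_b.

    The point is orthogonally projected onto the segment; the fraction is
    clamped to [0, 1].  Returns ``(fraction, off_chord_distance)`` so callers
    can judge how far the point actually was from the mixing line.
    """
    if not np.isclose(point.frequency, parent_a.frequency) or \
       not np.isclose(point.frequency, parent_b.frequency):
        raise ValueError("phasor points must share a modulation frequency")
    a = np.array([parent_a.d, parent_a.n])
    b = np.array([parent_b.d, parent_b.n])
    p = np.array([point.d, point.n])
    ab = b - a
    norm2 = float(np.dot(ab, ab))
    if norm2 < 1e-24:
        raise ValueError("parent phasors coincide; chord is degenerate")
    t = float(np.dot(p - a, ab) / norm2)
    t_clamped = min(1.0, max(0.0, t))
    off = float(np.linalg.norm(p - (a + t * ab)))
    return t_clamped, off


def centroid(points: list[PhasorPoint]) -> PhasorPoint:
    """Arithmetic mean of per-pixel phasor coordinates."""
    if not points:
        raise ValueError("cannot take the centroid of no points")
    freq = points[0].frequency
    if any(not np.isclose(p.frequency, freq) for p in points):
        raise ValueError("all points must share a modulation frequency")
    return PhasorPoint(freq, float(np.mean([p.d for p in points])),
                       float(np.mean([p.n for p in points])),
                       group=points[0].group)


def population_from_intensity_fraction(intensity_fraction: float,
                                       rel_intensity_a: float,
                                       rel_intensity_b: float) -> float:
    """Convert an intensity-weighted mixing fraction to a population fraction.

    The chord fraction weights each state by its brightness (its relative
    steady-state intensity, e.g. the per-population normalization J from a
    fitted model).  If state b is dimmer than state a, equal populations sit
    closer to a on the chord; this inverts that weighting:

        p_b / p_a = (x / (1 - x)) * (I_a / I_b)
    """
    if not 0.0 < intensity_fraction < 1.0:
        return float(intensity_fraction)
    if rel_intensity_a <= 0 or rel_intensity_b <= 0:
        raise ValueError("relative intensities must be positive")
    ratio = (intensity_fraction / (1.0 - intensity_fraction)) * (
        rel_intensity_a / rel_intensity_b)
    return ratio / (1.0 + ratio)
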