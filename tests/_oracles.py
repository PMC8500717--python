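"""Independent numerical oracles used by the tests.

These deliberately avoid the package's frequency-domain code path: the decay
is simulated in the time domain on a fine grid and its phase/modulation are
extracted by direct numerical Fourier integrals.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def time_domain_phase_modulation(tau, alpha, r0, gaussians, f_d,
                                 frequencies_mhz,
                                 dt: float = 0.02, t_max: float = 400.0):
    """Phase (deg) and modulation of a FRET-quenched decay, via the time domain.

    ``gaussians`` is a list of (mean, sd, amplitude) distance components with
    amplitudes summing to 1; ``f_d`` is the zero-FRET donor-only fraction.
    The intensity decay I(t) is accumulated over a fine distance grid per
    component (truncated at [max(0.01, mean - 6 sd), mean + 6 sd] and
    renormalized) and transformed with trapezoidal sine/cosine integrals.
    """
    t = np.arange(0.0, t_max, dt)
    intensity = np.zeros_like(t)
    tau = np.atleast_1d(np.asarray(tau, float))
    alpha = np.atleast_1d(np.asarray(alpha, float))
    for mean, sd, amp in gaussians:
        lo, hi = max(0.01, mean - 6 * sd), mean + 6 * sd
        r = np.linspace(lo, hi, 1501)
        p = norm.pdf(r, mean, sd)
        p /= np.trapezoid(p, r)
        # trapezoid weights over r, folded with the density
        wr = np.full_like(r, r[1] - r[0])
        wr[0] *= 0.5
        wr[-1] *= 0.5
        for c in range(len(tau)):
            tau_da = tau[c] / (1.0 + (r0 / r) ** 6)
            rate = 1.0 / tau_da
            # chunk over time to bound memory
            for start in range(0, len(t), 4000):
                tt = t[start:start + 4000]
                block = np.exp(-np.outer(rate, tt))
                intensity[start:start + 4000] += (
                    (1.0 - f_d) * amp * alpha[c] * (wr * p) @ block)
    if f_d > 0:
        for c in range(len(tau)):
            intensity += f_d * alpha[c] * np.exp(-t / tau[c])

    total = np.trapezoid(intensity, t)
    phases, mods = [], []
    for f in np.atleast_1d(frequencies_mhz):
        w = 2 * np.pi * f * 1e-3
        n = np.trapezoid(intensity * np.sin(w * t), t) / total
        d = np.trapezoid(intensity * np.cos(w * t), t) / total
        phases.append(np.degrees(np.arctan2(n, d)))
        mods.append(np.hypot(n, d))
    return np.asarray(phases), np.asarray(mods)
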