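"""Steady-state quenching analysis.

Metal-ion FRET acceptors are applied to a cuvette mid-recording, so the raw
observable is a fluorescence time course with reagent-addition events.  The
fraction of fluorescence left unquenched after an addition, corrected with a
no-acceptor-site control for nonspecific losses, gives the FRET efficiency

    E = 1 - F_with_site / F_without_site

whose uncertainty is propagated by Monte-Carlo resampling of the measured
means and standard errors.  The module also provides the Forster inversion
``R = R0 * (1/E - 1)**(1/6)``, single-exponential photobleach fits, and Hill
fits of dose-response data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TimeCourse",
    "FractionStats",
    "WindowSpec",
    "fraction_unquenched",
    "fret_efficiency_corrected",
    "forster_invert",
    "exp_decay_fit",
    "hill_fit",
]


@dataclass(frozen=True)
class TimeCourse:
    """Intensity trace with reagent-addition annotations."""

    time: np.ndarray                                   # s, strictly increasing
    intensity: np.ndarray                              # arbitrary units, >= 0
    events: tuple[tuple[float, str], ...] = ()         # (time_s, reagent label)

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if len(self.time) != len(self.intensity):
            raise ValueError("time and intensity must be equally long")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")

    def event_time(self, label: str) -> float:
        for t, lab in self.events:
            if lab == label:
                return t
        raise KeyError(f"no event labelled {label!r}")


@dataclass(frozen=True)
class FractionStats:
    """Mean fraction unquenched with its standard error (and optional n)."""

    mean: float
    sem: float = 0.0
    n: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.mean <= 1.2:   # small >1 drift tolerated
            raise ValueError("fraction must lie in (0, 1.2]")


@dataclass(frozen=True)
class WindowSpec:
    """Averaging windows around a reagent addition.

    Mixing after a manual addition settles in under ~10 s, so by default the
    'after' window skips the first two samples following the event (samples
    3-8) while the 'before' window takes the last five samples preceding it.
    """

    n_before: int = 5
    skip_after: int = 2
    n_after: int = 6


def fraction_unquenched(trace: TimeCourse, event: str,
                        window: WindowSpec = WindowSpec(),
                        background: float = 0.0) -> FractionStats:
    """Fraction of fluorescence remaining after a reagent addition.

    ``F = mean(intensity after) / mean(intensity before)`` with the optional
    constant ``background`` subtracted from both windows first.
    """
    t_event = trace.event_time(event)
    before = np.flatnonzero(trace.time < t_event)
    after = np.flatnonzero(trace.time >= t_event)
    before = before[-window.n_before:]
    after = after[window.skip_after:window.skip_after + window.n_after]
    if len(before) < 3 or len(after) < 3:
        raise ValueError("averaging windows must contain at least 3 samples")
    pre = trace.intensity[before] - background
    post = trace.intensity[after] - background
    f = float(np.mean(post) / np.mean(pre))
    # SEM of a ratio of two window means, first order
    se = f * np.sqrt((np.std(post, ddof=1) / np.sqrt(len(post)) / np.mean(post)) ** 2 +
                     (np.std(pre, ddof=1) / np.sqrt(len(pre)) / np.mean(pre)) ** 2)
    return FractionStats(mean=f, sem=float(se), n=len(post))


def fret_efficiency_corrected(f_site: FractionStats, f_no_site: FractionStats,
                              n_cycles: int = 1_000_000, seed: int = 0
                              ) -> tuple[float, float]:
    """FRET efficiency corrected for nonspecific quenching, with uncertainty.

    ``E = 1 - F_site / F_no_site`` where ``f_no_site`` comes from a construct
    lacking the acceptor site.  The standard error is estimated by Monte-Carlo
    resampling (default one million cycles) of the two input means treated as
    Gaussian with their standard errors.
    """
    if f_no_site.mean <= 0:
        raise ValueError("control fraction must be positive")
    e = 1.0 - f_site.mean / f_no_site.mean
    rng = np.random.default_rng(seed)
    site = rng.normal(f_site.mean, f_site.sem, n_cycles)
    ctrl = rng.normal(f_no_site.mean, f_no_site.sem, n_cycles)
    ctrl = np.where(np.abs(ctrl) < 1e-12, 1e-12, ctrl)
    samples = 1.0 - site / ctrl
    return float(e), float(np.std(samples, ddof=1))


def forster_invert(e: float, r0: float) -> float:
    """Distance from efficiency: R = R0 * (1/E - 1)**(1/6).

    Inverse of the single-distance Forster relation E(r) = 1/(1 + (r/R0)**6);
    strictly decreasing in E on (0, 1).
    """
    if not 0.0 < e < 1.0:
        raise ValueError("efficiency must lie strictly between 0 and 1")
    if r0 <= 0:
        raise ValueError("Forster distance must be positive")
    return r0 * (1.0 / e - 1.0) ** (1.0 / 6.0)


@dataclass(frozen=True)
class DecayFit:
    tau: float
    tau_se: float
    amplitude: float
    offset: float
    flagged: bool = False


def exp_decay_fit(trace: TimeCourse) -> DecayFit:
    """Least-squares fit of A*exp(-t/tau) + C to a photobleaching trace."""
    if len(trace.time) < 10:
        raise ValueError("need at least 10 points for a decay fit")
    t, y = trace.time, trace.intensity
    c0 = float(np.min(y))
    a0 = float(y[0] - c0)
    flagged = False
    if a0 <= 0:   # non-decaying trace
        a0 = max(abs(a0), 1e-6)
        flagged = True
    tau0 = float(t[-1] - t[0]) / 3.0

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    popt, pcov = curve_fit(model, t, y, p0=(a0, tau0, c0),
                           bounds=([0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                           maxfev=20000)
    tau_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.inf
    return DecayFit(tau=float(popt[1]), tau_se=tau_se, amplitude=float(popt[0]),
                    offset=float(popt[2]), flagged=flagged)


@dataclass(frozen=True)
class HillFit:
    k_half: float
    k_half_se: float
    slope: float
    slope_se: float
    flagged: bool = False


def hill_fit(doses: np.ndarray, response: np.ndarray,
             fix_max: bool = True) -> HillFit:
    """Hill-equation fit of dose-response data.

    Fits ``resp = x**h / (x**h + K**h)`` (maximal response fixed at 1, the
    convention when the response is a fraction such as an occupancy); with
    ``fix_max=False`` a free amplitude is fit as well.
    """
    doses = np.asarray(doses, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(doses) < 3:
        raise ValueError("need at least 3 dose points")
    flagged = doses.max() / max(doses[doses > 0].min(), 1e-30) < 3
    k0 = float(np.median(doses[doses > 0]))

    if fix_max:
        def model(x, k, h):
            return x ** h / (x ** h + k ** h)
        p0, lb, ub = (k0, 1.0), (1e-12, 0.1), (np.inf, 10.0)
    else:
        def model(x, k, h, amp):
            return amp * x ** h / (x ** h + k ** h)
        p0, lb, ub = (k0, 1.0, 1.0), (1e-12, 0.1, 0.0), (np.inf, 10.0, 2.0)

    popt, pcov = curve_fit(model, doses, response, p0=p0, bounds=(lb, ub),
                           maxfev=20000)
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.inf)
    return HillFit(k_half=float(popt[0]), k_half_se=float(se[0]),
                   slope=float(popt[1]), slope_se=float(se[1]), flagged=bool(flagged))
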