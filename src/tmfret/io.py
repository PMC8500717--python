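"""Readers and writers for the package's interchange formats.

CSV with a header row (and ``#`` comment lines) is the lingua franca for
tabular data; JSON for structured results and configuration.  Writers emit
deterministic output; readers validate and either fail loudly (malformed rows,
wrong schema) or attach warnings (physically suspicious values) rather than
silently accepting corrupt data.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .fd_model import FrequencyResponse
from .fitting import (
    PARAMETER_NAMES,
    ExperimentCondition,
    FitResult,
    FitWeights,
    ParameterVector,
    ProtocolConfig,
    fit_protocol,
)
from .phasor import PhasorPoint
from .spectra import Spectrum
from .steady_state import TimeCourse

__all__ = [
    "ParseError",
    "read_frequency_response",
    "write_frequency_response",
    "read_parameter_vector",
    "write_parameter_vector",
    "read_timecourse",
    "write_timecourse",
    "read_spectrum",
    "write_spectrum",
    "read_phasor_points",
    "write_phasor_points",
    "AnalysisConfig",
    "run_pipeline",
]

logger = logging.getLogger("tmfret")


class ParseError(ValueError):
    """A file failed schema validation; the message names the offending rows."""


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    for col in required:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
        if bad:
            raise ParseError(f"{path}: non-numeric values in column {col!r} "
                             f"at rows {bad}")
        df[col] = pd.to_numeric(df[col])
    return df


def read_frequency_response(path: str | Path) -> FrequencyResponse:
    """Read a frequency-response CSV (frequency_mhz, phase_deg, modulation).

    Frequencies must be ascending; phases outside (0, 90) degrees or
    modulations outside (0, 1] are physically suspicious for a simple decay
    and produce warnings naming the row indices.
    """
    df = _read_csv(path, ("frequency_mhz", "phase_deg", "modulation"))
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")
    freqs = df["frequency_mhz"].to_numpy(float)
    if np.any(np.diff(freqs) <= 0):
        raise ParseError(f"{path}: frequencies must be strictly ascending")
    phase = df["phase_deg"].to_numpy(float)
    mod = df["modulation"].to_numpy(float)
    odd_phase = np.flatnonzero((phase <= 0) | (phase >= 90)).tolist()
    if odd_phase:
        warnings.warn(f"{path}: phase outside (0, 90) degrees at rows {odd_phase}")
    odd_mod = np.flatnonzero((mod <= 0) | (mod > 1)).tolist()
    if odd_mod:
        warnings.warn(f"{path}: modulation outside (0, 1] at rows {odd_mod}")
    kwargs = {}
    if "n" in df.columns and "d" in df.columns:
        kwargs = dict(n=df["n"].to_numpy(float), d=df["d"].to_numpy(float))
    return FrequencyResponse(freqs, phase, mod, **kwargs)


def write_frequency_response(response: FrequencyResponse, path: str | Path) -> None:
    cols = {"frequency_mhz": response.frequencies,
            "phase_deg": response.phase,
            "modulation": response.modulation}
    if response.n is not None and response.d is not None:
        cols.update(n=response.n, d=response.d)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def read_parameter_vector(path: str | Path) -> ParameterVector:
    doc = json.loads(Path(path).read_text())
    unknown = set(doc) - set(PARAMETER_NAMES)
    if unknown:
        raise ParseError(f"{path}: unknown parameters {sorted(unknown)}")
    return ParameterVector.defaults(**doc)


def write_parameter_vector(params: ParameterVector, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.values(), indent=2, sort_keys=True) + "\n")


def read_timecourse(path: str | Path) -> TimeCourse:
    """Read a time-course CSV (time_s, intensity) with an events sidecar JSON."""
    df = _read_csv(path, ("time_s", "intensity"))
    sidecar = Path(path).with_suffix(".events.json")
    events: tuple = ()
    if sidecar.exists():
        events = tuple((float(t), str(lab))
                       for t, lab in json.loads(sidecar.read_text()))
    return TimeCourse(df["time_s"].to_numpy(float),
                      df["intensity"].to_numpy(float), events)


def write_timecourse(trace: TimeCourse, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "intensity": trace.intensity}
                 ).to_csv(path, index=False, float_format="%.10g")
    if trace.events:
        Path(path).with_suffix(".events.json").write_text(
            json.dumps([[t, lab] for t, lab in trace.events]) + "\n")


def read_spectrum(path: str | Path, kind: str = "emission") -> Spectrum:
    df = _read_csv(path, ("wavelength_nm", "value"))
    return Spectrum(df["wavelength_nm"].to_numpy(float),
                    df["value"].to_numpy(float), kind=kind)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind: {spectrum.kind}\n")
        pd.DataFrame({"wavelength_nm": spectrum.wavelength,
                      "value": spectrum.values}
                     ).to_csv(fh, index=False, float_format="%.10g")


def read_phasor_points(path: str | Path) -> list[PhasorPoint]:
    df = _read_csv(path, ("frequency_mhz", "d", "n"))
    groups = df["group"] if "group" in df.columns else [None] * len(df)
    return [PhasorPoint(float(f), float(d), float(n),
                        None if g is None or pd.isna(g) else str(g))
            for f, d, n, g in zip(df["frequency_mhz"], df["d"], df["n"], groups)]


def write_phasor_points(points: list[PhasorPoint], path: str | Path) -> None:
    pd.DataFrame({"frequency_mhz": [p.frequency for p in points],
                  "d": [p.d for p in points],
                  "n": [p.n for p in points],
                  "group": [p.group or "" for p in points]}
                 ).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# pipeline configuration and driver

class ConditionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str
    path: str
    steady_state_e: float | None = None


class WeightsSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    s_phase: float = 0.2
    s_modulation: float = 0.004
    s_efficiency: float = 0.01


class AnalysisConfig(BaseModel):
    """Schema-validated configuration of a staged-fit pipeline run."""

    model_config = ConfigDict(extra="forbid")

    conditions: list[ConditionSpec]
    r0: float = Field(gt=0)
    f_d_acceptor: float = Field(default=0.08, ge=0, le=1)
    weights: WeightsSpec = WeightsSpec()
    n_starts: int = 8
    seed: int = 1234
    output_dir: str = "tmfret_out"
    #: background calibration: either the path of a measured background
    #: response (CSV) or a single-exponential background lifetime in ns
    background_path: str | None = None
    background_tau: float = Field(default=2.5, gt=0)


def _distance_distribution_table(result: FitResult) -> pd.DataFrame:
    from .fd_model import distance_density

    params = result.parameters
    dist = params.distribution()
    r = np.arange(0.5, 40.0, 0.1)
    return pd.DataFrame({"r_angstrom": r, "density": distance_density(dist, r)})


def run_pipeline(config: AnalysisConfig) -> list[FitResult]:
    """Execute the staged-fit protocol described by a validated configuration.

    Reads each condition's frequency response, runs the staged fit in order,
    and writes per-stage fit JSON, distance-distribution CSV curves and a
    phasor CSV into the output directory.  Deterministic for fixed inputs and
    seeds; any stage failure aborts with the stage named.
    """
    from .phasor import DEFAULT_PHASOR_FREQUENCY, to_phasor

    from .fd_model import InstrumentModel

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sequence = []
    for spec in config.conditions:
        response = read_frequency_response(spec.path)
        if config.background_path is not None:
            bg = read_frequency_response(config.background_path)
            background = {float(f): (float(p), float(m)) for f, p, m in
                          zip(bg.frequencies, bg.phase, bg.modulation)}
        else:
            background = InstrumentModel.with_exponential_background(
                0.0, 0.5, response.frequencies,
                config.background_tau).background_phasor
        sequence.append(ExperimentCondition(
            label=spec.label, response=response,
            steady_state_e=spec.steady_state_e,
            background_phasor=background))
    protocol = ProtocolConfig(
        r0=config.r0, f_d_acceptor=config.f_d_acceptor,
        weights=FitWeights(config.weights.s_phase, config.weights.s_modulation,
                           config.weights.s_efficiency),
        n_starts=config.n_starts, seed=config.seed)

    logger.info("starting staged fit: %d conditions, seed %d",
                len(sequence), config.seed)
    try:
        results = fit_protocol(sequence, protocol)
    except Exception as exc:
        raise RuntimeError(f"staged fit failed: {exc}") from exc

    phasor_rows = []
    for condition, result in zip(sequence, results):
        stage = condition.label
        doc = {"condition": stage,
               "parameters": result.parameters.values(),
               "free_parameters": list(result.parameters.free_names()),
               "chi2": result.chi2,
               "reduced_chi2": result.reduced_chi2,
               "n_obs": result.n_obs,
               "converged": result.converged,
               "flags": list(result.flags)}
        (out / f"fit_{stage}.json").write_text(
            json.dumps(doc, indent=2, sort_keys=True) + "\n")
        _distance_distribution_table(result).to_csv(
            out / f"distance_distribution_{stage}.csv", index=False,
            float_format="%.10g")
        try:
            phasor_rows.append(to_phasor(condition.response,
                                         DEFAULT_PHASOR_FREQUENCY, group=stage))
        except KeyError:
            logger.info("condition %s lacks the %s MHz point; no phasor row",
                        stage, DEFAULT_PHASOR_FREQUENCY)
        logger.info("stage %-16s chi2 = %10.2f (reduced %6.2f)",
                    stage, result.chi2, result.reduced_chi2)
    if phasor_rows:
        write_phasor_points(phasor_rows, out / "phasor.csv")

    run_log = {"seed": config.seed, "n_starts": config.n_starts,
               "r0": config.r0, "f_d_acceptor": config.f_d_acceptor,
               "conditions": [spec.label for spec in config.conditions]}
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2,
                                                 sort_keys=True) + "\n")
    return results
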