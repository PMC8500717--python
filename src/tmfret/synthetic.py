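"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: frequency-
domain lifetime datasets (phase/modulation with Gaussian measurement noise),
full five-condition experiment sequences with the correct frozen-parameter
relationships, steady-state fluorescence time courses with reagent additions,
Gaussian-shaped emission/absorption spectra, per-pixel phasor scatters, and
small idealized protein structures for the rotamer sampler.  All generators
are pure functions of (parameters, seed).

``CONSTRUCTS`` collects the measured decay/distance parameter sets of the
benchmark maltose-binding-protein constructs; these are the default study
conditions for parameter-recovery experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .fd_model import (
    DistanceDistribution,
    DonorDecayModel,
    FretPair,
    FrequencyResponse,
    InstrumentModel,
    apparent_efficiency,
    forward_response,
)
from .fitting import ExperimentCondition, ParameterVector
from .phasor import PhasorPoint
from .spectra import Spectrum, forster_radius, overlap_integral
from .steady_state import TimeCourse

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "ConstructTruth",
    "CONSTRUCTS",
    "DEFAULT_FREQUENCIES",
    "generate_fd_dataset",
    "generate_experiment_sequence",
    "generate_phasor_pixels",
    "generate_timecourse",
    "generate_spectra",
    "generate_toy_structure",
]

#: Default modulation-frequency grid (MHz): harmonics of a 10 MHz pulsed source.
DEFAULT_FREQUENCIES = tuple(float(f) for f in range(10, 201, 10))

#: Lifetime of the synthetic background fluorescence (ns), in the 2-3 ns
#: range typical of cellular autofluorescence.
BACKGROUND_TAU = 2.5


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise magnitudes for the synthetic instrument.

    Defaults match the fitting module's default chi-square weights, so fits
    of default-noise data have reduced chi-square near 1.
    """

    s_phase: float = 0.2          # degrees, per frequency
    s_modulation: float = 0.004   # dimensionless, per frequency
    s_efficiency: float = 0.01    # on a steady-state efficiency observation
    intensity_noise: float = 0.005  # fractional, on time-course samples
    pixel_dispersion: float = 0.01  # per-pixel phasor (d, n) scatter

    def __post_init__(self) -> None:
        if min(self.s_phase, self.s_modulation, self.s_efficiency,
               self.intensity_noise, self.pixel_dispersion) < 0:
            raise ValueError("noise magnitudes must be nonnegative")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GroundTruth:
    """The full generating parameter vector, serialized beside every dataset."""

    values: dict[str, float]
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def parameter_vector(self) -> ParameterVector:
        return ParameterVector.defaults(**self.values)

    def to_json(self) -> str:
        return json.dumps({"values": self.values, "noise": asdict(self.noise),
                           "seed": self.seed}, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        doc = json.loads(text)
        return cls(values=doc["values"], noise=NoiseModel(**doc["noise"]),
                   seed=doc["seed"])


@dataclass(frozen=True)
class ConstructTruth:
    """Measured decay and distance-distribution parameters of one construct."""

    tau_d: float                       # donor lifetime, ns
    r0: float                          # Forster distance, Angstrom
    apo: tuple[float, float]           # (mean, sd) open-clamshell Gaussian, A
    holo: tuple[float, float]          # (mean, sd) closed-clamshell Gaussian, A
    f_d: float                         # donor-only fraction with acceptor bound
    a2_by_condition: dict[str, float] = field(default_factory=dict)


#: Benchmark parameter sets.  The MBP constructs place the donor (Acd) at
#: residue 295 (outer clamshell lip) or 322 (back side), with the acceptor a
#: cysteine-reactive Cu(2+)-TETAC or a Cu(2+)-di-histidine site; "free_*" are
#: the unconjugated fluorophores.
CONSTRUCTS: dict[str, ConstructTruth] = {
    "mbp295_tetac": ConstructTruth(
        tau_d=15.6, r0=14.9, apo=(23.7, 6.2), holo=(13.4, 6.5), f_d=0.08),
    "mbp322_tetac": ConstructTruth(
        tau_d=15.1, r0=14.9, apo=(13.6, 5.3), holo=(15.8, 5.5), f_d=0.08),
    "mbp295_dihis": ConstructTruth(
        tau_d=15.5, r0=12.2, apo=(18.3, 2.5), holo=(12.7, 1.3), f_d=0.0,
        a2_by_condition={"0.2mM": 0.38, "0.37mM": 0.60}),
}

#: Free-fluorophore decay models (no acceptor).
FREE_ACD = DonorDecayModel.single(16.0)
FREE_ANAP = DonorDecayModel.double(1.3, 3.3, 0.76)


def _background_table(frequencies) -> dict[float, tuple[float, float]]:
    inst = InstrumentModel.with_exponential_background(
        0.0, 0.5, frequencies, BACKGROUND_TAU)
    return inst.background_phasor


def generate_fd_dataset(truth: GroundTruth,
                        frequencies=DEFAULT_FREQUENCIES,
                        noise: NoiseModel | None = None,
                        seed: int | None = None,
                        ) -> tuple[FrequencyResponse, GroundTruth]:
    """Frequency-domain dataset: forward model plus independent Gaussian noise.

    Phase and modulation noise are drawn independently per frequency (their
    true covariance on a real instrument is unknown; independence is assumed).
    With a zero-noise model the output equals the forward model exactly.
    """
    noise = noise if noise is not None else truth.noise
    seed = seed if seed is not None else truth.seed
    params = truth.parameter_vector()
    instrument = params.instrument(_background_table(frequencies))
    clean = forward_response(params.decay(), params.distribution(),
                             params.pair(), instrument, frequencies)
    if noise.s_phase == 0 and noise.s_modulation == 0:
        return clean, GroundTruth(truth.values, noise, seed)
    rng = np.random.default_rng(seed)
    phase = clean.phase + rng.normal(0.0, noise.s_phase, len(clean))
    modulation = clean.modulation + rng.normal(0.0, noise.s_modulation, len(clean))
    noisy = FrequencyResponse(clean.frequencies, phase, modulation)
    return noisy, GroundTruth(truth.values, noise, seed)


#: Condition labels of a full experiment in measurement order.
SEQUENCE_LABELS = ("donor_only", "acceptor", "acceptor_ligand",
                   "subsaturating", "reversal")


def generate_experiment_sequence(construct: ConstructTruth,
                                 a2_subsaturating: float,
                                 noise: NoiseModel | None = None,
                                 seed: int = 0,
                                 frequencies=DEFAULT_FREQUENCIES,
                                 include_steady_state: bool = True,
                                 ) -> tuple[list[ExperimentCondition], list[GroundTruth]]:
    """Five-condition measurement sequence for one protein sample.

    Emits donor-only, acceptor (apo, A2 = 0), saturating ligand (A2 = 1),
    subsaturating ligand (A2 as given) and reversal conditions.  The donor
    decay, Forster distance and the two state Gaussians are shared across
    conditions, while the nuisance parameters t0 and f_B receive independent
    per-condition jitter (t0 ~ N(0, 0.05 ns), f_B ~ U(0.02, 0.08)) to emulate
    instrument drift between epochs.
    """
    if not 0.0 <= a2_subsaturating <= 1.0:
        raise ValueError("subsaturating occupancy must lie in [0, 1]")
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    background = _background_table(frequencies)

    shared = dict(tau_d1=construct.tau_d, alpha_1=1.0, r0=construct.r0,
                  rbar1=construct.apo[0], sigma1=construct.apo[1],
                  rbar2=construct.holo[0], sigma2=construct.holo[1])
    per_label = {
        "donor_only": dict(f_d=1.0, a2=0.0),
        "acceptor": dict(f_d=construct.f_d, a2=0.0),
        "acceptor_ligand": dict(f_d=construct.f_d, a2=1.0),
        "subsaturating": dict(f_d=construct.f_d, a2=a2_subsaturating),
        "reversal": dict(f_d=1.0, a2=0.0),
    }

    conditions: list[ExperimentCondition] = []
    truths: list[GroundTruth] = []
    for label in SEQUENCE_LABELS:
        values = dict(shared, **per_label[label],
                      t0=float(rng.normal(0.0, 0.05)),
                      f_b=float(rng.uniform(0.02, 0.08)))
        truth = GroundTruth(values=values, noise=noise,
                            seed=int(rng.integers(0, 2**31 - 1)))
        response, _ = generate_fd_dataset(truth, frequencies)
        steady_e = None
        if include_steady_state:
            params = truth.parameter_vector()
            e = apparent_efficiency(params.decay(), params.distribution(),
                                    params.pair())
            steady_e = float(e + rng.normal(0.0, noise.s_efficiency))
        conditions.append(ExperimentCondition(
            label=label, response=response, steady_state_e=steady_e,
            background_phasor=background))
        truths.append(truth)
    return conditions, truths


def generate_phasor_pixels(truth: GroundTruth, frequency: float = 10.0,
                           n_pixels: int = 256, seed: int | None = None,
                           group: str | None = None) -> list[PhasorPoint]:
    """Per-pixel phasor scatter emulating a confocal FLIM acquisition.

    Each pixel is the model's corrected-response phasor plus independent
    Gaussian scatter of magnitude ``noise.pixel_dispersion`` on (d, n).
    """
    params = truth.parameter_vector()
    clean = forward_response(params.decay(), params.distribution(), params.pair(),
                             InstrumentModel.ideal(), [frequency])
    d0, n0 = float(clean.d[0]), float(clean.n[0])
    rng = np.random.default_rng(seed if seed is not None else truth.seed)
    s = truth.noise.pixel_dispersion
    return [PhasorPoint(frequency, d0 + rng.normal(0.0, s),
                        n0 + rng.normal(0.0, s), group)
            for _ in range(n_pixels)]


def generate_timecourse(baseline: float = 1000.0,
                        quench_fraction: float = 0.3,
                        recovery_fraction: float = 0.92,
                        quench_time: float = 120.0,
                        recovery_time: float = 360.0,
                        duration: float = 600.0,
                        sample_interval: float = 5.0,
                        settling_tau: float = 3.0,
                        bleach_tau: float | None = None,
                        noise: NoiseModel | None = None,
                        seed: int = 0) -> TimeCourse:
    """Stepwise fluorescence time course with reagent-addition events.

    The intensity settles exponentially (time constant ``settling_tau`` < 10 s,
    emulating mixing dead time) to ``baseline * quench_fraction`` after the
    quencher addition and to ``baseline * recovery_fraction`` after the
    reversal reagent, with multiplicative Gaussian noise.  With ``bleach_tau``
    set and no events wanted, pass ``quench_time >= duration`` to obtain a
    photobleaching-only trace.
    """
    if not 0.0 <= quench_fraction <= 1.2 or not 0.0 <= recovery_fraction <= 1.2:
        raise ValueError("fractions must lie in [0, 1.2]")
    noise = noise if noise is not None else NoiseModel()
    t = np.arange(0.0, duration, sample_interval)
    level = np.full_like(t, baseline)
    events = []
    if quench_time < duration:
        target = baseline * quench_fraction
        after = t >= quench_time
        level[after] = target + (baseline - target) * np.exp(
            -(t[after] - quench_time) / settling_tau)
        events.append((quench_time, "quench"))
        if recovery_time < duration:
            rec = baseline * recovery_fraction
            after = t >= recovery_time
            level[after] = rec + (target - rec) * np.exp(
                -(t[after] - recovery_time) / settling_tau)
            events.append((recovery_time, "reversal"))
    if bleach_tau is not None:
        level = level * np.exp(-t / bleach_tau)
    rng = np.random.default_rng(seed)
    intensity = level * (1.0 + rng.normal(0.0, noise.intensity_noise, len(t)))
    return TimeCourse(time=t, intensity=np.clip(intensity, 0.0, None),
                      events=tuple(events))


def generate_spectra(donor_peak: float = 450.0, donor_width: float = 35.0,
                     acceptor_peak: float = 550.0, acceptor_width: float = 80.0,
                     acceptor_eps_max: float = 300.0,
                     quantum_yield: float = 0.8,
                     target_r0: float | None = None,
                     wavelengths=None) -> tuple[Spectrum, Spectrum]:
    """Gaussian-shaped donor emission and acceptor absorption spectra.

    When ``target_r0`` (Angstrom) is given, the acceptor amplitude is rescaled
    in closed form (R0**6 is linear in the overlap integral J, and J is linear
    in the absorptivity) so that the Forster distance computed from the pair
    equals the target.
    """
    if min(donor_width, acceptor_width, acceptor_eps_max) <= 0:
        raise ValueError("widths and amplitudes must be positive")
    wl = np.asarray(wavelengths, dtype=float) if wavelengths is not None \
        else np.arange(380.0, 800.0, 1.0)
    emission = np.exp(-0.5 * ((wl - donor_peak) / donor_width) ** 2)
    absorption = acceptor_eps_max * np.exp(
        -0.5 * ((wl - acceptor_peak) / acceptor_width) ** 2)
    donor = Spectrum(wl, emission, kind="emission")
    acceptor = Spectrum(wl, absorption, kind="absorption")
    if target_r0 is not None:
        j = overlap_integral(donor, acceptor)
        r0 = forster_radius(j, quantum_yield)
        acceptor = Spectrum(wl, absorption * (target_r0 / r0) ** 6,
                            kind="absorption")
    return donor, acceptor


# ---------------------------------------------------------------------------
# toy structures

_HELIX_GEOMETRY = dict(  # ideal alpha-helix internal coordinates
    phi=-57.0, psi=-47.0, omega=180.0,
    n_ca=1.458, ca_c=1.525, c_n=1.329,
    ang_n_ca_c=111.2, ang_ca_c_n=116.2, ang_c_n_ca=121.7,
)


def generate_toy_structure(kind: str = "helix", n_residues: int = 18):
    """Small idealized structures for exercising the rotamer sampler.

    ``helix``: ideal poly-alanine alpha-helix (1.5 A rise, ~100 degree twist
    per residue) with backbone N/CA/C/O and CB atoms — every site is solvent
    exposed.  ``buried``: the same helix with a cage of carbon pseudo-atoms
    enclosing the middle residue's side-chain direction, so no probe conformer
    can be placed there (a designed degenerate case).

    Returns a :class:`~tmfret.structure.StructureModel`.
    """
    import biotite.structure as struc

    from .structure import StructureModel, _place_atom, _virtual_cb

    if kind not in ("helix", "buried"):
        raise ValueError("kind must be 'helix' or 'buried'")
    g = _HELIX_GEOMETRY
    # backbone trace via sequential internal-coordinate placement
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([g["n_ca"], 0.0, 0.0])
    c0 = _place_atom(np.array([-1.0, 1.0, 0.0]), n0, ca0,
                     g["ca_c"], g["ang_n_ca_c"], g["phi"])
    backbone = [("N", n0), ("CA", ca0), ("C", c0)]
    chain = [n0, ca0, c0]
    for _ in range(1, n_residues):
        n = _place_atom(chain[-3], chain[-2], chain[-1],
                        g["c_n"], g["ang_ca_c_n"], g["psi"])
        ca = _place_atom(chain[-2], chain[-1], n,
                         g["n_ca"], g["ang_c_n_ca"], g["omega"])
        c = _place_atom(chain[-1], n, ca, g["ca_c"], g["ang_n_ca_c"], g["phi"])
        chain.extend([n, ca, c])
        backbone.extend([("N", n), ("CA", ca), ("C", c)])

    atoms = []
    for res_i in range(n_residues):
        n, ca, c = (backbone[3 * res_i + k][1] for k in range(3))
        cb = _virtual_cb(n, ca, c)
        entries = [("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("CB", "C", cb)]
        if res_i + 1 < n_residues:
            n_next = backbone[3 * (res_i + 1)][1]
            o = _place_atom(ca, c, n_next, 1.23, 120.5, 180.0)
            entries.insert(3, ("O", "O", o))
        for name, element, coord in entries:
            atom = struc.Atom(coord, chain_id="A", res_id=res_i + 1,
                              res_name="ALA", atom_name=name, element=element,
                              hetero=False)
            atoms.append(atom)

    if kind == "buried":
        mid = n_residues // 2
        n, ca, c = (backbone[3 * mid + k][1] for k in range(3))
        cb = _virtual_cb(n, ca, c)
        center = cb + 2.0 * (cb - ca) / np.linalg.norm(cb - ca)
        # nested Fibonacci spheres of blocking pseudo-atoms around the
        # side-chain exit vector: no probe conformer can avoid both shells
        res_counter = 1000
        for radius, m in ((3.0, 100), (6.0, 250)):
            idx = np.arange(m) + 0.5
            theta = np.arccos(1 - 2 * idx / m)
            phi_ang = np.pi * (1 + 5 ** 0.5) * idx
            shell = center + radius * np.stack([
                np.sin(theta) * np.cos(phi_ang),
                np.sin(theta) * np.sin(phi_ang),
                np.cos(theta)], axis=1)
            for coord in shell:
                atoms.append(struc.Atom(coord, chain_id="B", res_id=res_counter,
                                        res_name="CAG", atom_name="C",
                                        element="C", hetero=True))
                res_counter += 1

    array = struc.array(atoms)
    return StructureModel(atoms=array, source_id=f"toy_{kind}")


def structure_to_pdb_text(model) -> str:
    """Serialize a structure model to PDB-format text."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(model.atoms)
    return "\n".join(pdb.lines) + "\n"
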