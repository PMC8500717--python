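# Methods

This note documents the models implemented in `tmfret`, the defaults that
matter, the scope of the synthetic-data generator, and the numerical and
design choices made where more than one reasonable option existed.

## Frequency-domain lifetime model with distributed distances

A frequency-domain lifetime instrument reports, per modulation frequency
(MHz), the phase delay φ_ω (degrees) and modulation ratio m_ω of the emitted
fluorescence relative to the excitation. For a donor with decay components
(τ_Di, α_i) quenched by an acceptor at distance r, each component shortens to
τ_DAi(r) = τ_Di / (1 + (R₀/r)⁶). With the donor–acceptor distance distributed
as P(r), the real/imaginary response components are

    N_ω = (1−f_B)·(1/J)·∫ P(r) Σ_i α_i ω τ_DAi²/(1+ω²τ_DAi²) dr + f_B m_ωB sin φ_ωB
    D_ω = (1−f_B)·(1/J)·∫ P(r) Σ_i α_i τ_DAi /(1+ω²τ_DAi²) dr + f_B m_ωB cos φ_ωB
    J   = ∫ P(r) Σ_i α_i τ_DAi dr

and φ_ω = arctan(N/D) + ω t₀, m_ω = √(N²+D²). f_B is the fractional intensity
of background fluorescence with measured phasor (φ_ωB, m_ωB); t₀ is the
instrument-response time shift. The inverse correction (removing background
and time shift from measured data) is implemented in `correct_response` and
is the exact inverse of the forward mixing.

P(r) is a sum of up to two Gaussians (means r̄ᵢ, widths σᵢ, amplitudes
A₁ = 1−A₂ and A₂) scaled by (1−f_D), plus a donor-only fraction f_D that
undergoes no FRET. The apparent efficiency is E = 1 − J / Σ α_i τ_Di; the
denominator is the *unquenched* donor intensity, which is the only reading
under which E is a well-defined fractional intensity loss (E = 0 at f_D = 1,
E → 1/(1+(r̄/R₀)⁶) in the narrow single-Gaussian limit).

**Units.** Frequencies are stored in MHz and converted internally to angular
frequency in rad/ns (ω = 2π·f·10⁻³), lifetimes and t₀ in ns, distances in Å,
phases in degrees at every interface (radians internally).

### Quadrature

Each Gaussian component is integrated by fixed 257-node Gauss–Legendre
quadrature on [max(0.01 Å, r̄−6σ), r̄+6σ], with the truncated component
renormalized to its nominal mass. Tails beyond 6σ hold < 2·10⁻⁹ of the mass,
and truncation at positive r removes the unphysical negative-distance tail
that a raw Gaussian formally has; the evaluated density integrates to 1
within 10⁻⁶ across the tested parameter space. Against an independent
time-domain oracle (fine-grid simulation of I(t) followed by numerical
Fourier integrals) the forward model agrees to better than 0.1° in phase and
0.002 in modulation over 10–200 MHz.

### Donor-only term

The conventional representation of the donor-only population is a narrow
Gaussian at 150 Å (σ = 0.1 Å), where FRET is below 10⁻⁶ for any realistic R₀.
The package treats f_D analytically as an exactly-zero-FRET term, which is
numerically identical (verified to 10⁻⁵ in phase) and avoids integrating a
needlessly stiff spike; the literal 150 Å Gaussian remains available via
`DistanceDistribution(..., strict_donor_only=True)` for comparison.

## Staged fitting protocol

The 12-parameter vector is (f_D, τ_D1, α₁, τ_D2, R₀, r̄₁, σ₁, A₂, r̄₂, σ₂,
t₀, f_B). One measurement epoch is fit by minimizing

    χ² = Σ_ω (φ_obs−φ_pred)²/s_φ² + Σ_ω (m_obs−m_pred)²/s_m² + (E_obs−E_pred)²/s_E²

over its free subset. Measurement variances are rarely reported with the
data, so the weights default to s_φ = 0.2°, s_m = 0.004 and s_E = 0.01 —
representative single-frequency precisions for a frequency-domain rig — and
are configurable; with noiseless data the weighting affects only the χ²
scale, not the recovered parameters.

An experiment sequence is fit in stages, frozen values flowing forward:

| stage | condition            | free parameters        | fixed                     |
|-------|----------------------|------------------------|---------------------------|
| 1     | donor only           | τ_D1, t₀, f_B          | f_D = 1, α₁ = 1           |
| 2     | + acceptor           | r̄₁, σ₁, t₀, f_B        | A₂ = 0, f_D per chemistry |
| 3     | + saturating ligand  | r̄₂, σ₂, t₀, f_B        | A₂ = 1                    |
| 4     | subsaturating ligand | A₂, t₀, f_B            | both Gaussians frozen     |
| 5     | reversal             | f_D, t₀, f_B           |                           |

t₀ and f_B are refit in every stage because they absorb slow instrument
drift between epochs. f_D with the acceptor bound defaults to 0.08 for
Cu²⁺-TETAC (unlabelled-cysteine fraction calibrated with a long-R₀ quencher)
and 0 for Cu²⁺-di-histidine at saturating Cu²⁺ (assumed complete site
occupancy); both are overridable, and stage 3 inherits stage 2's f_D.

The optimizer is bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`), run from the supplied initial values plus
k−1 = 7 Latin-hypercube starts within bounds (seed 1234) with the best local
minimum kept. If a fit drives a σ to its 0.1 Å lower bound the result is
flagged: at instrument precision such a distribution is indistinguishable
from a discrete distance. Two-exponential donor fits are reported in
canonical ascending-lifetime order, since component labels are a symmetry of
the model. The stage-4 objective was checked to be unimodal in A₂ on (0,1)
for well-separated states (1-D profile scan in the test suite).

**Free-fluorophore decays.** Recovering a short double-exponential decay
(≈1.3/3.3 ns) with both t₀ and f_B free is badly conditioned when the
background itself has a 2–3 ns lifetime — the background fraction can absorb
a decay component. Free-dye measurements in clean buffer carry negligible
background, so those datasets are generated with f_B = 0 and fit with
(τ_D1, α₁, τ_D2, t₀) free; protein samples keep f_B free throughout.

## Phasor analysis

A response at one frequency maps to (D, N) = (m cos φ, m sin φ) of the
*corrected* response. Single-exponential decays lie on the universal circle
(radius ½ centred at (½, 0)); an intensity mixture of two signatures lies on
the chord between the parents at the intensity fraction of the second. The
default analysis frequency is 10 MHz, the fundamental of the pulsed source.
Group centroids are arithmetic means of per-pixel (D, N). Off-chord points
are orthogonally projected and the perpendicular distance reported as a
quality metric. The chord fraction is intensity-weighted; because the two
conformational states differ in brightness (their per-population J differs),
`population_from_intensity_fraction` converts it to a population fraction
using state-wise relative intensities from a fitted model. Both numbers are
reported; which one a given legacy analysis used cannot be established from
outside, and for the benchmark constructs they differ by ≲ 0.03.

## Steady-state analysis

Fraction unquenched after a reagent addition is the ratio of window means:
by default the last 5 samples before the event and samples 3–8 after it
(skipping two samples allows < 10 s of mixing dead time); windows are
configurable. Efficiency corrected for nonspecific losses is
E = 1 − F_site/F_control with the control construct lacking the acceptor
site; its uncertainty comes from Monte-Carlo resampling of the two means
with their standard errors (10⁶ cycles by default; doubling the cycle count
moves the reported s.e. by < 1%). Distances follow from the Förster
inversion R = R₀(1/E − 1)^{1/6}. Photobleaching traces are fit with
A e^{−t/τ} + C; dose–response curves with the Hill equation, maximal
response fixed at 1 when the response is itself a fraction (a free-amplitude
variant exists).

## Spectra and Förster distance

J = ∫F_D(λ) ε_A(λ) λ⁴ dλ / ∫F_D(λ) dλ with both spectra linearly
interpolated onto the finer grid on the common support (zero outside; no
extrapolation) and integrated by the trapezoid rule. R₀ =
(C·J·Q·η⁻⁴·κ²)^{1/6} with the standard constant C = 8.79×10⁻⁵ Å⁶·M·cm·nm⁻⁴
for J in M⁻¹cm⁻¹nm⁴, defaults η = 1.33 (aqueous buffer) and κ² = 2/3
(isotropic average; for a metal-ion acceptor with multiple transition
dipoles the 1/3–4/3 mixed-polarization bound changes R₀ by at most ~11–12%).
Relative quantum yields use Q = Q_ref·(slope/slope_ref)·(η²/η_ref²) from
integrated-emission-versus-absorbance dilution series.

## Structure-based distance prediction

β-carbon distances are read directly from PDB coordinates (CA fallback for
glycine, with a warning). Probe conformer clouds use deliberately simplified
idealized templates — coarse pseudo-atom chains with fixed bond lengths and
angles (Cu–Nε2 fixed at 2.03 Å for the histidine complex), grafted at the
site backbone and sampled by uniform random torsions (attempt budget 10 000,
default seed 42, bit-reproducible). Conformers are rejected on heavy-atom
clashes: "tight" policy 3.4 Å cutoff / 0 clashes, "loose" 2.5 Å / 5 clashes,
up to 200 accepted conformers per site. The labelled residue and its two
covalent sequence neighbours are excluded from the clash environment (their
backbone is unavoidably within any sensible cutoff of the probe's proximal
atoms); hydrogens are ignored. Di-histidine Cu²⁺ clouds pair conformers from
the i and i±4 sites and keep midpoints of pairs whose Cu positions agree
within 1 Å. Cloud-to-cloud distance distributions are all-pairs histograms
(0.5 Å bins, unit area) with the centroid distance reported alongside.

This sampler reproduces the size and position of conformer clouds, not any
particular published rotamer library; on real structures small systematic
offsets relative to force-field-optimized probe geometries are expected.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (parameters, seed). The frequency-domain
generator evaluates the forward model on the 10–200 MHz grid (harmonics of a
10 MHz source; 20 frequencies) and adds independent Gaussian noise of
s_φ = 0.2° and s_m = 0.004 — matched to the default fit weights so reduced
χ² ≈ 1 on defaults. Five-condition sequences share the structural parameters
and jitter the nuisance parameters per condition (t₀ ~ N(0, 0.05 ns),
f_B ~ U(0.02, 0.08)); the synthetic background is a 2.5 ns exponential, in
the range of cellular autofluorescence. Per-pixel phasor emulation scatters
256 pixels with 0.01 dispersion on (D, N). The bundled `CONSTRUCTS` table
records the benchmark constructs' measured parameters (lifetimes, R₀, state
Gaussians, donor-only fractions, subsaturating occupancies) as the default
study conditions.

Not emulated: photon-counting (Poisson) statistics, any covariance between
phase and modulation noise (independence is assumed and stated), detector
nonlinearity, full-frame FLIM images, inner-filter effects, and real probe
chemistry in the toy structures. Passing recovery tests therefore
demonstrate correctness and conditioning of the estimator under the stated
noise model, not robustness to every artefact of a real instrument.

## Validation problem sizes

Occupancy recovery uses 20 replicate five-condition sequences per condition;
distance and lifetime recovery use 10 replicate datasets (5 in the quicker
test-suite variants); each fit uses the default 8 multi-starts. These sizes
put the Monte-Carlo error of the replicate means well below the quantities'
tolerances while keeping a full validation run around a minute on one core.

## Known limitations

- r̄ and σ are correlated in single-condition fits; only simultaneous
  multi-condition information (the staged protocol) pins them down, and
  posterior correlations are not quantified (no Bayesian machinery).
- The distance distribution is parametric (≤ 2 Gaussians + donor-only);
  lifetime data cannot resolve arbitrary distribution shapes.
- Global analysis across samples, polarization/anisotropy, time-correlated
  single-photon counting data, and pixel-level image processing are out of
  scope.
- The crystal-structure validation requires downloading the two public PDB
  entries; all other functionality and tests run offline.
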