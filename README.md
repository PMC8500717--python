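# tmfret

Analysis of **time-resolved transition-metal-ion FRET (tmFRET)** experiments:
fitting frequency-domain fluorescence-lifetime data with models of
Gaussian-distributed donor–acceptor distances to recover, from a single
nanosecond-scale snapshot, both the structural heterogeneity *within* each
conformational state of a protein and the equilibrium distribution *among*
states.

tmFRET pairs a small fluorescent noncanonical amino acid donor (such as
acridonylalanine, Acd, with its long ~16 ns single-exponential lifetime) with
a nonfluorescent transition-metal acceptor (Cu²⁺ chelated by a
cysteine-reactive TETAC reagent, or Cu²⁺ bound to an engineered di-histidine
site). Because the acceptor quenches over 10–25 Å, the method reports
backbone-scale intramolecular distances. The package targets experiments of
the kind performed on maltose-binding protein (MBP), whose clamshell closure
on maltose binding moves donor/acceptor site pairs by several Ångström.

## The model

The donor decays with components τ_Di and amplitudes α_i. An acceptor at
distance *r* shortens each component to

    τ_DAi(r) = τ_Di / (1 + (R₀/r)⁶)

with R₀ the Förster distance. The donor–acceptor distance is distributed as a
sum of up to two Gaussians (means r̄₁, r̄₂; widths σ₁, σ₂; closed-state
fraction A₂) plus a zero-FRET donor-only fraction f_D. For modulated
excitation at angular frequency ω the predicted observables are the phase
delay φ_ω = arctan(N_ω/D_ω) + ω·t₀ and the modulation ratio
m_ω = √(N_ω² + D_ω²), where N and D are distance-integrals of the quenched
sine/cosine transforms, normalized by J = ∫P(r) Σ α_i τ_DAi(r) dr and mixed
with a measured background phasor in proportion f_B. The apparent FRET
efficiency is E = 1 − J / Σ α_i τ_Di.

Data from one experiment (donor-only → +acceptor → +ligand → subsaturating →
reversal) are fit in stages by bounded trust-region χ² minimization, with
3–4 free parameters per stage and earlier-stage values frozen forward — so
the subsaturating-ligand fit estimates a single structural number, the
closed-state occupancy A₂, from which K = A₂/(1−A₂) and ΔG = −ln K follow.

Also included: model-independent phasor analysis (universal circle, two-state
chord projection), steady-state quenching efficiency with Monte-Carlo
uncertainty, spectral overlap / Förster-distance computation, β-carbon and
rotamer-cloud distance predictions from PDB structures, and a synthetic-data
generator that emulates every input with known ground truth.

## Worked example

Recover the conformational distribution of an MBP-like construct at a
subsaturating ligand concentration, from synthetic data generated at the
di-histidine construct's measured parameters (donor lifetime 15.5 ns,
R₀ = 12.2 Å, open state 18.3 ± 2.5 Å, closed state 12.7 ± 1.3 Å, true
A₂ = 0.38):

```python
from tmfret.fitting import ProtocolConfig, fit_protocol, occupancy_to_equilibrium
from tmfret.synthetic import CONSTRUCTS, generate_experiment_sequence

construct = CONSTRUCTS["mbp295_dihis"]          # Acd donor, Cu2+-di-histidine
conditions, _ = generate_experiment_sequence(construct, a2_subsaturating=0.38,
                                             seed=7)
results = fit_protocol(conditions, ProtocolConfig(r0=construct.r0,
                                                  f_d_acceptor=construct.f_d))
for r in results:
    free = {k: round(r.parameters[k], 2) for k in r.parameters.free_names()}
    print(f"{r.condition_label:16s} reduced chi2 = {r.reduced_chi2:4.2f}  {free}")

a2 = results[3].parameters["a2"]
k_eq, dg = occupancy_to_equilibrium(a2)
print(f"closed-state occupancy A2 = {a2:.3f} -> K = {k_eq:.2f}, dG = {dg:+.2f} kT")
```

prints

```
donor_only       reduced chi2 = 1.38  {'tau_d1': 15.49, 't0': 0.0, 'f_b': 0.07}
acceptor         reduced chi2 = 1.11  {'rbar1': 18.9, 'sigma1': 3.39, 't0': -0.02, 'f_b': 0.07}
acceptor_ligand  reduced chi2 = 0.74  {'rbar2': 12.72, 'sigma2': 1.1, 't0': 0.07, 'f_b': 0.07}
subsaturating    reduced chi2 = 1.29  {'a2': 0.36, 't0': 0.02, 'f_b': 0.04}
reversal         reduced chi2 = 0.67  {'f_d': 0.97, 't0': -0.0, 'f_b': 0.05}
closed-state occupancy A2 = 0.365 -> K = 0.57, dG = +0.55 kT
```

Stage 1 recovers the donor lifetime; stages 2–3 recover the open- and
closed-state distance distributions; stage 4 reads off the occupancy of the
closed clamshell at the subsaturating condition (0.365 against a generating
value of 0.38, within the single-replicate noise); stage 5 confirms the
acceptor is removable. Reduced χ² near 1 indicates the fits sit at the
measurement-noise floor.

The same analyses are available from the shell:

```sh
tmfret simulate sequence --construct mbp295_dihis --a2 0.38 --out-dir seq
tmfret fit --config seq/config.json
tmfret phasor --in seq/donor_only.csv --freq 10
tmfret r0 --donor em.csv --acceptor abs.csv --qy 0.8
tmfret structure distance --pdb 1omp.pdb --site-a 295 --site-b 237
```

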