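"""Fitting tests: objective behaviour, parameter recovery, protocol rules."""

import numpy as np
import pytest

from tmfret.fitting import (
    ExperimentCondition,
    FitWeights,
    ParameterVector,
    ProtocolConfig,
    ProtocolError,
    chi_square,
    fit_condition,
    fit_protocol,
    occupancy_to_equilibrium,
)
from tmfret.synthetic import (
    CONSTRUCTS,
    GroundTruth,
    NoiseModel,
    generate_experiment_sequence,
    generate_fd_dataset,
)

FREQS = tuple(float(f) for f in range(10, 201, 10))


def make_condition(values: dict, label: str = "donor_only",
                   noise: NoiseModel | None = None, seed: int = 0
                   ) -> tuple[ExperimentCondition, GroundTruth]:
    truth = GroundTruth(values=values, noise=noise or NoiseModel.noiseless(),
                        seed=seed)
    response, record = generate_fd_dataset(truth, FREQS)
    from tmfret.synthetic import _background_table

    return ExperimentCondition(label=label, response=response,
                               background_phasor=_background_table(FREQS)), record


DONOR_TRUTH = dict(f_d=1.0, tau_d1=16.0, alpha_1=1.0, t0=0.1, f_b=0.05)


class TestChiSquare:
    def test_zero_at_generating_parameters(self):
        condition, truth = make_condition(DONOR_TRUTH)
        assert chi_square(truth.parameter_vector(), condition) == pytest.approx(
            0.0, abs=1e-16)

    def test_locally_increases_away_from_truth(self):
        condition, truth = make_condition(DONOR_TRUTH)
        base = chi_square(truth.parameter_vector(), condition)
        for name, delta in [("tau_d1", 0.1), ("t0", 0.02), ("f_b", 0.01)]:
            for sign in (+1, -1):
                perturbed = truth.parameter_vector()
                perturbed.set(name, perturbed[name] + sign * delta)
                assert chi_square(perturbed, condition) > base

    def test_bitwise_deterministic(self):
        condition, truth = make_condition(DONOR_TRUTH, noise=NoiseModel(), seed=5)
        params = truth.parameter_vector()
        params.set("tau_d1", 15.0)
        values = {chi_square(params, condition) for _ in range(5)}
        assert len(values) == 1


class TestFitCondition:
    def test_noiseless_exact_recovery(self):
        condition, truth = make_condition(DONOR_TRUTH)
        init = ParameterVector.defaults(f_d=1.0, tau_d1=10.0)
        init.set_free(("tau_d1", "t0", "f_b"))
        result = fit_condition(condition, init, n_starts=1)
        for name, expected in [("tau_d1", 16.0), ("t0", 0.1), ("f_b", 0.05)]:
            assert result.parameters[name] == pytest.approx(expected, rel=1e-4)

    def test_single_exponential_donor_recovery_with_noise(self):
        recovered = []
        for seed in range(5):
            condition, _ = make_condition(DONOR_TRUTH, noise=NoiseModel(),
                                          seed=seed)
            init = ParameterVector.defaults(f_d=1.0)
            init.set_free(("tau_d1", "t0", "f_b"))
            recovered.append(fit_condition(condition, init).parameters["tau_d1"])
        assert np.mean(recovered) == pytest.approx(16.0, abs=0.1)

    def test_double_exponential_donor_recovery(self):
        # free-Anap-like decay: 1.3 / 3.3 ns with amplitude fraction 0.76,
        # measured in buffer (negligible background fraction)
        truth_values = dict(f_d=1.0, tau_d1=1.3, alpha_1=0.76, tau_d2=3.3,
                            t0=0.05, f_b=0.0)
        recovered = np.zeros((5, 3))
        for seed in range(5):
            condition, _ = make_condition(truth_values, noise=NoiseModel(),
                                          seed=100 + seed)
            init = ParameterVector.defaults(f_d=1.0, tau_d1=2.0, alpha_1=0.5,
                                            tau_d2=5.0, f_b=0.0)
            init.set_free(("tau_d1", "alpha_1", "tau_d2", "t0"))
            p = fit_condition(condition, init).parameters
            recovered[seed] = (p["tau_d1"], p["tau_d2"], p["alpha_1"])
        mean = recovered.mean(axis=0)
        assert mean[0] == pytest.approx(1.3, rel=0.05)
        assert mean[1] == pytest.approx(3.3, rel=0.05)
        assert mean[2] == pytest.approx(0.76, rel=0.05)

    def test_canonical_component_order(self):
        # exchangeable components are reported with tau_d1 <= tau_d2
        truth_values = dict(f_d=1.0, tau_d1=1.3, alpha_1=0.76, tau_d2=3.3,
                            t0=0.0, f_b=0.0)
        condition, _ = make_condition(truth_values, noise=NoiseModel(), seed=9)
        init = ParameterVector.defaults(f_d=1.0, tau_d1=6.0, alpha_1=0.3,
                                        tau_d2=1.0, f_b=0.0)
        init.set_free(("tau_d1", "alpha_1", "tau_d2", "t0"))
        p = fit_condition(condition, init).parameters
        assert p["tau_d1"] <= p["tau_d2"]
        assert p["alpha_1"] == pytest.approx(0.76, abs=0.1)

    def test_too_few_observations_rejected(self):
        condition, _ = make_condition(DONOR_TRUTH)
        short = ExperimentCondition(
            label="donor_only",
            response=type(condition.response)(
                condition.response.frequencies[:1],
                condition.response.phase[:1],
                condition.response.modulation[:1]),
            background_phasor=condition.background_phasor)
        init = ParameterVector.defaults()
        init.set_free(("tau_d1", "t0", "f_b"))
        with pytest.raises(ValueError, match="observations"):
            fit_condition(short, init)


class TestFitProtocol:
    def test_noiseless_sequence_recovers_truth_exactly(self):
        construct = CONSTRUCTS["mbp295_dihis"]
        conditions, truths = generate_experiment_sequence(
            construct, 0.38, noise=NoiseModel.noiseless(), seed=3)
        results = fit_protocol(conditions, ProtocolConfig(
            r0=construct.r0, f_d_acceptor=construct.f_d, n_starts=1))
        by_label = {r.condition_label: r.parameters for r in results}
        assert by_label["donor_only"]["tau_d1"] == pytest.approx(15.5, rel=1e-4)
        assert by_label["acceptor"]["rbar1"] == pytest.approx(18.3, rel=1e-4)
        assert by_label["acceptor"]["sigma1"] == pytest.approx(2.5, rel=1e-3)
        assert by_label["acceptor_ligand"]["rbar2"] == pytest.approx(12.7, rel=1e-4)
        assert by_label["subsaturating"]["a2"] == pytest.approx(0.38, abs=1e-4)
        assert by_label["reversal"]["f_d"] == pytest.approx(1.0, abs=1e-3)

    def test_frozen_values_flow_forward(self):
        construct = CONSTRUCTS["mbp295_dihis"]
        conditions, _ = generate_experiment_sequence(
            construct, 0.38, noise=NoiseModel.noiseless(), seed=3)
        results = fit_protocol(conditions, ProtocolConfig(
            r0=construct.r0, f_d_acceptor=construct.f_d, n_starts=1))
        tau_stage1 = results[0].parameters["tau_d1"]
        for later in results[1:]:
            assert later.parameters["tau_d1"] == tau_stage1

    def test_missing_donor_only_stage_raises(self):
        construct = CONSTRUCTS["mbp295_dihis"]
        conditions, _ = generate_experiment_sequence(
            construct, 0.38, noise=NoiseModel.noiseless(), seed=3)
        with pytest.raises(ProtocolError):
            fit_protocol(conditions[1:], ProtocolConfig(r0=construct.r0))

    def test_subsaturating_requires_both_parent_stages(self):
        construct = CONSTRUCTS["mbp295_dihis"]
        conditions, _ = generate_experiment_sequence(
            construct, 0.38, noise=NoiseModel.noiseless(), seed=3)
        # drop the saturating-ligand stage
        broken = [c for c in conditions if c.label != "acceptor_ligand"]
        with pytest.raises(ProtocolError):
            fit_protocol(broken, ProtocolConfig(r0=construct.r0))

    def test_stage4_profile_has_unique_minimum(self):
        # 1-D chi-square profile over the occupancy is unimodal for
        # well-separated open/closed states
        construct = CONSTRUCTS["mbp295_dihis"]
        conditions, truths = generate_experiment_sequence(
            construct, 0.38, noise=NoiseModel.noiseless(), seed=11)
        sub = conditions[3]
        params = truths[3].parameter_vector()
        grid = np.linspace(0.01, 0.99, 99)
        profile = []
        for a2 in grid:
            p = params.copy()
            p.set("a2", a2)
            profile.append(chi_square(p, sub))
        profile = np.array(profile)
        minima = [i for i in range(1, len(grid) - 1)
                  if profile[i] < profile[i - 1] and profile[i] < profile[i + 1]]
        assert len(minima) == 1
        assert grid[minima[0]] == pytest.approx(0.38, abs=0.02)


class TestOccupancyThermodynamics:
    def test_symmetric_occupancy(self):
        k, dg = occupancy_to_equilibrium(0.5)
        assert k == pytest.approx(1.0)
        assert dg == pytest.approx(0.0)

    @pytest.mark.parametrize("a2,k,dg", [
        (0.38, 0.6129032258064516, 0.4895482253187058),
        (0.60, 1.5, -0.4054651081081645),
    ])
    def test_derived_values(self, a2, k, dg):
        k_hat, dg_hat = occupancy_to_equilibrium(a2)
        assert k_hat == pytest.approx(k, rel=1e-12)
        assert dg_hat == pytest.approx(dg, rel=1e-9)

    @pytest.mark.parametrize("a2", [0.0, 1.0, -0.1, 1.1])
    def test_boundary_rejected(self, a2):
        with pytest.raises(ValueError):
            occupancy_to_equilibrium(a2)


class TestParameterVector:
    def test_requires_all_twelve(self):
        with pytest.raises(ValueError):
            ParameterVector({"f_d": None})

    def test_defaults_rejects_unknown(self):
        with pytest.raises(ValueError, match="unknown"):
            ParameterVector.defaults(tau=16.0)

    def test_weights_scale_objective_only(self):
        condition, truth = make_condition(DONOR_TRUTH, noise=NoiseModel(), seed=2)
        params = truth.parameter_vector()
        c1 = chi_square(params, condition, FitWeights())
        c2 = chi_square(params, condition,
                        FitWeights(s_phase=0.4, s_modulation=0.008))
        assert c2 == pytest.approx(c1 / 4.0, rel=1e-9)
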