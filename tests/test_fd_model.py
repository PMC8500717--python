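"""Forward-model tests: closed forms, quadrature oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from tmfret.fd_model import (
    ConfigurationError,
    DistanceDistribution,
    DonorDecayModel,
    FretPair,
    FrequencyResponse,
    GaussianComponent,
    InstrumentModel,
    apparent_efficiency,
    correct_response,
    distance_density,
    forward_response,
    fret_quenched_tau,
)

from _oracles import time_domain_phase_modulation

FREQS = np.arange(10.0, 201.0, 10.0)


def no_fret_distribution() -> DistanceDistribution:
    """All mass donor-only: exactly zero FRET through the analytic path."""
    return DistanceDistribution.single(20.0, 1.0, donor_only_fraction=1.0)


class TestQuenchedTau:
    def test_halved_at_r0(self):
        assert fret_quenched_tau(16.0, 14.9, 14.9) == pytest.approx(8.0)

    def test_no_fret_limit(self):
        assert fret_quenched_tau(16.0, 1e6, 14.9) == pytest.approx(16.0)

    def test_direct_evaluation(self):
        # scalar-arithmetic oracle at the apo di-histidine geometry
        assert fret_quenched_tau(15.7, 18.8, 12.2) == pytest.approx(
            14.608982171454993, rel=1e-12)

    def test_strictly_increasing_in_r(self):
        r = np.linspace(5.0, 40.0, 200)
        tau = fret_quenched_tau(16.0, r, 14.9)
        assert np.all(np.diff(tau) > 0)

    @pytest.mark.parametrize("tau_d,r,r0", [(-1, 10, 14), (16, -1, 14), (16, 10, 0)])
    def test_nonpositive_inputs_rejected(self, tau_d, r, r0):
        with pytest.raises(ValueError):
            fret_quenched_tau(tau_d, r, r0)


class TestDistanceDensity:
    def test_gaussian_peak_height(self):
        dist = DistanceDistribution.single(15.0, 2.0)
        assert distance_density(dist, 15.0) == pytest.approx(
            1.0 / (2.0 * np.sqrt(2.0 * np.pi)), rel=1e-6)

    def test_two_component_integral_is_one(self):
        dist = DistanceDistribution.two_state(10.0, 1.5, 30.0, 2.5, a2=0.4)
        total, _ = quad(lambda r: distance_density(dist, r), 0.0, 60.0, limit=300)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_component_masses_against_quadrature_oracle(self):
        # two-Gaussian mixture of the di-histidine construct, occupancy 0.38
        dist = DistanceDistribution.two_state(18.3, 2.5, 12.7, 1.3, a2=0.38)
        mass1, _ = quad(lambda r: distance_density(dist, r), 18.3 - 2.5, 18.3 + 2.5)
        mass2, _ = quad(lambda r: distance_density(dist, r), 12.7 - 1.3, 12.7 + 1.3)
        # frozen from an independent scipy.integrate.quad + norm.cdf oracle
        # over the full mixture density (each window also catches the tail
        # of the other component)
        assert mass1 == pytest.approx(0.42651591293618896, abs=2e-4)
        assert mass2 == pytest.approx(0.2841142222560637, abs=2e-4)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(mean=st.floats(5.0, 40.0), sd=st.floats(0.1, 8.0),
           a2=st.floats(0.0, 1.0), f_d=st.floats(0.0, 0.9))
    def test_normalization_property(self, mean, sd, a2, f_d):
        dist = DistanceDistribution.two_state(mean, sd, 0.6 * mean, 0.5 * sd + 0.1,
                                              a2=a2, donor_only_fraction=f_d)
        # adaptive quadrature with breakpoints at the truncation edges
        edges = sorted({max(0.01, mean - 6 * sd), mean + 6 * sd,
                        max(0.01, 0.6 * mean - 6 * (0.5 * sd + 0.1)),
                        0.6 * mean + 6 * (0.5 * sd + 0.1), 149.4, 150.6})
        total, _ = quad(lambda r: distance_density(dist, r), 0.0, 160.0,
                        points=edges, limit=500)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestForwardResponse:
    @pytest.mark.parametrize("tau", [2.0, 8.0, 16.0])
    def test_single_exponential_closed_form(self, tau):
        decay = DonorDecayModel.single(tau)
        resp = forward_response(decay, no_fret_distribution(), FretPair(14.9),
                                InstrumentModel.ideal(), FREQS)
        w = 2 * np.pi * FREQS * 1e-3
        assert resp.phase == pytest.approx(np.degrees(np.arctan(w * tau)), abs=1e-9)
        assert resp.modulation == pytest.approx(1.0 / np.sqrt(1 + (w * tau) ** 2),
                                                abs=1e-12)

    def test_cartesian_polar_identity_with_time_shift(self):
        decay = DonorDecayModel.single(15.5)
        dist = DistanceDistribution.single(18.3, 2.5)
        inst = InstrumentModel(t0=0.5, f_b=0.0)
        resp = forward_response(decay, dist, FretPair(12.2), inst, FREQS)
        w = 2 * np.pi * FREQS * 1e-3
        phi_prime = np.radians(resp.phase) - w * inst.t0
        np.testing.assert_allclose(resp.modulation * np.sin(phi_prime), resp.n,
                                   atol=1e-12)
        np.testing.assert_allclose(resp.modulation * np.cos(phi_prime), resp.d,
                                   atol=1e-12)

    @pytest.mark.parametrize("tau,alpha,r0,gaussians,f_d", [
        # apo di-histidine construct geometry
        ((15.7,), (1.0,), 12.2, [(18.8, 3.5, 1.0)], 0.0),
        # wide TETAC apo cloud with a donor-only fraction
        ((15.6,), (1.0,), 14.9, [(23.7, 6.2, 1.0)], 0.08),
        # two-state mixture
        ((15.5,), (1.0,), 12.2, [(18.3, 2.5, 0.62), (12.7, 1.3, 0.38)], 0.0),
        # double-exponential donor
        ((14.0, 2.0), (0.7, 0.3), 14.9, [(15.0, 4.0, 1.0)], 0.0),
    ])
    def test_agrees_with_time_domain_oracle(self, tau, alpha, r0, gaussians, f_d):
        decay = DonorDecayModel(tuple(tau), tuple(alpha))
        comps = tuple(GaussianComponent(m, s, a) for m, s, a in gaussians)
        dist = DistanceDistribution(comps, donor_only_fraction=f_d)
        resp = forward_response(decay, dist, FretPair(r0),
                                InstrumentModel.ideal(), FREQS)
        phase_ref, mod_ref = time_domain_phase_modulation(
            tau, alpha, r0, gaussians, f_d, FREQS)
        np.testing.assert_allclose(resp.phase, phase_ref, atol=0.1)
        np.testing.assert_allclose(resp.modulation, mod_ref, atol=0.002)

    def test_narrow_gaussian_matches_discrete_distance_mixture(self):
        # as sigma -> 0 the model converges to two discrete quenched decays
        decay = DonorDecayModel.single(15.5)
        r0, r1, r2, a2 = 12.2, 18.3, 12.7, 0.38
        dist = DistanceDistribution.two_state(r1, 0.002, r2, 0.002, a2=a2)
        resp = forward_response(decay, dist, FretPair(r0),
                                InstrumentModel.ideal(), FREQS)
        tau1 = fret_quenched_tau(15.5, r1, r0)
        tau2 = fret_quenched_tau(15.5, r2, r0)
        w = 2 * np.pi * FREQS * 1e-3
        j = (1 - a2) * tau1 + a2 * tau2
        n = ((1 - a2) * w * tau1 ** 2 / (1 + (w * tau1) ** 2)
             + a2 * w * tau2 ** 2 / (1 + (w * tau2) ** 2)) / j
        d = ((1 - a2) * tau1 / (1 + (w * tau1) ** 2)
             + a2 * tau2 / (1 + (w * tau2) ** 2)) / j
        np.testing.assert_allclose(resp.phase, np.degrees(np.arctan2(n, d)), atol=1e-4)
        np.testing.assert_allclose(resp.modulation, np.hypot(n, d), atol=1e-6)

    def test_strict_donor_only_matches_analytic_shortcut(self):
        decay = DonorDecayModel.single(15.6)
        kw = dict(mean1=23.7, sd1=6.2, mean2=13.4, sd2=6.5, a2=0.3,
                  donor_only_fraction=0.08)
        analytic = DistanceDistribution.two_state(**kw)
        strict = DistanceDistribution.two_state(**kw, strict_donor_only=True)
        ra = forward_response(decay, analytic, FretPair(14.9),
                              InstrumentModel.ideal(), FREQS)
        rs = forward_response(decay, strict, FretPair(14.9),
                              InstrumentModel.ideal(), FREQS)
        np.testing.assert_allclose(ra.phase, rs.phase, atol=1e-5)
        np.testing.assert_allclose(ra.modulation, rs.modulation, atol=1e-7)

    def test_missing_background_phasor_raises(self):
        decay = DonorDecayModel.single(16.0)
        inst = InstrumentModel(t0=0.0, f_b=0.1, background_phasor={})
        with pytest.raises(ConfigurationError):
            forward_response(decay, no_fret_distribution(), FretPair(14.9),
                             inst, [10.0])

    def test_physical_ranges(self):
        decay = DonorDecayModel.double(14.0, 2.0, 0.7)
        dist = DistanceDistribution.two_state(18.0, 3.0, 12.0, 1.5, a2=0.5,
                                              donor_only_fraction=0.1)
        resp = forward_response(decay, dist, FretPair(13.0),
                                InstrumentModel.ideal(), FREQS)
        assert np.all((resp.phase > 0) & (resp.phase < 90))
        assert np.all((resp.modulation > 0) & (resp.modulation <= 1))


class TestApparentEfficiency:
    def test_forster_midpoint(self):
        decay = DonorDecayModel.single(16.0)
        dist = DistanceDistribution.single(14.9, 0.001)
        assert apparent_efficiency(decay, dist, FretPair(14.9)) == pytest.approx(
            0.5, abs=1e-5)

    def test_donor_only_population_gives_zero(self):
        decay = DonorDecayModel.single(16.0)
        assert apparent_efficiency(decay, no_fret_distribution(),
                                   FretPair(14.9)) == pytest.approx(0.0, abs=1e-12)

    def test_against_quadrature_oracle(self):
        # apo di-histidine construct: frozen scipy.integrate.quad value
        decay = DonorDecayModel.single(15.5)
        dist = DistanceDistribution.single(18.3, 2.5)
        assert apparent_efficiency(decay, dist, FretPair(12.2)) == pytest.approx(
            0.10839069348088703, abs=1e-6)

    def test_strictly_decreasing_in_mean_distance(self):
        decay = DonorDecayModel.single(15.5)
        effs = [apparent_efficiency(decay, DistanceDistribution.single(m, 2.0),
                                    FretPair(12.2))
                for m in np.linspace(8.0, 30.0, 23)]
        assert np.all(np.diff(effs) < 0)


class TestCorrectResponse:
    def test_identity_without_background_or_shift(self):
        decay = DonorDecayModel.single(16.0)
        resp = forward_response(decay, no_fret_distribution(), FretPair(14.9),
                                InstrumentModel.ideal(), FREQS)
        corrected = correct_response(resp, InstrumentModel.ideal())
        np.testing.assert_allclose(corrected.phase, resp.phase, atol=1e-12)
        np.testing.assert_allclose(corrected.modulation, resp.modulation, atol=1e-12)

    def test_round_trip_removes_background_and_shift(self):
        decay = DonorDecayModel.single(15.5)
        dist = DistanceDistribution.single(18.3, 2.5)
        pair = FretPair(12.2)
        dirty_inst = InstrumentModel.with_exponential_background(0.5, 0.2, FREQS)
        clean = forward_response(decay, dist, pair, InstrumentModel.ideal(), FREQS)
        dirty = forward_response(decay, dist, pair, dirty_inst, FREQS)
        corrected = correct_response(dirty, dirty_inst)
        np.testing.assert_allclose(corrected.phase, clean.phase, atol=1e-9)
        np.testing.assert_allclose(corrected.modulation, clean.modulation, atol=1e-9)

    def test_corrected_single_exponential_returns_to_universal_circle(self):
        decay = DonorDecayModel.single(16.0)
        dirty_inst = InstrumentModel.with_exponential_background(0.3, 0.15, FREQS)
        dirty = forward_response(decay, no_fret_distribution(), FretPair(14.9),
                                 dirty_inst, FREQS)
        corrected = correct_response(dirty, dirty_inst).with_cartesian()
        residual = np.hypot(corrected.d - 0.5, corrected.n) - 0.5
        np.testing.assert_allclose(residual, 0.0, atol=1e-9)


class TestTypes:
    def test_alpha_must_sum_to_one(self):
        with pytest.raises(ValueError):
            DonorDecayModel(tau=(16.0, 2.0), alpha=(0.7, 0.2))

    def test_amplitudes_must_sum_to_one(self):
        with pytest.raises(ValueError):
            DistanceDistribution((GaussianComponent(18.0, 2.0, 0.5),
                                  GaussianComponent(12.0, 1.0, 0.4)))

    def test_response_lookup(self):
        resp = FrequencyResponse([10.0, 20.0], [40.0, 55.0], [0.7, 0.5])
        assert resp.at(20.0) == (55.0, 0.5)
        with pytest.raises(KeyError):
            resp.at(30.0)
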