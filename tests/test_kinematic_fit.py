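"""Sign-constrained fits, bootstrap pruning, phasor extraction, VAF."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import velocity_neuron
from vermispop.kinematic_fit import (
    DirectionCoefficients,
    bootstrap_prune,
    fit_kinematic,
    to_response_vector,
    vaf,
)
from vermispop.synthetic_data import (
    Direction,
    GroundTruthNeuron,
    Modality,
    make_active_like_trajectory,
    make_sinusoid_stimulus,
    simulate_rate,
)


class TestFitKinematic:
    def test_noiseless_positive_branch_exact(self, active_stim):
        n = velocity_neuron(baseline=120.0)
        rate, _ = simulate_rate(n, active_stim)
        fit = fit_kinematic(rate, active_stim)
        assert fit.b == pytest.approx(120.0, abs=1e-5)
        assert fit.direction("ipsi").c_v == pytest.approx(0.5, abs=1e-6)
        assert fit.direction("ipsi").c_p == pytest.approx(0.0, abs=1e-6)
        assert fit.vaf == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_negative_branch_exact(self, active_stim):
        n = GroundTruthNeuron(
            id="neg", baseline=120.0,
            coeffs={
                (Modality.VESTIBULAR, Direction.IPSI): (0.0, -0.3, 0.0),
                (Modality.VESTIBULAR, Direction.CONTRA): (0.0, -0.3, 0.0),
            },
        )
        rate, _ = simulate_rate(n, active_stim)
        fit = fit_kinematic(rate, active_stim)
        assert fit.direction("ipsi").c_v == pytest.approx(-0.3, abs=1e-6)
        assert fit.direction("contra").c_v == pytest.approx(-0.3, abs=1e-6)

    def test_mixed_branches_per_direction(self, active_stim):
        n = GroundTruthNeuron(
            id="mix", baseline=150.0,
            coeffs={
                (Modality.VESTIBULAR, Direction.IPSI): (0.1, 0.5, 0.002),
                (Modality.VESTIBULAR, Direction.CONTRA): (-0.05, -0.3, 0.0),
            },
        )
        rate, _ = simulate_rate(n, active_stim)
        fit = fit_kinematic(rate, active_stim)
        assert fit.direction("ipsi").triple == pytest.approx((0.1, 0.5, 0.002), abs=1e-5)
        assert fit.direction("contra").triple == pytest.approx((-0.05, -0.3, 0.0), abs=1e-5)

    def test_sinusoid_collinear_design_still_identifies_phasor(self):
        # acc = -omega^2 * pos for a pure sinusoid: the triple is degenerate
        # but (S, phase) stays identifiable
        stim = make_sinusoid_stimulus(freq=1.0, peak_vel=40.0, n_cycles=4)
        n = GroundTruthNeuron(
            id="s", baseline=100.0,
            coeffs={
                (Modality.VESTIBULAR, Direction.IPSI): (0.0, 0.4, 0.02),
                (Modality.VESTIBULAR, Direction.CONTRA): (0.0, 0.4, 0.02),
            },
        )
        rate, _ = simulate_rate(n, stim)
        fit = fit_kinematic(rate, stim)
        vec = to_response_vector(fit, "ipsi")
        s_true, ph_true = n.sensitivity_phase(Modality.VESTIBULAR, Direction.IPSI)
        assert vec.sensitivity == pytest.approx(s_true, rel=1e-6)
        assert vec.phase_deg == pytest.approx(ph_true, abs=1e-4)

    def test_zero_stimulus_channel_rejected(self, active_stim):
        rate = np.full(len(active_stim.t), 50.0)
        with pytest.raises(ValueError, match="no kinematic signal"):
            fit_kinematic(rate, active_stim, channel="head_on_body")


class TestBootstrapPrune:
    def test_noiseless_keeps_true_terms_prunes_zeros(self, active_stim):
        n = GroundTruthNeuron(
            id="p", baseline=120.0,
            coeffs={
                (Modality.VESTIBULAR, Direction.IPSI): (0.2, 0.5, 0.0),
                (Modality.VESTIBULAR, Direction.CONTRA): (0.0, 0.5, 0.0),
            },
        )
        rate, _ = simulate_rate(n, active_stim)
        fit = bootstrap_prune(rate, active_stim, n_boot=200, rng_seed=0)
        assert fit.direction("ipsi").significant == {
            "c_p": True, "c_v": True, "c_a": False
        }
        assert fit.direction("contra").significant == {
            "c_p": False, "c_v": True, "c_a": False
        }
        assert fit.direction("contra").c_p == 0.0
        assert fit.direction("contra").c_a == 0.0

    def test_seed_determinism(self, active_stim, rng):
        n = velocity_neuron(noise_sd=5.0)
        rate, _ = simulate_rate(n, active_stim, rng=rng)
        a = bootstrap_prune(rate, active_stim, n_boot=150, rng_seed=11)
        b = bootstrap_prune(rate, active_stim, n_boot=150, rng_seed=11)
        assert a.direction("ipsi").ci_95 == b.direction("ipsi").ci_95
        assert a.direction("ipsi").triple == b.direction("ipsi").triple

    def test_small_n_boot_warns(self, active_stim, rng):
        n = velocity_neuron(noise_sd=5.0)
        rate, _ = simulate_rate(n, active_stim, rng=rng)
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_prune(rate, active_stim, n_boot=50, rng_seed=0)


class TestResponseVector:
    def test_all_zero_flags_degenerate(self):
        vec = to_response_vector(DirectionCoefficients(0.0, 0.0, 0.0))
        assert vec.degenerate and vec.sensitivity == 0.0 and vec.sign == 0

    def test_velocity_only(self):
        vec = to_response_vector(DirectionCoefficients(0.0, 0.5, 0.0))
        assert vec.sensitivity == pytest.approx(0.5)
        assert vec.phase_deg == pytest.approx(0.0)
        assert vec.sign == 1

    def test_acceleration_lead(self):
        vec = to_response_vector(DirectionCoefficients(0.0, 0.0, 0.1))
        assert vec.phase_deg == pytest.approx(90.0)
        assert vec.sensitivity == pytest.approx(2 * np.pi * 0.1)


class TestVaf:
    def test_perfect_and_mean_fits(self, rng):
        y = rng.normal(0, 1, 500)
        assert vaf(y, y) == pytest.approx(1.0)
        assert vaf(y, np.full_like(y, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_noise_matched_variance_near_zero(self, rng):
        y = np.sin(np.linspace(0, 20, 2000))
        noisy = y + rng.normal(0, y.std(), size=y.size)
        assert vaf(y, noisy) == pytest.approx(0.0, abs=0.1)

    def test_constant_observed_is_nan(self):
        assert np.isnan(vaf(np.ones(10), np.arange(10.0)))

    @given(a=st.floats(0.1, 5.0), b=st.floats(-10.0, 10.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 200)
        f = y + rng.normal(0, 0.5, 200)
        assert vaf(a * y + b, a * f + b) == pytest.approx(vaf(y, f), rel=1e-9)
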