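"""Phasor-sum prediction of combined responses and population regressions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vermispop.kinematic_fit import ResponseVector
from vermispop.summation import (
    compare_populations,
    pair_for_combined,
    predict_combined,
)
from vermispop.synthetic_data import Direction, Modality


def _vec(s, phase, direction=Direction.IPSI, modality=Modality.VESTIBULAR):
    return ResponseVector(
        sensitivity=s, phase_deg=phase, direction=direction, modality=modality
    )


class TestPredictCombined:
    def test_perfect_antagonism_flags_zero_magnitude(self):
        out = predict_combined(_vec(0.5, 0.0), _vec(0.5, 180.0))
        assert out.sensitivity == 0.0 and out.degenerate

    def test_unimodal_identity(self):
        out = predict_combined(_vec(0.5, 0.0), _vec(0.0, 123.0))
        assert out.sensitivity == pytest.approx(0.5)
        assert out.phase_deg == pytest.approx(0.0)

    def test_complex_arithmetic(self):
        out = predict_combined(_vec(0.4, 30.0), _vec(0.3, -90.0))
        mag = np.hypot(0.4 * np.cos(np.radians(30)), 0.4 * np.sin(np.radians(30)) - 0.3)
        ang = np.degrees(np.arctan2(0.4 * np.sin(np.radians(30)) - 0.3,
                                    0.4 * np.cos(np.radians(30))))
        assert out.sensitivity == pytest.approx(mag, rel=1e-9)
        assert out.phase_deg == pytest.approx(ang, abs=1e-9)
        assert out.sensitivity == pytest.approx(0.3606, abs=2e-4)
        assert out.phase_deg == pytest.approx(-16.1, abs=0.1)

    def test_frequency_mismatch_rejected(self):
        v = _vec(0.5, 0.0)
        p = ResponseVector(sensitivity=0.3, phase_deg=0.0, frequency=2.0)
        with pytest.raises(ValueError):
            predict_combined(v, p)

    @given(
        s1=st.floats(0.0, 1.0), p1=st.floats(-180.0, 180.0),
        s2=st.floats(0.0, 1.0), p2=st.floats(-180.0, 180.0),
        s3=st.floats(0.0, 1.0), p3=st.floats(-180.0, 180.0),
    )
    def test_commutative_and_associative(self, s1, p1, s2, p2, s3, p3):
        a, b, c = _vec(s1, p1), _vec(s2, p2), _vec(s3, p3)
        ab = predict_combined(a, b)
        ba = predict_combined(b, a)
        assert ab.sensitivity == pytest.approx(ba.sensitivity, abs=1e-12)
        abc1 = predict_combined(predict_combined(a, b), c)
        abc2 = predict_combined(a, predict_combined(b, c))
        assert abc1.sensitivity == pytest.approx(abc2.sensitivity, abs=1e-12)

    def test_pairing_uses_complementary_direction(self):
        vest = {Direction.IPSI: _vec(0.5, 0.0), Direction.CONTRA: _vec(0.2, 170.0)}
        prop = {
            Direction.IPSI: _vec(0.1, -10.0, Direction.IPSI, Modality.PROPRIOCEPTIVE),
            Direction.CONTRA: _vec(0.3, 160.0, Direction.CONTRA, Modality.PROPRIOCEPTIVE),
        }
        out = pair_for_combined(vest, prop, Direction.IPSI)
        ref = predict_combined(vest[Direction.IPSI], prop[Direction.CONTRA])
        assert out.sensitivity == ref.sensitivity and out.phase_deg == ref.phase_deg


class TestComparePopulations:
    def test_identical_arrays_slope_one(self):
        rng = np.random.default_rng(0)
        vecs = [_vec(s, p) for s, p in zip(rng.uniform(0.1, 1, 20),
                                           rng.uniform(-170, 170, 20))]
        out = compare_populations(vecs, vecs)
        assert out.sensitivity.slope == pytest.approx(1.0)
        assert out.sensitivity.r_squared == pytest.approx(1.0)
        assert out.phase.r_squared == pytest.approx(1.0)
        assert out.sensitivity.p_slope_vs_1 == pytest.approx(1.0)

    def test_r2_degrades_with_nonlinearity(self):
        rng = np.random.default_rng(1)
        s_pred = rng.uniform(0.1, 1.0, 40)
        phases = rng.uniform(-90, 90, 40)
        r2 = []
        for strength in (0.0, 0.15, 0.4):
            s_est = s_pred + strength * rng.normal(size=40) * s_pred
            out = compare_populations(
                [_vec(s, p) for s, p in zip(s_pred, phases)],
                [_vec(max(s, 1e-6), p) for s, p in zip(s_est, phases)],
            )
            r2.append(out.sensitivity.r_squared)
        assert r2[0] > r2[1] > r2[2]

    def test_phase_wrap_handled(self):
        # estimated phases near +-180 must not produce wrap artifacts
        pred = [_vec(0.5, 175.0), _vec(0.5, -175.0), _vec(0.4, 170.0),
                _vec(0.3, -170.0)]
        est = [_vec(0.5, -179.0), _vec(0.5, 179.0), _vec(0.4, 172.0),
               _vec(0.3, -168.0)]
        out = compare_populations(pred, est)
        assert out.phase.r_squared > 0.9

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError):
            compare_populations([_vec(0.5, 0)] * 2, [_vec(0.5, 0)] * 2)
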