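"""Linear summation model: predict combined-rotation responses from phasors.

The response of a cell to combined head-on-body rotation is predicted as the
complex (phasor) sum of its vestibular response in one direction and its
proprioceptive response in the complementary body-under-head direction (the
neck is stimulated in the complementary direction during head-on-body
motion). Population agreement between predicted and estimated responses is
summarized by ordinary least-squares regressions of estimated on predicted
sensitivity and phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematic_fit import ResponseVector
from .phasor import wrap_phase_deg
from .synthetic_data import Direction, Modality

__all__ = [
    "SummationComparison",
    "predict_combined",
    "pair_for_combined",
    "compare_populations",
]


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    slope_ci_95: tuple[float, float]
    p_slope_vs_1: float


@dataclass
class SummationComparison:
    sensitivity: RegressionSummary
    phase: RegressionSummary
    s_pred: np.ndarray
    s_est: np.ndarray
    phase_pred: np.ndarray
    phase_est: np.ndarray  # unwrapped about the prediction


def predict_combined(vest: ResponseVector, prop: ResponseVector) -> ResponseVector:
    """Phasor sum of a vestibular and a proprioceptive response vector.

    Each (S, phase) becomes the complex number S·e^{j·phase}; the sum is
    converted back with the phase wrapped to (−180, 180]. A zero-magnitude sum
    (perfect antagonism) is returned with the degenerate flag set.
    """
    if vest.frequency != prop.frequency:
        raise ValueError("phasors must share one frequency")
    z = vest.complex + prop.complex
    sens = float(abs(z))
    if sens < 1e-12:
        return ResponseVector(
            sensitivity=0.0, phase_deg=0.0, frequency=vest.frequency,
            direction=vest.direction, modality=Modality.COMBINED,
            sign=0, degenerate=True,
        )
    phase = wrap_phase_deg(float(np.degrees(np.angle(z))))
    return ResponseVector(
        sensitivity=sens, phase_deg=phase, frequency=vest.frequency,
        direction=vest.direction, modality=Modality.COMBINED,
        sign=1 if abs(phase) < 90.0 else -1,
    )


# Direction pairing for the combined paradigm: head-on-body motion in a
# direction stimulates the canals in that direction and the neck in the
# complementary body-under-head direction.
COMBINED_PAIRING: dict[Direction, Direction] = {
    Direction.IPSI: Direction.CONTRA,
    Direction.CONTRA: Direction.IPSI,
}


def pair_for_combined(
    vest_vectors: dict[Direction, ResponseVector],
    prop_vectors: dict[Direction, ResponseVector],
    direction: Direction,
    pairing: dict[Direction, Direction] = COMBINED_PAIRING,
) -> ResponseVector:
    """Predict the combined response in ``direction`` using the pairing table."""
    return predict_combined(vest_vectors[direction], prop_vectors[pairing[direction]])


def compare_populations(
    predicted: list[ResponseVector],
    estimated: list[ResponseVector],
) -> SummationComparison:
    """OLS regressions of estimated on predicted sensitivity and phase.

    Estimated phases are unwrapped about their predicted values before the
    regression to avoid ±180° wrap artifacts. Requires at least 3 neurons.
    """
    import statsmodels.api as sm

    if len(predicted) != len(estimated):
        raise ValueError("predicted and estimated lists must align")
    if len(predicted) < 3:
        raise ValueError("need at least 3 neurons for a population regression")
    s_pred = np.array([v.sensitivity for v in predicted])
    s_est = np.array([v.sensitivity for v in estimated])
    ph_pred = np.array([v.phase_deg for v in predicted])
    ph_est = np.array(
        [p + wrap_phase_deg(e - p)
         for p, e in zip(ph_pred, (v.phase_deg for v in estimated))]
    )

    def regress(x, y) -> RegressionSummary:
        if np.allclose(x, x[0]):
            raise ValueError("degenerate predictor: all predicted values equal")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        slope = float(model.params[1])
        ci = model.conf_int(alpha=0.05)
        # t-test of slope == 1; a numerically perfect fit (zero residuals up
        # to float noise) is treated as consistent with its own slope
        from scipy import stats as sps

        bse = float(model.bse[1])
        if bse <= 1e-10 * max(1.0, abs(slope)):
            p = 1.0 if abs(slope - 1.0) <= 1e-8 else 0.0
        else:
            tstat = (slope - 1.0) / bse
            p = float(2 * sps.t.sf(abs(tstat), df=model.df_resid))
        return RegressionSummary(
            slope=slope,
            intercept=float(model.params[0]),
            r_squared=float(model.rsquared),
            slope_ci_95=(float(ci[1][0]), float(ci[1][1])),
            p_slope_vs_1=p,
        )

    return SummationComparison(
        sensitivity=regress(s_pred, s_est),
        phase=regress(ph_pred, ph_est),
        s_pred=s_pred,
        s_est=s_est,
        phase_pred=ph_pred,
        phase_est=ph_est,
    )
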