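"""Cell taxonomy: preferred direction, Type I/II, modality class, tuning shape.

Conventions follow the recorded-population analysis: the preferred direction
is the one with the larger excitatory simple-spike response (Type I = ipsi,
Type II = contra); a cell is unimodal iff all proprioceptive coefficients are
pruned to zero in both directions; and the linear / rectifying / v-shaped
shapes are decided by a 0.2 (sp/s)/(°/s) threshold on direction sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinematic_fit import KinematicCoefficients, ResponseVector, to_response_vector
from .synthetic_data import Direction

__all__ = [
    "NeuronLabel",
    "preferred_direction",
    "modality_class",
    "tuning_shape",
    "classify_neuron",
    "SHAPE_THRESHOLD",
]

SHAPE_THRESHOLD = 0.2  # (sp/s)/(deg/s)


@dataclass
class NeuronLabel:
    preferred_direction: Direction
    cell_type: str  # "I" (ipsi-preferring) or "II" (contra-preferring)
    modality_class: str  # "unimodal" or "bimodal"
    shape_vest: str
    shape_prop: str | None = None
    flag: str | None = None  # e.g. "no_excitatory_direction"


def _is_excitatory(vec: ResponseVector) -> bool:
    """An excitatory response in a direction means firing increases for motion
    in that direction: positive branch for ipsi, negative branch for contra."""
    if vec.sign == 0:
        return False
    return vec.sign == (1 if vec.direction is Direction.IPSI else -1)


def preferred_direction(
    vectors: dict[Direction, ResponseVector],
) -> tuple[Direction, str | None]:
    """Direction of the (larger) excitatory response; ties break to ipsi.

    V-shaped cells (excitatory both ways) take the larger-sensitivity
    direction. If neither direction is excitatory the cell is flagged and the
    larger-|S| direction is returned.
    """
    ipsi, contra = vectors[Direction.IPSI], vectors[Direction.CONTRA]
    exc_i, exc_c = _is_excitatory(ipsi), _is_excitatory(contra)
    if exc_i and not exc_c:
        return Direction.IPSI, None
    if exc_c and not exc_i:
        return Direction.CONTRA, None
    # both excitatory (v-shaped) or neither: larger sensitivity, tie -> ipsi
    flag = None if (exc_i and exc_c) else "no_excitatory_direction"
    if contra.sensitivity > ipsi.sensitivity:
        return Direction.CONTRA, flag
    return Direction.IPSI, flag


def modality_class(prop_fit: KinematicCoefficients) -> str:
    """unimodal iff every proprioceptive coefficient is (pruned to) zero."""
    for d in Direction:
        if any(c != 0.0 for c in prop_fit.direction(d).triple):
            return "bimodal"
    return "unimodal"


def tuning_shape(
    s_pref: float,
    s_nonpref: float,
    excitatory_pref: bool,
    excitatory_nonpref: bool,
    threshold: float = SHAPE_THRESHOLD,
) -> str:
    """Classify the two-direction tuning shape (first matching rule wins).

    linear:     excitatory preferred + inhibitory non-preferred, with
                ||S_pref| − |S_nonpref|| <= threshold;
    rectifying: excitatory preferred, |S_nonpref| < threshold (minimal
                modulation);
    v_shaped:   excitatory in both directions, magnitudes within threshold;
    other:      anything else.
    """
    s_pref, s_nonpref = abs(s_pref), abs(s_nonpref)
    if excitatory_pref and not excitatory_nonpref and abs(s_pref - s_nonpref) <= threshold:
        return "linear"
    if excitatory_pref and s_nonpref < threshold:
        return "rectifying"
    if excitatory_pref and excitatory_nonpref and abs(s_pref - s_nonpref) <= threshold:
        return "v_shaped"
    return "other"


def classify_neuron(
    vest_fit: KinematicCoefficients,
    prop_fit: KinematicCoefficients | None = None,
    threshold: float = SHAPE_THRESHOLD,
) -> NeuronLabel:
    """Assign the full taxonomy from (bootstrap-pruned) condition fits."""
    vest_vecs = {d: to_response_vector(vest_fit, d) for d in Direction}
    pref, flag = preferred_direction(vest_vecs)
    nonpref = pref.opposite
    shape_v = tuning_shape(
        vest_vecs[pref].sensitivity,
        vest_vecs[nonpref].sensitivity,
        _is_excitatory(vest_vecs[pref]),
        _is_excitatory(vest_vecs[nonpref]),
        threshold,
    )
    mclass = "unimodal" if prop_fit is None else modality_class(prop_fit)
    shape_p = None
    if prop_fit is not None and mclass == "bimodal":
        prop_vecs = {d: to_response_vector(prop_fit, d) for d in Direction}
        ppref, _ = preferred_direction(prop_vecs)
        shape_p = tuning_shape(
            prop_vecs[ppref].sensitivity,
            prop_vecs[ppref.opposite].sensitivity,
            _is_excitatory(prop_vecs[ppref]),
            _is_excitatory(prop_vecs[ppref.opposite]),
            threshold,
        )
    return NeuronLabel(
        preferred_direction=pref,
        cell_type="I" if pref is Direction.IPSI else "II",
        modality_class=mclass,
        shape_vest=shape_v,
        shape_prop=shape_p,
        flag=flag,
    )
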