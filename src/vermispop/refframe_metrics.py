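"""Head- vs body-centered coding metrics.

Each vestibular-sensitive cell is placed on the head-centered ↔ body-centered
continuum by two ratios — head ratio = S_combined / S_vestibular and body
ratio = S_proprioceptive / S_vestibular — and a signed coding index,
(smaller ratio)/(larger ratio), positive for agonistic and negative for
antagonistic vestibular–neck phase relations. An ideal head encoder sits at
(1, 0); an ideal body encoder at (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from .phasor import wrap_phase_deg

__all__ = ["CodingIndices", "sensitivity_ratios", "coding_index", "compute_indices"]

# Designation cutoffs are a package convention (the underlying study reports
# percentages without printing its rule): "head" if head_ratio >= head_min and
# body_ratio <= body_max; "body" symmetric; otherwise "intermediate".
HEAD_RATIO_MIN = 0.8
BODY_RATIO_MAX = 0.2


@dataclass
class CodingIndices:
    head_ratio: float
    body_ratio: float
    coding_index: float  # signed, |.| <= 1
    designation: str  # "head" | "body" | "intermediate"
    flag: str | None = None


def sensitivity_ratios(
    s_vest: float, s_prop: float, s_combined: float
) -> tuple[float, float]:
    """(head_ratio, body_ratio) = (S_combined/S_vest, S_prop/S_vest).

    The vestibular sensitivity must be positive (the analyzed population is
    vestibular-responsive by selection).
    """
    if s_vest <= 0:
        raise ValueError("head/body ratios are undefined for S_vest <= 0")
    return s_combined / s_vest, s_prop / s_vest


def is_agonistic(phase_vest_deg: float, phase_prop_deg: float) -> bool:
    """Agonistic iff the phasors are within 90° of each other (ties antagonistic)."""
    return abs(wrap_phase_deg(phase_vest_deg - phase_prop_deg)) < 90.0


def coding_index(
    head_ratio: float, body_ratio: float, agonistic: bool
) -> tuple[float, str | None]:
    """Signed min/max ratio of the two sensitivity ratios.

    Magnitude = min/max of (head_ratio, body_ratio); sign positive if the
    vestibular and proprioceptive responses are agonistic. Both-zero ratios
    return 0 with a flag.
    """
    if head_ratio < 0 or body_ratio < 0:
        raise ValueError("ratios must be non-negative")
    hi = max(head_ratio, body_ratio)
    if hi == 0.0:
        return 0.0, "both_ratios_zero"
    magnitude = min(head_ratio, body_ratio) / hi
    return (magnitude if agonistic else -magnitude), None


def compute_indices(
    s_vest: float,
    s_prop: float,
    s_combined: float,
    phase_vest_deg: float,
    phase_prop_deg: float,
    head_ratio_min: float = HEAD_RATIO_MIN,
    body_ratio_max: float = BODY_RATIO_MAX,
) -> CodingIndices:
    """Full per-neuron metric set with the head/body/intermediate designation."""
    head_ratio, body_ratio = sensitivity_ratios(s_vest, s_prop, s_combined)
    idx, flag = coding_index(
        head_ratio, body_ratio, is_agonistic(phase_vest_deg, phase_prop_deg)
    )
    if head_ratio >= head_ratio_min and body_ratio <= body_ratio_max:
        designation = "head"
    elif body_ratio >= head_ratio_min and head_ratio <= body_ratio_max:
        designation = "body"
    else:
        designation = "intermediate"
    return CodingIndices(
        head_ratio=head_ratio,
        body_ratio=body_ratio,
        coding_index=idx,
        designation=designation,
        flag=flag,
    )
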