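"""End-to-end orchestration: stimuli sets, per-neuron characterization,
condition-concatenated rate matrices for the population model.

These helpers wire the generator, the constrained fits, the taxonomy and the
metrics together the way a full experiment is analyzed: active-like rotations
for the three dynamic conditions, sinusoidal whole-body rotations at five
static head positions for the gain-field paradigm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import gainfield as gf
from .classify import NeuronLabel, classify_neuron
from .kinematic_fit import (
    KinematicCoefficients,
    ResponseVector,
    bootstrap_prune,
    fit_kinematic,
    to_response_vector,
)
from .refframe_metrics import compute_indices
from .summation import COMBINED_PAIRING, pair_for_combined
from .synthetic_data import (
    GAIN_FIELD_POSITIONS,
    Condition,
    ConditionStimulus,
    Direction,
    GaussianTuning,
    GroundTruthNeuron,
    Modality,
    make_active_like_trajectory,
    make_sinusoid_stimulus,
    simulate_rate,
)

DYNAMIC_CONDITIONS = (
    Condition.WHOLE_BODY,
    Condition.BODY_UNDER_HEAD,
    Condition.HEAD_ON_BODY,
)


def standard_stimuli(
    n_repeats: int = 5,
    amplitude: float = 30.0,
    duration_half_cycle: float = 0.5,
    fs: float = 1000.0,
) -> dict[Condition, ConditionStimulus]:
    """The three dynamic active-like conditions on a common grid."""
    return {
        cond: make_active_like_trajectory(
            amplitude=amplitude,
            duration_half_cycle=duration_half_cycle,
            n_repeats=n_repeats,
            condition=cond,
            fs=fs,
        )
        for cond in DYNAMIC_CONDITIONS
    }


def gain_field_stimuli(
    positions=GAIN_FIELD_POSITIONS,
    n_cycles: int = 5,
    fs: float = 1000.0,
) -> list[ConditionStimulus]:
    """1-Hz ±40°/s whole-body sinusoids at each static head position."""
    return [
        make_sinusoid_stimulus(
            freq=1.0, peak_vel=40.0, head_offset=p,
            n_cycles=n_cycles, condition=Condition.GAIN_FIELD, fs=fs,
        )
        for p in positions
    ]


@dataclass
class NeuronCharacterization:
    neuron_id: str
    fits: dict[Condition, KinematicCoefficients]
    vectors: dict[tuple[Modality, Direction], ResponseVector]
    label: NeuronLabel


def characterize_neuron(
    neuron: GroundTruthNeuron,
    stimuli: dict[Condition, ConditionStimulus],
    n_boot: int = 0,
    rng: np.random.Generator | None = None,
) -> NeuronCharacterization:
    """Simulate, fit (optionally bootstrap-pruned) and label one neuron."""
    rng = rng if rng is not None else np.random.default_rng()
    fits: dict[Condition, KinematicCoefficients] = {}
    modality_of = {
        Condition.WHOLE_BODY: Modality.VESTIBULAR,
        Condition.BODY_UNDER_HEAD: Modality.PROPRIOCEPTIVE,
        Condition.HEAD_ON_BODY: Modality.COMBINED,
    }
    for cond in DYNAMIC_CONDITIONS:
        stim = stimuli[cond]
        rate, _ = simulate_rate(neuron, stim, rng=rng)
        if n_boot > 0:
            fits[cond] = bootstrap_prune(
                rate, stim, n_boot=n_boot, rng_seed=rng,
                modality=modality_of[cond],
            )
        else:
            fits[cond] = fit_kinematic(rate, stim, modality=modality_of[cond])
    vectors = {
        (modality_of[cond], d): to_response_vector(fits[cond], d)
        for cond in DYNAMIC_CONDITIONS
        for d in Direction
    }
    label = classify_neuron(
        fits[Condition.WHOLE_BODY], fits[Condition.BODY_UNDER_HEAD]
    )
    return NeuronCharacterization(
        neuron_id=neuron.id, fits=fits, vectors=vectors, label=label
    )


def characterize_population(
    neurons: list[GroundTruthNeuron],
    stimuli: dict[Condition, ConditionStimulus] | None = None,
    n_boot: int = 0,
    rng_seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-neuron summary table: phasors, taxonomy, reference-frame metrics."""
    stimuli = stimuli if stimuli is not None else standard_stimuli()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    rows = []
    for neuron in neurons:
        ch = characterize_neuron(neuron, stimuli, n_boot=n_boot, rng=rng)
        pref = ch.label.preferred_direction
        v = ch.vectors[(Modality.VESTIBULAR, pref)]
        p = ch.vectors[(Modality.PROPRIOCEPTIVE, COMBINED_PAIRING[pref])]
        c = ch.vectors[(Modality.COMBINED, pref)]
        row = {
            "neuron_id": ch.neuron_id,
            "preferred_direction": pref.value,
            "cell_type": ch.label.cell_type,
            "modality_class": ch.label.modality_class,
            "shape_vest": ch.label.shape_vest,
            "shape_prop": ch.label.shape_prop,
            "s_vest": v.sensitivity,
            "phase_vest": v.phase_deg,
            "s_prop": p.sensitivity,
            "phase_prop": p.phase_deg,
            "s_combined": c.sensitivity,
            "phase_combined": c.phase_deg,
        }
        pred = pair_for_combined(
            {d: ch.vectors[(Modality.VESTIBULAR, d)] for d in Direction},
            {d: ch.vectors[(Modality.PROPRIOCEPTIVE, d)] for d in Direction},
            pref,
        )
        row["s_combined_pred"] = pred.sensitivity
        row["phase_combined_pred"] = pred.phase_deg
        if v.sensitivity > 0:
            idx = compute_indices(
                v.sensitivity, p.sensitivity, c.sensitivity,
                v.phase_deg, p.phase_deg,
            )
            row.update(
                head_ratio=idx.head_ratio,
                body_ratio=idx.body_ratio,
                coding_index=idx.coding_index,
                designation=idx.designation,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def measure_tuning_curve(
    neuron: GroundTruthNeuron,
    stimuli: list[ConditionStimulus] | None = None,
    rng: np.random.Generator | None = None,
) -> gf.TuningCurve:
    """Measure and fit the vestibular gain field of one neuron.

    Fits the whole-body sinusoid at each static head position, extracts the
    preferred-direction vestibular sensitivity, and fits the Gaussian tuning.
    """
    stimuli = stimuli if stimuli is not None else gain_field_stimuli()
    pref = Direction.IPSI if neuron.is_type_i else Direction.CONTRA
    positions, sens = [], []
    for stim in stimuli:
        rate, _ = simulate_rate(neuron, stim, rng=rng)
        fit = fit_kinematic(rate, stim)
        positions.append(stim.head_position_offset)
        sens.append(to_response_vector(fit, pref).sensitivity)
    return gf.fit_gaussian_tuning(np.asarray(positions), np.asarray(sens))


def population_rate_matrix(
    neurons: list[GroundTruthNeuron],
    stimuli: list[ConditionStimulus],
    decimate: int = 1,
    rng: np.random.Generator | None = None,
    imputed_tuning: dict[str, gf.TuningCurve] | None = None,
) -> np.ndarray:
    """Condition-concatenated (n_samples, n_neurons) rate matrix.

    ``imputed_tuning`` substitutes a gain-field curve for cells lacking a
    measured one (the imputation path of the population model); unimodal
    cells never receive imputed tuning.
    """
    cols = []
    for neuron in neurons:
        nrn = neuron
        if imputed_tuning and neuron.id in imputed_tuning and neuron.is_bimodal:
            tc = imputed_tuning[neuron.id]
            nrn = replace(
                neuron, tuning=GaussianTuning(tc.amplitude, tc.mu, tc.sigma)
            )
        parts = [simulate_rate(nrn, s, rng=rng)[0][::decimate] for s in stimuli]
        cols.append(np.concatenate(parts))
    return np.column_stack(cols)
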