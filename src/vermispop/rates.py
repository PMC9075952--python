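"""Spike-train filtering and direction segmentation.

Firing rates are computed by convolving the spike delta train with a unit-gain
Kaiser low-pass window whose cutoff is twice the frequency range of the
stimulus, then trials are split into ipsi/contra movement segments at the
velocity zero-crossings of the driving channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic_data import (
    ConditionStimulus,
    Direction,
    Segment,
    SpikeTrain,
)

__all__ = ["RateTrace", "spikes_to_rate", "segment_directions", "stimulus_freq_range"]


@dataclass
class RateTrace:
    """A smooth firing-rate trace (sp/s) on the stimulus grid.

    May ring slightly below zero near spikes: the low-pass kernel's sidelobes
    are preserved to keep filtering linear and area-exact.
    """

    t: np.ndarray
    rate: np.ndarray
    neuron_id: str = ""
    trial_id: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if len(self.t) != len(self.rate):
            raise ValueError("t and rate must share one length")


def stimulus_freq_range(stim: ConditionStimulus) -> float:
    """Frequency range (Hz) of a stimulus for choosing the filter cutoff.

    Sinusoids: the stimulation frequency. Transient active-like pulses: the
    reciprocal of the half-cycle duration (2 Hz for 500-ms half-cycles). The
    rate filter cuts off at twice this range.
    """
    return stim.freq_range


def _kaiser_lowpass(cutoff_hz: float, fs: float, beta: float) -> np.ndarray:
    """Unit-DC-gain FIR low-pass (Kaiser window), odd length for zero phase."""
    numtaps = int(round(3.0 * fs / cutoff_hz))
    numtaps += 1 - numtaps % 2  # make odd
    return signal.firwin(numtaps, cutoff_hz, window=("kaiser", beta), fs=fs)


def spikes_to_rate(
    spikes: SpikeTrain | list[SpikeTrain],
    grid: np.ndarray,
    stimulus_freq_range_hz: float,
    beta: float = 6.0,
) -> RateTrace:
    """Convert spike train(s) to a smooth firing rate on a uniform grid.

    The delta train (one impulse of area 1 per spike) is convolved with a
    unit-area Kaiser low-pass window cut off at 2 × ``stimulus_freq_range_hz``.
    Filtering is linear: a list of trains yields the trial-averaged rate.
    An empty train maps to a zero trace.
    """
    grid = np.asarray(grid, dtype=float)
    dt = grid[1] - grid[0]
    if not np.allclose(np.diff(grid), dt):
        raise ValueError("grid must be uniform")
    fs = 1.0 / dt
    trains = spikes if isinstance(spikes, list) else [spikes]
    delta = np.zeros(len(grid))
    for train in trains:
        times = train.spike_times
        idx = np.clip(np.round((times - grid[0]) / dt).astype(int), 0, len(grid) - 1)
        np.add.at(delta, idx, 1.0 / dt)
    delta /= max(len(trains), 1)
    taps = _kaiser_lowpass(2.0 * stimulus_freq_range_hz, fs, beta)
    rate = signal.fftconvolve(delta, taps, mode="same")
    # NOTE: the windowed-sinc kernel rings slightly negative; clipping here
    # would destroy the filter's linearity and unit-area property, so small
    # negative excursions are left in place.
    trial_id = trains[0].trial_id if len(trains) == 1 else None
    neuron_id = trains[0].neuron_id if trains else ""
    return RateTrace(t=grid, rate=rate, neuron_id=neuron_id, trial_id=trial_id)


def segment_directions(
    stim: ConditionStimulus,
    rate: RateTrace | None = None,
) -> dict[Direction, list[Segment]]:
    """Split a stimulus into ipsi/contra segments by driving-channel velocity.

    Uses the stimulus's stored labels when present, otherwise derives
    non-overlapping segments covering all nonzero-velocity samples from the
    sign runs of the driving channel's velocity (ipsi = positive velocity).
    """
    vel = stim.trajectories[stim.driving_channel].vel
    if np.allclose(vel, 0.0):
        raise ValueError("stimulus has no movement to segment")
    if rate is not None and len(rate.rate) != len(vel):
        raise ValueError("rate trace and stimulus are on different grids")
    if stim.segments:
        segments = stim.segments
    else:
        sign = np.sign(vel)
        segments = []
        start = None
        current = 0.0
        for i, s in enumerate(np.append(sign, 0.0)):
            if s != current:
                if current != 0.0 and start is not None:
                    segments.append(
                        Segment(
                            start=start,
                            stop=i,
                            direction=(
                                Direction.IPSI if current > 0 else Direction.CONTRA
                            ),
                        )
                    )
                start = i if s != 0.0 else None
                current = s
    out: dict[Direction, list[Segment]] = {Direction.IPSI: [], Direction.CONTRA: []}
    for seg in segments:
        out[seg.direction].append(seg)
    return out
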