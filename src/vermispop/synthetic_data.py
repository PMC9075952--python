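"""Synthetic stimuli, ground-truth neurons, spike trains and target populations.

Everything downstream (filtering, constrained kinematic fits, taxonomy,
summation and population models) is exercised on data produced here, so the
generator encodes the study conditions explicitly:

- 500-ms "active-like" raised-cosine velocity half-cycles displacing the head
  or body by ±30° (mimicking orienting gaze-shift head movements);
- 1-Hz, ±40°/s sinusoidal whole-body rotations, optionally with the head held
  statically at one of five positions (−30…30°) for the gain-field paradigm;
- heterogeneous Purkinje-like neurons obeying a direction-dependent kinematic
  model (bias + position/velocity/acceleration terms per channel), with a
  ~75/25 bimodal/unimodal mix and sensitivity/phase distributions matching the
  recorded population statistics;
- rostral-fastigial-like targets built as non-positive weighted sums of
  Purkinje rates, and mossy-fiber-like inputs with independently drawn
  vestibular and neck (gain, phase) phasors.

All sampling is deterministic under a fixed seed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .phasor import (
    branch_sign,
    coeffs_to_sensitivity_phase,
    sensitivity_phase_to_coeffs,
)

DEFAULT_FS = 1000.0  # Hz, matches the 1-kHz acquisition grid

GAIN_FIELD_POSITIONS = (-30.0, -15.0, 0.0, 15.0, 30.0)  # degrees


class Channel(str, enum.Enum):
    HEAD_IN_SPACE = "head_in_space"
    BODY_IN_SPACE = "body_in_space"
    HEAD_ON_BODY = "head_on_body"


class Condition(str, enum.Enum):
    WHOLE_BODY = "whole_body"
    BODY_UNDER_HEAD = "body_under_head"
    HEAD_ON_BODY = "head_on_body"
    GAIN_FIELD = "gain_field"


class Direction(str, enum.Enum):
    IPSI = "ipsi"
    CONTRA = "contra"

    @property
    def opposite(self) -> "Direction":
        return Direction.CONTRA if self is Direction.IPSI else Direction.IPSI


class Modality(str, enum.Enum):
    VESTIBULAR = "vestibular"
    PROPRIOCEPTIVE = "proprioceptive"
    COMBINED = "combined"


@dataclass
class MotionTrajectory:
    """Time-aligned angular kinematics (deg, deg/s, deg/s²) for one channel."""

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    acc: np.ndarray
    channel: Channel

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.vel = np.asarray(self.vel, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        n = len(self.t)
        if not (len(self.pos) == len(self.vel) == len(self.acc) == n):
            raise ValueError("trajectory arrays must share one length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        self.channel = Channel(self.channel)

    @property
    def fs(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    def kinematic_matrix(self) -> np.ndarray:
        """(n, 3) design block of [position, velocity, acceleration]."""
        return np.column_stack([self.pos, self.vel, self.acc])

    def check_derivatives(self, tol_deg: float = 1e-6) -> None:
        """Verify displacement equals the integral of velocity (trapezoid)."""
        dt = np.diff(self.t)
        disp = np.sum((self.vel[1:] + self.vel[:-1]) / 2 * dt)
        if abs((self.pos[-1] - self.pos[0]) - disp) > tol_deg:
            raise ValueError("velocity is not the derivative of position")


@dataclass
class Segment:
    """Half-open sample range [start, stop) with a movement direction label."""

    start: int
    stop: int
    direction: Direction


@dataclass
class ConditionStimulus:
    """A full stimulus: per-channel trajectories plus direction segments."""

    condition: Condition
    trajectories: dict[Channel, MotionTrajectory]
    segments: list[Segment]
    head_position_offset: float = 0.0
    freq_range: float = 1.0  # Hz; drives the rate-filter cutoff (2x this)

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.trajectories = {Channel(k): v for k, v in self.trajectories.items()}
        self._check_condition_invariants()

    @property
    def t(self) -> np.ndarray:
        return next(iter(self.trajectories.values())).t

    def trajectory(self, channel: Channel | str) -> MotionTrajectory:
        return self.trajectories[Channel(channel)]

    @property
    def driving_channel(self) -> Channel:
        """The channel whose velocity defines movement direction and the fit."""
        return {
            Condition.WHOLE_BODY: Channel.HEAD_IN_SPACE,
            Condition.GAIN_FIELD: Channel.HEAD_IN_SPACE,
            Condition.BODY_UNDER_HEAD: Channel.BODY_IN_SPACE,
            Condition.HEAD_ON_BODY: Channel.HEAD_ON_BODY,
        }[self.condition]

    def _check_condition_invariants(self) -> None:
        def is_zero(ch: Channel) -> bool:
            tr = self.trajectories[ch]
            return bool(np.allclose(tr.vel, 0.0) and np.allclose(tr.acc, 0.0))

        cond = self.condition
        if cond is Condition.WHOLE_BODY and not is_zero(Channel.HEAD_ON_BODY):
            raise ValueError("whole-body rotation must keep head-on-body fixed")
        if cond is Condition.BODY_UNDER_HEAD and not is_zero(Channel.HEAD_IN_SPACE):
            raise ValueError("body-under-head rotation must keep the head earth-fixed")
        if cond is Condition.HEAD_ON_BODY and not is_zero(Channel.BODY_IN_SPACE):
            raise ValueError("head-on-body rotation must keep the body earth-fixed")
        if cond is Condition.GAIN_FIELD and not is_zero(Channel.HEAD_ON_BODY):
            raise ValueError("gain-field condition holds the head statically on the body")


@dataclass
class GaussianTuning:
    """Gain-field tuning: vestibular sensitivity vs static head-on-body position.

    ``amplitude`` is the peak sensitivity ((sp/s)/(°/s)) of the measured curve
    A·exp(−(p−μ)²/2σ²); the rate model rescales the vestibular drive by this
    curve normalized to the cell's own preferred-direction sensitivity.
    """

    amplitude: float
    mu: float
    sigma: float

    def __call__(self, position_deg: np.ndarray | float) -> np.ndarray | float:
        p = np.asarray(position_deg, dtype=float)
        out = self.amplitude * np.exp(-((p - self.mu) ** 2) / (2.0 * self.sigma**2))
        return float(out) if np.isscalar(position_deg) else out


@dataclass
class GroundTruthNeuron:
    """Forward model of one Purkinje-like cell.

    Coefficient triples (c_p, c_v, c_a) are keyed by (modality, direction).
    Within each key all three coefficients share one sign (the model's
    sign-consistency constraint). Unimodal cells have all proprioceptive
    triples zero. ``tuning``, if present, multiplies the vestibular drive by
    the cell's Gaussian gain field evaluated at the instantaneous head-on-body
    position, normalized so that a self-consistent cell is unscaled at 0°.
    """

    id: str
    baseline: float  # sp/s
    coeffs: dict[tuple[Modality, Direction], tuple[float, float, float]]
    tuning: GaussianTuning | None = None
    noise_sd: float = 0.0  # additive rate noise, sp/s
    shape_vest: str = "linear"
    shape_prop: str = "none"
    is_type_i: bool = True

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        for key, triple in self.coeffs.items():
            branch_sign(*triple)  # raises on mixed signs

    def coeff(self, modality: Modality, direction: Direction) -> tuple[float, float, float]:
        return self.coeffs.get((modality, direction), (0.0, 0.0, 0.0))

    @property
    def is_bimodal(self) -> bool:
        return any(
            any(c != 0.0 for c in self.coeff(Modality.PROPRIOCEPTIVE, d))
            for d in Direction
        )

    def sensitivity_phase(
        self, modality: Modality, direction: Direction, freq: float = 1.0
    ) -> tuple[float, float]:
        return coeffs_to_sensitivity_phase(*self.coeff(modality, direction), freq)

    @property
    def preferred_vest_sensitivity(self) -> float:
        pref = Direction.IPSI if self.is_type_i else Direction.CONTRA
        return self.sensitivity_phase(Modality.VESTIBULAR, pref)[0]


@dataclass
class SpikeTrain:
    spike_times: np.ndarray  # seconds, strictly increasing
    trial_id: int
    neuron_id: str
    condition: Condition

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if len(self.spike_times) > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError("spike times must be strictly increasing")


@dataclass
class PopulationSpec:
    """Sampling recipe for a heterogeneous Purkinje-like population.

    Sensitivity/phase means and SDs default to the recorded population
    statistics: Type I vestibular 0.42 ± 0.37 (sp/s)/(°/s) at 6 ± 31°, Type II
    0.31 ± 0.34 at 172 ± 42°; proprioceptive 0.12 ± 0.44 at 159 ± 29° (Type I
    cells) and 0.13 ± 0.46 at −27 ± 20° (Type II cells).
    """

    n_neurons: int = 73
    fraction_bimodal: float = 54.0 / 73.0
    fraction_type_i: float = 32.0 / 73.0
    shape_mix: dict[str, float] = field(
        default_factory=lambda: {
            "linear": 0.40,
            "rectifying": 0.35,
            "v_shaped": 0.20,
            "other": 0.05,
        }
    )
    vest_stats: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            # type: (S_mean, S_sd, phase_mean, phase_sd)
            "I": (0.42, 0.37, 6.0, 31.0),
            "II": (0.31, 0.34, 172.0, 42.0),
        }
    )
    prop_stats: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "I": (0.12, 0.44, 159.0, 29.0),
            "II": (0.13, 0.46, -27.0, 20.0),
        }
    )
    baseline_mean: float = 80.0  # sp/s; keeps rectification rare
    baseline_sd: float = 15.0
    noise_sd: float = 0.0
    with_tuning: bool = True
    tuning_sigma_mean: float = 7.2  # degrees
    tuning_sigma_sd: float = 2.0
    tuning_mu_sd: float = 5.0  # degrees
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name, frac in (
            ("fraction_bimodal", self.fraction_bimodal),
            ("fraction_type_i", self.fraction_type_i),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        total = sum(self.shape_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("shape_mix must sum to 1")


# ---------------------------------------------------------------------------
# Stimulus construction
# ---------------------------------------------------------------------------


def _assemble_stimulus(
    condition: Condition,
    t: np.ndarray,
    pos: np.ndarray,
    vel: np.ndarray,
    acc: np.ndarray,
    segments: list[Segment],
    head_offset: float = 0.0,
    freq_range: float = 1.0,
) -> ConditionStimulus:
    """Distribute one driving trajectory onto the three channels."""
    zeros = np.zeros_like(pos)

    def traj(ch: Channel, p, v, a) -> MotionTrajectory:
        return MotionTrajectory(t=t, pos=p, vel=v, acc=a, channel=ch)

    if condition is Condition.WHOLE_BODY:
        chans = {
            Channel.HEAD_IN_SPACE: traj(Channel.HEAD_IN_SPACE, pos, vel, acc),
            Channel.BODY_IN_SPACE: traj(Channel.BODY_IN_SPACE, pos, vel, acc),
            Channel.HEAD_ON_BODY: traj(Channel.HEAD_ON_BODY, zeros, zeros, zeros),
        }
    elif condition is Condition.BODY_UNDER_HEAD:
        chans = {
            Channel.HEAD_IN_SPACE: traj(Channel.HEAD_IN_SPACE, zeros, zeros, zeros),
            Channel.BODY_IN_SPACE: traj(Channel.BODY_IN_SPACE, pos, vel, acc),
            Channel.HEAD_ON_BODY: traj(Channel.HEAD_ON_BODY, -pos, -vel, -acc),
        }
    elif condition is Condition.HEAD_ON_BODY:
        chans = {
            Channel.HEAD_IN_SPACE: traj(Channel.HEAD_IN_SPACE, pos, vel, acc),
            Channel.BODY_IN_SPACE: traj(Channel.BODY_IN_SPACE, zeros, zeros, zeros),
            Channel.HEAD_ON_BODY: traj(Channel.HEAD_ON_BODY, pos, vel, acc),
        }
    elif condition is Condition.GAIN_FIELD:
        chans = {
            Channel.HEAD_IN_SPACE: traj(Channel.HEAD_IN_SPACE, pos + head_offset, vel, acc),
            Channel.BODY_IN_SPACE: traj(Channel.BODY_IN_SPACE, pos, vel, acc),
            Channel.HEAD_ON_BODY: traj(
                Channel.HEAD_ON_BODY, zeros + head_offset, zeros, zeros
            ),
        }
    else:  # pragma: no cover
        raise ValueError(condition)
    return ConditionStimulus(
        condition=condition,
        trajectories=chans,
        segments=segments,
        head_position_offset=head_offset,
        freq_range=freq_range,
    )


def make_active_like_trajectory(
    amplitude: float = 30.0,
    duration_half_cycle: float = 0.5,
    n_repeats: int = 10,
    direction_order: str = "alternating",
    condition: Condition | str = Condition.WHOLE_BODY,
    fs: float = DEFAULT_FS,
) -> ConditionStimulus:
    """Active-like stimulus: alternating 500-ms raised-cosine velocity pulses.

    Each half-cycle is a smooth unidirectional velocity profile
    v(t) = V/2·(1 − cos(2πt/T)) with V = 2·amplitude/T, displacing the driving
    channel by ±``amplitude`` degrees, emulating the head trajectory of ±30°
    orienting gaze shifts. ``n_repeats`` yields n ipsi + n contra segments.
    """
    if duration_half_cycle <= 0:
        raise ValueError("duration_half_cycle must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    condition = Condition(condition)
    n_half = int(round(duration_half_cycle * fs))
    n_cycles = 2 * n_repeats
    n = n_half * n_cycles
    t = np.arange(n) / fs
    tau = (np.arange(n_half) / fs)  # time within a half-cycle
    peak_vel = 2.0 * amplitude / duration_half_cycle
    v_pulse = peak_vel / 2.0 * (1.0 - np.cos(2.0 * np.pi * tau / duration_half_cycle))
    a_pulse = (
        peak_vel * np.pi / duration_half_cycle
        * np.sin(2.0 * np.pi * tau / duration_half_cycle)
    )
    # analytic displacement within a half-cycle
    p_pulse = peak_vel / 2.0 * (
        tau - duration_half_cycle / (2.0 * np.pi)
        * np.sin(2.0 * np.pi * tau / duration_half_cycle)
    )

    if direction_order == "alternating":
        signs = [1.0 if k % 2 == 0 else -1.0 for k in range(n_cycles)]
    elif direction_order == "blocked":
        signs = [1.0] * n_repeats + [-1.0] * n_repeats
    else:
        raise ValueError("direction_order must be 'alternating' or 'blocked'")

    pos = np.empty(n)
    vel = np.empty(n)
    acc = np.empty(n)
    segments: list[Segment] = []
    offset = 0.0
    for k, s in enumerate(signs):
        sl = slice(k * n_half, (k + 1) * n_half)
        vel[sl] = s * v_pulse
        acc[sl] = s * a_pulse
        pos[sl] = offset + s * p_pulse
        offset += s * amplitude
        segments.append(
            Segment(
                start=k * n_half,
                stop=(k + 1) * n_half,
                direction=Direction.IPSI if s > 0 else Direction.CONTRA,
            )
        )
    # transient stimulus: frequency range taken as 1 / half-cycle duration
    return _assemble_stimulus(
        condition, t, pos, vel, acc, segments,
        freq_range=1.0 / duration_half_cycle,
    )


def make_sinusoid_stimulus(
    freq: float = 1.0,
    peak_vel: float = 40.0,
    head_offset: float = 0.0,
    n_cycles: int = 5,
    condition: Condition | str | None = None,
    fs: float = DEFAULT_FS,
) -> ConditionStimulus:
    """Sinusoidal rotation: vel = peak_vel·sin(2πft), zero-mean position.

    With a nonzero ``head_offset`` (or ``condition='gain_field'``) the rotation
    is whole-body with the head statically oriented at ``head_offset`` degrees
    on the body, the gain-field paradigm (tested offsets −30…+30°).
    """
    import warnings

    if freq <= 0:
        raise ValueError("freq must be positive")
    if condition is None:
        condition = (
            Condition.GAIN_FIELD if head_offset != 0.0 else Condition.WHOLE_BODY
        )
    condition = Condition(condition)
    if condition is Condition.GAIN_FIELD and not -30.0 <= head_offset <= 30.0:
        warnings.warn(
            f"head offset {head_offset}° is outside the tested ±30° range",
            stacklevel=2,
        )
    n_per_cycle = int(round(fs / freq))
    n = n_per_cycle * n_cycles
    t = np.arange(n) / fs
    omega = 2.0 * np.pi * freq
    vel = peak_vel * np.sin(omega * t)
    pos = -peak_vel / omega * np.cos(omega * t)
    acc = peak_vel * omega * np.cos(omega * t)
    half = n_per_cycle // 2
    segments = []
    for k in range(2 * n_cycles):
        start, stop = k * half, min((k + 1) * half, n)
        if start >= stop:
            break
        segments.append(
            Segment(
                start=start,
                stop=stop,
                direction=Direction.IPSI if k % 2 == 0 else Direction.CONTRA,
            )
        )
    return _assemble_stimulus(
        condition, t, pos, vel, acc, segments, head_offset, freq_range=freq
    )


# ---------------------------------------------------------------------------
# Forward rate model
# ---------------------------------------------------------------------------


def simulate_rate(
    neuron: GroundTruthNeuron,
    stim: ConditionStimulus,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Evaluate the neuron's firing rate (sp/s) for a stimulus.

    Direction-dependent coefficient sets switch on the instantaneous velocity
    sign of the driving channel. During combined head-on-body rotation the
    proprioceptive system is driven in the complementary (opposite-label)
    direction, so the opposite-direction proprioceptive coefficients apply to
    the head-on-body channel. Vestibular drive is scaled by the Gaussian gain
    field (if any) evaluated at the current head-on-body position. The output
    is rectified at 0 sp/s; the fraction of rectified samples is returned.
    """
    for triple in neuron.coeffs.values():
        if not np.all(np.isfinite(triple)):
            raise ValueError("neuron coefficients must be finite")
    head = stim.trajectory(Channel.HEAD_IN_SPACE)
    hob = stim.trajectory(Channel.HEAD_ON_BODY)
    n = len(stim.t)
    rate = np.full(n, neuron.baseline, dtype=float)

    # Direction switching follows the stimulus's segment labels (equivalent to
    # the driving channel's velocity sign away from zero crossings); samples
    # outside labeled segments fall back to the instantaneous sign.
    if stim.segments:
        seg_ipsi = np.zeros(n, dtype=bool)
        covered = np.zeros(n, dtype=bool)
        for seg in stim.segments:
            covered[seg.start : seg.stop] = True
            if seg.direction is Direction.IPSI:
                seg_ipsi[seg.start : seg.stop] = True
    else:
        seg_ipsi = covered = None

    def add_contribution(traj: MotionTrajectory, modality: Modality,
                         flip_direction: bool = False,
                         scale: np.ndarray | float = 1.0) -> None:
        X = traj.kinematic_matrix()
        if seg_ipsi is not None:
            ipsi_mask = np.where(covered, seg_ipsi, traj.vel >= 0.0)
        else:
            ipsi_mask = traj.vel >= 0.0
        for direction, mask in ((Direction.IPSI, ipsi_mask),
                                (Direction.CONTRA, ~ipsi_mask)):
            key_dir = direction.opposite if flip_direction else direction
            triple = np.asarray(neuron.coeff(modality, key_dir))
            if not triple.any():
                continue
            contrib = X @ triple
            rate[mask] += (np.broadcast_to(np.asarray(scale, dtype=float), (n,))[mask]
                           * contrib[mask])

    # Vestibular drive: head-in-space kinematics, gain-field scaled.
    if neuron.tuning is not None:
        s_ref = neuron.preferred_vest_sensitivity
        scale = neuron.tuning(hob.pos) / s_ref if s_ref > 0 else 1.0
    else:
        scale = 1.0
    add_contribution(head, Modality.VESTIBULAR, scale=scale)

    # Proprioceptive drive.
    if stim.condition is Condition.BODY_UNDER_HEAD:
        add_contribution(
            stim.trajectory(Channel.BODY_IN_SPACE), Modality.PROPRIOCEPTIVE
        )
    elif stim.condition is Condition.HEAD_ON_BODY:
        add_contribution(hob, Modality.PROPRIOCEPTIVE, flip_direction=True)

    if neuron.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        rate = rate + rng.normal(0.0, neuron.noise_sd, size=n)

    rectified_fraction = float(np.mean(rate < 0.0))
    return np.clip(rate, 0.0, None), rectified_fraction


def simulate_spikes(
    rate: np.ndarray,
    t: np.ndarray,
    n_trials: int,
    rng_seed: int | np.random.Generator | None = None,
    neuron_id: str = "n0",
    condition: Condition = Condition.WHOLE_BODY,
) -> list[SpikeTrain]:
    """Draw inhomogeneous-Poisson spike trains from a rate trace.

    Per-bin Poisson counts at the grid resolution, spike times uniform within
    each bin; expected count per trial equals the integral of the rate.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be non-negative (rectify upstream)")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    dt = t[1] - t[0]
    trains = []
    for trial in range(n_trials):
        counts = rng.poisson(rate * dt)
        idx = np.repeat(np.arange(len(rate)), counts)
        times = t[idx] + rng.uniform(0.0, dt, size=len(idx))
        times.sort()
        # enforce strict ordering for coincident draws
        for i in range(1, len(times)):
            if times[i] <= times[i - 1]:
                times[i] = np.nextafter(times[i - 1], np.inf)
        trains.append(
            SpikeTrain(
                spike_times=times,
                trial_id=trial,
                neuron_id=neuron_id,
                condition=condition,
            )
        )
    return trains


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------


def _phase_for_branch(base_phase: float, want_positive_branch: bool) -> float:
    """Reflect a phase across ±90° if needed to land on the requested branch."""
    from .phasor import wrap_phase_deg

    on_positive = abs(wrap_phase_deg(base_phase)) < 90.0
    if on_positive == want_positive_branch:
        return wrap_phase_deg(base_phase)
    return wrap_phase_deg(180.0 - base_phase)


def _excitatory_branch(direction: Direction) -> bool:
    """An excitatory response in a direction maps to a coefficient branch:
    +1 for ipsi (positive velocity), −1 for contra."""
    return direction is Direction.IPSI


def _draw_direction_pair(
    rng: np.random.Generator,
    s_pref: float,
    phase_pref: float,
    pref_direction: Direction,
    shape: str,
    freq: float = 1.0,
) -> dict[Direction, tuple[float, float, float]]:
    """Build per-direction coefficient triples realizing a tuning shape.

    The preferred direction is excitatory with the drawn (S, phase); the
    non-preferred direction's magnitude and polarity follow the shape rules
    (0.2 (sp/s)/(°/s) threshold conventions).
    """
    nonpref = pref_direction.opposite
    if shape == "v_shaped":
        s_pref = max(s_pref, 0.25)
    phase_pref = _phase_for_branch(phase_pref, _excitatory_branch(pref_direction))
    out = {pref_direction: sensitivity_phase_to_coeffs(s_pref, phase_pref, freq)}

    jitter = rng.normal(0.0, 8.0)
    if shape == "linear":
        s_np = max(s_pref + rng.uniform(-0.15, 0.15), 0.02)
        excitatory = _excitatory_branch(pref_direction)  # same coefficients both ways
    elif shape == "rectifying":
        s_np = rng.uniform(0.02, 0.18)
        excitatory = _excitatory_branch(nonpref)
    elif shape == "v_shaped":
        s_np = max(0.2, s_pref - rng.uniform(0.0, 0.15))
        excitatory = _excitatory_branch(nonpref)
    elif shape == "other":
        s_np = s_pref + rng.uniform(0.25, 0.5)
        excitatory = _excitatory_branch(pref_direction)  # inhibitory, asymmetric
    else:
        raise ValueError(f"unknown shape {shape!r}")
    phase_np = _phase_for_branch(phase_pref + jitter, excitatory)
    out[nonpref] = sensitivity_phase_to_coeffs(s_np, phase_np, freq)
    return out


def _truncated_abs_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float = 0.05, hi: float = 1.5
) -> float:
    return float(np.clip(abs(rng.normal(mean, sd)), lo, hi))


def sample_population(spec: PopulationSpec) -> list[GroundTruthNeuron]:
    """Draw a seed-reproducible population realizing the spec's statistics.

    Counts of bimodal and Type I cells are exact (rounded fractions); drawn
    sensitivity/phase pairs are inverted into sign-consistent coefficient
    triples at f = 1 Hz so that a noiseless refit recovers them.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_neurons
    if n == 0:
        return []
    n_bimodal = int(round(spec.fraction_bimodal * n))
    n_type_i = int(round(spec.fraction_type_i * n))
    bimodal_flags = np.zeros(n, dtype=bool)
    bimodal_flags[:n_bimodal] = True
    rng.shuffle(bimodal_flags)
    type_i_flags = np.zeros(n, dtype=bool)
    type_i_flags[:n_type_i] = True
    rng.shuffle(type_i_flags)

    shapes = list(spec.shape_mix)
    shape_p = np.asarray([spec.shape_mix[s] for s in shapes], dtype=float)
    shape_p = shape_p / shape_p.sum()

    neurons = []
    for i in range(n):
        is_type_i = bool(type_i_flags[i])
        is_bimodal = bool(bimodal_flags[i])
        tkey = "I" if is_type_i else "II"
        pref = Direction.IPSI if is_type_i else Direction.CONTRA

        s_mean, s_sd, ph_mean, ph_sd = spec.vest_stats[tkey]
        s_vest = _truncated_abs_normal(rng, s_mean, s_sd)
        ph_vest = rng.normal(ph_mean, ph_sd)
        shape_vest = str(rng.choice(shapes, p=shape_p))
        vest = _draw_direction_pair(rng, s_vest, ph_vest, pref, shape_vest)

        coeffs: dict[tuple[Modality, Direction], tuple[float, float, float]] = {
            (Modality.VESTIBULAR, d): vest[d] for d in Direction
        }
        shape_prop = "none"
        if is_bimodal:
            p_mean, p_sd, pph_mean, pph_sd = spec.prop_stats[tkey]
            s_prop = _truncated_abs_normal(rng, p_mean, p_sd, lo=0.08)
            ph_prop = rng.normal(pph_mean, pph_sd)
            # preferred proprioceptive direction is implied by the phase branch
            prop_pref = (
                Direction.IPSI if abs((ph_prop + 180) % 360 - 180) < 90
                else Direction.CONTRA
            )
            shape_prop = str(rng.choice(shapes, p=shape_p))
            prop = _draw_direction_pair(rng, s_prop, ph_prop, prop_pref, shape_prop)
            for d in Direction:
                coeffs[(Modality.PROPRIOCEPTIVE, d)] = prop[d]

        tuning = None
        if spec.with_tuning and is_bimodal:
            mu = float(rng.normal(0.0, spec.tuning_mu_sd))
            sigma = float(max(rng.normal(spec.tuning_sigma_mean, spec.tuning_sigma_sd), 3.0))
            s_pref = coeffs_to_sensitivity_phase(*vest[pref])[0]
            # self-consistent: tuning curve passes through S_pref at 0°
            amplitude = s_pref * math.exp(mu**2 / (2.0 * sigma**2))
            tuning = GaussianTuning(amplitude=amplitude, mu=mu, sigma=sigma)

        neurons.append(
            GroundTruthNeuron(
                id=f"pc{i:03d}",
                baseline=float(max(rng.normal(spec.baseline_mean, spec.baseline_sd), 10.0)),
                coeffs=coeffs,
                tuning=tuning,
                noise_sd=spec.noise_sd,
                shape_vest=shape_vest,
                shape_prop=shape_prop,
                is_type_i=is_type_i,
            )
        )
    return neurons


# ---------------------------------------------------------------------------
# Mossy fibers and rFN-like targets
# ---------------------------------------------------------------------------


@dataclass
class MossyFiber:
    """Independent vestibular + neck phasor responder (both at f = 1 Hz)."""

    gain_vest: float
    phase_vest: float
    gain_neck: float
    phase_neck: float
    baseline: float = 50.0

    def rate(self, stim: ConditionStimulus, freq: float = 1.0) -> np.ndarray:
        head = stim.trajectory(Channel.HEAD_IN_SPACE)
        out = np.full(len(stim.t), self.baseline)
        cv = sensitivity_phase_to_coeffs(self.gain_vest, self.phase_vest, freq)
        out = out + head.kinematic_matrix() @ np.asarray(cv)
        # Neck drive mirrors the proprioceptive convention of the Purkinje model.
        if stim.condition is Condition.BODY_UNDER_HEAD:
            cn = sensitivity_phase_to_coeffs(self.gain_neck, self.phase_neck, freq)
            out = out + (
                stim.trajectory(Channel.BODY_IN_SPACE).kinematic_matrix()
                @ np.asarray(cn)
            )
        elif stim.condition is Condition.HEAD_ON_BODY:
            cn = sensitivity_phase_to_coeffs(self.gain_neck, self.phase_neck, freq)
            out = out + (
                stim.trajectory(Channel.HEAD_ON_BODY).kinematic_matrix()
                @ np.asarray(cn)
            )
        return np.clip(out, 0.0, None)


MOSSY_VARIANTS = {
    "ref": (0.6, 0.1, 20.0, 5.0),
    "gain2": (1.2, 0.2, 20.0, 5.0),
    "gain0.5": (0.3, 0.05, 20.0, 5.0),
    "phase2": (0.6, 0.1, 40.0, 10.0),
    "phase0.5": (0.6, 0.1, 10.0, 2.5),
}


def simulate_mossy_fiber(
    n_fibers: int,
    gain_mean: float = 0.6,
    gain_sd: float = 0.1,
    phase_mean_deg: float = 20.0,
    phase_sd: float = 5.0,
    rng_seed: int | np.random.Generator | None = None,
) -> list[MossyFiber]:
    """Draw mossy-fiber-like responders with normal (gain, phase) distributions.

    Defaults match vestibular-nuclei response statistics (0.6 ± 0.1
    (sp/s)/(°/s), 20 ± 5°); the doubled/halved gain and phase variants are
    available via :data:`MOSSY_VARIANTS`.
    """
    if gain_mean < 0:
        raise ValueError("gain_mean must be non-negative")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    fibers = []
    for _ in range(n_fibers):
        fibers.append(
            MossyFiber(
                gain_vest=float(max(rng.normal(gain_mean, gain_sd), 0.0)),
                phase_vest=float(rng.normal(phase_mean_deg, phase_sd)),
                gain_neck=float(max(rng.normal(gain_mean, gain_sd), 0.0)),
                phase_neck=float(rng.normal(phase_mean_deg, phase_sd)),
            )
        )
    return fibers


def simulate_rfn_target(
    purkinje_rates: np.ndarray,
    weights: np.ndarray,
    baseline: float = 60.0,
    mossy_rates: np.ndarray | None = None,
    mossy_weights: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng_seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """rFN-like target: non-positive-weighted Purkinje sum (+ mossy + noise).

    ``purkinje_rates`` is (n_samples, n_cells); all Purkinje weights must be
    ≤ 0 (inhibitory synapses) and mossy weights ≥ 0 (excitatory input).
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights > 0):
        raise ValueError("Purkinje weights must be non-positive")
    out = np.full(purkinje_rates.shape[0], float(baseline))
    out = out + purkinje_rates @ weights
    if mossy_rates is not None:
        mossy_weights = np.asarray(mossy_weights, dtype=float)
        if np.any(mossy_weights < 0):
            raise ValueError("mossy weights must be non-negative")
        out = out + mossy_rates @ mossy_weights
    if noise_sd > 0:
        rng = (
            rng_seed
            if isinstance(rng_seed, np.random.Generator)
            else np.random.default_rng(rng_seed)
        )
        out = out + rng.normal(0.0, noise_sd, size=len(out))
    return np.clip(out, 0.0, None)
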