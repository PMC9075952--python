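"""Plain-text I/O: trial CSVs, spike CSVs, coefficient JSON, run configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematic_fit import KinematicCoefficients
from .synthetic_data import (
    Channel,
    Condition,
    ConditionStimulus,
    Direction,
    MotionTrajectory,
    Segment,
    SpikeTrain,
)

TRIAL_COLUMNS = [
    "t",
    "head_pos", "head_vel", "head_acc",
    "body_pos", "body_vel", "body_acc",
    "hob_pos",
    "rate",
]


def write_trials_csv(path, stim: ConditionStimulus, rate: np.ndarray) -> None:
    head = stim.trajectory(Channel.HEAD_IN_SPACE)
    body = stim.trajectory(Channel.BODY_IN_SPACE)
    hob = stim.trajectory(Channel.HEAD_ON_BODY)
    df = pd.DataFrame(
        {
            "t": stim.t,
            "head_pos": head.pos, "head_vel": head.vel, "head_acc": head.acc,
            "body_pos": body.pos, "body_vel": body.vel, "body_acc": body.acc,
            "hob_pos": hob.pos,
            "rate": np.asarray(rate, dtype=float),
        }
    )
    df.to_csv(path, index=False)


def read_trials_csv(path, condition: Condition | str) -> tuple[ConditionStimulus, np.ndarray]:
    """Rebuild a stimulus (+ rate) from a trial CSV; segments are re-derived
    from the driving channel's velocity sign by :func:`rates.segment_directions`."""
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    dt = t[1] - t[0]

    def traj(prefix: str, ch: Channel) -> MotionTrajectory:
        pos = df[f"{prefix}_pos"].to_numpy()
        if f"{prefix}_vel" in df:
            vel = df[f"{prefix}_vel"].to_numpy()
            acc = df[f"{prefix}_acc"].to_numpy()
        else:
            vel = np.gradient(pos, dt)
            acc = np.gradient(vel, dt)
        return MotionTrajectory(t=t, pos=pos, vel=vel, acc=acc, channel=ch)

    hob_pos = df["hob_pos"].to_numpy()
    hob = MotionTrajectory(
        t=t,
        pos=hob_pos,
        vel=np.gradient(hob_pos, dt) if np.ptp(hob_pos) > 1e-9 else np.zeros_like(t),
        acc=np.zeros_like(t) if np.ptp(hob_pos) <= 1e-9 else np.gradient(
            np.gradient(hob_pos, dt), dt
        ),
        channel=Channel.HEAD_ON_BODY,
    )
    stim = ConditionStimulus(
        condition=Condition(condition),
        trajectories={
            Channel.HEAD_IN_SPACE: traj("head", Channel.HEAD_IN_SPACE),
            Channel.BODY_IN_SPACE: traj("body", Channel.BODY_IN_SPACE),
            Channel.HEAD_ON_BODY: hob,
        },
        segments=_derive_segments(stim_vel=_driving_vel(df, condition)),
        head_position_offset=float(hob_pos[0]),
    )
    return stim, df["rate"].to_numpy()


def _driving_vel(df: pd.DataFrame, condition) -> np.ndarray:
    cond = Condition(condition)
    if cond is Condition.BODY_UNDER_HEAD:
        return df["body_vel"].to_numpy()
    if cond is Condition.HEAD_ON_BODY:
        dt = df["t"].iloc[1] - df["t"].iloc[0]
        return np.gradient(df["hob_pos"].to_numpy(), dt)
    return df["head_vel"].to_numpy()


def _derive_segments(stim_vel: np.ndarray) -> list[Segment]:
    sign = np.sign(stim_vel)
    segments: list[Segment] = []
    current, start = 0.0, None
    for i, s in enumerate(np.append(sign, 0.0)):
        if s != current:
            if current != 0.0 and start is not None:
                segments.append(
                    Segment(
                        start=start, stop=i,
                        direction=Direction.IPSI if current > 0 else Direction.CONTRA,
                    )
                )
            start = i if s != 0.0 else None
            current = s
    return segments


def write_spikes_csv(path, trains: list[SpikeTrain]) -> None:
    rows = [
        {"trial_id": tr.trial_id, "spike_time_s": t}
        for tr in trains
        for t in tr.spike_times
    ]
    pd.DataFrame(rows, columns=["trial_id", "spike_time_s"]).to_csv(path, index=False)


def read_spikes_csv(path, neuron_id: str = "", condition=Condition.WHOLE_BODY) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(
            spike_times=np.sort(g["spike_time_s"].to_numpy()),
            trial_id=int(tid),
            neuron_id=neuron_id,
            condition=Condition(condition),
        )
        for tid, g in df.groupby("trial_id")
    ]


def coefficients_to_dict(fit: KinematicCoefficients) -> dict:
    return {
        "b": fit.b,
        "channel": fit.channel.value,
        "vaf": fit.vaf,
        "rss": fit.rss,
        "freq": fit.freq,
        "modality": fit.modality.value,
        "directions": {
            d.value: {
                "c_p": df.c_p, "c_v": df.c_v, "c_a": df.c_a,
                "ci_95": df.ci_95,
                "significant": df.significant,
                "present": df.present,
            }
            for d, df in fit.directions.items()
        },
    }


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_config(path) -> dict:
    """Read a JSON or YAML run configuration by extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yml", ".yaml"}:
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
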