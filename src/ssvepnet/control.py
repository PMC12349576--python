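"""Classifier-to-quadrotor command mapping with a kinematic flight model.

Four fixed objects sit on the ground plane; a decoded class k sends the
quadrotor to a waypoint directly above object k at a fixed cruise altitude
of 3 m.  Flight is constant-speed straight-line kinematics: each step moves
the vehicle toward the waypoint by min(speed*dt, remaining distance), never
changing altitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Scenario", "FlightState", "label_to_waypoint", "step_flight",
           "run_mission"]

DEFAULT_OBJECTS = (
    (1.0, 0.0, 0.12),    # class 0
    (0.0, -1.0, 0.12),   # class 1
    (-1.0, 0.0, 0.12),   # class 2
    (0.0, 1.0, 0.12),    # class 3
)


@dataclass(frozen=True)
class Scenario:
    objects: tuple = DEFAULT_OBJECTS
    start: tuple = (0.0, 0.0, 3.0)
    altitude: float = 3.0

    def __post_init__(self):
        if len(self.objects) != 4:
            raise ValueError("the scenario has exactly 4 target objects")


@dataclass(frozen=True)
class FlightState:
    position: tuple
    time: float = 0.0


def label_to_waypoint(label: int, sc: Scenario = Scenario()) -> np.ndarray:
    """Waypoint directly above object `label` at cruise altitude."""
    if label not in (0, 1, 2, 3):
        raise ValueError(f"label must be in 0..3, got {label}")
    x, y, _ = sc.objects[label]
    return np.array([x, y, sc.altitude])


def step_flight(s: FlightState, waypoint, speed: float, dt: float) -> FlightState:
    """Advance dt seconds toward the waypoint at constant speed and altitude."""
    if speed <= 0 or dt <= 0:
        raise ValueError("speed and dt must be positive")
    pos = np.asarray(s.position, dtype=np.float64)
    wp = np.asarray(waypoint, dtype=np.float64)
    delta = wp - pos
    dist = float(np.linalg.norm(delta))
    step = min(speed * dt, dist)
    if dist > 0:
        pos = pos + delta * (step / dist)
    return FlightState(position=tuple(pos), time=s.time + dt)


def run_mission(outputs, sc: Scenario = Scenario(), speed: float = 0.5,
                dt: float = 0.05, tol: float = 1e-3, max_steps: int = 100000):
    """Fly to the waypoint of each decoded output in sequence.

    outputs: a sequence of one-hot/score vectors (argmax taken) or plain
    class indices.  Returns a list of (time, x, y, z, decoded_label) rows;
    each leg terminates within `tol` metres of its waypoint.
    """
    state = FlightState(position=tuple(np.asarray(sc.start, dtype=np.float64)))
    traj = [(state.time, *state.position, -1)]
    for out in outputs:
        arr = np.asarray(out)
        label = int(arr) if arr.ndim == 0 else int(np.argmax(arr))
        wp = label_to_waypoint(label, sc)
        for _ in range(max_steps):
            if np.linalg.norm(np.asarray(state.position) - wp) <= tol:
                break
            state = step_flight(state, wp, speed, dt)
            traj.append((state.time, *state.position, label))
        else:
            raise RuntimeError("leg did not converge within max_steps")
    return traj
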