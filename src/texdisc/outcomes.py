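"""Kinematic outcome measures computed from exploration traces.

Three per-trial outcomes summarise exploratory behaviour:

- scanning duration (s): time spent in contact with a texture while moving
  faster than a speed threshold, averaged over the three textures;
- path length (m): distance swept along the scanning axis while in
  contact, averaged over the three textures;
- mean scanning speed (m/s): mean scanning-axis speed over the
  above-threshold contact samples.

The speed gate (default 0.01 m/s) applies to duration and mean speed but
not to path length.  Textures never visited contribute zero to the
averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .haptics import KinematicTrace

N_TEXTURES = 3


@dataclass(frozen=True)
class TrialKinematics:
    scanning_duration: float
    path_length: float
    mean_scanning_speed: float


def compute_kinematics(
    trace: KinematicTrace,
    speed_threshold: float = 0.01,
    full_3d_speed: bool = False,
) -> TrialKinematics:
    """Per-trial kinematic outcomes from one trace.

    Speed is the magnitude of the y-velocity (the scanning axis) unless
    ``full_3d_speed`` is set.  A trace with no contact samples yields all
    zeros with a warning.
    """
    dt = trace.dt
    if full_3d_speed:
        speed = np.linalg.norm(trace.velocity, axis=1)
    else:
        speed = np.abs(trace.velocity[:, 1])
    contact = trace.contact
    if not contact.any():
        warnings.warn("trace has no contact samples; outcomes are zero")
        return TrialKinematics(0.0, 0.0, 0.0)

    durations = np.zeros(N_TEXTURES)
    paths = np.zeros(N_TEXTURES)
    dy = np.abs(np.diff(trace.position[:, 1], prepend=trace.position[0, 1]))
    for tid in range(N_TEXTURES):
        on = contact & (trace.texture_id == tid)
        durations[tid] = dt * np.count_nonzero(on & (speed > speed_threshold))
        paths[tid] = dy[on].sum()

    moving = contact & (speed > speed_threshold)
    mean_speed = float(speed[moving].mean()) if moving.any() else 0.0
    return TrialKinematics(
        scanning_duration=float(durations.mean()),
        path_length=float(paths.mean()),
        mean_scanning_speed=mean_speed,
    )
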