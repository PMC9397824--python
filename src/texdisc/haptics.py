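"""Haptic rendering of virtual grating textures and a simulated exploration loop.

The virtual scene is a horizontal table carrying three parallel rectangular
textures (long axis along y).  A grating force field acts tangentially
(along y) whenever the end effector is in contact with a texture; a stiff
PD "virtual wall" renders the table surface along z; in the passive
(robot-guided) condition an additional PD controller with inertial
feedforward drags the hand along a cycloidal reference trajectory.  The
device is transparent along x.

Contact means: end-effector height below the table height AND the (x, y)
position strictly inside one texture rectangle.

Because no physical robot or human is attached here, trials are *simulated*:
the hand + end effector are modelled as a point mass with viscous hand
impedance, driven by the rendered forces plus a scripted voluntary-force
policy, and integrated with a semi-implicit Euler scheme at the haptic
servo rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .stimuli import TrialSpec

TRACE_COLUMNS = [
    "time_s", "x", "y", "z", "vx", "vy", "vz",
    "Fg", "Fz", "Fhg", "Fx", "Fy", "Fz_total", "contact", "texture_id",
]


@dataclass(frozen=True)
class HapticParams:
    """Controller gains and scene geometry.

    Units: forces N, stiffness N/m, damping N·s/m, lengths m, masses kg.

    The grating amplitude, wall and guidance gains and the scene
    dimensions follow the desk-scale device configuration; the feedforward
    mass makes the inertial term of the guidance law dimensionally
    explicit (the guidance force adds the reference acceleration to
    stiffness/damping terms; with ``feedforward_mass`` = 1 kg the two
    readings coincide numerically).  ``hand_mass`` and ``hand_damping``
    parameterise the simulated hand + end-effector plant.
    """

    grating_amplitude: float = 3.0      # C
    wall_stiffness: float = 1960.0      # K_z
    wall_damping: float = 28.0          # B_z
    guidance_stiffness: float = 300.0   # K_hg
    guidance_damping: float = 60.0      # B_hg
    table_height: float = 0.001         # z_tbl
    texture_length: float = 0.176       # along y
    texture_width: float = 0.02         # along x
    texture_gap: float = 0.01           # along x
    feedforward_mass: float = 1.0       # m_v
    hand_mass: float = 1.0              # m_h
    hand_damping: float = 5.0           # b_h
    position_resolution: float = 2e-5   # robot resolution, m (reporting only)

    def __post_init__(self) -> None:
        for name in (
            "grating_amplitude", "wall_stiffness", "wall_damping",
            "guidance_stiffness", "guidance_damping",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("texture_length", "texture_width", "texture_gap",
                     "hand_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def texture_centers_x(self) -> tuple[float, float, float]:
        """x-coordinates of the three texture centres; the middle one is at 0."""
        pitch = self.texture_width + self.texture_gap
        return (-pitch, 0.0, pitch)


@dataclass(frozen=True)
class RobotState:
    """End-effector kinematic state (m, m/s, s)."""

    position: tuple[float, float, float]
    velocity: tuple[float, float, float]
    time: float = 0.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (*self.position, *self.velocity)):
            raise ValueError("robot state must be finite")


@dataclass(frozen=True)
class ReferencePoint:
    """Guidance reference sample: position, velocity, acceleration along y."""

    y: float
    yd: float
    ydd: float
    time: float = 0.0


@dataclass(frozen=True)
class ForceBreakdown:
    """Rendered force components at one instant (N)."""

    f_grating: float      # F_g: raw grating force
    f_texture: float      # F_rd: grating gated by contact
    f_wall: float         # F_z
    f_guidance: float     # F_hg
    total: tuple[float, float, float]  # (x, y, z)


def grating_force(y_ee: float, frequency: float, amplitude: float = 3.0) -> float:
    """Tangential grating force C·sin(2π f y_EE), bounded by ±C."""
    if frequency <= 0:
        raise ValueError(f"frequency must be > 0, got {frequency}")
    return amplitude * math.sin(2.0 * math.pi * frequency * y_ee)


def contact_test(
    state: RobotState, params: HapticParams
) -> tuple[bool, Optional[int]]:
    """Is the end effector touching a texture, and which one?

    Contact requires z below the table height and (x, y) strictly inside
    one of the three texture rectangles.  Texture ids are 0, 1, 2 from
    negative to positive x; the middle texture (id 1) is centred at the
    origin.
    """
    x, y, z = state.position
    if z >= params.table_height:
        return False, None
    if abs(y) >= params.texture_length / 2.0:
        return False, None
    # strict interior containment; the tiny tolerance keeps points that sit
    # mathematically on a texture edge out of contact despite float rounding
    half_w = params.texture_width / 2.0 - 1e-12
    for tid, cx in enumerate(params.texture_centers_x()):
        if abs(x - cx) < half_w:
            return True, tid
    return False, None


def table_force(state: RobotState, params: HapticParams) -> float:
    """Virtual-wall force K_z(z_tbl − z_EE) − B_z ż_EE below the table, else 0."""
    z = state.position[2]
    zd = state.velocity[2]
    if z >= params.table_height:
        return 0.0
    return params.wall_stiffness * (params.table_height - z) + params.wall_damping * (-zd)


def cycloidal_reference(
    t: float, y_start: float, y_end: float, duration: float
) -> ReferencePoint:
    """Cycloidal point-to-point motion law along y.

    y(t) = y_start + Δ·(t/T − sin(2πt/T)/(2π)); velocity and acceleration
    are its analytic derivatives.  Velocity and acceleration vanish at both
    segment endpoints, so concatenated segments are C²-smooth; the peak
    speed 2Δ/T occurs at mid-segment.
    """
    if duration <= 0:
        raise ValueError("segment duration must be > 0")
    if t < 0 or t > duration:
        raise ValueError(f"t={t} outside segment [0, {duration}]")
    delta = y_end - y_start
    tau = t / duration
    y = y_start + delta * (tau - math.sin(2.0 * math.pi * tau) / (2.0 * math.pi))
    yd = (delta / duration) * (1.0 - math.cos(2.0 * math.pi * tau))
    ydd = (2.0 * math.pi * delta / duration**2) * math.sin(2.0 * math.pi * tau)
    return ReferencePoint(y=y, yd=yd, ydd=ydd, time=t)


def guidance_force(
    state: RobotState,
    ref: ReferencePoint,
    in_contact: bool,
    params: HapticParams,
) -> float:
    """PD guidance with inertial feedforward, gated on texture contact.

    F_hg = m_v·ÿ_R + K_hg(y_R − y_EE) + B_hg(ẏ_R − ẏ_EE) while in contact,
    zero otherwise.
    """
    if not in_contact:
        return 0.0
    y, yd = state.position[1], state.velocity[1]
    return (
        params.feedforward_mass * ref.ydd
        + params.guidance_stiffness * (ref.y - y)
        + params.guidance_damping * (ref.yd - yd)
    )


def total_force(
    state: RobotState,
    ref: Optional[ReferencePoint],
    frequency: float,
    params: HapticParams,
    mode: str = "active",
) -> ForceBreakdown:
    """Compose the rendered force: gated grating + wall + (passive) guidance.

    ``frequency`` is the spatial frequency of the texture under the end
    effector (irrelevant when not in contact).  The x-component is always
    zero: the device is transparent along x.
    """
    if mode not in ("active", "passive"):
        raise ValueError(f"mode must be 'active' or 'passive', got {mode!r}")
    in_contact, _ = contact_test(state, params)
    f_g = grating_force(state.position[1], frequency, params.grating_amplitude)
    f_rd = f_g if in_contact else 0.0
    f_z = table_force(state, params)
    if mode == "passive" and ref is not None:
        f_hg = guidance_force(state, ref, in_contact, params)
    else:
        f_hg = 0.0
    return ForceBreakdown(
        f_grating=f_g,
        f_texture=f_rd,
        f_wall=f_z,
        f_guidance=f_hg,
        total=(0.0, f_rd + f_hg, f_z),
    )


# ---------------------------------------------------------------------------
# Kinematic traces
# ---------------------------------------------------------------------------


@dataclass
class KinematicTrace:
    """Fixed-timestep record of a simulated (or logged) exploration trial.

    Arrays are aligned samples; ``texture_id`` is −1 outside contact.
    ``y_ref`` (the guidance reference, NaN when inactive) is kept in memory
    for controller diagnostics but is not part of the CSV schema.
    """

    time: np.ndarray
    position: np.ndarray        # (n, 3)
    velocity: np.ndarray        # (n, 3)
    f_grating: np.ndarray
    f_wall: np.ndarray
    f_guidance: np.ndarray
    f_total: np.ndarray         # (n, 3)
    contact: np.ndarray         # bool
    texture_id: np.ndarray      # int, -1 for none
    y_ref: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.time) == 0:
            raise ValueError("empty trace")
        dts = np.diff(self.time)
        if len(dts) and (np.any(dts <= 0) or not np.allclose(dts, dts[0])):
            raise ValueError("trace must have strictly increasing, constant timestep")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0

    @property
    def last_texture_visited(self) -> Optional[int]:
        """Texture attributed to a response given outside any texture."""
        visited = self.texture_id[self.texture_id >= 0]
        return int(visited[-1]) if len(visited) else None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "x": self.position[:, 0],
                "y": self.position[:, 1],
                "z": self.position[:, 2],
                "vx": self.velocity[:, 0],
                "vy": self.velocity[:, 1],
                "vz": self.velocity[:, 2],
                "Fg": self.f_grating,
                "Fz": self.f_wall,
                "Fhg": self.f_guidance,
                "Fx": self.f_total[:, 0],
                "Fy": self.f_total[:, 1],
                "Fz_total": self.f_total[:, 2],
                "contact": self.contact.astype(int),
                "texture_id": self.texture_id,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "KinematicTrace":
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trace is missing columns: {missing}")
        return cls(
            time=df["time_s"].to_numpy(float),
            position=df[["x", "y", "z"]].to_numpy(float),
            velocity=df[["vx", "vy", "vz"]].to_numpy(float),
            f_grating=df["Fg"].to_numpy(float),
            f_wall=df["Fz"].to_numpy(float),
            f_guidance=df["Fhg"].to_numpy(float),
            f_total=df[["Fx", "Fy", "Fz_total"]].to_numpy(float),
            contact=df["contact"].to_numpy(bool),
            texture_id=df["texture_id"].to_numpy(int),
        )

    @classmethod
    def from_csv(cls, path) -> "KinematicTrace":
        return cls.from_dataframe(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Exploration policies and the simulation loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExplorationPolicy:
    """Scripted voluntary behaviour of the simulated participant.

    In both conditions the simulated hand keeps the end effector pressed
    onto the current texture (a constant downward force) and centred on it
    along x.  In the active condition the hand additionally tracks a
    self-generated cycloidal scanning target along y; in the passive
    condition the hand exerts no voluntary y-force and the robot guidance
    does the scanning.

    ``target_speed`` sets the peak sweep speed (m/s); sweeps run the full
    texture length, ``sweeps_per_texture`` one-way segments per texture.
    """

    target_speed: float = 0.17
    sweeps_per_texture: int = 2
    press_force: float = 2.0        # downward, N
    transfer_duration: float = 0.5  # s, repositioning between textures
    settle_duration: float = 0.2    # s, pressing down before sweeping
    xz_stiffness: float = 400.0     # hand PD toward texture centre / height
    xz_damping: float = 40.0
    y_stiffness: float = 150.0      # active-mode tracking of the scan target
    y_damping: float = 25.0


def _integrate(
    trial: TrialSpec,
    mode: str,
    policy: ExplorationPolicy,
    params: HapticParams,
    dt: float,
) -> KinematicTrace:
    """Semi-implicit Euler loop over the scripted exploration schedule."""
    L = params.texture_length
    y_lo, y_hi = -L / 2 * 0.95, L / 2 * 0.95  # stay inside the texture edge
    sweep_T = 2.0 * (y_hi - y_lo) / policy.target_speed
    centers = params.texture_centers_x()
    freqs = [s.spatial_frequency for s in trial.triplet]

    # schedule: per texture — transfer, settle (press down), sweeps
    segments: list[tuple[str, float, int, float, float]] = []
    for tid in range(3):
        segments.append(("transfer", policy.transfer_duration, tid, y_lo, y_lo))
        segments.append(("settle", policy.settle_duration, tid, y_lo, y_lo))
        a, b = y_lo, y_hi
        for _ in range(policy.sweeps_per_texture):
            segments.append(("sweep", sweep_T, tid, a, b))
            a, b = b, a

    n_steps = int(round(sum(s[1] for s in segments) / dt)) + 1
    time = np.empty(n_steps)
    pos = np.empty((n_steps, 3))
    vel = np.empty((n_steps, 3))
    f_g = np.empty(n_steps)
    f_z = np.empty(n_steps)
    f_hg = np.empty(n_steps)
    f_tot = np.empty((n_steps, 3))
    contact_arr = np.zeros(n_steps, dtype=bool)
    tid_arr = np.full(n_steps, -1, dtype=int)
    y_ref_arr = np.full(n_steps, np.nan)

    # start above the first texture, out of contact
    x, y, z = centers[0], y_lo, params.table_height + 0.004
    vx = vy = vz = 0.0
    m = params.hand_mass
    b_h = params.hand_damping
    t_global = 0.0
    i = 0

    for kind, seg_T, tid, ya, yb in segments:
        seg_steps = int(round(seg_T / dt))
        cx = centers[tid]
        for k in range(seg_steps):
            if i >= n_steps:
                break
            t_seg = k * dt
            state = RobotState((x, y, z), (vx, vy, vz), t_global)
            in_contact, touched = contact_test(state, params)

            ref: Optional[ReferencePoint] = None
            if kind == "sweep":
                ref = cycloidal_reference(min(t_seg, seg_T), ya, yb, seg_T)

            freq = freqs[touched] if touched is not None else freqs[tid]
            fb = total_force(state, ref if mode == "passive" else None,
                             freq, params, mode)

            # voluntary hand force
            hx = policy.xz_stiffness * (cx - x) - policy.xz_damping * vx
            hy = 0.0
            if kind == "transfer":
                # lift above the table and glide to the segment start
                z_target = params.table_height + 0.004
                hz = policy.xz_stiffness * (z_target - z) - policy.xz_damping * vz
                hy = policy.y_stiffness * (ya - y) - policy.y_damping * vy
            else:
                hz = -policy.press_force \
                    + policy.xz_damping * (-vz if z < params.table_height else 0.0)
                if mode == "active" and ref is not None:
                    hy = (policy.y_stiffness * (ref.y - y)
                          + policy.y_damping * (ref.yd - vy))

            ax = (fb.total[0] + hx - b_h * vx) / m
            ay = (fb.total[1] + hy - b_h * vy) / m
            az = (fb.total[2] + hz - b_h * vz) / m

            # semi-implicit Euler
            vx += dt * ax
            vy += dt * ay
            vz += dt * az
            x += dt * vx
            y += dt * vy
            z += dt * vz

            if not all(math.isfinite(v) for v in (x, y, z, vx, vy, vz)):
                raise FloatingPointError(
                    "exploration simulation diverged (non-finite state) with "
                    f"params {params} at t={t_global:.4f}s"
                )

            time[i] = t_global
            pos[i] = (x, y, z)
            vel[i] = (vx, vy, vz)
            f_g[i] = fb.f_grating
            f_z[i] = fb.f_wall
            f_hg[i] = fb.f_guidance
            f_tot[i] = fb.total
            contact_arr[i] = in_contact
            tid_arr[i] = touched if touched is not None else -1
            if kind == "sweep" and mode == "passive" and in_contact:
                y_ref_arr[i] = ref.y
            t_global += dt
            i += 1

    n = i
    return KinematicTrace(
        time=time[:n], position=pos[:n], velocity=vel[:n],
        f_grating=f_g[:n], f_wall=f_z[:n], f_guidance=f_hg[:n],
        f_total=f_tot[:n], contact=contact_arr[:n], texture_id=tid_arr[:n],
        y_ref=y_ref_arr[:n],
    )


def simulate_trial_exploration(
    trial: TrialSpec,
    mode: str = "active",
    policy: Optional[ExplorationPolicy] = None,
    params: Optional[HapticParams] = None,
    dt: float = 1e-3,
    rng: Optional[np.random.Generator] = None,
) -> KinematicTrace:
    """Simulate one trial's texture exploration and return its trace.

    The point-mass hand/end-effector plant m·ẍ = F_rendered + F_hand − b·ẋ
    is integrated with semi-implicit Euler at timestep ``dt`` (default the
    1 kHz haptic servo period).  The scripted policy visits the three
    textures left to right, sweeping each one along its full length; in
    passive mode the robot guidance performs the sweeps, in active mode a
    voluntary hand controller does.  ``rng`` is accepted for policy
    variants that jitter the schedule; the default policy is deterministic.
    """
    if mode not in ("active", "passive"):
        raise ValueError(f"mode must be 'active' or 'passive', got {mode!r}")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    policy = policy or ExplorationPolicy()
    params = params or HapticParams()
    return _integrate(trial, mode, policy, params, dt)


def render_force_profile(
    frequency: float,
    params: Optional[HapticParams] = None,
    n_points: int = 200,
) -> pd.DataFrame:
    """Grating force sampled over one texture length, for a given frequency."""
    params = params or HapticParams()
    y = np.linspace(-params.texture_length / 2, params.texture_length / 2, n_points)
    fg = params.grating_amplitude * np.sin(2 * np.pi * frequency * y)
    return pd.DataFrame({"y_m": y, "Fg_N": fg})
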