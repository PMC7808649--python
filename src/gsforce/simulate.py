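"""Synthetic giant-slalom run generator with exact ground truth.

A skier descends a uniformly inclined slope (relief angle alpha) along a
sinusoidal lateral line: in the slope-fixed frame (x lateral, u fall-line
distance in the slope plane) the line is x(u) = A*sin(pi*u/G) with G the
gate spacing, so turn switches (curvature sign changes) fall at u = j*G
and gates at the lateral apexes.  Speed evolves by an energy balance
where a fraction c of the potential-energy release is dissipated:

    v(u)^2 = v0^2 + 2*(1 - c)*g*sin(alpha)*u

The specific radial force required by the trajectory is the centripetal
term plus the in-plane gravity component projected on the radial
direction; the athlete realizes it with total limb force F = F_r / RF
split limb_split:1 between outside and inside plates.  Plate vectors are
re-expressed in raw sensor units through the inverse of a per-boot
calibration matrix, sensor noise and >8 Hz vibration are added, a clock
offset is applied to the trajectory stream, and both streams carry the
pre- and post-run jump impulses used for synchronization.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import AthleteProfile, CohortSpec, CourseConfig

FS_FORCE = 200.0  # Hz, force-plate acquisition
FS_TRAJ = 10.0  # Hz, trajectory stream

# Fixed scene timeline on the force clock (seconds).
BASELINE_WINDOW = (0.0, 1.2)  # unloaded plates, used for zeroing
T_STAND = 1.5  # athlete steps onto both skis
T_JUMP_PRE = 3.0  # centre of the pre-run synchronization jump
T_RUN_START = 8.0  # skier leaves the start gate
POST_RUN_JUMP_DELAY = 3.0
POST_JUMP_TAIL = 3.0
TRAJ_CLOCK_START = -8.0  # GNSS logger starts on its own epoch

JUMP_AMPLITUDE_M = 0.35  # vertical COM excursion of the sync jump
JUMP_SIGMA_S = 0.18

R_MAX_M = 1000.0  # radius cap for near-straight trajectory samples

#: Direction of the plate-frame force vector (mostly boot-normal).
_PLATE_DIRECTION = np.array([0.15, 0.10, 1.0]) / np.linalg.norm([0.15, 0.10, 1.0])
_CALIBRATION_SCALE = 500.0  # N per raw unit


@dataclass
class RawRun:
    """The two raw streams of one trial, on independent clocks.

    Force stream: per-plate raw 3-axis channels (calibration matrix maps
    raw units to Newtons) plus an accelerometer-magnitude channel at
    200 Hz.  Trajectory stream: COM position and derived velocity at
    10 Hz.  ``manifest`` holds everything a processing stage may
    legitimately know (masses, matrices, rates, geometry) — never the
    injected clock offset or other ground truth.
    """

    t_force: np.ndarray
    raw: dict[str, np.ndarray]  # plate -> (3, N) raw units
    accel_mag: np.ndarray
    calibration: dict[str, np.ndarray]  # plate -> (3, 3), raw -> N
    t_traj: np.ndarray
    traj_pos: np.ndarray  # (3, M): x, y, z world metres
    traj_vel: np.ndarray  # (3, M)
    manifest: dict


@dataclass
class TruthRecord:
    """Simulator ground truth for recovery tests (never read by the pipeline)."""

    clock_offset_s: float
    dissipation_coeff: float
    limb_split: float
    rf_capability: float
    course_time_s: float
    switch_times_s: np.ndarray  # force clock, len n_gates + 1
    turn_radius_m: np.ndarray  # per-turn mean of capped samplewise radius
    turn_f_r_bw: np.ndarray  # per-turn mean specific radial force, BW
    turn_de_per_vin: np.ndarray  # J*s/kg/m, exact energy bookkeeping
    turn_v_in_ms: np.ndarray
    profile: AthleteProfile = field(repr=False, default=None)


class _SkierLine:
    """Analytic sinusoidal line in the slope plane with closed-form derivatives."""

    def __init__(self, course: CourseConfig, line_scale: float = 1.0):
        self.course = course
        self.amp = course.gate_offset_m * line_scale
        self.k = np.pi / course.gate_spacing_m

    def x(self, u):
        return self.amp * np.sin(self.k * u)

    def xp(self, u):
        return self.amp * self.k * np.cos(self.k * u)

    def xpp(self, u):
        return -self.amp * self.k**2 * np.sin(self.k * u)

    def arc_factor(self, u):
        """ds/du along the in-plane curve."""
        return np.sqrt(1.0 + self.xp(u) ** 2)

    def curvature_signed(self, u):
        """Signed in-plane curvature; positive = turn centre on +x side."""
        return self.xpp(u) / self.arc_factor(u) ** 3


def _speed_squared(u, course: CourseConfig, athlete: AthleteProfile):
    g, alpha = course.gravity, course.alpha_rad
    return athlete.v_start_ms**2 + 2.0 * (1.0 - athlete.dissipation_coeff) * g * np.sin(alpha) * u


def _radial_force_specific(u, v2, line: _SkierLine, course: CourseConfig):
    """Specific (per-mass) radial force in m/s^2 required by the line.

    Centripetal demand v^2*|kappa| minus the in-plane gravity component
    toward the turn centre: gravity helps when it points to the centre.
    """
    g, alpha = course.gravity, course.alpha_rad
    kap = line.curvature_signed(u)
    n = line.arc_factor(u)
    # unit radial (toward centre) in the (x, u) plane: sign(kappa)*(1, -x')/n
    # gravity in-plane vector is g*sin(alpha) along +u; its radial component
    # toward the centre is -sign(kappa)*g*sin(alpha)*x'/n.
    grav_toward_centre = -np.sign(kap) * g * np.sin(alpha) * line.xp(u) / n
    return v2 * np.abs(kap) - grav_toward_centre


def _jump_bump(t, centre):
    """Symmetric Gaussian vertical excursion of the sync jump and its derivatives."""
    s = (t - centre) / JUMP_SIGMA_S
    z = JUMP_AMPLITUDE_M * np.exp(-0.5 * s**2)
    zd = -z * s / JUMP_SIGMA_S
    zdd = z * (s**2 - 1.0) / JUMP_SIGMA_S**2
    return z, zd, zdd


def _highpass_noise(rng, n, fs, sd, cutoff_hz=10.0):
    """Band-limited 'vibration' noise above the force filter cutoff."""
    if sd <= 0 or n < 50:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = signal.butter(4, cutoff_hz, "highpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, white)
    return out * (sd / max(out.std(), 1e-12))


def _calibration_matrix(rng) -> np.ndarray:
    """Per-boot invertible matrix (scaled rotation), raw units -> Newtons."""
    angles = rng.uniform(-0.4, 0.4, size=3)
    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return _CALIBRATION_SCALE * (rz @ ry @ rx)


def simulate_run(course: CourseConfig, athlete: AthleteProfile) -> tuple[RawRun, TruthRecord]:
    """Generate one synthetic trial: raw streams plus exact ground truth.

    Raises ValueError with a diagnostic if the dissipation coefficient is
    so large that the skier would stop (v^2 <= 0) before the finish.
    """
    g, alpha = course.gravity, course.alpha_rad
    line = _SkierLine(course, athlete.line_scale)
    rng = np.random.default_rng(athlete.seed)

    # --- kinematics on a dense fall-line grid ------------------------------
    u_total = course.course_length_m
    du = 0.005
    u = np.arange(0.0, u_total + du, du)
    v2 = _speed_squared(u, course, athlete)
    if np.any(v2 <= 0.25):  # 0.5 m/s floor: the athlete effectively stops
        u_stop = u[np.argmax(v2 <= 0.25)]
        raise ValueError(
            f"dissipation_coeff={athlete.dissipation_coeff} dissipates more energy "
            f"than available: v^2 -> 0 at u={u_stop:.1f} m of {u_total:.1f} m"
        )
    v = np.sqrt(v2)
    ds_du = line.arc_factor(u)
    # t(u) by trapezoidal integration of ds / v
    dt_du = ds_du / v
    t_of_u = np.concatenate(([0.0], np.cumsum(0.5 * (dt_du[1:] + dt_du[:-1]) * du)))
    run_duration = float(t_of_u[-1])

    t_run_end = T_RUN_START + run_duration
    t_jump_post = t_run_end + POST_RUN_JUMP_DELAY
    t_end = t_jump_post + POST_JUMP_TAIL

    z0 = u_total * np.sin(alpha)
    sin_a, cos_a = np.sin(alpha), np.cos(alpha)

    def scene(t):
        """World position/velocity and run-phase kinematics at force-clock times."""
        t = np.asarray(t, dtype=float)
        tau = np.clip(t - T_RUN_START, 0.0, run_duration)
        uu = np.interp(tau, t_of_u, u)
        pos = np.vstack([line.x(uu), uu * cos_a, z0 - uu * sin_a])
        vv2 = _speed_squared(uu, course, athlete)
        udot = np.sqrt(vv2) / line.arc_factor(uu)
        moving = (t > T_RUN_START) & (t < t_run_end)
        udot = np.where(moving, udot, 0.0)
        vel = np.vstack([line.xp(uu) * udot, udot * cos_a, -udot * sin_a])
        # sync-jump vertical excursions while standing
        for centre in (T_JUMP_PRE, t_jump_post):
            zb, zbd, _ = _jump_bump(t, centre)
            pos[2] += np.where(moving, 0.0, zb)
            vel[2] += np.where(moving, 0.0, zbd)
        return pos, vel, uu, moving

    # --- force stream (200 Hz) --------------------------------------------
    n_f = int(round(t_end * FS_FORCE)) + 1
    t_f = np.arange(n_f) / FS_FORCE
    _, _, u_f, moving_f = scene(t_f)
    v2_f = _speed_squared(u_f, course, athlete)
    f_r_spec = _radial_force_specific(u_f, v2_f, line, course)  # m/s^2
    f_tot_spec = np.clip(f_r_spec, 0.0, None) / athlete.rf_capability

    m = athlete.system_mass_kg
    # jump spikes on the plates while standing
    jump_acc = np.zeros(n_f)
    for centre in (T_JUMP_PRE, t_jump_post):
        jump_acc += _jump_bump(t_f, centre)[2]
    standing = (t_f >= T_STAND) & ~moving_f
    f_stand = np.clip(m * (g + jump_acc), 0.0, None)

    total_force_n = np.where(moving_f, m * f_tot_spec, np.where(standing, f_stand, 0.0))

    # outside limb is on the convex side of the line (opposite the centre)
    kap_s = line.curvature_signed(u_f)
    w_out = athlete.limb_split / (1.0 + athlete.limb_split)
    w_left = np.where(moving_f, np.where(kap_s > 0, w_out, 1.0 - w_out), 0.5)

    calib = {"left": _calibration_matrix(rng), "right": _calibration_matrix(rng)}
    raw_offset = {p: rng.normal(0.0, 0.2, size=3) for p in calib}
    raw = {}
    bw_n = athlete.bw_newtons
    for plate, w in (("left", w_left), ("right", 1.0 - w_left)):
        mag = total_force_n * w
        vec = _PLATE_DIRECTION[:, None] * mag[None, :]
        vib = _highpass_noise(rng, n_f, FS_FORCE, athlete.vibration_sd_bw * bw_n)
        vec = vec + (vib * moving_f)[None, :]  # ski-snow vibration, run only
        vec = vec + rng.normal(0.0, athlete.noise_sd_force_bw * bw_n, size=vec.shape)
        raw[plate] = np.linalg.solve(calib[plate], vec) + raw_offset[plate][:, None]

    accel = (
        g
        + jump_acc
        + np.where(moving_f, 1.0, 0.0) * _highpass_noise(rng, n_f, FS_FORCE, 1.0)
        + rng.normal(0.0, 0.05, size=n_f)
    )

    # --- trajectory stream (10 Hz, its own clock) --------------------------
    offset = athlete.clock_offset_s
    n_t = int(round((t_end - TRAJ_CLOCK_START + 8.0) * FS_TRAJ)) + 1
    t_traj = TRAJ_CLOCK_START + np.arange(n_t) / FS_TRAJ
    pos_t, vel_t, _, _ = scene(t_traj + offset)
    pos_t = pos_t + rng.normal(0.0, athlete.noise_sd_position_m, size=pos_t.shape)
    vel_t = vel_t + rng.normal(0.0, athlete.noise_sd_position_m, size=vel_t.shape)

    manifest = {
        "fs_force_hz": FS_FORCE,
        "fs_traj_hz": FS_TRAJ,
        "system_mass_kg": m,
        "bw_newtons": bw_n,
        "baseline_window_s": list(BASELINE_WINDOW),
        "plate_sides": {"left": "-x", "right": "+x"},
        "slope_relief_deg": course.slope_relief_deg,
        "gravity": g,
        "n_gates": course.n_gates,
        "gate_spacing_m": course.gate_spacing_m,
        "seed": athlete.seed,
    }
    run = RawRun(
        t_force=t_f,
        raw=raw,
        accel_mag=accel,
        calibration=calib,
        t_traj=t_traj,
        traj_pos=pos_t,
        traj_vel=vel_t,
        manifest=manifest,
    )

    # --- ground truth ------------------------------------------------------
    G = course.gate_spacing_m
    switch_u = np.arange(course.n_gates + 1) * G
    switch_t = T_RUN_START + np.interp(switch_u, u, t_of_u)
    v_in = np.sqrt(_speed_squared(switch_u[:-1], course, athlete))
    de_turn = -athlete.dissipation_coeff * g * sin_a * G  # exact per-turn energy change
    # exact time-averages on the dense fall-line grid (dt weight = ds/v du)
    kap_dense = line.curvature_signed(u)
    r_dense = np.minimum(1.0 / np.maximum(np.abs(kap_dense), 1.0 / R_MAX_M), R_MAX_M)
    fr_dense = _radial_force_specific(u, v2, line, course) / g
    w = dt_du
    turn_of_u = np.clip((u // G).astype(int), 0, course.n_gates - 1)
    w_sum = np.bincount(turn_of_u, weights=w, minlength=course.n_gates)
    turn_r = np.bincount(turn_of_u, weights=w * r_dense, minlength=course.n_gates) / w_sum
    turn_fr = np.bincount(turn_of_u, weights=w * fr_dense, minlength=course.n_gates) / w_sum
    truth = TruthRecord(
        clock_offset_s=offset,
        dissipation_coeff=athlete.dissipation_coeff,
        limb_split=athlete.limb_split,
        rf_capability=athlete.rf_capability,
        course_time_s=run_duration,
        switch_times_s=switch_t,
        turn_radius_m=turn_r,
        turn_f_r_bw=turn_fr,
        turn_de_per_vin=de_turn / v_in,
        turn_v_in_ms=v_in,
        profile=athlete,
    )
    return run, truth


def make_cohort(
    spec: CohortSpec,
    course: CourseConfig | None = None,
    seed: int = 0,
) -> list[tuple[RawRun, TruthRecord]]:
    """Simulate a heterogeneous cohort; deterministic under (spec, course, seed)."""
    course = course or CourseConfig()
    if spec.degenerate:
        warnings.warn(
            "cohort spread is degenerate (all athletes identical); "
            "between-athlete correlations downstream are undefined",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).spawn(spec.n_athletes)
    out = []
    for i in range(spec.n_athletes):
        profile = AthleteProfile(
            system_mass_kg=float(rng.uniform(*spec.mass_range)),
            dissipation_coeff=float(rng.uniform(*spec.dissipation_range)),
            limb_split=float(rng.uniform(*spec.limb_split_range)),
            rf_capability=float(rng.uniform(*spec.rf_range)),
            line_scale=float(rng.uniform(*spec.line_scale_range)),
            clock_offset_s=float(rng.uniform(*spec.clock_offset_range)),
            noise_sd_force_bw=spec.noise_sd_force_bw,
            noise_sd_position_m=spec.noise_sd_position_m,
            vibration_sd_bw=spec.vibration_sd_bw,
            seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
        )
        out.append(simulate_run(course, profile))
    return out
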