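"""Turn two raw, unsynchronized, multi-rate streams into one clean run.

Stages, in the order they are applied by :func:`process_run`:

1. calibration matrices map raw plate channels to Newtons;
2. per-limb resultants (Euclidean norm of the three axes) are zeroed on
   the unloaded baseline window, normalized to bodyweight, and clipped
   at zero (an unloaded ski cannot pull);
3. the two stream clocks are aligned by cross-correlating the jump
   impulses visible on both sides (coarse alignment by impulse peak
   times, then a fine search within +/-100 frames of each peak pair,
   averaged over the pre- and post-run events);
4. the 10 Hz trajectory is resampled to the 200 Hz force clock by cubic
   spline, smoothed with a 2nd-order Savitzky-Golay filter (201-frame
   window), and low-passed (Butterworth, 2nd order, 1.5 Hz; force uses
   8 Hz), zero-phase by default so the streams stay time-aligned;
5. velocity and heading come from central differences of the filtered
   position; the heading angle beta is measured between the horizontal
   velocity projection and the across-slope (contour) axis, the
   convention under which the gravity radial term is g*sin(alpha)*cos(beta).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

from .config import FilterSpec
from .simulate import RawRun

SYNC_SEARCH_FRAMES = 100  # fine cross-correlation search, either side of a peak


@dataclass
class SyncedRun:
    """Single-clock, 200 Hz, filtered, BW-normalized run.

    Plate series are kept by physical side (left = -x, right = +x);
    outside/inside assignment is a per-turn notion resolved by the
    metrics stage from the turn-centre side.  ``f`` is the total force
    and equals ``f_left + f_right`` at every sample by construction.
    """

    t: np.ndarray
    f_left: np.ndarray  # BW
    f_right: np.ndarray  # BW
    f: np.ndarray  # BW
    pos: np.ndarray  # (3, N) world metres: x lateral, y fall-line proj., z altitude
    vel: np.ndarray  # (3, N) m/s
    speed: np.ndarray  # m/s
    beta: np.ndarray  # rad, heading vs across-slope axis, in [0, pi/2]
    alpha_rad: float
    bw_newtons: float
    fs_hz: float
    sync_offset_s: float  # estimated trajectory-clock offset (t_force - t_traj)
    gravity: float = 9.81


def apply_calibration(raw_channels: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Apply a calibration matrix samplewise: (3, N) raw units -> (3, N) Newtons."""
    matrix = np.asarray(matrix, dtype=float)
    raw_channels = np.asarray(raw_channels, dtype=float)
    if matrix.shape[0] != matrix.shape[1] or matrix.shape[1] != raw_channels.shape[0]:
        raise ValueError(
            f"calibration matrix {matrix.shape} does not match channels {raw_channels.shape}"
        )
    return matrix @ raw_channels


def zero_and_normalize(
    forces_n: np.ndarray,
    baseline: slice | np.ndarray,
    bw_newtons: float,
    clip: bool = False,
) -> np.ndarray:
    """Zero a force series on its unloaded baseline and express it in BW.

    ``baseline`` selects the unloaded pre-run samples (slice or boolean
    mask) whose mean maps to zero.  Warns if the baseline looks loaded
    (its spread is large relative to bodyweight).
    """
    forces_n = np.asarray(forces_n, dtype=float)
    base = forces_n[..., baseline]
    if base.size == 0:
        raise ValueError("empty baseline window")
    if np.any(np.abs(base - base.mean(axis=-1, keepdims=True)).max(axis=-1) > 0.2 * bw_newtons):
        warnings.warn("baseline window overlaps detected movement", stacklevel=2)
    out = (forces_n - base.mean(axis=-1, keepdims=True)) / float(bw_newtons)
    if clip:
        out = np.clip(out, 0.0, None)
    return out


def resample_cubic(
    t_in: np.ndarray, series: np.ndarray, t_out: np.ndarray
) -> np.ndarray:
    """Cubic-spline resampling (10 -> 200 Hz); passes through the knots exactly."""
    t_in = np.asarray(t_in, dtype=float)
    if t_in.size < 4:
        raise ValueError("need at least 4 samples for cubic resampling")
    if np.any(np.diff(t_in) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    spl = interpolate.CubicSpline(t_in, np.asarray(series, dtype=float), axis=-1)
    return spl(np.clip(t_out, t_in[0], t_in[-1]))


def smooth_and_filter(
    series: np.ndarray,
    spec: FilterSpec,
    which: str,
    fs_hz: float = 200.0,
) -> np.ndarray:
    """Smooth and low-pass one stream.

    ``which='position'`` applies Savitzky-Golay (polynomial edge fit at
    the borders) then the 1.5 Hz Butterworth; ``which='force'`` applies
    the 8 Hz Butterworth only.  Butterworth edges use reflected padding;
    zero-phase (forward-backward) application is the default.
    """
    series = np.asarray(series, dtype=float)
    spec.validate_for(fs_hz)
    if which == "position":
        if series.shape[-1] <= spec.savgol_window:
            raise ValueError("series shorter than the Savitzky-Golay window")
        series = signal.savgol_filter(
            series, spec.savgol_window, spec.savgol_order, mode="interp", axis=-1
        )
        cutoff = spec.butter_cutoff_position_hz
    elif which == "force":
        cutoff = spec.butter_cutoff_force_hz
    else:
        raise ValueError(f"unknown stream kind {which!r}")
    if series.shape[-1] < 12 * spec.butter_order:
        raise ValueError("series too short for the Butterworth warm-up")
    sos = signal.butter(spec.butter_order, cutoff, "lowpass", fs=fs_hz, output="sos")
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, series, axis=-1)
    return signal.sosfilt(sos, series, axis=-1)


def detect_jump_impulses(
    t: np.ndarray,
    magnitude: np.ndarray,
    min_separation_s: float = 5.0,
    rel_height: float = 0.5,
) -> tuple[float, float]:
    """Locate the pre- and post-run jump impulses on a magnitude series.

    Returns the times of the first and last isolated peaks exceeding
    ``rel_height`` of the strongest excursion from the median; raises if
    fewer than two such peaks exist (unusable trial).
    """
    t = np.asarray(t, dtype=float)
    x = np.abs(np.asarray(magnitude, dtype=float) - np.median(magnitude))
    if x.max() <= 0:
        raise ValueError("no impulses found: flat signal")
    fs = 1.0 / np.median(np.diff(t))
    dist = max(int(min_separation_s * fs), 1)
    peaks, _ = signal.find_peaks(x, height=rel_height * x.max(), distance=dist)
    if len(peaks) < 2:
        raise ValueError(f"expected two jump impulses, found {len(peaks)}")
    return float(t[peaks[0]]), float(t[peaks[-1]])


def _refine_lag(
    t_ref: np.ndarray,
    ref: np.ndarray,
    probe_spline: interpolate.CubicSpline,
    centre_ref: float,
    coarse_offset: float,
    fs: float,
    window_s: float,
) -> float:
    """Fine lag around one impulse by dense cross-correlation.

    ``ref`` lives on the force clock; the probe signal is a spline on the
    trajectory clock evaluated at (t_force - offset) for trial offsets
    within +/- SYNC_SEARCH_FRAMES force frames of the coarse offset.
    Returns the offset maximizing the windowed correlation, with
    parabolic sub-frame interpolation.
    """
    sel = (t_ref >= centre_ref - window_s) & (t_ref <= centre_ref + window_s)
    tw = t_ref[sel]

    def _detrend(y):
        c = np.polyfit(tw - tw.mean(), y, 1)
        return y - np.polyval(c, tw - tw.mean())

    rw = _detrend(ref[sel])
    lags = (np.arange(-SYNC_SEARCH_FRAMES, SYNC_SEARCH_FRAMES + 1)) / fs
    scores = np.empty(lags.size)
    for i, lag in enumerate(lags):
        pw = _detrend(probe_spline(tw - (coarse_offset + lag)))
        denom = np.sqrt((rw**2).sum() * (pw**2).sum())
        scores[i] = (rw * pw).sum() / denom if denom > 0 else 0.0
    j = int(np.argmax(scores))
    local_max, _ = signal.find_peaks(scores)
    if local_max.size >= 2:
        order = local_max[np.argsort(scores[local_max])][-2:]
        if abs(order[1] - order[0]) > 10 and scores[order[0]] > 0.95 * scores[order[1]]:
            warnings.warn("ambiguous correlation peak during synchronization", stacklevel=2)
    best = lags[j]
    if 0 < j < lags.size - 1:  # parabolic interpolation for sub-frame accuracy
        y0, y1, y2 = scores[j - 1], scores[j], scores[j + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-15:
            best += 0.5 * (y0 - y2) / denom / fs
    return coarse_offset + best


def _gate_stationary(run: RawRun, channel: np.ndarray, max_standing_speed: float = 2.0):
    """Median-detrend ``channel`` within stationary trajectory segments.

    The sync jumps happen while the skier stands still, so impulse
    searches are gated to segments whose horizontal displacement rate
    stays below ``max_standing_speed``; non-stationary samples map to
    zero.
    """
    fs = float(run.manifest["fs_traj_hz"])
    step = np.linalg.norm(np.diff(run.traj_pos[:2], axis=1), axis=0) * fs
    vh = signal.medfilt(np.concatenate([[step[0]], step]), 7)
    idx = np.flatnonzero(vh < max_standing_speed)
    if idx.size == 0:
        raise ValueError("no stationary segment found in the trajectory stream")
    out = np.zeros_like(channel)
    for seg in np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1):
        if seg.size >= 8:
            out[seg] = channel[seg] - np.median(channel[seg])
    return out


def estimate_clock_offset(run: RawRun) -> float:
    """Estimate the trajectory-clock offset (t_force - t_traj) from jump impulses.

    Both jumps are performed standing: on the trajectory side the
    vertical channel shows a symmetric Gaussian-like bump, on the force
    side the accelerometer magnitude carries the matching symmetric
    excursion.  Because both shapes are symmetric about the jump centre,
    their cross-correlation peaks at the true lag regardless of the
    shape difference; coarse alignment comes from the impulse peak
    times, the fine lag from a windowed correlation within +/-100
    force frames, averaged over the two events.
    """
    fs = float(run.manifest["fs_force_hz"])
    t_f, accel = run.t_force, run.accel_mag
    f_pre, f_post = detect_jump_impulses(t_f, accel)

    z_hp = _gate_stationary(run, run.traj_pos[2])
    t_pre, t_post = detect_jump_impulses(run.t_traj, z_hp, min_separation_s=5.0)

    # fine alignment on matching shapes: the stream's vertical-velocity
    # bump against the once-integrated (window-detrended) accelerometer
    vz_hp = _gate_stationary(run, run.traj_vel[2])
    spline = interpolate.CubicSpline(run.t_traj, vz_hp)
    v_ref = np.concatenate(
        [[0.0], np.cumsum(0.5 * np.diff(t_f) * ((accel[1:] - np.median(accel))
                                                + (accel[:-1] - np.median(accel))))]
    )
    offsets = []
    for cf, ct in ((f_pre, t_pre), (f_post, t_post)):
        coarse = cf - ct
        offsets.append(_refine_lag(t_f, v_ref, spline, cf, coarse, fs, 1.2))
    return float(np.mean(offsets))


def synchronize(run: RawRun, spec: "FilterSpec | None" = None) -> "SyncedRun":
    """Align the two streams onto the force clock and return the clean run.

    Convenience name for :func:`process_run`: the clock offset is
    removed via :func:`estimate_clock_offset` and the trajectory is
    interpolated onto the 200 Hz force grid.
    """
    return process_run(run, spec)


def process_run(run: RawRun, spec: FilterSpec | None = None) -> SyncedRun:
    """Full conditioning: calibrate, zero, normalize, synchronize, filter."""
    spec = spec or FilterSpec()
    fs = float(run.manifest["fs_force_hz"])
    bw = float(run.manifest["bw_newtons"])
    t = run.t_force
    b0, b1 = run.manifest["baseline_window_s"]
    baseline = (t >= b0) & (t <= b1)

    limbs = {}
    for plate, raw in run.raw.items():
        cal = apply_calibration(raw, run.calibration[plate])
        # per-axis zeroing before the norm: zeroing the resultant instead
        # would subtract the rectified baseline noise from every loaded
        # sample and bias the magnitudes by the offset-direction geometry
        cal_bw = zero_and_normalize(cal, baseline, bw)
        res = np.linalg.norm(cal_bw, axis=0)  # resultant per limb, BW
        limbs[plate] = np.clip(smooth_and_filter(res, spec, "force", fs), 0.0, None)

    offset = estimate_clock_offset(run)
    # trajectory onto the force clock: spline through the 10 Hz knots
    t_traj_on_force = run.t_traj + offset
    pos = resample_cubic(t_traj_on_force, run.traj_pos, t)
    pos = smooth_and_filter(pos, spec, "position", fs)
    vel = np.gradient(pos, 1.0 / fs, axis=-1)
    speed = np.linalg.norm(vel, axis=0)
    h = np.hypot(vel[0], vel[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.arccos(np.clip(np.abs(vel[0]) / np.where(h > 0, h, np.inf), 0.0, 1.0))

    f_left, f_right = limbs["left"], limbs["right"]
    return SyncedRun(
        t=t,
        f_left=f_left,
        f_right=f_right,
        f=f_left + f_right,
        pos=pos,
        vel=vel,
        speed=speed,
        beta=beta,
        alpha_rad=np.radians(float(run.manifest["slope_relief_deg"])),
        bw_newtons=bw,
        fs_hz=fs,
        sync_offset_s=offset,
        gravity=float(run.manifest.get("gravity", 9.81)),
    )
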