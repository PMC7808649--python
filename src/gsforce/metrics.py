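"""Per-turn kinetic and kinematic metrics.

For each turn the module computes the limb resultants and their
difference, the samplewise trajectory radius from sliding three-point
arc fits, the specific radial force

    F_r = v^2 / r  +/-  g * sin(alpha) * cos(beta)        [per mass]

(expressed in BW by dividing by g; the gravity term enters with + when
the in-plane gravity component points away from the instantaneous turn
centre and - when it points toward it), the ratio of force application
RF = mean(F_r) / mean(F_tot), and the velocity-normalized change in
specific mechanical energy across the turn

    de_mech / v_in = [ (v_out^2 - v_in^2)/2 + g (z_out - z_in) ] / v_in

which is negative when energy is dissipated and zero under conservation.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .conditioning import SyncedRun
from .segmentation import TurnBoundary

R_MAX_M = 1000.0
RADIUS_SPACING_FRAMES = 60  # three points at the native 10 Hz grid, on a 200 Hz clock


def resultant_force(fx, fy, fz) -> np.ndarray:
    """Euclidean magnitude of the three axis components (per plate, per sample)."""
    return np.sqrt(np.square(fx) + np.square(fy) + np.square(fz))


def limb_difference(f_out, f_ins, f_total=None):
    """Samplewise normalized limb difference and its mean.

    diff = |F_out - F_ins| / F with F the total force (F_out + F_ins
    unless given explicitly); samples with F == 0 are excluded from the
    mean.  Returns (diff_series, mean, n_excluded).
    """
    f_out = np.atleast_1d(np.asarray(f_out, dtype=float))
    f_ins = np.atleast_1d(np.asarray(f_ins, dtype=float))
    f = f_out + f_ins if f_total is None else np.atleast_1d(np.asarray(f_total, dtype=float))
    f_out, f_ins, f = np.broadcast_arrays(f_out, f_ins, f)
    valid = f > 0
    diff = np.full(f.shape, np.nan)
    diff[valid] = np.abs(f_out - f_ins)[valid] / f[valid]
    n_excluded = int(valid.size - valid.sum())
    mean = float(np.nanmean(diff)) if valid.any() else np.nan
    return diff, mean, n_excluded


def _circumcircle(a, b, c, r_max=R_MAX_M):
    """Circumscribed-circle radius and centre for stacked 3-D point triples.

    a, b, c: (..., 3) arrays.  Near-collinear triples are capped at
    ``r_max`` with a zero centre direction (flagged by the cap).
    """
    ab, ac = b - a, c - a
    cross = np.cross(ab, ac)
    cross2 = np.einsum("...i,...i", cross, cross)
    d_ab = np.linalg.norm(ab, axis=-1)
    d_ac = np.linalg.norm(ac, axis=-1)
    d_bc = np.linalg.norm(c - b, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = d_ab * d_ac * d_bc / (2.0 * np.sqrt(cross2))
        centre = a + (
            np.einsum("...i,...i", ac, ac)[..., None] * np.cross(cross, ab)
            + np.einsum("...i,...i", ab, ab)[..., None] * np.cross(ac, cross)
        ) / (2.0 * cross2)[..., None]
    bad = ~np.isfinite(r) | (r > r_max) | (cross2 <= 0)
    r = np.where(bad, r_max, r)
    centre = np.where(bad[..., None], np.nan, centre)
    return r, centre, bad


def turn_radius(
    pos: np.ndarray,
    spacing: int = RADIUS_SPACING_FRAMES,
    r_max: float = R_MAX_M,
):
    """Samplewise trajectory radius from sliding three-point arc fits.

    ``pos`` is (3, N); each interior sample i uses the triple
    (i - spacing, i, i + spacing), i.e. consecutive native-rate points
    on the upsampled clock.  Edges reuse the nearest interior fit;
    capped (near-collinear) samples are flagged.  Returns
    (r_series, centre_points, cap_flags).
    """
    p = np.asarray(pos, dtype=float).T  # (N, 3)
    n = p.shape[0]
    if n < 2 * spacing + 1:
        raise ValueError("need at least 2*spacing + 1 trajectory samples")
    a, b, c = p[: -2 * spacing], p[spacing:-spacing], p[2 * spacing :]
    r_mid, centre_mid, bad_mid = _circumcircle(a, b, c, r_max)
    r = np.empty(n)
    centre = np.empty((n, 3))
    bad = np.empty(n, dtype=bool)
    r[spacing:-spacing] = r_mid
    centre[spacing:-spacing] = centre_mid
    bad[spacing:-spacing] = bad_mid
    r[:spacing], r[-spacing:] = r_mid[0], r_mid[-1]
    centre[:spacing], centre[-spacing:] = centre_mid[0], centre_mid[-1]
    bad[:spacing], bad[-spacing:] = bad_mid[0], bad_mid[-1]
    return r, centre.T, bad


def radial_force(v, r, alpha_rad, beta_rad, gravity_sign=1.0, g=9.81):
    """Specific radial force in BW from the closed form.

    gravity_sign is +1 when the in-plane gravity component points away
    from the turn centre and -1 when it points toward it (resolved from
    geometry by the caller).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("turn radius must be positive")
    v = np.asarray(v, dtype=float)
    return (v**2 / r + gravity_sign * g * np.sin(alpha_rad) * np.cos(beta_rad)) / g


def ratio_of_forces(f_r_turnmean: float, f_tot_turnmean: float) -> float:
    """RF: turn-averaged radial force over turn-averaged total force."""
    if f_tot_turnmean <= 0:
        raise ValueError("turn-averaged total force must be positive")
    return float(f_r_turnmean) / float(f_tot_turnmean)


def delta_emech_per_vin(v_in, v_out, z_in, z_out, g=9.81) -> float:
    """Change in specific mechanical energy across a turn per entry velocity."""
    if v_in <= 0:
        raise ValueError("entry velocity must be positive")
    return ((v_out**2 - v_in**2) / 2.0 + g * (z_out - z_in)) / v_in


def radial_series(synced: SyncedRun, spacing: int = RADIUS_SPACING_FRAMES, r_max: float = R_MAX_M):
    """Samplewise radius, centre direction and radial force for a whole run.

    The gravity term is obtained by projecting gravity onto the unit
    vector toward the instantaneous turn centre, which equals
    +/- g*sin(alpha)*cos(beta) for a slope-plane trajectory; capped
    (straight) samples carry no gravity radial component.
    Returns (r, f_r_bw, centre_dir (3,N), cap_flags).
    """
    r, centre, bad = turn_radius(synced.pos, spacing, r_max)
    to_centre = centre - synced.pos
    norm = np.linalg.norm(to_centre, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m_hat = np.where(norm > 0, to_centre / norm, 0.0)
    m_hat = np.nan_to_num(m_hat)
    g = synced.gravity
    # gravity vector is (0, 0, -g); its component toward the centre is -g*m_z
    grav_toward_centre = -g * m_hat[2]
    f_r_spec = synced.speed**2 / r - grav_toward_centre
    return r, f_r_spec / g, m_hat, bad


@dataclass
class TurnRecord:
    """Every per-turn quantity of the analysis."""

    turn_index: int
    section: str
    t_turn: float  # s
    v_in: float  # m/s
    v_avg: float  # m/s
    length: float  # m, cumulated 3-D displacement
    d_alt: float  # m, altitude drop between switches (positive down)
    radius: float  # m, turn-averaged samplewise radius
    f_tot: float  # BW
    f_out: float  # BW
    f_ins: float  # BW
    f_diff: float  # dimensionless
    f_max: float  # BW
    f_maxout: float  # BW
    f_maxins: float  # BW
    f_r: float  # BW
    rf: float  # dimensionless
    de_mech_per_vin: float  # J*s/kg/m


def summarize_turn(
    synced: SyncedRun,
    boundary: TurnBoundary,
    precomputed=None,
) -> TurnRecord:
    """All per-turn metrics for one boundary.

    ``precomputed`` may carry the output of :func:`radial_series` for the
    whole run to avoid refitting arcs per turn.  The outside limb is the
    plate on the convex side of the turn (opposite the mean turn-centre
    side).
    """
    t = synced.t
    r_all, f_r_all, m_hat, _ = precomputed if precomputed is not None else radial_series(synced)
    sel = (t >= boundary.start_t) & (t < boundary.end_t)
    if not sel.any():
        raise ValueError(f"turn boundary {boundary} outside the run")

    centre_side = float(np.mean(m_hat[0, sel]))  # +: centre on +x side
    outside, inside = ("left", "right") if centre_side > 0 else ("right", "left")
    f_out = getattr(synced, f"f_{outside}")[sel]
    f_ins = getattr(synced, f"f_{inside}")[sel]
    f = synced.f[sel]

    _, f_diff, _ = limb_difference(f_out, f_ins, f)

    v_in = float(np.interp(boundary.start_t, t, synced.speed))
    v_out = float(np.interp(boundary.end_t, t, synced.speed))
    z_in = float(np.interp(boundary.start_t, t, synced.pos[2]))
    z_out = float(np.interp(boundary.end_t, t, synced.pos[2]))

    step = np.linalg.norm(np.diff(synced.pos[:, sel], axis=1), axis=0)
    f_r_mean = float(np.mean(f_r_all[sel]))
    f_tot_mean = float(np.mean(f))
    return TurnRecord(
        turn_index=boundary.turn_index,
        section=boundary.section,
        t_turn=float(boundary.duration),
        v_in=v_in,
        v_avg=float(np.mean(synced.speed[sel])),
        length=float(step.sum()),
        d_alt=z_in - z_out,
        radius=float(np.mean(r_all[sel])),
        f_tot=f_tot_mean,
        f_out=float(np.mean(f_out)),
        f_ins=float(np.mean(f_ins)),
        f_diff=f_diff,
        f_max=float(np.max(f)),
        f_maxout=float(np.max(f_out)),
        f_maxins=float(np.max(f_ins)),
        f_r=f_r_mean,
        rf=ratio_of_forces(f_r_mean, f_tot_mean),
        de_mech_per_vin=delta_emech_per_vin(v_in, v_out, z_in, z_out, synced.gravity),
    )


#: Metrics averaged at course and section level.
_MEAN_METRICS = [
    "t_turn", "v_in", "v_avg", "length", "d_alt", "radius",
    "f_tot", "f_out", "f_ins", "f_diff", "f_max", "f_maxout", "f_maxins",
    "f_r", "rf", "de_mech_per_vin",
]


@dataclass
class RunSummary:
    """Course time plus course- and section-averaged turn metrics."""

    course_time: float
    turns: pd.DataFrame  # one row per retained TurnRecord
    course_means: pd.Series
    section_means: pd.DataFrame  # index: section

    def value(self, metric: str, dataset: str = "course") -> float:
        if dataset == "course":
            return float(self.course_means[metric])
        return float(self.section_means.loc[dataset, metric])


def summarize_run(records: list[TurnRecord], course_time: float) -> RunSummary:
    """Unweighted means per section and over all retained turns."""
    turns = pd.DataFrame([asdict(r) for r in records])
    return RunSummary(
        course_time=float(course_time),
        turns=turns,
        course_means=turns[_MEAN_METRICS].mean(),
        section_means=turns.groupby("section")[_MEAN_METRICS].mean(),
    )


def process_metrics(synced: SyncedRun, boundaries: list[TurnBoundary]) -> RunSummary:
    """TurnRecords and RunSummary for a conditioned, segmented run.

    Course time is the duration of the moving phase on the synced clock.
    """
    pre = radial_series(synced)
    records = [summarize_turn(synced, b, precomputed=pre) for b in boundaries]
    moving = synced.speed > 2.0
    course_time = float(synced.t[moving][-1] - synced.t[moving][0]) if moving.any() else np.nan
    return summarize_run(records, course_time)
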