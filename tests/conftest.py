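"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gsforce import (
    AthleteProfile,
    CohortSpec,
    CourseConfig,
    PipelineConfig,
    SegmentationConfig,
    run_pipeline,
    simulate_run,
)
from gsforce.conditioning import SyncedRun

QUIET = dict(noise_sd_force_bw=0.0, noise_sd_position_m=0.0, vibration_sd_bw=0.0)

#: Low-relief course whose lateral line sits deep inside both filter
#: passbands, used for conservation-style properties where in-band
#: filter attenuation must not masquerade as energy dissipation.
GENTLE_COURSE = dict(n_gates=8, gate_spacing_m=30.0, gate_offset_m=0.5,
                     slope_relief_deg=2.0, section_map={})
GENTLE_SEGMENTATION = SegmentationConfig(first_turn=3, last_turn=6)


@pytest.fixture(scope="session")
def default_course():
    return CourseConfig()


@pytest.fixture(scope="session")
def quiet_sim(default_course):
    """Noise-free default-course run with ground truth."""
    return simulate_run(default_course, AthleteProfile(seed=5, clock_offset_s=1.5, **QUIET))


@pytest.fixture(scope="session")
def noisy_sim(default_course):
    """Default-noise run with a non-trivial clock offset."""
    return simulate_run(default_course, AthleteProfile(seed=3, clock_offset_s=3.21))


@pytest.fixture(scope="session")
def pipeline_result():
    """Default 15-athlete cohort through the full pipeline."""
    return run_pipeline(PipelineConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_pipeline_result():
    cohort = CohortSpec(noise_sd_force_bw=0.0, noise_sd_position_m=0.0, vibration_sd_bw=0.0,
                        clock_offset_range=(0.0, 0.0), line_scale_range=(1.0, 1.0))
    return run_pipeline(PipelineConfig(cohort=cohort, seed=11))


def make_synced(
    t: np.ndarray,
    f_left: np.ndarray,
    f_right: np.ndarray,
    pos: np.ndarray,
    alpha_rad: float = 0.0,
    g: float = 9.81,
) -> SyncedRun:
    """Hand-built SyncedRun for closed-form metric tests."""
    vel = np.gradient(pos, t, axis=-1)
    speed = np.linalg.norm(vel, axis=0)
    h = np.hypot(vel[0], vel[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.arccos(np.clip(np.abs(vel[0]) / np.where(h > 0, h, np.inf), 0, 1))
    return SyncedRun(
        t=t, f_left=f_left, f_right=f_right, f=f_left + f_right,
        pos=pos, vel=vel, speed=speed, beta=beta, alpha_rad=alpha_rad,
        bw_newtons=800.0, fs_hz=1.0 / float(np.median(np.diff(t))),
        sync_offset_s=0.0, gravity=g,
    )


# --------------------------------------------------------------------------
# independent oracles

def circle_radius_kasa(points: np.ndarray) -> float:
    """Algebraic (Kasa) least-squares circle radius for near-planar points.

    Independent of the sliding three-point arc fit: fits all points at
    once in the dominant plane via the linearized circle equation.
    """
    p = points.T - points.T.mean(axis=0)
    _, _, vt = np.linalg.svd(p, full_matrices=False)
    xy = p @ vt[:2].T  # project onto best-fit plane
    A = np.column_stack([2 * xy, np.ones(len(xy))])
    b = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    return float(np.sqrt(c + cx**2 + cy**2))


def _subset_fits(y: np.ndarray, X: np.ndarray):
    """SSR for every predictor subset, via the normal equations."""
    n, p = X.shape
    table = {}
    for k in range(p + 1):
        for cols in itertools.combinations(range(p), k):
            A = np.column_stack([np.ones(n)] + [X[:, c] for c in cols])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            table[cols] = float(((y - A @ coef) ** 2).sum())
    return table


def exhaustive_stepwise(y, X, enter_p=0.05, remove_p=0.10):
    """Replay the stepwise procedure from an exhaustive all-subsets table.

    Entry/removal decisions use partial F-tests computed purely from the
    enumerated subset SSRs (equivalent to the coefficient t-tests of the
    implementation, but derived through an entirely different route).
    Returns the selected column indices in entry order.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    ssr = _subset_fits(y, X)

    def partial_p(subset_with, subset_without):
        df = n - len(subset_with) - 1
        ssr_w, ssr_wo = ssr[tuple(sorted(subset_with))], ssr[tuple(sorted(subset_without))]
        if df <= 0 or ssr_w <= 0:
            return np.nan
        f = (ssr_wo - ssr_w) / (ssr_w / df)
        return float(sps.f.sf(f, 1, df))

    selected: list[int] = []
    changed = True
    while changed:
        changed = False
        cand = [(partial_p(selected + [j], selected), j) for j in range(p) if j not in selected
                and np.ptp(X[:, j]) > 0]
        cand = [(pv, j) for pv, j in cand if np.isfinite(pv)]
        if cand:
            pv, j = min(cand)
            if pv <= enter_p:
                selected.append(j)
                changed = True
        if selected:
            worst = max(
                (partial_p(selected, [k for k in selected if k != j]), j) for j in selected
            )
            if worst[0] > remove_p:
                selected.remove(worst[1])
                changed = True
    return selected


def synthetic_summaries(values: pd.DataFrame):
    """RunSummary-like objects from a per-athlete table of metric values.

    ``values`` columns are 'T' plus '<metric>_<dataset>' names; metrics
    not supplied default to zero.
    """
    from gsforce.metrics import _MEAN_METRICS, RunSummary
    from gsforce.stats import SECTIONS

    out = []
    for _, row in values.iterrows():
        course = pd.Series({m: row.get(f"{m}_course", 0.0) for m in _MEAN_METRICS})
        sections = pd.DataFrame(
            {m: [row.get(f"{m}_{s}", 0.0) for s in SECTIONS] for m in _MEAN_METRICS},
            index=list(SECTIONS),
        )
        out.append(RunSummary(course_time=float(row["T"]), turns=pd.DataFrame(),
                              course_means=course, section_means=sections))
    return out
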