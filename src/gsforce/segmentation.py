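"""Cut a synchronized run into turns and assign course sections.

Turn switches are the instants where the trajectory's lateral curvature
changes sign — the inflection between successive turns.  The default
detector takes the sign change of the second time-derivative of the
(filtered) lateral coordinate, which lands exactly on inflection points;
a third-derivative variant is also provided, whose zero crossings on a
sinusoid-like line sit a quarter-cycle away (at the gate apexes), so the
two methods agree on switch counts but not on phase.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import SegmentationConfig, assign_section


@dataclass(frozen=True)
class TurnBoundary:
    turn_index: int  # 1-based from the first detected switch
    start_t: float
    end_t: float
    section: str = "excluded"

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


def detect_turn_switches(
    t: np.ndarray,
    lateral: np.ndarray,
    speed: np.ndarray | None = None,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Ordered turn-switch times from the filtered lateral coordinate.

    Zero crossings of the chosen derivative (second for
    ``curvature_sign``, third for ``third_derivative_sign``) are located
    by linear interpolation, restricted to samples where the skier moves
    faster than ``min_speed_ms``, and thinned so consecutive switches
    are at least ``min_turn_duration_s`` apart (first crossing in a
    cluster wins).
    """
    config = config or SegmentationConfig()
    t = np.asarray(t, dtype=float)
    x = np.asarray(lateral, dtype=float)
    n_deriv = {"curvature_sign": 2, "third_derivative_sign": 3}.get(config.method)
    if n_deriv is None:
        raise ValueError(f"unknown switch detection method {config.method!r}")
    d = x
    for _ in range(n_deriv):
        d = np.gradient(d, t)
    moving = np.ones_like(t, dtype=bool) if speed is None else speed > config.min_speed_ms

    # floor against float cancellation noise: an exactly straight series
    # differentiates to ~eps-level garbage, not to genuine oscillation
    dt = float(np.median(np.diff(t)))
    floor = 1e-7 * np.ptp(x) / dt**n_deriv
    s = np.sign(np.where(np.abs(d) >= floor, d, 0.0))
    s[~moving] = 0.0
    nz = np.flatnonzero(s != 0)
    if nz.size < 2:
        return np.array([])
    a, b = nz[:-1], nz[1:]
    ok = (s[a] * s[b] < 0) & (t[b] - t[a] <= 0.5 * config.min_turn_duration_s)
    a, b = a[ok], b[ok]
    if a.size == 0:
        return np.array([])
    times = t[a] - d[a] * (t[b] - t[a]) / (d[b] - d[a])
    kept = [times[0]]
    for tt in times[1:]:
        if tt - kept[-1] >= config.min_turn_duration_s:
            kept.append(tt)
    return np.asarray(kept)


def select_analysis_turns(
    switches: np.ndarray,
    config: SegmentationConfig | None = None,
    section_map=None,
) -> list[TurnBoundary]:
    """Retain the analysis window (turns 3-16 by default) as boundaries.

    Turn i spans the interval between switches i and i+1 (1-based from
    the first detected switch), so 14 retained turns require at least 17
    detected switches.
    """
    config = config or SegmentationConfig()
    switches = np.asarray(switches, dtype=float)
    n_turns = switches.size - 1
    first, last = config.first_turn, config.last_turn
    if n_turns < last:
        raise ValueError(
            f"only {max(n_turns, 0)} complete turns detected; "
            f"need at least {last} to retain turns {first}-{last}"
        )
    return [
        TurnBoundary(
            turn_index=i,
            start_t=float(switches[i - 1]),
            end_t=float(switches[i]),
            section=assign_section(i, section_map),
        )
        for i in range(first, last + 1)
    ]


def segment_run(synced, config: SegmentationConfig | None = None, section_map=None):
    """Detect switches on a SyncedRun and return the retained boundaries."""
    config = config or SegmentationConfig()
    switches = detect_turn_switches(synced.t, synced.pos[0], synced.speed, config)
    if switches.size - 1 < config.last_turn:
        warnings.warn(
            f"{switches.size - 1} turns detected; course may not have been fully negotiated",
            stacklevel=2,
        )
    return select_analysis_turns(switches, config, section_map)
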