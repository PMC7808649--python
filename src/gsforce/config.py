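"""Configuration types for courses, athletes, and signal filters.

Units are SI throughout unless a field name says otherwise; forces are
expressed in bodyweight units (BW = force / (system mass * g)) once
normalized.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

GRAVITY = 9.81  # m/s^2

#: Section labels used throughout the analysis.
SECTIONS = ("speed", "overspeed", "flat")

#: Default section map for an 18-gate course: the analysis window is turns
#: 3-16; 'speed' covers the entry and exit turns (3-5, 15-16), 'overspeed'
#: the steep mid-course turns (6-10), 'flat' the low-relief turns (11-14).
DEFAULT_SECTION_MAP: dict[int, str] = {
    **{i: "speed" for i in (3, 4, 5, 15, 16)},
    **{i: "overspeed" for i in range(6, 11)},
    **{i: "flat" for i in range(11, 15)},
}

#: First and last turn index retained for analysis.
ANALYSIS_TURNS = (3, 16)


def assign_section(turn_index: int, section_map: Mapping[int, str] | None = None) -> str:
    """Map a 1-based turn index to its course section ('excluded' outside the map)."""
    m = DEFAULT_SECTION_MAP if section_map is None else section_map
    return m.get(int(turn_index), "excluded")


@dataclass(frozen=True)
class CourseConfig:
    """Geometry of a giant-slalom course on a uniformly inclined slope.

    The slope-fixed frame is x lateral (horizontal, across the slope),
    y the horizontal projection of the fall line, z altitude.  Gates sit
    at the lateral apexes of the skier line; gate_spacing_m is measured
    along the fall line *in the slope plane*, so the altitude drop per
    gate is gate_spacing_m * sin(alpha).
    """

    n_gates: int = 18
    slope_relief_deg: float = 25.0
    gate_spacing_m: float = 24.0
    gate_offset_m: float = 4.0  # lateral half-amplitude of the skier line
    gravity: float = GRAVITY
    section_map: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        if self.n_gates < 4:
            raise ValueError(f"n_gates must be >= 4, got {self.n_gates}")
        if not 0.0 <= self.slope_relief_deg < 90.0:
            raise ValueError("slope_relief_deg must be in [0, 90)")
        if self.gate_spacing_m <= 0 or self.gate_offset_m < 0:
            raise ValueError("gate geometry must be positive")

    @property
    def alpha_rad(self) -> float:
        return math.radians(self.slope_relief_deg)

    @property
    def course_length_m(self) -> float:
        """Fall-line distance (in the slope plane) from first to last switch."""
        return self.n_gates * self.gate_spacing_m

    def section_of(self, turn_index: int) -> str:
        return assign_section(turn_index, self.section_map)


@dataclass(frozen=True)
class AthleteProfile:
    """One simulated skier (plus equipment) and their sensor noise levels.

    dissipation_coeff is the fraction of the potential-energy release that
    the skier dissipates (ski-snow friction, skidding, drag folded
    together): 0 means a conservative run, 1 means steady speed on a
    uniform slope, slightly above 1 a decelerating run.

    rf_capability is the target ratio of force application (turn-averaged
    radial force over turn-averaged total force) the athlete realizes;
    limb_split the mean outside:inside force ratio (near 2:1 in elite GS).
    """

    system_mass_kg: float = 84.0
    dissipation_coeff: float = 0.95
    limb_split: float = 2.0
    rf_capability: float = 0.68
    v_start_ms: float = 15.0
    line_scale: float = 1.0  # multiplies the course gate offset (line choice)
    noise_sd_force_bw: float = 0.03
    noise_sd_position_m: float = 0.05
    vibration_sd_bw: float = 0.05  # band-limited (>8 Hz) plate vibration
    clock_offset_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.system_mass_kg <= 0:
            raise ValueError("system_mass_kg must be positive")
        if self.limb_split <= 0:
            raise ValueError("limb_split must be positive")
        if not 0.0 < self.rf_capability <= 1.0:
            raise ValueError("rf_capability must be in (0, 1]")
        if self.dissipation_coeff < 0:
            raise ValueError("dissipation_coeff must be >= 0")

    @property
    def bw_newtons(self) -> float:
        return self.system_mass_kg * GRAVITY

    def with_(self, **kw) -> "AthleteProfile":
        return replace(self, **kw)


@dataclass(frozen=True)
class FilterSpec:
    """Smoothing and low-pass settings for the two streams.

    Savitzky-Golay (order 2, 201-frame window at 200 Hz) smooths the
    resampled trajectory; 2nd-order Butterworth low-passes force at 8 Hz
    and position at 1.5 Hz.  zero_phase applies filters forward-backward
    so force and trajectory stay aligned in time.
    """

    savgol_order: int = 2
    savgol_window: int = 201
    butter_order: int = 2
    butter_cutoff_force_hz: float = 8.0
    butter_cutoff_position_hz: float = 1.5
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ValueError("savgol_window must be odd and > savgol_order")
        if self.butter_cutoff_force_hz <= 0 or self.butter_cutoff_position_hz <= 0:
            raise ValueError("cutoffs must be positive")

    def validate_for(self, fs_hz: float) -> None:
        nyq = fs_hz / 2.0
        if self.butter_cutoff_force_hz >= nyq or self.butter_cutoff_position_hz >= nyq:
            raise ValueError("Butterworth cutoffs must be below the stream Nyquist")


@dataclass(frozen=True)
class SegmentationConfig:
    """Turn-switch detection settings."""

    method: str = "curvature_sign"  # or "third_derivative_sign"
    min_turn_duration_s: float = 0.6
    min_speed_ms: float = 2.0
    first_turn: int = ANALYSIS_TURNS[0]
    last_turn: int = ANALYSIS_TURNS[1]


@dataclass(frozen=True)
class CohortSpec:
    """Parameter ranges for a heterogeneous simulated cohort.

    Ranges are (low, high) for uniform draws; degenerate (low == high)
    ranges are allowed but flagged because downstream correlations are
    undefined without between-athlete variance.
    """

    n_athletes: int = 15
    dissipation_range: tuple[float, float] = (0.88, 1.02)
    rf_range: tuple[float, float] = (0.60, 0.76)
    limb_split_range: tuple[float, float] = (1.6, 2.4)
    mass_range: tuple[float, float] = (72.0, 96.0)
    line_scale_range: tuple[float, float] = (0.95, 1.05)
    clock_offset_range: tuple[float, float] = (-5.0, 5.0)
    noise_sd_force_bw: float = 0.03
    noise_sd_position_m: float = 0.05
    vibration_sd_bw: float = 0.05

    def __post_init__(self) -> None:
        if self.n_athletes < 3:
            raise ValueError("a cohort needs at least 3 athletes")

    @property
    def degenerate(self) -> bool:
        return all(
            lo == hi
            for lo, hi in (
                self.dissipation_range,
                self.rf_range,
                self.limb_split_range,
            )
        )


@dataclass(frozen=True)
class StatsConfig:
    """Criteria for the statistical battery."""

    enter_p: float = 0.05
    remove_p: float = 0.10
    alpha: float = 0.05
    exclude_athletes: tuple[int, ...] = ()  # explicit outlier exclusion list


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end pipeline run needs, serializable."""

    course: CourseConfig = field(default_factory=CourseConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    filters: FilterSpec = field(default_factory=FilterSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
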