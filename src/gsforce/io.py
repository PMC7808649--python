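"""Plain-text readers and writers for every pipeline artifact.

All outputs are CSV or JSON with documented headers so the whole
artifact tree stays inspectable.  Table-style column names follow the
field's conventional symbols (T_turn, v_in, L, dalt, r, F_tot, F_out,
F_ins, F_diff, F_max, F_maxout, F_maxins, F_r, RF, de_mech_per_vin).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import (
    CohortSpec,
    CourseConfig,
    FilterSpec,
    PipelineConfig,
    SegmentationConfig,
    StatsConfig,
)
from .conditioning import SyncedRun
from .metrics import RunSummary
from .segmentation import TurnBoundary
from .simulate import RawRun, TruthRecord

TURN_COLUMNS = {
    "turn_index": "turn", "section": "section", "t_turn": "T_turn", "v_in": "v_in",
    "v_avg": "v_avg", "length": "L", "d_alt": "dalt", "radius": "r",
    "f_tot": "F_tot", "f_out": "F_out", "f_ins": "F_ins", "f_diff": "F_diff",
    "f_max": "F_max", "f_maxout": "F_maxout", "f_maxins": "F_maxins",
    "f_r": "F_r", "rf": "RF", "de_mech_per_vin": "de_mech_per_vin",
}


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def dump_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=1, sort_keys=True) + "\n")


def write_raw_run(run: RawRun, outdir: Path, truth: TruthRecord | None = None) -> None:
    """Force CSV (long format, one row per plate sample), trajectory CSV,
    manifest JSON with calibration matrices, optional truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for plate, raw in run.raw.items():
        frames.append(pd.DataFrame({
            "t_s": run.t_force, "plate": plate,
            "Fx_raw": raw[0], "Fy_raw": raw[1], "Fz_raw": raw[2],
            "accel_mag": run.accel_mag,
        }))
    pd.concat(frames).to_csv(outdir / "force_stream.csv", index=False)
    pd.DataFrame({
        "t_s": run.t_traj,
        "x_m": run.traj_pos[0], "y_m": run.traj_pos[1], "z_m": run.traj_pos[2],
        "vx_ms": run.traj_vel[0], "vy_ms": run.traj_vel[1], "vz_ms": run.traj_vel[2],
    }).to_csv(outdir / "trajectory_stream.csv", index=False)
    manifest = dict(run.manifest)
    manifest["calibration"] = {p: m.tolist() for p, m in run.calibration.items()}
    dump_json(manifest, outdir / "manifest.json")
    if truth is not None:
        d = dataclasses.asdict(truth)
        d.pop("profile", None)
        dump_json(d, outdir / "truth.json")


def read_raw_run(indir: Path) -> RawRun:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    calib = {p: np.asarray(m) for p, m in manifest.pop("calibration").items()}
    force = pd.read_csv(indir / "force_stream.csv")
    plates = sorted(force["plate"].unique())
    raw, accel, t_force = {}, None, None
    for plate in plates:
        sub = force[force["plate"] == plate]
        raw[plate] = sub[["Fx_raw", "Fy_raw", "Fz_raw"]].to_numpy().T
        t_force = sub["t_s"].to_numpy()
        accel = sub["accel_mag"].to_numpy()
    traj = pd.read_csv(indir / "trajectory_stream.csv")
    return RawRun(
        t_force=t_force, raw=raw, accel_mag=accel, calibration=calib,
        t_traj=traj["t_s"].to_numpy(),
        traj_pos=traj[["x_m", "y_m", "z_m"]].to_numpy().T,
        traj_vel=traj[["vx_ms", "vy_ms", "vz_ms"]].to_numpy().T,
        manifest=manifest,
    )


def write_synced_run(
    synced: SyncedRun, path: Path, boundaries: list[TurnBoundary] | None = None
) -> None:
    """Synced stream CSV: t_s, Fout_BW, Fins_BW, F_BW, diff, x_m, y_m, z_m, v_ms, beta_rad.

    Outside/inside are per-turn labels; with boundaries given, samples
    inside each turn are relabelled by the turn-centre side, remaining
    samples (and the no-boundary case) fall back to the samplewise
    larger/smaller limb.
    """
    from .metrics import limb_difference, radial_series

    f_out = np.maximum(synced.f_left, synced.f_right)
    f_ins = np.minimum(synced.f_left, synced.f_right)
    if boundaries:
        _, _, m_hat, _ = radial_series(synced)
        for b in boundaries:
            sel = (synced.t >= b.start_t) & (synced.t < b.end_t)
            if not sel.any():
                continue
            left_is_out = np.mean(m_hat[0, sel]) > 0
            f_out[sel] = synced.f_left[sel] if left_is_out else synced.f_right[sel]
            f_ins[sel] = synced.f_right[sel] if left_is_out else synced.f_left[sel]
    diff, _, _ = limb_difference(f_out, f_ins, synced.f)
    pd.DataFrame({
        "t_s": synced.t, "Fout_BW": f_out, "Fins_BW": f_ins, "F_BW": synced.f,
        "diff": diff, "x_m": synced.pos[0], "y_m": synced.pos[1], "z_m": synced.pos[2],
        "v_ms": synced.speed, "beta_rad": synced.beta,
    }).to_csv(path, index=False)


def write_boundaries(boundaries: list[TurnBoundary], path: Path) -> None:
    pd.DataFrame(
        [
            {"turn_index": b.turn_index, "start_s": b.start_t, "end_s": b.end_t,
             "section": b.section}
            for b in boundaries
        ]
    ).to_csv(path, index=False)


def write_turn_metrics(summary: RunSummary, path: Path) -> None:
    """One row per TurnRecord, conventionally named columns."""
    summary.turns.rename(columns=TURN_COLUMNS).to_csv(path, index=False)


def write_run_summary(summary: RunSummary, path: Path) -> None:
    dump_json(
        {
            "course_time_s": summary.course_time,
            "course_means": summary.course_means.to_dict(),
            "section_means": {
                sec: row.to_dict() for sec, row in summary.section_means.iterrows()
            },
        },
        path,
    )


def read_run_summary(path: Path) -> RunSummary:
    d = json.loads(Path(path).read_text())
    return RunSummary(
        course_time=d["course_time_s"],
        turns=pd.DataFrame(),
        course_means=pd.Series(d["course_means"]),
        section_means=pd.DataFrame.from_dict(d["section_means"], orient="index"),
    )


def _build(cls, d: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


def load_config(path: Path) -> PipelineConfig:
    """PipelineConfig from a YAML/JSON mapping with nested sections."""
    d = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(
        course=_build(CourseConfig, d.get("course", {})),
        cohort=_build(CohortSpec, d.get("cohort", {})),
        filters=_build(FilterSpec, d.get("filters", {})),
        segmentation=_build(SegmentationConfig, d.get("segmentation", {})),
        stats=_build(StatsConfig, d.get("stats", {})),
        seed=int(d.get("seed", 0)),
    )


def config_to_dict(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)
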