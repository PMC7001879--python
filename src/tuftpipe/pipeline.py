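"""Stage orchestration: simulate -> (register) -> segment -> analyze -> classify -> report.

Each stage is a plain function over the on-disk schemas in
:mod:`tuftpipe.io_formats`, so an end-to-end run and a staged run over the
same seeds produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io_formats as iof
from .classify import (AnalysisConfig, build_dendrite_record,
                       session_latency_regression,
                       session_second_peak_latencies, two_proportion_test)
from .errors import ConfigError, ValidationError
from .segmentation import SegmentationConfig, factorize
from .synthdata import (PopulationConfig, TaskConfig, generate_session,
                        render_movie)
from .traces import (compute_dff, extract_roi_trace, frame_average,
                     rigid_register, triggered_average, window_peak)

log = logging.getLogger("tuftpipe")

__all__ = ["RunConfig", "load_config", "run",
           "simulate_stage", "segment_stage", "analyze_stage",
           "classify_stage", "report_stage"]

FAST_OVERRIDES = {
    "task": {"n_trials": 50},
    "population": {"n_dendrites": 8},
    "segmentation": {"K": 8, "max_iter": 30},
    "frame_size_px": 64,
}


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    task: TaskConfig
    population: PopulationConfig
    segmentation: SegmentationConfig
    analysis: AnalysisConfig
    seeds: dict
    out_dir: str = "results/run"
    frame_size_px: int = 128
    register: bool = False

    def validate(self) -> None:
        self.task.validate()
        self.segmentation.validate()
        for name in ("session", "rendering", "segmentation", "control_windows"):
            if not isinstance(self.seeds.get(name), int):
                raise ConfigError(f"seed {name!r} must be an integer")


def _build(cls, payload: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} fields {sorted(unknown)}")
    kwargs = {}
    for k, v in payload.items():
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def load_config(path, fast: bool = False) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if fast:
        for sec, over in FAST_OVERRIDES.items():
            if isinstance(over, dict):
                raw.setdefault(sec, {}).update(over)
            else:
                raw[sec] = over
    seeds = {"session": 0, "rendering": 1, "segmentation": 2, "control_windows": 3}
    seeds.update(raw.get("seeds", {}))
    cfg = RunConfig(
        task=_build(TaskConfig, raw.get("task", {})),
        population=_build(PopulationConfig, raw.get("population", {})),
        segmentation=_build(SegmentationConfig, raw.get("segmentation", {})),
        analysis=_build(AnalysisConfig, raw.get("analysis", {})),
        seeds=seeds,
        out_dir=raw.get("out_dir", "results/run"),
        frame_size_px=int(raw.get("frame_size_px", 128)),
        register=bool(raw.get("register", False)),
    )
    cfg.analysis.control_seed = seeds["control_windows"]
    cfg.validate()
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps({
        "task": dataclasses.asdict(cfg.task),
        "population": dataclasses.asdict(cfg.population),
        "segmentation": dataclasses.asdict(cfg.segmentation),
        "analysis": dataclasses.asdict(cfg.analysis),
        "seeds": cfg.seeds, "frame_size_px": cfg.frame_size_px,
    }, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _resolve_out(cfg: RunConfig, out_dir=None) -> Path:
    out = Path(out_dir) if out_dir is not None else Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def simulate_stage(cfg: RunConfig, out_dir=None) -> dict:
    out = _resolve_out(cfg, out_dir)
    log.info("simulate: %d trials at %g fps", cfg.task.n_trials, cfg.task.frame_rate_hz)
    session = generate_session(cfg.task, cfg.seeds["session"])
    stack, gt = render_movie(session, cfg.population, cfg.seeds["rendering"],
                             frame_size_px=cfg.frame_size_px)
    iof.write_events(session, out / "events.csv")
    iof.write_whisker(session, out / "whisker.h5")
    iof.write_movie(stack, out / "movie.tif")
    (out / "ground_truth.json").write_text(json.dumps({
        "labels": [c.label for c in gt.classes],
        "preferred_phase_s": [c.preferred_phase_s for c in gt.classes],
    }, indent=2))
    (out / "config_used.json").write_text(json.dumps(
        {"hash": _config_hash(cfg), "seeds": cfg.seeds}, indent=2))
    return {"events": out / "events.csv", "movie": out / "movie.tif"}


def segment_stage(cfg: RunConfig, out_dir=None) -> dict:
    out = _resolve_out(cfg, out_dir)
    movie_path = out / "movie.tif"
    if not movie_path.exists():
        raise FileNotFoundError(f"expected movie at {movie_path}; run simulate first")
    stack = iof.read_movie(movie_path)
    if cfg.register:
        stack, _ = rigid_register(stack)
    log.info("segment: K=%d on %s frames", cfg.segmentation.K, stack.n_frames)
    result = factorize(stack, cfg.segmentation, seed=cfg.seeds["segmentation"])
    iof.write_factorization(result, out / "factorization.h5")
    return {"factorization": out / "factorization.h5"}


def analyze_stage(cfg: RunConfig, out_dir=None) -> dict:
    """Whole-frame analysis: per-delay second-peak latencies and the
    random-reward response amplitude of the frame-average trace."""
    out = _resolve_out(cfg, out_dir)
    for name in ("movie.tif", "events.csv"):
        if not (out / name).exists():
            raise FileNotFoundError(f"expected {out / name}; run simulate first")
    stack = iof.read_movie(out / "movie.tif")
    session = iof.read_events(out / "events.csv", out / "whisker.h5")
    if stack.n_frames != len(session.frame_times_s):
        raise ValidationError(
            f"movie has {stack.n_frames} frames but the event log implies "
            f"{len(session.frame_times_s)}")
    trace = frame_average(stack)
    dff = compute_dff(trace, session.frame_rate_hz)
    lats = session_second_peak_latencies(dff.values, session, cfg.analysis)
    rows = [{"delay_ms": d, "second_peak_latency_s": v} for d, v in lats.items()]
    if len(lats) >= 2:
        reg = session_latency_regression([lats])
        rows.append({"delay_ms": None, "second_peak_latency_s": None,
                     "slope": reg.slope, "intercept": reg.intercept,
                     "p_value": reg.p_value})
    rr_amp = None
    if len(session.random_reward_times_s) >= 1:
        try:
            avg = triggered_average(dff.values, session.random_reward_times_s,
                                    (2.0, 3.0), session.frame_rate_hz)
            _, rr_amp, _ = window_peak(avg, (0.0, cfg.analysis.event_window_s),
                                       cfg.analysis.interpolate)
        except Exception:
            pass
    cols = ["delay_ms", "second_peak_latency_s", "slope", "intercept", "p_value"]
    pd.DataFrame(rows, columns=cols).to_csv(out / "latency_regression.csv",
                                            index=False)
    (out / "frame_average.json").write_text(json.dumps(
        {"random_reward_peak_dff": rr_amp}))
    return {"latency_regression": out / "latency_regression.csv"}


def classify_stage(cfg: RunConfig, out_dir=None) -> dict:
    out = _resolve_out(cfg, out_dir)
    for name in ("movie.tif", "events.csv", "factorization.h5"):
        if not (out / name).exists():
            raise FileNotFoundError(f"expected {out / name}; run earlier stages first")
    stack = iof.read_movie(out / "movie.tif")
    session = iof.read_events(out / "events.csv", out / "whisker.h5")
    result = iof.read_factorization(out / "factorization.h5")
    rows = []
    for k in range(result.n_components):
        roi = extract_roi_trace(stack, result.footprint_image(k))
        dff = compute_dff(roi, session.frame_rate_hz)
        rec = build_dendrite_record(k, dff, session, cfg.analysis)
        reg = rec.reward_tracking_regression
        rows.append({
            "dendrite_id": k,
            "n_events": rec.n_events,
            "pretrial_rate_hz": rec.pretrial_rate,
            "trial_rate_hz": rec.trial_rate,
            "activity_preference": rec.activity_preference,
            "is_reward_tracking": rec.is_reward_tracking,
            "reward_tracking_slope": None if reg is None else reg.slope,
            "reward_tracking_p": None if reg is None else reg.p_value,
            "is_random_reward_responsive": rec.is_random_reward_responsive,
            "is_contact_responsive": rec.is_contact_responsive,
            "predicted_class": rec.predicted_class,
        })
    pd.DataFrame(rows).to_csv(out / "classification.csv", index=False)
    return {"classification": out / "classification.csv"}


def report_stage(cfg: RunConfig, out_dir=None) -> dict:
    """Machine-readable summary over the stage outputs."""
    out = _resolve_out(cfg, out_dir)
    cls_path = out / "classification.csv"
    if not cls_path.exists():
        raise FileNotFoundError(f"expected {cls_path}; run classify first")
    df = pd.read_csv(cls_path)
    summary = {
        "n_dendrites": int(len(df)),
        "class_counts": df["predicted_class"].value_counts().to_dict(),
        "n_reward_tracking": int(df["is_reward_tracking"].sum()),
        "n_random_reward_responsive": int(df["is_random_reward_responsive"].sum()),
    }
    # reward tracking among trial- vs pretrial-active dendrites
    tri = df[df["activity_preference"] == "trial"]
    pre = df[df["activity_preference"] == "pretrial"]
    if len(tri) and len(pre):
        t = two_proportion_test(int(tri["is_reward_tracking"].sum()), len(tri),
                                int(pre["is_reward_tracking"].sum()), len(pre))
        summary["reward_tracking_trial_vs_pretrial"] = {
            "k1": t.k1, "n1": t.n1, "k2": t.k2, "n2": t.n2,
            "z": t.z, "p_value": t.p_value}
    reg_path = out / "latency_regression.csv"
    if reg_path.exists():
        reg = pd.read_csv(reg_path)
        if "slope" in reg.columns and reg["slope"].notna().any():
            summary["latency_vs_delay_slope"] = float(reg["slope"].dropna().iloc[0])
    summary["config_hash"] = _config_hash(cfg)
    summary["seeds"] = cfg.seeds
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"summary": out / "summary.json"}


def run(cfg: RunConfig, out_dir=None) -> dict:
    """Full pipeline; equals running the five stages in order."""
    cfg.validate()
    paths = {}
    for stage in (simulate_stage, segment_stage, analyze_stage,
                  classify_stage, report_stage):
        log.info("stage %s", stage.__name__)
        paths.update(stage(cfg, out_dir))
    return paths
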