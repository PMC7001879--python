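"""On-disk formats.

* Movies: multi-page TIFF (the acquisition-software native container) with a
  JSON sidecar (``<name>.meta.json``) for frame rate and pixel size; HDF5
  (``.h5``/``.hdf5``) as an alternative for float data with the metadata in
  dataset attributes.
* Event logs: one CSV row per behavioral event with columns ``time_s,
  event_kind, trial_index, trial_type, outcome, reward_delay_ms``;
  ``event_kind`` is one of {trial_start, press, pole_on, first_contact,
  lever_lift, reward, random_reward, lick, timeout_start, trial_end}
  (``trial_end`` is a schema extension needed for lossless round-trips).
  Trial-scoped columns are empty for session-scoped events.
* Whisker trace and frame times: HDF5 datasets with a sample-rate attribute.
* Results: classification CSV + regression CSV + run-metadata JSON.

Readers validate invariants (sorted times, reward after lever lift, known
ids) and fail loudly rather than coercing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .errors import ConsistencyError, FormatError, ValidationError
from .synthdata.render import MovieStack
from .synthdata.session import BehavioralSession, TrialRecord

__all__ = [
    "EVENT_KINDS", "ResultsBundle",
    "write_movie", "read_movie",
    "write_events", "read_events",
    "write_whisker", "read_whisker",
    "write_results",
]

EVENT_KINDS = ("trial_start", "press", "pole_on", "first_contact", "lever_lift",
               "reward", "random_reward", "lick", "timeout_start", "trial_end")

_TIFF_SUFFIXES = (".tif", ".tiff")
_H5_SUFFIXES = (".h5", ".hdf5")


@dataclass
class ResultsBundle:
    """Everything one pipeline run reports."""

    classification: pd.DataFrame       # one row per dendrite
    latency_regression: pd.DataFrame   # one row per regression
    metadata: dict
    dendrite_ids: list = field(default_factory=list)


# ---------------------------------------------------------------- movies

def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_movie(stack: MovieStack, path) -> None:
    """Write a movie stack; round-trips are exact for the stored dtype."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, stack.data)
        _sidecar(path).write_text(json.dumps({
            "frame_rate_hz": stack.frame_rate_hz,
            "um_per_px": stack.um_per_px,
        }))
    elif path.suffix.lower() in _H5_SUFFIXES:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("movie", data=stack.data)
            ds.attrs["frame_rate_hz"] = stack.frame_rate_hz
            ds.attrs["um_per_px"] = stack.um_per_px
    else:
        raise FormatError(f"unsupported movie container {path.suffix!r}")


def read_movie(path) -> MovieStack:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"movie file not found: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        frames = []
        try:
            tf = tifffile.TiffFile(path)
        except Exception as exc:
            raise FormatError(f"cannot open TIFF {path}: {exc}") from exc
        with tf:
            for i, page in enumerate(tf.pages):
                try:
                    frames.append(page.asarray())
                except Exception as exc:
                    raise FormatError(
                        f"corrupt TIFF {path}: failed at frame {i}") from exc
        if not frames:
            raise FormatError(f"TIFF {path} contains 0 frames")
        data = np.stack(frames)
        meta = {"frame_rate_hz": 1.0, "um_per_px": 1.0}
        side = _sidecar(path)
        if side.exists():
            meta.update(json.loads(side.read_text()))
        return MovieStack(data=data, frame_rate_hz=float(meta["frame_rate_hz"]),
                          um_per_px=float(meta["um_per_px"]))
    if path.suffix.lower() in _H5_SUFFIXES:
        with h5py.File(path, "r") as f:
            if "movie" not in f:
                raise FormatError(f"{path} lacks a 'movie' dataset")
            ds = f["movie"]
            if ds.shape[0] == 0:
                raise FormatError(f"{path} contains 0 frames")
            return MovieStack(data=ds[()],
                              frame_rate_hz=float(ds.attrs["frame_rate_hz"]),
                              um_per_px=float(ds.attrs.get("um_per_px", 1.0)))
    raise FormatError(f"unsupported movie container {path.suffix!r}")


# ------------------------------------------------------------- event logs

def _fmt(x) -> str:
    if x is None:
        return ""
    return repr(float(x)) if isinstance(x, float) else str(x)


def write_events(session: BehavioralSession, path) -> None:
    """Event-log CSV for one session (times sorted, full float precision)."""
    rows = []

    def row(t, kind, trial=None):
        rows.append({
            "time_s": float(t),
            "event_kind": kind,
            "trial_index": None if trial is None else trial.trial_index,
            "trial_type": None if trial is None else trial.trial_type,
            "outcome": None if trial is None else trial.outcome,
            "reward_delay_ms": None if trial is None else trial.reward_delay_ms,
        })

    for tr in session.trials:
        row(tr.press_time_s, "trial_start", tr)
        row(tr.press_time_s, "press", tr)
        row(tr.pole_onset_s, "pole_on", tr)
        if tr.first_contact_s is not None:
            row(tr.first_contact_s, "first_contact", tr)
        if tr.response_time_s is not None:
            row(tr.response_time_s, "lever_lift", tr)
        if tr.reward_time_s is not None:
            row(tr.reward_time_s, "reward", tr)
        if tr.outcome == "FalseAlarm":
            row(tr.response_time_s, "timeout_start", tr)
        row(tr.trial_end_s, "trial_end", tr)
    for t in session.random_reward_times_s:
        row(t, "random_reward")
    for t in session.lick_times_s:
        row(t, "lick")
    rows.sort(key=lambda r: (r["time_s"], EVENT_KINDS.index(r["event_kind"])))

    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("time_s,event_kind,trial_index,trial_type,outcome,reward_delay_ms\n")
        for r in rows:
            fh.write(",".join([
                repr(r["time_s"]), r["event_kind"],
                "" if r["trial_index"] is None else str(r["trial_index"]),
                r["trial_type"] or "", r["outcome"] or "",
                "" if r["reward_delay_ms"] is None else str(r["reward_delay_ms"]),
            ]) + "\n")
    # session-level attributes ride in a small sidecar
    _sidecar(path).write_text(json.dumps({
        "session_id": session.session_id,
        "task_variant": session.task_variant,
        "frame_rate_hz": session.frame_rate_hz,
    }))


def write_whisker(session: BehavioralSession, path) -> None:
    """Whisker trace + frame times as HDF5 datasets with rate attributes."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("whisker_angle", data=session.whisker_angle)
        ds.attrs["sample_rate_hz"] = session.whisker_rate_hz
        ft = f.create_dataset("frame_times_s", data=session.frame_times_s)
        ft.attrs["frame_rate_hz"] = session.frame_rate_hz


def read_whisker(path):
    with h5py.File(path, "r") as f:
        theta = f["whisker_angle"][()]
        rate = float(f["whisker_angle"].attrs["sample_rate_hz"])
        frame_times = f["frame_times_s"][()]
        frame_rate = float(f["frame_times_s"].attrs["frame_rate_hz"])
    return theta, rate, frame_times, frame_rate


def read_events(path, whisker_path=None) -> BehavioralSession:
    """Rebuild a session (movie-independent fields) from its event log."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"trial_index": "Int64", "reward_delay_ms": "Int64"},
                     float_precision="round_trip")
    required = {"time_s", "event_kind", "trial_index", "trial_type", "outcome",
                "reward_delay_ms"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path} missing columns {sorted(required - set(df.columns))}")
    bad_kinds = set(df["event_kind"]) - set(EVENT_KINDS)
    if bad_kinds:
        raise FormatError(f"{path} has unknown event kinds {sorted(bad_kinds)}")
    if (df["time_s"] < 0).any():
        rows = list(df.index[df["time_s"] < 0])
        raise ValidationError(f"negative event times at rows {rows}")
    if not df["time_s"].is_monotonic_increasing:
        bad = list(df.index[df["time_s"].diff() < 0])
        raise ValidationError(f"event times not sorted; offending rows {bad}")

    trials = []
    for idx, grp in df[df["trial_index"].notna()].groupby("trial_index"):
        kinds = {k: grp.loc[grp["event_kind"] == k, "time_s"]
                 for k in EVENT_KINDS}

        def one(kind):
            vals = kinds[kind]
            return float(vals.iloc[0]) if len(vals) else None

        outcome = grp["outcome"].iloc[0]
        lift, reward = one("lever_lift"), one("reward")
        if reward is not None and lift is not None and reward < lift:
            rows = list(grp.index[grp["event_kind"] == "reward"])
            raise ValidationError(
                f"trial {idx}: reward precedes lever lift (rows {rows})")
        delay = grp["reward_delay_ms"].dropna()
        trials.append(TrialRecord(
            trial_index=int(idx),
            trial_type=grp["trial_type"].iloc[0],
            press_time_s=one("press"),
            pole_onset_s=one("pole_on"),
            outcome=outcome,
            trial_end_s=one("trial_end"),
            first_contact_s=one("first_contact"),
            response_time_s=lift,
            reward_delay_ms=int(delay.iloc[0]) if len(delay) else None,
            reward_time_s=reward,
        ))
    trials.sort(key=lambda t: t.trial_index)

    meta = {"session_id": path.stem, "task_variant": "pole_detection",
            "frame_rate_hz": 4.0}
    side = _sidecar(path)
    if side.exists():
        meta.update(json.loads(side.read_text()))

    if whisker_path is not None:
        theta, wrate, frame_times, frate = read_whisker(whisker_path)
    else:
        theta, wrate = np.zeros(0), 100.0
        end = max((t.trial_end_s for t in trials), default=0.0) + 8.0
        frate = float(meta["frame_rate_hz"])
        frame_times = np.arange(0.0, end, 1.0 / frate)

    return BehavioralSession(
        trials=trials,
        random_reward_times_s=list(
            df.loc[df["event_kind"] == "random_reward", "time_s"]),
        lick_times_s=list(df.loc[df["event_kind"] == "lick", "time_s"]),
        whisker_angle=theta,
        whisker_rate_hz=wrate,
        frame_times_s=frame_times,
        session_id=str(meta["session_id"]),
        task_variant=str(meta["task_variant"]),
        frame_rate_hz=float(meta["frame_rate_hz"]),
    )


# ---------------------------------------------------------- factorization

def write_factorization(result, path) -> None:
    """Footprints as sparse (component, pixel, weight) triplets; traces dense."""
    from .segmentation import FactorizationResult  # local to avoid cycle

    assert isinstance(result, FactorizationResult)
    comp, pix = np.nonzero(result.A.T)
    with h5py.File(path, "w") as f:
        f.create_dataset("footprint_component", data=comp.astype(np.int32))
        f.create_dataset("footprint_pixel", data=pix.astype(np.int32))
        f.create_dataset("footprint_weight", data=result.A.T[comp, pix])
        f.create_dataset("traces", data=result.C)
        f.create_dataset("background_image", data=result.b)
        f.create_dataset("background_trace", data=result.f)
        f.create_dataset("objective_history", data=result.objective_history)
        f.attrs["frame_shape"] = result.frame_shape
        f.attrs["converged"] = result.converged
        f.attrs["n_components"] = result.n_components


def read_factorization(path):
    from .segmentation import FactorizationResult

    with h5py.File(path, "r") as f:
        shape = tuple(int(x) for x in f.attrs["frame_shape"])
        K = int(f.attrs["n_components"])
        A = np.zeros((shape[0] * shape[1], K))
        A[f["footprint_pixel"][()], f["footprint_component"][()]] = \
            f["footprint_weight"][()]
        return FactorizationResult(
            A=A, C=f["traces"][()], b=f["background_image"][()],
            f=f["background_trace"][()],
            objective_history=f["objective_history"][()],
            frame_shape=shape, converged=bool(f.attrs["converged"]))


# ---------------------------------------------------------------- results

def write_results(bundle: ResultsBundle, out_dir) -> dict:
    """Write classification CSV, regression CSV and metadata JSON.

    Raises ``ConsistencyError`` if the classification table references a
    dendrite id absent from the factorization result.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle.dendrite_ids and "dendrite_id" in bundle.classification.columns:
        unknown = set(bundle.classification["dendrite_id"]) - set(bundle.dendrite_ids)
        if unknown:
            raise ConsistencyError(
                f"classification references unknown dendrite ids {sorted(unknown)}")
    paths = {
        "classification": out / "classification.csv",
        "latency_regression": out / "latency_regression.csv",
        "metadata": out / "metadata.json",
    }
    bundle.classification.to_csv(paths["classification"], index=False)
    bundle.latency_regression.to_csv(paths["latency_regression"], index=False)
    paths["metadata"].write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True))
    return paths
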