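"""File formats for sessions, features, references and reports.

Everything is plain text: comma-separated CSV with a header row for
time series and feature tables, JSON for metadata, references, trees
and evaluation reports.  All angles are degrees and all times seconds
in every file; missing values are empty fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .observer import GazeRecording, ParticipantRecord
from .normative import NormativeReference, ZScoreProfile
from .stimulus import SessionConfig, StimulusTrajectory
from .stp import FEATURE_NAMES, STPFeatures

__all__ = [
    "write_session",
    "read_session",
    "write_cohort",
    "read_cohort",
    "write_features_csv",
    "read_features_csv",
    "write_features_json",
    "write_reference",
    "read_reference",
    "write_zscore_csv",
    "write_report",
]


def _stim_frame(trials: Sequence[StimulusTrajectory]) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(trials):
        rows.append(pd.DataFrame({
            "trial": i, "t": t.timestamps, "x_deg": t.x, "y_deg": t.y,
            "mode": t.mode,
        }))
    return pd.concat(rows, ignore_index=True)


def _gaze_frame(trials: Sequence[GazeRecording]) -> pd.DataFrame:
    rows = []
    for i, g in enumerate(trials):
        rows.append(pd.DataFrame({
            "trial": i, "t": g.timestamps, "x": g.x, "y": g.y,
            "valid": g.valid.astype(int),
        }))
    return pd.concat(rows, ignore_index=True)


def write_session(
    directory: Path,
    mode: str,
    pairs: Sequence[Tuple[StimulusTrajectory, GazeRecording]],
    config: Optional[SessionConfig] = None,
    extra_meta: Optional[dict] = None,
) -> None:
    """Write one session (stimulus + gaze CSVs and a JSON sidecar)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stims = [p[0] for p in pairs]
    gazes = [p[1] for p in pairs]
    _stim_frame(stims).to_csv(directory / f"stimulus_{mode}.csv", index=False)
    _gaze_frame(gazes).to_csv(directory / f"gaze_{mode}.csv", index=False)
    meta = {
        "mode": mode,
        "rate": stims[0].rate,
        "n_trials": len(pairs),
        "units": gazes[0].units,
    }
    if config is not None:
        meta["config"] = dataclasses.asdict(config)
    if extra_meta:
        meta.update(extra_meta)
    (directory / f"session_{mode}.json").write_text(json.dumps(meta, indent=2))


def read_session(
    directory: Path, mode: str
) -> List[Tuple[StimulusTrajectory, GazeRecording]]:
    """Read a session written by :func:`write_session`."""
    directory = Path(directory)
    meta = json.loads((directory / f"session_{mode}.json").read_text())
    try:
        stim_df = pd.read_csv(directory / f"stimulus_{mode}.csv")
        gaze_df = pd.read_csv(directory / f"gaze_{mode}.csv")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed session CSV in {directory}: {exc}") from exc
    pairs = []
    for trial, sdf in stim_df.groupby("trial", sort=True):
        gdf = gaze_df[gaze_df["trial"] == trial]
        if len(gdf) != len(sdf):
            raise ValueError(f"trial {trial}: stimulus/gaze length mismatch")
        stim = StimulusTrajectory(
            timestamps=sdf["t"].to_numpy(), x=sdf["x_deg"].to_numpy(),
            y=sdf["y_deg"].to_numpy(), mode=mode, rate=float(meta["rate"]),
        )
        if mode == "displaced" and "config" in meta:
            period = int(round(meta["config"]["jump_interval"] * meta["rate"]))
            stim.jump_indices = np.arange(period, stim.n_samples, period)
        gaze = GazeRecording(
            timestamps=gdf["t"].to_numpy(), x=gdf["x"].to_numpy(),
            y=gdf["y"].to_numpy(), valid=gdf["valid"].to_numpy().astype(bool),
            rate=float(meta["rate"]), units=meta.get("units", "deg"),
        )
        pairs.append((stim, gaze))
    return pairs


def write_cohort(
    directory: Path,
    cohort: Sequence[ParticipantRecord],
    config: SessionConfig,
    seed: Optional[int] = None,
    jitter_rel: Optional[float] = None,
) -> None:
    """Write per-participant session files plus a cohort manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": seed,
        "jitter_rel": jitter_rel,
        "participants": [],
    }
    for p in cohort:
        pdir = directory / p.participant_id
        for mode, pairs in p.sessions.items():
            write_session(pdir, mode, pairs, config)
        manifest["participants"].append({
            "id": p.participant_id,
            "label": p.label,
            "observer": dataclasses.asdict(p.observer),
        })
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(directory: Path) -> Tuple[List[dict], dict]:
    """Read a cohort manifest; sessions are loaded lazily via read_session."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return manifest["participants"], manifest


def write_features_csv(
    path: Path, features: Dict[str, STPFeatures], labels: Optional[Dict[str, str]] = None
) -> None:
    """One row per participant, 40 columns in canonical order."""
    rows = []
    for pid, f in features.items():
        row = {"participant": pid}
        if labels is not None:
            row["label"] = labels.get(pid, "")
        row.update({n: f.values[n] for n in FEATURE_NAMES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_features_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [n for n in FEATURE_NAMES if n not in df.columns]
    if missing:
        raise ValueError(f"features file lacks columns: {missing[:5]}")
    return df


def write_features_json(path: Path, features: STPFeatures) -> None:
    payload = {
        "values": features.values,
        "metadata": features.metadata,
        "warnings": features.warnings,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_reference(path: Path, ref: NormativeReference) -> None:
    payload = {
        name: {"median": ref.medians[name], "mad": ref.mads[name], "n": ref.n}
        for name in FEATURE_NAMES
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_reference(path: Path) -> NormativeReference:
    payload = json.loads(Path(path).read_text())
    medians = {k: v["median"] for k, v in payload.items()}
    mads = {k: v["mad"] for k, v in payload.items()}
    n = next(iter(payload.values()))["n"]
    return NormativeReference(medians=medians, mads=mads, n=n)


def write_zscore_csv(path: Path, profile: ZScoreProfile) -> None:
    """Spider-plot-ready export: feature, z, flag."""
    pd.DataFrame({
        "feature": list(profile.z.keys()),
        "z": list(profile.z.values()),
        "flag": [int(profile.flags[k]) for k in profile.z],
    }).to_csv(path, index=False)


def write_report(path: Path, report: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"cannot serialise {type(o)}")
    Path(path).write_text(json.dumps(report, indent=2, default=default))
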