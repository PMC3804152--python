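"""File formats: marker TSV, subject JSON, map CSV (+ JSON sidecar),
trials CSV, and run manifests.

All normalized quantities carry explicit unit suffixes in headers
(``x_footlen``, ``v_heights_per_s``) to prevent silent unit confusion.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .body import MarkerFrame, Segment, SubjectModel
from .maps import BalanceMap

__all__ = [
    "read_marker_tsv",
    "write_marker_tsv",
    "read_subject_json",
    "write_subject_json",
    "read_map_csv",
    "write_map_csv",
    "read_trials_csv",
    "write_trials_csv",
    "write_manifest",
]


# --- marker TSV --------------------------------------------------------------
# Header: time<TAB><name>_x<TAB><name>_y<TAB><name>_z ...; meters; one frame
# per row; empty cells or NaN mark missing markers.


def read_marker_tsv(path) -> list[MarkerFrame]:
    df = pd.read_csv(path, sep="\t")
    if "time" not in df.columns:
        raise ValueError(f"{path}: marker TSV must have a 'time' column")
    names = []
    for col in df.columns:
        if col.endswith("_x"):
            base = col[:-2]
            if f"{base}_y" in df.columns and f"{base}_z" in df.columns:
                names.append(base)
    if not names:
        raise ValueError(f"{path}: no <name>_x/_y/_z marker columns found")
    frames = []
    for _, row in df.iterrows():
        pos = {}
        for n in names:
            p = (row[f"{n}_x"], row[f"{n}_y"], row[f"{n}_z"])
            if np.all(np.isfinite(p)):
                pos[n] = (float(p[0]), float(p[1]), float(p[2]))
        frames.append(MarkerFrame(time=float(row["time"]), positions=pos))
    return frames


def write_marker_tsv(frames, path) -> None:
    names = sorted({n for fr in frames for n in fr.positions})
    cols = {"time": [fr.time for fr in frames]}
    for n in names:
        for k, ax in enumerate(("x", "y", "z")):
            cols[f"{n}_{ax}"] = [
                fr.positions[n][k] if n in fr.positions else np.nan
                for fr in frames
            ]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# --- subject JSON ------------------------------------------------------------


def write_subject_json(subject: SubjectModel, path) -> None:
    data = asdict(subject)
    data["segment_table"] = [asdict(s) for s in subject.segment_table]
    Path(path).write_text(json.dumps(data, indent=2))


_REQUIRED = ("mass", "height", "d_toe", "d_heel", "ankle_height",
             "foot_length", "mu", "tau_pf_max", "tau_df_max")


def read_subject_json(path) -> SubjectModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: invalid JSON ({e})") from e
    for key in _REQUIRED:
        if key not in data:
            raise ValueError(f"{path}: missing required subject field '{key}'")
        if not isinstance(data[key], (int, float)):
            raise ValueError(f"{path}: subject field '{key}' must be a number")
    kwargs = {k: float(data[k]) for k in _REQUIRED}
    if "segment_table" in data:
        segs = []
        for i, s in enumerate(data["segment_table"]):
            for key in ("name", "fraction", "fraction_sd", "proximal", "distal"):
                if key not in s:
                    raise ValueError(
                        f"{path}: segment_table[{i}] missing field '{key}'"
                    )
            segs.append(Segment(s["name"], float(s["fraction"]),
                                float(s["fraction_sd"]),
                                tuple(s["proximal"]), tuple(s["distal"])))
        kwargs["segment_table"] = tuple(segs)
    if "ankle_markers" in data:
        kwargs["ankle_markers"] = tuple(data["ankle_markers"])
    return SubjectModel(**kwargs)


# --- map CSV + sidecar -------------------------------------------------------


def write_map_csv(bmap: BalanceMap, path) -> None:
    path = Path(path)
    pd.DataFrame({
        "x_footlen": bmap.x,
        "v_upper": bmap.v_upper,
        "v_lower": bmap.v_lower,
        "v_zero": bmap.v_zero,
    }).to_csv(path, index=False, float_format="%.9g")
    sidecar = dict(bmap.meta)
    sidecar["model"] = bmap.model
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_map_csv(path) -> BalanceMap:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("x_footlen", "v_upper", "v_lower", "v_zero"):
        if col not in df.columns:
            raise ValueError(f"{path}: map CSV missing column '{col}'")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return BalanceMap(
        x=df["x_footlen"].to_numpy(),
        v_upper=df["v_upper"].to_numpy(),
        v_lower=df["v_lower"].to_numpy(),
        v_zero=df["v_zero"].to_numpy(),
        model=meta.get("model", "unknown"),
        meta=meta,
    )


# --- trials CSV --------------------------------------------------------------

_TRIAL_COLS = ("trial_id", "x_footlen", "v_heights_per_s", "outcome", "condition")


def write_trials_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _TRIAL_COLS[:4]:
        if col not in df.columns:
            raise ValueError(f"{path}: trials CSV missing column '{col}'")
    if "condition" not in df.columns:
        df["condition"] = ""
    return df


# --- run manifest ------------------------------------------------------------


def write_manifest(out_dir, subcommand: str, params: dict) -> Path:
    """Record every resolved parameter value plus the software version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "stsbalance",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": params,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
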