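"""Readers and writers for the on-disk formats.

* Pose CSV: one file per camera view, long format with header
  ``frame,time_s,joint,x,y,z,confidence``; occluded detections leave the
  coordinate fields empty.
* Pose HDF5: one file per recording holding every view (``views/<id>/data``
  float32 (T, N, 4) and ``views/<id>/missing``) plus a JSON metadata
  attribute (fps, joint names, sync offsets, chest centre, ...).
* Topology: plain text, one ``joint_a,joint_b`` bone per line.
* Ratings CSV: one row per (recording, rater, cycle) with the six
  per-cycle dimension points, the 0-4 item totals, the ordinal overall
  rating and any failure codes; totals are validated against the cycle
  points on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .scoring import DIMENSIONS, OVERALL_CATEGORIES, ChecklistScore
from .simulate import GroundTruth
from .skeleton import MultiviewRecording, PoseSequence, SkeletonGraph

__all__ = [
    "read_pose_csv", "write_pose_csv", "read_pose_h5", "write_pose_h5",
    "read_topology", "write_topology", "read_ratings", "write_ratings",
    "ratings_rows", "SchemaError",
]

_POSE_COLUMNS = ["frame", "time_s", "joint", "x", "y", "z", "confidence"]


class SchemaError(ValueError):
    """A file does not conform to the expected schema."""


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def write_topology(path, graph: SkeletonGraph):
    lines = [f"{graph.joint_names[i]},{graph.joint_names[j]}"
             for i, j in sorted(graph.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path) -> SkeletonGraph:
    bones = []
    names: list[str] = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split(",")
        if len(parts) != 2:
            raise SchemaError(f"bad bone line {ln!r}")
        a, b = (p.strip() for p in parts)
        for n in (a, b):
            if n not in names:
                names.append(n)
        bones.append((a, b))
    if not bones:
        raise SchemaError("empty topology file")
    return SkeletonGraph.from_named_edges(names, bones)


# ---------------------------------------------------------------------------
# pose CSV (one view per file)
# ---------------------------------------------------------------------------

def write_pose_csv(path, seq: PoseSequence, graph: SkeletonGraph):
    bad = ~np.isfinite(seq.data[..., :3]).all(axis=2) & ~seq.missing_mask
    if bad.any():
        raise SchemaError("non-finite coordinate outside the missing mask")
    T, N = seq.data.shape[:2]
    frames = np.repeat(np.arange(T), N)
    joints = np.tile(np.array(graph.joint_names), T)
    flat = seq.data.reshape(T * N, 4)
    miss = seq.missing_mask.reshape(T * N)
    df = pd.DataFrame({
        "frame": frames,
        "time_s": frames / seq.fps,
        "joint": joints,
        "x": np.where(miss, np.nan, flat[:, 0]),
        "y": np.where(miss, np.nan, flat[:, 1]),
        "z": np.where(miss, np.nan, flat[:, 2]),
        "confidence": flat[:, 3],
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_pose_csv(path, fps: float, view_id: str | None = None) -> tuple[PoseSequence, list[str]]:
    """Load one view; returns the sequence and the joint-name order found."""
    df = pd.read_csv(path)
    missing_cols = [c for c in _POSE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"pose file lacks columns {missing_cols}")
    if fps <= 0:
        raise SchemaError("fps must be positive")
    joints = list(dict.fromkeys(df["joint"]))
    n = len(joints)
    frames = np.sort(df["frame"].unique())
    if len(df) != len(frames) * n:
        raise SchemaError("inconsistent joint count across frames")
    df = df.sort_values(["frame", "joint"], key=lambda s: (
        s if s.name == "frame" else s.map({j: k for k, j in enumerate(joints)})))
    data = df[["x", "y", "z", "confidence"]].to_numpy().reshape(len(frames), n, 4)
    mask = ~np.isfinite(data[..., :3]).all(axis=2)
    data[..., :3][mask] = np.nan
    if np.any((data[..., 3] < 0) | (data[..., 3] > 1)):
        raise SchemaError("confidence outside [0, 1]")
    name = view_id if view_id is not None else Path(path).stem
    return PoseSequence(name, fps, data, mask), joints


# ---------------------------------------------------------------------------
# pose HDF5 (all views of a recording)
# ---------------------------------------------------------------------------

def write_pose_h5(path, rec: MultiviewRecording, graph: SkeletonGraph, fps: float | None = None):
    with h5py.File(path, "w") as f:
        meta = {
            "recording_id": rec.recording_id,
            "joint_names": list(graph.joint_names),
            "fps": fps if fps is not None else next(iter(rec.views.values())).fps,
            "sync_offsets": rec.sync_offsets,
            **{k: v for k, v in rec.metadata.items()
               if isinstance(v, (str, int, float, list, dict, bool))},
        }
        f.attrs["metadata"] = json.dumps(meta)
        g = f.create_group("views")
        for k, seq in rec.views.items():
            vg = g.create_group(k)
            vg.create_dataset("data", data=seq.data.astype(np.float32))
            vg.create_dataset("missing", data=seq.missing_mask)
            vg.attrs["fps"] = seq.fps


def read_pose_h5(path) -> tuple[MultiviewRecording, list[str]]:
    with h5py.File(path, "r") as f:
        try:
            meta = json.loads(f.attrs["metadata"])
        except KeyError as e:
            raise SchemaError("missing metadata attribute") from e
        views = {}
        for k in f["views"]:
            vg = f["views"][k]
            data = vg["data"][...].astype(float)
            mask = vg["missing"][...].astype(bool)
            fps = float(vg.attrs["fps"])
            if fps <= 0:
                raise SchemaError("negative or zero fps")
            views[k] = PoseSequence(k, fps, data, mask)
    offsets = {k: int(v) for k, v in meta.get("sync_offsets", {}).items()}
    rec = MultiviewRecording(meta.get("recording_id", Path(path).stem), views,
                             offsets, metadata=meta)
    return rec, list(meta["joint_names"])


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

def ratings_rows(recording_id: str, source: ChecklistScore | GroundTruth,
                 rater: str) -> list[dict]:
    """Flatten a checklist result into ratings-table rows (one per cycle)."""
    if isinstance(source, ChecklistScore):
        cycles = [c.points for c in source.cycles if c.scorable]
        codes = {d: ";".join(sorted({c for cyc in source.cycles if cyc.scorable
                                     for c in cyc.codes.get(d, [])}))
                 for d in DIMENSIONS}
        overall = source.overall_per_cycle
        totals = source.item_totals
    else:
        cycles = source.per_cycle_points
        codes = {d: ";".join(source.codes[d]) for d in DIMENSIONS}
        overall = source.overall_per_cycle
        totals = source.item_totals
    rows = []
    for ci, pts in enumerate(cycles):
        row = {"recording_id": recording_id, "rater": rater, "cycle": ci + 1}
        for d in DIMENSIONS:
            row[d] = int(pts[d])
        for d in DIMENSIONS:
            row[f"{d}_total"] = int(totals[d])
        row["overall"] = overall[ci]
        row["codes"] = ";".join(f"{d}:{codes[d]}" for d in DIMENSIONS if codes[d])
        rows.append(row)
    return rows


def write_ratings(path, rows: list[dict] | pd.DataFrame):
    df = pd.DataFrame(rows)
    _validate_ratings(df)
    df.to_csv(path, index=False)


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    _validate_ratings(df)
    return df


def _validate_ratings(df: pd.DataFrame):
    need = ["recording_id", "rater", "cycle", *DIMENSIONS,
            *[f"{d}_total" for d in DIMENSIONS], "overall"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"ratings table lacks columns {missing}")
    bad = set(df["overall"]) - set(OVERALL_CATEGORIES)
    if bad:
        raise SchemaError(f"unknown overall rating categories {sorted(bad)}")
    for d in DIMENSIONS:
        if not df[d].isin((0, 1)).all():
            raise SchemaError(f"per-cycle {d} points must be 0 or 1")
    for (rid, rater), grp in df.groupby(["recording_id", "rater"]):
        for d in DIMENSIONS:
            tot = grp[f"{d}_total"].unique()
            if len(tot) != 1 or int(tot[0]) != int(grp[d].sum()):
                raise SchemaError(
                    f"item total for {d} of {rid}/{rater} does not equal "
                    f"the sum of its cycle points")
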