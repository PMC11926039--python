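"""Skeleton graphs and multiview 3D pose sequences.

The human body is modelled as an undirected graph whose nodes are tracked
joints and whose edges are bones.  A recording is a set of per-camera pose
sequences, each a ``T x N x C`` array of world coordinates (meters) plus a
per-joint detection confidence, together with integer frame offsets that
temporally align the cameras.

Two joint layouts ship with the package: the 33-landmark full-body layout
produced by common markerless pose estimators, and a reduced 17-joint subset
(head, shoulders, elbows, wrists, hands, hips, knees, ankles, heels) that is
cheaper to simulate and to push through the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "SkeletonGraph",
    "PoseSequence",
    "MultiviewRecording",
    "normalized_adjacency",
    "center_and_scale",
    "center_static",
    "resample_time",
    "interpolate_missing",
    "mediapipe33_graph",
    "reduced17_graph",
    "get_topology",
]

N_CHANNELS = 4  # x, y, z, confidence


class DegenerateGraphError(ValueError):
    """Raised when a graph cannot be degree-normalised (zero-degree node)."""


class UnnormalisableError(ValueError):
    """Raised when a pose sequence lacks the anchor joints needed to normalise."""


@dataclass(frozen=True)
class SkeletonGraph:
    """Joint topology: named nodes and an undirected bone set.

    Edges are stored as sorted index pairs; self-edges are rejected.  The
    graph must be connected so that graph convolutions can propagate
    information between any two joints.
    """

    joint_names: tuple[str, ...]
    edges: frozenset[tuple[int, int]]

    def __post_init__(self):
        n = len(self.joint_names)
        if n == 0:
            raise ValueError("graph needs at least one joint")
        if len(set(self.joint_names)) != n:
            raise ValueError("duplicate joint names")
        norm = set()
        for i, j in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) references joint outside [0,{n})")
            if i == j:
                raise ValueError(f"self-edge at joint {i}")
            norm.add((min(i, j), max(i, j)))
        object.__setattr__(self, "edges", frozenset(norm))
        if n > 1 and not self._connected():
            raise ValueError("skeleton graph must be connected")

    def _connected(self) -> bool:
        n = self.N
        adj = [[] for _ in range(n)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        seen = {0}
        stack = [0]
        while stack:
            for m in adj[stack.pop()]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return len(seen) == n

    @property
    def N(self) -> int:
        return len(self.joint_names)

    def index(self, name: str) -> int:
        return self.joint_names.index(name)

    def adjacency(self) -> np.ndarray:
        """Binary adjacency matrix A with A[i,j] = 1 iff (i,j) is a bone."""
        a = np.zeros((self.N, self.N))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    @classmethod
    def from_named_edges(cls, joint_names: Iterable[str],
                         bones: Iterable[tuple[str, str]]) -> "SkeletonGraph":
        names = tuple(joint_names)
        idx = {n: i for i, n in enumerate(names)}
        return cls(names, frozenset((idx[a], idx[b]) for a, b in bones))


@dataclass
class PoseSequence:
    """One camera view's motion record.

    ``data`` has shape (T, N, 4): x, y, z in meters in that camera's world
    frame (vertical axis +Y) and a detection confidence in [0, 1].
    ``missing_mask`` flags frame-joint entries with no usable detection;
    coordinates there may be NaN.
    """

    view_id: str
    fps: float
    data: np.ndarray
    missing_mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != N_CHANNELS:
            raise ValueError(f"data must be (T, N, {N_CHANNELS}), got {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one frame")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.data.shape[:2], dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.data.shape[:2]:
            raise ValueError("missing_mask shape must be (T, N)")
        conf = self.data[..., 3]
        ok = ~self.missing_mask
        if np.any((conf[ok] < 0) | (conf[ok] > 1)):
            raise ValueError("confidence must lie in [0, 1]")
        if not np.all(np.isfinite(self.data[ok])):
            raise ValueError("coordinates must be finite where not missing")

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def N(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.T / self.fps

    def times(self) -> np.ndarray:
        return np.arange(self.T) / self.fps

    def copy(self) -> "PoseSequence":
        return PoseSequence(self.view_id, self.fps, self.data.copy(),
                            self.missing_mask.copy())


@dataclass
class MultiviewRecording:
    """All camera views of one CPR performance plus alignment offsets.

    ``sync_offsets[k]`` is the frame index in view ``k`` at which the common
    (canonical) clock starts: canonical frame f appears in view k at frame
    f + sync_offsets[k].
    """

    recording_id: str
    views: dict[str, PoseSequence]
    sync_offsets: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.views:
            raise ValueError("recording needs at least one view")
        ns = {v.N for v in self.views.values()}
        if len(ns) != 1:
            raise ValueError("all views must share one joint topology")
        for k in self.views:
            self.sync_offsets.setdefault(k, 0)
        # overlap of [offset, offset+T) across views must be nonempty
        lo = max(self.sync_offsets[k] for k in self.views)
        hi = min(self.sync_offsets[k] + self.views[k].T for k in self.views)
        if hi <= lo:
            raise ValueError("sync offsets leave no common temporal overlap")


# ---------------------------------------------------------------------------
# topologies
# ---------------------------------------------------------------------------

_MP33_NAMES = (
    "nose",
    "left_eye_inner", "left_eye", "left_eye_outer",
    "right_eye_inner", "right_eye", "right_eye_outer",
    "left_ear", "right_ear",
    "mouth_left", "mouth_right",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_pinky", "right_pinky",
    "left_index", "right_index",
    "left_thumb", "right_thumb",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
    "left_heel", "right_heel",
    "left_foot_index", "right_foot_index",
)

_MP33_BONES = [
    ("nose", "left_eye_inner"), ("left_eye_inner", "left_eye"),
    ("left_eye", "left_eye_outer"), ("left_eye_outer", "left_ear"),
    ("nose", "right_eye_inner"), ("right_eye_inner", "right_eye"),
    ("right_eye", "right_eye_outer"), ("right_eye_outer", "right_ear"),
    ("mouth_left", "mouth_right"), ("nose", "mouth_left"), ("nose", "mouth_right"),
    ("left_shoulder", "right_shoulder"),
    ("left_shoulder", "left_elbow"), ("left_elbow", "left_wrist"),
    ("right_shoulder", "right_elbow"), ("right_elbow", "right_wrist"),
    ("left_wrist", "left_pinky"), ("left_wrist", "left_index"),
    ("left_wrist", "left_thumb"), ("left_pinky", "left_index"),
    ("right_wrist", "right_pinky"), ("right_wrist", "right_index"),
    ("right_wrist", "right_thumb"), ("right_pinky", "right_index"),
    ("left_shoulder", "left_hip"), ("right_shoulder", "right_hip"),
    ("left_hip", "right_hip"),
    ("left_hip", "left_knee"), ("left_knee", "left_ankle"),
    ("right_hip", "right_knee"), ("right_knee", "right_ankle"),
    ("left_ankle", "left_heel"), ("left_heel", "left_foot_index"),
    ("left_ankle", "left_foot_index"),
    ("right_ankle", "right_heel"), ("right_heel", "right_foot_index"),
    ("right_ankle", "right_foot_index"),
    ("nose", "left_shoulder"), ("nose", "right_shoulder"),
]

_R17_NAMES = (
    "nose",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_index", "right_index",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
    "left_heel", "right_heel",
)

_R17_BONES = [
    ("nose", "left_shoulder"), ("nose", "right_shoulder"),
    ("left_shoulder", "right_shoulder"),
    ("left_shoulder", "left_elbow"), ("left_elbow", "left_wrist"),
    ("right_shoulder", "right_elbow"), ("right_elbow", "right_wrist"),
    ("left_wrist", "left_index"), ("right_wrist", "right_index"),
    ("left_shoulder", "left_hip"), ("right_shoulder", "right_hip"),
    ("left_hip", "right_hip"),
    ("left_hip", "left_knee"), ("left_knee", "left_ankle"),
    ("right_hip", "right_knee"), ("right_knee", "right_ankle"),
    ("left_ankle", "left_heel"), ("right_ankle", "right_heel"),
]


def mediapipe33_graph() -> SkeletonGraph:
    """Full 33-landmark body layout with the standard bone list."""
    return SkeletonGraph.from_named_edges(_MP33_NAMES, _MP33_BONES)


def reduced17_graph() -> SkeletonGraph:
    """17-joint subset: head, shoulders, elbows, wrists, hands, hips, knees,
    ankles, heels."""
    return SkeletonGraph.from_named_edges(_R17_NAMES, _R17_BONES)


def get_topology(name: str) -> SkeletonGraph:
    if name in ("mediapipe-33", "mediapipe33", "full33"):
        return mediapipe33_graph()
    if name in ("reduced-17", "reduced17"):
        return reduced17_graph()
    raise ValueError(f"unknown topology {name!r}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalized_adjacency(graph: SkeletonGraph, add_self_loops: bool = True) -> np.ndarray:
    """Symmetric degree-normalised adjacency D^{-1/2} A' D^{-1/2}.

    A' is the binary bone adjacency, plus the identity when
    ``add_self_loops`` (the default — without self-loops a node's own
    features never reach its output).  All eigenvalues of the result lie in
    [-1, 1].
    """
    a = graph.adjacency()
    if add_self_loops:
        a = a + np.eye(graph.N)
    deg = a.sum(axis=1)
    if np.any(deg == 0):
        bad = [graph.joint_names[i] for i in np.flatnonzero(deg == 0)]
        raise DegenerateGraphError(f"zero-degree joints {bad}: cannot normalise")
    d = 1.0 / np.sqrt(deg)
    return a * d[:, None] * d[None, :]


def _anchor_mean(seq: PoseSequence, idx: list[int]) -> np.ndarray:
    """Per-frame mean position of anchor joints, NaN-aware. Shape (T, 3)."""
    import warnings as _warnings
    pos = seq.data[:, idx, :3].copy()
    pos[seq.missing_mask[:, idx]] = np.nan
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        return np.nanmean(pos, axis=1)


def center_and_scale(seq: PoseSequence, graph: SkeletonGraph) -> PoseSequence:
    """Translate each frame so mid-hip is the origin and scale globally so
    the median torso length (mid-hip to mid-shoulder) is 1.

    Removes camera placement and body size; confidences are untouched.  The
    result is idempotent and invariant to global translation and uniform
    scaling of the input.
    """
    try:
        hips = [graph.index("left_hip"), graph.index("right_hip")]
        shoulders = [graph.index("left_shoulder"), graph.index("right_shoulder")]
    except ValueError as e:
        raise UnnormalisableError("topology lacks hip/shoulder anchors") from e

    mid_hip = _anchor_mean(seq, hips)
    mid_sh = _anchor_mean(seq, shoulders)
    if np.all(np.isnan(mid_hip)) or np.all(np.isnan(mid_sh)):
        raise UnnormalisableError("anchor joints missing in every frame")

    torso = np.linalg.norm(mid_sh - mid_hip, axis=1)
    scale = np.nanmedian(torso)
    if not np.isfinite(scale) or scale <= 0:
        raise UnnormalisableError("degenerate torso length")

    # frames with missing hips: carry the nearest defined mid-hip
    t = np.arange(seq.T)
    for c in range(3):
        col = mid_hip[:, c]
        bad = np.isnan(col)
        if bad.any():
            col[bad] = np.interp(t[bad], t[~bad], col[~bad])
    out = seq.data.copy()
    out[:, :, :3] = (out[:, :, :3] - mid_hip[:, None, :]) / scale
    return PoseSequence(seq.view_id, seq.fps, out, seq.missing_mask.copy())


def center_static(seq: PoseSequence, graph: SkeletonGraph) -> PoseSequence:
    """Translate the whole sequence by the median mid-hip position.

    Unlike :func:`center_and_scale` this applies one constant offset and no
    rescaling: per-view camera placement is removed while metric units and
    whole-body motion (e.g. the compression bobbing common to all joints)
    are preserved — the checklist thresholds are absolute centimeters, so
    the model input keeps them."""
    try:
        hips = [graph.index("left_hip"), graph.index("right_hip")]
    except ValueError as e:
        raise UnnormalisableError("topology lacks hip anchors") from e
    mid_hip = _anchor_mean(seq, hips)
    if np.all(np.isnan(mid_hip)):
        raise UnnormalisableError("hip joints missing in every frame")
    offset = np.nanmedian(mid_hip, axis=0)
    out = seq.data.copy()
    out[:, :, :3] -= offset
    return PoseSequence(seq.view_id, seq.fps, out, seq.missing_mask.copy())


def resample_time(seq: PoseSequence, target_T: int) -> PoseSequence:
    """Linear-in-time resampling of a pose sequence to ``target_T`` frames.

    Endpoints are preserved.  A resampled frame is flagged missing for a
    joint if either of the source frames it interpolates between is missing.
    """
    if target_T < 2:
        raise ValueError("target_T must be >= 2")
    if seq.T == 1:
        raise ValueError("cannot interpolate a single-frame sequence")
    if target_T == seq.T:
        return seq.copy()
    src = np.arange(seq.T, dtype=float)
    pos = np.linspace(0.0, seq.T - 1.0, target_T)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, seq.T - 1)
    w = (pos - lo)[:, None, None]
    data = (1 - w) * seq.data[lo] + w * seq.data[hi]
    mask = seq.missing_mask[lo] | seq.missing_mask[hi]
    new_fps = seq.fps * (target_T - 1) / (seq.T - 1)
    return PoseSequence(seq.view_id, new_fps, data, mask)


def interpolate_missing(seq: PoseSequence) -> PoseSequence:
    """Fill missing coordinates by per-joint linear interpolation in time.

    Edge gaps are filled by holding the nearest observed frame.  The mask is
    cleared for joints with at least one observation; confidence values are
    kept as recorded.
    """
    data = seq.data.copy()
    mask = seq.missing_mask.copy()
    t = np.arange(seq.T, dtype=float)
    for j in range(seq.N):
        bad = mask[:, j]
        if not bad.any():
            continue
        good = ~bad
        if not good.any():
            continue  # nothing to anchor on; leave as is
        for c in range(3):
            data[bad, j, c] = np.interp(t[bad], t[good], data[good, j, c])
        mask[:, j] = False
    return PoseSequence(seq.view_id, seq.fps, data, mask)
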