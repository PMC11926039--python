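"""Rule-based kinematic scoring of CPR chest-compression quality.

Implements the six-dimension expert checklist algorithmically: compressions
are detected as prominent troughs of mean-wrist height, grouped into cycles
at rest pauses, and each cycle is awarded one point per dimension:

* hand  — wrist centre within one hand margin of the chest centre,
* arm   — straight arms: minimal elbow flex OR minimal elbow-angle
          variability,
* shoulder — shoulders over the patient: chest-to-mid-shoulder line within
          a tolerance of vertical,
* depth — mean compression depth 5-6 cm,
* rate  — 100-120 compressions per minute,
* release — complete recoil: hands return to within a tolerance of the
          neutral height between compressions.

Failure codes record *how* a dimension failed (e.g. ``too_shallow`` vs
``too_deep``).  All thresholds live in :class:`Thresholds` and are
expressed in the units experts use (centimeters, degrees, compressions per
minute); pose data is in meters.

Conventions: depth is judged as (neutral − trough) so incomplete recoil is
penalised once, under release, rather than leaking into depth; hand
placement distance is measured in the horizontal plane; the release
residual of the final compression of a cycle is excluded because the
return-to-rest confounds it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .skeleton import PoseSequence, SkeletonGraph, interpolate_missing

__all__ = [
    "DIMENSIONS", "OVERALL_CATEGORIES", "CompressionEvent", "CycleSegment",
    "Thresholds", "CycleScore", "ChecklistScore", "detect_compressions",
    "segment_cycles", "detect_sync_claps", "compute_sync_offsets",
    "score_cycle", "aggregate_items", "score_recording", "overall_rating",
]

DIMENSIONS = ("hand", "arm", "shoulder", "depth", "rate", "release")

# ordinal, worst to best
OVERALL_CATEGORIES = ("Unacceptable", "Poor", "Borderline", "Good", "Excellent")

_CM = 0.01  # meters per centimeter


class UnscorableError(ValueError):
    """Raised when a sequence cannot be scored at all."""


@dataclass(frozen=True)
class Thresholds:
    """Checklist pass criteria and detector settings.

    Depth and rate windows come from resuscitation guidance (5-6 cm,
    100-120/min).  The hand margin instantiates "one average hand margin"
    as an adult hand breadth; the elbow and shoulder tolerances quantify
    "straight arms" and "shoulders over the patient".
    """

    hand_margin_cm: float = 9.0
    elbow_min_angle_deg: float = 160.0
    elbow_var_max_deg: float = 5.0
    shoulder_max_lean_deg: float = 10.0
    depth_min_cm: float = 5.0
    depth_max_cm: float = 6.0
    rate_min_cpm: float = 100.0
    rate_max_cpm: float = 120.0
    recoil_max_residual_cm: float = 1.0
    min_peak_prominence_cm: float = 2.0
    min_peak_separation_s: float = 0.25
    pause_gap_s: float = 2.0
    min_compressions_per_cycle: int = 5

    def __post_init__(self):
        if not (self.depth_min_cm < self.depth_max_cm):
            raise ValueError("empty depth window")
        if not (self.rate_min_cpm < self.rate_max_cpm):
            raise ValueError("empty rate window")
        for f in ("hand_margin_cm", "elbow_min_angle_deg", "elbow_var_max_deg",
                  "shoulder_max_lean_deg", "recoil_max_residual_cm",
                  "min_peak_prominence_cm", "min_peak_separation_s", "pause_gap_s"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class CompressionEvent:
    """One detected compression: trough, flanking release maximum, and the
    derived depth/recoil measurements (cm)."""

    trough_time_s: float
    peak_time_s: float
    depth_cm: float          # neutral minus trough height
    excursion_cm: float      # release peak minus trough height
    recoil_residual_cm: float  # neutral minus release peak


@dataclass
class CycleSegment:
    start_frame: int
    end_frame: int
    compression_indices: list[int]

    @property
    def n_compressions(self) -> int:
        return len(self.compression_indices)


@dataclass
class CycleScore:
    points: dict[str, int]
    codes: dict[str, list[str]]
    measures: dict[str, float]
    scorable: bool = True


@dataclass
class ChecklistScore:
    cycles: list[CycleScore]
    item_totals: dict[str, int]
    overall_per_cycle: list[str]
    overall: str
    n_unscorable: int = 0


# ---------------------------------------------------------------------------
# signal helpers
# ---------------------------------------------------------------------------

def _mean_joint_track(seq: PoseSequence, graph: SkeletonGraph,
                      names: list[str]) -> np.ndarray:
    """(T, 3) mean position of the named joints with missing data filled."""
    idx = [graph.index(n) for n in names]
    if seq.missing_mask.any():
        if np.all(seq.missing_mask[:, idx]):
            raise UnscorableError(f"joints {names} missing in every frame")
        seq = interpolate_missing(seq)
    return seq.data[:, idx, :3].mean(axis=1)


def _refine_extremum(sig: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample quadratic refinement of an extremum at index ``i``.

    Returns (fractional index, refined value).  Falls back to the sample
    itself when the local curvature vanishes (flat signal).
    """
    if i <= 0 or i >= len(sig) - 1:
        return float(i), float(sig[i])
    a, b, c = sig[i - 1], sig[i], sig[i + 1]
    denom = a - 2 * b + c
    if abs(denom) < 1e-12:
        return float(i), float(b)
    d = 0.5 * (a - c) / denom
    d = float(np.clip(d, -0.6, 0.6))
    val = b - 0.25 * (a - c) * d
    return i + d, float(val)


def _estimate_neutral(height: np.ndarray, fps: float, first_trough: int,
                      period_s: float, release_heights: np.ndarray) -> float:
    """Neutral (rest) wrist height.

    Median over the still window just before the first compression (up to
    2 s, at least 1 s, whichever the recording offers and is actually
    still); falls back to the 95th percentile of release heights when no
    still window exists (task starts immediately).
    """
    end = int(round(first_trough - 0.6 * period_s * fps))
    for window_s in (2.0, 1.5, 1.0):
        start = end - int(round(window_s * fps))
        if start >= 0 and end - start >= 3:
            window = height[start:end]
            if np.std(window) < 0.5 * _CM:
                return float(np.median(window))
    if len(release_heights):
        return float(np.percentile(release_heights, 95))
    raise UnscorableError("cannot estimate neutral height")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _harmonic_fit(sig: np.ndarray, fr_a: float, fr_b: float) -> tuple[float, float] | None:
    """Least-squares ``c0 + c1 cos + c2 sin`` fit of one compression period
    of a signal between two (fractional-frame) trough times.

    Returns (level, amplitude); exact for a noise-free harmonic at any
    sampling phase and free of the bias that reading off extreme samples
    acquires under noise."""
    j = np.arange(max(int(np.ceil(fr_a)), 0),
                  min(int(np.floor(fr_b)), len(sig) - 1) + 1)
    if len(j) < 4 or fr_b - fr_a <= 1:
        return None
    w = 2 * np.pi / (fr_b - fr_a)
    phase = w * (j - fr_a)
    design = np.column_stack([np.ones_like(phase), np.cos(phase), np.sin(phase)])
    c, *_ = np.linalg.lstsq(design, sig[j], rcond=None)
    return float(c[0]), float(np.hypot(c[1], c[2]))


def detect_compressions(seq: PoseSequence, graph: SkeletonGraph,
                        thresholds: Thresholds = Thresholds()) -> list[CompressionEvent]:
    """Detect individual chest compressions from mean-wrist height.

    Troughs of the height signal with prominence of at least
    ``min_peak_prominence_cm`` and spacing ``min_peak_separation_s`` are
    compressions; each is paired with the release maximum that follows it.
    Returns an empty list when no compression is found.

    Depth and recoil come from per-segment harmonic least squares: between
    consecutive troughs the compression waveform is modelled as
    ``c0 + c1 cos(wt) + c2 sin(wt)`` with the segment's own frequency, so
    the trough depth is ``neutral - c0 + amp`` and the release residual
    ``neutral - c0 - amp`` with ``amp = hypot(c1, c2)``.  The fit is exact
    for noise-free harmonic motion at any sampling phase and, unlike
    reading off the extreme samples, carries no noise-selection bias.
    """
    height = _mean_joint_track(seq, graph, ["left_wrist", "right_wrist"])[:, 1]
    inverted = np.median(height) - height
    dist = max(int(round(thresholds.min_peak_separation_s * seq.fps)), 1)
    troughs, _ = find_peaks(inverted,
                            prominence=thresholds.min_peak_prominence_cm * _CM,
                            distance=dist)
    if len(troughs) == 0:
        return []

    gaps = np.diff(troughs)
    period = float(np.median(gaps)) / seq.fps if len(gaps) else 0.6

    t_idx = np.array([_refine_extremum(-height, i)[0] for i in troughs])

    # release maximum after each trough (timing only), capped at one period
    horizon = max(int(round(period * seq.fps)), 2)
    p_idx, internal = [], []
    for k, i in enumerate(troughs):
        j_end = troughs[k + 1] if k + 1 < len(troughs) else min(i + horizon, len(height) - 1)
        seg = height[i:j_end + 1]
        j = i + int(np.argmax(seg)) if len(seg) >= 2 else i
        p_idx.append(_refine_extremum(height, j)[0])
        # a release is 'internal' when the next trough follows within a cycle
        internal.append(k + 1 < len(troughs)
                        and gaps[k] <= thresholds.pause_gap_s * seq.fps)
    p_idx = np.array(p_idx)
    internal = np.array(internal, bool)

    fits = [_harmonic_fit(height, t_idx[k], t_idx[k + 1]) if internal[k] else None
            for k in range(len(troughs) - 1)] + [None]

    release_heights = np.array([f[0] + f[1] for f in fits if f is not None])
    neutral = _estimate_neutral(height, seq.fps, troughs[0], period,
                                release_heights if len(release_heights)
                                else height[troughs])

    events = []
    pf = period * seq.fps
    for k in range(len(troughs)):
        fit = fits[k] if fits[k] is not None else (fits[k - 1] if k > 0 else None)
        if fit is None:
            # lone compression: fit one period centred on the trough
            fit = _harmonic_fit(height, t_idx[k] - pf / 2, t_idx[k] + pf / 2)
        if fit is None:  # too short to fit: fall back to the raw extremes
            depth = (neutral - height[troughs[k]]) / _CM
            resid = 0.0
        else:
            c0, amp = fit
            depth = (neutral - c0 + amp) / _CM
            resid = (neutral - c0 - amp) / _CM
        events.append(CompressionEvent(
            trough_time_s=t_idx[k] / seq.fps,
            peak_time_s=p_idx[k] / seq.fps,
            depth_cm=float(depth),
            excursion_cm=float(max(depth - resid, 0.0)),
            recoil_residual_cm=float(resid),
        ))
    return events


def segment_cycles(events: list[CompressionEvent],
                   thresholds: Thresholds = Thresholds(),
                   fps: float = 30.0) -> list[CycleSegment]:
    """Group compressions into cycles wherever the inter-compression gap
    exceeds ``pause_gap_s`` (a rest pause)."""
    if not events:
        return []
    times = np.array([e.trough_time_s for e in events])
    gaps = np.diff(times)
    breaks = np.flatnonzero(gaps > thresholds.pause_gap_s)
    bounds = [0, *(breaks + 1), len(events)]
    half = float(np.median(gaps[gaps <= thresholds.pause_gap_s]) / 2) if np.any(
        gaps <= thresholds.pause_gap_s) else 0.3
    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        start = int(max(round((times[a] - half) * fps), 0))
        end = int(round((times[b - 1] + half) * fps))
        segs.append(CycleSegment(start, end, list(range(a, b))))
    return segs


def detect_sync_claps(seq: PoseSequence, graph: SkeletonGraph) -> list[float]:
    """Times (s) of synchronisation claps: inter-wrist distance below 3 cm
    while the wrists are above shoulder height."""
    li, ri = graph.index("left_wrist"), graph.index("right_wrist")
    s = interpolate_missing(seq) if seq.missing_mask.any() else seq
    wl, wr = s.data[:, li, :3], s.data[:, ri, :3]
    dist = np.linalg.norm(wl - wr, axis=1)
    wrist_y = 0.5 * (wl[:, 1] + wr[:, 1])
    sh = _mean_joint_track(s, graph, ["left_shoulder", "right_shoulder"])[:, 1]
    cond = (dist < 3 * _CM) & (wrist_y > sh)
    if not cond.any():
        warnings.warn("no synchronisation clap found", stacklevel=2)
        return []
    edges = np.flatnonzero(np.diff(cond.astype(int)))
    starts = [0] if cond[0] else []
    starts += list(edges[~cond[edges]] + 1)
    ends = list(edges[cond[edges]] + 1)
    if cond[-1]:
        ends.append(len(cond))
    return [0.5 * (a + b - 1) / seq.fps for a, b in zip(starts, ends)]


def compute_sync_offsets(views: dict[str, PoseSequence], graph: SkeletonGraph,
                         reference: str | None = None) -> dict[str, int]:
    """Per-view frame offsets from the first detected clap, relative to the
    reference view (default: lexicographically first)."""
    claps = {k: detect_sync_claps(v, graph) for k, v in views.items()}
    if reference is None:
        reference = sorted(views)[0]
    if not claps[reference]:
        raise UnscorableError(f"no clap in reference view {reference}")
    ref = claps[reference][0]
    out = {}
    for k, v in views.items():
        if not claps[k]:
            raise UnscorableError(f"no clap in view {k}")
        out[k] = int(round((claps[k][0] - ref) * v.fps))
    return out


def _elbow_angles(seq: PoseSequence, graph: SkeletonGraph) -> np.ndarray:
    """(T,) mean over sides of the elbow joint angle in degrees."""
    if seq.missing_mask.any():
        seq = interpolate_missing(seq)
    angles = []
    for side in ("left", "right"):
        s = seq.data[:, graph.index(f"{side}_shoulder"), :3]
        e = seq.data[:, graph.index(f"{side}_elbow"), :3]
        w = seq.data[:, graph.index(f"{side}_wrist"), :3]
        u, v = s - e, w - e
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos = (u * v).sum(axis=1) / np.maximum(nu * nv, 1e-9)
        angles.append(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
    return np.mean(angles, axis=0)


def score_cycle(seq: PoseSequence, events: list[CompressionEvent],
                segment: CycleSegment, graph: SkeletonGraph,
                thresholds: Thresholds, chest_center: np.ndarray) -> CycleScore:
    """Award the six checklist points for one compression cycle.

    ``chest_center`` is the neutral chest point in the sequence's world
    frame (known in simulation; estimate it otherwise, e.g. via
    :func:`estimate_chest_center`).
    """
    th = thresholds
    if segment.n_compressions < th.min_compressions_per_cycle:
        return CycleScore({}, {}, {}, scorable=False)
    chest = np.asarray(chest_center, dtype=float)
    ev = [events[i] for i in segment.compression_indices]
    sl = slice(segment.start_frame, min(segment.end_frame + 1, seq.T))

    points: dict[str, int] = {}
    codes: dict[str, list[str]] = {d: [] for d in DIMENSIONS}
    meas: dict[str, float] = {}

    # hand: horizontal wrist-centre offset from the chest centre
    wc = _mean_joint_track(seq, graph, ["left_wrist", "right_wrist"])[sl]
    d_head = float(np.median(wc[:, 0] - chest[0]))   # +x toward the head
    d_left = float(np.median(wc[:, 2] - chest[2]))   # +z toward patient left
    hand_dist = float(np.hypot(d_head, d_left)) / _CM
    meas["hand_dist_cm"] = hand_dist
    points["hand"] = int(hand_dist <= th.hand_margin_cm)
    if not points["hand"]:
        codes["hand"].append("toward_head" if abs(d_head) >= abs(d_left) and d_head > 0
                             else "toward_feet" if abs(d_head) >= abs(d_left)
                             else "toward_left" if d_left > 0 else "toward_right")

    # arm: straight (minimal flex) OR locked (minimal variability).  The
    # elbow angle is cycle-locked, so fit one harmonic per compression
    # period (between trough times): min = level - amplitude and the
    # sinusoid's standard deviation is amplitude / sqrt(2).
    ang = _elbow_angles(seq, graph)
    fr = [e.trough_time_s * seq.fps for e in ev]
    fits = [f for f in (_harmonic_fit(ang, a, b) for a, b in zip(fr, fr[1:]))
            if f is not None]
    if fits:
        min_angle = float(np.mean([c0 - amp for c0, amp in fits]))
        ang_std = float(np.mean([amp for _, amp in fits]) / np.sqrt(2.0))
    else:
        seg_ang = ang[sl]
        min_angle = float(np.min(seg_ang))
        ang_std = float(np.std(seg_ang))
    meas["elbow_min_deg"] = float(min_angle)
    meas["elbow_std_deg"] = ang_std
    points["arm"] = int(min_angle >= th.elbow_min_angle_deg
                        or ang_std <= th.elbow_var_max_deg)
    if not points["arm"]:
        codes["arm"].append("bent_elbows")

    # shoulder: chest-to-mid-shoulder line vs vertical
    ms = _mean_joint_track(seq, graph, ["left_shoulder", "right_shoulder"])[sl]
    vec = ms - chest
    horiz = np.hypot(vec[:, 0], vec[:, 2])
    lean = float(np.median(np.degrees(np.arctan2(horiz, vec[:, 1]))))
    meas["shoulder_lean_deg"] = lean
    points["shoulder"] = int(lean <= th.shoulder_max_lean_deg)
    if not points["shoulder"]:
        codes["shoulder"].append("not_over_patient")

    # depth: neutral-to-trough depression
    depth = float(np.mean([e.depth_cm for e in ev]))
    meas["depth_cm"] = depth
    points["depth"] = int(th.depth_min_cm <= depth <= th.depth_max_cm)
    if not points["depth"]:
        codes["depth"].append("too_shallow" if depth < th.depth_min_cm else "too_deep")

    # rate: 60 / median inter-trough interval
    times = np.array([e.trough_time_s for e in ev])
    rate = 60.0 / float(np.median(np.diff(times)))
    meas["rate_cpm"] = rate
    points["rate"] = int(th.rate_min_cpm <= rate <= th.rate_max_cpm)
    if not points["rate"]:
        codes["rate"].append("too_slow" if rate < th.rate_min_cpm else "too_fast")

    # release: mean recoil residual, final compression excluded (its release
    # runs into the rest pause)
    resid = float(np.mean([e.recoil_residual_cm for e in ev[:-1]])) if len(ev) > 1 else 0.0
    meas["recoil_residual_cm"] = resid
    points["release"] = int(resid <= th.recoil_max_residual_cm)
    if not points["release"]:
        codes["release"].append("incomplete_recoil")

    return CycleScore(points, {d: codes[d] for d in DIMENSIONS}, meas)


def overall_rating(points_sum: int) -> str:
    """Synthetic-label convention mapping a cycle's six points to the
    ordinal overall categories (not the experts' holistic mapping)."""
    if points_sum >= 6:
        return "Excellent"
    if points_sum == 5:
        return "Good"
    if points_sum == 4:
        return "Borderline"
    if points_sum >= 2:
        return "Poor"
    return "Unacceptable"


def aggregate_items(cycle_scores: list[CycleScore]) -> ChecklistScore:
    """Sum per-cycle points into 0-4 item totals and attach overall ratings."""
    scorable = [c for c in cycle_scores if c.scorable]
    if not scorable:
        raise UnscorableError("no scorable cycles")
    totals = {d: sum(c.points[d] for c in scorable) for d in DIMENSIONS}
    overall_pc = [overall_rating(sum(c.points.values())) for c in scorable]
    med = int(round(float(np.median([sum(c.points.values()) for c in scorable]))))
    return ChecklistScore(
        cycles=cycle_scores,
        item_totals=totals,
        overall_per_cycle=overall_pc,
        overall=overall_rating(med),
        n_unscorable=len(cycle_scores) - len(scorable),
    )


def estimate_chest_center(seq: PoseSequence, graph: SkeletonGraph,
                          events: list[CompressionEvent]) -> np.ndarray:
    """Fallback chest centre: median horizontal wrist position at troughs,
    at the neutral release height."""
    wc = _mean_joint_track(seq, graph, ["left_wrist", "right_wrist"])
    idx = np.clip(np.round([e.trough_time_s * seq.fps for e in events]).astype(int),
                  0, seq.T - 1)
    x = float(np.median(wc[idx, 0]))
    z = float(np.median(wc[idx, 2]))
    y = float(np.median([e.depth_cm * _CM + wc[i, 1] for e, i in zip(events, idx)]))
    return np.array([x, y, z])


def score_recording(seq: PoseSequence, graph: SkeletonGraph,
                    thresholds: Thresholds = Thresholds(),
                    chest_center: np.ndarray | None = None) -> ChecklistScore:
    """Full pipeline on one view: detect, segment, score, aggregate."""
    events = detect_compressions(seq, graph, thresholds)
    if not events:
        raise UnscorableError("no compressions detected")
    segs = segment_cycles(events, thresholds, seq.fps)
    if chest_center is None:
        chest_center = estimate_chest_center(seq, graph, events)
    cycles = [score_cycle(seq, events, s, graph, thresholds, chest_center)
              for s in segs]
    return aggregate_items(cycles)
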