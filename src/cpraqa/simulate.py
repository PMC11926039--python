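"""Parametric generator of multiview CPR skeleton recordings.

Emulates the study protocol — a rescuer kneeling beside a manikin performs
four sets of thirty chest compressions with rest pauses, bracketed by
synchronisation claps, filmed by six cameras — as 3D joint trajectories
with known, controllable quality defects:

* ``rate_cpm`` / ``depth_cm`` / ``recoil_deficit_cm`` drive the wrist-height
  waveform (oscillating between neutral − recoil and neutral − depth),
* ``hand_offset_cm`` displaces the hands on the chest plane,
* ``elbow_flex_deg`` / ``elbow_var_deg`` set the elbow angle
  180° − flex + var·sin(phase),
* ``shoulder_lean_deg`` tilts the chest-to-shoulder line off vertical.

Because every defect maps one-to-one onto a checklist dimension, the
ground-truth labels follow analytically from the parameters
(:func:`derive_ground_truth`), giving an exact oracle for the kinematic
scorer and a labelled corpus for the assessment network.  Per camera view
the generator adds Gaussian position noise, drops joints with a
view-dependent occlusion probability (rear cameras lose wrists more often),
and draws detection confidences from Beta distributions (visible ~ B(8,2),
occluded ~ B(2,8)).

World frame: meters, vertical +Y, manikin head toward +X, rescuer kneeling
on the manikin's left (+Z).  Arm segment lengths flex by a few percent so
that prescribed elbow angles are met exactly; real arms are rigid, which is
one of the documented gaps between simulation and reality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scoring import DIMENSIONS, Thresholds, overall_rating
from .skeleton import (MultiviewRecording, PoseSequence, SkeletonGraph,
                       get_topology)

__all__ = [
    "QualityParams", "ViewConfig", "SimulationConfig", "GroundTruth",
    "ParamSampler", "simulate_recording", "derive_ground_truth",
    "generate_dataset", "NOMINAL_PARAMS",
]


@dataclass(frozen=True)
class QualityParams:
    """Generative CPR quality parameters (one recording, constant defects)."""

    rate_cpm: float = 110.0
    depth_cm: float = 5.5
    recoil_deficit_cm: float = 0.0
    hand_offset_cm: tuple[float, float] = (0.0, 0.0)  # (toward head, toward patient-left)
    elbow_flex_deg: float = 0.0
    elbow_var_deg: float = 0.0
    shoulder_lean_deg: float = 0.0
    n_cycles: int = 4
    compressions_per_cycle: int = 30
    pause_s: float = 5.0

    def __post_init__(self):
        if self.rate_cpm <= 0 or self.rate_cpm > 250:
            raise ValueError("rate_cpm must be in (0, 250]")
        if self.depth_cm <= 0:
            raise ValueError("depth_cm must be positive")
        if self.depth_cm > 15:
            raise ValueError("depth_cm exceeds plausible arm travel")
        if self.recoil_deficit_cm < 0 or self.recoil_deficit_cm >= self.depth_cm:
            raise ValueError("need 0 <= recoil_deficit_cm < depth_cm")
        if self.elbow_flex_deg < 0 or self.elbow_var_deg < 0:
            raise ValueError("elbow parameters must be nonnegative")
        if self.elbow_var_deg > self.elbow_flex_deg:
            raise ValueError("elbow_var_deg > elbow_flex_deg would hyperextend the elbow")
        if self.shoulder_lean_deg < 0 or self.shoulder_lean_deg >= 90:
            raise ValueError("shoulder_lean_deg must be in [0, 90)")
        if self.n_cycles < 1 or self.compressions_per_cycle < 1 or self.pause_s < 0:
            raise ValueError("invalid protocol structure")


NOMINAL_PARAMS = QualityParams()


@dataclass(frozen=True)
class ViewConfig:
    view_id: str
    noise_cm: float = 0.5
    occlusion_prob: float = 0.02

    def __post_init__(self):
        if self.noise_cm < 0 or not (0 <= self.occlusion_prob <= 1):
            raise ValueError("invalid view noise/occlusion settings")


def _default_views() -> tuple[ViewConfig, ...]:
    # six-camera rig: 1 wide front, 2/3 rear left/right, 4 low front,
    # 5/6 side; rear views occlude the arms more often
    occ = {"1": 0.01, "2": 0.04, "3": 0.04, "4": 0.01, "5": 0.02, "6": 0.02}
    return tuple(ViewConfig(k, 0.5, occ[k]) for k in "123456")


# joints the rear cameras struggle with
_ARM_JOINTS = {"left_wrist", "right_wrist", "left_elbow", "right_elbow",
               "left_index", "right_index", "left_pinky", "right_pinky",
               "left_thumb", "right_thumb"}
_REAR_VIEWS = {"2", "3"}


@dataclass(frozen=True)
class SimulationConfig:
    fps: float = 30.0
    views: tuple[ViewConfig, ...] = field(default_factory=_default_views)
    include_claps: bool = True
    topology: str = "mediapipe-33"
    anthropometry_jitter: float = 0.1
    max_sync_offset_frames: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not self.views:
            raise ValueError("need at least one view")


@dataclass
class GroundTruth:
    """Checklist labels implied analytically by the quality parameters."""

    per_cycle_points: list[dict[str, int]]
    codes: dict[str, list[str]]
    item_totals: dict[str, int]
    overall_per_cycle: list[str]

    def __post_init__(self):
        for d in DIMENSIONS:
            assert self.item_totals[d] == sum(c[d] for c in self.per_cycle_points)


def derive_ground_truth(params: QualityParams,
                        thresholds: Thresholds = Thresholds()) -> GroundTruth:
    """Apply the checklist criteria directly to the generative parameters.

    The defects are constant within a recording, so every cycle carries the
    same points.  The arm criterion mirrors the scorer's disjunction: the
    minimum elbow angle is 180 − flex − var and the angle variability of a
    sinusoid is var/sqrt(2).
    """
    th = thresholds
    points: dict[str, int] = {}
    codes: dict[str, list[str]] = {d: [] for d in DIMENSIONS}

    off_h, off_l = params.hand_offset_cm
    dist = float(np.hypot(off_h, off_l))
    points["hand"] = int(dist <= th.hand_margin_cm)
    if not points["hand"]:
        codes["hand"].append("toward_head" if abs(off_h) >= abs(off_l) and off_h > 0
                             else "toward_feet" if abs(off_h) >= abs(off_l)
                             else "toward_left" if off_l > 0 else "toward_right")

    min_angle = 180.0 - params.elbow_flex_deg - params.elbow_var_deg
    var_std = params.elbow_var_deg / np.sqrt(2.0)
    points["arm"] = int(min_angle >= th.elbow_min_angle_deg
                        or var_std <= th.elbow_var_max_deg)
    if not points["arm"]:
        codes["arm"].append("bent_elbows")

    points["shoulder"] = int(params.shoulder_lean_deg <= th.shoulder_max_lean_deg)
    if not points["shoulder"]:
        codes["shoulder"].append("not_over_patient")

    points["depth"] = int(th.depth_min_cm <= params.depth_cm <= th.depth_max_cm)
    if not points["depth"]:
        codes["depth"].append("too_shallow" if params.depth_cm < th.depth_min_cm
                              else "too_deep")

    points["rate"] = int(th.rate_min_cpm <= params.rate_cpm <= th.rate_max_cpm)
    if not points["rate"]:
        codes["rate"].append("too_slow" if params.rate_cpm < th.rate_min_cpm
                             else "too_fast")

    points["release"] = int(params.recoil_deficit_cm <= th.recoil_max_residual_cm)
    if not points["release"]:
        codes["release"].append("incomplete_recoil")

    per_cycle = [dict(points) for _ in range(params.n_cycles)]
    totals = {d: params.n_cycles * points[d] for d in DIMENSIONS}
    overall = [overall_rating(sum(points.values()))] * params.n_cycles
    return GroundTruth(per_cycle, codes, totals, overall)


# ---------------------------------------------------------------------------
# kinematic template
# ---------------------------------------------------------------------------

@dataclass
class _Body:
    """Anthropometry of the kneeling-rescuer template (meters)."""

    arm_seg: float = 0.27       # upper arm = forearm nominal length
    shoulder_w: float = 0.36
    hip_w: float = 0.30
    torso: float = 0.45
    trunk_pitch_deg: float = 35.0  # hip-to-shoulder line vs vertical
    chest_h: float = 0.22          # manikin chest height above floor

    def jittered(self, rng: np.random.Generator, amount: float) -> "_Body":
        j = lambda v: v * (1.0 + rng.uniform(-amount, amount))
        return _Body(j(self.arm_seg), j(self.shoulder_w), j(self.hip_w),
                     j(self.torso), self.trunk_pitch_deg, self.chest_h)


def _timeline(params: QualityParams, cfg: SimulationConfig):
    """Canonical schedule: still / clap / still / cycles+pauses / still / clap."""
    p = 60.0 / params.rate_cpm
    cyc = params.compressions_per_cycle * p
    pre_still, clap_w, setup_still, post_still, tail_still = 0.4, 0.6, 2.0, 1.0, 0.4
    t = 0.0
    clap_windows = []
    if cfg.include_claps:
        t += pre_still
        clap_windows.append((t, t + clap_w))
        t += clap_w
    t += setup_still
    cycle_starts = []
    for c in range(params.n_cycles):
        cycle_starts.append(t)
        t += cyc
        if c < params.n_cycles - 1:
            t += params.pause_s
    t += post_still
    if cfg.include_claps:
        clap_windows.append((t, t + clap_w))
        t += clap_w
        t += tail_still
    return t, cycle_starts, clap_windows, p


def _waveforms(times: np.ndarray, params: QualityParams, cycle_starts, period):
    """Wrist-height offset h(t) (<=0, meters) and elbow angle phi(t) (deg)."""
    h = np.zeros_like(times)
    phi = np.full_like(times, 180.0 - params.elbow_flex_deg)
    depth = params.depth_cm / 100.0
    rec = params.recoil_deficit_cm / 100.0
    f = params.rate_cpm / 60.0
    dur = params.compressions_per_cycle * period
    for s in cycle_starts:
        tp = times - s
        m = (tp >= 0) & (tp <= dur)
        tpm = tp[m]
        wave = rec + (depth - rec) * 0.5 * (1 - np.cos(2 * np.pi * f * tpm))
        blend = np.clip(tpm / (0.25 * period), 0, 1) * \
            np.clip((dur - tpm) / (0.25 * period), 0, 1)
        h[m] = -wave * blend
        phi[m] = 180.0 - params.elbow_flex_deg + \
            params.elbow_var_deg * np.sin(2 * np.pi * f * tpm)
    return h, phi


def _solve_elbow(sh: np.ndarray, wr: np.ndarray, phi_deg: np.ndarray) -> np.ndarray:
    """Elbow position meeting the prescribed joint angle exactly.

    Isoceles two-segment chain: both segments get length
    |shoulder-wrist| / (2 sin(phi/2)); the elbow sits off the midpoint in the
    parasagittal plane, bowing toward the rescuer's body (+Z)."""
    a = wr - sh
    L = np.linalg.norm(a, axis=1, keepdims=True)
    half = np.radians(phi_deg)[:, None] / 2.0
    sin_h = np.maximum(np.sin(half), 1e-6)
    u = L / (2.0 * sin_h)
    off = u * np.cos(half)
    mid = 0.5 * (sh + wr)
    xhat = np.array([1.0, 0.0, 0.0])
    p = np.cross(a, xhat)
    norm = np.linalg.norm(p, axis=1, keepdims=True)
    p = p / np.maximum(norm, 1e-9)
    flip = np.where(np.abs(p[:, 2]) > 1e-6, np.sign(p[:, 2]), np.sign(p[:, 1] + 1e-12))
    p = p * flip[:, None]
    return mid + p * off


def _clap_override(times, windows, mid_sh, body):
    """Wrist trajectories during clap windows: hands raised above the
    shoulders and brought within 2 cm."""
    wl = np.full((len(times), 3), np.nan)
    wr = np.full((len(times), 3), np.nan)
    centers = []
    for (a, b) in windows:
        m = (times >= a) & (times < b)
        tau = (times[m] - a) / (b - a)
        tri = np.clip(1.0 - 2.0 * np.abs(tau - 0.5), 0, 1)
        sep = 0.35 - (0.35 - 0.02) * np.minimum(tri / 0.85, 1.0)
        cc = mid_sh[m] + np.array([0.0, 0.25, -0.05])
        wl[m] = cc + np.stack([-sep / 2, np.zeros_like(sep), np.zeros_like(sep)], axis=1)
        wr[m] = cc + np.stack([sep / 2, np.zeros_like(sep), np.zeros_like(sep)], axis=1)
        centers.append(0.5 * (a + b))
    return wl, wr, centers


def _canonical_motion(params: QualityParams, cfg: SimulationConfig,
                      graph: SkeletonGraph, body: _Body):
    """Noise-free joint trajectories on the canonical clock.

    Returns (T, N, 3) positions plus metadata (chest centre, clap times)."""
    total, cycle_starts, clap_windows, period = _timeline(params, cfg)
    T = int(round(total * cfg.fps))
    times = np.arange(T) / cfg.fps
    h, phi = _waveforms(times, params, cycle_starts, period)

    chest = np.array([0.0, body.chest_h, 0.0])
    off = np.array([params.hand_offset_cm[0], 0.0, params.hand_offset_cm[1]]) / 100.0
    theta = np.radians(params.shoulder_lean_deg)
    lean_dir = np.array([0.0, np.cos(theta), np.sin(theta)])

    wc = chest + off + np.outer(h, [0.0, 1.0, 0.0])
    d_arm = 2.0 * body.arm_seg * np.sin(np.radians(phi) / 2.0)
    mid_sh = chest + np.outer(h + d_arm, lean_dir)

    delta = np.array([0.012, 0.01, 0.0])
    wrist_l, wrist_r = wc + delta, wc - delta

    if clap_windows:
        cl, cr, clap_times = _clap_override(times, clap_windows, mid_sh, body)
        use = ~np.isnan(cl[:, 0])
        wrist_l[use], wrist_r[use] = cl[use], cr[use]
    else:
        clap_times = []

    xhat = np.array([1.0, 0.0, 0.0])
    sh_l = mid_sh - 0.5 * body.shoulder_w * xhat
    sh_r = mid_sh + 0.5 * body.shoulder_w * xhat
    phi_eff = phi.copy()
    if clap_windows:
        phi_eff[use] = 120.0  # bent arms while clapping
    elb_l = _solve_elbow(sh_l, wrist_l, phi_eff)
    elb_r = _solve_elbow(sh_r, wrist_r, phi_eff)

    beta = np.radians(body.trunk_pitch_deg)
    mid_hip = mid_sh + body.torso * np.array([0.0, -np.cos(beta), np.sin(beta)])
    hip_l = mid_hip - 0.5 * body.hip_w * xhat
    hip_r = mid_hip + 0.5 * body.hip_w * xhat
    nose = mid_sh + np.array([0.0, 0.17, -0.08])

    def leg(hip):
        knee = np.stack([hip[:, 0], np.full(T, 0.06), hip[:, 2] + 0.10], axis=1)
        ankle = knee + np.array([0.0, 0.02, 0.40])
        heel = ankle + np.array([0.0, -0.04, 0.04])
        foot = ankle + np.array([0.0, -0.04, 0.12])
        return knee, ankle, heel, foot

    knee_l, ankle_l, heel_l, foot_l = leg(hip_l)
    knee_r, ankle_r, heel_r, foot_r = leg(hip_r)

    pos = {
        "nose": nose,
        "left_shoulder": sh_l, "right_shoulder": sh_r,
        "left_elbow": elb_l, "right_elbow": elb_r,
        "left_wrist": wrist_l, "right_wrist": wrist_r,
        "left_index": wrist_l + np.array([0.01, -0.02, -0.09]),
        "right_index": wrist_r + np.array([-0.01, -0.02, -0.09]),
        "left_pinky": wrist_l + np.array([-0.015, -0.02, -0.08]),
        "right_pinky": wrist_r + np.array([0.015, -0.02, -0.08]),
        "left_thumb": wrist_l + np.array([0.03, -0.01, -0.04]),
        "right_thumb": wrist_r + np.array([-0.03, -0.01, -0.04]),
        "left_hip": hip_l, "right_hip": hip_r,
        "left_knee": knee_l, "right_knee": knee_r,
        "left_ankle": ankle_l, "right_ankle": ankle_r,
        "left_heel": heel_l, "right_heel": heel_r,
        "left_foot_index": foot_l, "right_foot_index": foot_r,
        "left_eye_inner": nose + np.array([-0.015, 0.03, 0.0]),
        "left_eye": nose + np.array([-0.025, 0.03, 0.0]),
        "left_eye_outer": nose + np.array([-0.035, 0.03, 0.0]),
        "right_eye_inner": nose + np.array([0.015, 0.03, 0.0]),
        "right_eye": nose + np.array([0.025, 0.03, 0.0]),
        "right_eye_outer": nose + np.array([0.035, 0.03, 0.0]),
        "left_ear": nose + np.array([-0.07, 0.02, 0.02]),
        "right_ear": nose + np.array([0.07, 0.02, 0.02]),
        "mouth_left": nose + np.array([-0.015, -0.01, 0.0]),
        "mouth_right": nose + np.array([0.015, -0.01, 0.0]),
    }
    data = np.stack([pos[name] for name in graph.joint_names], axis=1)
    meta = {
        "chest_center": chest.tolist(),
        "clap_times_s": list(clap_times),
        "cycle_starts_s": list(cycle_starts),
        "neutral_height_m": float(chest[1]),
        "period_s": period,
    }
    return data, meta


def simulate_recording(params: QualityParams,
                       config: SimulationConfig = SimulationConfig(),
                       thresholds: Thresholds = Thresholds(),
                       recording_id: str = "sim",
                       ) -> tuple[MultiviewRecording, GroundTruth]:
    """Generate one multiview recording and its analytic ground truth.

    Deterministic given ``config.seed``.  Each view is the canonical motion
    shifted by a small random sync offset, with Gaussian noise, occlusions
    and Beta-distributed confidences applied independently per view.
    """
    rng = np.random.default_rng(config.seed)
    graph = get_topology(config.topology)
    body = _Body().jittered(rng, config.anthropometry_jitter)
    if params.depth_cm / 100.0 > min(0.5 * body.chest_h, 0.4 * 2 * body.arm_seg):
        raise ValueError("compression depth exceeds plausible chest travel / arm reach")
    canon, meta = _canonical_motion(params, config, graph, body)
    T, N, _ = canon.shape

    views: dict[str, PoseSequence] = {}
    offsets: dict[str, int] = {}
    arm_idx = np.array([i for i, n in enumerate(graph.joint_names) if n in _ARM_JOINTS])
    for i, vc in enumerate(config.views):
        o = 0 if i == 0 else int(rng.integers(0, config.max_sync_offset_frames + 1))
        offsets[vc.view_id] = o
        src = np.clip(np.arange(T) - o, 0, T - 1)
        data = np.empty((T, N, 4))
        data[:, :, :3] = canon[src]
        if vc.noise_cm > 0:
            data[:, :, :3] += rng.normal(0.0, vc.noise_cm / 100.0, size=(T, N, 3))
        p = np.full(N, vc.occlusion_prob)
        if vc.view_id in _REAR_VIEWS and len(arm_idx):
            p[arm_idx] = np.minimum(2 * p[arm_idx], 1.0)
        mask = rng.random((T, N)) < p
        conf = rng.beta(8.0, 2.0, size=(T, N))
        conf[mask] = rng.beta(2.0, 8.0, size=int(mask.sum()))
        data[:, :, 3] = conf
        data[:, :, :3][mask] = np.nan
        views[vc.view_id] = PoseSequence(vc.view_id, config.fps, data, mask)

    rec = MultiviewRecording(
        recording_id=recording_id, views=views, sync_offsets=offsets,
        metadata={**meta, "params": params.__dict__ | {
            "hand_offset_cm": list(params.hand_offset_cm)},
            "topology": config.topology, "seed": config.seed},
    )
    return rec, derive_ground_truth(params, thresholds)


# ---------------------------------------------------------------------------
# dataset sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSampler:
    """Uniform sampler over quality parameters, straddling every pass/fail
    boundary so each checklist dimension occurs in both states.

    The recoil range is additionally capped at depth − 3 cm so every
    compression keeps at least 3 cm of visible excursion, and elbow
    variability is capped at the flex (no hyperextension)."""

    depth_range: tuple[float, float] = (3.0, 8.0)
    rate_range: tuple[float, float] = (70.0, 150.0)
    recoil_range: tuple[float, float] = (0.0, 2.5)
    hand_offset_range: tuple[float, float] = (-12.0, 12.0)
    flex_range: tuple[float, float] = (0.0, 35.0)
    var_range: tuple[float, float] = (0.0, 12.0)
    lean_range: tuple[float, float] = (0.0, 25.0)
    n_cycles: int = 4
    compressions_per_cycle: int = 30
    pause_s: float = 5.0

    def __post_init__(self):
        for f in ("depth_range", "rate_range", "recoil_range",
                  "hand_offset_range", "flex_range", "var_range", "lean_range"):
            lo, hi = getattr(self, f)
            if lo > hi:
                raise ValueError(f"empty sampler range {f}")

    def sample(self, rng: np.random.Generator) -> QualityParams:
        u = rng.uniform
        depth = u(*self.depth_range)
        rec_hi = min(self.recoil_range[1], depth - 3.0)
        rec = u(self.recoil_range[0], max(rec_hi, self.recoil_range[0]))
        flex = u(*self.flex_range)
        var = u(self.var_range[0], min(self.var_range[1], max(flex, self.var_range[0])))
        return QualityParams(
            rate_cpm=u(*self.rate_range),
            depth_cm=depth,
            recoil_deficit_cm=rec,
            hand_offset_cm=(u(*self.hand_offset_range), u(*self.hand_offset_range)),
            elbow_flex_deg=flex,
            elbow_var_deg=var,
            shoulder_lean_deg=u(*self.lean_range),
            n_cycles=self.n_cycles,
            compressions_per_cycle=self.compressions_per_cycle,
            pause_s=self.pause_s,
        )


def generate_dataset(n: int,
                     sampler: ParamSampler = ParamSampler(),
                     config: SimulationConfig = SimulationConfig(),
                     seed: int = 0,
                     thresholds: Thresholds = Thresholds(),
                     ) -> tuple[list[tuple[MultiviewRecording, GroundTruth]], pd.DataFrame]:
    """Sample ``n`` labelled recordings; reproducible from ``seed``.

    Returns the recordings with their ground truth plus a manifest table
    recording every parameter draw and the implied labels."""
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(seed)
    sampler_rng = np.random.default_rng(root.spawn(1)[0])
    sim_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(n + 1)[1:]]

    out = []
    rows = []
    for i in range(n):
        params = sampler.sample(sampler_rng)
        rid = f"sim{i:04d}"
        cfg = replace(config, seed=sim_seeds[i])
        rec, gt = simulate_recording(params, cfg, thresholds, recording_id=rid)
        out.append((rec, gt))
        row = {
            "recording_id": rid, "seed": sim_seeds[i],
            "rate_cpm": params.rate_cpm, "depth_cm": params.depth_cm,
            "recoil_deficit_cm": params.recoil_deficit_cm,
            "hand_offset_head_cm": params.hand_offset_cm[0],
            "hand_offset_left_cm": params.hand_offset_cm[1],
            "elbow_flex_deg": params.elbow_flex_deg,
            "elbow_var_deg": params.elbow_var_deg,
            "shoulder_lean_deg": params.shoulder_lean_deg,
        }
        for d in DIMENSIONS:
            row[f"{d}_total"] = gt.item_totals[d]
        row["overall"] = gt.overall_per_cycle[0]
        rows.append(row)
    return out, pd.DataFrame(rows)
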