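"""Reproducible synthetic-data experiments.

Bundles the standard study-scale runs used to validate the package: the
scorer-versus-generator agreement sweep, estimator accuracy checks, and the
cross-validated comparison of the multiview network against a constant
baseline, including the one-corrupted-view robustness contrast.  The same
functions back the test suite and the acceptance script so both report the
same quantities.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .model import ModelConfig, small_model_config
from .scoring import DIMENSIONS, score_recording
from .simulate import (ParamSampler, SimulationConfig, ViewConfig,
                       generate_dataset, simulate_recording)
from .skeleton import PoseSequence, get_topology
from .train import (TrainConfig, checklist_agreement, cross_validate,
                    labels_vector, predict_dataset, prepare_features)

__all__ = [
    "agreement_sweep", "estimator_accuracy", "build_samples",
    "cv_against_baseline", "corrupted_view_contrast",
]

_FAST_VIEWS = (ViewConfig("1", 0.5, 0.01), ViewConfig("4", 0.5, 0.01),
               ViewConfig("5", 0.5, 0.02))


def default_experiment_config(seed: int = 0, **overrides) -> TrainConfig:
    """CPU-scale training recipe for the standard synthetic benchmark:
    30 epochs with 1/(1+t/300) learning-rate decay on top of the reference
    optimiser settings (Adam, lr 0.01, weight decay 0.1)."""
    kw = dict(epochs=30, lr_decay_tau=300.0, seed=seed)
    kw.update(overrides)
    return TrainConfig(**kw)


def _sim_config(noise_cm: float, occlusion: float, seed: int,
                views=("1",), topology="reduced-17") -> SimulationConfig:
    return SimulationConfig(
        views=tuple(ViewConfig(v, noise_cm, occlusion) for v in views),
        topology=topology, seed=seed)


def agreement_sweep(n: int = 100, noise_cm: float = 0.0, occlusion: float = 0.0,
                    seed: int = 0, sampler: ParamSampler = ParamSampler(),
                    ) -> dict[str, float]:
    """Per-dimension per-cycle agreement (%) between the kinematic scorer
    and the analytic ground truth over ``n`` random recordings."""
    graph = get_topology("reduced-17")
    rng = np.random.default_rng(seed)
    agree = {d: 0 for d in DIMENSIONS}
    total = {d: 0 for d in DIMENSIONS}
    for i in range(n):
        params = sampler.sample(rng)
        cfg = _sim_config(noise_cm, occlusion, seed=seed * 1_000_003 + i)
        rec, gt = simulate_recording(params, cfg)
        cc = np.array(rec.metadata["chest_center"])
        score = score_recording(rec.views["1"], graph, chest_center=cc)
        for d, (a, t) in checklist_agreement(score, gt).items():
            agree[d] += a
            total[d] += t
    return {d: 100.0 * agree[d] / total[d] for d in DIMENSIONS}


def estimator_accuracy(seed: int = 0) -> dict[str, float]:
    """Worst-case rate and depth estimation errors on noise-free signals.

    Rate over {80, 100, 110, 120, 140} cpm; depth at the generator default,
    both at zero noise."""
    graph = get_topology("reduced-17")
    rate_errs, depth_errs = [], []
    from .simulate import QualityParams
    for k, rate in enumerate((80.0, 100.0, 110.0, 120.0, 140.0)):
        params = QualityParams(rate_cpm=rate)
        cfg = _sim_config(0.0, 0.0, seed=seed + k)
        rec, _ = simulate_recording(params, cfg)
        cc = np.array(rec.metadata["chest_center"])
        score = score_recording(rec.views["1"], graph, chest_center=cc)
        for c in score.cycles:
            if c.scorable:
                rate_errs.append(abs(c.measures["rate_cpm"] - rate))
                depth_errs.append(abs(c.measures["depth_cm"] - params.depth_cm))
    return {"rate_max_abs_err_cpm": float(max(rate_errs)),
            "depth_max_abs_err_cm": float(max(depth_errs))}


# ---------------------------------------------------------------------------
# learning experiments
# ---------------------------------------------------------------------------

def build_samples(n: int, seed: int, views: tuple[str, ...] = ("1", "4", "5"),
                  topology: str = "reduced-17", target_T: int = 150,
                  keep_raw_view: str | None = None, keep_raw_ids=None):
    """Generate ``n`` labelled recordings and preprocess them into model
    features, discarding raw motion as it goes (memory-friendly).

    Returns (samples id->(features, labels), raw id->PoseSequence for the
    requested view/ids, manifest)."""
    graph = get_topology(topology)
    cfg = SimulationConfig(views=tuple(v for v in _FAST_VIEWS if v.view_id in views),
                           topology=topology, seed=0)
    recs, manifest = generate_dataset(n, config=cfg, seed=seed)
    keep_raw_ids = set(keep_raw_ids or [])
    samples, raw = {}, {}
    for rec, gt in recs:
        feats = prepare_features(rec, graph, views, target_T)
        samples[rec.recording_id] = (feats, labels_vector(gt))
        if keep_raw_view and rec.recording_id in keep_raw_ids:
            raw[rec.recording_id] = rec.views[keep_raw_view]
        rec.views.clear()  # release raw frames
    return samples, raw, manifest


def cv_against_baseline(samples: dict, config: TrainConfig,
                        model_config: ModelConfig | None = None) -> dict:
    """Cross-validate the multiview network and the constant-median
    baseline on preprocessed samples."""
    graph = get_topology("reduced-17")
    if model_config is None:
        model_config = small_model_config(views=config.views)
    return cross_validate(samples, graph, config, model_config)


def corrupted_view_contrast(samples: dict, raw_view1: dict, cv_result: dict,
                            config: TrainConfig, corrupt_sigma_cm: float = 5.0,
                            seed: int = 0,
                            model_config: ModelConfig | None = None) -> dict:
    """Fusion robustness: corrupt view 1 of the fold-0 test recordings with
    heavy Gaussian noise and compare the multiview model (one corrupted
    view among three) against a single-view model that sees only the
    corrupted view.  Both models were trained on clean data."""
    graph = get_topology("reduced-17")
    fold0 = cv_result["folds"][0]
    mv_model = cv_result["fold_models"][0]

    rng = np.random.default_rng(seed)
    corrupted = {}
    for rid in fold0.test_ids:
        seq = raw_view1[rid]
        data = seq.data.copy()
        data[:, :, :3] += rng.normal(0.0, corrupt_sigma_cm / 100.0,
                                     size=data[:, :, :3].shape)
        noisy = PoseSequence(seq.view_id, seq.fps, data, seq.missing_mask.copy())
        feats = prepare_features(_OneView(noisy), graph, ("1",), config.resample_T)
        corrupted[rid] = feats["1"]

    test_mv = [({**samples[rid][0], "1": corrupted[rid]}, samples[rid][1])
               for rid in fold0.test_ids]
    agreed = np.stack([samples[rid][1] for rid in fold0.test_ids])
    mv_pred = predict_dataset(mv_model, test_mv)
    mv_total = float(np.abs(mv_pred - agreed).mean(axis=0).sum())

    # single-view model trained on the clean view-1 stream of the same fold
    if model_config is None:
        model_config = small_model_config(views=("1",))
    sv_cfg = replace(config, views=("1",))
    from .train import train_model
    train = [({"1": samples[rid][0]["1"]}, samples[rid][1])
             for rid in fold0.train_ids]
    sv_model, _ = train_model(train, graph, sv_cfg, model_config)
    test_sv = [({"1": corrupted[rid]}, samples[rid][1]) for rid in fold0.test_ids]
    sv_pred = predict_dataset(sv_model, test_sv)
    sv_total = float(np.abs(sv_pred - agreed).mean(axis=0).sum())
    return {"multiview_corrupted_total_mae": mv_total,
            "singleview_corrupted_total_mae": sv_total}


class _OneView:
    """Adapter exposing a single PoseSequence with the MultiviewRecording
    interface expected by prepare_features."""

    def __init__(self, seq: PoseSequence):
        self.views = {seq.view_id: seq}
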