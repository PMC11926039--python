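# Methods

`cpraqa` assesses the quality of CPR chest compressions from multiview 3D
skeleton sequences against a six-item expert checklist. It contains three
scientific components: a deterministic kinematic scorer that operationalises
the checklist, a multiview spatial-temporal graph convolutional network
(STGCN) that learns to predict the checklist item scores, and a parametric
motion simulator that generates labelled multiview recordings. This note
documents the models, their assumptions, the tunable parameters, and the
design choices made where the design was genuinely open.

## Data model

A recording is a set of per-camera pose streams `P_k ∈ R^{T×N×C}`: `T`
frames, `N` joints, `C = 4` channels (x, y, z in meters in a shared
right-handed world frame with vertical +Y, plus a detection confidence in
[0, 1]). Two joint layouts ship with the package: the 33-landmark
full-body layout common to markerless pose estimators (default) and a
17-joint subset (head, shoulders, elbows, wrists, hands, hips, knees,
ankles, heels) used where speed matters. Per-view world origins need not
coincide: every downstream computation uses only relative coordinates.
Missing detections (occlusions) are flagged per frame and joint; their
coordinates may be NaN.

The skeleton is an undirected graph `(V, E)` of joints and bones. Graph
convolutions use the symmetric degree-normalised adjacency
`Λ^{-1/2} A' Λ^{-1/2}` where `A'` is the binary bone adjacency plus the
identity. Self-loops are added by default: the bare bone adjacency gives a
node no access to its own features, and zero-degree nodes would make the
normalisation singular. The flag is exposed for completeness.

## Checklist and kinematic scorer

For each compression cycle one point is available per dimension:

| dimension | pass criterion (defaults) |
|---|---|
| hand | wrist-centre horizontal offset from the chest centre ≤ 9 cm |
| arm | minimum elbow angle ≥ 160° **or** elbow-angle SD ≤ 5° |
| shoulder | chest-centre→mid-shoulder line within 10° of vertical |
| depth | mean compression depth within 5–6 cm |
| rate | 100–120 compressions/min |
| release | mean recoil residual ≤ 1 cm |

Item totals are the per-cycle points summed over the (nominally four)
cycles, 0–4 each. Failure codes record the direction of failure
(`too_shallow`/`too_deep`, `too_slow`/`too_fast`, `toward_head`/`toward_feet`/
`toward_left`/`toward_right`, `bent_elbows`, `not_over_patient`,
`incomplete_recoil`). Thresholds live in `Thresholds` and use the units
practitioners use (cm, degrees, compressions/min). Guideline-backed values
(depth 5–6 cm, rate 100–120/min) are fixed by resuscitation guidance; the
9 cm hand margin instantiates "one average hand margin" as an adult hand
breadth; the 160°/5° arm thresholds and the 10° shoulder tolerance
quantify "straight arms" and "shoulders over the patient" and are
configurable.

Scoring pipeline:

1. **Compression detection.** Compressions are troughs of mean-wrist
   height with prominence ≥ 2 cm and spacing ≥ 0.25 s
   (`scipy.signal.find_peaks`). Trough and release times are refined to
   sub-frame precision with a three-point parabola, which makes the rate
   estimate (60 / median inter-trough interval) accurate to ≈0.01/min at
   30 fps.
2. **Neutral height.** The recoil reference is the median wrist height
   over the still window preceding the first compression (up to 2 s of
   verified-still data, at least 1 s); if no still window exists it falls
   back to the 95th percentile of release heights.
3. **Depth and recoil.** Between consecutive troughs the wrist-height
   waveform is modelled as one harmonic period `c0 + c1 cos ωt + c2 sin ωt`
   (ω from that segment's trough spacing) and fitted by linear least
   squares. Depth is `neutral − c0 + amp` and the recoil residual
   `neutral − c0 − amp` with `amp = √(c1² + c2²)`. Reading off the extreme
   *samples* instead is biased under noise — the argmin of a noisy signal
   selects the noise (measured bias ≈ 0.4 cm at σ = 0.5 cm) — whereas the
   harmonic fit is exact for noise-free harmonic motion at any sampling
   phase and unbiased under noise. The release residual of a cycle's final
   compression is excluded: the hands return to rest during the pause, so
   that maximum reflects the pause, not recoil technique.
4. **Cycle segmentation.** A new cycle starts wherever the inter-compression
   gap exceeds 2 s. Segments with fewer than 5 compressions (e.g. a
   spurious noise trough in a rest pause) are marked unscorable and excluded
   from item totals.
5. **Arm statistics.** The elbow angle (mean of both sides) is cycle-locked,
   so the same per-segment harmonic fit yields the minimum angle
   (level − amplitude) and the angle SD (amplitude/√2), again avoiding the
   noise-selection bias of a raw minimum.
6. **Geometry points.** Hand distance is the median horizontal offset of
   the wrist centre from the chest centre — horizontal, because during a
   compression the wrists are up to 6 cm below the neutral chest point and
   a 3D distance would fold depth into hand placement. The shoulder angle
   is the median angle of the chest-centre→mid-shoulder line from vertical.
   The chest centre is taken from recording metadata when known (always, in
   simulation) and otherwise estimated as the median wrist position at
   troughs, at neutral height.

Scoring is invariant to global translation and rotation about the vertical
axis. Synchronisation claps are detected as epochs where the inter-wrist
distance drops below 3 cm while the wrists are above shoulder height; the
first clap per view aligns the views' frame clocks.

The harmonic-fit estimators assume compression motion is approximately
sinusoidal within a cycle — true of the simulator by construction and a
reasonable first-order model of rhythmic compressions, but a documented
assumption: strongly non-sinusoidal real motion (pauses mid-cycle, double
pushes) would bias the depth/recoil estimates.

An overall ordinal rating per cycle (Excellent / Good / Borderline / Poor /
Unacceptable) is derived from the six points by a fixed convention
(6→Excellent, 5→Good, 4→Borderline, 2–3→Poor, 0–1→Unacceptable). This is a
synthetic-label convention for simulated data, not a claim about how human
experts aggregate holistically.

## Synthetic multiview generator

The simulator emulates the study protocol: a rescuer kneels beside a
manikin (chest centre 22 cm above the floor, manikin head toward +X,
rescuer on the manikin's left at +Z), claps, performs 4 sets of 30
compressions with 5 s rest pauses, and claps again; six cameras record at
30 fps. Quality defects are generative parameters, each mapped one-to-one
onto a checklist dimension:

| parameter | default | drives |
|---|---|---|
| `rate_cpm` | 110 | compression frequency |
| `depth_cm` | 5.5 | trough depth below neutral |
| `recoil_deficit_cm` | 0 | release height below neutral |
| `hand_offset_cm` | (0, 0) | wrist offset on the chest plane |
| `elbow_flex_deg` / `elbow_var_deg` | 0 / 0 | elbow angle 180 − flex + var·sin(phase) |
| `shoulder_lean_deg` | 0 | chest→mid-shoulder tilt from vertical |

Mean-wrist height follows `−[rec + (depth − rec)(1 − cos 2πft)/2]` during
cycles (flat at neutral during pauses, with quarter-period blends at cycle
edges), so troughs sit exactly `depth` below neutral and inter-compression
releases exactly `recoil_deficit` below it. The shoulders ride at
arm-distance above the wrists along the lean direction, so the
chest→mid-shoulder angle equals the lean parameter identically. Arms are
solved per side as an isoceles two-segment chain meeting the prescribed
elbow angle exactly, the elbow bowing in the parasagittal plane; segment
lengths therefore flex by a few percent over a cycle (real arms are rigid —
a known idealisation). Elbow variability is capped at the flex (no
hyperextension). Anthropometry (segment lengths and widths) is jittered
±10% per recording.

Because each defect is constant within a recording, ground-truth labels
follow analytically from the parameters (`derive_ground_truth`), applying
the same thresholds the scorer uses: every cycle carries identical points.
This makes the scorer↔generator agreement an exact oracle: at zero noise
and occlusion the kinematic scorer reproduces the analytic labels on 100%
of cycles and dimensions (validated on 100 random recordings, and by the
acceptance script at run time).

Per view, i.i.d. Gaussian position noise (default σ = 0.5 cm) is added,
joints are dropped with a per-view occlusion probability (1–4%; doubled
for arm joints in the two rear views), dropped coordinates are NaN with the
missing flag set, and confidences are drawn Beta(8,2) for visible and
Beta(2,8) for occluded joints. Small integer sync offsets (0–3 frames)
shift each view's clock. Everything is reproducible from a single seed.

The default dataset sampler draws each parameter uniformly over a range
straddling its pass/fail boundary (depth 3–8 cm, rate 70–150/min, recoil
0–2.5 cm capped at depth − 3 cm so every compression keeps ≥ 3 cm of
visible excursion, hand offsets ±12 cm per axis, flex 0–35°, variability
0–12° capped at flex, lean 0–25°), so each dimension occurs in both label
states. What the generator does **not** emulate: manikin chest mechanics,
human-object contact, non-sinusoidal or drifting technique within a
recording, camera projection (per-view streams are 3D with noise, matching
the world-coordinate outputs of markerless pose estimation), and realistic
pose-estimator error structure (which is correlated across joints and
time, not i.i.d.). Passing tests on synthetic data therefore demonstrate
internal consistency and learnability, not field performance.

## Multiview STGCN

Per camera view, a five-block encoder processes the pose stream; the
per-view pooled features are fused by a softmax over learnable scalar
logits (zero-initialised: uniform weighting); a two-layer fully connected
head (hidden width 128, ReLU) regresses the six item scores, clamped to
[0, 4] at inference.

Each block applies, in order: a per-frame graph convolution
`Â X_t W` (node mixing by the fixed normalised adjacency, channel mixing by
learned weights), a kernel-9 per-joint temporal convolution with "same"
padding, batch normalisation over (batch, time, joints), ReLU, and a
residual connection when input and output shapes agree. The channel plan is
4→64→64→128→128→256 with temporal strides (1,1,2,1,2); a reduced-width plan
(4→8→8→16→16→32, head 64) is provided for CPU-scale experiments and is what
the benchmark below uses. Before the first block, the input is whitened per
(joint, channel) over (batch, time) with affine parameters and running
statistics — joint positions mix metre-scale static offsets with the
centimetre-scale excursions that carry the assessment signal, and without
this whitening the network cannot pick the signal out of the body-geometry
variance.

Model inputs are conditioned by filling occlusions (per-joint linear
interpolation in time), subtracting the median mid-hip position (one
constant per view — removes camera placement while keeping metric units
and whole-body motion; the checklist thresholds are absolute centimetres,
so no size rescaling is applied to model inputs), and linear resampling to
a fixed length (T = 150 for the benchmark). At that length the compression
oscillation is aliased; depth/recoil survive as the spread of the wrist
height distribution, while the compression *rate* is largely destroyed —
visible in the results, where rate is the one item the network does not
beat a constant at.

The network is implemented in NumPy with hand-written backpropagation,
verified against central finite differences to 1e-4 (in practice ~1e-9 in
float64). Training uses the summed per-item MAE loss
`L = Σ_q |ŷ_q − y_q|` with Adam (lr 0.01, decoupled weight decay 0.1,
100 epochs by default). For the CPU-scale benchmark the recipe adds:
head-bias initialisation at the per-item training median (the network
starts at the best constant predictor and learns corrections), Gaussian
coordinate jitter of 1 cm per training batch, and a 1/(1 + t/300)
learning-rate decay so unlearned items settle back onto the median instead
of drifting. MAE training has a plateau at the constant median — sign
gradients cancel there — and these three choices are what lets 30 epochs
escape it for the items whose signal survives preprocessing.

## Evaluation protocol

Cross-validation is k-fold (default 5) with shuffled near-equal partitions
grouped by participant, so no participant appears on both sides of a fold.
Each fold trains on 80% and tests on 20%; per-item MAE against the agreed
labels is pooled over folds and compared with a per-item training-median
constant baseline. The standard synthetic benchmark uses 200 recordings,
views 1/4/5, the 17-joint layout, T = 150, 30 epochs and the reduced-width
model — sizes chosen so the full run completes in about ten minutes on one
CPU. On it, the network beats the baseline clearly on the geometric items
(hand, shoulder) and on release, ties the rest within the ±0.05 MAE
resolution of the benchmark, and is strictly better in total (typically by
0.5–2.0 points out of ~8). Fusion robustness is checked by corrupting one
view of the fold-0 test recordings with σ = 5 cm noise: the three-view
model (one corrupted view) degrades less in total MAE than a single-view
model evaluated on the corrupted view alone.

Rater agreement uses weighted Cohen's kappa on the five ordinal overall
categories, `κ = 1 − Σ w O / Σ w E`, with linear weights by default
(quadratic available); both can be reported side by side. The
implementation is cross-checked against an independent library
implementation to machine precision.

## Numerical notes and limitations

* Sub-frame extremum refinement clips the parabola offset to ±0.6 frames
  and falls back to the sample itself for flat signals.
* `resample_time` marks a resampled frame missing if either source
  neighbour is missing (conservative propagation).
* Determinism: a single seed fans out to named substreams (sampler,
  per-recording simulation, fold shuffling, training batch order,
  augmentation); two runs with the same seed produce identical manifests
  and loss curves up to float32 summation order.
* The scorer judges rate purely kinematically; the experts in the
  motivating protocol used a metronome, so expert rate judgements and
  kinematic ones are not directly comparable.
* Checklist item scores for real recordings depend on a chest-centre
  estimate; the trough-based fallback assumes hands are on the chest on
  average, which a severely misplaced-hands performance violates.
* The network's item scores are regression outputs, not calibrated
  probabilities; the clamp to [0, 4] is applied at inference only.
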