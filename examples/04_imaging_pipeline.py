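"""The imaging pipeline on a synthetic movie with known ground truth.

Renders a small movie of fluorescent somata with neuropil contamination
and rigid drift, then runs the full pipeline: registration, ROI/annulus
trace extraction, rolling-percentile dF/F, neuropil subtraction, the
pixelwise wall-distance map, and the inactive/active/tuned rules.
"""

import numpy as np

from walltrack.behavior import (
    CorridorTrial,
    CouplingParams,
    TrackingPolicy,
    imaging_schedule,
    simulate_session,
)
from walltrack.ephys import anova_tuning_test, distance_tuning
from walltrack.imaging import (
    RoiSet,
    classify_roi,
    dff,
    downsample_to_frames,
    extract_roi_traces,
    neuropil_correct,
    pixelwise_map,
    register_movie,
    rolling_baseline,
)
from walltrack.neurons import (
    CalciumKernelParams,
    NeuronModel,
    make_roi_grid,
    render_movie,
)

params = CouplingParams()
trials = [
    CorridorTrial(mode="open_loop", open_loop_distance=float(d), schedule=imaging_schedule())
    for d in np.linspace(4.0, 34.0, 12)
]
behavior = simulate_session(trials, TrackingPolicy(kind="ideal", speed=20.0), params, seed=0)
t = behavior["t"].to_numpy()
fr = 7.0
n_frames = int(np.floor((t[-1] + params.dt) * fr))
frame_times = np.arange(n_frames) / fr

# 6 somata: four tuned to different distances, two untuned
rng = np.random.default_rng(0)
models = [
    NeuronModel(kind="unimodal", baseline=1.0, amplitude=12.0, preferred=p, width=4.0)
    for p in (8.0, 14.0, 20.0, 26.0)
] + [NeuronModel(kind="untuned", baseline=3.0)] * 2
u_beh = behavior["u_right"].to_numpy()
roi_dff = np.stack([
    downsample_to_frames(0.2 * (m.tuning(u_beh) - m.baseline), t, frame_times, fr)
    for m in models
])
labels = make_roi_grid((64, 64), len(models), seed=0)
rois = RoiSet.from_labels(labels)
neuropil = 0.2 * np.abs(np.convolve(rng.normal(0, 1, n_frames), np.ones(9) / 9, "same"))
scene = 100.0 * (1.0 + 0.3 * np.clip(rng.normal(0, 1, (64, 64)), -0.9, None))
steps = rng.integers(-1, 2, (n_frames, 2))
steps[0] = 0
shifts = np.clip(np.cumsum(steps, axis=0), -2, 2)
movie = render_movie(
    rois.masks, roi_dff, neuropil, np.full((64, 64), 0.5), shifts,
    CalciumKernelParams(), frame_rate=fr, seed=rng, baseline_image=scene,
)
print(f"rendered {movie.stack.shape} movie with drift up to "
      f"{np.abs(shifts).max()} px and shared neuropil contamination")

motions, corrected = register_movie(movie.stack, reference=movie.stack[0])
exact = int((motions == shifts).all(axis=1).sum())
print(f"registration: {exact}/{n_frames} frames recovered exactly\n")

roi_F, ann_F = extract_roi_traces(corrected, rois)
u_f = downsample_to_frames(u_beh, t, frame_times, fr)
v_f = downsample_to_frames(behavior["v"].to_numpy(), t, frame_times, fr)
tid_f = np.round(downsample_to_frames(behavior["trial_id"].to_numpy(), t, frame_times, fr)).astype(int)

print("ROI  truth            status          p        peak-bin (mm)")
for k, model in enumerate(models):
    roi_d = dff(roi_F[k], rolling_baseline(roi_F[k], fr))
    ann_d = dff(ann_F[k], rolling_baseline(ann_F[k], fr))
    corr_d = neuropil_correct(roi_d, ann_d)
    curve = distance_tuning(corr_d, u_f, v_f, tid_f)
    p = anova_tuning_test(curve.per_trial)
    cls = classify_roi(corr_d, curve, p)
    peak = curve.bin_centers[np.nanargmax(curve.mean)]
    truth = f"{model.kind[:8]:8s} {model.preferred if model.kind != 'untuned' else '':>4}"
    print(f"  {k}  {truth}      {cls.status:14s}  {p:8.2e}  {peak:.1f}")
print("Tuned ROIs are recovered at their injected preferred distances;")
print("untuned ROIs are not flagged.\n")

pmap = pixelwise_map(corrected, u_f, np.ones(n_frames, bool))
for k in (0, 3):
    ys, xs = np.nonzero(rois.masks[k])
    pref = np.median(pmap.preferred[ys, xs])
    r2 = np.median(pmap.r2[ys, xs])
    print(f"pixelwise map over ROI {k}: median preferred {pref:.1f} mm, median r2 {r2:.2f}")
print("Map hue (preferred distance) and brightness (r2) reproduce the injected")
print("tuning pixel by pixel.")
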