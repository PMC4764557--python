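"""Wall-distance tuning of a synthetic unit from open-loop trials.

Generates a session of open-loop wall sweeps, a unimodal neuron with
known preferred distance, Poisson spikes, and then runs the tuning
analysis: 2-ms binning, 3-mm distance bins during running, ANOVA
significance, and the activation/suppression modulation index.
"""

import numpy as np

from walltrack.behavior import (
    CorridorTrial,
    CouplingParams,
    TrackingPolicy,
    running_mask,
    simulate_session,
)
from walltrack.ephys import (
    anova_tuning_test,
    baseline_response,
    bin_spike_rate,
    direction_summary,
    distance_tuning,
    movement_windows,
    tuning_summary,
)
from walltrack.neurons import NeuronModel, generate_spikes, rate_from_behavior

params = CouplingParams()
trials = [
    CorridorTrial(mode="open_loop", open_loop_distance=float(d))
    for d in np.linspace(4.0, 34.0, 30)
]
behavior = simulate_session(trials, TrackingPolicy(kind="ideal", speed=20.0), params, seed=0)

model = NeuronModel(
    kind="unimodal", baseline=2.0, amplitude=12.0, preferred=15.0, width=5.0,
    direction_gain=2.0,
)
rate = rate_from_behavior(model, behavior)
spikes = generate_spikes(rate, params.dt, seed=4)
print(f"Simulated {spikes.size} spikes over {behavior['t'].iloc[-1]:.0f} s "
      f"(ground truth: unimodal, preferred 15 mm, 2x gain on wall approach)\n")

binned, _ = bin_spike_rate(spikes, params.dt, 0.0, len(behavior) * params.dt)
binned = binned[: len(behavior)]
u = behavior["u_right"].to_numpy()
v = behavior["v"].to_numpy()
run = running_mask(v)

baseline = baseline_response(binned, u, run, out_of_reach=30.0)
curve = distance_tuning(binned, u, v, behavior["trial_id"], sample_mask=run)
p = anova_tuning_test(curve.per_trial)
summary = tuning_summary(curve, baseline=baseline, p_value=p)

peak_at = curve.bin_centers[np.nanargmax(curve.mean)]
print(f"baseline (wall out of reach): {baseline:.2f} Hz")
print(f"tuning-curve peak:            {summary.peak:.2f} Hz at {peak_at:.1f} mm")
print(f"ANOVA across distance bins:   p = {p:.2e}  -> tuned: {summary.tuned}")
print(f"activation {summary.activation:.2f} Hz, suppression {summary.suppression:.2f} Hz, "
      f"modulation index {summary.modulation:.2f}")
print("A modulation index near 1 marks a purely activated unit; the peak bin")
print("recovers the 15-mm preferred distance within one 3-mm bin.\n")

towards, away = movement_windows(behavior)
d = direction_summary(binned, behavior["t"].to_numpy(), towards, away)
print(f"direction index {d.index:.2f} (towards range {d.towards_range:.1f} Hz, "
      f"away range {d.away_range:.1f} Hz): positive = stronger response while")
print("the wall approaches, matching the injected 2x approach gain.")
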