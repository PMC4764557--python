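"""Session-level orchestration: config, seeding, the end-to-end workflow.

``run_pipeline`` chains behavior simulation, synthetic-neuron generation,
the spike-train analyses and (optionally) the imaging pipeline on a small
synthetic movie, then aggregates a population report: per-unit summary
table, fractions of ROIs inactive / active / tuned, and histograms of
tuning-peak locations and modulation indices. Every numeric threshold is
carried in :class:`SessionConfig` and echoed into the run manifest, and
all randomness derives from the config's named seeds, so a fixed config
reproduces its outputs exactly.
"""

from __future__ import annotations

import argparse
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (
    CorridorTrial,
    CouplingParams,
    OpenLoopSchedule,
    TrackingPolicy,
    imaging_schedule,
    running_mask,
    save_behavior,
    simulate_session,
)
from .ephys import (
    anova_tuning_test,
    baseline_response,
    bin_spike_rate,
    direction_summary,
    distance_tuning,
    movement_windows,
    tuning_summary,
)
from .imaging import (
    RoiSet,
    classify_roi,
    dff,
    downsample_to_frames,
    extract_roi_traces,
    neuropil_correct,
    register_movie,
    rolling_baseline,
)
from .neurons import (
    CalciumKernelParams,
    PopulationSpec,
    UnitRecording,
    generate_spikes,
    make_population,
    make_roi_grid,
    rate_from_behavior,
    render_movie,
    save_spikes,
    spikes_to_dff,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
ROI_STATUSES = ("inactive", "active_untuned", "tuned")


@dataclass(frozen=True)
class AnalysisThresholds:
    """Every analysis threshold in one place (units in field names' docs).

    run_speed_cms: running threshold (strict) in cm/s. bin_width_mm:
    wall-distance bin width. alpha: ANOVA significance level.
    active_dff / range_dff: the active-ROI 90th-percentile and tuned-ROI
    range thresholds in dF/F. out_of_reach_mm: wall distance defining
    baseline epochs. min_trials: trials required for a bin to enter a
    tuning curve.
    """

    run_speed_cms: float = 3.0
    bin_width_mm: float = 3.0
    alpha: float = 0.05
    active_dff: float = 1.0
    range_dff: float = 0.3
    out_of_reach_mm: float = 30.0
    min_trials: int = 3

    def __post_init__(self) -> None:
        for name in ("run_speed_cms", "bin_width_mm", "alpha", "active_dff", "range_dff", "out_of_reach_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ImagingConfig:
    """Synthetic movie settings for the imaging arm of the pipeline."""

    enabled: bool = True
    frame_shape: tuple[int, int] = (64, 64)
    n_rois: int = 9
    frame_rate: float = 7.0
    max_shift: int = 2
    noise_sd: float = 0.0
    neuropil_dff_scale: float = 0.2


@dataclass
class SessionConfig:
    """Single source of truth for one synthetic session.

    Seeds are named per stage (behavior, neurons, movie); fixing them
    makes every output byte-identical across runs.
    """

    seeds: dict = field(default_factory=lambda: {"behavior": 1, "neurons": 2, "movie": 3})
    coupling: CouplingParams = field(default_factory=CouplingParams)
    policy: TrackingPolicy = field(
        default_factory=lambda: TrackingPolicy(kind="noisy", steering_gain=0.5, noise_sd=2.0, speed=20.0, speed_sd=4.0)
    )
    trials: list[CorridorTrial] = field(default_factory=list)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    kernel: CalciumKernelParams = field(default_factory=CalciumKernelParams)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        cfg = cls()
        if "seeds" in d:
            cfg.seeds = {**cfg.seeds, **d["seeds"]}
        if "coupling" in d:
            cfg.coupling = CouplingParams(**d["coupling"])
        if "policy" in d:
            cfg.policy = TrackingPolicy(**d["policy"])
        if "trials" in d:
            cfg.trials = _build_trials(d["trials"], cfg.coupling)
        if "population" in d:
            cfg.population = PopulationSpec(**d["population"])
        if "thresholds" in d:
            cfg.thresholds = AnalysisThresholds(**d["thresholds"])
        if "imaging" in d:
            im = dict(d["imaging"])
            if "frame_shape" in im:
                im["frame_shape"] = tuple(im["frame_shape"])
            cfg.imaging = ImagingConfig(**im)
        if "kernel" in d:
            cfg.kernel = CalciumKernelParams(**d["kernel"])
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


def _build_trials(spec: dict | list, coupling: CouplingParams) -> list[CorridorTrial]:
    """Trial list from a config mapping (or an explicit list of dicts)."""
    if isinstance(spec, list):
        return [CorridorTrial(**t) for t in spec]
    trials: list[CorridorTrial] = []
    ol = spec.get("open_loop")
    if ol:
        sched = imaging_schedule() if ol.get("schedule") == "imaging" else OpenLoopSchedule()
        distances = open_loop_distances(
            int(ol.get("count", 30)),
            float(ol.get("min", coupling.min_wall_distance)),
            float(ol.get("max", coupling.max_wall_distance)),
        )
        trials += [
            CorridorTrial(mode="open_loop", open_loop_distance=d, schedule=sched)
            for d in distances
        ]
    clo = spec.get("closed_loop")
    if clo:
        angles = clo.get("turn_angles", [-11.3, 0.0, 11.3])
        trials += [
            CorridorTrial(mode="closed_loop", turn_angle=float(angles[i % len(angles)]))
            for i in range(int(clo.get("count", 0)))
        ]
    return trials


def open_loop_distances(n: int, lo: float, hi: float) -> np.ndarray:
    """Hold distances tiling [lo, hi] mm for an open-loop sweep."""
    return np.linspace(lo, hi, n)


def default_trials(
    coupling: CouplingParams,
    n_open: int = 30,
    n_closed: int = 6,
    schedule: OpenLoopSchedule | None = None,
) -> list[CorridorTrial]:
    """Desk-scale default: an open-loop distance sweep plus closed-loop bends."""
    sched = schedule or OpenLoopSchedule()
    trials = [
        CorridorTrial(mode="open_loop", open_loop_distance=float(d), schedule=sched)
        for d in open_loop_distances(n_open, coupling.min_wall_distance, coupling.max_wall_distance)
    ]
    angles = [-11.3, 0.0, 11.3]
    trials += [
        CorridorTrial(mode="closed_loop", turn_angle=angles[i % 3]) for i in range(n_closed)
    ]
    return trials


@dataclass
class PopulationReport:
    """Aggregate statistics of one analyzed session."""

    n_units: int
    ephys: dict
    histograms: dict
    imaging: dict | None = None
    unit_table: str | None = None
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationReport":
        return cls(**d)


def _histogram(values, edges) -> dict:
    values = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    return {"edges": list(np.round(np.asarray(edges, float), 6)), "counts": [int(c) for c in counts]}


def analyze_units(
    behavior: pd.DataFrame,
    units: list[UnitRecording],
    thresholds: AnalysisThresholds,
) -> pd.DataFrame:
    """Per-unit tuning analysis; returns one summary row per unit.

    Columns: unit_id, depth_um, spike_width_class, n_spikes, baseline,
    peak, minimum, activation, suppression, modulation, p_value, tuned,
    peak_distance, direction_index.
    """
    t = behavior["t"].to_numpy()
    dt = float(t[1] - t[0])
    u = behavior["u_right"].to_numpy()
    v = behavior["v"].to_numpy()
    trial_id = behavior["trial_id"].to_numpy()
    run = running_mask(v, thresholds.run_speed_cms)
    t_stop = t[-1] + dt
    try:
        towards_w, away_w = movement_windows(behavior)
    except ValueError:
        towards_w, away_w = [], []
    rows = []
    for unit in units:
        rate, _ = bin_spike_rate(unit.spike_times, bin_width=dt, t_start=t[0], t_stop=t_stop)
        rate = rate[: t.size]
        try:
            baseline = baseline_response(rate, u, run, thresholds.out_of_reach_mm)
        except ValueError:
            baseline = np.nan
        curve = distance_tuning(
            rate,
            u,
            v,
            trial_id,
            bin_width=thresholds.bin_width_mm,
            speed_threshold=thresholds.run_speed_cms,
            min_trials=thresholds.min_trials,
            sample_mask=run,
        )
        try:
            p = anova_tuning_test(curve.per_trial)
        except ValueError:  # too few populated bins on very short sessions
            p = np.nan
        summary = tuning_summary(curve, baseline=baseline, p_value=p) \
            if np.isfinite(baseline) else None
        peak_distance = float(curve.bin_centers[np.nanargmax(curve.mean)]) if curve.defined.any() else np.nan
        if towards_w and away_w:
            try:
                direction = direction_summary(rate, t, towards_w, away_w).index
            except ValueError:
                direction = np.nan
        else:
            direction = np.nan
        rows.append(
            {
                "unit_id": unit.unit_id,
                "depth_um": unit.depth_um,
                "spike_width_class": unit.spike_width_class,
                "n_spikes": int(unit.spike_times.size),
                "baseline": baseline,
                "peak": summary.peak if summary else np.nan,
                "minimum": summary.minimum if summary else np.nan,
                "activation": summary.activation if summary else np.nan,
                "suppression": summary.suppression if summary else np.nan,
                "modulation": summary.modulation if summary else np.nan,
                "p_value": p,
                "tuned": bool(p < thresholds.alpha),
                "peak_distance": peak_distance,
                "direction_index": direction,
            }
        )
    return pd.DataFrame(rows)


def _imaging_arm(
    behavior: pd.DataFrame,
    models,
    config: SessionConfig,
    seed: int,
) -> dict:
    """Render a small synthetic movie and run the imaging pipeline on it.

    Ground-truth somata are ``n_rois`` models sampled evenly across the
    population (so tuned and untuned kinds are both represented).
    Returns counts/fractions by ROI status plus recovery diagnostics.
    """
    im = config.imaging
    rng = np.random.default_rng(seed)
    t = behavior["t"].to_numpy()
    dt = float(t[1] - t[0])
    fr = im.frame_rate
    n_frames = int(np.floor((t[-1] + dt) * fr))
    frame_times = np.arange(n_frames) / fr
    if len(models) > im.n_rois:
        idx = np.unique(np.linspace(0, len(models) - 1, im.n_rois).round().astype(int))
        models = [models[i] for i in idx]
    labels = make_roi_grid(im.frame_shape, len(models))
    rois = RoiSet.from_labels(labels)
    roi_dff = np.empty((len(models), n_frames))
    roi_spikes = []
    for k, model in enumerate(models):
        rate = rate_from_behavior(model, behavior)
        spikes = generate_spikes(rate, dt, rng)
        roi_spikes.append(spikes)
        trace = spikes_to_dff(spikes, config.kernel, t)
        roi_dff[k] = downsample_to_frames(trace, t, frame_times, fr)
    roi_dff = np.nan_to_num(roi_dff)
    # smooth shared neuropil field: low-pass noise trace, flat spatial profile
    neuropil = np.convolve(rng.normal(0, 1, n_frames), np.ones(15) / 15, mode="same")
    neuropil = im.neuropil_dff_scale * (neuropil - neuropil.min())
    profile = np.full(im.frame_shape, 0.5)
    # static speckle background so the rigid drift is observable; ~30%
    # contrast keeps the correlation peak sharp even on small fields
    texture = np.clip(rng.normal(0.0, 1.0, im.frame_shape), -0.9, None)
    baseline_image = config.kernel.baseline_f * (1.0 + 0.3 * texture)
    steps = rng.integers(-1, 2, size=(n_frames, 2))
    steps[0] = 0  # drift starts aligned with the ROI map
    shifts = np.clip(np.cumsum(steps, axis=0), -im.max_shift, im.max_shift)
    kernel = dataclasses.replace(config.kernel, noise_sd=im.noise_sd)
    movie = render_movie(
        rois.masks, roi_dff, neuropil, profile, shifts, kernel,
        frame_rate=fr, seed=rng, roi_spikes=roi_spikes,
        baseline_image=baseline_image,
    )
    motions, corrected = register_movie(movie.stack, reference=movie.stack[0])
    roi_F, ann_F = extract_roi_traces(corrected, rois)
    th = config.thresholds
    u_f = downsample_to_frames(behavior["u_right"].to_numpy(), t, frame_times, fr)
    v_f = downsample_to_frames(behavior["v"].to_numpy(), t, frame_times, fr)
    trial_f = np.round(
        downsample_to_frames(behavior["trial_id"].to_numpy(), t, frame_times, fr)
    ).astype(int)
    statuses = []
    for k in range(len(models)):
        F0 = rolling_baseline(roi_F[k], fr)
        roi_d = dff(roi_F[k], F0)
        ann_d = dff(ann_F[k], rolling_baseline(ann_F[k], fr))
        corrected_dff = neuropil_correct(roi_d, ann_d)
        curve = distance_tuning(
            corrected_dff, u_f, v_f, trial_f,
            bin_width=th.bin_width_mm, speed_threshold=th.run_speed_cms,
            min_trials=th.min_trials,
        )
        p = anova_tuning_test(curve.per_trial)
        cls = classify_roi(
            corrected_dff, curve, p,
            alpha=th.alpha, range_threshold=th.range_dff, active_threshold=th.active_dff,
        )
        statuses.append(cls.status)
    counts = {s: statuses.count(s) for s in ROI_STATUSES}
    n = len(statuses)
    fractions = {s: counts[s] / n for s in ROI_STATUSES}
    return {
        "n_rois": n,
        "counts": counts,
        "fractions": fractions,
        "registration_max_error": int(np.max(np.abs(motions - shifts))),
    }


def run_pipeline(config: SessionConfig, out_dir) -> PopulationReport:
    """Execute simulate -> analyze -> report; deterministic given seeds.

    Writes ``behavior/``, ``neural/`` and ``report/`` subdirectories (and
    the imaging summary when enabled) under ``out_dir`` plus a manifest
    recording seeds, thresholds and the package version.
    """
    out = Path(out_dir)
    trials = config.trials or default_trials(config.coupling)
    for sub in ("behavior", "neural", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    logger.info("thresholds: %s", config.thresholds)

    behavior = simulate_session(
        trials, config.policy, config.coupling, seed=config.seeds["behavior"]
    )
    save_behavior(behavior, out / "behavior" / "behavior.csv")
    pd.DataFrame(
        [
            {
                "trial_id": i,
                "mode": tr.mode,
                "turn_angle": tr.turn_angle,
                "open_loop_distance": tr.open_loop_distance,
                "stim_condition": tr.stim_condition,
            }
            for i, tr in enumerate(trials)
        ]
    ).to_csv(out / "behavior" / "trials.csv", index=False)

    models = make_population(config.population, seed=config.seeds["neurons"])
    dt = config.coupling.dt
    rng = np.random.default_rng(config.seeds["neurons"] + 1)
    units = []
    for i, model in enumerate(models):
        rate = rate_from_behavior(model, behavior)
        spikes = generate_spikes(rate, dt, rng)
        units.append(UnitRecording(spike_times=spikes, unit_id=i))
    save_spikes(units, out / "neural" / "spikes.csv")

    table = analyze_units(behavior, units, config.thresholds)
    truth = pd.DataFrame({"unit_id": range(len(models)), "true_kind": [m.kind for m in models]})
    table = table.merge(truth, on="unit_id")
    table_path = out / "report" / "unit_table.csv"
    table.to_csv(table_path, index=False)

    imaging_summary = None
    if config.imaging.enabled:
        imaging_summary = _imaging_arm(behavior, models, config, config.seeds["movie"])

    tuned = table["tuned"].to_numpy()
    histograms = {
        "modulation": _histogram(table["modulation"], np.linspace(-1, 1, 21)),
        "direction_index": _histogram(table["direction_index"], np.linspace(-1, 1, 21)),
        "peak_distance": _histogram(
            table.loc[tuned, "peak_distance"],
            np.arange(0.0, config.coupling.max_wall_distance + config.thresholds.bin_width_mm,
                      config.thresholds.bin_width_mm),
        ),
    }
    report = PopulationReport(
        n_units=len(units),
        ephys={
            "n_units": len(units),
            "n_tuned": int(tuned.sum()),
            "fraction_tuned": float(tuned.mean()) if len(units) else 0.0,
        },
        histograms=histograms,
        imaging=imaging_summary,
        unit_table=str(table_path.relative_to(out)),
    )
    write_report(report, out / "report")
    manifest = {
        "package": "walltrack",
        "version": __version__,
        "seeds": config.seeds,
        "thresholds": dataclasses.asdict(config.thresholds),
        "coupling": dataclasses.asdict(config.coupling),
        "n_trials": len(trials),
        "n_units": len(units),
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return report


def write_report(report: PopulationReport, out_dir) -> Path:
    """Write the report as versioned JSON; returns the file path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if report.imaging is not None:
        total = sum(report.imaging["fractions"].values())
        if report.imaging["n_rois"] and abs(total - 1.0) > 1e-9:
            raise ValueError("ROI status fractions must sum to 1")
    path = out / "report.json"
    with open(path, "w") as f:
        json.dump(report.to_dict(), f, indent=2, sort_keys=True)
    return path


def load_report(path) -> PopulationReport:
    """Round-trip read of a report written by :func:`write_report`."""
    with open(path) as f:
        return PopulationReport.from_dict(json.load(f))


def main(argv=None) -> int:
    """Thin CLI for the end-to-end workflow: walltrack-run --config C --seed S --out DIR."""
    parser = argparse.ArgumentParser(description="Run the synthetic simulate→analyze→report pipeline")
    parser.add_argument("--config", type=str, default=None, help="YAML session config")
    parser.add_argument("--seed", type=int, default=None, help="override all stage seeds")
    parser.add_argument("--out", type=str, required=True, help="output directory")
    args = parser.parse_args(argv)
    logging.basicConfig(level=logging.INFO)
    config = SessionConfig.from_yaml(args.config) if args.config else SessionConfig()
    if args.seed is not None:
        ss = np.random.SeedSequence(args.seed).generate_state(3)
        config.seeds = {
            "behavior": int(ss[0] % 2**31),
            "neurons": int(ss[1] % 2**31),
            "movie": int(ss[2] % 2**31),
        }
        logger.info("seed override: %s", config.seeds)
    report = run_pipeline(config, args.out)
    print(json.dumps(report.ephys, indent=2))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
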