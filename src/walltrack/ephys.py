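"""Spike-train tuning analyses.

Implements the wall-distance tuning workflow for extracellular units (and
for calcium dF/F traces, which share the same binning machinery): 2-ms
spike-rate binning on the behavior clock, per-trial tuning curves in 3-mm
wall-distance bins restricted to running, a one-way ANOVA significance
test across bins with trials as replicates, baseline / activation /
suppression quantification and its modulation index, direction-of-motion
tuning, contralateral-vs-ipsilateral laterality, open- vs closed-loop
comparison, running-speed tuning, and the fast/slow multiplicative gain
index.

All ratio indices share the form (a - b) / (a + b) and therefore live in
[-1, 1] whenever defined and flip sign under swapping the two inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class TuningCurve:
    """Mean response +/- SE per wall-distance bin, over qualifying trials.

    Bins lie on a fixed grid starting at 0 with width ``bin_width`` mm;
    bins entered by fewer than the minimum number of trials are NaN.
    ``per_trial`` (trials x bins) holds the per-trial bin means used for
    the ANOVA. ``baseline`` is the response when the wall is out of
    reach, when available.
    """

    bin_centers: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_trials: np.ndarray
    bin_width: float = 3.0
    baseline: float | None = None
    per_trial: np.ndarray | None = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.mean)

    @property
    def range(self) -> float:
        """Max minus min of the curve over defined bins."""
        d = self.defined
        if not d.any():
            return float("nan")
        return float(np.nanmax(self.mean) - np.nanmin(self.mean))


@dataclass(frozen=True)
class TuningSummary:
    """Activation/suppression summary of one tuning curve.

    activation = peak - baseline; suppression = baseline - minimum;
    modulation = (activation - suppression)/(activation + suppression),
    NaN when the denominator is not positive. A purely activated unit has
    modulation 1, a purely suppressed unit -1, mixed units near 0.
    """

    baseline: float
    peak: float
    minimum: float
    activation: float
    suppression: float
    modulation: float
    p_value: float | None = None
    tuned: bool | None = None


@dataclass(frozen=True)
class DirectionSummary:
    """Rate ranges during wall movement toward vs away from the animal."""

    towards_range: float
    away_range: float
    index: float


@dataclass(frozen=True)
class ComparisonIndex:
    """A named (a - b)/(a + b) comparison between two conditions."""

    kind: str
    value: float
    inputs: dict = field(default_factory=dict)


def bin_spike_rate(
    spike_times: np.ndarray,
    bin_width: float = 0.002,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike rate (Hz) in uniform time bins; returns (rate, bin_centers).

    Counts per bin divided by the bin width. With the default 2-ms bins
    and a behavior series on the same clock the two align sample for
    sample.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if t_stop is None:
        t_stop = spike_times.max() + bin_width if spike_times.size else t_start + bin_width
    n_bins = int(np.round((t_stop - t_start) / bin_width))
    edges = t_start + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(spike_times, bins=edges)
    centers = edges[:-1] + bin_width / 2.0
    return counts / bin_width, centers


def _bin_index(u: np.ndarray, bin_width: float) -> np.ndarray:
    return np.floor(np.asarray(u, dtype=float) / bin_width).astype(int)


def per_trial_bin_means(
    response: np.ndarray,
    u: np.ndarray,
    trial_id: np.ndarray,
    bin_width: float = 3.0,
    sample_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial mean response in wall-distance bins.

    Returns ``(per_trial, bin_centers, trial_ids)`` where ``per_trial``
    is a trials x bins array, NaN where a trial never visits a bin.
    Samples excluded by ``sample_mask`` do not contribute.
    """
    response = np.asarray(response, dtype=float)
    u = np.asarray(u, dtype=float)
    trial_id = np.asarray(trial_id)
    keep = np.ones(response.size, dtype=bool) if sample_mask is None else np.asarray(sample_mask, bool)
    if not keep.any():
        raise ValueError("sample mask excludes every sample")
    resp, u_k, tid = response[keep], u[keep], trial_id[keep]
    bins = _bin_index(u_k, bin_width)
    b_min, b_max = bins.min(), bins.max()
    n_bins = b_max - b_min + 1
    trial_ids = np.unique(tid)
    t_index = np.searchsorted(trial_ids, tid)
    flat = t_index * n_bins + (bins - b_min)
    sums = np.bincount(flat, weights=resp, minlength=trial_ids.size * n_bins)
    counts = np.bincount(flat, minlength=trial_ids.size * n_bins)
    with np.errstate(invalid="ignore"):
        per_trial = (sums / counts).reshape(trial_ids.size, n_bins)
    centers = (np.arange(b_min, b_max + 1) + 0.5) * bin_width
    return per_trial, centers, trial_ids


def _nan_mean_se(per_trial: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Across-trial mean, standard error and counts, ignoring NaN cells."""
    valid = ~np.isnan(per_trial)
    n = valid.sum(axis=0)
    filled = np.where(valid, per_trial, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=0) / n
        resid = np.where(valid, per_trial - mean[None, :], 0.0)
        var = (resid**2).sum(axis=0) / np.maximum(n - 1, 1)
    se = np.where(n > 1, np.sqrt(var / np.maximum(n, 1)), 0.0)
    return mean, se, n


def distance_tuning(
    response: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    trial_id: np.ndarray,
    bin_width: float = 3.0,
    speed_threshold: float = 3.0,
    min_trials: int = 3,
    sample_mask: np.ndarray | None = None,
    baseline: float | None = None,
) -> TuningCurve:
    """Wall-distance tuning curve during running.

    A per-trial curve is the mean response inside ``bin_width``-mm bins
    of wall distance; trial curves are then averaged (mean +/- SE) over
    trials whose mean run speed exceeds ``speed_threshold`` cm/s. Bins
    entered by fewer than ``min_trials`` qualifying trials are dropped
    (NaN) and logged. ``sample_mask`` can further restrict which samples
    contribute (e.g. a running mask).
    """
    v = np.asarray(v, dtype=float)
    trial_id = np.asarray(trial_id)
    trial_ids_all = np.unique(trial_id)
    mean_speed = np.array([v[trial_id == t].mean() for t in trial_ids_all])
    qualifying = trial_ids_all[mean_speed > speed_threshold]
    if qualifying.size == 0:
        raise ValueError(
            f"no trials with mean speed > {speed_threshold} cm/s"
        )
    trial_keep = np.isin(trial_id, qualifying)
    keep = trial_keep if sample_mask is None else trial_keep & np.asarray(sample_mask, bool)
    per_trial, centers, _ = per_trial_bin_means(
        response, u, trial_id, bin_width=bin_width, sample_mask=keep
    )
    mean, se, n = _nan_mean_se(per_trial)
    sparse = n < min_trials
    if sparse.any():
        logger.debug("dropping %d bins with < %d trials", int(sparse.sum()), min_trials)
        mean = np.where(sparse, np.nan, mean)
        se = np.where(sparse, np.nan, se)
        per_trial = np.where(sparse[None, :], np.nan, per_trial)
    return TuningCurve(
        bin_centers=centers,
        mean=mean,
        se=se,
        n_trials=n,
        bin_width=bin_width,
        baseline=baseline,
        per_trial=per_trial,
    )


def anova_tuning_test(per_trial: np.ndarray) -> float:
    """One-way ANOVA across distance bins with trials as replicates.

    ``per_trial`` is trials x bins with NaN for unvisited combinations.
    Bins with fewer than two trials are excluded. Because a trial's bin
    mean is far more precise in bins it dwells in than in bins it merely
    passes through, group variances are strongly unequal; the test is
    therefore Welch's heteroscedasticity-robust one-way ANOVA, which
    keeps the false-positive rate at its nominal level under these
    conditions (the classical equal-variance F test is markedly
    conservative here). Degenerate inputs: all values identical -> p = 1
    by convention; zero within-bin variance with differing bin means ->
    p = 0 (the limiting case).
    """
    per_trial = np.asarray(per_trial, dtype=float)
    groups = []
    for j in range(per_trial.shape[1]):
        col = per_trial[:, j]
        col = col[~np.isnan(col)]
        if col.size >= 2:
            groups.append(col)
    if len(groups) < 2:
        raise ValueError("need at least 2 bins with at least 2 trials each")
    variances = np.array([g.var(ddof=1) for g in groups])
    means = np.array([g.mean() for g in groups])
    if np.all(variances == 0):
        if np.allclose(means, means[0]):
            logger.debug("degenerate ANOVA input (zero variance); returning p=1")
            return 1.0
        return 0.0
    if np.any(variances == 0):
        # Welch weights diverge for a zero-variance group; fall back to
        # the classical equal-variance F test for these rare inputs.
        with np.errstate(invalid="ignore", divide="ignore"):
            p = stats.f_oneway(*groups).pvalue
        return 1.0 if np.isnan(p) else float(p)
    from statsmodels.stats.oneway import anova_oneway

    res = anova_oneway(groups, use_var="unequal", welch_correction=True)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def baseline_response(
    response: np.ndarray,
    u: np.ndarray,
    run_mask: np.ndarray,
    out_of_reach: float = 30.0,
) -> float:
    """Mean response while running with the wall out of reach (u > threshold)."""
    response = np.asarray(response, dtype=float)
    mask = (np.asarray(u, dtype=float) > out_of_reach) & np.asarray(run_mask, bool)
    if not mask.any():
        raise ValueError(f"no running samples with wall distance > {out_of_reach} mm")
    return float(response[mask].mean())


def tuning_summary(
    curve: TuningCurve,
    baseline: float | None = None,
    p_value: float | None = None,
) -> TuningSummary:
    """Activation, suppression and modulation index of a tuning curve.

    The baseline (response with the wall out of reach) comes from the
    argument or from ``curve.baseline``. Modulation is
    (activation - suppression)/(activation + suppression); when the
    denominator is not positive the index is NaN (reported missing).
    """
    if baseline is None:
        baseline = curve.baseline
    if baseline is None:
        raise ValueError("no baseline available; provide out-of-reach epochs")
    if not curve.defined.any():
        raise ValueError("tuning curve has no defined bins")
    peak = float(np.nanmax(curve.mean))
    minimum = float(np.nanmin(curve.mean))
    activation = peak - baseline
    suppression = baseline - minimum
    # the index uses non-negative activation/suppression so it stays in
    # [-1, 1] even when sampling noise puts the whole curve above (or
    # below) baseline; the raw signed values are still reported
    act, sup = max(activation, 0.0), max(suppression, 0.0)
    denom = act + sup
    modulation = (act - sup) / denom if denom > 0 else float("nan")
    tuned = None if p_value is None else bool(p_value < 0.05)
    return TuningSummary(
        baseline=float(baseline),
        peak=peak,
        minimum=minimum,
        activation=activation,
        suppression=suppression,
        modulation=float(modulation),
        p_value=p_value,
        tuned=tuned,
    )


# ---------------------------------------------------------------------------
# Direction of wall motion


def movement_windows(
    behavior: pd.DataFrame,
    dead_band: float = 1.0,
    min_duration: float = 0.2,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Epochs of wall movement toward / away from the animal.

    Derived from the sign of the contralateral wall velocity with a dead
    band of ``dead_band`` mm/s; epochs shorter than ``min_duration`` s
    are discarded. Returns (towards_windows, away_windows) as lists of
    (start, end) times. Towards = wall velocity < 0 (distance shrinking).
    """
    t = behavior["t"].to_numpy()
    wv = behavior["wall_velocity"].to_numpy()
    trial = behavior["trial_id"].to_numpy()
    state = np.where(wv < -dead_band, -1, np.where(wv > dead_band, 1, 0))
    towards, away = [], []
    start = 0
    for i in range(1, len(state) + 1):
        boundary = (
            i == len(state)
            or state[i] != state[start]
            or trial[i] != trial[start]
        )
        if boundary:
            if state[start] != 0 and t[i - 1] - t[start] >= min_duration:
                window = (float(t[start]), float(t[i - 1]))
                (towards if state[start] == -1 else away).append(window)
            start = i
    return towards, away


def _window_profile(
    rate: np.ndarray,
    t: np.ndarray,
    windows: list[tuple[float, float]],
    window_s: float,
    profile_bin_s: float,
) -> np.ndarray:
    """Trial-averaged rate profile aligned to window onsets (length window_s).

    The averaged profile is rebinned to ``profile_bin_s`` so that its
    range is not dominated by single raw clock bins.
    """
    dt = t[1] - t[0]
    n = int(round(window_s / dt))
    rows = []
    for start, _ in windows:
        i0 = int(np.searchsorted(t, start - 1e-9))
        if i0 + n <= rate.size:
            rows.append(rate[i0 : i0 + n])
    if not rows:
        raise ValueError("no complete movement windows")
    profile = np.mean(rows, axis=0)
    n_sub = max(1, int(round(profile_bin_s / dt)))
    n_out = profile.size // n_sub
    return profile[: n_out * n_sub].reshape(n_out, n_sub).mean(axis=1)


def direction_summary(
    rate: np.ndarray,
    t: np.ndarray,
    towards_windows: list[tuple[float, float]],
    away_windows: list[tuple[float, float]],
    window_s: float = 1.0,
    profile_bin_s: float = 0.05,
) -> DirectionSummary:
    """Direction modulation from rate ranges during wall movement.

    The trial-averaged rate profile is computed over the first
    ``window_s`` seconds of each movement window and rebinned to
    ``profile_bin_s``; the range is its max minus min.
    index = (towards - away)/(towards + away) on ranges: 1 for units
    responding only to approach, -1 only to withdrawal, near 0 for
    symmetric units. NaN when both ranges are zero.
    """
    if not towards_windows or not away_windows:
        raise ValueError("need at least one window in each direction")
    rate = np.asarray(rate, dtype=float)
    t = np.asarray(t, dtype=float)
    towards = _window_profile(rate, t, towards_windows, window_s, profile_bin_s)
    away = _window_profile(rate, t, away_windows, window_s, profile_bin_s)
    tw = float(towards.max() - towards.min())
    aw = float(away.max() - away.min())
    denom = tw + aw
    index = (tw - aw) / denom if denom > 0 else float("nan")
    return DirectionSummary(towards_range=tw, away_range=aw, index=float(index))


# ---------------------------------------------------------------------------
# Comparison indices


def laterality_index(contra: TuningCurve, ipsi: TuningCurve) -> ComparisonIndex:
    """(contra range - ipsi range)/(contra range + ipsi range).

    1 for units responding only to the contralateral wall, -1 only to the
    ipsilateral wall. Requires curves on matching bin grids; undefined
    (NaN) when both ranges are zero.
    """
    if contra.bin_width != ipsi.bin_width:
        raise ValueError("curves must share the bin grid")
    cr, ir = contra.range, ipsi.range
    denom = cr + ir
    value = (cr - ir) / denom if denom > 0 else float("nan")
    return ComparisonIndex(
        kind="laterality", value=float(value), inputs={"contra_range": cr, "ipsi_range": ir}
    )


def open_closed_index(
    open_rate: np.ndarray,
    open_u: np.ndarray,
    closed_rate: np.ndarray,
    closed_u: np.ndarray,
) -> ComparisonIndex:
    """(open - closed)/(open + closed) on mean rates over the shared distance range.

    Rates are restricted to wall distances sampled in both conditions
    before averaging, so the comparison is not confounded by different
    distance coverage. 0 means equal rates in open and closed loop.
    """
    open_rate, open_u = np.asarray(open_rate, float), np.asarray(open_u, float)
    closed_rate, closed_u = np.asarray(closed_rate, float), np.asarray(closed_u, float)
    lo = max(open_u.min(), closed_u.min())
    hi = min(open_u.max(), closed_u.max())
    if not (hi > lo):
        raise ValueError("open and closed conditions share no wall-distance range")
    mo = float(open_rate[(open_u >= lo) & (open_u <= hi)].mean())
    mc = float(closed_rate[(closed_u >= lo) & (closed_u <= hi)].mean())
    denom = mo + mc
    value = (mo - mc) / denom if denom > 0 else float("nan")
    return ComparisonIndex(
        kind="open_vs_closed",
        value=float(value),
        inputs={"open_mean": mo, "closed_mean": mc, "range": (lo, hi)},
    )


def speed_tuning(
    response: np.ndarray,
    v: np.ndarray,
    trial_id: np.ndarray,
    out_of_reach_mask: np.ndarray,
    speed_bin_width: float = 5.0,
    min_trials: int = 3,
) -> tuple[TuningCurve, float]:
    """Running-speed tuning while the wall is out of reach.

    Per trial, the mean response and mean speed over out-of-reach samples
    define one observation; trials are grouped into speed bins and the
    curve is the across-trial mean +/- SE, with significance from a
    one-way ANOVA across speed bins (trials as replicates).
    """
    mask = np.asarray(out_of_reach_mask, bool)
    if not mask.any():
        raise ValueError("out-of-reach mask is empty")
    response = np.asarray(response, float)[mask]
    v = np.asarray(v, float)[mask]
    tid = np.asarray(trial_id)[mask]
    trial_ids = np.unique(tid)
    if trial_ids.size < 4:
        raise ValueError("too few trials with out-of-reach samples")
    trial_resp = np.array([response[tid == t].mean() for t in trial_ids])
    trial_speed = np.array([v[tid == t].mean() for t in trial_ids])
    per_trial, centers, _ = per_trial_bin_means(
        trial_resp, trial_speed, np.arange(trial_ids.size), bin_width=speed_bin_width
    )
    mean, se, n = _nan_mean_se(per_trial)
    sparse = n < min_trials
    mean = np.where(sparse, np.nan, mean)
    se = np.where(sparse, np.nan, se)
    per_trial = np.where(sparse[None, :], np.nan, per_trial)
    p = anova_tuning_test(per_trial)
    curve = TuningCurve(
        bin_centers=centers,
        mean=mean,
        se=se,
        n_trials=n,
        bin_width=speed_bin_width,
        per_trial=per_trial,
    )
    return curve, p


def split_trials_by_speed(
    v: np.ndarray,
    trial_id: np.ndarray,
    speed_threshold: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Median split of running trials into fast and slow halves.

    Running trials (mean speed above threshold) are split at the median
    of per-trial mean speeds; returns (fast_trial_ids, slow_trial_ids).
    """
    v = np.asarray(v, float)
    trial_id = np.asarray(trial_id)
    ids = np.unique(trial_id)
    mean_speed = np.array([v[trial_id == t].mean() for t in ids])
    running = mean_speed > speed_threshold
    ids, mean_speed = ids[running], mean_speed[running]
    if ids.size < 2:
        raise ValueError("need at least 2 running trials to split")
    median = np.median(mean_speed)
    return ids[mean_speed > median], ids[mean_speed <= median]


def speed_gain_index(fast: TuningCurve, slow: TuningCurve) -> ComparisonIndex:
    """Log multiplicative gain mapping the slow curve onto the fast curve.

    g minimizes sum (fast - g*slow)^2 over bins defined in both curves
    (closed form <fast, slow>/<slow, slow>); the index is ln(g). Positive
    values mean higher rates during fast running. Undefined when the slow
    curve is all zero on the shared bins.
    """
    if fast.bin_width != slow.bin_width:
        raise ValueError("curves must share the bin grid")
    f = {c: m for c, m in zip(fast.bin_centers, fast.mean)}
    s = {c: m for c, m in zip(slow.bin_centers, slow.mean)}
    common = [c for c in f if c in s and not (np.isnan(f[c]) or np.isnan(s[c]))]
    if not common:
        raise ValueError("curves share no defined bins")
    fv = np.array([f[c] for c in common])
    sv = np.array([s[c] for c in common])
    ss = float(np.dot(sv, sv))
    if ss == 0:
        value = float("nan")
        g = float("nan")
    else:
        g = float(np.dot(fv, sv) / ss)
        value = float(np.log(g)) if g > 0 else float("nan")
    return ComparisonIndex(kind="speed_gain", value=value, inputs={"gain": g, "n_bins": len(common)})
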