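"""Synthetic neural data with known ground truth.

Forward models tied to a behavioral trajectory: parametric wall-distance
tuning (monotonic, unimodal, multimodal, untuned) with optional
direction-of-wall-motion and running-speed sensitivity; inhomogeneous
Poisson spike generation; a linear GCaMP-style calcium kernel calibrated
so a single spike yields a fixed peak dF/F (default 0.3) with a 600-ms
post-peak half-decay; and a renderer producing small fluorescence movies
(somata plus a shared neuropil field, rigid drift, Gaussian noise) with
full ground-truth annotations for validating the imaging pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import fftconvolve
from scipy.special import expit

TUNING_KINDS = (
    "monotonic_decreasing",
    "monotonic_increasing",
    "unimodal",
    "multimodal",
    "untuned",
)


@dataclass(frozen=True)
class NeuronModel:
    """Ground-truth rate model of one neuron.

    The rate (Hz) factorizes as ``tuning(u) * direction_factor *
    speed_factor``, floored at zero:

    * ``monotonic_decreasing`` — rate rises sigmoidally as the wall
      approaches (half-maximal at ``preferred`` mm, slope scale ``width``);
      equals ``baseline`` when the wall is out of reach.
    * ``monotonic_increasing`` — rate is ``baseline`` far away and is
      suppressed sigmoidally (by up to ``amplitude``) as the wall comes
      close, i.e. rate increases with wall distance.
    * ``unimodal`` — Gaussian bump of height ``amplitude`` at
      ``preferred`` with SD ``width`` on top of ``baseline``.
    * ``multimodal`` — sum of Gaussian bumps (tuple-valued
      ``amplitude``/``preferred``/``width``).
    * ``untuned`` — constant ``baseline``.

    ``direction_gain`` multiplies the rate while the wall moves toward
    the animal (wall velocity < 0); motion away and zero velocity use
    factor 1. ``speed_slope`` gives a multiplicative running-speed factor
    ``1 + speed_slope * v`` (v in cm/s). ``laterality`` selects which
    wall drives the neuron.
    """

    kind: str = "unimodal"
    baseline: float = 2.0
    amplitude: float | tuple[float, ...] = 10.0
    preferred: float | tuple[float, ...] = 15.0
    width: float | tuple[float, ...] = 5.0
    direction_gain: float = 1.0
    speed_slope: float = 0.0
    laterality: str = "contra"

    def __post_init__(self) -> None:
        if self.kind not in TUNING_KINDS:
            raise ValueError(f"unknown tuning kind {self.kind!r}")
        if self.laterality not in ("contra", "ipsi", "both"):
            raise ValueError(f"unknown laterality {self.laterality!r}")

    def tuning(self, u) -> np.ndarray:
        """Tuning component of the rate (Hz) at wall distance ``u`` (mm)."""
        u = np.asarray(u, dtype=float)
        if self.kind == "untuned":
            out = np.full_like(u, self.baseline)
        elif self.kind == "monotonic_decreasing":
            out = self.baseline + self.amplitude * expit((self.preferred - u) / self.width)
        elif self.kind == "monotonic_increasing":
            out = self.baseline - self.amplitude * expit((self.preferred - u) / self.width)
        elif self.kind == "unimodal":
            out = self.baseline + self.amplitude * np.exp(
                -0.5 * ((u - self.preferred) / self.width) ** 2
            )
        else:  # multimodal
            amps = np.atleast_1d(np.asarray(self.amplitude, dtype=float))
            prefs = np.atleast_1d(np.asarray(self.preferred, dtype=float))
            widths = np.atleast_1d(np.asarray(self.width, dtype=float))
            out = np.full_like(u, self.baseline)
            for a, p, w in zip(amps, prefs, widths):
                out = out + a * np.exp(-0.5 * ((u - p) / w) ** 2)
        return np.maximum(out, 0.0)

    def rate(self, u, wall_velocity=0.0, v=0.0) -> np.ndarray:
        """Firing rate (Hz) given wall distance, wall velocity and run speed."""
        u = np.asarray(u, dtype=float)
        if np.any(u < 0):
            raise ValueError("wall distance must be >= 0")
        wall_velocity = np.broadcast_to(np.asarray(wall_velocity, dtype=float), u.shape)
        v = np.broadcast_to(np.asarray(v, dtype=float), u.shape)
        direction = np.where(wall_velocity < 0, self.direction_gain, 1.0)
        speed = np.maximum(1.0 + self.speed_slope * v, 0.0)
        return np.maximum(self.tuning(u) * direction * speed, 0.0)


def neuron_rate(model: NeuronModel, u, wall_velocity=0.0, v=0.0) -> np.ndarray:
    """Functional form of :meth:`NeuronModel.rate`."""
    return model.rate(u, wall_velocity, v)


def rate_from_behavior(model: NeuronModel, behavior: pd.DataFrame) -> np.ndarray:
    """Evaluate the model's rate along a behavior time series.

    The driving wall is chosen by the model's laterality: ``contra`` uses
    ``u_right``, ``ipsi`` uses ``u_left`` and ``both`` the nearer wall.
    """
    if model.laterality == "contra":
        u = behavior["u_right"].to_numpy()
        wv = behavior["wall_velocity"].to_numpy()
    elif model.laterality == "ipsi":
        u = behavior["u_left"].to_numpy()
        dt = float(behavior["t"].iloc[1] - behavior["t"].iloc[0])
        wv = np.gradient(u, dt)
    else:
        u_l = behavior["u_left"].to_numpy()
        u_r = behavior["u_right"].to_numpy()
        u = np.minimum(u_l, u_r)
        dt = float(behavior["t"].iloc[1] - behavior["t"].iloc[0])
        wv = np.gradient(u, dt)
    return model.rate(u, wv, behavior["v"].to_numpy())


def generate_spikes(
    rate: np.ndarray,
    dt: float,
    seed: int | np.random.Generator = 0,
    t0: float = 0.0,
) -> np.ndarray:
    """Inhomogeneous Poisson spike times from a rate series (Hz).

    Per clock bin the spike count is Poisson(rate * dt) with spike times
    uniform within the bin; reproducible given the seed. Warns when
    ``rate * dt`` exceeds 1 anywhere (a finer clock is advisable).
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be >= 0")
    lam = rate * dt
    if lam.size and lam.max() > 1.0:
        warnings.warn(
            f"rate*dt reaches {lam.max():.2f} > 1; consider a finer clock",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = rng.poisson(lam)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    starts = t0 + np.repeat(np.arange(lam.size) * dt, counts)
    times = starts + rng.random(total) * dt
    return np.sort(times)


@dataclass(frozen=True)
class UnitRecording:
    """Spike times plus metadata for one sorted unit.

    Depth is in micrometers relative to the middle of layer 4. The spike
    width class (``regular`` > 450 us, ``fast`` < 350 us, else
    ``intermediate``) is carried as metadata only.
    """

    spike_times: np.ndarray
    unit_id: int = 0
    depth_um: float = 0.0
    spike_width_class: str = "regular"
    laterality: str = "contra"

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        if st.size and (np.any(np.diff(st) < 0) or st[0] < 0):
            raise ValueError("spike times must be sorted and non-negative")
        object.__setattr__(self, "spike_times", st)


def save_spikes(units: list[UnitRecording], path) -> None:
    """Write spikes of a unit list as a long CSV (unit_id, t, metadata)."""
    rows = []
    for u in units:
        rows.append(
            pd.DataFrame(
                {
                    "unit_id": u.unit_id,
                    "t": u.spike_times,
                    "depth_um": u.depth_um,
                    "spike_width_class": u.spike_width_class,
                    "laterality": u.laterality,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def load_spikes(path) -> list[UnitRecording]:
    """Read a spikes CSV written by :func:`save_spikes`."""
    df = pd.read_csv(path)
    units = []
    for uid, grp in df.groupby("unit_id", sort=True):
        units.append(
            UnitRecording(
                spike_times=np.sort(grp["t"].to_numpy()),
                unit_id=int(uid),
                depth_um=float(grp["depth_um"].iloc[0]),
                spike_width_class=str(grp["spike_width_class"].iloc[0]),
                laterality=str(grp["laterality"].iloc[0]),
            )
        )
    return units


# ---------------------------------------------------------------------------
# Calcium forward model


@dataclass(frozen=True)
class CalciumKernelParams:
    """GCaMP6s-like impulse response parameters.

    The kernel is a difference of exponentials
    ``(1 - exp(-t/tau_r)) * exp(-t/tau_d)`` normalized so an isolated
    spike peaks at ``amplitude`` dF/F, with the decay constant solved
    numerically so the post-peak half-decay equals ``half_decay_ms``.
    """

    rise_ms: float = 200.0
    half_decay_ms: float = 600.0
    amplitude: float = 0.3
    baseline_f: float = 100.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rise_ms", "half_decay_ms", "amplitude", "baseline_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _kernel_shape(t: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    return (1.0 - np.exp(-t / tau_r)) * np.exp(-t / tau_d)


def _solve_decay(tau_r: float, half_decay: float) -> tuple[float, float]:
    """Decay constant and peak time so the post-peak half-decay is as requested."""

    def peak_time(tau_d: float) -> float:
        return tau_r * np.log(1.0 + tau_d / tau_r)

    def half_decay_of(tau_d: float) -> float:
        tp = peak_time(tau_d)
        peak = _kernel_shape(np.array([tp]), tau_r, tau_d)[0]

        def f(t):
            return _kernel_shape(np.array([t]), tau_r, tau_d)[0] - 0.5 * peak

        return brentq(f, tp, tp + 50.0 * tau_d) - tp

    def g(tau_d: float) -> float:
        return half_decay_of(tau_d) - half_decay

    tau_d = brentq(g, half_decay * 0.2, half_decay * 10.0)
    return tau_d, peak_time(tau_d)


def calcium_kernel(params: CalciumKernelParams, dt: float) -> np.ndarray:
    """Sampled single-spike dF/F kernel on a clock of step ``dt`` seconds."""
    tau_r = params.rise_ms / 1000.0
    tau_d, tp = _solve_decay(tau_r, params.half_decay_ms / 1000.0)
    # extend until the tail is negligible relative to the peak
    t_end = tp + 12.0 * tau_d
    t = np.arange(0.0, t_end, dt)
    shape = _kernel_shape(t, tau_r, tau_d)
    return params.amplitude * shape / shape.max()


def spikes_to_dff(
    spike_times: np.ndarray,
    params: CalciumKernelParams,
    t: np.ndarray,
) -> np.ndarray:
    """Linear calcium forward model: dF/F trace on clock ``t`` from spikes.

    Each spike adds one amplitude-normalized kernel; responses superpose
    linearly. ``t`` must be uniform with step well below the rise time.
    """
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        raise ValueError("clock must have at least 2 samples")
    dt = t[1] - t[0]
    spike_times = np.asarray(spike_times, dtype=float)
    edges = np.concatenate([t, [t[-1] + dt]])
    counts, _ = np.histogram(spike_times, bins=edges)
    if counts.sum() == 0:
        return np.zeros_like(t)
    kernel = calcium_kernel(params, dt)
    return fftconvolve(counts.astype(float), kernel)[: t.size]


def rate_to_dff(
    rate: np.ndarray, params: CalciumKernelParams, dt: float
) -> np.ndarray:
    """Expected (noise-free) dF/F given a rate series: kernel * (rate*dt)."""
    rate = np.asarray(rate, dtype=float)
    kernel = calcium_kernel(params, dt)
    return fftconvolve(rate * dt, kernel)[: rate.size]


# ---------------------------------------------------------------------------
# Movie rendering


@dataclass
class CalciumMovie:
    """T x H x W fluorescence stack with frame times and ground truth.

    ``ground_truth`` (synthetic movies only) holds the ROI masks, the
    injected per-ROI dF/F traces and spike times, the per-frame rigid
    shifts applied, and the neuropil trace/profile.
    """

    stack: np.ndarray
    frame_times: np.ndarray
    plane_id: int = 0
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.stack)):
            raise ValueError("movie intensities must be finite")


def render_movie(
    roi_masks: list[np.ndarray],
    roi_dff: np.ndarray,
    neuropil_dff: np.ndarray,
    neuropil_profile: np.ndarray,
    shifts: np.ndarray,
    params: CalciumKernelParams,
    frame_rate: float = 7.0,
    seed: int | np.random.Generator = 0,
    roi_spikes: list[np.ndarray] | None = None,
    baseline_image: np.ndarray | None = None,
) -> CalciumMovie:
    """Render a synthetic movie of fluorescent somata.

    Pixel intensity before shifting is
    ``F_b * (1 + sum_i roi_dff[i] * mask_i + neuropil_dff * profile)``
    where ``F_b`` is either the scalar ``params.baseline_f`` or the
    ``baseline_image`` pattern (textured backgrounds make the rigid
    drift observable, as real vasculature and neuropil do); each frame
    is then rolled rigidly by its integer ``(dy, dx)`` shift and
    Gaussian noise of SD ``params.noise_sd`` is added. Shifts use
    circular boundary conditions, and an error is raised if any ROI's
    bounding box would cross the frame edge under the largest shift.
    All inputs are stored as ground truth on the returned movie.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shifts = np.asarray(shifts, dtype=int)
    roi_dff = np.asarray(roi_dff, dtype=float)
    neuropil_dff = np.asarray(neuropil_dff, dtype=float)
    n_frames = roi_dff.shape[1] if roi_dff.size else neuropil_dff.size
    if shifts.shape != (n_frames, 2):
        raise ValueError(f"shifts must have shape ({n_frames}, 2)")
    shape = neuropil_profile.shape
    max_dy = int(np.max(np.abs(shifts[:, 0]), initial=0))
    max_dx = int(np.max(np.abs(shifts[:, 1]), initial=0))
    for i, mask in enumerate(roi_masks):
        if mask.shape != shape:
            raise ValueError("ROI mask shape mismatch")
        ys, xs = np.nonzero(mask)
        if ys.size == 0:
            raise ValueError(f"ROI {i} mask is empty")
        if (
            ys.min() - max_dy < 0
            or ys.max() + max_dy >= shape[0]
            or xs.min() - max_dx < 0
            or xs.max() + max_dx >= shape[1]
        ):
            raise ValueError(f"shift pushes ROI {i} out of frame")

    stack = np.empty((n_frames,) + shape, dtype=np.float32)
    base = 1.0 + neuropil_dff[:, None] * neuropil_profile.ravel()[None, :]
    stack_flat = stack.reshape(n_frames, -1)
    stack_flat[:] = base
    for mask, trace in zip(roi_masks, roi_dff):
        idx = np.flatnonzero(mask.ravel())
        stack_flat[:, idx] += trace[:, None]
    if baseline_image is not None:
        if baseline_image.shape != shape:
            raise ValueError("baseline_image shape mismatch")
        if np.any(baseline_image <= 0):
            raise ValueError("baseline_image must be positive")
        stack_flat *= baseline_image.ravel()[None, :]
    else:
        stack *= params.baseline_f
    for i in range(n_frames):
        dy, dx = shifts[i]
        if dy or dx:
            stack[i] = np.roll(stack[i], (dy, dx), axis=(0, 1))
    if params.noise_sd > 0:
        stack += rng.normal(0.0, params.noise_sd, stack.shape).astype(np.float32)
    frame_times = np.arange(n_frames) / frame_rate
    gt = {
        "roi_masks": [m.copy() for m in roi_masks],
        "roi_dff": roi_dff.copy(),
        "neuropil_dff": neuropil_dff.copy(),
        "neuropil_profile": neuropil_profile.copy(),
        "shifts": shifts.copy(),
        "baseline_image": (
            baseline_image.copy()
            if baseline_image is not None
            else np.full(shape, params.baseline_f)
        ),
    }
    if roi_spikes is not None:
        gt["roi_spikes"] = [np.asarray(s, dtype=float) for s in roi_spikes]
    return CalciumMovie(stack=stack, frame_times=frame_times, ground_truth=gt)


def save_movie(movie: CalciumMovie, tiff_path, sidecar_path=None) -> None:
    """Write the stack as multi-frame TIFF plus an HDF5 ground-truth sidecar."""
    import tifffile

    tifffile.imwrite(str(tiff_path), movie.stack)
    if sidecar_path is not None:
        import h5py

        with h5py.File(str(sidecar_path), "w") as f:
            f.create_dataset("frame_times", data=movie.frame_times)
            f.attrs["plane_id"] = movie.plane_id
            gt = f.create_group("ground_truth")
            for key, val in movie.ground_truth.items():
                if isinstance(val, list):
                    g = gt.create_group(key)
                    for i, item in enumerate(val):
                        g.create_dataset(str(i), data=item)
                else:
                    gt.create_dataset(key, data=val)


def load_movie(tiff_path, sidecar_path=None) -> CalciumMovie:
    """Read a movie written by :func:`save_movie`."""
    import tifffile

    stack = tifffile.imread(str(tiff_path))
    frame_times = np.arange(stack.shape[0], dtype=float)
    plane_id = 0
    gt: dict = {}
    if sidecar_path is not None:
        import h5py

        with h5py.File(str(sidecar_path), "r") as f:
            frame_times = f["frame_times"][()]
            plane_id = int(f.attrs["plane_id"])
            for key, val in f["ground_truth"].items():
                if isinstance(val, h5py.Group):
                    gt[key] = [val[str(i)][()] for i in range(len(val))]
                else:
                    gt[key] = val[()]
    return CalciumMovie(stack=stack, frame_times=frame_times, plane_id=plane_id, ground_truth=gt)


def make_roi_grid(
    shape: tuple[int, int],
    n_rois: int,
    radius: int = 3,
    margin: int = 12,
    jitter: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Labeled image of disk-shaped somata on a jittered grid.

    ROIs are placed row-major on a grid leaving ``margin`` pixels at the
    frame border (so annuli and modest rigid shifts stay in frame), with
    each center displaced by up to ``jitter`` pixels so the layout is not
    periodic (a perfect lattice would make rigid registration ambiguous,
    and real somata are not on a grid). Raises if the frame cannot hold
    ``n_rois`` non-overlapping disks.
    """
    H, W = shape
    spacing = 2 * (radius + jitter) + 4
    ys = np.arange(margin, H - margin + 1, spacing)
    xs = np.arange(margin, W - margin + 1, spacing)
    if ys.size * xs.size < n_rois:
        raise ValueError(f"frame {shape} too small for {n_rois} ROIs")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=int)
    yy, xx = np.mgrid[0:H, 0:W]
    k = 0
    for cy in ys:
        for cx in xs:
            if k >= n_rois:
                return labels
            k += 1
            jy, jx = rng.integers(-jitter, jitter + 1, size=2)
            labels[(yy - cy - jy) ** 2 + (xx - cx - jx) ** 2 <= radius**2] = k
    return labels


# ---------------------------------------------------------------------------
# Populations


@dataclass(frozen=True)
class PopulationSpec:
    """Counts per tuning family and parameter ranges for a population.

    Preferred distances are drawn from ``preferred_range`` with a bias
    toward small distances (Beta(1.2, 2) over the range), emulating the
    over-representation of near wall distances in the recorded maps while
    still tiling the reachable space.
    """

    counts: dict = field(
        default_factory=lambda: {
            "monotonic_decreasing": 10,
            "monotonic_increasing": 5,
            "unimodal": 20,
            "multimodal": 5,
            "untuned": 10,
        }
    )
    baseline_range: tuple[float, float] = (1.0, 5.0)
    amplitude_range: tuple[float, float] = (5.0, 20.0)
    preferred_range: tuple[float, float] = (4.0, 50.0)
    width_range: tuple[float, float] = (3.0, 8.0)
    direction_gain_range: tuple[float, float] = (1.0, 1.0)
    speed_slope_range: tuple[float, float] = (0.0, 0.0)
    laterality: str = "contra"


def make_population(spec: PopulationSpec, seed: int = 0) -> list[NeuronModel]:
    """Draw a reproducible population of :class:`NeuronModel` from a spec."""
    rng = np.random.default_rng(seed)

    def draw_preferred() -> float:
        lo, hi = spec.preferred_range
        return float(lo + (hi - lo) * rng.beta(1.2, 2.0))

    def uniform(rng_range) -> float:
        lo, hi = rng_range
        return float(lo) if lo == hi else float(rng.uniform(lo, hi))

    models = []
    for kind in TUNING_KINDS:
        for _ in range(int(spec.counts.get(kind, 0))):
            if kind == "multimodal":
                n_peaks = 2
                amplitude = tuple(uniform(spec.amplitude_range) for _ in range(n_peaks))
                preferred = tuple(sorted(draw_preferred() for _ in range(n_peaks)))
                width = tuple(uniform(spec.width_range) for _ in range(n_peaks))
            else:
                amplitude = uniform(spec.amplitude_range)
                preferred = draw_preferred()
                width = uniform(spec.width_range)
            models.append(
                NeuronModel(
                    kind=kind,
                    baseline=uniform(spec.baseline_range),
                    amplitude=amplitude,
                    preferred=preferred,
                    width=width,
                    direction_gain=uniform(spec.direction_gain_range),
                    speed_slope=uniform(spec.speed_slope_range),
                    laterality=spec.laterality,
                )
            )
    return models
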