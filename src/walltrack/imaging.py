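"""Two-photon calcium imaging analysis.

Rigid motion correction (integer shifts from the peak of an FFT-based
cross-correlation), ROI and neuropil-annulus trace extraction, dF/F with
a 20th-percentile 160-s rolling baseline, neuropil subtraction, pixelwise
wall-distance regression maps (preferred distance + r^2 per pixel), the
inactive / active / tuned ROI classification, and spline smoothing of
tuning curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.ndimage import distance_transform_edt
from skimage.registration import phase_cross_correlation

from .ephys import TuningCurve

logger = logging.getLogger(__name__)


@dataclass
class FluoTrace:
    """Raw fluorescence, rolling baseline and dF/F for one ROI."""

    F: np.ndarray
    F0: np.ndarray
    dff: np.ndarray
    frame_times: np.ndarray


@dataclass
class RoiSet:
    """Per-ROI pixel masks and neuropil annulus masks.

    Each annulus covers pixels 3-8 px (configurable) outside the ROI
    boundary and excludes the pixels of every ROI, so somatic and
    neuropil masks are disjoint.
    """

    masks: list[np.ndarray]
    annuli: list[np.ndarray]
    labels: list[str]

    @classmethod
    def from_labels(
        cls, label_img: np.ndarray, annulus_inner: int = 3, annulus_outer: int = 8
    ) -> "RoiSet":
        """Build masks and annuli from a labeled image (0 = background)."""
        label_img = np.asarray(label_img)
        ids = np.unique(label_img)
        ids = ids[ids > 0]
        any_roi = label_img > 0
        masks, annuli, labels = [], [], []
        for i in ids:
            mask = label_img == i
            dist = distance_transform_edt(~mask)
            annulus = (dist >= annulus_inner) & (dist <= annulus_outer) & ~any_roi
            masks.append(mask)
            annuli.append(annulus)
            labels.append(str(i))
        return cls(masks=masks, annuli=annuli, labels=labels)

    def __len__(self) -> int:
        return len(self.masks)


@dataclass
class PixelwiseMap:
    """Per-pixel preferred wall distance (mm) and regression r^2."""

    preferred: np.ndarray
    r2: np.ndarray
    bin_centers: np.ndarray


@dataclass(frozen=True)
class RoiClassification:
    """inactive / active_untuned / tuned status of one ROI.

    tuned: ANOVA p < alpha and tuning-curve range > range_threshold
    (dF/F). active: 90th percentile of dF/F > active_threshold. The
    tuned rule takes precedence.
    """

    status: str
    p_value: float
    tuning_range: float
    q90: float


def register_movie(
    stack: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid registration by integer shifts from FFT cross-correlation.

    Returns ``(motions, corrected)`` where ``motions[i] = (dy, dx)`` is
    the estimated displacement of frame ``i`` relative to the reference
    (the shift that was applied to the underlying scene) and
    ``corrected`` has each frame rolled back by its motion. The reference
    defaults to the mean frame. All-zero frames get motion (0, 0) with a
    warning.
    """
    stack = np.asarray(stack)
    if reference is None:
        reference = stack.mean(axis=0)
    if reference.shape != stack.shape[1:]:
        raise ValueError("reference shape must match frame shape")
    n = stack.shape[0]
    motions = np.zeros((n, 2), dtype=int)
    corrected = np.empty_like(stack)
    for i in range(n):
        frame = stack[i]
        if not np.any(frame):
            warnings.warn(f"frame {i} is all zero; assuming no motion", stacklevel=2)
            corrected[i] = frame
            continue
        shift, _, _ = phase_cross_correlation(
            reference, frame, upsample_factor=1, normalization=None
        )
        # phase_cross_correlation returns the shift registering the frame
        # onto the reference; the scene motion is its negation.
        motion = -np.round(shift).astype(int)
        motions[i] = motion
        corrected[i] = np.roll(frame, (-motion[0], -motion[1]), axis=(0, 1))
    return motions, corrected


def rolling_baseline(
    F: np.ndarray,
    frame_rate: float,
    window_s: float = 160.0,
    percentile: float = 20.0,
) -> np.ndarray:
    """Rolling-percentile baseline F0: per-frame percentile of a centered window.

    The window is ``window_s`` seconds wide (truncated at the session
    edges). Raises if the resulting baseline is not strictly positive
    anywhere, since dF/F would be undefined.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 1 or F.size < 2:
        raise ValueError("F must be a 1-D trace with at least 2 frames")
    half = max(1, int(round(window_s * frame_rate / 2.0)))
    T = F.size
    F0 = np.empty(T)
    for i in range(T):
        lo = max(0, i - half)
        hi = min(T, i + half + 1)
        F0[i] = np.percentile(F[lo:hi], percentile)
    if np.any(F0 <= 0):
        raise ValueError("rolling baseline is non-positive; dF/F undefined")
    return F0


def dff(F: np.ndarray, F0: np.ndarray) -> np.ndarray:
    """Fractional fluorescence change (F - F0) / F0."""
    F = np.asarray(F, dtype=float)
    F0 = np.asarray(F0, dtype=float)
    if np.any(F0 <= 0):
        raise ValueError("F0 must be strictly positive")
    return (F - F0) / F0


def extract_roi_traces(
    stack: np.ndarray, rois: RoiSet
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-intensity traces over each ROI mask and its neuropil annulus.

    Returns ``(roi_F, annulus_F)`` of shape (n_rois, n_frames).
    """
    stack = np.asarray(stack)
    flat = stack.reshape(stack.shape[0], -1)
    roi_F = np.empty((len(rois), stack.shape[0]))
    ann_F = np.empty_like(roi_F)
    for k, (mask, annulus) in enumerate(zip(rois.masks, rois.annuli)):
        for out, m, name in ((roi_F, mask, "ROI"), (ann_F, annulus, "annulus")):
            idx = np.flatnonzero(m.ravel())
            if idx.size == 0:
                raise ValueError(f"{name} mask {k} is empty")
            out[k] = flat[:, idx].mean(axis=1)
    return roi_F, ann_F


def neuropil_correct(
    roi_dff: np.ndarray, annulus_dff: np.ndarray, coefficient: float = 1.0
) -> np.ndarray:
    """Corrected dF/F: ROI dF/F minus ``coefficient`` times the annulus dF/F."""
    roi_dff = np.asarray(roi_dff, dtype=float)
    annulus_dff = np.asarray(annulus_dff, dtype=float)
    if roi_dff.shape != annulus_dff.shape:
        raise ValueError("traces must have the same shape")
    return roi_dff - coefficient * annulus_dff


def downsample_to_frames(
    values: np.ndarray, t: np.ndarray, frame_times: np.ndarray, frame_rate: float
) -> np.ndarray:
    """Behavior series resampled to the imaging frame clock by within-frame mean.

    Frames with no behavior samples get NaN.
    """
    values = np.asarray(values, dtype=float)
    t = np.asarray(t, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    edges = np.concatenate([frame_times, [frame_times[-1] + 1.0 / frame_rate]])
    idx = np.searchsorted(edges, t, side="right") - 1
    valid = (idx >= 0) & (idx < frame_times.size)
    sums = np.bincount(idx[valid], weights=values[valid], minlength=frame_times.size)
    counts = np.bincount(idx[valid], minlength=frame_times.size)
    with np.errstate(invalid="ignore"):
        return sums / counts


def pixelwise_map(
    stack: np.ndarray,
    u_frames: np.ndarray,
    frame_mask: np.ndarray,
    bin_width: float = 3.0,
) -> PixelwiseMap:
    """Per-pixel wall-distance regression map.

    Each pixel's time series (on frames selected by ``frame_mask``,
    typically open-loop running frames) is regressed on an indicator
    basis of ``bin_width``-mm wall-distance bins, i.e. fitted by per-bin
    means. The preferred distance is the bin with the maximum fitted
    response and r^2 = 1 - SS_res/SS_tot (0 for constant pixels).
    """
    stack = np.asarray(stack)
    u_frames = np.asarray(u_frames, dtype=float)
    frame_mask = np.asarray(frame_mask, bool) & ~np.isnan(u_frames)
    if frame_mask.sum() < 2:
        raise ValueError("fewer than 2 usable frames")
    X = stack[frame_mask].reshape(frame_mask.sum(), -1).astype(float)
    u = u_frames[frame_mask]
    bins = np.floor(u / bin_width).astype(int)
    uniq = np.unique(bins)
    if uniq.size < 2:
        raise ValueError("fewer than 2 occupied wall-distance bins")
    bin_idx = np.searchsorted(uniq, bins)
    n_bins = uniq.size
    counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
    means = np.zeros((n_bins, X.shape[1]))
    np.add.at(means, bin_idx, X)
    means /= counts[:, None]
    pred = means[bin_idx]
    ss_res = ((X - pred) ** 2).sum(axis=0)
    ss_tot = ((X - X.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    centers = (uniq + 0.5) * bin_width
    preferred = centers[np.argmax(means, axis=0)]
    H, W = stack.shape[1:]
    return PixelwiseMap(
        preferred=preferred.reshape(H, W),
        r2=np.clip(r2, 0.0, 1.0).reshape(H, W),
        bin_centers=centers,
    )


def classify_roi(
    corrected_dff: np.ndarray,
    curve: TuningCurve,
    p_value: float,
    alpha: float = 0.05,
    range_threshold: float = 0.3,
    active_threshold: float = 1.0,
) -> RoiClassification:
    """Inactive / active-untuned / tuned classification of one ROI.

    tuned: ANOVA p below ``alpha`` and tuning-curve range above
    ``range_threshold`` dF/F (takes precedence). active: 90th percentile
    of the corrected dF/F above ``active_threshold``. Otherwise inactive.
    """
    q90 = float(np.quantile(np.asarray(corrected_dff, float), 0.9))
    rng = curve.range
    if p_value < alpha and rng > range_threshold:
        status = "tuned"
    elif q90 > active_threshold:
        status = "active_untuned"
    else:
        status = "inactive"
    return RoiClassification(status=status, p_value=float(p_value), tuning_range=rng, q90=q90)


def smooth_tuning(curve: TuningCurve, smoothing: float = 1.0) -> TuningCurve:
    """Smooth a tuning curve with a univariate smoothing spline.

    The spline is fit to the defined bins, weighted by 1/SE when SEs are
    available and positive, and evaluated back at the bin centers; the
    smoothing factor bounds the weighted residual sum of squares. Curves
    with fewer than 4 defined bins are returned unchanged with a warning.
    """
    d = curve.defined
    if d.sum() < 4:
        warnings.warn("fewer than 4 defined bins; returning curve unchanged", stacklevel=2)
        return curve
    x = curve.bin_centers[d]
    y = curve.mean[d]
    se = curve.se[d]
    w = 1.0 / se if np.all(se > 0) else None
    spline = UnivariateSpline(x, y, w=w, s=smoothing, k=3)
    mean = curve.mean.copy()
    mean[d] = spline(x)
    return replace(curve, mean=mean)
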