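# Methods

This note documents the models behind `walltrack`, the choices made where
the design was genuinely open, and what the synthetic-data validation does
and does not establish about real recordings.

## Closed-loop corridor model

The virtual corridor couples wall position to locomotion:
Δu = γ·v·sin(ε)·Δt with ε = ϕ − ψ. Speeds are in cm/s and wall distances
in mm, so the update is converted by a factor of 10; angles are degrees at
every interface and radians only inside the sine. The integration step
defaults to **Δt = 2 ms**, chosen so the behavior clock coincides with the
2-ms spike binning used by the analyses and no resampling is needed
between them. The update is first-order consistent: halving Δt converges
to the same trajectory (checked in the tests).

Geometry: corridor halfwidth 19 mm (snout-to-wall when centered), walls
clamped to approach no closer than 4 mm, trials 200 cm long. A single
lateral-offset state drives both walls, so
`u_left + u_right = 2 × halfwidth` holds at every step by construction;
clamp events are logged. Whether a real rig moves one or both walls at a
bend is not observable from these analyses, so width conservation was
adopted as the simplest consistent convention.

**Tracking policies** stand in for the animal, which in the experiments
*is* the controller. `ideal` sets ϕ = ψ (zero angle error, used for
fixtures where the stimulus, not the behavior, is under study);
`proportional` steers against the sensed wall-distance asymmetry,
ϕ = k·(u_right − u_left) (deg/mm) — a pure proportional controller with
the expected steady-state offset; `noisy` adds an angular random walk with
increment SD σ·√Δt (σ in deg/√s). These are explicitly synthetic: nothing
about whisking, reward, or motor dynamics is modeled.

**Open-loop trials** move the contralateral wall on a fixed schedule
regardless of locomotion: ramp in, hold at the trial's distance, ramp out,
returning to the centered 19-mm position. Defaults are 1/2/1 s (the 4-s
extracellular-recording structure; the sources state 4 s with 1-s in and
1-s out, and the hold duration follows by subtraction) or 2/4/2 s for the
imaging structure; both are configurable. Hold distances in the default
session tile 4–34 mm, so far-hold trials (> 30 mm) supply the
out-of-reach baseline epochs.

Behavioral metrics: **angle error** |ϕ − ψ| evaluated at the final sample
of the turn (the evaluation point is stated only as "end of the turn", so
the last sample is used); **wall-distance bias**, the mean end-of-trial
wall distance on stimulated trials minus the mean wall distance across
unstimulated trials; the **running mask**, strictly v > 3 cm/s; and the
**illusory-corridor power law**, linear from 0 mW at the center to 4.5 mW
at the edge, driving only the hemisphere opposite the offset.

## Neural forward models

Rates factorize as `tuning(u) × direction × speed`, floored at zero.
Tuning families: sigmoid (logistic in u) for monotonic units — increasing
rate as the wall approaches, or suppression from a high baseline — a
Gaussian bump for unimodal units, a sum of two Gaussians for multimodal
units, and a constant for untuned units. All families return exactly the
baseline when the wall is out of reach. Defaults: baselines 1–5 Hz,
amplitudes 5–20 Hz, tuning widths 3–8 mm, preferred distances drawn from
4–50 mm with a Beta(1.2, 2) bias toward small distances so the population
tiles the whisker's reach with the observed over-representation of near
walls. Direction sensitivity is a multiplicative gain applied while the
wall moves toward the animal (wall velocity < 0, dead band at zero);
speed sensitivity is a linear multiplicative factor 1 + slope·v.

**Spikes** are an inhomogeneous Poisson process realized per clock bin
(count ~ Poisson(rate·Δt), times uniform within the bin), seeded. A
warning is issued if rate·Δt exceeds 1.

**Calcium kernel.** ΔF/F is modeled as a linear, time-invariant
superposition of single-spike kernels
`A·(1 − e^(−t/τ_r))·e^(−t/τ_d)` with τ_r = 200 ms rise. No functional
form is prescribed by the indicator's published rise/half-decay numbers,
so the decay constant is solved numerically (Brent's method) such that the
kernel falls to half its peak exactly 600 ms after the peak, and A is set
so an isolated spike peaks at 0.3 ΔF/F. Saturation and nonlinearity of
the indicator are deliberately not modeled.

**Movies.** Pixel intensity is
`F_b(x,y)·(1 + Σ_i roiΔF/F_i·mask_i + neuropilΔF/F·profile)`, rigidly
rolled by per-frame integer shifts, plus optional Gaussian noise. Two
fixture-design points matter for registration realism: ROI centers are
jittered off the layout grid (a perfectly periodic grid of somata makes
cross-correlation ambiguous at lattice offsets), and the static background
`F_b(x,y)` should be textured — ~20–30 % speckle contrast, standing in
for vasculature and stationary neuropil structure — because a spatially
flat background leaves rigid motion unobservable. Default synthetic scale
is 64–128 px frames at 7 Hz, a desk-scale stand-in for 512×512 three-plane
acquisition; per-plane frame rate is config (the sources quote both 7.1
and 7.8 Hz and the package takes no position).

## Spike-train analyses

Tuning curves: per trial, the mean response inside 3-mm wall-distance bins
(bins on a fixed grid anchored at 0); curves average these per-trial
curves (mean ± SE) over trials whose mean run speed exceeds 3 cm/s, with a
sample-level running mask applied as well. Bins entered by fewer than 3
qualifying trials are dropped — the minimum is a package choice, exposed
in config. The same machinery serves spikes (2-ms binned rates) and ΔF/F.

**Tuning significance** is a one-way ANOVA across distance bins with
trials as replicates, computed as **Welch's heteroscedasticity-robust
ANOVA**. The reason is structural: a trial's bin mean is far more precise
in the bin it holds in (~2 s of samples) than in bins it merely ramps
through (~0.1 s), so group variances are strongly unequal, with larger
variances in the larger groups. Under that structure the classical
equal-variance F test is markedly conservative (measured false-positive
rate ≈ 0.02 at α = 0.05 on untuned units), while Welch's variant sits at
the nominal level (≈ 0.05; verified on 1000 simulated untuned units in the
acceptance tests). Degenerate inputs use p = 1 (no variance anywhere) or
p = 0 (separated constant groups) by convention.

**Baseline** is the mean response during running with the contralateral
wall out of reach, defaulting to u > 30 mm — the sources give no number
beyond "out of reach of the whiskers", and whisker reach exceeds the
19-mm centered distance; the threshold is config. Activation = peak −
baseline, suppression = baseline − minimum, modulation =
(act − sup)/(act + sup). The summary reports the raw signed activation
and suppression, but the index floors both at zero, which keeps it in
[−1, 1] when sampling noise places the whole measured curve above (or
below) baseline and reproduces the published limits: purely activated
units score 1, purely suppressed −1, mixed near 0. When act + sup = 0 the
index is undefined and reported missing; the same missing-value convention
applies to every ratio index below.

**Direction tuning**: towards/away epochs come from the sign of the
discrete contralateral wall velocity with a ±1 mm/s dead band (minimum
epoch duration 0.2 s). Rate profiles are trial-averaged over a 1-s window
from movement onset and rebinned to 50 ms before taking the range
(max − min): at desk-scale trial counts the raw 2-ms trial average is
still effectively a raster whose range is a single-bin artifact. Window
and profile-bin widths are parameters. Index: (towards range − away
range)/(sum).

**Laterality** compares tuning-curve ranges to the contralateral and
ipsilateral wall: (contra − ipsi)/(sum). **Open vs closed loop** compares
mean rates restricted to the wall-distance range sampled in both
conditions: (open − closed)/(sum). **Speed**: trials are split at the
median of per-trial mean speeds among running trials; the gain g mapping
the slow curve onto the fast one is the closed-form least-squares scalar
⟨fast, slow⟩/⟨slow, slow⟩ over shared bins, and the index is ln g
(natural log; the base is a package choice). Speed tuning itself bins
per-trial mean rates during out-of-reach epochs by speed and applies the
same Welch ANOVA.

## Imaging pipeline

Rigid registration estimates one integer (dy, dx) per frame from the peak
of an FFT-based cross-correlation against a reference image (default: the
mean frame; fixtures with known ground truth pass an explicit reference).
No subpixel or nonrigid correction is attempted. All-zero frames get zero
motion with a warning.

ΔF/F = (F − F0)/F0 with F0 the 20th percentile of F in a 160-s rolling
window, centered and truncated at the session edges (alignment is a
package choice; the sources do not state it). The pipeline is invariant
to any positive gain on F. Neuropil ΔF/F is computed identically in an
annulus 3–8 px outside the ROI boundary (excluding all ROI pixels) and
subtracted with coefficient 1.0 (no coefficient is stated; it is config).
The percentile baseline presumes sparse activity — for somata active most
of the session the estimated F0 rides up and baseline-relative responses
are distorted; this is a property of the method, not of the
implementation.

The pixelwise map regresses each pixel's time series (open-loop running
frames; behavior downsampled to the frame clock by within-frame means) on
an indicator basis of 3-mm distance bins — equivalently per-bin means.
An indicator basis rather than a single linear term was chosen because
the published maps are non-monotonic in preferred distance; whether the
original analysis used the same basis is not asserted. Preferred distance
is the bin of maximum fitted response; r² = 1 − SS_res/SS_tot, defined as
0 for constant pixels.

Classification: **tuned** if ANOVA p < 0.05 *and* tuning-curve range
> 0.3 ΔF/F (tuned takes precedence); otherwise **active** if the 90th
percentile of the corrected ΔF/F exceeds 1.0; otherwise **inactive**. The
corrected (neuropil-subtracted) ΔF/F is the working signal throughout,
including for the active criterion.

Curve smoothing uses a cubic univariate smoothing spline evaluated at the
bin centers, weighted by 1/SE when SEs are available, with smoothing
factor 1.0 by default. Spline smoothing factors are ecosystem-specific,
so numerical equivalence with any other stack is not claimed; the default
leaves flat curves untouched and perturbs smooth curves by less than one
SE per bin. Curves with fewer than 4 defined bins are returned unchanged
with a warning.

ROI masks are inputs (drawn manually in the original workflow); the
package only constructs them for synthetic ground truth. Automated
segmentation and spike inference are out of scope.

## Session workflow and validation scales

`run_pipeline` chains behavior → spikes → analyses → (optional) imaging →
report, with named seeds for each stage; fixed seeds reproduce every
output byte-for-byte. The default synthetic session uses 30 open-loop
trials (holds tiling 4–34 mm) plus 6 closed-loop bends, populations of a
few dozen units, and a 64×64, ~9-ROI movie — sizes chosen so the full
suite runs comfortably on a laptop-class single core. Validation runs use
50 units for tuning-peak recovery, 1000 untuned units for ANOVA
calibration, and a 128×128 × ~2000-frame noiseless movie with 20 ROIs for
registration and end-to-end classification.

What the synthetic validation shows: the analyses recover known tuning
parameters, the index family attains its defining limits, the significance
test is calibrated under the simulated trial structure, and the imaging
pipeline is internally consistent down to exact shift recovery. What it
does not show: robustness to the things the generator omits — whisking
dynamics, nonstationary baselines, indicator nonlinearity, non-rigid
motion, overlapping or drifting ROIs, correlated population noise — so
agreement here does not by itself certify performance on real recordings,
and the headline population fractions of any real dataset are not
reproduced by construction.
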