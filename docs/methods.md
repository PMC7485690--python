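# Methods

## The measurement being modelled

Slimfield single-molecule tracking of fluorescent-protein fusions in
rod-shaped bacteria: cells are bleached down until one or two emitters remain
visible, then streamed at 7.4–30 ms per frame (1,500 frames, 106-nm pixels).
Localizations are linked into trajectories; the pooled single-frame
displacements, confinement episodes, FRAP recovery traces and focus positions
carry the biology — how chromosome-organizing proteins partition between
mobile and DNA-bound states, how long they stay bound, and where they sit in
the cell.

Because raw data of this kind are not deposited, the package treats the
published summary values as *generating* parameters: the synthetic module
produces data with exactly the statistical structure the analyses assume, and
the test suite requires each analysis stage to recover the generating values.
A passing suite therefore demonstrates estimator correctness and
identifiability at realistic sample sizes — not the correctness of the
original measurements.

## Simulation model

Molecules perform 2D Brownian motion (the image plane; all downstream
analyses use 2D localizations) inside a stadium-shaped cell outline — the
projection of a spherocylinder of pole-to-pole length L and radius R
(defaults 3.0 and 0.45 µm; the radius is a conventional *B. subtilis* value,
exposed as configuration). Per frame interval Δt:

- displacement: Gaussian, per-coordinate variance 2DΔt for the current
  state's D;
- boundary: specular reflection at the cell outline (folding about the
  boundary normal, iterated for rare long steps). The nucleoid sub-region is
  not modelled;
- state switching: evaluated once per interval with probability
  1 − exp(−Δt/τ_residence); states are constant within a frame (first-order
  approximation, adequate for Δt ≪ τ). Two-state models must satisfy
  detailed balance f₁/τ₁ = f₂/τ₂, enforced at construction;
- photobleaching: the track ends with probability 1 − exp(−Δt/τ_bleach) per
  interval, making observed track lengths geometric; the default
  τ_bleach = 0.237 s corresponds to the ~7.9-step mean track length of 30-ms
  acquisitions (the geometric mean track length is 1/(e^{Δt/τ}−1) ≈ τ/Δt − ½
  steps, i.e. 7.4 at these settings — the small difference is the
  discretization of a continuous lifetime);
- localization noise: i.i.d. Gaussian per coordinate, added to *reported*
  positions only; motion blur within the exposure is not modelled.

Movies render each live molecule as a symmetric 2D Gaussian PSF (default
σ = 1 px) whose integral is `mean_photons`, over a uniform background, with
Poisson shot noise, as 16-bit TIFF. Pixel centres sit at integer
coordinates, origin top-left; x_um = x_px · pixel_size exactly.

### Apparent coefficients and the recovery presets

The published D values are *apparent* coefficients: they already include the
effects of in-cell confinement and localization error, because they were
estimated from in-cell displacement data without correction (the package
likewise reports apparent D by default; a σ²/Δt correction is an explicit
option). Simulating those values *inside* a cell would apply confinement
twice: at D = 0.38 µm²/s and Δt = 30 ms in a 3.0 × 0.9 µm cell the apparent
D drops a further 10–15%. The named presets therefore generate
parameter-recovery data in an unconfined proxy geometry (radius ≫ √(4DΔt))
with zero localization noise — the generative model then *is* the Rayleigh
mixture being fitted, which is the only regime in which "recover the
published number" is a well-posed check. Confined, noisy, movie-level
simulation remains the realistic mode (and is what the end-to-end
detection→linking→fit test uses, with a correspondingly wider tolerance that
absorbs the known confinement bias).

The Smc-YFP fractions were published as 66/35 (rounding to 101%); the preset
normalizes to 65/35.

## Jump-distance mixture estimation

Primary estimator: maximum likelihood by EM on the raw pooled step lengths,
with the mixture weights parameterized so they sum to 1 exactly. Fixed-D
components (the 0.02 µm²/s slow/static floor for condensin-family datasets)
skip the scale update and optimize only their weight. A binned least-squares
fit (lmfit) is retained because published fits of this kind are displayed on
the binned empirical density; both estimators agree within standard errors on
well-sampled data and this is tested. Numerical choices: D floored at
10⁻⁴ µm²/s (the D → 0 component is a point mass with no proper density);
EM initialized from the one-component closed form Σr²/(4nΔt) split 2×/0.2×;
convergence at relative log-likelihood change < 10⁻¹⁰; R² always reported
against the binned density (50 bins by default) for comparability with
display-style fits. Standard errors come from bootstrap over *tracks* (not
steps), respecting within-track correlation; the error estimator used for
the published ± values is not stated, so bootstrap SE is this package's
choice. Model selection between one and two components uses ΔBIC > 10 plus
a 5% minimum on both fractions — a second component carrying almost no
weight is not evidence of a second state.

## Dwell-time analysis

A confinement episode is a maximal run of consecutive positions within
106 nm (one pixel, configurable) of the run's *first* position, scanned
greedily left-to-right; runs of ≥ 3 positions (2 frame intervals) count.
The anchored-first-position convention is one of several defensible readings
of "rested within a circle"; it is locked by an independent brute-force
oracle in the tests rather than asserted as the original tool's convention.
Episodes reaching the end of a track are marked censored but included as
observed durations by default — the same downward bias a bleaching-limited
experiment accepts; a censoring-aware likelihood is available.

Survival fits maximize the mixture likelihood for
S(t) = f₁e^(−t/τ₁) + (1−f₁)e^(−t/τ₂), left-truncated at the 2-step minimum
and renormalized, so f₁ estimates the pre-truncation mixture weight. When
the frame interval is known (always, in this pipeline) the likelihood is
interval-censored on the frame grid — P(d ≤ T < d + Δt) — which removes the
≈ Δt/2 downward bias a continuous density incurs on floor-discretized
durations (~7% at τ = 210 ms, Δt = 30 ms); the continuous form is used when
no interval is supplied, and the untruncated one-component MLE reduces to
the sample mean. Optimization is Nelder–Mead on (log τ₁, log(τ₂−τ₁),
logit f₁), which enforces ordering and bounds by construction; τ₂ beyond
10× the longest event is flagged unidentifiable. Bleaching correction
treats unbinding and bleaching as competing exponentials,
1/τ_corr = 1/τ_obs − 1/τ_bleach, flagged unreliable beyond τ_obs/τ_bleach >
0.5 and undefined at ≥ 1.

## FRAP

Single-exponential recovery I(t) = plateau − (plateau − I₀)e^(−kt), fitted
per cell by nonlinear least squares (lmfit), t½ = ln2/k with SE from the fit
covariance. A single-exponential model class reflects exchange-limited
recovery of a bleached cluster; diffusion-coupled FRAP models are out of
scope. Curves are normalized to percent of the pre-bleach mean with the time
origin at the first post-bleach sample; bleach depths under 10% warn. Flat
curves yield a flagged, non-converged fit rather than a half-time. Group
comparison is a two-sample t-test on per-cell half-times — Welch by default,
pooled-variance available; per-cell fitting (rather than fitting the
averaged curve) is the default, since whether published half-times average
per-cell fits or fit an averaged curve is not stated. No photofading
correction is applied by default.

Synthetic FRAP defaults: bleach depth 0.5, plateau 90% (recovery to
slightly below pre-bleach, as expected when part of the pool is bleached),
2% Gaussian noise, 5-s sampling — chosen once as typical for bacterial
FRAP ensembles.

## Foci geometry

Pole distance is computed along the cell axis (1D projection onto the
pole-to-pole segment, clamped to [0, L]), since axial position is the
quantity of interest; full 2D distance is an option. Correlation with cell
length is Pearson's r with a two-sided p; constant inputs make r undefined
and are reported as 0 with a flag. Nearest-focus distances are per
channel-A focus to the closest channel-B focus in the same cell; cells
lacking a channel are skipped and counted. The colocalization threshold is
*not* an established constant — the default 0.25 µm is diffraction-scale,
and every result reports the threshold used. Cell-length bins: small
< 2.25 µm ≤ medium ≤ 3.2 µm < large, the standard cell-cycle proxy
thresholds for these growth conditions.

The foci generator places (by default) two channel-A foci per cell at a
pole distance drawn from a linear-in-length model, with channel-B foci
offset by an isotropic 2D Gaussian — so A–B distances are exactly
Rayleigh(σ_offset), giving closed-form checks: mean distance σ√(π/2),
colocalization fraction 1 − exp(−thr²/2σ²).

## Problem sizes and determinism

Recovery tests and the acceptance script use ~10⁴ pooled steps per dataset
(≈ 1,400 molecules at 30-ms frames), 20 simulation seeds, 5,000 dwell
events, and 20-cell FRAP ensembles — the same order as the original
datasets, chosen so that estimator bias, not sampling noise, dominates the
comparison. Every generator takes one explicit integer seed feeding a
single numpy `default_rng` stream; identical seeds give bit-identical
outputs, and pipeline reports embed seed, config hash and package version.

## Known limitations

- No anomalous diffusion (FBM/CTRW), blinking photophysics, 3D/astigmatic
  localization, motion blur, or nucleoid sub-structure in the generator;
  passing recovery tests says nothing about data violating those
  assumptions.
- Greedy nearest-neighbour linking is only exact at very low density; the
  density guard warns, it does not fix.
- The synthetic data are exactly the model class the fits assume (by
  design); real-data deviations (heterogeneous localization error,
  drift, non-exponential bleaching) are not represented.
- The dwell-event convention (anchored first position) is a documented
  choice; other windowing conventions would shift τ estimates.
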