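# Methods

## The measurement model

The package treats lower-limb corticospinal laterality as observable
through two routes that the analysis battery then relates to behavior.

**Functional route (TMS/EMG).** Stimulating one motor cortex while
recording rectified EMG from the vastus lateralis of each leg yields, per
trial, an MEP burst whose size is quantified as area (mV·ms) inside a
post-stimulus window, normalized by the area of a pre-trigger window that
captures ongoing voluntary activation. Normalization makes the response a
unitless multiple of background drive, so it is invariant to electrode
gain and skin impedance (scaling a whole trace leaves it unchanged).
Block means over the trials at one intensity give one recruitment-curve
point; the curve over intensities (expressed in % of motor threshold) is
summarized by its unweighted OLS slope. Straight-line fitting, rather than
a sigmoid, matches how shallow lower-limb recruitment curves are treated
in this regime; fit quality is tracked as the Pearson r between intensity
and response, and fits with r ≤ 0.85 are **flagged, never discarded** — a
reusable tool must define behavior for poor fits, and silently dropping
them would bias cohort summaries. "Balanced" laterality is assigned only
at FCR exactly 1; the interpretation is otherwise the binary >1 / <1
reading.

**Structural route (diffusion MRI).** All volumes are assumed
pre-registered to one grid (shape, voxel dimensions and space tag are
checked, never resampled). ROI means are arithmetic means over strictly
binary masks — no partial-volume weighting. The FA asymmetry index is
antisymmetric in its arguments, zero at symmetry and bounded by [−1, 1].
Lesion volume is voxel count × voxel volume; lesion–CST overlap counts
lesion voxels whose CST probability exceeds a threshold, by default 10% of
the map maximum (an absolute threshold in [0, 1] can be given instead).
Overlap is monotone non-increasing in the threshold.

**Battery.** Spearman's rho uses average ranks for ties and a two-tailed
p from the t approximation with n−2 df — adequate at the cohort sizes
targeted here (n ≈ 13–200); exact permutation p-values are not attempted.
Multiplicity correction is multiplicative (Bonferroni) with capping at 1,
with the family defined per report section as the set of correlations
actually computed. The 2×2 fully-within-subject ANOVA is computed by the
explicit sums-of-squares decomposition; for this design the interaction
F with df (1, n−1) equals the squared paired t on each subject's
difference of differences, an identity the test suite enforces to 1e-10.
Stepwise regression is forward selection on partial-F p-values with the
conventional 0.05 entry / 0.10 removal thresholds; exactly collinear
candidates are dropped with a warning before selection.

## The synthetic cohort generator

The generator exists so that every downstream stage can be exercised and
validated without patient data. One latent severity value s ∈ [0, 1] per
subject drives all correlated quantities:

- **Paretic FCR**: monotone increasing in s via the map
  lo + (hi − lo)·s^γ with γ solved from (lo, hi, mean) so that the
  configured population mean *and* range hold simultaneously under
  uniform severity (defaults: mean 1.7 over 0.27–2.6). A linear map
  cannot satisfy both.
- **Non-paretic FCR**: same map family applied to an independent uniform
  draw (defaults: mean 0.55 over 0.2–0.83) — deliberately uncorrelated
  with severity so the downstream null finding has a generative ground
  truth.
- **Ipsilesional PLIC FA**: declines linearly from the intact value at
  s = 0 (an undamaged tract has zero asymmetry) with slope
  2·(FA_intact − FA_lesioned_mean), keeping the population mean at the
  configured 0.42 against 0.54 contralesionally. ALIC FA is symmetric by
  construction.
- **Behavior**: Fugl-Meyer (12–34, mean 23.8) and walking speed
  (5.4–89.75 m/min, mean 39.8) decrease monotonically in s through the
  same power-map family, plus additive Gaussian noise (1 FM point,
  2 m/min by default); walking speed converts a latent 10 m walk time.

Latent uniforms are drawn **stratified** — one draw per equal-width bin
of [0, 1), order shuffled. Each draw is still marginally uniform and the
whole cohort is deterministic per seed, but sample means of any smooth
function of the latent match the population value far more tightly than
iid sampling would; this is what makes the configured group means
recoverable to ±0.01 (FA) and ±0.05 (FCR) at cohort sizes of 50–200.

**EMG traces.** Each trace spans −150 to +100 ms around the stimulus at
2 kHz. A deterministic tonic level (0.02 mV) is present only before the
stimulus — modelling voluntary pre-activation with a post-stimulus silent
period — so the pre-trigger area is nonzero even in noiseless simulations
while the MEP window contains exactly zero signal at 100 %MT. The MEP is
a Gaussian-envelope burst (envelope sd = window width / 8) whose area is
true_slope × (intensity − 100) × pre-trigger area; the envelope is
normalized over exactly the samples the analysis window integrates, so
with noise off the fitted slope equals the latent slope to machine
precision. Burst shape is irrelevant to the analysis (only areas are
used); the Gaussian is chosen for smoothness. Additive Gaussian noise
(default sd 0.005 mV against the 0.02 mV tonic level) enters before
rectification. Noise inflates both window areas roughly equally, shifting
curve intercepts but not slopes to first order, and its residual
multiplicative effect cancels in the slope ratio — cohort-mean FCR bias
stays below 5% at default noise (enforced by test).

**FA phantoms.** 24×24×16 voxels at 2 mm isotropic: mirrored PLIC and
ALIC boxes (72 voxels each), a background FA of 0.30, truncated-Gaussian
per-voxel noise (sd 0.02; Rician noise is deliberately not modelled — at
ROI-mean scale the difference is negligible), a bilateral CST probability
map with in-plane Gaussian profile descending through each PLIC, and an
ellipsoidal lesion near the lesioned PLIC whose radius grows with
severity (empty at s = 0). ROI boxes are checked for disjointness and
grid fit; overlapping definitions are refused.

## Parameter defaults that matter

| parameter | default | units | why |
|---|---|---|---|
| n_subjects | 13 | — | size of the shipped clinical table |
| intensity_grid | 100–150 step 10 | %MT | 6 points; a line fit needs ≥ 2, fit r needs ≥ 3 |
| trials_per_block | 8 | — | typical MEP block size |
| mep_window | 20–60 | ms | lower-limb VL latency regime |
| pre_trigger_window | −110 to −10 | ms | 100 ms of pre-activation clear of the artifact |
| tonic_emg_mv | 0.02 | mV | background drive during pre-activation |
| emg_noise_sd | 0.005 | mV | 25% of tonic level |
| fa_noise_sd | 0.02 | FA | per-voxel; ~0.002 at ROI-mean scale |
| contra_slope_range | 0.02–0.05 | response/%MT | normalized responses reach ~1–2.5 at 150 %MT |
| fit-quality flag | r ≤ 0.85 | — | threshold below which a fit is flagged |
| CST overlap threshold | 0.1 × map max | — | probability floor defining "on the tract" |

The analysis windows and the motor-threshold criterion (MEP area
exceeding pre-trigger area by 0.1 mV·ms in ≥ 50% of trials at an
intensity) are declared defaults, configurable because conventions differ
between laboratories.

## What passing tests do and do not show

The generator embeds the expected effect structure (severity couples FCR,
FA asymmetry and impairment; the non-paretic leg and the control ROI stay
null), so green tests demonstrate that the pipeline *recovers what was
put in* — calibration, units, determinism and statistical identities.
They do not validate the biology, nor realistic EMG artifacts (no
stimulus artifact, no spectral structure, no trial-to-trial excitability
drift), nor real DWI physics (no tensors, no Rician noise, no
registration error). Lesion size is geometrically tied to severity in the
phantom, so lesion-volume correlations in synthetic cohorts are stronger
than the null finding reported for patients; this is a property of the
phantom, not a claim, and no test asserts a lesion-volume effect
direction.

## Numerical choices

- Window areas integrate the rectified trace with the trapezoid rule over
  the closed sample interval covering the window, so constant signals
  give exact closed-form areas at any sampling rate whose grid hits the
  bounds.
- A trial whose pre-trigger area is at or below machine epsilon cannot be
  normalized: it is flagged invalid, excluded from its block mean, and
  logged — a block fails only if every trial is invalid.
- Constant-response recruitment curves get slope 0 with undefined (NaN)
  fit r and are flagged degenerate; all-identical intensities are an
  error (the slope is not identifiable).
- FCR requires a strictly positive contralateral slope and a non-negative
  ipsilateral slope; anything else is an error, not a NaN.
- Degenerate cohorts (zero-variance columns) surface as per-pair
  "degenerate" notes in the correlation table rather than aborting the
  run.
- Reports are written atomically (temp file + rename); identical seeds
  yield byte-identical outputs.

## Known limitations

- The published clinical table is shipped as printed (2-dp rounding);
  correlations involving its FA-asymmetry column land within ±0.05 of the
  published values, not exactly on them, and are flagged with their
  rounding provenance. The published F and t statistics and corrected
  p-values require unprinted per-subject slopes or unstated correction
  family sizes and are reported as not desk-reproducible.
- Motor-threshold estimation is provided for absolute-intensity sessions,
  but the generator emits intensities already normalized to %MT, so the
  default pipeline does not exercise it.
- No figure generation, no voxel-wise (TBSS-style) statistics, no
  tractography: the CST probability map is an input, not a reconstruction.
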