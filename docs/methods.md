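# Methods

## Scope and design

`colidecay` reimplements, as a tested library, the quantitative analysis
of toxin-induced DNA-damage response in bacterial co-cultures: spatial
decay profiling of an SOS (recA-promoter) YFP reporter around producer
colonies, and flow-cytometry percent-positive classification. No raw
imaging or cytometry data accompany the study design it follows, so the
package pairs every analysis stage with a synthetic generator whose
ground truth is exactly known; correctness is established by parameter
recovery and closed-form oracles rather than by comparison to archived
data.

## Synthetic toxin field and scene model

The toxin concentration around a producer colony of radius R is modelled
as secretion with first-order extracellular loss:

    T(r) = A                      r ≤ R
    T(r) = A · exp(−(r − R)/λ)    r > R

with amplitude A (arbitrary units) and decay length λ (µm). The true 2-D
steady state of diffusion with first-order decay around a disc source is
a Bessel-K₀ profile; the radial exponential was chosen instead because it
is exactly invertible (dist₅₀ = λ·ln 2), which is what the recovery
oracles need, while λ keeps the same interpretation as a characteristic
penetration length. Fields of several colonies combine by maximum
(switchable to sum): the maximum keeps the single-colony closed form
exact near each colony, at the cost of under-adding where fields overlap.

Channels render as: YFP = b + g·T on reporter material (baseline b, gain
g), constitutive CFP on reporter material, constitutive mCherry on
producer footprints; zero-mean Gaussian noise of one SD everywhere,
clipped at 0 and quantized to 16-bit. This deliberately omits optics
(PSF), shot noise, flat-field structure and colony growth — it is
sufficient to exercise smoothing, baseline and threshold logic, and no
conclusion about camera physics is drawn from it. Scenes are static
snapshots; time courses are sequences of independently rendered scenes.

Pixel size is mandatory configuration (the magnification-to-µm
calibration is instrument-specific and not recoverable from the assay
description); pipelines default to 4 µm/px, a plausible plate-microscopy
scale at 2.5× that keeps default scenes a few hundred pixels wide.

Default decay lengths are fixed from the reported saturation ranges of
the two producer strains via λ = dist₅₀/ln 2: engineered lawn 300 µm,
natural (Nissle 1917) lawn 167 µm, engineered colony pairs 170 µm,
natural colony pairs 115 µm. Default intensities (A = 1000, b = 100,
g = 1, noise SD 20) give a 10:1 signal-to-noise peak typical of a healthy
reporter; replicate structure defaults to 3 biological × 10 technical
replicates per condition.

## Profile extraction

Cross-sections are sampled along a straight line from the producer-colony
centre outward, by bilinear interpolation (`scipy.ndimage.map_coordinates`,
order 1), at an arithmetic step defaulting to one pixel equivalent. The
original analysis relied on user-marked lines and colony edges; here
lines come from the synthetic ground truth (or from a YAML session file
recording what an operator would have marked), and the producer edge is
detected automatically as the half-maximum crossing of the mCherry
plateau, with a contrast floor of 5× the far-field SD guarding against
sections that miss the colony. Alignment shifts the distance origin to
the YFP peak (lawn assay) or the mCherry edge (colony assay) and masks
samples at negative distances; for non-contacting pairs the agar gap —
where no reporter material exists — is masked, padded by two samples
against ±1 px edge-detection slack.

Sub-pixel sampling steps are supported but interpolate away part of the
pixel noise; the response-floor calibration below assumes pixel-rate
sampling for noisy data (the default).

## Decay analysis

Pipeline order: smooth → baseline (on the smoothed tail; a switch allows
raw) → YFP₅₀ → dist₅₀.

- **Smoothing**: centered moving average, window 20 samples, truncating
  symmetrically near edges (MATLAB-`smooth`-like). Window units are
  samples, which equal pixels at the default sampling step. Smoothing is
  applied per contiguous unmasked run, so it never bleeds across the
  masked agar gap.
- **Baseline**: mean of the 20 unmasked samples furthest from the
  producer. In the colony assay the baseline is subtracted per colony to
  remove expression-level offsets before the shared reference is applied.
- **YFP₅₀** = baseline + (max − baseline)/2, taken from the smoothed
  curve.
- **dist₅₀**: first downward crossing of YFP₅₀ scanning outward from the
  peak, with linear interpolation between the bracketing samples. First
  crossing is the conservative choice: noisy tails can re-cross.
  Monotonically rising profiles return an explicit "no-crossing" flag,
  never a number.
- **Non-contacting inference**: these curves do not reach the full
  reporter response, so the crossing is taken against the contacting
  colonies' YFP₅₀ averaged across all replicates (on the
  baseline-subtracted scale). A crossing that falls inside the masked gap
  is flagged `crossing-in-gap`; a reference above the whole measurable
  profile is flagged `reference-above-profile`. When a masked gap
  precedes the first measurable sample the two situations cannot be
  distinguished and the gap flag takes precedence.
- **Response floor**: a profile is flagged `no-response` unless
  max − baseline exceeds k× the raw tail SD. k defaults to 5 rather than
  the 3 that a per-sample argument would suggest, because the aligned
  profile's first sample (the raw argmax used as the peak origin) carries
  no smoothing support and therefore rides at the *extreme* of the raw
  noise — about 3.2–4 SD over a thousand samples — which a 3-SD floor
  would misread as a response on gain-zero (pks⁻-like) profiles.
- **Averaging**: replicates are linearly resampled onto the intersection
  of their unmasked ranges; mean and SD (n−1) are reported per distance,
  with per-distance n and a low-n flag.

No parametric exponential or Hill fit is performed anywhere: dist₅₀ is a
nonparametric metric and stays one.

## Cytometry

Event tables are CSV with columns event_id, FSC_A, FSC_H, SSC_A, CFP_A,
YFP_A, mCherry_A, PE_A (and a ground-truth label column for synthetic
tables); CSV is the canonical format for this package. Gates form a tree
rooted at `all_events`, with rectangle, threshold and ratio-band
primitives; membership of a gate implies membership of its parent.

Gate geometry is configuration because the original gates were drawn
visually on overlaid control samples. `default_gates(reference)` derives
the standard tree from a clean single-cell reference: the debris bound is
placed 6 log-SDs below the reference scatter cluster (i.e. in the empty
valley, where visual gating would put it — a strict percentile bound
would clip ~1% of genuine cells), and the singlet gate keeps FSC-H/FSC-A
within (2/3, 3/2) of the reference median ratio, excluding doublets,
which sit near half the singlet ratio because their area doubles while
their height does not.

Reporters are events with high CFP and low mCherry; producers the
reverse; both-high and both-low are unclassified. The DNA-damage cutoff
is mean + 3 sample SD (n−1) of the gated reporter YFP distribution at
t = 0 h, reused unchanged at all later times; "positive" means strictly
greater than the cutoff (ties negative — the conservative convention).
The timecourse applies the rule to log-transformed intensities by
default: cytometer fluorescence is log-normal, and on the raw scale a
3-SD cutoff sits only ~2 SD up the skewed log distribution, inflating the
false-positive floor an order of magnitude. `compute_cutoff` and
`percent_positive` themselves are scale-agnostic.

The propidium-iodide lysis fraction is the percent of gated singlets
above a PE cutoff placed at the log-midpoint of the stained and unstained
populations.

## Flow-mixture generator

Subpopulations (reporter responders/non-responders, producers at a 10:1
producer:reporter ratio, debris, doublets, PI-positive lysed cells) are
log-normal per channel, with marker tags as +3 log-unit offsets, a
responder YFP shift of 2.4 log units (6 YFP log-SDs, comfortably
separable), debris 3 log units down in scatter, and doublets doubling
FSC-A/SSC-A while keeping singlet FSC-H. Group sizes are deterministic
(largest-remainder) by default so recovery tests see the exact
ground-truth fraction; a multinomial mode resamples them per draw to
emulate between-replicate sampling variation and is used by the lysis
pipeline, where deterministic counts would make triplicates identical.
The lysis ground truth is the *same* 1.3% in both strains: the emulated
condition is "low lysis, no strain effect", so observed differences are
pure sampling noise.

What the generator does not emulate: spectral spillover between
channels, instrument drift, autofluorescence tails, aggregates beyond
two cells, or any correlation between damage state and scatter. Passing
recovery tests therefore demonstrates the correctness of the gating and
threshold logic, not robustness to those real-data effects.

## Statistics

Group comparisons use the two-tailed Welch t-test (unequal variances,
fractional Welch–Satterthwaite df, via `scipy.stats.ttest_ind`), applied
to biological-replicate means; two zero-variance groups with equal means
return p = 1 by convention. CFU/mL per plate is count × dilution factor /
plated volume, with the 1:1 serial scheme mapping dilution index k to
factor 2ᵏ; the pooled estimate weights plates by raw counts (total
colonies over total effective volume — the inverse-variance combination
under Poisson counting). The contamination bound is the exact one-sided
binomial (Clopper–Pearson) upper limit, ≈ 3/n at 95% for zero observed
producers.

## Known limitations

- The lawn-assay origin is the raw YFP argmax; with noisy data the
  argmax lands up to ~0.05 λ outside the colony edge, shortening dist₅₀
  by a few µm (≈2% at default noise). Noise-free recovery is exact to
  the sampling step.
- Near the start of an unmasked run the smoothing window truncates, so
  the curve there is inflated less than in the interior. When a
  non-contacting pair's crossing falls within half a window of the gap
  edge (small λ relative to the gap), this biases the
  contacting/non-contacting comparison by ~1–2 µm. Synthetic replicates
  are far more precise than biological ones, so at the natural-strain
  configuration (λ = 115 µm, gap 50 µm) a Welch test across synthetic
  replicates can flag this sub-2-µm artifact as significant even though
  it is an order of magnitude below the 10-µm equivalence margin used
  throughout; with the default engineered configuration (λ = 170 µm) the
  crossing clears the truncated region and the groups agree to ~0.1 µm.
- The exponential field is a modelling convenience; with Bessel-K₀ decay
  dist₅₀ would no longer equal λ·ln 2, though the monotone λ–dist₅₀
  relationship the tests rely on is preserved.
- FCS files are not read; convert to the CSV schema first.

## Problem sizes

Default runs use 10 colonies per lawn plate, 3 × 10 colony pairs per
group, 50,000 events per cytometry table (100,000 in the recovery tests,
10⁶ draws for threshold calibration), and images a few hundred pixels on
a side at 4 µm/px — sizes chosen so a full assay completes in seconds on
one core while keeping Monte-Carlo error well inside every tolerance the
tests assert.
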