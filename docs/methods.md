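# Methods

This note documents the models, numerical choices, and limitations behind
`peribout`, in the spirit of a package methods appendix. Nothing here
states an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Bout definition and microstructure

Licks are partitioned at inter-lick intervals ≥ 10 s; maximal clusters
with ≥ 3 licks are bouts. Two boundary decisions are deliberate and
literal: an interval of *exactly* 10 s splits (the separation criterion is
"at least 10 s"), and 1–2-lick clusters are discarded rather than merged
into a neighbor (the definition is cluster-local). Bout duration is
last-lick minus first-lick with no spout-access padding. This is not the
classical burst/cluster microstructure hierarchy; it is the definition the
photometry alignment uses, applied consistently to behavior.

"Lick frequency" has no canonical definition at the session level; we use
the reciprocal of the mean intra-bout inter-lick interval,
Σ(nᵢ − 1)/Σ dᵢ over bouts, which is insensitive to bout count and zero
when no bouts exist. A 7-lick bout at exact 0.1-s spacing scores 10 Hz.

## Isosbestic correction

The correction is a frequency-domain regression: with S(f) and C(f) the
real FFTs of the 465 and 405 nm streams, a single real scale
a = Re⟨S, C⟩/⟨C, C⟩ is fit over 0 < f ≤ 0.05 Hz, the band where
photobleaching dominates both channels. The corrected trace is
IFFT(S − aC) (DC removed) divided by the fitted slow baseline
IFFT(aC·1[f ≤ 0.05 Hz]), giving fractional units. Subtracting aC at *all*
frequencies removes wideband shared artifacts, not only bleach. Exactly
affine inputs (S = aC + b) cancel to zero at machine precision; the
residual's mean is zero by construction, so only deviations relative to a
local baseline are meaningful — which is what the per-snip z-scoring
consumes. A constant control channel has no low-frequency structure to
fit and raises a degenerate-fit error; streams under 60 s leave too few
sub-0.05 Hz components and are rejected. Because the fit assumes the FFT's
periodic extension, a strongly non-periodic bleach leaks a small ripple
into the first/last tens of seconds; bouts without complete peri-event
windows are excluded anyway, which also excludes the worst of this edge
region.

## Snip grid and z-scoring

The 230-bin, 0.1-s grid (5 s baseline, 6 s early lick, 2 s late lick, 10 s
post) is fixed package-wide. The 0.1-s bin width follows from the
six-bin/0.6-s consecutive rule. For bouts of 4–8 s the licking period
minus its final 2 s is linearly time-rescaled onto the 60-bin early grid
(bout start maps to the first bin, end−2 s to the last); for longer bouts
the early grid is the literal first 6 s and the bout middle is excluded.
Rescaling was chosen over overlapping windows because it keeps early-grid
bin *identity* tied to within-bout fraction, exposing onset timing in a
duration-heterogeneous pool; its cost is that absolute early-lick timing
blurs across durations, which is why timing-sensitive analyses use the
8-s minimum where the grid is literal. Bins are means of covered samples;
a stretched bin narrower than one sample falls back to interpolation at
the bin center.

Z-scoring uses each snip's own 50 baseline bins with the n−1 sample SD
(immaterial vs n at 50 bins, but conventional). Zero baseline variance
flags the snip as artifact instead of dividing by zero.

The artifact screen (max |consecutive-bin difference| > 12, strict) runs
on corrected, binned, **pre-z-score** values. The threshold's units are
therefore corrected fractional units; a threshold of 12 in z units would
be unreachable. The original analysis does not state its units, so the
threshold is an exposed parameter (`artifact_threshold`), with 12 as the
default.

## Waveform inference

The bootstrap resamples bout snips with replacement (n_boot = 1000),
pooled across mice — the resampling unit is the bout, matching an analysis
that uses all bouts from a region and condition; mouse-stratified
resampling is available as an option for sensitivity analyses. CIs are
per-bin percentile intervals (2.5/97.5). Percentile rather than BCa was
chosen because it is the standard for this family of peri-event waveform
analyses and is exactly what "a 95% confidence interval constructed around
the mean" implies in that lineage; the reported mean is the plug-in sample
mean. With one distinct snip value the CI collapses onto the mean.

Significance windows are maximal runs of ≥ 6 bins with ci_lo > 0 (above)
or ci_hi < 0 (below); baseline bins are excluded from reporting by default
since they define zero. Two-waveform comparison reports runs of ≥ 6 bins
where the intervals are disjoint; intervals touching at an endpoint count
as overlapping (the conservative reading). Raising the consecutive
threshold can only remove windows, so the per-session false-positive
fraction is monotone non-increasing in it; `scripts/acceptance.py`
computes the null fraction at thresholds 1, 6 and 10 on 500 null sessions
of 30 snips each (white-noise snips z-scored to their baseline — the
pipeline's null condition).

Epoch AUCs integrate the binned step function (Σ z · 0.1 s) over the four
behavior-defined epochs (early lick, late lick, and the post-bout 10 s
split in two). Step-function integration rather than the trapezoid rule
keeps a constant z = 1 over a 5-s epoch at exactly 5 z·s; AUCs are not
normalized by epoch duration, so the two licking epochs have different
maximal areas.

## Synthetic data

The generator encodes the study conditions rather than convenience
values: 30-min sessions; a Poisson bout count (default expectation 20–25
depending on the cohort helper); log-normal bout durations (default mean
12 s — long enough that most bouts clear the 8-s strict criterion); 8 Hz
intra-bout lick rate with gamma-jittered intervals; inter-bout gaps of
15 s plus an exponential excess (mean 25 s) so generated bouts are always
separable under the 10-s rule. Photometry uses a single-exponential bleach
with a non-zero asymptote (τ = 900 s, floor 0.25 of initial) and
channel-specific gains. Motion artifacts and the transient kernel enter
*multiplicatively* (fractional deflections of the fluorescence level):
physically, motion changes coupling efficiency in proportion to each
channel's light level, and this is what makes artifacts exactly
common-mode across channels with different gains. The kernel is piecewise
linear: zero until `suppression_onset_s` after bout start, a 1-s ramp to
−A, hold through the bout, then either sustained suppression for
`suppression_offset_s` with a 2-s recovery (VMH-like) or a linear rise
crossing zero to +A/2 at `rebound_onset_s` after bout end (PVH-like).
The shape is the simplest one exposing the onset/offset timing the
detector must recover; in vivo amplitudes are free parameters (the source
figures publish z-scored traces only), and the cohort helpers set them in
z units via the corrected-trace noise model
(σ_bin ≈ σ_channel·√2/(bleach·√(f_s·0.1))).

Multispout sessions are 100 trials (five sucrose concentrations × 20, in
a seeded pseudorandom order) with negative-binomial per-trial lick counts
(dispersion 8 — overdispersed relative to Poisson, as real lick counts
are), mean = rate × 3 s × treatment factor. Vehicle rates
(0.65/1.5/2.0/2.4/3.0 Hz, monotone in concentration) and the treatment
factor 244.88/572.38 ≈ 0.43 are calibrated so that cohort session totals
land near the published group means; a log-normal per-mouse factor
(CV 0.25, shared across a mouse's two sessions) produces realistic
between-subject spread while keeping the treatment contrast
within-subject.

What the generator does **not** emulate: carrier demodulation and
hardware noise spectra (streams are born demodulated with white Gaussian
noise), hemodynamic or pH confounds, correlated drift beyond the shared
bleach, mouse-level heterogeneity in photometry dynamics, or trial-order
effects in the multispout. Passing tests therefore demonstrate that the
algorithms recover what they are defined to recover under this signal
model, not that the model captures every failure mode of real recordings.

## Group statistics

The repeated-measures ANOVA works in orthonormal-contrast space: for an
effect with contrast matrix C (q × cells), Z = YC′ gives per-subject
scores; F = (n·‖z̄‖²/q)/(SS_resid/(q(n−1))) and the Greenhouse–Geisser
ε̂ = tr(S)²/(q·tr(S²)) from the sample covariance S of Z, clipped to
[1/q, 1]. Two-way effects use Kronecker products of factor contrasts with
the complementary uniform vector. At k = 2, ε = 1 identically and
F equals the squared paired t. Both the uncorrected p and the
GG-corrected p are always returned; the *recommended* p applies the
correction when ε̂ < 0.75 (a transparent proxy for "sphericity violated",
since the underlying report does not name its sphericity test). Under a
true-sphericity null the correction is conservative because ε̂ is biased
downward at small n — the test suite verifies exact 5% calibration of the
uncorrected p and conservativity of the recommended p at n = 8, k = 5.

Holm is the standard step-down with monotonicity enforcement. Planned
paired comparisons are uncorrected by design (hypothesis-driven); a
zero-variance non-zero difference is flagged degenerate rather than
reported as t = ∞. Welch's ANOVA uses the usual
weights-by-precision statistic with Welch–Satterthwaite df. The Dunnett
many-to-one post hoc is evaluated by seeded Monte Carlo: each replicate
redraws every group from a normal with its observed variance, recomputes
the unpooled many-to-one t statistics, and the family-wise p for
comparison i is the add-one fraction of replicates whose max |t| reaches
|t_i| (default 10⁵ draws, accuracy ~10⁻²·|p(1−p)|^½ and controlled by the
draw count). Unlike classical Dunnett quadrature this does not assume
equal variances; in the equal-variance case it agrees with the
multivariate-t implementation, which the tests verify.

The ±2 SD outlier screen is a single pass using the full-input mean and
sample SD with a strict inequality. Note a structural property: with
n ≤ 5 no single value can exceed 2 full-sample SDs (the maximum
standardized deviation is (n−1)/√n), so the screen only bites at the
n ≈ 30 group sizes it is meant for, where ~4.6% of normal draws are
removed on average.

## In vitro quantification

ΔF/F₀ uses F₀ = mean of the 10 frames immediately before ligand addition;
the per-cell scalar is the post-ligand maximum (a plateau mean can be
derived from the returned series — the choice matters little for
step-like responses, and max is the default because it is well-defined
for transient ones). Basal brightness is the mean of the top 10% of pixel
values with ties at the cutoff included, making it permutation-invariant.

## Problem sizes

The test suite and acceptance script size their simulations for a
single-CPU desk run: 1000 oracle trains; 500 × (100 snips × 10 bins)
coverage simulations; two 10-session region cohorts (~200 usable bouts
each) for timing recovery; 500 null sessions of 30 snips; 200 multispout
cohorts of 8 mice. These sizes put Monte-Carlo error comfortably inside
the asserted tolerances (e.g. coverage SE ≈ 0.3 percentage points).

## Known limitations

- The frequency-domain fit assumes the bleach shape is shared up to one
  scale; channel-specific bleaching kinetics would leave a slow residual.
- Windows report bin indices on a piecewise time axis (early bins anchored
  to bout start, late/post to bout end); a single "time" column in
  exported CSVs uses the nominal −5…+18 s axis and should be interpreted
  per segment.
- The Dunnett Monte Carlo conditions on observed variances (a parametric
  bootstrap of the null); exactness holds asymptotically, and at very
  small n its p-values carry the usual plug-in optimism of order 1/n.
- Bout-locked kernels from adjacent bouts may overlap a following snip's
  baseline when inter-bout gaps are short; this mirrors real recordings
  and slightly biases z amplitudes, but does not move timing.
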