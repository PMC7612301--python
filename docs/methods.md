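# Methods

This note documents the models, numerical choices and limitations behind
`ieegstim`, in the order the pipeline runs.

## Synthetic sessions

The generator produces the statistical structure the analysis assumes, not
a biophysical simulation. Background activity per channel is 1/f^α-sloped
Gaussian noise with α = 1 (FFT-shaped, normalised to 50 µV SD) plus a
10 µV, 10 Hz sinusoid with random phase — the minimal model that gives
Welch estimates a realistic spectral slope and a visible alpha peak in
every band of interest. Electrode coordinates are drawn inside a 60 mm
sphere whose Fibonacci-sampled shell serves as the brain surface.

Trials default to 60 per session (with `n_trials=None` the count is drawn
as round(N(60, 13.9)) clipped at 18, matching the session-size distribution
of typical stimulation experiments), organised in groups of three with
3–6 s within-group gaps and 30–36 s between groups, so every session
contains inter-stimulus intervals long enough for baseline epochs.
Stimulation parameters are constrained to the protocol the analysis
expects: amplitude 0.25–3.5 mA, frequency ∈ {10, 25, 50, 100, 200} Hz,
duration 0.5 s or 4.6 s with the long duration tied to 50 Hz. Gap
distributions within these bounds are a modelling assumption (the protocol
constrains only the < 10 s within-group rule) and are exposed in
`GeneratorConfig`.

Band-limited effects are injected by adding (√factor − 1) times the
band-passed component (4th-order zero-phase Butterworth) of the 1-s post
window, under a 50 ms raised-cosine ramp envelope — band power scales by
the factor while the ramps keep the artifact detector quiet. Artifact
channels instead get an additive 500 µV step at stimulation offset decaying
with τ = 0.8 s, which triggers both screening criteria by construction.

Paired sessions share subject, geometry and stimulation location; the
second session's effect map satisfies log f₂ = k·log f₁ + N(0, σ). The
coupling acts on the log-factor scale because effect-map entries are
multiplicative band-power factors and must stay positive, while the
proportionality constant k may be negative (k = −1 exactly reverses the
direction of every injected effect).

`generate_effect_tables` bypasses signal synthesis entirely: independent
zero-mean normal effect vectors per session pair, the null model used for
the no-correlation control. With sd = 0 the vectors are degenerate and the
consistency machinery flags them unusable rather than erroring.

What the generator does *not* emulate: non-stationary background (sleep
stages, drug tapering), line noise, true volume conduction or connectivity
between channels, evoked potentials, and long-term carry-over of
stimulation into baseline epochs. Passing tests therefore demonstrate that
the statistics recover what was injected under the stated noise model, not
that the pipeline is robust to every pathology of clinical recordings.

## Preprocessing

Windows are half-open `[start, end)` in seconds from the first sample. Per
trial: pre = [onset − 1.05, onset − 0.05), post = [offset + 0.05,
offset + 1.05). Baseline epochs are inter-stimulus intervals ≥ 20 s trimmed
by 5 s on each side; the recording edges count as interval boundaries (with
the same guard), so a stimulation-free recording still yields baseline.
Pseudo-trials are laid out from the epoch start with the session's median
within-group gap, in groups of three, until the baseline pair count reaches
the stimulation pair count. Trials too close to a recording edge are
skipped (never zero-padded — padding would bias Welch estimates) with a
logged warning.

Grouping uses the offset-to-onset gap with a strict < 10 s rule
(gap ≥ 10 s starts a new group).

Artifact screening runs on **raw** segments, before detrending: both
criteria compare average voltages (first half of post vs second half of
pre; the slow return of the trial-averaged post), which per-segment
centring would erase. Thresholds the protocol leaves open are set to
T1 = the Bonferroni-corrected two-sided t critical value at α = 0.05
across channels, and T2 = 5 × the SD of the trial-averaged pre signal; both
are configurable. With fewer than 10 trials screening is skipped (all
channels kept) with a warning.

Detrending removes each channel's least-squares line — an orthogonal
projection, hence idempotent. Common-average re-referencing subtracts the
per-sample mean over valid, non-stimulation channels from every retained
channel; artifact channels are dropped, stimulation channels are
re-referenced without contributing. At least two valid reference channels
are required.

## Spectra

Welch PSD of each 1-s segment: window length half the segment, overlap a
quarter of the segment (three 0.5 s Hamming windows, 2 Hz grid). The taper
and the natural-log base are fixed implementation choices; both shift
absolute levels only and cancel in the paired pre/post statistics. Band
power integrates the PSD trapezoidally over grid points in the closed
interval [low, high] — including both edge points makes contiguous band
integrals add exactly to the integral over their union, and the shared
edge is measure-zero; band *membership* of shared edges remains half-open.
Power is floored at 1e−12 before the log so silent segments stay finite.

## Effect statistic

U is the signed-rank z with zero differences discarded (classical
Wilcoxon, as MATLAB's `signrank`), mid-ranks for ties and the
Σ(t³ − t)/48 variance correction. No continuity correction by default
(`continuity_correction=True` switches it on; at n = 60 the two differ by
< 0.06). Cells with fewer than 10 usable pairs are flagged missing (NaN)
and excluded downstream. The paired-samples effect size reported with
extrema comparisons is Cohen's d (mean difference over SD of differences).
Degenerate paired t statistics (zero-variance differences) are reported
capped at 1e6 with a flag.

## Consistency

r₀ is cosine similarity; the n factors of the defining expectation cancel.
atanh is applied after clipping r₀ to ±(1 − 1e−10), giving a finite cap
≈ ±11.86 — perfectly collinear point sets occur in tests and in strongly
injected sessions. Curve radii advance in steps of 0.2 while *more than*
2 % of the points and at least 3 points remain (the "just before covering
98 %" stop rule made precise); points exactly on the circle are retained.
The maximum consistency is the signed coefficient of largest magnitude;
ties break toward the smallest radius, favouring the estimate with more
data. The baseline band is computed per radius (2.5th/97.5th percentiles
across baseline pairs, at radii reached by at least 2 pairs); its maximum
over radii is the reference for the global-maximum comparison.

## Pair regression

The ten covariates follow their definitions exactly; all difference
covariates are absolute, so construction is symmetric in session order.
Stimulation depth is the minimum distance from the anode–cathode midpoint
to the surface point set, negative iff the midpoint falls outside the
surface's convex hull (Delaunay membership test) — adequate for spherical
synthetic surfaces and convex-ish cortical hulls, not for deeply folded
ones. Stimulation duration is excluded from the model because it co-varies
with frequency; covariates are not standardised (F tests are unaffected).

The "ANOVA effect" per term is the Type II F statistic, computed from
nested-model residual sums of squares (with single-column terms and no
interactions this equals the Type III value); `statsmodels` OLS provides
the fit, R², adjusted R² and confidence intervals. Aliased covariates are
dropped greedily by rank. Bootstrap ANOVA resamples pairs with replacement
(default 200 resamples), redrawing rank-deficient samples, and summarises
per-term F distributions with box-plot statistics (median, quartiles,
adjacent values under the 1.5 × IQR rule).

## Problem sizes

The test suite and acceptance script run on deliberately compact problems
chosen to exercise every code path with stable statistics: 8-channel,
60-trial sessions at 500 Hz for signal-level checks (the 500 Hz default
comfortably resolves the 55 Hz gamma edge); 50 seeds per arm for
signal-level parameter recovery in the tests (25 per arm in the acceptance
script); 101 pairs × 200 cells for the null-simulation control; 100
regression replicates (50 in the script) at n = 101 with 200 bootstrap
resamples. Channel counts scale freely; nothing in the implementation
depends on these sizes.

## Known limitations

- The EDF writer is minimal (plain EDF, 16-bit, per-channel physical range
  from observed min/max): sufficient for round-tripping synthetic sessions,
  not a general-purpose exporter (no EDF+ annotations, no discontinuous
  records).
- Inside/outside classification for stimulation depth uses the convex hull,
  which overestimates "inside" for concave surfaces.
- The baseline band needs ≥ 20 pairs for stable percentiles; below that a
  warning is issued and the band is indicative only.
- No line-noise filtering, ICA cleaning or montage handling beyond the
  common average — the pipeline assumes those concerns are absent (true for
  the generator) or handled upstream.
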