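# Methods

This note documents the models, estimators, and design choices in
`stimnet`, and what the synthetic-data tests do and do not establish about
real recordings.

## Analysis model

The unit of analysis is the virtual electrode: the difference of two
adjacent physical contacts (bipolar montage), which cancels common-
reference noise exactly. All stages consume and produce these.

**Spectral estimation.** Every spectral quantity uses the multitaper
method with DPSS tapers: time-bandwidth product NW = 4, at most 8 tapers,
tapers with spectral concentration < 0.9 dropped (for 1-s windows this
retains 7 tapers). Power spectral densities are one-sided, in µV²/Hz, with
unit-energy tapers and uniform (non-adaptive) taper weighting. Band power
is the mean PSD over frequency bins whose centers fall inside the band,
endpoints inclusive. For narrow bands the implementation evaluates the DFT
only at the needed bins (two real matrix products); this is algebraically
identical to the FFT path and tested against it.

**Connectivity.** Coherence is
`C_xy(f) = |⟨S_xy⟩| / sqrt(⟨S_xx⟩⟨S_yy⟩)`, with cross- and auto-spectra
averaged over all baseline windows and tapers *before* normalization. The
low-frequency network averages `C_xy(f)` over bins in 5–13 Hz; per-
frequency networks (4–50 Hz, 1 Hz steps, 47 networks) take single bins
with no band averaging. One ambiguity: "averaged between 5 and 13 Hz"
could also mean averaging cross-spectra across the band before
normalizing; bin-averaged coherence is implemented because it keeps each
bin's normalization exact, and with 1-s windows the two differ little.
A baseline of at least 100 one-second windows is recommended (a warning is
emitted below that).

**HFB amplitude-envelope networks.** 50–200 Hz in fifteen 10 Hz sub-bands:
notch at the line frequency (zero-phase IIR, Q = 30), zero-phase FIR
band-pass per sub-band (symmetric odd-length Hamming-window design,
≥ 40 dB stop-band, applied by centered convolution so no group delay),
Hilbert amplitude divided by its own mean (making the network invariant to
per-channel gain), sub-band average, zero-phase FIR low-pass below 1 Hz,
Pearson correlation, Fisher z on off-diagonals. Two seconds are trimmed at
each edge before correlating to discard filter transients. Envelope
values are already unbounded, so they enter the NMA regression without the
logit.

**Distance.** Pairwise Euclidean distance between electrode midpoints is
divided by the layout's maximum pairwise distance (a dimensionless,
bounded choice; the normalization is configurable and enters the model
only as a covariate, so any strictly monotone variant changes results
marginally) and linearized as `exp(−d)`: 1.0 at zero separation, `e^−1` at
the layout's maximum separation.

**Evoked power.** Per trial, power windows are [−950, −50) ms before
stimulation onset and [+50, +950) ms after offset; 0-based half-open
sample indexing with `start = round(t·fs)` makes the 900 ms and 350 ms
windows exact to the sample at 500, 1000, and 1600 Hz. The paired
t-statistic is computed on natural-log powers (the base is immaterial —
t is scale-free). No per-electrode p-values are attached, because
sequential trials are not independent. Whole-brain averages drop
electrodes with t > 10 (guarding against artifact-corrupted raw power);
this ceiling is not applied inside the NMA regression. Trials at different
stimulation amplitudes and pulse frequencies are pooled.

**Artifact screening.** Per channel, the trialwise mean voltage in the
350 ms before onset is compared with the 350 ms after offset by a paired
t-test and by a Levene test for unequal variances (Brown–Forsythe,
median-centered, for robustness; mean-centering is a switch). Either test
at P < 0.01 excludes the channel, so the null exclusion rate is
1 − 0.99² ≈ 2%. The 350 ms windows abut the stimulation interval exactly.

**NMA.** OLS of the per-electrode t-statistics on an intercept,
linearized distance, and logit connectivity (coherence clipped to
[1e−6, 1 − 1e−6] before the logit, since degenerate synthetic estimates
can touch the bounds). The permutation null shuffles the predictor *rows*
(connectivity and distance jointly, preserving their pairing — the
literal reading of permuting "the order of the predictors"); shuffling
connectivity alone is available as `mode="connectivity"`. Permutations are
independent uniform draws (collisions allowed, identity not excluded),
1000 by default, seeded. z uses the null's n−1 sample SD; p is the
add-one-smoothed two-tailed count, so it is never exactly zero. Sites
with fewer than 10 included electrodes raise a hard error.

**Group analyses.** Stimulation sites are categorized by white matter:
expert in-white-matter labels first, the rest split at the median
distance-to-white-matter. The default reads "near white matter" as
*closer* than the median (the semantically coherent direction; the
opposite reading of the percentile rule exists in the literature and is
available as `direction="near_is_far"`). Ties at the median go to "near".
The ordered-trend statistic is min(t(near vs gray), t(in vs near)) under
label permutation. Terciles split by rank with remainders assigned to the
middle bin; hub and strongest-five analyses are intended for in/near-white
matter sites. The NMA-by-frequency profile recomputes the statistic per
1 Hz network, tests each frequency against zero across sites, applies
Benjamini–Hochberg step-up FDR over the 47 frequencies, and smooths only
the returned display curve (3-point moving average), never the
statistics. Directional counts of individually significant sites are
tested against an exact upper-tail binomial with success probability α.

## Synthetic data: what is planted and what is not

The generator produces the statistical structure the analysis assumes,
with exact bookkeeping:

- **Layouts**: uniform in a 60 × 60 × 40 mm box, rejection-sampled to a
  3.5 mm minimum spacing (matching real 3.5–10 mm contact spacing);
  absolute geometry is irrelevant because distance enters only as a
  covariate. White-matter distance ~ Uniform(0, 10) mm. Virtual electrode
  i is the pair (C*i*, C*i+1*), so adjacent electrodes genuinely share a
  physical contact and the shared-contact exclusion is exercised.
- **Baseline coherence**: independent narrowband latent sources (sinusoid
  with per-10-s-period random phase) mixed into channels plus white
  noise — the simplest model with controllable coherence targets.
  Channel SNR (source variance over noise variance) defaults to 2.
- **Stimulation sessions**: per-trial pre/post log theta power is drawn
  Normal with post-mean shift
  `δ_e = β0 + β_conn·logit(c_e) + β_dist·d_e`, and each 900 ms segment is
  a fixed theta carrier (bin-centered near 6.5 Hz) scaled so its
  multitaper theta power equals the drawn value *exactly* (power is
  quadratic in amplitude). Ground truth therefore lives at precisely the
  level the pipeline measures, and the drawn log powers are exposed
  directly (`simulate_log_power_trials`) for Monte-Carlo calibration at
  scale; the equality of the two routes is itself a test.
- **Defaults** (`β0 = 0.05`, `β_conn = 0.02`, `β_dist = 0.1`,
  `noise_sd = 0.2` natural-log units, 240 trials, 60 electrodes): trial
  counts and electrode scale follow the stimulation paradigm being
  modeled; the per-trial log-power SD is not reported for real data, so
  0.2 was chosen once to give per-electrode t-statistics of realistic
  single-digit magnitude at 240 trials, and the effect sizes sit well
  clear of both the null and saturation. With these defaults the planted
  connectivity term explains far more than 15% of t-statistic variance.
- **Artifacts**: a DC offset and/or variance inflation applied to the
  post-stimulation 350 ms screening windows of chosen channels. Variance
  scaling is centered on the channel's across-trial mean so that it
  inflates trial-to-trial variability — the quantity the Levene screen
  tests.
- **HFB rest**: channel groups share a slow band-limited (0.05–0.5 Hz)
  Gaussian amplitude envelope at 50% depth on independent broadband
  carriers. The slow noise is synthesized spectrally (band-masked FFT of
  white noise) because time-domain IIR filtering is numerically
  ill-conditioned at such corners and its edge transients would correlate
  all channels.

What the generator does **not** emulate: 1/f background spectra, volume
conduction, non-sinusoidal or non-stationary oscillations, stimulation
waveform physics, autocorrelated trial sequences, or any biophysics.
Passing tests therefore establish that the estimators and statistics are
correct and calibrated under the assumed model — not that the assumptions
hold in clinical recordings. In particular the permutation null assumes
exchangeable electrodes given the predictors, which real spatially
correlated noise can violate.

## Calibration and problem sizes

The acceptance tests fix these study conditions: null calibration uses
200 sessions (60 electrodes, 240 trials, β_conn = 0, 1000 permutations) and
requires the two-tailed 5% rejection rate in [2%, 9%]; recovery uses 100
sessions through the full segment + multitaper path and requires NMA
detection (z ≥ 1.96) in ≥ 80% and the mean OLS estimate of β_conn within
±5% of the planted value; coherence recovery requires AUC ≥ 0.95 for
source-sharing vs non-sharing pairs at SNR 2 with 100 windows; the
artifact screen must catch a +50 µV offset at 240 trials always and hold
its null exclusion rate in [0.5%, 4%] over 1000 channels. For the
white-matter trend, 12 sites (4 per category) with 2 SD gaps were fixed
after a prospective power analysis showed ≥ 1 SD gaps reach the required
≥ 90% detection only marginally at this n; 2 SD is comfortably inside the
allowed regime, and the type-I rate is checked in [2%, 9%] under label
exchangeability.

Cross-spectra, band coherence, OLS coefficients, and BH-FDR are each
checked against independent literal implementations (taper-DFT-average
loops, normal equations, brute-force step-up) at 1e−10/1e−8/1e−12, and
band power against MNE's multitaper PSD.

## Numerical notes and limitations

- Determinism: every stochastic routine takes a seed
  (`numpy.random.default_rng`); identical inputs and seeds give
  bit-identical outputs, including the full pipeline report hash.
- Degenerate inputs: all-zero power segments return 0 and are flagged
  before the log; zero-variance log-power differences give t = NaN with a
  flag; constant connectivity rows and collinear designs raise; empty
  theta-responsive subsets are flagged states, not errors.
- EDF input is supported read-only (16-bit quantization makes it lossy);
  the bit-exact interchange format is the HDF5 container with JSON
  sidecar. Tables (layouts, events, adjacency, contrasts) are UTF-8 TSV.
- The notch handles the line fundamental only; harmonics above it are
  outside the analyzed 4–50 Hz coherence range but do intersect the HFB
  band, where the 10 Hz sub-band structure dilutes rather than removes
  them.
- No directed or phase-lag connectivity measures, no multivariate
  prediction model combining networks, and no anatomical localization:
  white-matter distances and labels are inputs.
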