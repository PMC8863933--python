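# Methods

This note documents the models and procedures implemented in
`mosaicspeech`, the parameters that matter, the numerical choices behind
them, and what the synthetic-data layer does and does not emulate.

## The stimulus chain

### Critical-band analysis

Audio is decomposed into contiguous critical bands on the Zwicker/Bark
scale. The band edges come from the standard critical-bandwidth table
(interior edges 100, 200, 300, 400, 510, 630, 770, 920, 1080, 1270, 1480,
1720, 2000, 2320, 2700, 3150, 3700, 4400, 5300 Hz); clipping the table to
50–6400 Hz yields exactly 20 bands, the configuration used throughout.
This is the unique Bark-table realisation of a 20-band bank over that
range.

The filterbank is zero-phase frequency-domain masking. Interior band edges
carry raised-cosine amplitude transitions one tenth of the narrower
neighbouring bandwidth wide; the two halves of each transition are
complementary, so the per-band masks sum exactly to a brickwall band-pass
over the full analysis range and the band signals sum to the band-limited
input (machine-precision reconstruction; the test suite checks < 1%
against an independently constructed brickwall reference). The outer edges
are hard cutoffs, which keeps band-energy bookkeeping exact at the price
of some ringing in the outermost bands. Each raised-cosine transition of
width *t* carries 3/8 of the brickwall power, i.e. an analytic −*t*/8
correction per edge to a band's effective noise bandwidth; the band-noise
tests use this closed form.

### Sound energy density

Band intensity (squared amplitude, no calibration constant — only ratios
matter downstream) is smoothed by a Gaussian moving average with
σ = 5 ms, truncated at ±4σ (< 0.01% kernel mass lost) and renormalised
over the valid support at the signal edges, so constant intensity maps to
a constant envelope up to the endpoints. The kernel's modulation transfer
is exp(−2π²σ²f²); the measured response matches this within 0.1% at
10–80 Hz. Note that the −3 dB point of this kernel is ≈ 26.5 Hz; a 45-Hz
figure sometimes quoted for σ = 5 ms smoothing corresponds to a different
cut-off convention, so the kernel is implemented exactly and no cut-off
parameter exists. Convolution runs in the FFT domain (the kernel spans
~1800 taps at 44.1 kHz).

### Mosaic and noise-vocoded synthesis

Mosaicking averages each band's energy density within fixed-length
segments (40, 80, 160, 320 ms in the standard conditions; a final partial
segment is averaged over its actual length so total energy is preserved).
Independent white-noise carriers are generated per band from substreams of
one master seed, filtered by the same masks, and their own energy density
is segment-averaged the same way; the per-segment amplitude gain is
√(patch / carrier-segment-average), with a floor of 10⁻¹⁰ × the peak
carrier reference to keep silent patches from amplifying noise. Noise
vocoding is the same chain without segmentation: the gain is the pointwise
ratio of source to carrier smoothed energy density, and the condition is
tagged 0 ms. The summed waveform is RMS-matched to the source (< 1%),
with a hard guard against full-scale overflow.

Ramp convention (underdetermined in the source description, isolated in
one function): per-segment gains are interpolated across each boundary by
a raised-cosine transition of 5 ms centred on the boundary, and the whole
stimulus is gated by 5-ms raised-cosine fade-in/out. Because adjacent
segments share one coherent band carrier, interpolating the *gain* (rather
than cross-fading two power-complementary windows) produces zero power dip
between equal-gain segments. The transition half-width is clipped to the
shortest adjacent segment, which makes one-sample segments well defined;
in that limit mosaicking reproduces noise vocoding exactly (verified to
machine precision).

### What patch re-analysis can and cannot recover

Re-analysing a mosaic stimulus through the same filterbank + smoother and
segment-averaging recovers the construction grid only up to the smoothing
kernel's boundary flux: the ±4σ = ±20 ms kernel transports energy between
adjacent segments in proportion to their power contrast (≈ σ/(L√2π) ≈ 5%
per boundary side at L = 40 ms). For speech-like material, whose
adjacent-segment contrasts routinely exceed 3×, per-patch recovery within
5% is therefore impossible at short segment durations *even for an ideal
piecewise-constant-power stimulus* — this is a property of the analysis,
not an implementation defect. Conservation improves monotonically with
segment duration (the flux fraction scales as 1/L); the acceptance
machinery reports the measured rates at 40–320 ms, and the strict
invariant is asserted at 320 ms where the flux is small.

## Modulation power spectrum

The MPS is computed Flinker-style: Gaussian-windowed STFT (σ = 16 ms, hop
2 ms), power interpolated onto a log-spaced frequency axis (50–6400 Hz,
12 bins/octave), log taken with a floor of 10⁻¹⁰ × the maximum (making
the MPS exactly invariant to input gain), mean removed per 1-s chunk (50%
overlap, chunk coverage centred on the signal so time reversal maps chunks
onto chunks), 2-D FFT, squared magnitude averaged over chunks. The grid
keeps the signed temporal-modulation axis (upward and downward sweeps are
distinct; time-reversing the input mirrors the map about 0 Hz to machine
precision) and the non-negative spectral-modulation half-plane, with row
multiplicities (2 for interior rows) restoring the full-plane Parseval
identity: total weighted power equals the chunk-averaged variance of the
mean-removed log-spectrogram, exactly.

All STFT parameters are configurable; the defaults above are this
package's fixed choice since the upstream description does not restate
them.

### Pixelwise mixed ANOVA

The confound check runs, at every MPS pixel, a two-way mixed ANOVA on log
power with segment duration as the within-replicate factor and language as
the between-replicate factor; sentences are the replicates. The language
effect is tested against between-sentence variation within languages;
segment duration and the interaction against the sentence × duration
residual. The implementation is vectorised over pixels, requires a
balanced design (every sentence at every duration, equal sentence counts
per language), and agrees with `pingouin.mixed_anova` to 8 significant
figures on single pixels. Under the null, 5% ± 0.5% of pixels fall below
p = 0.05. Log rather than linear power is used (the upstream choice is
unstated); the floor is 10⁻¹⁰ × max.

Sign maps follow the hot/cold display convention: +1 where power is more
prominent at shorter segment durations (negative linear trend of the
duration level means), in the designated hot language (mean difference),
or — for the interaction — where the duration trend advantage and the
language difference point the same way (a label-swap leaves the
interaction sign invariant and flips the language sign exactly).

## Experimental design and scoring

Designs are randomised blocks: each block presents every condition exactly
once in random order, sentences are drawn without replacement per
participant from the sentence × condition universe (1000 combinations for
a 200-sentence inventory at 5 conditions, 390 for 78 sentences), and the
first block is practice. Thirty trials per participant, five of them
practice, at the standard 6 × 5 design.

Nominal segment duration is normalised by speaker rate: effective = nominal
× (speaker unit rate / mean rate over speakers). The direction — a
faster-than-average speaker yields a *longer* effective duration, because
each segment spans more linguistic units — is this package's reading of an
underdetermined convention, and is configurable by inverting the ratio.

Responses are scored per unit (mora or tone-marked syllable) by global
order-preserving alignment against the reference: match = same homophone
class (+1), mismatch and gap = 0, leftmost-preferring tie-break. An
aligned unit is correct only if its segmental class matches and — for
tonal languages — its tone also matches; a segmental match with a wrong
tone is counted as a tone-only error and scored incorrect. A blank
response scores zero. The dynamic program equals an exhaustive maximal
order-preserving matching on sequences up to 8 units (property-tested),
and adding a unit to a response can never lower the score. How mislocated
partial responses map to reference positions is underdetermined upstream;
order-preserving alignment is one defensible operationalisation.

## Statistical models

### Logistic GLMM

Unit-level binary outcomes are fitted with a logistic mixed model with a
single participant random intercept, by maximum likelihood. The
random-effect integral is evaluated with adaptive Gauss–Hermite quadrature
(default 15 nodes, minimum 9): per group, a Newton search finds the
posterior mode of the intercept, and the quadrature grid is centred there
and scaled by the local curvature. The quadrature agrees with brute-force
`scipy.integrate.quad` integration to < 10⁻⁴ in log-likelihood on small
data sets, and the model reduces to an ordinary logistic GLM as
σ_u → 0. Rows with identical (group, covariates, outcome) are collapsed to
weighted sufficient statistics before fitting, which makes a full
31-participant study fit in well under a second.

Optimisation is BFGS with analytic gradients (the score is the posterior
expectation of the complete-data score under the quadrature weights, whose
grid-dependence error is of quadrature order — verified against finite
differences to 10⁻⁸) over (β, log σ_u), started from a GLM fit, in a
column-scaled parameter space so millisecond-scale covariates do not
ill-condition the search. Convergence requires the gradient norm below
10⁻⁶ *relative to the log-likelihood magnitude* (an absolute criterion is
meaningless across data sizes); failure raises a diagnostic error with the
optimiser trace. Separation is flagged when a coefficient's curvature
vanishes on the linear-predictor scale. Standard errors come from the
numerically differentiated Hessian at the optimum; Wald χ² per coefficient
is (β/SE)². AICc uses k = (fixed effects + 1 variance component) and
n = unit-level rows; AUC uses conditional fitted probabilities with
empirical-Bayes intercepts.

### Beta-binomial regression

Trial-level (n_correct, n_units) counts are fitted with a beta-binomial
likelihood: mean μ = logistic(Xβ), intra-trial correlation ρ ∈ [0, 1) via
α = μ(1−ρ)/ρ, β = (1−μ)(1−ρ)/ρ. The log-likelihood approaches the
binomial logistic one as ρ → 0 (difference < 0.01 at ρ = 10⁻⁶, with a
numerically stable binomial branch below ρ = 10⁻⁸). Fitting is BFGS with
the analytic digamma-form score over (β, logit ρ), started from a GLM fit.
Boundary fits (ρ ≈ 0 or 1, or all trials fully correct/incorrect) are
flagged with warnings. AICc uses n = trials, the model's observation
level; AUC expands trial counts to unit-level outcomes against the fitted
trial means. This μ/ρ parameterisation is declared rather than inherited:
the exact form used by proprietary statistical software is not public, and
fractional-denominator-df F approximations are deliberately not
replicated — inference is by Wald tests.

Both models recover their generating parameters at the full study design
size (16 + 15 participants, 25 scored trials each) with slope bias ≈ 1%
over 200 replicates, well within the 2-SE / 10% criteria the test suite
asserts.

## Synthetic data

### Pseudo-speech

A sentence is a sequence of syllable-like units at the profile's unit rate
(±10% duration jitter): a harmonic source (1/h rolloff to 6 kHz, 5%
aspiration noise) whose per-unit f0 contour is drawn from the profile —
four lexical-tone templates (high level, rising, dipping, falling) around
a 220-Hz female-range base for the tonal profile, flat contours with
sentence-level declination for the non-tonal one — shaped by two random
formant resonances (F1 300–800 Hz, F2 900–2200 Hz, as two half-unit
stationary filters approximating a glide) plus a fixed F3 at 2.8 kHz, and
gated by a raised-cosine syllable envelope. Default profiles: non-tonal,
8 units/s, 200 sentences of 19 ± 3.1 units; tonal, 5.5 units/s, 78
sentences of 10 ± 1.3 units; 10 speakers per language with 5% relative
rate scatter.

What this emulates: syllable-rate amplitude modulation, formant structure,
tonal vs. flat pitch, speaker-rate variation, annotation schemas. What it
does not: real phonotactics, coarticulation, or intelligible speech — so
passing tests demonstrate the *machinery* (synthesis bookkeeping, design
logic, estimator calibration) on speech-shaped signals, not perceptual
validity on real recordings.

### Simulated listener

Each unit is correct with probability
p = γ + (λ−γ)·logistic((d₅₀ − d)/s + language offset + participant
intercept), where d is the speech-rate-normalised segment duration (0 for
the vocoder control, which lands on the ceiling), the participant
intercept is N(0, σ²) on the logit scale, and tonal units that would be
correct flip to a tone-only error with a fixed rate. Units are independent
given the trial (the GLMM's own assumption); overdispersion beyond that
enters through the beta-binomial pathway, which has its own direct
simulator for recovery checks.

Calibration defaults — λ = 0.99, γ = 0.08, d₅₀ = 85 ms, s = 11 ms, tonal
offset −0.6 logits, participant SD 0.5, tone-error rate 0.12 — were chosen
once so the default curve echoes the studied shape: non-tonal ceiling
≈ 97% at 40 ms, tonal ≈ 85% (a 12–18% gap from offset plus tone errors,
so the two-language *mean* at ceiling is ≈ 91%, not > 95%), both floors
≈ 6–8% beyond 160 ms. These are calibration defaults for exercising the
pipeline, not empirical claims.

## Pipeline scaling

The default end-to-end run simulates behaviour at the full study design
(16 + 15 participants over the 200/78-sentence inventories — responses
are driven by the psychometric model, not by rendered audio) while
synthesising audio and MPS maps for a 2-sentence-per-language subset at 5
conditions (20 stimuli, 16 mosaic MPS maps). This keeps a complete run
around a minute on one CPU; the audio subset size is a pure compute choice
and is configurable. Every output file carries a JSON sidecar recording
the package version, stage, master seed and full configuration; stage
seeds are derived from the master seed via hashed `SeedSequence` branches,
so reruns are bit-identical.

## Known limitations

- Patch-energy re-analysis at short segment durations is bounded by
  smoothing-kernel boundary flux (see above); this is intrinsic to the
  σ = 5 ms analysis chain.
- The pixelwise ANOVA requires a balanced design; unbalanced sentence
  counts per language are rejected rather than approximated.
- The filterbank's hard outer edges ring; gammatone/ERB banks and loudness
  models are out of scope.
- The beta-binomial AUC treats units within a trial as exchangeable.
- WAV I/O is scipy-based (PCM16/float32, mono, polyphase resampling on
  load); exotic container formats are not supported.
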