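# mosaicspeech

Tools for studying how degrading the *temporal resolution* of speech
affects its intelligibility, for auditory psychophysicists and speech
scientists. The package implements the complete computational chain
around mosaic-speech experiments — stimulus synthesis, acoustic confound
analysis, experimental design and scoring, and the intelligibility
statistics — together with a synthetic pseudo-speech / simulated-listener
layer, so every stage runs and is testable without licensed recordings or
human participants.

## What it computes

**Stimuli.** Speech is decomposed into 20 critical bands (Zwicker/Bark
scale, 50–6400 Hz) and each band's sound energy density is computed as a
Gaussian moving average (σ = 5 ms) of intensity. Three degradations:

- *Mosaic speech*: energy density is averaged within fixed time segments
  (segment duration *SD* = 40, 80, 160, 320 ms), and each time ×
  critical-band patch drives a matched band-noise carrier with gain
  √(patch / carrier-segment-average), with 5-ms raised-cosine gates —
  periodicity and temporal fine structure removed, temporal resolution
  degraded to *SD*.
- *Noise-vocoded speech*: the same chain without segmentation (the 0-ms
  control condition).
- *Locally time-reversed speech*: consecutive *SD*-length waveform
  segments each reversed in place.

**Modulation power spectrum (MPS).** The squared 2-D Fourier transform of
the mean-removed log-spectrogram over (temporal modulation in Hz, signed ×
spectral modulation in cycles/octave), chunk-averaged; plus a pixelwise
two-way mixed ANOVA (SD within sentences, language between) producing the
p-value and sign maps used to check the stimuli for spectrotemporal
confounds.

**Experiment.** Randomised block designs (every condition once per block,
sentences sampled without replacement; first block practice), speech-rate
normalisation of segment durations (nominal × speaker rate / mean rate),
and per-unit scoring of transcribed responses by order-preserving
alignment, with homophone equivalence and tone-sign checking for tonal
languages.

**Statistics.** Two statsmodels-style model classes whose `fit()` returns
a results object with coefficients, standard errors, Wald χ² tests, AICc
and AUC, and a `summary()` table:

- `LogisticGLMM` — unit-level logistic mixed model with a participant
  random intercept, ML via adaptive Gauss–Hermite quadrature:
  logit P(correct) = Xβ + u, u ~ N(0, σ²ᵤ).
- `BetaBinomial` — trial-level beta-binomial regression:
  μ = logistic(Xβ), overdispersion ρ via α = μ(1−ρ)/ρ,
  β = (1−μ)(1−ρ)/ρ.

**Synthetic data.** Pseudo-speech with syllable-rate amplitude
modulation, formant structure and tonal vs. flat pitch contours, and a
simulated listener whose per-unit accuracy follows a ceiling–slope–floor
psychometric curve over normalised segment duration with participant- and
language-level effects.

## Worked example

```python
from mosaicspeech import zwicker_band_edges, make_mosaic_speech, RunConfig
from mosaicspeech.pipeline import run_response_stage, run_analysis_stage
from mosaicspeech.synthetic import generate_pseudo_speech, japanese_profile

bands = zwicker_band_edges(50, 6400)          # 20 critical bands
sig, annot = generate_pseudo_speech(japanese_profile(), n_units=8, seed=1)
stim = make_mosaic_speech(sig, bands, segment_duration_ms=160, seed=7)
print(f"source: {sig.duration:.2f} s RMS {sig.rms:.3f} -> {stim.kind}, RMS {stim.audio.rms:.3f}")

cfg = RunConfig(seed=42, output_dir="run", run_mps=False)
responses = run_response_stage(cfg)           # 16 + 15 simulated listeners
report = run_analysis_stage(cfg, None, responses)
```

prints

```
source: 1.03 s RMS 0.100 -> mosaic, RMS 0.100
```

and the report's intelligibility table is

```
language  segment_duration_ms  percent_correct  se  n_participants
japanese                  0.0             98.5 0.4              16
japanese                 40.0             96.9 0.5              16
japanese                 80.0             63.1 3.2              16
japanese                160.0              7.3 0.7              16
japanese                320.0              8.6 0.6              16
mandarin                  0.0             87.3 1.2              15
mandarin                 40.0             82.3 1.1              15
mandarin                 80.0             49.1 4.0              15
mandarin                160.0              7.3 1.0              15
mandarin                320.0              9.1 1.2              15
```

— the curve the simulator is calibrated to: ceiling through 40 ms, a
steep fall between 40 and 160 ms, a floor below 10% beyond, and the tonal
language sitting 12–18% lower at ceiling. Fitting the trial-level counts:

```python
from mosaicspeech.stats import BetaBinomial

scored = responses[(~responses.is_practice) & (responses.segment_duration_ms > 0)]
terms = ["language", "norm_segment_duration_ms", "language:norm_segment_duration_ms"]
print(BetaBinomial.from_dataframe(scored, "n_correct", "n_units", terms).fit().summary())
```

```
Beta-binomial regression (logit mean, ML)
  trials: 620
  log-likelihood: -1328.27   AICc: 2666.6   AUC: 0.889
  rho: 0.1964

                                               coef     se  wald_chi2      p
Intercept                                    2.0112 0.1258   255.7873 0.0000
language[mandarin]                          -0.8673 0.1628    28.3880 0.0000
norm_segment_duration_ms                    -0.0165 0.0011   244.9370 0.0000
language[mandarin]:norm_segment_duration_ms  0.0033 0.0013     6.9128 0.0086
```

Both main effects (language, normalised segment duration) are strongly
supported; the AUC ≈ 0.89 summarises how well the fitted means rank the
unit outcomes, and ρ ≈ 0.20 is the estimated intra-trial correlation.

A command-line interface mirrors the library:

```sh
mosaicspeech run --seed 42 --output-dir run      # full synthetic study
mosaicspeech degrade --input in.wav --kind mosaic --segment-ms 40 \
    --seed 7 --output out.wav                    # one stimulus + JSON sidecar
mosaicspeech design --n-sentences 200 --output design.csv
mosaicspeech score --reference "ma2 ka1" --response "ma3 ka1" --tonal
mosaicspeech fit --responses run/responses/responses.csv --family betabinomial
```

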