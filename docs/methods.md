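# Methods

`coo-id` quantifies vocal individuality in short, harmonic-rich, weakly
frequency-modulated calls ("coo" calls) from per-call acoustic measurements.
It bundles four stages — a source-filter call synthesizer, an acoustic
feature extractor, the corrected-CV/PIC individuality statistics with a
nonparametric screen, and a PCA → DFA → leave-one-out classification stage —
plus a pipeline that runs them end to end under one master seed.

## The synthesizer

The generator implements the standard source-filter production model:

- **Source.** A band-limited additive pulse train: harmonics of the per-call
  f0 contour with amplitudes 1/h², i.e. a −12 dB/octave glottal tilt. A first
  difference adds the +6 dB/octave lip-radiation characteristic, so the
  radiated waveform carries the −6 dB/octave net tilt that formant analysis
  with single pre-emphasis assumes. Contours come in four families (flat,
  fall, rise, arc) with a depth expressed as a fraction of the call's mean
  f0; contours that would leave the 75–1200 Hz analysis window are clipped
  with a warning.
- **Filter.** A cascade of second-order resonators at the closed-open
  uniform-tube positions F_k = (2k−1)·ΔF/2, k = 1…6, with
  ΔF = c/(2L), c = 350 m/s (the warm-humid-tract convention) and L the
  vocal-tract length. Per-individual additive offsets perturb F1–F4; the 5th
  and 6th resonances sit at their unperturbed tube positions so the spectrum
  above F4 is filled the way a real tract fills it — a tract truncated at F4
  leaves the LPC analysis modelling roll-off with its remaining poles and
  destabilizes the F4 estimate. Resonator bandwidths grow mildly with centre
  frequency (80 + 0.03·F Hz, capped at 200 Hz).
- **Noise.** White aspiration noise passed through the same resonator
  cascade and mixed at a linear RMS gain relative to the harmonic part; this
  single gain controls the measured harmonics-to-noise ratio monotonically.
- **Envelope.** Raised-cosine onset/offset of 25 ms (or 10 % of the call,
  whichever is shorter); the waveform is peak-normalized to 0.9, standing in
  for the level standardization recordings receive in practice.

`make_population(k, separation, within_scale, seed)` draws k caller
profiles. Every between-individual SD scales with `separation` and every
within-individual (call-to-call) SD with `within_scale`; `separation = 0`
yields a null population of identical profiles. Baselines: mean f0
340 Hz (between-SD 40 Hz per unit separation, within-SD 12 Hz), vocal tract
9.6 cm (between-SD 0.3 cm), formant offsets SD 45 Hz clipped at ±90 Hz,
duration 0.55 s (between-SD 0.07 s, within-CV 0.08), noise gain 0.06
(log-SD 0.35). Sampled f0 is clipped to 240–460 Hz and tract length to
9.3–9.9 cm: this keeps the fundamental well below F1 and the 5th resonance
above the 8 kHz formant ceiling, the regime in which the stated analysis
settings (five formants below 8 kHz, order-10 LPC) are internally
consistent. For seven callers the default call counts follow the unbalanced
reference pattern 12, 16, 33, 23, 40, 24, 14 (162 calls).

What the generator does *not* emulate: field noise and reverberation,
amplitude-modulation structure, vocal-fold biomechanics (jitter/shimmer),
context-dependent call types, or recording-chain colouration. Passing tests
therefore certify the *analysis chain* — that the statistics recover known
structure from audio — not robustness to real field recordings.

## Feature extraction

Fourteen parameters per call: duration; mean/SD/min/max/range/start/end f0;
mean HNR; mean F1–F4; ΔF.

- **Pitch** (`extract_pitch`): frame-local normalized cross-correlation,
  time step 0.01 s, window and maximum lag of one 75 Hz period, candidate
  lags spanning 75–1200 Hz, parabolic peak interpolation. A frame is voiced
  when its peak correlation reaches 0.45. Among local maxima within 0.04 of
  the best correlation the *shortest* lag wins — for harmonic sources the
  half-period correlation is strongly negative, so this suppresses
  period-doubling (octave-down) errors without a dynamic-programming path
  finder. The full path-finder is unnecessary for weakly modulated calls and
  is deliberately omitted.
- **f0 summary**: statistics over voiced frames only; SD is the sample
  (n−1) SD; range = max − min by construction.
- **Duration**: last minus first voiced frame time plus one time step. Edge
  resolution is one analysis window (~27 ms per side), so durations carry
  that uncertainty; silence padding shifts the measured span by at most
  about 1.5 windows.
- **HNR** (`compute_hnr`): same correlation machinery, window of
  `periods_per_window` (default 1) periods of the 75 Hz minimum pitch; frame
  HNR = 10·log₁₀(r/(1−r)) with r clipped to [1e−6, 1−1e−6] (±60 dB); frames
  below 0.1 × the global peak amplitude are skipped; the call value is the
  mean over retained frames.
- **Formants** (`extract_formants`): resample to 16 kHz (2 × the 8 kHz
  ceiling), pre-emphasize above 50 Hz, 0.05 s Gaussian-tapered frames every
  0.01 s, Burg LPC of order 10 (2 × the five-formant budget), roots of the
  LPC polynomial converted to frequency/bandwidth pairs; candidates kept
  when 50 Hz < F < 7950 Hz and bandwidth < 400 Hz, assigned
  lowest-four-by-frequency per frame, averaged over frames where defined.
  Frames below a tenth of the peak frame RMS are treated as silence. If
  fewer than half the active frames yield four candidates the call is
  flagged as a formant failure (and excluded with a logged reason when the
  pipeline runs in screening mode).
- **ΔF** (`estimate_delta_f`): zero-intercept least-squares slope of F_k on
  (2k−1)/2, the closed-at-glottis uniform-tube regression:
  ΔF = Σ F_k x_k / Σ x_k².

Known limitation: when the fundamental approaches F1 (f0 ≳ F1/2), the
spectral envelope is sampled too coarsely by the harmonics and per-call F1
estimates snap toward harmonic positions. At the generator's default
register the median F1 error stays near 4 %; higher registers degrade it.
This is a property of LPC on high-pitched voices, not of this
implementation specifically.

## Individuality statistics

The coefficient of variation uses the small-sample correction
CV = 100·(1 + 1/4n)·(SD/x̄). Per parameter:

- CV_w is computed within each caller and averaged, unweighted, across
  callers;
- CV_b defaults to the CV over all calls pooled (`between_mode=
  "pooled_calls"`); the per-caller-means variant is available as
  `"individual_means"` since published usage is split between the two
  conventions;
- PIC = CV_b / mean CV_w; PIC > 1 marks a parameter whose between-caller
  variation exceeds its within-caller variation.

The screen mirrors the standard nonparametric route: a Kruskal–Wallis test
per parameter (tie-corrected H, chi-square p); when significant at 0.05, all
k(k−1)/2 pairwise Mann–Whitney U tests two-tailed at the Bonferroni level
family_alpha / C(k,2) — 0.05/21 ≈ 0.002 for seven callers. Pairwise p-values
use exact enumeration for tie-free samples of at most 8 per group and the
tie/continuity-corrected normal approximation otherwise.

Null-calibration caveat: PIC is a ratio of estimated CVs and its null
sampling spread shrinks roughly as 1/√n per caller. With ~8 calls per
caller, null PIC for noisy parameters ranges over roughly ±0.15; by ~24
calls per caller the ±0.1 band holds across parameters and seeds. The null
suite therefore uses 24 calls per caller.

## Discrimination

- **PCA** on the correlation matrix of the 14 parameters (mixed units make
  the covariance option inappropriate as a default; it remains available).
  Components with eigenvalue > 0.6 (relaxed Kaiser rule) are retained and
  varimax-rotated (classic pairwise-rotation algorithm, criterion tolerance
  1e−8, at most 500 sweeps; orthogonal, so communalities are preserved).
  Scores use the regression method, Z·R⁺·Λ. The pseudo-inverse is required,
  not a convenience: range f0 = max f0 − min f0 makes the correlation matrix
  singular by exactly one rank.
- **Normality check**: one-sample Kolmogorov–Smirnov of each component's
  scores against a normal with the component's own mean and SD; reported,
  not used as a gate.
- **DFA**: linear discriminant on the retained component scores; pooled
  within-class covariance with ridge λ = 1e−8 × (mean diagonal) so
  near-singular leave-one-out folds stay invertible; class priors equal to
  observed group sizes by default (`priors="uniform"` available); canonical
  functions from the generalized eigenproblem of between- versus
  within-class scatter, min(k−1, p) of them, with eigenvalues and percent of
  between-class variance. Posterior ties break by class order
  (deterministic).
- **LOOCV**: each call classified by a discriminant refit on the remaining
  calls. Priors are computed once from the full sample and held fixed across
  folds — the behaviour of the reference procedure, which sets the
  group-size adjustment once — and standardization/PCA are likewise fitted
  once on the full data set before the loop (the reference analysis ran PCA
  once, then cross-validated inside the DFA only). Re-estimating priors per
  fold adds a systematic bias against each held-out call's own class and
  pushes null accuracy below chance.
- **Headline numbers**: accuracy = 100 × trace/total of the confusion
  matrix; chance = 100/k; a one-sided exact binomial tail
  P[X ≥ correct | Binomial(total, 1/k)] tests whether classification beats
  chance (the claim is directional, hence one-sided).

## Problem sizes used by the test suite

The suite synthesizes its own audio. The reference-scale checks use one
7-caller, 162-call population (~90 s of audio); the null-calibration suite
uses twenty 7-caller populations of 24 calls each at 0.45 s per call. These
sizes are where the estimators' behaviour has converged enough for the
stated bands while keeping the suite quick on one CPU.

## Numerical and degenerate-input choices

- Formant analysis resampling uses a rational polyphase filter (160/441 for
  44.1 kHz → 16 kHz).
- Correlation peaks at segment borders are not interpolated (no interior
  maximum → frame unvoiced).
- A parameter with zero within-caller SD for some caller yields PIC = NaN
  for that parameter — reported, never silently dropped.
- All-identical values in the rank tests raise a degenerate-ranks error
  rather than returning p = 1.
- Synthesis determinism: per-call seeds are drawn once from the master seed,
  so identical configurations produce bit-identical WAV files.
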