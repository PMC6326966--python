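# coo-id

Vocal-individuality analysis for harmonic "coo"-type contact calls, built for
bioacousticians who want a reproducible, scriptable version of the classic
caller-identity workup: measure source- and filter-related acoustic
parameters per call, ask which parameters could encode caller identity, and
quantify how well callers can actually be told apart.

The package also ships a source-filter call synthesizer, so the whole chain
can be exercised — and its statistical behaviour calibrated — on audio with
known ground truth, without any field recordings.

## What it computes

For each call (mono WAV, one call per file) fourteen parameters are
measured with conventional analysis settings (pitch window 75–1200 Hz, time
step 0.01 s; five formants below 8 kHz via Burg LPC; cross-correlation HNR):
duration; mean, SD, min, max, range, start and end fundamental frequency
(f0); mean harmonics-to-noise ratio (HNR); mean formants F1–F4; and formant
dispersion ΔF, the zero-intercept regression slope of F_k on (2k−1)/2 under
the closed-open uniform-tube model (ΔF = c/2L).

Three analyses follow:

1. **Potential for individual identity coding (PIC).** With the
   small-sample-corrected coefficient of variation
   CV = 100·(1 + 1/4n)·(SD/x̄), each parameter gets a within-caller CV
   (averaged over callers), a between-caller CV (all calls pooled), and
   PIC = CV_b / mean CV_w. PIC > 1 flags a parameter that varies more
   between callers than within a caller.
2. **Nonparametric screening.** Kruskal–Wallis per parameter across callers;
   where significant, all pairwise Mann–Whitney U tests at the Bonferroni
   level α/C(k,2) (0.05/21 ≈ 0.002 for seven callers).
3. **Discrimination.** Standardized PCA on the 14-parameter correlation
   matrix, components retained at eigenvalue > 0.6 and varimax-rotated;
   linear discriminant analysis on the component scores with priors matching
   the observed group sizes; resubstitution and leave-one-out confusion
   matrices; accuracy versus the 100/k % chance level with a one-sided exact
   binomial test.

## Worked example

Run the full pipeline on a synthetic population of 7 callers with moderate
individuality (162 calls with the unbalanced per-caller counts
12, 16, 33, 23, 40, 24, 14):

```bash
coo-id run --k 7 --separation 1.0 --out reports --seed 1
```

This synthesizes the calls, extracts features, and writes `features.csv`,
`table1.csv` (PIC), `table2.csv` (screening), `table3.csv` (confusion
matrices), `pca_summary.csv`, `dfa_summary.json` and `run.log` into
`reports/`. With seed 1 it prints/writes:

```
$ head -3 reports/table1.csv
parameter,mean_cv_w,cv_b,pic
duration,8.386268477472564,13.847547321320487,1.65121679069996
mean_f0,3.4723147797121032,7.593638265288055,2.1869095249243675
```

Every parameter has PIC > 1 (minimum 1.65 for duration): each measured
parameter varies more between callers than within a caller, as expected for
a population generated with between-caller separation. From
`dfa_summary.json`:

```
"retained_pcs": 4,
"n_discriminant_functions": 4,
"resubstitution_accuracy_pct": 100.0,
"loocv_accuracy_pct": 100.0,
"chance_level_pct": 14.285714285714286,
"binomial_p": 1.2419883373173194e-137
```

Four rotated components pass the 0.6 eigenvalue rule, the DFA separates all
seven synthetic callers perfectly under leave-one-out cross-validation, and
the one-sided binomial test against the 14.3 % chance level is effectively
zero. Lower `--separation` (or raise `--within-scale`) to move the
population toward the null regime, where LOOCV accuracy falls into the
binomial band around chance and all PIC values settle near 1.

The stages are also available individually (`coo-id synth`, `features`,
`stats`, `discriminate`, `fixture`) and as library functions
(`coo_id.extract_features`, `coo_id.pic_table`, `coo_id.run_discrimination`,
...), including on your own feature CSVs.

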