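# Methods

`thetaconn` analyses phase-based theta connectivity of cued-memory EEG
epochs: pre-sleep wake, slow-wave sleep with auditory cueing, and post-sleep
wake, with left- and right-hand cue conditions. Everything runs end-to-end
on synthetic studies whose effects are planted and therefore known; this note
describes the models, the numerical choices, and what passing tests do and
do not demonstrate.

## Connectivity estimators

For two channels with analytic signals `z_x`, `z_y` and instantaneous phases
`phi_x`, `phi_y`, over a window of `T` samples:

- **PLV** `= | (1/T) sum_t exp(i (phi_x(t) - phi_y(t))) |`. Equal to 1 iff
  the phase difference is constant; amplitude-independent; blind to whether
  coupling is lagged or instantaneous, so volume conduction inflates it.
- **wPLI** `= | mean_t Im(P_xy(t)) | / mean_t |Im(P_xy(t))|`, with
  `P_xy = z_x conj(z_y)` the per-sample cross-spectrum. Purely zero-lag
  (volume-conducted) coupling has `Im(P_xy) = 0` and contributes nothing;
  when *every* sample's imaginary part is zero the ratio is 0/0 and the
  estimator returns 0 with a degeneracy flag, and the cell is excluded from
  significance testing.

Both are computed per trial on three 1 s windows with 50 % overlap after cue
onset (w1: 0–1 s, w2: 0.5–1.5 s, w3: 1–2 s; at least 3 theta cycles each).
The analytic signal is taken by FFT over the full 2.5 s epoch and sliced to
the window afterwards, so no window boundary carries a transform edge.

## Filtering

Epochs are short (2.5 s), while a time-domain FIR with 40 dB stopband at
1 and 12 Hz would be ~1.65 s long at 100 Hz — longer than the epoch — and
its edge transients measurably bias the surrogate test (see below). The
band-pass is therefore a zero-phase spectral-gain filter applied circularly
per epoch: gain exactly 1 on [3, 8] Hz, raised-cosine transitions 2 Hz wide,
exactly 0 at and beyond 1 Hz and 10 Hz. Re-applying the filter leaves
passband content unchanged; DC is removed entirely. The first/last 0.25 s of
each epoch are flagged as edge-affected in the metadata (analysis windows
start at cue onset and epochs carry 0.5 s pre-onset padding, so the flagged
region does not intersect w1–w3 on the post-onset side).

## Synthetic data generator

Each channel is `carrier + pink/snr`:

- **Carrier**: a Gaussian process with spectrum flat across 1–10 Hz (the
  analysis band plus the filter transitions) and unit RMS fixed analytically,
  not from the sample. Gaussianity is a load-bearing choice: phase-randomised
  surrogates of a Gaussian process are distributionally exchangeable with it,
  which is what makes the surrogate null calibrate at its nominal level on
  uncoupled channels. A constant-amplitude drifting oscillator (the obvious
  alternative) is non-Gaussian and was measured to inflate the null keep-rate
  to ~15 %. The flatness across the filter skirts likewise makes
  time-scrambled-then-refiltered surrogates spectrally comparable to the
  real data.
- **Noise**: 1/f (exponent 1) Gaussian noise at an oscillation-to-noise
  amplitude ratio `snr` (default 2).
- **Coupling**: a planted pair (p, q) with strength `kappa` in [0, 1] and lag
  in radians injects p's base carrier, phase-rotated by the lag, into q:
  `q_osc = w0 * own + kappa * rotate(base_p, lag)`, `w0 = max(0, 1 - sum
  kappa)` when several couplings target q. The source side always uses the
  base oscillator, so hub channels drive many targets undiluted. `kappa = 1`
  with no noise gives PLV = wPLI = 1 exactly; `kappa = 0` leaves channels
  independent. Couplings can be restricted to sessions, conditions, and a
  time interval within the epoch (50 ms cosine ramps).
- **Volume conduction** (optional): an instantaneous mixing matrix, by
  default leakage of relative weight 0.4 to the two ring-neighbouring
  electrodes, rows normalised. Mixing is linear, so the data stay Gaussian
  and the surrogate calibration argument still applies.
- **Determinism**: every (subject, session, condition) cell derives its RNG
  as `SeedSequence(seed, spawn_key=(session_idx, condition_idx, subject))`,
  so any cell can be regenerated in isolation, bit-identically.

### Reference planted-effect structure

C5 and C6 act as hub oscillators. Session-dependent strengths (Pre 0.78,
Sleep 0.92, Post 0.68) couple C5→F3, C6→F4 (hemisphere↔frontal) and C5→C6
(inter-hemispheric); within-hemisphere couplings C5→{CP3, P7} and
C6→{CP4, P8} have base strength 0.75 plus a 0.15 increment for the
hemisphere contralateral to the cued hand during Sleep and Post only. Each
coupling group has its own lag, so co-targets of one hub are lagged relative
to each other (no accidental zero-lag pairs). These values were calibrated
once, at design time, so that every link the ROI contrasts rely on clears
both the per-trial surrogate test and the stability filter in *all*
sessions; weaker strengths leave whole summary cells empty (missing), at
which point a Pre-vs-Post contrast cannot be formed at all. The saturating
map from kappa to PLV means session differences appear as ~0.02–0.07 PLV
units — comfortably detectable across 16 subjects.

### Behavioural generator

Block medians follow `base - learn_max * (1 - exp(-rate * block))` (base
480 ms, asymptotic sequence skill 80 ms, rate 1/12 per block, 48 sequence +
4 random blocks per sequence per session), minus an overnight gain (20 ms)
after sleep, minus a TMR benefit (40 ms) for the reactivated sequence on
left-hand trials only. Observed block RTs are lognormal around the model
median (sigma 0.06), so the zero-noise limit reproduces the planted numbers
exactly — in particular `ssi(Re) − ssi(NRe) = tmr_gain` for the left hand
identically, independent of the learning curve. Random blocks carry no
sequence-specific gain.

When a connectivity–behaviour link is requested, a per-subject factor
`u ~ N(1, sd)` (clipped to [0.2, 1.8]) scales *both* the hand-specific
coupling increment and the TMR benefit. The linked-study conditions use
sd 0.5 with RT noise sigma 0.03: with the default sigma 0.06 the planted
40 ms × sd gain spread is smaller than the metric's sampling noise and the
correlation attenuates to ~0.4, which is a property of the effect size, not
of the estimator.

## Surrogate testing

Phase surrogates permute the positive-frequency rFFT phases per channel
(Hermitian symmetry enforced; DC and Nyquist kept real), preserving the
amplitude spectrum to machine precision. Time surrogates permute samples;
because scrambling whitens the spectrum, time surrogates are re-band-passed
with the preprocessing filter before connectivity — without this the null is
not comparable to narrowband data. Each (pair, window, trial) cell gets its
own 100-value null; the keep rule is `real > ` the rank-based 95th-centile
(upper order statistic), identical to the empirical p-value
`(1 + #{null ≥ real}) / (n + 1) ≤ α`. With 100 surrogates the exact null
keep probability is 5/101 ≈ 4.95 %; linear quantile interpolation would
instead give ≈ 5.9 %, which is why the order statistic matters. Measured
keep-rates on uncoupled data are 4.7–5.2 % (phase) and 4.7–6.5 % (time) for
both metrics.

## Stability filter and ROI summaries

A link is retained for a (session, condition, metric, window) when it is
significant in ≥ 60 % of a subject's trials for ≥ 50 % of subjects
("across participants" read as the fraction of participants meeting the
within-participant criterion — trial pooling across subjects would erase the
subject structure the RM-ANOVA needs). Summaries average the retained
links' *significant-trial* values (pruned zeros are disregarded, matching
the pruning semantics); a cell with no significant retained-link trial is
missing, never zero. Filtering precedes trial averaging.

For the L-vs-R cued-hand contrast the retained set is instead computed from
trials pooled over both conditions within the session: selecting links
separately per condition lets the two summaries differ through link
selection alone, a double-dipping artifact that inflates between-condition
differences. Session contrasts use the per-(session, condition) filter.

Regions: Frontal {F3, Fz, F4}, left motor {C5, CP3, P7}, right motor
{C6, CP4, P8}; Cz, Pz, O1, O2 never enter any summary. Contrasts:
LHem↔Frontal, RHem↔Frontal, LHem↔RHem, within-LHem, within-RHem.

## Statistics

- Session RM-ANOVA per contrast (pingouin; Greenhouse–Geisser correction
  when Mauchly's test rejects sphericity), on per-subject values averaged
  over conditions; subjects with missing cells dropped listwise with a
  logged count. A mixed design with a between-subjects group factor is
  available through the same entry point.
- Post-hocs: paired t-test, replaced by Wilcoxon signed-rank when
  Shapiro–Wilk rejects normality of the paired differences at α = 0.05;
  Holm–Bonferroni adjustment within each comparison family. The family is
  the three session pairs for one contrast, window, and metric.
- Correlations: Spearman's rho (Pearson behind a flag) with a 95 %
  percentile bootstrap CI (50 000 paired resamples by default) and a
  permutation p-value (same count, +1 correction). Percentile CIs measured
  96.4 % null coverage at n = 12; no acceleration correction is needed at
  these sample sizes.
- Bayesian ANOVA is intentionally absent.

## Problem sizes

Defaults: 16 subjects, 60 trials per cell, 100 Hz, 100 surrogates, 50 000
bootstrap resamples. The validation studies in the test-suite use 16
subjects × 20 trials per cell × 100 surrogates (planted-effect recovery) and
60 trials × 100 surrogates (null calibration); these sizes give standard
errors well below the planted effect sizes while keeping a full run in
minutes on one core. The heavy paths are vectorised: batched FFTs for
surrogates and analytic signals, batched matrix products for PLV, chunked
broadcasting for wPLI.

## What the synthetic studies do not show

The generator reproduces the *statistical* structure the analysis targets —
narrowband coupling with session/condition/time labels, 1/f background,
optional zero-lag mixing, block-level learning curves — not real sleep EEG.
There are no slow oscillations, spindles, arousals, artifacts, non-
stationarities within a session, or volume-conduction geometry beyond
nearest-neighbour leakage; channel spectra are identical by construction.
Passing recovery tests therefore demonstrates that the pipeline detects the
effects it claims to detect at realistic sizes and calibrates its nulls
correctly — not that real recordings satisfy the generator's assumptions.
Real-data deviations (non-Gaussian amplitude dynamics, broadband artifacts)
would primarily stress the surrogate exchangeability assumption, which is
exactly why both shuffle schemes and both metrics are carried everywhere.

## Known limitations

- Undirected metrics only; no directionality or source-space analysis.
- The wPLI cross-spectrum is the per-sample product of analytic signals
  (time-domain Hilbert formulation), not a tapered spectral estimate.
- Surrogate exchangeability is exact only for Gaussian inputs; the
  generator is Gaussian by design, real data need not be.
- The stability filter makes summary cells missing rather than zero; with
  few subjects or weak coupling, listwise dropping can cost power.
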