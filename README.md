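# thetaconn

Phase-based EEG connectivity analysis for targeted memory reactivation (TMR)
sleep studies, built as a fully tested pipeline that runs end-to-end on
synthetic data with planted, labelled effects.

In a TMR experiment, sounds paired with a learned motor sequence are replayed
during slow-wave sleep to bias consolidation. The analysis question is how
theta-band (3–8 Hz) phase coupling between scalp regions changes across
pre-sleep wake, sleep, and post-sleep wake, whether the cued hand can be read
out from within-hemisphere coupling, and whether sleep connectivity predicts
overnight behavioural improvement. `thetaconn` implements that analysis for
a 13-channel 10–20 montage and, because the raw study data are not needed,
ships a generator that emulates their statistical structure.

## The estimators

For channels x, y with analytic-signal phases φ_x, φ_y over a 1 s window of
T samples (three windows per trial: 0–1, 0.5–1.5, 1–2 s after cue onset):

```
PLV  = | (1/T) Σ_t exp(i(φ_x(t) − φ_y(t))) |
wPLI = | Σ_t Im P_xy(t) | / Σ_t |Im P_xy(t)| ,   P_xy = z_x · conj(z_y)
```

PLV measures phase locking regardless of lag and is therefore inflated by
volume conduction; wPLI weights phase leads/lags by the imaginary
cross-spectrum and suppresses zero-lag mixing. Per-trial values are tested
against a 100-surrogate null (phase-randomised or time-scrambled copies of
the same epoch) at the 95th centile, unstable links are discarded (significant
in < 60 % of trials within a subject or < 50 % of subjects), and the surviving
links are averaged into ROI contrasts (hemisphere↔frontal, between- and
within-hemisphere) that feed repeated-measures ANOVA, Holm-corrected paired
post-hocs, and bootstrap-corrected Spearman correlations against
sequence-specific skill (sss) and improvement (ssi) from block reaction
times.

See `docs/methods.md` for the models, numerical choices, and limitations.

## Worked example

```python
import numpy as np
import thetaconn as tc
from thetaconn.pipeline import PipelineConfig, analyse_study

cfg = PipelineConfig(n_subjects=16, n_trials_per_cell=20,
                     n_surrogates=100, seed=1, behaviour_link_sd=0.5)
study = tc.generate_study(cfg.simulation_config(),
                          effects=tc.BehaviouralEffects(rt_noise_sd=0.03),
                          behaviour_link_sd=0.5)
res = analyse_study(study, cfg)
print(res.anova[["contrast", "F", "p"]])
print(res.correlation)
```

prints (about one minute on one core):

```
       contrast           F             p
0  LHem-Frontal   94.436831  1.132182e-13
1     LHem-RHem   94.733640  1.087106e-13
2  RHem-Frontal  158.340919  1.142490e-16
3   within-LHem   14.153868  4.687336e-05
4   within-RHem   17.657684  8.542562e-06

{'x': 'within-RHem Sleep L w2', 'y': 'Re ssi_early (L hand)',
 'rho': 0.638, 'p': 0.008, 'ci': (0.155, 0.875), 'n': 16, 'n_boot': 5000}
```

The ANOVA rows are the Session effect (w3) per ROI contrast: the planted
Sleep > Pre > Post coupling produces large F statistics for the
hemisphere↔frontal and between-hemisphere contrasts. The correlation row is
the planted link between within-right-hemisphere sleep connectivity after
left-hand cues and the overnight improvement of the reactivated sequence:
the generator couples both to a per-subject factor, and the pipeline
recovers the association with a positive rho and a bootstrap CI excluding
zero. `res.session_posthoc` and `res.hand_posthoc` hold the Holm-corrected
pairwise tests (Sleep vs Pre vs Post; L vs R cues per session).

The same run is available from the shell:

```
phase-connect run --config study.yaml --out runs/demo --seed 1
```

which writes `epochs.h5`, tidy CSV tables for connectivity summaries, skill
metrics and statistics, plus a `manifest.json` with content hashes of every
stage output. Individual stages (`simulate`, `preprocess`, `connect`,
`surrogate`, `summarise`, `behav`, `stats`) are also exposed.

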