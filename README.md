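# airbreath

Analysis pipeline for experiments on **social air-breathing fish** — species
such as *Corydoras* catfish that supplement gill respiration by gulping air at
the surface, especially under hypoxia.  The package is aimed at behavioural
ecophysiologists who measure (a) individual oxygen demand by intermittent-flow
respirometry and (b) group air-breathing behaviour on video, and who want the
full path from raw traces and event logs to mixed-model inference to be
scripted, tested and reproducible.

## What it computes

**Standard metabolic rate (SMR).**  An intermittent-flow respirometry system
alternates flush and closed phases (defaults: 2 min flush every 8 min over
16 h, sampling every 2 s).  For each closed phase, after discarding the first
minute, the O₂ decline slope *b* (mg O₂ L⁻¹ h⁻¹) is fitted by OLS; bacterial
background respiration, measured in blank chambers before and after the trial
and interpolated linearly in time, is subtracted; and uptake is

&nbsp;&nbsp;ṀO₂ = (|b_fish| − |b_blank|) · V_eff,&nbsp;&nbsp;V_eff = V_chamber + V_tubing − V_fish (L).

SMR is the 0.2-quantile of the per-cycle ṀO₂ values (the "lowest 20th
percentile" estimator; a mean-of-lowest-20% variant is available behind a
switch, and the method used is recorded in the output).

**Air-breathing synchrony.**  Each 12-min trial's time-stamped breath events
are counted in 5-s bins and the coefficient of dispersion
CD = s²/x̄ of the counts is computed (sample variance, n−1).  CD = 1 is the
Poisson (independent-breathing) reference; CD > 1 marks temporally clustered
— synchronised — air breathing.  Trials without events have no defined CD and
are reported missing, never as zero.

**Group kinematics.**  From per-frame 2-D positions: activity = mean swimming
speed (cm s⁻¹, unweighted mean over fish of per-fish mean frame-to-frame
displacement × frame rate) and cohesion = mean pairwise inter-individual
distance (cm; smaller = tighter group).  Missing tracking frames are skipped,
never interpolated.

**Inference.**  A battery of mixed models mirroring the repeated-measures
design (fish nested in groups, measured at 25/30 °C and 100/60/20 % air
saturation): Gaussian linear mixed models for log SMR, CD, speed and cohesion
(statsmodels `MixedLM`), and an in-house Laplace-approximate maximum-likelihood
**negative-binomial GLMM** (log link, nested random intercepts) for breath
counts — validated against R's glmmTMB.  Model choice is backward elimination
by likelihood-ratio tests at α = 0.05 (ML fits), with body mass always
retained while SMR stays in a model; every fit reports Nakagawa–Schielzeth
marginal/conditional R².

**Synthetic data.**  `airbreath.synth` generates all four input streams with
known ground truth: respirometry traces with prescribed per-cycle uptake and
background, breath events from a common-trigger (batch-arrival) process whose
participation probability p tunes synchrony at fixed total rate, and
persistent-random-walk trajectories with centroid attraction κ in a circular
arena.  Identical seeds give byte-identical CSVs.

## Worked example

```bash
airbreath simulate --seed 3 --out sim/ --frames 1000
airbreath run --config config.yaml     # or drive the stages individually:
airbreath smr --traces sim/traces.csv --blanks sim/blanks.csv \
              --chambers sim/chambers.csv --out smr.csv
```

or from Python:

```python
from airbreath.synth import StudyDesign, EffectConfig, simulate_study
from airbreath.pipeline import RunConfig, run_all

tables = simulate_study(StudyDesign(n_groups=2, group_size=3,
                                    respirometry_duration_h=1.0),
                        EffectConfig(trace_noise_sd=0.02), seed=7, n_frames=200)
# ... write tables to CSV, then:
# run_all(RunConfig(out_dir="out", traces=..., events=..., ...))
```

On that two-group study the run writes `smr.csv`, `trials.csv`,
`kinematics.csv`, the joined `dataset_*.csv`, one `model_*.csv` per fitted
model and `manifest.json`.  The selected SMR model prints

```
model 'smr' (gaussian), n=12, logLik=17.113
  formula: np.log(smr) ~ np.log(mass) + C(temp)
  var[group] = 0.00000
  var[fish_id:group] = 0.00076
  residual var = 0.00271
               estimate      se     stat       p
Intercept       -1.8792  0.0876 -21.4498  0.0000
C(temp)[T.30]    0.3660  0.0300  12.1865  0.0000
np.log(mass)     0.8656  0.1830   4.7298  0.0000
```

i.e. even this small study recovers the generator's truth: allometric mass
exponent 0.89 (fitted 0.87), a ×1.5 SMR increase at 30 °C (fitted
e^0.366 = 1.44), and an intercept of ln 0.15 = −1.90 at 1 g and 25 °C.  The
`model_group_abf.csv` table likewise recovers the severe-hypoxia effect on
group breath counts: relative to the 20 %-saturation reference, breaths drop
by e^−0.64 ≈ 0.53 at 100 % (truth: 1/1.45 ≈ 0.69).

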