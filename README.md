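# metarousal

Analysis toolkit for studying how arousal state — pharmacological
(catecholaminergic / cholinergic elevation vs. placebo) or spontaneous
(prestimulus pupil-linked) — affects perceptual versus metacognitive
decision-making, together with a synthetic study generator that makes the
whole pipeline testable against known ground truth.

It is written for cognitive neuroscientists analyzing two-choice
discrimination tasks with binary confidence reports, EEG, and
pupillometry.

## What it computes

**Type-1 / type-2 signal detection.** For each subject and condition the
package computes perceptual sensitivity and bias from the z-transformed
hit and false-alarm rates,

    d' = z(H) − z(FA),        c = −(z(H) + z(FA)) / 2,

and metacognitive sensitivity **meta-d'** — the sensitivity an SDT-ideal
observer would need to produce the observed response-conditional
confidence counts — by maximum likelihood, with the type-1 criterion
fixed in meta space at `meta_c = c·(meta-d'/d')` and one type-2 criterion
offset free per response side.  Metacognitive efficiency is summarized as
M-diff = meta-d' − d' and M-ratio = meta-d'/d'.

**Hierarchical Bayesian group models.**  Group-level inference on
log M-ratio: a paired two-condition model (bivariate-normal subject
effects; the drug effect is the posterior of the condition-mean
difference) and a linear regression of log M-ratio on pupil bin.  Both are
sampled by an adaptive Metropolis-within-Gibbs sampler with joint
scale moves, and checked with split-chain Gelman–Rubin R̂.

**Pupillometry.**  Blink interpolation, zero-phase 10 Hz low-pass,
normalization as % difference from the block mean, −500–0 ms prestimulus
baselines, five equally populated bins per session × block, per-bin SDT
measures, and first/second-order polynomial regressions on bin number
(1–5) tested with group t tests and JZS Bayes factors.

**Response-locked ERPs.**  Centroparietal (CP1/CPz/CP2, "CPP") and
frontal (F1/Fz/F2, "FP") ROI time courses, the metacognitive-effect
statistic ME = (C_hi − C_lo) + (I_lo − I_hi) over accuracy × confidence
cells, and cluster-based permutation tests over time (paired t and
repeated-measures ANOVA effects; max-cluster-mass null).

**Temporal-generalization decoding.**  Shrinkage-LDA orientation decoding
at every train × test timepoint (GAT matrices scored by AUC), within-task
10-fold and cross-task (train on a localizer, test per
drug × accuracy × confidence subcondition), stratum-balanced
undersampling, activation patterns (covariance × weights), and 2D
cluster-corrected one-sided tests against chance.

**Synthetic studies.**  `metarousal.synthetic` generates complete studies
(default: 27 subjects × 3 drug sessions × 600 trials) from an
equal-variance SDT observer with separate metacognitive noise, balanced
stimulus classes, truncated lognormal RTs, latent pupil-arousal bins
coupled to sensitivity, EEG-like epochs carrying CPP/FP components and an
orientation pattern, and a 3:1 weighted up-down staircase.  Ground truth
is stored beside every bundle.

## Worked example

Simulate one placebo session of the default observer and score it:

```python
from metarousal.synthetic import ObserverConfig, SessionConfig, simulate_behavior
from metarousal import sdt

obs = ObserverConfig()                      # d'=1.4, sigma_meta=0.95, 600 trials
trials = simulate_behavior(obs, SessionConfig(), seed=3)
filtered, report = sdt.exclude_trials(trials)
print(report.n_retained, "analyzable trials")
print(sdt.subject_metrics(filtered))
```

prints

```
594 analyzable trials
d_prime    1.364
criterion -0.112
meta_d     0.702
m_diff    -0.663
m_ratio    0.514
conf_rate  0.510
```

The observer performs at ~75% correct (d' ≈ 1.4) with roughly balanced
confidence reports; its metacognitive noise makes confidence less
diagnostic of accuracy than the choices themselves, so meta-d' (0.70)
falls well short of d' — an M-ratio near 0.5, typical of this task class.
The exclusion report shows the missed-trial and RT-window bookkeeping.

The full chain — behavior, pupil bins, hierarchical M-ratio, ERP
clusters, decoding — runs from the command line:

```sh
metarousal report --seed 1 --out out/
metarousal simulate --seed 1 --out sim/
metarousal sdt --trials sim/trials.csv --out sdt/
```

`report` writes `report.json` with the drug effects on d', meta-d' and
M-diff, the pupil-bin polynomial fits, the CPP/FP cluster statistics, the
decoding clusters, and a JSON run manifest (seed, config hash, versions).

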