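# Methods

This note documents the models, estimators, and numerical choices behind
`metarousal`, and what the synthetic-data generator does and does not
emulate.

## The generative observer

Behavior is generated by an equal-variance signal-detection observer with
a separate metacognitive stage.  On each trial with stimulus
s ∈ {ccw, cw}, perceptual evidence is x ~ N(±d′/2, 1) and the response is
"cw" iff x > c.  Confidence derives from a metacognitive sample
y = x + N(0, σ_meta): "high" iff y > c + c₂ for cw responses and
y < c − c₂ for ccw responses.  The type-2 criteria are
response-conditional and symmetric by default (one scalar offset c₂ per
side), the minimal parameterization for binary confidence.

Two exact identities anchor the tests: with σ_meta = 0 and symmetric
criteria the generative meta-d′ equals d′, and accuracy at c = 0 is
Φ(d′/2).

**Generative meta-d′ is computed exactly, not by formula.**  The
folk approximation meta-d′ ≈ d′/√(1 + σ_meta²) is substantially biased
here: because confidence is conditioned on a response made from x, the
metacognitive sample sometimes confidently contradicts the response,
which costs type-2 sensitivity beyond pure attenuation.
`synthetic.generative_meta_d` therefore computes the large-sample
stimulus × response × confidence cell probabilities from the joint
normal distribution of (x, y) and fits the package's own meta-d′ MLE to
them; `sigma_meta_for_ratio` inverts this mapping by root-finding.  (At
d′ = 1.5, a target M-ratio of 0.5 needs σ_meta ≈ 1.06, not √3.)

**Default observer.**  d′ = 1.4 (≈ 75.8% correct, the staircased level),
criterion 0, c₂ = 1.0 (≈ 49% high-confidence reports), σ_meta = 0.95
(generative meta-d′ ≈ 0.73, M-ratio ≈ 0.52).  These were calibrated once
against the study-design targets (≈ 75% accuracy, ≈ 50/50 confidence,
group-mean meta-d′ ≈ 0.75) and frozen.  RTs are lognormal on the ms scale
(μ = 6.50, σ = 0.16; mean ≈ 680 ms, SD ≈ 110 ms), truncated by rejection
to the 100–1400 ms response window; ~1% of trials are missed.  Stimulus
classes are balanced exactly 50% CW within every block.

**Study-level structure** (`StudyConfig`, defaults = the study design):
27 subjects × 3 sessions (PLC/DNP/ATX) × 600 trials; subject-level d′ ~
N(1.4, 0.35) and criterion ~ N(0, 0.15).  The catecholaminergic phenotype
is an additive d′ boost (+0.3 under ATX) with σ_meta inflated per subject
so the generative meta-d′ stays at its placebo value — better perception,
unchanged metacognition, hence a negative M-diff effect.  Pupil-linked
arousal is a latent bin (1–5, equally populated per block) moving
effective d′ by a1·b + a2·b² with defaults (0.2, −0.025): an inverted-U
peaking above the middle bin, so bin-wise d′ carries both a positive
linear and a negative quadratic component; metacognitive noise co-scales
per bin (same held-meta-d′ mechanism) so meta-d′ stays flat across bins.
Pupil baselines are bin centers 5% apart plus 1.5% jitter, re-centered to
exactly 0% per block.

**Epochs.**  Stimulus-locked trials × channels × samples arrays with
AR(1) temporal noise (coefficient 0.95 at 512 Hz; 0.9 when generating at
128 Hz directly) under an exponential spatial covariance over schematic
10-20 positions (length scale 0.6).  Components: a centroparietal ramp
rising from 100 ms to the trial's RT with amplitude
base + accuracy·βacc + confidence·βconf + drug term (Gaussian topography
around CPz); a frontal drift over the 600 ms before the response whose
end-point amplitude includes κ·(+1 if accuracy and confidence agree,
−1 otherwise) — so the metacognitive-effect statistic
ME = (C_hi − C_lo) + (I_lo − I_hi) is ≈ 4κ at the response — plus a drug
term (topography around Fz); and a fixed posterior-weighted orientation
topography, added with sign ±1 per stimulus class (or per *response*,
which reproduces below-chance decodability of error trials) inside a
latency window, scaled by `pattern_snr` × noise SD.  The topography is
fixed by its own seed so localizer and main-task sets share it.

What the generator does **not** emulate: raw continuous EEG, ocular or
movement artifacts, volume-conduction realism, 1/f spectra, non-Gaussian
RT/accuracy dependences (RT is independent of accuracy and confidence),
learning across sessions, and any drug effect on RT or criterion.
Passing tests therefore demonstrate the estimators' correctness and the
pipeline's sensitivity/specificity under a well-specified observer — not
robustness to real-data pathologies.

**Staircase.**  Weighted up-down on opacity: +0.01 after errors,
−0.01/weight_ratio after correct answers, stop at 50 behavioral
reversals (outcome changes), threshold = mean opacity on reversal trials.
The stationary point satisfies p·(down) = (1 − p)·(up), i.e. p =
ratio/(ratio + 1) = 75% for the default 3:1 weighting, independent of
the psychometric function's shape.  The simulated observer's accuracy is
0.5 + 0.5·Φ((opacity − threshold)/slope).

## Estimators

**Type-1.**  "cw" is the signal class (documented so the criterion sign
is reproducible).  Marginal rates of exactly 0 or 1 are padded to 1/(2N)
and 1 − 1/(2N) of the stimulus row; no correction otherwise.

**Meta-d′ MLE.**  The response-conditional high-confidence probabilities
are ratios of Gaussian tail areas beyond the type-2 criteria to tail
areas beyond meta_c, per stimulus and response side.  The multinomial
log-likelihood is maximized by L-BFGS-B with meta-d′ ∈ [−5, 5] and
criterion offsets ∈ [0, 5], from up to five jittered starts (the first
start is the type-1 d′ with offsets from the observed confidence rate).
If a response side of the 2×2×2 table contains a zero cell, 1/8 is added
to each of that side's four cells.  When |d′| < 10⁻³ the meta-space
anchoring meta_c = c·(meta-d′/d′) is undefined; the fit falls back to
meta_c = c and flags the result.

**Hierarchical models.**  Subject-level likelihood is the same type-2
multinomial evaluated at meta-d′ = exp(log M-ratio)·d̂′ with d̂′ and ĉ
fixed at their point estimates (meta_c = ĉ·exp(logMratio)); type-2
offsets are sampled per subject with Half-Normal(2) priors.  Paired
model: (lmr_A, lmr_B) per subject ~ bivariate normal with means
μ_A, μ_B ~ N(0, 1), SDs ~ Half-Normal(1), correlation ~ Uniform(−1, 1);
the drug effect is the posterior of μ_A − μ_B.  Bin model: subject × bin
mean = μ + β_bin·(bin − 3) + subject offset, with Half-Normal(1) scale
priors.  Sampling is random-walk Metropolis-within-Gibbs, vectorized over
chains and subjects, with per-block proposal scales adapted every 25
warmup iterations toward ~30% acceptance and frozen afterwards.  Because
the group-SD posteriors can concentrate near zero (a funnel), each
iteration also performs a joint scale move that multiplies a condition's
subject deviations and its group SD by a common factor; the
bivariate-normal quadratic form is invariant under this move and its
normalization cancels against the transformation Jacobian, so only the
type-2 likelihood and the SD prior enter the acceptance ratio.  With the
default 3 chains × (2,000 warmup + 10,000 samples), max split-chain R̂
on the standard 20-subject fixture is ≈ 1.01–1.03.  Convergence is
assessed with classic split-chain Gelman–Rubin R̂ (not rank-normalized).
Log M-ratio is bounded to ±5 for numerical stability.

**Cluster-based permutation tests.**  Clusters form where the pointwise
statistic exceeds the cluster-α quantile (paired t for two-condition
tests; sphericity-assumed repeated-measures F from orthonormal
within-subject contrasts for factorial effects — for purely two-level
effects F is exactly the squared paired t).  Cluster mass is the sum of
the statistic; the null is the maximum mass over 1,024 permutations by
default (sign-flips of subject difference curves or contrast scores;
within-subject label permutation of the three-level drug factor), with
the +1 Monte-Carlo correction.  1D adjacency is temporal contiguity; 2D
(GAT) adjacency is 4-connectivity.  Null calibration in the test suite
bounds the family-wise error at ≤ 0.08 for nominal 0.05 over 500 runs.
Response-locked statistics are computed at 128 Hz on the 600 ms
preceding the response.

**Bayes factors.**  Default JZS: BF01 is the ratio of the central-t
density to the Cauchy-prior (scale 0.707) marginal of the noncentral-t
density, integrated by adaptive quadrature; one-sided variants truncate
(and renormalize) the prior to the stated direction.  For the reference
inputs t(26) = 2.06 (one-sided) and t(26) = 0.49 (two-sided) this yields
BF01 = 0.411 and 4.395.

**Decoding.**  LDA weights w = Σ̂⁻¹(μ_cw − μ_ccw) with
Σ̂ = (1 − λ)S + λ·(tr S/p)·I and λ from the analytic Ledoit–Wolf
estimator (a fixed λ can be forced); the intercept is midway between
projected class means.  AUC is the rank statistic with ties counted ½.
Training sets are balanced by undersampling every
stimulus × response-accuracy stratum to the minimum count.  Activation
patterns are the data covariance times the weights.

## Pipeline conventions

All analysis windows are half-open [start, end).  Times are seconds in
epoch containers and milliseconds in trial tables.  Trials are excluded
for: lost fixation, no response, RT < 100 ms or > 1400 ms (counted in
that priority order).  Pupil bins are assigned within session × block;
remainder trials go to the low-pupil bins and ties break by trial order.
Per-bin SDT measures pool across sessions and blocks (a per-session
variant is a straightforward caller-side change; pooling was chosen
because bin-level measures are reported across conditions).  Bin
regressions use raw (not orthogonalized) powers of bin number 1–5.
Baseline correction subtracts the −80–0 ms prestimulus mean;
response-locking re-windows each trial to the sample nearest its RT and
drops (with a log entry) trials whose window leaves the epoch.

## Problem sizes

The package's own test and acceptance runs use these sizes, chosen as a
balance of statistical resolution and single-CPU runtime: staircase
convergence over 200 runs; decoding-null over 10–20 seeds of 100-trial
epoch sets at 64 Hz; hierarchical convergence at the full 3 × (2,000 +
10,000) sampler length on 20 subjects × 1,000 trials; FWER calibration
over 500 null datasets with 255 permutations; the end-to-end qualitative
run at 27 subjects × 300 trials with epochs generated directly at the
128 Hz analysis rate and 256 permutations.  The `report` driver defaults
to 27 subjects × 400 trials with all stages enabled (its in-run
hierarchical stage uses a shortened 500 + 2,000 sampler; R̂ reported
there is expected to exceed 1.1 and is diagnostic output, not a
convergence claim).

## Known limitations

Single-subject meta-d′ assumes equal-variance SDT and binary confidence;
multi-level confidence scales and response-specific meta-d′ are out of
scope.  The hierarchical sampler treats d′ and c as known per subject.
The rmANOVA assumes sphericity (exact only for two-level effects) and
supports fully within-subject designs; between-subject factors are not
implemented.  Greenhouse–Geisser correction, rank-normalized R̂, and
unequal-variance observers are not provided.  The pupil low-pass assumes
a regularly sampled trace; blink deconvolution is replaced by linear
interpolation.
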