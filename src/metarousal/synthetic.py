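"""Synthetic study generator with known ground truth.

Emulates a three-session (placebo / donepezil / atomoxetine) within-subject
orientation-discrimination study: an equal-variance SDT observer with
separate metacognitive noise produces binary orientation responses and
binary confidence, pupil baselines carry a latent arousal bin that can
modulate effective sensitivity, EEG-like epochs carry a centroparietal
ramp (CPP), a frontal drift (FP) with a metacognitive-correctness
interaction, and an orientation-specific spatial pattern.  A weighted
up-down staircase models the titration procedure.

Generative observer
-------------------
Per trial with stimulus s in {ccw, cw}: evidence x ~ N(+-d'/2, 1); the
response is cw iff x > c.  A metacognitive sample y = x + N(0, sigma_meta)
drives confidence: high iff y > c + c2 for cw responses and y < c - c2 for
ccw responses (response-conditional criteria, symmetric by default).  With
sigma_meta = 0 and symmetric criteria, the generative meta-d' equals d';
for sigma_meta > 0 it falls below d' (see :func:`generative_meta_d` for
the exact large-sample value, which also lies below the naive
d' / sqrt(1 + sigma_meta^2) because the metacognitive sample can
confidently contradict the response).

Default parameters target the study's descriptive statistics: ~75%
accuracy (d' = 1.4), ~50% high-confidence reports (c2 = 1.0), meta-d'
~= 0.75 (sigma_meta = 0.95), lognormal RTs with mean ~690 ms truncated to
[100, 1400] ms, and ~1% missed trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import ndtr

from ._montage import DEFAULT_CHANNELS, channel_positions
from .erp import EpochSet

__all__ = [
    "ObserverConfig",
    "SessionConfig",
    "EpochGenConfig",
    "StaircaseConfig",
    "StaircaseRun",
    "StudyConfig",
    "StudyBundle",
    "simulate_behavior",
    "simulate_pupil",
    "simulate_session",
    "simulate_epochs",
    "simulate_staircase",
    "make_study",
    "sigma_meta_for_ratio",
    "simulate_group_counts",
]

DRUGS = ("PLC", "DNP", "ATX")


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(float(v)):
            raise ValueError(f"non-finite value in {name}")


@dataclass
class ObserverConfig:
    """Equal-variance SDT observer with separate metacognitive noise."""

    d_prime_true: float = 1.4
    criterion_true: float = 0.0
    sigma_meta: float = 0.95
    conf_criteria: tuple[float, float] = (1.0, 1.0)  # (ccw side, cw side)
    n_trials: int = 600
    p_cw: float = 0.5

    def __post_init__(self) -> None:
        _check_finite(
            "ObserverConfig", self.d_prime_true, self.criterion_true,
            self.sigma_meta, *self.conf_criteria, self.p_cw,
        )
        if self.d_prime_true < 0 or self.sigma_meta < 0:
            raise ValueError("d_prime_true and sigma_meta must be >= 0")
        if not 0 <= self.p_cw <= 1:
            raise ValueError("p_cw must lie in [0, 1]")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")


@dataclass
class SessionConfig:
    """One drug session: block structure, RT model, optional pupil coupling.

    ``rt_model`` is (mu, sigma) of a lognormal on the millisecond scale,
    truncated to [100, 1400] ms.  ``pupil_coupling`` is (a0, a1, a2): the
    effective d' on a trial in latent arousal bin b (1-5) is
    a0 + a1*b + a2*b^2; ``None`` disables the coupling (flat d').
    """

    drug_label: str = "PLC"
    n_blocks: int = 2
    rt_model: tuple[float, float] = (6.50, 0.16)
    p_missed: float = 0.01
    p_fixation_lost: float = 0.0
    pupil_coupling: tuple[float, float, float] | None = None
    # optional per-bin metacognitive noise (5 values); used to hold the
    # generative meta-d' flat while the coupling moves d' across bins
    sigma_meta_by_bin: tuple[float, ...] | None = None
    pupil_bin_spread_pct: float = 5.0    # spacing between latent bin centers
    pupil_noise_pct: float = 1.5         # within-bin baseline jitter

    def __post_init__(self) -> None:
        _check_finite("SessionConfig", *self.rt_model, self.p_missed)
        if self.drug_label not in DRUGS:
            raise ValueError(f"drug_label must be one of {DRUGS}")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0 <= self.p_missed < 1 or not 0 <= self.p_fixation_lost < 1:
            raise ValueError("probabilities must lie in [0, 1)")
        if self.pupil_coupling is not None:
            _check_finite("pupil_coupling", *self.pupil_coupling)


def _per_drug(value: dict[str, float] | float, drug: str) -> float:
    if isinstance(value, dict):
        return float(value.get(drug, 0.0))
    return float(value)


@dataclass
class EpochGenConfig:
    """Synthetic epoch morphology: CPP ramp, FP drift, orientation pattern.

    ``cpp_gain`` keys: base, accuracy_term, confidence_term, drug_term (a
    per-drug dict).  ``fp_gain`` keys: base, kappa (scalar or per-drug
    dict; multiplies the metacognitive-correctness indicator, +1 for
    high-confidence-correct / low-confidence-incorrect trials and -1
    otherwise), drug_term.  ``pattern_snr`` scales the orientation
    topography relative to the noise SD; the topography itself is fixed by
    ``pattern_seed`` so that localizer and main-task epoch sets share it.
    """

    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    sfreq: float = 512.0
    window: tuple[float, float] = (-0.2, 1.5)
    cpp_gain: dict = field(default_factory=lambda: {
        "base": 4.0, "accuracy_term": 1.5, "confidence_term": 1.0,
        "drug_term": {"PLC": 0.0, "DNP": 0.0, "ATX": 0.0},
    })
    fp_gain: dict = field(default_factory=lambda: {
        "base": -2.0, "kappa": 1.0, "drug_term": {"PLC": 0.0, "DNP": 0.0, "ATX": 0.0},
    })
    pattern_snr: float = 1.0
    pattern_window: tuple[float, float] = (0.1, 0.6)
    pattern_seed: int = 12345
    # "stimulus": topography sign follows the presented orientation;
    # "response": it follows the reported orientation, so error trials carry
    # the opposite-class pattern (below-chance decodability of errors)
    pattern_follows: str = "stimulus"
    noise_sd: float = 8.0
    noise_ar: float = 0.95
    noise_spatial_lambda: float = 0.6

    REQUIRED = ("CP1", "CPz", "CP2", "F1", "Fz", "F2")

    def __post_init__(self) -> None:
        if self.pattern_snr < 0:
            raise ValueError("pattern_snr must be >= 0")
        for ch in self.REQUIRED:
            if ch not in self.channel_names:
                raise ValueError(f"required channel {ch!r} missing from channel_names")


@dataclass
class StaircaseConfig:
    """Weighted up-down staircase on stimulus opacity.

    The observer's accuracy is a cumulative Gaussian of opacity with lower
    asymptote 0.5: p(correct) = 0.5 + 0.5 * Phi((opacity - threshold) /
    slope).  After an error the opacity increases by ``step_error``; after
    a correct response it decreases by ``step_error / weight_ratio``.  The
    run stops after ``n_reversals_stop`` behavioral reversals (changes in
    the correct/error sequence).
    """

    start_opacity: float = 0.15
    step_error: float = 0.01
    weight_ratio: float = 3.0
    n_reversals_stop: int = 50
    psychometric: tuple[float, float] = (0.05, 0.02)
    max_trials: int = 20000

    def __post_init__(self) -> None:
        if self.weight_ratio <= 0:
            raise ValueError("weight_ratio must be positive")
        if not 0 < self.start_opacity <= 1:
            raise ValueError("start_opacity must lie in (0, 1]")
        if self.psychometric[1] <= 0:
            raise ValueError("psychometric slope must be positive")


@dataclass
class StaircaseRun:
    opacities: np.ndarray
    outcomes: np.ndarray
    reversal_indices: np.ndarray
    threshold: float
    accuracy_at_threshold: float


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _balanced_stimuli(n: int, p_cw: float, rng: np.random.Generator) -> np.ndarray:
    n_cw = int(round(n * p_cw))
    stim = np.array([1] * n_cw + [0] * (n - n_cw))
    rng.shuffle(stim)
    return stim


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, n: int,
    lo: float = 100.0, hi: float = 1400.0,
) -> np.ndarray:
    out = np.exp(rng.normal(mu, sigma, n))
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = np.exp(rng.normal(mu, sigma, int(bad.sum())))
    return np.clip(out, lo, hi)


def _block_sizes(n: int, n_blocks: int) -> list[int]:
    base, rem = divmod(n, n_blocks)
    return [base + (1 if i < rem else 0) for i in range(n_blocks)]


def _simulate_block(
    obs: ObserverConfig,
    sess: SessionConfig,
    n: int,
    rng: np.random.Generator,
    d_eff: np.ndarray | None = None,
    sigma_eff: np.ndarray | None = None,
) -> pd.DataFrame:
    stim = _balanced_stimuli(n, obs.p_cw, rng)
    d = obs.d_prime_true if d_eff is None else np.asarray(d_eff)
    sm = obs.sigma_meta if sigma_eff is None else np.asarray(sigma_eff)
    c = obs.criterion_true
    x = rng.normal((2 * stim - 1) * d / 2.0, 1.0)
    resp = (x > c).astype(int)
    y = x + rng.normal(0.0, 1.0, n) * sm
    c2_ccw, c2_cw = obs.conf_criteria
    high = np.where(resp == 1, y > c + c2_cw, y < c - c2_ccw)
    rt = _truncated_lognormal(rng, *sess.rt_model, n)
    missed = rng.random(n) < sess.p_missed
    fixlost = rng.random(n) < sess.p_fixation_lost
    df = pd.DataFrame({
        "stimulus": np.where(stim == 1, "cw", "ccw"),
        "response": np.where(missed, "none", np.where(resp == 1, "cw", "ccw")),
        "confidence": np.where(missed, "none", np.where(high, "high", "low")),
        "rt_ms": np.where(missed, np.nan, np.round(rt, 1)),
        "fixation_lost": fixlost.astype(int),
    })
    return df


def simulate_behavior(
    obs: ObserverConfig, sess: SessionConfig, seed: int
) -> pd.DataFrame:
    """Simulate one session of the SDT observer (flat d', no pupil coupling).

    CW/CCW counts are exactly balanced at ``p_cw`` within every block.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for b, nb in enumerate(_block_sizes(obs.n_trials, sess.n_blocks)):
        df = _simulate_block(obs, sess, nb, rng)
        df.insert(0, "block", b + 1)
        blocks.append(df)
    out = pd.concat(blocks, ignore_index=True)
    out.insert(0, "drug", sess.drug_label)
    out.insert(2, "trial_index", np.arange(len(out)))
    out["pupil_baseline_pct"] = np.nan
    return out


def simulate_pupil(
    trials: pd.DataFrame, sess: SessionConfig, seed: int
) -> pd.DataFrame:
    """Attach a latent arousal bin and a prestimulus pupil baseline.

    Within every block each trial draws a latent bin (1-5, exactly equally
    populated up to remainder) and a baseline value (% difference from the
    block mean) centered on its bin; baselines are re-centered so every
    block averages exactly 0%.
    """
    rng = np.random.default_rng(seed)
    out = trials.copy()
    out["pupil_bin_true"] = 0
    centers = (np.arange(5) - 2.0) * sess.pupil_bin_spread_pct
    for _, idx in out.groupby("block", sort=True).groups.items():
        n = len(idx)
        reps = [n // 5 + (1 if i < n % 5 else 0) for i in range(5)]
        bins = np.repeat(np.arange(1, 6), reps)
        rng.shuffle(bins)
        base = centers[bins - 1] + rng.normal(0.0, sess.pupil_noise_pct, n)
        base = base - base.mean()
        out.loc[idx, "pupil_bin_true"] = bins
        out.loc[idx, "pupil_baseline_pct"] = np.round(base, 3)
    return out


def simulate_session(
    obs: ObserverConfig, sess: SessionConfig, seed: int
) -> pd.DataFrame:
    """Full coupled generator path: pupil bins first, then behavior whose
    effective d' follows ``sess.pupil_coupling`` per latent bin."""
    rng = np.random.default_rng(seed)
    skeleton = simulate_behavior(obs, sess, seed)  # fixes block structure
    trials = simulate_pupil(skeleton[["drug", "block", "trial_index"]].copy(),
                            sess, seed + 1)
    blocks = []
    for b in sorted(trials["block"].unique()):
        sub = trials[trials["block"] == b]
        d_eff = sigma_eff = None
        bins = sub["pupil_bin_true"].to_numpy()
        if sess.pupil_coupling is not None:
            a0, a1, a2 = sess.pupil_coupling
            d_eff = np.maximum(a0 + a1 * bins + a2 * bins**2, 0.0)
        if sess.sigma_meta_by_bin is not None:
            sigma_eff = np.asarray(sess.sigma_meta_by_bin)[bins - 1]
        df = _simulate_block(obs, sess, len(sub), rng, d_eff=d_eff,
                             sigma_eff=sigma_eff)
        df.index = sub.index
        blocks.append(pd.concat([sub.reset_index(drop=True),
                                 df.reset_index(drop=True)], axis=1))
    out = pd.concat(blocks, ignore_index=True)
    cols = ["drug", "block", "trial_index", "stimulus", "response",
            "confidence", "rt_ms", "pupil_baseline_pct", "fixation_lost",
            "pupil_bin_true"]
    return out[cols]


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

def _ar1_spatial_noise(
    rng: np.random.Generator, n: int, pos: np.ndarray, t: int,
    sd: float, ar: float, lam: float,
) -> np.ndarray:
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    cov = np.exp(-dist / lam)
    chol = np.linalg.cholesky(cov + 1e-9 * np.eye(len(pos)))
    white = rng.standard_normal((n, len(pos), t))
    spat = np.einsum("ij,njt->nit", chol, white)
    # AR(1) along time, scaled to keep stationary variance sd^2
    out = lfilter([1.0], [1.0, -ar], spat, axis=-1)
    return out * (sd * np.sqrt(1.0 - ar**2))


def _gauss_topo(pos: np.ndarray, center: np.ndarray, width: float) -> np.ndarray:
    d2 = np.sum((pos - center) ** 2, axis=1)
    return np.exp(-d2 / (2 * width**2))


def simulate_epochs(
    trials: pd.DataFrame, cfg: EpochGenConfig, seed: int
) -> EpochSet:
    """Stimulus-locked synthetic epochs for the given trials.

    data = AR(1)/spatially-correlated noise
         + CPP ramp peaking at the trial's RT (centroparietal topography)
         + FP negative drift over the 600 ms preceding the response,
           carrying kappa * (+-1 metacognitive-correctness) at the response
         + an orientation-specific spatial pattern in a latency window.
    Missed trials receive noise and (if applicable) the pattern only.
    """
    rng = np.random.default_rng(seed)
    names = list(cfg.channel_names)
    pos = channel_positions(names)
    sfreq = cfg.sfreq
    t0, t1 = cfg.window
    times = np.arange(round(t0 * sfreq), round(t1 * sfreq)) / sfreq
    nt = len(times)
    n = len(trials)

    data = _ar1_spatial_noise(
        rng, n, pos, nt, cfg.noise_sd, cfg.noise_ar, cfg.noise_spatial_lambda
    )

    cpp_topo = _gauss_topo(pos, pos[names.index("CPz")], 0.35)
    fp_topo = _gauss_topo(pos, pos[names.index("Fz")], 0.35)

    # orientation pattern: fixed topography, posterior-weighted, unit norm
    prng = np.random.default_rng(cfg.pattern_seed)
    post_w = np.exp(-((pos[:, 1] + 0.7) / 0.45) ** 2)
    pattern = prng.standard_normal(len(names)) * post_w
    pattern /= np.linalg.norm(pattern)

    resp = trials["response"].to_numpy()
    if cfg.pattern_follows == "response":
        stim_sign = np.where(resp == "cw", 1.0, np.where(resp == "ccw", -1.0, 0.0))
    elif cfg.pattern_follows == "stimulus":
        stim_sign = trials["stimulus"].map({"cw": 1.0, "ccw": -1.0}).to_numpy()
    else:
        raise ValueError("pattern_follows must be 'stimulus' or 'response'")
    answered = resp != "none"
    correct = (resp == trials["stimulus"].to_numpy()) & answered
    high = trials["confidence"].eq("high").to_numpy() & answered
    drug = trials["drug"].to_numpy() if "drug" in trials else np.array(["PLC"] * n)
    rt_s = pd.to_numeric(trials["rt_ms"], errors="coerce").to_numpy() / 1000.0

    pw = (times >= cfg.pattern_window[0]) & (times < cfg.pattern_window[1])
    amp_pat = cfg.pattern_snr * cfg.noise_sd
    data += (stim_sign[:, None] * amp_pat * pattern)[:, :, None] * pw[None, None, :]

    cg, fg = cfg.cpp_gain, cfg.fp_gain
    for i in np.flatnonzero(answered & np.isfinite(rt_s)):
        rt = rt_s[i]
        a_cpp = (
            cg["base"]
            + cg["accuracy_term"] * correct[i]
            + cg["confidence_term"] * high[i]
            + _per_drug(cg.get("drug_term", 0.0), drug[i])
        )
        ramp = np.zeros(nt)
        rise = (times > 0.1) & (times <= rt)
        if rt > 0.1:
            ramp[rise] = (times[rise] - 0.1) / (rt - 0.1)
        fall = (times > rt) & (times <= rt + 0.25)
        ramp[fall] = 1.0 - (times[fall] - rt) / 0.25
        data[i] += a_cpp * np.outer(cpp_topo, ramp)

        mc = 1.0 if (correct[i] == high[i]) else -1.0
        a_fp = (
            fg["base"]
            + _per_drug(fg.get("drug_term", 0.0), drug[i])
            + _per_drug(fg.get("kappa", 0.0), drug[i]) * mc
        )
        drift = np.clip((times - (rt - 0.6)) / 0.6, 0.0, 1.0)
        drift[times > rt + 0.25] = np.maximum(
            0.0, 1.0 - (times[times > rt + 0.25] - rt - 0.25) / 0.3
        )
        data[i] += a_fp * np.outer(fp_topo, drift)

    meta = trials.reset_index(drop=True).copy()
    meta["accuracy"] = np.where(answered, np.where(correct, "correct", "error"), "none")
    return EpochSet(
        data=data, times=times, sfreq=sfreq, lock="stimulus",
        channels=names, metadata=meta,
    )


# ---------------------------------------------------------------------------
# staircase
# ---------------------------------------------------------------------------

def _p_correct(opacity: np.ndarray | float, thr: float, slope: float):
    return 0.5 + 0.5 * ndtr((np.asarray(opacity, dtype=float) - thr) / slope)


def simulate_staircase(cfg: StaircaseConfig, seed: int) -> StaircaseRun:
    """Run the weighted up-down staircase on a cumulative-Gaussian observer.

    Converges near the opacity where p(correct) = weight_ratio /
    (weight_ratio + 1): with the default 3:1 weighting, ~75% correct.
    """
    rng = np.random.default_rng(seed)
    thr, slope = cfg.psychometric
    step_up = cfg.step_error
    step_down = cfg.step_error / cfg.weight_ratio
    op = cfg.start_opacity
    opacities, outcomes, reversals = [], [], []
    prev = None
    for t in range(cfg.max_trials):
        opacities.append(op)
        correct = rng.random() < _p_correct(op, thr, slope)
        outcomes.append(correct)
        if prev is not None and correct != prev:
            reversals.append(t)
            if len(reversals) >= cfg.n_reversals_stop:
                break
        prev = correct
        op = float(np.clip(op + (step_up if not correct else -step_down), 0.0, 1.0))
    opacities = np.array(opacities)
    outcomes = np.array(outcomes)
    rev = np.array(reversals, dtype=int)
    threshold = float(opacities[rev].mean()) if len(rev) else float(opacities.mean())
    n_eval = 10000
    acc = float((rng.random(n_eval) < _p_correct(threshold, thr, slope)).mean())
    return StaircaseRun(
        opacities=opacities, outcomes=outcomes, reversal_indices=rev,
        threshold=threshold, accuracy_at_threshold=acc,
    )


# ---------------------------------------------------------------------------
# study bundle
# ---------------------------------------------------------------------------

def generative_meta_d(
    d_prime: float,
    sigma_meta: float,
    c2: float = 1.0,
    criterion: float = 0.0,
) -> float:
    """Large-sample meta-d' implied by the generative observer.

    Computes the exact stimulus x response x confidence cell probabilities
    of the observer (evidence x and metacognitive sample y = x + noise are
    jointly normal) and fits the meta-d' MLE to them.  Note this lies well
    below d' / sqrt(1 + sigma_meta^2): trials where y disagrees with the
    response carry confidently wrong reports, an extra type-2 cost.
    """
    from scipy.stats import multivariate_normal

    from .sdt import ConfusionCounts, fit_meta_d, type1_sdt

    sm = max(float(sigma_meta), 1e-4)
    d, c = float(d_prime), float(criterion)
    cov = np.array([[1.0, 1.0], [1.0, 1.0 + sm**2]])
    big = 50.0
    cells = np.zeros((2, 2, 2))
    for s, mu in enumerate((-d / 2.0, d / 2.0)):
        mv = multivariate_normal([mu, mu], cov)

        def F(a, b):
            return float(mv.cdf([a, b]))

        p_cw = 1.0 - F(c, big)
        p_cw_hi = 1.0 - F(c, big) - F(big, c + c2) + F(c, c + c2)
        p_ccw = F(c, big)
        p_ccw_hi = F(c, c - c2)
        cells[s, 1, 1] = p_cw_hi
        cells[s, 1, 0] = p_cw - p_cw_hi
        cells[s, 0, 1] = p_ccw_hi
        cells[s, 0, 0] = p_ccw - p_ccw_hi
    counts = ConfusionCounts(np.maximum(cells, 0.0) * 1e6)
    return fit_meta_d(counts, type1_sdt(counts)).meta_d


from functools import lru_cache


@lru_cache(maxsize=4096)
def _held_meta_sigma(d_eff: float, target_meta: float) -> float:
    """Sigma_meta at which an observer with sensitivity ``d_eff`` keeps the
    generative meta-d' at ``target_meta`` (inputs rounded by callers so the
    cache is effective)."""
    from scipy.optimize import brentq

    if generative_meta_d(d_eff, 0.0) <= target_meta:
        return 0.0
    return float(brentq(
        lambda v: generative_meta_d(d_eff, v) - target_meta, 0.0, 8.0,
        xtol=5e-3,
    ))


def sigma_meta_for_ratio(m_ratio: float, d_prime: float = 1.4) -> float:
    """Metacognitive noise SD giving a target generative M-ratio at the
    given d' (inverts :func:`generative_meta_d` numerically)."""
    from scipy.optimize import brentq

    if not 0 < m_ratio <= 1:
        raise ValueError("m_ratio must lie in (0, 1]")
    if m_ratio > 0.999:
        return 0.0
    f = lambda sm: generative_meta_d(d_prime, sm) / d_prime - m_ratio
    return float(brentq(f, 0.0, 8.0, xtol=1e-3))


@dataclass
class StudyConfig:
    """Group-level study conditions (the defaults are the study design)."""

    n_subjects: int = 27
    n_trials: int = 600
    drugs: tuple[str, ...] = DRUGS
    d_prime_mean: float = 1.4
    d_prime_subject_sd: float = 0.35
    criterion_sd: float = 0.15
    sigma_meta: float = 0.95
    # additive drug effects on d'
    drug_d_effect: dict = field(default_factory=lambda: {"PLC": 0.0, "DNP": 0.0, "ATX": 0.3})
    # hold the generative meta-d' fixed across drugs by inflating sigma_meta
    # where a drug raises d' (the ATX phenotype: better d', unchanged meta-d')
    hold_meta_d: bool = True
    # inverted-U arousal coupling peaking above the middle bin, so bin-wise
    # d' carries both a positive linear and a negative quadratic component
    pupil_coupling_rel: tuple[float, float] | None = (0.2, -0.025)  # (a1, a2)
    session: SessionConfig = field(default_factory=SessionConfig)
    epochs: EpochGenConfig = field(default_factory=EpochGenConfig)


@dataclass
class StudyBundle:
    config: StudyConfig
    seed: int
    trials: pd.DataFrame          # all subjects/sessions concatenated
    ground_truth: pd.DataFrame    # one row per subject x session

    def session_trials(self, subject: int, drug: str) -> pd.DataFrame:
        m = (self.trials["subject"] == subject) & (self.trials["drug"] == drug)
        return self.trials.loc[m].reset_index(drop=True)

    def session_epochs(self, subject: int, drug: str,
                       cfg: EpochGenConfig | None = None) -> EpochSet:
        """Epochs are generated lazily and deterministically per session."""
        cfg = cfg or self.config.epochs
        sess_idx = self.config.drugs.index(drug)
        rng_seed = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(7, subject, sess_idx)
        ).generate_state(1)[0] % (2**31)
        return simulate_epochs(self.session_trials(subject, drug), cfg, int(rng_seed))


def make_study(cfg: StudyConfig | None = None, seed: int = 0) -> StudyBundle:
    """Generate the full study: per-subject x per-session trial tables plus
    a ground-truth record; deterministic given the seed."""
    cfg = cfg or StudyConfig()
    master = np.random.SeedSequence(seed)
    truth_rows = []
    tables = []
    for s in range(cfg.n_subjects):
        srng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(1, s))
        )
        d_base = max(0.2, srng.normal(cfg.d_prime_mean, cfg.d_prime_subject_sd))
        c_subj = srng.normal(0.0, cfg.criterion_sd)
        for k, drug in enumerate(cfg.drugs):
            d_drug = d_base + _per_drug(cfg.drug_d_effect, drug)
            sm = cfg.sigma_meta
            target_meta = None
            if cfg.hold_meta_d:
                # inflate metacognitive noise so the generative meta-d'
                # stays at its no-drug value despite any d' boost
                target_meta = round(generative_meta_d(
                    round(d_base, 2), cfg.sigma_meta), 3)
                if d_drug != d_base:
                    sm = _held_meta_sigma(round(d_drug, 2), target_meta)
            sigma_by_bin = None
            if cfg.pupil_coupling_rel is not None:
                a1, a2 = cfg.pupil_coupling_rel
                coupling = (d_drug - (a1 * 3 + a2 * 9), a1, a2)  # centered at bin 3
                if cfg.hold_meta_d:
                    bins = np.arange(1, 6)
                    d_bins = np.maximum(
                        coupling[0] + a1 * bins + a2 * bins**2, 0.2)
                    sigma_by_bin = tuple(
                        _held_meta_sigma(round(float(db), 2), target_meta)
                        for db in d_bins
                    )
            else:
                coupling = None
            sess = replace(cfg.session, drug_label=drug,
                           pupil_coupling=coupling,
                           sigma_meta_by_bin=sigma_by_bin)
            obs = ObserverConfig(
                d_prime_true=d_drug, criterion_true=c_subj,
                sigma_meta=sm, n_trials=cfg.n_trials,
            )
            sess_seed = int(np.random.SeedSequence(
                entropy=seed, spawn_key=(2, s, k)
            ).generate_state(1)[0] % (2**31))
            tab = simulate_session(obs, sess, sess_seed)
            tab.insert(0, "session", k + 1)
            tab.insert(0, "subject", s)
            tables.append(tab)
            truth_rows.append({
                "subject": s, "session": k + 1, "drug": drug,
                "d_prime_true": d_drug, "criterion_true": c_subj,
                "sigma_meta": sm,
                "meta_d_true_approx": d_drug / np.sqrt(1 + sm**2),
                "pupil_a1": coupling[1] if coupling else 0.0,
                "pupil_a2": coupling[2] if coupling else 0.0,
            })
    trials = pd.concat(tables, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return StudyBundle(config=cfg, seed=seed, trials=trials, ground_truth=truth)


def simulate_group_counts(
    n_subjects: int,
    d_prime: float,
    m_ratio: float,
    n_trials: int,
    seed: int,
    d_prime_sd: float = 0.2,
):
    """Per-subject confusion tables for a group with a target M-ratio.

    Returns (list of ConfusionCounts, list of true d') - the standard input
    for the hierarchical group fits.
    """
    from .sdt import tabulate_counts

    sm = sigma_meta_for_ratio(m_ratio)
    rng = np.random.default_rng(seed)
    counts, d_true = [], []
    for s in range(n_subjects):
        d_s = max(0.2, rng.normal(d_prime, d_prime_sd))
        obs = ObserverConfig(d_prime_true=d_s, sigma_meta=sm, n_trials=n_trials)
        sess = SessionConfig(p_missed=0.0)
        tab = simulate_behavior(obs, sess, int(rng.integers(2**31)))
        counts.append(tabulate_counts(tab))
        d_true.append(d_s)
    return counts, d_true
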