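"""Single-subject signal-detection quantities.

Type-1 sensitivity (d') and bias (criterion c) come from z-transformed hit
and false-alarm rates with "cw" designated the signal class, so

    d' = z(H) - z(FA),      c = -(z(H) + z(FA)) / 2,

where H = P(respond cw | cw stimulus) and FA = P(respond cw | ccw stimulus).

Metacognitive sensitivity (meta-d') is the type-1 sensitivity an
SDT-ideal observer would need to produce the observed response-conditional
confidence data.  It is estimated by maximizing the multinomial likelihood
of the binary-confidence counts conditional on the response, under an
equal-variance Gaussian observer whose type-1 criterion is fixed in meta
space at meta_c = c * (meta_d / d') and with one free type-2 criterion
offset per response side.  Metacognitive efficiency is summarized as
M-diff = meta-d' - d' and M-ratio = meta-d' / d'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

__all__ = [
    "ConfusionCounts",
    "TypeOneEstimates",
    "MetaDFit",
    "EfficiencyScores",
    "ExclusionReport",
    "exclude_trials",
    "tabulate_counts",
    "type1_sdt",
    "fit_meta_d",
    "efficiency",
    "confidence_rate",
]

STIMULI = ("ccw", "cw")
RESPONSES = ("ccw", "cw")
CONFIDENCES = ("low", "high")

RT_MIN_MS = 100.0
RT_MAX_MS = 1400.0

_EPS_DPRIME = 1e-3  # below this |d'|, meta-space anchoring is undefined


@dataclass
class ConfusionCounts:
    """Stimulus x response x confidence counts, the sufficient statistic for
    every SDT fit.  Axis order: stimulus (ccw, cw) x response (ccw, cw) x
    confidence (low, high)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 2, 2):
            raise ValueError("counts must be 2x2x2 (stimulus x response x confidence)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("counts table is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def type1_table(self) -> np.ndarray:
        """2x2 stimulus x response table, confidence marginalized out."""
        return self.counts.sum(axis=2)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.counts + other.counts)


@dataclass
class TypeOneEstimates:
    d_prime: float
    criterion: float
    hit_rate: float
    fa_rate: float


@dataclass
class MetaDFit:
    meta_d: float
    meta_c: float
    c2: tuple[float, float]  # absolute type-2 criteria (ccw side, cw side)
    loglik: float
    converged: bool
    n_restarts_used: int
    anchoring_fallback: bool = False


@dataclass
class EfficiencyScores:
    m_diff: float
    m_ratio: float | None
    log_m_ratio: float | None
    m_ratio_defined: bool


@dataclass
class ExclusionReport:
    n_input: int
    n_missed: int
    n_rt_fast: int
    n_rt_slow: int
    n_fixation_lost: int
    n_retained: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def exclude_trials(
    trials: pd.DataFrame,
    rt_min_ms: float = RT_MIN_MS,
    rt_max_ms: float = RT_MAX_MS,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the behavioral exclusion rules.

    Removes missed trials (no response), reaction times outside
    [rt_min_ms, rt_max_ms], and fixation-lost trials.  Reasons are tallied
    in priority order (fixation loss, then missed, then RT) so each trial is
    counted once.
    """
    n_input = len(trials)
    fix = (
        trials["fixation_lost"].astype(bool)
        if "fixation_lost" in trials
        else pd.Series(False, index=trials.index)
    )
    missed = trials["response"].eq("none") & ~fix
    rt = pd.to_numeric(trials["rt_ms"], errors="coerce")
    answered = ~missed & ~fix
    fast = answered & (rt < rt_min_ms)
    slow = answered & (rt > rt_max_ms)
    keep = answered & ~fast & ~slow
    out = trials.loc[keep].copy()
    report = ExclusionReport(
        n_input=n_input,
        n_missed=int(missed.sum()),
        n_rt_fast=int(fast.sum()),
        n_rt_slow=int(slow.sum()),
        n_fixation_lost=int(fix.sum()),
        n_retained=len(out),
    )
    if len(out) == 0:
        raise ValueError("no analyzable trials after exclusion")
    return out, report


def tabulate_counts(trials: pd.DataFrame) -> ConfusionCounts:
    """Build the 2x2x2 confusion table from filtered trials."""
    counts = np.zeros((2, 2, 2), dtype=int)
    for col, vocab in (("stimulus", STIMULI), ("response", RESPONSES), ("confidence", CONFIDENCES)):
        bad = set(trials[col].unique()) - set(vocab)
        if bad:
            raise ValueError(f"unknown {col} labels: {sorted(bad)}")
    si = trials["stimulus"].map({s: i for i, s in enumerate(STIMULI)}).to_numpy()
    ri = trials["response"].map({r: i for i, r in enumerate(RESPONSES)}).to_numpy()
    ci = trials["confidence"].map({c: i for i, c in enumerate(CONFIDENCES)}).to_numpy()
    np.add.at(counts, (si, ri, ci), 1)
    return ConfusionCounts(counts)


def type1_sdt(counts: ConfusionCounts, correction: str = "half_count") -> TypeOneEstimates:
    """d' and criterion from the type-1 margin of the confusion table.

    Rates of exactly 0 or 1 are padded to 1/(2N) and 1 - 1/(2N) of the
    corresponding stimulus row (``correction="half_count"``); pass
    ``correction="none"`` to fail loudly instead.
    """
    t1 = counts.type1_table()
    n_ccw, n_cw = t1.sum(axis=1)
    if n_ccw == 0 or n_cw == 0:
        raise ValueError("degenerate table: both stimulus classes are required")
    hit = t1[1, 1] / n_cw       # respond cw | cw
    fa = t1[0, 1] / n_ccw       # respond cw | ccw
    if correction == "half_count":
        if hit in (0.0, 1.0):
            hit = np.clip(hit, 1 / (2 * n_cw), 1 - 1 / (2 * n_cw))
        if fa in (0.0, 1.0):
            fa = np.clip(fa, 1 / (2 * n_ccw), 1 - 1 / (2 * n_ccw))
    elif correction == "none":
        if hit in (0.0, 1.0) or fa in (0.0, 1.0):
            raise ValueError("marginal rate of 0 or 1 with correction disabled")
    else:
        raise ValueError(f"unknown correction policy {correction!r}")
    zh, zf = ndtri(hit), ndtri(fa)
    return TypeOneEstimates(
        d_prime=float(zh - zf),
        criterion=float(-(zh + zf) / 2),
        hit_rate=float(hit),
        fa_rate=float(fa),
    )


def _type2_loglik(
    params: np.ndarray,
    c_hat: float,
    d_hat: float,
    n_high: np.ndarray,
    n_low: np.ndarray,
    anchoring_fallback: bool,
) -> float:
    """Negative log-likelihood of response-conditional confidence counts.

    ``n_high``/``n_low`` have shape (2 stimuli, 2 responses).
    """
    meta_d, off_ccw, off_cw = params
    meta_c = c_hat if anchoring_fallback else c_hat * meta_d / d_hat
    mu = np.array([-meta_d / 2.0, meta_d / 2.0])  # per stimulus
    # response cw: evidence above meta_c; high if above meta_c + off_cw
    den_cw = ndtr(mu - meta_c)
    num_cw = ndtr(mu - meta_c - off_cw)
    # response ccw: evidence below meta_c; high if below meta_c - off_ccw
    den_ccw = ndtr(meta_c - mu)
    num_ccw = ndtr(meta_c - off_ccw - mu)
    p_high = np.stack([num_ccw / np.maximum(den_ccw, 1e-300),
                       num_cw / np.maximum(den_cw, 1e-300)], axis=1)
    p_high = np.clip(p_high, 1e-10, 1 - 1e-10)
    ll = np.sum(n_high * np.log(p_high) + n_low * np.log1p(-p_high))
    return -ll


def fit_meta_d(
    counts: ConfusionCounts,
    t1: TypeOneEstimates | None = None,
    *,
    n_restarts: int = 5,
    seed: int = 0,
    bounds_meta_d: tuple[float, float] = (-5.0, 5.0),
    bounds_offset: tuple[float, float] = (0.0, 5.0),
) -> MetaDFit:
    """Maximum-likelihood meta-d' fit for binary confidence data.

    The type-1 criterion is held fixed in meta space at
    meta_c = c * (meta_d / d'); one non-negative type-2 criterion offset per
    response side is free.  If a response side of the confidence table
    contains a zero cell, 1/(2*4) is added to each of that side's four
    cells.  Bounded L-BFGS-B from ``n_restarts`` jittered starting points.
    """
    t1 = t1 or type1_sdt(counts)
    d_hat, c_hat = t1.d_prime, t1.criterion
    fallback = abs(d_hat) < _EPS_DPRIME

    c = counts.counts.astype(float)
    for r in range(2):
        if np.any(c[:, r, :] == 0):
            c[:, r, :] += 1.0 / (2 * 4)
    n_low, n_high = c[:, :, 0], c[:, :, 1]

    rng = np.random.default_rng(seed)
    # start at the type-1 estimate with offsets from the overall high rate
    p_high_obs = n_high.sum() / c.sum()
    off0 = max(0.1, abs(ndtri(np.clip(1 - p_high_obs, 0.05, 0.95))))
    best = None
    n_used = 0
    for i in range(n_restarts):
        x0 = np.array([d_hat, off0, off0])
        if i > 0:
            x0 = x0 + rng.normal(0, [0.5, 0.25, 0.25])
        x0[0] = np.clip(x0[0], *bounds_meta_d)
        x0[1:] = np.clip(x0[1:], *bounds_offset)
        res = minimize(
            _type2_loglik,
            x0,
            args=(c_hat, d_hat, n_high, n_low, fallback),
            method="L-BFGS-B",
            bounds=[bounds_meta_d, bounds_offset, bounds_offset],
            options={"ftol": 1e-9, "gtol": 1e-7},
        )
        n_used = i + 1
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if res.success and i >= 1:
            break
    meta_d, off_ccw, off_cw = best.x
    meta_c = c_hat if fallback else c_hat * meta_d / d_hat
    return MetaDFit(
        meta_d=float(meta_d),
        meta_c=float(meta_c),
        c2=(float(meta_c - off_ccw), float(meta_c + off_cw)),
        loglik=float(-best.fun),
        converged=bool(best.success),
        n_restarts_used=n_used,
        anchoring_fallback=fallback,
    )


def efficiency(fit: MetaDFit, t1: TypeOneEstimates) -> EfficiencyScores:
    """M-diff and M-ratio from a meta-d' fit and type-1 estimates."""
    if not (np.isfinite(fit.meta_d) and np.isfinite(t1.d_prime)):
        raise ValueError("estimates must be finite")
    m_diff = fit.meta_d - t1.d_prime
    if t1.d_prime == 0:
        return EfficiencyScores(m_diff, None, None, False)
    m_ratio = fit.meta_d / t1.d_prime
    log_mr = float(np.log(m_ratio)) if m_ratio > 0 else None
    return EfficiencyScores(
        float(m_diff), float(m_ratio), log_mr, m_ratio_defined=True
    )


def confidence_rate(trials: pd.DataFrame) -> float:
    """Proportion of answered trials reported with high confidence."""
    answered = trials["confidence"].isin(CONFIDENCES)
    n = int(answered.sum())
    if n == 0:
        raise ValueError("no answered trials")
    return float(trials.loc[answered, "confidence"].eq("high").sum() / n)


def subject_metrics(trials: pd.DataFrame) -> dict:
    """Convenience: all single-subject SDT quantities from filtered trials."""
    counts = tabulate_counts(trials)
    t1 = type1_sdt(counts)
    fit = fit_meta_d(counts, t1)
    eff = efficiency(fit, t1)
    return {
        "d_prime": t1.d_prime,
        "criterion": t1.criterion,
        "meta_d": fit.meta_d,
        "meta_c": fit.meta_c,
        "m_diff": eff.m_diff,
        "m_ratio": eff.m_ratio,
        "conf_rate": confidence_rate(trials),
        "n_trials": counts.total,
    }
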