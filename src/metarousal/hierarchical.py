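"""Hierarchical Bayesian group inference on log M-ratio.

Two models are provided, both sampled with a self-contained
Metropolis-within-Gibbs random-walk sampler (no external PPL):

* a paired two-condition model: each subject's pair of log M-ratios is
  drawn from a bivariate normal with condition means (mu_A, mu_B), SDs and
  a correlation; the reported drug effect is the posterior of mu_A - mu_B;
* a pupil-bin regression model: the subject x bin log M-ratio mean is
  mu + beta_bin * (bin - 3) + subject offset.

In both, the subject-level likelihood is the response-conditional
type-2 multinomial of the meta-d' observer evaluated at
meta-d' = exp(logMratio) * d-hat, with the subject's d' and criterion
fixed at their point estimates and the type-1 criterion anchored in meta
space at meta_c = c-hat * exp(logMratio).  Type-2 criterion offsets are
sampled per subject (Half-Normal(2) priors).

Priors: condition means ~ Normal(0, 1); group SDs ~ Half-Normal(1);
correlation ~ Uniform(-1, 1).  Proposal scales adapt during warmup toward
~30% acceptance and are frozen afterwards.  Convergence is assessed with
the classic split-chain Gelman-Rubin R-hat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .sdt import ConfusionCounts, type1_sdt

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "PosteriorSummary",
    "fit_group_paired",
    "fit_group_bin_regression",
    "split_rhat",
    "diagnose",
    "summarize",
]

_LMR_BOUND = 5.0
_OFF_PRIOR_SD = 2.0


@dataclass
class McmcConfig:
    n_samples: int = 10000
    n_warmup: int = 2000
    n_chains: int = 3
    seed: int = 0
    proposal_scales: dict = field(default_factory=lambda: {
        "lmr": 0.3, "off": 0.15, "group": 0.2,
    })

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_warmup < 0:
            raise ValueError("n_samples must be > 0 and n_warmup >= 0")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence checks")


@dataclass
class PosteriorSamples:
    """MCMC draws, one (n_chains, n_samples) array per parameter."""

    draws: dict[str, np.ndarray]
    n_warmup: int
    seed: int
    labels: tuple[str, ...] = ()

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def to_long_frame(self):
        import pandas as pd

        rows = []
        for name, arr in self.draws.items():
            c, it = arr.shape
            rows.append(pd.DataFrame({
                "parameter": name,
                "chain": np.repeat(np.arange(c), it),
                "iteration": np.tile(np.arange(it), c),
                "value": arr.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class PosteriorSummary:
    mean: float
    sd: float
    ci95: tuple[float, float]
    p_gt_zero: float
    rhat: float | None
    flagged: bool = False


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def _prep_counts(counts: list[ConfusionCounts]):
    """Stack padded type-2 counts and type-1 point estimates.

    Applies the same response-side zero-cell padding as the single-subject
    MLE (1/8 to each of a side's four cells when the side has a zero).
    """
    n = len(counts)
    n_high = np.empty((n, 2, 2))
    n_low = np.empty((n, 2, 2))
    d_hat = np.empty(n)
    c_hat = np.empty(n)
    for i, cc in enumerate(counts):
        c = cc.counts.astype(float)
        for r in range(2):
            if np.any(c[:, r, :] == 0):
                c[:, r, :] += 1.0 / 8.0
        n_low[i] = c[:, :, 0]
        n_high[i] = c[:, :, 1]
        t1 = type1_sdt(cc)
        d_hat[i] = t1.d_prime
        c_hat[i] = t1.criterion
    if np.any(np.abs(d_hat) < 1e-3):
        raise ValueError("a subject has |d'| ~ 0; the M-ratio model is undefined")
    return n_high, n_low, d_hat, c_hat


def _t2_loglik(lmr, off_ccw, off_cw, d_hat, c_hat, n_high, n_low):
    """Type-2 log-likelihood, broadcasting over leading (chain, ...) axes.

    ``n_high``/``n_low`` carry trailing (stimulus, response) axes.
    """
    # proposals beyond the lmr bound are rejected by the samplers; clip
    # here only to keep their (discarded) likelihoods finite
    emd = np.exp(np.clip(lmr, -20.0, 20.0))
    meta_d = emd * d_hat
    meta_c = emd * c_hat
    ll = 0.0
    for s, sign in enumerate((-1.0, 1.0)):
        mu = sign * meta_d / 2.0
        den_cw = ndtr(mu - meta_c)
        num_cw = ndtr(mu - meta_c - off_cw)
        den_ccw = ndtr(meta_c - mu)
        num_ccw = ndtr(meta_c - off_ccw - mu)
        p_cw = np.clip(num_cw / np.maximum(den_cw, 1e-300), 1e-9, 1 - 1e-9)
        p_ccw = np.clip(num_ccw / np.maximum(den_ccw, 1e-300), 1e-9, 1 - 1e-9)
        ll = (
            ll
            + n_high[..., s, 1] * np.log(p_cw)
            + n_low[..., s, 1] * np.log1p(-p_cw)
            + n_high[..., s, 0] * np.log(p_ccw)
            + n_low[..., s, 0] * np.log1p(-p_ccw)
        )
    return ll


def _bvn_logpdf(a, b, mu_a, mu_b, s_a, s_b, rho):
    za = (a - mu_a) / s_a
    zb = (b - mu_b) / s_b
    om = 1.0 - rho**2
    return (
        -np.log(2 * np.pi * s_a * s_b) - 0.5 * np.log(om)
        - (za**2 - 2 * rho * za * zb + zb**2) / (2 * om)
    )


class _Block:
    """Adaptive random-walk scale for one update block (per chain)."""

    def __init__(self, scale: float, n_chains: int):
        self.scale = np.full(n_chains, float(scale))
        self.acc = np.zeros(n_chains)
        self.tries = 0

    def record(self, acc_rate_per_chain: np.ndarray) -> None:
        self.acc += acc_rate_per_chain
        self.tries += 1

    def adapt(self) -> None:
        if self.tries == 0:
            return
        rate = self.acc / self.tries
        self.scale *= np.exp(1.2 * (rate - 0.3))
        self.scale = np.clip(self.scale, 1e-3, 10.0)
        self.acc[:] = 0.0
        self.tries = 0


def _offset_logprior(o0, o1):
    lp = -(o0**2 + o1**2) / (2 * _OFF_PRIOR_SD**2)
    return np.where((o0 >= 0) & (o1 >= 0), lp, -np.inf)


# ---------------------------------------------------------------------------
# paired two-condition model
# ---------------------------------------------------------------------------

def fit_group_paired(
    counts_a: list[ConfusionCounts],
    counts_b: list[ConfusionCounts],
    cfg: McmcConfig | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> PosteriorSamples:
    """Posterior over group log M-ratio in two paired conditions.

    Returns draws for the condition means, group SDs, correlation, and the
    paired difference ``mu_diff = mu_A - mu_B``.
    """
    cfg = cfg or McmcConfig()
    if len(counts_a) != len(counts_b):
        raise ValueError("conditions must contain the same subjects")
    nHa, nLa, da, ca = _prep_counts(counts_a)
    nHb, nLb, db, cb = _prep_counts(counts_b)
    n = len(counts_a)
    c = cfg.n_chains
    rng = np.random.default_rng(cfg.seed)

    def ll_a(lmr, o0, o1):
        return _t2_loglik(lmr, o0, o1, da, ca, nHa, nLa)

    def ll_b(lmr, o0, o1):
        return _t2_loglik(lmr, o0, o1, db, cb, nHb, nLb)

    for attempt in range(10):
        lmrA = 0.1 * rng.standard_normal((c, n))
        lmrB = 0.1 * rng.standard_normal((c, n))
        offA = 0.7 + 0.1 * rng.random((c, n, 2))
        offB = 0.7 + 0.1 * rng.random((c, n, 2))
        cllA = ll_a(lmrA, offA[..., 0], offA[..., 1])
        cllB = ll_b(lmrB, offB[..., 0], offB[..., 1])
        if np.all(np.isfinite(cllA)) and np.all(np.isfinite(cllB)):
            break
    else:
        raise RuntimeError("could not find a finite-likelihood initial state")

    muA = np.zeros(c)
    muB = np.zeros(c)
    lsA = np.full(c, np.log(0.5))
    lsB = np.full(c, np.log(0.5))
    zr = np.zeros(c)

    blocks = {
        "lmrA": _Block(cfg.proposal_scales["lmr"], c),
        "lmrB": _Block(cfg.proposal_scales["lmr"], c),
        "offA": _Block(cfg.proposal_scales["off"], c),
        "offB": _Block(cfg.proposal_scales["off"], c),
        "muA": _Block(cfg.proposal_scales["group"], c),
        "muB": _Block(cfg.proposal_scales["group"], c),
        "lsA": _Block(cfg.proposal_scales["group"], c),
        "lsB": _Block(cfg.proposal_scales["group"], c),
        "zr": _Block(cfg.proposal_scales["group"], c),
        "sclA": _Block(cfg.proposal_scales["group"], c),
        "sclB": _Block(cfg.proposal_scales["group"], c),
    }

    n_iter = cfg.n_warmup + cfg.n_samples
    names = ("mu_A", "mu_B", "sigma_A", "sigma_B", "rho", "mu_diff")
    draws = {k: np.empty((c, cfg.n_samples)) for k in names}

    def bvn_terms(la, lb, mA, mB, sA, sB, rho):
        return _bvn_logpdf(la, lb, mA[:, None], mB[:, None],
                           sA[:, None], sB[:, None], rho[:, None])

    for it in range(n_iter):
        sA = np.exp(lsA)
        sB = np.exp(lsB)
        rho = np.tanh(zr)

        # --- subject-level log M-ratio, condition A then B
        for tag, which in (("lmrA", 0), ("lmrB", 1)):
            blk = blocks[tag]
            cur = lmrA if which == 0 else lmrB
            cll = cllA if which == 0 else cllB
            off = offA if which == 0 else offB
            llf = ll_a if which == 0 else ll_b
            prop = cur + blk.scale[:, None] * rng.standard_normal((c, n))
            pll = llf(prop, off[..., 0], off[..., 1])
            if which == 0:
                dpri = (bvn_terms(prop, lmrB, muA, muB, sA, sB, rho)
                        - bvn_terms(cur, lmrB, muA, muB, sA, sB, rho))
            else:
                dpri = (bvn_terms(lmrA, prop, muA, muB, sA, sB, rho)
                        - bvn_terms(lmrA, cur, muA, muB, sA, sB, rho))
            logr = (pll - cll) + dpri
            logr = np.where(np.abs(prop) <= _LMR_BOUND, logr, -np.inf)
            acc = np.log(rng.random((c, n))) < logr
            cur[acc] = prop[acc]
            cll[acc] = pll[acc]
            blk.record(acc.mean(axis=1))

        # --- type-2 criterion offsets
        for tag, which in (("offA", 0), ("offB", 1)):
            blk = blocks[tag]
            off = offA if which == 0 else offB
            cur_lmr = lmrA if which == 0 else lmrB
            cll = cllA if which == 0 else cllB
            llf = ll_a if which == 0 else ll_b
            prop = off + blk.scale[:, None, None] * rng.standard_normal((c, n, 2))
            pll = llf(cur_lmr, prop[..., 0], prop[..., 1])
            logr = (pll - cll) + (_offset_logprior(prop[..., 0], prop[..., 1])
                                  - _offset_logprior(off[..., 0], off[..., 1]))
            acc = np.log(rng.random((c, n))) < logr
            off[acc] = prop[acc]
            cll[acc] = pll[acc]
            blk.record(acc.mean(axis=1))

        # --- group-level scalars
        def group_update(tag, cur, logpost):
            blk = blocks[tag]
            prop = cur + blk.scale * rng.standard_normal(c)
            logr = logpost(prop) - logpost(cur)
            acc = np.log(rng.random(c)) < logr
            cur[acc] = prop[acc]
            blk.record(acc.astype(float))
            return cur

        muA = group_update("muA", muA, lambda v: (
            bvn_terms(lmrA, lmrB, v, muB, sA, sB, rho).sum(axis=1) - v**2 / 2))
        muB = group_update("muB", muB, lambda v: (
            bvn_terms(lmrA, lmrB, muA, v, sA, sB, rho).sum(axis=1) - v**2 / 2))
        lsA = group_update("lsA", lsA, lambda v: (
            bvn_terms(lmrA, lmrB, muA, muB, np.exp(v), sB, rho).sum(axis=1)
            - np.exp(v) ** 2 / 2 + v))
        sA = np.exp(lsA)
        lsB = group_update("lsB", lsB, lambda v: (
            bvn_terms(lmrA, lmrB, muA, muB, sA, np.exp(v), rho).sum(axis=1)
            - np.exp(v) ** 2 / 2 + v))
        sB = np.exp(lsB)
        zr = group_update("zr", zr, lambda v: (
            bvn_terms(lmrA, lmrB, muA, muB, sA, sB, np.tanh(v)).sum(axis=1)
            + np.log1p(-np.tanh(v) ** 2)))

        # --- joint scale moves: rescale a condition's group SD together
        # with its subject deviations (escapes the funnel at sigma -> 0;
        # the bivariate-normal quadratic form is invariant, and its
        # normalization cancels against the transformation Jacobian)
        for tag, which in (("sclA", 0), ("sclB", 1)):
            blk = blocks[tag]
            eps = blk.scale * rng.standard_normal(c)
            if which == 0:
                cur_lmr, cur_ls, mu_c, off, cll, llf = lmrA, lsA, muA, offA, cllA, ll_a
            else:
                cur_lmr, cur_ls, mu_c, off, cll, llf = lmrB, lsB, muB, offB, cllB, ll_b
            prop_lmr = mu_c[:, None] + (cur_lmr - mu_c[:, None]) * np.exp(eps)[:, None]
            prop_ls = cur_ls + eps
            pll = llf(prop_lmr, off[..., 0], off[..., 1])
            logr = (pll - cll).sum(axis=1)
            logr += (-np.exp(prop_ls) ** 2 / 2 + prop_ls) - (
                -np.exp(cur_ls) ** 2 / 2 + cur_ls)
            logr = np.where(np.abs(prop_lmr).max(axis=1) <= _LMR_BOUND,
                            logr, -np.inf)
            acc = np.log(rng.random(c)) < logr
            cur_lmr[acc] = prop_lmr[acc]
            cll[acc] = pll[acc]
            cur_ls[acc] = prop_ls[acc]
            blk.record(acc.astype(float))
        sA = np.exp(lsA)
        sB = np.exp(lsB)

        if it < cfg.n_warmup:
            if (it + 1) % 25 == 0:
                for blk in blocks.values():
                    blk.adapt()
        else:
            j = it - cfg.n_warmup
            draws["mu_A"][:, j] = muA
            draws["mu_B"][:, j] = muB
            draws["sigma_A"][:, j] = np.exp(lsA)
            draws["sigma_B"][:, j] = np.exp(lsB)
            draws["rho"][:, j] = np.tanh(zr)
            draws["mu_diff"][:, j] = muA - muB

    return PosteriorSamples(draws=draws, n_warmup=cfg.n_warmup, seed=cfg.seed,
                            labels=tuple(labels))


# ---------------------------------------------------------------------------
# pupil-bin regression model
# ---------------------------------------------------------------------------

def fit_group_bin_regression(
    counts_by_bin: list[list[ConfusionCounts]],
    cfg: McmcConfig | None = None,
    n_bins: int = 5,
) -> PosteriorSamples:
    """Posterior over the linear pupil-bin slope of log M-ratio.

    ``counts_by_bin[subject][bin]`` holds one confusion table per subject
    and bin (bins coded 1..n_bins, centered internally on the middle bin).
    Returns draws for ``mu``, ``beta_bin``, ``sigma_subj`` and
    ``sigma_resid``.
    """
    cfg = cfg or McmcConfig()
    n = len(counts_by_bin)
    if any(len(row) != n_bins for row in counts_by_bin):
        raise ValueError(f"every subject needs exactly {n_bins} bins")
    flat = [cc for row in counts_by_bin for cc in row]
    nH, nL, d_hat, c_hat = _prep_counts(flat)
    shape = (n, n_bins)
    nH = nH.reshape(*shape, 2, 2)
    nL = nL.reshape(*shape, 2, 2)
    d_hat = d_hat.reshape(shape)
    c_hat = c_hat.reshape(shape)
    bins_c = np.arange(1, n_bins + 1) - (n_bins + 1) / 2.0

    c = cfg.n_chains
    rng = np.random.default_rng(cfg.seed)

    def ll(lmr, o0, o1):
        return _t2_loglik(lmr, o0, o1, d_hat, c_hat, nH, nL)

    lmr = 0.1 * rng.standard_normal((c, n, n_bins))
    off = 0.7 + 0.1 * rng.random((c, n, n_bins, 2))
    u = 0.1 * rng.standard_normal((c, n))
    mu = np.zeros(c)
    beta = np.zeros(c)
    ls_s = np.full(c, np.log(0.3))
    ls_e = np.full(c, np.log(0.3))
    cll = ll(lmr, off[..., 0], off[..., 1])
    if not np.all(np.isfinite(cll)):
        raise RuntimeError("non-finite likelihood at initialization")

    blocks = {
        "lmr": _Block(cfg.proposal_scales["lmr"], c),
        "off": _Block(cfg.proposal_scales["off"], c),
        "u": _Block(cfg.proposal_scales["lmr"], c),
        "mu": _Block(cfg.proposal_scales["group"], c),
        "beta": _Block(cfg.proposal_scales["group"], c),
        "ls_s": _Block(cfg.proposal_scales["group"], c),
        "ls_e": _Block(cfg.proposal_scales["group"], c),
        "scl_s": _Block(cfg.proposal_scales["group"], c),
        "scl_e": _Block(cfg.proposal_scales["group"], c),
    }

    def pred(mu_, beta_, u_):
        return (mu_[:, None, None] + beta_[:, None, None] * bins_c
                + u_[:, :, None])

    def norm_lp(x, m, sd):
        return -0.5 * ((x - m) / sd) ** 2 - np.log(sd)

    n_iter = cfg.n_warmup + cfg.n_samples
    names = ("mu", "beta_bin", "sigma_subj", "sigma_resid")
    draws = {k: np.empty((c, cfg.n_samples)) for k in names}

    for it in range(n_iter):
        s_s = np.exp(ls_s)
        s_e = np.exp(ls_e)
        m_pred = pred(mu, beta, u)

        # subject x bin log M-ratio
        blk = blocks["lmr"]
        prop = lmr + blk.scale[:, None, None] * rng.standard_normal(lmr.shape)
        pll = ll(prop, off[..., 0], off[..., 1])
        dpri = (norm_lp(prop, m_pred, s_e[:, None, None])
                - norm_lp(lmr, m_pred, s_e[:, None, None]))
        logr = np.where(np.abs(prop) <= _LMR_BOUND, (pll - cll) + dpri, -np.inf)
        acc = np.log(rng.random(lmr.shape)) < logr
        lmr[acc] = prop[acc]
        cll[acc] = pll[acc]
        blk.record(acc.mean(axis=(1, 2)))

        # offsets
        blk = blocks["off"]
        prop = off + blk.scale[:, None, None, None] * rng.standard_normal(off.shape)
        pll = ll(lmr, prop[..., 0], prop[..., 1])
        logr = (pll - cll) + (_offset_logprior(prop[..., 0], prop[..., 1])
                              - _offset_logprior(off[..., 0], off[..., 1]))
        acc = np.log(rng.random(lmr.shape)) < logr
        off[acc] = prop[acc]
        cll[acc] = pll[acc]
        blk.record(acc.mean(axis=(1, 2)))

        # subject offsets
        blk = blocks["u"]
        prop_u = u + blk.scale[:, None] * rng.standard_normal(u.shape)
        d_terms = (norm_lp(lmr, pred(mu, beta, prop_u), s_e[:, None, None])
                   - norm_lp(lmr, pred(mu, beta, u), s_e[:, None, None])).sum(axis=2)
        d_terms += norm_lp(prop_u, 0.0, s_s[:, None]) - norm_lp(u, 0.0, s_s[:, None])
        acc = np.log(rng.random(u.shape)) < d_terms
        u[acc] = prop_u[acc]
        blk.record(acc.mean(axis=1))

        # group scalars
        def upd(tag, cur, logpost):
            blk = blocks[tag]
            prop = cur + blk.scale * rng.standard_normal(c)
            logr = logpost(prop) - logpost(cur)
            acc = np.log(rng.random(c)) < logr
            cur[acc] = prop[acc]
            blk.record(acc.astype(float))
            return cur

        mu = upd("mu", mu, lambda v: (
            norm_lp(lmr, pred(v, beta, u), s_e[:, None, None]).sum(axis=(1, 2))
            - v**2 / 2))
        beta = upd("beta", beta, lambda v: (
            norm_lp(lmr, pred(mu, v, u), s_e[:, None, None]).sum(axis=(1, 2))
            - v**2 / 2))
        ls_s = upd("ls_s", ls_s, lambda v: (
            norm_lp(u, 0.0, np.exp(v)[:, None]).sum(axis=1)
            - np.exp(v) ** 2 / 2 + v))
        ls_e = upd("ls_e", ls_e, lambda v: (
            norm_lp(lmr, pred(mu, beta, u), np.exp(v)[:, None, None]).sum(axis=(1, 2))
            - np.exp(v) ** 2 / 2 + v))

        # joint scale moves (funnel escapes), as in the paired model
        s_e = np.exp(ls_e)
        blk = blocks["scl_e"]
        eps = blk.scale * rng.standard_normal(c)
        m_pred = pred(mu, beta, u)
        prop_lmr = m_pred + (lmr - m_pred) * np.exp(eps)[:, None, None]
        prop_ls = ls_e + eps
        pll = ll(prop_lmr, off[..., 0], off[..., 1])
        logr = (pll - cll).sum(axis=(1, 2))
        logr += (-np.exp(prop_ls) ** 2 / 2 + prop_ls) - (
            -np.exp(ls_e) ** 2 / 2 + ls_e)
        logr = np.where(np.abs(prop_lmr).max(axis=(1, 2)) <= _LMR_BOUND,
                        logr, -np.inf)
        acc = np.log(rng.random(c)) < logr
        lmr[acc] = prop_lmr[acc]
        cll[acc] = pll[acc]
        ls_e[acc] = prop_ls[acc]
        blk.record(acc.astype(float))
        s_e = np.exp(ls_e)

        blk = blocks["scl_s"]
        eps = blk.scale * rng.standard_normal(c)
        prop_u = u * np.exp(eps)[:, None]
        prop_ls = ls_s + eps
        # u-prior quadratic invariant; only the lmr|pred terms and the
        # sigma_subj prior change
        d_terms = (norm_lp(lmr, pred(mu, beta, prop_u), s_e[:, None, None])
                   - norm_lp(lmr, pred(mu, beta, u), s_e[:, None, None])
                   ).sum(axis=(1, 2))
        d_terms += (-np.exp(prop_ls) ** 2 / 2 + prop_ls) - (
            -np.exp(ls_s) ** 2 / 2 + ls_s)
        acc = np.log(rng.random(c)) < d_terms
        u[acc] = prop_u[acc]
        ls_s[acc] = prop_ls[acc]
        blk.record(acc.astype(float))

        if it < cfg.n_warmup:
            if (it + 1) % 25 == 0:
                for blk in blocks.values():
                    blk.adapt()
        else:
            j = it - cfg.n_warmup
            draws["mu"][:, j] = mu
            draws["beta_bin"][:, j] = beta
            draws["sigma_subj"][:, j] = np.exp(ls_s)
            draws["sigma_resid"][:, j] = np.exp(ls_e)

    return PosteriorSamples(draws=draws, n_warmup=cfg.n_warmup, seed=cfg.seed)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def split_rhat(chain_draws: np.ndarray) -> float:
    """Classic split-chain Gelman-Rubin R-hat for one parameter.

    ``chain_draws`` is (n_chains, n_iterations).  Returns NaN when the
    within-chain variance is zero (constant chains).
    """
    arr = np.asarray(chain_draws, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("expected (n_chains, n_iterations) draws")
    half = arr.shape[1] // 2
    if half < 2:
        raise ValueError("too few iterations for split R-hat")
    splits = np.concatenate([arr[:, :half], arr[:, half: 2 * half]], axis=0)
    m, L = splits.shape
    w = splits.var(axis=1, ddof=1).mean()
    b = L * splits.mean(axis=1).var(ddof=1)
    if w <= 0:
        return float("nan")
    var_plus = (L - 1) / L * w + b / L
    return float(np.sqrt(var_plus / w))


def summarize(samples: PosteriorSamples, parameter: str) -> PosteriorSummary:
    arr = samples.draws[parameter]
    flat = arr.ravel()
    if arr.shape[0] >= 2:
        rhat = split_rhat(arr)
        flagged = not np.isfinite(rhat)
    else:
        rhat, flagged = None, True
    lo, hi = np.percentile(flat, [2.5, 97.5])
    return PosteriorSummary(
        mean=float(flat.mean()),
        sd=float(flat.std(ddof=1)),
        ci95=(float(lo), float(hi)),
        p_gt_zero=float((flat > 0).mean()),
        rhat=rhat,
        flagged=flagged,
    )


def diagnose(samples: PosteriorSamples) -> dict:
    """Per-parameter posterior summaries plus the maximum R-hat."""
    out = {name: summarize(samples, name) for name in samples.draws}
    rhats = [s.rhat for s in out.values() if s.rhat is not None and np.isfinite(s.rhat)]
    return {
        "parameters": out,
        "rhat_max": float(max(rhats)) if rhats else float("nan"),
    }
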