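"""Shared statistics: t tests, repeated-measures ANOVA, JZS Bayes factors,
and the cluster-based permutation engine.

Conventions
-----------
* Tails are named ``"two-sided"``, ``"greater"`` and ``"less"``.
* Bayes factors are reported as evidence for the null, ``BF01 = 1 / BF10``.
* Cluster mass is the sum of the test statistic over the cluster.
* Monte-Carlo cluster p values use the +1 correction,
  ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import integrate, ndimage
from scipy import stats as sps
from scipy.special import ndtr

Tail = Literal["two-sided", "greater", "less"]

__all__ = [
    "StatResult",
    "BfConfig",
    "Cluster",
    "ClusterResult",
    "t_test",
    "rm_anova",
    "effect_contrast",
    "rm_anova_map",
    "jzs_bf01",
    "permutation_engine",
    "paired_t_map",
    "one_sample_t_map",
]


@dataclass
class StatResult:
    """A single frequentist test with optional effect size and Bayes factor."""

    statistic: float
    df: float | tuple[float, float]
    p: float
    tail: Tail = "two-sided"
    cohen_d: float | None = None
    partial_eta_sq: float | None = None
    bf01: float | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "tail": self.tail,
            "cohen_d": self.cohen_d,
            "partial_eta_sq": self.partial_eta_sq,
            "bf01": self.bf01,
            "degenerate": self.degenerate,
        }


@dataclass
class BfConfig:
    """Prior settings for the JZS default Bayes factor."""

    cauchy_scale: float = 0.707
    sided: Literal["two", "one_positive", "one_negative"] = "two"

    def __post_init__(self) -> None:
        if not self.cauchy_scale > 0:
            raise ValueError("cauchy_scale must be positive")


@dataclass
class Cluster:
    indices: np.ndarray  # integer indices into the flattened stat map
    mass: float
    p_value: float
    sign: int = 1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    stat_map: np.ndarray
    threshold: float
    cluster_alpha: float
    n_permutations: int
    tail: Tail
    degenerate: bool = False

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]

    def mask(self, alpha: float = 0.05) -> np.ndarray:
        """Boolean map marking every point inside a significant cluster."""
        m = np.zeros(self.stat_map.size, dtype=bool)
        for c in self.significant(alpha):
            m[c.indices] = True
        return m.reshape(self.stat_map.shape)


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def _tail_p(t: float, df: float, tail: Tail) -> float:
    if tail == "two-sided":
        return 2.0 * sps.t.sf(abs(t), df)
    if tail == "greater":
        return float(sps.t.sf(t, df))
    if tail == "less":
        return float(sps.t.cdf(t, df))
    raise ValueError(f"unknown tail {tail!r}")


def t_test(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    *,
    paired: bool = False,
    popmean: float = 0.0,
    tail: Tail = "two-sided",
    bf: BfConfig | None = None,
) -> StatResult:
    """One-sample, paired, or (unpaired) two-sample t test.

    For one-sample and paired data Cohen's d is ``mean(diff)/sd(diff)``.
    A zero-variance input yields a flagged degenerate result rather than an
    exception, since permutation null draws routinely produce such data.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if paired:
            if len(x) != len(y):
                raise ValueError("paired samples must have equal length")
            return t_test(x - y, popmean=popmean, tail=tail, bf=bf)
        t, _ = sps.ttest_ind(x, y)
        df = len(x) + len(y) - 2
        sp = np.sqrt(
            ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
        )
        d = (x.mean() - y.mean()) / sp if sp > 0 else np.nan
        if not np.isfinite(t):
            return StatResult(np.nan, df, np.nan, tail, degenerate=True)
        p = _tail_p(float(t), df, tail)
        res = StatResult(float(t), df, p, tail, cohen_d=float(d))
        if bf is not None:
            res.bf01 = jzs_bf01(float(t), n=(len(x), len(y)), cfg=bf)
        return res

    diff = x - popmean
    n = len(diff)
    if n < 2:
        raise ValueError("need at least two observations")
    sd = diff.std(ddof=1)
    if sd == 0:
        return StatResult(np.nan, n - 1, np.nan, tail, degenerate=True)
    t = diff.mean() / (sd / np.sqrt(n))
    res = StatResult(
        float(t), n - 1, _tail_p(float(t), n - 1, tail), tail,
        cohen_d=float(diff.mean() / sd),
    )
    if bf is not None:
        res.bf01 = jzs_bf01(float(t), n=n, cfg=bf)
    return res


# ---------------------------------------------------------------------------
# repeated-measures ANOVA from cell means
# ---------------------------------------------------------------------------

def _orthonormal_contrast(levels: int) -> np.ndarray:
    """(levels-1) x levels orthonormal contrast rows (Helmert, normalized)."""
    c = np.zeros((levels - 1, levels))
    for i in range(levels - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    return c


def effect_contrast(levels: Sequence[int], effect: Sequence[int]) -> np.ndarray:
    """Kronecker contrast matrix selecting one within-subject effect.

    ``levels`` lists the number of levels per factor (in cell-axis order);
    ``effect`` lists the factor indices participating in the effect.  Factors
    outside the effect are averaged out.  Returns a (df_effect, n_cells)
    matrix with mutually orthogonal rows.
    """
    mats = []
    for i, lv in enumerate(levels):
        if i in effect:
            mats.append(_orthonormal_contrast(lv))
        else:
            mats.append(np.full((1, lv), 1.0 / lv))
    m = mats[0]
    for nxt in mats[1:]:
        m = np.kron(m, nxt)
    return m


def _f_from_scores(z: np.ndarray) -> tuple[float, float, float, float]:
    """Sphericity-assumed F from orthonormal-contrast scores (n_subj, k[, ...])."""
    n = z.shape[0]
    k = z.shape[1]
    zbar = z.mean(axis=0)
    ss_eff = n * np.sum(zbar**2, axis=0)
    ss_err = np.sum((z - zbar) ** 2, axis=(0, 1))
    df1 = k
    df2 = k * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_eff / df1) / (ss_err / df2)
    return f, df1, df2, ss_eff / (ss_eff + ss_err)


def rm_anova(
    cell_means: np.ndarray,
    factors: dict[str, int],
    effects: Sequence[Sequence[str]] | None = None,
    *,
    bf: BfConfig | None = None,
) -> dict[tuple[str, ...], StatResult]:
    """Fully within-subject factorial ANOVA from per-subject cell means.

    ``cell_means`` has shape (n_subjects, l1, l2, ...) matching the factor
    order in ``factors`` (an ordered name -> levels mapping).  Sphericity is
    assumed; for purely two-level effects the F statistic is exactly the
    square of the paired t on the contrast scores.
    """
    names = list(factors)
    levels = [factors[f] for f in names]
    n_subj = cell_means.shape[0]
    if cell_means.shape[1:] != tuple(levels):
        raise ValueError(
            f"cell_means shape {cell_means.shape[1:]} does not match levels {levels}"
        )
    if not np.all(np.isfinite(cell_means)):
        bad = np.where(~np.isfinite(cell_means).reshape(n_subj, -1).all(axis=1))[0]
        raise ValueError(f"missing cells for subjects {bad.tolist()}")
    flat = cell_means.reshape(n_subj, -1)
    if effects is None:
        from itertools import combinations

        effects = [
            c for r in range(1, len(names) + 1) for c in combinations(names, r)
        ]
    out: dict[tuple[str, ...], StatResult] = {}
    for eff in effects:
        eff = tuple(eff)
        idx = [names.index(f) for f in eff]
        m = effect_contrast(levels, idx)
        z = flat @ m.T
        f, df1, df2, peta = _f_from_scores(z[:, :, None])
        f = float(np.squeeze(f))
        p = float(sps.f.sf(f, df1, df2))
        res = StatResult(f, (df1, df2), p, "greater", partial_eta_sq=float(np.squeeze(peta)))
        if bf is not None and df1 == 1:
            t = float(np.sign(z.mean()) * np.sqrt(f))
            res.bf01 = jzs_bf01(t, n=n_subj, cfg=bf)
        out[eff] = res
    return out


def rm_anova_map(
    data: np.ndarray,
    levels: Sequence[int],
    effect: Sequence[int],
) -> tuple[np.ndarray, float, float]:
    """Pointwise repeated-measures F over trailing map axes.

    ``data`` has shape (n_subjects, n_cells, *map_shape) with cells flattened
    in the factor order of ``levels``.  Returns the F map and (df1, df2).
    """
    m = effect_contrast(levels, effect)
    z = np.einsum("kc,nc...->nk...", m, data)
    f, df1, df2, _ = _f_from_scores(z)
    return f, df1, df2


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------

def jzs_bf01(
    t_statistic: float,
    n: int | tuple[int, int],
    cfg: BfConfig | None = None,
) -> float:
    """Default JZS Bayes factor in favor of the null for a t statistic.

    The alternative places a Cauchy prior (scale ``cfg.cauchy_scale``) on the
    standardized effect size; one-sided variants truncate the prior to the
    stated direction.  Computed by adaptive quadrature of the noncentral-t
    marginal likelihood.  ``n`` is the sample size (or a pair for a
    two-sample test, using the effective n = n1*n2/(n1+n2)).
    """
    cfg = cfg or BfConfig()
    if isinstance(n, tuple):
        n1, n2 = n
        neff = n1 * n2 / (n1 + n2)
        nu = n1 + n2 - 2
    else:
        neff = float(n)
        nu = n - 1
    if nu < 1:
        raise ValueError("need n >= 2")
    if not np.isfinite(t_statistic):
        raise ValueError("t statistic must be finite")
    r = cfg.cauchy_scale
    sq = np.sqrt(neff)

    def integrand(delta: float) -> float:
        return sps.nct.pdf(t_statistic, nu, delta * sq) * sps.cauchy.pdf(delta, 0, r)

    if cfg.sided == "two":
        num, err = integrate.quad(integrand, -np.inf, np.inf)
    elif cfg.sided == "one_positive":
        num, err = integrate.quad(lambda d: 2.0 * integrand(d), 0, np.inf)
    elif cfg.sided == "one_negative":
        num, err = integrate.quad(lambda d: 2.0 * integrand(d), -np.inf, 0)
    else:
        raise ValueError(f"unknown sidedness {cfg.sided!r}")
    den = sps.t.pdf(t_statistic, nu)
    if num <= 0 or not np.isfinite(num) or err > max(num, 1e-12):
        raise FloatingPointError("Bayes factor integration failed")
    return float(den / num)


# ---------------------------------------------------------------------------
# cluster-based permutation engine
# ---------------------------------------------------------------------------

def paired_t_map(diff: np.ndarray) -> np.ndarray:
    """Pointwise paired/one-sample t over axis 0 (subjects)."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t


one_sample_t_map = paired_t_map

_STRUCT_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _clusters_from_map(
    stat: np.ndarray, threshold: float, tail: Tail
) -> list[tuple[np.ndarray, float, int]]:
    """Suprathreshold clusters: (flat indices, signed mass, sign)."""
    out = []
    signs = {"greater": [1], "less": [-1], "two-sided": [1, -1]}[tail]
    struct = _STRUCT_2D if stat.ndim == 2 else None
    for sign in signs:
        supra = (sign * stat) > threshold
        if not supra.any():
            continue
        lab, nlab = ndimage.label(supra, structure=struct)
        for i in range(1, nlab + 1):
            sel = lab == i
            mass = float(np.abs(stat[sel]).sum())
            out.append((np.flatnonzero(sel.ravel()), mass, sign))
    return out


def _max_mass(stat: np.ndarray, threshold: float, tail: Tail) -> float:
    cl = _clusters_from_map(stat, threshold, tail)
    return max((m for _, m, _ in cl), default=0.0)


def permutation_engine(
    stat_map: Callable[[np.ndarray], np.ndarray],
    data: np.ndarray,
    *,
    threshold: float,
    scheme: str | Callable[[np.ndarray, np.random.Generator], np.ndarray] = "sign_flip",
    n_perm: int = 1024,
    cluster_alpha: float = 0.05,
    tail: Tail = "greater",
    seed: int = 0,
) -> ClusterResult:
    """Max-cluster-mass permutation test on an arbitrary statistic map.

    ``data`` carries subjects on axis 0.  ``stat_map`` maps data to a 1D or
    2D statistic map (2D adjacency is 4-connectivity).  ``threshold`` is the
    pointwise cluster-forming statistic value corresponding to
    ``cluster_alpha`` and must match the declared ``tail``.  The permutation
    ``scheme`` is either ``"sign_flip"`` (multiply each subject's map
    contribution by a random sign), ``"within_subject_relabel"`` (permute
    axis 1 independently per subject), or a callable ``(data, rng) -> data``.
    """
    import warnings

    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives coarse p values")
    rng = np.random.default_rng(seed)
    observed = np.asarray(stat_map(data), dtype=float)
    degenerate = not np.all(np.isfinite(observed))
    obs_clusters = _clusters_from_map(
        np.nan_to_num(observed), threshold, tail
    )

    if scheme == "sign_flip":
        def permute(d: np.ndarray, r: np.random.Generator) -> np.ndarray:
            signs = r.choice([-1.0, 1.0], size=(d.shape[0],) + (1,) * (d.ndim - 1))
            return d * signs
    elif scheme == "within_subject_relabel":
        def permute(d: np.ndarray, r: np.random.Generator) -> np.ndarray:
            out = np.empty_like(d)
            for i in range(d.shape[0]):
                out[i] = d[i, r.permutation(d.shape[1])]
            return out
    elif callable(scheme):
        permute = scheme
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    null_max = np.empty(n_perm)
    for j in range(n_perm):
        perm_stat = np.nan_to_num(np.asarray(stat_map(permute(data, rng)), dtype=float))
        null_max[j] = _max_mass(perm_stat, threshold, tail)

    clusters = [
        Cluster(
            indices=idx,
            mass=mass,
            p_value=float((1 + np.sum(null_max >= mass)) / (n_perm + 1)),
            sign=sign,
        )
        for idx, mass, sign in obs_clusters
    ]
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(
        clusters=clusters,
        stat_map=observed,
        threshold=threshold,
        cluster_alpha=cluster_alpha,
        n_permutations=n_perm,
        tail=tail,
        degenerate=degenerate,
    )
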