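"""Response-locked ERP analysis: CPP and FP ROI time courses, window
statistics, the accuracy x confidence "metacognitive effect", and
cluster-corrected tests over time.

All windows are half-open, [start, end).  ROIs follow the field's
convention: CPP over CP1/CPz/CP2, FP over F1/Fz/F2.  Time-course
statistics are run on data downsampled to 128 Hz and, response-locked,
restricted to the 600 ms preceding the response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as stats_core
from .stats import ClusterResult, Tail

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet",
    "ROIS",
    "baseline_correct",
    "response_lock",
    "downsample",
    "roi_average",
    "condition_erps",
    "window_mean",
    "metacog_effect",
    "cluster_test_paired",
    "cluster_rmanova",
]

ROIS = {
    "CPP": ("CP1", "CPz", "CP2"),
    "FP": ("F1", "Fz", "F2"),
}

DESIGN_LEVELS = {
    "accuracy": ("correct", "error"),
    "confidence": ("high", "low"),
}


@dataclass
class EpochSet:
    """Trials x channels x samples with a time axis and trial metadata."""

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    lock: str  # "stimulus" | "response"
    channels: list[str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n, ch, t = self.data.shape
        if t != len(self.times):
            raise ValueError("time axis length does not match data")
        if ch != len(self.channels):
            raise ValueError("channel list length does not match data")
        if len(self.metadata) != n:
            raise ValueError("metadata rows do not match trial count")
        if self.lock not in ("stimulus", "response"):
            raise ValueError("lock must be 'stimulus' or 'response'")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_indices(self, names) -> np.ndarray:
        missing = [c for c in names if c not in self.channels]
        if missing:
            raise ValueError(f"channel(s) {missing} not present in epochs")
        return np.array([self.channels.index(c) for c in names])

    def copy_with(self, **kw) -> "EpochSet":
        return replace(self, **kw)


def _window_slice(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    sel = (times >= lo) & (times < hi)
    if not sel.any():
        raise ValueError(f"window {window} does not intersect the time axis")
    return sel


def baseline_correct(
    epochs: EpochSet, window: tuple[float, float] = (-0.08, 0.0)
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the prestimulus window."""
    if epochs.lock != "stimulus":
        raise ValueError("baseline correction requires stimulus-locked epochs")
    if window[0] < epochs.times[0] or window[1] > epochs.times[-1] + 1.0 / epochs.sfreq:
        raise ValueError(f"baseline window {window} not covered by epochs")
    sel = _window_slice(epochs.times, window)
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


def response_lock(
    epochs: EpochSet, window: tuple[float, float] = (-0.8, 0.2)
) -> EpochSet:
    """Re-window each trial around the sample nearest its reaction time.

    Trials whose response-locked window would exceed the epoch span (and
    missed trials, which have no RT) are dropped with a log entry.
    """
    rt_s = pd.to_numeric(epochs.metadata["rt_ms"], errors="coerce").to_numpy() / 1000.0
    n_lo = int(round(window[0] * epochs.sfreq))
    n_hi = int(round(window[1] * epochs.sfreq))
    new_times = np.arange(n_lo, n_hi) / epochs.sfreq
    keep, segments = [], []
    for i in range(epochs.n_trials):
        if not np.isfinite(rt_s[i]):
            continue
        center = int(np.argmin(np.abs(epochs.times - rt_s[i])))
        lo, hi = center + n_lo, center + n_hi
        if lo < 0 or hi > len(epochs.times):
            continue
        keep.append(i)
        segments.append(epochs.data[i, :, lo:hi])
    dropped = epochs.n_trials - len(keep)
    if dropped:
        logger.info("response_lock: dropped %d/%d trials (missing RT or "
                    "window outside epoch)", dropped, epochs.n_trials)
    if not keep:
        raise ValueError("response locking dropped all trials")
    return EpochSet(
        data=np.stack(segments),
        times=new_times,
        sfreq=epochs.sfreq,
        lock="response",
        channels=list(epochs.channels),
        metadata=epochs.metadata.iloc[keep].reset_index(drop=True),
    )


def downsample(epochs: EpochSet, target_sfreq: float = 128.0) -> EpochSet:
    """Mean-pool consecutive samples down to the target rate (the factor
    must be an integer)."""
    factor = epochs.sfreq / target_sfreq
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("sfreq must be an integer multiple of target_sfreq")
    k = int(round(factor))
    if k == 1:
        return epochs
    t = (epochs.data.shape[2] // k) * k
    data = epochs.data[:, :, :t].reshape(
        epochs.data.shape[0], epochs.data.shape[1], -1, k
    ).mean(axis=3)
    times = epochs.times[:t].reshape(-1, k).mean(axis=1)
    return epochs.copy_with(data=data, times=times, sfreq=target_sfreq)


def roi_average(epochs: EpochSet, roi: str | tuple[str, ...]) -> np.ndarray:
    """Trials x time ROI-mean amplitude."""
    names = ROIS[roi] if isinstance(roi, str) else roi
    idx = epochs.channel_indices(names)
    return epochs.data[:, idx, :].mean(axis=1)


def condition_erps(
    epochs: EpochSet,
    roi: str | tuple[str, ...],
    factors: tuple[str, ...] = ("drug", "accuracy", "confidence"),
    levels: dict[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-design-cell ROI ERPs.

    Returns (cells, erps): ``cells`` is a DataFrame with one row per design
    cell (factor levels plus trial count; empty cells are flagged), ``erps``
    is the matching cells x time array (NaN rows for empty cells).
    """
    lv = dict(DESIGN_LEVELS)
    if "drug" in factors:
        lv.setdefault("drug", tuple(pd.unique(epochs.metadata["drug"])))
    if levels:
        lv.update(levels)
    tc = roi_average(epochs, roi)
    from itertools import product

    rows, erps = [], []
    for combo in product(*(lv[f] for f in factors)):
        m = np.ones(epochs.n_trials, dtype=bool)
        for f, val in zip(factors, combo):
            m &= epochs.metadata[f].to_numpy() == val
        n = int(m.sum())
        rows.append(dict(zip(factors, combo), n_trials=n, empty=n == 0))
        erps.append(tc[m].mean(axis=0) if n else np.full(tc.shape[1], np.nan))
    return pd.DataFrame(rows), np.stack(erps)


def window_mean(
    timecourse: np.ndarray, times: np.ndarray, window: tuple[float, float]
) -> np.ndarray | float:
    """Mean amplitude over the half-open window [start, end)."""
    sel = _window_slice(np.asarray(times), window)
    out = np.asarray(timecourse)[..., sel].mean(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def metacog_effect(
    c_hi: float, c_lo: float, i_lo: float, i_hi: float
) -> float:
    """The FP metacognitive-effect statistic (C_hi - C_lo) + (I_lo - I_hi).

    Positive values mean metacognitively correct trials (high-confidence
    correct, low-confidence incorrect) carry larger amplitude than
    metacognitively incorrect ones.
    """
    for v in (c_hi, c_lo, i_lo, i_hi):
        if not np.isfinite(v):
            raise ValueError("metacog_effect requires all four cell amplitudes")
    return float((c_hi - c_lo) + (i_lo - i_hi))


def cluster_test_paired(
    series_a: np.ndarray,
    series_b: np.ndarray,
    *,
    tail: Tail = "two-sided",
    cluster_alpha: float = 0.05,
    n_perm: int = 1024,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-corrected paired t test over time.

    ``series_a``/``series_b`` are subjects x time.  Clusters form where the
    pointwise paired t exceeds the ``cluster_alpha`` quantile for the
    declared tail; the null is built by sign-flipping subject difference
    curves and taking the maximum cluster mass.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must share shape")
    if a.shape[0] < 2:
        raise ValueError("need at least two subjects")
    diff = a - b
    df = diff.shape[0] - 1
    q = cluster_alpha / 2 if tail == "two-sided" else cluster_alpha
    threshold = float(sps.t.isf(q, df))
    return stats_core.permutation_engine(
        stats_core.paired_t_map, diff,
        threshold=threshold, scheme="sign_flip", n_perm=n_perm,
        cluster_alpha=cluster_alpha, tail=tail, seed=seed,
    )


def cluster_rmanova(
    data: np.ndarray,
    factors: dict[str, int],
    effects: list[tuple[str, ...]],
    *,
    cluster_alpha: float = 0.05,
    n_perm: int = 1024,
    seed: int = 0,
) -> dict[tuple[str, ...], ClusterResult]:
    """Cluster-corrected repeated-measures ANOVA over time, one result per
    requested effect.

    ``data`` is subjects x cells x time with cells flattened in factor
    order.  Effects whose factors are all two-level use a sign-flip null on
    the per-subject contrast scores; effects involving a factor with more
    than two levels permute that factor's labels within subject.
    """
    names = list(factors)
    levels = [factors[f] for f in names]
    n_subj, n_cells, n_time = data.shape
    if n_cells != int(np.prod(levels)):
        raise ValueError("cell axis does not match the factor levels")
    out: dict[tuple[str, ...], ClusterResult] = {}
    for e_idx, eff in enumerate(effects):
        eff = tuple(eff)
        idx = [names.index(f) for f in eff]
        m = stats_core.effect_contrast(levels, idx)
        df1, df2 = m.shape[0], m.shape[0] * (n_subj - 1)
        threshold = float(sps.f.isf(cluster_alpha, df1, df2))
        multi = [i for i in idx if levels[i] > 2]

        if not multi:
            # two-level-only effect: work on contrast scores, sign-flip null
            z = np.einsum("kc,nct->nkt", m, data)

            def stat_map(zz, df1=df1):
                f, *_ = stats_core._f_from_scores(zz)
                return f

            res = stats_core.permutation_engine(
                stat_map, z, threshold=threshold, scheme="sign_flip",
                n_perm=n_perm, cluster_alpha=cluster_alpha,
                tail="greater", seed=seed + e_idx,
            )
        else:
            # permute the multi-level factor's labels within subject
            fi = multi[0]
            cells = np.arange(n_cells).reshape(levels)

            def stat_map(d, m=m):
                z = np.einsum("kc,nct->nkt", m, d)
                f, *_ = stats_core._f_from_scores(z)
                return f

            def permute(d, rng, fi=fi, cells=cells):
                out_ = np.empty_like(d)
                for i in range(d.shape[0]):
                    perm = rng.permutation(levels[fi])
                    reorder = np.take(cells, perm, axis=fi).ravel()
                    out_[i] = d[i, reorder]
                return out_

            res = stats_core.permutation_engine(
                stat_map, data, threshold=threshold, scheme=permute,
                n_perm=n_perm, cluster_alpha=cluster_alpha,
                tail="greater", seed=seed + e_idx,
            )
        out[eff] = res
    return out
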