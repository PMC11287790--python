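"""Pupillometry: preprocessing, prestimulus baselines, equal-population
binning, per-bin behavioral measures, and polynomial bin regressions.

Traces are normalized as the percentage difference from the block mean.
Binning ranks trials by prestimulus baseline within each session x block
and cuts them into five groups as equal as possible (remainder trials go
to the low-pupil bins; ties break by trial order), so every bin contains
the same number of trials from every session and block by construction.
Bin regressions are ordinary least squares of a behavioral measure on raw
bin number 1-5 (first- or second-order polynomial), tested at the group
level with two-sided one-sample t tests against zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from . import sdt
from .stats import BfConfig, StatResult, t_test

logger = logging.getLogger(__name__)

__all__ = [
    "PupilTrace",
    "preprocess_pupil",
    "baseline_pupil",
    "assign_bins",
    "per_bin_behavior",
    "fit_bin_polynomials",
    "group_test",
]


@dataclass
class PupilTrace:
    """One block's pupil trace (arbitrary units in, % of block mean out)."""

    samples: np.ndarray
    sfreq: float = 500.0
    blink_mask: np.ndarray | None = None
    block_id: int | str | None = None
    normalized: bool = False
    high_blink_coverage: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.blink_mask is None:
            self.blink_mask = np.zeros(len(self.samples), dtype=bool)
        self.blink_mask = np.asarray(self.blink_mask, dtype=bool)
        if len(self.blink_mask) != len(self.samples):
            raise ValueError("blink_mask length must match samples")


def _interpolate_blinks(x: np.ndarray, mask: np.ndarray, pad: int) -> np.ndarray:
    """Linear interpolation across blink spans, widened by ``pad`` samples."""
    if not mask.any():
        return x.copy()
    wide = mask.copy()
    idx = np.flatnonzero(mask)
    for p in range(1, pad + 1):
        wide[np.clip(idx - p, 0, len(x) - 1)] = True
        wide[np.clip(idx + p, 0, len(x) - 1)] = True
    good = ~wide
    if good.sum() < 2:
        return x.copy()
    out = x.copy()
    t = np.arange(len(x))
    out[wide] = np.interp(t[wide], t[good], x[good])
    return out


def preprocess_pupil(
    trace: PupilTrace,
    lowpass_hz: float = 10.0,
    blink_pad_s: float = 0.05,
    filter_order: int = 3,
) -> PupilTrace:
    """Blink interpolation, zero-phase low-pass, % normalization per block.

    The low-pass is a 3rd-order Butterworth applied forward-backward.  If
    blinks cover more than half the block the result is flagged.
    """
    if trace.sfreq <= 20:
        raise ValueError("sampling rate too low for a 10 Hz low-pass")
    x = _interpolate_blinks(
        trace.samples, trace.blink_mask, int(round(blink_pad_s * trace.sfreq))
    )
    coverage = float(trace.blink_mask.mean())
    flagged = coverage > 0.5
    if flagged:
        warnings.warn(
            f"blinks cover {coverage:.0%} of block {trace.block_id}; "
            "interpolation dominates the trace"
        )
    b, a = butter(filter_order, lowpass_hz / (trace.sfreq / 2.0), btype="low")
    if len(x) > 3 * max(len(a), len(b)):
        x = filtfilt(b, a, x)
    mean = x.mean()
    if mean == 0:
        norm = x * 0.0
    else:
        norm = 100.0 * (x - mean) / mean
    return PupilTrace(
        samples=norm, sfreq=trace.sfreq, blink_mask=trace.blink_mask,
        block_id=trace.block_id, normalized=True, high_blink_coverage=flagged,
    )


def baseline_pupil(
    trace: PupilTrace,
    stimulus_times: np.ndarray,
    window: tuple[float, float] = (-0.5, 0.0),
) -> np.ndarray:
    """Mean normalized pupil in [window) s relative to each stimulus onset.

    Trials whose window leaves the recorded trace come back NaN (flagged
    missing).
    """
    st = np.asarray(stimulus_times, dtype=float)
    out = np.full(len(st), np.nan)
    n = len(trace.samples)
    for i, t0 in enumerate(st):
        lo = int(round((t0 + window[0]) * trace.sfreq))
        hi = int(round((t0 + window[1]) * trace.sfreq))
        if lo < 0 or hi > n or hi <= lo:
            continue
        out[i] = trace.samples[lo:hi].mean()
    return out


def assign_bins(
    trials: pd.DataFrame,
    n_bins: int = 5,
    group_cols: tuple[str, ...] = ("subject", "session", "block"),
) -> pd.DataFrame:
    """Equal-population pupil bins within each session x block.

    Trials are rank-ordered by ``pupil_baseline_pct`` (stable sort, so ties
    break by trial order) and cut into ``n_bins`` groups; when the count is
    not divisible, the extra trials go to the low-pupil bins.  Bin 1 is the
    smallest-pupil bin.
    """
    if "pupil_baseline_pct" not in trials:
        raise ValueError("pupil_baseline_pct column required")
    cols = [c for c in group_cols if c in trials.columns]
    out = trials.copy()
    out["pupil_bin"] = 0
    grouping = out.groupby(cols, sort=False).groups.items() if cols else [
        (None, out.index)
    ]
    for _, idx in grouping:
        n = len(idx)
        if n < n_bins:
            raise ValueError(
                f"block with {n} trials cannot be split into {n_bins} bins"
            )
        order = np.argsort(
            out.loc[idx, "pupil_baseline_pct"].to_numpy(), kind="stable"
        )
        sizes = [n // n_bins + (1 if i < n % n_bins else 0) for i in range(n_bins)]
        bins = np.repeat(np.arange(1, n_bins + 1), sizes)
        assigned = np.empty(n, dtype=int)
        assigned[order] = bins
        out.loc[idx, "pupil_bin"] = assigned
    return out


def per_bin_behavior(
    trials: pd.DataFrame, n_bins: int = 5
) -> pd.DataFrame:
    """Per subject x bin SDT measures, pooled across sessions and blocks.

    Columns: d_prime, conf_rate, meta_d, m_diff, mean_pupil_pct, n_trials.
    Degenerate bins raise with the subject/bin context attached.
    """
    if "pupil_bin" not in trials:
        raise ValueError("run assign_bins first")
    rows = []
    for (subj, b), sub in trials.groupby(["subject", "pupil_bin"], sort=True):
        try:
            counts = sdt.tabulate_counts(sub)
            t1 = sdt.type1_sdt(counts)
            fit = sdt.fit_meta_d(counts, t1)
            eff = sdt.efficiency(fit, t1)
        except ValueError as e:
            raise ValueError(f"subject {subj}, bin {b}: {e}") from e
        rows.append({
            "subject": subj, "bin": int(b),
            "d_prime": t1.d_prime, "conf_rate": sdt.confidence_rate(sub),
            "meta_d": fit.meta_d, "m_diff": eff.m_diff,
            "mean_pupil_pct": float(sub["pupil_baseline_pct"].mean()),
            "n_trials": len(sub),
        })
    return pd.DataFrame(rows)


def fit_bin_polynomials(
    bintable: pd.DataFrame, measure: str, order: int = 1
) -> pd.DataFrame:
    """Per-subject OLS of a measure on raw bin number (order 1 or 2).

    Subjects with missing bins are dropped with a log entry.  Returns one
    row per subject with beta0, beta1 (and beta2 for the quadratic model).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    n_bins = bintable["bin"].max()
    rows = []
    for subj, sub in bintable.groupby("subject", sort=True):
        if len(sub) < n_bins or sub[measure].isna().any():
            logger.info("dropping subject %s: incomplete bins", subj)
            continue
        sub = sub.sort_values("bin")
        coefs = np.polyfit(sub["bin"].to_numpy(dtype=float),
                           sub[measure].to_numpy(dtype=float), order)
        row = {"subject": subj, "measure": measure,
               "beta0": coefs[-1], "beta1": coefs[-2]}
        if order == 2:
            row["beta2"] = coefs[-3]
        rows.append(row)
    if not rows:
        raise ValueError("no subject had a complete set of bins")
    return pd.DataFrame(rows)


def group_test(
    polyfits: pd.DataFrame, coef: str, bf: BfConfig | None = None
) -> StatResult:
    """Two-sided one-sample t of a polynomial coefficient against zero."""
    return t_test(polyfits[coef].to_numpy(), tail="two-sided",
                  bf=bf or BfConfig())
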