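"""Mass-univariate regression ERPs and descriptive single-trial displays.

Single-trial voltages at each channel × time point are regressed on trial
predictors (ordinary least squares, intercept included); betas are divided by
their standard errors to give t-maps, which bias unreliable estimates toward
zero before group-level cluster statistics.  Trials with a masked sample at a
given point are dropped listwise at that point only.

Also provides the descriptive views used to expose component overlap:
predicted ERPs at predictor terciles, RT-sorted ERP images with per-trial
event markers, and median-split averages with RT histograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    """Trials × predictors design with named columns (intercept included)."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design must be 2-D")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("name count mismatch")

    @classmethod
    def from_predictors(cls, center: bool = True, **predictors: np.ndarray) -> "DesignMatrix":
        """Build intercept + named predictor columns (optionally centred)."""
        cols = [np.ones(len(next(iter(predictors.values()))))]
        names = ["intercept"]
        for name, values in predictors.items():
            v = np.asarray(values, dtype=float)
            if center:
                v = v - v.mean()
            cols.append(v)
            names.append(name)
        return cls(np.column_stack(cols), names)

    @property
    def n_predictors(self) -> int:
        return self.matrix.shape[1]

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class TMaps:
    """First-level betas and t-values: predictors × channels × time."""

    betas: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: np.ndarray
    n_used: np.ndarray
    predictor_names: list[str]
    channel_labels: list[str]
    times: np.ndarray

    def predictor(self, name: str) -> int:
        return self.predictor_names.index(name)


def fit_mass_univariate(epochs: EpochSet, design: DesignMatrix) -> TMaps:
    """OLS at every channel × time point; returns betas, SEs, t, df.

    At each point only trials with unmasked data enter the fit; points with
    fewer than n_predictors + 2 usable trials, or a rank-deficient design on
    the usable trials, are marked missing (NaN) and logged.
    """
    X = design.matrix
    n_trials, p = X.shape
    if n_trials != epochs.n_trials:
        raise ValueError("design and epochs disagree on trial count")
    n_ch, n_t = epochs.n_channels, epochs.n_times
    betas = np.full((p, n_ch, n_t), np.nan)
    se = np.full((p, n_ch, n_t), np.nan)
    tvals = np.full((p, n_ch, n_t), np.nan)
    df = np.zeros((n_ch, n_t))
    n_used = np.zeros((n_ch, n_t), dtype=int)

    valid = ~epochs.mask  # trials x ch x time
    n_skipped = 0
    # group time points by identical trial-validity pattern per channel to
    # solve each distinct pattern once
    for c in range(n_ch):
        vc = valid[:, c, :]
        patterns, inverse = np.unique(vc, axis=1, return_inverse=True)
        for gi in range(patterns.shape[1]):
            rows = patterns[:, gi]
            tcols = np.flatnonzero(inverse == gi)
            n_ok = int(rows.sum())
            if n_ok < p + 2:
                n_skipped += tcols.size
                continue
            Xs = X[rows]
            if np.linalg.matrix_rank(Xs) < p:
                n_skipped += tcols.size
                continue
            Y = epochs.data[rows][:, c, :][:, tcols]
            XtX_inv = np.linalg.inv(Xs.T @ Xs)
            B = XtX_inv @ Xs.T @ Y
            resid = Y - Xs @ B
            dof = n_ok - p
            sigma2 = (resid ** 2).sum(axis=0) / dof
            se_b = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
            betas[:, c, tcols] = B
            se[:, c, tcols] = se_b
            with np.errstate(divide="ignore", invalid="ignore"):
                tvals[:, c, tcols] = B / se_b
            df[c, tcols] = dof
            n_used[c, tcols] = n_ok
    if n_skipped:
        logger.info("mass-univariate fit skipped %d points (too few trials or rank-deficient)",
                    n_skipped)
    return TMaps(
        betas=betas, se=se, t=tvals, df=df, n_used=n_used,
        predictor_names=list(design.names),
        channel_labels=list(epochs.channel_labels),
        times=epochs.times,
    )


def tercile_levels(values: np.ndarray) -> np.ndarray:
    """Mean predictor value within each tercile (ascending)."""
    values = np.asarray(values, dtype=float)
    edges = np.quantile(values, [1 / 3, 2 / 3])
    bins = np.digitize(values, edges)
    return np.array([values[bins == k].mean() for k in range(3)])


def predicted_erps(tmaps: TMaps, predictor: str, levels: np.ndarray) -> dict[float, np.ndarray]:
    """Model-predicted ERP per predictor level: intercept + level × beta."""
    b0 = tmaps.betas[tmaps.predictor("intercept")]
    b = tmaps.betas[tmaps.predictor(predictor)]
    return {float(level): b0 + level * b for level in levels}


@dataclass
class ERPImage:
    """RT (or other key)-sorted single-trial voltage raster at one channel."""

    matrix: np.ndarray          # sorted trials x time (NaN = masked)
    order: np.ndarray           # original trial indices in display order
    sort_values: np.ndarray     # sorted key values
    markers: np.ndarray | None  # per-row event time in the epoch frame (s)
    times: np.ndarray


def erp_image(
    epochs: EpochSet,
    channel: str,
    sort_key: np.ndarray,
    smooth: int = 1,
    rts: np.ndarray | None = None,
) -> ERPImage:
    """Single-trial raster sorted by ``sort_key`` with optional trial smoothing.

    ``smooth`` is a moving-average window (in trials) applied down the sorted
    rows, ignoring masked samples.  When ``rts`` is given, the marker track
    holds the counterpart event's time per row: the stimulus at −RT for
    response-locked epochs, the response at +RT for stimulus-locked epochs.
    """
    sort_key = np.asarray(sort_key, dtype=float)
    if sort_key.size != epochs.n_trials:
        raise ValueError("sort_key length mismatch")
    if not np.all(np.isfinite(sort_key)):
        raise ValueError("sort_key must be finite for all trials")
    if smooth < 1 or smooth > epochs.n_trials:
        raise ValueError("smooth window must be in [1, n_trials]")
    ci = epochs.channel_index(channel)
    order = np.argsort(sort_key, kind="stable")
    mat = epochs.data[order, ci, :].copy()
    mat[epochs.mask[order, ci, :]] = np.nan
    if smooth > 1:
        sm = np.full_like(mat, np.nan)
        half_lo = (smooth - 1) // 2
        half_hi = smooth - 1 - half_lo
        for r in range(mat.shape[0]):
            block = mat[max(0, r - half_lo) : min(mat.shape[0], r + half_hi + 1)]
            cnt = np.isfinite(block).sum(axis=0)
            with np.errstate(invalid="ignore"):
                sm[r] = np.nansum(block, axis=0) / np.where(cnt == 0, np.nan, cnt)
        mat = sm
    markers = None
    if rts is not None:
        rts = np.asarray(rts, dtype=float)[order]
        markers = -rts if epochs.lock == "response" else rts
    return ERPImage(matrix=mat, order=order, sort_values=sort_key[order],
                    markers=markers, times=epochs.times)


@dataclass
class MedianSplit:
    """Fast/slow median-split averages with per-group RT summaries."""

    fast_mean: np.ndarray       # channels x time
    slow_mean: np.ndarray
    fast_index: np.ndarray
    slow_index: np.ndarray
    fast_rts: np.ndarray
    slow_rts: np.ndarray
    onset_hist_bins: np.ndarray
    fast_onset_hist: np.ndarray
    slow_onset_hist: np.ndarray
    times: np.ndarray


def median_split_average(
    epochs: EpochSet,
    rt: np.ndarray,
    rt_max: float | None = None,
    n_hist_bins: int = 30,
) -> MedianSplit:
    """Mean ERPs for a fast/slow RT median split (ties go to fast).

    Trials with ``rt > rt_max`` (or non-finite RT) are excluded first.  The
    onset histograms give the counterpart event time (stimulus at −RT for
    response-locked epochs) per group.
    """
    rt = np.asarray(rt, dtype=float)
    if rt.size != epochs.n_trials:
        raise ValueError("rt length mismatch")
    keep = np.isfinite(rt)
    if rt_max is not None:
        keep &= rt <= rt_max
    if keep.sum() < 2:
        raise ValueError("fewer than 2 trials after rt_max filtering")
    idx = np.flatnonzero(keep)
    med = np.median(rt[idx])
    fast = idx[rt[idx] <= med]
    slow = idx[rt[idx] > med]
    if fast.size == 0 or slow.size == 0:
        raise ValueError("empty median-split group")

    def group_mean(sel: np.ndarray) -> np.ndarray:
        sub = epochs.data[sel].copy()
        sub[epochs.mask[sel]] = np.nan
        cnt = np.isfinite(sub).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.nansum(sub, axis=0) / np.where(cnt == 0, np.nan, cnt)

    onsets_fast = -rt[fast] if epochs.lock == "response" else rt[fast]
    onsets_slow = -rt[slow] if epochs.lock == "response" else rt[slow]
    lo = min(onsets_fast.min(), onsets_slow.min())
    hi = max(onsets_fast.max(), onsets_slow.max())
    bins = np.linspace(lo, hi + 1e-9, n_hist_bins + 1)
    return MedianSplit(
        fast_mean=group_mean(fast),
        slow_mean=group_mean(slow),
        fast_index=fast,
        slow_index=slow,
        fast_rts=rt[fast],
        slow_rts=rt[slow],
        onset_hist_bins=bins,
        fast_onset_hist=np.histogram(onsets_fast, bins=bins)[0],
        slow_onset_hist=np.histogram(onsets_slow, bins=bins)[0],
        times=epochs.times,
    )
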