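"""Epoching, baseline correction, artefact rejection, resampling, adjacency.

Conventions: time is sample-indexed internally; second↔sample conversion
rounds to the nearest sample; epoch windows are half-open ``[start, end)``.
Any statistic over a window uses only unmasked samples.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.signal import resample_poly
from scipy.spatial.distance import cdist

from .containers import AdjacencyGraph, EpochSet, EventTable, Recording

logger = logging.getLogger(__name__)


def _seconds_to_samples(t: float, srate: float) -> int:
    return int(round(t * srate))


def epoch_events(
    recording: Recording,
    events: EventTable,
    lock: str,
    window: tuple[float, float],
    mask_outside_trial: bool = True,
) -> EpochSet:
    """Cut epochs around stimulus or response events.

    The sample at time 0 is the lock event's sample; the window is half-open
    ``[start, end)`` seconds.  With ``mask_outside_trial``, stimulus-locked
    samples after the response and response-locked samples before the
    stimulus are invalidated (set missing) to avoid spill-over from other
    trials or intertrial intervals.  Trials whose window falls outside the
    recording are excluded (count logged); response-locked epoching drops
    trials without a response.

    Raises
    ------
    ValueError
        If no trial yields a valid epoch.
    """
    if lock not in ("stimulus", "response"):
        raise ValueError("lock must be 'stimulus' or 'response'")
    srate = recording.srate
    start = _seconds_to_samples(window[0], srate)
    stop = _seconds_to_samples(window[1], srate)
    if stop <= start:
        raise ValueError("empty epoch window")
    n_times = stop - start
    times = np.arange(start, stop) / srate

    stim = events.stimulus_samples.astype(float)
    resp = events.response_samples
    if lock == "stimulus":
        locks = stim
        eligible = np.ones(len(events), dtype=bool)
    else:
        locks = resp
        eligible = events.has_response
        n_dropped = int((~eligible).sum())
        if n_dropped:
            logger.info("response-locked epoching dropped %d trials without response", n_dropped)

    in_bounds = eligible.copy()
    lo = locks + start
    hi = locks + stop
    with np.errstate(invalid="ignore"):
        in_bounds &= np.isfinite(locks) & (lo >= 0) & (hi <= recording.n_samples)
    n_oob = int((eligible & ~in_bounds).sum())
    if n_oob:
        logger.info("excluded %d trials with epoch window outside the recording", n_oob)
    keep = np.flatnonzero(in_bounds)
    if keep.size == 0:
        raise ValueError("no trials yield a valid epoch")

    n_ch = recording.n_channels
    data = np.empty((keep.size, n_ch, n_times))
    mask = np.zeros((keep.size, n_ch, n_times), dtype=bool)
    for k, tr in enumerate(keep):
        c = int(locks[tr])
        data[k] = recording.data[:, c + start : c + stop]
        if mask_outside_trial:
            # invalidate samples outside the trial's [stimulus, response] span
            rel = np.arange(start, stop)
            if lock == "stimulus":
                if np.isfinite(resp[tr]):
                    off = int(resp[tr]) - c
                    mask[k, :, rel > off] = True
            else:
                off = int(stim[tr]) - c
                mask[k, :, rel < off] = True

    return EpochSet(
        data=data,
        mask=mask,
        times=times,
        srate=srate,
        lock=lock,
        channel_labels=list(recording.channel_labels),
        kept_trial_ids=keep,
    )


def baseline_correct(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``[start, end)`` seconds.

    Only unmasked baseline samples enter the mean.  Trials with no unmasked
    baseline sample on some channel are left uncorrected on that channel and
    flagged in ``flags['baseline_missing']`` (trial indices), never silently
    zeroed.
    """
    sel = (epochs.times >= window[0] - 1e-12) & (epochs.times < window[1] - 1e-12)
    if not sel.any():
        raise ValueError("baseline window does not overlap the epoch time axis")
    seg = epochs.data[:, :, sel]
    segmask = epochs.mask[:, :, sel]
    counts = (~segmask).sum(axis=2)
    sums = np.where(segmask, 0.0, seg).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    missing = counts == 0
    means[missing] = 0.0
    flagged = np.flatnonzero(missing.any(axis=1))
    if flagged.size:
        logger.warning("%d trials lack unmasked baseline samples on some channel", flagged.size)
    out = epochs.data - means[:, :, None]
    flags = dict(epochs.flags)
    if flagged.size:
        flags["baseline_missing"] = flagged
    return EpochSet(
        data=out,
        mask=epochs.mask.copy(),
        times=epochs.times,
        srate=epochs.srate,
        lock=epochs.lock,
        channel_labels=list(epochs.channel_labels),
        kept_trial_ids=epochs.kept_trial_ids,
        baseline_window=(float(window[0]), float(window[1])),
        flags=flags,
    )


def reject_epochs(
    epochs: EpochSet,
    amp_limit: float = 150.0,
    gradient_limit: float = 50.0,
) -> tuple[EpochSet, np.ndarray]:
    """Reject trials containing artefacts.

    A trial is rejected when any unmasked sample on any channel exceeds
    ``±amp_limit`` µV, or when any absolute difference between successive
    unmasked samples exceeds ``gradient_limit`` µV.  Defaults follow standard
    trial-rejection thresholds (±150 µV amplitude, 50 µV gradient).

    Returns the surviving epochs and the boolean rejection mask (True =
    rejected) for audit.
    """
    if amp_limit <= 0 or gradient_limit <= 0:
        raise ValueError("limits must be positive")
    valid = ~epochs.mask
    amp_bad = np.any((np.abs(epochs.data) > amp_limit) & valid, axis=(1, 2))
    diffs = np.abs(np.diff(epochs.data, axis=2))
    pair_valid = valid[:, :, 1:] & valid[:, :, :-1]
    grad_bad = np.any((diffs > gradient_limit) & pair_valid, axis=(1, 2))
    rejected = amp_bad | grad_bad
    if rejected.all():
        raise ValueError("all trials rejected")
    n_rej = int(rejected.sum())
    if n_rej:
        logger.info("rejected %d/%d trials (amplitude %d, gradient %d)",
                    n_rej, epochs.n_trials, int(amp_bad.sum()), int(grad_bad.sum()))
    return epochs.subset(np.flatnonzero(~rejected)), rejected


def build_adjacency(positions: np.ndarray, distance_threshold: float) -> AdjacencyGraph:
    """Channels i, j are neighbours iff their Euclidean distance < threshold."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] < 1:
        raise ValueError("positions must be n_channels x n_dims with >= 1 channel")
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be positive")
    d = cdist(positions, positions)
    n = positions.shape[0]
    offdiag = ~np.eye(n, dtype=bool)
    if np.any((d == 0) & offdiag):
        warnings.warn("duplicate channel coordinates: neighbours at distance 0")
    matrix = (d < distance_threshold) & offdiag
    return AdjacencyGraph(n_channels=n, matrix=matrix)


def resample(obj: Recording | EpochSet, target_srate: float):
    """Integer-factor decimation with anti-alias filtering.

    The target rate must divide the source rate evenly.  Constant signals are
    preserved.  For epochs, samples whose anti-alias filter support touched a
    masked sample are conservatively masked in the output.
    """
    factor = obj.srate / target_srate
    q = int(round(factor))
    if abs(factor - q) > 1e-9 or q < 1:
        raise ValueError(f"target rate must evenly divide source rate (factor {factor})")
    if q == 1:
        if isinstance(obj, Recording):
            return Recording(obj.data.copy(), obj.srate, list(obj.channel_labels),
                             None if obj.channel_positions is None else obj.channel_positions.copy())
        return obj.subset(np.arange(obj.n_trials))

    if isinstance(obj, Recording):
        data = resample_poly(obj.data, 1, q, axis=1, padtype="line")
        return Recording(data, target_srate, list(obj.channel_labels),
                         None if obj.channel_positions is None else obj.channel_positions.copy())

    # epochs: NaN-fill masked samples so invalidity propagates through the filter
    src = obj.data.copy()
    src[obj.mask] = np.nan
    data = resample_poly(src, 1, q, axis=2, padtype="line")
    mask = ~np.isfinite(data)
    data[mask] = 0.0
    times = obj.times[::q]
    times = times[: data.shape[2]]
    data = data[:, :, : times.size]
    mask = mask[:, :, : times.size]
    return EpochSet(
        data=data,
        mask=mask,
        times=times,
        srate=target_srate,
        lock=obj.lock,
        channel_labels=list(obj.channel_labels),
        kept_trial_ids=obj.kept_trial_ids,
        baseline_window=obj.baseline_window,
        flags=dict(obj.flags),
    )
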