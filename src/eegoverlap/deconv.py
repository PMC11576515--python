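"""FIR (stick-basis) linear deconvolution of overlapping event responses.

Stimulus and response events are modelled simultaneously: each event type
contributes, for every predictor, one column per latency bin of its FIR
window (one bin per sample at the working rate).  Solving the resulting
sparse least-squares system jointly attributes continuous-EEG variance to
event-type kernels, separating overlapping stimulus- and response-locked
activity that event-locked averaging confounds.  Continuous covariates are
mean-centred within event type, so intercept kernels read as the average
waveform for that event type.

No baseline correction is applied to deconvolution estimates.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import lsmr

from .containers import EventTable, Recording

logger = logging.getLogger(__name__)


@dataclass
class EventTypeSpec:
    """Predictors and FIR window for one event type.

    ``predictors`` are covariate column names in the event table; the
    intercept is always included.  ``window`` is [start, end) seconds
    relative to the event.
    """

    predictors: list[str] = field(default_factory=list)
    window: tuple[float, float] = (-2.0, 2.0)

    def __post_init__(self) -> None:
        if not np.isfinite(self.window).all() or self.window[1] <= self.window[0]:
            raise ValueError("window must be finite with end > start")


@dataclass
class EventDesignSpec:
    """Per-event-type design: stimulus and/or response, each with its window."""

    event_types: dict[str, EventTypeSpec]
    srate: float

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for etype, ts in self.event_types.items():
            for p in ["intercept"] + list(ts.predictors):
                key = (etype, p)
                if key in seen:
                    raise ValueError(f"duplicate predictor {p!r} for event type {etype!r}")
                seen.add(key)

    def n_bins(self, etype: str) -> int:
        ts = self.event_types[etype]
        return int(round(ts.window[1] * self.srate)) - int(round(ts.window[0] * self.srate))

    def bin_times(self, etype: str) -> np.ndarray:
        ts = self.event_types[etype]
        start = int(round(ts.window[0] * self.srate))
        return np.arange(start, start + self.n_bins(etype)) / self.srate


@dataclass
class TimeExpandedDesign:
    """Sparse time-expanded design: rows = recording samples, columns =
    (event type × predictor × latency bin)."""

    matrix: sp.csr_matrix
    columns: list[tuple[str, str, int]]   # (event type, predictor, bin index)
    spec: EventDesignSpec
    n_samples: int
    excluded: np.ndarray                  # bool per sample, dropped from the fit
    n_clipped_events: int = 0
    centering: dict = field(default_factory=dict)

    def column_slice(self, etype: str, predictor: str) -> slice:
        idx = [i for i, (e, p, _) in enumerate(self.columns) if e == etype and p == predictor]
        if not idx:
            raise KeyError(f"no columns for ({etype!r}, {predictor!r})")
        return slice(idx[0], idx[-1] + 1)

    def type_columns(self, etype: str) -> np.ndarray:
        return np.array([i for i, (e, _, _) in enumerate(self.columns) if e == etype])


def _event_samples(events: EventTable, etype: str) -> np.ndarray:
    if etype == "stimulus":
        return events.stimulus_samples.astype(float)
    if etype == "response":
        return events.response_samples
    raise ValueError(f"unknown event type {etype!r}")


def time_expand(
    events: EventTable,
    spec: EventDesignSpec,
    n_samples: int,
) -> TimeExpandedDesign:
    """Build the sparse FIR design: one stick column per predictor × latency.

    For each event at sample s and latency bin ℓ, row s+ℓ of column
    (type, predictor, ℓ) holds the predictor value (1 for the intercept;
    covariates mean-centred within event type, with missing values treated
    as the centre, i.e. contributing intercept-only).  Events whose window
    extends beyond the recording are clipped (logged).
    """
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    columns: list[tuple[str, str, int]] = []
    centering: dict = {}
    col_base = 0
    n_clipped = 0

    for etype, ts in spec.event_types.items():
        samples = _event_samples(events, etype)
        present = np.isfinite(samples)
        samples = samples[present].astype(int)
        lat0 = int(round(ts.window[0] * spec.srate))
        n_bins = spec.n_bins(etype)
        lats = np.arange(lat0, lat0 + n_bins)

        pred_values = [np.ones(samples.size)]
        pred_names = ["intercept"]
        for pname in ts.predictors:
            v = events.frame[pname].to_numpy(dtype=float)[present]
            finite = np.isfinite(v)
            centre = v[finite].mean() if finite.any() else 0.0
            n_missing = int((~finite).sum())
            if n_missing:
                logger.info("%d %s events missing %r; modelled intercept-only", n_missing, etype, pname)
            v = np.where(finite, v - centre, 0.0)
            centering[(etype, pname)] = centre
            pred_values.append(v)
            pred_names.append(pname)

        r = samples[:, None] + lats[None, :]            # events x bins
        inside = (r >= 0) & (r < n_samples)
        clipped = ~inside.all(axis=1)
        n_clipped += int(clipped.sum())
        for pname, v in zip(pred_names, pred_values):
            c = col_base + np.broadcast_to(np.arange(n_bins), r.shape)
            rows.append(r[inside])
            cols.append(c[inside])
            vals.append(np.broadcast_to(v[:, None], r.shape)[inside])
            columns.extend((etype, pname, b) for b in range(n_bins))
            col_base += n_bins

    if n_clipped:
        logger.info("clipped %d events whose FIR window exceeded the recording", n_clipped)
    matrix = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_samples, col_base),
    ).tocsr()
    return TimeExpandedDesign(
        matrix=matrix,
        columns=columns,
        spec=spec,
        n_samples=n_samples,
        excluded=np.zeros(n_samples, dtype=bool),
        n_clipped_events=n_clipped,
        centering=centering,
    )


def exclude_artifact_intervals(
    recording: Recording,
    design: TimeExpandedDesign,
    amp_limit: float = 250.0,
    guard: int = 0,
) -> TimeExpandedDesign:
    """Drop samples where any channel exceeds ``±amp_limit`` µV from the fit.

    ``guard`` dilates the exclusion mask by that many samples on each side.
    The returned design carries the exclusion mask; the affected rows are
    removed at solve time, so the fit is invariant to data values there.
    Raises if more than 90% of samples would be excluded.
    """
    if amp_limit <= 0:
        raise ValueError("amp_limit must be positive")
    bad = np.any(np.abs(recording.data) > amp_limit, axis=0)
    if guard > 0 and bad.any():
        kernel = np.ones(2 * guard + 1, dtype=bool)
        bad = np.convolve(bad, kernel, mode="same") > 0
    excluded = design.excluded | bad
    frac = excluded.mean()
    if frac > 0.9:
        raise ValueError(f"{frac:.0%} of samples excluded as artefacts")
    n_new = int(bad.sum())
    if n_new:
        logger.info("excluded %d samples (%.2f%%) exceeding ±%g µV",
                    n_new, 100 * bad.mean(), amp_limit)
    return TimeExpandedDesign(
        matrix=design.matrix,
        columns=design.columns,
        spec=design.spec,
        n_samples=design.n_samples,
        excluded=excluded,
        n_clipped_events=design.n_clipped_events,
        centering=design.centering,
    )


@dataclass
class DeconvModel:
    """Fitted deconvolution: per-event-type FIR kernels per predictor/channel."""

    kernels: dict[tuple[str, str], np.ndarray]   # (etype, predictor) -> bins x channels (µV/unit)
    solution: np.ndarray                         # columns x channels raw solution
    design: TimeExpandedDesign
    channel_labels: list[str]
    diagnostics: dict

    def kernel(self, etype: str, predictor: str = "intercept") -> np.ndarray:
        return self.kernels[(etype, predictor)]

    def kernel_times(self, etype: str) -> np.ndarray:
        return self.design.spec.bin_times(etype)

    def energy_share(self, etypes: tuple[str, str] = ("stimulus", "response"),
                     predictor: str = "intercept") -> dict[str, float]:
        """Share of recovered kernel energy (Σ kernel²) per event type."""
        e = {t: float((self.kernel(t, predictor) ** 2).sum()) for t in etypes}
        total = sum(e.values())
        return {t: (v / total if total > 0 else np.nan) for t, v in e.items()}


def solve_deconv(
    design: TimeExpandedDesign,
    recording: Recording,
    tol: float = 1e-10,
    max_iter: int | None = None,
    ridge: float = 0.0,
) -> DeconvModel:
    """Minimum-norm least squares per channel via LSMR on the sparse design.

    Excluded rows are removed before the solve.  Raises on non-convergence
    at the iteration cap, with residual diagnostics.
    """
    keep = ~design.excluded
    if not keep.any() or design.matrix.shape[1] == 0:
        raise ValueError("empty design after exclusion")
    A = design.matrix[keep]
    if max_iter is None:
        max_iter = max(10 * design.matrix.shape[1], 1000)
    n_cols = design.matrix.shape[1]
    n_ch = recording.n_channels
    solution = np.zeros((n_cols, n_ch))
    info = {"iterations": [], "residual_norm": [], "istop": []}
    for c in range(n_ch):
        y = recording.data[c, keep]
        x, istop, itn, normr, *_ = lsmr(A, y, damp=np.sqrt(ridge) if ridge > 0 else 0.0,
                                        atol=tol, btol=tol, maxiter=max_iter)
        if istop == 7:
            raise RuntimeError(
                f"LSMR hit the iteration cap ({max_iter}) on channel "
                f"{recording.channel_labels[c]}; residual norm {normr:.3e}"
            )
        solution[:, c] = x
        info["iterations"].append(int(itn))
        info["residual_norm"].append(float(normr))
        info["istop"].append(int(istop))

    kernels: dict[tuple[str, str], np.ndarray] = {}
    for etype, ts in design.spec.event_types.items():
        for pname in ["intercept"] + list(ts.predictors):
            sl = design.column_slice(etype, pname)
            kernels[(etype, pname)] = solution[sl, :]
    return DeconvModel(
        kernels=kernels,
        solution=solution,
        design=design,
        channel_labels=list(recording.channel_labels),
        diagnostics=info,
    )


def add_rt_modulation(
    spec: EventDesignSpec,
    kind: str = "continuous",
    rt_column: str = "rt",
) -> EventDesignSpec:
    """Let stimulus-locked activity vary with response time.

    Adds an RT covariate to the stimulus event type, mirroring the
    response-side RT regressor: ``kind='continuous'`` adds the RT column
    itself; ``kind='median_split'`` adds ``<rt_column>_split`` (a ±0.5
    indicator the caller materializes in the event table).
    """
    if "stimulus" not in spec.event_types:
        raise ValueError("spec has no stimulus event type")
    if kind not in ("continuous", "median_split"):
        raise ValueError("kind must be 'continuous' or 'median_split'")
    new = copy.deepcopy(spec)
    col = rt_column if kind == "continuous" else f"{rt_column}_split"
    if col not in new.event_types["stimulus"].predictors:
        new.event_types["stimulus"].predictors.append(col)
    return new


def correct_overlap(
    recording: Recording,
    model: DeconvModel,
    remove: set[str],
) -> Recording:
    """Subtract the reconstructed contribution of the named event types.

    E.g. removing the stimulus contribution before response-locked epoching
    yields overlap-corrected data in which any remaining response-locked
    structure cannot be stimulus-evoked.
    """
    unknown = remove - set(model.design.spec.event_types)
    if unknown:
        raise ValueError(f"unknown event type(s): {sorted(unknown)}")
    cols = np.concatenate([model.design.type_columns(t) for t in sorted(remove)])
    A = model.design.matrix[:, cols]
    contrib = A @ model.solution[cols, :]      # samples x channels
    data = recording.data - contrib.T
    return Recording(
        data=data,
        srate=recording.srate,
        channel_labels=list(recording.channel_labels),
        channel_positions=None if recording.channel_positions is None
        else recording.channel_positions.copy(),
    )
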