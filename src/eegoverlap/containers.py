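"""Core data containers and standard-format I/O.

A :class:`Recording` is a continuous multi-channel voltage series; an
:class:`EventTable` holds per-trial events (stimulus onset, response, RT) and
the eight behavioural measures; an :class:`EpochSet` is a trials × channels ×
time tensor with a missing-value mask; an :class:`AdjacencyGraph` encodes the
channel neighbourhood used by spatiotemporal clustering.

Recordings round-trip through a raw float32 binary + JSON sidecar bundle and
can be read from EDF (via MNE).  Event tables and montages are plain TSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The eight behavioural measures entering the construct PCA, in canonical
#: column order.  "value_difference" is |max − min| of the two item values,
#: "overall_value" their mean, "set_salience" the absolute mean-centred
#: overall value.
MEASURE_NAMES = [
    "chosen_value",
    "unchosen_value",
    "value_difference",
    "overall_value",
    "set_salience",
    "anxiety",
    "liking",
    "confidence",
]

EVENT_COLUMNS = [
    "participant_id",
    "stimulus_sample",
    "response_sample",
    "stimulus_time",
    "response_time",
    "rt",
] + MEASURE_NAMES


@dataclass
class Recording:
    """Continuous multi-channel EEG (µV).

    Parameters
    ----------
    data
        channels × samples voltage array in µV.
    srate
        Sampling rate in Hz.
    channel_labels
        One label per data row.
    channel_positions
        Optional channels × 3 coordinates (arbitrary length units) used to
        build spatial adjacency.
    """

    data: np.ndarray
    srate: float
    channel_labels: list[str]
    channel_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} rows"
            )
        if self.channel_positions is not None:
            self.channel_positions = np.asarray(self.channel_positions, dtype=float)
            if self.channel_positions.shape != (self.data.shape[0], 3):
                raise ValueError("channel_positions must be n_channels x 3")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.srate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None


class EventTable:
    """Per-trial event table.

    Wraps a :class:`pandas.DataFrame` with the columns in
    :data:`EVENT_COLUMNS`.  ``response_sample`` is NaN for trials without a
    response (deadline exceeded); ``rt`` is seconds from stimulus to response.
    Event times are stored both in samples and in seconds.
    """

    def __init__(self, frame: pd.DataFrame, srate: float):
        missing = [c for c in ("participant_id", "stimulus_sample") if c not in frame]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        frame = frame.copy()
        if "response_sample" not in frame:
            frame["response_sample"] = np.nan
        if "stimulus_time" not in frame:
            frame["stimulus_time"] = frame["stimulus_sample"] / srate
        if "response_time" not in frame:
            frame["response_time"] = frame["response_sample"] / srate
        if "rt" not in frame:
            frame["rt"] = frame["response_time"] - frame["stimulus_time"]
        self._validate(frame, srate)
        self.frame = frame.reset_index(drop=True)
        self.srate = float(srate)

    @staticmethod
    def _validate(frame: pd.DataFrame, srate: float) -> None:
        resp = frame["response_sample"].to_numpy(dtype=float)
        stim = frame["stimulus_sample"].to_numpy(dtype=float)
        has = np.isfinite(resp)
        if np.any(resp[has] <= stim[has]):
            raise ValueError("response_sample must exceed stimulus_sample")
        rt = frame["rt"].to_numpy(dtype=float)
        implied = (resp - stim) / srate
        bad = has & np.isfinite(rt) & (np.abs(rt - implied) > 1.0 / srate)
        if np.any(bad):
            raise ValueError("rt inconsistent with sample indices by more than one sample")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_response(self) -> np.ndarray:
        return np.isfinite(self.frame["response_sample"].to_numpy(dtype=float))

    @property
    def rt(self) -> np.ndarray:
        return self.frame["rt"].to_numpy(dtype=float)

    @property
    def stimulus_samples(self) -> np.ndarray:
        return self.frame["stimulus_sample"].to_numpy(dtype=int)

    @property
    def response_samples(self) -> np.ndarray:
        """Response sample indices as float (NaN where absent)."""
        return self.frame["response_sample"].to_numpy(dtype=float)

    def measures(self) -> pd.DataFrame:
        cols = [c for c in MEASURE_NAMES if c in self.frame]
        return self.frame[cols]

    def subset(self, index: np.ndarray) -> "EventTable":
        return EventTable(self.frame.iloc[np.asarray(index)], self.srate)


@dataclass
class EpochSet:
    """Epoched trials: trials × channels × time, with a missing-value mask.

    ``mask`` is True where a sample is invalid — typically because it fell
    outside its trial's [stimulus, response] range and was invalidated to
    avoid spill-over from neighbouring trials.  ``times`` is seconds relative
    to the lock event (uniform step 1/srate, time 0 = the lock sample).
    """

    data: np.ndarray
    mask: np.ndarray
    times: np.ndarray
    srate: float
    lock: str
    channel_labels: list[str]
    kept_trial_ids: np.ndarray
    baseline_window: tuple[float, float] | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape != self.mask.shape:
            raise ValueError("data and mask shapes differ")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length mismatch")
        if self.lock not in ("stimulus", "response"):
            raise ValueError("lock must be 'stimulus' or 'response'")
        steps = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(steps, 1.0 / self.srate, atol=1e-9):
            raise ValueError("times must be uniform with step 1/srate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None

    def valid_data(self) -> np.ndarray:
        """Data with masked samples replaced by NaN."""
        out = self.data.copy()
        out[self.mask] = np.nan
        return out

    def mean(self) -> np.ndarray:
        """Channels × time mean over unmasked samples."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.valid_data(), axis=0)

    def subset(self, index: np.ndarray) -> "EpochSet":
        index = np.asarray(index)
        return EpochSet(
            data=self.data[index],
            mask=self.mask[index],
            times=self.times,
            srate=self.srate,
            lock=self.lock,
            channel_labels=list(self.channel_labels),
            kept_trial_ids=np.asarray(self.kept_trial_ids)[index],
            baseline_window=self.baseline_window,
            flags=dict(self.flags),
        )


@dataclass
class AdjacencyGraph:
    """Symmetric, irreflexive neighbour relation over channel indices."""

    n_channels: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (self.n_channels, self.n_channels):
            raise ValueError("adjacency matrix shape mismatch")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.matrix)):
            raise ValueError("adjacency must be irreflexive")

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.matrix[i])

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum()) // 2


# ---------------------------------------------------------------------------
# I/O


def write_event_table(events: EventTable, path: str | Path) -> None:
    """Write an event table as TSV (documented columns, samples and seconds)."""
    frame = events.frame.copy()
    for col in EVENT_COLUMNS:
        if col not in frame:
            frame[col] = np.nan
    extra = [c for c in frame.columns if c not in EVENT_COLUMNS]
    frame = frame[EVENT_COLUMNS + extra]
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_event_table(path: str | Path, srate: float) -> EventTable:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    return EventTable(frame, srate)


def write_raw_bundle(recording: Recording, path: str | Path) -> None:
    """Write a recording as raw float32 binary + JSON sidecar.

    ``<path>.dat`` holds channel-major float32 samples; ``<path>.json`` holds
    srate, labels, positions and array shape.
    """
    path = Path(path)
    data32 = recording.data.astype(np.float32)
    data32.tofile(path.with_suffix(".dat"))
    sidecar = {
        "srate": recording.srate,
        "channel_labels": recording.channel_labels,
        "channel_positions": None
        if recording.channel_positions is None
        else recording.channel_positions.tolist(),
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "dtype": "float32",
        "order": "C",
        "units": "uV",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_raw_bundle(path: str | Path) -> Recording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path.with_suffix(".dat"), dtype=sidecar["dtype"])
    data = data.reshape(sidecar["n_channels"], sidecar["n_samples"])
    positions = sidecar.get("channel_positions")
    return Recording(
        data=np.asarray(data, dtype=float),
        srate=sidecar["srate"],
        channel_labels=list(sidecar["channel_labels"]),
        channel_positions=None if positions is None else np.asarray(positions),
    )


def read_recording_edf(path: str | Path) -> Recording:
    """Read a continuous recording from EDF via MNE (data returned in µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads volts
    return Recording(
        data=data,
        srate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def write_montage(labels: Sequence[str], positions: np.ndarray, path: str | Path) -> None:
    """Write a montage TSV of label, x, y, z."""
    frame = pd.DataFrame(positions, columns=["x", "y", "z"])
    frame.insert(0, "label", list(labels))
    frame.to_csv(path, sep="\t", index=False)


def read_montage(path: str | Path) -> tuple[list[str], np.ndarray]:
    frame = pd.read_csv(path, sep="\t")
    return list(frame["label"]), frame[["x", "y", "z"]].to_numpy(dtype=float)


def standard_positions(labels: Sequence[str]) -> np.ndarray:
    """3D template coordinates (metres) for 10-20 labels, from MNE's montage."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    out = []
    for lab in labels:
        if lab not in pos:
            raise KeyError(f"label {lab!r} not in the 10-20 template montage")
        out.append(pos[lab])
    return np.asarray(out, dtype=float)
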