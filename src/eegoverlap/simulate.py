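"""Synthetic behaviour and EEG with known ground truth.

Behavioural measures are generated from two correlated latent constructs —
*appraisal* (a: how positively the choice set is evaluated) and *choice
difficulty* (c: how hard the decision is).  Eight per-trial measures follow:
liking and overall value load on a; anxiety loads positively and confidence
and value difference negatively on c; chosen/unchosen value and set salience
are deterministic functions of the others.  Response times come from a
shifted lognormal whose log-scale decreases with value difference and overall
value, truncated at a response deadline.

Continuous EEG is the sum of per-trial placed components — a stimulus-locked
transient (raised-cosine bump peaking ≈350 ms post-stimulus, amplitude
modulated by appraisal), an optional response-locked biphasic component
(modulated by difficulty), an optional accumulation ramp rising from shortly
after the stimulus to a peak at the response — projected through per-channel
topography weights, plus noise.  Every placement is stored in a
:class:`GroundTruth` so that downstream analyses can be validated against the
exact generative signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import EventTable, Recording, standard_positions

DEFAULT_CHANNELS = ["Fz", "Cz", "CP1", "CP2", "Pz", "P3", "P4", "Oz"]


# ---------------------------------------------------------------------------
# Behaviour


@dataclass
class BehaviourConfig:
    """Two-latent-construct behavioural generator.

    Latents (a, c) are standard bivariate normal with correlation
    ``latent_corr``.  The five stochastic measures are linear in the latents
    with independent Gaussian noise; loadings are ``(weight on a, weight on
    −c)`` so that positive numbers mean "appraisal-like" / "ease-like".
    RTs: ``rt = rt_shift + exp(rt_mu0 + beta_vd*VD + beta_ov*OV + rt_sigma*ε)``
    with both betas ≤ 0, truncated at ``rt_cap`` (truncated trials are marked
    as "no response").
    """

    n_trials: int = 4637
    latent_corr: float = 0.2
    # measure = intercept + w_a * a + w_ec * (-c) + noise_sd * eps
    load_overall_value: tuple[float, float] = (0.15, 0.0)
    load_value_difference: tuple[float, float] = (0.0, 0.15)
    load_liking: tuple[float, float] = (1.0, 0.0)
    load_anxiety: tuple[float, float] = (0.0, -1.0)
    load_confidence: tuple[float, float] = (0.0, 1.0)
    overall_value_base: float = 0.5
    value_difference_base: float = 0.5
    noise_sd_values: float = 0.06
    noise_sd_ratings: float = 0.4
    # rating scales saturate: liking/anxiety/confidence are clipped at
    # ±rating_clip, emulating bounded response scales
    rating_clip: float = 1.5
    choice_beta: float = 5.0
    rt_shift: float = 0.3
    rt_mu0: float = 0.1
    rt_sigma: float = 0.4
    rt_beta_vd: float = -0.4
    rt_beta_ov: float = -0.3
    rt_cap: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_cap <= self.rt_shift:
            raise ValueError("rt_cap must exceed rt_shift")
        if self.noise_sd_values < 0 or self.noise_sd_ratings < 0:
            raise ValueError("noise sds must be non-negative")
        if self.rt_beta_vd > 0 or self.rt_beta_ov > 0:
            raise ValueError("RT coefficients must be <= 0 (faster with easier/better sets)")

    @property
    def loading_matrix(self) -> np.ndarray:
        """5 × 2 matrix mapping (a, −c) to the stochastic measures."""
        return np.array(
            [
                self.load_overall_value,
                self.load_value_difference,
                self.load_liking,
                self.load_anxiety,
                self.load_confidence,
            ]
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BehaviourConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("load_overall_value", "load_value_difference", "load_liking",
                    "load_anxiety", "load_confidence"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def simulate_trial_measures(
    config: BehaviourConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw per-trial measures and RTs from the two-construct model.

    Returns
    -------
    measures
        DataFrame with the eight measures plus ``rt`` (NaN where the deadline
        was exceeded), ``chose_best`` and ``responded``.
    latents
        n_trials × 2 array of (a, c).
    """
    if np.linalg.matrix_rank(config.loading_matrix) < 2:
        raise ValueError("degenerate loading matrix: rank < 2")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_trials
    rho = config.latent_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    latents = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    a, c = latents[:, 0], latents[:, 1]
    ease = -c

    w = config.loading_matrix
    ov = config.overall_value_base + w[0, 0] * a + w[0, 1] * ease \
        + config.noise_sd_values * rng.standard_normal(n)
    vd = config.value_difference_base + w[1, 0] * a + w[1, 1] * ease \
        + config.noise_sd_values * rng.standard_normal(n)
    vd = np.clip(vd, 0.0, None)  # value difference = |max - min| >= 0
    def rating(row: int) -> np.ndarray:
        x = w[row, 0] * a + w[row, 1] * ease + config.noise_sd_ratings * rng.standard_normal(n)
        return np.clip(x, -config.rating_clip, config.rating_clip)

    liking = rating(2)
    anxiety = rating(3)
    confidence = rating(4)

    v_high = ov + vd / 2.0
    v_low = ov - vd / 2.0
    # choices: softmax on value difference; accuracy grows with VD
    p_best = 1.0 / (1.0 + np.exp(-config.choice_beta * vd))
    chose_best = rng.random(n) < p_best
    chosen = np.where(chose_best, v_high, v_low)
    unchosen = np.where(chose_best, v_low, v_high)
    salience = np.abs(ov - ov.mean())

    mu = config.rt_mu0 + config.rt_beta_vd * vd + config.rt_beta_ov * ov
    rt = config.rt_shift + np.exp(mu + config.rt_sigma * rng.standard_normal(n))
    responded = rt <= config.rt_cap
    rt = np.where(responded, rt, np.nan)

    measures = pd.DataFrame(
        {
            "chosen_value": chosen,
            "unchosen_value": unchosen,
            "value_difference": vd,
            "overall_value": ov,
            "set_salience": salience,
            "anxiety": anxiety,
            "liking": liking,
            "confidence": confidence,
            "rt": rt,
            "chose_best": chose_best,
            "responded": responded,
        }
    )
    return measures, latents


# ---------------------------------------------------------------------------
# EEG


def raised_cosine_kernel(onset: float, duration: float, srate: float) -> tuple[int, np.ndarray]:
    """Unit-peak raised-cosine bump on [onset, onset+duration) seconds.

    Peaks at onset + duration/2.  Returns (start offset in samples, waveform).
    """
    n = int(round(duration * srate))
    t = np.arange(n) / srate
    wave = np.sin(np.pi * t / duration) ** 2
    return int(round(onset * srate)), wave


def biphasic_kernel(half_width: float, srate: float) -> tuple[int, np.ndarray]:
    """Unit-peak full sine cycle on [-half_width, half_width) around the event."""
    n = int(round(2 * half_width * srate))
    t = np.arange(n) / srate
    wave = np.sin(2 * np.pi * t / (2 * half_width))
    return -int(round(half_width * srate)), wave


KERNELS = {
    "raised_cosine": raised_cosine_kernel,
    "biphasic": biphasic_kernel,
}


def build_kernel(spec: dict, srate: float) -> tuple[int, np.ndarray]:
    """Build (start offset in samples, waveform) from a kernel spec dict."""
    spec = dict(spec)
    kind = spec.pop("kind")
    try:
        fn = KERNELS[kind]
    except KeyError:
        raise ValueError(f"unknown kernel kind {kind!r}") from None
    return fn(srate=srate, **spec)


@dataclass
class EEGSimConfig:
    """Continuous-EEG generator with overlapping components.

    Amplitudes are µV at the topography's peak channel.  The stimulus
    transient's amplitude on trial i is ``stim_base_amp + stim_gain_appraisal
    * a_i``; the response component's is ``resp_base_amp + resp_gain_choice *
    (−c_i)`` (difficult choices → smaller/negative-going response component).
    Setting a gain and base to 0 removes the component.  The optional ramp
    rises linearly from ``stimulus + ramp_onset_offset`` to ``ramp_peak_amp``
    at the response, then decays to 0 over ``ramp_fall`` seconds.
    """

    channel_labels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    channel_positions: np.ndarray | None = None
    srate: float = 250.0
    iti: float = 1.8
    lead_in: float = 1.0
    stim_kernel: dict = field(default_factory=lambda: {"kind": "raised_cosine", "onset": 0.0, "duration": 0.7})
    stim_base_amp: float = 5.0
    stim_gain_appraisal: float = 1.5
    stim_topo_center: str = "Pz"
    resp_kernel: dict = field(default_factory=lambda: {"kind": "biphasic", "half_width": 0.15})
    resp_base_amp: float = 0.0
    resp_gain_choice: float = 0.0
    resp_topo_center: str = "Cz"
    ramp_onset_offset: float = 0.2
    ramp_peak_amp: float = 0.0
    ramp_fall: float = 0.15
    ramp_topo_center: str = "Pz"
    topo_sigma: float = 0.07
    noise_white_sd: float = 2.0
    noise_pink_sd: float = 0.0
    noise_pink_exponent: float = 1.0
    no_response_layout_time: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_positions is None:
            self.channel_positions = standard_positions(self.channel_labels)
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)

    def topography(self, center: str) -> np.ndarray:
        """Spatial Gaussian weights (peak 1 at the centre channel)."""
        idx = self.channel_labels.index(center)
        d = np.linalg.norm(self.channel_positions - self.channel_positions[idx], axis=1)
        return np.exp(-((d / self.topo_sigma) ** 2))


@dataclass
class Placement:
    """One component instance placed in the continuous recording."""

    component: str
    trial: int
    start_sample: int
    waveform: np.ndarray      # amplitude already applied
    topography: np.ndarray    # per-channel weights


@dataclass
class GroundTruth:
    """Exact generative decomposition: recording = Σ placements + noise."""

    placements: list[Placement]
    noise: np.ndarray
    latents: np.ndarray
    config: EEGSimConfig

    def component_signal(self, n_samples: int, components: set[str] | None = None) -> np.ndarray:
        """Channels × samples sum of the named placed components."""
        n_ch = self.noise.shape[0]
        out = np.zeros((n_ch, n_samples))
        for p in self.placements:
            if components is not None and p.component not in components:
                continue
            a, b = p.start_sample, p.start_sample + p.waveform.size
            out[:, a:b] += p.topography[:, None] * p.waveform[None, :]
        return out


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], exponent: float) -> np.ndarray:
    """1/f^exponent noise, unit variance per channel."""
    n_ch, n = shape
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = (rng.standard_normal((n_ch, freqs.size)) + 1j * rng.standard_normal((n_ch, freqs.size))) * scale
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_recording(
    measures: pd.DataFrame,
    latents: np.ndarray,
    config: EEGSimConfig,
    participant_id: str = "sim01",
) -> tuple[Recording, EventTable, GroundTruth]:
    """Lay out trials sequentially and synthesize the continuous EEG.

    Trial i's stimulus falls ``iti`` seconds after trial i−1's response (or
    after ``no_response_layout_time`` for deadline trials).  Raises if the
    inter-trial interval cannot accommodate the component windows without
    crossing into the next trial's stimulus kernel start.
    """
    rng = np.random.default_rng(config.seed)
    sr = config.srate
    n_trials = len(measures)
    if latents.shape[0] != n_trials:
        raise ValueError("latents and measures disagree on trial count")
    rts = measures["rt"].to_numpy(dtype=float)

    stim_off, stim_wave = build_kernel(config.stim_kernel, sr)
    resp_off, resp_wave = build_kernel(config.resp_kernel, sr)
    stim_span = (stim_off + stim_wave.size) / sr
    resp_span = (resp_off + resp_wave.size) / sr
    if config.iti < max(stim_span - 0.0, resp_span) - 1e-9:
        raise ValueError(
            f"iti {config.iti}s too short for component windows "
            f"(stimulus span {stim_span:.2f}s, response span {resp_span:.2f}s)"
        )

    stim_samples = np.empty(n_trials, dtype=int)
    resp_samples = np.full(n_trials, np.nan)
    cursor = int(round(config.lead_in * sr))
    for i in range(n_trials):
        stim_samples[i] = cursor
        if np.isfinite(rts[i]):
            resp_samples[i] = cursor + int(round(rts[i] * sr))
            end = resp_samples[i]
        else:
            end = cursor + int(round(config.no_response_layout_time * sr))
        cursor = int(end + round(config.iti * sr))
    n_samples = cursor + int(round(config.lead_in * sr))

    n_ch = len(config.channel_labels)
    signal = np.zeros((n_ch, n_samples))
    placements: list[Placement] = []

    a = latents[:, 0]
    ease = -latents[:, 1]
    stim_topo = config.topography(config.stim_topo_center)
    resp_topo = config.topography(config.resp_topo_center)
    ramp_topo = config.topography(config.ramp_topo_center)

    def place(component: str, trial: int, start: int, wave: np.ndarray, topo: np.ndarray) -> None:
        if wave.size == 0 or not np.any(wave):
            return
        p = Placement(component, trial, start, wave.copy(), topo.copy())
        placements.append(p)
        signal[:, start : start + wave.size] += topo[:, None] * wave[None, :]

    for i in range(n_trials):
        amp_s = config.stim_base_amp + config.stim_gain_appraisal * a[i]
        if config.stim_base_amp != 0 or config.stim_gain_appraisal != 0:
            place("stimulus", i, stim_samples[i] + stim_off, amp_s * stim_wave, stim_topo)
        if np.isfinite(resp_samples[i]):
            r = int(resp_samples[i])
            amp_r = config.resp_base_amp + config.resp_gain_choice * ease[i]
            if config.resp_base_amp != 0 or config.resp_gain_choice != 0:
                place("response", i, r + resp_off, amp_r * resp_wave, resp_topo)
            if config.ramp_peak_amp != 0:
                ramp_start = stim_samples[i] + int(round(config.ramp_onset_offset * sr))
                if ramp_start < r:
                    rise = np.linspace(0.0, 1.0, r - ramp_start, endpoint=False)
                    n_fall = int(round(config.ramp_fall * sr))
                    fall = np.linspace(1.0, 0.0, n_fall)
                    wave = config.ramp_peak_amp * np.concatenate([rise, fall])
                    place("ramp", i, ramp_start, wave, ramp_topo)

    noise = np.zeros((n_ch, n_samples))
    if config.noise_white_sd > 0:
        noise += config.noise_white_sd * rng.standard_normal((n_ch, n_samples))
    if config.noise_pink_sd > 0:
        noise += config.noise_pink_sd * _pink_noise(rng, (n_ch, n_samples), config.noise_pink_exponent)

    recording = Recording(
        data=signal + noise,
        srate=sr,
        channel_labels=list(config.channel_labels),
        channel_positions=config.channel_positions.copy(),
    )

    frame = measures.copy()
    frame["participant_id"] = participant_id
    frame["stimulus_sample"] = stim_samples
    frame["response_sample"] = resp_samples
    frame["stimulus_time"] = stim_samples / sr
    frame["response_time"] = resp_samples / sr
    frame["rt"] = (resp_samples - stim_samples) / sr
    events = EventTable(frame, sr)
    truth = GroundTruth(placements=placements, noise=noise, latents=latents.copy(), config=config)
    return recording, events, truth
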