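"""Neurally informed drift-diffusion simulation with stimulus/motor jitter.

The accumulator starts at a/2 between absorbing bounds at 0 and a and evolves
by Euler–Maruyama, dx = v dt + s √dt ε.  Non-decision time is split into a
pre-accumulation (stimulus) part t_s ~ U(0, stim_jitter) and a post-decision
(motor) part t_m ~ U(0, motor_jitter), so that the accumulation process is
tied tightly to neither the stimulus nor the response when both jitters are
non-zero.  RT = t_s + DT + t_m.

Boundary absorption uses a Brownian-bridge crossing test within each step
(default on), which removes the O(√dt) first-passage bias of naive Euler
stepping; the crossing time within the final step is linearly interpolated,
so in the noiseless case DT = (a/2)/v holds exactly.  For symmetric bounds
and start a/2 the mean decision time has the closed form
``(a/(2v)) · tanh(a v / (2 s²))``, used as an independent oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The three jitter scenarios (stim_jitter, motor_jitter) in seconds, keyed by
#: the stim/motor ratio they realize.
JITTER_SCENARIOS = {
    "2/1": (0.2, 0.1),
    "1/1": (0.2, 0.2),
    "1/2": (0.1, 0.2),
}


@dataclass
class DDMConfig:
    """Drift-diffusion configuration.

    ``drift`` maps condition name → drift rate (evidence strength); trials
    are assigned conditions in proportion to ``condition_mix``.  ``bound`` is
    the bound separation a (absorbing at 0 and a, start a/2); ``noise_sd`` is
    the diffusion coefficient s.  Jitters are the widths of the uniform
    stimulus/motor non-decision-time distributions.
    """

    drift: dict = field(default_factory=lambda: {"strong": 1.0, "weak": 0.5})
    condition_mix: dict = field(default_factory=lambda: {"strong": 0.5, "weak": 0.5})
    bound: float = 1.0
    noise_sd: float = 0.5
    dt: float = 0.002
    stim_jitter: float = 0.2
    motor_jitter: float = 0.1
    n_trials: int = 500
    max_time: float = 5.0
    hold_during_motor: bool = True
    bridge_correction: bool = True
    store_traces: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.bound <= 0:
            raise ValueError("dt and bound must be positive")
        if self.stim_jitter < 0 or self.motor_jitter < 0:
            raise ValueError("jitters must be non-negative")

    @property
    def jitter_ratio(self) -> str:
        """stim_jitter/motor_jitter, e.g. '2/1' (inf if motor_jitter = 0)."""
        if self.motor_jitter == 0:
            return "inf" if self.stim_jitter > 0 else "0/0"
        r = self.stim_jitter / self.motor_jitter
        from fractions import Fraction

        f = Fraction(r).limit_denominator(10)
        return f"{f.numerator}/{f.denominator}"


@dataclass
class DDMTraces:
    """Simulated accumulator traces on a common dt grid.

    ``traces[i]`` is trial i's signal from stimulus onset: 0 during t_s, then
    |accumulated evidence toward the chosen bound| during accumulation
    (reaching a/2 at threshold), then — if ``hold_during_motor`` — held at
    a/2 for the motor time and dropped to 0 at the response.
    """

    traces: list[np.ndarray]
    dt: float
    t_stim: np.ndarray
    decision_time: np.ndarray
    t_motor: np.ndarray
    condition: np.ndarray
    flagged: np.ndarray

    @property
    def srate(self) -> float:
        return 1.0 / self.dt


def simulate_ddm(
    config: DDMConfig,
    rng: np.random.Generator | None = None,
) -> tuple[DDMTraces, np.ndarray, np.ndarray]:
    """Simulate first-passage trials; returns (traces, rts, choices).

    ``choices`` is +1 for upper-bound and −1 for lower-bound absorption.
    Trials that fail to absorb within ``max_time`` are flagged (RT NaN).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_trials
    a = config.bound
    s = config.noise_sd
    dt = config.dt

    conditions = list(config.drift)
    probs = np.array([config.condition_mix.get(k, 0.0) for k in conditions], dtype=float)
    probs = probs / probs.sum()
    cond_idx = rng.choice(len(conditions), size=n, p=probs)
    v = np.array([config.drift[conditions[k]] for k in cond_idx])

    t_s = rng.uniform(0.0, config.stim_jitter, size=n) if config.stim_jitter > 0 else np.zeros(n)
    t_m = rng.uniform(0.0, config.motor_jitter, size=n) if config.motor_jitter > 0 else np.zeros(n)

    max_steps = int(np.ceil(config.max_time / dt))
    x = np.full(n, a / 2.0)
    active = np.ones(n, dtype=bool)
    dt_dec = np.full(n, np.nan)
    choice = np.zeros(n)
    paths = [np.full(n, a / 2.0)] if config.store_traces else None
    sqdt = np.sqrt(dt)

    for step in range(max_steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        x_old = x[idx]
        dx = v[idx] * dt
        if s > 0:
            dx = dx + s * sqdt * rng.standard_normal(idx.size)
        x_new = x_old + dx

        t_now = step * dt
        hit_up = x_new >= a
        hit_lo = x_new <= 0.0
        frac = np.ones(idx.size)
        # linear interpolation of the crossing time within the step
        with np.errstate(divide="ignore", invalid="ignore"):
            f_up = np.where(hit_up, (a - x_old) / (x_new - x_old), 1.0)
            f_lo = np.where(hit_lo, (0.0 - x_old) / (x_new - x_old), 1.0)
        frac = np.minimum(f_up, f_lo)
        absorbed = hit_up | hit_lo
        bound_val = np.where(f_up <= f_lo, a, 0.0)

        if config.bridge_correction and s > 0:
            # Brownian-bridge probability of an intra-step excursion across a
            # bound even though both endpoints lie inside
            inside = ~absorbed
            u = rng.random(idx.size)
            p_up = np.exp(-2.0 * np.clip(a - x_old, 0, None) * np.clip(a - x_new, 0, None) / (s * s * dt))
            p_lo = np.exp(-2.0 * np.clip(x_old, 0, None) * np.clip(x_new, 0, None) / (s * s * dt))
            bridge_up = inside & (u < p_up)
            bridge_lo = inside & ~bridge_up & (u < p_up + p_lo)
            absorbed = absorbed | bridge_up | bridge_lo
            bound_val = np.where(bridge_up, a, bound_val)
            bound_val = np.where(bridge_lo, 0.0, bound_val)
            frac = np.where(bridge_up | bridge_lo, 0.5, frac)

        done = idx[absorbed]
        if done.size:
            dt_dec[done] = t_now + frac[absorbed] * dt
            choice[done] = np.where(bound_val[absorbed] >= a / 2.0, 1.0, -1.0)
            x[done] = bound_val[absorbed]
            active[done] = False
        cont = idx[~absorbed]
        x[cont] = np.clip(x_new[~absorbed], 0.0, a)
        if paths is not None:
            snap = paths[-1].copy()
            snap[idx] = np.where(absorbed, bound_val, np.clip(x_new, 0.0, a))
            paths.append(snap)

    flagged = active.copy()
    if flagged.any():
        choice[flagged] = 0.0
    rts = t_s + dt_dec + t_m
    rts[flagged] = np.nan

    traces: list[np.ndarray] = []
    if config.store_traces:
        path_mat = np.stack(paths, axis=1)  # n x steps+1, accumulator value
        for i in range(n):
            if flagged[i]:
                traces.append(np.array([]))
                continue
            n_pre = int(round(t_s[i] / dt))
            n_dec = int(np.ceil(dt_dec[i] / dt))
            n_mot = int(round(t_m[i] / dt))
            # evidence toward the chosen bound, 0 at start, a/2 at threshold
            dec_path = (path_mat[i, : n_dec + 1] - a / 2.0) * choice[i]
            dec_path = np.clip(dec_path, None, a / 2.0)
            dec_path[-1] = a / 2.0
            parts = [np.zeros(n_pre), dec_path]
            if config.hold_during_motor and n_mot > 0:
                parts.append(np.full(n_mot, a / 2.0))
            parts.append(np.zeros(1))
            traces.append(np.concatenate(parts))

    out = DDMTraces(
        traces=traces,
        dt=dt,
        t_stim=t_s,
        decision_time=dt_dec,
        t_motor=t_m,
        condition=np.array([conditions[k] for k in cond_idx]),
        flagged=flagged,
    )
    return out, rts, choice


def mean_first_passage_time(bound: float, drift: float, noise_sd: float) -> float:
    """Closed-form mean decision time for start a/2, absorbing bounds 0 and a.

    ``E[T] = (a/(2v)) · tanh(a v / (2 s²))``; the v → 0 limit is a²/(4s²).
    """
    a, v, s = bound, drift, noise_sd
    if v == 0:
        return a * a / (4.0 * s * s)
    return (a / (2.0 * v)) * np.tanh(a * v / (2.0 * s * s))
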