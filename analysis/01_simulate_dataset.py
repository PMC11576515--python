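"""Simulate the reference synthetic dataset: behaviour + overlap-only EEG.

Generates 4,637 trials of the eight behavioural measures from the
two-construct model, then a smaller continuous-EEG session (400 trials,
stimulus transient only) with its event table, and writes everything under
results/dataset/: behaviour TSV, events TSV, recording bundle, montage, and a
summary of RT structure (RT must fall with value difference and overall
value).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from eegoverlap import (
    BehaviourConfig,
    simulate_recording,
    simulate_trial_measures,
    write_event_table,
    write_montage,
    write_raw_bundle,
)
from eegoverlap.experiments import fast_rt_behaviour, overlap_only_eeg

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    behaviour = BehaviourConfig(seed=SEED)
    measures, latents = simulate_trial_measures(behaviour)
    measures.to_csv(OUT / "behaviour.tsv", sep="\t", index=False)

    ok = measures[measures.responded]
    summary = []
    for col in ("value_difference", "overall_value"):
        bins = pd.qcut(ok[col], 3, labels=["low", "mid", "high"])
        mean_rt = ok.groupby(bins, observed=True)["rt"].mean()
        summary.append(mean_rt.rename(f"mean_rt_by_{col}"))
        print(f"mean RT by {col} tercile:", np.round(mean_rt.to_numpy(), 3))
    pd.concat(summary, axis=1).to_csv(OUT / "rt_by_terciles.tsv", sep="\t")

    eeg_measures, eeg_latents = simulate_trial_measures(fast_rt_behaviour(400, SEED + 1))
    eeg = overlap_only_eeg(SEED + 2)
    recording, events, truth = simulate_recording(eeg_measures, eeg_latents, eeg)
    write_raw_bundle(recording, OUT / "recording")
    write_event_table(events, OUT / "events.tsv")
    write_montage(eeg.channel_labels, eeg.channel_positions, OUT / "montage.tsv")
    print(
        f"recording: {recording.n_channels} channels x {recording.n_samples} samples "
        f"at {recording.srate:.0f} Hz ({recording.duration:.0f} s), "
        f"{len(events)} trials, mean RT {np.nanmean(events.rt):.3f} s"
    )


if __name__ == "__main__":
    main()
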