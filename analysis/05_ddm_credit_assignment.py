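"""Credit assignment of accumulation activity under stimulus/motor jitter.

Simulates drift-diffusion accumulator traces under the three non-decision
jitter scenarios (stim/motor = 0.2/0.1, 0.2/0.2, 0.1/0.2 s), deconvolves
each continuous trace stream with stimulus and response events, and reports
the share of recovered accumulation energy assigned to the stimulus kernel:
as motor variability grows relative to stimulus variability the share moves
toward the stimulus event.  Includes a zero-jitter control.  Report under
results/ddm_assignment/.
"""

from pathlib import Path

from eegoverlap.experiments import DDMAssignmentConfig, run_ddm_assignment

SEED = 51
OUT = Path(__file__).resolve().parent.parent / "results" / "ddm_assignment"


def main() -> None:
    rep = run_ddm_assignment(DDMAssignmentConfig(seed=SEED, out_dir=str(OUT)))
    cols = ["scenario", "stim_jitter", "motor_jitter", "stim_share", "resp_share",
            "strong_weak_contrast_peak", "r_squared"]
    print(rep["scenarios"][cols].round(3).to_string(index=False))
    print(
        f"zero-jitter control: shares sum to "
        f"{sum(rep['zero_jitter_shares'].values()):.6f}, "
        f"reconstruction R² = {rep['zero_jitter_r_squared']:.3f}"
    )
    print("checks:", rep["checks"])


if __name__ == "__main__":
    main()
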