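"""Deconvolution rescue: the spurious response-locked effect disappears.

Simulates eight participants of overlap-only EEG, analyses each twice —
naive response-locked mass-univariate regression with an RT predictor, and
joint stimulus+response FIR deconvolution with the RT covariate on the
response events — then runs the group cluster-mass permutation test on both.
The naive RT contrast is spuriously significant; after deconvolution it is
gone, and the deconvolved stimulus kernel matches the generative one.
Report under results/deconv_rescue/.
"""

from pathlib import Path

from eegoverlap.experiments import DeconvRescueConfig, run_deconv_rescue

SEED = 41
OUT = Path(__file__).resolve().parent.parent / "results" / "deconv_rescue"


def main() -> None:
    rep = run_deconv_rescue(DeconvRescueConfig(seed=SEED, out_dir=str(OUT)))
    print(
        f"naive response-locked RT contrast: {rep['naive_n_significant']} significant "
        f"cluster(s), min p = {rep['naive_min_p']:.3f}"
    )
    print(
        f"after deconvolution: {rep['deconv_n_significant']} significant cluster(s), "
        f"min p = {rep['deconv_min_p']:.3f}"
    )
    print(
        f"stimulus-kernel nRMSE: {rep['stim_kernel_nrmse']:.3f} (default noise), "
        f"{rep['stim_kernel_nrmse_high_snr']:.3f} (high SNR)"
    )
    print(
        f"response intercept kernel peak = "
        f"{rep['response_intercept_peak_ratio_high_snr']:.1%} of stimulus peak; "
        f"naive response-locked average peak = "
        f"{rep['naive_average_peak_ratio_high_snr']:.1%}"
    )
    print("checks:", rep["checks"])


if __name__ == "__main__":
    main()
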