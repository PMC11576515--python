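"""Score the appraisal and choice constructs from the behavioural measures.

Reads results/dataset/behaviour.tsv (run 01_simulate_dataset.py first),
min-max normalizes the eight measures, selects the number of components by
permutation testing (1,000 column shuffles, 95th percentile), fits the
rotated PCA and writes eigenvalue report, rotated loadings and trial scores
under results/constructs/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from eegoverlap import (
    estimate_ncomp_permutation,
    fit_constructs,
    normalize_measures,
)

SEED = 21
ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "constructs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    measures = pd.read_csv(ROOT / "dataset" / "behaviour.tsv", sep="\t")

    X, bounds = normalize_measures(measures)
    n_sig, observed, null = estimate_ncomp_permutation(X, n_perm=1000, seed=SEED)
    crit = np.percentile(null, 95.0, axis=0)
    report = pd.DataFrame(
        {
            "component": np.arange(1, observed.size + 1),
            "eigenvalue": observed,
            "null_95th": crit,
            "significant": observed > crit,
        }
    )
    report.to_csv(OUT / "eigenvalues.tsv", sep="\t", index=False)
    print(f"significant components: {n_sig}")
    print(report.round(4).to_string(index=False))

    model = fit_constructs(measures, n_comp=n_sig)
    loadings = model.loadings_frame().reset_index(names="measure")
    loadings.to_csv(OUT / "loadings.tsv", sep="\t", index=False)
    scores = pd.DataFrame(model.scores, columns=model.labels)
    scores.to_csv(OUT / "scores.tsv", sep="\t", index=False)
    print("\nrotated loadings:")
    print(loadings.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
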