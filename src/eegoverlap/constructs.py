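"""Appraisal/Choice construct scoring by permutation-tested rotated PCA.

The eight trial measures are min–max normalized to [0, 1]; the number of
principal components to retain is chosen by permutation testing (each null
dataset shuffles every column independently, destroying cross-column
structure while preserving marginals; a component is significant when its
observed eigenvalue exceeds the 95th percentile of that component's null
eigenvalue distribution).  Retained components are rotated with
Kaiser-normalized ("normalized") varimax and trial scores are the normalized
indicators multiplied by the rotated loadings.

Component labels follow the loading convention: *appraisal* is the component
with the larger absolute loading on liking, sign-fixed to load positively on
liking; *choice* (difficulty) is sign-fixed to load negatively on confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import MEASURE_NAMES


def normalize_measures(measures: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    """Min–max normalize each measure to [0, 1]; returns (matrix, bounds).

    Raises on constant columns, naming the measure.
    """
    if isinstance(measures, pd.DataFrame):
        cols = [c for c in MEASURE_NAMES if c in measures.columns]
        if cols:
            measures = measures[cols]
        names = list(measures.columns)
        X = measures.to_numpy(dtype=float)
    else:
        X = np.asarray(measures, dtype=float)
        names = [f"m{i}" for i in range(X.shape[1])]
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    constant = np.flatnonzero(span == 0)
    if constant.size:
        raise ValueError(f"constant measure(s): {[names[i] for i in constant]}")
    Xn = (X - lo) / span
    bounds = pd.DataFrame({"measure": names, "min": lo, "max": hi})
    return Xn, bounds


def _eigenvalues(X: np.ndarray, use_correlation: bool) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    if use_correlation:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / sd
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    return np.sort(np.linalg.eigvalsh(cov))[::-1]


def estimate_ncomp_permutation(
    X: np.ndarray,
    n_perm: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
    use_correlation: bool = False,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Permutation test for the number of principal components.

    Returns (n_significant, observed eigenvalues, null eigenvalues of shape
    n_perm × n_measures).  Component k is significant iff its observed
    eigenvalue exceeds the ``percentile`` of the null distribution of
    eigenvalue k.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many rows as columns")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    observed = _eigenvalues(X, use_correlation)
    null = np.empty((n_perm, X.shape[1]))
    work = np.empty_like(X)
    for p in range(n_perm):
        for j in range(X.shape[1]):
            work[:, j] = X[rng.permutation(X.shape[0]), j]
        null[p] = _eigenvalues(work, use_correlation)
    crit = np.percentile(null, percentile, axis=0)
    n_sig = int(np.sum(observed > crit))
    return n_sig, observed, null


def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; with ``normalize``, Kaiser row-normalization.

    Returns (rotated loadings, rotation matrix).  Raises on non-convergence.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    if normalize:
        comm = np.sqrt((L ** 2).sum(axis=1))
        comm[comm == 0] = 1.0
        L = L / comm[:, None]
    R = np.eye(k)
    d = 0.0
    for i in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    else:
        raise RuntimeError(
            f"varimax failed to converge in {max_iter} iterations (criterion {d:.3e})"
        )
    rotated = L @ R
    if normalize:
        rotated = rotated * comm[:, None]
    return rotated, R


@dataclass
class ConstructModel:
    """Fitted construct-scoring model.

    ``loadings`` are measures × retained components after rotation and
    sign/label fixing; ``scores = normalized data @ loadings``.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    labels: list[str]
    measure_names: list[str]
    bounds: pd.DataFrame
    unrotated: np.ndarray
    n_significant: int | None = None

    @property
    def appraisal(self) -> np.ndarray:
        return self.scores[:, self.labels.index("appraisal")]

    @property
    def choice(self) -> np.ndarray:
        return self.scores[:, self.labels.index("choice")]

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loadings, index=self.measure_names, columns=self.labels)


def fit_constructs(
    measures: pd.DataFrame | np.ndarray,
    n_comp: int = 2,
    use_correlation: bool = False,
) -> ConstructModel:
    """PCA + normalized-varimax rotation + score projection on 0–1 measures.

    Components are labelled by the loading convention (appraisal = larger
    |loading| on liking, ties broken by overall value; choice = the other,
    oriented so larger = more difficult, i.e. negative loading on
    confidence).
    """
    if n_comp < 1:
        raise ValueError("n_comp must be >= 1")
    Xn, bounds = normalize_measures(measures)
    names = list(bounds["measure"])
    work = Xn
    if use_correlation:
        work = (Xn - Xn.mean(axis=0)) / Xn.std(axis=0, ddof=1)
    pca = PCA(n_components=min(work.shape), svd_solver="full")
    pca.fit(work)
    eigenvalues = pca.explained_variance_.copy()
    unrotated = pca.components_[:n_comp].T  # measures x n_comp, unit columns
    rotated, _ = varimax(unrotated, normalize=True)

    labels = [f"pc{j + 1}" for j in range(n_comp)]
    if n_comp >= 2 and "liking" in names:
        i_lik = names.index("liking")
        order = np.argsort(-np.abs(rotated[i_lik, :]))
        if "overall_value" in names and np.isclose(
            np.abs(rotated[i_lik, order[0]]), np.abs(rotated[i_lik, order[1]])
        ):
            i_ov = names.index("overall_value")
            order = order[np.argsort(-np.abs(rotated[i_ov, order]))]
        appraisal_col, choice_col = int(order[0]), int(order[1])
        cols = [appraisal_col, choice_col] + [
            j for j in range(n_comp) if j not in (appraisal_col, choice_col)
        ]
        rotated = rotated[:, cols]
        labels = ["appraisal", "choice"] + [f"pc{j + 1}" for j in range(2, n_comp)]
        if rotated[i_lik, 0] < 0:
            rotated[:, 0] *= -1.0
        if "confidence" in names:
            i_conf = names.index("confidence")
            if rotated[i_conf, 1] > 0:
                rotated[:, 1] *= -1.0
    scores = Xn @ rotated
    return ConstructModel(
        eigenvalues=eigenvalues,
        loadings=rotated,
        scores=scores,
        labels=labels,
        measure_names=names,
        bounds=bounds,
        unrotated=unrotated,
    )


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> float:
    """Mean |Tucker congruence| between matched columns of A and B.

    Columns are matched greedily on absolute congruence, so the statistic is
    invariant to column order and sign.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    k = A.shape[1]
    num = A.T @ B
    den = np.sqrt(np.outer((A ** 2).sum(axis=0), (B ** 2).sum(axis=0)))
    C = np.abs(num / den)
    rows = list(range(k))
    cols = list(range(k))
    vals = []
    for _ in range(k):
        sub = C[np.ix_(rows, cols)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        vals.append(sub[i, j])
        rows.pop(i)
        cols.pop(j)
    return float(np.mean(vals))
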