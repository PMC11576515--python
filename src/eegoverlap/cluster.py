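"""Group-level spatiotemporal cluster-mass permutation inference.

Per-participant channel × time maps (first-level t-values or deconvolution
betas) are reduced to a one-sample group t-map; suprathreshold points
(two-tailed cluster-forming threshold, default P = 0.005) are grouped into
clusters of like polarity that are connected through channel adjacency at
the same time point or through temporal contiguity (±1 sample) at the same
channel.  Cluster mass is the sum of absolute t-values.  The null
distribution of the per-polarity maximum cluster mass is built by randomly
sign-flipping whole participants' maps (the standard one-sample permutation
scheme); observed clusters are significant when their mass exceeds the top
2.5% of the corresponding max-mass null, and p-values follow the
inverted-percentile ×2 two-sided rule, floored at 2/n_perm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import AdjacencyGraph

logger = logging.getLogger(__name__)


def group_tmap(maps: np.ndarray) -> tuple[np.ndarray, int]:
    """One-sample t across participants at every point; df = n − 1.

    ``maps`` is participants × channels × time.  Zero-variance points get a
    NaN sentinel (excluded from clustering, logged).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3 or maps.shape[0] < 3:
        raise ValueError("need >= 3 participants of channels x time maps")
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    zero = sd == 0
    nonzero_mean = zero & (mean != 0)
    if np.any(zero & ~ (mean == 0)):
        logger.info("%d zero-variance points flagged and excluded from clustering",
                    int(nonzero_mean.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero] = np.where(mean[zero] == 0, 0.0, np.nan)
    return t, n - 1


@dataclass
class Cluster:
    """Connected suprathreshold set with polarity and mass = Σ|t|."""

    members: list[tuple[int, int]]      # (channel, time) indices
    polarity: int                       # +1 or -1
    mass: float
    p_value: float | None = None
    significant: bool | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    def peak(self, tmap: np.ndarray) -> tuple[int, int]:
        vals = [abs(tmap[c, t]) for c, t in self.members]
        return self.members[int(np.argmax(vals))]


def _neighbor_offsets(adjacency: AdjacencyGraph) -> list[np.ndarray]:
    return [adjacency.neighbors(i) for i in range(adjacency.n_channels)]


def find_clusters(
    tmap: np.ndarray,
    adjacency: AdjacencyGraph,
    threshold_p: float = 0.005,
    df: int = 1,
    include_diagonal: bool = False,
) -> list[Cluster]:
    """Connected components of suprathreshold points, split by polarity.

    Points are connected when they share a time sample and are adjacent
    channels, or share a channel at adjacent time samples (±1); with
    ``include_diagonal`` also adjacent channels at adjacent times.  NaN
    points never enter clusters; opposite polarities never merge.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    n_ch, n_t = tmap.shape
    if adjacency.n_channels != n_ch:
        raise ValueError("adjacency size mismatch")
    crit = stats.t.ppf(1.0 - threshold_p / 2.0, df)
    with np.errstate(invalid="ignore"):
        sign = np.where(tmap > crit, 1, np.where(tmap < -crit, -1, 0))
    sign[~np.isfinite(tmap)] = 0
    neigh = _neighbor_offsets(adjacency)
    visited = np.zeros((n_ch, n_t), dtype=bool)
    clusters: list[Cluster] = []
    supra = np.argwhere(sign != 0)
    for c0, t0 in supra:
        if visited[c0, t0]:
            continue
        pol = sign[c0, t0]
        stack = [(int(c0), int(t0))]
        visited[c0, t0] = True
        members: list[tuple[int, int]] = []
        mass = 0.0
        while stack:
            c, t = stack.pop()
            members.append((c, t))
            mass += abs(tmap[c, t])
            cand: list[tuple[int, int]] = []
            for dt in (-1, 1):
                tt = t + dt
                if 0 <= tt < n_t:
                    cand.append((c, tt))
                    if include_diagonal:
                        cand.extend((int(cc), tt) for cc in neigh[c])
            cand.extend((int(cc), t) for cc in neigh[c])
            for cc, tt in cand:
                if not visited[cc, tt] and sign[cc, tt] == pol:
                    visited[cc, tt] = True
                    stack.append((cc, tt))
        clusters.append(Cluster(members=members, polarity=int(pol), mass=float(mass)))
    clusters.sort(key=lambda cl: -cl.mass)
    return clusters


@dataclass
class ClusterResult:
    """Observed clusters with permutation p-values and max-mass nulls."""

    clusters: list[Cluster]
    tmap: np.ndarray
    df: int
    null_max_mass: dict[int, np.ndarray]   # polarity -> n_perm max masses
    threshold_p: float
    n_perm: int
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def _perm_tmaps(X: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized sign-flip group t-maps.

    ``X`` is participants × points; ``signs`` is n_perm × participants of ±1.
    Because signs square to one, Σx² is permutation-invariant, so only the
    mean changes per permutation.
    """
    n = X.shape[0]
    sumsq = (X ** 2).sum(axis=0)
    mean = signs @ X / n
    var = (sumsq / n - mean ** 2) * (n / (n - 1))
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean / np.sqrt(var / n)


def permutation_pvalues(
    maps: np.ndarray,
    adjacency: AdjacencyGraph,
    threshold_p: float = 0.005,
    n_perm: int = 1000,
    seed: int = 0,
    include_diagonal: bool = False,
) -> ClusterResult:
    """Cluster-mass permutation test by participant sign-flipping.

    Each permutation flips the sign of whole participants' maps, recomputes
    the group t-map and records the maximum cluster mass per polarity (0 when
    no cluster forms).  An observed cluster is significant iff its mass
    exceeds the 97.5th percentile of its polarity's max-mass null; reported
    p = 2 × (fraction of permutation max masses ≥ observed), floored at
    2/n_perm and clipped to 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    floor = 2.0 / n_perm
    if floor > 0.05:
        warnings.warn(f"n_perm={n_perm} floors p at {floor:.3f} > 0.05")
    maps = np.asarray(maps, dtype=float)
    n_sub, n_ch, n_t = maps.shape
    tmap, df = group_tmap(maps)
    observed = find_clusters(tmap, adjacency, threshold_p, df, include_diagonal)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    X = maps.reshape(n_sub, n_ch * n_t)
    null = {1: np.zeros(n_perm), -1: np.zeros(n_perm)}
    chunk = max(1, int(5e6 // max(X.shape[1], 1)))
    for s0 in range(0, n_perm, chunk):
        T = _perm_tmaps(X, signs[s0 : s0 + chunk])
        for k in range(T.shape[0]):
            perm_clusters = find_clusters(
                T[k].reshape(n_ch, n_t), adjacency, threshold_p, df, include_diagonal
            )
            for pol in (1, -1):
                masses = [c.mass for c in perm_clusters if c.polarity == pol]
                null[pol][s0 + k] = max(masses) if masses else 0.0

    for cl in observed:
        dist = null[cl.polarity]
        exceed = int((dist >= cl.mass).sum())
        p = 2.0 * exceed / n_perm
        cl.p_value = float(min(1.0, max(p, floor)))
        cl.significant = cl.mass > np.percentile(dist, 97.5)
    return ClusterResult(
        clusters=observed,
        tmap=tmap,
        df=df,
        null_max_mass=null,
        threshold_p=threshold_p,
        n_perm=n_perm,
        seed=seed,
        params={"include_diagonal": include_diagonal, "scheme": "participant sign-flip"},
    )
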