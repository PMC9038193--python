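"""Spatial-bias statistics for cache/check location distributions.

Covers the entropy test against a uniform null, split-half within- versus
across-bird correlations, PCA plus 2-means clustering of smoothed bias
maps, and the lag-stability regression. Bias maps live on the cache-site
grid (feeders carry no cache/check mass); entropy is therefore bounded by
log2(64) = 6 bits in the reference arena.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .arena import ArenaGeometry
from .choice import BiasDistribution, compute_pbias
from .events import BirdDataset
from .state import compute_mask, derive_state


def plot_bias_map(p_cache_sites, arena: ArenaGeometry, path, title=None):
    """Write a heatmap of a cache-site bias map to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows, cols = arena.grid_shape
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(
        np.asarray(p_cache_sites, float).reshape(rows, cols),
        origin="lower", cmap="viridis",
    )
    fig.colorbar(im, ax=ax, fraction=0.046, label="probability")
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def entropy(pbias) -> float:
    """Shannon entropy of a probability vector, in bits (0 log 0 = 0)."""
    p = pbias.p if isinstance(pbias, BiasDistribution) else np.asarray(pbias, float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("probability vector sums to zero")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def entropy_null_test(
    observed_entropy: float,
    n_events: int,
    n_sites: int = 64,
    n_sim: int = 10000,
    seed: int | None = 0,
) -> float:
    """p-value of an observed entropy against a uniform-sampling null.

    Draws ``n_sim`` multinomial samples of ``n_events`` events from a
    uniform distribution over ``n_sites`` sites and returns the fraction
    of simulated entropies at or below the observed value.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, np.full(n_sites, 1.0 / n_sites), size=n_sim)
    p = counts / n_events
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    sims = -(p * logs).sum(axis=1)
    return float(np.mean(sims <= observed_entropy))


# ---------------------------------------------------------------------------
# bias maps
# ---------------------------------------------------------------------------

def _gauss3x3(sigma_sites: float = 1.0) -> np.ndarray:
    off = np.arange(-1, 2)
    k = np.exp(-(off[:, None] ** 2 + off[None, :] ** 2) / (2 * sigma_sites**2))
    return k / k.sum()


def smooth_bias_map(p_cache_sites: np.ndarray, arena: ArenaGeometry) -> np.ndarray:
    """3x3 Gaussian smoothing (sigma = one site pitch) of a grid bias map.

    The window is truncated and renormalized at arena edges so mass is
    conserved locally. Input and output are length-64 vectors over cache
    sites in grid order.
    """
    rows, cols = arena.grid_shape
    grid = np.asarray(p_cache_sites, float).reshape(rows, cols)
    kernel = _gauss3x3()
    num = ndimage.convolve(grid, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(grid), kernel, mode="constant", cval=0.0)
    return (num / den).ravel()


def bias_map(
    dataset: BirdDataset, arena: ArenaGeometry, mask_label: str = "caches_caching"
) -> np.ndarray:
    """Per-bird bias over the 64 cache sites (feeders dropped, renormalized)."""
    st = derive_state(dataset, arena)
    mask = compute_mask(dataset, st, mask_label)
    pb = compute_pbias(dataset, mask, arena.n_sites)
    p = pb.p[arena.cache_sites]
    return p / p.sum()


def _session_map(
    dataset: BirdDataset, sessions, arena: ArenaGeometry, mask_label: str
) -> np.ndarray | None:
    sub = dataset.subset_sessions(sessions)
    if sub.n_events == 0:
        return None
    st = derive_state(sub, arena)
    mask = compute_mask(sub, st, mask_label)
    if not mask.G.any():
        return None
    p = compute_pbias(sub, mask, arena.n_sites).p[arena.cache_sites]
    return p / p.sum()


# ---------------------------------------------------------------------------
# split-half correlations
# ---------------------------------------------------------------------------

@dataclass
class SplitHalfResult:
    within_corr: float           # median across birds, averaged over splits
    per_bird_corr: dict[str, float]
    null_medians: np.ndarray     # across-bird medians from identity shuffles
    p_value: float               # fraction of shuffled medians >= observed
    excluded: list[str]


def _pearson(a, b) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def splithalf_correlations(
    datasets: list[BirdDataset],
    arena: ArenaGeometry,
    mask_label: str = "caches_caching",
    n_shuffle: int = 1000,
    n_splits: int = 20,
    seed: int | None = 0,
    clusters: dict[str, int] | None = None,
) -> SplitHalfResult:
    """Within- versus across-bird similarity of spatial biases.

    Each bird's sessions are split into two near-equal groups; the Pearson
    correlation between the two half-biases (over the 64 cache sites) is
    the within-bird statistic. The across-bird null shuffles bird
    identities between the halves; when per-bird cluster labels are given,
    a bird may only take the identity of a bird in the same cluster.
    """
    rng = np.random.default_rng(seed)
    usable, excluded = [], []
    for ds in datasets:
        if ds.n_sessions < 2:
            import warnings

            warnings.warn(f"bird {ds.bird} has one session; excluded from split-half")
            excluded.append(ds.bird)
        else:
            usable.append(ds)
    if len(usable) < 2:
        raise ValueError("need at least two birds with >= 2 sessions")

    halves = []  # per split: (A-maps, B-maps) arrays of shape (B, 64)
    for _ in range(n_splits):
        A_maps, B_maps = [], []
        for ds in usable:
            sessions = rng.permutation(ds.sessions)
            half = len(sessions) // 2
            a = _session_map(ds, sessions[:half], arena, mask_label)
            b = _session_map(ds, sessions[half:], arena, mask_label)
            A_maps.append(a)
            B_maps.append(b)
        halves.append((np.array(A_maps), np.array(B_maps)))

    birds = [ds.bird for ds in usable]
    per_bird = {
        bird: float(
            np.mean([_pearson(A[i], Bm[i]) for A, Bm in halves])
        )
        for i, bird in enumerate(birds)
    }
    within = float(np.median(list(per_bird.values())))

    # identity shuffles (within-cluster if requested)
    B = len(usable)
    groups = [np.arange(B)]
    if clusters is not None:
        labels = np.array([clusters[b] for b in birds])
        groups = [np.flatnonzero(labels == v) for v in np.unique(labels)]
    null = np.empty(n_shuffle)
    for k in range(n_shuffle):
        perm = np.arange(B)
        for g in groups:
            perm[g] = rng.permutation(perm[g])
        A, Bm = halves[rng.integers(len(halves))]
        null[k] = np.median([_pearson(A[i], Bm[perm[i]]) for i in range(B)])
    p = float(np.mean(null >= within))
    return SplitHalfResult(within, per_bird, null, p, excluded)


# ---------------------------------------------------------------------------
# PCA + clustering
# ---------------------------------------------------------------------------

@dataclass
class PCClusterResult:
    coefficients: np.ndarray     # (B, n_components) PC scores per bird
    components: np.ndarray       # (n_components, 64) PC maps
    variance_explained: np.ndarray
    labels: np.ndarray           # cluster label per bird (0 = center-preferring)
    degenerate: bool


def pc_clustering(
    pbias_matrix: np.ndarray,
    arena: ArenaGeometry,
    n_components: int = 2,
    n_clusters: int = 2,
    seed: int | None = 0,
) -> PCClusterResult:
    """Principal components and 2-means clusters of smoothed bias maps.

    Maps are smoothed with the 3x3 Gaussian window before PCA. Cluster
    labels are ordered by the mean map's center-of-mass distance from the
    arena center, so label 0 is the center-preferring group.
    """
    X = np.asarray(pbias_matrix, float)
    if X.shape[0] < max(n_components, n_clusters):
        raise ValueError("fewer birds than components/clusters requested")
    Xs = np.array([smooth_bias_map(row, arena) for row in X])
    if np.allclose(Xs.var(axis=0), 0):
        return PCClusterResult(
            np.zeros((X.shape[0], n_components)),
            np.zeros((n_components, X.shape[1])),
            np.zeros(n_components),
            np.zeros(X.shape[0], dtype=int),
            degenerate=True,
        )
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(Xs)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(scores[:, :1])
    # order labels by distance of the cluster-mean map's mass from center
    locs = arena.locations[arena.cache_sites]
    r = np.linalg.norm(locs, axis=1)
    spread = [
        float((Xs[labels == v].mean(axis=0) * r).sum())
        for v in range(n_clusters)
    ]
    order = np.argsort(spread)
    relabel = np.empty(n_clusters, dtype=int)
    relabel[order] = np.arange(n_clusters)
    return PCClusterResult(
        scores, pca.components_, pca.explained_variance_ratio_,
        relabel[labels], degenerate=False,
    )


# ---------------------------------------------------------------------------
# lag stability
# ---------------------------------------------------------------------------

@dataclass
class LagStabilityResult:
    lags: np.ndarray
    curve: np.ndarray       # median across birds of per-bird median correlation
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    p_value: float          # two-sided bootstrap p for slope != 0


def _per_bird_lag_curve(maps: list[np.ndarray], max_lag: int) -> np.ndarray:
    out = np.full(max_lag, np.nan)
    n = len(maps)
    for lag in range(1, max_lag + 1):
        vals = [
            _pearson(maps[i], maps[i + lag])
            for i in range(n - lag)
        ]
        if vals:
            out[lag - 1] = np.median(vals)
    return out


def lag_stability(
    datasets: list[BirdDataset],
    arena: ArenaGeometry,
    mask_label: str = "caches_caching",
    max_lag: int | None = None,
    min_pairs: int = 2,
    min_birds: int = 5,
    lag_cap: int = 8,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> LagStabilityResult:
    """Drift of the spatial bias across sessions.

    Per-session bias maps (smoothed) are correlated at session lags 1..N;
    N is the largest lag with at least ``min_pairs`` session pairs in at
    least ``min_birds`` birds, capped at ``lag_cap``. A line is regressed
    on the median curve; its slope CI and two-sided p come from
    bootstrapping birds.
    """
    rng = np.random.default_rng(seed)
    per_bird_maps = []
    for ds in datasets:
        maps = []
        for s in ds.sessions:
            m = _session_map(ds, [s], arena, mask_label)
            if m is not None:
                maps.append(smooth_bias_map(m, arena))
        per_bird_maps.append(maps)

    if max_lag is None:
        counts = np.zeros(lag_cap, dtype=int)
        for lag in range(1, lag_cap + 1):
            counts[lag - 1] = sum(
                1 for maps in per_bird_maps if len(maps) - lag >= min_pairs
            )
        valid = np.flatnonzero(counts >= min(min_birds, len(datasets)))
        if valid.size == 0:
            raise ValueError("no session lag has enough pairs across birds")
        max_lag = int(valid[-1]) + 1
    if max_lag < 2:
        raise ValueError("need at least two lags for the stability regression")

    lags = np.arange(1, max_lag + 1)

    def curve_and_slope(maps_list):
        curves = np.array(
            [_per_bird_lag_curve(m, max_lag) for m in maps_list if len(m) >= 2]
        )
        curve = np.nanmedian(curves, axis=0)
        ok = np.isfinite(curve)
        slope, intercept = np.polyfit(lags[ok], curve[ok], 1)
        return curve, float(slope), float(intercept)

    curve, slope, intercept = curve_and_slope(per_bird_maps)
    B = len(per_bird_maps)
    boot = np.empty(n_boot)
    for k in range(n_boot):
        sample = rng.integers(0, B, size=B)
        try:
            _, s, _ = curve_and_slope([per_bird_maps[b] for b in sample])
        except (TypeError, np.linalg.LinAlgError):
            s = np.nan
        boot[k] = s
    boot = boot[np.isfinite(boot)]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    p = 2.0 * min(np.mean(boot <= 0), np.mean(boot >= 0))
    return LagStabilityResult(
        lags, curve, slope, intercept, (float(lo), float(hi)), float(min(p, 1.0))
    )
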