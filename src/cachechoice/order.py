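"""Retrieval-order analysis and model-free diagnostics.

The order analysis asks whether the order in which seeds are cached
predicts the order of their retrieval (primacy/recency), against a null
in which each retrieval picks uniformly among the caches available at
that moment. Transient caches — caches retrieved immediately, with no
intervening interaction elsewhere — can be excluded, since they trivially
inflate the order-1 recency fraction.

The diagnostics are model-free counterparts of the fitted effects:
distance-to-previous-site and distance-from-occupied-sites profiles
against bias-only expectations, checks-to-find-cache against a
trajectory shuffle, and the fraction of caches into empty sites among
long-unchecked sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .arena import ArenaGeometry
from .choice import compute_pbias
from .events import BirdDataset
from .state import compute_mask, derive_state


def transient_caches(dataset: BirdDataset) -> np.ndarray:
    """Flags caches that are retrieved by the immediately next interaction
    at the same site (the bird never leaves the perch)."""
    ev = dataset.events
    deltas = ev["delta"].to_numpy()
    sites = ev["site"].to_numpy()
    trials = ev["trial"].to_numpy()
    flags = np.zeros(len(ev), dtype=bool)
    if len(ev) > 1:
        flags[:-1] = (
            (deltas[:-1] > 0)
            & (deltas[1:] < 0)
            & (sites[:-1] == sites[1:])
            & (trials[:-1] == trials[1:])
        )
    return flags


@dataclass
class OrderAnalysis:
    align: str
    orders: np.ndarray           # 1..K
    observed: np.ndarray         # fraction of retrievals at each order
    null_mean: np.ndarray
    null_low: np.ndarray         # 2.5th percentile
    null_high: np.ndarray        # 97.5th percentile
    significant: np.ndarray      # observed outside the 95% CI
    n_retrievals: int


def _cache_retrieval_sequence(dataset: BirdDataset, exclude_transient: bool):
    """Ordered (kind, site, trial) tuples of tracked caches and retrievals.

    Uses the derived state so withdrawals of carried-over seeds are not
    counted as retrievals.
    """
    from .arena import default_arena

    ev = dataset.events
    deltas = ev["delta"].to_numpy()
    sites = ev["site"].to_numpy()
    trials = ev["trial"].to_numpy()
    # a site index may exceed the default arena: build a minimal arena mask
    n_sites = int(sites.max()) + 1 if len(sites) else 1
    drop = np.zeros(len(ev), dtype=bool)
    if exclude_transient:
        tr = transient_caches(dataset)
        drop |= tr
        drop[1:] |= tr[:-1]  # the paired immediate retrieval
    seq = []
    occupied: dict = {}
    for i in range(len(ev)):
        if drop[i]:
            continue
        s, d, r = int(sites[i]), int(deltas[i]), int(trials[i])
        if d > 0:
            seq.append(("cache", s, r, i))
        elif d < 0 and occupied.get((r, s), 0) > 0:
            seq.append(("retrieval", s, r, i))
        if d > 0:
            occupied[(r, s)] = occupied.get((r, s), 0) + 1
        elif d < 0:
            occupied[(r, s)] = max(occupied.get((r, s), 0) - 1, 0)
    return seq


def _orders_for_sequence(seq, chooser=None, rng=None):
    """Retrieval orders for a cache/retrieval sequence.

    ``chooser`` None replays the observed choices; "random" picks
    uniformly among available caches at each retrieval (the null).
    Returns (first-aligned orders, recent-aligned orders).
    """
    available: dict[int, list[int]] = {}  # trial -> list of cache serials
    serial = 0
    site_of: dict[int, int] = {}
    site_stack: dict[tuple, list[int]] = {}
    first_orders, recent_orders = [], []
    for kind, s, r, _ in seq:
        if kind == "cache":
            available.setdefault(r, []).append(serial)
            site_stack.setdefault((r, s), []).append(serial)
            site_of[serial] = s
            serial += 1
        else:
            avail = available.get(r, [])
            if not avail:
                continue
            if chooser == "random":
                pick = int(rng.integers(len(avail)))
            else:
                stack = site_stack.get((r, s), [])
                if not stack:
                    continue
                pick = avail.index(stack[-1])
            chosen = avail.pop(pick)
            stack = site_stack.get((r, site_of[chosen]), [])
            if chosen in stack:
                stack.remove(chosen)
            # order among the caches that were available, by caching order
            first_orders.append(pick + 1)
            recent_orders.append(len(avail) + 1 - pick)
    return first_orders, recent_orders


def retrieval_order(
    dataset: BirdDataset,
    align: str = "recent",
    exclude_transient: bool = False,
    n_sim: int = 1000,
    seed: int | None = 0,
) -> OrderAnalysis:
    """Fraction of retrievals by cache order, against a random-order null.

    ``align="first"`` ranks available caches oldest-first (order 1 = the
    first cache still available); ``align="recent"`` ranks newest-first.
    The null replays the same cache schedule, choosing uniformly among the
    currently available caches at each retrieval.
    """
    if align not in ("first", "recent"):
        raise ValueError("align must be 'first' or 'recent'")
    seq = _cache_retrieval_sequence(dataset, exclude_transient)
    obs_first, obs_recent = _orders_for_sequence(seq)
    obs = obs_first if align == "first" else obs_recent
    if not obs:
        raise ValueError("no retrievals of tracked caches in dataset")
    K = max(obs)
    rng = np.random.default_rng(seed)
    null_fracs = []
    for _ in range(n_sim):
        nf, nr = _orders_for_sequence(seq, chooser="random", rng=rng)
        vals = nf if align == "first" else nr
        K = max(K, max(vals) if vals else 1)
        null_fracs.append(vals)
    obs_frac = np.bincount(obs, minlength=K + 1)[1:] / len(obs)
    null_mat = np.array(
        [
            np.bincount(v, minlength=K + 1)[1:] / max(len(v), 1)
            for v in null_fracs
        ]
    )
    lo, hi = np.percentile(null_mat, [2.5, 97.5], axis=0)
    return OrderAnalysis(
        align=align,
        orders=np.arange(1, K + 1),
        observed=obs_frac,
        null_mean=null_mat.mean(axis=0),
        null_low=lo,
        null_high=hi,
        significant=(obs_frac < lo) | (obs_frac > hi),
        n_retrievals=len(obs),
    )


# ---------------------------------------------------------------------------
# checks to find a cache
# ---------------------------------------------------------------------------

@dataclass
class ChecksToFindResult:
    observed_counts: np.ndarray   # per-trial checks up to and incl. the find
    shuffled_counts: np.ndarray   # pooled over shuffles (nan = never found)
    observed_mean: float
    observed_sd: float
    shuffled_mean: float
    shuffled_sd: float
    observed_median: float
    shuffled_median: float
    observed_found_fraction: float
    shuffled_found_fraction: float


def checks_to_find_cache(
    dataset: BirdDataset,
    arena: ArenaGeometry,
    n_shuffle: int = 100,
    seed: int | None = 0,
) -> ChecksToFindResult:
    """Checks needed to find a cache, versus trajectory-shuffled trials.

    For each Retrieval-task trial the observed count is the number of
    feeder-closed checks up to and including the first check of an
    occupied site. The null reassigns each trial's ordered check sequence
    to another trial's cache configuration (within bird) and recounts.
    Because a trial's recorded sequence ends soon after its own caches are
    retrieved, a foreign configuration may never be visited at all; such
    pairs are recorded as missing and excluded from the summaries, with
    the found fractions reported alongside.
    """
    st = derive_state(dataset, arena)
    ev = dataset.events
    phases = ev["phase"].to_numpy()
    sites = ev["site"].to_numpy()
    trials = ev["trial"].to_numpy()

    sequences, configs = [], []
    for r in np.unique(trials):
        in_trial = trials == r
        closed = in_trial & (phases == 2)
        if not closed.any():
            continue
        first = np.flatnonzero(closed)[0]
        config = set(np.flatnonzero(st.occupancy[first]))
        if not config:
            continue
        sequences.append(sites[closed])
        configs.append(config)
    if not sequences:
        raise ValueError("no complete feeder-closed trials with caches")

    def count(seqd, config):
        for k, s in enumerate(seqd):
            if s in config:
                return float(k + 1)
        return np.nan

    observed = np.array([count(q, c) for q, c in zip(sequences, configs)])
    rng = np.random.default_rng(seed)
    n = len(sequences)
    shuffled = []
    for _ in range(n_shuffle):
        perm = rng.permutation(n)
        shuffled.extend(count(sequences[i], configs[perm[i]]) for i in range(n))
    shuffled = np.array(shuffled)
    obs_ok = observed[np.isfinite(observed)]
    shf_ok = shuffled[np.isfinite(shuffled)]
    return ChecksToFindResult(
        observed, shuffled,
        float(obs_ok.mean()) if obs_ok.size else np.nan,
        float(obs_ok.std(ddof=1)) if obs_ok.size > 1 else 0.0,
        float(shf_ok.mean()) if shf_ok.size else np.nan,
        float(shf_ok.std(ddof=1)) if shf_ok.size > 1 else 0.0,
        float(np.median(obs_ok)) if obs_ok.size else np.nan,
        float(np.median(shf_ok)) if shf_ok.size else np.nan,
        float(np.isfinite(observed).mean()),
        float(np.isfinite(shuffled).mean()),
    )


# ---------------------------------------------------------------------------
# distance profiles
# ---------------------------------------------------------------------------

@dataclass
class DistanceProfile:
    observed: np.ndarray         # one distance per masked event, cm
    expected: np.ndarray         # pooled bias-draw expectation (distances)
    expected_weights: np.ndarray
    observed_median: float
    expected_median: float


def distance_profiles(
    dataset: BirdDataset,
    arena: ArenaGeometry,
    reference: str = "previous",
    mask_label: str = "caches_caching",
) -> DistanceProfile:
    """Observed versus bias-expected distances of events to special places.

    ``reference="previous"`` measures the distance from each masked event
    to the previous interaction site; ``"occupied"`` measures the minimum
    distance to any occupied site. The expectation replaces each observed
    choice with the bird's bias distribution (all other state unchanged)
    and pools the implied distance distribution over events.
    """
    if reference not in ("previous", "occupied"):
        raise ValueError("reference must be 'previous' or 'occupied'")
    st = derive_state(dataset, arena)
    mask = compute_mask(dataset, st, mask_label)
    pb = compute_pbias(dataset, mask, arena.n_sites)
    D = arena.distance_matrix()
    sites = dataset.events["site"].to_numpy()

    obs, exp_d, exp_w = [], [], []
    for i in np.flatnonzero(mask.H):
        if reference == "previous":
            ref = st.prev_site[i]
            if ref < 0:
                continue
            dist_to_ref = D[:, ref]
        else:
            occ = np.flatnonzero(st.occupancy[i])
            if occ.size == 0:
                continue
            dist_to_ref = D[:, occ].min(axis=1)
        obs.append(dist_to_ref[sites[i]])
        exp_d.append(dist_to_ref)
        exp_w.append(pb.p)
    if not obs:
        # degenerate but well-defined: no qualifying events
        empty = np.array([])
        return DistanceProfile(empty, empty, empty, np.nan, np.nan)
    expected = np.concatenate(exp_d)
    weights = np.concatenate(exp_w)
    weights = weights / weights.sum()
    order = np.argsort(expected)
    cdf = np.cumsum(weights[order])
    exp_median = float(expected[order][np.searchsorted(cdf, 0.5)])
    return DistanceProfile(
        np.array(obs), expected, weights, float(np.median(obs)), exp_median
    )


# ---------------------------------------------------------------------------
# caching into long-unchecked empty sites
# ---------------------------------------------------------------------------

@dataclass
class UncheckedEmptyResult:
    min_gap_s: float
    n_caches: int
    n_into_empty: int
    fraction: float
    chance: float                # occupancy-derived chance level
    p_value: float               # binomial, one-sided above chance


def unchecked_empty_caching(
    dataset: BirdDataset,
    arena: ArenaGeometry,
    min_gap: float = 1800.0,
) -> UncheckedEmptyResult:
    """Do caches still avoid occupied sites among long-unchecked sites?

    Considers Caching-task caches whose chosen site the bird *has* seen
    this session but not for at least ``min_gap`` seconds — sites whose
    contents the bird once knew and has had ample time to forget. The
    fraction landing on empty sites is compared against the chance level
    implied by the instantaneous occupancy of the long-unchecked site
    pool. Never-visited sites are excluded (the bird has no knowledge to
    retain about them).
    """
    st = derive_state(dataset, arena)
    ev = dataset.events
    phases = ev["phase"].to_numpy()
    deltas = ev["delta"].to_numpy()
    sites = ev["site"].to_numpy()
    cache_sites = arena.is_cache_site

    n_caches = n_empty = 0
    chance_sum = 0.0
    for i in np.flatnonzero((phases == 0) & (deltas > 0)):
        s = sites[i]
        t = st.time_since[i, s]
        if not np.isfinite(t) or t < min_gap:
            continue
        pool = (
            cache_sites
            & np.isfinite(st.time_since[i])
            & (st.time_since[i] >= min_gap)
        )
        if not pool.any():
            continue
        n_caches += 1
        n_empty += int(st.occupancy[i, s] == 0)
        chance_sum += 1.0 - st.occupancy[i, pool].mean()
    if n_caches == 0:
        warnings.warn(f"no caches into sites unchecked for >= {min_gap} s")
        return UncheckedEmptyResult(min_gap, 0, 0, np.nan, np.nan, np.nan)
    chance = chance_sum / n_caches
    chance = min(max(chance, 1e-12), 1 - 1e-12)
    p = float(
        stats.binomtest(n_empty, n_caches, chance, alternative="greater").pvalue
    )
    return UncheckedEmptyResult(
        min_gap, n_caches, n_empty, n_empty / n_caches, chance, p
    )
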