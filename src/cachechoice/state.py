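"""Arena state immediately preceding each interaction, and interaction masks.

For every event i and site s the derived state records occupancy n[i, s],
time since the bird's last interaction with s in the current trial t[i, s]
(+inf if none), checked-empty flags c[i, s], recache flags n_r[i, s], the
totals N[i] and C[i] over cache sites, the previous-site pointer, and the
next-seed-action flag mu[i]. All quantities describe the instant *before*
the event is applied.

Cache sites are treated as empty at the start of every trial. Seeds left
over from an earlier trial are ignored: their withdrawal is not a
retrieval (the event is flagged ``excluded_retrieval``), but a later
re-placement of the seed counts as a cache.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import ArenaGeometry
from .events import BirdDataset

MASK_LABELS = (
    "caches_caching",
    "first_checks_caching",
    "checks_closed",
    "checks_until_find",
    "first_checks_closed",
)


class StateConsistencyError(ValueError):
    """Raised when the event log contradicts the occupancy bookkeeping."""


@dataclass
class DerivedState:
    """Per-event, per-site behavioral state of the arena (see module doc)."""

    occupancy: np.ndarray       # (I, S) 0/1, cache sites only
    total_occupancy: np.ndarray  # (I,) N
    time_since: np.ndarray      # (I, S) seconds, +inf if no interaction this trial
    checked_empty: np.ndarray   # (I, S) 0/1
    total_checked_empty: np.ndarray  # (I,) C
    recache: np.ndarray         # (I, S) 0/1, recache[i] <= occupancy[i]
    mu: np.ndarray              # (I,) next-seed-action-is-cache flag
    prev_site: np.ndarray       # (I,) site index, -1 if none this session
    excluded_retrieval: np.ndarray  # (I,) withdrawals of carried-over seeds
    found_cache_before: np.ndarray  # (I,) any earlier event this trial hit an
    # occupied site (state cumsum of n[j, s_j] over the trial, > 0)

    @property
    def n_events(self) -> int:
        return self.occupancy.shape[0]


@dataclass
class InteractionMask:
    """Indicator pair (G, H) selecting a subset of one bird's interactions.

    G selects the task-level subset that defines the baseline distribution
    p_bias; H selects the events that enter the likelihood.
    """

    label: str
    G: np.ndarray
    H: np.ndarray


def derive_state(dataset: BirdDataset, arena: ArenaGeometry) -> DerivedState:
    """Replay the event log and record the arena state before each event."""
    ev = dataset.events
    I, S = len(ev), arena.n_sites
    sites = ev["site"].to_numpy()
    deltas = ev["delta"].to_numpy()
    times = ev["time"].to_numpy()
    trials = ev["trial"].to_numpy()
    phases = ev["phase"].to_numpy()
    sess = ev["session"].to_numpy()
    is_cache_site = arena.is_cache_site

    occupancy = np.zeros((I, S), dtype=np.uint8)
    time_since = np.full((I, S), np.inf)
    checked_empty = np.zeros((I, S), dtype=np.uint8)
    recache = np.zeros((I, S), dtype=np.uint8)
    prev_site = np.full(I, -1, dtype=int)
    excluded = np.zeros(I, dtype=bool)
    found_before = np.zeros(I, dtype=bool)

    # running state
    model_count = np.zeros(S, dtype=int)      # seeds tracked by the analysis
    physical_count = np.zeros(S, dtype=int)   # seeds physically present
    last_time = np.full(S, np.nan)            # last interaction this trial
    checked = np.zeros(S, dtype=bool)         # checked this trial
    last_cache_recache = np.zeros(S, dtype=bool)
    cur_trial = cur_sess = None
    prev = -1
    found = 0

    for i in range(I):
        s, d, t = sites[i], deltas[i], times[i]
        if sess[i] != cur_sess:
            cur_sess = sess[i]
            physical_count[:] = 0  # arena reset between sessions
            prev = -1
        if trials[i] != cur_trial:
            cur_trial = trials[i]
            model_count[:] = 0
            last_time[:] = np.nan
            checked[:] = False
            last_cache_recache[:] = False
            found = 0

        # ---- record state immediately before event i ----
        occ = model_count > 0
        occupancy[i] = occ
        seen = ~np.isnan(last_time)
        time_since[i, seen] = t - last_time[seen]
        checked_empty[i] = checked & ~occ & is_cache_site
        recache[i] = occ & last_cache_recache
        prev_site[i] = prev
        found_before[i] = found > 0
        found += int(occ[s])

        # ---- apply event i ----
        if is_cache_site[s]:
            if d > 0:
                model_count[s] += d
                physical_count[s] += d
                last_cache_recache[s] = phases[i] == 2
            elif d < 0:
                if physical_count[s] + d < 0:
                    raise StateConsistencyError(
                        f"bird {dataset.bird}: retrieval at empty site {s} "
                        f"(event {i}, t={t:.1f}s)"
                    )
                physical_count[s] += d
                if model_count[s] == 0:
                    excluded[i] = True  # carried-over seed: not a retrieval
                else:
                    model_count[s] = max(model_count[s] + d, 0)
            checked[s] = True
            last_time[s] = t
        else:  # feeder: retrievals only, never occupied/checked-empty
            last_time[s] = t
        prev = s

    total_occ = occupancy[:, is_cache_site].sum(axis=1).astype(np.int64)
    total_ce = checked_empty.sum(axis=1).astype(np.int64)

    # mu: the next seed-involving event in the trial, counting from the
    # event itself, is a cache (the state is defined at the instant before
    # event i, so event i is in its own future)
    mu = np.zeros(I, dtype=np.uint8)
    next_sign = 0
    for i in range(I - 1, -1, -1):
        if i < I - 1 and trials[i] != trials[i + 1]:
            next_sign = 0
        if deltas[i] != 0:
            next_sign = np.sign(deltas[i])
        mu[i] = 1 if next_sign > 0 else 0

    return DerivedState(
        occupancy=occupancy,
        total_occupancy=total_occ,
        time_since=time_since,
        checked_empty=checked_empty,
        total_checked_empty=total_ce,
        recache=recache,
        mu=mu,
        prev_site=prev_site,
        excluded_retrieval=excluded,
        found_cache_before=found_before,
    )


def compute_mask(
    dataset: BirdDataset, state: DerivedState, subset_label: str
) -> InteractionMask:
    """Indicator masks (G, H) for the five canonical interaction subsets.

    - ``caches_caching``: all caches in the Caching task.
    - ``first_checks_caching``: the first check after retrieving each seed
      that is subsequently cached.
    - ``checks_closed``: all checks in the feeder-closed phase.
    - ``checks_until_find``: feeder-closed checks up to and including the
      first check of an occupied site (all of them if none is found).
    - ``first_checks_closed``: the first check of each feeder-closed phase.
    """
    ev = dataset.events
    phases = ev["phase"].to_numpy()
    deltas = ev["delta"].to_numpy()
    prev_delta = np.concatenate([[0], deltas[:-1]])
    prev_phase = np.concatenate([[-1], phases[:-1]])

    if subset_label == "caches_caching":
        G = (phases == 0) & (deltas > 0)
        H = G.copy()
    elif subset_label == "first_checks_caching":
        G = (phases == 0) & (deltas > 0)
        H = (phases == 0) & (prev_delta < 0) & (state.mu == 1)
    elif subset_label == "checks_closed":
        G = phases == 2
        H = G.copy()
    elif subset_label == "checks_until_find":
        G = phases == 2
        H = (phases == 2) & ~state.found_cache_before
    elif subset_label == "first_checks_closed":
        G = phases == 2
        H = (phases == 2) & (prev_phase == 1)
    else:
        raise ValueError(
            f"unknown subset label {subset_label!r}; expected one of {MASK_LABELS}"
        )
    return InteractionMask(subset_label, G.astype(bool), H.astype(bool))
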