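"""Derived arena state and interaction masks."""

import numpy as np
import pytest

from cachechoice import compute_mask, derive_state
from cachechoice.state import MASK_LABELS, StateConsistencyError

from conftest import make_dataset


class TestDerivedState:
    def test_trial_start_is_empty(self, toy_dataset, arena):
        st = derive_state(toy_dataset, arena)
        assert st.occupancy[0].sum() == 0
        assert st.total_checked_empty[0] == 0
        assert st.prev_site[0] == -1

    def test_hand_simulated_sequence(self, arena):
        # cache@3, check@5, retrieve@3: before the third event the arena
        # holds one seed (site 3) and one checked-empty site (site 5)
        ds = make_dataset(
            [(0, 0, 0, 1.0, 3, 1), (0, 0, 0, 2.0, 5, 0), (0, 0, 0, 3.0, 3, -1)]
        )
        st = derive_state(ds, arena)
        i = 2
        assert st.occupancy[i, 3] == 1
        assert st.checked_empty[i, 5] == 1
        assert st.total_occupancy[i] == 1
        assert st.total_checked_empty[i] == 1
        assert st.prev_site[i] == 5
        assert st.time_since[i, 3] == pytest.approx(2.0)
        assert st.time_since[i, 5] == pytest.approx(1.0)
        assert np.isinf(st.time_since[i, 7])

    def test_carried_over_seed_ignored(self, arena):
        # seed cached in trial 0 is withdrawn in trial 1 (not a retrieval)
        # and re-placed (a cache)
        ds = make_dataset(
            [
                (0, 0, 1, 1.0, 3, 1),
                (0, 1, 1, 10.0, 3, -1),   # carried-over withdrawal
                (0, 1, 1, 12.0, 4, 1),    # re-placement counts as a cache
            ]
        )
        st = derive_state(ds, arena)
        assert st.excluded_retrieval.tolist() == [False, True, False]
        assert st.occupancy[1, 3] == 0  # empty at trial start despite the seed

    def test_retrieval_at_truly_empty_site_errors(self, arena):
        ds = make_dataset([(0, 0, 0, 1.0, 3, -1)])
        with pytest.raises(StateConsistencyError, match="empty site"):
            derive_state(ds, arena)

    def test_checked_empty_requires_vacancy(self, caching_bird, arena):
        st = derive_state(caching_bird, arena)
        assert not np.any(st.checked_empty & st.occupancy)
        assert np.all(st.recache <= st.occupancy)

    def test_totals_consistent(self, caching_bird, arena):
        st = derive_state(caching_bird, arena)
        cs = arena.is_cache_site
        assert np.array_equal(
            st.total_occupancy, st.occupancy[:, cs].sum(axis=1)
        )
        assert np.array_equal(
            st.total_checked_empty, st.checked_empty.sum(axis=1)
        )

    def test_replay_matches_brute_force(self, caching_bird, arena):
        """Incremental bookkeeping agrees with a from-scratch recomputation
        of the state at arbitrary events (independent dict-based oracle)."""
        st = derive_state(caching_bird, arena)
        ev = caching_bird.events
        rng = np.random.default_rng(0)
        for i in rng.choice(len(ev), size=12, replace=False):
            trial = ev["trial"].iloc[i]
            sess = ev["session"].iloc[i]
            count, checked, last = {}, set(), {}
            prev = -1
            for j in range(i):
                if ev["session"].iloc[j] != sess:
                    continue
                prev = ev["site"].iloc[j]
                if ev["trial"].iloc[j] != trial:
                    continue
                s, d = int(ev["site"].iloc[j]), int(ev["delta"].iloc[j])
                if arena.is_cache_site[s]:
                    if d > 0:
                        count[s] = count.get(s, 0) + d
                    elif d < 0 and count.get(s, 0) > 0:
                        count[s] = max(count.get(s, 0) + d, 0)
                    checked.add(s)
                last[s] = ev["time"].iloc[j]
            occ = {s for s, c in count.items() if c > 0}
            ce = {s for s in checked if s not in occ}
            assert set(np.flatnonzero(st.occupancy[i])) == occ
            assert set(np.flatnonzero(st.checked_empty[i])) == ce
            assert st.prev_site[i] == prev
            for s, t in last.items():
                assert st.time_since[i, s] == pytest.approx(
                    ev["time"].iloc[i] - t
                )


class TestMasks:
    def test_cache_mask_counts_caches(self, arena):
        rows = [(0, 0, 0, float(t), t % 8, 0) for t in range(1, 11)]
        rows += [(0, 0, 0, 20.0 + k, 10 + k, 1) for k in range(4)]
        ds = make_dataset(rows)
        st = derive_state(ds, arena)
        m = compute_mask(ds, st, "caches_caching")
        assert m.H.sum() == 4
        assert np.array_equal(m.G, m.H)

    def test_first_check_after_retrieval_before_cache(self, toy_dataset, arena):
        st = derive_state(toy_dataset, arena)
        m = compute_mask(toy_dataset, st, "first_checks_caching")
        # events 1 (cache@3 after feeder seed) and 4 (cache@10 after feeder
        # seed) directly follow retrievals and precede the next cache
        assert list(np.flatnonzero(m.H)) == [1, 4]

    def test_checks_until_find_stops_at_first_hit(self, arena):
        # feeder-closed checks at empty, empty, occupied, empty sites
        ds = make_dataset(
            [
                (0, 0, 1, 1.0, 7, 1),     # cache during feeder-open
                (0, 0, 2, 130.0, 1, 0),
                (0, 0, 2, 131.0, 2, 0),
                (0, 0, 2, 132.0, 7, -1),  # finds the cache
                (0, 0, 2, 133.0, 3, 0),
            ]
        )
        st = derive_state(ds, arena)
        m = compute_mask(ds, st, "checks_until_find")
        assert list(np.flatnonzero(m.H)) == [1, 2, 3]

    def test_no_cache_found_includes_whole_trial(self, arena):
        ds = make_dataset(
            [
                (0, 0, 1, 1.0, 7, 1),
                (0, 0, 2, 130.0, 1, 0),
                (0, 0, 2, 131.0, 2, 0),
                (0, 0, 2, 132.0, 3, 0),
            ]
        )
        st = derive_state(ds, arena)
        m = compute_mask(ds, st, "checks_until_find")
        assert m.H.sum() == 3

    def test_first_closed_check_per_trial(self, retrieval_bird, arena):
        st = derive_state(retrieval_bird, arena)
        m = compute_mask(retrieval_bird, st, "first_checks_closed")
        assert m.H.sum() == retrieval_bird.n_trials
        # a first check is also a check: nested masks are consistent
        m_all = compute_mask(retrieval_bird, st, "checks_closed")
        m_find = compute_mask(retrieval_bird, st, "checks_until_find")
        assert np.all(m.H <= m_all.H)
        assert np.all(m_find.H <= m_all.H)

    def test_masks_idempotent(self, retrieval_bird, arena):
        st = derive_state(retrieval_bird, arena)
        a = compute_mask(retrieval_bird, st, "checks_until_find")
        b = compute_mask(retrieval_bird, st, "checks_until_find")
        assert np.array_equal(a.H, b.H)

    def test_unknown_label(self, toy_dataset, arena):
        st = derive_state(toy_dataset, arena)
        with pytest.raises(ValueError, match="unknown subset"):
            compute_mask(toy_dataset, st, "nope")

    @pytest.mark.parametrize("label", MASK_LABELS)
    def test_h_implies_g_task(self, retrieval_bird, arena, label):
        st = derive_state(retrieval_bird, arena)
        m = compute_mask(retrieval_bird, st, label)
        phases = retrieval_bird.events["phase"].to_numpy()
        task_phase = 0 if label.endswith("caching") else 2
        assert np.all(phases[m.H] == task_phase)
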