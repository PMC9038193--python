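"""Spatial-bias statistics: entropy, split-half, PCA clustering, lag drift."""

import numpy as np
import pandas as pd
import pytest

from cachechoice import ParameterVector
from cachechoice.bias import (
    entropy,
    entropy_null_test,
    lag_stability,
    pc_clustering,
    smooth_bias_map,
    splithalf_correlations,
)
from cachechoice.events import BirdDataset
from cachechoice.simulate import AgentPolicy, dirichlet_bias, simulate_bird


class TestEntropy:
    def test_uniform_is_six_bits(self):
        assert entropy(np.full(64, 1 / 64)) == pytest.approx(6.0)

    def test_single_site_is_zero_bits(self):
        assert entropy(np.eye(64)[10]) == pytest.approx(0.0)

    def test_two_equal_outcomes(self):
        p = np.zeros(64)
        p[[0, 1]] = 0.5
        assert entropy(p) == pytest.approx(1.0)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            entropy(np.array([0.5, -0.5, 1.0]))

    def test_invariant_under_relabeling_and_maximal_iff_uniform(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(64))
        assert entropy(p) == pytest.approx(entropy(rng.permutation(p)))
        assert entropy(p) < 6.0


class TestEntropyNull:
    def test_strong_bias_rejected(self):
        p = np.full(64, 0.1 / 63)
        p[5] = 0.9
        H = entropy(p)
        assert entropy_null_test(H, 200, n_sim=2000, seed=0) < 0.001

    def test_zero_sims_rejected(self):
        with pytest.raises(ValueError, match="n_sim"):
            entropy_null_test(5.0, 100, n_sim=0)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="n_events"):
            entropy_null_test(5.0, 0)


def _bird_from_maps(maps, bird, n_events=80, seed=0):
    """Synthetic bird whose session k caches are drawn from maps[k]."""
    rng = np.random.default_rng(seed)
    rows = []
    t = 0.0
    for k, m in enumerate(maps):
        sites = rng.choice(64, size=n_events, p=m)
        for s in sites:
            t += 1.0
            rows.append((k, k, 0, t, int(s), 1))
    return BirdDataset(
        bird,
        pd.DataFrame(
            rows, columns=["session", "trial", "phase", "time", "site", "delta"]
        ),
    )


class TestSplitHalf:
    def test_duplicated_sessions_correlate_perfectly(self, arena):
        rng = np.random.default_rng(1)
        m = rng.dirichlet(np.ones(64))
        birds = [
            _bird_from_maps([m] * 6, f"b{b}", n_events=2000, seed=b)
            for b in range(2)
        ]
        # huge per-session samples from a fixed map: within-bird halves are
        # nearly identical
        res = splithalf_correlations(
            birds, arena, n_shuffle=50, n_splits=5, seed=0
        )
        assert all(v > 0.95 for v in res.per_bird_corr.values())

    def test_distinct_biases_within_above_across(self, arena):
        rng = np.random.default_rng(2)
        birds = [
            _bird_from_maps(
                [rng.dirichlet(np.ones(64) * 0.5)] * 6, f"b{b}", seed=b
            )
            for b in range(6)
        ]
        res = splithalf_correlations(
            birds, arena, n_shuffle=200, n_splits=10, seed=0
        )
        assert res.p_value < 0.01

    def test_identical_bias_exchangeable(self, arena):
        rng = np.random.default_rng(3)
        m = rng.dirichlet(np.ones(64))
        birds = [
            _bird_from_maps([m] * 6, f"b{b}", n_events=60, seed=10 + b)
            for b in range(6)
        ]
        res = splithalf_correlations(
            birds, arena, n_shuffle=200, n_splits=10, seed=0
        )
        assert res.p_value > 0.01  # no within-bird excess

    def test_single_session_bird_excluded(self, arena):
        rng = np.random.default_rng(4)
        maps = [rng.dirichlet(np.ones(64)) for _ in range(3)]
        birds = [
            _bird_from_maps([maps[0]] * 4, "a"),
            _bird_from_maps([maps[1]] * 4, "b"),
            _bird_from_maps([maps[2]], "c"),
        ]
        with pytest.warns(UserWarning, match="one session"):
            res = splithalf_correlations(birds, arena, n_shuffle=20, n_splits=3)
        assert res.excluded == ["c"]


class TestSmoothing:
    def test_impulse_spreads_to_neighbors(self, arena):
        p = np.zeros(64)
        p[9 * 0 + 27] = 1.0  # interior site, row 3 col 3
        sm = smooth_bias_map(p, arena).reshape(8, 8)
        k = np.exp(-np.array([0.0, 1.0, 2.0]) / 2)  # offsets 0, 1, diagonal
        total = k[0] + 4 * k[1] + 4 * k[2]
        assert sm[3, 3] == pytest.approx(k[0] / total)
        assert sm[3, 4] == pytest.approx(k[1] / total)
        assert sm[2, 2] == pytest.approx(k[2] / total)

    def test_edge_truncation_renormalizes(self, arena):
        p = np.zeros(64)
        p[0] = 1.0  # corner
        sm = smooth_bias_map(p, arena).reshape(8, 8)
        # the corner keeps the largest share and the 2x2 corner block holds
        # all of the impulse's spread
        assert sm[0, 0] > sm[0, 1] > sm[1, 1] > 0


class TestPCClustering:
    def test_center_and_edge_birds_separate(self, arena):
        locs = arena.locations[arena.cache_sites]
        r = np.linalg.norm(locs, axis=1)
        center = np.exp(-(r**2) / (2 * 10**2))
        edge = 1.0 - np.exp(-(r**2) / (2 * 15**2))
        rng = np.random.default_rng(0)
        maps = []
        for b in range(8):
            base = center if b < 4 else edge
            m = base * rng.uniform(0.8, 1.2, size=64)
            maps.append(m / m.sum())
        res = pc_clustering(np.array(maps), arena, seed=0)
        assert res.labels[:4].tolist() == [0] * 4   # center-preferring
        assert res.labels[4:].tolist() == [1] * 4
        assert res.variance_explained[0] > 0.5

    def test_identical_maps_flagged_degenerate(self, arena):
        maps = np.tile(np.full(64, 1 / 64), (5, 1))
        res = pc_clustering(maps, arena, seed=0)
        assert res.degenerate

    def test_too_few_birds(self, arena):
        with pytest.raises(ValueError, match="fewer birds"):
            pc_clustering(np.ones((1, 64)) / 64, arena)


class TestLagStability:
    def test_stationary_bias_has_flat_slope(self, arena):
        rng = np.random.default_rng(5)
        birds = [
            _bird_from_maps(
                [rng.dirichlet(np.ones(64) * 0.7)] * 10, f"b{b}",
                n_events=100, seed=b,
            )
            for b in range(6)
        ]
        res = lag_stability(birds, arena, n_boot=200, seed=0)
        assert res.slope_ci[0] <= 0.0 <= res.slope_ci[1]
        assert res.p_value > 0.05

    def test_drifting_bias_has_negative_slope(self, arena):
        rng = np.random.default_rng(6)
        birds = []
        for b in range(6):
            start = rng.dirichlet(np.ones(64) * 0.7)
            end = rng.dirichlet(np.ones(64) * 0.7)
            maps = [
                (1 - k / 9) * start + (k / 9) * end for k in range(10)
            ]
            birds.append(
                _bird_from_maps(maps, f"b{b}", n_events=100, seed=b)
            )
        res = lag_stability(birds, arena, n_boot=200, seed=0)
        assert res.slope < 0
        assert res.slope_ci[1] < 0
        assert res.p_value < 0.05

    def test_single_lag_errors(self, arena):
        rng = np.random.default_rng(7)
        birds = [
            _bird_from_maps([rng.dirichlet(np.ones(64))] * 3, f"b{b}")
            for b in range(3)
        ]
        with pytest.raises(ValueError, match="lag"):
            lag_stability(birds, arena, max_lag=1, n_boot=10)
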