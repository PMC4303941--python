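"""Spot-module selection, segmentation and phase classification."""

from __future__ import annotations

import numpy as np
import pytest

from somportrait.io import StudyDesign
from somportrait.som import SomModel, SomParams, population_map
from somportrait.spots import (
    build_summary_map,
    classify_spot_phase,
    connected_components,
    percentile_masks,
    select_correlation_spots,
    select_kmeans_spots,
    select_percentile_spots,
    spot_profile,
)


def _fake_model(meta, rows, cols, weeks=None, assignment=None):
    K = rows * cols
    meta = np.asarray(meta, float)
    if assignment is None:
        assignment = np.arange(K) % K
    n = len(assignment)
    return SomModel(
        params=SomParams(rows=rows, cols=cols),
        meta=meta,
        assignment=np.asarray(assignment),
        protein_ids=[f"P{i}" for i in range(n)],
        time_points=weeks or list(range(meta.shape[1])),
        quantization_error_initial=1.0,
        quantization_error=0.5,
    )


def _flood_fill(mask, rows, cols):
    """Brute-force 8-neighborhood components, as an independent oracle."""
    grid = np.asarray(mask, bool).reshape(rows, cols)
    seen = np.zeros_like(grid)
    comps = []
    for r in range(rows):
        for c in range(cols):
            if grid[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.add(y * cols + x)
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < rows and 0 <= nx < cols and grid[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                comps.append(frozenset(comp))
    return comps


class TestConnectedComponents:
    def test_single_block_is_one_spot(self):
        mask = np.zeros(40 * 40, bool)
        grid = mask.reshape(40, 40)
        grid[10:14, 20:28] = True  # one 4x8 block
        assert len(connected_components(mask, 40, 40)) == 1

    @pytest.mark.parametrize("density", [0.1, 0.3, 0.6])
    def test_matches_flood_fill_oracle(self, density, rng):
        for _ in range(60):
            rows = int(rng.integers(2, 41))
            cols = int(rng.integers(2, 41))
            mask = rng.random(rows * cols) < density
            got = set(connected_components(mask, rows, cols))
            want = set(_flood_fill(mask, rows, cols))
            assert got == want


class TestPercentileSelection:
    def test_k1600_selects_32_nodes_per_polarity(self, rng):
        meta = rng.standard_normal((1600, 5))
        model = _fake_model(meta, 40, 40)
        over, under = percentile_masks(model, mode="averaged", percentile=2.0)
        assert over.sum() == 32 and under.sum() == 32

    def test_cutoff_ties_included(self):
        meta = np.zeros((100, 2))
        meta[:40, :] = 1.0  # 40-way tie at the cutoff value
        model = _fake_model(meta, 10, 10)
        over, _ = percentile_masks(model, mode="averaged", percentile=2.0)
        assert over.sum() == 40

    def test_over_under_disjoint(self, rng):
        meta = rng.standard_normal((100, 6))
        model = _fake_model(meta, 10, 10)
        over, under = percentile_masks(model, mode="averaged", percentile=10.0)
        assert not (over & under).any()

    def test_invalid_percentile_rejected(self, rng):
        model = _fake_model(rng.standard_normal((100, 4)), 10, 10)
        for bad in (0.0, 50.0, -1.0):
            with pytest.raises(ValueError):
                percentile_masks(model, percentile=bad)

    def test_member_counts_match_population_map(self, trained_model):
        spots = select_percentile_spots(trained_model)
        pop = population_map(trained_model).ravel()
        for s in spots:
            assert s.n_members == pop[sorted(s.nodes)].sum()

    def test_over_spots_have_positive_maximum(self, trained_model):
        for s in select_percentile_spots(trained_model):
            if s.polarity == "over":
                assert s.mean_profile.max() > 0
            else:
                assert s.mean_profile.min() < 0


class TestCorrelationSelection:
    def test_identical_profiles_single_map_spot(self):
        meta = np.tile(np.array([1.0, -1.0, 0.5, -0.5]), (64, 1))
        model = _fake_model(meta, 8, 8)
        spots = select_correlation_spots(model, threshold=0.9)
        assert len(spots) == 1
        assert spots[0].n_nodes == 64

    def test_threshold_one_groups_only_duplicates(self, rng):
        meta = rng.standard_normal((16, 6))
        model = _fake_model(meta, 4, 4)
        spots = select_correlation_spots(model, threshold=1.0)
        # no duplicates planted: every node is its own spot
        assert len(spots) == 16

    def test_invalid_threshold(self, rng):
        model = _fake_model(rng.standard_normal((16, 4)), 4, 4)
        with pytest.raises(ValueError):
            select_correlation_spots(model, threshold=0.0)

    def test_cluster_count_close_to_kmeans(self):
        # two planted antiphase profile families on a small map
        rng = np.random.default_rng(0)
        t = np.arange(12)
        wave = np.cos(2 * np.pi * t / 12)
        meta = np.vstack(
            [wave + 0.05 * rng.standard_normal((32, 12)),
             -wave + 0.05 * rng.standard_normal((32, 12))]
        )
        model = _fake_model(meta, 8, 8)
        corr = select_correlation_spots(model, threshold=0.8)
        km = select_kmeans_spots(model, k=2)
        assert abs(len(corr) - len(km)) <= 2


class TestKmeansSelection:
    def test_two_antiphase_clusters_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(1)
        t = np.arange(12)
        wave = np.cos(2 * np.pi * t / 12)
        meta = np.vstack(
            [wave + 0.1 * rng.standard_normal((32, 12)),
             -wave + 0.1 * rng.standard_normal((32, 12))]
        )
        # lay the two families out contiguously so clusters stay connected
        model = _fake_model(meta, 8, 8)
        spots = select_kmeans_spots(model, k=2, seed=0)
        node_label = np.empty(64, int)
        for i, s in enumerate(spots):
            for n in s.nodes:
                node_label[n] = i
        truth = np.array([0] * 32 + [1] * 32)
        assert adjusted_rand_score(truth, node_label) >= 0.9

    def test_k_validation(self, rng):
        model = _fake_model(rng.standard_normal((16, 4)), 4, 4)
        with pytest.raises(ValueError):
            select_kmeans_spots(model, k=1)
        with pytest.raises(ValueError):
            select_kmeans_spots(model, k=17)

    def test_cluster_sizes_sum_to_k(self, rng):
        model = _fake_model(rng.standard_normal((36, 5)), 6, 6)
        spots = select_kmeans_spots(model, k=4, seed=0)
        assert sum(s.n_nodes for s in spots) == 36


class TestSpotProfile:
    def test_single_node_spot_profile(self, rng):
        meta = rng.standard_normal((16, 6))
        model = _fake_model(meta, 4, 4)
        spots = select_correlation_spots(model, threshold=1.0)
        for s in spots:
            profile, phase, lag = spot_profile(s, model)
            node = next(iter(s.nodes))
            assert np.array_equal(profile, meta[node])
            assert phase == int(np.argmax(meta[node]))

    def test_phase_recovery_on_planted_cosine(self):
        t = np.arange(-4, 19)
        phi = 8
        wave = np.cos(2 * np.pi * (t - phi) / 30)
        meta = np.tile(wave, (16, 1))
        model = _fake_model(meta, 4, 4, weeks=list(t))
        spots = select_correlation_spots(model, threshold=0.9)
        _, phase, _ = spot_profile(spots[0], model)
        assert abs(phase - phi) <= 1


class TestPhaseClassification:
    @pytest.mark.parametrize(
        "week,expected",
        [(3, "early"), (9, "intermediate"), (14, "late"), (-3, "early"), (17, "late")],
    )
    def test_reference_windows(self, week, expected, rng):
        meta = rng.standard_normal((16, 4))
        model = _fake_model(meta, 4, 4)
        spot = select_correlation_spots(model, threshold=1.0)[0]
        spot.phase_week = week
        assert classify_spot_phase(spot, StudyDesign.default()) == expected


class TestSummaryMap:
    def test_flags_disjoint(self, trained_model):
        summary = build_summary_map(trained_model)
        assert not (summary.over & summary.under).any()

    def test_letters_by_decreasing_size(self, trained_model):
        spots = [s for s in select_percentile_spots(trained_model) if s.polarity == "over"]
        sizes = [s.n_members for s in spots]
        assert sizes == sorted(sizes, reverse=True)
        assert spots[0].id == "A"
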