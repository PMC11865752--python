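"""Trajectory math: frame extraction, paired RMSD, smoothing, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from achescreen.synthdata import GeneratorConfig, gen_trace
from achescreen.trajzones import (
    CoordinateSet,
    RMSDTrace,
    SmoothingParams,
    abs_forward_difference,
    diversity_select,
    ema,
    extract_statistical_frames,
    minmax_normalize,
    pairwise_rmsd,
    rank_rmsf,
    sample_zone_frames,
    segment_zones,
)


class TestStatisticalFrames:
    def test_hand_traced_selector_order(self):
        trace = RMSDTrace.from_values(np.arange(1.0, 11.0))
        assert extract_statistical_frames(trace) == [4, 0, 9, 1, 2, 8, 7]

    def test_constant_trace_backfills_earliest(self):
        trace = RMSDTrace.from_values(np.zeros(100))
        assert extract_statistical_frames(trace) == [0, 1, 2, 3, 4, 5, 6]

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            extract_statistical_frames(RMSDTrace.from_values(np.ones(6)))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 10.0), min_size=7, max_size=60), st.integers(0, 10))
    def test_always_seven_distinct_frames(self, values, _):
        frames = extract_statistical_frames(RMSDTrace.from_values(values))
        assert len(frames) == 7 == len(set(frames))
        assert all(0 <= f < len(values) for f in frames)


class TestPairwiseRMSD:
    def _cs(self, coords):
        return CoordinateSet(
            labels=tuple(f"a{i}" for i in range(len(coords))),
            coords=np.asarray(coords, dtype=float),
        )

    def test_identical_coordinates_zero(self):
        a = self._cs([[0, 0, 0], [1, 2, 3]])
        assert pairwise_rmsd(a, a) == 0.0

    def test_superposition_removes_rigid_motion(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 2, (10, 3))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = pts @ rot.T + np.array([3.0, -1.0, 5.0])
        assert pairwise_rmsd(self._cs(pts), self._cs(moved), superpose=True) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_hand_arithmetic_without_superposition(self):
        a = self._cs([[0, 0, 0], [1, 0, 0]])
        b = self._cs([[0, 0, 0], [2, 0, 0]])
        assert pairwise_rmsd(a, b) == pytest.approx(np.sqrt(0.5))

    def test_label_mismatch_rejected(self):
        a = self._cs([[0, 0, 0]])
        b = CoordinateSet(labels=("other",), coords=np.zeros((1, 3)))
        with pytest.raises(ValueError):
            pairwise_rmsd(a, b)


def _greedy_maximin_oracle(d, n_keep):
    """Independent straightforward re-derivation of the greedy maximin rule."""
    m = d.shape[0]
    pairs = [(d[i, j], i, j) for i in range(m) for j in range(i + 1, m)]
    best = max(pairs, key=lambda t: (t[0], -t[1], -t[2]))
    chosen = [best[1], best[2]]
    while len(chosen) < n_keep:
        scored = []
        for c in range(m):
            if c in chosen:
                continue
            scored.append((min(d[c, x] for x in chosen), -c))
        chosen.append(-max(scored)[1])
    return chosen[:n_keep]


class TestDiversitySelect:
    def test_identical_items_tie_rule(self):
        d = np.zeros((7, 7))
        assert diversity_select(d, 5) == [0, 1, 2, 3, 4]

    def test_one_d_positions_hand_trace(self):
        pos = np.arange(7.0)
        d = np.abs(pos[:, None] - pos[None, :])
        assert diversity_select(d, 5) == [0, 6, 3, 1, 2]

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            pts = rng.uniform(0, 1, (7, 3))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            assert diversity_select(d, 5) == _greedy_maximin_oracle(d, 5)

    def test_n_keep_exceeding_items_rejected(self):
        with pytest.raises(ValueError):
            diversity_select(np.zeros((3, 3)), 4)

    def test_ten_trajectories_yield_fifty(self):
        total = 0
        for seed in range(10):
            cfg = GeneratorConfig(seed=seed, trace_len=200)
            trace, _ = gen_trace(cfg)
            frames = extract_statistical_frames(trace)
            vals = np.asarray(trace.values)[frames]
            d = np.abs(vals[:, None] - vals[None, :])
            total += len(diversity_select(d, 5))
        assert total == 50


class TestRankRMSF:
    def test_descending_order(self):
        assert rank_rmsf({1: 0.5, 2: 1.2, 3: 0.9}, n_top=2) == [2, 3]

    def test_single_residue(self):
        assert rank_rmsf({7: 0.3}, n_top=1) == [7]

    def test_tie_lower_residue_first(self):
        assert rank_rmsf({5: 1.0, 3: 1.0}, n_top=2) == [3, 5]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_rmsf({}, n_top=1)


class TestSmoothing:
    def test_ema_constant_fixed_point(self):
        assert np.allclose(ema([3.0] * 20, period=5), 3.0)

    def test_ema_period_one_identity(self):
        x = [1.0, 5.0, 2.0, 7.0]
        assert np.allclose(ema(x, period=1), x)

    def test_ema_hand_recursion(self):
        assert np.allclose(ema([1, 1, 1, 4], period=3), [1, 1, 1, 2.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=40), st.integers(1, 20))
    def test_ema_bounded_by_running_extremes(self, values, period):
        out = ema(values, period)
        run_min = np.minimum.accumulate(values)
        run_max = np.maximum.accumulate(values)
        assert (out >= run_min - 1e-9).all() and (out <= run_max + 1e-9).all()

    def test_minmax_hand_arithmetic(self):
        out, flag = minmax_normalize([2.0, 4.0, 6.0])
        assert np.allclose(out, [0.0, 0.5, 1.0]) and not flag

    def test_minmax_degenerate_flag(self):
        out, flag = minmax_normalize([5.0] * 4)
        assert np.allclose(out, 0.0) and flag

    def test_minmax_idempotent_on_normalized(self):
        x = np.array([0.0, 0.25, 0.6, 1.0])
        out, _ = minmax_normalize(x)
        assert np.allclose(out, x)

    def test_derivative_ramp_and_vee(self):
        assert np.allclose(abs_forward_difference(np.arange(0, 10, 2.0), spacing=1.0), 2.0)
        assert np.allclose(abs_forward_difference([0.0, 1.0, 0.0], spacing=1.0), 1.0)
        assert np.allclose(abs_forward_difference([4.0] * 5, spacing=1.0), 0.0)


class TestSegmentZones:
    def test_constant_trace_fully_stable(self):
        trace = RMSDTrace.from_values(np.full(2000, 2.0))
        seg = segment_zones(trace, SmoothingParams(ema_period=200))
        assert seg.unstable == ()
        assert len(seg.stable) == 1
        a, b = seg.stable[0]
        assert (a, b) == (trace.times[0], trace.times[-1])

    def test_single_planted_transition(self):
        cfg = GeneratorConfig(seed=0, trace_len=5000)
        trace, truth = gen_trace(cfg, change_points_ns=(250.0,))
        seg = segment_zones(trace, SmoothingParams(ema_period=500))
        assert len(seg.unstable) == 1 and len(seg.stable) == 2
        a, b = seg.unstable[0]
        span = cfg.trace_span_ns
        assert max(a - 250.0, 250.0 - b, 0.0) <= 0.02 * span

    def test_two_planted_transitions_ordering(self):
        cfg = GeneratorConfig(seed=1, trace_len=5000)
        trace, truth = gen_trace(cfg, change_points_ns=(150.0, 350.0))
        seg = segment_zones(trace, SmoothingParams(ema_period=500))
        assert len(seg.unstable) == 2 and len(seg.stable) == 3
        starts = [a for a, _ in seg.unstable]
        assert starts == sorted(starts)

    def test_zones_cover_span(self):
        cfg = GeneratorConfig(seed=2, trace_len=3000)
        trace, _ = gen_trace(cfg, change_points_ns=(250.0,))
        seg = segment_zones(trace, SmoothingParams(ema_period=300))
        edges = sorted(list(seg.stable) + list(seg.unstable))
        assert edges[0][0] == trace.times[0]
        assert edges[-1][1] == trace.times[-1]
        for (a0, b0), (a1, b1) in zip(edges, edges[1:]):
            assert b0 == pytest.approx(a1)

    def test_mismatched_grids_rejected(self):
        t1 = RMSDTrace.from_values(np.ones(100))
        t2 = RMSDTrace.from_values(np.ones(100), dt_ns=0.02)
        with pytest.raises(ValueError):
            segment_zones([t1, t2])


class TestSampleZoneFrames:
    def test_three_planted_value_clusters(self):
        vals = np.concatenate([
            np.full(10, 1.0), np.full(10, 2.0), np.full(10, 3.0),
        ])
        vals[5] = 1.0  # exact centers exist in every group
        trace = RMSDTrace.from_values(vals)
        from achescreen.trajzones import ZoneSegmentation
        zones = ZoneSegmentation(stable=((trace.times[0], trace.times[-1]),), unstable=())
        stable, unstable = sample_zone_frames(trace, zones, k_stable=3, seed=0)
        assert len(stable) == 3
        assert sorted(vals[stable]) == [1.0, 2.0, 3.0]

    def test_identical_frames_single_representative(self):
        trace = RMSDTrace.from_values(np.full(20, 2.0))
        from achescreen.trajzones import ZoneSegmentation
        zones = ZoneSegmentation(stable=((trace.times[0], trace.times[-1]),), unstable=())
        stable, _ = sample_zone_frames(trace, zones, k_stable=3, seed=0)
        assert len(stable) == 1

    def test_planted_outlier_in_unstable_zone(self):
        rng = np.random.default_rng(0)
        vals = 2.0 + rng.normal(0, 0.1, 50)
        vals[23] = 2.0 + 5 * 0.1 * 6  # far outlier
        trace = RMSDTrace.from_values(vals)
        from achescreen.trajzones import ZoneSegmentation
        zones = ZoneSegmentation(stable=(), unstable=((trace.times[0], trace.times[-1]),))
        _, unstable = sample_zone_frames(trace, zones, z_cut=2.0, seed=0)
        assert 23 in unstable
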