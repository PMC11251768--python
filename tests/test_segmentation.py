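"""Velocity stencil, exploration score, GA operators and the segmentation
pipeline, with brute-force oracles on small instances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mothnav.segmentation import (GAConfig, Segmentation, Trajectory,
                                  compute_velocity, crossover,
                                  exploration_score, ga_fit, mutate,
                                  next_generation, objective,
                                  segment_trajectory, segmentation_accuracy,
                                  select_k_elbow, _SegmentScorer)

from conftest import make_trajectory

TWO_PI = 2 * np.pi


class TestVelocityStencil:
    def test_straight_line_gives_minus_slope(self):
        # printed stencil: uniform slope c per sample -> every v_i = -c
        c = 0.7
        i = np.arange(30.0)
        traj = make_trajectory(np.column_stack([c * i, 0 * i, 0 * i]))
        v = compute_velocity(traj).velocities
        assert np.allclose(v[:, 0], -c)

    def test_constant_position_gives_zero(self):
        traj = make_trajectory(np.tile([1.0, 2.0, 3.0], (12, 1)))
        assert np.allclose(compute_velocity(traj).velocities, 0.0)

    def test_componentwise_linearity(self, straight_line_traj):
        v = compute_velocity(straight_line_traj).velocities
        assert np.allclose(v, np.tile([-1.0, -2.0, -3.0], (v.shape[0], 1)))

    def test_valid_range_and_length(self, straight_line_traj):
        vs = compute_velocity(straight_line_traj)
        assert vs.velocities.shape[0] == straight_line_traj.n - 4
        assert vs.valid_range == (2, straight_line_traj.n - 3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_velocity(make_trajectory(np.zeros((4, 3))))


class TestExplorationScore:
    def test_identical_velocities_score_zero(self):
        assert exploration_score(np.tile([0.3, 0.1, 0.0], (8, 1))) == \
            pytest.approx(0.0, abs=1e-20)

    def test_two_vector_closed_form(self):
        v = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert exploration_score(v, duration=2) == pytest.approx(1 / TWO_PI)

    @given(c=st.floats(0.1, 10))
    @settings(deadline=None, max_examples=20)
    def test_quadratic_homogeneity(self, c):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(15, 3))
        assert exploration_score(c * v) == pytest.approx(
            c**2 * exploration_score(v), rel=1e-9)

    @given(shift=st.lists(st.floats(-5, 5), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=20)
    def test_translation_invariance(self, shift):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(12, 3))
        assert exploration_score(v + np.array(shift)) == pytest.approx(
            exploration_score(v), rel=1e-6, abs=1e-12)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            exploration_score(np.empty((0, 3)))


def _labelled_segmentation(bounds, labels, m):
    return Segmentation(k=len(labels), breakpoints=np.asarray(bounds),
                        labels=tuple(labels), objective_value=0.0,
                        n_velocity_samples=m)


class TestObjective:
    def test_single_uniform_segment_scores_zero(self):
        i = np.arange(20.0)
        traj = make_trajectory(np.column_stack([i, i, i]))
        seg = _labelled_segmentation([], ["o"], traj.n - 4)
        assert objective(traj, seg, "paper_literal") == pytest.approx(0.0, abs=1e-15)

    def test_sign_sum_matches_per_segment_scores(self, rng):
        # oracle: recompute each segment's score directly and sign-sum it
        traj = make_trajectory(np.cumsum(rng.normal(size=(60, 3)), axis=0))
        v = compute_velocity(traj).velocities
        seg = _labelled_segmentation([20, 40], ["s", "o", "s"], v.shape[0])
        expect = (-exploration_score(v[:20]) + exploration_score(v[20:40])
                  - exploration_score(v[40:]))
        assert objective(traj, seg, "paper_literal") == pytest.approx(expect)
        assert objective(traj, seg, "dispersion_positive_for_exploration") == \
            pytest.approx(-expect)

    def test_best_phase_equals_enumeration(self, rng):
        # for a fixed 2-split the optimal labelling is the max over both
        # alternating assignments
        traj = make_trajectory(np.cumsum(rng.normal(size=(50, 3)), axis=0))
        v = compute_velocity(traj).velocities
        m = v.shape[0]
        scorer = _SegmentScorer(v)
        bounds = np.array([0, 17, m])
        best, _ = scorer.best_phase(bounds[None, :])
        candidates = []
        for labels in (["s", "o"], ["o", "s"]):
            seg = _labelled_segmentation([17], labels, m)
            candidates.append(objective(traj, seg, "paper_literal"))
        assert best[0] == pytest.approx(max(candidates))

    def test_non_alternating_labels_rejected(self):
        with pytest.raises(ValueError):
            _labelled_segmentation([10], ["s", "s"], 30)


class FixedRng:
    """Deterministic stand-in exposing the Generator methods the GA uses."""

    def __init__(self, ints=(0,), floats=(0.0,)):
        self._ints = itertools.cycle(ints)
        self._floats = itertools.cycle(floats)

    def integers(self, *a, **k):
        return next(self._ints)

    def random(self, *a, **k):
        return next(self._floats)


class TestMutate:
    def test_shifts_exactly_one_breakpoint_by_one(self, rng):
        bp = np.array([10, 20, 30])
        out = mutate(bp, m=60, rng=rng, min_segment_length=5)
        diff = out - bp
        assert np.sum(diff != 0) <= 1
        assert np.all(np.isin(diff, [-1, 0, 1]))

    def test_infeasible_shift_returns_identity(self):
        # single breakpoint at the minimum feasible index, decrement drawn
        bp = np.array([5])
        out = mutate(bp, m=10, rng=FixedRng(ints=(0,), floats=(0.9,)),
                     min_segment_length=5)
        assert np.array_equal(out, bp)

    def test_increment_decrement_balance(self, rng):
        ups = downs = 0
        bp = np.array([50])
        for _ in range(10_000):
            out = mutate(bp, m=100, rng=rng, min_segment_length=5)
            ups += out[0] == 51
            downs += out[0] == 49
        assert ups + downs == 10_000
        assert abs(ups - downs) < 4 * np.sqrt(10_000) / 2


class TestCrossover:
    def test_printed_exchange_example(self):
        i1 = np.array([10, 20, 30, 40])
        i2 = np.array([12, 22, 32, 42])
        c1, c2 = crossover(i1, i2, m=60, rng=FixedRng(ints=(2,)),
                           min_segment_length=5)
        assert np.array_equal(c1, [10, 20, 32, 42])
        assert np.array_equal(c2, [12, 22, 30, 40])

    def test_identical_parents_yield_identical_children(self, rng):
        p = np.array([10, 20, 30])
        c1, c2 = crossover(p, p, m=60, rng=rng)
        assert np.array_equal(c1, p) and np.array_equal(c2, p)

    def test_single_breakpoint_skips_crossover(self, rng):
        a, b = np.array([10]), np.array([25])
        c1, c2 = crossover(a, b, m=60, rng=rng)
        assert np.array_equal(c1, a) and np.array_equal(c2, b)

    def test_two_breakpoints_exchange_tail(self):
        a, b = np.array([10, 20]), np.array([15, 40])
        c1, c2 = crossover(a, b, m=60, rng=FixedRng(ints=(1,)),
                           min_segment_length=5)
        assert np.array_equal(c1, [10, 40]) and np.array_equal(c2, [15, 20])

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=50)
    def test_children_always_feasible(self, seed):
        rng = np.random.default_rng(seed)
        m, L, k1 = 120, 5, 5
        def parent():
            x = np.sort(rng.integers(0, m - (k1 + 1) * L + 1, size=k1))
            return x + L * np.arange(1, k1 + 1)
        c1, c2 = crossover(parent(), parent(), m=m, rng=rng, min_segment_length=L)
        for c in (c1, c2):
            bounds = np.concatenate(([0], c, [m]))
            assert np.all(np.diff(bounds) >= L)


class TestNextGeneration:
    def test_full_royalty_keeps_population(self, rng):
        cfg = GAConfig(population_size=6, royalty_fraction=1.0, generations=1)
        pop = np.array([[10, 20], [11, 21], [12, 22], [13, 23], [14, 24], [15, 25]])
        fit = np.arange(6.0)
        out = next_generation(pop, fit, m=60, cfg=cfg, rng=rng)
        assert {tuple(r) for r in out} == {tuple(r) for r in pop}

    def test_dominant_individual_dominates_selection(self, rng):
        cfg = GAConfig(population_size=40, royalty_fraction=0.025,
                       mutation_probability=0.0, crossover_probability=0.0)
        pop = np.tile(np.arange(40)[:, None] + np.array([[10, 40]]), 1)
        fit = np.full(40, 1.0)
        fit[7] = 100.0
        counts = np.zeros(40)
        for _ in range(200):
            out = next_generation(pop, fit, m=200, cfg=cfg, rng=rng)
            for i in range(40):
                counts[i] += int(np.sum(np.all(out == pop[i], axis=1)))
        counts[7] -= 200  # discount the elite copy itself
        # the fittest individual is selected far more often than any other
        assert counts[7] == counts.max()
        assert counts[7] > 2.5 * np.median(counts)


class TestGaFit:
    @staticmethod
    def _two_regime(seed, n=120, split=60):
        rng = np.random.default_rng(seed)
        drift = np.tile([0.02, 0.0, 0.0], (split, 1))
        noise = rng.normal(scale=0.02, size=(n - split, 3))
        steps = np.vstack([drift, noise])
        return make_trajectory(np.cumsum(steps, axis=0)), split

    def test_recovers_constructed_breakpoint(self):
        hits = 0
        for seed in range(10):
            traj, split = self._two_regime(seed)
            cfg = GAConfig(population_size=60, generations=80, seed=seed)
            seg = ga_fit(traj, 2, cfg)
            hits += abs(int(seg.breakpoints[0]) - (split - 2)) <= 5
        assert hits >= 9

    def test_matches_exhaustive_search_small(self):
        # oracle: enumerate all feasible splits for k <= 3, n <= 60; a
        # population larger than the feasible-split count makes the GA a
        # thorough search, so it must hit the optimum every time
        trials = 8
        cfg = GAConfig(population_size=1500, generations=150)
        for seed in range(trials):
            rng = np.random.default_rng(100 + seed)
            n = int(rng.integers(40, 61))
            traj = make_trajectory(np.cumsum(rng.normal(size=(n, 3)), axis=0))
            k = int(rng.integers(2, 4))
            scorer = _SegmentScorer(compute_velocity(traj).velocities)
            m = scorer.m
            L = 5
            if k == 2:
                cand = [np.array([b]) for b in range(L, m - L + 1)]
            else:
                cand = [np.array([b1, b2]) for b1 in range(L, m - 2 * L + 1)
                        for b2 in range(b1 + L, m - L + 1)]
            best = max(float(scorer.best_phase(
                np.concatenate(([0], bp, [m]))[None, :])[0][0]) for bp in cand)
            seg = ga_fit(traj, k, GAConfig(seed=seed,
                                           population_size=cfg.population_size,
                                           generations=cfg.generations))
            assert seg.objective_value == pytest.approx(best, rel=1e-9)

    def test_same_seed_same_result(self, straight_line_traj):
        rng0 = np.random.default_rng(0)
        a = ga_fit(straight_line_traj, 2, GAConfig(seed=5))
        b = ga_fit(straight_line_traj, 2, GAConfig(seed=5))
        assert np.array_equal(a.breakpoints, b.breakpoints)
        assert a.labels == b.labels

    def test_infeasible_k_rejected(self, straight_line_traj):
        with pytest.raises(ValueError):
            ga_fit(straight_line_traj, 20, GAConfig())


class TestElbow:
    def test_worked_chord_example(self):
        assert select_k_elbow({2: 0.0, 3: 9.0, 4: 10.0, 5: 10.5}) == 3

    def test_linear_curve_ties_to_first_interior(self):
        assert select_k_elbow({k: 2.0 * k for k in range(2, 8)}) == 3

    def test_translation_invariance(self):
        base = {2: 0.0, 3: 9.0, 4: 10.0, 5: 10.5}
        shifted = {k: v + 123.4 for k, v in base.items()}
        assert select_k_elbow(base) == select_k_elbow(shifted)

    def test_few_points_fall_back_to_argmax(self):
        assert select_k_elbow({2: 1.0, 3: 5.0}) == 3


class TestPipeline:
    def test_output_always_alternates(self, rng):
        traj = make_trajectory(np.cumsum(rng.normal(size=(200, 3)), axis=0))
        seg = segment_trajectory(traj, GAConfig(population_size=30,
                                                generations=30, k_max=5, seed=0))
        for a, b in zip(seg.labels, seg.labels[1:]):
            assert a != b

    def test_straight_line_is_handled_gracefully(self):
        i = np.arange(120.0)
        traj = make_trajectory(np.column_stack([i * 0.01, 0 * i, 0 * i]))
        seg = segment_trajectory(traj, GAConfig(population_size=30,
                                                generations=30, k_max=5, seed=1))
        assert seg.k >= 2
        assert len(seg.sample_labels()) == traj.n - 4


class TestAccuracy:
    def test_exact_match_scores_one(self):
        lab = np.array(list("ssoo"))
        assert segmentation_accuracy(lab, lab) == 1.0

    def test_complement_scores_zero(self):
        a = np.array(list("ssoo"))
        b = np.array(list("oossS"[:4]))
        b = np.where(a == "s", "o", "s")
        assert segmentation_accuracy(b, a) == 0.0

    def test_half_match(self):
        a = np.array(["s"] * 50 + ["o"] * 50)
        b = np.array(["s"] * 100)
        assert segmentation_accuracy(b, a) == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segmentation_accuracy(np.array(["s"]), np.array(["s", "o"]))
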