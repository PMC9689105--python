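"""IB scoring, capacity prior, solver, and frontier geometry."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import rel_entr

from colornaming import (
    EfficiencyScore,
    Frontier,
    IBSolution,
    NamingSystem,
    annealed_solution,
    capacity_prior,
    degenerate_language,
    distance_to_frontier,
    frontier_samples,
    gaussian_meanings,
    make_grid_universe,
    mode_map,
    mutual_information,
    random_convex_language,
    score_system,
    solve_ib,
)
from colornaming.ib import MeaningModel, expected_kl_loss


class TestGaussianMeanings:
    def test_large_variance_limit_is_uniform(self, toy_universe):
        m = gaussian_meanings(toy_universe, 1e12).m
        assert np.allclose(m, 1.0 / toy_universe.n_chips, atol=1e-6)

    def test_small_variance_limit_is_one_hot(self, toy_universe):
        m = gaussian_meanings(toy_universe, 1e-3).m
        assert np.allclose(m, np.eye(toy_universe.n_chips), atol=1e-9)

    def test_two_chip_kernel_hand_computed(self):
        # sqdist = 100, sigma_sq = 50 -> m_1 = [1, e^-1] normalised
        u = make_grid_universe(1, 2, 10.0)
        m = gaussian_meanings(u, 50.0).m
        expected = np.array([1.0, np.exp(-1.0)])
        assert np.allclose(m[0], expected / expected.sum())

    def test_nonpositive_variance_rejected(self, toy_universe):
        with pytest.raises(ValueError):
            gaussian_meanings(toy_universe, 0.0)


class TestCapacityPrior:
    def test_identical_rows_give_uniform_prior(self):
        m = np.tile([0.3, 0.7], (3, 1))
        mm = MeaningModel(m, np.array([0.2, 0.3, 0.5]), 1.0)
        out = capacity_prior(mm)
        assert np.allclose(out.prior, 1.0 / 3)

    def test_symmetric_binary_channel(self):
        mm = MeaningModel(np.array([[0.9, 0.1], [0.1, 0.9]]), np.array([0.7, 0.3]), 1.0)
        out = capacity_prior(mm)
        assert np.allclose(out.prior, [0.5, 0.5], atol=1e-6)

    def test_asymmetric_channel_matches_direct_maximisation(self):
        # independent oracle: maximise I(C;U) over the simplex numerically
        m = np.array([[0.97, 0.02, 0.01], [0.05, 0.90, 0.05], [0.30, 0.30, 0.40]])
        mm = MeaningModel(m, np.full(3, 1 / 3), 1.0)

        def neg_mi(x):
            p = np.append(x, 1.0 - x.sum())
            return -mutual_information(p[:, None] * m)

        best = min(
            (
                minimize(neg_mi, x0, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12})
                for x0 in ([0.3, 0.3], [0.5, 0.2], [0.2, 0.5], [0.45, 0.45])
            ),
            key=lambda r: r.fun,
        )
        oracle = np.append(best.x, 1.0 - best.x.sum())
        out = capacity_prior(mm, tol=1e-12)
        assert np.allclose(out.prior, oracle, atol=1e-4)

    def test_nonconvergence_reports_gap(self):
        m = np.array([[0.97, 0.02, 0.01], [0.05, 0.90, 0.05], [0.30, 0.30, 0.40]])
        mm = MeaningModel(m, np.full(3, 1 / 3), 1.0)
        from colornaming.ib import ConvergenceError

        with pytest.raises(ConvergenceError) as exc:
            capacity_prior(mm, tol=1e-15, max_iter=2)
        assert exc.value.last_value is not None


class TestScoreSystem:
    def test_degenerate_system_scores_zero_complexity_max_loss(self, toy_meanings, toy_universe):
        sc = score_system(toy_meanings, degenerate_language(toy_universe))
        assert sc.complexity == 0.0
        assert sc.informativity == 0.0
        assert sc.information_loss == pytest.approx(toy_meanings.i_mu(), abs=1e-12)

    def test_identity_system_complexity_is_entropy(self):
        u = make_grid_universe(1, 4, 50.0)
        mm = gaussian_meanings(u, 1.0)  # near-one-hot meanings, uniform prior
        sc = score_system(mm, NamingSystem(np.eye(4), list("abcd")))
        assert sc.complexity == pytest.approx(2.0, abs=1e-12)

    def test_information_loss_equals_expected_kl(self, toy_meanings, toy_universe, rng):
        # two independent routes to the same quantity
        for n_terms in (1, 3, 7):
            sys_ = random_convex_language(toy_universe, n_terms, rng)
            sc = score_system(toy_meanings, sys_)
            assert sc.information_loss == pytest.approx(
                expected_kl_loss(toy_meanings, sys_), abs=1e-9
            )

    def test_data_processing_bounds(self, toy_meanings, toy_universe, rng):
        imu = toy_meanings.i_mu()
        for n_terms in (2, 5, 9):
            sys_ = random_convex_language(toy_universe, n_terms, rng)
            sc = score_system(toy_meanings, sys_)
            assert sc.informativity <= imu + 1e-9
            assert sc.informativity <= sc.complexity + 1e-9

    def test_dimension_mismatch_rejected(self, toy_meanings):
        with pytest.raises(ValueError):
            score_system(toy_meanings, NamingSystem(np.ones((5, 1)), ["w"]))


class TestSolveIB:
    def test_beta_zero_and_one_give_degenerate_solution(self, toy_meanings):
        for beta in (0.0, 1.0):
            sol = solve_ib(toy_meanings, beta)
            assert sol.score.complexity == pytest.approx(0.0, abs=1e-6)

    def test_annealed_objective_matches_exhaustive_search(self):
        """5-chip/2-term toy problem: annealing reaches the optimum found by
        enumerating all 2^5 deterministic encoders."""
        u = make_grid_universe(1, 5, 10.0)
        mm = capacity_prior(gaussian_meanings(u, 64.0))
        beta = 10.0
        best = np.inf
        for bits in itertools.product([0, 1], repeat=5):
            q = np.zeros((5, 2))
            q[np.arange(5), bits] = 1.0
            sc = score_system(mm, NamingSystem(q, ["a", "b"]))
            best = min(best, sc.complexity - beta * sc.informativity)
        sol = annealed_solution(mm, beta, n_terms=2)
        obj = sol.score.complexity - beta * sol.score.informativity
        assert obj <= best + 1e-6

    def test_max_iter_exceeded_raises_with_objective(self, toy_meanings):
        from colornaming.ib import ConvergenceError

        with pytest.raises(ConvergenceError) as exc:
            solve_ib(toy_meanings, 4.0, tol=0.0, max_iter=3)
        assert np.isfinite(exc.value.last_value)


class TestFrontier:
    def test_anchored_at_zero_complexity(self, toy_frontier):
        assert toy_frontier.complexity[0] == 0.0

    def test_monotone_and_concave(self, toy_frontier):
        cx, inf = toy_frontier.complexity, toy_frontier.informativity
        assert np.all(np.diff(cx) >= -1e-12)
        assert np.all(np.diff(inf) >= -1e-12)
        # concavity of the piecewise-linear interpolation: slopes non-increasing
        slopes = np.diff(inf) / np.diff(cx)
        assert np.all(np.diff(slopes) <= 1e-9)

    def test_identity_limit_reaches_full_informativity(self, toy_meanings, toy_frontier):
        assert toy_frontier.informativity.max() == pytest.approx(
            toy_meanings.i_mu(), abs=1e-3
        )

    def test_random_convex_systems_dominated(self, toy_meanings, toy_universe, toy_frontier):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_terms = int(rng.integers(1, 13))
            sys_ = random_convex_language(toy_universe, n_terms, rng)
            d = distance_to_frontier(score_system(toy_meanings, sys_), toy_frontier)
            assert d >= -1e-6

    def test_non_monotone_schedule_rejected(self, toy_meanings):
        from colornaming.ib import compute_frontier

        with pytest.raises(ValueError):
            compute_frontier(toy_meanings, [1.0, 10.0, 5.0])


class TestDistance:
    def _flat_frontier(self):
        def sol(cx, loss):
            n = 4
            q = np.ones((n, 1))
            return IBSolution(1.0, NamingSystem(q, ["w"]),
                              EfficiencyScore(cx, 0.0, loss))

        return Frontier([sol(0.0, 1.0), sol(2.0, 1.0)])

    def test_point_above_flat_frontier(self):
        fr = self._flat_frontier()
        d = distance_to_frontier(EfficiencyScore(1.0, 0.0, 1.5), fr)
        assert d == pytest.approx(0.5)

    def test_point_below_is_negative(self):
        fr = self._flat_frontier()
        d = distance_to_frontier(EfficiencyScore(1.0, 0.0, 0.5), fr)
        assert d == pytest.approx(-0.5)

    def test_frontier_solutions_score_zero(self, toy_meanings, toy_frontier):
        sol = toy_frontier.solutions[len(toy_frontier.solutions) // 2]
        assert abs(distance_to_frontier(sol.score, toy_frontier)) < 1e-9

    def test_degenerate_anchor_scores_zero(self, toy_meanings, toy_universe, toy_frontier):
        sc = score_system(toy_meanings, degenerate_language(toy_universe))
        assert distance_to_frontier(sc, toy_frontier) == pytest.approx(0.0, abs=1e-12)


class TestFrontierSamples:
    def test_endpoints_for_n2(self, toy_frontier, toy_meanings):
        systems = frontier_samples(toy_frontier, 2)
        assert score_system(toy_meanings, systems[0]).complexity == pytest.approx(0.0)
        assert score_system(toy_meanings, systems[1]).complexity == pytest.approx(
            toy_frontier.complexity.max(), abs=1e-9
        )

    def test_42_samples_nearest_to_uniform_grid(self, toy_frontier, toy_meanings):
        systems = frontier_samples(toy_frontier, 42)
        assert len(systems) == 42
        cx = np.array([score_system(toy_meanings, s).complexity for s in systems])
        targets = np.linspace(
            toy_frontier.complexity.min(), toy_frontier.complexity.max(), 42
        )
        # target grid is arithmetic; each pick is the closest solved point
        assert np.allclose(np.diff(targets), targets[1] - targets[0])
        for c, t in zip(cx, targets):
            gap = np.abs(toy_frontier.complexity - t).min()
            assert abs(c - t) <= gap + 1e-9

    def test_degenerate_frontier_rejected(self, toy_universe):
        deg = degenerate_language(toy_universe)
        fr = Frontier([IBSolution(0.0, deg, EfficiencyScore(0.0, 0.0, 1.0))])
        with pytest.raises(ValueError):
            frontier_samples(fr, 2)


class TestModeMap:
    def test_tie_breaks_to_lowest_index(self):
        ns = NamingSystem(np.array([[0.5, 0.5], [0.2, 0.8]]), ["A", "B"])
        assert mode_map(ns).tolist() == [0, 1]

    def test_deterministic_system_reproduced(self, toy_universe, rng):
        sys_ = random_convex_language(toy_universe, 5, rng)
        assert np.array_equal(mode_map(sys_), np.argmax(sys_.q, axis=1))

    def test_toy_elicitation_mode(self):
        from colornaming.universe import load_wcs_naming

        u = make_grid_universe(1, 2, 10.0)
        ns = load_wcs_naming("1\t1\t1\tA\n1\t2\t1\tA\n1\t1\t2\tA\n1\t2\t2\tB\n", u, 1)
        assert [ns.terms[i] for i in mode_map(ns)] == ["A", "A"]
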