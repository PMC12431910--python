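"""Single-node game layer: fields, equilibria, Nash/ESS classification."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from replinet.games import (
    PayoffMatrix,
    average_fitness,
    classify_equilibrium,
    diagonal_reduction,
    ess_gap,
    fitness,
    interior_equilibrium,
    is_ess,
    is_nash,
    named_game,
    on_simplex,
    random_payoff,
    random_simplex_point,
    replicator_rhs,
)


def simplex_points(n, count, seed=7):
    return np.random.default_rng(seed).dirichlet(np.ones(n), size=count)


class TestPayoffMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="square"):
            PayoffMatrix([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError, match="two species"):
            PayoffMatrix([[1.0]])
        with pytest.raises(ValueError, match="finite"):
            PayoffMatrix([[np.inf, 0], [0, 0]])

    def test_named_games(self, RPS, HDG):
        assert np.array_equal(RPS.entries, [[0, 1, -1], [-1, 0, 1], [1, -1, 0]])
        assert np.array_equal(HDG.entries, [[2, 3], [4, 1]])
        assert named_game("rps").label == "RPS"
        with pytest.raises(KeyError, match="unknown game"):
            named_game("chicken")

    def test_csv_round_trip(self, HDG, tmp_path):
        path = tmp_path / "game.csv"
        HDG.to_csv(path)
        back = PayoffMatrix.from_csv(path)
        np.testing.assert_array_equal(back.entries, HDG.entries)


class TestFitness:
    @pytest.mark.parametrize(
        "game,x,expected",
        [
            ("RPS", (1 / 3, 1 / 3, 1 / 3), (0.0, 0.0, 0.0)),
            ("RPS", (0.9, 0.05, 0.05), (0.0, -0.85, 0.85)),
            ("HDG", (0.5, 0.5), (2.5, 2.5)),
        ],
    )
    def test_values(self, game, x, expected):
        np.testing.assert_allclose(fitness(named_game(game), x), expected, atol=1e-15)

    @pytest.mark.parametrize(
        "game,x,expected",
        [
            ("RPS", (0.9, 0.05, 0.05), 0.0),  # skew-symmetric: x^T A x = 0
            ("HDG", (0.5, 0.5), 2.5),
            ("HDG", (1.0, 0.0), 2.0),
        ],
    )
    def test_average(self, game, x, expected):
        assert average_fitness(named_game(game), x) == pytest.approx(expected, abs=1e-15)

    def test_dimension_mismatch_names_sizes(self, HDG):
        with pytest.raises(ValueError, match="2x2.*3 species"):
            fitness(HDG, (0.2, 0.3, 0.5))


class TestReplicatorField:
    @pytest.mark.parametrize(
        "game,x,expected",
        [
            ("RPS", (1 / 3, 1 / 3, 1 / 3), (0, 0, 0)),
            ("RPS", (0.9, 0.05, 0.05), (0.0, -0.0425, 0.0425)),
            ("HDG", (1.0, 0.0), (0.0, 0.0)),
        ],
    )
    def test_values(self, game, x, expected):
        np.testing.assert_allclose(replicator_rhs(named_game(game), x), expected, atol=1e-15)

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_components_sum_to_zero(self, n):
        A = random_payoff(n, seed=3)
        for x in simplex_points(n, 25):
            assert abs(replicator_rhs(A, x).sum()) < 1e-12

    def test_faces_invariant_exactly(self):
        A = random_payoff(3, seed=4)
        x = np.array([0.0, 0.25, 0.75])
        assert replicator_rhs(A, x)[0] == 0.0


class TestInteriorEquilibrium:
    def test_rps_center(self, RPS):
        np.testing.assert_allclose(interior_equilibrium(RPS), [1 / 3] * 3, atol=1e-14)

    def test_hdg_mixed(self, HDG):
        np.testing.assert_allclose(interior_equilibrium(HDG), [0.5, 0.5], atol=1e-14)

    def test_absent_for_dominated_game(self):
        assert interior_equilibrium([[1, 1], [0, 0]]) is None
        report = interior_equilibrium([[1, 1], [0, 0]], full=True)
        assert report.status == "absent"

    def test_degenerate_manifold_flagged(self):
        # Identical rows: every simplex point is an equilibrium.
        report = interior_equilibrium(np.zeros((3, 3)), full=True)
        assert report.status == "degenerate"
        assert report.point is None

    def test_solution_is_a_fixed_point(self, rng):
        # Whenever a point is returned it must equalize all fitnesses.
        found = 0
        for seed in range(40):
            A = random_payoff(3, seed=seed)
            x = interior_equilibrium(A)
            if x is None:
                continue
            found += 1
            f = fitness(A, x)
            assert np.max(np.abs(f - average_fitness(A, x))) < 1e-10
        assert found > 0


class TestNashAndEss:
    def test_hdg_classification(self, HDG):
        assert is_nash(HDG, (0.5, 0.5))
        assert not is_nash(HDG, (1.0, 0.0))  # hawk invades the dove vertex
        assert is_ess(HDG, (0.5, 0.5))

    def test_rps_center_is_nash_not_ess(self, RPS):
        assert is_nash(RPS, (1 / 3, 1 / 3, 1 / 3))
        # skew-symmetric game: the strict out-scoring inequality fails
        assert not is_ess(RPS, (1 / 3, 1 / 3, 1 / 3))

    def test_negative_diagonal_game_is_ess(self):
        assert is_ess(np.diag([-1.0, -1.0]), (0.5, 0.5))
        assert is_ess(np.diag([-1.0, -1.0, -1.0]), (1 / 3, 1 / 3, 1 / 3))

    def test_ess_argument_validation(self, HDG):
        with pytest.raises(ValueError, match="radius"):
            is_ess(HDG, (0.5, 0.5), radius=0.0)
        with pytest.raises(ValueError, match="n_samples"):
            is_ess(HDG, (0.5, 0.5), n_samples=0)

    def test_ess_implies_nash_on_random_games(self):
        for n in (2, 3):
            for seed in range(25):
                A = random_payoff(n, seed=seed)
                x = interior_equilibrium(A)
                candidates = [np.eye(n)[k] for k in range(n)]
                if x is not None:
                    candidates.append(x)
                for cand in candidates:
                    if is_ess(A, cand, seed=seed):
                        assert is_nash(A, cand)

    def test_report_implication_chain(self, HDG, RPS):
        rep = classify_equilibrium(HDG, (0.5, 0.5))
        assert rep.is_fixed_point and rep.is_nash and rep.is_ess and rep.is_interior
        rep = classify_equilibrium(HDG, (1.0, 0.0))
        assert rep.is_fixed_point and not rep.is_nash and not rep.is_ess
        rep = classify_equilibrium(RPS, (1 / 3, 1 / 3, 1 / 3))
        assert rep.is_nash and not rep.is_ess


class TestDiagonalReduction:
    def test_hdg_reduces_to_negative_diagonal(self, HDG):
        np.testing.assert_array_equal(diagonal_reduction(HDG).entries, np.diag([-2.0, -2.0]))

    def test_already_diagonal_unchanged(self):
        np.testing.assert_array_equal(
            diagonal_reduction(np.diag([-1.0, -1.0])).entries, np.diag([-1.0, -1.0])
        )

    @pytest.mark.parametrize("game", ["RPS", "HDG"])
    def test_field_preserved_on_simplex(self, game):
        A = named_game(game)
        B = diagonal_reduction(A)
        if A.n >= 3:
            assert np.all(B.entries[-1] == 0.0)
        for x in simplex_points(A.n, 100, seed=11):
            np.testing.assert_allclose(
                replicator_rhs(A, x), replicator_rhs(B, x), atol=1e-12
            )


class TestEssGap:
    def test_zero_at_reference(self, HDG):
        assert ess_gap(HDG, (0.5, 0.5), (0.5, 0.5)) == 0.0

    def test_quadratic_form_for_diagonal_game(self):
        assert ess_gap(np.diag([-1.0, -1.0]), (0.5, 0.5), (0.25, 0.75)) == pytest.approx(1 / 8)

    def test_hdg_example(self, HDG):
        assert ess_gap(HDG, (0.5, 0.5), (0.9, 0.1)) == pytest.approx(0.64)


class TestRandomGenerators:
    def test_random_payoff_deterministic_and_scaled(self):
        A = random_payoff(3, scale=2.0, seed=5)
        B = random_payoff(3, scale=2.0, seed=5)
        np.testing.assert_array_equal(A.entries, B.entries)
        assert np.array_equal(random_payoff(4, scale=0.0, seed=1).entries, np.zeros((4, 4)))
        with pytest.raises(ValueError):
            random_payoff(1)

    def test_random_simplex_point_contract(self):
        x = random_simplex_point(3, seed=9)
        np.testing.assert_array_equal(x, random_simplex_point(3, seed=9))
        assert on_simplex(x, tol=1e-12)

    def test_random_simplex_mean_is_barycenter(self):
        n, m = 3, 100_000
        samples = np.random.default_rng(12).dirichlet(np.ones(n), size=m)
        # Dirichlet(1,..,1) coordinate variance = (n-1)/(n^2 (n+1))
        se = np.sqrt((n - 1) / (n**2 * (n + 1)) / m)
        assert np.all(np.abs(samples.mean(axis=0) - 1 / n) < 3 * se)


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_average_fitness_vanishes_for_skew_symmetric(seed):
    rng = np.random.default_rng(seed)
    B = rng.normal(size=(3, 3))
    A = B - B.T
    x = rng.dirichlet(np.ones(3))
    assert abs(average_fitness(A, x)) < 1e-13
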