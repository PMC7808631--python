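"""Label-propagation kernel, closed-form oracle and the two identifiers."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from labelrank import (
    ContactNetwork,
    LabelWeights,
    MatrixKind,
    blrsi,
    build_matrix,
    closed_form_scores,
    labels_from_observation,
    propagate_labels,
    vlrsi,
)
from labelrank.epidemic import ObservationMode
from labelrank.exceptions import InfeasibleObservationError
from labelrank.ranking import write_scores

from conftest import I, S, U, obs_from, random_connected_graph

TIGHT = dict(tol_scale=1e-12, max_iter=100_000)


class TestLabels:
    def test_default_weights_complete(self):
        y = labels_from_observation(obs_from([I, S]))
        assert list(y) == [1.0, -1.0]

    def test_snapshot_unknown_is_zero(self):
        y = labels_from_observation(
            obs_from([I, U, S], mode=ObservationMode.SNAPSHOT_UNIFORM)
        )
        assert list(y) == [1.0, 0.0, -1.0]

    def test_custom_weights(self):
        y = labels_from_observation(obs_from([I, S]), LabelWeights(-2.0, 1.0))
        assert list(y) == [1.0, -2.0]

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LabelWeights(0.0, 0.0)


class TestMatrices:
    def test_sym_entries_on_path(self, p3):
        m = build_matrix(p3, MatrixKind.SYM).toarray()
        expected = 1.0 / np.sqrt(2.0)
        assert np.allclose(np.diag(m), 0.0)
        for i, j in [(0, 1), (1, 0), (1, 2), (2, 1)]:
            assert m[i, j] == pytest.approx(expected)
        assert np.allclose(m, m.T)

    def test_row_and_col_stochastic(self):
        g = random_connected_graph(np.random.default_rng(0))
        row = build_matrix(g, MatrixKind.ROW)
        col = build_matrix(g, MatrixKind.COL)
        assert np.allclose(np.asarray(row.sum(axis=1)).ravel(), 1.0)
        assert np.allclose(np.asarray(col.sum(axis=0)).ravel(), 1.0)
        assert np.allclose(row.toarray().T, col.toarray())

    def test_sym_rows_sum_to_one_on_regular_graph(self, k5):
        m = build_matrix(k5, MatrixKind.SYM)
        assert np.allclose(np.asarray(m.sum(axis=1)).ravel(), 1.0)


class TestPropagation:
    def test_all_ones_fixed_point_on_regular_graph(self, k5):
        y = np.ones(5)
        res = propagate_labels(build_matrix(k5), y, alpha=0.7, **TIGHT)
        assert np.allclose(res.f, 1.0, atol=1e-8)

    def test_p3_closed_form_values(self, p3):
        """Hand-derived fixed point: f1 = 0.5/(1 - 2a^2), a = 0.5/sqrt(2)."""
        y = np.array([1.0, 1.0, -1.0])
        f = closed_form_scores(p3, y, 0.5).f
        assert f == pytest.approx([0.7357, 0.6667, -0.2643], abs=1e-4)

    @pytest.mark.parametrize("kind", list(MatrixKind))
    def test_iteration_matches_closed_form(self, kind):
        rng = np.random.default_rng(17)
        for _ in range(25):
            g = random_connected_graph(rng)
            y = rng.normal(size=g.n)
            alpha = float(rng.uniform(0.1, 0.9))
            exact = closed_form_scores(g, y, alpha, kind).f
            iterated = propagate_labels(build_matrix(g, kind), y, alpha, **TIGHT).f
            assert np.allclose(iterated, exact, atol=1e-6)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        g = random_connected_graph(rng)
        y1, y2 = rng.normal(size=g.n), rng.normal(size=g.n)
        f = lambda y: closed_form_scores(g, y, 0.5).f
        assert np.allclose(f(y1 + y2), f(y1) + f(y2), atol=1e-9)

    def test_monotonicity_in_y(self):
        """(1-a)(I-aM)^-1 has nonnegative entries: raising any y_j cannot
        lower any score."""
        rng = np.random.default_rng(4)
        g = random_connected_graph(rng)
        y = rng.normal(size=g.n)
        base = closed_form_scores(g, y, 0.5).f
        for j in range(min(g.n, 5)):
            bumped = y.copy()
            bumped[j] += 1.0
            assert np.all(closed_form_scores(g, bumped, 0.5).f >= base - 1e-10)

    def test_zero_labels_give_zero_scores(self, p5):
        assert np.allclose(closed_form_scores(p5, np.zeros(5), 0.5).f, 0.0)

    def test_alpha_out_of_range(self, p3):
        for alpha in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                propagate_labels(build_matrix(p3), np.zeros(3), alpha)

    def test_nonconvergence_flagged_not_raised(self, p3):
        res = propagate_labels(build_matrix(p3), np.array([1.0, 1.0, -1.0]),
                               alpha=0.9, tol_scale=1e-15, max_iter=3)
        assert not res.converged and res.iterations == 3

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_property(self, seed):
        """Iterated scores agree with the direct linear solve on any small
        connected graph for every matrix normalisation."""
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng, n_max=15)
        y = rng.normal(size=g.n)
        for kind in MatrixKind:
            exact = closed_form_scores(g, y, 0.5, kind).f
            iterated = propagate_labels(build_matrix(g, kind), y, 0.5, **TIGHT).f
            assert np.allclose(iterated, exact, atol=1e-6)


class TestBlrsi:
    def test_p3_prefers_inner_infected_node(self, p3):
        assert blrsi(p3, obs_from([I, I, S]), alpha=0.5) == 0

    def test_singleton_candidate(self, p5):
        assert blrsi(p5, obs_from([S, S, I, S, S])) == 2

    def test_star_center_wins(self, star5):
        obs = obs_from([I, I, I, I, S])  # center + 3 leaves infected
        assert blrsi(star5, obs) == 0
        exact = closed_form_scores(star5, labels_from_observation(obs), 0.5).f
        infected = [0, 1, 2, 3]
        assert int(np.argmax(exact[infected])) == 0

    def test_candidate_restriction(self, p5):
        """The argmax is restricted to observed-infected nodes even when an
        uninfected node scores higher globally."""
        obs = obs_from([I, S, I, I, I])
        src, scores = blrsi(p5, obs, return_scores=True, alpha=0.5)
        assert obs.values[src] == I

    def test_requires_complete_observation(self, p3):
        with pytest.raises(ValueError, match="COMPLETE"):
            blrsi(p3, obs_from([I, U, S], mode=ObservationMode.SNAPSHOT_UNIFORM))

    def test_requires_infected(self, p3):
        with pytest.raises(InfeasibleObservationError):
            blrsi(p3, obs_from([S, S, S]))

    def test_tie_breaks_to_lowest_id(self, k3):
        # complete symmetry: all nodes infected, all scores equal
        assert blrsi(k3, obs_from([I, I, I])) == 0


class TestVlrsi:
    def test_single_positive_mass_on_path(self, p3):
        obs = obs_from([U, I, U], mode=ObservationMode.SNAPSHOT_UNIFORM)
        assert vlrsi(p3, obs) == 1

    def test_matches_closed_form_argmax(self, p5):
        obs = obs_from([I, U, U, U, S], mode=ObservationMode.SNAPSHOT_UNIFORM)
        exact = closed_form_scores(p5, labels_from_observation(obs), 0.5).f
        assert vlrsi(p5, obs) == int(np.argmax(exact))

    def test_agrees_with_blrsi_when_global_argmax_is_infected(self, p3):
        obs = obs_from([I, I, S])
        src, scores = vlrsi(p3, obs, return_scores=True)
        if obs.values[int(np.argmax(scores.f))] == I:
            assert src == blrsi(p3, obs)

    def test_requires_infected_label(self, p3):
        with pytest.raises(InfeasibleObservationError):
            vlrsi(p3, obs_from([U, S, U], mode=ObservationMode.SNAPSHOT_UNIFORM))


def test_scores_csv_export(tmp_path, p3):
    _, scores = vlrsi(p3, obs_from([I, I, S]), return_scores=True)
    path = tmp_path / "scores.csv"
    write_scores(scores, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "node_id,score" and len(lines) == 4
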