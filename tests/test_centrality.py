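"""Centrality indices, checked against brute-force path enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symptomnet.centrality import (betweenness, centrality_table, closeness,
                                   directed_centrality_table,
                                   directed_strength, shortest_path_lengths,
                                   standardize, strength)
from .conftest import random_small_weights


# ---------------------------------------------------------------------------
# Brute-force oracles (exhaustive path enumeration; independent of the
# graph-library implementation)
# ---------------------------------------------------------------------------

def brute_force_paths(W, s, t):
    """All simple s-t paths with their lengths (edge length 1/|w|)."""
    p = W.shape[0]
    out = []
    others = [v for v in range(p) if v not in (s, t)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = (s, *mid, t)
            length = 0.0
            for a, b in zip(path, path[1:]):
                if W[a, b] == 0:
                    break
                length += 1.0 / abs(W[a, b])
            else:
                out.append((path, length))
    return out


def brute_force_distances(W):
    p = W.shape[0]
    D = np.full((p, p), np.inf)
    np.fill_diagonal(D, 0.0)
    for s in range(p):
        for t in range(s + 1, p):
            paths = brute_force_paths(W, s, t)
            if paths:
                D[s, t] = D[t, s] = min(l for _, l in paths)
    return D


def brute_force_betweenness(W):
    p = W.shape[0]
    bc = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            paths = brute_force_paths(W, s, t)
            if not paths:
                continue
            dmin = min(l for _, l in paths)
            shortest = [pa for pa, l in paths if abs(l - dmin) < 1e-12]
            for v in range(p):
                if v in (s, t):
                    continue
                through = sum(1 for pa in shortest if v in pa)
                bc[v] += through / len(shortest)
    return bc


# ---------------------------------------------------------------------------

class TestStrength:
    def test_direct_sum_with_absolute_values(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = -0.3
        assert strength(W)[0] == pytest.approx(0.8)

    def test_empty_network(self):
        assert not strength(np.zeros((4, 4))).any()

    def test_reduces_to_degree_on_unit_weights(self, rng):
        W = (random_small_weights(rng, 6, signed=False) != 0).astype(float)
        np.testing.assert_allclose(strength(W), W.sum(axis=1))


class TestDistances:
    def test_chain_distance(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        D = shortest_path_lengths(W)
        assert D[0, 2] == pytest.approx(2.0)

    def test_disconnected_pair_is_infinite(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        assert np.isinf(shortest_path_lengths(W)[0, 2])

    def test_doubling_weights_halves_distances(self, rng):
        W = random_small_weights(rng, 5)
        D1 = shortest_path_lengths(W)
        D2 = shortest_path_lengths(2 * W)
        finite = np.isfinite(D1)
        np.testing.assert_allclose(D2[finite], D1[finite] / 2)


class TestCloseness:
    def test_chain_middle_inverse_sum(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        assert closeness(W, "inverse_sum")[1] == pytest.approx(0.5)

    def test_chain_end_harmonic(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        assert closeness(W, "harmonic")[0] == pytest.approx(1.5)

    def test_isolated_node_is_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 2.0
        c = closeness(W)
        assert c[2] == 0.0

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            closeness(np.zeros((3, 3)), "median")


class TestBetweenness:
    def test_star_center(self):
        W = np.zeros((5, 5))
        for leaf in range(1, 5):
            W[0, leaf] = W[leaf, 0] = 1.0
        b = betweenness(W)
        assert b[0] == pytest.approx(6.0)   # C(4,2) pairs
        assert not b[1:].any()

    def test_triangle_all_zero(self):
        W = np.ones((3, 3)) - np.eye(3)
        assert not betweenness(W).any()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 7))
        W = random_small_weights(rng, p, density=0.6)
        np.testing.assert_allclose(betweenness(W), brute_force_betweenness(W),
                                   atol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_closeness_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 7))
        W = random_small_weights(rng, p, density=0.6)
        D = brute_force_distances(W)
        got = closeness(W, "harmonic")
        for i in range(p):
            d = np.delete(D[i], i)
            expected = np.sum(1.0 / d[np.isfinite(d) & (d > 0)])
            assert got[i] == pytest.approx(expected, abs=1e-9)


class TestInvariances:
    @given(st.integers(0, 10_000))
    @settings(max_examples=15)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        p = 5
        W = random_small_weights(rng, p)
        perm = rng.permutation(p)
        Wp = W[np.ix_(perm, perm)]
        np.testing.assert_allclose(strength(Wp), strength(W)[perm], atol=1e-9)
        np.testing.assert_allclose(betweenness(Wp), betweenness(W)[perm],
                                   atol=1e-9)
        np.testing.assert_allclose(closeness(Wp), closeness(W)[perm],
                                   atol=1e-9)

    def test_sign_invariance(self, rng):
        W = random_small_weights(rng, 6)
        np.testing.assert_allclose(strength(W), strength(np.abs(W)))
        np.testing.assert_allclose(betweenness(W), betweenness(np.abs(W)))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            strength(np.array([[0, 1.0], [0, 0]]))


class TestDirectedStrength:
    def test_single_edge(self):
        B = np.zeros((6, 6))
        B[2, 5] = 1.2
        instr, outstr = directed_strength(B)
        assert outstr[2] == pytest.approx(1.2)
        assert instr[5] == pytest.approx(1.2)
        assert outstr.sum() == pytest.approx(instr.sum())

    def test_diagonal_excluded_by_default(self):
        B = np.diag([1.0, 2.0, 3.0])
        instr, outstr = directed_strength(B)
        assert not instr.any() and not outstr.any()
        instr2, outstr2 = directed_strength(B, include_self=True)
        np.testing.assert_allclose(outstr2, [1, 2, 3])

    def test_total_in_equals_total_out(self, rng):
        B = rng.normal(size=(7, 7))
        instr, outstr = directed_strength(B)
        assert instr.sum() == pytest.approx(outstr.sum())


class TestStandardize:
    def test_hand_example(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_constant_vector_warns_and_zeroes(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            z = standardize([2.0, 2.0, 2.0])
        assert not z.any()
        assert "constant" in caplog.text

    def test_mean_zero_sd_one(self, rng):
        z = standardize(rng.normal(size=30))
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1)


class TestTables:
    def test_centrality_table_columns(self, rng):
        W = random_small_weights(rng, 5)
        tab = centrality_table(W)
        for col in ("strength", "closeness", "betweenness"):
            assert col in tab and f"{col}_z" in tab
            if tab[col].std(ddof=1) > 0:
                assert tab[f"{col}_z"].mean() == pytest.approx(0, abs=1e-9)
                assert tab[f"{col}_z"].std(ddof=1) == pytest.approx(1)

    def test_directed_table(self, rng):
        B = rng.normal(size=(4, 4))
        tab = directed_centrality_table(B)
        assert "in_strength" in tab and "out_strength_z" in tab
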