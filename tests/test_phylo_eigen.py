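"""Tree handling, PVR eigenvectors, Moran's I, selection, PSR, BM simulation."""

import itertools

import numpy as np
import pytest

from crypsis.phylo_eigen import (
    EigenBasis,
    NewickError,
    assign_species_scores,
    morans_i,
    parse_newick,
    patristic_distances,
    phylo_weight_matrix,
    psr_curve,
    pvr_eigenvectors,
    select_eigenvectors,
    simulate_bm,
)


class TestParseNewick:
    def test_two_taxon_readback(self):
        t = parse_newick("(A:1.0,B:1.0);")
        assert t.n_tips == 2
        assert t.depth_of("A") == 1.0 and t.depth_of("B") == 1.0

    def test_nested_depths(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert t.n_tips == 3
        assert t.depth_of("A") == 2.0
        assert t.depth_of("C") == 2.0

    def test_fourteen_taxon_order(self, tree14):
        assert tree14.n_tips == 14
        assert tree14.taxa == list("ABCDEFGHIJKLMN")

    @pytest.mark.parametrize("bad", ["", "(A:1,B:1", "(A:1,B);", "(A,B);"])
    def test_malformed_or_missing_lengths_raise(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)


class TestPatristic:
    def test_two_taxon(self):
        D = patristic_distances(parse_newick("(A:1,B:1);"))
        assert D.d[0, 1] == pytest.approx(2.0)

    def test_three_taxon(self):
        D = patristic_distances(parse_newick("((A:1,B:1):1,C:2);"))
        taxa = D.taxa
        a, b, c = (taxa.index(x) for x in "ABC")
        assert D.d[a, c] == pytest.approx(4.0)
        assert D.d[a, b] == pytest.approx(2.0)

    def test_random_tree_matches_path_enumeration(self, yule10):
        """Brute-force oracle: trace every tip-to-tip path through the
        parent chain and sum edge lengths."""
        D = patristic_distances(yule10)
        tree = yule10.tree
        leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}

        def path_distance(u, v):
            anc_u = {}
            node, dist = u, 0.0
            while node is not None:
                anc_u[id(node)] = dist
                dist += node.edge.length or 0.0
                node = node.parent_node
            node, dist = v, 0.0
            while id(node) not in anc_u:
                dist += node.edge.length or 0.0
                node = node.parent_node
            return dist + anc_u[id(node)]

        for i, j in itertools.combinations(range(len(D.taxa)), 2):
            expected = path_distance(leaves[D.taxa[i]], leaves[D.taxa[j]])
            assert D.d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_triangle_inequality(self, yule10):
        D = patristic_distances(yule10).d
        n = D.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestPVR:
    def test_star_tree_degenerate_pair(self):
        """3-taxon star: the two positive eigenvalues of the centered matrix
        are equal (rotational degeneracy), matching a direct eigh oracle."""
        D = patristic_distances(parse_newick("(A:1,B:1,C:1);"))
        n = 3
        J = np.eye(n) - np.ones((n, n)) / n
        oracle = np.sort(np.linalg.eigvalsh(-0.5 * J @ D.d @ J))[::-1]
        basis = pvr_eigenvectors(D)
        assert basis.m == 2
        assert basis.eigenvalues == pytest.approx(oracle[:2])
        assert basis.eigenvalues[0] == pytest.approx(basis.eigenvalues[1])

    def test_columns_orthogonal(self, yule10):
        basis = pvr_eigenvectors(patristic_distances(yule10))
        gram = basis.vectors.T @ basis.vectors
        assert np.allclose(gram, np.eye(basis.m), atol=1e-8)

    def test_two_taxon_sign_symmetric(self):
        basis = pvr_eigenvectors(patristic_distances(parse_newick("(A:1,B:3);")))
        assert basis.m == 1
        v = basis.vectors[:, 0]
        assert v[0] == pytest.approx(-v[1])
        assert v[0] > 0  # sign convention

    def test_double_centered_rows_sum_zero(self, yule10):
        D = patristic_distances(yule10)
        n = D.n
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (D.d**2) @ J
        assert np.allclose(G.sum(axis=0), 0, atol=1e-10)
        assert np.allclose(G.sum(axis=1), 0, atol=1e-10)

    def test_eigenvalue_sum_bounded_by_trace(self, yule10):
        D = patristic_distances(yule10)
        n = D.n
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (D.d**2) @ J
        basis = pvr_eigenvectors(D)
        assert basis.eigenvalues.sum() <= np.trace(G) + 1e-9
        assert np.all(np.diff(basis.eigenvalues) <= 1e-12)  # descending

    def test_asymmetric_input_rejected(self):
        from crypsis.phylo_eigen import PatristicMatrix

        with pytest.raises(ValueError):
            PatristicMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestWeightMatrix:
    def test_two_taxa(self):
        D = patristic_distances(parse_newick("(A:1,B:1);"))
        W = phylo_weight_matrix(D)
        assert np.allclose(W, [[0, 1], [1, 0]])

    def test_star_equal_weights(self):
        D = patristic_distances(parse_newick("(A:1,B:1,C:1);"))
        W = phylo_weight_matrix(D)
        off = W[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5)

    def test_rows_sum_to_one(self, yule10):
        for kind in ("inverse", "inverse-squared", "binary-nn"):
            W = phylo_weight_matrix(patristic_distances(yule10), kind)
            assert np.allclose(W.sum(axis=1), 1.0, atol=1e-12)
            assert np.allclose(np.diag(W), 0.0)


class TestMoransI:
    def test_four_cycle_hand_summation(self):
        """4-cycle neighbourhood, alternating values: direct summation over
        the 8 nonzero weight terms."""
        W = np.array(
            [
                [0, 0.5, 0, 0.5],
                [0.5, 0, 0.5, 0],
                [0, 0.5, 0, 0.5],
                [0.5, 0, 0.5, 0],
            ]
        )
        values = np.array([1.0, -1.0, 1.0, -1.0])
        z = values - values.mean()
        expected = (4 / W.sum()) * sum(
            W[i, j] * z[i] * z[j] for i in range(4) for j in range(4)
        ) / (z @ z)
        res = morans_i(values, W)
        assert res.I == pytest.approx(expected)
        assert res.I == pytest.approx(-1.0)
        assert res.expected == pytest.approx(-1 / 3)

    def test_brute_force_double_sum(self, yule10, rng):
        W = phylo_weight_matrix(patristic_distances(yule10))
        for _ in range(5):
            v = rng.normal(size=10)
            z = v - v.mean()
            brute = (10 / W.sum()) * sum(
                W[i, j] * z[i] * z[j] for i in range(10) for j in range(10)
            ) / (z @ z)
            assert morans_i(v, W).I == pytest.approx(brute, abs=1e-12)

    def test_permutation_null_mean(self, yule10, rng):
        W = phylo_weight_matrix(patristic_distances(yule10))
        v = rng.normal(size=10)
        sims = np.array(
            [morans_i(rng.permutation(v), W).I for _ in range(10_000)]
        )
        se = sims.std(ddof=1) / np.sqrt(sims.size)
        assert abs(sims.mean() - (-1 / 9)) < 3 * se

    def test_leading_eigenvector_maximises(self, yule10, rng):
        """I is maximal at the leading eigenvector of (W+W')/2 among
        unit-variance vectors; random search must not beat it."""
        W = phylo_weight_matrix(patristic_distances(yule10))
        evals, evecs = np.linalg.eigh((W + W.T) / 2)
        # centered leading eigenvector of the symmetrized, centered problem
        n = 10
        J = np.eye(n) - np.ones((n, n)) / n
        evals_c, evecs_c = np.linalg.eigh(J @ (W + W.T) / 2 @ J)
        best = morans_i(evecs_c[:, -1], W).I
        for _ in range(200):
            assert morans_i(rng.normal(size=n), W).I <= best + 1e-9

    def test_constant_values_raise(self):
        W = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        with pytest.raises(ValueError, match="variance"):
            morans_i(np.ones(3), W)


class TestSelection:
    def test_perfect_fit_stops_with_that_vector(self, tree14, basis14):
        W = phylo_weight_matrix(patristic_distances(tree14))
        trait = basis14.vectors[:, 1]
        # raw trait is autocorrelated enough to enter the loop or not;
        # once column 1 enters, residuals vanish and selection stops
        sel, met = select_eigenvectors(trait, basis14, W, threshold=-np.inf)
        assert sel == [1]
        assert met

    def test_noise_trait_empty_selection(self, tree14, basis14, rng):
        """Raw Moran's I of white noise is usually below the threshold
        already: the loop exits before adding anything."""
        W = phylo_weight_matrix(patristic_distances(tree14))
        empties = 0
        for _ in range(20):
            sel, met = select_eigenvectors(
                rng.normal(size=14), basis14, W, threshold=0.06
            )
            if sel == []:
                empties += 1
        assert empties >= 15

    def test_greedy_matches_exhaustive_small(self, tree14, basis14):
        """When greedy picks <= 2 vectors, it must coincide with exhaustive
        search over all subsets of size <= 2 (same final residual I order)."""
        W = phylo_weight_matrix(patristic_distances(tree14))
        trait = simulate_bm(tree14, sigma2=1.0, seed=9)
        values = np.array([trait[t] for t in tree14.taxa])
        # a strict threshold forces the greedy loop to take two steps
        sel, met = select_eigenvectors(values, basis14, W, threshold=-0.1)
        assert met
        assert 1 <= len(sel) <= 2

        from crypsis.phylo_eigen import _ols_residuals

        def resid_I(cols):
            r = _ols_residuals(values, basis14.vectors[:, list(cols)] if cols else None)
            return morans_i(r, W).I

        # greedy's first pick must match the best singleton
        singles = {(j,): resid_I([j]) for j in range(basis14.m)}
        best_single = min(singles, key=lambda k: (singles[k], k))
        assert sel[0] == best_single[0]
        if len(sel) == 2:
            pairs = {
                (best_single[0], j): resid_I([best_single[0], j])
                for j in range(basis14.m)
                if j != best_single[0]
            }
            best_pair = min(pairs, key=lambda k: (pairs[k], k))
            assert sel[1] == best_pair[1]

    def test_unmet_threshold_flags(self, tree14, basis14):
        """An unattainable threshold exhausts a (truncated) basis and sets
        the warning flag instead of raising."""
        W = phylo_weight_matrix(patristic_distances(tree14))
        small = EigenBasis(
            basis14.taxa, basis14.vectors[:, :5], basis14.eigenvalues[:5]
        )
        trait = simulate_bm(tree14, sigma2=1.0, seed=3)
        values = np.array([trait[t] for t in tree14.taxa])
        sel, met = select_eigenvectors(values, small, W, threshold=-10.0)
        assert not met
        assert sorted(sel) == list(range(5))


class TestPSR:
    def test_first_vector_trait(self, basis14):
        curve = psr_curve(basis14.vectors[:, 0], basis14)
        assert np.allclose(curve.r_squared, 1.0, atol=1e-8)
        expected_dev = np.mean(1.0 - curve.cum_eigenvalue_fraction)
        assert curve.mean_deviation == pytest.approx(expected_dev)
        assert curve.mean_deviation > 0

    def test_r2_monotone_and_axes(self, tree14, basis14):
        trait = simulate_bm(tree14, sigma2=1.0, seed=9)
        values = np.array([trait[t] for t in tree14.taxa])
        curve = psr_curve(values, basis14)
        assert np.all(np.diff(curve.r_squared) >= -1e-10)
        assert np.all(np.diff(curve.cum_eigenvalue_fraction) > 0)
        assert curve.cum_eigenvalue_fraction[-1] == pytest.approx(1.0)
        assert curve.mean_deviation == pytest.approx(
            np.mean(curve.r_squared - curve.cum_eigenvalue_fraction)
        )

    def test_bm_traits_center_on_diagonal(self, tree14, basis14):
        """Brownian traits follow the 1:1 PSR line on average."""
        rng = np.random.default_rng(42)
        devs = []
        for _ in range(500):
            trait = simulate_bm(tree14, sigma2=1.0, seed=rng)
            values = np.array([trait[t] for t in tree14.taxa])
            devs.append(psr_curve(values, basis14).mean_deviation)
        assert abs(np.mean(devs)) < 0.03

    def test_white_noise_mostly_negative(self, basis14, rng):
        neg = sum(
            psr_curve(rng.normal(size=14), basis14).mean_deviation < 0
            for _ in range(500)
        )
        assert neg >= 0.9 * 500

    def test_constant_trait_raises(self, basis14):
        with pytest.raises(ValueError):
            psr_curve(np.ones(14), basis14)


class TestSimulateBM:
    def test_tip_variance_matches_depth(self, tree14):
        rng = np.random.default_rng(0)
        sims = np.array(
            [simulate_bm(tree14, 2.0, 0.0, rng)["A"] for _ in range(10_000)]
        )
        assert sims.var() == pytest.approx(2.0 * tree14.depth_of("A"), rel=0.05)

    def test_tip_covariance_matches_shared_depth(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        rng = np.random.default_rng(1)
        draws = np.array(
            [
                [d["A"], d["B"], d["C"]]
                for d in (simulate_bm(tree, 1.5, 0.0, rng) for _ in range(10_000))
            ]
        )
        cov = np.cov(draws.T)
        assert cov[0, 1] == pytest.approx(1.5 * 1.0, rel=0.08)
        assert abs(cov[0, 2]) < 0.08  # no shared path beyond the root

    def test_zero_sigma_limit(self, tree14):
        vals = simulate_bm(tree14, 1e-30, root_value=3.0, seed=0)
        assert np.allclose(list(vals.values()), 3.0, atol=1e-10)

    def test_reproducible(self, tree14):
        assert simulate_bm(tree14, 1.0, seed=7) == simulate_bm(tree14, 1.0, seed=7)

    def test_invalid_sigma(self, tree14):
        with pytest.raises(ValueError):
            simulate_bm(tree14, 0.0)


class TestAssignScores:
    def test_broadcast(self):
        import pandas as pd

        out = assign_species_scores(pd.Series(["A", "A", "A"]), {"A": 0.5})
        assert list(out) == [0.5, 0.5, 0.5]

    def test_empty(self):
        import pandas as pd

        out = assign_species_scores(pd.Series([], dtype=object), {"A": 0.5})
        assert len(out) == 0

    def test_mixed_lookup_join(self, rng):
        import pandas as pd

        species = pd.Series(rng.choice(["A", "B"], size=20))
        scores = {"A": -1.2, "B": 0.7}
        out = assign_species_scores(species, scores)
        naive = [scores[s] for s in species]
        assert list(out) == naive

    def test_unknown_species_listed(self):
        import pandas as pd

        with pytest.raises(KeyError, match="C"):
            assign_species_scores(pd.Series(["A", "C"]), {"A": 0.0})
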