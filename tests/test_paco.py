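"""Principal coordinates, Procrustes superimposition and the global-fit test."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import squareform, pdist

import cophylo as cp
from cophylo.errors import ValidationError
from cophylo.paco import pcoa, procrustes_superimpose

from _oracles import grid_procrustes_m2
from conftest import random_links, uniform_cell_links


def _dm(labels, values):
    return cp.DistanceMatrix(tuple(labels), np.asarray(values, float))


class TestPcoa:
    def test_two_points_embed_on_one_axis(self):
        coords = pcoa(_dm("ab", [[0, 3], [3, 0]]))
        assert coords.coordinates.shape == (2, 1)
        assert abs(coords.coordinates[0, 0] - coords.coordinates[1, 0]) == pytest.approx(3.0)

    def test_all_zero_matrix_keeps_no_axes(self):
        coords = pcoa(_dm("abc", np.zeros((3, 3))))
        assert coords.coordinates.shape == (3, 0)
        assert coords.eigenvalues.size == 0

    def test_euclidean_matrix_reconstructs_distances(self):
        points = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 2.0], [-1.2, 0.7]])
        d = squareform(pdist(points))
        coords = pcoa(_dm("abcd", d))
        again = squareform(pdist(coords.coordinates))
        assert np.allclose(again, d, atol=1e-9)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000), st.integers(3, 10), st.integers(1, 4))
    def test_random_point_clouds_reconstruct(self, seed, n, dim):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(n, dim))
        d = squareform(pdist(points))
        coords = pcoa(_dm([f"t{i}" for i in range(n)], d))
        assert np.all(np.diff(coords.eigenvalues) <= 1e-12)
        assert np.allclose(squareform(pdist(coords.coordinates)), d, atol=1e-8)

    def test_patristic_matrix_matches_skbio(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        d = cp.simulate_host_tree(7, seed=5).patristic_distances()
        ours = pcoa(d)
        theirs = skbio_ord.pcoa(d.values, method="eigh")
        th_eig = np.sort(theirs.eigvals.values)[::-1]
        th_eig = th_eig[th_eig > 1e-9]
        assert np.allclose(ours.eigenvalues, th_eig[: ours.eigenvalues.size], atol=1e-8)
        ref = squareform(pdist(theirs.samples.values))
        assert np.allclose(squareform(pdist(ours.coordinates)), ref, atol=1e-8)

    @pytest.mark.parametrize("correction", ["lingoes", "cailliez"])
    def test_corrections_make_noneuclidean_embeddable(self, correction):
        # a metric but non-Euclidean matrix (star with unequal legs collapses
        # under double-centering to negative eigenvalues)
        d = np.array(
            [[0, 2, 2, 1.1], [2, 0, 2, 1.1], [2, 2, 0, 1.1], [1.1, 1.1, 1.1, 0]]
        )
        coords = pcoa(_dm("abcd", d), correction=correction)
        again = squareform(pdist(coords.coordinates))
        # corrected embeddings preserve distances up to the added constant
        assert np.all(again >= d - 1e-9)
        assert np.all(coords.eigenvalues > 0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            cp.DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestProcrustes:
    def test_identity_configurations_give_zero(self):
        x = np.array([[0.0, 0], [1, 0], [0, 2], [3, 1]])
        fit = procrustes_superimpose(x, x.copy())
        assert fit.m2 == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_rigid_rotation_scaling_translation_of_x_gives_zero(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(6, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))  # random orthogonal (maybe reflecting)
        y = 2.5 * x @ q + rng.normal(size=3)
        fit = procrustes_superimpose(x, y)
        assert fit.m2 == pytest.approx(0.0, abs=1e-9)

    @settings(derandomize=True, max_examples=15)
    @given(st.integers(0, 10_000))
    def test_m2_invariant_under_joint_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        base = procrustes_superimpose(x, y).m2
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = rng.normal(size=2)
        moved = procrustes_superimpose(x @ rot + shift, y @ rot + shift).m2
        assert moved == pytest.approx(base, rel=1e-9, abs=1e-12)

    def test_m2_sums_residuals_and_matches_grid_oracle(self):
        rng = np.random.default_rng(42)
        x, y = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        fit = procrustes_superimpose(x, y)
        assert fit.m2 == pytest.approx(float(fit.residuals.sum()))
        assert fit.m2 == pytest.approx(grid_procrustes_m2(x, y), abs=1e-8)

    def test_column_padding_never_truncates(self):
        x = np.array([[0.0, 0, 0], [1, 2, 3], [2, 0, 1]])
        y = np.array([[0.0], [1.0], [5.0]])
        fit = procrustes_superimpose(x, y)
        assert fit.rotation.shape == (3, 3)

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            procrustes_superimpose(np.zeros((3, 2)), np.zeros((4, 2)))


class TestGlobalFit:
    def test_perfect_congruence_gives_minimal_p(self, congruent_pair):
        host, symb, links = congruent_pair
        res = cp.paco_global_fit(host, symb, links, n_perm=199, seed=0)
        assert res.fit.m2 == pytest.approx(0.0, abs=1e-9)
        # observed is never beaten, only possibly tied by the identity redraw
        assert res.p_value <= (1 + 5) / 200

    def test_deterministic_under_seed(self, congruent_pair):
        host, symb, links = congruent_pair
        a = cp.paco_global_fit(host, symb, links, n_perm=99, seed=7)
        b = cp.paco_global_fit(host, symb, links, n_perm=99, seed=7)
        assert a.fit.m2 == b.fit.m2 and a.p_value == b.p_value

    def test_seed_changes_null_draws(self, congruent_pair):
        host, symb, links = congruent_pair
        host2 = cp.simulate_host_tree(6, seed=1)
        symb2 = cp.simulate_host_tree(6, seed=2)
        for leaf in symb2.leaves():
            leaf.label = leaf.label.replace("H", "s")
        rng = np.random.default_rng(0)
        links2 = random_links(rng, host2, symb2)
        a = cp.paco_global_fit(host2, symb2, links2, n_perm=299, seed=1)
        b = cp.paco_global_fit(host2, symb2, links2, n_perm=299, seed=2)
        assert a.fit.m2 == b.fit.m2  # observed statistic is seed-free
        assert a.p_value != b.p_value  # null draws are not

    @pytest.mark.parametrize("scheme", ["full-shuffle", "row-shuffle"])
    def test_schemes_give_valid_p_values(self, congruent_pair, scheme):
        host, symb, links = congruent_pair
        res = cp.paco_global_fit(host, symb, links, n_perm=99, seed=3, permutation_scheme=scheme)
        assert 0.0 < res.p_value <= 1.0
        assert res.permutation_scheme == scheme

    def test_label_mismatch_names_the_label(self, congruent_pair):
        host, symb, _ = congruent_pair
        bad = cp.AssociationMap([("A", "a"), ("Z", "b")])
        with pytest.raises(ValidationError, match="'Z'"):
            cp.paco_global_fit(host, symb, bad, n_perm=9, seed=0)

    def test_null_p_values_roughly_uniform(self):
        """Type-I behaviour at desk scale: random links should reject at ~alpha."""
        rng = np.random.default_rng(12345)
        n_rep, n_perm = 120, 99
        rejections = 0
        for i in range(n_rep):
            host = cp.simulate_host_tree(8, seed=10_000 + i)
            symb = cp.simulate_host_tree(8, seed=20_000 + i)
            for leaf in symb.leaves():
                leaf.label = leaf.label.replace("H", "s")
            links = uniform_cell_links(rng, host, symb)
            res = cp.paco_global_fit(host, symb, links, n_perm=n_perm, seed=30_000 + i)
            rejections += res.p_value <= 0.05
        from scipy.stats import binom

        lo, hi = binom.ppf([0.005, 0.995], n_rep, 0.05)
        assert lo <= rejections <= hi


class TestJackknife:
    def test_congruent_pair_gives_zero_estimates(self, congruent_pair):
        host, symb, links = congruent_pair
        jack = cp.jackknife_link_residuals(host, symb, links)
        for est, upper in jack:
            assert est == pytest.approx(0.0, abs=1e-9)
            assert upper == pytest.approx(0.0, abs=1e-9)

    def test_estimates_match_direct_loo_recomputation(self):
        host = cp.simulate_host_tree(6, seed=8)
        symb = cp.simulate_host_tree(6, seed=9)
        for leaf in symb.leaves():
            leaf.label = leaf.label.replace("H", "s")
        links = cp.AssociationMap(list(zip(host.leaf_labels, symb.leaf_labels)))
        jack = cp.jackknife_link_residuals(host, symb, links)

        # independent recomputation: explicit pseudovalue bookkeeping around
        # plain least-squares superimpositions of the expanded configurations
        from cophylo.paco import _expanded_configurations

        x, y, _, _ = _expanded_configurations(host, symb, links)
        n = len(links)
        full = procrustes_superimpose(x, y).residuals
        for i in range(n):
            pvs = []
            for j in range(n):
                if j == i:
                    continue
                keep = [k for k in range(n) if k != j]
                sub = procrustes_superimpose(x[keep], y[keep]).residuals
                r_without_j = sub[keep.index(i)]
                pvs.append(n * full[i] - (n - 1) * r_without_j)
            assert jack[i][0] == pytest.approx(max(np.mean(pvs), 0.0), abs=1e-10)
            assert jack[i][1] >= jack[i][0] - 1e-12

    def test_order_independence(self):
        host = cp.simulate_host_tree(5, seed=3)
        symb = cp.simulate_host_tree(5, seed=4)
        for leaf in symb.leaves():
            leaf.label = leaf.label.replace("H", "s")
        links = list(zip(host.leaf_labels, symb.leaf_labels))
        fwd = cp.jackknife_link_residuals(host, symb, cp.AssociationMap(links))
        rev = cp.jackknife_link_residuals(host, symb, cp.AssociationMap(links[::-1]))
        for (e1, u1), (e2, u2) in zip(fwd, rev[::-1]):
            assert e1 == pytest.approx(e2, abs=1e-10)
            assert u1 == pytest.approx(u2, abs=1e-10)

    def test_fewer_than_three_links_rejected(self, congruent_pair):
        host, symb, _ = congruent_pair
        links = cp.AssociationMap([("A", "a"), ("B", "b")])
        with pytest.raises(ValidationError, match="at least 3"):
            cp.jackknife_link_residuals(host, symb, links)
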