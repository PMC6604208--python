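import numpy as np
import pandas as pd
import pytest

from awmnet.pcit import GeneNetwork, build_network, centralities, pcit_edges


def pcit_oracle(corr):
    """Literal three-nested-loop PCIT: returns the keep mask over pairs."""
    g = corr.shape[0]
    keep = np.ones((g, g), bool)
    np.fill_diagonal(keep, False)
    for x in range(g):
        for y in range(g):
            if x == y:
                continue
            for z in range(g):
                if z in (x, y):
                    continue
                def partial(a, b, c):
                    den = (1 - corr[a, c] ** 2) * (1 - corr[b, c] ** 2)
                    if den <= 0:
                        return np.nan
                    return (corr[a, b] - corr[a, c] * corr[b, c]) / np.sqrt(den)

                terms = []
                for pc, raw in [
                    (partial(x, y, z), corr[x, y]),
                    (partial(x, z, y), corr[x, z]),
                    (partial(y, z, x), corr[y, z]),
                ]:
                    if np.isfinite(pc) and abs(raw) > 1e-12:
                        terms.append(pc / raw)
                if not terms:
                    continue
                eps = np.mean(terms)
                if (abs(corr[x, y]) <= abs(eps * corr[x, z])
                        and abs(corr[x, y]) <= abs(eps * corr[y, z])):
                    keep[x, y] = False
                    break
    keep &= keep.T  # symmetric decision
    dup = (np.abs(corr) >= 1 - 1e-12)
    np.fill_diagonal(dup, False)
    keep |= dup
    return keep


def frame_from_corr_target(rng, n_genes, n_traits):
    return pd.DataFrame(
        rng.standard_normal((n_genes, n_traits)),
        index=[f"g{i}" for i in range(n_genes)],
    )


class TestPcitEdges:
    def test_exact_chain_tolerance_arithmetic(self):
        """r_xy = r_yz = 0.8, r_xz = 0.64: the x-z partial through y is exactly 0.

        In a 3-gene system the trio tolerance is eps = (0.781 + 0 + 0.781)/3 =
        0.5206, so the elimination bound for the indirect x-z pair is
        eps * 0.8 = 0.4165 < |r_xz| = 0.64: a single trio is not enough
        evidence to prune any edge, and all three survive.  (Pruning of
        mediated pairs emerges in larger systems where other conditioning
        genes produce larger tolerances.)
        """
        corr = np.array([[1.0, 0.8, 0.64], [0.8, 1.0, 0.8], [0.64, 0.8, 1.0]])
        L = np.linalg.cholesky(corr)
        M = np.random.default_rng(0).standard_normal((16, 3))
        M -= M.mean(axis=0)
        Q = np.linalg.qr(M)[0]  # orthonormal zero-mean columns
        vals = (Q @ L.T).T  # rows have exactly the target sample correlations
        assert np.allclose(np.corrcoef(vals), corr)
        z = pd.DataFrame(vals, index=["x", "y", "z"])
        edges = {(a, b) for a, b, _ in pcit_edges(z)}
        assert edges == {("x", "y"), ("x", "z"), ("y", "z")}

    @pytest.mark.parametrize("n_genes,seed", [(10, 0), (25, 1), (50, 2), (40, 3)])
    def test_matches_triple_loop_oracle(self, n_genes, seed):
        rng = np.random.default_rng(seed)
        z = frame_from_corr_target(rng, n_genes, 16)
        edges = {(a, b) for a, b, _ in pcit_edges(z)}
        corr = np.corrcoef(z.to_numpy())
        keep = pcit_oracle(corr)
        genes = list(z.index)
        expected = {(genes[i], genes[j]) for i in range(n_genes)
                    for j in range(i + 1, n_genes) if keep[i, j]}
        assert edges == expected

    def test_null_density_below_half(self):
        """i.i.d. noise profiles: PCIT prunes a majority of the 190 pairs."""
        dens = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            z = frame_from_corr_target(rng, 20, 16)
            dens.append(len(pcit_edges(z)) / (20 * 19 / 2))
        assert np.mean(dens) < 0.5

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        z = frame_from_corr_target(rng, 15, 12)
        perm = rng.permutation(15)
        zp = z.iloc[perm]
        e1 = {frozenset(e[:2]) for e in pcit_edges(z)}
        e2 = {frozenset(e[:2]) for e in pcit_edges(zp)}
        assert e1 == e2

    def test_per_gene_affine_rescale_invariance(self):
        """Correlations are scale-free: rescaling/shifting each gene profile
        (positive scale) leaves the edge set unchanged."""
        rng = np.random.default_rng(6)
        z = frame_from_corr_target(rng, 12, 10)
        scale = rng.uniform(0.5, 3.0, size=(12, 1))
        shift = rng.normal(size=(12, 1))
        z2 = z * scale + shift
        assert {e[:2] for e in pcit_edges(z)} == {e[:2] for e in pcit_edges(z2)}

    def test_planted_latent_module_stays_connected(self):
        """5 genes loading 0.9 on one factor stay fully connected in >= most seeds."""
        full = 0
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            f = rng.standard_normal(16)
            module = 0.9 * f + np.sqrt(1 - 0.81) * rng.standard_normal((5, 16))
            noise = rng.standard_normal((15, 16))
            z = pd.DataFrame(np.vstack([module, noise]),
                             index=[f"g{i}" for i in range(20)])
            edges = {frozenset(e[:2]) for e in pcit_edges(z)}
            mod_pairs = {frozenset((f"g{i}", f"g{j}"))
                         for i in range(5) for j in range(i + 1, 5)}
            full += mod_pairs <= edges
        assert full >= 8

    def test_degenerate_inputs_rejected(self):
        z = pd.DataFrame(np.ones((3, 5)))
        with pytest.raises(ValueError, match="zero-variance"):
            pcit_edges(z)
        with pytest.raises(ValueError, match="3 genes"):
            pcit_edges(pd.DataFrame(np.random.default_rng(0).normal(size=(2, 5))))

    def test_duplicate_rows_warned_and_kept(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((4, 10))
        z = pd.DataFrame(np.vstack([base, base[0]]),
                         index=["a", "b", "c", "d", "a2"])
        with pytest.warns(UserWarning, match="duplicates"):
            edges = {frozenset(e[:2]) for e in pcit_edges(z)}
        assert frozenset(("a", "a2")) in edges


class TestNetwork:
    def test_isolated_nodes_retained(self):
        net = build_network([], ["a", "b", "c", "d", "e"])
        assert len(net.nodes) == 5 and net.n_edges == 0
        assert all(d == 0 for d in net.degree().values())

    def test_duplicate_edges_collapse(self):
        net = build_network([("a", "b", 0.5), ("a", "b", 0.5)], ["a", "b"])
        assert net.n_edges == 1

    def test_triangle(self):
        net = build_network([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)], ["a", "b", "c"])
        assert net.n_edges == 3
        assert set(net.degree().values()) == {2}

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            build_network([("a", "x", 1)], ["a", "b"])


class TestCentralities:
    def test_star_graph(self):
        edges = [("hub", f"l{i}", 1.0) for i in range(10)]
        net = build_network(edges, ["hub"] + [f"l{i}" for i in range(10)])
        deg, eig = centralities(net)
        assert deg["hub"] == 10 and all(deg[f"l{i}"] == 1 for i in range(10))
        assert eig["hub"] == pytest.approx(1.0)
        assert all(eig[f"l{i}"] < 1 for i in range(10))

    def test_complete_graph(self):
        genes = [f"g{i}" for i in range(5)]
        edges = [(a, b, 1.0) for i, a in enumerate(genes) for b in genes[i + 1:]]
        net = build_network(edges, genes)
        deg, eig = centralities(net)
        assert set(deg.values()) == {4}
        assert np.allclose(list(eig.values()), 1.0)

    def test_matches_dense_eigensolver(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(30)]
        edges = [(genes[i], genes[j], 1.0) for i in range(30) for j in range(i + 1, 30)
                 if rng.random() < 0.15]
        net = build_network(edges, genes)
        _, eig = centralities(net)
        import networkx as nx

        A = nx.to_numpy_array(net.graph, nodelist=genes)
        w, V = np.linalg.eigh(A)
        v = np.abs(V[:, np.argmax(w)])
        v /= v.max()
        got = np.array([eig[g] for g in genes])
        assert np.allclose(got, v, atol=1e-8)

    def test_edgeless_network_uniform(self):
        net = build_network([], ["a", "b"])
        _, eig = centralities(net)
        assert eig == {"a": 1.0, "b": 1.0}
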