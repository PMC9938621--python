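import numpy as np
import pandas as pd
import pytest

from fluidert import coexnet, synthdata
from fluidert.coexnet import NetworkError, NetworkParams

from conftest import make_dataset, balanced_stages


def tom_oracle(A):
    """Triple-loop topological overlap, independent of the vectorized path."""
    n = A.shape[0]
    k = [sum(A[i, u] for u in range(n) if u != i) for i in range(n)]
    W = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            W[i, j] = (l + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return W


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        vals = np.array([[1, 2, 3, 4.0], [2, 4, 6, 8.0]])
        ds = make_dataset(vals, ["PR", "RE", "PO", "RE"])
        adj = coexnet.build_adjacency(ds, NetworkParams())
        assert adj.iloc[0, 1] == pytest.approx(1.0)

    def test_soft_power_hand_value(self, rng):
        # construct two genes with exact sample correlation 0.5
        x = np.array([1.0, -1.0, 1.0, -1.0, 0, 0, 0, 0])
        y = np.array([1.0, -1.0, 0, 0, 1.0, -1.0, 0, 0])
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.5)
        ds = make_dataset(np.vstack([x, y]), ["PR", "RE", "PO", "RE"] * 2)
        adj = coexnet.build_adjacency(ds, NetworkParams(soft_power=6))
        assert adj.iloc[0, 1] == pytest.approx(0.5 ** 6, rel=1e-12)  # 0.015625

    def test_signed_network_distinguishes_anticorrelation(self):
        vals = np.array([[1, 2, 3, 4.0], [-1, -2, -3, -4.0]])
        ds = make_dataset(vals, ["PR", "RE", "PO", "RE"])
        unsigned = coexnet.build_adjacency(ds, NetworkParams(sign="unsigned"))
        signed = coexnet.build_adjacency(ds, NetworkParams(sign="signed"))
        assert unsigned.iloc[0, 1] == pytest.approx(1.0)
        assert signed.iloc[0, 1] == pytest.approx(0.0)

    def test_range_and_symmetry(self, rng):
        ds = make_dataset(rng.normal(0, 1, (15, 9)), balanced_stages(3))
        A = coexnet.build_adjacency(ds, NetworkParams()).to_numpy()
        assert ((A >= 0) & (A <= 1)).all()
        np.testing.assert_allclose(A, A.T)
        np.testing.assert_allclose(np.diag(A), 1.0)

    def test_zero_variance_gene_rejected(self):
        ds = make_dataset([[1, 1, 1, 1.0], [1, 2, 3, 4.0], [0, 2, 1, 3.0]],
                          ["PR", "RE", "PO", "RE"])
        with pytest.raises(NetworkError, match="g1"):
            coexnet.build_adjacency(ds, NetworkParams())


class TestTOM:
    def test_three_node_hand_value(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        tom = coexnet.tom_similarity(pd.DataFrame(A))
        # (l + a) / (min(k) + 1 - a) = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert tom.iloc[0, 1] == pytest.approx(0.5, rel=1e-12)

    def test_empty_network(self):
        A = np.eye(4)
        tom = coexnet.tom_similarity(pd.DataFrame(A)).to_numpy()
        off = tom[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        for n in (5, 10, 25):
            C = rng.uniform(-1, 1, (n, n))
            A = np.abs((C + C.T) / 2) ** 3
            np.fill_diagonal(A, 1.0)
            tom = coexnet.tom_similarity(pd.DataFrame(A)).to_numpy()
            np.testing.assert_allclose(tom, tom_oracle(A), atol=1e-12)

    def test_rejects_asymmetric(self):
        A = np.eye(3)
        A[0, 1] = 0.5
        with pytest.raises(NetworkError):
            coexnet.tom_similarity(pd.DataFrame(A))


def planted_block_dataset(rng, block_sizes=(40, 40), cor=0.9, n_samples=30):
    blocks = []
    for size in block_sizes:
        factor = rng.normal(0, 1, n_samples)
        lam = np.sqrt(cor / (1 - cor))
        blocks.append(lam * factor[None, :] + rng.normal(0, 1, (size, n_samples)))
    vals = np.vstack(blocks)
    stages = (["PR", "RE", "PO"] * ((n_samples + 2) // 3))[:n_samples]
    return make_dataset(vals, stages), block_sizes


class TestModuleDetection:
    def test_recovers_planted_blocks(self, rng):
        from sklearn.metrics import adjusted_rand_score
        ds, sizes = planted_block_dataset(rng, cor=0.98)
        asn = coexnet.analyze_network(ds, params=NetworkParams(min_module_size=20))
        truth = np.repeat(np.arange(len(sizes)), sizes)
        ari = adjusted_rand_score(truth, pd.factorize(asn.labels)[0])
        assert ari == pytest.approx(1.0)
        assert len(asn.modules) == 2

    def test_independent_genes_all_grey(self, rng):
        ds = make_dataset(rng.normal(0, 1, (60, 24)), balanced_stages(8))
        params = NetworkParams(min_module_size=10)
        asn = coexnet.detect_modules(
            coexnet.tom_similarity(coexnet.build_adjacency(ds, params)), params)
        assert set(asn.labels) == {"grey"}

    def test_permutation_invariance(self, rng):
        ds, _ = planted_block_dataset(rng, cor=0.95)
        params = NetworkParams(min_module_size=20)
        asn1 = coexnet.analyze_network(ds, params=params)
        perm = rng.permutation(ds.n_genes)
        ds_perm = ds.subset_genes([ds.gene_ids[i] for i in perm])
        asn2 = coexnet.analyze_network(ds_perm, params=params)
        # identical partition up to labels
        df = pd.DataFrame({"a": asn1.labels, "b": asn2.labels.reindex(asn1.labels.index)})
        assert df.groupby("a")["b"].nunique().max() == 1
        assert df.groupby("b")["a"].nunique().max() == 1

    def test_too_few_genes_all_grey(self, rng):
        ds = make_dataset(rng.normal(0, 1, (5, 9)), balanced_stages(3))
        params = NetworkParams(min_module_size=30)
        tom = coexnet.tom_similarity(coexnet.build_adjacency(ds, params))
        asn = coexnet.detect_modules(tom, params)
        assert set(asn.labels) == {"grey"}


class TestEigengene:
    def test_perfect_monotone_module_correlates_plus_one(self):
        base = np.array([1, 1, 2, 2, 3, 3.0])
        vals = np.vstack([base, 2 * base, base + 5, 3 * base])
        ds = make_dataset(vals, ["PR", "PR", "RE", "RE", "PO", "PO"])
        asn = coexnet.ModuleAssignment(pd.Series("turquoise", index=ds.values.index))
        asn = coexnet.module_eigengene_and_correlation(ds, asn)
        assert asn.stage_correlation.loc["turquoise", "r"] == pytest.approx(1.0)

    def test_sign_flip_antisymmetry(self, rng):
        vals = rng.normal(0, 1, (6, 9))
        ds = make_dataset(vals, balanced_stages(3))
        neg = make_dataset(-vals, balanced_stages(3))
        lab = pd.Series("blue", index=ds.values.index)
        e1 = coexnet.module_eigengene_and_correlation(
            ds, coexnet.ModuleAssignment(lab.copy()))
        e2 = coexnet.module_eigengene_and_correlation(
            neg, coexnet.ModuleAssignment(lab.copy()))
        np.testing.assert_allclose(e1.eigengenes["blue"], -e2.eigengenes["blue"],
                                   atol=1e-10)
        assert e1.stage_correlation.loc["blue", "r"] == pytest.approx(
            -e2.stage_correlation.loc["blue", "r"])

    def test_stage_independent_module_has_small_r(self, rng):
        rs = []
        for _ in range(100):
            vals = rng.normal(0, 1, (8, 12))
            ds = make_dataset(vals, balanced_stages(4))
            lab = pd.Series("blue", index=ds.values.index)
            asn = coexnet.module_eigengene_and_correlation(
                ds, coexnet.ModuleAssignment(lab))
            rs.append(asn.stage_correlation.loc["blue", "r"])
        assert abs(np.mean(rs)) < 0.1

    def test_unit_norm(self, rng):
        ds = make_dataset(rng.normal(0, 1, (10, 9)), balanced_stages(3))
        lab = pd.Series("blue", index=ds.values.index)
        asn = coexnet.module_eigengene_and_correlation(ds, coexnet.ModuleAssignment(lab))
        assert np.linalg.norm(asn.eigengenes["blue"]) == pytest.approx(1.0)


class TestHubs:
    def test_star_topology_center_is_hub(self):
        n = 11
        A = np.full((n, n), 0.1)
        A[0, :] = A[:, 0] = 0.9
        np.fill_diagonal(A, 1.0)
        genes = [f"g{i:02d}" for i in range(n)]
        adj = pd.DataFrame(A, index=genes, columns=genes)
        asn = coexnet.ModuleAssignment(pd.Series("turquoise", index=adj.index))
        asn = coexnet.hub_genes(adj, asn)
        assert asn.hub_genes["turquoise"] == "g00"

    def test_exact_tie_breaks_lexicographically(self):
        A = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.2], [0.2, 0.2, 1.0]])
        genes = ["gb", "ga", "gc"]
        adj = pd.DataFrame(A, index=genes, columns=genes)
        asn = coexnet.ModuleAssignment(pd.Series("blue", index=adj.index))
        asn = coexnet.hub_genes(adj, asn)
        # gb and ga tie at kWithin 0.7; lexicographically smaller id wins
        assert asn.hub_genes["blue"] == "ga"

    def test_planted_hub_recovered_from_simulation(self):
        cfg = synthdata.SimulationConfig(n_patients=48, n_genes=150, n_deg=120,
                                         module_sizes=(40, 30), n_modules=2, seed=9)
        ds, truth = synthdata.simulate_training_cohort(cfg)
        asn = coexnet.analyze_network(ds, list(truth.module_membership),
                                      NetworkParams(min_module_size=20))
        detected = {h for m, h in asn.hub_genes.items() if m != "grey"}
        assert detected == set(truth.hub_genes.values())

    def test_grey_hub_excluded_from_panel(self):
        asn = coexnet.ModuleAssignment(pd.Series(dtype=object))
        asn.hub_genes = {"turquoise": "g1", "grey": "g9", "blue": "g2"}
        assert coexnet.panel_hubs(asn) == ["g2", "g1"]
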