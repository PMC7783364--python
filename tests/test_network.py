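"""Signed adjacency, scale-free fit, TOM modules, edges, hubs, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kskpipe import network, simulate
from kskpipe.network import CoexpressionNetwork


def _expr_from_corr(r: float, n: int = 400, seed: int = 0) -> pd.DataFrame:
    """Two genes with sample correlation very close to r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    y = r * x + math.sqrt(max(0.0, 1 - r * r)) * e
    return pd.DataFrame([x, y], index=["a", "b"])


class TestSignedAdjacency:
    def test_perfect_correlation_weight_one(self):
        x = np.arange(10, dtype=float)
        expr = pd.DataFrame([x, 2 * x + 3], index=["a", "b"])
        net = network.signed_adjacency(expr, beta=5)
        assert net.weights[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation_weight_zero(self):
        x = np.arange(10, dtype=float)
        expr = pd.DataFrame([x, -x], index=["a", "b"])
        net = network.signed_adjacency(expr, beta=5)
        assert net.weights[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_beta5(self):
        """r = 0 maps to 0.5^5 = 0.03125 exactly (closed form, hand-checked)."""
        x = np.array([1.0, -1.0, 1.0, -1.0], dtype=float)
        y = np.array([1.0, 1.0, -1.0, -1.0], dtype=float)  # exactly orthogonal
        net = network.signed_adjacency(pd.DataFrame([x, y], index=["a", "b"]), beta=5)
        assert net.weights[0, 1] == pytest.approx(0.03125)

    def test_bounds_symmetry_unit_diagonal(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(40, 15)), index=[f"g{i}" for i in range(40)])
        net = network.signed_adjacency(expr)
        w = net.weights
        assert np.allclose(w, w.T)
        assert np.all((w >= 0) & (w <= 1))
        assert np.allclose(np.diag(w), 1.0)

    def test_monotone_in_correlation(self):
        weights = [
            network.signed_adjacency(_expr_from_corr(r), beta=5).weights[0, 1]
            for r in (-0.9, -0.3, 0.3, 0.9)
        ]
        assert weights == sorted(weights)

    def test_zero_variance_gene_named(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["ok", "flatgene"]
        )
        with pytest.raises(ValueError, match="flatgene"):
            network.signed_adjacency(expr)


class TestScaleFree:
    def test_power_law_connectivity_fits(self):
        """Exact power-law degree frequencies give R^2 near 1.

        Ten distinct connectivity values k with counts proportional to
        k^-1.5: every non-empty bin holds one value, so the binned log-log
        points lie on a line up to count rounding.
        """
        ks = np.linspace(10, 100, 10)
        counts = np.round(20000 * ks**-1.5).astype(int)
        k = np.repeat(ks, counts)
        r2, mean_k = network.scale_free_r2(k, n_bins=10)
        assert r2 >= 0.99
        assert mean_k == pytest.approx(k.mean())

    def test_identical_connectivities_degenerate(self):
        expr = _expr_from_corr(0.5)
        net = network.signed_adjacency(expr)
        with pytest.raises(ValueError, match="identical"):
            network.scale_free_fit(net)  # two genes: k1 == k2 always

    def test_smallest_passing_beta_selected(self, count_fixture):
        counts, meta, lengths, _ = count_fixture
        from kskpipe.expression import rpkm

        expr = np.log2(rpkm(counts.iloc[:150], lengths.iloc[:150]) + 1)
        betas = (1, 2, 3, 4, 5, 6, 8, 10, 12, 15, 20, 30)
        # oracle: explicit sweep with the same fit
        expected = None
        for b in betas:
            net = network.signed_adjacency(expr, beta=b)
            r2, _ = network.scale_free_fit(net)
            if r2 > 0.6:
                expected = (b, r2)
                break
        if expected is None:
            with pytest.raises(ValueError, match="no beta"):
                network.pick_soft_threshold(expr, betas=betas)
        else:
            assert network.pick_soft_threshold(expr, betas=betas) == pytest.approx(expected)


class TestTom:
    def test_two_gene_tom_equals_weight(self):
        w = 0.37
        net = CoexpressionNetwork(["a", "b"], np.array([[1.0, w], [w, 1.0]]))
        tom = network.tom_similarity(net)
        assert tom[0, 1] == pytest.approx(w)

    def test_bounds_and_diagonal(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(30, 12)), index=[f"g{i}" for i in range(30)])
        tom = network.tom_similarity(network.signed_adjacency(expr))
        assert np.all((tom >= 0) & (tom <= 1))
        assert np.allclose(np.diag(tom), 1.0)
        assert np.allclose(tom, tom.T)


class TestModules:
    @staticmethod
    def _block_expr(block_sizes, rho, n_samples, seed):
        """Genes in blocks correlated at about rho around uncorrelated latents.

        The fixture premise is that block latents are (near-)orthogonal; at
        30 samples two latents can correlate ~0.4 by chance, in which case
        merging them is the correct clustering outcome, so the premise is
        asserted rather than assumed.
        """
        rng = np.random.default_rng(seed)
        rows, labels, latents = [], [], []
        for b, size in enumerate(block_sizes, start=1):
            z = rng.normal(size=n_samples)
            latents.append(z)
            for _ in range(size):
                e = rng.normal(size=n_samples)
                rows.append(math.sqrt(rho) * z + math.sqrt(1 - rho) * e)
                labels.append(b)
        if len(latents) > 1:
            cc = np.corrcoef(np.array(latents))
            off = np.abs(cc[np.triu_indices(len(latents), 1)])
            assert off.max() < 0.25, "fixture premise violated: correlated latents"
        genes = [f"g{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=genes), dict(zip(genes, labels))

    def test_two_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        expr, truth = self._block_expr([40, 40], rho=0.81, n_samples=30, seed=3)
        net = network.signed_adjacency(expr)
        mods = network.detect_modules(net, min_module_size=30, cut_height=0.8)
        assert mods.n_modules() == 2
        pred = [mods.assignments[g] for g in expr.index]
        assert adjusted_rand_score(list(truth.values()), pred) == pytest.approx(1.0)

    def test_single_block_single_module(self):
        expr, _ = self._block_expr([60], rho=0.81, n_samples=30, seed=3)
        mods = network.detect_modules(network.signed_adjacency(expr), cut_height=0.8)
        assert mods.n_modules() == 1
        assert set(mods.assignments.values()) == {1}

    def test_three_block_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        expr, truth = self._block_expr([50, 50, 50], rho=0.8, n_samples=30, seed=6)
        mods = network.detect_modules(network.signed_adjacency(expr), cut_height=0.8)
        pred = [mods.assignments[g] for g in expr.index]
        assert adjusted_rand_score(list(truth.values()), pred) >= 0.9

    def test_small_clusters_unassigned(self):
        expr, _ = self._block_expr([40, 10], rho=0.9, n_samples=30, seed=5)
        mods = network.detect_modules(network.signed_adjacency(expr), min_module_size=30,
                                      cut_height=0.8)
        sizes = pd.Series(list(mods.assignments.values())).value_counts()
        assert sizes.get(1, 0) >= 30
        assert 10 <= sizes.get(0, 0)  # the small block stays unassigned

    def test_invalid_cut_height(self):
        expr, _ = self._block_expr([40], rho=0.8, n_samples=10, seed=6)
        net = network.signed_adjacency(expr)
        with pytest.raises(ValueError, match="cut_height"):
            network.detect_modules(net, cut_height=1.5)


class TestEdgesAndHubs:
    def test_exact_threshold_excluded(self):
        w = np.array([[1.0, 0.43, 0.44], [0.43, 1.0, 0.2], [0.44, 0.2, 1.0]])
        net = CoexpressionNetwork(["a", "b", "c"], w)
        edges = network.edge_list(net, weight_min=0.43)
        assert len(edges) == 1
        assert (edges.iloc[0]["gene_a"], edges.iloc[0]["gene_b"]) == ("a", "c")

    def test_weight_min_one_empty(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(10, 8)), index=[f"g{i}" for i in range(10)])
        net = network.signed_adjacency(expr)
        assert network.edge_list(net, weight_min=1.0).empty

    def test_edge_list_matches_pair_scan(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(25, 10)), index=[f"g{i}" for i in range(25)])
        net = network.signed_adjacency(expr, beta=2)
        edges = network.edge_list(net, weight_min=0.3)
        oracle = set()
        for i in range(25):
            for j in range(i + 1, 25):
                if net.weights[i, j] > 0.3:
                    oracle.add((net.genes[i], net.genes[j]))
        assert {(r.gene_a, r.gene_b) for r in edges.itertuples()} == oracle

    def test_star_center_is_hub(self):
        edges = pd.DataFrame(
            {"gene_a": ["hub"] * 60, "gene_b": [f"leaf{i}" for i in range(60)],
             "weight": [0.5] * 60}
        )
        assert network.hub_genes(edges, min_connections=50) == ["hub"]

    def test_degree_exactly_fifty_not_hub(self):
        edges = pd.DataFrame(
            {"gene_a": ["x"] * 50, "gene_b": [f"leaf{i}" for i in range(50)],
             "weight": [0.5] * 50}
        )
        assert network.hub_genes(edges, min_connections=50) == []

    def test_hub_degrees_match_brute_force(self, default_run):
        edges = pd.read_csv(default_run.out_dir / "edges.tsv", sep="\t")
        degree: dict[str, int] = {}
        for r in edges.itertuples():
            degree[r.gene_a] = degree.get(r.gene_a, 0) + 1
            degree[r.gene_b] = degree.get(r.gene_b, 0) + 1
        expected = sorted(g for g, d in degree.items() if d > 50)
        assert network.hub_genes(edges, min_connections=50) == expected


def hypergeom_tail_exact(a, m, d, n):
    """Independent oracle: exact rational hypergeometric upper tail."""
    num = sum(math.comb(d, x) * math.comb(n - d, m - x) for x in range(a, min(m, d) + 1))
    return num / math.comb(n, m)


class TestEnrichment:
    def test_table_8_2_2_8_matches_enumeration(self):
        # module 10, DEG 10, universe 20, overlap 8
        module = {f"g{i}" for i in range(10)}
        deg = {f"g{i}" for i in range(8)} | {"h1", "h2"}
        universe = module | deg | {f"x{i}" for i in range(8)}
        assert len(universe) == 20
        res = network.module_enrichment(module, deg, universe)
        assert res.overlap == 8
        assert res.p == pytest.approx(hypergeom_tail_exact(8, 10, 10, 20), rel=1e-9)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(30)}
        module = {f"g{i}" for i in range(10)}
        deg = {f"g{i}" for i in range(10, 20)}
        res = network.module_enrichment(module, deg, universe)
        assert res.overlap == 0 and res.p == pytest.approx(1.0)

    def test_module_equals_universe_p_one(self):
        universe = {f"g{i}" for i in range(25)}
        deg = {f"g{i}" for i in range(5)}
        res = network.module_enrichment(universe, deg, universe)
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy_one_sided_fisher(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = int(rng.integers(4, 61))
            m = int(rng.integers(1, n + 1))
            d = int(rng.integers(1, n + 1))
            a_min = max(0, m + d - n)
            a = int(rng.integers(a_min, min(m, d) + 1))
            logp = network.fisher_enrichment_logp(a, m, d, n)
            _, p_sp = stats.fisher_exact([[a, m - a], [d - a, n - m - d + a]],
                                         alternative="greater")
            assert math.exp(logp) == pytest.approx(p_sp, rel=1e-8, abs=1e-12)

    def test_extreme_table_finite_log_p(self):
        """A table with p below 1e-300 keeps a finite log-space value."""
        logp = network.fisher_enrichment_logp(2000, 2000, 2000, 4000)
        log10p = logp / math.log(10)
        assert np.isfinite(log10p)
        assert log10p < -300

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            network.module_enrichment(set(), set(), set())
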