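"""Gene-set integration: intersections and Venn accounting, exact
hypergeometric enrichment with BH, PPI network statistics, and the
pipeline runner."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import pleiomap as pm
from pleiomap.integrate import harmonize, run_pipeline

from conftest import synthetic_supplementary_sets


class TestIntersect:
    def test_basic_overlap(self):
        overlaps, core, _ = pm.intersect_gene_sets({"a", "b", "c"}, {"t": {"b", "c", "d"}})
        assert overlaps["t"] == {"B", "C"}
        assert core == {"B", "C"}

    def test_identical_sets_concentrate_venn_mass(self):
        base = {"g1", "g2", "g3"}
        sets = {f"t{i}": set(base) for i in range(5)}
        overlaps, core, venn = pm.intersect_gene_sets(base, sets)
        assert core == harmonize(base)
        assert venn["11111"] == 3
        assert sum(v for k, v in venn.items() if k != "11111") == 0

    def test_venn_counts_sum_to_union_against_enumeration(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        for _ in range(10):
            gmv = set(rng.choice(genes, 25, replace=False))
            sets = {
                t: set(rng.choice(genes, int(rng.integers(5, 30)), replace=False))
                for t in ["A", "B", "C"]
            }
            overlaps, _, venn = pm.intersect_gene_sets(gmv, sets)
            union = set().union(*overlaps.values())
            assert sum(venn.values()) == len(union)
            # brute-force region membership for every gene
            traits = sorted(overlaps)
            for g in union:
                bits = "".join("1" if g in overlaps[t] else "0" for t in traits)
                region = {
                    x for x in union
                    if all((x in overlaps[t]) == (b == "1") for t, b in zip(traits, bits))
                }
                assert venn[bits] == len(region)

    def test_trait_order_invariance(self):
        gmv = {"a", "b", "c", "d"}
        s1 = {"X": {"a", "b"}, "Y": {"b", "c"}}
        s2 = {"Y": {"b", "c"}, "X": {"a", "b"}}
        o1, c1, v1 = pm.intersect_gene_sets(gmv, s1)
        o2, c2, v2 = pm.intersect_gene_sets(gmv, s2)
        assert o1 == o2 and c1 == c2 and v1 == v2

    def test_empty_imaging_set_warns(self):
        with pytest.warns(UserWarning):
            overlaps, core, _ = pm.intersect_gene_sets(set(), {"t": {"a"}})
        assert core == set()

    def test_published_overlap_counts_and_core(self):
        """Worked example on a synthetic stand-in for the published
        per-trait gene lists: five overlap counts (20/17/78/87/82) and the
        six-gene core are reproduced exactly."""
        imaging, trait_sets, core_expected, counts = synthetic_supplementary_sets()
        overlaps, core, _ = pm.intersect_gene_sets(imaging, trait_sets)
        assert {t: len(v) for t, v in overlaps.items()} == counts
        assert core == set(core_expected)


class TestEnrichment:
    def test_closed_form_fixture(self):
        # N=10, K=5, n=5, x=5 -> 1/C(10,5) = 1/252
        genes = [f"g{i}" for i in range(10)]
        table = pm.hypergeom_enrichment(genes[:5], {"s": set(genes[:5])}, genes)
        assert table["p"].iloc[0] == pytest.approx(1 / 252)

    def test_zero_overlap_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        table = pm.hypergeom_enrichment(genes[:3], {"s": set(genes[5:])}, genes)
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universe(self):
        """Upper-tail p equals exact enumeration over all C(N, n) draws
        for universes of size <= 12."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            N = int(rng.integers(6, 13))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            members = set(rng.choice(universe, K, replace=False))
            n = int(rng.integers(1, N))
            query = list(rng.choice(universe, n, replace=False))
            x = len(set(query) & members)
            total = hits = 0
            for draw in combinations(universe, n):
                total += 1
                hits += len(set(draw) & members) >= x
            table = pm.hypergeom_enrichment(query, {"s": members}, universe)
            assert table["p"].iloc[0] == pytest.approx(hits / total, rel=1e-10)

    def test_bh_matches_textbook_step_up(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(60)]
        collection = {
            f"s{j}": set(rng.choice(universe, 15, replace=False)) for j in range(12)
        }
        query = list(rng.choice(universe, 20, replace=False))
        table = pm.hypergeom_enrichment(query, collection, universe)
        p = table.sort_values("p")["p"].to_numpy()
        m = len(p)
        stepup = np.minimum.accumulate((p * m / np.arange(1, m + 1))[::-1])[::-1]
        assert np.allclose(np.sort(table["q"].to_numpy()), stepup)

    def test_query_outside_universe_dropped(self):
        with pytest.warns(UserWarning):
            table = pm.hypergeom_enrichment(["a", "zz"], {"s": {"a"}}, ["a", "b"])
        assert table["n"].iloc[0] == 1

    def test_planted_enriched_set_ranks_first(self):
        """A planted set containing all signal genes comes out on top."""
        signal = {f"GENE{i + 1:05d}" for i in range(12)}
        ann, sets, _ = pm.simulate_annotations(
            n_genes=200, planted_sets={"PLANTED": signal}, seed=3
        )
        table = pm.hypergeom_enrichment(signal, sets, set(ann["gene"]))
        assert table["set"].iloc[0] == "PLANTED"


class TestPpiStats:
    def _edges(self, pairs, score=900):
        return pd.DataFrame(
            [(a, b, score) for a, b in pairs],
            columns=["protein1", "protein2", "combined_score"],
        )

    def test_triangle_betweenness_zero(self):
        stats_ = pm.ppi_subnetwork_stats(
            ["a", "b", "c"], self._edges([("a", "b"), ("b", "c"), ("a", "c")])
        )
        assert stats_["m_obs"] == 3
        assert all(v == 0 for v in stats_["betweenness"].values())

    def test_path_center_betweenness_one(self):
        stats_ = pm.ppi_subnetwork_stats(["a", "b", "c"], self._edges([("a", "b"), ("b", "c")]))
        assert stats_["betweenness"]["B"] == pytest.approx(1.0)
        assert stats_["betweenness"]["A"] == 0.0

    def test_betweenness_matches_exhaustive_enumeration(self):
        """Unnormalized betweenness equals direct shortest-path counting
        on random graphs with <= 8 nodes."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            nodes = [f"n{i}" for i in range(n)]
            pairs = [
                (a, b) for a, b in combinations(nodes, 2) if rng.random() < 0.45
            ]
            if not pairs:
                continue
            stats_ = pm.ppi_subnetwork_stats(nodes, self._edges(pairs))
            g = nx.Graph(
                [(a.upper(), b.upper()) for a, b in pairs]
            )

            def brute(v):
                total = 0.0
                for s, t in combinations(g.nodes, 2):
                    if s == v or t == v:
                        continue
                    try:
                        paths = list(nx.all_shortest_paths(g, s, t))
                    except nx.NetworkXNoPath:
                        continue
                    total += sum(v in p[1:-1] for p in paths) / len(paths)
                return total

            for v in g.nodes:
                assert stats_["betweenness"][v] == pytest.approx(brute(v))

    def test_score_threshold_and_autoscaling(self):
        edges = self._edges([("a", "b")], score=350)  # 0.35 < 0.4 dropped
        stats_ = pm.ppi_subnetwork_stats(["a", "b"], edges)
        assert stats_["m_obs"] == 0
        stats_ = pm.ppi_subnetwork_stats(["a", "b"], edges, score_threshold=0.3)
        assert stats_["m_obs"] == 1

    def test_missing_gene_counted_as_isolated(self):
        stats_ = pm.ppi_subnetwork_stats(["a", "b", "ghost"], self._edges([("a", "b")]))
        assert stats_["missing"] == ["GHOST"]
        assert stats_["betweenness"]["GHOST"] == 0.0

    def test_density_null_formula(self):
        pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")]
        stats_ = pm.ppi_subnetwork_stats(["a", "b", "c"], self._edges(pairs), null="density")
        density = 2 * 4 / (4 * 3)
        assert stats_["m_exp"] == pytest.approx(3 * density)

    def test_degree_null_not_anticonservative_on_er(self):
        """Random queries on an Erdos-Renyi background yield p_edges >
        0.05 in at least 90% of replicates."""
        rng = np.random.default_rng(5)
        n_nodes, n_rep = 60, 500
        nodes = [f"n{i}" for i in range(n_nodes)]
        high = 0
        for rep in range(n_rep):
            g = nx.fast_gnp_random_graph(n_nodes, 0.06, seed=rep)
            edges = pd.DataFrame(
                [(nodes[a], nodes[b], 900) for a, b in g.edges],
                columns=["protein1", "protein2", "combined_score"],
            )
            if len(edges) == 0:
                continue
            query = rng.choice(nodes, 8, replace=False)
            stats_ = pm.ppi_subnetwork_stats(query, edges)
            high += stats_["p_edges"] > 0.05
        assert high / n_rep >= 0.9

    def test_planted_module_detected(self):
        _, _, ppi = pm.simulate_annotations(n_genes=120, ppi_modules=(10,), seed=6)
        module = [f"GENE{i + 1:05d}" for i in range(10)]
        stats_ = pm.ppi_subnetwork_stats(module, ppi)
        assert stats_["m_obs"] > stats_["m_exp"]
        assert stats_["p_edges"] < 0.01


@pytest.fixture(scope="module")
def fast_config():
    return {
        "gwas": {"m_snps": 4_000, "block_size": 50},
        "atlas": {"n_samples": 120},
        "peaks": {"n_studies": 8},
        "n_perm": 30,
        "n_boot": 80,
    }


class TestPipeline:
    def test_manifest_reproducible(self, fast_config, tmp_path):
        run_pipeline(dict(fast_config), tmp_path / "a", seed=3)
        run_pipeline(dict(fast_config), tmp_path / "b", seed=3)
        ma = (tmp_path / "a" / "manifest.json").read_text()
        mb = (tmp_path / "b" / "manifest.json").read_text()
        assert ma == mb

    def test_stage_subset_skips_imaging(self, fast_config, tmp_path):
        config = dict(fast_config)
        config["stages"] = ["conjfdr", "loci"]
        report = run_pipeline(config, tmp_path, seed=1)
        assert "n_loci" in report
        assert "n_pls_genes" not in report
        assert not (tmp_path / "gene_scores.tsv").exists()
        assert (tmp_path / "loci.tsv").exists()

    def test_unknown_stage_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            run_pipeline({"stages": ["bogus"]}, tmp_path)

    def test_end_to_end_core_gene_audit(self, fast_config, tmp_path):
        """The core gene set is nonempty and essentially every core gene
        is planted (shared-block gene = imaging signal gene); unplanted
        members are reported."""
        report = run_pipeline(dict(fast_config), tmp_path, seed=2)
        core = set(report["core_genes"])
        assert core
        false_members = set(report["core_false_members"])
        assert false_members <= core
        assert len(false_members) <= max(1, len(core) // 3)
        planted = {f"GENE{b + 1:05d}" for b in range(report["n_shared_blocks"] + 200)}
        assert core <= planted  # names drawn from the shared universe
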