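import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import brainko as bk
from brainko.stats import (
    StatsError,
    sample_degree_matched,
    score_connectivity,
    write_enrichment_tsv,
)


gene_sets = st.sets(st.sampled_from([f"g{i}" for i in range(12)]), max_size=8)


class TestListDistance:
    def test_partial_overlap(self):
        assert bk.list_distance({"g1", "g2", "g3"}, {"g2", "g3", "g4"}) == 2

    def test_identity(self):
        assert bk.list_distance({"a", "b"}, {"a", "b"}) == 0

    def test_disjoint_top_lists(self):
        a = {f"a{i}" for i in range(100)}
        b = {f"b{i}" for i in range(100)}
        assert bk.list_distance(a, b) == 200

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(gene_sets, gene_sets, gene_sets)
    def test_is_a_metric(self, a, b, c):
        assert bk.list_distance(a, a) == 0
        assert bk.list_distance(a, b) == bk.list_distance(b, a)
        assert bk.list_distance(a, c) <= bk.list_distance(a, b) + bk.list_distance(b, c)


class TestClusterStructures:
    def test_most_similar_pair_merges_first(self):
        shared = [f"s{i}" for i in range(90)]
        lists = {
            "A": shared + [f"a{i}" for i in range(10)],
            "B": shared + [f"b{i}" for i in range(10)],
            "C": [f"c{i}" for i in range(100)],
        }
        tree = bk.cluster_structures(lists)
        # A and B (distance 20) join below the merge with C (distance 200)
        ab_parent = tree.lca(["A", "B"])
        assert {leaf.name for leaf in ab_parent.tips()} == {"A", "B"}

    def test_identical_lists_merge_at_zero_height(self):
        lists = {"A": ["g1", "g2"], "B": ["g1", "g2"], "C": ["g1", "g2"]}
        tree = bk.cluster_structures(lists)
        for node in tree.traverse():
            if node.length:
                assert node.length == pytest.approx(0.0)

    def test_two_structures_single_merge(self):
        tree = bk.cluster_structures({"A": ["g1"], "B": ["g2"]})
        assert {leaf.name for leaf in tree.tips()} == {"A", "B"}

    def test_newick_serialisable(self, tmp_path):
        tree = bk.cluster_structures({"A": ["g1"], "B": ["g2"], "C": ["g1"]})
        path = tmp_path / "tree.nwk"
        from brainko.stats import write_newick

        write_newick(tree, path)
        text = path.read_text()
        assert text.strip().endswith(";") and "A" in text

    def test_single_structure_rejected(self):
        with pytest.raises(StatsError, match="nothing to cluster"):
            bk.cluster_structures({"A": ["g1"]})


def _enumerate_mw_p(x, y):
    """Exact one-sided p by enumerating all splits of the pooled sample."""
    pooled = list(x) + list(y)
    n_x = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
        1 for xi in x for yi in y if xi == yi
    )
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for xi in xs for yi in ys if xi > yi) + 0.5 * sum(
            1 for xi in xs for yi in ys if xi == yi
        )
        total += 1
        if u >= u_obs - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_small_sample_exact_value(self):
        u, p = bk.mann_whitney_greater([3, 4], [1, 2])
        assert u == 4
        assert p == pytest.approx(1 / 6)

    def test_identical_samples_not_significant(self):
        _, p = bk.mann_whitney_greater([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_for_tiny_samples(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(1.0, 1.0, size=rng.integers(3, 8))
        y = rng.normal(0.0, 1.0, size=rng.integers(3, 8))
        _, p = bk.mann_whitney_greater(x, y)
        assert p == pytest.approx(_enumerate_mw_p(x, y), abs=1e-12)

    def test_asymptotic_close_to_exact(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.8, 1.0, 7)
        y = rng.normal(0.0, 1.0, 7)
        _, p_exact = bk.mann_whitney_greater(x, y)
        from scipy.stats import mannwhitneyu

        p_approx = mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
        assert abs(p_exact - p_approx) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(StatsError, match="empty sample"):
            bk.mann_whitney_greater([], [1.0])


class TestEnrich:
    def test_hand_computed_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(20)]
        term = universe[:5]
        study = universe[:3] + universe[10:12]  # 3 hits
        rows = bk.enrich(study, {"term": term}, universe)
        assert rows[0].hits == 3
        assert rows[0].p_value == pytest.approx(1126 / 15504)

    def test_term_equal_to_universe_has_unit_p(self):
        universe = [f"g{i}" for i in range(10)]
        rows = bk.enrich(universe[:4], {"all": universe}, universe)
        assert rows[0].p_value == pytest.approx(1.0)

    def test_bh_step_up_hand_fixture(self):
        # craft three terms whose raw p values are 0.01, 0.02, 0.04 and
        # check the adjusted values against the hand-run step-up procedure
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.04], method="fdr_bh")
        assert q == pytest.approx([0.03, 0.03, 0.04])

    def test_q_values_monotone_in_p(self):
        universe = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        annotation = {
            f"t{k}": sorted(rng.choice(universe, size=8, replace=False)) for k in range(6)
        }
        study = universe[:10]
        rows = bk.enrich(study, annotation, universe)
        ordered = sorted(rows, key=lambda r: r.p_value)
        qs = [r.q_value for r in ordered]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(0 <= r.q_value <= 1 for r in rows)

    def test_study_outside_universe_rejected(self):
        with pytest.raises(StatsError, match="study outside universe"):
            bk.enrich({"zz"}, {"t": ["g1"]}, {"g1"})

    def test_exclusion_set_removed_before_testing(self):
        universe = [f"g{i}" for i in range(20)]
        term = universe[:5]
        rows = bk.enrich(universe[:5], {"t": term}, universe, exclude=universe[:5])
        assert rows[0].hits == 0


class TestConnectivity:
    def _sparse_net_with_clique(self):
        edges = [(f"n{i}", f"n{i+1}", 0.95) for i in range(14)]  # path of 15 nodes
        clique = ["c0", "c1", "c2", "c3"]
        edges += [(a, b, 0.95) for a, b in itertools.combinations(clique, 2)]
        edges += [("c0", "n0", 0.95)]  # connect components
        return bk.GeneNetwork.from_edges(edges), clique

    def test_zero_internal_edges_gives_probability_one(self):
        net, _ = self._sparse_net_with_clique()
        observed, prob, freq = bk.connectivity_score(
            net, {"n0", "n5", "n10"}, n_random=50, seed=0
        )
        assert observed == 0
        assert prob == 1.0 and freq == 1.0

    def test_embedded_clique_is_extreme(self):
        net, clique = self._sparse_net_with_clique()
        n = 100
        observed, prob, _ = bk.connectivity_score(net, clique, n_random=n, seed=1)
        assert observed == 6
        assert prob <= 2 / (n + 1)

    def test_replicates_preserve_degree_sequence(self):
        net, _ = self._sparse_net_with_clique()
        genes = ["n1", "n5", "c1"]  # degrees 2, 2, 3: exact matches exist
        rng = np.random.default_rng(2)
        want = sorted(net.degree(g) for g in genes)
        for _ in range(20):
            rep = sample_degree_matched(net, genes, rng)
            assert len(rep) == len(genes)
            assert sorted(net.degree(g) for g in rep) == want

    def test_nearest_degree_fallback_when_no_exact_match(self, caplog):
        import logging

        # hub has the unique maximum degree: no exact-degree replacement exists
        net = bk.GeneNetwork.from_edges([("hub", f"l{i}", 0.9) for i in range(5)])
        rng = np.random.default_rng(0)
        with caplog.at_level(logging.WARNING, logger="brainko.stats"):
            rep = sample_degree_matched(net, ["hub"], rng)
        assert "widened" in caplog.text
        assert rep <= {f"l{i}" for i in range(5)}


class TestRerank:
    def _rows(self):
        return [
            bk.EnrichmentRow(term="wired", term_size=5, hits=3, p_value=0.01,
                             connectivity_prob=0.001),
            bk.EnrichmentRow(term="loose", term_size=5, hits=3, p_value=0.01,
                             connectivity_prob=0.5),
        ]

    def test_most_connected_first(self):
        ordered = bk.rerank_by_connectivity(self._rows())
        assert [r.term for r in ordered] == ["wired", "loose"]
        assert ordered[0].rank_by_connectivity == 1

    def test_probability_ties_fall_back_to_p_order(self):
        rows = self._rows()
        for r in rows:
            r.connectivity_prob = 0.2
        rows[1].p_value = 0.001
        ordered = bk.rerank_by_connectivity(rows)
        assert [r.term for r in ordered] == ["loose", "wired"]

    def test_significant_but_poorly_connected_term_drops(self):
        # a term highly significant by overlap but with weakly connected genes
        # falls behind less significant, tightly wired terms after re-ranking
        rows = [
            bk.EnrichmentRow(term="hub_term", term_size=6, hits=4, p_value=0.02,
                             connectivity_prob=0.01),
            bk.EnrichmentRow(term="scattered", term_size=6, hits=5, p_value=0.001,
                             connectivity_prob=0.9),
        ]
        by_p = sorted(rows, key=lambda r: r.p_value)
        assert by_p[0].term == "scattered"
        ordered = bk.rerank_by_connectivity(rows)
        assert ordered[0].term == "hub_term"

    def test_enrichment_tsv_written(self, tmp_path):
        path = tmp_path / "enrich.tsv"
        write_enrichment_tsv(bk.rerank_by_connectivity(self._rows()), path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t")[0] == "term"
        assert len(lines) == 3


class TestKnownTargetCurve:
    def test_all_known_everywhere(self):
        effects = {f"g{i}": float(i) for i in range(10)}
        curve = bk.known_target_ratio_curve(effects, set(effects), n_bins=5)
        assert all(ratio == 1.0 for _, _, ratio in curve)

    def test_none_known(self):
        effects = {f"g{i}": float(i) for i in range(10)}
        curve = bk.known_target_ratio_curve(effects, set(), n_bins=5)
        assert all(ratio == 0.0 for _, _, ratio in curve)

    def test_top_half_known_two_bins(self):
        effects = {f"g{i}": float(i) for i in range(10)}
        known = {f"g{i}" for i in range(5, 10)}
        curve = bk.known_target_ratio_curve(effects, known, n_bins=2)
        assert [ratio for _, _, ratio in curve] == [0.0, 1.0]

    def test_bin_ranges_ascend(self):
        rng = np.random.default_rng(1)
        effects = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0, 10, 50))}
        curve = bk.known_target_ratio_curve(effects, set(), n_bins=5)
        lows = [lo for lo, _, _ in curve]
        assert lows == sorted(lows)


class TestGMT:
    def test_round_trip(self, tmp_path):
        sets = {"apoptosis": ["CASP3", "CASP8"], "other": ["TP53"]}
        path = tmp_path / "sets.gmt"
        bk.write_gmt(sets, path, description="na")
        assert bk.read_gmt(path) == sets

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_one_field\n")
        with pytest.raises(StatsError, match="malformed GMT"):
            bk.read_gmt(path)


class TestScoreConnectivity:
    def test_connectivity_columns_filled_for_hit_sets(self):
        net, clique = bk.GeneNetwork(), None
        import itertools as it

        edges = [(a, b, 0.95) for a, b in it.combinations(["c0", "c1", "c2", "c3"], 2)]
        edges += [(f"m{i}", f"m{i+1}", 0.95) for i in range(10)]
        edges += [("c0", "m0", 0.95)]
        net = bk.GeneNetwork.from_edges(edges)
        study = ["c0", "c1", "c2", "c3", "m3"]
        annotation = {"cliqueterm": ["c0", "c1", "c2", "c3"], "pathterm": ["m1", "m3", "m5"]}
        rows = bk.enrich(study, annotation, sorted(net.nodes))
        rows = score_connectivity(rows, net, annotation, study, n_random=50, seed=0)
        by_term = {r.term: r for r in rows}
        assert by_term["cliqueterm"].observed_edges == 6
        assert by_term["cliqueterm"].connectivity_prob < by_term["pathterm"].connectivity_prob
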