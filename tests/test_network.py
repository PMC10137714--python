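"""Edge retention rule, hubs, ORA closed forms, and GSEA running sum."""

import math

import numpy as np
import pandas as pd
import pytest

from tsrnakit.duplex import DuplexHit
from tsrnakit.network import (NetworkEdge, build_network, correlate,
                              enrichment_score, gsea_preranked, hub_nodes,
                              ora_hypergeometric, read_gmt)


class TestCorrelate:
    def test_perfect_linear(self):
        x = [1.0, 2, 3, 4, 5]
        r, p, defined = correlate(x, [2 * v + 1 for v in x])
        assert defined and r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = [1.0, 2, 3, 4, 5]
        r, _, _ = correlate(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        r, p, _ = correlate(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(r_hand, abs=1e-12)
        t = r_hand * math.sqrt(4 / (1 - r_hand ** 2))
        from scipy import stats
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 4), abs=1e-12)

    def test_constant_vector_flagged(self):
        r, p, defined = correlate([1.0, 1, 1], [1.0, 2, 3])
        assert not defined and math.isnan(r)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [1, 2])


def _de_row(direction):
    sig = direction != "ns"
    return {"log2fc": 2.0 if direction == "up_in_A" else -2.0,
            "p_value": 0.01 if sig else 0.9, "fdr": 0.05,
            "significant": sig, "direction": direction}


def _toy_network(reg_dir, gene_dir, corr_sign, with_hit):
    samples = ["A1", "A2", "A3", "B1", "B2", "B3"]
    de_reg = pd.DataFrame({"r1": _de_row(reg_dir)}).T
    de_mrna = pd.DataFrame({"g1": _de_row(gene_dir)}).T
    base = np.array([10.0, 12, 11, 80, 82, 81])
    reg_expr = pd.DataFrame({"r1": base}, index=samples).T
    gene = base * corr_sign + (100.0 if corr_sign < 0 else 0.0)
    gene_expr = pd.DataFrame({"g1": gene}, index=samples).T
    hits = [DuplexHit("r1", "g1", 10, 15, -25.0, "full_2_7", ())] \
        if with_hit else []
    return build_network(de_reg, de_mrna, hits, reg_expr, gene_expr)


class TestEdgeRetention:
    def test_full_conjunction_retains(self):
        edges, degree = _toy_network("up_in_B", "up_in_A", -1, True)
        assert len(edges) == 1 and edges[0].retained
        assert set(degree["node"]) == {"r1", "g1"}

    @pytest.mark.parametrize("reg_dir,gene_dir,corr_sign,with_hit", [
        ("up_in_B", "up_in_A", +1, True),   # positively correlated
        ("up_in_B", "up_in_B", -1, True),   # same DE direction
        ("ns", "up_in_A", -1, True),        # regulator not DE
        ("up_in_B", "ns", -1, True),        # target not DE
    ])
    def test_any_broken_condition_rejects(self, reg_dir, gene_dir, corr_sign,
                                          with_hit):
        edges, _ = _toy_network(reg_dir, gene_dir, corr_sign, with_hit)
        assert len(edges) == 1 and not edges[0].retained

    def test_no_hit_no_edge(self):
        edges, _ = _toy_network("up_in_B", "up_in_A", -1, False)
        assert edges == []


class TestHubNodes:
    def test_star_graph_center(self):
        edges = [NetworkEdge("C", f"g{i}", -25.0, -0.9, 0.01, True)
                 for i in range(5)]
        assert hub_nodes(edges, 1) == [("C", 5)]

    def test_empty(self):
        assert hub_nodes([], 3) == []

    def test_degree_ties_lexicographic(self):
        edges = [NetworkEdge("b", "x1", -25.0, -0.9, 0.01, True),
                 NetworkEdge("a", "x2", -25.0, -0.9, 0.01, True)]
        top = hub_nodes(edges, 4)
        assert top == [("a", 1), ("b", 1), ("x1", 1), ("x2", 1)]


class TestOra:
    def test_complete_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        res = ora_hypergeometric(universe[:5], universe,
                                 {"term": universe[:5]})
        assert res.loc["term", "p_value"] == pytest.approx(
            1 / math.comb(20, 5), abs=1e-12)

    def test_zero_overlap_exact(self):
        universe = [f"g{i}" for i in range(20)]
        res = ora_hypergeometric(universe[:5], universe,
                                 {"term": universe[15:18]})
        # P(X >= 0) = 1 exactly
        assert res.loc["term", "p_value"] == pytest.approx(1.0, abs=1e-12)

    def test_query_equals_universe(self):
        universe = [f"g{i}" for i in range(10)]
        res = ora_hypergeometric(universe, universe, {"t": universe[:4]})
        assert res.loc["t", "overlap"] == 4
        assert res.loc["t", "p_value"] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(["x"], ["a", "b"], {"t": ["a"]})


def brute_force_es(genes, scores, members, weight=1.0):
    """Direct running-sum computation, step by step."""
    hit_w = sum(abs(s) ** weight for g, s in zip(genes, scores)
                if g in members)
    miss = 1.0 / (len(genes) - len([g for g in genes if g in members]))
    total, best = 0.0, 0.0
    for g, s in zip(genes, scores):
        if g in members:
            total += abs(s) ** weight / hit_w
        else:
            total -= miss
        if abs(total) > abs(best):
            best = total
    return best


class TestGsea:
    def test_set_at_top_gives_unit_es(self):
        ranked = pd.Series(np.linspace(5, 1, 10),
                           index=[f"g{i}" for i in range(10)])
        es, _ = enrichment_score(list(ranked.index), ranked.to_numpy(),
                                 ["g0", "g1", "g2"])
        assert es == pytest.approx(1.0)

    def test_set_at_bottom_negative(self):
        ranked = pd.Series(np.linspace(5, 1, 10),
                           index=[f"g{i}" for i in range(10)])
        es, _ = enrichment_score(list(ranked.index), ranked.to_numpy(),
                                 ["g7", "g8", "g9"])
        assert es < 0

    def test_matches_brute_force_running_sum(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(10)]
        for _ in range(20):
            scores = rng.normal(size=10)
            order = np.argsort(-scores)
            ranked_genes = [genes[i] for i in order]
            ranked_scores = scores[order]
            members = set(rng.choice(genes, size=3, replace=False))
            es, _ = enrichment_score(ranked_genes, ranked_scores, members)
            assert es == pytest.approx(
                brute_force_es(ranked_genes, ranked_scores, members))

    def test_unweighted_es_invariant_to_monotone_rescaling(self):
        genes = [f"g{i}" for i in range(12)]
        scores = np.linspace(6, -6, 12)
        members = ["g1", "g4", "g9"]
        es1, _ = enrichment_score(genes, scores, members, weight=0.0)
        es2, _ = enrichment_score(genes, 10 * scores + 3, members, weight=0.0)
        assert es1 == pytest.approx(es2)

    def test_permutation_p_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        ranked = pd.Series(rng.normal(size=40),
                           index=[f"g{i}" for i in range(40)])
        gmt = {"t1": [f"g{i}" for i in range(0, 8)],
               "t2": [f"g{i}" for i in range(20, 26)]}
        a = gsea_preranked(ranked, gmt, n_perm=200, seed=7)
        b = gsea_preranked(ranked, gmt, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_set_skipped(self):
        ranked = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        res = gsea_preranked(ranked, {"t": ["zzz"]}, n_perm=10, seed=0)
        assert len(res) == 0


def test_read_gmt_roundtrip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("t1\tdesc\tg1\tg2\tg3\nt2\tdesc\tg9\n")
    sets = read_gmt(path)
    assert sets == {"t1": ["g1", "g2", "g3"], "t2": ["g9"]}
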