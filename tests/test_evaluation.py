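import random

import networkx as nx
import numpy as np
import pytest

from conftest import random_graph
from oracles import confusion_sweep_auroc
from diffcentral import (
    GOAnnotationMap,
    RewireConfig,
    SampleInstance,
    build_instance_set,
    goc_score,
    restrict_go_level,
    rewire,
    rewiring_experiment,
    roc_pr_sweep,
    top_fraction,
)
from diffcentral.evaluation import term_levels
from diffcentral.measures import compute_measure


class TestTopFraction:
    @pytest.mark.parametrize(
        "n,k,expected",
        [(10, 100, 10), (250, 1, 3), (100, 7, 7)],
    )
    def test_ceil_rule(self, n, k, expected):
        ranking = [f"g{i}" for i in range(n)]
        assert len(top_fraction(ranking, k)) == expected

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            top_fraction(["a"], 0)


class TestRocPrSweep:
    def test_perfect_ranking(self):
        ranking = [f"g{i}" for i in range(50)]
        curve = roc_pr_sweep(ranking, set(ranking[:5]))
        assert curve.auroc == pytest.approx(1.0)

    def test_hand_trapezoid_example(self):
        curve = roc_pr_sweep(["g1", "g2", "g3", "g4"], {"g1", "g3"}, full_resolution=True)
        assert curve.auroc == pytest.approx(0.75)

    def test_matches_confusion_matrix_oracle(self):
        rng = random.Random(8)
        for _ in range(30):
            n = rng.randint(4, 20)
            ranking = [f"g{i}" for i in range(n)]
            rng.shuffle(ranking)
            gold = set(rng.sample(ranking, rng.randint(1, n - 1)))
            curve = roc_pr_sweep(ranking, gold, full_resolution=True)
            assert curve.auroc == pytest.approx(
                confusion_sweep_auroc(ranking, gold, set(ranking)), abs=1e-12
            )

    def test_random_ranking_near_half(self):
        rng = random.Random(4)
        ranking = [f"g{i}" for i in range(2000)]
        rng.shuffle(ranking)
        gold = set(rng.sample(ranking, 100))
        curve = roc_pr_sweep(ranking, gold)
        assert curve.auroc == pytest.approx(0.5, abs=0.08)

    def test_reversal_sums_to_one(self):
        rng = random.Random(12)
        ranking = [f"g{i}" for i in range(40)]
        rng.shuffle(ranking)
        gold = set(rng.sample(ranking, 7))
        fwd = roc_pr_sweep(ranking, gold, full_resolution=True).auroc
        rev = roc_pr_sweep(ranking[::-1], gold, full_resolution=True).auroc
        # trapezoid discretization: each ranking credits half a step per gold gene
        assert fwd + rev == pytest.approx(1.0, abs=1 / len(gold))

    def test_bounds_and_monotonicity(self):
        ranking = [f"g{i}" for i in range(30)]
        curve = roc_pr_sweep(ranking, {"g3", "g9", "g25"})
        pts = curve.points
        for col in ("tpr", "fpr", "precision", "recall"):
            assert ((0 <= pts[col]) & (pts[col] <= 1)).all()
        assert pts["tpr"].is_monotonic_increasing
        assert pts["fpr"].is_monotonic_increasing

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_sweep(["a", "b"], {"z"})


def _chain_ontology():
    """Root -> ... chain of depth 8 with a fork at level 5 and a deep term."""
    dag = nx.DiGraph()
    terms = [f"T{i}" for i in range(9)]
    for child, parent in zip(terms[1:], terms):
        dag.add_edge(child, parent)  # Ti at level i
    # a level-7 term with two distinct level-5 ancestors
    dag.add_edge("T5b", "T4")
    dag.add_edge("deep6", "T5")
    dag.add_edge("deep6b", "T5b")
    dag.add_edge("deep7", "deep6")
    dag.add_edge("deep7", "deep6b")
    return dag


class TestGoLevelRestriction:
    def test_term_levels_shortest_path(self):
        dag = _chain_ontology()
        levels = term_levels(dag)
        assert levels["T0"] == 0 and levels["T5"] == 5 and levels["deep7"] == 7

    def test_level5_kept_level3_dropped(self):
        ann = GOAnnotationMap({"g": {"T5", "T3"}}, _chain_ontology())
        out = restrict_go_level(ann, level=5)
        assert out.annotations["g"] == {"T5"}

    def test_deep_term_resolves_to_all_level5_ancestors(self):
        ann = GOAnnotationMap({"g": {"deep7"}}, _chain_ontology())
        out = restrict_go_level(ann, level=5)
        assert out.annotations["g"] == {"T5", "T5b"}

    def test_bfs_ancestor_oracle_on_random_dags(self):
        """Replacement terms = exactly the ancestors whose min depth is 5."""
        dag = _chain_ontology()
        levels = term_levels(dag)
        for term in dag.nodes:
            if levels[term] <= 5:
                continue
            expected = {a for a in nx.descendants(dag, term) if levels[a] == 5}
            out = restrict_go_level(GOAnnotationMap({"g": {term}}, dag), 5)
            assert out.annotations["g"] == expected


class TestGocScore:
    def _ann(self, mapping):
        dag = nx.DiGraph()
        dag.add_nodes_from({t for ts in mapping.values() for t in ts})
        return GOAnnotationMap({g: set(ts) for g, ts in mapping.items()}, dag)

    def test_identical_annotations_give_test_size(self):
        ann = self._ann({"t1": {"a"}, "t2": {"a"}, "r1": {"a"}, "r2": {"a"}})
        assert goc_score(["t1", "t2"], ["r1", "r2"], ann) == pytest.approx(2.0)

    def test_disjoint_annotations_give_zero(self):
        ann = self._ann({"t": {"a"}, "r": {"b"}})
        assert goc_score(["t"], ["r"], ann) == 0.0

    def test_three_gene_worked_example(self):
        ann = self._ann({"t": {"g1", "g2"}, "r1": {"g1"}, "r2": {"g2", "g3"}})
        assert goc_score(["t"], ["r1", "r2"], ann) == pytest.approx(5 / 12)

    def test_linear_in_test_list(self):
        rng = random.Random(3)
        terms = [f"x{i}" for i in range(6)]
        mapping = {f"g{i}": set(rng.sample(terms, rng.randint(1, 4))) for i in range(10)}
        ann = self._ann(mapping)
        t1, t2 = ["g0", "g1", "g2"], ["g3", "g4"]
        ref = ["g5", "g6", "g7"]
        assert goc_score(t1 + t2, ref, ann) == pytest.approx(
            goc_score(t1, ref, ann) + goc_score(t2, ref, ann)
        )

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            goc_score(["t"], [], self._ann({"t": {"a"}}))


class TestRewire:
    def test_ratio_zero_is_identity(self, tiny_interactome):
        out = rewire(tiny_interactome, 0, seed=1)
        assert set(map(frozenset, out.edges)) == set(map(frozenset, tiny_interactome.edges))

    def test_invariants_on_random_graphs(self):
        rng = random.Random(77)
        for _ in range(20):
            g = random_graph(rng, n_min=8, n_max=25, p=0.3)
            if g.number_of_edges() < 2:
                continue
            ratio = rng.choice([5, 10, 20, 50])
            out = rewire(g, ratio, seed=rng.randint(0, 10**6))
            assert set(out.nodes) == set(g.nodes)
            assert out.number_of_edges() == g.number_of_edges()
            new_edges = set(map(frozenset, out.edges)) - set(map(frozenset, g.edges))
            for e in new_edges:
                u, v = tuple(e)
                assert not g.has_edge(u, v)  # inserted pairs were non-adjacent

    def test_same_seed_reproducible(self, tiny_interactome):
        a = rewire(tiny_interactome, 50, seed=9)
        b = rewire(tiny_interactome, 50, seed=9)
        assert set(map(frozenset, a.edges)) == set(map(frozenset, b.edges))

    def test_infeasible_on_complete_graph(self):
        g = nx.complete_graph(5)
        with pytest.raises(ValueError, match="non-adjacent"):
            rewire(g, 50, seed=0)


class TestRewiringExperiment:
    @pytest.fixture
    def setup(self, tiny_interactome):
        genes = set(tiny_interactome.nodes)
        instances = [
            SampleInstance(f"i{k}", set(genes), genes - ({"g2"} if k % 2 else set()), set())
            for k in range(4)
        ]
        fns = {"m_deg1": lambda pairs: compute_measure("m_deg1", pairs)}
        return tiny_interactome, instances, fns

    def test_ratio_zero_reproduces_plain_evaluation(self, setup):
        H, instances, fns = setup
        res = rewiring_experiment(H, instances, fns, {"g1"},
                                  RewireConfig(ratios=(0,), replicates=2, seed=5))
        pairs = build_instance_set(H, instances)
        plain = roc_pr_sweep(compute_measure("m_deg1", pairs).ranking(), {"g1"}, pairs.universe)
        assert np.allclose(res.runs["auroc"], plain.auroc)

    def test_graph_count_bookkeeping(self, setup):
        H, instances, fns = setup
        res = rewiring_experiment(H, instances, fns, {"g1"},
                                  RewireConfig(ratios=(5, 10), replicates=3, seed=5))
        assert res.graphs_built == 2 * len(instances) * 2 * 3
        assert len(res.runs) == 2 * 3  # one row per (ratio, replicate) per measure
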