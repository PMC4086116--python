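"""Gene scoring: reciprocal-p sums, cross-category propagation against a
dense linear-operator oracle, HITS-with-priors against a power-iteration
oracle and against the standard HITS routine."""

import networkx as nx
import numpy as np
import pytest

from mirprio.enrichment import enrich
from mirprio.generank import (
    HitsPriorConfig,
    PropagationConfig,
    category_scores,
    fuse_and_rank,
    hits_with_priors,
    propagate,
)
from mirprio.io import GeneList


# --- reciprocal-p category scores -----------------------------------------

class TestCategoryScores:
    def test_sum_of_reciprocal_pvalues(self, toy_corpus, toy_query):
        enr = enrich(toy_query, toy_corpus, min_K=2, max_K=100)
        scores = category_scores(enr, toy_query)
        sig = enr.significant.set_index("concept_id")
        expected_a = sum(
            1.0 / sig.loc[cid, "p_raw"]
            for cid in sig.index
            if "A" in sig.loc[cid, "members_hit"] and sig.loc[cid, "category"] == "GO_BP"
        )
        assert scores["A"]["GO_BP"] == pytest.approx(expected_a)

    def test_gene_in_no_significant_concept_scores_zero(self, toy_corpus):
        query = GeneList(genes=("A", "B", "C", "D"))
        enr = enrich(query, toy_corpus, min_K=2, max_K=100)
        scores = category_scores(enr, query)
        in_any = set().union(*enr.significant["members_hit"]) if len(enr.significant) else set()
        for g in query:
            if g not in in_any:
                assert all(v == 0.0 for v in scores[g].values())

    def test_identical_annotation_identical_score(self, toy_corpus, toy_query):
        enr = enrich(toy_query, toy_corpus, min_K=2, max_K=100)
        scores = category_scores(enr, toy_query)
        # A and B share exactly the same concepts (BP1, BP3, P1, P3)
        assert scores["A"] == scores["B"]

    def test_adding_a_significant_concept_never_decreases(self, toy_corpus, toy_query):
        enr = enrich(toy_query, toy_corpus, min_K=2, max_K=100)
        base = category_scores(enr, toy_query)
        # re-run with a laxer alpha so strictly more concepts are significant
        enr_lax = enrich(toy_query, toy_corpus, alpha_sig=1.0, min_K=2, max_K=100)
        lax = category_scores(enr_lax, toy_query)
        for g in toy_query:
            for c in base[g]:
                assert lax[g][c] >= base[g][c] - 1e-12


# --- cross-category propagation -------------------------------------------

def dense_propagation_oracle(enr, genes, cat_scores, damping, tol, max_iter):
    """Same operator, independently built as dense matrices."""
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    sig = enr.significant
    cats = sorted(
        c for c in sig["category"].unique()
        if sum(cat_scores[g].get(c, 0.0) for g in genes) > 0
    )
    mats = []
    for c in cats:
        rows = sig[sig["category"] == c]
        w = 1.0 / rows["p_raw"].to_numpy(float)
        w = w / w.sum()
        M = np.zeros((n, n))
        for weight, hit in zip(w, rows["members_hit"]):
            members = [idx[g] for g in hit if g in idx]
            if not members:
                continue
            for g in members:
                for g2 in members:
                    M[g, g2] += weight / len(members)
        mats.append(M)
    M = sum(mats) / len(mats)
    per_cat = []
    for c in cats:
        v = np.array([cat_scores[g].get(c, 0.0) for g in genes])
        per_cat.append(v / v.sum())
    x0 = np.mean(per_cat, axis=0)
    x0 = x0 / x0.sum()
    x = x0.copy()
    for _ in range(max_iter):
        y = damping * (M @ x) + (1 - damping) * x0
        y = y / y.sum()
        if np.max(np.abs(y - x)) < tol:
            return y
        x = y
    return x


class TestPropagate:
    def _enr(self, corpus, query):
        return enrich(query, corpus, alpha_sig=1.0, min_K=2, max_K=100)

    def test_single_category_converges_immediately(self, toy_corpus):
        query = GeneList(genes=("A", "B", "C"))
        corpus_one = toy_corpus.restrict(["GO_BP"])
        enr = self._enr(corpus_one, query)
        cat = category_scores(enr, query)
        combined, info = propagate(cat, enr, query)
        assert info.converged
        assert sum(combined.values()) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_genes_get_uniform_scores(self, toy_corpus):
        # A and B have identical annotations everywhere
        query = GeneList(genes=("A", "B"))
        enr = self._enr(toy_corpus, query)
        cat = category_scores(enr, query)
        combined, _ = propagate(cat, enr, query)
        assert combined["A"] == pytest.approx(combined["B"], abs=1e-12)
        assert combined["A"] == pytest.approx(0.5, abs=1e-10)

    def test_fixed_point_matches_dense_oracle(self, small_bundle):
        genes = GeneList(genes=tuple(sorted(small_bundle.training)), label="t")
        enr = self._enr(small_bundle.corpus, genes)
        cat = category_scores(enr, genes)
        cfg = PropagationConfig(tol=1e-12, max_iter=2000)
        combined, info = propagate(cat, enr, genes, config=cfg)
        assert info.converged
        oracle = dense_propagation_oracle(
            enr, list(genes), cat, cfg.damping, 1e-12, 2000
        )
        got = np.array([combined[g] for g in genes])
        assert np.max(np.abs(got - oracle)) < 1e-9

    def test_mass_conserved_every_iteration(self, small_bundle):
        genes = GeneList(genes=tuple(sorted(small_bundle.training)), label="t")
        enr = self._enr(small_bundle.corpus, genes)
        cat = category_scores(enr, genes)
        _, info = propagate(cat, enr, genes)
        assert info.converged and info.n_iter <= 1000
        assert all(abs(m - 1.0) < 1e-9 for m in info.masses)

    def test_all_zero_scores_warns_and_returns_zeros(self, toy_corpus, caplog):
        query = GeneList(genes=("A", "B", "C"))
        enr = enrich(query, toy_corpus, alpha_sig=1e-12, min_K=2, max_K=100)
        cat = category_scores(enr, query)
        combined, info = propagate(cat, enr, query)
        assert set(combined.values()) == {0.0}
        assert info.converged


# --- HITS with priors ------------------------------------------------------

def hits_priors_oracle(adj, prior, beta, n_iter=20000):
    """Independently coded dense power iteration."""
    a = prior.copy()
    h = prior.copy()
    for _ in range(n_iter):
        a = (1 - beta) * _l1(adj.T @ h) + beta * prior
        h = (1 - beta) * _l1(adj @ a) + beta * prior
    return a


def _l1(v):
    s = v.sum()
    return v / s if s > 0 else v


def random_connected_graph(n, rng):
    g = nx.gnp_random_graph(n, 3.0 / n, seed=int(rng.integers(2**31)))
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()
    mapping = {node: f"N{node:03d}" for node in g.nodes}
    return nx.relabel_nodes(g, mapping)


class TestHitsWithPriors:
    def test_beta_one_returns_prior(self):
        edges = [("A", "B"), ("B", "C"), ("C", "D")]
        out = hits_with_priors(edges, ["A", "C"], HitsPriorConfig(beta=1.0))
        assert out == {"A": 0.5, "B": 0.0, "C": 0.5, "D": 0.0}

    def test_beta_zero_matches_standard_hits(self):
        rng = np.random.default_rng(11)
        g = random_connected_graph(12, rng)
        edges = list(g.edges)
        out = hits_with_priors(edges, list(g.nodes)[:3], HitsPriorConfig(beta=0.0, tol=1e-12))
        _, authorities = nx.hits(g, max_iter=5000, tol=1e-12)
        total = sum(authorities.values())
        for node in g.nodes:
            assert out[node] == pytest.approx(authorities[node] / total, abs=1e-6)

    @pytest.mark.parametrize("n,seed", [(5, 0), (20, 1), (50, 2)])
    def test_fixed_point_matches_power_iteration_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(n, rng)
        nodes = sorted(g.nodes)
        root = nodes[: max(2, n // 5)]
        out = hits_with_priors(list(g.edges), root, HitsPriorConfig(beta=0.3, tol=1e-14))
        adj = nx.to_numpy_array(g, nodelist=nodes)
        prior = np.array([1.0 if v in root else 0.0 for v in nodes])
        prior /= prior.sum()
        oracle = hits_priors_oracle(adj, prior, 0.3, n_iter=5000)
        got = np.array([out[v] for v in nodes])
        assert np.max(np.abs(got - oracle)) < 1e-10

    def test_output_is_probability_vector_and_label_invariant(self):
        edges = [("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")]
        out = hits_with_priors(edges, ["A"], HitsPriorConfig(beta=0.4))
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in out.values())
        relabel = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        edges2 = [(relabel[u], relabel[v]) for u, v in edges]
        out2 = hits_with_priors(edges2, ["W"], HitsPriorConfig(beta=0.4))
        for k, v in out.items():
            assert out2[relabel[k]] == pytest.approx(v, abs=1e-12)

    def test_root_absent_from_graph_is_an_error(self):
        with pytest.raises(ValueError, match="root"):
            hits_with_priors([("A", "B")], ["Z"], HitsPriorConfig())


# --- fusion and ranking -----------------------------------------------------

class TestFuseAndRank:
    def test_no_interactome_preserves_combined_order(self):
        combined = {"A": 0.5, "B": 0.3, "C": 0.2}
        table = fuse_and_rank(combined)
        assert table.genes_by_rank == ["A", "B", "C"]
        assert np.isnan(table.table["interactome"]).all()

    def test_weight_one_ignores_interactome(self):
        combined = {"A": 0.5, "B": 0.3}
        inter = {"A": 0.0, "B": 1.0}
        table = fuse_and_rank(combined, interactome=inter, weight=1.0)
        assert table.genes_by_rank == ["A", "B"]

    def test_opposing_signals_tie_broken_by_gene_id(self):
        combined = {"A": 1.0, "B": 0.0}
        inter = {"A": 0.0, "B": 1.0}
        table = fuse_and_rank(combined, interactome=inter, weight=0.5)
        assert table.genes_by_rank == ["A", "B"]
        assert table.table.at["A", "final"] == pytest.approx(table.table.at["B", "final"])

    def test_ranks_are_a_permutation(self, small_bundle):
        genes = sorted(small_bundle.genes)[:20]
        rng = np.random.default_rng(0)
        combined = {g: float(rng.random()) for g in genes}
        inter = {g: float(rng.random()) for g in genes}
        table = fuse_and_rank(combined, interactome=inter, weight=0.5)
        assert sorted(table.table["rank"]) == list(range(1, 21))
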