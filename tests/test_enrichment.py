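import numpy as np
import pytest

from moable.enrichment import (
    RankedGeneList,
    direct_signature_enrichment,
    enrichment_score,
    gsea_preranked,
    _es_from_positions,
)
from moable.errors import ValidationError
from moable.io_formats import PathwayCollection


def oracle_running_sum_es(genes, scores, gene_set, p):
    """Independent step-by-step running-sum implementation."""
    n = len(genes)
    hits = [g in gene_set for g in genes]
    k = sum(hits)
    nr = sum(abs(s) ** p for s, h in zip(scores, hits) if h)
    cur, best, best_abs = 0.0, 0.0, -1.0
    for g, s, h in zip(genes, scores, hits):
        if h:
            cur += (abs(s) ** p / nr) if nr > 0 else 1.0 / k
        else:
            cur -= 1.0 / (n - k) if n > k else 0.0
        if abs(cur) > best_abs + 1e-12:
            best, best_abs = cur, abs(cur)
    return best


class TestRankedGeneList:
    def test_sorted_descending_with_gene_id_tiebreak(self):
        r = RankedGeneList(["b", "a", "c"], [1.0, 1.0, 2.0])
        assert r.genes == ["c", "a", "b"]

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValidationError):
            RankedGeneList(["a", "a"], [1.0, 2.0])


class TestEnrichmentScore:
    def test_lone_top_hit_unweighted(self):
        ranked = RankedGeneList(["g1", "g2"], [1.0, 0.5])
        es, running = enrichment_score(ranked, {"g1"}, 0.0)
        assert es == pytest.approx(1.0)
        np.testing.assert_allclose(running, [1.0, 0.0])

    def test_set_covering_whole_list(self):
        ranked = RankedGeneList(["a", "b", "c"], [3.0, 2.0, 1.0])
        es, _ = enrichment_score(ranked, {"a", "b", "c"}, 1.0)
        assert es == pytest.approx(1.0)

    def test_matches_independent_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 51))
            k = int(rng.integers(1, min(n, 10) + 1))
            genes = [f"g{i}" for i in range(n)]
            ranked = RankedGeneList(genes, rng.standard_normal(n))
            gs = set(rng.choice(ranked.genes, size=k, replace=False))
            for p in (0.0, 1.0):
                es, _ = enrichment_score(ranked, gs, p)
                assert es == pytest.approx(
                    oracle_running_sum_es(ranked.genes, ranked.scores, gs, p),
                    abs=1e-9,
                )

    def test_p0_equals_classic_ks_statistic(self, rng):
        """Unweighted ES is the signed sup-difference of the hit and miss
        empirical CDFs along the ranking."""
        for _ in range(100):
            n = int(rng.integers(8, 40))
            genes = [f"g{i}" for i in range(n)]
            ranked = RankedGeneList(genes, rng.standard_normal(n))
            k = int(rng.integers(2, 7))
            gs = set(rng.choice(ranked.genes, size=k, replace=False))
            hits = np.array([g in gs for g in ranked.genes])
            diff = np.cumsum(hits) / k - np.cumsum(~hits) / (n - k)
            ks = diff[np.argmax(np.abs(diff))]
            es, _ = enrichment_score(ranked, gs, 0.0)
            assert abs(es) == pytest.approx(abs(ks), abs=1e-9)
            if abs(diff.max() + diff.min()) > 1e-9:  # no peak/trough tie
                assert es == pytest.approx(ks, abs=1e-9)

    def test_p0_reversal_antisymmetry(self, rng):
        n = 20
        genes = [f"g{i:02d}" for i in range(n)]
        scores = np.sort(rng.standard_normal(n))[::-1]
        ranked = RankedGeneList(genes, scores)
        gs = set(rng.choice(genes, size=5, replace=False))
        es, _ = enrichment_score(ranked, gs, 0.0)
        rev = RankedGeneList(genes, -scores)
        # on the reversed list the same set occupies mirrored positions; with
        # p=0 the running sum is the mirror image, so ES flips sign
        es_rev, _ = enrichment_score(rev, gs, 0.0)
        assert es_rev == pytest.approx(-es, abs=1e-9)

    def test_disjoint_set_rejected(self):
        ranked = RankedGeneList(["a", "b"], [1.0, 0.5])
        with pytest.raises(ValidationError):
            enrichment_score(ranked, {"zzz"}, 1.0)

    def test_vectorized_null_path_equals_full_scan(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 40))
            k = int(rng.integers(1, min(n, 8) + 1))
            scores = rng.standard_normal(n)
            if rng.random() < 0.3:
                scores = np.round(scores)  # provoke ties and zeros
            ranked = RankedGeneList([f"g{i}" for i in range(n)], scores)
            pos = rng.choice(n, size=k, replace=False)
            gs = {ranked.genes[i] for i in pos}
            for p in (0.0, 1.0):
                es, _ = enrichment_score(ranked, gs, p)
                es_vec = _es_from_positions(ranked.scores, pos[None, :], p)[0]
                assert es_vec == pytest.approx(es, abs=1e-9)


class TestGseaPreranked:
    @pytest.fixture
    def ranked(self, rng):
        genes = [f"g{i:02d}" for i in range(40)]
        return RankedGeneList(genes, rng.standard_normal(40))

    @pytest.fixture
    def pathways(self, ranked, rng):
        return PathwayCollection({
            f"P{j}": set(rng.choice(ranked.genes, size=6, replace=False))
            for j in range(5)
        })

    def test_deterministic_given_seed(self, ranked, pathways):
        a = gsea_preranked(ranked, pathways, n_perm=10, seed=3)
        b = gsea_preranked(ranked, pathways, n_perm=10, seed=3)
        assert a == b

    def test_invariant_to_pathway_input_order(self, ranked, pathways):
        a = gsea_preranked(ranked, pathways, n_perm=50, seed=3)
        rev = PathwayCollection(dict(reversed(list(pathways.pathways.items()))))
        b = gsea_preranked(ranked, rev, n_perm=50, seed=3)
        assert a == b

    def test_p_value_floor(self, ranked, pathways):
        res = gsea_preranked(ranked, pathways, n_perm=20, seed=0)
        assert all(r.p_value >= 1 / 21 for r in res)
        assert all(0 < r.p_value <= 1 for r in res)
        assert all(0 <= r.fdr <= 1 for r in res)
        assert all(abs(r.es) <= 1 for r in res)

    def test_size_bounds_exclude_pathways(self, ranked):
        pc = PathwayCollection({
            "small": set(ranked.genes[:2]),
            "ok": set(ranked.genes[:8]),
        })
        res = gsea_preranked(ranked, pc, n_perm=10, seed=0, min_size=5)
        assert [r.pathway_id for r in res] == ["ok"]

    def test_no_overlap_pathway_skipped(self, ranked):
        pc = PathwayCollection({"alien": {"zz1", "zz2", "zz3", "zz4", "zz5"}})
        assert gsea_preranked(ranked, pc, n_perm=10, seed=0) == []

    def test_null_pvalues_approximately_uniform(self, rng):
        from scipy.stats import kstest
        pvals = []
        for _ in range(300):
            genes = [f"g{i}" for i in range(50)]
            ranked = RankedGeneList(genes, rng.standard_normal(50))
            gs = set(rng.choice(genes, size=8, replace=False))
            res = gsea_preranked(ranked, PathwayCollection({"P": gs}),
                                 n_perm=100, seed=int(rng.integers(2**31)),
                                 min_size=1)
            pvals.append(res[0].p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_target_pathway_wins(self, rng):
        """Connectivity-like rankings with one strongly connected gene: the
        pathway holding that gene gets the lowest p among enriched candidates
        for most simulated compounds."""
        wins = 0
        n_sim = 50
        genes = [f"g{i:02d}" for i in range(50)]
        pw = {f"P{j}": set(genes[5 * j:5 * j + 5]) for j in range(10)}
        pc = PathwayCollection(pw)
        for s in range(n_sim):
            lrng = np.random.default_rng(1000 + s)
            target = genes[int(lrng.integers(50))]
            true_pid = next(p for p, gs in pw.items() if target in gs)
            scores = lrng.normal(0, 0.1, 50)
            scores[genes.index(target)] = 0.9
            # sibling pathway genes mildly co-connected
            for g in pw[true_pid]:
                scores[genes.index(g)] += 0.25
            ranked = RankedGeneList(list(genes), scores)
            res = gsea_preranked(ranked, pc, n_perm=200, seed=s)
            pos = [r for r in res if r.es >= 0]
            pmin = min(r.p_value for r in pos)
            if any(r.pathway_id == true_pid and r.p_value <= pmin for r in pos):
                wins += 1
        assert wins / n_sim >= 0.70


class TestDirectSignatureEnrichment:
    def test_equals_gsea_on_preranked_list(self, rng):
        genes = [f"g{i}" for i in range(30)]
        values = rng.standard_normal(30)
        pc = PathwayCollection({
            f"P{j}": set(rng.choice(genes, size=6, replace=False))
            for j in range(3)
        })
        a = direct_signature_enrichment(values, genes, pc, n_perm=50, seed=9)
        b = gsea_preranked(RankedGeneList(genes, values), pc, n_perm=50, seed=9)
        assert a == b

    def test_top_loaded_pathway_has_maximal_es(self, rng):
        genes = [f"g{i:02d}" for i in range(20)]
        values = np.linspace(2.0, -2.0, 20)
        pc = PathwayCollection({
            "top": set(genes[:5]),
            "mid": set(genes[8:13]),
            "bottom": set(genes[-5:]),
        })
        res = direct_signature_enrichment(values, genes, pc, n_perm=20, seed=0)
        by_id = {r.pathway_id: r.es for r in res}
        assert by_id["top"] == max(by_id.values())
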