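import numpy as np
import pytest

from modelcongruence.data_io import (ExpressionMatrix, GeneSetCollection,
                                     SampleAnnotation)
from modelcongruence.de_gsea import (DEResult, EnrichmentResult,
                                     de_results_from_frame,
                                     differential_expression,
                                     enrichment_score, filter_pathways,
                                     preranked_gsea)

from oracles import (bh_adjust, exhaustive_gsea_pvalue, unweighted_ks_es,
                     weighted_ks_es)


def _tumor(vals, labels):
    genes = [f"g{i}" for i in range(vals.shape[0])]
    ids = [f"s{j}" for j in range(vals.shape[1])]
    x = ExpressionMatrix(genes, ids, vals)
    ann = [SampleAnnotation(s, "tumor", lab) for s, lab in zip(ids, labels)]
    return x, ann


class TestDifferentialExpression:
    def test_planted_shift_flagged(self):
        rng = np.random.default_rng(0)
        vals = 0.3 * rng.standard_normal((20, 100))
        vals[0, :50] += 1.0  # log2FC = 1 on gene 0
        x, ann = _tumor(vals, ["A"] * 50 + ["B"] * 50)
        res = differential_expression(x, ann, "A")
        assert res[0].is_de
        assert res[0].log2fc == pytest.approx(1.0, abs=0.2)

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(1)
        rates = []
        for _ in range(20):
            vals = rng.standard_normal((1000, 40))
            x, ann = _tumor(vals, ["A"] * 20 + ["B"] * 20)
            res = differential_expression(x, ann, "A")
            rates.append(np.mean([r.is_de for r in res]))
        assert np.mean(rates) <= 0.08

    def test_conjunction_rule(self):
        res = DEResult(gene="g", log2fc=1.0, pval=0.1, adj_pval=0.2, is_de=False)
        assert not res.is_de  # |log2FC| past threshold but adj p too large
        import pandas as pd
        df = pd.DataFrame([{"gene": "g", "log2fc": 1.0, "pval": 0.1,
                            "adj_pval": 0.2}])
        assert not de_results_from_frame(df)[0].is_de
        df2 = pd.DataFrame([{"gene": "g", "log2fc": 1.0, "pval": 1e-5,
                             "adj_pval": 1e-4}])
        assert de_results_from_frame(df2)[0].is_de

    def test_small_class_errors(self):
        vals = np.random.default_rng(2).standard_normal((5, 5))
        x, ann = _tumor(vals, ["A"] * 2 + ["B"] * 3)
        with pytest.raises(ValueError, match=">= 3 samples"):
            differential_expression(x, ann, "A")

    def test_nb_wald_on_counts(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(50, size=(10, 30)).astype(float)
        base[0, :15] *= 4  # planted 4-fold change
        genes = [f"g{i}" for i in range(10)]
        ids = [f"s{j}" for j in range(30)]
        x = ExpressionMatrix(genes, ids, base, scale="counts")
        ann = [SampleAnnotation(s, "tumor", "A" if j < 15 else "B")
               for j, s in enumerate(ids)]
        res = differential_expression(x, ann, "A", method="nb_wald")
        assert res[0].is_de
        assert res[0].log2fc == pytest.approx(2.0, abs=0.5)

    def test_nb_wald_requires_counts(self):
        vals = np.random.default_rng(4).standard_normal((5, 10))
        x, ann = _tumor(vals, ["A"] * 5 + ["B"] * 5)
        with pytest.raises(ValueError, match="counts"):
            differential_expression(x, ann, "A", method="nb_wald")

    def test_bh_matches_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((50, 20))
        x, ann = _tumor(vals, ["A"] * 10 + ["B"] * 10)
        res = differential_expression(x, ann, "A")
        adj_oracle = bh_adjust([r.pval for r in res])
        for r, q in zip(res, adj_oracle):
            assert r.adj_pval == pytest.approx(q, abs=1e-12)
            assert r.adj_pval >= r.pval - 1e-15


class TestEnrichmentScore:
    def test_weight_zero_equals_classical_ks(self, rng):
        values = np.sort(rng.standard_normal(10))[::-1]
        members = np.array([True, False, True, False, False,
                            True, False, False, False, False])
        es = enrichment_score(values, members, weight_p=0.0)
        assert es == pytest.approx(unweighted_ks_es(list(members)), abs=1e-12)

    def test_weighted_matches_oracle(self, rng):
        values = np.sort(rng.standard_normal(12))[::-1]
        members = np.zeros(12, dtype=bool)
        members[[0, 3, 7, 11]] = True
        es = enrichment_score(values, members, weight_p=1.0)
        assert es == pytest.approx(weighted_ks_es(values, list(members), 1.0), abs=1e-12)

    def test_full_universe_rejected(self):
        with pytest.raises(ValueError, match="proper subset"):
            enrichment_score(np.array([1.0, 0.5]), np.array([True, True]))


class TestPrerankedGsea:
    def test_top_block_is_enriched(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(200)]
        vals = np.sort(rng.standard_normal(200))[::-1]
        ranks = dict(zip(genes, vals))
        sets = GeneSetCollection({"TOP": set(genes[:20])})
        res = preranked_gsea(ranks, sets, n_perm=10000, seed=0)
        assert res[0].nes > 0
        assert res[0].adj_pval < 0.05

    def test_rank_negation_flips_nes(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(60)]
        vals = rng.standard_normal(60)
        sets = GeneSetCollection({"P1": set(genes[:10]), "P2": set(genes[25:40])})
        pos = preranked_gsea(dict(zip(genes, vals)), sets, n_perm=500, seed=3)
        neg = preranked_gsea(dict(zip(genes, -vals)), sets, n_perm=500, seed=3)
        for a, b in zip(pos, neg):
            assert a.nes == pytest.approx(-b.nes, abs=1e-12)
            assert a.pval == b.pval

    def test_small_universe_matches_enumeration(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(10)]
        vals = np.sort(rng.standard_normal(10))[::-1]
        members = [True, False, True, False, False, False, True, False, False, False]
        ranks = dict(zip(genes, vals))
        sets = GeneSetCollection({"P": {g for g, m in zip(genes, members) if m}})
        n_perm = 20000
        res = preranked_gsea(ranks, sets, n_perm=n_perm, seed=1)
        p0 = exhaustive_gsea_pvalue(vals, members, weight_p=1.0)
        expected = (1 + n_perm * p0) / (1 + n_perm)  # add-one estimator mean
        mc_se = np.sqrt(p0 * (1 - p0) / n_perm)
        assert abs(res[0].pval - expected) <= 2 * mc_se + 1e-9

    def test_pathway_exceeding_universe_errors(self):
        ranks = {"a": 1.0, "b": 0.5}
        sets = GeneSetCollection({"P": {"a", "b"}})
        with pytest.raises(ValueError, match="whole ranked universe"):
            preranked_gsea(ranks, sets, n_perm=10, seed=0)

    def test_empty_ranks_error(self):
        with pytest.raises(ValueError, match="empty rank"):
            preranked_gsea({}, GeneSetCollection({"P": {"a"}}), n_perm=10)


def _enr(pathway, nes, size, pinned=False):
    return EnrichmentResult(pathway=pathway, es=np.sign(nes), nes=nes,
                            pval=0.01, adj_pval=0.02, size=size, pinned=pinned)


def _de_table(n_de_by_pathway, sets):
    out = []
    for pname, n in n_de_by_pathway.items():
        for g in sorted(sets[pname])[:n]:
            out.append(DEResult(gene=g, log2fc=1.0, pval=1e-4, adj_pval=1e-3,
                                is_de=True))
    return out


class TestFilterPathways:
    def _setup(self):
        sets = GeneSetCollection({
            "BOTH": {f"a{i}" for i in range(100)},
            "ANALYSIS_ONLY": {f"b{i}" for i in range(25)},
            "PINME": {f"c{i}" for i in range(50)},
        })
        enr = [_enr("BOTH", -1.8, 100), _enr("ANALYSIS_ONLY", 1.6, 25),
               _enr("PINME", 0.854, 50)]
        de = _de_table({"BOTH": 22, "ANALYSIS_ONLY": 22, "PINME": 22}, sets)
        return enr, de, sets

    def test_rule_application(self):
        enr, de, sets = self._setup()
        analysis, selection = filter_pathways(enr, de, sets)
        assert "BOTH" in analysis and "BOTH" in selection
        assert "ANALYSIS_ONLY" in analysis and "ANALYSIS_ONLY" not in selection

    def test_pinned_carry_through(self):
        enr, de, sets = self._setup()
        _, selection = filter_pathways(enr, de, sets, pinned=["PINME"])
        assert "PINME" in selection
        assert next(r for r in enr if r.pathway == "PINME").pinned

    def test_strict_boundaries(self):
        sets = GeneSetCollection({
            "SIZE30": {f"d{i}" for i in range(30)},
            "SIZE200": {f"e{i}" for i in range(200)},
            "NES15": {f"f{i}" for i in range(50)},
            "DE20": {f"h{i}" for i in range(50)},
        })
        enr = [_enr("SIZE30", 2.0, 30), _enr("SIZE200", 2.0, 200),
               _enr("NES15", 1.5, 50), _enr("DE20", 2.0, 50)]
        de = _de_table({"SIZE30": 25, "SIZE200": 25, "NES15": 25, "DE20": 20},
                       sets)
        analysis, selection = filter_pathways(enr, de, sets)
        assert "DE20" not in analysis          # exactly 20 DE genes fails > 20
        assert "SIZE30" not in selection        # size 30 fails 30 < size
        assert "SIZE200" not in selection       # size 200 fails size < 200
        assert "NES15" not in selection         # |NES| = 1.5 fails > 1.5

    def test_idempotent_and_order_independent(self):
        enr, de, sets = self._setup()
        a1, s1 = filter_pathways(enr, de, sets, pinned=["PINME"])
        a2, s2 = filter_pathways(list(reversed(enr)), de, sets, pinned=["PINME"])
        assert set(a1) == set(a2) and set(s1) == set(s2)
        a3, s3 = filter_pathways(enr, de, sets, pinned=["PINME"])
        assert a3 == a1 and s3 == s1
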