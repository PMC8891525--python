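from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from neurotau.errors import DataError, SchemaError
from neurotau.spatial_assoc import ParcelProfile
from neurotau.transcriptome import (
    ExpressionMatrix,
    GeneSetCollection,
    hypergeometric_enrichment,
    rank_genes,
    read_expression,
    read_gmt,
    shared_terms,
    write_gmt,
)


def exact_hypergeom_tail(N, K, n, k):
    """P[X >= k] by exact combinatorial sum (rational arithmetic)."""
    total = comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, j) * comb(N - K, n - j), total)
    return acc


def reference_bh(p):
    """Step-up BH oracle."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def make_expression(n_genes=50, n_parcels=40, seed=0, left_fraction=0.5):
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    parcels = list(range(1, n_parcels + 1))
    values = pd.DataFrame(rng.normal(size=(n_genes, n_parcels)),
                          index=genes, columns=parcels)
    n_left = int(left_fraction * n_parcels)
    hemi = pd.Series(
        ["left"] * n_left + ["right"] * (n_parcels - n_left), index=parcels
    )
    return ExpressionMatrix(values=values, hemisphere=hemi), parcels


class TestRankGenes:
    def _target(self, parcels, values):
        return ParcelProfile(parcel_ids=np.asarray(parcels),
                             values=np.asarray(values, float), source_name="t")

    def test_identity_and_negation_assignments(self):
        expr, parcels = make_expression(seed=1)
        rng = np.random.default_rng(2)
        t = rng.normal(size=len(parcels))
        expr.values.iloc[0] = t  # gene 0 == target
        expr.values.iloc[1] = -t  # gene 1 == -target
        ranks = rank_genes(expr, self._target(parcels, t), hemisphere="both")
        assert ranks.iloc[0]["r"] == pytest.approx(1.0)
        assert ranks.iloc[0]["list"] == "positive"
        assert ranks.iloc[1]["r"] == pytest.approx(-1.0)
        assert ranks.iloc[1]["list"] == "negative"

    def test_negating_target_swaps_lists(self):
        expr, parcels = make_expression(seed=3)
        rng = np.random.default_rng(4)
        t = rng.normal(size=len(parcels))
        expr.values.iloc[:5] += 2.0 * t  # strong positive genes
        up = rank_genes(expr, self._target(parcels, t), hemisphere="both")
        down = rank_genes(expr, self._target(parcels, -t), hemisphere="both")
        np.testing.assert_allclose(up["r"], -down["r"], atol=1e-12)
        swapped = down["list"].replace({"positive": "negative",
                                        "negative": "positive"})
        assert (up["list"] == swapped).all()

    def test_left_hemisphere_restriction(self):
        expr, parcels = make_expression(seed=5)
        rng = np.random.default_rng(6)
        t = rng.normal(size=len(parcels))
        # gene 0 matches the target on left parcels only
        left = expr.parcels("left")
        expr.values.loc[expr.genes[0], :] = rng.normal(size=len(parcels))
        expr.values.loc[expr.genes[0], left] = t[: len(left)]
        target_left = self._target(parcels, t)
        ranks = rank_genes(expr, target_left, hemisphere="left")
        assert ranks.iloc[0]["r"] == pytest.approx(1.0)
        assert int(ranks["n_parcels"].max()) == len(left)

    def test_constant_gene_excluded_from_family(self):
        expr, parcels = make_expression(n_genes=20, seed=7)
        expr.values.iloc[3] = 5.0
        rng = np.random.default_rng(8)
        ranks = rank_genes(expr, self._target(parcels, rng.normal(size=len(parcels))),
                           hemisphere="both")
        assert ranks.iloc[3]["list"] == "excluded"
        tested = ranks["list"] != "excluded"
        # Bonferroni family = tested genes only: p_fwe = p * 19
        sub = ranks[tested]
        np.testing.assert_allclose(
            sub["p_fwe"], np.minimum(sub["p"] * 19, 1.0), atol=1e-12
        )

    def test_null_genes_rarely_significant(self):
        expr, parcels = make_expression(n_genes=500, n_parcels=60, seed=9)
        rng = np.random.default_rng(10)
        ranks = rank_genes(expr, self._target(parcels, rng.normal(size=len(parcels))),
                           hemisphere="both")
        assert (ranks["list"].isin(["positive", "negative"])).sum() <= 1


class TestHypergeometricEnrichment:
    def test_worked_example_exact(self):
        # N=20, n=5, K=4, k=3 -> p = 496/15504
        sets = GeneSetCollection(terms={"T": frozenset(f"g{i}" for i in range(4))})
        universe = {f"g{i}" for i in range(20)}
        gene_list = {"g0", "g1", "g2", "g10", "g11"}  # overlap 3
        res = hypergeometric_enrichment(gene_list, sets, universe)
        expected = exact_hypergeom_tail(20, 4, 5, 3)
        assert expected == Fraction(496, 15504)
        assert res.loc["T", "p_hyper"] == pytest.approx(float(expected), rel=1e-12)

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(25)]
        for trial in range(10):
            K = int(rng.integers(1, 20))
            n = int(rng.integers(1, 20))
            term = set(rng.choice(universe, K, replace=False))
            lst = set(rng.choice(universe, n, replace=False))
            res = hypergeometric_enrichment(
                lst, GeneSetCollection(terms={"T": frozenset(term)}), set(universe)
            )
            k = len(term & lst)
            expected = float(exact_hypergeom_tail(25, K, n, k))
            assert res.loc["T", "p_hyper"] == pytest.approx(expected, rel=1e-10)

    def test_zero_overlap_and_full_term(self):
        universe = {f"g{i}" for i in range(20)}
        sets = GeneSetCollection(
            terms={"DISJOINT": frozenset(["g15", "g16"]), "ALL": frozenset(universe)}
        )
        res = hypergeometric_enrichment({"g0", "g1"}, sets, universe)
        assert res.loc["DISJOINT", "p_hyper"] == pytest.approx(1.0)
        assert res.loc["ALL", "k"] == 2
        assert res.loc["ALL", "p_hyper"] == pytest.approx(1.0)

    def test_bh_matches_reference_step_up(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(100)]
        terms = {
            f"T{j}": frozenset(rng.choice(universe, rng.integers(5, 40), replace=False))
            for j in range(30)
        }
        lst = set(rng.choice(universe, 20, replace=False))
        res = hypergeometric_enrichment(lst, GeneSetCollection(terms=terms),
                                        set(universe))
        np.testing.assert_allclose(
            res["q_fdr"], reference_bh(res["p_hyper"].to_numpy()), atol=1e-12
        )

    def test_list_outside_universe_rejected(self):
        sets = GeneSetCollection(terms={"T": frozenset(["a"])})
        with pytest.raises(DataError):
            hypergeometric_enrichment({"zzz"}, sets, {"a", "b"})


class TestSharedTerms:
    def _result(self, qs):
        frame = pd.DataFrame({"q_fdr": list(qs.values())},
                             index=pd.Index(qs.keys(), name="term"))
        return frame

    def test_identical_inputs_return_all_significant(self):
        a = self._result({"t1": 0.01, "t2": 0.2, "t3": 0.04})
        assert shared_terms(a, a) == ["t1", "t3"]

    def test_disjoint_significance_empty(self):
        a = self._result({"t1": 0.01, "t2": 0.9})
        b = self._result({"t1": 0.9, "t2": 0.01})
        assert shared_terms(a, b) == []

    def test_single_shared_term_sorted_by_max_q(self):
        a = self._result({"t1": 0.01, "t2": 0.03, "t3": 0.9})
        b = self._result({"t1": 0.04, "t2": 0.9, "t3": 0.01})
        assert shared_terms(a, b) == ["t1"]

    def test_disjoint_collections_rejected(self):
        a = self._result({"t1": 0.01})
        b = self._result({"x1": 0.01})
        with pytest.raises(DataError):
            shared_terms(a, b)


class TestGMTAndExpressionIO:
    def test_gmt_round_trip(self, tmp_path):
        sets = GeneSetCollection(
            terms={"A": frozenset(["g1", "g2"]), "B": frozenset(["g3"])},
            descriptions={"A": "first", "B": "second"},
        )
        write_gmt(sets, tmp_path / "s.gmt")
        back = read_gmt(tmp_path / "s.gmt")
        assert back.terms == sets.terms
        assert back.descriptions == sets.descriptions

    def test_expression_round_trip(self, tmp_path):
        expr, parcels = make_expression(n_genes=5, n_parcels=6, seed=11)
        expr.values.rename_axis("gene").to_csv(tmp_path / "e.tsv", sep="\t")
        pd.DataFrame(
            {"parcel_id": parcels, "hemisphere": expr.hemisphere.loc[parcels]}
        ).to_csv(tmp_path / "p.tsv", sep="\t", index=False)
        back = read_expression(tmp_path / "e.tsv", tmp_path / "p.tsv")
        np.testing.assert_allclose(back.values.to_numpy(), expr.values.to_numpy())
        assert list(back.parcels("left")) == list(expr.parcels("left"))

    def test_duplicate_gene_symbols_rejected(self):
        values = pd.DataFrame(np.zeros((2, 12)), index=["g1", "g1"],
                              columns=range(12))
        hemi = pd.Series(["left"] * 12, index=range(12))
        with pytest.raises(SchemaError):
            ExpressionMatrix(values=values, hemisphere=hemi)
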