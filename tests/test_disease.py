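"""Cofactor-disease incidence, hypergeometric enrichment against exhaustive
enumeration, NODF against a brute-force oracle, and the nested ranking."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cofactornet import (
    CofactorTable,
    DiseaseGeneMap,
    ValidationError,
    build_incidence,
    disease_gene_enrichment,
    disease_nestedness_index,
    disease_report,
    generate_cofactor_table,
    generate_disease_map,
    nodf,
)
from cofactornet.stats import bh_adjust
from cofactornet.synthetic import SyntheticSpec


class TestIncidence:
    def test_weight_counts_shared_proteins(self):
        catalog = CofactorTable.from_pairs([("g1", "Zn"), ("g2", "Zn"), ("g3", "Zn")])
        dmap = DiseaseGeneMap({"d": frozenset({"g1", "g2"})})
        inc = build_incidence(catalog, dmap)
        assert inc.weights.loc["d", "Zn"] == 2

    def test_disjoint_disease_rows_are_dropped(self):
        catalog = CofactorTable.from_pairs([("g1", "Zn")])
        dmap = DiseaseGeneMap({"d1": frozenset({"g1"}), "d2": frozenset({"x"})})
        inc = build_incidence(catalog, dmap)
        assert inc.diseases == ["d1"]

    def test_weights_match_bruteforce_set_intersections(self):
        spec = SyntheticSpec(
            seed=5, n_cofactors=15, n_proteins=100, n_extra_proteins=10,
            n_background_genes=30, n_diseases=6, nestedness_shape="noisy_nested",
        )
        catalog = generate_cofactor_table(spec)
        dmap, _ = generate_disease_map(spec, catalog)
        inc = build_incidence(catalog, dmap)
        for d in inc.diseases:
            for c in inc.cofactors:
                expected = len(catalog.proteins_for(c) & dmap.entries[d])
                assert inc.weights.loc[d, c] == expected


class TestIncidenceExports:
    def _incidence(self):
        catalog = CofactorTable.from_pairs(
            [("g1", "Zn"), ("g2", "Zn"), ("g2", "Mg"), ("g3", "Mg")]
        )
        dmap = DiseaseGeneMap(
            {"d1": frozenset({"g1", "g2"}), "d2": frozenset({"g3"})}
        )
        return build_incidence(catalog, dmap)

    def test_mtx_triplets_round_trip_through_scipy(self, tmp_path):
        from scipy.io import mmread
        from cofactornet.disease import write_incidence_mtx

        inc = self._incidence()
        path = tmp_path / "incidence.mtx"
        write_incidence_mtx(inc, path)
        m = mmread(path).toarray()
        assert np.array_equal(m, inc.weights.to_numpy())

    def test_graphml_export_carries_weights(self, tmp_path):
        import networkx as nx
        from cofactornet.disease import write_incidence_graphml

        inc = self._incidence()
        path = tmp_path / "incidence.graphml"
        write_incidence_graphml(inc, path)
        g = nx.read_graphml(path)
        assert g.nodes["d1"]["kind"] == "disease"
        assert g.edges["d1", "Zn"]["weight"] == 2
        assert not g.has_edge("d2", "Zn")


class TestHypergeometricEnrichment:
    def test_closed_form_all_marked_drawn(self):
        universe = {f"g{i}" for i in range(10)}
        marked = {f"g{i}" for i in range(5)}
        res = disease_gene_enrichment(marked, marked, universe)
        assert res.p_value == pytest.approx(1 / comb(10, 5), rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        res = disease_gene_enrichment(
            {f"g{i}" for i in range(5)}, {f"g{i}" for i in range(5, 10)}, universe
        )
        assert res.p_value == 1.0

    def test_universe_must_contain_both_sets(self):
        with pytest.raises(ValidationError):
            disease_gene_enrichment({"a"}, {"b"}, {"b"})

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 5, 5), (12, 6, 3), (12, 4, 8)])
    def test_matches_exhaustive_enumeration(self, N, K, n):
        universe = [f"g{i}" for i in range(N)]
        marked = set(universe[:K])
        for draw in itertools.combinations(universe, n):
            k = len(marked & set(draw))
            res = disease_gene_enrichment(marked, set(draw), set(universe))
            # exhaustive oracle: fraction of all C(N, n) draws with >= k marked
            count = sum(
                1
                for other in itertools.combinations(universe, n)
                if len(marked & set(other)) >= k
            )
            assert res.p_value == pytest.approx(count / comb(N, n), rel=1e-9)
            break  # one draw per parameter set is enough for the tail identity

    def test_bh_q_values_monotone_in_p_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def bruteforce_nodf(m):
    """Direct double-loop NODF oracle."""
    m = np.asarray(m)
    terms = []
    for mat in (m, m.T):
        fills = mat.sum(axis=1)
        for i, j in itertools.combinations(range(mat.shape[0]), 2):
            hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
            if fills[hi] <= fills[lo] or fills[lo] == 0:
                terms.append(0.0)
            else:
                terms.append(100.0 * np.sum(mat[hi] * mat[lo]) / fills[lo])
    return float(np.mean(terms))


class TestNodf:
    def test_perfectly_nested_staircase_is_100(self):
        n = 6
        m = np.array([[1 if j <= n - 1 - i else 0 for j in range(n)] for i in range(n)])
        assert nodf(m) == pytest.approx(100.0)

    def test_checkerboard_is_zero(self):
        assert nodf(np.eye(2, dtype=int)) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((6, 6)) < 0.5).astype(int)
        assert nodf(m) == pytest.approx(bruteforce_nodf(m))

    @given(st.integers(0, 2**20 - 1), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_under_row_and_column_permutation(self, bits, perm_seed):
        m = np.array([int(b) for b in f"{bits:020b}"]).reshape(4, 5)
        rng = np.random.default_rng(perm_seed)
        shuffled = m[rng.permutation(4)][:, rng.permutation(5)]
        assert nodf(shuffled) == pytest.approx(nodf(m))

    def test_degenerate_matrix_scores_zero(self):
        assert nodf(np.array([[1, 0, 1]])) == 0.0


def _nested_catalog_and_map(n_diseases=5, seed=0):
    spec = SyntheticSpec(
        seed=seed, n_cofactors=20, n_proteins=150, n_extra_proteins=10,
        n_background_genes=30, n_diseases=n_diseases,
        nestedness_shape="perfectly_nested",
    )
    catalog = generate_cofactor_table(spec)
    dmap, truth = generate_disease_map(spec, catalog)
    return catalog, dmap, truth


class TestNestednessIndex:
    def test_superset_disease_gets_zero_and_narrowest_gets_one(self):
        catalog, dmap, truth = _nested_catalog_and_map()
        inc = build_incidence(catalog, dmap)
        res = disease_nestedness_index(inc)
        assert res.per_disease_index[truth["order"][0]] == 0.0
        assert res.per_disease_index[truth["order"][-1]] == 1.0
        assert res.row_order == truth["order"]

    def test_identical_repertoires_rank_lexicographically(self):
        catalog = CofactorTable.from_pairs(
            [(f"g{i}", c) for i in range(8) for c in ("Zn", "Mg")]
        )
        genes = frozenset(f"g{i}" for i in range(8))
        dmap = DiseaseGeneMap({"b": genes, "a": genes, "c": genes})
        res = disease_nestedness_index(build_incidence(catalog, dmap))
        assert res.row_order == ["a", "b", "c"]
        assert res.per_disease_index == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_index_non_increasing_in_repertoire_size(self):
        for seed in range(10):
            catalog, dmap, truth = _nested_catalog_and_map(n_diseases=6, seed=seed)
            inc = build_incidence(catalog, dmap)
            res = disease_nestedness_index(inc)
            sizes = [len(truth["supports"][d]) for d in res.row_order]
            assert sizes == sorted(sizes, reverse=True)

    def test_min_genes_filter_is_strict(self):
        catalog = CofactorTable.from_pairs(
            [(f"g{i}", f"C{i}") for i in range(12)]
        )
        dmap = DiseaseGeneMap(
            {
                "big": frozenset(f"g{i}" for i in range(10)),
                "six": frozenset(f"g{i}" for i in range(6)),
                "five": frozenset(f"g{i}" for i in range(5)),
            }
        )
        res = disease_nestedness_index(build_incidence(catalog, dmap), min_genes=5)
        assert set(res.row_order) == {"big", "six"}  # "five" has exactly 5 -> excluded
        assert res.excluded == ["five"]

    def test_fewer_than_two_retained_gives_single_zero_index(self):
        catalog = CofactorTable.from_pairs([(f"g{i}", "Zn") for i in range(8)])
        dmap = DiseaseGeneMap({"only": frozenset(f"g{i}" for i in range(8))})
        res = disease_nestedness_index(build_incidence(catalog, dmap))
        assert res.per_disease_index == {"only": 0.0}
        assert res.matrix_nodf == 0.0


class TestDiseaseReport:
    def test_cofactor_share_percentages(self):
        catalog, dmap, truth = _nested_catalog_and_map(n_diseases=5, seed=1)
        inc = build_incidence(catalog, dmap)
        nest = disease_nestedness_index(inc)
        report = disease_report(inc, nest, dmap, n_cofactors_in_catalog=49)
        top = report.iloc[0]
        assert top["disease_id"] == truth["order"][0]
        expected_pct = round(100 * top["n_cofactors"] / 49)
        assert top["pct_of_studied_cofactors"] == expected_pct

    def test_26_of_49_cofactors_is_53_percent(self):
        # the broadest-repertoire arithmetic: 26 distinct cofactors of 49
        from cofactornet.stats import percentage

        assert percentage(26, 49, 0) == 53.0
        assert percentage(49, 49, 0) == 100.0

    def test_empty_incidence_gives_empty_report(self):
        catalog = CofactorTable.from_pairs([("g1", "Zn")])
        dmap = DiseaseGeneMap({"d": frozenset({"x"})})
        inc = build_incidence(catalog, dmap)
        nest = disease_nestedness_index(inc)
        report = disease_report(inc, nest, dmap)
        assert len(report) == 0
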