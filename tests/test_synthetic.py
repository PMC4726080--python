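"""Synthetic generators: determinism, planted structure, moment checks."""

import dataclasses
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from cofactornet import (
    SyntheticSpec,
    ValidationError,
    build_incidence,
    generate_cofactor_table,
    generate_disease_map,
    generate_expression,
    generate_ppi_with_planted_modules,
    nodf,
)


def spec(**kw) -> SyntheticSpec:
    base = dict(
        seed=1,
        n_cofactors=15,
        n_proteins=100,
        n_extra_proteins=50,
        n_modules=3,
        module_size=8,
        background_edge_prob=0.01,
        n_background_genes=40,
        n_diseases=6,
    )
    base.update(kw)
    return SyntheticSpec(**base)


class TestDeterminism:
    def test_same_seed_gives_identical_outputs(self):
        s = spec(seed=5, nestedness_shape="perfectly_nested")
        c1, c2 = generate_cofactor_table(s), generate_cofactor_table(s)
        assert c1 == c2
        g1, m1 = generate_ppi_with_planted_modules(s, c1)
        g2, m2 = generate_ppi_with_planted_modules(s, c2)
        assert m1 == m2 and set(g1.edges()) == set(g2.edges())
        e1, t1 = generate_expression(s, c1)
        e2, t2 = generate_expression(s, c2)
        assert e1.data.equals(e2.data) and t1 == t2
        d1, o1 = generate_disease_map(s, c1)
        d2, o2 = generate_disease_map(s, c2)
        assert d1.entries == d2.entries and o1 == o2

    def test_different_seeds_differ(self):
        c1 = generate_cofactor_table(spec(seed=1))
        c2 = generate_cofactor_table(spec(seed=2))
        assert c1 != c2


class TestCatalogGenerator:
    def test_zero_pair_density_forces_single_cofactor(self):
        table = generate_cofactor_table(spec(n_proteins=10, pair_density=0.0))
        assert len(table) == 10
        assert all(len(table.cofactors_for(p)) == 1 for p in table.proteins)

    def test_mean_cofactors_per_protein_matches_target(self):
        # target the curated scale: ~1.23 cofactors per protein
        target = 1.23
        m = 15
        density = (target - 1.0) / (m - 1)
        means = []
        for seed in range(50):
            t = generate_cofactor_table(spec(seed=seed, n_proteins=200, pair_density=density))
            means.append(len(t) / len(t.proteins))
        n_total = 50 * 200
        sd = np.sqrt((m - 1) * density * (1 - density) / n_total)
        assert abs(np.mean(means) - target) < 3 * sd

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            generate_cofactor_table(spec(n_cofactors=0))
        with pytest.raises(ValidationError):
            generate_cofactor_table(spec(pair_density=1.5))


class TestPlantedModulePPI:
    def test_full_intra_no_background_gives_disjoint_cliques(self):
        s = spec(n_modules=2, module_size=5, intra_module_edge_prob=1.0,
                 background_edge_prob=0.0)
        g, modules = generate_ppi_with_planted_modules(s, generate_cofactor_table(s))
        assert len(modules) == 2 and not (modules[0] & modules[1])
        for mod in modules:
            sub = g.subgraph(mod)
            assert sub.number_of_edges() == 5 * 4 // 2
        assert g.number_of_edges() == 2 * 10

    def test_singleton_modules_and_no_background_gives_empty_graph(self):
        s = spec(n_modules=3, module_size=1, background_edge_prob=0.0)
        g, _ = generate_ppi_with_planted_modules(s, generate_cofactor_table(s))
        assert g.number_of_edges() == 0

    def test_edge_count_matches_binomial_moments(self):
        s = spec(n_proteins=80, n_extra_proteins=40, n_modules=3, module_size=10,
                 intra_module_edge_prob=0.8, background_edge_prob=0.02)
        catalog = generate_cofactor_table(s)
        n = 120
        intra = 3 * 10 * 9 // 2
        bg = n * (n - 1) // 2 - intra
        expected = intra * 0.8 + bg * 0.02
        var = intra * 0.8 * 0.2 + bg * 0.02 * 0.98
        counts = []
        for seed in range(30):
            g, _ = generate_ppi_with_planted_modules(
                dataclasses.replace(s, seed=seed), catalog
            )
            counts.append(g.number_of_edges())
        se = np.sqrt(var / 30)
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_impossible_sizes_rejected(self):
        s = spec(n_proteins=10, n_extra_proteins=0, n_modules=5, module_size=10)
        with pytest.raises(ValidationError):
            generate_ppi_with_planted_modules(s, generate_cofactor_table(s))


class TestExpressionGenerator:
    def test_zero_noise_gives_perfect_within_group_correlation(self):
        s = spec(coexpr_noise_sd=0.0, n_proteins=200)
        catalog = generate_cofactor_table(s)
        expr, truth = generate_expression(s, catalog)
        group = next(g for g in truth["coexpr_groups"].values() if len(g) >= 3)
        profiles = expr.data.loc[group].to_numpy()
        corr = np.corrcoef(profiles)
        assert np.allclose(corr, 1.0)

    def test_planted_enriched_gene_classifies_enriched(self):
        from cofactornet import classify_gene

        s = spec(coexpr_noise_sd=0.0, enriched_fold=10.0)
        catalog = generate_cofactor_table(s)
        expr, truth = generate_expression(s, catalog)
        for gene, tissue in list(truth["tissue_enriched"].items())[:10]:
            cls = classify_gene(expr.profile(gene), expr.tissues, 1.0, 5.0)
            assert cls.category == "tissue_enriched"
            assert cls.evidence == (tissue,)

    def test_within_group_correlation_decreases_with_noise(self):
        catalog = generate_cofactor_table(spec(n_proteins=150))
        means = []
        for sd in (0.0, 0.5, 1.0, 2.0):
            rs = []
            for seed in range(50):
                s = spec(seed=seed, n_proteins=150, coexpr_noise_sd=sd)
                expr, truth = generate_expression(s, catalog)
                for group in truth["coexpr_groups"].values():
                    if len(group) < 3:
                        continue
                    corr = np.corrcoef(expr.data.loc[group].to_numpy())
                    iu = np.triu_indices_from(corr, k=1)
                    rs.append(corr[iu].mean())
            means.append(np.mean(rs))
        assert means == sorted(means, reverse=True)

    def test_not_detected_genes_are_all_zero(self):
        s = spec()
        expr, truth = generate_expression(s, generate_cofactor_table(s))
        for gene in truth["not_detected"]:
            assert (expr.profile(gene) == 0).all()


class TestDiseaseGenerator:
    def test_perfectly_nested_incidence_is_stepwise_nested(self):
        s = spec(n_diseases=5, nestedness_shape="perfectly_nested")
        catalog = generate_cofactor_table(s)
        dmap, truth = generate_disease_map(s, catalog)
        incidence = build_incidence(catalog, dmap)
        support = incidence.support()
        sets = {
            d: frozenset(support.columns[support.loc[d].astype(bool)])
            for d in support.index
        }
        order = truth["order"]
        for a, b in zip(order, order[1:]):
            assert sets[a] > sets[b]
        # induced support equals the planted repertoire exactly
        for d in order:
            assert sets[d] == frozenset(truth["supports"][d])

    def test_random_shape_less_nested_than_perfect(self):
        from cofactornet import disease_nestedness_index

        def score(shape, seed):
            s = spec(seed=seed, n_diseases=6, nestedness_shape=shape)
            catalog = generate_cofactor_table(s)
            dmap, _ = generate_disease_map(s, catalog)
            incidence = build_incidence(catalog, dmap)
            return disease_nestedness_index(incidence).matrix_nodf

        nested = [score("perfectly_nested", seed) for seed in range(20)]
        randoms = [score("random", seed) for seed in range(20)]
        assert np.mean(randoms) < np.mean(nested)

    def test_perfectly_nested_needs_two_diseases(self):
        with pytest.raises(ValidationError):
            spec(n_diseases=1, nestedness_shape="perfectly_nested").validate()

    def test_ground_truth_not_encoded_in_identifiers(self):
        s = spec(n_diseases=6, nestedness_shape="perfectly_nested", seed=3)
        dmap, truth = generate_disease_map(s, generate_cofactor_table(s))
        assert truth["order"] != sorted(truth["order"])
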