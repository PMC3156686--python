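"""Genetic means, variance partitioning, derived traits, trait trees."""

import numpy as np
import pandas as pd
import pytest

from gwasnet.pheno import (
    TraitRecipe,
    derived_traits,
    genetic_means,
    nj_tree,
    trait_distance_matrix,
    trait_tree,
    variance_partition,
)
from gwasnet.simulate import (
    SimConfig,
    VarianceTargets,
    sim_phenotypes,
    sim_population,
)
from tests.conftest import toy_phenotypes


class TestGeneticMeans:
    def test_balanced_design_equals_raw_means(self, small_dataset):
        reps = small_dataset.phenotypes
        means = genetic_means(reps)
        raw = reps.pivot_table(index="accession", columns="trait",
                               values="value")
        # balanced layout: block adjustment cannot move the means
        pd.testing.assert_frame_equal(
            means, raw.loc[means.index, means.columns],
            check_exact=False, atol=1e-9, check_names=False)

    def test_two_by_two_hand_oracle(self):
        # y = mu + acc + block; hand least squares gives adjusted means
        # 2 and 4: the accession difference is exactly 2
        reps = toy_phenotypes({
            ("A", "b1", "c"): 1.0, ("A", "b2", "c"): 3.0,
            ("B", "b1", "c"): 3.0, ("B", "b2", "c"): 5.0})
        m = genetic_means(reps)["t"]
        assert m["B"] - m["A"] == pytest.approx(2.0, abs=1e-10)
        assert m["A"] == pytest.approx(2.0, abs=1e-10)

    def test_block_adjustment_beats_raw_means_under_missingness(self):
        rng = np.random.default_rng(3)
        acc_eff = {f"a{i}": v for i, v in
                   enumerate(rng.standard_normal(12))}
        rows = []
        for i, (a, eff) in enumerate(acc_eff.items()):
            for b, beff in [("b1", 0.0), ("b2", 10.0)]:
                # unbalanced: half the accessions miss block 2
                if b == "b2" and i % 2 == 0:
                    continue
                rows.append((a, b, "c", "t",
                             eff + beff + 0.01 * rng.standard_normal()))
        reps = pd.DataFrame(rows, columns=[
            "accession", "replicate", "context", "trait", "value"])
        adj = genetic_means(reps)["t"]
        raw = reps.groupby("accession")["value"].mean()
        truth = pd.Series(acc_eff) + 5.0  # average block effect
        adj_err = (adj - truth).abs().max()
        raw_err = (raw - truth).abs().max()
        assert adj_err < 0.05
        assert raw_err > 1.0

    def test_invariant_to_block_relabeling(self, small_dataset):
        reps = small_dataset.phenotypes
        m1 = genetic_means(reps)
        relabeled = reps.assign(
            replicate=reps["replicate"].map(
                lambda r: {"rep1": "repD", "rep2": "repC",
                           "rep3": "repB", "rep4": "repA"}[r]))
        m2 = genetic_means(relabeled)
        pd.testing.assert_frame_equal(m1, m2, atol=1e-9,
                                      check_exact=False)

    def test_accession_with_all_missing_dropped(self):
        reps = toy_phenotypes({
            ("A", "b1", "c"): 1.0, ("B", "b1", "c"): 2.0,
            ("C", "b1", "c"): np.nan})
        m = genetic_means(reps)["t"]
        assert "C" not in m.index
        assert m[["A", "B"]].notna().all()


class TestVariancePartition:
    def test_null_trait_etas_near_zero(self):
        vt = VarianceTargets(structure=0, accession=0, context=0,
                             replicate=0, context_structure=0,
                             context_accession=0)
        cfg = SimConfig(n_accessions=96, n_subpops=8, n_snps=100,
                        n_genes_per_chromosome=(20,), n_traits=20,
                        n_replicates=4, variance_targets=vt, seed=21)
        geno, structure, _ = sim_population(cfg)
        reps, _ = sim_phenotypes(geno, structure, cfg)
        vp = variance_partition(reps, structure)
        for term in ["S", "T", "R(T)", "T:S"]:
            assert vp[f"eta2_{term}"].mean() < 0.05
        # accession terms carry many degrees of freedom, so their null
        # expectation is df/(N-1), not zero
        n_cells = 96 * 4 * 2
        assert vp["eta2_A(S)"].mean() == pytest.approx(
            88 / (n_cells - 1), abs=0.05)

    def test_recovers_generator_targets(self):
        vt = VarianceTargets(structure=0.12, accession=0.35, context=0.05,
                             replicate=0.03, context_structure=0.02,
                             context_accession=0.10)
        cfg = SimConfig(n_accessions=96, n_subpops=8, n_snps=100,
                        n_genes_per_chromosome=(20,), n_traits=10,
                        n_replicates=8, variance_targets=vt, seed=22)
        geno, structure, _ = sim_population(cfg)
        reps, truth = sim_phenotypes(geno, structure, cfg)
        vp = variance_partition(reps, structure)
        pairs = [("structure", "eta2_S"), ("accession", "eta2_A(S)"),
                 ("context", "eta2_T"), ("context_accession",
                                         "eta2_T:A(S)")]
        for target_col, eta_col in pairs:
            err = np.abs(vp[eta_col].to_numpy()
                         - truth.variance_fractions[target_col].to_numpy())
            assert err.max() < 0.07, (eta_col, err.max())

    def test_eta_sum_bounded_by_one(self, small_dataset):
        vp = variance_partition(small_dataset.phenotypes,
                                small_dataset.structure)
        cols = [c for c in vp.columns if c.startswith("eta2_")]
        assert (vp[cols].sum(axis=1) <= 1.0 + 1e-9).all()
        assert (vp[cols].sum(axis=1)
                <= vp["R2"] + 1e-9).all()

    def test_accession_eta_monotone_in_generator_fraction(self):
        etas = []
        for frac in (0.1, 0.3, 0.6):
            vt = VarianceTargets(structure=0.05, accession=frac,
                                 context=0.05, replicate=0.02,
                                 context_structure=0.0,
                                 context_accession=0.05)
            cfg = SimConfig(n_accessions=48, n_subpops=4, n_snps=100,
                            n_genes_per_chromosome=(20,), n_traits=5,
                            n_replicates=4, variance_targets=vt, seed=23)
            geno, structure, _ = sim_population(cfg)
            reps, _ = sim_phenotypes(geno, structure, cfg)
            vp = variance_partition(reps, structure)
            etas.append(vp["eta2_A(S)"].mean())
        assert etas[0] < etas[1] < etas[2]

    def test_single_replicate_aliases_interaction(self):
        # with one replicate per context cell, T:A(S) saturates the data
        # and the residual; the affected eta2 must be NaN, not 0
        cfg = SimConfig(n_accessions=24, n_subpops=4, n_snps=100,
                        n_genes_per_chromosome=(20,), n_traits=1,
                        n_replicates=1, seed=24)
        geno, structure, _ = sim_population(cfg)
        reps, _ = sim_phenotypes(geno, structure, cfg)
        vp = variance_partition(reps, structure)
        assert np.isnan(vp["eta2_R(T)"]).all()

    def test_requires_both_contexts(self, small_dataset):
        reps = small_dataset.phenotypes
        one = reps[reps["context"] == "ctx1"]
        with pytest.raises(ValueError):
            variance_partition(one, small_dataset.structure)


class TestDerivedTraits:
    @pytest.fixture()
    def toy_means(self):
        return pd.DataFrame(
            {"a": [1.0, 2.0], "b": [2.0, 0.0], "c": [4.0, 8.0]},
            index=["x", "y"])

    def test_sum_and_ratio_arithmetic(self, toy_means):
        out = derived_traits(toy_means, [
            TraitRecipe("a_plus_b", "sum", ("a", "b")),
            TraitRecipe("c_over_b", "ratio", ("c", "b")),
        ])
        assert out.loc["x", "a_plus_b"] == 3.0
        assert out.loc["x", "c_over_b"] == 2.0
        assert np.isnan(out.loc["y", "c_over_b"])  # 8 / 0 -> missing

    def test_matches_spreadsheet_oracle(self):
        rng = np.random.default_rng(8)
        means = pd.DataFrame(
            rng.uniform(0.5, 4.0, size=(6, 5)),
            columns=list("abcde"),
            index=[f"acc{i}" for i in range(6)])
        recipes = [
            TraitRecipe("total", "sum", ("a", "b", "c", "d", "e")),
            TraitRecipe("w_sum", "sum", ("a", "c"), weights=(2.0, 0.5)),
            TraitRecipe("ab_ratio", "ratio", ("a", "b")),
            TraitRecipe("tot_over_e", "ratio", ("total", "e")),
        ]
        out = derived_traits(means, recipes)
        M = means.to_numpy()
        np.testing.assert_allclose(out["total"], M.sum(axis=1))
        np.testing.assert_allclose(out["w_sum"],
                                   2.0 * M[:, 0] + 0.5 * M[:, 2])
        np.testing.assert_allclose(out["ab_ratio"], M[:, 0] / M[:, 1])
        np.testing.assert_allclose(out["tot_over_e"],
                                   M.sum(axis=1) / M[:, 4])

    def test_unknown_operand_rejected(self, toy_means):
        with pytest.raises(ValueError, match="unknown traits"):
            derived_traits(toy_means,
                           [TraitRecipe("bad", "sum", ("a", "zz"))])

    def test_duplicate_name_rejected(self, toy_means):
        with pytest.raises(ValueError, match="already exists"):
            derived_traits(toy_means,
                           [TraitRecipe("a", "sum", ("b", "c"))])


class TestTraitTree:
    def test_duplicated_traits_are_siblings_at_distance_zero(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(30)
        means = pd.DataFrame({
            "t1": base, "t2": base.copy(),
            "t3": rng.standard_normal(30),
            "t4": rng.standard_normal(30),
            "t5": rng.standard_normal(30)})
        d = trait_distance_matrix(means)
        assert d.loc["t1", "t2"] == pytest.approx(0.0, abs=1e-12)
        tree = trait_tree(means)
        t1 = tree.find("t1")
        siblings = {t.name for t in t1.parent.children if t.name}
        assert "t2" in siblings
        assert tree.find("t1").distance(tree.find("t2")) == pytest.approx(
            0.0, abs=1e-9)

    def test_nj_matches_hand_computed_oracle(self):
        # 4-taxon toy: d(A,B)=0.2, d(C,D)=0.9, all cross pairs 0.8.
        # Textbook NJ gives leaf branches A,B = 0.1, C,D = 0.45 and an
        # internal branch 0.25; the additive metric is reproduced exactly.
        labels = list("ABCD")
        D = pd.DataFrame(
            [[0.0, 0.2, 0.8, 0.8],
             [0.2, 0.0, 0.8, 0.8],
             [0.8, 0.8, 0.0, 0.9],
             [0.8, 0.8, 0.9, 0.0]], index=labels, columns=labels)
        tree = nj_tree(D)
        tip = {x: tree.find(x) for x in labels}
        expected = {("A", "B"): 0.2, ("A", "C"): 0.8, ("A", "D"): 0.8,
                    ("B", "C"): 0.8, ("B", "D"): 0.8, ("C", "D"): 0.9}
        for (i, j), dist in expected.items():
            assert tip[i].distance(tip[j]) == pytest.approx(dist,
                                                            abs=1e-9)
        assert tip["A"].parent is tip["B"].parent

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        means = pd.DataFrame(
            rng.standard_normal((25, 5)),
            columns=[f"t{i}" for i in range(5)])
        t1 = trait_tree(means)
        warped = means.copy()
        warped["t2"] = np.exp(3.0 * warped["t2"])  # monotone
        t2 = trait_tree(warped)
        assert t1.compare_rfd(t2) == 0.0
        d1 = trait_distance_matrix(means)
        d2 = trait_distance_matrix(warped)
        pd.testing.assert_frame_equal(d1, d2, atol=1e-12)

    def test_constant_trait_excluded(self):
        rng = np.random.default_rng(6)
        means = pd.DataFrame(
            rng.standard_normal((20, 5)),
            columns=[f"t{i}" for i in range(5)])
        means["t4"] = 1.0
        tree = trait_tree(means)
        assert {t.name for t in tree.tips()} == {"t0", "t1", "t2", "t3"}
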