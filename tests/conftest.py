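"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from gwasnet.simulate import (
    CausalGeneSpec,
    ModuleSpec,
    SimConfig,
    simulate_dataset,
    sim_annotation,
    sim_coexpression,
    sim_population,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_accessions=48, n_subpops=4, n_snps=600,
        n_genes_per_chromosome=(40, 40), n_traits=4, n_replicates=4,
        fst=0.3, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def structured_panel():
    """96-accession, 8-subpopulation genotype panel (no phenotypes)."""
    cfg = SimConfig(n_accessions=96, n_subpops=8, n_snps=2000,
                    n_genes_per_chromosome=(100, 100), fst=0.3,
                    n_traits=1, seed=7)
    geno, structure, snp_map = sim_population(cfg)
    return cfg, geno, structure, snp_map


@pytest.fixture(scope="session")
def powered_study():
    """Strong-effect study with enough accessions to detect the planted
    genes: 96 accessions, 10 causal genes spread over 10 traits."""
    import dataclasses

    from gwasnet.assoc import (KinshipEigen, emma_scan, kinship,
                               significance_calls)
    from gwasnet.genes import call_genes, snp_gene_index
    from gwasnet.pheno import genetic_means
    from gwasnet.simulate import (default_causal_spec, sim_annotation,
                                  sim_phenotypes)

    cfg = SimConfig(n_accessions=96, n_subpops=8, n_snps=1500,
                    n_genes_per_chromosome=(75, 75), n_traits=10,
                    n_replicates=4, fst=0.3, seed=42)
    geno, structure, snp_map0 = sim_population(cfg)
    annotation, snp_map = sim_annotation(cfg, snp_map0)
    causal = default_causal_spec(annotation, snp_map, cfg.n_traits,
                                 seed=cfg.seed + 7)
    cfg = dataclasses.replace(cfg, causal_spec=causal)
    reps, truth = sim_phenotypes(geno, structure, cfg,
                                 annotation=annotation, snp_map=snp_map)
    means = genetic_means(reps)
    eig = KinshipEigen.from_kinship(kinship(geno))
    results = [emma_scan(geno, means, eig, t) for t in means.columns]
    calls = significance_calls(results, q=0.01)
    index = snp_gene_index(snp_map, annotation)
    tables = {c: call_genes(calls, index, c)
              for c in ("min1", "min2", "frac20")}
    return {"cfg": cfg, "geno": geno, "structure": structure,
            "snp_map": snp_map, "annotation": annotation,
            "phenotypes": reps, "truth": truth, "means": means,
            "results": results, "calls": calls, "index": index,
            "tables": tables}


@pytest.fixture(scope="session")
def module_network_factory():
    """Factory for 300-gene correlation matrices with planted modules."""

    def make(seed: int, n_modules: int = 1, module_size: int = 30,
             level: float = 0.85):
        mods = [
            ModuleSpec(
                genes=tuple(f"g1_{i:04d}"
                            for i in range(m * module_size,
                                           (m + 1) * module_size)),
                level=level)
            for m in range(n_modules)
        ]
        cfg = SimConfig(n_accessions=10, n_subpops=2, n_snps=10,
                        n_genes_per_chromosome=(300,), n_traits=1,
                        seed=seed, module_spec=mods)
        _, _, snp_map = sim_population(cfg)
        annotation, _ = sim_annotation(cfg, snp_map)
        corr = sim_coexpression(cfg, annotation)
        return cfg, corr, mods

    return make


def toy_phenotypes(values: dict[tuple[str, str, str], float],
                   trait: str = "t") -> pd.DataFrame:
    """Build a long-format replicate table from
    {(accession, replicate, context): value}."""
    rows = [(a, r, c, trait, v) for (a, r, c), v in values.items()]
    return pd.DataFrame(
        rows, columns=["accession", "replicate", "context", "trait",
                       "value"])
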