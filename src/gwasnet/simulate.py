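"""Synthetic data generation for structured inbred GWA panels.

Generates everything the downstream analysis consumes — genotypes with
population structure, gene annotation, replicated context-dependent
phenotypes and a gene co-expression correlation matrix — together with a
truth record (planted causal genes/SNPs, realized variance components,
module memberships), so the whole pipeline can be exercised and validated
without external data.

The design emulates a panel of ~96 fully inbred accessions drawn from 8
subpopulations, phenotyped in replicate under two contexts (e.g. control
vs. treated, or two tissues). Genotypes are biallelic dosages in {0, 1}:
inbred lines carry a single haplotype, so heterozygotes never occur.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLANK_BP = 1000  # gene window flank used throughout the pipeline

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CausalGeneSpec:
    """A planted causal gene: which traits it affects and how strongly.

    ``effect`` is the per-allele effect size in trait standard deviations
    before variance normalisation. ``context_specific`` restricts the
    effect to the second context (index 1), modelling genotype-by-context
    interaction.
    """

    gene: str
    traits: tuple[int, ...]
    effect: float = 1.0
    context_specific: bool = False
    n_snps: int = 2


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module: a gene set and its within-module
    correlation level."""

    genes: tuple[str, ...]
    level: float = 0.8


@dataclass(frozen=True)
class VarianceTargets:
    """Per-trait target fractions of total phenotypic variance.

    Defaults mirror a replicated structured panel where roughly a third of
    the variance is stably genetic (accession), ~12% tracks demographic
    structure, context itself is a modest main effect and the
    accession-by-context interaction carries ~10%.
    """

    structure: float = 0.12
    accession: float = 0.35
    context: float = 0.05
    replicate: float = 0.03
    context_structure: float = 0.02
    context_accession: float = 0.10

    @property
    def residual(self) -> float:
        used = (self.structure + self.accession + self.context
                + self.replicate + self.context_structure
                + self.context_accession)
        return 1.0 - used

    def validate(self) -> None:
        vals = dataclasses.asdict(self)
        for name, v in vals.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"variance target {name}={v} outside [0, 1]")
        if self.residual < -1e-12:
            raise ValueError(
                f"variance targets sum to {1 - self.residual:.3f} > 1")


@dataclass
class SimConfig:
    """Full specification of a synthetic study.

    Fixing ``seed`` makes every generated artifact bit-identical across
    runs; all randomness flows through ``numpy.random.default_rng(seed)``
    streams derived per stage.
    """

    n_accessions: int = 96
    n_subpops: int = 8
    n_snps: int = 3000
    n_genes_per_chromosome: tuple[int, ...] = (120, 120, 120, 120, 120)
    gene_length: int = 2000
    gene_gap: int = 5000
    snp_in_gene_fraction: float = 0.9
    fst: float = 0.3
    n_traits: int = 40
    n_replicates: int = 4
    n_contexts: int = 2
    causal_spec: list[CausalGeneSpec] = field(default_factory=list)
    variance_targets: VarianceTargets | Sequence[VarianceTargets] = field(
        default_factory=VarianceTargets)
    module_spec: list[ModuleSpec] = field(default_factory=list)
    background_corr_sd: float = 0.02
    module_corr_sd: float = 0.05
    polygenic_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions <= 0 or self.n_snps <= 0 or self.n_traits <= 0:
            raise ValueError("dimensions must be positive")
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst={self.fst} outside (0, 1)")
        if self.n_subpops <= 0 or self.n_accessions < self.n_subpops:
            raise ValueError("need at least one accession per subpopulation")
        if self.n_contexts != 2:
            raise ValueError("exactly two contexts are supported")
        for vt in self.targets_per_trait():
            vt.validate()

    def targets_per_trait(self) -> list[VarianceTargets]:
        if isinstance(self.variance_targets, VarianceTargets):
            return [self.variance_targets] * self.n_traits
        targets = list(self.variance_targets)
        if len(targets) != self.n_traits:
            raise ValueError("one VarianceTargets per trait required")
        return targets


@dataclass
class SyntheticTruth:
    """Record of what was planted, for scoring recovery downstream."""

    causal_snps: pd.DataFrame  # snp, gene, trait, effect, context_specific
    causal_genes: list[str]
    module_membership: dict[str, int]  # gene -> module index
    variance_fractions: pd.DataFrame  # trait x component realized fractions


# ---------------------------------------------------------------------------
# population / genotypes
# ---------------------------------------------------------------------------


def _chrom_length(cfg: SimConfig, n_genes: int) -> int:
    return n_genes * (cfg.gene_length + cfg.gene_gap) + cfg.gene_gap


def sim_population(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Draw structured inbred genotypes under a Balding–Nichols model.

    Ancestral allele frequencies are uniform on (0.1, 0.9); each
    subpopulation's frequency is Beta-distributed around the ancestral one
    with dispersion set by ``fst``; each inbred accession then draws a
    single allele (dosage 0 or 1 — no heterozygotes). SNPs with minor
    allele count < 2 after simulation are discarded and replaced, so the
    returned panel has exactly ``cfg.n_snps`` informative markers.

    Returns
    -------
    geno : DataFrame, accessions x SNPs, int8 dosages in {0, 1}
    structure : Series mapping accession id -> subpopulation label
    snp_map : DataFrame with columns (snp, chrom, pos), 1-based positions
        sorted within chromosome
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_accessions, cfg.n_subpops
    # even split; remainder assigned round-robin to the first subpops
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    subpop = np.repeat(np.arange(k), sizes)
    accessions = [f"acc{i:03d}" for i in range(n)]
    structure = pd.Series(
        [f"S{p + 1}" for p in subpop], index=accessions, name="subpop")

    a_par = (1.0 - cfg.fst) / cfg.fst
    cols: list[np.ndarray] = []
    while len(cols) < cfg.n_snps:
        batch = max(64, int(1.3 * (cfg.n_snps - len(cols))))
        p_anc = rng.uniform(0.1, 0.9, size=batch)
        p_sub = rng.beta(p_anc * a_par, (1.0 - p_anc) * a_par,
                         size=(k, batch))
        draws = (rng.random((n, batch)) < p_sub[subpop, :]).astype(np.int8)
        mac = np.minimum(draws.sum(axis=0), n - draws.sum(axis=0))
        for j in np.nonzero(mac >= 2)[0]:
            cols.append(draws[:, j])
            if len(cols) == cfg.n_snps:
                break
    X = np.column_stack(cols)

    # distribute SNPs across chromosomes proportionally to gene content;
    # provisional uniform positions (sim_annotation may re-place them)
    n_chrom = len(cfg.n_genes_per_chromosome)
    weights = np.asarray(cfg.n_genes_per_chromosome, dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * cfg.n_snps).astype(int)
    counts[: cfg.n_snps - counts.sum()] += 1
    rows = []
    snp_idx = 0
    for c in range(n_chrom):
        length = _chrom_length(cfg, cfg.n_genes_per_chromosome[c])
        pos = np.sort(rng.choice(
            np.arange(1, length + 1), size=counts[c], replace=False))
        for p in pos:
            rows.append((f"snp{snp_idx:05d}", f"chr{c + 1}", int(p)))
            snp_idx += 1
    snp_map = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
    geno = pd.DataFrame(X, index=pd.Index(accessions, name="accession"),
                        columns=snp_map["snp"].tolist())
    structure.index.name = "accession"
    return geno, structure, snp_map


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def sim_annotation(
    cfg: SimConfig,
    snp_map: pd.DataFrame,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out non-overlapping genes and re-place SNPs relative to them.

    Genes are tiled deterministically along each chromosome (1-based
    inclusive coordinates): gene i starts at ``1 + i * (length + gap)``.
    A fraction ``cfg.snp_in_gene_fraction`` of each chromosome's SNPs is
    re-positioned uniformly inside the ±1 kb window of a random gene, the
    rest land in intergenic space, so gene-window mapping downstream has
    known coverage.

    Returns the annotation table (gene, chrom, start, end, order) and the
    updated SNP map (positions re-sorted within chromosome).
    """
    rng = np.random.default_rng(cfg.seed + 104729 if seed is None else seed)
    rows = []
    order = 0
    for c, n_genes in enumerate(cfg.n_genes_per_chromosome):
        chrom = f"chr{c + 1}"
        length = _chrom_length(cfg, n_genes)
        for i in range(n_genes):
            start = 1 + i * (cfg.gene_length + cfg.gene_gap)
            end = start + cfg.gene_length - 1
            if end > length:
                raise ValueError(
                    f"gene layout overflows {chrom} (length {length})")
            rows.append((f"g{c + 1}_{i:04d}", chrom, start, end, order))
            order += 1
    annotation = pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "order"])

    new_rows = []
    for c, n_genes in enumerate(cfg.n_genes_per_chromosome):
        chrom = f"chr{c + 1}"
        genes_c = annotation[annotation["chrom"] == chrom]
        sub = snp_map[snp_map["chrom"] == chrom]
        m = len(sub)
        in_gene = rng.random(m) < cfg.snp_in_gene_fraction
        pos = np.empty(m, dtype=np.int64)
        gi = rng.integers(0, len(genes_c), size=m)
        for j in range(m):
            g = genes_c.iloc[gi[j]]
            if in_gene[j]:
                lo = max(1, g["start"] - FLANK_BP)
                hi = g["end"] + FLANK_BP
            else:  # intergenic: beyond the window, before the next gene
                lo = g["end"] + FLANK_BP + 1
                hi = g["end"] + cfg.gene_gap - FLANK_BP
                if hi < lo:
                    lo, hi = g["end"] + FLANK_BP + 1, g["end"] + cfg.gene_gap
            pos[j] = rng.integers(lo, hi + 1)
        new = sub.copy()
        new["pos"] = pos
        new = new.sort_values("pos", kind="mergesort")
        new_rows.append(new)
    snp_map2 = pd.concat(new_rows, ignore_index=True)
    return annotation, snp_map2


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale so the empirical variance equals target_var."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    sd = x.std()
    if sd < 1e-12:
        return np.zeros_like(x)
    return x * (np.sqrt(target_var) / sd)


def _center_within(x: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Subtract the group mean from each element (nested centering)."""
    out = x.astype(float).copy()
    for g in np.unique(groups):
        out[groups == g] -= out[groups == g].mean()
    return out


def _interaction_residual(M: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Project a context-by-accession matrix onto the pure nested
    interaction space: zero mean over contexts for every accession and
    zero mean over accessions within each group for every context."""
    R = M - M.mean(axis=0, keepdims=True)
    for g in np.unique(groups):
        sel = groups == g
        # the subtracted group-context means are constant over contexts'
        # complement, so both zero-mean properties hold exactly after
        # this single pass (balanced two-factor layout)
        R[:, sel] -= R[:, sel].mean(axis=1, keepdims=True)
    return R


def sim_phenotypes(
    geno: pd.DataFrame,
    structure: pd.Series,
    cfg: SimConfig,
    annotation: pd.DataFrame | None = None,
    snp_map: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate replicated two-context phenotypes with planted causal SNPs.

    Each trait is a sum of components — subpopulation (structure) effect,
    accession genetic value (planted causal SNP effects plus a polygenic
    term), context main effect, replicate-block effect nested in context,
    context-by-structure and context-by-accession interactions, and i.i.d.
    residual noise. Each component is empirically standardized to its
    target variance fraction, so a variance decomposition of the output
    recovers the targets up to design non-orthogonality.

    Context-specific causal effects are added to the second context only
    (their variance is booked against the interaction target); their SNPs
    therefore show no marginal effect in the first context.

    Causal genes must have at least ``n_snps`` markers inside their ±1 kb
    window; pass ``annotation`` and ``snp_map`` whenever ``causal_spec``
    is non-empty.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 15485863)
    accessions = list(geno.index)
    n = len(accessions)
    subpop_codes = pd.Categorical(structure.loc[accessions]).codes
    n_sub = subpop_codes.max() + 1
    targets = cfg.targets_per_trait()

    # resolve causal SNPs inside each causal gene's window
    causal_rows = []
    per_trait_main: dict[int, list[tuple[str, float]]] = {}
    per_trait_ctx: dict[int, list[tuple[str, float]]] = {}
    if cfg.causal_spec:
        if annotation is None or snp_map is None:
            raise ValueError(
                "annotation and snp_map required when causal genes are planted")
        ann = annotation.set_index("gene")
        for spec in cfg.causal_spec:
            g = ann.loc[spec.gene]
            in_win = snp_map[
                (snp_map["chrom"] == g["chrom"])
                & (snp_map["pos"] >= g["start"] - FLANK_BP)
                & (snp_map["pos"] <= g["end"] + FLANK_BP)
            ]["snp"].tolist()
            if len(in_win) < spec.n_snps:
                raise ValueError(
                    f"causal gene {spec.gene} has {len(in_win)} window SNPs, "
                    f"needs {spec.n_snps}")
            chosen = list(rng.choice(in_win, size=spec.n_snps, replace=False))
            for snp in chosen:
                for t in spec.traits:
                    causal_rows.append(
                        (snp, spec.gene, t, spec.effect, spec.context_specific))
                    bucket = per_trait_ctx if spec.context_specific \
                        else per_trait_main
                    bucket.setdefault(t, []).append((snp, spec.effect))

    records = []
    var_rows = []
    comp_names = ["structure", "accession", "context", "replicate",
                  "context_structure", "context_accession", "residual"]
    for t_idx in range(cfg.n_traits):
        vt = targets[t_idx]
        # accession genetic value: planted causal + polygenic background,
        # centered within subpopulation so it is the nested A(S) effect
        # and does not leak into the structure term
        g_raw = cfg.polygenic_sd * rng.standard_normal(n)
        for snp, eff in per_trait_main.get(t_idx, []):
            g_raw = g_raw + eff * geno[snp].to_numpy(dtype=float)
        A = _standardize(_center_within(g_raw, subpop_codes), vt.accession)
        S = _standardize(
            rng.standard_normal(n_sub)[subpop_codes], vt.structure)
        c = np.sqrt(vt.context)
        T = np.array([-c, c])  # two contexts, zero-mean main effect
        R = rng.standard_normal((cfg.n_contexts, cfg.n_replicates))
        R -= R.mean(axis=1, keepdims=True)  # blocks nested in context
        R = _standardize(R.ravel(), vt.replicate).reshape(R.shape) \
            if R.std() > 1e-12 else np.zeros_like(R)
        TS_raw = rng.standard_normal((cfg.n_contexts, n_sub))[:, subpop_codes]
        TS = _interaction_residual(TS_raw, np.zeros(n, dtype=int))
        TS = _standardize(TS.ravel(), vt.context_structure
                          ).reshape(cfg.n_contexts, n)
        ctx_effects = per_trait_ctx.get(t_idx, [])
        if ctx_effects:
            d = np.zeros(n)
            for snp, eff in ctx_effects:
                d = d + eff * geno[snp].to_numpy(dtype=float)
            # active in the second context only, so the SNP has exactly
            # zero marginal effect in the first; the deviation from the
            # accession mean is +/- d/2, hence the factor 2 in the scale
            # that books the interaction variance budget. The accession
            # main absorbs an extra context_accession share (recorded in
            # the realized fractions).
            d = _center_within(d, subpop_codes)
            sd = d.std()
            kappa = 2.0 * np.sqrt(vt.context_accession) / sd if sd > 1e-12 \
                else 0.0
            TA = np.vstack([np.zeros(n), kappa * d])
        else:
            TA = _interaction_residual(
                rng.standard_normal((cfg.n_contexts, n)), subpop_codes)
            TA = _standardize(TA.ravel(), vt.context_accession
                              ).reshape(cfg.n_contexts, n)
        eps_sd = np.sqrt(max(vt.residual, 0.0))

        comp_var = {
            "structure": S.var(), "accession": A.var(),
            "context": T.var(), "replicate": R.var(),
            "context_structure": TS.var(), "context_accession": TA.var(),
            "residual": eps_sd ** 2,
        }
        var_rows.append([comp_var[cname] for cname in comp_names])

        trait = f"trait{t_idx:02d}"
        for ci in range(cfg.n_contexts):
            for ri in range(cfg.n_replicates):
                eps = eps_sd * rng.standard_normal(n)
                y = S + A + T[ci] + R[ci, ri] + TS[ci] + TA[ci] + eps
                for a_i, acc in enumerate(accessions):
                    records.append(
                        (acc, f"rep{ri + 1}", f"ctx{ci + 1}", trait,
                         y[a_i]))

    reps = pd.DataFrame(
        records,
        columns=["accession", "replicate", "context", "trait", "value"])
    causal_df = pd.DataFrame(
        causal_rows,
        columns=["snp", "gene", "trait", "effect", "context_specific"])
    var_df = pd.DataFrame(
        var_rows, columns=comp_names,
        index=[f"trait{i:02d}" for i in range(cfg.n_traits)])
    var_df = var_df.div(var_df.sum(axis=1), axis=0)
    truth = SyntheticTruth(
        causal_snps=causal_df,
        causal_genes=sorted({s.gene for s in cfg.causal_spec}),
        module_membership={g: m for m, spec in enumerate(cfg.module_spec)
                           for g in spec.genes},
        variance_fractions=var_df,
    )
    return reps, truth


# ---------------------------------------------------------------------------
# co-expression
# ---------------------------------------------------------------------------


def sim_coexpression(
    cfg: SimConfig,
    annotation: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a gene-by-gene expression-correlation matrix.

    Off-diagonal entries are near zero except inside planted modules,
    where they are drawn around the module's correlation level. The raw
    symmetric matrix is repaired to positive semi-definiteness by clipping
    eigenvalues at a small positive floor and renormalizing the diagonal
    to 1, so it is a valid correlation matrix.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 32452843)
    genes = annotation["gene"].tolist()
    gene_pos = {g: i for i, g in enumerate(genes)}
    p = len(genes)
    for spec in cfg.module_spec:
        if not -1.0 < spec.level < 1.0:
            raise ValueError(f"module correlation level {spec.level} "
                             "outside (-1, 1)")
        missing = set(spec.genes) - set(gene_pos)
        if missing:
            raise ValueError(f"module genes not in annotation: {missing}")
    seen: set[str] = set()
    for spec in cfg.module_spec:
        dup = seen & set(spec.genes)
        if dup:
            raise ValueError(f"module gene sets overlap: {dup}")
        seen |= set(spec.genes)

    C = cfg.background_corr_sd * rng.standard_normal((p, p))
    C = (C + C.T) / np.sqrt(2.0)
    for spec in cfg.module_spec:
        idx = np.array([gene_pos[g] for g in spec.genes])
        block = spec.level + cfg.module_corr_sd * rng.standard_normal(
            (len(idx), len(idx)))
        block = (block + block.T) / 2.0
        C[np.ix_(idx, idx)] = block
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -0.99, 0.99)
    np.fill_diagonal(C, 1.0)

    # PSD repair: eigenvalue clipping at a small positive floor, then
    # renormalize so the diagonal is exactly 1 again
    w, V = np.linalg.eigh(C)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        C = (V * w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=genes, columns=genes)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    """Bundle of all artifacts of one synthetic study."""

    config: SimConfig
    genotypes: pd.DataFrame
    structure: pd.Series
    snp_map: pd.DataFrame
    annotation: pd.DataFrame
    phenotypes: pd.DataFrame
    coexpression: pd.DataFrame
    truth: SyntheticTruth


def default_causal_spec(
    annotation: pd.DataFrame,
    snp_map: pd.DataFrame,
    n_traits: int,
    n_genes: int = 10,
    effect: float = 2.5,
    seed: int = 0,
) -> list[CausalGeneSpec]:
    """Pick causal genes (with >= 2 window SNPs) and assign 2 traits each.

    The default per-allele effect (2.5 polygenic SDs) emulates the
    major-effect biosynthetic polymorphisms that dominate natural
    variation in plant defense metabolites.
    """
    rng = np.random.default_rng(seed)
    from .genes import snp_gene_index  # local import to avoid cycle

    index = snp_gene_index(snp_map, annotation, flank=FLANK_BP)
    eligible = sorted(g for g, c in index.gene_snp_count.items() if c >= 2)
    chosen = rng.choice(eligible, size=min(n_genes, len(eligible)),
                        replace=False)
    specs = []
    for g in chosen:
        traits = tuple(int(t) for t in
                       rng.choice(n_traits, size=min(2, n_traits),
                                  replace=False))
        specs.append(CausalGeneSpec(gene=str(g), traits=traits,
                                    effect=effect))
    return specs


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Run every generator stage in order under one master seed."""
    geno, structure, snp_map0 = sim_population(cfg)
    annotation, snp_map = sim_annotation(cfg, snp_map0)
    causal = cfg.causal_spec
    if not causal:
        causal = default_causal_spec(
            annotation, snp_map, cfg.n_traits, seed=cfg.seed + 7)
        cfg = dataclasses.replace(cfg, causal_spec=causal)
    modules = cfg.module_spec
    if not modules:
        # plant one module per causal gene, padded with nearby genes
        genes = annotation["gene"].tolist()
        rng = np.random.default_rng(cfg.seed + 11)
        used: set[str] = set()
        modules = []
        for spec in causal[:4]:
            pool = [g for g in genes if g not in used and g != spec.gene]
            extra = list(rng.choice(pool, size=5, replace=False))
            members = tuple([spec.gene] + extra)
            used |= set(members)
            modules.append(ModuleSpec(genes=members, level=0.8))
        cfg = dataclasses.replace(cfg, module_spec=modules)
    pheno, truth = sim_phenotypes(
        geno, structure, cfg, annotation=annotation, snp_map=snp_map)
    coexpr = sim_coexpression(cfg, annotation)
    truth.module_membership = {g: m for m, spec in enumerate(cfg.module_spec)
                               for g in spec.genes}
    return SimulatedDataset(
        config=cfg, genotypes=geno, structure=structure, snp_map=snp_map,
        annotation=annotation, phenotypes=pheno, coexpression=coexpr,
        truth=truth)
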