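"""Simulation of a pseudo-F2 herbicide-resistance mapping population.

The generator emulates the study design this package analyses: an F2-like
population segregating for a dominant nontarget-site resistance locus, with

* two fully heterozygous F1 parents whose gametes recombine along each
  scaffold under the Haldane map function;
* a causal resistance locus on one scaffold, phenotyped on a 1-10 visual
  damage scale (10 = undamaged) for two herbicides (the second trait
  segregates at an independent locus, so trait independence is testable);
* a linked cluster of cis-regulated genes whose R-haplotype copy is
  expressed ``f``-fold higher, giving both differential expression between
  R and S cohorts and an allelic-imbalance ratio rho = f/(1+f) in
  heterozygotes;
* SNPs riding the parental haplotypes (alt allele on the R-parent
  haplotype) with allelic read depths, written as a VCF;
* 1,000-bp promoters with planted motif consensus sequences in the
  cis-regulated genes; and
* qPCR Ct values for one target and three housekeeping genes.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``, so runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    CountMatrix,
    GeneModel,
    PositionFrequencyMatrix,
    VariantRecord,
    write_counts_tsv,
    write_ct_tsv,
    write_design_tsv,
    write_fasta,
    write_gff_genes,
    write_jaspar_pfm,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "F2Genotypes",
    "SimData",
    "haldane_recomb_fraction",
    "simulate_f2_genotypes",
    "assign_phenotypes",
    "select_extremes",
    "simulate_expression",
    "simulate_allelic_depths",
    "simulate_promoters",
    "simulate_qpcr",
    "simulate_pfms",
    "simulate_dataset",
]

HERBICIDE_A = "24D"
HERBICIDE_B = "HPPD"


@dataclass
class SimConfig:
    """Parameters of the pseudo-F2 simulation (defaults = study conditions)."""

    n_scaffolds: int = 16
    scaffold_length_bp: int = 20_000_000
    genes_per_scaffold: int = 400
    gene_length_bp: int = 2_000
    n_f2: int = 100
    n_selected_per_category: int = 4
    causal_scaffold: int = 3  # 0-based index
    causal_pos_bp: int = 5_000_000
    trait_b_scaffold: int = 7
    trait_b_pos_bp: int = 10_000_000
    n_cis_genes: int = 12
    cluster_span_bp: int = 3_000_000
    fold_change_f: float = 3.0
    nb_dispersion: float = 0.02
    mean_depth: float = 60.0
    baseline_log_mean: float = np.log(300.0)
    baseline_log_sd: float = 1.0
    recomb_rate_cM_per_Mb: float = 4.0
    rating_noise_sd: float = 1.0
    rating_cutoff: int = 3  # rating > cutoff -> R (boundary value is S)
    snps_per_cis_gene: int = 3
    background_snp_rate: float = 0.05
    seq_error_rate: float = 0.002
    motif_plant_prob: float = 0.9
    n_planted_motifs: int = 2
    promoter_length_bp: int = 1_000
    qpcr_intercept: float = 30.0
    qpcr_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_scaffolds",
            "scaffold_length_bp",
            "genes_per_scaffold",
            "n_f2",
            "n_selected_per_category",
            "n_cis_genes",
            "cluster_span_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.causal_scaffold < self.n_scaffolds:
            raise ValueError("causal_scaffold out of range")
        if self.fold_change_f <= 0 or self.nb_dispersion <= 0:
            raise ValueError("fold_change_f and nb_dispersion must be > 0")
        if not 0 <= self.motif_plant_prob <= 1:
            raise ValueError("motif_plant_prob must be in [0, 1]")
        half = self.cluster_span_bp // 2
        if self.causal_pos_bp - half < 0 or self.causal_pos_bp + half > self.scaffold_length_bp:
            raise ValueError("cis-gene cluster does not fit on the causal scaffold")

    @property
    def ase_ratio_rho(self) -> float:
        f = self.fold_change_f
        return f / (1.0 + f)

    def scaffold_name(self, idx: int) -> str:
        return f"Scaffold_{idx + 1}"


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, for recovery checks."""

    causal_scaffold: str
    causal_pos_bp: int
    causal_interval: tuple[int, int]  # first..last cis gene start (1-based)
    cis_gene_ids: list[str]
    r_snp_positions: list[tuple[str, int]]  # SNPs inside cis genes
    ase_ratio_rho: float
    planted_motif_ids: list[str]
    causal_genotype: dict[str, int]  # sample -> R-allele dosage at causal locus
    trait_b_genotype: dict[str, int]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["r_snp_positions"] = [list(t) for t in self.r_snp_positions]
        return json.dumps(d, indent=1)


@dataclass
class F2Genotypes:
    """Phased haplotypes of the F2 population on a per-gene marker grid.

    ``haplotypes[scaffold]`` has shape ``(n_f2, 2, n_markers)`` with 1 where
    the gamete carries the R-parent haplotype.  The marker grid is the gene
    start positions; the causal position is tracked separately.
    """

    sample_ids: list[str]
    positions: dict[str, np.ndarray]
    haplotypes: dict[str, np.ndarray]
    causal_dosage: np.ndarray  # R alleles at the causal locus, per individual
    trait_b_dosage: np.ndarray


@dataclass
class SimData:
    """One complete simulated dataset (in memory)."""

    config: SimConfig
    genes: list[GeneModel]
    genotypes: F2Genotypes
    design: pd.DataFrame
    selected_samples: list[str]
    counts: CountMatrix
    variants: list[VariantRecord]
    promoters: dict[str, str]
    pfms: list[PositionFrequencyMatrix]
    ct_table: pd.DataFrame
    truth: SimTruth


def haldane_recomb_fraction(d_morgans: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction r = 0.5 (1 - e^(-2d)) for map distance d."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=float)))


def _gene_grid(cfg: SimConfig) -> tuple[list[GeneModel], dict[str, np.ndarray]]:
    genes: list[GeneModel] = []
    positions: dict[str, np.ndarray] = {}
    spacing = cfg.scaffold_length_bp / (cfg.genes_per_scaffold + 1)
    for s in range(cfg.n_scaffolds):
        name = cfg.scaffold_name(s)
        starts = np.round((np.arange(cfg.genes_per_scaffold) + 1) * spacing).astype(int)
        positions[name] = starts
        for i, st in enumerate(starts):
            strand = "+" if i % 2 == 0 else "-"
            genes.append(
                GeneModel(f"g{s + 1:02d}_{i + 1:04d}", name, int(st), int(st) + cfg.gene_length_bp - 1, strand)
            )
    return genes, positions


def _simulate_gametes(positions_bp: np.ndarray, n_gametes: int, cfg: SimConfig, rng) -> np.ndarray:
    """Markov walk along one scaffold: 0/1 parental phase per marker."""
    m = positions_bp.size
    d = np.diff(positions_bp) * cfg.recomb_rate_cM_per_Mb / 1e6 / 100.0  # Morgans
    r = haldane_recomb_fraction(d)
    init = rng.integers(0, 2, size=(n_gametes, 1))
    if m == 1:
        return init.astype(np.int8)
    switches = rng.random((n_gametes, m - 1)) < r
    states = (init + np.concatenate([np.zeros((n_gametes, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1)) % 2
    return states.astype(np.int8)


def simulate_f2_genotypes(cfg: SimConfig, rng: np.random.Generator) -> F2Genotypes:
    """Draw phased F2 haplotypes from two fully heterozygous F1 parents.

    Each F2 individual receives two independent gametes; each gamete is a
    Markov walk over the marker grid switching parental phase with the
    Haldane recombination fraction between adjacent markers.
    """
    genes, positions = _gene_grid(cfg)
    sample_ids = [f"F2_{i + 1:03d}" for i in range(cfg.n_f2)]
    haplotypes: dict[str, np.ndarray] = {}
    causal_dosage = np.zeros(cfg.n_f2, dtype=int)
    trait_b_dosage = np.zeros(cfg.n_f2, dtype=int)
    for s in range(cfg.n_scaffolds):
        name = cfg.scaffold_name(s)
        grid = positions[name]
        extra = []
        if s == cfg.causal_scaffold:
            extra.append(cfg.causal_pos_bp)
        if s == cfg.trait_b_scaffold:
            extra.append(cfg.trait_b_pos_bp)
        full = np.unique(np.concatenate([grid, np.array(extra, dtype=int)])) if extra else grid
        gam = _simulate_gametes(full, 2 * cfg.n_f2, cfg, rng).reshape(cfg.n_f2, 2, full.size)
        if s == cfg.causal_scaffold:
            ci = int(np.searchsorted(full, cfg.causal_pos_bp))
            causal_dosage = gam[:, :, ci].sum(axis=1)
        if s == cfg.trait_b_scaffold:
            bi = int(np.searchsorted(full, cfg.trait_b_pos_bp))
            trait_b_dosage = gam[:, :, bi].sum(axis=1)
        # restrict back to the gene grid
        keep = np.searchsorted(full, grid)
        haplotypes[name] = gam[:, :, keep]
        positions[name] = grid
    return F2Genotypes(sample_ids, positions, haplotypes, causal_dosage, trait_b_dosage)


def _ratings(dosage: np.ndarray, cfg: SimConfig, rng) -> np.ndarray:
    base = np.where(dosage >= 1, 9.0, 1.0)  # dominant resistance
    noisy = np.round(base + rng.normal(0.0, cfg.rating_noise_sd, size=dosage.size))
    return np.clip(noisy, 1, 10).astype(int)


def assign_phenotypes(genotypes: F2Genotypes, cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Visual damage ratings (1-10, 10 = undamaged) and derived R/S labels."""
    r_a = _ratings(genotypes.causal_dosage, cfg, rng)
    r_b = _ratings(genotypes.trait_b_dosage, cfg, rng)
    design = pd.DataFrame(
        {
            "population": "SIM",
            f"rating_{HERBICIDE_A}": r_a,
            f"rating_{HERBICIDE_B}": r_b,
            f"label_{HERBICIDE_A}": np.where(r_a > cfg.rating_cutoff, "R", "S"),
            f"label_{HERBICIDE_B}": np.where(r_b > cfg.rating_cutoff, "R", "S"),
        },
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
    )
    return design


def select_extremes(design: pd.DataFrame, cfg: SimConfig) -> list[str]:
    """Pick the most extreme plants per joint phenotype category.

    Mirrors the sequencing design: ``n_selected_per_category`` plants from
    each of the four (herbicide A x herbicide B) R/S categories, taking the
    most resistant plants in R categories and the most sensitive in S
    categories; ties break on sample id.
    """
    chosen: list[str] = []
    k = cfg.n_selected_per_category
    for la in ("R", "S"):
        for lb in ("R", "S"):
            sub = design[(design[f"label_{HERBICIDE_A}"] == la) & (design[f"label_{HERBICIDE_B}"] == lb)]
            score = sub[f"rating_{HERBICIDE_A}"] + sub[f"rating_{HERBICIDE_B}"]
            ascending = la == "S" and lb == "S"
            if la != lb:
                score = sub[f"rating_{HERBICIDE_A}"] - sub[f"rating_{HERBICIDE_B}"]
                ascending = la == "S"
            ordered = score.sort_values(ascending=ascending, kind="mergesort")
            chosen.extend(ordered.index[:k])
            shortfall = k - min(k, len(sub))
            if shortfall:
                # rare joint categories: top up with unchosen plants matching the
                # primary-herbicide label, closest to the category's phenotype
                pool = design[(design[f"label_{HERBICIDE_A}"] == la) & ~design.index.isin(chosen)]
                if len(pool) < shortfall:
                    raise ValueError(f"category {la}{lb}: not enough {la}-labelled plants to select")
                fill = pool[f"rating_{HERBICIDE_B}"].sort_values(ascending=lb == "S", kind="mergesort")
                chosen.extend(fill.index[:shortfall])
    return sorted(chosen)


def _cis_genes(genes: list[GeneModel], cfg: SimConfig) -> list[GeneModel]:
    name = cfg.scaffold_name(cfg.causal_scaffold)
    half = cfg.cluster_span_bp / 2
    candidates = [
        g
        for g in genes
        if g.scaffold == name and abs(g.start - cfg.causal_pos_bp) <= half
    ]
    candidates.sort(key=lambda g: g.start)
    if len(candidates) < cfg.n_cis_genes:
        raise ValueError("not enough genes within cluster_span_bp for n_cis_genes")
    # spread the cis genes evenly across the whole cluster span
    idx = np.unique(np.round(np.linspace(0, len(candidates) - 1, cfg.n_cis_genes)).astype(int))
    return [candidates[i] for i in idx]


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with var = m + dispersion * m^2 (gamma-Poisson parameterisation)."""
    n = 1.0 / dispersion
    mean = np.maximum(mean, 1e-9)
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_expression(
    genotypes: F2Genotypes,
    genes: list[GeneModel],
    cfg: SimConfig,
    rng: np.random.Generator,
    samples: list[str] | None = None,
) -> tuple[CountMatrix, np.ndarray, list[str]]:
    """Negative-binomial gene counts under the cis-regulation model.

    Each haplotype of gene ``g`` contributes rate mu_g/2; the R-parent copy
    of a cis-regulated gene contributes ``f`` times that.  Returns the count
    matrix, the per-gene baseline means mu, and the cis gene ids.
    """
    if samples is None:
        samples = genotypes.sample_ids
    idx = [genotypes.sample_ids.index(s) for s in samples]
    mu = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=len(genes))
    cis = {g.gene_id for g in _cis_genes(genes, cfg)}
    gene_order = {g.gene_id: j for j, g in enumerate(genes)}

    mean = np.empty((len(genes), len(samples)))
    # per-scaffold haplotype blocks: marker j on scaffold s is gene j of that scaffold
    per_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        per_scaffold.setdefault(g.scaffold, []).append(g)
    for scaffold, glist in per_scaffold.items():
        hap = genotypes.haplotypes[scaffold][idx]  # (S, 2, M)
        n_r = hap.sum(axis=1).T  # (M, S) copies of R haplotype
        rows = np.array([gene_order[g.gene_id] for g in glist])
        mu_s = mu[rows][:, None]
        is_cis = np.array([g.gene_id in cis for g in glist])[:, None]
        factor = np.where(is_cis, (2 - n_r) * 0.5 + n_r * 0.5 * cfg.fold_change_f, 1.0)
        mean[rows] = mu_s * factor
    counts = _nb_draw(rng, mean, cfg.nb_dispersion)
    df = pd.DataFrame(counts, index=[g.gene_id for g in genes], columns=samples)
    return CountMatrix(df), mu, sorted(cis)


def simulate_allelic_depths(
    genotypes: F2Genotypes,
    genes: list[GeneModel],
    cfg: SimConfig,
    rng: np.random.Generator,
    samples: list[str] | None = None,
) -> tuple[list[VariantRecord], list[tuple[str, int]]]:
    """Place SNPs inside genes and draw genotypes and allelic read depths.

    Every SNP's alt allele rides the R-parent haplotype, so genotype equals
    the local haplotype pair.  Heterozygote depths: total ~ Poisson(scaled
    expression), alt ~ Binomial(total, rho) with rho = f/(1+f) in
    cis-regulated genes and 0.5 elsewhere.  Homozygotes put all reads on the
    carried allele apart from sequencing-error reads at ``seq_error_rate``.
    Returns the records and the cis-gene SNP positions.
    """
    if samples is None:
        samples = genotypes.sample_ids
    idx = [genotypes.sample_ids.index(s) for s in samples]
    cis = _cis_genes(genes, cfg)
    cis_ids = {g.gene_id for g in cis}
    rho = cfg.ase_ratio_rho

    per_scaffold: dict[str, list[tuple[int, GeneModel]]] = {}
    for g in genes:
        per_scaffold.setdefault(g.scaffold, []).append(g)

    records: list[VariantRecord] = []
    r_positions: list[tuple[str, int]] = []
    for scaffold in sorted(per_scaffold):
        glist = per_scaffold[scaffold]
        hap = genotypes.haplotypes[scaffold][idx]  # (S, 2, M)
        for j, g in enumerate(glist):
            is_cis = g.gene_id in cis_ids
            if is_cis:
                n_snps = cfg.snps_per_cis_gene
            else:
                n_snps = int(rng.random() < cfg.background_snp_rate)
            if n_snps == 0:
                continue
            offsets = np.sort(rng.choice(np.arange(10, cfg.gene_length_bp - 10, 40), size=n_snps, replace=False))
            dosage = hap[:, :, j].sum(axis=1)  # (S,)
            # genotype-dependent mean read depth (cis genes are overexpressed in R)
            if is_cis:
                depth_factor = (2 - dosage) * 0.5 + dosage * 0.5 * cfg.fold_change_f
            else:
                depth_factor = np.ones_like(dosage, dtype=float)
            for off in offsets:
                pos = g.start + int(off)
                ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
                total = rng.poisson(cfg.mean_depth * depth_factor)
                p_alt = np.where(
                    dosage == 1,
                    rho if is_cis else 0.5,
                    np.where(dosage == 2, 1.0 - cfg.seq_error_rate, cfg.seq_error_rate),
                )
                alt_depth = rng.binomial(total, p_alt)
                ref_depth = total - alt_depth
                gts = {}
                ads = {}
                for k, s in enumerate(samples):
                    gts[s] = (HOM_REF, HET, HOM_ALT)[dosage[k]]
                    ads[s] = (int(ref_depth[k]), int(alt_depth[k]))
                records.append(
                    VariantRecord(
                        scaffold=scaffold,
                        pos=pos,
                        ref_allele=str(ref),
                        alt_allele=str(alt),
                        site_annotations={
                            "QD": float(np.round(rng.uniform(15, 35), 2)),
                            "FS": float(np.round(rng.uniform(0, 10), 2)),
                            "MQ": 60.0,
                            "MQRankSum": float(np.round(rng.normal(0, 1), 2)),
                            "ReadPosRankSum": float(np.round(rng.normal(0, 1), 2)),
                        },
                        genotypes=gts,
                        allelic_depths=ads,
                    )
                )
                if is_cis:
                    r_positions.append((scaffold, pos))
    records.sort(key=lambda r: (r.scaffold, r.pos))
    return records, r_positions


def simulate_pfms(n_motifs: int, length: int, rng: np.random.Generator) -> list[PositionFrequencyMatrix]:
    """A synthetic motif library with strongly informative columns."""
    pfms = []
    for m in range(n_motifs):
        consensus = rng.integers(0, 4, size=length)
        counts = np.full((4, length), 5.0)
        counts[consensus, np.arange(length)] = 85.0
        pfms.append(PositionFrequencyMatrix(f"SIM{m + 1:04d}", counts))
    return pfms


def simulate_promoters(
    genes: list[GeneModel],
    cfg: SimConfig,
    pfms: list[PositionFrequencyMatrix],
    rng: np.random.Generator,
    cis_gene_ids: set[str] | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Uniform-background promoters with motif consensi planted in cis genes.

    The first ``n_planted_motifs`` matrices of ``pfms`` are the planted set;
    each cis promoter receives each planted consensus independently with
    probability ``motif_plant_prob`` at a uniform offset.
    """
    if cis_gene_ids is None:
        cis_gene_ids = {g.gene_id for g in _cis_genes(genes, cfg)}
    planted = pfms[: cfg.n_planted_motifs]
    bases = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    for g in genes:
        seq = rng.integers(0, 4, size=cfg.promoter_length_bp)
        if g.gene_id in cis_gene_ids:
            for p in planted:
                if rng.random() < cfg.motif_plant_prob:
                    cons = np.array(["ACGT".index(b) for b in p.consensus])
                    off = int(rng.integers(0, cfg.promoter_length_bp - p.length + 1))
                    seq[off : off + p.length] = cons
        promoters[g.gene_id] = "".join(bases[seq])
    return promoters, [p.motif_id for p in planted]


def simulate_qpcr(
    genotypes: F2Genotypes,
    genes: list[GeneModel],
    cfg: SimConfig,
    rng: np.random.Generator,
    samples: list[str],
    target_gene: str | None = None,
) -> pd.DataFrame:
    """Ct table for the target gene plus three housekeeping genes.

    Ct = intercept - log2(expression + 1) + Normal(0, sigma).  Housekeeping
    expression is genotype-independent; the reference sensitive parent
    ("WUS", all-S genotype) is appended as the last row.
    """
    cis = _cis_genes(genes, cfg)
    if target_gene is None:
        target_gene = cis[0].gene_id
    target = next(g for g in genes if g.gene_id == target_gene)
    scaffold_genes = [g for g in genes if g.scaffold == target.scaffold]
    j = next(i for i, g in enumerate(scaffold_genes) if g.gene_id == target_gene)
    idx = [genotypes.sample_ids.index(s) for s in samples]
    dosage = genotypes.haplotypes[target.scaffold][idx][:, :, j].sum(axis=1)
    mu = 100.0
    expr_target = mu * ((2 - dosage) * 0.5 + dosage * 0.5 * cfg.fold_change_f)
    expr_target = np.append(expr_target, mu)  # WUS reference: SS
    rows = list(samples) + ["WUS"]
    a, sd = cfg.qpcr_intercept, cfg.qpcr_noise_sd
    table = {target_gene: a - np.log2(expr_target + 1) + rng.normal(0, sd, len(rows))}
    for hk in ("HK1", "HK2", "HK3"):
        table[hk] = a - np.log2(mu + 1) + rng.normal(0, sd, len(rows))
    return pd.DataFrame(table, index=pd.Index(rows, name="sample_id"))


def simulate_dataset(cfg: SimConfig, out_dir: str | Path | None = None) -> SimData:
    """Run the full generator and optionally write all files to ``out_dir``."""
    rng = np.random.default_rng(cfg.seed)
    genes, _ = _gene_grid(cfg)
    genotypes = simulate_f2_genotypes(cfg, rng)
    design = assign_phenotypes(genotypes, cfg, rng)
    selected = select_extremes(design, cfg)
    counts, _mu, cis_ids = simulate_expression(genotypes, genes, cfg, rng, samples=selected)
    variants, r_positions = simulate_allelic_depths(genotypes, genes, cfg, rng, samples=selected)
    pfms = simulate_pfms(max(cfg.n_planted_motifs, 8), 8, rng)
    promoters, planted_ids = simulate_promoters(genes, cfg, pfms, rng, set(cis_ids))
    ct = simulate_qpcr(genotypes, genes, cfg, rng, samples=selected[: min(14, len(selected))])
    cis_models = [g for g in genes if g.gene_id in set(cis_ids)]
    truth = SimTruth(
        causal_scaffold=cfg.scaffold_name(cfg.causal_scaffold),
        causal_pos_bp=cfg.causal_pos_bp,
        causal_interval=(min(g.start for g in cis_models), max(g.end for g in cis_models)),
        cis_gene_ids=list(cis_ids),
        r_snp_positions=r_positions,
        ase_ratio_rho=cfg.ase_ratio_rho,
        planted_motif_ids=planted_ids,
        causal_genotype={s: int(genotypes.causal_dosage[genotypes.sample_ids.index(s)]) for s in selected},
        trait_b_genotype={s: int(genotypes.trait_b_dosage[genotypes.sample_ids.index(s)]) for s in selected},
    )
    data = SimData(cfg, genes, genotypes, design, selected, counts, variants, promoters, pfms, ct, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_gff_genes(genes, out / "genes.gff3")
        write_design_tsv(design, out / "design.tsv")
        write_counts_tsv(counts, out / "counts.tsv")
        write_vcf(variants, selected, out / "variants.vcf")
        write_fasta(promoters, out / "promoters.fa")
        write_jaspar_pfm(pfms, out / "motifs.jaspar")
        write_ct_tsv(ct, out / "ct.tsv")
        (out / "truth.json").write_text(truth.to_json())
    return data
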