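"""End-to-end orchestration: DEGs -> clusters -> condition SNPs -> overlap -> ASE.

``run_all`` executes every stage on one set of input files with one seed and
emits a JSON report listing, per scaffold, the intervals where significant
DEG clusters and condition-specific SNP windows co-occur — the genomic
co-location evidence that motivates the ASE test.  Overlap is defined as a
non-empty intersection between a merged DEG-cluster interval and the merged
span of 500-kb windows holding at least one condition-specific SNP.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .ase import ase_frame, ase_test, classify_alleles
from .cluster_detect import (
    chromosome_overrepresentation,
    detect_clusters,
    window_counts,
    window_stats_frame,
)
from .diffexpr import call_degs, classify_samples, deg_ids, test_differential_expression
from .io_formats import (
    read_counts_tsv,
    read_design_tsv,
    read_fasta,
    read_gff_genes,
    read_jaspar_pfm,
    read_vcf,
    write_newick,
)
from .relatedness import cut_tree, genotype_matrix, hclust_average, ibs_distance
from .snp_assoc import (
    FilterSpec,
    adaptive_permutation,
    allelic_fisher,
    call_condition_snps,
    hard_filter,
    snp_cluster_filter,
    snp_window_track,
)
from .tfbs import pfm_to_scoring_matrix, scan_all, tfbs_overrepresentation

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Inputs and per-stage parameters for one pipeline run."""

    genes_path: str
    counts_path: str
    design_path: str
    vcf_path: str
    promoters_path: str | None = None
    pfm_path: str | None = None
    herbicide: str = "24D"
    rating_cutoff: float = 3
    deg_fdr: float = 0.1
    cluster_window_bp: int = 1_000_000
    cluster_offset_bp: int = 500_000
    cluster_fdr: float = 0.05
    track_window_bp: int = 500_000
    filter_mode: str = "final"
    max_perm: int = 1000
    snp_alpha: float = 0.05
    ase_min_het: int = 3
    ase_fdr: float = 0.1
    tfbs_min_rel_score: float = 0.9
    relatedness_region: tuple[str, int, int] | None = None
    cut_height_fraction: float = 0.5
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_sim_dir(cls, sim_dir: str | Path, **kwargs) -> "RunConfig":
        d = Path(sim_dir)
        return cls(
            genes_path=str(d / "genes.gff3"),
            counts_path=str(d / "counts.tsv"),
            design_path=str(d / "design.tsv"),
            vcf_path=str(d / "variants.vcf"),
            promoters_path=str(d / "promoters.fa") if (d / "promoters.fa").exists() else None,
            pfm_path=str(d / "motifs.jaspar") if (d / "motifs.jaspar").exists() else None,
            **kwargs,
        )


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    out = []
    for start, stop in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], stop))
        else:
            out.append((start, stop))
    return out


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            lo, hi = max(s1, s2), min(e1, e2)
            if lo < hi:
                out.append((lo, hi))
    return _merge_intervals(out)


def overlap_report(window_stats, snp_track: pd.DataFrame, cluster_fdr: float = 0.05) -> list[dict]:
    """Per-scaffold intersections of significant DEG windows and SNP windows.

    DEG evidence intervals are the FDR-significant hypergeometric windows
    (``adj_p < cluster_fdr``); SNP evidence intervals are the track windows
    holding at least one condition-specific SNP; both live on the same
    coordinate grid, so overlap is plain interval intersection.
    """
    deg_by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for w in window_stats:
        if w.adj_p < cluster_fdr and w.k > 0:
            deg_by_scaffold.setdefault(w.scaffold, []).append((w.start, w.end))
    snp_by_scaffold: dict[str, list[tuple[int, int]]] = {}
    hot = snp_track[snp_track["k"] > 0] if len(snp_track) else snp_track
    for row in hot.itertuples():
        snp_by_scaffold.setdefault(row.scaffold, []).append((int(row.start), int(row.stop)))
    out = []
    for scaffold in sorted(set(deg_by_scaffold) & set(snp_by_scaffold)):
        inter = _intersect(
            _merge_intervals(deg_by_scaffold[scaffold]), _merge_intervals(snp_by_scaffold[scaffold])
        )
        for lo, hi in inter:
            # windows bin raw coordinate values half-open; report the
            # inclusive bp interval they cover
            out.append({"scaffold": scaffold, "start": max(lo, 1), "stop": hi - 1})
    return out


def run_all(config: RunConfig) -> dict:
    """Run every stage and return (and optionally write) the run report."""
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if not k.endswith("_path") and k != "out_dir"
        },
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    genes = stage("read_genes")(lambda: read_gff_genes(config.genes_path))
    counts = stage("read_counts")(lambda: read_counts_tsv(config.counts_path))
    design = stage("read_design")(lambda: read_design_tsv(config.design_path))
    variants, n_multi = stage("read_vcf")(lambda: read_vcf(config.vcf_path))

    labels_all = classify_samples(design, config.herbicide, cutoff=config.rating_cutoff)
    labels = labels_all.reindex(counts.samples)

    de = stage("diffexpr")(lambda: test_differential_expression(counts, labels))
    degs = call_degs(de, fdr=config.deg_fdr)
    dids = deg_ids(degs)
    report["n_degs"] = len(dids)

    clusters, wstats = stage("clusters")(
        lambda: detect_clusters(
            genes,
            dids,
            window_bp=config.cluster_window_bp,
            offset_bp=config.cluster_offset_bp,
            cluster_fdr=config.cluster_fdr,
            label=config.herbicide,
        )
    )
    deg_track = window_counts(genes, dids, window_bp=config.track_window_bp, step_bp=config.track_window_bp)
    scaffold_enrich = chromosome_overrepresentation(genes, dids)
    report["clusters"] = [
        {"scaffold": c.scaffold, "start": c.start, "stop": c.stop, "n_degs": len(c.deg_ids), "adj_p": c.adj_p}
        for c in clusters
    ]

    vcf_samples = sorted(variants[0].genotypes) if variants else []
    snp_labels = labels_all.reindex(vcf_samples)
    kept, tally = stage("hard_filter")(lambda: hard_filter(variants, FilterSpec(), mode=config.filter_mode))
    kept = snp_cluster_filter(kept)
    report["snp_filter"] = {"input": len(variants), "multiallelic_excluded": n_multi, "kept": len(kept), "tally": tally}

    assoc = stage("snp_assoc")(
        lambda: adaptive_permutation(
            kept, snp_labels, max_perm=config.max_perm, alpha=config.snp_alpha, seed=config.seed
        )
    )
    assoc = call_condition_snps(assoc, alpha=config.snp_alpha)
    snp_track = snp_window_track(assoc, window_bp=config.track_window_bp, step_bp=config.track_window_bp)
    report["n_condition_snps"] = int(assoc["is_condition_snp"].sum())
    report["permutation_note"] = (
        "empirical p from adaptive Monte-Carlo label permutation; condition SNPs "
        "require BH-adjusted exact p and empirical p both <= alpha"
    )

    overlaps = overlap_report(wstats, snp_track, cluster_fdr=config.cluster_fdr)
    report["overlaps"] = overlaps

    cond = [r for r in kept if (r.scaffold, r.pos) in set(map(tuple, assoc.loc[assoc["is_condition_snp"], ["scaffold", "pos"]].itertuples(index=False)))]
    classifications = stage("ase")(lambda: classify_alleles(cond, snp_labels))
    ase_results = ase_test(cond, classifications, min_het=config.ase_min_het, fdr=config.ase_fdr)
    ase_df = ase_frame(ase_results, fdr=config.ase_fdr)
    report["n_ase_tested"] = len(ase_results)
    report["n_ase_significant"] = int(ase_df["significant"].sum()) if len(ase_df) else 0

    tfbs_df = None
    if config.promoters_path and config.pfm_path and dids:
        promoters = read_fasta(config.promoters_path)
        pfms = read_jaspar_pfm(config.pfm_path)
        matrices = [pfm_to_scoring_matrix(p) for p in pfms]
        hits = stage("tfbs")(lambda: scan_all(promoters, matrices, min_rel_score=config.tfbs_min_rel_score))
        tfbs_df = tfbs_overrepresentation(hits, dids, set(promoters))
        report["tfbs_top"] = tfbs_df.head(5).to_dict(orient="records")

    tree = None
    groups = None
    region = config.relatedness_region
    if region is None and overlaps:
        top = overlaps[0]
        region = (top["scaffold"], top["start"], top["stop"])
    if region is not None and vcf_samples:
        try:
            gm = genotype_matrix(kept, vcf_samples, region=region)
            tree = hclust_average(ibs_distance(gm))
            groups = cut_tree(tree, config.cut_height_fraction)
            report["relatedness"] = {
                "region": list(region),
                "n_groups": int(groups.nunique()),
            }
        except ValueError:
            report["relatedness"] = {"region": list(region), "n_groups": None}

    if out_dir:
        pd.DataFrame(
            [
                {"gene_id": d.gene_id, "effect": d.effect, "p": d.p, "q": d.q, "is_deg": d.is_deg}
                for d in degs
            ]
        ).to_csv(out_dir / "degs.tsv", sep="\t", index=False)
        window_stats_frame(wstats).to_csv(out_dir / "cluster_windows.tsv", sep="\t", index=False)
        deg_track.to_csv(out_dir / "deg_track.tsv", sep="\t", index=False)
        scaffold_enrich.to_csv(out_dir / "scaffold_enrichment.tsv", sep="\t")
        assoc.to_csv(out_dir / "assoc.tsv", sep="\t", index=False)
        snp_track.to_csv(out_dir / "snp_track.tsv", sep="\t", index=False)
        ase_df.to_csv(out_dir / "ase.tsv", sep="\t", index=False)
        if tfbs_df is not None:
            tfbs_df.to_csv(out_dir / "tfbs.tsv", sep="\t", index=False)
        if tree is not None:
            (out_dir / "tree.nwk").write_text(write_newick(tree) + "\n")
            groups.to_csv(out_dir / "groups.tsv", sep="\t")
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
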