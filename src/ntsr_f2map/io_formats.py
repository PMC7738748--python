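"""Readers and writers for every external format the pipeline touches.

Coordinate conventions: external formats (GFF3, VCF) are 1-based inclusive
and are stored verbatim on the domain objects; all internal interval
arithmetic (window tiling, promoter extraction) is 0-based half-open and the
conversion happens exactly once, at the boundary of this module's types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "VariantRecord",
    "CountMatrix",
    "PositionFrequencyMatrix",
    "GffParseError",
    "read_gff_genes",
    "write_gff_genes",
    "read_vcf",
    "write_vcf",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_fasta",
    "write_fasta",
    "write_newick",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_ct_tsv",
    "write_ct_tsv",
]

# Genotype call vocabulary used across the pipeline.
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")


class GffParseError(ValueError):
    """Raised for malformed GFF3 input, naming the offending line."""


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored to a scaffold interval (1-based inclusive)."""

    gene_id: str
    scaffold: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def start0(self) -> int:
        """0-based half-open start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end (== 1-based inclusive end)."""
        return self.end


@dataclass
class VariantRecord:
    """A biallelic SNP with per-sample genotypes and allelic depths.

    ``genotypes`` maps sample id to one of ``hom_ref``/``het``/``hom_alt``/
    ``missing``; ``allelic_depths`` maps sample id to an ``(ref, alt)`` depth
    pair, or ``None`` where the AD field was absent.
    """

    scaffold: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    site_annotations: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, str] = field(default_factory=dict)
    allelic_depths: dict[str, tuple[int, int] | None] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int]:
        return (self.scaffold, self.pos)


@dataclass
class CountMatrix:
    """Gene-by-sample expression counts with unique labels on both axes."""

    counts: pd.DataFrame  # genes x samples

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class PositionFrequencyMatrix:
    """A 4 x L base-count matrix (rows A, C, G, T) for one motif."""

    motif_id: str
    counts: np.ndarray  # shape (4, L)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: motif length must be >= 1")
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.motif_id}: column with no positive count")

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


# ---------------------------------------------------------------------------
# GFF3


def read_gff_genes(path) -> list[GeneModel]:
    """Read features of type ``gene`` from a GFF3 file.

    Coordinates are taken verbatim (GFF3 is 1-based inclusive).  Raises
    :class:`GffParseError` naming the line number for malformed lines and a
    ``ValueError`` for duplicate gene IDs.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            scaffold, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GffParseError(f"line {lineno}: non-integer coordinates") from exc
            gene_id = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gene_id = item[3:]
                    break
            if gene_id is None:
                raise GffParseError(f"line {lineno}: gene feature without ID attribute")
            if gene_id in seen:
                raise ValueError(f"duplicate gene ID {gene_id!r} (line {lineno})")
            seen.add(gene_id)
            if strand not in ("+", "-"):
                raise GffParseError(f"line {lineno}: strand must be + or -")
            genes.append(GeneModel(gene_id, scaffold, start, end, strand))
    return genes


def write_gff_genes(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\tntsr_f2map\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# VCF


def _classify_gt(gt: tuple) -> str:
    if gt is None or any(a is None for a in gt):
        return MISSING
    alleles = set(gt)
    if alleles == {0}:
        return HOM_REF
    if alleles == {1}:
        return HOM_ALT
    if alleles == {0, 1}:
        return HET
    return MISSING  # multiallelic call on a record we keep should not occur


def read_vcf(path) -> tuple[list[VariantRecord], int]:
    """Read biallelic SNPs from a VCF 4.x file with GT and AD FORMAT fields.

    Returns ``(records, n_multiallelic_excluded)``.  Records with more than
    one ALT allele are excluded and counted; the five GATK site annotations
    (QD, FS, MQ, MQRankSum, ReadPosRankSum) are parsed from INFO when
    present.  An absent AD field for a called genotype leaves the depths
    ``None`` (flagged-missing) rather than failing.
    """
    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise ValueError("VCF lacks a GT FORMAT definition")
    records: list[VariantRecord] = []
    n_multi = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            n_multi += 1
            continue
        annotations = {}
        for k in INFO_KEYS:
            if k in rec.info:
                v = rec.info[k]
                annotations[k] = float(v[0] if isinstance(v, tuple) else v)
        genotypes: dict[str, str] = {}
        depths: dict[str, tuple[int, int] | None] = {}
        for sample, call in rec.samples.items():
            cls = _classify_gt(call.get("GT"))
            genotypes[sample] = cls
            ad = call.get("AD")
            if cls == MISSING or ad is None or any(a is None for a in ad):
                depths[sample] = None
            else:
                depths[sample] = (int(ad[0]), int(ad[1]))
        records.append(
            VariantRecord(
                scaffold=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=alts[0],
                site_annotations=annotations,
                genotypes=genotypes,
                allelic_depths=depths,
            )
        )
    vf.close()
    return records, n_multi


_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(records: Sequence[VariantRecord], samples: Sequence[str], path) -> None:
    """Write records as an uncompressed VCF 4.2 file with GT:AD genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for k in INFO_KEYS:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        scaffolds = sorted({r.scaffold for r in records})
        for s in scaffolds:
            fh.write(f"##contig=<ID={s}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for r in sorted(records, key=lambda r: (r.scaffold, r.pos)):
            info = (
                ";".join(f"{k}={r.site_annotations[k]:g}" for k in INFO_KEYS if k in r.site_annotations)
                or "."
            )
            cols = [r.scaffold, str(r.pos), ".", r.ref_allele, r.alt_allele, ".", "PASS", info, "GT:AD"]
            for s in samples:
                gt = _GT_STRING[r.genotypes.get(s, MISSING)]
                ad = r.allelic_depths.get(s)
                cols.append(f"{gt}:{ad[0]},{ad[1]}" if ad is not None else f"{gt}:.")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# JASPAR PFMs


def read_jaspar_pfm(path) -> list[PositionFrequencyMatrix]:
    """Read motifs from a JASPAR-format PFM file (">ID name" + 4 A/C/G/T rows)."""
    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(PositionFrequencyMatrix(motif_id=m.matrix_id or m.name, counts=counts))
    return out


def write_jaspar_pfm(pfms: Iterable[PositionFrequencyMatrix], path) -> None:
    with open(path, "w") as fh:
        for p in pfms:
            fh.write(f">{p.motif_id} {p.motif_id}\n")
            for i, base in enumerate("ACGT"):
                row = " ".join(f"{v:.0f}" for v in p.counts[i])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Newick

# A merge tree is either a leaf label (str) or a tuple (left, right, height)
# with height = the dissimilarity at which left and right were merged.


def _tree_height(node) -> float:
    return 0.0 if isinstance(node, str) else float(node[2])


def _newick(node, parent_height: float) -> str:
    h = _tree_height(node)
    length = parent_height - h
    if length < 0:
        raise ValueError(f"negative branch length {length} (child above parent)")
    if isinstance(node, str):
        return f"{node}:{length:g}"
    left, right, _ = node
    return f"({_newick(left, h)},{_newick(right, h)}):{length:g}"


def write_newick(tree) -> str:
    """Serialise a binary merge tree to Newick with branch lengths.

    Branch lengths are parent merge height minus child merge height (leaves
    have height 0).  A single leaf serialises to ``"label;"``.
    """
    if isinstance(tree, str):
        return f"{tree};"
    h = _tree_height(tree)
    left, right, _ = tree
    return f"({_newick(left, h)},{_newick(right, h)});"


# ---------------------------------------------------------------------------
# TSV tables


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def write_counts_tsv(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_design_tsv(path) -> pd.DataFrame:
    """Sample design table: sample_id, population, per-herbicide ratings."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def read_ct_tsv(path) -> pd.DataFrame:
    """qPCR Ct table: rows = samples, columns = genes (target + housekeeping)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_ct_tsv(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, sep="\t", index_label="sample_id")
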