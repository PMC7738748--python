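"""Allele-specific expression from allelic read depths.

For each condition-specific SNP: heterozygous-expressed individuals are
those with reads on both alleles; homozygous R and S plants anchor which
allele is the R allele; and a paired t-test on per-heterozygote
(R depth, S depth) pairs asks whether one parental allele is preferentially
expressed — the signature of cis-regulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io_formats import HOM_ALT, HOM_REF, VariantRecord

__all__ = [
    "AlleleClassification",
    "ASEResult",
    "find_heterozygotes",
    "classify_alleles",
    "ase_test",
    "ase_frame",
]


@dataclass
class AlleleClassification:
    key: tuple[str, int]
    r_allele: str  # 'ref', 'alt', or 'unclassified'
    n_hom_r_support: int
    n_hom_s_support: int


@dataclass
class ASEResult:
    key: tuple[str, int]
    depths: list[tuple[int, int]]  # per-heterozygote (r_depth, s_depth)
    n_het: int
    mean_r_fraction: float
    p: float
    q: float
    zero_variance: bool = False


def find_heterozygotes(
    records: list[VariantRecord], min_allele_depth: int = 2
) -> dict[tuple[str, int], list[str]]:
    """Samples showing expression of both alleles at each SNP.

    A sample counts as heterozygous-expressed iff both of its allele depths
    are at least ``min_allele_depth``.
    """
    out: dict[tuple[str, int], list[str]] = {}
    for rec in records:
        hets = [
            s
            for s, ad in rec.allelic_depths.items()
            if ad is not None and ad[0] >= min_allele_depth and ad[1] >= min_allele_depth
        ]
        out[rec.key] = sorted(hets)
    return out


def classify_alleles(records: list[VariantRecord], labels: pd.Series) -> dict[tuple[str, int], AlleleClassification]:
    """Assign the R allele per SNP from homozygous individuals.

    The R allele is called only when homozygous-R plants unanimously carry
    one allele, homozygous-S plants unanimously carry the other, and the two
    differ; otherwise the SNP is left unclassified.
    """
    out = {}
    for rec in records:
        hom_r = []
        hom_s = []
        for s, gt in rec.genotypes.items():
            if s not in labels.index or gt not in (HOM_REF, HOM_ALT):
                continue
            (hom_r if labels[s] == "R" else hom_s).append(gt)
        r_allele = "unclassified"
        if hom_r and hom_s and len(set(hom_r)) == 1 and len(set(hom_s)) == 1:
            a = "alt" if hom_r[0] == HOM_ALT else "ref"
            b = "alt" if hom_s[0] == HOM_ALT else "ref"
            if a != b:
                r_allele = a
        out[rec.key] = AlleleClassification(rec.key, r_allele, len(hom_r), len(hom_s))
    return out


def ase_test(
    records: list[VariantRecord],
    classifications: dict[tuple[str, int], AlleleClassification],
    min_het: int = 3,
    min_allele_depth: int = 2,
    fdr: float = 0.1,
    log_ratio: bool = False,
) -> list[ASEResult]:
    """Paired test of allelic imbalance at classified SNPs.

    Each heterozygous-expressed individual contributes an (R depth, S depth)
    pair; the default test is a paired two-sided t-test on the differences
    R - S (``log_ratio=True`` tests log2((R+1)/(S+1)) instead).  SNPs with
    fewer than ``min_het`` heterozygotes or without an R-allele call are
    excluded.  ``q`` is BH across all tested SNPs.
    """
    hets = find_heterozygotes(records, min_allele_depth=min_allele_depth)
    tested: list[ASEResult] = []
    for rec in records:
        cls = classifications.get(rec.key)
        if cls is None or cls.r_allele == "unclassified":
            continue
        samples = hets.get(rec.key, [])
        if len(samples) < min_het:
            continue
        pairs = []
        for s in samples:
            ad = rec.allelic_depths[s]
            r, s_depth = (ad[1], ad[0]) if cls.r_allele == "alt" else (ad[0], ad[1])
            pairs.append((int(r), int(s_depth)))
        arr = np.asarray(pairs, dtype=float)
        if log_ratio:
            diffs = np.log2(arr[:, 0] + 1) - np.log2(arr[:, 1] + 1)
        else:
            diffs = arr[:, 0] - arr[:, 1]
        zero_var = bool(np.all(diffs == diffs[0]) and np.all(diffs == 0)) or bool(np.std(diffs) == 0)
        if zero_var:
            p = 1.0
        else:
            p = float(stats.ttest_rel(arr[:, 0], arr[:, 1])[1]) if not log_ratio else float(
                stats.ttest_1samp(diffs, 0.0)[1]
            )
        total = arr.sum()
        mean_r = float(arr[:, 0].sum() / total) if total > 0 else np.nan
        tested.append(ASEResult(rec.key, pairs, len(samples), mean_r, p, np.nan, zero_var))
    if tested:
        q = bh_adjust([t.p for t in tested])
        for t, qi in zip(tested, q):
            t.q = float(qi)
    return tested


def ase_frame(results: list[ASEResult], fdr: float = 0.1) -> pd.DataFrame:
    """Tabular view of ASE results with a significance flag at ``q <= fdr``."""
    return pd.DataFrame(
        [
            {
                "scaffold": r.key[0],
                "pos": r.key[1],
                "n_het": r.n_het,
                "mean_r_fraction": r.mean_r_fraction,
                "p": r.p,
                "q": r.q,
                "significant": bool(r.q <= fdr),
            }
            for r in results
        ]
    )
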