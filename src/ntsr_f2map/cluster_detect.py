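"""Genomic coexpression-cluster detection for DEG sets.

A sliding hypergeometric window test asks, for each window along each
scaffold, how surprising the observed number of DEGs is given the
genome-wide DEG rate.  Windows significant after BH correction are merged
into cluster calls whose bounds are trimmed to the first and last member
DEG.  A separate per-scaffold Fisher test (Bonferroni-corrected) flags
whole scaffolds enriched for DEGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io_formats import GeneModel

__all__ = [
    "WindowStat",
    "ClusterCall",
    "window_counts",
    "hypergeom_tail",
    "detect_clusters",
    "chromosome_overrepresentation",
]


@dataclass
class WindowStat:
    scaffold: str
    start: int  # 0-based half-open window bounds
    end: int
    n: int  # genes in window
    k: int  # DEGs in window
    p: float
    adj_p: float


@dataclass
class ClusterCall:
    scaffold: str
    label: str
    start: int  # 1-based position of first member DEG
    stop: int  # 1-based end of last member DEG
    deg_ids: list[str]
    min_p: float
    adj_p: float


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts DEGs in a draw of ``n`` genes from ``N`` total of which ``K``
    are DEGs.  ``k = 0`` gives exactly 1.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent hypergeometric arguments k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _windows(scaffold_span: int, window_bp: int, step_bp: int) -> list[tuple[int, int]]:
    out = []
    start = 0
    while start < scaffold_span:
        out.append((start, start + window_bp))
        start += step_bp
    return out


def window_counts(
    genes: list[GeneModel],
    deg_ids: set[str],
    window_bp: int = 500_000,
    step_bp: int = 500_000,
) -> pd.DataFrame:
    """DEG and gene counts per window tiling each scaffold from 0.

    Windows are half-open ``[start, start + window_bp)`` and bin the raw
    1-based start coordinate of each gene (a gene at bp 500,000 falls in the
    second 500-kb window), so a non-overlapping tiling conserves the total
    DEG count.
    """
    rows = []
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for scaffold in sorted(by_scaffold):
        glist = sorted(by_scaffold[scaffold], key=lambda g: g.start)
        starts = np.array([g.start for g in glist])
        is_deg = np.array([g.gene_id in deg_ids for g in glist])
        span = int(starts.max()) + 1 if len(glist) else 0
        for w_start, w_end in _windows(span, window_bp, step_bp):
            inside = (starts >= w_start) & (starts < w_end)
            rows.append(
                {
                    "scaffold": scaffold,
                    "start": w_start,
                    "end": w_end,
                    "n": int(inside.sum()),
                    "k": int((inside & is_deg).sum()),
                }
            )
    return pd.DataFrame(rows)


def detect_clusters(
    genes: list[GeneModel],
    deg_ids: set[str],
    window_bp: int = 1_000_000,
    offset_bp: int = 500_000,
    cluster_fdr: float = 0.05,
    label: str = "",
) -> tuple[list[ClusterCall], list[WindowStat]]:
    """Call DEG clusters from overlapping hypergeometric windows.

    Every window (default 1 Mb, advanced by 500 kb) is tested against the
    genome-wide totals N (all genes) and K (all DEGs); BH correction is
    applied across all tested windows; significant (adj_p < cluster_fdr)
    overlapping or adjacent windows on one scaffold are merged and the
    reported cluster bounds are the first/last member DEG coordinates.
    """
    if not genes:
        raise ValueError("no genes")
    N = len(genes)
    K = len({g.gene_id for g in genes} & deg_ids)
    wc = window_counts(genes, deg_ids, window_bp=window_bp, step_bp=offset_bp)
    p = np.array([hypergeom_tail(int(r.k), int(r.n), K, N) for r in wc.itertuples()])
    adj = bh_adjust(p)
    stats_out = [
        WindowStat(r.scaffold, int(r.start), int(r.end), int(r.n), int(r.k), float(pi), float(ai))
        for r, pi, ai in zip(wc.itertuples(), p, adj)
    ]
    # merge significant windows per scaffold
    sig = [w for w in stats_out if w.adj_p < cluster_fdr and w.k > 0]
    by_scaffold: dict[str, list[WindowStat]] = {}
    for w in sig:
        by_scaffold.setdefault(w.scaffold, []).append(w)
    gene_lookup: dict[str, list[GeneModel]] = {}
    for g in genes:
        gene_lookup.setdefault(g.scaffold, []).append(g)
    calls: list[ClusterCall] = []
    for scaffold in sorted(by_scaffold):
        ws = sorted(by_scaffold[scaffold], key=lambda w: w.start)
        merged: list[list[WindowStat]] = [[ws[0]]]
        for w in ws[1:]:
            if w.start <= merged[-1][-1].end:  # overlapping or adjacent
                merged[-1].append(w)
            else:
                merged.append([w])
        for group in merged:
            span0 = (group[0].start, group[-1].end)
            members = sorted(
                (
                    g
                    for g in gene_lookup[scaffold]
                    if g.gene_id in deg_ids and span0[0] <= g.start < span0[1]
                ),
                key=lambda g: g.start,
            )
            if not members:
                continue
            calls.append(
                ClusterCall(
                    scaffold=scaffold,
                    label=label,
                    start=members[0].start,
                    stop=members[-1].end,
                    deg_ids=[g.gene_id for g in members],
                    min_p=min(w.p for w in group),
                    adj_p=min(w.adj_p for w in group),
                )
            )
    return calls, stats_out


def chromosome_overrepresentation(genes: list[GeneModel], deg_ids: set[str]) -> pd.DataFrame:
    """Per-scaffold DEG enrichment: two-sided Fisher, Bonferroni-adjusted."""
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    if not by_scaffold:
        raise ValueError("no scaffolds")
    total = len(genes)
    total_deg = len({g.gene_id for g in genes} & deg_ids)
    m = len(by_scaffold)
    rows = []
    for scaffold in sorted(by_scaffold):
        glist = by_scaffold[scaffold]
        on = len(glist)
        deg_on = sum(g.gene_id in deg_ids for g in glist)
        table = [[deg_on, total_deg - deg_on], [on - deg_on, (total - total_deg) - (on - deg_on)]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append(
            {
                "scaffold": scaffold,
                "n_genes": on,
                "n_degs": deg_on,
                "p": p,
                "adj_p": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows).set_index("scaffold")


def window_stats_frame(stats_out: list[WindowStat]) -> pd.DataFrame:
    """Window track as a BED-like frame (scaffold, start, stop, k, n, p, adj_p)."""
    return pd.DataFrame(
        [
            {
                "scaffold": w.scaffold,
                "start": w.start,
                "stop": w.end,
                "k": w.k,
                "n": w.n,
                "p": w.p,
                "adj_p": w.adj_p,
            }
            for w in stats_out
        ]
    )
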