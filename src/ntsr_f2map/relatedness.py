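"""Identity-by-state relatedness at a locus, UPGMA trees, Newick export.

The per-gene "which plants share an allele" question is answered with an
IBS (identity-by-state) distance over genotype dosages restricted to a
genomic interval, followed by average-linkage hierarchical clustering with
a deterministic lexicographic tie-break, so trees are reproducible and
independent of sample input order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import HET, HOM_ALT, HOM_REF, VariantRecord

__all__ = ["genotype_matrix", "ibs_distance", "hclust_average", "cut_tree", "tree_height"]

_DOSAGE = {HOM_REF: 0.0, HET: 1.0, HOM_ALT: 2.0}


def genotype_matrix(
    records: list[VariantRecord],
    samples: list[str],
    region: tuple[str, int, int] | None = None,
) -> pd.DataFrame:
    """Samples x loci alt-allele dosages (0/1/2, NaN = missing).

    ``region`` is (scaffold, start, stop), 1-based inclusive, e.g. the CDS
    of a focal gene.
    """
    recs = records
    if region is not None:
        scaffold, start, stop = region
        recs = [r for r in records if r.scaffold == scaffold and start <= r.pos <= stop]
    if not recs:
        raise ValueError("no loci in the requested region")
    data = {
        f"{r.scaffold}:{r.pos}": [_DOSAGE.get(r.genotypes.get(s, "missing"), np.nan) for s in samples]
        for r in recs
    }
    return pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))


def ibs_distance(gm: pd.DataFrame, allow_missing: bool = False) -> pd.DataFrame:
    """IBS dissimilarity: d(i,j) = mean over shared typed loci of |gi - gj| / 2.

    d lies in [0, 1] with d(i,i) = 0.  A sample pair with no shared typed
    locus is an error unless ``allow_missing``, in which case its distance
    is NaN.
    """
    if gm.shape[0] < 2 or gm.shape[1] < 1:
        raise ValueError("need >= 2 samples and >= 1 locus")
    x = gm.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(x[i]) & ~np.isnan(x[j])
            if not both.any():
                if not allow_missing:
                    raise ValueError(
                        f"samples {gm.index[i]!r} and {gm.index[j]!r} share no typed locus"
                    )
                d[i, j] = d[j, i] = np.nan
                continue
            d[i, j] = d[j, i] = np.mean(np.abs(x[i, both] - x[j, both]) / 2.0)
    return pd.DataFrame(d, index=gm.index, columns=gm.index)


def _min_label(node) -> str:
    if isinstance(node, str):
        return node
    return min(_min_label(node[0]), _min_label(node[1]))


def hclust_average(dist: pd.DataFrame):
    """Average-linkage (UPGMA) merge tree over a symmetric distance matrix.

    Ties on the minimum inter-cluster distance are broken by the
    lexicographically smallest pair of cluster labels (a cluster's label is
    its smallest member), so the tree is deterministic and input-order free.
    Returns a nested ``(left, right, height)`` tuple tree (leaves are
    sample-id strings).
    """
    d = dist.to_numpy(dtype=float)
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("distance matrix is not symmetric")
    labels = [str(s) for s in dist.index]
    clusters: dict[int, tuple] = {i: labels[i] for i in range(len(labels))}
    sizes = {i: 1 for i in range(len(labels))}
    dmat = {(i, j): d[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))}
    if len(labels) == 1:
        return labels[0]
    next_id = len(labels)
    while len(clusters) > 1:
        best = None
        for (i, j), dij in dmat.items():
            if i not in clusters or j not in clusters:
                continue
            key = (dij, tuple(sorted((_min_label(clusters[i]), _min_label(clusters[j])))))
            if best is None or key < best[0]:
                best = (key, i, j)
        (dij, _), i, j = best
        left, right = clusters[i], clusters[j]
        if _min_label(left) > _min_label(right):
            left, right = right, left
        node = (left, right, float(dij))
        si, sj = sizes[i], sizes[j]
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dmat[tuple(sorted((i, k)))]
            djk = dmat[tuple(sorted((j, k)))]
            dmat[tuple(sorted((next_id, k)))] = (si * dik + sj * djk) / (si + sj)
        del clusters[i], clusters[j]
        clusters[next_id] = node
        sizes[next_id] = si + sj
        next_id += 1
    return clusters.popitem()[1]


def tree_height(tree) -> float:
    return 0.0 if isinstance(tree, str) else float(tree[2])


def _leaves(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    return _leaves(node[0]) + _leaves(node[1])


def cut_tree(tree, height_fraction: float) -> pd.Series:
    """Group labels from cutting the tree at a fraction of its total height.

    The cut height is ``height_fraction * max merge height``; groups are the
    maximal subtrees whose merge height is <= the cut (leaves count as
    height 0).  ``height_fraction`` must lie in (0, 1].
    """
    if not 0 < height_fraction <= 1:
        raise ValueError("height_fraction must be in (0, 1]")
    h_cut = height_fraction * tree_height(tree)
    groups: list[list[str]] = []

    def descend(node):
        if tree_height(node) <= h_cut:
            groups.append(_leaves(node))
        else:
            descend(node[0])
            descend(node[1])

    descend(tree)
    groups.sort(key=lambda g: min(g))
    out = {}
    for gid, members in enumerate(groups):
        for m in members:
            out[m] = gid
    return pd.Series(out, name="group").sort_index()
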