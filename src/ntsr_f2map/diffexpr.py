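"""R/S classification, differential expression, FDR control, and qPCR.

The DE engine here is deliberately transparent: library-size normalisation
to counts-per-million, log2(CPM + 1), and a per-gene Welch two-sample
t-test.  A per-gene p-value table computed by an external engine can be
injected instead, so the downstream cluster / SNP / ASE stages are agnostic
to how the DEG list was produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix

__all__ = [
    "DEGResult",
    "QpcrResult",
    "classify_samples",
    "segregation_independence_test",
    "test_differential_expression",
    "bh_adjust",
    "call_degs",
    "delta_delta_ct",
    "regress_expression_on_rating",
]


@dataclass
class DEGResult:
    gene_id: str
    effect: float  # log2 fold change, positive = higher in R
    p: float
    q: float
    is_deg: bool


@dataclass
class QpcrResult:
    sample_id: str
    target: str
    delta_ct: float
    delta_delta_ct: float
    rel_expr: float


def classify_samples(design: pd.DataFrame, herbicide: str, cutoff: float = 3) -> pd.Series:
    """Derive R/S labels from damage ratings: rating > cutoff -> R, else S.

    The rating scale is 1-10 with 10 = no damage, so high ratings mean
    resistant.  A rating exactly at the cutoff is classified S.
    """
    col = f"rating_{herbicide}"
    if col not in design.columns:
        raise KeyError(f"design table has no column {col!r}")
    ratings = design[col]
    if ((ratings < 1) | (ratings > 10)).any():
        raise ValueError("ratings must be within 1-10")
    return pd.Series(np.where(ratings > cutoff, "R", "S"), index=design.index, name=f"label_{herbicide}")


def segregation_independence_test(labels_a: pd.Series | list, labels_b: pd.Series | list) -> tuple[np.ndarray, float]:
    """Two-sided Fisher exact test of independence of two R/S traits.

    Returns the 2x2 joint count table [[RR, RS], [SR, SS]] (rows = trait A)
    and the exact p-value.  A table with a zero margin is degenerate and
    returns p = 1 with a warning.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    table = np.array(
        [
            [np.sum((a == "R") & (b == "R")), np.sum((a == "R") & (b == "S"))],
            [np.sum((a == "S") & (b == "R")), np.sum((a == "S") & (b == "S"))],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p = 1")
        return table, 1.0
    return table, float(stats.fisher_exact(table, alternative="two-sided")[1])


def _log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0).astype(float)
    lib[lib == 0] = 1.0
    return np.log2(counts.div(lib, axis=1) * 1e6 + 1.0)


def test_differential_expression(
    counts: CountMatrix,
    labels: pd.Series,
    method: str = "welch_logcpm",
    external_p: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene effect (log2 FC, R minus S) and p-value.

    ``method='welch_logcpm'`` (default): Welch t-test on log2(CPM+1).
    ``method='external'``: adopt ``external_p`` (columns ``effect``, ``p``
    indexed by gene), e.g. output of a bootstrap-based engine.
    """
    if method == "external":
        if external_p is None:
            raise ValueError("external method requires external_p")
        df = external_p.reindex(counts.genes)
        return df[["effect", "p"]].copy()
    if method != "welch_logcpm":
        raise ValueError(f"unknown method {method!r}")
    labels = labels.reindex(counts.samples)
    r_samples = [s for s in counts.samples if labels[s] == "R"]
    s_samples = [s for s in counts.samples if labels[s] == "S"]
    if len(r_samples) < 2 or len(s_samples) < 2:
        raise ValueError("need >= 2 samples per group")
    x = _log_cpm(counts.counts)
    xr = x[r_samples].to_numpy()
    xs = x[s_samples].to_numpy()
    effect = xr.mean(axis=1) - xs.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xr, xs, axis=1, equal_var=False)
    # zero variance in both groups: no evidence either way
    flat = (xr.std(axis=1) == 0) & (xs.std(axis=1) == 0)
    p = np.where(flat, 1.0, p)
    effect = np.where(flat & (effect == 0), 0.0, effect)
    p = np.nan_to_num(p, nan=1.0)
    return pd.DataFrame({"effect": effect, "p": p}, index=counts.genes)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} min(1, m p_(j) / j) over the sorted p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_degs(results: pd.DataFrame, fdr: float = 0.1) -> list[DEGResult]:
    """Flag DEGs at BH-adjusted p <= fdr (boundary value is a DEG)."""
    q = bh_adjust(results["p"].to_numpy())
    out = []
    for (gene, row), qi in zip(results.iterrows(), q):
        out.append(DEGResult(gene, float(row["effect"]), float(row["p"]), float(qi), bool(qi <= fdr)))
    return out


def deg_ids(degs: list[DEGResult]) -> set[str]:
    return {d.gene_id for d in degs if d.is_deg}


def delta_delta_ct(
    ct_table: pd.DataFrame,
    target: str,
    housekeeping: list[str],
    reference_sample: str,
) -> list[QpcrResult]:
    """Relative expression by the 2^(-ddCt) method.

    dCt = Ct_target - mean(Ct_housekeeping); ddCt = dCt_sample -
    dCt_reference; rel_expr = 2^(-ddCt).  Samples with any missing Ct are
    skipped with a warning; the reference sample has rel_expr exactly 1.
    """
    if not housekeeping:
        raise ValueError("need at least one housekeeping gene")
    if reference_sample not in ct_table.index:
        raise ValueError(f"reference sample {reference_sample!r} absent from Ct table")
    cols = [target] + list(housekeeping)
    missing = ct_table[cols].isna().any(axis=1)
    if missing[reference_sample]:
        raise ValueError("reference sample has missing Ct values")
    dct = ct_table[target] - ct_table[list(housekeeping)].mean(axis=1)
    ddct = dct - dct[reference_sample]
    out = []
    for sample in ct_table.index:
        if missing[sample]:
            warnings.warn(f"sample {sample}: missing Ct, skipped")
            continue
        out.append(
            QpcrResult(sample, target, float(dct[sample]), float(ddct[sample]), float(2.0 ** (-ddct[sample])))
        )
    return out


def regress_expression_on_rating(rel_expr: pd.Series, ratings: pd.Series) -> tuple[float, float]:
    """OLS slope of relative expression on phenotype rating, with t-test p."""
    common = rel_expr.index.intersection(ratings.index)
    if len(common) < 3:
        raise ValueError("need >= 3 samples")
    x = ratings[common].to_numpy(dtype=float)
    y = rel_expr[common].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError("constant rating: slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)
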