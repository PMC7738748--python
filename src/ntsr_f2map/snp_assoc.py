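"""Variant hard filters and condition-specific SNP association.

SNPs passing the GATK-style site filters and the clustered-SNP filter are
tested for allele-frequency differences between resistant (R) and sensitive
(S) plants with a two-sided Fisher exact test on allele counts, backed by
an adaptive Monte-Carlo permutation test of the sample labels.  A SNP is
called condition-specific when both its BH-adjusted exact p and its
empirical permutation p fall at or below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io_formats import HET, HOM_ALT, HOM_REF, VariantRecord

__all__ = [
    "FilterSpec",
    "hard_filter",
    "snp_cluster_filter",
    "fisher_two_sided",
    "allelic_fisher",
    "adaptive_permutation",
    "call_condition_snps",
    "snp_window_track",
]

DEFAULT_CHECKPOINTS = (50, 100, 200, 500)


@dataclass
class FilterSpec:
    """Named variant-filter thresholds.

    ``final`` mode applies the post-recalibration filters (QD < 2 or
    FS > 30 fails); ``discovery_strict`` applies the bootstrap-set filters
    (QD < 2, FS > 60, MQ < 40, MQRankSum < -12.5, ReadPosRankSum < -8).
    An absent annotation never fails its rule.
    """

    qd_min: float = 2.0
    fs_max_final: float = 30.0
    fs_max_strict: float = 60.0
    mq_min: float = 40.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0
    snp_cluster_window_bp: int = 35
    snp_cluster_count: int = 3

    def rules(self, mode: str) -> dict[str, tuple[str, float]]:
        """Map annotation key -> (fail direction, threshold)."""
        if mode == "final":
            return {"QD": ("<", self.qd_min), "FS": (">", self.fs_max_final)}
        if mode == "discovery_strict":
            return {
                "QD": ("<", self.qd_min),
                "FS": (">", self.fs_max_strict),
                "MQ": ("<", self.mq_min),
                "MQRankSum": ("<", self.mq_rank_sum_min),
                "ReadPosRankSum": ("<", self.read_pos_rank_sum_min),
            }
        raise ValueError(f"unknown filter mode {mode!r}")


def hard_filter(
    records: list[VariantRecord], spec: FilterSpec | None = None, mode: str = "final"
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Drop records whose present annotations violate any threshold.

    Returns kept records and a per-rule rejection tally (a record failing
    several rules increments each of them).
    """
    spec = spec or FilterSpec()
    rules = spec.rules(mode)
    tally = {k: 0 for k in rules}
    kept = []
    for rec in records:
        failed = False
        for key, (direction, threshold) in rules.items():
            v = rec.site_annotations.get(key)
            if v is None:
                continue
            if (direction == "<" and v < threshold) or (direction == ">" and v > threshold):
                tally[key] += 1
                failed = True
        if not failed:
            kept.append(rec)
    return kept, tally


def snp_cluster_filter(
    records: list[VariantRecord], window_bp: int = 35, count: int = 3
) -> list[VariantRecord]:
    """Remove SNP clusters: any run of >= count SNPs spanning <= window_bp.

    Mirrors the GATK ``-window 35 -cluster 3`` variant filter: every SNP
    that is part of such a run (on one scaffold) is removed.
    """
    recs = sorted(records, key=lambda r: (r.scaffold, r.pos))
    remove = set()
    by_scaffold: dict[str, list[VariantRecord]] = {}
    for r in recs:
        by_scaffold.setdefault(r.scaffold, []).append(r)
    for scaffold, rs in by_scaffold.items():
        pos = [r.pos for r in rs]
        for i in range(len(pos) - count + 1):
            if pos[i + count - 1] - pos[i] <= window_bp:
                remove.update(range(i, i + count))
        by_scaffold[scaffold] = [rs[i] for i in range(len(rs)) if i not in remove]
        remove = set()
    out = []
    for scaffold in sorted(by_scaffold):
        out.extend(by_scaffold[scaffold])
    return out


@lru_cache(maxsize=1_000_000)
def _fisher_cached(a: int, r1: int, c1: int, n: int) -> float:
    """Two-sided Fisher p for the 2x2 table with cell (1,1) = a and margins
    (r1, n - r1) x (c1, n - c1), by hypergeometric point-probability
    summation (the same tail definition as R's fisher.test)."""
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    xs = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(xs, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return 1.0 if p > 1 - 1e-12 else p


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (cached backend)."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    n = a + b + c + d
    if n == 0 or (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return _fisher_cached(int(a), int(a + b), int(a + c), int(n))


_ALLELES = {HOM_REF: (2, 0), HET: (1, 1), HOM_ALT: (0, 2)}


def _allele_count_arrays(records: list[VariantRecord], samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP, per-sample (ref, alt) allele contributions; missing -> 0."""
    ref = np.zeros((len(records), len(samples)), dtype=np.int64)
    alt = np.zeros_like(ref)
    for i, rec in enumerate(records):
        for j, s in enumerate(samples):
            gt = rec.genotypes.get(s, "missing")
            if gt in _ALLELES:
                ref[i, j], alt[i, j] = _ALLELES[gt]
    return ref, alt


def allelic_fisher(records: list[VariantRecord], labels: pd.Series) -> pd.DataFrame:
    """Case/control allelic association per SNP.

    Each non-missing sample contributes two allele observations by
    genotype; the 2x2 table is [R: ref, alt; S: ref, alt] and the test is
    two-sided Fisher exact.  Monomorphic SNPs get p = 1.
    """
    samples = [s for s in labels.index]
    is_r = labels.to_numpy() == "R"
    if is_r.all() or not is_r.any():
        raise ValueError("need at least one R and one S sample")
    ref, alt = _allele_count_arrays(records, samples)
    rows = []
    for i, rec in enumerate(records):
        r_ref = int(ref[i, is_r].sum())
        r_alt = int(alt[i, is_r].sum())
        s_ref = int(ref[i, ~is_r].sum())
        s_alt = int(alt[i, ~is_r].sum())
        p = fisher_two_sided([[r_ref, r_alt], [s_ref, s_alt]])
        rows.append(
            {
                "scaffold": rec.scaffold,
                "pos": rec.pos,
                "r_ref": r_ref,
                "r_alt": r_alt,
                "s_ref": s_ref,
                "s_alt": s_alt,
                "fisher_p": p,
            }
        )
    return pd.DataFrame(rows)


def _clopper_pearson(b: int, t: int, conf: float = 0.95) -> tuple[float, float]:
    a = (1 - conf) / 2
    lo = 0.0 if b == 0 else float(stats.beta.ppf(a, b, t - b + 1))
    hi = 1.0 if b == t else float(stats.beta.ppf(1 - a, b + 1, t - b))
    return lo, hi


def adaptive_permutation(
    records: list[VariantRecord],
    labels: pd.Series,
    max_perm: int = 1000,
    checkpoints: tuple[int, ...] = DEFAULT_CHECKPOINTS,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    assoc: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Adaptive Monte-Carlo permutation p-values for the allelic test.

    R/S labels are permuted jointly across samples (group sizes fixed); per
    SNP the statistic is the Fisher exact p itself and ``emp_p = (b+1)/(t+1)``
    where ``b`` counts permutations at least as extreme as observed.  At
    each checkpoint a SNP whose 95% Clopper-Pearson interval for the
    empirical p excludes ``alpha`` stops permuting; every surviving SNP
    stops at ``max_perm``.
    """
    from math import comb

    if rng is None:
        rng = np.random.default_rng(seed)
    samples = list(labels.index)
    is_r = labels.to_numpy() == "R"
    n_r = int(is_r.sum())
    if n_r == 0 or n_r == len(samples):
        raise ValueError("need at least one R and one S sample")
    if comb(len(samples), n_r) < 2:
        raise ValueError("fewer than 2 distinct label arrangements")
    if assoc is None:
        assoc = allelic_fisher(records, labels)
    p_obs = assoc["fisher_p"].to_numpy()
    ref, alt = _allele_count_arrays(records, samples)
    tot = ref + alt
    c1 = ref.sum(axis=1)  # total ref alleles per SNP
    n_all = tot.sum(axis=1)

    n_snps = len(records)
    b = np.zeros(n_snps, dtype=np.int64)
    t_done = np.zeros(n_snps, dtype=np.int64)
    active = np.ones(n_snps, dtype=bool)
    stops = sorted({c for c in checkpoints if c < max_perm} | {max_perm})
    base = np.zeros(len(samples), dtype=bool)
    base[:n_r] = True
    prev = 0
    tol = 1 + 1e-9
    for stop in stops:
        if not active.any():
            break
        chunk = stop - prev
        perms = np.stack([rng.permutation(base) for _ in range(chunk)], axis=1)  # (S, chunk)
        act = np.flatnonzero(active)
        a_mat = ref[act] @ perms  # ref alleles in permuted R group
        r1_mat = tot[act] @ perms
        for row, i in enumerate(act):
            c1_i, n_i = int(c1[i]), int(n_all[i])
            count = 0
            thresh = p_obs[i] * tol
            for a_v, r1_v in zip(a_mat[row], r1_mat[row]):
                if r1_v == 0 or r1_v == n_i or c1_i == 0 or c1_i == n_i:
                    p = 1.0
                else:
                    p = _fisher_cached(int(a_v), int(r1_v), c1_i, n_i)
                if p <= thresh:
                    count += 1
            b[i] += count
            t_done[i] = stop
        # adaptive pruning
        if stop < max_perm:
            for i in act:
                lo, hi = _clopper_pearson(int(b[i]), int(t_done[i]))
                if alpha < lo or alpha > hi:
                    active[i] = False
        prev = stop
    emp_p = (b + 1) / (t_done + 1)
    out = assoc.copy()
    out["emp_p"] = emp_p
    out["permutations_done"] = t_done
    return out


def call_condition_snps(assoc: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag condition-specific SNPs.

    ``q`` is BH over the exact Fisher p-values; a SNP is condition-specific
    when both ``q <= alpha`` and ``emp_p <= alpha``.
    """
    out = assoc.copy()
    out["q"] = bh_adjust(out["fisher_p"].to_numpy()) if len(out) else []
    if "emp_p" not in out.columns:
        raise ValueError("run adaptive_permutation first (emp_p missing)")
    out["is_condition_snp"] = (out["q"] <= alpha) & (out["emp_p"] <= alpha)
    return out


def snp_window_track(
    assoc: pd.DataFrame, window_bp: int = 500_000, step_bp: int = 500_000
) -> pd.DataFrame:
    """Count flagged SNPs per window (same binning as the DEG track)."""
    rows = []
    flagged = assoc[assoc["is_condition_snp"]] if "is_condition_snp" in assoc.columns else assoc
    for scaffold, sub in assoc.groupby("scaffold"):
        span = int(sub["pos"].max())
        fl = flagged[flagged["scaffold"] == scaffold]
        pos = fl["pos"].to_numpy()
        start = 0
        while start < span:
            k = int(((pos >= start) & (pos < start + window_bp)).sum())
            rows.append({"scaffold": scaffold, "start": start, "stop": start + window_bp, "k": k})
            start += step_bp
    return pd.DataFrame(rows)
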