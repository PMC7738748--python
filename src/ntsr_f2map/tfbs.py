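"""Promoter extraction, PWM scanning, and TFBS over-representation.

Position frequency matrices are converted to log-odds scoring matrices
against a uniform background; promoters are scanned on both strands and a
hit is any window whose score reaches 90% of the matrix's (min, max)-
normalised range, the convention of the common R motif-scanning tools.
Over-representation of motif-bearing promoters in a DEG set is assessed
with the same upper-tail hypergeometric test used for genomic clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_detect import hypergeom_tail
from .diffexpr import bh_adjust
from .io_formats import GeneModel, PositionFrequencyMatrix

__all__ = [
    "ScoringMatrix",
    "MotifHit",
    "extract_promoters",
    "pfm_to_scoring_matrix",
    "scan_promoter",
    "scan_all",
    "tfbs_overrepresentation",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class ScoringMatrix:
    motif_id: str
    weights: np.ndarray  # 4 x L log2-odds
    min_score: float
    max_score: float

    @property
    def length(self) -> int:
        return int(self.weights.shape[1])


@dataclass
class MotifHit:
    gene_id: str
    motif_id: str
    offset: int  # 0-based position in the promoter (forward coordinates)
    strand: str
    relative_score: float


def extract_promoters(
    genes: list[GeneModel], genome: dict[str, str], length: int = 1000, min_length: int = 50
) -> dict[str, str]:
    """The ``length`` bases upstream of each gene's transcription start.

    For + strand genes this is the window ending immediately before the
    gene start; for - strand genes the window beginning immediately after
    the gene end, reverse-complemented.  Promoters truncated below
    ``min_length`` by a scaffold edge are skipped with a warning.
    """
    out: dict[str, str] = {}
    for g in genes:
        if g.scaffold not in genome:
            raise KeyError(f"gene {g.gene_id}: scaffold {g.scaffold!r} absent from genome")
        seq = genome[g.scaffold]
        if g.strand == "+":
            lo = max(0, g.start0 - length)
            prom = seq[lo : g.start0]
        else:
            prom = seq[g.end0 : g.end0 + length]
            prom = prom.translate(_COMPLEMENT)[::-1]
        if len(prom) < min_length:
            warnings.warn(f"gene {g.gene_id}: promoter truncated to {len(prom)} bp, skipped")
            continue
        out[g.gene_id] = prom
    return out


def pfm_to_scoring_matrix(
    pfm: PositionFrequencyMatrix, pseudocount: float = 0.8, background: float = 0.25
) -> ScoringMatrix:
    """Log2-odds scoring matrix from base counts.

    Per column: prob = (count + pseudocount * background) / (colsum +
    pseudocount); weight = log2(prob / background).  min/max scores are the
    sums of the per-column minima/maxima.
    """
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    if pseudocount <= 0 and (colsum == 0).any():
        raise ValueError("zero column sum with zero pseudocount")
    probs = (counts + pseudocount * background) / (colsum + pseudocount)
    weights = np.log2(probs / background)
    return ScoringMatrix(
        pfm.motif_id,
        weights,
        float(weights.min(axis=0).sum()),
        float(weights.max(axis=0).sum()),
    )


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[ord(b)] = i
    return code[arr]


def _window_scores(encoded: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw score at every offset plus a validity mask (no N in window)."""
    L = weights.shape[1]
    n_off = encoded.size - L + 1
    if n_off <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(encoded, L)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    scores = weights[safe, np.arange(L)].sum(axis=1)
    return scores, valid


def scan_promoter(
    seq: str, matrix: ScoringMatrix, min_rel_score: float = 0.9, gene_id: str = ""
) -> list[MotifHit]:
    """Report motif hits on both strands at relative score >= threshold.

    The relative score is (raw - min) / (max - min).  Minus-strand hits are
    found by scanning the forward sequence with the reverse-complemented
    matrix; their offsets are forward-strand coordinates of the site start.
    Windows containing any non-ACGT base are skipped.
    """
    encoded = _encode(seq)
    denom = matrix.max_score - matrix.min_score
    hits: list[MotifHit] = []
    rc_weights = matrix.weights[::-1, ::-1]
    for strand, weights in (("+", matrix.weights), ("-", rc_weights)):
        scores, valid = _window_scores(encoded, weights)
        if scores.size == 0:
            continue
        rel = (scores - matrix.min_score) / denom if denom > 0 else np.ones_like(scores)
        for off in np.flatnonzero(valid & (rel >= min_rel_score)):
            hits.append(MotifHit(gene_id, matrix.motif_id, int(off), strand, float(rel[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_all(
    promoters: dict[str, str],
    matrices: list[ScoringMatrix],
    min_rel_score: float = 0.9,
) -> pd.DataFrame:
    """Scan every promoter with every matrix; long-format hit table.

    Batched implementation: promoters of equal length are stacked and each
    matrix is applied with one vectorised pass per motif column, which is
    what makes scanning thousands of promoters cheap.  Hit-for-hit
    equivalent to :func:`scan_promoter` (asserted in tests).
    """
    by_length: dict[int, list[str]] = {}
    for gid, seq in promoters.items():
        by_length.setdefault(len(seq), []).append(gid)
    rows = []
    for length, gids in by_length.items():
        base_codes = np.stack([_encode(promoters[g]) for g in gids])  # (n, Lp)
        valid_base = base_codes >= 0
        safe = np.where(valid_base, base_codes, 0).astype(np.int64)
        word_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

        def window_state(L: int):
            """Rolling base-4 word codes and validity for length-L windows."""
            if L not in word_cache:
                n_off = length - L + 1
                codes = np.zeros((len(gids), n_off), dtype=np.int64)
                valid = np.ones((len(gids), n_off), dtype=bool)
                for j in range(L):
                    codes += safe[:, j : j + n_off] << (2 * (L - 1 - j))
                    valid &= valid_base[:, j : j + n_off]
                word_cache[L] = (codes, valid)
            return word_cache[L]

        for m in matrices:
            L = m.length
            n_off = length - L + 1
            if n_off <= 0:
                continue
            denom = m.max_score - m.min_score
            for strand, weights in (("+", m.weights), ("-", m.weights[::-1, ::-1])):
                if L <= 12:
                    # score every possible L-mer once, then look windows up
                    table = weights[:, 0]
                    for j in range(1, L):
                        table = np.add.outer(table, weights[:, j]).ravel()
                    codes, valid = window_state(L)
                    scores = table[codes]
                else:
                    scores = np.zeros((len(gids), n_off))
                    valid = np.ones((len(gids), n_off), dtype=bool)
                    for j in range(L):
                        scores += weights[:, j][safe[:, j : j + n_off]]
                        valid &= valid_base[:, j : j + n_off]
                rel = (scores - m.min_score) / denom if denom > 0 else np.ones_like(scores)
                for i, off in zip(*np.nonzero(valid & (rel >= min_rel_score))):
                    rows.append(
                        {
                            "gene_id": gids[i],
                            "motif_id": m.motif_id,
                            "offset": int(off),
                            "strand": strand,
                            "relative_score": float(rel[i, off]),
                        }
                    )
    df = pd.DataFrame(rows, columns=["gene_id", "motif_id", "offset", "strand", "relative_score"])
    return df.sort_values(["gene_id", "motif_id", "offset", "strand"], kind="mergesort").reset_index(
        drop=True
    )


def tfbs_overrepresentation(
    hits: pd.DataFrame, deg_ids: set[str], all_gene_ids: set[str]
) -> pd.DataFrame:
    """Per-motif DEG over-representation of motif-bearing promoters.

    For each motif: N = genes with promoters, K = genes with >= 1 hit,
    n = DEG genes, k = DEG genes with >= 1 hit; p = P(X >= k) upper-tail
    hypergeometric, BH-adjusted across the motif library.
    """
    deg = deg_ids & all_gene_ids
    if not deg:
        raise ValueError("empty DEG set")
    N = len(all_gene_ids)
    n = len(deg)
    rows = []
    for motif_id, sub in hits.groupby("motif_id"):
        with_hit = set(sub["gene_id"]) & all_gene_ids
        K = len(with_hit)
        k = len(with_hit & deg)
        rows.append({"motif_id": motif_id, "K": K, "k": k, "p": hypergeom_tail(k, n, K, N)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    return df
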