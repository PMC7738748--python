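import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ntsr_f2map.io_formats import VariantRecord
from ntsr_f2map.snp_assoc import (
    FilterSpec,
    adaptive_permutation,
    allelic_fisher,
    call_condition_snps,
    fisher_two_sided,
    hard_filter,
    snp_cluster_filter,
    snp_window_track,
)


def _rec(pos, annotations=None, genotypes=None, depths=None, scaffold="s1"):
    genotypes = genotypes or {}
    return VariantRecord(
        scaffold=scaffold,
        pos=pos,
        ref_allele="A",
        alt_allele="G",
        site_annotations=annotations or {},
        genotypes=genotypes,
        allelic_depths=depths or {s: (5, 5) for s in genotypes},
    )


class TestHardFilter:
    def test_qd_rule_boundary(self):
        recs = [_rec(10 * (i + 1), {"QD": qd}) for i, qd in enumerate([1.0, 2.0, 5, 5, 5, 5])]
        kept, tally = hard_filter(recs, FilterSpec(), mode="final")
        assert len(kept) == 5  # QD == 2.0 passes: the rule is "fails if < 2.0"
        assert tally == {"QD": 1, "FS": 0}

    def test_fs_mode_dependence(self):
        rec = _rec(5, {"FS": 31.0})
        kept_final, _ = hard_filter([rec], mode="final")
        kept_strict, _ = hard_filter([rec], mode="discovery_strict")
        assert kept_final == [] and kept_strict == [rec]

    def test_absent_annotations_pass(self):
        rec = _rec(5, {})
        for mode in ("final", "discovery_strict"):
            kept, _ = hard_filter([rec], mode=mode)
            assert kept == [rec]

    def test_strict_rank_sum_rules(self):
        bad = _rec(5, {"MQRankSum": -13.0})
        ok = _rec(6, {"MQRankSum": -12.5, "ReadPosRankSum": -8.0, "MQ": 40.0})
        kept, tally = hard_filter([bad, ok], mode="discovery_strict")
        assert kept == [ok] and tally["MQRankSum"] == 1

    def test_idempotent(self):
        recs = [_rec(i * 100, {"QD": float(q)}) for i, q in enumerate([1, 3, 4, 1, 9])]
        once, _ = hard_filter(recs)
        twice, _ = hard_filter(once)
        assert once == twice


class TestSnpClusterFilter:
    def test_triplet_within_window_removed(self):
        recs = [_rec(p) for p in (100, 120, 130)]
        assert snp_cluster_filter(recs) == []

    def test_spread_positions_kept(self):
        recs = [_rec(p) for p in (100, 200, 300)]
        assert snp_cluster_filter(recs) == recs

    def test_pair_below_count_kept(self):
        recs = [_rec(p) for p in (100, 120)]
        assert snp_cluster_filter(recs) == recs

    def test_run_longer_than_count_fully_removed(self):
        recs = [_rec(p) for p in (100, 110, 120, 130, 500)]
        assert [r.pos for r in snp_cluster_filter(recs)] == [500]

    def test_scaffolds_independent(self):
        recs = [_rec(100, scaffold="s1"), _rec(110, scaffold="s2"), _rec(120, scaffold="s3")]
        assert len(snp_cluster_filter(recs)) == 3

    def test_input_order_independent(self, rng):
        recs = [_rec(int(p)) for p in rng.choice(10_000, 50, replace=False)]
        shuffled = list(recs)
        rng.shuffle(shuffled)
        a = {r.pos for r in snp_cluster_filter(recs)}
        b = {r.pos for r in snp_cluster_filter(shuffled)}
        assert a == b


class TestFisher:
    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(300):
            t = rng.integers(0, 12, size=(2, 2))
            assert fisher_two_sided(t) == pytest.approx(
                stats.fisher_exact(t, alternative="two-sided")[1], rel=1e-9, abs=1e-12
            )

    def test_matches_enumeration_oracle(self):
        # margins (8,8)/(8,8): enumerate all tables with fixed margins
        def oracle(a, r1, c1, n):
            def prob(x):
                return (
                    comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1)
                )

            p_obs = prob(a)
            return sum(prob(x) for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1) if prob(x) <= p_obs * (1 + 1e-9))

        assert fisher_two_sided([[0, 8], [8, 0]]) == pytest.approx(oracle(0, 8, 8, 16), abs=1e-12)
        assert fisher_two_sided([[3, 5], [6, 2]]) == pytest.approx(oracle(3, 8, 9, 16), abs=1e-12)


def _cohort(n_r=4, n_s=4, r_gt="hom_alt", s_gt="hom_ref", pos=100):
    samples = [f"r{i}" for i in range(n_r)] + [f"s{i}" for i in range(n_s)]
    genotypes = {f"r{i}": r_gt for i in range(n_r)} | {f"s{i}": s_gt for i in range(n_s)}
    labels = pd.Series(["R"] * n_r + ["S"] * n_s, index=samples)
    return _rec(pos, genotypes=genotypes), labels


class TestAllelicFisher:
    def test_perfectly_split_cohort(self):
        rec, labels = _cohort()
        df = allelic_fisher([rec], labels)
        row = df.iloc[0]
        assert (row.r_ref, row.r_alt, row.s_ref, row.s_alt) == (0, 8, 8, 0)
        # exact enumeration with margins (8,8)/(8,8): 2/C(16,8)
        assert row.fisher_p == pytest.approx(2 / comb(16, 8), abs=1e-15)

    def test_identical_distribution_p_one(self):
        rec, labels = _cohort(r_gt="het", s_gt="het")
        assert allelic_fisher([rec], labels)["fisher_p"].iloc[0] == 1.0

    def test_missing_samples_excluded(self):
        rec, labels = _cohort()
        rec.genotypes["r0"] = "missing"
        row = allelic_fisher([rec], labels).iloc[0]
        assert row.r_alt == 6

    def test_null_calibration_conservative(self, rng):
        """Permuting labels on a null SNP gives at-or-below-nominal rejections."""
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            gts = rng.choice(["hom_ref", "het", "hom_alt"], size=10, p=[0.25, 0.5, 0.25])
            genotypes = {f"x{i}": g for i, g in enumerate(gts)}
            labels = pd.Series(["R"] * 5 + ["S"] * 5, index=list(genotypes))
            rec = _rec(1, genotypes=genotypes)
            hits += allelic_fisher([rec], labels)["fisher_p"].iloc[0] <= 0.05
        assert hits / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestAdaptivePermutation:
    def test_null_snp_pruned_early(self):
        rec, labels = _cohort(r_gt="het", s_gt="het")
        out = adaptive_permutation([rec], labels, max_perm=1000, seed=0)
        assert out["emp_p"].iloc[0] == 1.0
        assert out["permutations_done"].iloc[0] == 50  # first checkpoint

    def test_fixed_seed_reproducible(self):
        rec, labels = _cohort()
        a = adaptive_permutation([rec], labels, seed=7)
        b = adaptive_permutation([rec], labels, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_matches_full_enumeration_at_n6(self, rng):
        """Non-adaptive empirical p approaches the exact permutation p."""
        samples = [f"x{i}" for i in range(6)]
        gts = ["hom_alt", "hom_alt", "het", "hom_ref", "hom_ref", "het"]
        rec = _rec(1, genotypes=dict(zip(samples, gts)))
        labels = pd.Series(["R", "R", "R", "S", "S", "S"], index=samples)
        obs = allelic_fisher([rec], labels)["fisher_p"].iloc[0]
        # exact permutation distribution over all C(6,3) label splits
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            perm = pd.Series(["R" if i in combo else "S" for i in range(6)], index=samples)
            p = allelic_fisher([rec], perm)["fisher_p"].iloc[0]
            total += 1
            hits += p <= obs * (1 + 1e-9)
        exact = hits / total
        out = adaptive_permutation([rec], labels, max_perm=2000, checkpoints=(), seed=3)
        emp = out["emp_p"].iloc[0]
        se = np.sqrt(exact * (1 - exact) / 2000)
        assert abs(emp - exact) < 3 * se + 1 / 2000

    def test_single_label_rejected(self):
        rec, _ = _cohort()
        labels = pd.Series(["R"] * 8, index=list(rec.genotypes))
        with pytest.raises(ValueError):
            adaptive_permutation([rec], labels, seed=0)


class TestCallConditionSnps:
    def test_flags_require_both_criteria(self):
        assoc = pd.DataFrame(
            {
                "scaffold": ["s1"] * 3,
                "pos": [1, 2, 3],
                "fisher_p": [1e-6, 0.5, 1e-6],
                "emp_p": [0.001, 0.9, 0.2],
            }
        )
        out = call_condition_snps(assoc, alpha=0.05)
        assert out["is_condition_snp"].tolist() == [True, False, False]

    def test_window_track_counts_flagged_snps(self):
        assoc = pd.DataFrame(
            {
                "scaffold": ["s1"] * 3,
                "pos": [100, 600_000, 700_000],
                "fisher_p": [1e-6] * 3,
                "emp_p": [0.001] * 3,
            }
        )
        out = call_condition_snps(assoc, alpha=0.05)
        track = snp_window_track(out)
        assert track.loc[track["start"] == 0, "k"].iloc[0] == 1
        assert track.loc[track["start"] == 500_000, "k"].iloc[0] == 2
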