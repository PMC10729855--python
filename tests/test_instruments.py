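"""Instrument-selection funnel: significance, clumping, strength, pruning."""

import numpy as np
import pandas as pd
import pytest

import metamr as m
from metamr.instruments import snp_r2

from conftest import make_sumstats


def _row(snp, pos=100, eaf=0.3, beta=0.1, se=0.02, p=1e-6, n=5000, chrom="1"):
    return (snp, chrom, pos, "A", "G", eaf, beta, se, p, n)


CFG = m.SelectionConfig()


class TestPvalueFilter:
    def test_strict_threshold(self):
        stats = make_sumstats("t", [_row("rs1", p=1e-6), _row("rs2", p=1e-4)])
        kept = m.select_by_pvalue(stats, CFG)
        assert list(kept.df["snp_id"]) == ["rs1"]

    def test_all_nonsignificant_gives_empty(self):
        stats = make_sumstats("t", [_row("rs1", p=0.5), _row("rs2", p=0.5)])
        assert m.select_by_pvalue(stats, CFG).n_snps == 0

    def test_count_matches_brute_force_on_synthetic(self):
        exposure, _, _, _ = m.simulate_pair(
            m.SimConfig(seed=9, n_snps=100, n_null_snps=900,
                        instrument_r2_range=(1e-4, 3e-3))
        )
        kept = m.select_by_pvalue(exposure, CFG)
        brute = sum(1 for p in exposure.df["pvalue"] if p < CFG.p_exposure)
        assert kept.n_snps == brute


def brute_force_clump(df, ld, r2_thresh, window_bp):
    """Independently coded greedy reference: smallest p first, ties by id."""
    rows = sorted(df.to_dict("records"), key=lambda r: (r["pvalue"], r["snp_id"]))
    kept = []
    while rows:
        idx = rows.pop(0)
        kept.append(idx["snp_id"])
        rows = [
            r for r in rows
            if not (
                r["chrom"] == idx["chrom"]
                and abs(r["pos"] - idx["pos"]) <= window_bp
                and ld.r2_between(idx["snp_id"], r["snp_id"]) >= r2_thresh
            )
        ]
    return kept


class TestClump:
    def test_two_linked_snps_keep_smaller_p(self):
        stats = make_sumstats("t", [_row("rs1", pos=100, p=1e-8),
                                    _row("rs2", pos=10_100, p=1e-6)])
        ld = m.LdMatrix(["rs1", "rs2"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        kept = m.clump(stats, ld, CFG)
        assert list(kept.df["snp_id"]) == ["rs1"]

    def test_unlinked_snps_all_retained(self):
        stats = make_sumstats("t", [_row(f"rs{i}", pos=100 + i) for i in range(5)])
        ld = m.LdMatrix([f"rs{i}" for i in range(5)], np.eye(5))
        assert m.clump(stats, ld, CFG).n_snps == 5

    def test_outside_window_not_clumped(self):
        stats = make_sumstats("t", [_row("rs1", pos=100, p=1e-8),
                                    _row("rs2", pos=100 + 600_000, p=1e-6)])
        ld = m.LdMatrix(["rs1", "rs2"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert m.clump(stats, ld, CFG).n_snps == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        ids = [f"rs{i:02d}" for i in range(n)]
        rows = [_row(ids[i], pos=int(rng.integers(1, 2_000_000)),
                     p=float(rng.uniform(1e-10, 1e-6))) for i in range(n)]
        a = rng.uniform(0, 1, (n, n))
        r2 = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(r2, 1.0)
        ld = m.LdMatrix(ids, r2)
        stats = make_sumstats("t", rows)
        kept = m.clump(stats, ld, CFG)
        oracle = brute_force_clump(stats.df, ld, CFG.clump_r2, CFG.clump_window_kb * 1000)
        assert list(kept.df["snp_id"]) == oracle

    def test_missing_from_panel_treated_independent(self):
        stats = make_sumstats("t", [_row("rs1", p=1e-8), _row("rsX", pos=200, p=1e-6)])
        ld = m.LdMatrix(["rs1"], np.array([[1.0]]))
        log = []
        kept = m.clump(stats, ld, CFG, log=log)
        assert kept.n_snps == 2
        assert any(e["snp_id"] == "rsX" for e in log)


class TestStrength:
    def test_f_formula_arithmetic(self):
        # r^2 = 0.01 at n = 7824 gives F = 0.01*7822/0.99
        beta = np.sqrt(0.01 / (2 * 0.3 * 0.7))
        stats = make_sumstats("t", [_row("rs1", eaf=0.3, beta=beta, n=7824)])
        _, per_snp, total = m.instrument_strength(stats, CFG)
        assert per_snp["r2_explained"].iloc[0] == pytest.approx(0.01, rel=1e-12)
        assert per_snp["f_stat"].iloc[0] == pytest.approx(0.01 * 7822 / 0.99, rel=1e-12)
        assert total == pytest.approx(0.01, rel=1e-12)

    def test_zero_beta_dropped(self):
        stats = make_sumstats("t", [_row("rs1", beta=0.0)])
        log = []
        kept, per_snp, _ = m.instrument_strength(stats, CFG, log=log)
        assert kept.n_snps == 0 and log[0]["stage"] == "strength"

    def test_f_exactly_ten_dropped_strict(self):
        # eaf route with exact floats: r^2 = 2*0.5*0.5*1.0 = 0.5, F = 0.5*10/0.5 = 10
        stats = make_sumstats("t", [_row("rs1", eaf=0.5, beta=1.0, se=1.0, n=12)])
        kept, _, _ = m.instrument_strength(stats, CFG)
        assert kept.n_snps == 0

    def test_r2_formula_preference(self):
        r2, formula = snp_r2([0.1, 0.1], [0.02, 0.02], [0.3, np.nan], [5000, 5000])
        assert formula[0] == "eaf" and formula[1] == "zscore"
        assert r2[0] == pytest.approx(2 * 0.3 * 0.7 * 0.01)
        z2 = 25.0
        assert r2[1] == pytest.approx(z2 / (z2 + 4998))

    def test_impossible_r2_is_data_error(self):
        stats = make_sumstats("t", [_row("rs1", eaf=0.5, beta=2.0)])
        with pytest.raises(m.DataError):
            m.instrument_strength(stats, CFG)


class TestPruneAndConfounders:
    def test_outcome_associated_removed(self):
        sub = make_sumstats("e", [_row("rs1"), _row("rs2", pos=200)])
        out = make_sumstats("o", [_row("rs1", p=1e-7), _row("rs2", pos=200, p=0.3)])
        kept = m.prune_outcome_associated(sub, out, CFG)
        assert list(kept.df["snp_id"]) == ["rs2"]

    def test_absent_from_outcome_retained_here(self):
        sub = make_sumstats("e", [_row("rs1")])
        out = make_sumstats("o", [_row("rs2", p=1e-9)])
        assert m.prune_outcome_associated(sub, out, CFG).n_snps == 1

    def test_survivor_count_matches_recount(self):
        exposure, outcome, _, _ = m.simulate_pair(m.SimConfig(seed=3, theta_true=0.5))
        kept = m.prune_outcome_associated(exposure, outcome, CFG)
        p = outcome.df.set_index("snp_id")["pvalue"]
        brute = sum(1 for s in exposure.df["snp_id"] if p.get(s, 1.0) >= CFG.p_outcome_prune)
        assert kept.n_snps == brute

    def test_empty_annotation_table_is_noop(self):
        sub = make_sumstats("e", [_row("rs1")])
        ann = pd.DataFrame(columns=["snp_id", "trait"])
        kept, report = m.screen_confounders(sub, ann, ["hypothyroidism"])
        assert kept.n_snps == 1 and report.empty

    def test_designated_confounder_removed(self):
        sub = make_sumstats("e", [_row("rs1"), _row("rs2", pos=200)])
        ann = pd.DataFrame({"snp_id": ["rs1"], "trait": ["Self-reported hypothyroidism or myxedema"]})
        kept, report = m.screen_confounders(sub, ann, ["hypothyroidism"])
        assert list(kept.df["snp_id"]) == ["rs2"]
        assert report["action"].iloc[0] == "removed"

    def test_removal_count_equals_join_count(self):
        sub = make_sumstats("e", [_row(f"rs{i}", pos=100 + i) for i in range(10)])
        ann = pd.DataFrame({
            "snp_id": ["rs1", "rs3", "rs5", "rs99"],
            "trait": ["hypothyroidism", "height", "myxedema", "hypothyroidism"],
        })
        designated = ["hypothyroidism", "myxedema"]
        kept, report = m.screen_confounders(sub, ann, designated)
        join = ann[ann["trait"].str.lower().str.contains("|".join(designated))
                   & ann["snp_id"].isin(sub.df["snp_id"])]
        assert 10 - kept.n_snps == join["snp_id"].nunique() == len(report)


class TestMinSnps:
    def _strength(self, stats):
        return m.instrument_strength(stats, CFG)

    @pytest.mark.parametrize("n,expect_kept", [(3, False), (4, True), (477, True)])
    def test_minimum_count_rule_inclusive(self, n, expect_kept):
        stats = make_sumstats("t", [_row(f"rs{i:03d}", pos=100 + i) for i in range(n)])
        sub, per_snp, total = self._strength(stats)
        res = m.enforce_min_snps(sub, per_snp, total, CFG)
        if expect_kept:
            assert isinstance(res, m.InstrumentSet) and len(res.snp_ids) == n
        else:
            assert isinstance(res, m.ExclusionVerdict) and res.n_snps == 3


class TestPipelineMonotonicity:
    def test_stages_subset_and_log_accounts_for_removals(self):
        exposure, outcome, ld, _ = m.simulate_pair(
            m.SimConfig(seed=21, n_snps=40, n_null_snps=60,
                        instrument_r2_range=(5e-4, 0.02),
                        ld_block_sizes=tuple([10] * 10), ld_within_block_r2=0.8)
        )
        log = []
        s1 = m.select_by_pvalue(exposure, CFG)
        s2 = m.clump(s1, ld, CFG, log=log)
        s3, per_snp, total = m.instrument_strength(s2, CFG, log=log)
        s4 = m.prune_outcome_associated(s3, outcome, CFG, log=log)
        ids = [set(s.df["snp_id"]) for s in (s1, s2, s3, s4)]
        assert ids[1] <= ids[0] and ids[2] <= ids[1] and ids[3] <= ids[2]
        removed = [e for e in log if "treated_independent" not in e["reason"]]
        assert len(removed) == len(ids[0]) - len(ids[3])
        assert len({e["snp_id"] for e in removed}) == len(removed)

    def test_clumped_set_internally_independent(self):
        exposure, _, ld, _ = m.simulate_pair(
            m.SimConfig(seed=22, n_snps=40, ld_block_sizes=tuple([8] * 5),
                        ld_within_block_r2=0.5)
        )
        kept = m.clump(m.select_by_pvalue(exposure, CFG), ld, CFG)
        ids = list(kept.df["snp_id"])
        pos = kept.df.set_index("snp_id")["pos"]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if abs(pos[a] - pos[b]) <= CFG.clump_window_kb * 1000:
                    assert ld.r2_between(a, b) < CFG.clump_r2

    def test_planted_strong_instruments_survive(self):
        cfg = m.SimConfig(seed=23, n_snps=30, instrument_r2_range=(0.01, 0.03))
        exposure, outcome, ld, truth = m.simulate_pair(cfg)
        log = []
        s1 = m.select_by_pvalue(exposure, CFG)
        s2 = m.clump(s1, ld, CFG, log=log)
        s3, _, _ = m.instrument_strength(s2, CFG, log=log)
        # true per-SNP r2 >= 1% at n=7824 sits far above the F>10 boundary
        assert s3.n_snps == 30
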