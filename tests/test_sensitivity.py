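"""Heterogeneity, outlier, stability and directionality diagnostics."""

import numpy as np
import pandas as pd
import pytest

import metamr as m
from metamr.sensitivity import SensitivityReport

from conftest import make_harmonized


def _report(**over):
    base = dict(
        q_stat=3.0, q_df=4, q_p=0.4, egger_intercept=0.001, egger_intercept_p=0.5,
        presso_global_p=0.3, presso_outliers=[], presso_distortion_p=None,
        radial_q=3.0, radial_outliers=[], loo_estimates=pd.DataFrame(),
        loo_stable=True, steiger_direction=True, steiger_p=0.001,
    )
    base.update(over)
    return SensitivityReport(**base)


def _est(p):
    return m.MREstimate("IVW", 0.3, 0.1, p, 5)


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        b_exp = np.array([0.1, 0.2, 0.4])
        h = make_harmonized(b_exp, 0.3 * b_exp, se_out=0.05)
        r = m.wald_ratios(h)
        q, df, p = m.cochran_q(r, m.ivw(h).beta)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2 and p == pytest.approx(1.0)

    def test_four_snp_hand_summed_arithmetic(self):
        theta = np.array([0.1, 0.3, 0.5, 0.2])
        se = np.array([0.1, 0.2, 0.1, 0.05])
        b_exp = np.ones(4)
        h = make_harmonized(b_exp, theta, se_out=se)
        r = m.wald_ratios(h)
        w = 1.0 / se**2
        theta_ivw = np.sum(w * theta) / np.sum(w)
        q_hand = float(np.sum(w * (theta - theta_ivw) ** 2))
        q, df, _ = m.cochran_q(r, theta_ivw)
        assert q == pytest.approx(q_hand, abs=1e-12)

    def test_mean_q_tracks_overdispersion(self):
        # with ratio variances phi * se^2 the expected Q is ~ phi*(J-1)
        rng = np.random.default_rng(0)
        phi, j, reps = 2.0, 10, 400
        qs = []
        for _ in range(reps):
            se = np.full(j, 0.05)
            theta = rng.normal(0.3, np.sqrt(phi) * se)
            h = make_harmonized(np.ones(j), theta, se_out=se)
            r = m.wald_ratios(h)
            w = 1.0 / se**2
            qs.append(m.cochran_q(r, float(np.sum(w * theta) / np.sum(w)))[0])
        assert np.mean(qs) == pytest.approx(phi * (j - 1), rel=0.10)


class TestPresso:
    def test_too_few_instruments(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.03, 0.06, 0.09], se_out=0.02)
        with pytest.raises(m.InsufficientInstrumentsError):
            m.mr_presso(h, seed=1)

    def test_planted_outlier_flagged_and_corrected(self):
        cfg = m.preset("one_outlier", seed=42)
        e, o, _, truth = m.simulate_pair(cfg)
        h = m.harmonize(e, o)
        res = m.mr_presso(h, n_sim=1000, seed=7)
        assert truth.invalid_snps[0] in res.outliers
        assert res.corrected is not None and res.distortion_p is not None
        assert abs(res.corrected.beta - 0.3) < abs(m.ivw(h).beta - 0.3)

    def test_outlier_removal_weakly_reduces_q(self):
        for s in range(5):
            cfg = m.preset("one_outlier", seed=100 + s)
            e, o, _, _ = m.simulate_pair(cfg)
            h = m.harmonize(e, o)
            res = m.mr_presso(h, n_sim=500, seed=s)
            if not res.outliers:
                continue
            r_full = m.wald_ratios(h)
            q_full = m.cochran_q(r_full, m.ivw(h).beta)[0]
            keep = ~h.df["snp_id"].isin(res.outliers)
            sub = m.HarmonizedSet("e", "o", h.df[keep].reset_index(drop=True))
            q_sub = m.cochran_q(m.wald_ratios(sub), m.ivw(sub).beta)[0]
            assert q_sub <= q_full + 1e-12

    def test_seeded_reproducibility(self):
        cfg = m.preset("clean", seed=5, n_snps=10)
        e, o, _, _ = m.simulate_pair(cfg)
        h = m.harmonize(e, o)
        r1 = m.mr_presso(h, n_sim=300, seed=9)
        r2 = m.mr_presso(h, n_sim=300, seed=9)
        assert r1.global_p == r2.global_p and r1.observed_rss == r2.observed_rss


class TestRadial:
    def test_first_order_slope_is_ivw(self):
        rng = np.random.default_rng(4)
        for s in range(10):
            j = rng.integers(3, 20)
            b_exp = rng.uniform(0.05, 0.5, j)
            b_out = 0.3 * b_exp + rng.normal(0, 0.05, j)
            se_out = rng.uniform(0.01, 0.08, j)
            h = make_harmonized(b_exp, b_out, se_out=se_out)
            res = m.radial_mr(h)
            assert res.slope == pytest.approx(m.ivw(h).beta, abs=1e-10)

    def test_homogeneous_data_no_outliers(self):
        b_exp = np.linspace(0.1, 0.5, 8)
        h = make_harmonized(b_exp, 0.3 * b_exp, se_out=0.05)
        assert m.radial_mr(h).outliers == []

    def test_planted_outlier_has_largest_q(self):
        cfg = m.preset("one_outlier", seed=11)
        e, o, _, truth = m.simulate_pair(cfg)
        h = m.harmonize(e, o)
        res = m.radial_mr(h)
        worst = res.per_snp_q.loc[res.per_snp_q["q_j"].idxmax(), "snp_id"]
        assert worst == truth.invalid_snps[0]

    def test_second_order_weights_run(self):
        b_exp = np.linspace(0.1, 0.5, 6)
        h = make_harmonized(b_exp, 0.3 * b_exp + 0.01, se_out=0.05)
        res = m.radial_mr(h, weight_order="second")
        assert np.isfinite(res.slope)


class TestLeaveOneOut:
    def test_identical_effects_stable_with_j_entries(self):
        b_exp = np.full(6, 0.2)
        h = make_harmonized(b_exp, 0.3 * b_exp, se_out=0.05)
        res = m.leave_one_out(h)
        assert len(res.estimates) == 6 and res.stable
        np.testing.assert_allclose(res.estimates["beta"], res.full_beta, atol=1e-12)

    def test_single_dominant_snp_flags_unstable(self):
        # one high-precision SNP carries the entire signal
        b_exp = np.array([0.3] + [0.1] * 5)
        b_out = np.array([0.15] + [0.0] * 5)
        se_out = np.array([0.005] + [0.05] * 5)
        h = make_harmonized(b_exp, b_out, se_out=se_out)
        assert not m.leave_one_out(h).stable


class TestSteiger:
    def test_equal_r2_indeterminate(self):
        h = make_harmonized([0.2, 0.3, 0.4], [0.2, 0.3, 0.4], se_out=0.01,
                            se_exp=0.01, n_exp=5000, n_out=5000)
        res = m.steiger(h)
        assert res.pvalue == pytest.approx(1.0)
        assert not res.direction_ok

    def test_forced_ordering(self):
        h = make_harmonized([0.3, 0.4, 0.5], [0.01, 0.012, 0.008],
                            se_out=0.03, se_exp=0.01, n_exp=7824, n_out=377277)
        res = m.steiger(h)
        assert res.direction_ok and res.r2_exposure > res.r2_outcome

    def test_swap_symmetry(self):
        rng = np.random.default_rng(6)
        b_exp = rng.uniform(0.1, 0.4, 5)
        b_out = rng.uniform(0.01, 0.05, 5)
        df = make_harmonized(b_exp, b_out, se_out=0.02, se_exp=0.01,
                             n_exp=8000, n_out=300000).df
        h_fwd = m.HarmonizedSet("e", "o", df)
        sw = df.rename(columns={"b_exp": "b_out", "b_out": "b_exp",
                                "se_exp": "se_out", "se_out": "se_exp",
                                "n_exp": "n_out", "n_out": "n_exp"})
        h_rev = m.HarmonizedSet("o", "e", sw)
        f, r = m.steiger(h_fwd), m.steiger(h_rev)
        assert f.pvalue == pytest.approx(r.pvalue, abs=1e-12)
        assert f.direction_ok != r.direction_ok


class TestClassify:
    def test_all_criteria_met_supported(self):
        assert m.classify_causal(_est(0.03), _report()) == "supported"

    def test_nonsignificant_ivw(self):
        assert m.classify_causal(_est(0.2), _report()) == "not_significant"

    def test_heterogeneity_detected(self):
        assert m.classify_causal(_est(0.03), _report(q_p=0.01)) == \
            "heterogeneous_or_pleiotropic"

    def test_pleiotropic_intercept_detected(self):
        assert m.classify_causal(_est(0.03), _report(egger_intercept_p=0.02)) == \
            "heterogeneous_or_pleiotropic"

    def test_presso_global_detected(self):
        assert m.classify_causal(_est(0.03), _report(presso_global_p=0.01)) == \
            "heterogeneous_or_pleiotropic"

    def test_loo_instability(self):
        assert m.classify_causal(_est(0.03), _report(loo_stable=False)) == "unstable"

    def test_reverse_direction(self):
        assert m.classify_causal(_est(0.03), _report(steiger_direction=False)) == \
            "wrong_direction"

    def test_ordering_significance_first(self):
        v = m.classify_causal(_est(0.5), _report(q_p=0.001, loo_stable=False))
        assert v == "not_significant"


class TestRunSensitivity:
    def test_full_suite_on_clean_pair(self):
        cfg = m.preset("clean", seed=3, n_snps=12)
        e, o, _, _ = m.simulate_pair(cfg)
        h = m.harmonize(e, o)
        report, verdict = m.run_sensitivity(h, seed=2, n_sim=300)
        assert report.q_df == 11
        assert len(report.loo_estimates) == 12
        assert report.verdict == verdict
        assert verdict in ("supported", "heterogeneous_or_pleiotropic")
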