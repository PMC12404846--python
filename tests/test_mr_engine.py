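"""Instrument selection, harmonization and the MR estimator suite."""

import math

import numpy as np
import pandas as pd
import pytest

from pvmr import mr_engine as mr
from pvmr.mr_engine import (
    GeneRegion,
    MRConfig,
    cochran_q,
    egger,
    f_statistic,
    harmonize,
    ivw,
    ld_clump,
    run_mr_pipeline,
    select_cis_pqtls,
    simple_mode,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from pvmr.synthetic_data import GwasSimConfig, simulate_gwas_pair


def stats_frame(rows):
    """rows: (snp, pos, beta, se, pval) on chr1 with A/C alleles."""
    return pd.DataFrame(
        {
            "snp": [r[0] for r in rows],
            "chr": "1",
            "pos": [r[1] for r in rows],
            "ea": "A",
            "oa": "C",
            "eaf": 0.3,
            "beta": [r[2] for r in rows],
            "se": [r[3] for r in rows],
            "pval": [r[4] for r in rows],
            "n": 10_000,
        }
    )


def pairs_frame(theta, se_out, beta_exp=None, se_exp=0.01):
    theta = np.asarray(theta, dtype=float)
    beta_exp = np.full(len(theta), 0.2) if beta_exp is None else np.asarray(beta_exp, dtype=float)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(len(theta))],
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "beta_out": theta * beta_exp,
            "se_out": se_out,
        }
    )


class TestSelection:
    region = GeneRegion("GENE", "1", 1_000_000, 1_010_000, cis_window_bp=500_000)

    @pytest.mark.parametrize(
        "pos, pval, kept",
        [
            (500_001, 1e-9, True),   # 499,999 bp upstream of the region start
            (499_999, 1e-9, False),  # 500,001 bp upstream: outside the flank
            (1_005_000, 6e-8, False),  # inside the window, p above threshold
            (1_510_000, 1e-9, True),   # exactly at the downstream boundary
        ],
    )
    def test_window_and_pvalue_rules(self, pos, pval, kept):
        df = stats_frame([("rs1", pos, 0.1, 0.01, pval)])
        out = select_cis_pqtls(df, self.region)
        assert (len(out) == 1) == kept

    def test_wrong_chromosome_excluded(self):
        df = stats_frame([("rs1", 1_005_000, 0.1, 0.01, 1e-9)]).assign(chr="2")
        assert select_cis_pqtls(df, self.region).empty

    def test_f_statistic_arithmetic(self):
        assert f_statistic(0.1, 0.02) == pytest.approx(25.0)
        assert f_statistic(0.0, 0.02) == 0.0
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)


def brute_force_clump(candidates, ld, r2_threshold, window_bp):
    """Independent reimplementation: explicit greedy over the sorted list."""
    order = candidates.sort_values(["pval", "snp"], kind="mergesort").reset_index(drop=True)
    accepted = []
    for _, row in order.iterrows():
        if all(
            abs(row["pos"] - o["pos"]) > window_bp or ld.loc[row["snp"], o["snp"]] < r2_threshold
            for o in accepted
        ):
            accepted.append(row)
    return sorted(r["snp"] for r in accepted)


class TestClumping:
    def test_correlated_pair_keeps_most_significant(self):
        df = stats_frame([("rs1", 100, 0.3, 0.01, 1e-20), ("rs2", 200, 0.2, 0.01, 1e-10)])
        ld = pd.DataFrame([[1.0, 0.8], [0.8, 1.0]], index=["rs1", "rs2"], columns=["rs1", "rs2"])
        out = ld_clump(df, ld)
        assert out["snp"].tolist() == ["rs1"]

    def test_independent_snps_all_kept(self):
        df = stats_frame([("rs1", 100, 0.3, 0.01, 1e-20), ("rs2", 200, 0.2, 0.01, 1e-10),
                          ("rs3", 300, 0.1, 0.01, 1e-9)])
        ld = pd.DataFrame(np.eye(3), index=df["snp"], columns=df["snp"])
        assert len(ld_clump(df, ld)) == 3

    def test_missing_ld_entry_is_fatal(self):
        df = stats_frame([("rs1", 100, 0.3, 0.01, 1e-20), ("rs2", 200, 0.2, 0.01, 1e-10)])
        ld = pd.DataFrame([[1.0]], index=["rs1"], columns=["rs1"])
        with pytest.raises(KeyError, match="rs2"):
            ld_clump(df, ld)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            m = 50
            snps = [f"rs{i}" for i in range(m)]
            df = stats_frame(
                [(s, int(p), 0.1, 0.01, float(pv))
                 for s, p, pv in zip(snps, rng.integers(0, 5_000_000, m), rng.uniform(1e-30, 1e-8, m))]
            )
            r = rng.uniform(0, 1, size=(m, m))
            r2 = (r + r.T) / 2 * (rng.random((m, m)) < 0.1)
            r2 = np.maximum(r2, r2.T)
            np.fill_diagonal(r2, 1.0)
            ld = pd.DataFrame(r2, index=snps, columns=snps)
            ours = sorted(ld_clump(df, ld, r2_threshold=0.3, window_bp=2_000_000)["snp"])
            assert ours == brute_force_clump(df, ld, 0.3, 2_000_000)

    def test_result_is_maximal(self):
        """No excluded SNP could be added without violating the r2 rule."""
        rng = np.random.default_rng(3)
        m = 30
        snps = [f"rs{i}" for i in range(m)]
        df = stats_frame(
            [(s, int(p), 0.1, 0.01, float(pv))
             for s, p, pv in zip(snps, rng.integers(0, 1_000_000, m), rng.uniform(1e-30, 1e-8, m))]
        )
        r2 = rng.uniform(0, 0.6, size=(m, m))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = pd.DataFrame(r2, index=snps, columns=snps)
        kept = set(ld_clump(df, ld, r2_threshold=0.3, window_bp=10_000_000)["snp"])
        for snp in set(snps) - kept:
            assert any(ld.loc[snp, k] >= 0.3 for k in kept)


def summ(snp, ea, oa, eaf, beta, se=0.01):
    return pd.DataFrame(
        {"snp": [snp], "chr": "1", "pos": [100], "ea": [ea], "oa": [oa], "eaf": [eaf],
         "beta": [beta], "se": [se], "pval": [1e-10], "n": 1000}
    )


class TestHarmonize:
    def test_matching_alleles_pass_through(self):
        h = harmonize(summ("rs1", "A", "C", 0.3, 0.2), summ("rs1", "A", "C", 0.31, 0.05))
        assert h.loc[0, "action"] == "none"
        assert h.loc[0, "beta_out"] == 0.05

    def test_reversed_alleles_flip_outcome_beta(self):
        h = harmonize(summ("rs1", "A", "C", 0.3, 0.2), summ("rs1", "C", "A", 0.7, 0.05))
        assert h.loc[0, "action"] == "flipped"
        assert h.loc[0, "beta_out"] == -0.05
        assert h.loc[0, "eaf_out"] == pytest.approx(0.3)

    def test_flip_is_an_involution(self):
        def flip(df):
            return df.assign(ea=df["oa"], oa=df["ea"], beta=-df["beta"], eaf=1 - df["eaf"])

        exposure = summ("rs1", "A", "C", 0.3, 0.2)
        outcome = summ("rs1", "C", "A", 0.7, 0.05)
        once = harmonize(exposure, outcome)
        twice = harmonize(exposure, flip(flip(outcome)))
        assert once.loc[0, "beta_out"] == twice.loc[0, "beta_out"] == -0.05
        assert once.loc[0, "eaf_out"] == twice.loc[0, "eaf_out"]

    def test_palindromic_ambiguous_frequency_dropped(self):
        h = harmonize(summ("rs1", "A", "T", 0.50, 0.2), summ("rs1", "A", "T", 0.50, 0.05))
        assert h.empty
        assert h.attrs["dropped"] == [("rs1", "palindromic_ambiguous_eaf")]

    def test_palindromic_resolved_by_frequency(self):
        # exposure eaf 0.1 vs outcome 0.9: the outcome is on the other strand
        h = harmonize(summ("rs1", "A", "T", 0.10, 0.2), summ("rs1", "A", "T", 0.90, 0.05))
        assert h.loc[0, "beta_out"] == -0.05

    def test_incompatible_alleles_dropped_with_reason(self):
        h = harmonize(summ("rs1", "A", "C", 0.3, 0.2), summ("rs1", "A", "G", 0.3, 0.05))
        assert h.empty
        assert h.attrs["dropped"] == [("rs1", "incompatible_alleles")]


class TestEstimators:
    def test_wald_ratio_arithmetic(self):
        pair = pd.DataFrame(
            {"beta_exp": [0.5], "se_exp": [0.02], "beta_out": [0.1], "se_out": [0.05]}
        )
        est = wald_ratio(pair)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_wald_ratio_null_outcome_gives_or_one(self):
        pair = pd.DataFrame({"beta_exp": [0.5], "se_exp": [0.02], "beta_out": [0.0], "se_out": [0.05]})
        est = wald_ratio(pair)
        assert est.beta == 0.0
        assert est.or_ == 1.0
        assert est.ci95[0] < 1.0 < est.ci95[1]

    def test_wald_ratio_zero_exposure_rejected(self):
        pair = pd.DataFrame({"beta_exp": [0.0], "se_exp": [0.02], "beta_out": [0.1], "se_out": [0.05]})
        with pytest.raises(ValueError):
            wald_ratio(pair)

    def test_ivw_on_k_copies_equals_wald_with_scaled_se(self):
        one = pairs_frame([0.25], se_out=0.04)
        k = 4
        copies = pd.concat([one] * k, ignore_index=True)
        pooled = ivw(copies)
        single = wald_ratio(one)
        assert pooled.beta == pytest.approx(single.beta)
        assert pooled.se == pytest.approx(single.se / math.sqrt(k))

    def test_ivw_requires_two_instruments(self):
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(pairs_frame([0.2], se_out=0.04))

    def test_ivw_equals_weighted_regression_through_origin_oracle(self):
        rng = np.random.default_rng(8)
        theta = rng.normal(0.2, 0.1, size=12)
        se_out = rng.uniform(0.02, 0.08, size=12)
        pairs = pairs_frame(theta, se_out=se_out)
        est = ivw(pairs)
        # oracle: WLS of ratio on a constant-1 regressor, weights 1/se^2
        ratios = pairs["beta_out"] / pairs["beta_exp"]
        w = (pairs["beta_exp"] / pairs["se_out"]) ** 2
        import statsmodels.api as sm

        fit = sm.WLS(ratios, np.ones(len(ratios)), weights=w).fit()
        assert est.beta == pytest.approx(float(fit.params.iloc[0]), rel=1e-10)

    def test_egger_recovers_slope_and_pleiotropy_intercept(self):
        rng = np.random.default_rng(15)
        n, theta, delta = 50, 0.3, 0.05
        beta_exp = rng.uniform(0.05, 0.4, size=n)
        se_out = np.full(n, 0.01)
        beta_out = theta * beta_exp + delta + rng.normal(0, se_out)
        pairs = pd.DataFrame(
            {"beta_exp": beta_exp, "se_exp": 0.005, "beta_out": beta_out, "se_out": se_out}
        )
        est, intercept = egger(pairs)
        assert est.beta == pytest.approx(theta, abs=0.05)
        assert intercept.value == pytest.approx(delta, abs=0.02)
        assert intercept.pval < 0.01  # planted directional pleiotropy is detected

    def test_egger_rejects_constant_exposure_betas(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            egger(pairs_frame([0.1, 0.2, 0.3], se_out=0.04))  # beta_exp all equal

    def test_weighted_median_symmetric_ratios(self):
        pairs = pairs_frame([0.1, 0.2, 0.3], se_out=0.04)
        est = weighted_median(pairs, seed=1)
        assert est.beta == pytest.approx(0.2, abs=1e-9)

    def test_weighted_median_resists_invalid_minority(self):
        rng = np.random.default_rng(2)
        theta = np.concatenate([np.full(6, 0.3) + rng.normal(0, 0.01, 6), np.full(4, 1.5)])
        pairs = pairs_frame(theta, se_out=0.02)
        wm = weighted_median(pairs, seed=3)
        pooled = ivw(pairs)
        assert abs(wm.beta - 0.3) < abs(pooled.beta - 0.3)

    def test_all_identical_ratios_returned_by_every_method(self):
        pairs = pairs_frame([0.25] * 5, se_out=0.04)
        for est in (weighted_median(pairs, seed=0), simple_mode(pairs, seed=0), weighted_mode(pairs, seed=0)):
            assert est.beta == pytest.approx(0.25, abs=1e-6)

    def test_modes_locate_the_majority_cluster(self):
        rng = np.random.default_rng(4)
        theta = np.concatenate([0.3 + rng.normal(0, 0.01, 12), [2.0, 2.1, -1.0]])
        pairs = pairs_frame(theta, se_out=0.02)
        assert simple_mode(pairs, seed=5).beta == pytest.approx(0.3, abs=0.05)
        assert weighted_mode(pairs, seed=5).beta == pytest.approx(0.3, abs=0.05)

    def test_estimate_confidence_interval_brackets_or(self):
        est = ivw(pairs_frame([0.1, 0.3, 0.2], se_out=0.05))
        lo, hi = est.ci95
        assert lo < est.or_ < hi


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        pairs = pairs_frame([0.2, 0.2], se_out=0.04)
        rep = cochran_q(pairs, ivw(pairs).beta)
        assert rep.cochran_q == pytest.approx(0.0, abs=1e-12)
        assert rep.q_pval == pytest.approx(1.0)
        assert rep.q_df == 1

    def test_outlier_inflates_q(self):
        pairs = pairs_frame([0.2] * 19 + [3.0], se_out=0.02)
        rep = cochran_q(pairs, ivw(pairs).beta)
        assert rep.q_pval < 0.05


class TestPipeline:
    def run(self, theta, control_effect, seed=21, **kw):
        cfg = GwasSimConfig(seed=seed, theta=theta, control_effect=control_effect,
                            n_snps=10, ld_block_size=1, r2_within_block=0.0, n_instruments=10)
        sim = simulate_gwas_pair(cfg)
        return run_mr_pipeline(
            sim.exposure, sim.outcome, sim.control, cfg.region(), sim.ld, MRConfig(seed=seed), **kw
        )

    def test_validated_control_with_null_primary(self):
        report = self.run(theta=0.0, control_effect=0.5)
        assert report.status == "ok"
        assert report.control_estimate.pval < 0.05
        assert report.primary_estimates["ivw"].pval > 0.05
        assert report.sensitivity is not None
        assert report.sensitivity.q_df == report.primary_estimates["ivw"].n_snp - 1

    def test_null_control_blocks_primary_analysis(self):
        report = self.run(theta=0.3, control_effect=0.0)
        assert report.status == "instruments_not_validated"
        assert report.primary_estimates == {}

    def test_wrong_direction_control_blocks(self):
        report = self.run(theta=0.0, control_effect=-0.5)
        assert report.status == "instruments_not_validated"

    def test_no_instruments_when_nothing_significant(self):
        cfg = GwasSimConfig(seed=9, theta=0.0, n_snps=10, ld_block_size=1,
                            r2_within_block=0.0, n_instruments=10, instrument_beta=0.0)
        sim = simulate_gwas_pair(cfg)
        report = run_mr_pipeline(sim.exposure, sim.outcome, sim.control, cfg.region(), sim.ld)
        assert report.status == "no_instruments"

    def test_replication_outcome_estimated_when_gate_passes(self):
        cfg = GwasSimConfig(seed=31, theta=0.2, control_effect=0.5,
                            n_snps=10, ld_block_size=1, r2_within_block=0.0, n_instruments=10)
        sim = simulate_gwas_pair(cfg)
        report = run_mr_pipeline(
            sim.exposure, sim.outcome, sim.control, cfg.region(), sim.ld, MRConfig(seed=1),
            replication_outcome_stats=sim.outcome.copy(),
        )
        assert report.status == "ok"
        assert "ivw" in report.replication_estimates
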