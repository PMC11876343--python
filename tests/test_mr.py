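"""MR estimators vs. closed-form oracles; QC rules; consensus; MVMR."""

import numpy as np
import pandas as pd
import pytest

from pgslink import mr
from pgslink.errors import (CollinearityError, InsufficientInstrumentsError,
                            NoOverlapError)


def _inst(bx, by, sx=None, sy=None, **extra):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    df = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(len(bx))],
        "effect_allele": "A", "other_allele": "G",
        "beta_exposure": bx,
        "se_exposure": sx if sx is not None else np.full(len(bx), 0.02),
        "beta_outcome": by,
        "se_outcome": sy if sy is not None else np.full(len(bx), 0.05),
        "eaf_exposure": 0.3, "eaf_outcome": 0.3,
    })
    df["f_stat"] = (df["beta_exposure"] / df["se_exposure"]) ** 2
    for k, v in extra.items():
        df[k] = v
    return df


def _sumstats(ids, ea, oa, beta, se, eaf, pos=None):
    n = len(ids)
    return pd.DataFrame({
        "variant_id": ids, "chrom": 1,
        "pos": pos if pos is not None else [1000 * (i + 1) for i in range(n)],
        "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se,
        "pval": 1e-10, "n": 10000, "trait_type": "quant", "case_prop": np.nan})


class TestHarmonize:
    def test_identical_labels_unchanged(self):
        e = _sumstats(["v1"], ["A"], ["G"], [0.3], [0.02], [0.2])
        o = _sumstats(["v1"], ["A"], ["G"], [0.1], [0.05], [0.2])
        h = mr.harmonize(e, o)
        assert h["beta_outcome"].iloc[0] == 0.1

    def test_swapped_labels_flip_beta_and_eaf(self):
        e = _sumstats(["v1"], ["A"], ["G"], [0.3], [0.02], [0.2])
        o = _sumstats(["v1"], ["G"], ["A"], [0.1], [0.05], [0.8])
        h = mr.harmonize(e, o)
        assert h["beta_outcome"].iloc[0] == -0.1
        assert abs(h["eaf_outcome"].iloc[0] - 0.2) < 1e-12

    def test_ambiguous_palindrome_dropped(self):
        e = _sumstats(["v1", "v2"], ["A", "A"], ["T", "G"], [0.3, 0.2],
                      [0.02, 0.02], [0.50, 0.3])
        o = _sumstats(["v1", "v2"], ["A", "A"], ["T", "G"], [0.1, 0.1],
                      [0.05, 0.05], [0.50, 0.3])
        h = mr.harmonize(e, o)
        assert list(h["variant_id"]) == ["v2"]

    def test_unambiguous_palindrome_aligned_by_frequency(self):
        e = _sumstats(["v1"], ["A"], ["T"], [0.3], [0.02], [0.10])
        o = _sumstats(["v1"], ["T"], ["A"], [0.1], [0.05], [0.90])
        h = mr.harmonize(e, o)
        # exposure effect allele is the minor one (0.10); the outcome's
        # effect allele is major (0.90), so frequency matching flips it
        assert h["beta_outcome"].iloc[0] == -0.1
        assert abs(h["eaf_outcome"].iloc[0] - 0.10) < 1e-12

    def test_no_overlap_raises(self):
        e = _sumstats(["v1"], ["A"], ["G"], [0.3], [0.02], [0.2])
        o = _sumstats(["v9"], ["A"], ["G"], [0.1], [0.05], [0.2])
        with pytest.raises(NoOverlapError):
            mr.harmonize(e, o)


class TestInstrumentQc:
    def test_f_stat_rule(self):
        inst = _inst([0.1, 0.5], [0.0, 0.0], sx=[0.04, 0.02])
        # (0.1/0.04)^2 = 6.25 < 10 -> dropped
        out, skip = mr.instrument_qc(inst)
        assert list(out["variant_id"]) == ["v1"]

    def test_pleiotropy_five_protein_rule(self):
        inst = _inst([0.5, 0.5], [0.1, 0.1], n_proteins_hit=[5, 4])
        out, _ = mr.instrument_qc(inst)
        assert list(out["variant_id"]) == ["v1"]

    def test_cis_minimum_skip(self):
        inst = _inst([0.5, 0.5, 0.5], [0.1, 0.1, 0.1],
                     is_cis=[True, True, False])
        out, skip = mr.instrument_qc(inst, cis_only=True)
        assert len(out) == 2
        assert skip is not None and "cis" in skip


class TestIvw:
    def test_single_instrument_wald_ratio(self):
        inst = _inst([0.5], [0.2], sy=[0.05])
        fit = mr.ivw(inst)
        assert fit.method == "wald"
        assert abs(fit.estimate - 0.4) < 1e-12
        assert abs(fit.se - 0.05 / 0.5) < 1e-12

    def test_exact_proportionality(self):
        inst = _inst([0.2, 0.5, 0.8], [0.1, 0.25, 0.4])
        fit = mr.ivw(inst)
        assert abs(fit.estimate - 0.5) < 1e-12
        assert fit.cochran_q < 1e-20

    def test_matches_wls_through_origin_oracle(self):
        rng = np.random.default_rng(60)
        bx = rng.normal(0.4, 0.1, 5)
        by = 0.3 * bx + rng.normal(0, 0.02, 5)
        sy = rng.uniform(0.03, 0.08, 5)
        fit = mr.ivw(_inst(bx, by, sy=sy))
        w = 1.0 / sy ** 2
        est = np.sum(w * bx * by) / np.sum(w * bx ** 2)
        se = np.sqrt(1.0 / np.sum(w * bx ** 2))
        assert abs(fit.estimate - est) < 1e-12
        assert abs(fit.se - se) < 1e-12


class TestMedianMr:
    def test_simple_median_odd_count(self):
        inst = _inst([1.0, 1.0, 1.0], [0.2, 0.5, 0.9])
        fit = mr.median_mr(inst, weighted=False, n_boot=200, seed=1)
        assert abs(fit.estimate - 0.5) < 1e-12

    def test_weighted_median_dominant_weight(self):
        # ratios (0.2, 0.5, 0.9), weights (1, 10, 1) via bx^2/sy^2
        bx = np.array([1.0, np.sqrt(10.0), 1.0])
        by = np.array([0.2, 0.5 * np.sqrt(10.0), 0.9])
        fit = mr.median_mr(_inst(bx, by, sy=[1.0, 1.0, 1.0]),
                           weighted=True, n_boot=200, seed=2)
        assert abs(fit.estimate - 0.5) < 1e-12

    def test_identical_ratios(self):
        inst = _inst([0.3, 0.5, 0.7], [0.3 * 0.7, 0.5 * 0.7, 0.7 * 0.7],
                     sx=[1e-6] * 3, sy=[1e-6] * 3)
        fit = mr.median_mr(inst, weighted=True, n_boot=200, seed=3)
        assert abs(fit.estimate - 0.7) < 1e-9
        assert fit.se < 1e-4

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr.median_mr(_inst([0.5, 0.5], [0.1, 0.1]))


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        fit, intercept = mr.egger(_inst(bx, 0.3 * bx))
        assert abs(fit.estimate - 0.3) < 1e-10
        assert abs(intercept.estimate) < 1e-12

    def test_directional_pleiotropy_shift(self):
        rng = np.random.default_rng(61)
        bx = rng.uniform(0.2, 0.8, 20)
        by = 0.3 * bx + 0.1 + rng.normal(0, 1e-6, 20)
        fit, intercept = mr.egger(_inst(bx, by))
        assert abs(intercept.estimate - 0.1) < 1e-4
        assert abs(fit.estimate - 0.3) < 1e-4

    def test_null_intercept_p_uniform(self):
        """Intercept p-values under no pleiotropy are uniform (KS)."""
        from scipy import stats
        rng = np.random.default_rng(62)
        ps = []
        for _ in range(500):
            bx = rng.uniform(0.2, 0.8, 15)
            sy = np.full(15, 0.05)
            by = 0.3 * bx + sy * rng.standard_normal(15)
            _, intercept = mr.egger(_inst(bx, by, sy=sy))
            ps.append(intercept.pval)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestConsensus:
    def _fits(self, ps, egger_int_p=0.5):
        methods = ("simple_median", "weighted_median", "ivw", "egger_slope")
        fits = {m: mr.MRFit(m, 0.3, 0.1, p, 5) for m, p in zip(methods, ps)}
        fits["egger_intercept"] = mr.MRFit("egger_intercept", 0.0, 0.1,
                                           egger_int_p, 5)
        return fits

    def test_median_of_four_pvalues(self):
        recs = mr.consensus({"p1": self._fits([0.001, 0.002, 0.03, 0.7])}, "o")
        assert abs(recs[0].median_p - 0.016) < 1e-12

    def test_all_half(self):
        recs = mr.consensus({"p1": self._fits([0.5] * 4)}, "o")
        assert recs[0].median_p == 0.5

    def test_pleiotropy_gate_excludes(self):
        recs = mr.consensus({"p1": self._fits([1e-8] * 4, egger_int_p=0.01)}, "o")
        assert recs[0].pleiotropy_flag
        assert recs[0].significant is False

    def test_reverse_mr_family_threshold(self):
        # 0.05 / (2922 proteins x 4 methods) prints as 4.3e-06
        thr = 0.05 / (2922 * 4)
        assert f"{thr:.1e}" == "4.3e-06"


class TestMvmr:
    def test_reduces_to_ivw_when_second_exposure_null(self):
        rng = np.random.default_rng(63)
        bx = rng.uniform(0.2, 0.8, 10)
        by = 0.4 * bx + rng.normal(0, 0.01, 10)
        inst = _inst(bx, by).rename(columns={"beta_exposure": "beta_protein",
                                             "se_exposure": "se_protein"})
        inst["beta_bmi"] = rng.normal(0, 0.3, 10)  # needs variation, no effect
        inst["se_bmi"] = 0.02
        # make the outcome depend only on the protein betas
        fit = mr.mvmr(inst)
        ivw_fit = mr.ivw(_inst(bx, by))
        assert abs(fit.estimates["protein"] - 0.4) < 0.05
        # exact reduction when bmi betas are exactly zero is singular; check
        # near-orthogonal case recovers the univariable target instead
        assert abs(fit.estimates["bmi"]) < 0.05

    def test_dual_exposure_recovery(self):
        rng = np.random.default_rng(64)
        J = 50
        b1 = rng.normal(0, 0.3, J)
        b2 = rng.normal(0, 0.3, J)
        sy = np.full(J, 0.02)
        by = 0.3 * b1 + 0.2 * b2 + sy * rng.standard_normal(J)
        inst = pd.DataFrame({
            "beta_protein": b1, "se_protein": 0.01,
            "beta_bmi": b2, "se_bmi": 0.01,
            "beta_outcome": by, "se_outcome": sy})
        fit = mr.mvmr(inst)
        assert abs(fit.estimates["protein"] - 0.3) < 0.05
        assert abs(fit.estimates["bmi"] - 0.2) < 0.05
        assert fit.conditional_f["protein"] > 10
        assert fit.retained

    def test_q_statistic_null_uniform(self):
        from scipy import stats
        rng = np.random.default_rng(65)
        ps = []
        for _ in range(500):
            J = 20
            b1 = rng.normal(0, 0.3, J)
            b2 = rng.normal(0, 0.3, J)
            sy = np.full(J, 0.05)
            by = 0.3 * b1 + 0.2 * b2 + sy * rng.standard_normal(J)
            inst = pd.DataFrame({
                "beta_protein": b1, "se_protein": 0.01,
                "beta_bmi": b2, "se_bmi": 0.01,
                "beta_outcome": by, "se_outcome": sy})
            ps.append(mr.mvmr(inst).q_pleiotropy_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_proportional_exposures_collinear(self):
        b1 = np.array([0.2, 0.4, 0.6, 0.8])
        inst = pd.DataFrame({
            "beta_protein": b1, "se_protein": 0.01,
            "beta_bmi": 2 * b1, "se_bmi": 0.01,
            "beta_outcome": 0.3 * b1, "se_outcome": 0.05})
        with pytest.raises(CollinearityError):
            mr.mvmr(inst)


class TestInvariants:
    def test_all_estimators_exact_on_noise_free_ratio(self):
        bx = np.array([0.2, 0.5, 0.8, 0.3, 0.6])
        inst = _inst(bx, 0.7 * bx)
        assert abs(mr.ivw(inst).estimate - 0.7) < 1e-12
        assert abs(mr.median_mr(inst, False, n_boot=100, seed=0).estimate - 0.7) < 1e-12
        assert abs(mr.median_mr(inst, True, n_boot=100, seed=0).estimate - 0.7) < 1e-12
        slope, _ = mr.egger(inst)
        assert abs(slope.estimate - 0.7) < 1e-10

    def test_joint_allele_relabelling_invariance(self):
        rng = np.random.default_rng(66)
        bx = rng.uniform(0.2, 0.8, 6)
        by = 0.4 * bx + rng.normal(0, 0.02, 6)
        e = _sumstats([f"v{j}" for j in range(6)], ["A"] * 6, ["G"] * 6,
                      bx, [0.02] * 6, [0.3] * 6)
        o = _sumstats([f"v{j}" for j in range(6)], ["A"] * 6, ["G"] * 6,
                      by, [0.05] * 6, [0.3] * 6)
        # relabel both sides: swap effect/other and negate betas
        e2 = e.copy()
        e2["effect_allele"], e2["other_allele"] = e["other_allele"], e["effect_allele"]
        e2["beta"] = -e["beta"]
        e2["eaf"] = 1 - e["eaf"]
        o2 = o.copy()
        o2["effect_allele"], o2["other_allele"] = o["other_allele"], o["effect_allele"]
        o2["beta"] = -o["beta"]
        o2["eaf"] = 1 - o["eaf"]
        fit1 = mr.ivw(mr.harmonize(e, o))
        fit2 = mr.ivw(mr.harmonize(e2, o2))
        assert abs(fit1.estimate - fit2.estimate) < 1e-12

    def test_ivw_type_one_error_calibrated(self):
        rng = np.random.default_rng(67)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            bx = rng.uniform(0.2, 0.8, 20)
            sy = np.full(20, 0.05)
            by = sy * rng.standard_normal(20)
            hits += mr.ivw(_inst(bx, by, sy=sy)).pval < 0.05
        assert 0.03 <= hits / n_sim <= 0.07

    def test_ivw_ci_coverage(self):
        rng = np.random.default_rng(68)
        covered = 0
        n_sim = 500
        for _ in range(n_sim):
            bx = rng.uniform(0.2, 0.8, 20)
            sy = np.full(20, 0.05)
            by = 0.3 * bx + sy * rng.standard_normal(20)
            fit = mr.ivw(_inst(bx, by, sy=sy))
            covered += abs(fit.estimate - 0.3) <= 1.959963984540054 * fit.se
        assert 0.90 <= covered / n_sim <= 0.98


def test_meta_analysis_fixed_effect():
    a = _sumstats(["v1", "v2"], ["A", "A"], ["G", "G"], [0.2, 0.4],
                  [0.1, 0.1], [0.3, 0.3])
    b = _sumstats(["v1", "v2"], ["A", "A"], ["G", "G"], [0.4, 0.2],
                  [0.1, 0.1], [0.3, 0.3])
    m = mr.meta_analyze([a, b])
    np.testing.assert_allclose(m["beta"], [0.3, 0.3])
    np.testing.assert_allclose(m["se"], [0.1 / np.sqrt(2)] * 2)
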