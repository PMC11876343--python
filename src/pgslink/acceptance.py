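"""Self-contained benchmark computations for the package's headline claims.

Each function recomputes one quantity from scratch — analytic thresholds,
null-calibration rates, parameter recoveries on synthetic data, causal-
direction and colocalization scenario discrimination, and end-to-end
pipeline recovery — by running the package's own machinery. Used by the
acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from . import assoc, coloc, mr, survival
from . import mediation as med
from .config import SimConfig
from .simulate import (GenotypeMatrix, compute_summary_stats, make_truth,
                       simulate_cohort, simulate_genotypes, simulate_trial,
                       _standardized, _true_pgs)


# ---------------------------------------------------------------------------
# analytic thresholds
# ---------------------------------------------------------------------------

def discovery_bonferroni_threshold(alpha=0.05, n_scores=10, n_proteins=2922):
    """Discovery threshold of the proteome-wide two-stage scan."""
    return assoc.bonferroni_threshold(alpha, n_scores, n_proteins)


def reverse_mr_bonferroni_threshold(alpha=0.05, n_proteins=2922, n_methods=4):
    """Per-test threshold for the proteins x MR-methods family."""
    return alpha / (n_proteins * n_methods)


# ---------------------------------------------------------------------------
# null calibration (type-I error at alpha = 0.05)
# ---------------------------------------------------------------------------

def _toy_geno(rng, n, m, maf_lo=0.1, maf_hi=0.5):
    mafs = rng.uniform(maf_lo, maf_hi, m)
    D = rng.binomial(2, mafs, size=(n, m)).astype(float)
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)], "chrom": 1,
        "pos": np.arange(1, m + 1) * 1000,
        "effect_allele": "A", "other_allele": "G", "maf": mafs,
        "region_id": "indep", "cis_protein": ""})
    return GenotypeMatrix(D, variants, [f"s{i}" for i in range(n)])


def gwas_type1(seed, n_variants=1000, n=800):
    """Fraction of independent null variants with p < 0.05."""
    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    for chunk in range(2):
        geno = _toy_geno(np.random.default_rng(seed + chunk), n, n_variants // 2)
        y = rng.normal(size=n)
        covar = rng.normal(size=(n, 3))
        ss = compute_summary_stats(geno, y, covariates=covar)
        hits += int((ss["pval"] < 0.05).sum())
        total += len(ss)
    return hits / total


def _null_instruments(rng, J=20, effect=0.0):
    bx = rng.uniform(0.2, 0.8, J)
    sy = np.full(J, 0.05)
    by = effect * bx + sy * rng.standard_normal(J)
    return pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(J)],
        "beta_exposure": bx, "se_exposure": np.full(J, 0.01),
        "beta_outcome": by, "se_outcome": sy,
        "f_stat": (bx / 0.01) ** 2})


def ivw_type1(seed, n_sim=1000):
    rng = np.random.default_rng(seed)
    hits = sum(mr.ivw(_null_instruments(rng)).pval < 0.05
               for _ in range(n_sim))
    return hits / n_sim


def egger_intercept_type1(seed, n_sim=500):
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        _, intercept = mr.egger(_null_instruments(rng, J=15, effect=0.3))
        hits += intercept.pval < 0.05
    return hits / n_sim


def mvmr_q_type1(seed, n_sim=500):
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        J = 20
        b1 = rng.normal(0, 0.3, J)
        b2 = rng.normal(0, 0.3, J)
        sy = np.full(J, 0.05)
        by = 0.3 * b1 + 0.2 * b2 + sy * rng.standard_normal(J)
        inst = pd.DataFrame({
            "beta_protein": b1, "se_protein": 0.01,
            "beta_bmi": b2, "se_bmi": 0.01,
            "beta_outcome": by, "se_outcome": sy})
        hits += mr.mvmr(inst).q_pleiotropy_p < 0.05
    return hits / n_sim


def ph_test_type1(seed, n_sim=500, n=150):
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    for _ in range(n_sim):
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n) / np.exp(0.3 * x)
        c = rng.exponential(2.0, n)
        df = pd.DataFrame({"time": np.minimum(t, c),
                           "event": (t <= c).astype(int), "x": x})
        _, p = survival.ph_test(df, "x")
        if p is not None:
            hits += p < 0.05
            done += 1
    return hits / done


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def _chain_config(seed, **over):
    base = dict(n_discovery=10000, n_replication=500, n_gwas_exposure=500,
                n_gwas_outcome=500, n_proteins=2, n_variants_per_cis_region=10,
                pgs_n_variants=50, n_true_targets=2, n_trans_hit=1,
                n_distinct_regions=0, n_trial_causal=1, seed=seed)
    base.update(over)
    return SimConfig(**base)


def pgs_protein_beta_recovery(seed, n_seeds=3):
    """Mean absolute error of the scanned PGS->protein beta vs. truth."""
    errs = []
    for s in range(n_seeds):
        cfg = _chain_config(seed + s)
        ledger = make_truth(cfg)
        geno = simulate_genotypes(cfg)
        cohort, ledger = simulate_cohort(cfg, geno, ledger)
        pgs = _standardized(_true_pgs(geno, ledger.pgs_weights))
        covar = cohort[["age", "sex"]]
        for protein in ledger.true_target_proteins():
            res = assoc.linear_assoc(_standardized(cohort[protein].to_numpy()),
                                     pgs, covar)
            errs.append(abs(res.beta - ledger.pgs_total[protein]))
    return float(np.mean(errs))


def mediated_fraction_recovery(seed, fractions=(0.0, 0.25, 0.5, 0.75, 1.0),
                               n_seeds=8):
    """Max |estimated - true| mediated proportion over the fraction grid."""
    worst = 0.0
    per_frac = {}
    for frac in fractions:
        ests = []
        for s in range(n_seeds):
            cfg = _chain_config(seed + s, mediated_fraction=frac)
            ledger = make_truth(cfg)
            geno = simulate_genotypes(cfg)
            cohort, ledger = simulate_cohort(cfg, geno, ledger)
            pgs = _standardized(_true_pgs(geno, ledger.pgs_weights))
            res = med.mediate_continuous(
                pgs, cohort["bmi"].to_numpy(),
                _standardized(cohort["prot_000"].to_numpy()),
                covariates=cohort[["age", "sex"]].to_numpy(float),
                n_boot=100, seed=cfg.seed)
            # scanned protein is standardized; rescale to the truth's scale
            ests.append(res.nie / res.te)
        err = abs(float(np.mean(ests)) - frac)
        per_frac[frac] = float(np.mean(ests))
        worst = max(worst, err)
    return worst, per_frac


def ivw_coverage(seed, n_sim=500, true_effect=0.3):
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_sim):
        inst = _null_instruments(rng, J=20, effect=true_effect)
        fit = mr.ivw(inst)
        covered += abs(fit.estimate - true_effect) <= 1.959963984540054 * fit.se
    return covered / n_sim


def mvmr_recovery(seed, n_sim=20, J=50, eff=(0.3, 0.2)):
    """Max absolute error of the two MVMR exposure estimates."""
    rng = np.random.default_rng(seed)
    est = np.zeros(2)
    for _ in range(n_sim):
        b1 = rng.normal(0, 0.3, J)
        b2 = rng.normal(0, 0.3, J)
        sy = np.full(J, 0.02)
        by = eff[0] * b1 + eff[1] * b2 + sy * rng.standard_normal(J)
        inst = pd.DataFrame({
            "beta_protein": b1, "se_protein": 0.01,
            "beta_bmi": b2, "se_bmi": 0.01,
            "beta_outcome": by, "se_outcome": sy})
        fit = mr.mvmr(inst)
        est += (fit.estimates["protein"], fit.estimates["bmi"])
    est /= n_sim
    return float(np.max(np.abs(est - np.array(eff)))), est


def cox_loghr_recovery(seed, n_seeds=10, n=5000, true_loghr=0.5):
    """Mean Cox estimate of a planted per-SD log hazard ratio."""
    cfg = _chain_config(seed, n_discovery=n, trial_log_hr=true_loghr,
                        censor_rate=1e-9)
    ledger = make_truth(cfg)
    ledger.trial_log_hr = {"mace": {"prot_000": true_loghr}}
    ledger.confounded_trial_protein = None
    geno = simulate_genotypes(cfg)
    cohort, ledger = simulate_cohort(cfg, geno, ledger)
    ests = []
    for s in range(n_seeds):
        trial = simulate_trial(cfg, cohort, ledger, endpoints=("mace",),
                               subseed=s)
        fit = survival.cox_fit(trial, "prot_000_t0", ["age", "prior_hf"],
                               time_col="time_mace", event_col="event_mace")
        ests.append(fit.estimate)
    return float(np.mean(ests))


# ---------------------------------------------------------------------------
# scenario discrimination
# ---------------------------------------------------------------------------

def _direction_scenario(rng, direction, n_exp=2000, n_out=4000):
    """Compact forward- vs reverse-causal two-sample MR scenario.

    Forward: the protein has strong cis pQTLs and a causal effect on the
    binary trait. Reverse: the trait has its own genetic instruments and
    the protein level responds to the trait's genetic liability.
    """
    m_cis, m_trait = 12, 6
    m = m_cis + m_trait
    seed_pair = [int(rng.integers(2 ** 31)), int(rng.integers(2 ** 31))]
    geno_exp = _toy_geno(np.random.default_rng(seed_pair[0]), n_exp, m,
                         maf_lo=0.2)
    geno_out = _toy_geno(np.random.default_rng(seed_pair[1]), n_out, m,
                         maf_lo=0.2)
    # cis region near position 0; trait loci far away, 600 kb apart so the
    # 500 kb reverse-MR clump window keeps them all
    for g in (geno_exp, geno_out):
        g.variants.loc[m_cis:, "pos"] = 10_000_000 + \
            np.arange(m_trait) * 600_000

    cis_idx = [2, 6, 10]
    beta_cis = np.sqrt(0.15 / len(cis_idx))
    trait_idx = np.arange(m_cis, m)
    beta_trait = 0.45  # per-variant log-odds; genome-wide significant at n_out

    def protein_and_trait(geno, n, rng_local):
        Z = (geno.dosages - geno.dosages.mean(0)) / geno.dosages.std(0)
        g_cis = Z[:, cis_idx].sum(1) * beta_cis
        g_trait = Z[:, trait_idx].sum(1) * beta_trait
        if direction == "forward":
            protein = g_cis + np.sqrt(1 - 0.15) * rng_local.normal(size=n)
            eta = 0.6 * protein
        else:
            eta = g_trait
            protein = 0.45 * eta + rng_local.normal(size=n)
        trait = (rng_local.random(n) < expit(-1.6 + eta)).astype(float)
        return protein, trait

    p_exp, _ = protein_and_trait(geno_exp, n_exp,
                                 np.random.default_rng(seed_pair[0] + 1))
    _, t_out = protein_and_trait(geno_out, n_out,
                                 np.random.default_rng(seed_pair[1] + 1))
    pqtl_ss = compute_summary_stats(geno_exp, p_exp)
    trait_ss = compute_summary_stats(geno_out, t_out, trait_type="cc")
    return geno_exp, geno_out, pqtl_ss, trait_ss


def direction_discrimination(seed, n_runs=100):
    """Fraction of runs where forward vs reverse MR point the right way."""
    from .scoring import ClumpParams, clump
    rng = np.random.default_rng(seed)
    correct = 0
    for i in range(n_runs):
        direction = "forward" if i % 2 == 0 else "reverse"
        geno_exp, geno_out, pqtl_ss, trait_ss = _direction_scenario(
            rng, direction)
        # forward: clumped cis pQTLs (within the cis region) as instruments
        fwd_sig = False
        ws = clump(pqtl_ss, geno_exp, ClumpParams(5e-8, 0.1, 250.0))
        cis_vids = set(pqtl_ss.loc[pqtl_ss["pos"] < 1_000_000, "variant_id"])
        ws.table = ws.table[ws.table["variant_id"].isin(cis_vids)]
        if len(ws) >= 3:
            exposure = pqtl_ss[pqtl_ss["variant_id"].isin(ws.table["variant_id"])]
            inst = mr.harmonize(exposure, trait_ss)
            inst, _ = mr.instrument_qc(inst)
            if len(inst) >= 3:
                fits = mr.run_methods(inst, seed=int(rng.integers(2 ** 31)))
                ps = [fits[m].pval for m in ("simple_median", "weighted_median",
                                             "ivw", "egger_slope")]
                fwd_sig = float(np.median(ps)) < 0.05
        # reverse: clumped trait variants against the protein
        rev = mr.reverse_mr(trait_ss, {"protein": pqtl_ss}, geno_out,
                            clump_params=ClumpParams(5e-8, 0.001, 500.0),
                            seed=int(rng.integers(2 ** 31)))[0]
        rev_sig = (rev.skip_reason is None
                   and np.isfinite(rev.median_p) and rev.median_p < 0.05)
        if direction == "forward":
            correct += fwd_sig and not rev_sig
        else:
            correct += rev_sig and not fwd_sig
    return correct / n_runs


def coloc_discrimination(seed, n_runs=100, n=3000):
    """Shared scenarios should be PP.H4-dominant, distinct PP.H3-dominant."""
    rng = np.random.default_rng(seed)
    h4_ok = 0
    h3_ok = 0
    n_each = n_runs // 2
    for scenario in ("shared", "distinct"):
        for _ in range(n_each):
            sub = int(rng.integers(2 ** 31))
            g1 = _toy_geno(np.random.default_rng(sub), n, 15, maf_lo=0.2)
            g2 = _toy_geno(np.random.default_rng(sub + 1), n, 15, maf_lo=0.2)
            r = np.random.default_rng(sub + 2)
            z1 = (g1.dosages[:, 5] - g1.dosages[:, 5].mean()) / g1.dosages[:, 5].std()
            j2 = 5 if scenario == "shared" else 11
            z2 = (g2.dosages[:, j2] - g2.dosages[:, j2].mean()) / g2.dosages[:, j2].std()
            y1 = 0.35 * z1 + r.normal(size=n)
            y2 = 0.35 * z2 + r.normal(size=n)
            ss1 = compute_summary_stats(g1, y1)
            ss2 = compute_summary_stats(g2, y2)
            post = coloc.coloc(ss1, ss2)
            if scenario == "shared":
                h4_ok += post.pp_h4 > post.pp_h3
            else:
                h3_ok += post.pp_h3 > post.pp_h4
    return h4_ok / n_each, h3_ok / n_each


def repeat_timepoint_inflation(seed, n_runs=20):
    """Fraction of reverse-causation trials with repeat HR > baseline HR."""
    cfg = SimConfig(seed=seed, n_discovery=3000, n_replication=200,
                    n_gwas_exposure=200, n_gwas_outcome=200, n_proteins=4,
                    n_variants_per_cis_region=10, pgs_n_variants=40,
                    n_true_targets=2, n_trans_hit=1, n_distinct_regions=0,
                    n_trial_causal=2)
    ledger = make_truth(cfg)
    geno = simulate_genotypes(cfg)
    cohort, ledger = simulate_cohort(cfg, geno, ledger)
    protein = next(p for p in ledger.trial_log_hr["mace"]
                   if p != ledger.confounded_trial_protein)
    inflated = 0
    for s in range(n_runs):
        trial = simulate_trial(cfg, cohort, ledger, endpoints=("mace",),
                               reverse_causation=True, subseed=s)
        out = survival.repeat_measurement_scan(trial, [protein])
        inflated += out["hr_repeat"].iloc[0] > out["hr_baseline"].iloc[0]
    return inflated / n_runs


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def pipeline_recovery(seed, out_dir):
    """Run the default-scale pipeline; count recovered causal proteins."""
    from .pipeline import run_pipeline
    manifest = run_pipeline(SimConfig(seed=seed), out_dir)
    truth = set(manifest["summary"]["true_targets"])
    sig = set(manifest["summary"]["mr_significant_proteins"])
    return len(truth & sig), len(truth), manifest
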