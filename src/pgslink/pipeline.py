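"""End-to-end orchestration: simulate -> score -> scan -> mediation ->
MR (forward, MVMR, reverse) -> colocalization -> trial survival ->
enrichment, with a manifest recording seeds, digests and row counts.

Every intermediate file is plain TSV/JSON; identical config and seed
reproduce byte-identical outputs. A stage failure is recorded in the
manifest and downstream stages are skipped.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, coloc, mr, scoring, simulate, survival
from . import mediation as med
from .config import SimConfig
from .enrich import PathwayCollection, enrich, write_gmt
from .errors import PgslinkError

CIS_WINDOW_BP = 1_000_000
PQTL_P = 5e-8


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def make_pathways(ledger, n_random: int = 20, pathway_size: int = 8,
                  seed: int = 0) -> PathwayCollection:
    """Synthetic pathway collection: one pathway enriched in the planted
    target proteins plus random same-size pathways over the panel."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    proteins = list(ledger.protein_ids)
    targets = ledger.true_target_proteins()
    pathways = {"planted_target_set": set(targets[:pathway_size]) or set(proteins[:3])}
    for i in range(n_random):
        members = rng.choice(proteins, size=min(pathway_size, len(proteins)),
                             replace=False)
        pathways[f"random_{i:02d}"] = set(members)
    return PathwayCollection(pathways, source="synthetic")


def pqtl_hit_counts(protein_sumstats: dict, p_threshold: float = PQTL_P) -> pd.Series:
    """variant_id -> number of proteins with a significant pQTL there."""
    counts = None
    for ss in protein_sumstats.values():
        hit = (ss["pval"] < p_threshold).astype(int).to_numpy()
        counts = hit if counts is None else counts + hit
    first = next(iter(protein_sumstats.values()))
    return pd.Series(counts, index=first["variant_id"].to_numpy())


def cis_bounds(variants: pd.DataFrame, protein: str) -> tuple:
    cis = variants[variants["cis_protein"] == protein]
    chrom = int(cis["chrom"].iloc[0])
    tss = int(cis["pos"].median())
    return chrom, tss - CIS_WINDOW_BP, tss + CIS_WINDOW_BP


def forward_mr(protein_ss: dict, outcome_ss: pd.DataFrame,
               ld_source, variants: pd.DataFrame,
               cis_only: bool = True, seed: int = 0) -> list:
    """Per-protein two-sample MR with clumped pQTL instruments."""
    hit_counts = pqtl_hit_counts(protein_ss)
    fits = {}
    params = scoring.ClumpParams(p_threshold=PQTL_P, r2_threshold=0.1, window_kb=250.0)
    for protein, ss in protein_ss.items():
        try:
            ws = scoring.clump(ss, ld_source, params)
            if len(ws) == 0:
                fits[protein] = "no genome-wide-significant pQTLs"
                continue
            exposure = ss[ss["variant_id"].isin(ws.table["variant_id"])]
            inst = mr.harmonize(exposure, outcome_ss)
            inst["n_proteins_hit"] = hit_counts.reindex(inst["variant_id"]).to_numpy()
            chrom, lo, hi = cis_bounds(variants, protein)
            vpos = variants.set_index("variant_id")
            inst["is_cis"] = [
                (vpos.loc[v, "chrom"] == chrom) and (lo <= vpos.loc[v, "pos"] <= hi)
                for v in inst["variant_id"]]
            inst, skip = mr.instrument_qc(inst, cis_only=cis_only)
            if skip:
                fits[protein] = skip
                continue
            fits[protein] = mr.run_methods(inst, seed=seed)
        except PgslinkError as exc:
            fits[protein] = str(exc)
    return mr.consensus(fits, outcome_id="disease")


COVAR_COLS = ["age", "sex"] + [f"pc{k}" for k in range(1, 11)]


def _stage_simulate(ctx):
    config, out = ctx["config"], ctx["out"]
    ledger = simulate.make_truth(config)
    geno_cohort = simulate.simulate_genotypes(config, subseed=0)
    cohort, ledger = simulate.simulate_cohort(config, geno_cohort, ledger, subseed=0)
    geno_exp = simulate.simulate_genotypes(config, n_samples=config.n_gwas_exposure,
                                           subseed=1, sample_prefix="E")
    cohort_exp, _ = simulate.simulate_cohort(config, geno_exp, ledger, subseed=1)
    geno_out = simulate.simulate_genotypes(config, n_samples=config.n_gwas_outcome,
                                           subseed=2, sample_prefix="O")
    cohort_out, _ = simulate.simulate_cohort(config, geno_out, ledger, subseed=2)
    trial = simulate.simulate_trial(config, cohort, ledger)
    ledger.to_json(out / "truth_ledger.json")
    _write(cohort, out / "cohort.tsv")
    _write(trial, out / "trial.tsv")
    ctx.update(ledger=ledger, geno_cohort=geno_cohort, cohort=cohort,
               geno_exp=geno_exp, cohort_exp=cohort_exp,
               geno_out=geno_out, cohort_out=cohort_out, trial=trial)
    return {"cohort": len(cohort), "variants": geno_cohort.n_variants,
            "trial": len(trial)}


def _stage_score(ctx):
    config, out = ctx["config"], ctx["out"]
    ledger, geno_cohort, cohort = ctx["ledger"], ctx["geno_cohort"], ctx["cohort"]
    vi = geno_cohort.variants.set_index("variant_id")
    weights = scoring.WeightSet(pd.DataFrame({
        "variant_id": list(ledger.pgs_weights),
        "effect_allele": [vi.loc[v, "effect_allele"] for v in ledger.pgs_weights],
        "other_allele": [vi.loc[v, "other_allele"] for v in ledger.pgs_weights],
        "weight": list(ledger.pgs_weights.values()),
    }), score_id="pgs_disease_gw")
    scoring.write_weights(weights, out / "pgs_weights.txt")
    score = scoring.compute_pgs(geno_cohort, weights)
    val = scoring.validate_pgs(score, cohort["incident_disease"].to_numpy(),
                               cohort[COVAR_COLS].to_numpy(float))
    ctx["score"] = score
    return {"n_weights": len(weights), "validation_p": val[2]}


def _stage_assoc(ctx):
    out, cohort, score = ctx["out"], ctx["cohort"], ctx["score"]
    base_cohort = assoc.filter_prevalent(cohort)
    keep = cohort["prevalent_disease"].to_numpy() == 0
    score_f = scoring.ScoreVector(raw=score.raw[keep],
                                  standardized=score.standardized[keep],
                                  sample_ids=list(np.array(score.sample_ids)[keep]),
                                  score_id=score.score_id)
    report = assoc.run_scan(base_cohort, [score_f])
    _write(report.discovery, out / "scan_discovery.tsv")
    _write(report.replication, out / "scan_replication.tsv")
    adj = assoc.adjusted_scan(base_cohort, [score_f], mode="bmi",
                              base_report=report)
    _write(adj.flags, out / "scan_adjusted_bmi_flags.tsv")
    if len(report.replication):
        replicated = sorted(report.replication.loc[
            report.replication["replicated"], "protein_id"])
    else:
        replicated = []
    ctx.update(base_cohort=base_cohort, score_f=score_f, report=report,
               replicated=replicated)
    return {"discovery_sig": int(report.discovery["significant"].sum()),
            "replicated": len(replicated)}


def _stage_mediation(ctx):
    config, out = ctx["config"], ctx["out"]
    base_cohort, replicated = ctx["base_cohort"], ctx["replicated"]
    covar = base_cohort[COVAR_COLS].to_numpy(float)
    pgs_vec = ctx["score_f"].standardized
    rows = []
    for protein in replicated:
        r = med.mediate_continuous(pgs_vec, base_cohort["bmi"].to_numpy(),
                                   base_cohort[protein].to_numpy(),
                                   covariates=covar, n_boot=200,
                                   seed=config.seed)
        rows.append(dict(exposure="pgs", mediator="bmi", outcome=protein,
                         nde=r.nde, nie=r.nie, te=r.te,
                         prop_mediated=r.prop_mediated,
                         p_direct=r.p_direct, p_indirect=r.p_indirect,
                         p_total=r.p_total,
                         classification=med.classify_mediation(r)))
    for protein in replicated:
        try:
            r = med.mediate_binary(pgs_vec, base_cohort[protein].to_numpy(),
                                   base_cohort["incident_disease"].to_numpy(float),
                                   covariates=covar, n_boot=100,
                                   seed=config.seed)
            rows.append(dict(exposure="pgs", mediator=protein,
                             outcome="incident_disease",
                             nde=r.nde, nie=r.nie, te=r.te,
                             prop_mediated=r.prop_mediated,
                             p_direct=r.p_direct, p_indirect=r.p_indirect,
                             p_total=r.p_total,
                             classification=med.classify_mediation(r)))
        except PgslinkError as exc:
            rows.append(dict(exposure="pgs", mediator=protein,
                             outcome="incident_disease", skip_reason=str(exc)))
    table = pd.DataFrame(rows)
    _write(table, out / "mediation.tsv")
    return {"rows": len(table)}


def _stage_sumstats(ctx):
    out = ctx["out"]
    ledger = ctx["ledger"]
    cohort_exp, geno_exp = ctx["cohort_exp"], ctx["geno_exp"]
    cohort_out, geno_out = ctx["cohort_out"], ctx["geno_out"]
    covar_exp = cohort_exp[COVAR_COLS].to_numpy(float)
    protein_ss = simulate.protein_sumstats(geno_exp, cohort_exp,
                                           ledger.protein_ids,
                                           covariates=covar_exp)
    covar_out = cohort_out[COVAR_COLS].to_numpy(float)
    disease_ss = simulate.compute_summary_stats(
        geno_out, cohort_out["incident_disease"].to_numpy(float),
        covariates=covar_out, trait_type="cc")
    bmi_ss = simulate.compute_summary_stats(
        geno_out, cohort_out["bmi"].to_numpy(float),
        covariates=covar_out, trait_type="quant")
    simulate.write_sumstats(disease_ss, out / "gwas_disease.tsv")
    simulate.write_sumstats(bmi_ss, out / "gwas_bmi.tsv")
    ctx.update(protein_ss=protein_ss, disease_ss=disease_ss, bmi_ss=bmi_ss)
    return {"proteins": len(protein_ss), "variants": len(disease_ss)}


def _stage_mr(ctx):
    config, out = ctx["config"], ctx["out"]
    protein_ss, disease_ss, bmi_ss = (ctx["protein_ss"], ctx["disease_ss"],
                                      ctx["bmi_ss"])
    geno_exp, geno_out = ctx["geno_exp"], ctx["geno_out"]
    records = forward_mr(protein_ss, disease_ss, geno_exp, geno_exp.variants,
                         cis_only=True, seed=config.seed)
    _write(mr.consensus_table(records), out / "mr_consensus.tsv")

    mvmr_rows = []
    params = scoring.ClumpParams(p_threshold=PQTL_P, r2_threshold=0.1,
                                 window_kb=250.0)
    bmi_idx = bmi_ss.set_index("variant_id")
    for protein in ctx["ledger"].protein_ids:
        try:
            ws = scoring.clump(protein_ss[protein], geno_exp, params)
            if len(ws) < 3:
                continue
            exposure = protein_ss[protein][
                protein_ss[protein]["variant_id"].isin(ws.table["variant_id"])]
            inst = mr.harmonize(exposure, disease_ss)
            inst["beta_bmi"] = bmi_idx.reindex(inst["variant_id"])["beta"].to_numpy()
            inst["se_bmi"] = bmi_idx.reindex(inst["variant_id"])["se"].to_numpy()
            inst = inst.rename(columns={"beta_exposure": "beta_protein",
                                        "se_exposure": "se_protein"})
            fit = mr.mvmr(inst.dropna(subset=["beta_bmi"]))
            mvmr_rows.append(dict(protein_id=protein,
                                  est_protein=fit.estimates["protein"],
                                  est_bmi=fit.estimates["bmi"],
                                  p_protein=fit.pvals["protein"],
                                  f_protein=fit.conditional_f["protein"],
                                  f_bmi=fit.conditional_f["bmi"],
                                  q_p=fit.q_pleiotropy_p,
                                  retained=fit.retained))
        except PgslinkError:
            continue
    _write(pd.DataFrame(mvmr_rows), out / "mvmr.tsv")

    reverse = mr.reverse_mr(disease_ss, protein_ss, geno_out, seed=config.seed)
    _write(mr.consensus_table(reverse), out / "reverse_mr.tsv")
    sig = sorted(r.protein_id for r in records if r.significant)
    ctx["mr_significant"] = sig
    return {"mr_significant": len(sig), "mvmr_rows": len(mvmr_rows)}


def _stage_coloc(ctx):
    out = ctx["out"]
    ledger, geno_exp = ctx["ledger"], ctx["geno_exp"]
    protein_ss, disease_ss = ctx["protein_ss"], ctx["disease_ss"]
    rows = []
    for protein in ledger.protein_ids:
        chrom, lo, hi = cis_bounds(geno_exp.variants, protein)
        r1 = coloc.region_slice(disease_ss, chrom, lo, hi)
        r2 = coloc.region_slice(protein_ss[protein], chrom, lo, hi)
        shared = set(r1["variant_id"]) & set(r2["variant_id"])
        r1 = r1[r1["variant_id"].isin(shared)]
        r2 = r2[r2["variant_id"].isin(shared)]
        # only regions with suggestive signal on both sides, as in practice
        if len(shared) < 2 or r1["pval"].min() > 1e-6 or r2["pval"].min() > 1e-6:
            continue
        post = coloc.coloc(r1, r2)
        rows.append(dict(
            protein_id=protein, region=f"cis_{protein}",
            pp_h0=post.pp_h0, pp_h1=post.pp_h1, pp_h2=post.pp_h2,
            pp_h3=post.pp_h3, pp_h4=post.pp_h4,
            n_variants=post.n_variants,
            decision=coloc.coloc_decision(post),
            truth=ledger.coloc_scenario.get(f"cis_{protein}")))
    table = pd.DataFrame(rows)
    _write(table, out / "coloc.tsv")
    return {"regions": len(table)}


def _stage_trial(ctx):
    config, out = ctx["config"], ctx["out"]
    ledger, trial, score = ctx["ledger"], ctx["trial"], ctx["score"]
    endpoints = ("mace", "hhf", "renal")
    disc = survival.endpoint_scan(trial, ledger.protein_ids, endpoints,
                                  tier="base", role="discovery", ph_flag=False)
    _write(disc, out / "endpoints_base.tsv")
    hits = disc[disc["significant"]] if "significant" in disc else disc.iloc[:0]
    hit_proteins = sorted(set(hits["protein_id"])) if len(hits) else []
    repeat = survival.repeat_measurement_scan(
        trial, hit_proteins or ledger.protein_ids[:3], endpoint="mace")
    _write(repeat, out / "repeat_modes.tsv")
    tm = survival.pgs_trial_mediation(trial, score.standardized,
                                      hit_proteins[:5], endpoint="mace",
                                      n_boot=100, seed=config.seed)
    _write(tm if not tm.empty else pd.DataFrame(
        [{"skip_reason": tm.attrs.get("skip_reason", "")}]),
        out / "trial_mediation.tsv")
    return {"endpoint_sig": int(len(hits)), "mediation_rows": len(tm)}


def _stage_enrich(ctx):
    config, out = ctx["config"], ctx["out"]
    ledger = ctx["ledger"]
    pathways = make_pathways(ledger, seed=config.seed)
    write_gmt(pathways, out / "pathways.gmt")
    hits = set(ctx["replicated"]) or set(ctx.get("mr_significant", []))
    background = set(ledger.protein_ids)
    table = enrich(hits & background, background, pathways) if hits \
        else pd.DataFrame()
    _write(table if not table.empty else pd.DataFrame([{"note": "no hits"}]),
           out / "enrichment.tsv")
    return {"pathways_tested": len(table)}


_STAGES = [
    ("simulate", _stage_simulate),
    ("score", _stage_score),
    ("assoc", _stage_assoc),
    ("mediation", _stage_mediation),
    ("sumstats", _stage_sumstats),
    ("mr", _stage_mr),
    ("coloc", _stage_coloc),
    ("trial", _stage_trial),
    ("enrich", _stage_enrich),
]


def run_pipeline(config: SimConfig, out_dir, seed: int | None = None) -> dict:
    """Execute every stage on one synthetic study; returns the manifest.

    A stage failure marks that stage failed in the manifest and skips all
    downstream stages; the manifest is always written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = SimConfig.from_dict({**config.to_dict(), "seed": seed})
    config.validate()
    manifest = {"config": config.to_dict(), "stages": {}, "files": {}}
    ctx = {"config": config, "out": out}
    failed = False
    for name, fn in _STAGES:
        if failed:
            manifest["stages"][name] = {"status": "skipped", "counts": {},
                                        "seconds": 0.0}
            continue
        t0 = time.perf_counter()
        try:
            counts = fn(ctx)
            manifest["stages"][name] = {
                "status": "ok", "counts": counts,
                "seconds": round(time.perf_counter() - t0, 2)}
        except Exception as exc:
            manifest["stages"][name] = {
                "status": "failed", "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=5),
                "seconds": round(time.perf_counter() - t0, 2)}
            failed = True

    manifest["summary"] = {
        "replicated_proteins": ctx.get("replicated", []),
        "mr_significant_proteins": ctx.get("mr_significant", []),
        "true_targets": (ctx["ledger"].true_target_proteins()
                         if "ledger" in ctx else []),
        "bonferroni_threshold": (ctx["report"].bonferroni_threshold
                                 if "report" in ctx else None),
    }
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _digest(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def write_report(manifest: dict, out_dir, make_figures: bool = True) -> dict:
    """Summary tables (and optional static figures) from a completed run."""
    out = Path(out_dir)
    tables = {}
    mr_path = out / "mr_consensus.tsv"
    if mr_path.exists():
        mr_table = pd.read_csv(mr_path, sep="\t")
        forest = []
        for _, r in mr_table.iterrows():
            if not np.isfinite(r.get("ivw_est", np.nan)):
                continue
            est, se = r["ivw_est"], r["ivw_se"]
            forest.append(dict(protein_id=r["protein_id"], estimate=est, se=se,
                               odds_ratio=float(np.exp(est)),
                               ci_low=float(np.exp(est - 1.959963984540054 * se)),
                               ci_high=float(np.exp(est + 1.959963984540054 * se)),
                               median_p=r["median_p"]))
        forest_df = pd.DataFrame(forest)
        _write(forest_df, out / "report_mr_forest.tsv")
        tables["mr_forest"] = forest_df
    disc_path = out / "scan_discovery.tsv"
    if disc_path.exists():
        disc = pd.read_csv(disc_path, sep="\t")
        counts = disc.groupby("score_id")["significant"].sum().reset_index()
        counts.columns = ["score_id", "n_significant"]
        _write(counts, out / "report_assoc_counts.tsv")
        tables["assoc_counts"] = counts
        if make_figures and len(disc):
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.scatter(disc["beta"], -np.log10(disc["pval"]), s=8)
            ax.set_xlabel("PGS-protein beta (per SD)")
            ax.set_ylabel("-log10 p")
            fig.savefig(out / "report_volcano.svg")
            plt.close(fig)
    return tables
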