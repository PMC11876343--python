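"""Two-stage PGS-protein association scanning.

Discovery uses a Bonferroni threshold over scores x proteins; hits are
re-tested in the replication stratum with a Benjamini-Hochberg correction
applied separately within each score. Adjustment variants (adiposity or
pQTL dosages as extra covariates) classify each pair as still significant
or attenuated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import CollinearityError, EmptyCohortError, InsufficientDataError
from .simulate import _standardized


@dataclass
class AssocResult:
    score_id: str
    protein_id: str
    beta: float
    se: float
    t_stat: float
    pval: float
    r2_partial: float
    n: int


@dataclass
class ScanReport:
    discovery: pd.DataFrame
    replication: pd.DataFrame
    bonferroni_threshold: float
    alpha: float
    flags: pd.DataFrame = field(default_factory=pd.DataFrame)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_threshold(alpha: float, n_scores: int, n_proteins: int) -> float:
    """Discovery significance threshold alpha / (scores x proteins)."""
    return alpha / (n_scores * n_proteins)


def linear_assoc(y, x, covariates=None, score_id="x", protein_id="y") -> AssocResult:
    """Least-squares fit of y on [1, x, covariates]; inference for x.

    r2_partial = t^2 / (t^2 + df) is the variance in y uniquely explained
    by x given the covariates.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if covariates is None:
        X = np.column_stack([np.ones(n), x])
        names = ["const", "x"]
    else:
        C = pd.DataFrame(covariates)
        X = np.column_stack([np.ones(n), x, C.to_numpy(float)])
        names = ["const", "x"] + [str(c) for c in C.columns]
    if n <= X.shape[1]:
        raise InsufficientDataError(f"n={n} too small for {X.shape[1]} predictors")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10 * abs(r[0, 0])]
        raise CollinearityError(bad or names)
    fit = sm.OLS(y, X).fit()
    t = float(fit.tvalues[1])
    df = int(fit.df_resid)
    return AssocResult(score_id=score_id, protein_id=protein_id,
                       beta=float(fit.params[1]), se=float(fit.bse[1]),
                       t_stat=t, pval=float(fit.pvalues[1]),
                       r2_partial=t * t / (t * t + df), n=n)


def filter_prevalent(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop samples with prevalent disease at baseline."""
    out = cohort[cohort["prevalent_disease"] == 0].reset_index(drop=True)
    out.attrs["n_removed"] = len(cohort) - len(out)
    return out


def _covariate_frame(cohort: pd.DataFrame, extra=None) -> pd.DataFrame:
    C = pd.DataFrame({
        "age": cohort["age"].to_numpy(float),
        "sex": cohort["sex"].to_numpy(float),
    })
    C["age_sex"] = C["age"] * C["sex"]
    for k in range(1, 11):
        C[f"pc{k}"] = cohort[f"pc{k}"].to_numpy(float)
    if extra is not None:
        for name, col in extra.items():
            C[name] = np.asarray(col, dtype=float)
    return C


def _scan_stage(cohort, scores, protein_ids, extra=None) -> pd.DataFrame:
    if len(cohort) == 0:
        raise EmptyCohortError("no samples left in cohort stratum")
    mask = cohort.index.to_numpy()
    covar = _covariate_frame(cohort, extra)
    rows = []
    for sv in scores:
        x = _standardized(np.asarray(sv.standardized)[mask])
        for protein in protein_ids:
            y = _standardized(cohort[protein].to_numpy(float))
            res = linear_assoc(y, x, covar, score_id=sv.score_id, protein_id=protein)
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def run_scan(cohort: pd.DataFrame, scores, protein_ids=None,
             alpha: float = 0.05, extra=None) -> ScanReport:
    """Two-stage scan: discovery Bonferroni, within-score replication FDR.

    ``cohort`` must already exclude prevalent-disease samples (see
    :func:`filter_prevalent`). Replication is attempted only for
    discovery-significant pairs; q-values are computed separately within
    each score, never pooled, and a pair replicates iff q < 0.05.
    """
    if protein_ids is None:
        protein_ids = [c for c in cohort.columns if c.startswith("prot_")]
    cohort = cohort.reset_index(drop=True)
    disc = cohort[cohort["stratum"] == "discovery"]
    repl = cohort[cohort["stratum"] == "replication"]
    if len(disc) == 0:
        raise EmptyCohortError("discovery stratum is empty")
    threshold = bonferroni_threshold(alpha, max(1, len(scores)), len(protein_ids))

    discovery = _scan_stage(disc, scores, protein_ids, extra={
        k: np.asarray(v)[disc.index] for k, v in extra.items()} if extra else None)
    discovery["significant"] = discovery["pval"] < threshold

    hits = discovery[discovery["significant"]]
    if hits.empty or repl.empty:
        replication = pd.DataFrame(columns=list(discovery.columns) + ["qval", "replicated"])
    else:
        parts = []
        for score_id, grp in hits.groupby("score_id", sort=False):
            sv = next(s for s in scores if s.score_id == score_id)
            stage = _scan_stage(repl, [sv], list(grp["protein_id"]), extra={
                k: np.asarray(v)[repl.index] for k, v in extra.items()} if extra else None)
            stage["qval"] = bh_fdr(stage["pval"])
            parts.append(stage)
        replication = pd.concat(parts, ignore_index=True)
        replication["replicated"] = replication["qval"] < 0.05
    return ScanReport(discovery=discovery, replication=replication,
                      bonferroni_threshold=threshold, alpha=alpha)


def adjusted_scan(cohort: pd.DataFrame, scores, mode: str,
                  protein_ids=None, alpha: float = 0.05,
                  pqtl_dosages: pd.DataFrame | None = None,
                  base_report: ScanReport | None = None) -> ScanReport:
    """Re-run the scan with extra covariates and classify each pair.

    ``mode`` is one of {"bmi", "wc", "whr", "pqtl"}; "pqtl" requires a
    sample x variant dosage frame of independent cis/trans pQTLs. Pairs
    are classified against the unadjusted discovery stage as
    still_significant or attenuated_to_nonsignificance; pairs significant
    only after adjustment are flagged (gained_after_adjustment) and
    excluded from headline counts to avoid collider bias.
    """
    if protein_ids is None:
        protein_ids = [c for c in cohort.columns if c.startswith("prot_")]
    if mode in ("bmi", "wc", "whr"):
        extra = {mode: cohort[mode].to_numpy(float)}
    elif mode == "pqtl":
        if pqtl_dosages is None:
            raise ValueError("mode='pqtl' requires pqtl_dosages")
        extra = {str(c): pqtl_dosages[c].to_numpy(float) for c in pqtl_dosages.columns}
    else:
        raise ValueError(f"unknown adjustment mode {mode!r}")
    if base_report is None:
        base_report = run_scan(cohort, scores, protein_ids, alpha=alpha)
    adj = run_scan(cohort, scores, protein_ids, alpha=alpha, extra=extra)

    base = base_report.discovery.set_index(["score_id", "protein_id"])
    new = adj.discovery.set_index(["score_id", "protein_id"])
    flags = []
    for key in new.index:
        was = bool(base.loc[key, "significant"]) if key in base.index else False
        now = bool(new.loc[key, "significant"])
        if was and now:
            status = "still_significant"
        elif was and not now:
            status = "attenuated_to_nonsignificance"
        elif not was and now:
            status = "gained_after_adjustment"
        else:
            status = "nonsignificant"
        flags.append((key[0], key[1], status))
    adj.flags = pd.DataFrame(flags, columns=["score_id", "protein_id", "status"])
    return adj


def compare_betas(results_a: pd.DataFrame, results_b: pd.DataFrame,
                  subset: str = "all", threshold: float | None = None):
    """Pearson correlation and OLS slope of beta_b on beta_a over matched proteins.

    ``subset='significant_only'`` restricts to pairs significant in table a
    (column 'significant' or pval < threshold).
    """
    merged = results_a.merge(results_b, on="protein_id", suffixes=("_a", "_b"))
    if subset == "significant_only":
        if "significant_a" in merged.columns:
            merged = merged[merged["significant_a"]]
        elif threshold is not None:
            merged = merged[merged["pval_a"] < threshold]
        else:
            raise ValueError("significant_only needs a 'significant' column or threshold")
    if len(merged) < 3:
        raise InsufficientDataError(f"only {len(merged)} matched pairs")
    a = merged["beta_a"].to_numpy(float)
    b = merged["beta_b"].to_numpy(float)
    r, pval = stats.pearsonr(a, b)
    slope = float(np.polyfit(a, b, 1)[0])
    return float(r), slope, float(pval)
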