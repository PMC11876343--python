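"""Two-sample, multivariable, and reverse Mendelian randomisation.

Implements the standard summary-statistics estimators — Wald ratio,
fixed-effect IVW, simple and weighted median, MR-Egger — plus instrument
QC (F-statistic, pleiotropy hit-count, minimum cis instrument count), a
median-p consensus rule over the four estimators with an Egger-intercept
pleiotropy gate, MVMR with conditional F and Q heterogeneity gates, and
reverse MR built on LD clumping of the trait GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import bh_fdr
from .errors import (CollinearityError, InsufficientInstrumentsError,
                     NoOverlapError)
from .scoring import ClumpParams, clump

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
PALINDROME_EAF_LIMIT = 0.42


@dataclass
class MRFit:
    method: str
    estimate: float
    se: float
    pval: float
    n_instruments: int
    cochran_q: float | None = None
    cochran_q_p: float | None = None


@dataclass
class MVMRFit:
    estimates: dict          # exposure -> estimate
    ses: dict
    pvals: dict
    conditional_f: dict
    q_pleiotropy: float
    q_pleiotropy_p: float
    n_instruments: int
    retained: bool


@dataclass
class MRConsensus:
    protein_id: str
    outcome_id: str
    fits: dict               # method -> MRFit
    median_p: float
    pleiotropy_flag: bool
    fdr_q: float | None = None
    bonferroni_sig: bool | None = None
    significant: bool | None = None
    skip_reason: str | None = None


# ---------------------------------------------------------------------------
# harmonization and QC
# ---------------------------------------------------------------------------

def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Align outcome effect alleles to the exposure orientation.

    Outcome betas are sign-flipped (and EAF complemented) where the allele
    labels are swapped; palindromic (A/T, C/G) variants are dropped when
    the minor-allele frequency is ambiguous (min(eaf, 1-eaf) > 0.42 on
    either side), otherwise aligned by frequency; irreconcilable allele
    pairs are dropped.
    """
    merged = exposure.merge(outcome, on="variant_id", suffixes=("_exp", "_out"))
    merged = merged.dropna(subset=["beta_exp", "se_exp", "beta_out", "se_out"])
    if merged.empty:
        raise NoOverlapError("no shared variants between exposure and outcome")
    rows = []
    for r in merged.itertuples(index=False):
        ea_x, oa_x = r.effect_allele_exp, r.other_allele_exp
        ea_y, oa_y = r.effect_allele_out, r.other_allele_out
        beta_y, eaf_y = r.beta_out, r.eaf_out
        palindromic = (ea_x, oa_x) in _PALINDROMIC
        if palindromic:
            amb_x = min(r.eaf_exp, 1 - r.eaf_exp) > PALINDROME_EAF_LIMIT
            amb_y = min(eaf_y, 1 - eaf_y) > PALINDROME_EAF_LIMIT
            if amb_x or amb_y:
                continue
            # align by frequency: same minor side means same orientation
            if (r.eaf_exp < 0.5) != (eaf_y < 0.5):
                beta_y, eaf_y = -beta_y, 1 - eaf_y
        elif (ea_y, oa_y) == (ea_x, oa_x):
            pass
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_y, eaf_y = -beta_y, 1 - eaf_y
        else:
            continue
        rows.append(dict(
            variant_id=r.variant_id, effect_allele=ea_x, other_allele=oa_x,
            beta_exposure=r.beta_exp, se_exposure=r.se_exp,
            beta_outcome=beta_y, se_outcome=r.se_out,
            eaf_exposure=r.eaf_exp, eaf_outcome=eaf_y,
            f_stat=(r.beta_exp / r.se_exp) ** 2))
    if not rows:
        raise NoOverlapError("no harmonizable variants")
    return pd.DataFrame(rows)


def instrument_qc(instruments: pd.DataFrame, f_min: float = 10.0,
                  pleiotropy_max: int = 4, min_cis: int = 3,
                  cis_only: bool = False) -> tuple[pd.DataFrame, str | None]:
    """Instrument filters: weak (F < f_min) and pleiotropic
    (pQTL for > pleiotropy_max proteins) instruments are dropped.

    Columns ``n_proteins_hit`` and ``is_cis`` are honoured when present.
    Returns (filtered instruments, skip_reason); skip_reason is set when
    cis-only mode retains fewer than ``min_cis`` cis instruments.
    """
    out = instruments.copy()
    out = out[out["f_stat"] >= f_min]
    if "n_proteins_hit" in out.columns:
        out = out[out["n_proteins_hit"].fillna(1) <= pleiotropy_max]
    skip = None
    if cis_only:
        if "is_cis" in out.columns:
            out = out[out["is_cis"].astype(bool)]
        if len(out) < min_cis:
            skip = f"only {len(out)} cis instruments after QC (need >= {min_cis})"
    return out.reset_index(drop=True), skip


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(instruments: pd.DataFrame) -> MRFit:
    """Single-instrument ratio estimate beta_y/beta_x with first-order SE."""
    r = instruments.iloc[0]
    est = r["beta_outcome"] / r["beta_exposure"]
    se = r["se_outcome"] / abs(r["beta_exposure"])
    z = est / se
    return MRFit("wald", float(est), float(se), float(2 * stats.norm.sf(abs(z))), 1)


def ivw(instruments: pd.DataFrame) -> MRFit:
    """Fixed-effect inverse-variance-weighted estimate.

    Weighted least squares of beta_y on beta_x through the origin with
    weights 1/se_y^2; Cochran's Q reported for heterogeneity.
    """
    if len(instruments) < 1:
        raise InsufficientInstrumentsError("IVW needs >= 1 instrument")
    if len(instruments) == 1:
        return wald_ratio(instruments)
    bx = instruments["beta_exposure"].to_numpy(float)
    by = instruments["beta_outcome"].to_numpy(float)
    sy2 = instruments["se_outcome"].to_numpy(float) ** 2
    denom = np.sum(bx ** 2 / sy2)
    est = np.sum(bx * by / sy2) / denom
    se = np.sqrt(1.0 / denom)
    q = float(np.sum((by - est * bx) ** 2 / sy2))
    qp = float(stats.chi2.sf(q, len(bx) - 1))
    z = est / se
    return MRFit("ivw", float(est), float(se), float(2 * stats.norm.sf(abs(z))),
                 len(bx), cochran_q=q, cochran_q_p=qp)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: cumulative p_j = (S_j - w_j/2) / W."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cum = np.cumsum(w) - w / 2.0
    p = cum / w.sum()
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def median_mr(instruments: pd.DataFrame, weighted: bool = True,
              n_boot: int = 1000, seed: int = 0) -> MRFit:
    """Simple or weighted median of the per-instrument Wald ratios.

    The weighted form uses weights beta_x^2 / se_y^2; the SE comes from a
    parametric bootstrap resampling (beta_x, beta_y) from their sampling
    distributions.
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError("median estimators need >= 3 instruments")
    bx = instruments["beta_exposure"].to_numpy(float)
    by = instruments["beta_outcome"].to_numpy(float)
    sx = instruments["se_exposure"].to_numpy(float)
    sy = instruments["se_outcome"].to_numpy(float)

    def estimate(bx_, by_):
        ratios = by_ / bx_
        w = (bx_ ** 2 / sy ** 2) if weighted else np.ones_like(ratios)
        return _weighted_median(ratios, w)

    est = estimate(bx, by)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = estimate(bx + sx * rng.standard_normal(len(bx)),
                            by + sy * rng.standard_normal(len(by)))
    se = float(boots.std(ddof=1))
    z = est / se if se > 0 else np.inf
    return MRFit("weighted_median" if weighted else "simple_median",
                 float(est), se, float(2 * stats.norm.sf(abs(z))), len(bx))


def egger(instruments: pd.DataFrame) -> tuple[MRFit, MRFit]:
    """MR-Egger: WLS of beta_y on beta_x with intercept, weights 1/se_y^2.

    Instruments are oriented so all beta_x >= 0. The slope is the causal
    estimate; the intercept t-test (df = J - 2) is the directional
    pleiotropy test.
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    bx = instruments["beta_exposure"].to_numpy(float).copy()
    by = instruments["beta_outcome"].to_numpy(float).copy()
    sy = instruments["se_outcome"].to_numpy(float)
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    theta = np.linalg.solve(XtWX, WX.T @ by)
    resid = by - X @ theta
    dof = len(bx) - 2
    sigma2 = float(np.sum(w * resid ** 2) / dof)
    cov = np.linalg.inv(XtWX) * sigma2
    se0, se1 = np.sqrt(np.diag(cov))
    t0, t1 = theta[0] / se0, theta[1] / se1
    slope = MRFit("egger_slope", float(theta[1]), float(se1),
                  float(2 * stats.t.sf(abs(t1), dof)), len(bx))
    intercept = MRFit("egger_intercept", float(theta[0]), float(se0),
                      float(2 * stats.t.sf(abs(t0), dof)), len(bx))
    return slope, intercept


def run_methods(instruments: pd.DataFrame, seed: int = 0) -> dict:
    """All four estimators plus the Egger intercept, keyed by method name."""
    fits = {"ivw": ivw(instruments)}
    fits["simple_median"] = median_mr(instruments, weighted=False, seed=seed)
    fits["weighted_median"] = median_mr(instruments, weighted=True, seed=seed + 1)
    slope, intercept = egger(instruments)
    fits["egger_slope"] = slope
    fits["egger_intercept"] = intercept
    return fits


def consensus(per_protein_fits: dict, outcome_id: str,
              bonferroni_alpha: float = 0.05,
              n_methods: int = 4) -> list[MRConsensus]:
    """Median-p consensus over {simple_median, weighted_median, ivw,
    egger_slope} with the Egger-intercept pleiotropy gate.

    The median of the four p-values is the even-count median (mean of the
    2nd and 3rd order statistics). BH FDR is applied across proteins; the
    Bonferroni family is proteins x methods. Pleiotropy-flagged proteins
    (Egger intercept p < 0.05) are excluded from the significant set.
    """
    records = []
    for protein_id, fits in per_protein_fits.items():
        if fits is None or isinstance(fits, str):
            records.append(MRConsensus(protein_id, outcome_id, {}, np.nan,
                                       False, skip_reason=fits or "skipped"))
            continue
        ps = [fits[m].pval for m in ("simple_median", "weighted_median",
                                     "ivw", "egger_slope")]
        median_p = float(np.median(ps))
        flag = fits["egger_intercept"].pval < 0.05
        records.append(MRConsensus(protein_id, outcome_id, fits, median_p, bool(flag)))
    tested = [r for r in records if r.skip_reason is None]
    if tested:
        qs = bh_fdr([r.median_p for r in tested])
        bonf = bonferroni_alpha / (len(tested) * n_methods)
        for r, q in zip(tested, qs):
            r.fdr_q = float(q)
            r.bonferroni_sig = r.median_p < bonf
            r.significant = bool(q < 0.05 and not r.pleiotropy_flag)
    return records


def consensus_table(records: list[MRConsensus]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = dict(protein_id=r.protein_id, outcome_id=r.outcome_id,
                   median_p=r.median_p, pleiotropy_flag=r.pleiotropy_flag,
                   fdr_q=r.fdr_q, bonferroni_sig=r.bonferroni_sig,
                   significant=r.significant, skip_reason=r.skip_reason)
        for m, fit in (r.fits or {}).items():
            row[f"{m}_est"] = fit.estimate
            row[f"{m}_se"] = fit.se
            row[f"{m}_p"] = fit.pval
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multivariable MR
# ---------------------------------------------------------------------------

def mvmr(instruments: pd.DataFrame,
         exposures: tuple[str, str] = ("protein", "bmi")) -> MVMRFit:
    """Two-exposure MVMR by WLS of beta_y on both exposure betas (no
    intercept, weights 1/se_y^2).

    Gates follow instrument-strength practice: retained iff both
    conditional F > 10 and the pleiotropy Q-statistic (df = J - 2) has
    p > 0.05. Conditional F for exposure k is the weighted residual sum of
    squares of its instrument betas regressed on the other exposure's
    betas, divided by (J - 1).
    """
    cols = [f"beta_{e}" for e in exposures]
    se_cols = [f"se_{e}" for e in exposures]
    J = len(instruments)
    if J < 3:
        raise InsufficientInstrumentsError("MVMR needs >= 3 instruments")
    B = instruments[cols].to_numpy(float)
    by = instruments["beta_outcome"].to_numpy(float)
    sy2 = instruments["se_outcome"].to_numpy(float) ** 2
    w = 1.0 / sy2
    XtWX = (B * w[:, None]).T @ B
    if np.linalg.cond(XtWX) > 1e12:
        raise CollinearityError(cols, "proportional instrument effects across exposures")
    theta = np.linalg.solve(XtWX, (B * w[:, None]).T @ by)
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    z = theta / se
    pvals = 2 * stats.norm.sf(np.abs(z))

    resid = by - B @ theta
    q = float(np.sum(w * resid ** 2))
    q_p = float(stats.chi2.sf(q, J - 2))

    cond_f = {}
    for k, exp_k in enumerate(exposures):
        other = B[:, 1 - k]
        bx = B[:, k]
        sx2 = instruments[se_cols[k]].to_numpy(float) ** 2
        wk = 1.0 / sx2
        denom = np.sum(wk * other ** 2)
        delta = np.sum(wk * other * bx) / denom if denom > 0 else 0.0
        rk = bx - delta * other
        cond_f[exp_k] = float(np.sum(wk * rk ** 2) / (J - 1))

    retained = all(f > 10 for f in cond_f.values()) and q_p > 0.05
    return MVMRFit(
        estimates={e: float(t) for e, t in zip(exposures, theta)},
        ses={e: float(s) for e, s in zip(exposures, se)},
        pvals={e: float(p) for e, p in zip(exposures, pvals)},
        conditional_f=cond_f, q_pleiotropy=q, q_pleiotropy_p=q_p,
        n_instruments=J, retained=bool(retained))


# ---------------------------------------------------------------------------
# reverse MR
# ---------------------------------------------------------------------------

REVERSE_CLUMP = ClumpParams(p_threshold=5e-8, r2_threshold=0.001, window_kb=500.0)


def reverse_mr(trait_sumstats: pd.DataFrame, protein_sumstats: dict,
               ld_source, clump_params: ClumpParams | None = None,
               seed: int = 0) -> list[MRConsensus]:
    """Trait -> protein MR: clump the trait GWAS for instruments, then run
    the four-method pipeline against each protein's summary statistics.
    """
    params = clump_params or REVERSE_CLUMP
    index_set = clump(trait_sumstats, ld_source, params)
    if len(index_set) == 0:
        return [MRConsensus(p, "trait", {}, np.nan, False,
                            skip_reason="no genome-wide-significant trait variants")
                for p in protein_sumstats]
    exposure = trait_sumstats[trait_sumstats["variant_id"].isin(
        index_set.table["variant_id"])]
    fits = {}
    for protein_id, ss in protein_sumstats.items():
        try:
            inst = harmonize(exposure, ss)
            inst, skip = instrument_qc(inst)
            if skip or len(inst) < 3:
                fits[protein_id] = skip or f"only {len(inst)} instruments"
                continue
            fits[protein_id] = run_methods(inst, seed=seed)
        except (NoOverlapError, InsufficientInstrumentsError) as exc:
            fits[protein_id] = str(exc)
    return consensus(fits, outcome_id="trait_to_protein")


def meta_analyze(stats_list: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis of per-stratum summary
    statistics sharing variant orientation (pan-ancestry sensitivity MR)."""
    base = stats_list[0][["variant_id", "chrom", "pos",
                          "effect_allele", "other_allele"]].copy()
    w_sum = np.zeros(len(base))
    bw_sum = np.zeros(len(base))
    eaf = np.zeros(len(base))
    n_tot = np.zeros(len(base))
    for ss in stats_list:
        ss = ss.set_index("variant_id").loc[base["variant_id"]]
        w = 1.0 / ss["se"].to_numpy(float) ** 2
        w_sum += w
        bw_sum += w * ss["beta"].to_numpy(float)
        n = ss["n"].to_numpy(float)
        eaf += ss["eaf"].to_numpy(float) * n
        n_tot += n
    beta = bw_sum / w_sum
    se = np.sqrt(1.0 / w_sum)
    out = base
    out["eaf"] = eaf / n_tot
    out["beta"] = beta
    out["se"] = se
    out["pval"] = 2 * stats.norm.sf(np.abs(beta / se))
    out["n"] = n_tot.astype(int)
    out["trait_type"] = stats_list[0]["trait_type"].iloc[0]
    out["case_prop"] = stats_list[0]["case_prop"].iloc[0]
    return out
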