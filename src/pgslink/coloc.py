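"""Approximate-Bayes-factor colocalization under a single causal variant.

For each variant the Wakefield log approximate Bayes factor summarises
the evidence for association; per-region sums in log space give posterior
probabilities for the five hypotheses H0 (no association), H1/H2 (one
trait only), H3 (two distinct causal variants) and H4 (one shared causal
variant), under per-variant priors p1, p2 and p12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import InsufficientOverlapError

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
PRIOR_SD_QUANT = 0.15   # per-SD effect prior for quantitative traits (x sdY)
PRIOR_SD_CC = 0.20      # log-odds effect prior for case-control traits


@dataclass
class ColocPosterior:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_variants: int
    priors: tuple
    log_abf_sums: tuple = ()

    def as_array(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


def wakefield_labf(beta, se, prior_sd) -> np.ndarray:
    """log ABF = 0.5 * (ln(V/(V+W)) + z^2 * W/(V+W)) with V = se^2, W = prior_sd^2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        raise ValueError("non-finite beta/se")
    if np.any(se <= 0) or prior_sd <= 0:
        raise ValueError("se and prior_sd must be > 0")
    V = se ** 2
    W = float(prior_sd) ** 2
    z2 = (beta / se) ** 2
    return 0.5 * (np.log(V / (V + W)) + z2 * W / (V + W))


def _prior_sd(region: pd.DataFrame) -> float:
    trait_type = str(region["trait_type"].iloc[0]) if "trait_type" in region else "quant"
    if trait_type == "cc":
        return PRIOR_SD_CC
    sdY = float(region["sdY"].iloc[0]) if "sdY" in region else 1.0
    return PRIOR_SD_QUANT * sdY


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)); -inf when the difference underflows."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc(region1: pd.DataFrame, region2: pd.DataFrame,
          priors: tuple = DEFAULT_PRIORS,
          labf1=None, labf2=None) -> ColocPosterior:
    """Colocalization posterior for two traits over shared variants.

    ``region1``/``region2`` are per-variant summary statistics (variant_id,
    beta, se, optionally trait_type/sdY); pre-computed log ABFs may be
    supplied instead via ``labf1``/``labf2`` (aligned, equal length).
    """
    p1, p2, p12 = priors
    if labf1 is None or labf2 is None:
        merged = region1.merge(region2, on="variant_id", suffixes=("_1", "_2"))
        if len(merged) < 2:
            raise InsufficientOverlapError(
                f"only {len(merged)} shared variants between regions")
        labf1 = wakefield_labf(merged["beta_1"], merged["se_1"], _prior_sd(region1))
        labf2 = wakefield_labf(merged["beta_2"], merged["se_2"], _prior_sd(region2))
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if len(labf1) != len(labf2):
        raise ValueError("log ABF vectors must be aligned")
    L1 = logsumexp(labf1)
    L2 = logsumexp(labf2)
    L12 = logsumexp(labf1 + labf2)
    lw = np.array([
        0.0,
        np.log(p1) + L1,
        np.log(p2) + L2,
        np.log(p1) + np.log(p2) + _logdiff(L1 + L2, L12),
        np.log(p12) + L12,
    ])
    pp = np.exp(lw - logsumexp(lw))
    pp = pp / pp.sum()
    return ColocPosterior(*pp, n_variants=len(labf1), priors=tuple(priors),
                          log_abf_sums=(float(L1), float(L2), float(L12)))


def coloc_decision(post: ColocPosterior) -> bool:
    """Strong colocalization: PP.H3 + PP.H4 > 0.99 and PP.H4/PP.H3 > 5
    (ratio treated as +inf when PP.H3 = 0)."""
    if post.pp_h3 + post.pp_h4 <= 0.99:
        return False
    if post.pp_h3 == 0.0:
        return post.pp_h4 > 0.99
    return post.pp_h4 / post.pp_h3 > 5.0


def select_regions(gwas1: pd.DataFrame, gwas2: pd.DataFrame,
                   p_threshold: float = 1e-6,
                   window_kb: float = 250.0) -> list[tuple]:
    """Region pairs seeded by variants passing p < threshold in BOTH GWAS.

    Each seed variant spawns a +/- window_kb interval (1-based inclusive);
    overlapping seed intervals on the same chromosome are merged. Returns
    a list of (chrom, start, end) tuples.
    """
    m = gwas1.merge(gwas2, on="variant_id", suffixes=("_1", "_2"))
    seeds = m[(m["pval_1"] < p_threshold) & (m["pval_2"] < p_threshold)]
    if seeds.empty:
        return []
    w = int(window_kb * 1000)
    intervals = sorted((int(r.chrom_1), max(1, int(r.pos_1) - w), int(r.pos_1) + w)
                       for r in seeds.itertuples(index=False))
    merged = [list(intervals[0])]
    for chrom, start, end in intervals[1:]:
        last = merged[-1]
        if chrom == last[0] and start <= last[2]:
            last[2] = max(last[2], end)
        else:
            merged.append([chrom, start, end])
    return [tuple(iv) for iv in merged]


def region_slice(sumstats: pd.DataFrame, chrom, start, end) -> pd.DataFrame:
    """Variants of one region, bounds inclusive."""
    s = sumstats
    return s[(s["chrom"] == chrom) & (s["pos"] >= start) & (s["pos"] <= end)].copy()
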