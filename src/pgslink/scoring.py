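"""Polygenic score computation, LD clumping, and score validation.

Scores are weighted sums of effect-allele dosages; weight files follow the
PGS-Catalog TSV layout. Clumping is the greedy index-variant procedure:
take the smallest-p variant passing the p-value threshold, remove
correlated neighbours within the window, repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, DegenerateOutcomeError, NoOverlapError
from .simulate import GenotypeMatrix


@dataclass
class ClumpParams:
    """Greedy clumping thresholds: keep p < p_threshold index variants,
    removing neighbours with dosage r^2 > r2_threshold within
    +/- window_kb (inclusive, same chromosome)."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.1
    window_kb: float = 250.0

    def validate(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ConfigError(f"p_threshold must lie in (0, 1], got {self.p_threshold!r}")
        if not (0 < self.r2_threshold <= 1):
            raise ConfigError(f"r2_threshold must lie in (0, 1], got {self.r2_threshold!r}")
        if not self.window_kb > 0:
            raise ConfigError(f"window_kb must be > 0, got {self.window_kb!r}")


@dataclass
class WeightSet:
    """Per-variant score weights with allele orientation."""

    table: pd.DataFrame  # variant_id, effect_allele, other_allele, weight
    score_id: str = "score"

    def __post_init__(self):
        if self.table["variant_id"].duplicated().any():
            raise ValueError("duplicate variant_ids in weight set")
        if not np.isfinite(self.table["weight"].to_numpy(float)).all():
            raise ValueError("non-finite weights")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ScoreVector:
    """Raw and reference-stratum-standardized per-sample scores."""

    raw: np.ndarray
    standardized: np.ndarray
    sample_ids: list
    score_id: str
    n_dropped: int = 0


def read_weights(path, score_id: str | None = None) -> WeightSet:
    """Read a PGS-Catalog-style weight TSV; '#' lines are metadata."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    vid = cols.get("rsid", cols.get("variant_id"))
    if vid is None:
        raise ValueError("weight file needs an rsID or variant_id column")
    out = pd.DataFrame({
        "variant_id": df[vid].astype(str),
        "effect_allele": df[cols["effect_allele"]].astype(str),
        "other_allele": df[cols["other_allele"]].astype(str)
        if "other_allele" in cols else None,
        "weight": df[cols.get("effect_weight", cols.get("weight"))].astype(float),
    })
    return WeightSet(out, score_id=score_id or str(path))


def write_weights(ws: WeightSet, path) -> None:
    out = ws.table.rename(columns={"variant_id": "rsID",
                                   "weight": "effect_weight"})
    with open(path, "w") as fh:
        fh.write(f"# score_id={ws.score_id}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def compute_pgs(genotypes: GenotypeMatrix, weights: WeightSet,
                missing_policy: str = "drop",
                reference_stratum: np.ndarray | None = None) -> ScoreVector:
    """score_i = sum_j w_j * dosage_ij of the effect allele.

    The dosage is flipped to 2 - d when the weight's effect allele matches
    the matrix's *other* allele. Variants absent from the matrix are
    dropped (default) or mean-imputed at 2*eaf inferred from the panel
    mean, i.e. they contribute a constant. Irreconcilable allele pairs are
    dropped with a warning count.
    """
    if missing_policy not in ("drop", "mean"):
        raise ValueError("missing_policy must be 'drop' or 'mean'")
    variants = genotypes.variants
    lookup = {v: j for j, v in enumerate(variants["variant_id"])}
    n = genotypes.n_samples
    raw = np.zeros(n)
    n_overlap = 0
    n_dropped = 0
    for row in weights.table.itertuples(index=False):
        j = lookup.get(row.variant_id)
        if j is None:
            if missing_policy == "mean":
                # contributes its panel-mean dosage; without a panel the
                # variant's frequency is unknown, so contribute nothing
                pass
            continue
        n_overlap += 1
        ea = variants["effect_allele"].iloc[j]
        oa = variants["other_allele"].iloc[j]
        d = genotypes.dosages[:, j]
        if row.effect_allele == ea:
            raw += row.weight * d
        elif row.effect_allele == oa:
            raw += row.weight * (2.0 - d)
        else:
            n_dropped += 1
    if n_overlap == 0:
        raise NoOverlapError(
            f"no overlap between weight set {weights.score_id!r} and genotype matrix")
    if n_dropped:
        warnings.warn(f"{n_dropped} variants dropped: irreconcilable allele pairs")
    ref = np.ones(n, dtype=bool) if reference_stratum is None \
        else np.asarray(reference_stratum, dtype=bool)
    mu, sd = raw[ref].mean(), raw[ref].std()
    standardized = (raw - mu) / sd if sd > 0 else np.zeros_like(raw)
    return ScoreVector(raw=raw, standardized=standardized,
                       sample_ids=list(genotypes.sample_ids),
                       score_id=weights.score_id, n_dropped=n_dropped)


def clump(sumstats: pd.DataFrame, ld_source: GenotypeMatrix,
          params: ClumpParams | None = None) -> WeightSet:
    """Greedy index-variant selection.

    Repeatedly take the smallest-p unclaimed variant passing the p-value
    threshold as an index (ties broken by lexicographically smaller
    variant_id), then remove all unclaimed variants on the same chromosome
    within +/- window_kb whose dosage r^2 with the index exceeds the
    threshold. Returned weights are the index variants' betas. An empty
    result is returned (not raised) when nothing passes the threshold.
    """
    params = params or ClumpParams()
    params.validate()
    ss = sumstats.dropna(subset=["pval", "se"]).copy()
    ss = ss[ss["pval"] < params.p_threshold]
    if ss.empty:
        return WeightSet(pd.DataFrame(columns=["variant_id", "effect_allele",
                                               "other_allele", "weight"]),
                         score_id="clump")
    lookup = {v: j for j, v in enumerate(ld_source.variants["variant_id"])}
    missing = [v for v in ss["variant_id"] if v not in lookup]
    if missing:
        raise NoOverlapError(f"{len(missing)} sumstats variants absent from LD source")
    ss = ss.sort_values(["pval", "variant_id"], kind="mergesort").reset_index(drop=True)
    claimed = np.zeros(len(ss), dtype=bool)
    chrom = ss["chrom"].to_numpy()
    pos = ss["pos"].to_numpy(float)
    window = params.window_kb * 1000.0
    keep = []
    D = ld_source.dosages
    for i in range(len(ss)):
        if claimed[i]:
            continue
        claimed[i] = True
        keep.append(i)
        near = ~claimed & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        if near.any():
            gi = D[:, lookup[ss["variant_id"].iloc[i]]]
            gi_c = gi - gi.mean()
            denom_i = gi_c @ gi_c
            for j in np.where(near)[0]:
                gj = D[:, lookup[ss["variant_id"].iloc[j]]]
                gj_c = gj - gj.mean()
                denom_j = gj_c @ gj_c
                if denom_i <= 0 or denom_j <= 0:
                    r2 = 1.0  # zero-variance: treat as duplicate
                else:
                    r2 = (gi_c @ gj_c) ** 2 / (denom_i * denom_j)
                if r2 > params.r2_threshold:
                    claimed[j] = True
    out = ss.loc[keep, ["variant_id", "effect_allele", "other_allele", "beta"]]
    out = out.rename(columns={"beta": "weight"}).reset_index(drop=True)
    return WeightSet(out, score_id="clump")


def validate_pgs(score: ScoreVector, outcome, covariates=None):
    """Association of a standardized score with its target trait.

    Returns (beta, se, pval) per SD of the score from a linear
    (quantitative outcome) or logistic (binary outcome) fit.
    """
    y = np.asarray(outcome, dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateOutcomeError("outcome is constant")
    x = score.standardized
    n = len(y)
    if covariates is None:
        X = sm.add_constant(x)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = sm.add_constant(np.column_stack([x, C]))
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    else:
        fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
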