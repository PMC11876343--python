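"""Synthetic cohort, GWAS, and trial generator with a recorded ground truth.

The generator plants a PGS -> BMI -> protein -> incident-disease mediation
chain, cis/trans pQTL architecture with Markov-chain LD inside regions,
non-overlapping exposure/outcome GWAS samples, colocalization regions with
shared or distinct causal variants, and trial-like censored survival with
protein-dependent hazards. Every nonzero planted effect is recorded in a
:class:`TruthLedger` so downstream stages can be tested for parameter
recovery rather than against opaque fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .config import SimConfig
from .errors import ConfigError

SUMSTATS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "trait_type", "case_prop",
]

_ALLELES = np.array(["A", "C", "G", "T"])


@dataclass
class GenotypeMatrix:
    """Per-sample allele dosages plus a variant annotation table.

    ``dosages`` is samples x variants with values in [0, 2]; ``variants``
    has one row per dosage column (variant_id, chrom, pos, effect_allele,
    other_allele, maf, region_id).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list

    def __post_init__(self):
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage columns must match variant rows")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return self.dosages[:, idx[0]]


@dataclass
class TruthLedger:
    """Generator-side record of every planted effect.

    Sufficient to compute the expected outcome of every downstream
    recovery test: cis/trans pQTL effects, PGS->protein paths and their
    mediated fractions, protein->disease log-odds, trial log hazard
    ratios, and the colocalization scenario of each cis region.
    """

    pgs_weights: dict = field(default_factory=dict)          # variant_id -> true weight
    gamma_bmi: float = 0.0                                   # PGS -> BMI (per SD)
    cis_effects: dict = field(default_factory=dict)          # protein -> {variant_id: beta}
    trans_effects: dict = field(default_factory=dict)        # protein -> {variant_id: beta}
    pgs_direct: dict = field(default_factory=dict)           # protein -> delta (direct path)
    bmi_path: dict = field(default_factory=dict)             # protein -> b (BMI -> protein)
    pgs_total: dict = field(default_factory=dict)            # protein -> delta + gamma*b
    mediated_fraction: dict = field(default_factory=dict)    # protein -> gamma*b / total
    disease_log_odds: dict = field(default_factory=dict)     # protein -> per-SD log-odds
    bmi_disease_log_odds: float = 0.0
    disease_intercept: float = 0.0
    trial_log_hr: dict = field(default_factory=dict)         # endpoint -> {protein: log-HR}
    coloc_scenario: dict = field(default_factory=dict)       # region_id -> shared|distinct|null
    distinct_disease_variants: dict = field(default_factory=dict)  # region_id -> variant_id
    confounded_trial_protein: str | None = None
    protein_ids: list = field(default_factory=list)

    def true_target_proteins(self) -> list:
        return [p for p, t in self.pgs_total.items() if abs(t) > 0]

    def causal_disease_proteins(self) -> list:
        return [p for p, b in self.disease_log_odds.items() if abs(b) > 0]

    def variant_protein_hits(self) -> dict:
        """variant_id -> number of proteins it has a planted effect on."""
        hits: dict[str, set] = {}
        for table in (self.cis_effects, self.trans_effects):
            for protein, effs in table.items():
                for vid in effs:
                    hits.setdefault(vid, set()).add(protein)
        return {vid: len(ps) for vid, ps in hits.items()}

    def to_json(self, path) -> None:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


# ---------------------------------------------------------------------------
# variant map and genotypes
# ---------------------------------------------------------------------------

def variant_map(config: SimConfig) -> pd.DataFrame:
    """Deterministic variant annotation shared by every sample draw.

    Each protein gets a cis region (``region_id = cis_<protein>``) of
    ``n_variants_per_cis_region`` variants around its TSS; the PGS block is
    ``pgs_n_variants`` mutually independent single-variant regions placed
    far from every cis region. Positions are strictly increasing within a
    chromosome.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    rows = []
    m = config.n_variants_per_cis_region
    spacing = 10_000
    for p in range(config.n_proteins):
        protein = f"prot_{p:03d}"
        chrom = (p % 22) + 1
        tss = 5_000_000 + (p // 22) * 10_000_000
        # variants in one LD block share a similar frequency: a regional
        # base MAF with small jitter keeps the target adjacent-dosage
        # correlation feasible for the binary Markov chain
        base_maf = rng.uniform(*config.maf_range)
        lo, hi = config.maf_range
        mafs = np.clip(base_maf + rng.uniform(-0.02, 0.02, size=m), lo, hi)
        for j in range(m):
            ea, oa = rng.choice(4, size=2, replace=False)
            rows.append((f"{protein}_v{j:02d}", chrom, tss - 100_000 + spacing * j,
                         _ALLELES[ea], _ALLELES[oa], mafs[j], f"cis_{protein}", protein))
    for j in range(config.pgs_n_variants):
        chrom = (j % 22) + 1
        pos = 150_000_000 + (j // 22) * 1_000_000
        maf = rng.uniform(*config.maf_range)
        ea, oa = rng.choice(4, size=2, replace=False)
        rows.append((f"pgs_v{j:03d}", chrom, pos, _ALLELES[ea], _ALLELES[oa],
                     maf, f"pgs_{j:03d}", ""))
    df = pd.DataFrame(rows, columns=[
        "variant_id", "chrom", "pos", "effect_allele", "other_allele",
        "maf", "region_id", "cis_protein"])
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def _markov_haplotypes(rng, mafs, rho, n):
    """n haplotypes over len(mafs) sites with adjacent-allele correlation rho.

    Binary first-order Markov chain: transition probabilities are derived
    from the bivariate Bernoulli covariance rho*sqrt(p1 q1 p2 q2) and
    clipped to [0, 1] where the exact target is infeasible for a given
    marginal pair.
    """
    k = len(mafs)
    h = np.empty((n, k), dtype=np.int8)
    h[:, 0] = rng.random(n) < mafs[0]
    for t in range(1, k):
        m_prev, m_cur = mafs[t - 1], mafs[t]
        cov = rho * np.sqrt(m_prev * (1 - m_prev) * m_cur * (1 - m_cur))
        p_given1 = np.clip(m_cur + cov / m_prev, 0.0, 1.0)
        p_given0 = np.clip(m_cur - cov / (1 - m_prev), 0.0, 1.0)
        u = rng.random(n)
        h[:, t] = np.where(h[:, t - 1] == 1, u < p_given1, u < p_given0)
    return h


def simulate_genotypes(config: SimConfig, n_samples: int | None = None,
                       subseed: int = 0, sample_prefix: str = "S") -> GenotypeMatrix:
    """Draw dosages for ``n_samples`` (default: discovery + replication).

    Haplotypes are Markov chains within each region and independent across
    regions; dosage is the sum of two independent haplotypes, so the
    adjacent-variant dosage correlation targets ``ld_rho``. ``subseed``
    selects an independent sample draw over the same variant map (used for
    the non-overlapping GWAS samples).
    """
    config.validate()
    if n_samples is None:
        n_samples = config.n_discovery + config.n_replication
    variants = variant_map(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202, subseed]))
    dosages = np.empty((n_samples, len(variants)), dtype=np.float64)
    for region_id, idx in variants.groupby("region_id", sort=False).groups.items():
        idx = np.asarray(idx)
        order = np.argsort(variants.loc[idx, "pos"].to_numpy())
        idx = idx[order]
        mafs = variants.loc[idx, "maf"].to_numpy()
        h1 = _markov_haplotypes(rng, mafs, config.ld_rho, n_samples)
        h2 = _markov_haplotypes(rng, mafs, config.ld_rho, n_samples)
        dosages[:, idx] = (h1 + h2).astype(np.float64)
    sample_ids = [f"{sample_prefix}{i:06d}" for i in range(n_samples)]
    return GenotypeMatrix(dosages=dosages, variants=variants, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _standardized(x):
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _true_pgs(genotypes: GenotypeMatrix, weights: dict) -> np.ndarray:
    vid = genotypes.variants["variant_id"].to_numpy()
    w = np.array([weights.get(v, 0.0) for v in vid])
    return genotypes.dosages @ w


def make_truth(config: SimConfig) -> TruthLedger:
    """Draw all planted effect sizes (deterministic under config.seed)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    variants = variant_map(config)
    ledger = TruthLedger(gamma_bmi=config.gamma_bmi,
                         bmi_disease_log_odds=config.bmi_disease_log_odds)
    proteins = [f"prot_{p:03d}" for p in range(config.n_proteins)]
    ledger.protein_ids = proteins

    pgs_ids = variants.loc[variants["region_id"].str.startswith("pgs_"), "variant_id"]
    w = rng.normal(0.0, 1.0, size=len(pgs_ids))
    ledger.pgs_weights = dict(zip(pgs_ids, w / np.sqrt(len(pgs_ids))))

    # cis architecture: causal variants spread across the region so their
    # pairwise LD (rho^gap) is weak and sum of squared betas ~ cis h2
    m = config.n_variants_per_cis_region
    gap = max(1, m // config.n_causal_cis)
    causal_idx = list(range(gap // 2, m, gap))[: config.n_causal_cis]
    beta_cis = np.sqrt(config.protein_h2_cis / max(1, len(causal_idx)))
    for p, protein in enumerate(proteins):
        signs = rng.choice([-1.0, 1.0], size=len(causal_idx))
        ledger.cis_effects[protein] = {
            f"{protein}_v{j:02d}": float(s * beta_cis) for j, s in zip(causal_idx, signs)
        }

    # trans hub: one variant with effects on n_trans_hit proteins, exercising
    # the >=5-protein pleiotropy filter
    hub_idx = config.n_proteins // 2
    hub_protein = proteins[hub_idx]
    hub_vid = f"{hub_protein}_v{m // 2:02d}"
    beta_trans = np.sqrt(config.trans_h2)
    hit = 0
    for step in range(1, config.n_proteins):
        if hit >= config.n_trans_hit:
            break
        protein = proteins[(hub_idx + step) % config.n_proteins]
        ledger.trans_effects.setdefault(protein, {})[hub_vid] = float(beta_trans)
        hit += 1

    # PGS -> protein chain with the configured mediated fraction
    f = config.mediated_fraction
    tau = config.pgs_total_effect
    gamma = config.gamma_bmi
    for protein in proteins[: config.n_true_targets]:
        b = f * tau / gamma if gamma != 0 else 0.0
        delta = (1.0 - f) * tau
        ledger.bmi_path[protein] = float(b)
        ledger.pgs_direct[protein] = float(delta)
        ledger.pgs_total[protein] = float(delta + gamma * b)
        ledger.mediated_fraction[protein] = float(f if tau != 0 else 0.0)
    for protein in proteins[config.n_true_targets:]:
        ledger.bmi_path[protein] = 0.0
        ledger.pgs_direct[protein] = 0.0
        ledger.pgs_total[protein] = 0.0
        ledger.mediated_fraction[protein] = 0.0

    # disease: the first n_true_targets proteins are causal, completing the
    # PGS -> protein -> disease chain
    for protein in proteins:
        ledger.disease_log_odds[protein] = (
            float(config.disease_log_odds)
            if protein in proteins[: config.n_true_targets] else 0.0
        )

    # colocalization scenarios: causal-protein regions share their causal
    # variant with the disease; n_distinct_regions get a separate direct
    # disease variant; the rest are null on the disease side
    causal_set = set(proteins[: config.n_true_targets])
    distinct = [p for p in proteins if p not in causal_set][: config.n_distinct_regions]
    for protein in proteins:
        region = f"cis_{protein}"
        if protein in causal_set:
            ledger.coloc_scenario[region] = "shared"
        elif protein in distinct:
            ledger.coloc_scenario[region] = "distinct"
            # direct disease effect on a cis variant that is NOT a protein pQTL
            non_causal = [j for j in range(m) if j not in causal_idx]
            vid = f"{protein}_v{non_causal[len(non_causal) // 2]:02d}"
            ledger.distinct_disease_variants[region] = vid
        else:
            ledger.coloc_scenario[region] = "null"

    # trial endpoints: overlapping causal sets drawn from the disease-causal
    # proteins; one protein's hazard flows entirely through NT-proBNP
    k = config.n_trial_causal
    causal = proteins[: config.n_true_targets]
    ledger.trial_log_hr = {
        "mace": {p: float(config.trial_log_hr) for p in causal[:k]},
        "hhf": {p: float(config.trial_log_hr) for p in causal[max(0, k - 2): 2 * k - 2]},
        "renal": {p: float(config.trial_log_hr) for p in causal[-k:]},
    }
    ledger.confounded_trial_protein = proteins[config.n_true_targets] \
        if config.n_proteins > config.n_true_targets else None
    return ledger


def _variance_budget(config: SimConfig, ledger: TruthLedger, protein: str) -> float:
    delta = ledger.pgs_direct[protein]
    b = ledger.bmi_path[protein]
    gamma = ledger.gamma_bmi
    v_struct = delta ** 2 + b ** 2 + 2 * delta * b * gamma
    v_cis = sum(e ** 2 for e in ledger.cis_effects.get(protein, {}).values())
    v_trans = sum(e ** 2 for e in ledger.trans_effects.get(protein, {}).values())
    resid = 1.0 - v_struct - v_cis - v_trans
    if resid <= 0:
        raise ConfigError(
            f"variance components for {protein} exceed 1 "
            f"(structural {v_struct:.3f} + cis {v_cis:.3f} + trans {v_trans:.3f})")
    return resid


def _genetic_component(genotypes: GenotypeMatrix, effects: dict) -> np.ndarray:
    """Sum of per-variant effects on standardized dosages."""
    out = np.zeros(genotypes.n_samples)
    variants = genotypes.variants
    lookup = dict(zip(variants["variant_id"], range(len(variants))))
    for vid, beta in effects.items():
        j = lookup[vid]
        maf = variants["maf"].iloc[j]
        sd = np.sqrt(2 * maf * (1 - maf))
        out += beta * (genotypes.dosages[:, j] - 2 * maf) / sd
    return out


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    def gap(c):
        return special.expit(c + eta).mean() - prevalence
    return optimize.brentq(gap, -30.0, 30.0)


def simulate_cohort(config: SimConfig, genotypes: GenotypeMatrix,
                    ledger: TruthLedger | None = None,
                    subseed: int = 0) -> tuple[pd.DataFrame, TruthLedger]:
    """Phenotypes, proteins and disease status for the genotyped samples.

    BMI = gamma * PGS + noise; each protein is a sum of cis/trans pQTL
    effects, a direct PGS path, and a BMI path scaled so the PGS->protein
    total effect has the configured mediated fraction; incident disease is
    a logistic liability in causal proteins, BMI and covariates with the
    intercept calibrated to ``disease_prevalence``.
    """
    config.validate()
    if ledger is None:
        ledger = make_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404, subseed]))
    n = genotypes.n_samples

    pgs_raw = _true_pgs(genotypes, ledger.pgs_weights)
    pgs = _standardized(pgs_raw)
    gamma = ledger.gamma_bmi
    bmi = gamma * pgs + np.sqrt(max(1e-12, 1 - gamma ** 2)) * rng.normal(size=n)

    cohort = pd.DataFrame({
        "sample_id": genotypes.sample_ids,
        "age": rng.normal(57.0, 8.0, size=n),
        "sex": rng.integers(0, 2, size=n),
    })
    for k in range(1, 11):
        cohort[f"pc{k}"] = rng.normal(size=n)
    cohort["bmi"] = bmi
    cohort["wc"] = 0.8 * bmi + 0.6 * rng.normal(size=n)
    cohort["whr"] = 0.6 * bmi + 0.8 * rng.normal(size=n)

    protein_levels = {}
    for protein in ledger.protein_ids:
        g = _genetic_component(genotypes, ledger.cis_effects.get(protein, {}))
        g += _genetic_component(genotypes, ledger.trans_effects.get(protein, {}))
        resid_var = _variance_budget(config, ledger, protein)
        level = (ledger.pgs_direct[protein] * pgs
                 + ledger.bmi_path[protein] * bmi
                 + g
                 + np.sqrt(resid_var) * rng.normal(size=n))
        protein_levels[protein] = level
    cohort = pd.concat([cohort, pd.DataFrame(protein_levels, index=cohort.index)], axis=1)

    # disease liability: causal proteins + BMI + mild age/sex terms; for
    # 'distinct' coloc regions, an extra direct variant effect
    eta = ledger.bmi_disease_log_odds * bmi
    for protein, lor in ledger.disease_log_odds.items():
        if lor != 0.0:
            eta = eta + lor * _standardized(cohort[protein].to_numpy())
    for region, vid in ledger.distinct_disease_variants.items():
        eta = eta + 0.4 * _standardized(genotypes.column(vid))
    eta = eta + 0.01 * (cohort["age"].to_numpy() - 57.0) + 0.1 * cohort["sex"].to_numpy()
    intercept = _calibrate_intercept(eta, config.disease_prevalence)
    ledger.disease_intercept = float(intercept)
    p_dis = special.expit(intercept + eta)

    prevalent = rng.random(n) < config.disease_prevalence / 2.0
    incident = (rng.random(n) < p_dis) & ~prevalent
    cohort["prevalent_disease"] = prevalent.astype(int)
    cohort["incident_disease"] = incident.astype(int)
    cohort["followup_time"] = rng.uniform(5.0, 10.0, size=n)

    n_disc = min(config.n_discovery, n)
    cohort["stratum"] = np.where(np.arange(n) < n_disc, "discovery", "replication")
    return cohort, ledger


# ---------------------------------------------------------------------------
# trial
# ---------------------------------------------------------------------------

def simulate_trial(config: SimConfig, cohort: pd.DataFrame,
                   ledger: TruthLedger, endpoints=("mace", "hhf", "renal"),
                   reverse_causation: bool = False,
                   subseed: int = 0) -> pd.DataFrame:
    """Trial-like survival table from a simulated cohort.

    Event times are exponential with log-hazard = sum of causal protein
    effects (plus a clinical NT-proBNP pathway for the designated
    confounded protein); censoring is independent exponential dropout at
    ``censor_rate`` plus administrative end of follow-up. Two protein
    timepoints are recorded at the configured test-retest correlation;
    with ``reverse_causation`` the repeat measurement is inflated in
    subjects whose event occurs early.
    """
    config.validate()
    if config.censor_rate <= 0:
        raise ConfigError("censor_rate must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505, subseed]))
    n = len(cohort)
    trial = pd.DataFrame({
        "sample_id": cohort["sample_id"].to_numpy(),
        "arm": rng.integers(0, 2, size=n),
        "age": cohort["age"].to_numpy(),
        "sex": cohort["sex"].to_numpy(),
    })
    for k in range(1, 11):
        trial[f"pc{k}"] = cohort[f"pc{k}"].to_numpy()

    # clinical-tier covariates
    trial["prior_hf"] = (rng.random(n) < 0.15).astype(int)
    trial["cad_history"] = (rng.random(n) < 0.3).astype(int)
    trial["afib"] = (rng.random(n) < 0.08).astype(int)
    trial["egfr"] = rng.normal(75.0, 15.0, size=n)
    trial["uacr"] = rng.lognormal(1.0, 0.8, size=n)

    conf = ledger.confounded_trial_protein
    if conf is not None:
        ntprobnp = 0.8 * _standardized(cohort[conf].to_numpy()) + 0.6 * rng.normal(size=n)
    else:
        ntprobnp = rng.normal(size=n)
    trial["ntprobnp"] = ntprobnp

    rho = config.test_retest_rho
    prot_cols = {}
    for protein in ledger.protein_ids:
        base = _standardized(cohort[protein].to_numpy())
        prot_cols[f"{protein}_t0"] = base
        prot_cols[f"{protein}_t1"] = (rho * base
                                      + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(size=n))
    trial = pd.concat([trial, pd.DataFrame(prot_cols, index=trial.index)], axis=1)

    base_hazard = 0.04  # events per year at covariate means
    admin_end = config.admin_censor_years
    surv_cols = {}
    for endpoint in endpoints:
        effects = ledger.trial_log_hr.get(endpoint, {})
        eta = np.zeros(n)
        for protein, loghr in effects.items():
            if protein == conf:
                continue
            eta += loghr * _standardized(cohort[protein].to_numpy())
        if conf is not None and conf in effects:
            # hazard acts through the clinical biomarker, not the protein
            eta += effects[conf] * _standardized(ntprobnp)
        eta += 0.02 * (trial["age"].to_numpy() - 57.0) + 0.2 * trial["prior_hf"].to_numpy()
        t_event = rng.exponential(1.0, size=n) / (base_hazard * np.exp(eta))
        t_censor = np.minimum(rng.exponential(1.0 / config.censor_rate, size=n), admin_end)
        time = np.minimum(t_event, t_censor)
        event = (t_event <= t_censor).astype(int)
        surv_cols[f"time_{endpoint}"] = time
        surv_cols[f"event_{endpoint}"] = event
        if reverse_causation:
            early = (event == 1) & (time < admin_end / 2.0)
            for protein in effects:
                trial.loc[early, f"{protein}_t1"] += 0.8
    trial = pd.concat([trial, pd.DataFrame(surv_cols, index=trial.index)], axis=1)
    return trial


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def _covariate_design(covariates, n) -> np.ndarray:
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _logistic_newton(X, y, beta0, max_iter=30, tol=1e-8):
    beta = beta0.copy()
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, None
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = special.expit(eta)
    w = mu * (1 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
    return beta, cov


def compute_summary_stats(genotypes: GenotypeMatrix, phenotype,
                          covariates=None, trait_type: str = "quant") -> pd.DataFrame:
    """Marginal per-variant association statistics (one variant at a time).

    Quantitative traits use covariate-residualized least squares (exact
    single-predictor OLS after projecting covariates out of both phenotype
    and dosage); binary traits use a per-variant logistic Newton fit warm
    started from the covariate-only model. Zero-variance variants are
    emitted with undefined (NaN) standard errors so downstream stages can
    exclude them. Effect-allele frequency is column mean dosage / 2.
    """
    y = np.asarray(phenotype, dtype=float)
    n = genotypes.n_samples
    if len(y) != n:
        raise ValueError("phenotype length must equal sample count")
    if trait_type not in ("quant", "cc"):
        raise ValueError(f"trait_type must be 'quant' or 'cc', got {trait_type!r}")
    G = genotypes.dosages
    C = _covariate_design(covariates, n)
    eaf = G.mean(axis=0) / 2.0
    var_g = G.var(axis=0)
    ok = var_g > 1e-12

    m = genotypes.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)

    if trait_type == "quant":
        y_r = _residualize(y[:, None], C)[:, 0]
        G_r = _residualize(G, C)
        gj2 = np.einsum("ij,ij->j", G_r, G_r)
        ok = ok & (gj2 > 1e-12)
        yy = float(y_r @ y_r)
        gy = G_r.T @ y_r
        beta[ok] = gy[ok] / gj2[ok]
        dof = n - C.shape[1] - 1
        rss = np.maximum(yy - beta[ok] ** 2 * gj2[ok], 0.0)
        sigma2 = rss / max(dof, 1)
        se[ok] = np.sqrt(sigma2 / gj2[ok])
        case_prop = np.nan
    else:
        y = y.astype(float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("cc trait must be binary 0/1")
        case_prop = float(y.mean())
        b0, _ = _logistic_newton(C, y, np.zeros(C.shape[1]))
        X = np.column_stack([C, np.zeros(n)])
        start = np.append(b0, 0.0)
        for j in np.where(ok)[0]:
            X[:, -1] = G[:, j]
            bj, cov = _logistic_newton(X, y, start)
            if cov is not None and cov[-1, -1] > 0:
                beta[j] = bj[-1]
                se[j] = np.sqrt(cov[-1, -1])

    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))

    out = genotypes.variants[["variant_id", "chrom", "pos",
                              "effect_allele", "other_allele"]].copy()
    out["eaf"] = eaf
    out["beta"] = beta
    out["se"] = se
    out["pval"] = pval
    out["n"] = n
    out["trait_type"] = trait_type
    out["case_prop"] = case_prop
    return out[SUMSTATS_COLUMNS]


def protein_sumstats(genotypes: GenotypeMatrix, cohort: pd.DataFrame,
                     protein_ids, covariates=None) -> dict:
    """pQTL summary statistics for many proteins at once.

    Shares the covariate projection across proteins so a full
    proteome-by-genome scan is a single matrix product.
    """
    n = genotypes.n_samples
    C = _covariate_design(covariates, n)
    G_r = _residualize(genotypes.dosages, C)
    gj2 = np.einsum("ij,ij->j", G_r, G_r)
    ok = gj2 > 1e-12
    eaf = genotypes.dosages.mean(axis=0) / 2.0
    dof = n - C.shape[1] - 1
    base = genotypes.variants[["variant_id", "chrom", "pos",
                               "effect_allele", "other_allele"]]
    out = {}
    Y = np.column_stack([_standardized(cohort[p].to_numpy()) for p in protein_ids])
    Y_r = _residualize(Y, C)
    B = (G_r.T @ Y_r)  # m x P
    yy = np.einsum("ij,ij->j", Y_r, Y_r)
    for k, protein in enumerate(protein_ids):
        beta = np.full(len(gj2), np.nan)
        se = np.full(len(gj2), np.nan)
        beta[ok] = B[ok, k] / gj2[ok]
        rss = np.maximum(yy[k] - beta[ok] ** 2 * gj2[ok], 0.0)
        se[ok] = np.sqrt(rss / max(dof, 1) / gj2[ok])
        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta / se
        df = base.copy()
        df["eaf"] = eaf
        df["beta"] = beta
        df["se"] = se
        df["pval"] = 2.0 * stats.norm.sf(np.abs(z))
        df["n"] = n
        df["trait_type"] = "quant"
        df["case_prop"] = np.nan
        out[protein] = df[SUMSTATS_COLUMNS]
    return out


# ---------------------------------------------------------------------------
# text I/O (all outputs are plain TSV/JSON)
# ---------------------------------------------------------------------------

def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sumstats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotypes(genotypes: GenotypeMatrix, dosage_path, variant_path) -> None:
    pd.DataFrame(genotypes.dosages,
                 index=pd.Index(genotypes.sample_ids, name="sample_id"),
                 columns=genotypes.variants["variant_id"]).to_csv(
        dosage_path, sep="\t", float_format="%.6g")
    genotypes.variants.to_csv(variant_path, sep="\t", index=False, float_format="%.10g")


def read_genotypes(dosage_path, variant_path) -> GenotypeMatrix:
    d = pd.read_csv(dosage_path, sep="\t", index_col=0)
    v = pd.read_csv(variant_path, sep="\t")
    return GenotypeMatrix(dosages=d.to_numpy(float), variants=v,
                          sample_ids=list(d.index))
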