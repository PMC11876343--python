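"""Simulation configuration.

The generator emulates a biobank-style discovery/replication proteomics
cohort, two non-overlapping GWAS samples (exposure pQTL and binary-outcome
GWAS) for two-sample Mendelian randomisation, and a trial-like survival
sample, with every planted effect recorded in a truth ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Counts are sample or feature counts; proportions live in [0, 1].
    ``ld_rho`` is the target Pearson correlation between adjacent variant
    dosages within a cis region (haplotypes follow a first-order Markov
    chain; regions are mutually independent). ``mediated_fraction`` is the
    fraction of each planted PGS->protein total effect that flows through
    BMI. ``trial_log_hr`` is the per-SD log hazard ratio of each causal
    protein on its trial endpoint; ``censor_rate`` is the exponential
    dropout-censoring rate per year.
    """

    n_discovery: int = 4000
    n_replication: int = 2000
    n_gwas_exposure: int = 4000
    n_gwas_outcome: int = 20000
    n_proteins: int = 50
    n_variants_per_cis_region: int = 20
    ld_rho: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    pgs_n_variants: int = 200
    mediated_fraction: float = 0.3
    protein_h2_cis: float = 0.2
    disease_prevalence: float = 0.1
    trial_log_hr: float = 0.4
    censor_rate: float = 0.05
    seed: int = 0

    # generator knobs beyond the headline parameters
    n_true_targets: int = 10            # proteins with a planted PGS->protein effect
    pgs_total_effect: float = 0.15      # per-SD PGS effect on each target protein
    gamma_bmi: float = 0.3              # per-SD PGS effect on BMI
    n_causal_cis: int = 4               # causal cis variants per protein
    disease_log_odds: float = 0.5       # per-SD log-odds of each causal protein
    bmi_disease_log_odds: float = 0.3
    trans_h2: float = 0.05              # variance from the trans hub, where present
    n_trans_hit: int = 6                # proteins hit by the shared trans hub variant
    n_distinct_regions: int = 5         # regions with a distinct disease causal variant
    test_retest_rho: float = 0.7        # trial baseline/repeat protein correlation
    n_trial_causal: int = 5             # causal proteins per trial endpoint
    admin_censor_years: float = 5.0

    def validate(self) -> None:
        counts = dict(
            n_discovery=self.n_discovery,
            n_replication=self.n_replication,
            n_gwas_exposure=self.n_gwas_exposure,
            n_gwas_outcome=self.n_gwas_outcome,
            n_proteins=self.n_proteins,
            n_variants_per_cis_region=self.n_variants_per_cis_region,
            pgs_n_variants=self.pgs_n_variants,
        )
        for name, value in counts.items():
            if not (isinstance(value, (int, np.integer)) and value > 0):
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if not np.isfinite(self.ld_rho) or not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError(f"ld_rho must lie in [0, 1), got {self.ld_rho!r}")
        lo, hi = self.maf_range
        if not (np.isfinite(lo) and np.isfinite(hi) and 0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must be ordered within (0, 0.5], got {self.maf_range!r}")
        for name in ("mediated_fraction", "protein_h2_cis", "disease_prevalence"):
            value = getattr(self, name)
            if not np.isfinite(value) or not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")
        if not np.isfinite(self.trial_log_hr):
            raise ConfigError("trial_log_hr must be finite")
        if not np.isfinite(self.censor_rate) or self.censor_rate <= 0:
            raise ConfigError(f"censor_rate must be > 0, got {self.censor_rate!r}")
        if not (-1.0 < self.test_retest_rho < 1.0 + 1e-12):
            raise ConfigError("test_retest_rho must lie in (-1, 1]")
        if self.n_true_targets > self.n_proteins:
            raise ConfigError("n_true_targets cannot exceed n_proteins")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg
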