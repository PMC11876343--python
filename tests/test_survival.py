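"""Cox endpoint analysis: grid-search oracle, PH diagnostics, tiers, repeats."""

import numpy as np
import pandas as pd
import pytest

from pgslink import simulate, survival
from pgslink.config import SimConfig
from pgslink.errors import DegenerateOutcomeError, NoEventsError

from conftest import SMALL_KWARGS


def _cox_partial_loglik(beta, times, events, x):
    """Tie-free Cox partial log-likelihood for one covariate."""
    ll = 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxFit:
    def test_newton_matches_grid_search_oracle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 0, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        df = pd.DataFrame({"time": times, "event": events, "x": x})
        fit = survival.cox_fit(df, "x")
        grid = np.linspace(-3, 3, 600001)
        lls = [_cox_partial_loglik(b, times, events, x) for b in
               np.linspace(-3, 3, 6001)]
        coarse = np.linspace(-3, 3, 6001)[int(np.argmax(lls))]
        fine = np.linspace(coarse - 0.01, coarse + 0.01, 40001)
        lls_f = [_cox_partial_loglik(b, times, events, x) for b in fine]
        oracle = fine[int(np.argmax(lls_f))]
        assert abs(fit.estimate - oracle) < 1e-6

    def test_ci_bounds_consistent_with_estimate(self):
        rng = np.random.default_rng(90)
        n = 500
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n) / np.exp(0.4 * x)
        c = rng.exponential(2.0, n)
        df = pd.DataFrame({"time": np.minimum(t, c),
                           "event": (t <= c).astype(int), "x": x})
        fit = survival.cox_fit(df, "x")
        assert abs(fit.ci_low - np.exp(fit.estimate - 1.959963984540054 * fit.se)) < 1e-10
        assert abs(fit.ci_high - np.exp(fit.estimate + 1.959963984540054 * fit.se)) < 1e-10
        assert fit.n_events <= fit.n

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(91)
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n) / np.exp(0.5 * x)
        df = pd.DataFrame({"time": t, "event": 1, "x": x})
        fit1 = survival.cox_fit(df, "x")
        df2 = df.assign(time=df["time"] * 365.25)
        fit2 = survival.cox_fit(df2, "x")
        assert abs(fit1.estimate - fit2.estimate) < 1e-8

    def test_censoring_sweep_unbiased(self):
        rng = np.random.default_rng(92)
        n = 4000
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n) / np.exp(0.5 * x)
        for censor_scale in (10.0, 1.0, 0.25):   # ~10% to ~80% censoring
            c = rng.exponential(censor_scale, n)
            df = pd.DataFrame({"time": np.minimum(t, c),
                               "event": (t <= c).astype(int), "x": x})
            fit = survival.cox_fit(df, "x")
            assert abs(fit.estimate - 0.5) < 0.08

    def test_constant_covariate_raises(self):
        df = pd.DataFrame({"time": [1.0, 2, 3], "event": [1, 1, 0],
                           "x": [1.0, 1.0, 1.0]})
        with pytest.raises(DegenerateOutcomeError):
            survival.cox_fit(df, "x")

    def test_zero_events_raises(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0],
                           "x": [0.0, 1.0]})
        with pytest.raises(NoEventsError):
            survival.cox_fit(df, "x")


class TestPhTest:
    def test_single_covariate_global_equals_term(self):
        rng = np.random.default_rng(93)
        n = 400
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n) / np.exp(0.3 * x)
        df = pd.DataFrame({"time": t, "event": 1, "x": x})
        per_term, global_p = survival.ph_test(df, "x")
        assert abs(per_term.iloc[0] - global_p) < 1e-10

    def test_null_ph_p_uniformish(self):
        """Under exact PH the global test p is not systematically small."""
        from scipy import stats
        rng = np.random.default_rng(94)
        ps = []
        for _ in range(200):
            n = 150
            x = rng.normal(size=n)
            t = rng.exponential(1.0, n) / np.exp(0.3 * x)
            c = rng.exponential(2.0, n)
            df = pd.DataFrame({"time": np.minimum(t, c),
                               "event": (t <= c).astype(int), "x": x})
            _, p = survival.ph_test(df, "x")
            ps.append(p)
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= frac <= 0.10

    def test_time_varying_effect_detected(self):
        rng = np.random.default_rng(95)
        detected = 0
        for _ in range(30):
            n = 600
            x = rng.normal(size=n)
            # effect reverses sign mid-study
            t1 = rng.exponential(1.0, n) / np.exp(1.0 * x)
            flip = t1 > np.median(t1)
            t = t1.copy()
            t[flip] = np.median(t1) + rng.exponential(1.0, flip.sum()) \
                / np.exp(-1.0 * x[flip])
            df = pd.DataFrame({"time": t, "event": 1, "x": x})
            _, p = survival.ph_test(df, "x")
            detected += p < 0.05
        assert detected >= 24

    def test_too_few_events_skipped(self):
        df = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 1, 0, 0],
                           "x": [0.0, 1, 0, 1]})
        per_term, p = survival.ph_test(df, "x")
        assert per_term is None and p is None


class TestEndpointScan:
    def test_causal_proteins_recovered_and_tiers(self, small_trial, small_study):
        ledger = small_study["ledger"]
        scan = survival.endpoint_scan(small_trial, ledger.protein_ids,
                                      endpoints=("mace",), tier="base",
                                      role="discovery", ph_flag=False)
        sig = set(scan.loc[scan["significant"], "protein_id"])
        causal = {p for p in ledger.trial_log_hr["mace"]
                  if p != ledger.confounded_trial_protein}
        assert len(causal & sig) >= len(causal) - 1

    def test_replication_restricted_to_discovery_hits(self, small_trial,
                                                      small_study):
        ledger = small_study["ledger"]
        disc = survival.endpoint_scan(small_trial, ledger.protein_ids,
                                      endpoints=("mace",), role="discovery",
                                      ph_flag=False)
        hits = disc[disc["significant"]][["protein_id", "endpoint"]]
        repl = survival.endpoint_scan(small_trial, ledger.protein_ids,
                                      endpoints=("mace",), role="replication",
                                      discovery_hits=hits, ph_flag=False)
        assert set(zip(repl["protein_id"], repl["endpoint"])) == \
            set(zip(hits["protein_id"], hits["endpoint"]))

    def test_tier_covariate_sets_nested(self):
        base = set(survival.TIERS["base"])
        clinical = set(survival.TIERS["clinical"])
        full = set(survival.TIERS["clinical_plus_ntprobnp"])
        assert base < clinical < full

    def test_ntprobnp_tier_attenuates_confounded_protein(self, small_study):
        """The protein whose hazard flows through NT-proBNP is significant
        at the base tier but not once NT-proBNP is adjusted for."""
        cfg = small_study["config"]
        ledger = small_study["ledger"]
        conf = ledger.confounded_trial_protein
        # put the confounded protein among the endpoint's causal set
        ledger2 = simulate.make_truth(cfg)
        ledger2.trial_log_hr = {"mace": {conf: 0.5}}
        trial = simulate.simulate_trial(cfg, small_study["cohort"], ledger2,
                                        endpoints=("mace",))
        base = survival.endpoint_scan(trial, [conf], endpoints=("mace",),
                                      tier="base", ph_flag=False)
        adj = survival.endpoint_scan(trial, [conf], endpoints=("mace",),
                                     tier="clinical_plus_ntprobnp",
                                     ph_flag=False)
        assert base["pval"].iloc[0] < 0.05 / 3
        assert adj["pval"].iloc[0] > base["pval"].iloc[0] * 10


class TestRepeatMeasurements:
    def test_perfect_retest_identical_fits(self, small_study):
        cfg = SimConfig(**{**SMALL_KWARGS, "seed": 96, "test_retest_rho": 1.0})
        ledger = simulate.make_truth(cfg)
        cohort, ledger = simulate.simulate_cohort(
            cfg, simulate.simulate_genotypes(cfg), ledger)
        trial = simulate.simulate_trial(cfg, cohort, ledger,
                                        endpoints=("mace",))
        protein = next(iter(ledger.trial_log_hr["mace"]))
        out = survival.repeat_measurement_scan(trial, [protein])
        assert abs(out["hr_baseline"].iloc[0] - out["hr_repeat"].iloc[0]) < 1e-8

    def test_reverse_causation_inflates_repeat_hr(self):
        cfg = SimConfig(**{**SMALL_KWARGS, "seed": 97, "n_discovery": 3000})
        ledger = simulate.make_truth(cfg)
        cohort, ledger = simulate.simulate_cohort(
            cfg, simulate.simulate_genotypes(cfg), ledger)
        protein = next(p for p in ledger.trial_log_hr["mace"]
                       if p != ledger.confounded_trial_protein)
        inflated = 0
        attenuated_forward = 0
        n_rep = 25
        for s in range(n_rep):
            trial = simulate.simulate_trial(cfg, cohort, ledger,
                                            endpoints=("mace",),
                                            reverse_causation=True, subseed=s)
            out = survival.repeat_measurement_scan(trial, [protein])
            inflated += out["hr_repeat"].iloc[0] > out["hr_baseline"].iloc[0]
            # contrast: under pure forward causation the repeat measurement
            # carries no information beyond baseline, so adjusting for
            # baseline collapses the repeat coefficient
            fwd = simulate.simulate_trial(cfg, cohort, ledger,
                                          endpoints=("mace",),
                                          reverse_causation=False, subseed=s)
            out_f = survival.repeat_measurement_scan(fwd, [protein])
            attenuated_forward += (out_f["hr_repeat_adjusted"].iloc[0]
                                   < out_f["hr_repeat"].iloc[0])
        assert inflated >= int(0.8 * n_rep)
        assert attenuated_forward >= int(0.8 * n_rep)


class TestTrialMediation:
    def test_gate_closed_without_pgs_endpoint_association(self, small_trial,
                                                          small_study):
        rng = np.random.default_rng(98)
        fake_pgs = rng.normal(size=len(small_trial))
        out = survival.pgs_trial_mediation(small_trial, fake_pgs,
                                           small_study["ledger"].protein_ids[:3])
        assert out.empty
        assert "not associated" in out.attrs["skip_reason"]

    def test_planted_chain_detected(self, small_study):
        """PGS -> protein -> event: indirect q < 0.05 for a true mediator."""
        from pgslink import scoring
        cfg = small_study["config"]
        ledger = small_study["ledger"]
        geno = small_study["geno"]
        cohort = small_study["cohort"]
        trial = simulate.simulate_trial(cfg, cohort, ledger,
                                        endpoints=("mace",), subseed=5)
        pgs = simulate._standardized(
            simulate._true_pgs(geno, ledger.pgs_weights))
        causal = [p for p in ledger.trial_log_hr["mace"]
                  if p != ledger.confounded_trial_protein]
        out = survival.pgs_trial_mediation(trial, pgs, causal,
                                           endpoint="mace", n_boot=100, seed=3)
        if out.empty:
            pytest.skip(f"gate closed: {out.attrs.get('skip_reason')}")
        assert (out["q_indirect"] < 0.05).any()
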