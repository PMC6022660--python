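"""Effect sizes, group comparisons and competing-risks analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dpscore import (
    HazardSpec,
    SimulationConfig,
    anova_tukey,
    cif_estimate,
    cohens_d,
    fine_gray,
    phenotype_report,
    simulate_cohort,
    simulate_conversion_data,
    simulate_genotypes,
)
from dpscore.simulate import TruthRecord, _subject_ids


class TestCohensD:
    def test_unit_shift_with_unit_pooled_sd(self):
        a = np.array([0.0, 1.0, 2.0]) + 1.0
        b = np.array([0.0, 1.0, 2.0])
        d, _ = cohens_d(a, b)
        assert d == pytest.approx(1.0)

    def test_identical_groups_give_zero_with_ci_spanning_zero(self, rng):
        x = rng.normal(size=50)
        d, (lo, hi) = cohens_d(x, x.copy())
        assert d == 0.0 and lo < 0 < hi

    def test_antisymmetry(self, rng):
        a, b = rng.normal(1, 1, 40), rng.normal(0, 1, 60)
        d_ab, _ = cohens_d(a, b)
        d_ba, _ = cohens_d(b, a)
        assert d_ab == pytest.approx(-d_ba)

    def test_ci_covers_true_shift(self, rng):
        hits = 0
        for _ in range(100):
            a = rng.normal(0.8, 1.0, 200)
            b = rng.normal(0.0, 1.0, 200)
            _, (lo, hi) = cohens_d(a, b)
            hits += lo <= 0.8 <= hi
        assert hits >= 93

    def test_noncentral_t_interval_close_to_normal(self, rng):
        a, b = rng.normal(0.5, 1, 80), rng.normal(0, 1, 80)
        _, ci_n = cohens_d(a, b, ci_method="normal")
        _, ci_t = cohens_d(a, b, ci_method="noncentral-t")
        assert ci_n[0] == pytest.approx(ci_t[0], abs=0.05)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestAnovaTukey:
    def test_two_groups_reduce_to_pooled_t_test(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        res = anova_tukey(np.concatenate([a, b]), ["a"] * 30 + ["b"] * 25)
        t_p = sps.ttest_ind(a, b).pvalue
        assert res["tukey"]["p_adj"].iloc[0] == pytest.approx(t_p, abs=1e-6)

    def test_null_f_pvalues_roughly_uniform(self, rng):
        pvals = []
        for _ in range(200):
            x = rng.normal(size=90)
            pvals.append(anova_tukey(x, np.repeat(["a", "b", "c"], 30))["p"])
        assert sps.kstest(pvals, "uniform").statistic < 0.1

    def test_diagnosis_bands_are_strongly_ordered(self):
        cfg = SimulationConfig(n_subjects=400, label_noise=0.0, seed=23)
        _, truth, cov = simulate_cohort(cfg)
        dps = truth.subjects.set_index("subject_id")["gamma"]
        diag = cov.set_index("subject_id")["diagnosis"].loc[dps.index]
        res = anova_tukey(dps.to_numpy(), diag.to_numpy())
        assert res["p"] < 1e-10
        assert (res["tukey"]["p_adj"] < 0.001).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([1.0, 2.0], ["a", "a"])


class TestCifEstimate:
    def test_single_conversion_jumps_to_one(self):
        rec = pd.DataFrame({"time_months": [5.0], "status": [1], "carrier": [0]})
        curve = cif_estimate(rec)["all"]
        assert list(curve["time"]) == [5.0]
        assert curve["cif"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_two_subject_case(self, toy_survival):
        """Death at 3 leaves one at risk; conversion at 6 contributes S(6-)*1/1."""
        curve = cif_estimate(toy_survival, event=1)["all"]
        assert curve["cif"].iloc[-1] == pytest.approx(0.5)

    def test_conservation_of_probability(self):
        truth = TruthRecord(subjects=pd.DataFrame({"subject_id": _subject_ids(300)}))
        cfg = SimulationConfig(n_subjects=300, n_variants=4, seed=29)
        geno = simulate_genotypes(cfg, truth)
        surv = simulate_conversion_data(cfg, geno, causal_index=0)
        cif1 = cif_estimate(surv, event=1)["all"]
        cif2 = cif_estimate(surv, event=2)["all"]
        grid = np.unique(surv.loc[surv.status > 0, "time_months"])
        on1 = np.interp(grid, cif1["time"], cif1["cif"], left=0.0)
        on2 = np.interp(grid, cif2["time"], cif2["cif"], left=0.0)
        # overall KM survival for "any event"
        s = np.ones_like(grid)
        t = surv["time_months"].to_numpy()
        st = surv["status"].to_numpy()
        surv_prob = 1.0
        for i, tk in enumerate(grid):
            n_at = (t >= tk).sum()
            d = ((t == tk) & (st > 0)).sum()
            surv_prob *= 1 - d / n_at
            s[i] = surv_prob
        assert np.max(np.abs(on1 + on2 + s - 1.0)) < 1e-10

    def test_monotone_and_bounded(self, small_study):
        _, study = small_study
        for curve in cif_estimate(study["survival"], by="carrier").values():
            assert (np.diff(curve["cif"]) >= -1e-12).all()
            assert ((curve["cif"] >= 0) & (curve["cif"] <= 1)).all()

    def test_no_events_gives_flat_zero(self):
        rec = pd.DataFrame({"time_months": [4.0, 8.0], "status": [0, 0],
                            "carrier": [0, 1]})
        curve = cif_estimate(rec)["all"]
        assert len(curve) == 0 or (curve["cif"] == 0).all()

    def test_aalen_johansen_reduces_to_km_complement(self, rng):
        """Without competing events the CIF is 1 - Kaplan-Meier survival."""
        from lifelines import KaplanMeierFitter

        n = 300
        t = rng.exponential(5, n)
        cens = rng.uniform(0, 10, n)
        time = np.minimum(t, cens)
        status = (t <= cens).astype(int)
        rec = pd.DataFrame({"time_months": time, "status": status})
        curve = cif_estimate(rec)["all"]
        km = KaplanMeierFitter().fit(time, status)
        at = curve["time"].to_numpy()
        km_sf = km.survival_function_at_times(at).to_numpy()
        assert np.max(np.abs(curve["cif"].to_numpy() - (1 - km_sf))) < 1e-10


class TestFineGray:
    def _fixture(self, seed=42, n=150):
        rng = np.random.default_rng(seed)
        carrier = rng.integers(0, 2, n)
        age = rng.normal(0, 1, n)
        t_conv = rng.exponential(1 / (0.10 * np.where(carrier == 1, 0.5, 1.0)))
        t_death = rng.exponential(1 / 0.05, n)
        cens = rng.uniform(2, 12, n)
        time = np.minimum(np.minimum(t_conv, t_death), cens)
        status = np.where(time == t_conv, 1, np.where(time == t_death, 2, 0))
        return pd.DataFrame({"time_months": time * 12, "status": status,
                             "carrier": carrier, "age": age})

    def test_matches_frozen_cmprsk_oracle(self):
        """Coefficients frozen from cmprsk::crr on this exact synthetic table."""
        res = fine_gray(self._fixture(), covariate_cols=("carrier", "age"))
        assert res["coef"] == pytest.approx(-0.4743947967, abs=1e-6)
        assert res["all_coefs"]["age"][0] == pytest.approx(-0.2462345855, abs=1e-6)

    def test_no_competing_events_equals_cox(self):
        from lifelines import CoxPHFitter

        df = self._fixture()
        df.loc[df.status == 2, "status"] = 0
        res = fine_gray(df, covariate_cols=("carrier", "age"))
        cph = CoxPHFitter().fit(
            df.rename(columns={"time_months": "T"})[["T", "status", "carrier", "age"]],
            "T", event_col="status")
        assert res["coef"] == pytest.approx(cph.params_["carrier"], abs=1e-6)
        assert res["all_coefs"]["age"][0] == pytest.approx(cph.params_["age"], abs=1e-6)

    def test_null_ci_coverage(self):
        covered = 0
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            n = 600
            carrier = rng.integers(0, 2, n)
            t_conv = rng.exponential(1 / 0.08, n)
            t_death = rng.exponential(1 / 0.04, n)
            time = np.minimum(np.minimum(t_conv, t_death), 10.0)
            status = np.where(time == t_conv, 1, np.where(time == t_death, 2, 0))
            df = pd.DataFrame({"time_months": time * 12, "status": status,
                               "carrier": carrier})
            lo, hi = fine_gray(df)["ci"]
            covered += lo <= 1.0 <= hi
        assert covered >= 25

    def test_bonferroni_adjustment(self):
        res = fine_gray(self._fixture(), n_tests=4)
        assert res["p_bonferroni"] == pytest.approx(min(1.0, res["p"] * 4))

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0], "status": [0, 2],
                           "carrier": [0, 1]})
        with pytest.raises(ValueError, match="no events"):
            fine_gray(df)


class TestPhenotypeReport:
    def _inputs(self, rng, n=300):
        ids = [f"s{i}" for i in range(n)]
        apoe4 = pd.Series(rng.binomial(2, 0.3, n), index=ids, dtype=float)
        age = pd.Series(rng.normal(74, 7, n), index=ids)
        sex = pd.Series(rng.integers(0, 2, n), index=ids, dtype=float)
        diag = pd.Series(rng.choice(["HC", "MCI", "AD"], n), index=ids)
        return ids, apoe4, age, sex, diag

    def test_perfect_correlation_detected(self, rng):
        ids, apoe4, age, sex, diag = self._inputs(rng)
        phen = pd.DataFrame({"dps": 2.0 * apoe4}, index=ids)
        rep = phenotype_report(phen, diag, apoe4, age, sex)
        assert rep["correlations"].loc[0, "r"] == pytest.approx(1.0)

    def test_null_correlation_small(self, rng):
        hits = 0
        for _ in range(20):
            ids, apoe4, age, sex, diag = self._inputs(rng, n=1000)
            phen = pd.DataFrame({"dps": rng.normal(size=1000)}, index=ids)
            rep = phenotype_report(phen, diag, apoe4, age, sex)
            hits += abs(rep["correlations"].loc[0, "r"]) < 0.1
        assert hits >= 19

    def test_partial_correlation_equals_residual_oracle(self, rng):
        ids, apoe4, age, sex, diag = self._inputs(rng)
        phen = pd.DataFrame({"dps": 0.3 * apoe4 + 0.05 * age + rng.normal(size=300)},
                            index=ids)
        rep = phenotype_report(phen, diag, apoe4, age, sex)
        C = np.column_stack([np.ones(300), age, sex])
        def resid(v):
            beta, *_ = np.linalg.lstsq(C, v, rcond=None)
            return v - C @ beta
        r_oracle = sps.pearsonr(resid(apoe4.to_numpy()),
                                resid(phen["dps"].to_numpy()))[0]
        assert rep["correlations"].loc[0, "r_partial"] == pytest.approx(r_oracle, abs=1e-10)

    def test_effect_size_table_has_all_contrasts(self, rng):
        ids, apoe4, age, sex, diag = self._inputs(rng)
        phen = pd.DataFrame({"dps": rng.normal(size=300),
                             "suvr": rng.normal(size=300)}, index=ids)
        rep = phenotype_report(phen, diag, apoe4, age, sex)
        assert len(rep["effect_sizes"]) == 6  # 2 phenotypes x 3 contrasts

    def test_constant_phenotype_rejected(self, rng):
        ids, apoe4, age, sex, diag = self._inputs(rng)
        phen = pd.DataFrame({"dps": np.ones(300)}, index=ids)
        with pytest.raises(ValueError, match="constant"):
            phenotype_report(phen, diag, apoe4, age, sex)
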