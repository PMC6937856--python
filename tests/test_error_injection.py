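import numpy as np
import pandas as pd
import pytest

from sdvimpact.audit_engine import audit_compare, summarize_discrepancies
from sdvimpact.error_injection import (
    CorrectionModel, ErrorModel, build_audit_dataset, build_post_audit,
    inject_errors, sample_audit_subset,
)
from sdvimpact.synthetic_cohort import CohortSimParams, simulate_truth

NON_POST_COLUMNS = ["clinical_aids", "aids_diagnosis_date"]


def _rates(miss=0.0, corrupt=0.0, unver=0.0):
    return {"default": {"make_missing": miss, "corrupt_value": corrupt,
                        "unverifiable": unver}}


class TestInjectErrors:
    def test_zero_rates_yield_identity_and_empty_log(self, truth_small):
        truth, _ = truth_small
        pre, log = inject_errors(truth, ErrorModel(seed=1))
        assert log.empty
        for name in truth.tables:
            a = truth.tables[name]
            b = pre.tables[name]
            if name == "patients":  # replacement variables are post-audit only
                a = a.drop(columns=NON_POST_COLUMNS)
                b = b.drop(columns=NON_POST_COLUMNS)
            pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                          b.reset_index(drop=True))

    def test_saturated_missingness_blanks_every_death_date(self, truth_small):
        truth, _ = truth_small
        model = ErrorModel(rates={"default": {}, "death_date": {"make_missing": 1.0}},
                           seed=2)
        pre, log = inject_errors(truth, model)
        assert pre.patients["death_date"].isna().all()
        n_dates = truth.patients["death_date"].notna().sum()
        assert (log["operation"] == "make_missing").sum() == n_dates

    def test_missingness_rate_recovered_within_binomial_tolerance(self):
        truth, _ = simulate_truth(CohortSimParams(n_sites=9, patients_per_site=60, seed=5))
        n = len(truth.visits)
        assert n >= 10_000
        model = ErrorModel(rates={"default": {}, "visit_date": {"make_missing": 0.10}},
                           seed=6)
        pre, log = inject_errors(truth, model)
        observed = pre.visits["visit_date"].isna().mean()
        tol = 3 * np.sqrt(0.1 * 0.9 / n)
        assert abs(observed - 0.10) < tol
        assert int((log["operation"] == "make_missing").sum()) == \
            int(pre.visits["visit_date"].isna().sum())

    def test_systematic_site_effect_swaps_every_qualifying_date(self, truth_small):
        truth, _ = truth_small
        site = truth.patients["site_id"].iloc[0]
        model = ErrorModel(systematic_site_effects=[(site, "visit_date", "month_day_swap")],
                           seed=7)
        pre, log = inject_errors(truth, model)
        site_pids = set(truth.patients.loc[truth.patients["site_id"] == site, "patient_id"])
        tv = truth.visits.set_index("row_uid")
        swapped = log[log["operation"] == "systematic"]
        # every qualifying (day<=12, day!=month) date at that site is logged
        n_qualifying = sum(
            1 for _, r in truth.visits.iterrows()
            if r["patient_id"] in site_pids and pd.notna(r["visit_date"])
            and r["visit_date"].day <= 12 and r["visit_date"].day != r["visit_date"].month)
        assert len(swapped) == n_qualifying > 0
        for _, r in swapped.head(20).iterrows():
            old = tv.at[r["occurrence"], "visit_date"]
            new = pre.visits.set_index("row_uid").at[r["occurrence"], "visit_date"]
            assert (new.day, new.month) == (old.month, old.day)

    def test_unknown_site_or_variable_fatal(self, truth_small):
        truth, _ = truth_small
        with pytest.raises(ValueError, match="unknown site"):
            inject_errors(truth, ErrorModel(
                systematic_site_effects=[("nowhere", "visit_date", "month_day_swap")]))
        with pytest.raises(ValueError, match="unknown variable"):
            inject_errors(truth, ErrorModel(
                systematic_site_effects=[(truth.patients["site_id"].iloc[0],
                                          "bogus", "month_day_swap")]))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ErrorModel(rates=_rates(miss=1.5)).validate()
        with pytest.raises(ValueError):
            ErrorModel(record_ops={"drop_patient": -0.1}).validate()


class TestAuditSampling:
    def test_full_completion_returns_all_selected(self, truth_small):
        truth, _ = truth_small
        pre, _ = inject_errors(truth, ErrorModel(seed=1))
        sel, comp = sample_audit_subset(pre, 10, 1.0, seed=4)
        assert comp == sel
        assert len(sel) == 30  # 3 sites x 10

    def test_selection_is_stratified_and_deterministic(self, truth_small):
        truth, _ = truth_small
        pre, _ = inject_errors(truth, ErrorModel(seed=1))
        sel1, comp1 = sample_audit_subset(pre, 10, 0.79, seed=4)
        sel2, comp2 = sample_audit_subset(pre, 10, 0.79, seed=4)
        assert sel1 == sel2 and comp1 == comp2
        per_site = pd.Series([s.split("-0")[0] for s in sel1]).value_counts()
        assert (per_site == 10).all()

    def test_study_scale_expected_completed_near_250(self):
        truth, _ = simulate_truth(CohortSimParams(n_sites=9, patients_per_site=60, seed=9))
        pre, _ = inject_errors(truth, ErrorModel(seed=2))
        sel, comp = sample_audit_subset(pre, 35, 0.79, seed=5)
        assert len(sel) == 9 * 35
        expected = 315 * 0.79
        tol = 3 * np.sqrt(315 * 0.79 * 0.21)
        assert abs(len(comp) - expected) < tol

    def test_oversized_target_selects_whole_site(self, truth_small, caplog):
        truth, _ = truth_small
        pre, _ = inject_errors(truth, ErrorModel(seed=1))
        sel, _ = sample_audit_subset(pre, 10_000, 1.0, seed=4)
        assert len(sel) == pre.patients["patient_id"].nunique()


class TestAuditedDataset:
    def test_full_audit_recovers_truth_for_completed_records(self, truth_small):
        truth, _ = truth_small
        model = ErrorModel(rates=_rates(miss=0.1, corrupt=0.1),
                           record_ops={"drop_visit": 0.05}, seed=3)
        pre, _ = inject_errors(truth, model)
        _, comp = sample_audit_subset(pre, 10, 1.0, seed=4)
        aud = build_audit_dataset(truth, pre, comp, 0.0, 1.0, seed=5)
        comparisons = audit_compare(truth, aud, scope=set(comp))
        assert (comparisons["category"] == "match").all()
        assert set(aud.patients["patient_id"]) == set(comp)

    def test_partial_audit_fraction_controls_denominator(self, truth_small):
        truth, _ = truth_small
        pre, _ = inject_errors(truth, ErrorModel(seed=3))
        _, comp = sample_audit_subset(pre, 25, 1.0, seed=4)
        aud = build_audit_dataset(truth, pre, comp, 0.0, 0.75, seed=5)
        full = build_audit_dataset(truth, pre, comp, 0.0, 1.0, seed=5)
        frac = len(aud.audited_fields) / len(full.audited_fields)
        n = len(full.audited_fields)
        assert abs(frac - 0.75) < 3 * np.sqrt(0.75 * 0.25 / n)

    def test_unverifiable_marks_at_configured_rate(self, truth_small):
        truth, _ = truth_small
        pre, _ = inject_errors(truth, ErrorModel(seed=3))
        _, comp = sample_audit_subset(pre, 25, 1.0, seed=4)
        aud = build_audit_dataset(truth, pre, comp, {"visit_date": 0.05}, 1.0, seed=6)
        n = sum(1 for (_, v, _) in aud.audited_fields if v == "visit_date")
        k = sum(1 for (_, v, _) in aud.unverifiable_marks if v == "visit_date")
        assert n > 500
        assert abs(k / n - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)


class TestPostAudit:
    def test_perfect_correction_restores_truth(self, truth_small):
        truth, _ = truth_small
        emodel = ErrorModel(rates=_rates(miss=0.08, corrupt=0.08),
                            record_ops={"drop_patient": 0.1, "drop_visit": 0.05,
                                        "duplicate_patient": 0.05,
                                        "add_unregistered_patient": 0.05}, seed=3)
        pre, elog = inject_errors(truth, emodel)
        cmodel = CorrectionModel(correction_probability=1.0,
                                 backlog_entry_probability=1.0,
                                 newly_added_patient_rate=1.0,
                                 residual_error_rate=0.0,
                                 spurious_removal_probability=1.0, seed=4)
        post = build_post_audit(truth, pre, cmodel, error_log=elog)
        assert set(post.patients["patient_id"]) == set(truth.patients["patient_id"])
        comparisons = audit_compare(truth, post)
        assert (comparisons["category"] == "match").all()

    def test_no_correction_equals_pre_audit(self, truth_small):
        truth, _ = truth_small
        emodel = ErrorModel(rates=_rates(miss=0.10), seed=3)  # missingness only
        pre, elog = inject_errors(truth, emodel)
        cmodel = CorrectionModel(correction_probability=0.0,
                                 backlog_entry_probability=0.0,
                                 newly_added_patient_rate=0.0,
                                 spurious_removal_probability=0.0, seed=4)
        post = build_post_audit(truth, pre, cmodel, error_log=elog)
        comparisons = audit_compare(pre, post)
        assert (comparisons["category"] == "match").all()
        assert set(post.patients["patient_id"]) == set(pre.patients["patient_id"])

    def test_freeze_truncation_removes_late_records(self, truth_small):
        truth, _ = truth_small
        emodel = ErrorModel(rates={"default": {},
                                   "visit_date": {"corrupt_value": 0.3}}, seed=8)
        pre, elog = inject_errors(truth, emodel)
        cmodel = CorrectionModel(correction_probability=0.0, seed=4)
        post = build_post_audit(truth, pre, cmodel, error_log=elog)
        freeze = post.freeze_dates
        site_of = dict(zip(post.patients["patient_id"], post.patients["site_id"]))
        late = [d for pid, d in zip(post.visits["patient_id"], post.visits["visit_date"])
                if pd.notna(d) and d > freeze[site_of[pid]]]
        assert late == []
        # pre-audit, by contrast, does contain post-freeze corrupted dates
        pre_late = [d for pid, d in zip(pre.visits["patient_id"], pre.visits["visit_date"])
                    if pd.notna(d) and pid in site_of and d > freeze[site_of[pid]]]
        assert len(pre_late) > 0

    def test_missing_freeze_date_fatal(self, truth_small):
        truth, _ = truth_small
        pre, elog = inject_errors(truth, ErrorModel(seed=3))
        some_site = truth.patients["site_id"].iloc[0]
        freeze = {s: d for s, d in truth.freeze_dates.items() if s != some_site}
        with pytest.raises(ValueError, match="freeze date"):
            build_post_audit(truth, pre, CorrectionModel(), freeze_dates=freeze,
                             error_log=elog)

    def test_monotone_quality_across_seeds(self):
        """With no residual errors, post-audit agreement with truth is at
        least the pre-audit agreement, per variable, over 20 seeds.

        Corruptions here are missingness plus non-date value errors: a date
        corrupted past the site freeze would be truncated away post-audit
        together with its neighbouring fields, which is a freeze-boundary
        effect rather than a correction-quality one.
        """
        wins = 0
        for seed in range(20):
            truth, _ = simulate_truth(CohortSimParams(
                n_sites=3, patients_per_site=12, seed=100 + seed,
                visit_interval_days=(240.0, 30.0)))
            emodel = ErrorModel(rates={
                "default": {"make_missing": 0.12},
                "weight": {"make_missing": 0.12, "corrupt_value": 0.15},
                "cd4_value": {"make_missing": 0.12, "corrupt_value": 0.15},
                "sex": {"corrupt_value": 0.10},
                "mode_of_infection": {"corrupt_value": 0.10}},
                record_ops={"drop_patient": 0.1, "drop_visit": 0.05},
                seed=200 + seed)
            pre, elog = inject_errors(truth, emodel)
            cmodel = CorrectionModel(correction_probability=0.6,
                                     backlog_entry_probability=0.5,
                                     newly_added_patient_rate=0.8,
                                     residual_error_rate=0.0, seed=300 + seed)
            post = build_post_audit(truth, pre, cmodel, error_log=elog)
            s_pre = summarize_discrepancies(audit_compare(truth, pre), ["variable"])
            s_post = summarize_discrepancies(audit_compare(truth, post), ["variable"])
            m = s_pre.merge(s_post, on="variable", suffixes=("_pre", "_post"))
            agree_pre = m["n_match_pre"] / m["audited_count_pre"]
            agree_post = m["n_match_post"] / m["audited_count_post"]
            ok = (agree_post >= agree_pre - 1e-12).all()
            wins += ok
            assert ok, m[agree_post < agree_pre]
        assert wins == 20
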