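import numpy as np
import pandas as pd
import pytest

from repurpose import cohort as co
from repurpose.signatures import InputError
from repurpose.synthetic import SimulationConfig, gen_ehr

TS = pd.Timestamp


def exposures(rows):
    return pd.DataFrame(
        rows,
        columns=["person_id", "ingredient", "start_date", "end_date", "setting", "route"],
    ).assign(
        start_date=lambda d: pd.to_datetime(d["start_date"]),
        end_date=lambda d: pd.to_datetime(d["end_date"]),
    )


class TestBuildWindow:
    def test_date_arithmetic_oracle(self):
        exp = exposures([("p1", "x", "2010-01-01", "2010-06-30", "outpatient", "systemic")])
        win, reason = co.build_window(exp)
        assert reason == "ok"
        assert win.index_date == TS("2010-01-01")
        assert win.baseline_start == TS("2009-01-01")
        assert win.effective_treatment_start == TS("2010-01-31")
        assert win.treatment_end == TS("2010-06-30")

    def test_shorter_than_induction_is_ineligible(self):
        exp = exposures([("p1", "x", "2010-01-01", "2010-01-16", "outpatient", "systemic")])
        win, reason = co.build_window(exp)
        assert win is None and reason == "treatment_shorter_than_induction"

    def test_long_exposure_capped_at_one_year(self):
        exp = exposures([("p1", "x", "2010-01-01", "2011-12-01", "outpatient", "systemic")])
        win, _ = co.build_window(exp)
        assert win.treatment_end == TS("2010-01-01") + pd.Timedelta(days=365)

    def test_missing_end_date_imputed_with_default_supply(self):
        exp = exposures([("p1", "x", "2010-01-01", None, "outpatient", "systemic")])
        win, _ = co.build_window(exp, default_supply_days=90)
        assert win.treatment_end == TS("2010-04-01")

    def test_no_outpatient_exposure_is_ineligible(self):
        exp = exposures([("p1", "x", "2010-01-01", "2010-06-30", "inpatient", "systemic")])
        win, reason = co.build_window(exp)
        assert win is None and reason == "no_outpatient_exposure"

    def test_order_independent_and_idempotent(self):
        rows = [
            ("p1", "x", "2010-05-01", "2010-07-01", "outpatient", "systemic"),
            ("p1", "x", "2010-01-01", "2010-03-01", "outpatient", "systemic"),
        ]
        a, _ = co.build_window(exposures(rows))
        b, _ = co.build_window(exposures(rows[::-1]))
        c, _ = co.build_window(exposures(rows))
        assert a == b == c
        assert a.index_date == TS("2010-01-01")


class TestPeriodMedians:
    @pytest.fixture
    def window(self):
        return co.ObservationWindow("p1", TS("2010-01-01"), TS("2010-06-30"))

    def measurements(self, rows):
        return pd.DataFrame(
            rows, columns=["person_id", "concept", "date", "value", "setting"]
        ).assign(date=lambda d: pd.to_datetime(d["date"]))

    def test_median_of_three(self, window):
        meas = self.measurements(
            [("p1", "LDL-C", d, v, "outpatient")
             for d, v in [("2009-06-01", 130), ("2009-08-01", 150), ("2009-12-01", 170),
                          ("2010-03-01", 120)]]
        )
        out = co.period_medians(meas, {"p1": window}, "LDL-C")
        assert out["baseline"].item() == 150 and out["treatment"].item() == 120

    def test_induction_measurement_excluded_from_treatment(self, window):
        meas = self.measurements(
            [("p1", "LDL-C", "2009-06-01", 140, "outpatient"),
             ("p1", "LDL-C", "2010-01-11", 999, "outpatient"),  # index+10d
             ("p1", "LDL-C", "2010-03-01", 100, "outpatient")]
        )
        out = co.period_medians(meas, {"p1": window}, "LDL-C")
        assert out["treatment"].item() == 100

    def test_index_date_measurement_counts_as_baseline(self, window):
        meas = self.measurements(
            [("p1", "LDL-C", "2010-01-01", 111, "outpatient"),
             ("p1", "LDL-C", "2010-05-01", 100, "outpatient")]
        )
        out = co.period_medians(meas, {"p1": window}, "LDL-C")
        assert out["baseline"].item() == 111

    def test_inpatient_values_ignored(self, window):
        meas = self.measurements(
            [("p1", "LDL-C", "2009-06-01", 140, "outpatient"),
             ("p1", "LDL-C", "2009-07-01", 999, "inpatient"),
             ("p1", "LDL-C", "2010-03-01", 100, "outpatient")]
        )
        out = co.period_medians(meas, {"p1": window}, "LDL-C")
        assert out["baseline"].item() == 140


class TestRemoveOutliers:
    def test_gross_outlier_dropped_by_hand_computed_fences(self):
        base = np.linspace(95, 105, 20)
        df = pd.DataFrame(
            {"person_id": [f"p{i}" for i in range(21)],
             "baseline": np.append(base, 500.0),
             "treatment": np.append(base - 5, 95.0)}
        )
        q1, q3 = np.percentile(df["baseline"], [25, 75])
        assert 500.0 > q3 + 1.5 * (q3 - q1)  # the fence catches it
        kept, dropped = co.remove_outliers(df)
        assert dropped == ["p20"] and len(kept) == 20

    def test_all_equal_medians_drop_nothing(self):
        df = pd.DataFrame({"person_id": list("abcd"), "baseline": [100.0] * 4,
                           "treatment": [90.0] * 4})
        kept, dropped = co.remove_outliers(df)
        assert dropped == [] and len(kept) == 4

    def test_symmetric_data_is_identity(self):
        vals = np.array([90, 95, 100, 105, 110], dtype=float)
        df = pd.DataFrame({"person_id": list("abcde"), "baseline": vals,
                           "treatment": vals[::-1]})
        kept, dropped = co.remove_outliers(df)
        assert dropped == []

    def test_small_cohort_skipped_with_warning(self, caplog):
        df = pd.DataFrame({"person_id": list("abc"), "baseline": [1.0, 2.0, 999.0],
                           "treatment": [1.0, 2.0, 999.0]})
        with caplog.at_level("WARNING"):
            kept, dropped = co.remove_outliers(df)
        assert len(kept) == 3 and "too small" in caplog.text


class TestElixhauser:
    CODE_MAP = pd.DataFrame(
        {"prefix": ["428", "I50", "250", "E11"],
         "category": ["chf", "chf", "diabetes", "diabetes"]}
    )

    def conditions(self, rows):
        return pd.DataFrame(rows, columns=["person_id", "code", "date"]).assign(
            date=lambda d: pd.to_datetime(d["date"])
        )

    def test_no_conditions_is_zero(self):
        value, cats = co.elixhauser_index(
            self.conditions([]), TS("2009-01-01"), TS("2010-01-01"), self.CODE_MAP
        )
        assert value == 0 and cats == frozenset()

    def test_two_categories_count_two(self):
        cond = self.conditions(
            [("p", "428.0", "2009-05-01"), ("p", "E11.9", "2009-06-01"),
             ("p", "I50.1", "2009-07-01")]
        )
        value, cats = co.elixhauser_index(cond, TS("2009-01-01"), TS("2010-01-01"),
                                          self.CODE_MAP)
        assert value == 2 and cats == frozenset({"chf", "diabetes"})

    def test_nondecreasing_in_as_of_date(self):
        cond = self.conditions(
            [("p", "428.0", "2009-05-01"), ("p", "250.1", "2010-06-01")]
        )
        v1, _ = co.elixhauser_index(cond, TS("2009-01-01"), TS("2010-01-01"), self.CODE_MAP)
        v2, _ = co.elixhauser_index(cond, TS("2009-01-01"), TS("2010-12-01"), self.CODE_MAP)
        assert v1 <= v2 and (v1, v2) == (1, 2)

    def test_weighted_sum(self):
        cond = self.conditions([("p", "428.0", "2009-05-01"), ("p", "250.1", "2009-06-01")])
        weights = pd.Series({"chf": 7.0, "diabetes": 0.0})
        value, _ = co.elixhauser_index(cond, TS("2009-01-01"), TS("2010-01-01"),
                                       self.CODE_MAP, weights=weights)
        assert value == 7.0

    def test_empty_map_is_config_error(self):
        with pytest.raises(InputError):
            co.elixhauser_index(self.conditions([]), TS("2009-01-01"),
                                TS("2010-01-01"), self.CODE_MAP.iloc[0:0])


@pytest.fixture(scope="module")
def planted_ehr():
    cfg = SimulationConfig(seed=21, n_persons=30)
    drugs = {"cand": 0.0, "small": -5.0}
    violations = {
        "cand": {
            "age_out_of_range": 3,
            "missing_period_measurement": 4,
            "approved_drug_coexposure": 5,
            "non_systemic_route": 2,
        }
    }
    ehr, manifest = gen_ehr(cfg, drugs, n_per_drug={"small": 19},
                            violations=violations)
    return ehr, manifest


class TestExclusionCascade:
    def test_cascade_removes_exactly_the_planted_violations(self, planted_ehr):
        ehr, manifest = planted_ehr
        windows, _ = co.build_windows(ehr, "cand")
        sel = co.apply_exclusions(ehr, windows, {"anchor-approved"}, "cand",
                                  "LDL-C", route_filter=True)
        removed = set(sel.removals.items())
        expected = manifest.violation_set("cand")
        assert removed == expected
        assert len(sel.retained) == 30 and not sel.untestable

    def test_attrition_counts_nonincreasing_and_stepwise(self, planted_ehr):
        ehr, manifest = planted_ehr
        windows, _ = co.build_windows(ehr, "cand")
        sel = co.apply_exclusions(ehr, windows, {"anchor-approved"}, "cand",
                                  "LDL-C", route_filter=True)
        counts = [n for _, n in sel.attrition.steps]
        assert counts == sorted(counts, reverse=True)
        steps = dict(sel.attrition.steps)
        assert steps["eligible_window"] == 44
        assert steps["age_in_range"] == 41
        assert steps["biomarker_both_periods"] == 37
        assert steps["no_approved_drug"] == 32
        assert steps["systemic_route_only"] == 30

    def test_small_cohort_flagged_untestable(self, planted_ehr):
        ehr, _ = planted_ehr
        windows, _ = co.build_windows(ehr, "small")
        sel = co.apply_exclusions(ehr, windows, {"anchor-approved"}, "small", "LDL-C")
        assert len(sel.retained) == 19 and sel.untestable

    def test_tested_drug_itself_approved_not_excluded(self, planted_ehr):
        ehr, _ = planted_ehr
        windows, _ = co.build_windows(ehr, "cand")
        # when the tested drug is on the approved list, its own users stay
        sel = co.apply_exclusions(ehr, windows, {"cand", "anchor-approved"},
                                  "cand", "LDL-C")
        assert "approved_drug_coexposure" in set(sel.removals.values())
        sel_self = co.apply_exclusions(ehr, windows, {"cand"}, "cand", "LDL-C")
        assert "approved_drug_coexposure" not in set(sel_self.removals.values())

    def test_retained_persons_have_no_blocked_overlap(self, planted_ehr):
        ehr, _ = planted_ehr
        windows, _ = co.build_windows(ehr, "cand")
        sel = co.apply_exclusions(ehr, windows, {"anchor-approved"}, "cand", "LDL-C")
        exp = ehr.drug_exposures
        anchor = exp[exp["ingredient"] == "anchor-approved"]
        for pid, win in sel.retained.items():
            mine = anchor[anchor["person_id"] == pid]
            ends = mine["end_date"].fillna(mine["start_date"] + 90 * co.DAY)
            assert not ((mine["start_date"] <= win.treatment_end)
                        & (ends >= win.baseline_start)).any()


class TestModelTable:
    def test_two_rows_per_person_and_coding(self, planted_ehr):
        ehr, _ = planted_ehr
        build = co.build_cohort(ehr, "cand", "LDL-C", {"anchor-approved"},
                                route_filter=True)
        table = build.model_table
        assert (table.groupby("person_id").size() == 2).all()
        assert set(table["period"]) == {"baseline", "treatment"}
        base = table[table["period"] == "baseline"]
        assert (base["drugExposure"] == 0).all()
        assert set(table["Gender"]) <= {0, 1} and set(table["Ethnicity"]) <= {0, 1}

    def test_normalization_contract(self, planted_ehr):
        ehr, _ = planted_ehr
        build = co.build_cohort(ehr, "cand", "LDL-C", {"anchor-approved"},
                                route_filter=True)
        for col in ("Age", "Comorbidity"):
            vals = build.model_table[col].to_numpy()
            assert abs(vals.mean()) < 1e-9
            assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-9) or vals.std() == 0

    def test_attrition_final_count_matches_table(self, planted_ehr):
        ehr, _ = planted_ehr
        build = co.build_cohort(ehr, "cand", "LDL-C", {"anchor-approved"},
                                route_filter=True)
        assert build.attrition.steps[-1][1] == build.model_table["person_id"].nunique()

    def test_medians_rescannable_from_raw_measurements(self, planted_ehr):
        # every value feeding a median is outpatient and inside its period
        ehr, _ = planted_ehr
        windows, _ = co.build_windows(ehr, "cand")
        sel = co.apply_exclusions(ehr, windows, {"anchor-approved"}, "cand", "LDL-C")
        med = co.period_medians(ehr.measurements, sel.retained, "LDL-C")
        meas = ehr.measurements
        outp = meas[(meas["setting"] == "outpatient") & (meas["concept"] == "LDL-C")]
        for rec in med.itertuples(index=False):
            win = sel.retained[rec.person_id]
            mine = outp[outp["person_id"] == rec.person_id]
            b = mine.loc[win.in_baseline(mine["date"]), "value"]
            t = mine.loc[win.in_effective_treatment(mine["date"]), "value"]
            assert rec.baseline == np.median(b) and rec.treatment == np.median(t)
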