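"""Indicator construction: eligibility, lower-bound missing-value policies,
two-thirds rules, missingness accounting and case-wise deletion."""

import numpy as np
import pandas as pd
import pytest

from mpikit.afcore import dcol, equal_nested_weights
from mpikit.indicators import (
    assemble_matrix,
    build_attendance,
    build_child_mortality,
    build_living_standards,
    build_nutrition,
    build_schooling,
    casewise_delete,
    filter_usual_members,
    missingness_report,
)
from mpikit.specs import default_specs
from mpikit.synthetic import GeneratorConfig, generate_population

from conftest import make_wave

SPECS = default_specs()


def one_value(series: pd.Series, hh: int, wave: pd.DataFrame):
    vals = series[wave["hh_id"] == hh].unique()
    assert len(vals) == 1
    return vals[0]


class TestUsualMembers:
    def test_no_visitors_unchanged(self):
        wave = make_wave([{"hh_id": 1}, {"hh_id": 2}])
        out = filter_usual_members(wave)
        assert len(out) == 2

    def test_visitor_child_removes_nutrition_eligibility(self):
        # the only under-5 is a visitor with a deprived z-score
        wave = make_wave([
            {"hh_id": 1, "person_id": 1},
            {"hh_id": 1, "person_id": 2, "age_years": 2, "age_months": 30,
             "haz": -3.0, "waz": -3.0, "bmi": np.nan, "usual_member": 0},
        ])
        # the remaining adult is measured and nourished -> non-deprived
        d = build_nutrition(filter_usual_members(wave), SPECS["nutr"])
        assert d.tolist() == [0.0]

    def test_flag_required(self):
        wave = make_wave([{"hh_id": 1}]).drop(columns="usual_member")
        with pytest.raises(ValueError, match="usual_member"):
            filter_usual_members(wave)


class TestNutrition:
    def test_stunted_child_deprives_household(self):
        wave = make_wave([
            {"hh_id": 1},
            {"hh_id": 1, "person_id": 2, "age_years": 3, "age_months": 40,
             "haz": -2.5, "waz": 0.0, "bmi": np.nan},
        ])
        assert one_value(build_nutrition(wave, SPECS["nutr"]), 1, wave) == 1.0

    def test_no_measured_age_members_non_deprived(self):
        wave = make_wave([{"hh_id": 1, "age_years": 80, "age_months": 960, "bmi": np.nan}])
        assert build_nutrition(wave, SPECS["nutr"]).tolist() == [0.0]

    def test_bmi_exactly_at_cutoff_not_undernourished(self):
        wave = make_wave([{"hh_id": 1, "bmi": 18.5}])
        assert build_nutrition(wave, SPECS["nutr"]).tolist() == [0.0]

    def test_zscore_boundary_strict(self):
        wave = make_wave([
            {"hh_id": 1, "age_years": 2, "age_months": 30, "haz": -2.0, "waz": -2.0,
             "bmi": np.nan},
        ])
        assert build_nutrition(wave, SPECS["nutr"]).tolist() == [0.0]

    def test_eligible_but_unmeasured_household_missing(self):
        wave = make_wave([{"hh_id": 1, "bmi": np.nan}])
        assert np.isnan(build_nutrition(wave, SPECS["nutr"]).iloc[0])


class TestChildMortality:
    def test_mother_reports_qualifying_death(self):
        wave = make_wave([
            {"hh_id": 1, "sex": "f", "age_years": 30, "age_months": 360,
             "woman_death_any": 1.0, "woman_death_5y_u18": 1.0},
        ])
        assert build_child_mortality(wave, SPECS["cm"]).tolist() == [1.0]

    def test_no_woman_male_reports_none(self):
        wave = make_wave([{"hh_id": 1, "male_cm_report": 0.0}])
        assert build_child_mortality(wave, SPECS["cm"]).tolist() == [0.0]

    def test_no_woman_no_male_report_missing(self):
        wave = make_wave([{"hh_id": 1, "male_cm_report": np.nan}])
        assert np.isnan(build_child_mortality(wave, SPECS["cm"]).iloc[0])

    def test_old_death_not_counted_under_dated_variant(self):
        wave = make_wave([
            {"hh_id": 1, "sex": "f", "age_years": 40, "age_months": 480,
             "woman_death_any": 1.0, "woman_death_5y_u18": 0.0},
        ])
        assert build_child_mortality(wave, SPECS["cm"]).tolist() == [0.0]
        any_death = SPECS["cm"].__class__(name="cm", use_death_dates=False)
        assert build_child_mortality(wave, any_death).tolist() == [1.0]


class TestSchooling:
    def test_one_achiever_suffices(self):
        wave = make_wave([
            {"hh_id": 1, "yschool": 2.0},
            {"hh_id": 1, "person_id": 2, "age_years": 12, "age_months": 150,
             "yschool": 6.0, "bmi": np.nan, "bmiz": 0.0},
        ])
        assert one_value(build_schooling(wave, SPECS["educ"]), 1, wave) == 0.0

    def test_two_thirds_rule_yields_missing(self):
        rows = [
            {"hh_id": 1, "yschool": 4.0},
            {"hh_id": 1, "person_id": 2, "yschool": np.nan},
            {"hh_id": 1, "person_id": 3, "yschool": np.nan},
        ]
        wave = make_wave(rows)
        assert np.isnan(build_schooling(wave, SPECS["educ"]).iloc[0])

    def test_two_thirds_with_achiever_still_non_deprived(self):
        rows = [
            {"hh_id": 1, "yschool": 7.0},
            {"hh_id": 1, "person_id": 2, "yschool": np.nan},
            {"hh_id": 1, "person_id": 3, "yschool": np.nan},
        ]
        wave = make_wave(rows)
        assert build_schooling(wave, SPECS["educ"]).iloc[0] == 0.0

    def test_all_report_under_six_deprived(self):
        wave = make_wave([
            {"hh_id": 1, "yschool": 5.0},
            {"hh_id": 1, "person_id": 2, "yschool": 0.0},
        ])
        assert one_value(build_schooling(wave, SPECS["educ"]), 1, wave) == 1.0


class TestAttendance:
    def child(self, pid, **over):
        return {"hh_id": 1, "person_id": pid, "age_years": 9, "age_months": 112,
                "bmi": np.nan, "bmiz": 0.0, "yschool": np.nan, **over}

    def test_out_of_school_child_deprives(self):
        wave = make_wave([{"hh_id": 1}, self.child(2, attending=0.0)])
        assert one_value(build_attendance(wave, SPECS["satt"]), 1, wave) == 1.0

    def test_two_thirds_missing_while_rest_attend(self):
        wave = make_wave([
            {"hh_id": 1},
            self.child(2, attending=1.0),
            self.child(3, attending=np.nan),
            self.child(4, attending=np.nan),
        ])
        assert np.isnan(build_attendance(wave, SPECS["satt"]).iloc[0])

    def test_no_school_age_children_non_deprived(self):
        wave = make_wave([{"hh_id": 1}])
        assert build_attendance(wave, SPECS["satt"]).tolist() == [0.0]

    def test_age_band_follows_entry_age(self):
        # entry age 7 => a 6-year-old is not school-age
        spec = SPECS["satt"].__class__(name="satt", school_entry_age=7)
        wave = make_wave([self.child(1, age_years=6, age_months=76, attending=0.0)])
        assert build_attendance(wave, spec).tolist() == [0.0]


class TestLivingStandards:
    def build(self, wave):
        return build_living_standards(wave, SPECS)

    def test_charcoal_deprives(self):
        wave = make_wave([{"hh_id": 1, "fuel": "charcoal"}])
        assert self.build(wave)["ckfl"].tolist() == [1.0]

    def test_improved_toilet_shared_flag_missing_non_deprived(self):
        wave = make_wave([{"hh_id": 1, "toilet": "flush", "toilet_shared": np.nan}])
        assert self.build(wave)["sani"].tolist() == [0.0]

    def test_improved_but_shared_deprives(self):
        wave = make_wave([{"hh_id": 1, "toilet": "flush", "toilet_shared": 1.0}])
        assert self.build(wave)["sani"].tolist() == [1.0]

    def test_safe_water_time_missing_non_deprived(self):
        wave = make_wave([{"hh_id": 1, "water_source": "piped", "water_time": np.nan}])
        assert self.build(wave)["wtr"].tolist() == [0.0]

    def test_thirty_minute_round_trip_deprives(self):
        wave = make_wave([{"hh_id": 1, "water_source": "piped", "water_time": 30.0}])
        assert self.build(wave)["wtr"].tolist() == [1.0]

    def test_two_small_assets_non_deprived(self):
        wave = make_wave([{"hh_id": 1, "asset_radio": 1.0, "asset_tv": 1.0}])
        assert self.build(wave)["asst"].tolist() == [0.0]

    def test_single_bicycle_no_car_deprives(self):
        wave = make_wave([
            {"hh_id": 1, "asset_radio": 0.0, "asset_tv": 0.0, "asset_bike": 1.0}
        ])
        assert self.build(wave)["asst"].tolist() == [1.0]

    def test_car_alone_non_deprived(self):
        wave = make_wave([
            {"hh_id": 1, "asset_radio": 0.0, "asset_tv": 0.0, "asset_car": 1.0}
        ])
        assert self.build(wave)["asst"].tolist() == [0.0]

    def test_rudimentary_walls_deprive_but_rudimentary_floor_does_not(self):
        wave = make_wave([{"hh_id": 1, "walls": "rudimentary"},
                          {"hh_id": 2, "floor": "rudimentary"}])
        d = self.build(wave)["hsg"]
        assert d.tolist() == [1.0, 0.0]

    def test_unknown_category_code_names_item(self):
        wave = make_wave([{"hh_id": 1, "fuel": "plutonium"}])
        with pytest.raises(ValueError, match="cooking fuel.*plutonium"):
            self.build(wave)


class TestAssembleAndMissingness:
    def test_fixture_a_scores(self, fixture_a_matrix):
        assert fixture_a_matrix["c"].tolist() == pytest.approx(
            [7 / 18, 2 / 9, 1 / 3, 0.0]
        )

    def test_household_constancy_on_synthetic_data(self, scheme):
        pop = generate_population(GeneratorConfig(seed=5, n_households=300))
        wave = pop.data.copy()
        wave["weight"] = 1.0
        matrix = assemble_matrix(wave, SPECS, scheme)
        for j in scheme.indicators:
            per_hh = matrix.groupby("hh_id")[dcol(j)].nunique(dropna=False)
            assert (per_hh == 1).all()

    def test_missing_indicator_blanks_score(self, scheme):
        wave = make_wave([{"hh_id": 1, "male_cm_report": np.nan}])  # cm missing
        matrix = assemble_matrix(wave, SPECS, scheme)
        assert np.isnan(matrix[dcol("cm")].iloc[0])
        assert np.isnan(matrix["c"].iloc[0])

    def test_missingness_report_counts(self, scheme):
        rows = [{"hh_id": h, "psu": h} for h in range(1, 11)]
        for h in (1, 2):
            rows[h - 1]["male_cm_report"] = np.nan  # cm unbuildable
        wave = make_wave(rows)
        matrix = assemble_matrix(wave, SPECS, scheme)
        rep = missingness_report(matrix, scheme)
        assert rep.mv_uw["cm"] == pytest.approx(20.0)
        assert rep.mv_w["cm"] == pytest.approx(20.0)
        assert rep.retained_uw == pytest.approx(80.0)

    def test_missingness_report_weighted(self, scheme):
        rows = [{"hh_id": h, "psu": h, "weight": 1.0} for h in range(1, 11)]
        for h in (1, 2):
            rows[h - 1]["male_cm_report"] = np.nan
            rows[h - 1]["weight"] = 3.0
        wave = make_wave(rows)
        matrix = assemble_matrix(wave, SPECS, scheme)
        rep = missingness_report(matrix, scheme)
        assert rep.mv_uw["cm"] == pytest.approx(20.0)
        assert rep.mv_w["cm"] == pytest.approx(600 / 14)

    def test_casewise_delete_matches_report(self, scheme):
        rows = [{"hh_id": h, "psu": h} for h in range(1, 11)]
        for h in (1, 2, 3):
            rows[h - 1]["male_cm_report"] = np.nan
        wave = make_wave(rows)
        matrix = assemble_matrix(wave, SPECS, scheme)
        rep = missingness_report(matrix, scheme)
        kept = casewise_delete(matrix, scheme)
        assert len(kept) / len(matrix) * 100.0 == pytest.approx(rep.retained_uw)
        assert set(kept["hh_id"]) == set(range(4, 11))

    def test_casewise_delete_identity_when_complete(self, fixture_a_matrix, scheme):
        kept = casewise_delete(fixture_a_matrix, scheme)
        assert len(kept) == len(fixture_a_matrix)

    def test_empty_sample_rejected(self, scheme):
        wave = make_wave([{"hh_id": 1, "male_cm_report": np.nan}])
        matrix = assemble_matrix(wave, SPECS, scheme)
        with pytest.raises(ValueError, match="every observation"):
            casewise_delete(matrix, scheme)
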