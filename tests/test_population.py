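"""Tests for virtual-patient generation, schedules and lifestyle sectioning."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from glycosim import (METParams, classify_cohort, classify_lifestyle,
                      default_population_spec, generate_patient,
                      generate_population, generate_schedule, met_hours)
from glycosim.datasets import participant_records
from glycosim.population import (FieldDist, activity_intensity_trace,
                                 deck_from_csv, deck_to_csv)


def degenerate_spec():
    spec = default_population_spec()
    for g in spec.groups.values():
        g.fields = {k: FieldDist(mean=fd.mean, sd=0.0)
                    for k, fd in g.fields.items()}
    spec = dataclasses.replace(spec, hr_rest=FieldDist(mean=75.4, sd=0.0))
    return spec


class TestPatientGeneration:
    def test_fields_within_truncation_bounds(self, rng):
        spec = default_population_spec()
        g = spec.group("male", "active")
        for _ in range(200):
            p = generate_patient("male", "active", spec, rng)
            for name, attr in [("age", p.age), ("height", p.height),
                               ("bmi", p.bmi), ("basal_glucose", p.basal_glucose),
                               ("cho_total", p.cho_total)]:
                lo, hi = g.fields[name].bounds(spec.truncation_sd)
                assert lo <= attr <= hi or (name == "age" and attr >= 20.0)
            assert p.bmi == pytest.approx(p.weight / p.height ** 2, abs=1e-9)
            assert p.hr_max == pytest.approx(220.0 - p.age)
            assert p.n_meals in (3, 4)

    def test_degenerate_spec_returns_group_means(self, rng):
        spec = degenerate_spec()
        p = generate_patient("male", "active", spec, rng)
        assert p.basal_glucose == 88.06
        assert p.cho_total == 300.0
        assert p.height == 1.69
        assert p.bmi == 23.59
        # weight follows from the BMI identity: 23.59 * 1.69^2
        assert p.weight == pytest.approx(23.59 * 1.69 ** 2)
        assert p.weight == pytest.approx(67.39, abs=0.05)

    def test_sample_means_recover_spec(self):
        # CLT check at n=4000 for the symmetric-truncation fields
        spec = default_population_spec()
        for grp in spec.groups.values():
            grp.n = 0
        spec.groups[("female", "sedentary")].n = 4000
        deck = generate_population(spec, seed=42)
        g = spec.group("female", "sedentary")
        n = len(deck)
        for name in ("basal_glucose", "cho_total", "height", "bmi"):
            vals = np.array([getattr(p, name if name != "basal_glucose"
                                     else "basal_glucose") for p in deck])
            fd = g.fields[name]
            assert abs(vals.mean() - fd.mean) < 3 * fd.sd / np.sqrt(n)

    def test_age_mean_matches_truncated_normal_oracle(self):
        # the age floor at 20 y truncates asymmetrically; the sample mean
        # must match the analytic truncated-normal mean, not the raw mean
        spec = default_population_spec()
        for grp in spec.groups.values():
            grp.n = 0
        spec.groups[("male", "active")].n = 4000
        deck = generate_population(spec, seed=7)
        ages = np.array([p.age for p in deck])
        fd = spec.group("male", "active").fields["age"]
        lo = max(fd.mean - 3 * fd.sd, spec.age_floor)
        hi = fd.mean + 3 * fd.sd
        a, b = (lo - fd.mean) / fd.sd, (hi - fd.mean) / fd.sd
        expected = stats.truncnorm.mean(a, b, loc=fd.mean, scale=fd.sd)
        sd_trunc = stats.truncnorm.std(a, b, loc=fd.mean, scale=fd.sd)
        assert abs(ages.mean() - expected) < 3 * sd_trunc / np.sqrt(len(ages))

    def test_reproducibility(self):
        spec = default_population_spec()
        for g in spec.groups.values():
            g.n = 10
        d1 = generate_population(spec, seed=99)
        d2 = generate_population(spec, seed=99)
        assert d1 == d2

    def test_deck_csv_round_trip(self, tmp_path):
        spec = default_population_spec()
        for g in spec.groups.values():
            g.n = 3
        deck = generate_population(spec, seed=5)
        path = tmp_path / "deck.csv"
        deck_to_csv(deck, path)
        back = deck_from_csv(path)
        assert len(back) == len(deck)
        assert back[0].basal_glucose == pytest.approx(deck[0].basal_glucose)


@pytest.fixture(scope="module")
def small_deck():
    spec = default_population_spec()
    for g in spec.groups.values():
        g.n = 10
    return generate_population(spec, seed=11)


class TestScheduleGeneration:

    def test_meals_partition_daily_carbohydrates(self, small_deck, rng):
        for p in small_deck:
            sched = generate_schedule(p, rng)
            assert len(sched.meals) == p.n_meals
            assert sched.total_grams == pytest.approx(p.cho_total, abs=0.01)

    def test_five_activities_each_within_3h_of_a_meal(self, small_deck, rng):
        for p in small_deck:
            sched = generate_schedule(p, rng)
            assert len(sched.activities) == 5
            meal_starts = [m.t0 for m in sched.meals]
            for a in sched.activities:
                delays = [a.t0 - t0 for t0 in meal_starts if a.t0 >= t0]
                assert delays and min(delays) <= 180.0

    def test_sedentary_intensity_band(self, rng):
        # sedentary activity stays within the 8-30 % oxygen-consumption band
        spec = default_population_spec()
        p = generate_patient("female", "sedentary", spec, rng)
        minutes_in_band = total_minutes = 0
        for _ in range(100):
            sched = generate_schedule(p, rng)
            for a in sched.activities:
                total_minutes += a.duration
                if 8.0 <= a.hr_pct <= 30.0:
                    minutes_in_band += a.duration
        assert minutes_in_band / total_minutes >= 0.95

    def test_classifier_schedule_coherence(self, rng):
        # active-group schedules classify active (>= 8 h above 1.5 MET)
        # and sedentary-group schedules classify sedentary, per the rule
        spec = default_population_spec()
        for g in spec.groups.values():
            g.n = 50
        deck = generate_population(spec, seed=21)
        agree = {"active": 0, "sedentary": 0}
        totals = {"active": 0, "sedentary": 0}
        for p in deck:
            sched = generate_schedule(p, rng)
            hours = met_hours(activity_intensity_trace(sched))
            totals[p.lifestyle] += 1
            agree[p.lifestyle] += classify_lifestyle(hours) == p.lifestyle
        for lifestyle in ("active", "sedentary"):
            assert agree[lifestyle] / totals[lifestyle] >= 0.90


class TestLifestyleClassifier:
    @pytest.mark.parametrize("hours,expected", [
        (14.78, "active"),      # housekeeper with the longest activity day
        (6.12, "sedentary"),    # the worked office-worker day
        (8.16, "active"),       # boundary-adjacent retirees/professionals
        (8.0, "active"),        # the rule is 'greater than or equal to 8 h'
        (7.999, "sedentary"),
    ])
    def test_eight_hour_rule(self, hours, expected):
        assert classify_lifestyle(hours) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_lifestyle(25.0)
        with pytest.raises(ValueError):
            classify_lifestyle(-1.0)

    def test_observed_cohort_splits_seven_thirteen(self):
        records = participant_records()
        assert len(records) == 20
        result = classify_cohort(records)
        assert result["counts"] == {"active": 7, "sedentary": 13}

    def test_degenerate_cohorts(self):
        records = participant_records()
        all_active = [dataclasses.replace(r, active_time=24.0) for r in records]
        all_rest = [dataclasses.replace(r, active_time=0.0) for r in records]
        assert classify_cohort(all_active)["counts"]["active"] == 20
        assert classify_cohort(all_rest)["counts"]["sedentary"] == 20


class TestMetHours:
    def test_rest_all_day_is_zero_hours(self):
        # MET(0) ~ 1.32 < 1.5, so a flat zero-intensity day counts nothing
        u = np.zeros(1441)
        assert met_hours(u) == 0.0

    def test_peak_intensity_all_day_is_24_hours(self):
        u = np.full(1441, 89.26)
        assert met_hours(u) == 24.0

    def test_six_hour_block_counts_six_hours(self):
        # MET(50) ~ 6.9 > 1.5; outside the block MET(0) < 1.5
        u = np.zeros(1441)
        u[360:720] = 50.0
        assert met_hours(u) == 6.0
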