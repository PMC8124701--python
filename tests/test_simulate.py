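"""Scenario schedule structure, glucose stand-in model and dataset assembly."""

import numpy as np
import pytest

from seasonalcgm.data import HYPO_TREATMENT, NIGHT
from seasonalcgm.simulate import (
    ScenarioConfig,
    Schedule,
    VirtualPatient,
    build_datasets,
    generate_schedule,
    schedule_events,
    simulate_glucose,
)


class TestSchedule:
    def test_default_four_month_counts(self):
        sched = generate_schedule(ScenarioConfig(days=120), seed=0)
        assert len(sched.meals) == 360
        labels = [l for _, l in schedule_events(sched)]
        assert labels.count(NIGHT) == 119

    def test_weekly_missed_boluses(self):
        cfg = ScenarioConfig(days=14, missed_bolus_mode="weekly")
        sched = generate_schedule(cfg, seed=1)
        assert sum(m["missed"] for m in sched.meals) == 2

    def test_sporadic_missed_bolus_separation(self):
        cfg = ScenarioConfig(days=120, missed_bolus_mode="sporadic")
        sched = generate_schedule(cfg, seed=3)
        days = sorted(m["day"] for m in sched.meals if m["missed"])
        assert all(b - a >= 14 for a, b in zip(days, days[1:]))

    def test_mealtime_and_size_variability(self):
        sched = generate_schedule(ScenarioConfig(days=120), seed=5)
        for slot in (0, 1, 2):
            times = np.array([m["time_min"] % 1440 for m in sched.meals
                              if m["slot"] == slot])
            assert 17 <= times.std() <= 23          # 20 ± 3 min
            sizes = np.array([m["grams"] for m in sched.meals if m["slot"] == slot])
            assert 0.08 <= sizes.std() / sizes.mean() <= 0.12   # CV 10 ± 2%

    def test_carb_count_error_skews_low(self):
        sched = generate_schedule(ScenarioConfig(days=120), seed=6)
        ratio = np.array([m["announced"] / m["grams"] for m in sched.meals])
        assert ratio.min() > 0.69 and ratio.max() < 1.11
        assert ratio.mean() < 1.0  # U(−30%, +10%) under-counts on average

    def test_exercise_only_on_configured_days(self):
        cfg = ScenarioConfig(days=28, exercise=True)
        sched = generate_schedule(cfg, seed=7)
        assert sched.exercise, "exercise sessions expected"
        assert all(ex["day"] % 7 in (1, 3, 5) for ex in sched.exercise)

    def test_deterministic_under_seed(self):
        cfg = ScenarioConfig(days=10)
        a = generate_schedule(cfg, seed=9)
        b = generate_schedule(cfg, seed=9)
        assert [m["time_min"] for m in a.meals] == [m["time_min"] for m in b.meals]


class TestSimulateGlucose:
    def _quiet_patient(self):
        return VirtualPatient(noise_sd=1e-9)

    def _empty_schedule(self, days=2):
        cfg = ScenarioConfig(days=days)
        return Schedule(meals=[], exercise=[],
                        horizon_samples=days * 288, config=cfg)

    def test_no_inputs_constant_basal(self):
        sim = simulate_glucose(self._empty_schedule(), self._quiet_patient(), seed=0)
        np.testing.assert_allclose(sim.cgm.values, 120.0, atol=0.1)

    def test_meal_peak_closed_form(self):
        # peak of grams·bio·gain·(t/τ)e^{−t/τ} is grams·bio·gain·e^{−1} at t = τ
        cfg = ScenarioConfig(days=2, pk_jitter=0.0, bioavail_jitter=0.0,
                             circadian_amp=0.0)
        sched = Schedule(
            meals=[{"day": 0, "slot": 0, "label": "Breakfast", "time_min": 120.0,
                    "grams": 50.0, "announced": 50.0, "units_per_ratio": 0.0,
                    "missed": True}],
            exercise=[], horizon_samples=2 * 288, config=cfg)
        pat = self._quiet_patient()
        sim = simulate_glucose(sched, pat, cfg, seed=0)
        peak = sim.cgm.values.max() - pat.basal_glucose
        assert peak == pytest.approx(50.0 * pat.meal_gain * np.exp(-1.0), rel=0.02)
        t_peak = np.argmax(sim.cgm.values) * 5.0 - 120.0
        assert abs(t_peak - pat.tau_meal) <= 10.0

    def test_hypo_rescue_logs_single_episode_event(self):
        # a large unannounced bolus forces hypoglycemia
        cfg = ScenarioConfig(days=1, pk_jitter=0.0, bioavail_jitter=0.0,
                             circadian_amp=0.0)
        sched = Schedule(
            meals=[{"day": 0, "slot": 0, "label": "Breakfast", "time_min": 240.0,
                    "grams": 1.0, "announced": 200.0, "units_per_ratio": 200.0,
                    "missed": False}],
            exercise=[], horizon_samples=288, config=cfg)
        sim = simulate_glucose(sched, self._quiet_patient(), cfg, seed=0)
        assert sim.cgm.values.min() < cfg.hypo_threshold
        hypo_events = [l for l in sim.events.labels if l == HYPO_TREATMENT]
        assert len(hypo_events) == len(sim.ground_truth["episodes"])
        assert len(sim.ground_truth["rescues"]) >= len(sim.ground_truth["episodes"])

    def test_output_clamped_to_cgm_range(self):
        cfg = ScenarioConfig(days=7)
        sched = generate_schedule(cfg, seed=0)
        pat = VirtualPatient(insulin_gain=300.0)  # absurd dosing to force rails
        sim = simulate_glucose(sched, pat, cfg, seed=0)
        assert sim.cgm.values.min() >= 40.0 and sim.cgm.values.max() <= 400.0

    def test_determinism(self):
        cfg = ScenarioConfig(days=5)
        pat = VirtualPatient()
        a = simulate_glucose(generate_schedule(cfg, seed=2), pat, cfg, seed=3)
        b = simulate_glucose(generate_schedule(cfg, seed=2), pat, cfg, seed=3)
        np.testing.assert_array_equal(a.cgm.values, b.cgm.values)
        assert a.events.equals(b.events)


class TestBuildDatasets:
    def test_three_datasets_structure(self):
        out = build_datasets(days_train=10, days_val=7, seeds=(1, 2, 3))
        assert set(out) == {"train", "val_normal", "val_abnormal"}
        assert len(out["train"].cgm) == 10 * 288
        assert len(out["val_normal"].cgm) == 7 * 288
        # abnormal set carries exercise ground truth on Tue/Thu/Sat only
        ex_days = {e["day"] % 7 for e in out["val_abnormal"].ground_truth["exercise"]}
        assert ex_days and ex_days <= {1, 3, 5}
        assert not out["val_normal"].ground_truth["exercise"]

    def test_exclusions_iff_missed_bolus(self):
        out = build_datasets(days_train=30, days_val=5, seeds=(4, 5, 6))
        missed = [m for m in out["train"].ground_truth["meals"] if m["missed"]]
        assert bool(out["train"].exclusion_flags) == bool(missed)
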