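"""Desk-scale type 1 diabetes scenario simulator.

Generates CGM traces and event logs with the statistical structure of an
open-loop therapy scenario: three daily meals (nominal 40/90/60 g at 7:00,
14:00 and 21:00, mealtime SD 20 min, size CV 10%), carb-counting error
U(−30%, +10%), absorption and insulin-pharmacokinetic jitter ±30%,
bioavailability jitter ±10%, circadian insulin-sensitivity modulation ±30%,
the 15-15 hypoglycemia rescue rule, sporadic or weekly missed boluses, and
optional exercise sessions (Tue/Thu/Sat, nominal 60 min at 18:00).

The glucose model is a deliberately simple impulse-response stand-in — a
unit-area gamma kernel per meal/bolus, a sinusoidal insulin-sensitivity
rhythm and AR(1) sensor noise — not a physiological simulator; its purpose
is to expose the modeling framework to comparable event and variability
structure.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    BREAKFAST,
    DINNER,
    HYPO_TREATMENT,
    LUNCH,
    NIGHT,
    EventLog,
    GlucoseSeries,
    write_cgm_csv,
    write_events_csv,
)

__all__ = [
    "ScenarioConfig",
    "VirtualPatient",
    "Schedule",
    "SimOutput",
    "generate_schedule",
    "simulate_glucose",
    "build_datasets",
]

SAMPLES_PER_DAY = 288  # 5-min sampling
MINUTES_PER_DAY = 1440


@dataclasses.dataclass
class ScenarioConfig:
    """Study-scenario parameters; defaults follow the training scenario."""

    days: int = 120
    meal_nominal: tuple = ((7.0, 40.0), (14.0, 90.0), (21.0, 60.0))  # (clock h, g)
    mealtime_sd: float = 20.0          # min
    meal_cv: float = 0.10
    carb_count_err: tuple = (-0.30, 0.10)   # uniform range on announced carbs
    pk_jitter: float = 0.30            # meal/insulin time-constant jitter
    bioavail_jitter: float = 0.10
    circadian_amp: float = 0.30
    night_delay: float = 6.0           # hours after dinner
    rescue_grams: float = 15.0
    rescue_recheck: float = 15.0       # min
    hypo_threshold: float = 70.0       # mg/dL
    missed_bolus_mode: str = "sporadic"    # 'sporadic' (>=14 d apart), 'weekly', 'none'
    missed_bolus_min_sep: int = 14     # days, sporadic mode
    exercise: bool = False
    exercise_days: tuple = (1, 3, 5)   # Tue/Thu/Sat (day 0 = Monday)
    exercise_start: float = 18.0       # clock hours
    exercise_start_sd: float = 20.0    # min
    exercise_duration: float = 60.0    # min
    exercise_duration_cv: float = 0.10
    sampling_period: int = 5           # min
    start_time: str = "2021-03-01T00:00:00"   # a Monday

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        for frac in (self.meal_cv, self.pk_jitter, self.bioavail_jitter,
                     self.circadian_amp, self.exercise_duration_cv):
            if not 0 <= frac < 1:
                raise ValueError("fractional parameters must lie in [0, 1)")
        if self.missed_bolus_mode not in ("sporadic", "weekly", "none"):
            raise ValueError("missed_bolus_mode must be sporadic/weekly/none")

    def to_flat_text(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name}: {getattr(self, f.name)!r}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclasses.dataclass
class VirtualPatient:
    """Impulse-response stand-in patient.

    Gains are chosen so nominal meals with correct boluses roughly return to
    basal, while under-bolusing produces sustained hyperglycemia.
    """

    basal_glucose: float = 120.0   # mg/dL
    carb_ratio: float = 10.0       # g of carbs covered per insulin unit
    meal_gain: float = 3.0         # mg/dL peak-scale per gram
    insulin_gain: float = 30.0     # mg/dL per unit
    tau_meal: float = 40.0         # min
    tau_insulin: float = 55.0      # min
    noise_sd: float = 2.0          # mg/dL, stationary SD of the AR(1) noise
    noise_ar: float = 0.7

    def __post_init__(self) -> None:
        if min(self.meal_gain, self.insulin_gain, self.tau_meal, self.tau_insulin) <= 0:
            raise ValueError("gains and time constants must be positive")


@dataclasses.dataclass
class Schedule:
    """Meal/bolus/exercise plan on the sampling grid (offsets in samples)."""

    meals: list        # dicts: day, slot, label, time_min, grams, announced, units, missed
    exercise: list     # dicts: day, start_min, duration_min
    horizon_samples: int
    config: ScenarioConfig


@dataclasses.dataclass
class SimOutput:
    cgm: GlucoseSeries
    events: EventLog
    exclusion_flags: list     # event indices tainted by training-mode missed boluses
    ground_truth: dict


_SLOT_LABELS = (BREAKFAST, LUNCH, DINNER)


def _pick_missed_days(cfg: ScenarioConfig, rng: np.random.Generator) -> set:
    """Days carrying a missed bolus, per the configured mode."""
    missed = set()
    if cfg.missed_bolus_mode == "weekly":
        for week_start in range(0, cfg.days, 7):
            week = range(week_start, min(week_start + 7, cfg.days))
            missed.add(int(rng.choice(list(week))))
    elif cfg.missed_bolus_mode == "sporadic":
        # roughly one per ~20 days, never closer than the minimum separation
        last = -10**9
        for day in range(cfg.days):
            if day - last >= cfg.missed_bolus_min_sep and rng.random() < 1.0 / 20.0:
                missed.add(day)
                last = day
    return missed


def generate_schedule(config: ScenarioConfig, seed: int = 0) -> Schedule:
    """Draw the jittered meal/bolus/exercise plan for the whole horizon."""
    rng = np.random.default_rng(seed)
    missed_days = _pick_missed_days(config, rng)
    horizon_min = config.days * MINUTES_PER_DAY
    meals = []
    for day in range(config.days):
        for _attempt in range(100):
            times = []
            for clock_h, _g in config.meal_nominal:
                t = day * MINUTES_PER_DAY + clock_h * 60.0 + rng.normal(0.0, config.mealtime_sd)
                times.append(t)
            if all(b - a > 2 * config.sampling_period for a, b in zip(times, times[1:])):
                break
        else:
            raise RuntimeError("could not draw non-colliding meal times")
        missed_slot = rng.integers(0, len(config.meal_nominal)) if day in missed_days else -1
        for slot, ((_h, grams_nom), t) in enumerate(zip(config.meal_nominal, times)):
            grams = max(1.0, grams_nom * (1.0 + config.meal_cv * rng.normal()))
            err = rng.uniform(*config.carb_count_err)
            announced = grams * (1.0 + err)
            missed = slot == missed_slot
            meals.append({
                "day": day,
                "slot": slot,
                "label": _SLOT_LABELS[slot],
                "time_min": float(t),
                "grams": float(grams),
                "announced": float(announced),
                "units_per_ratio": float(0.0 if missed else announced),
                "missed": bool(missed),
            })
    exercise = []
    if config.exercise:
        for day in range(config.days):
            if day % 7 in config.exercise_days:
                start = day * MINUTES_PER_DAY + config.exercise_start * 60.0 \
                    + rng.normal(0.0, config.exercise_start_sd)
                dur = config.exercise_duration * (1.0 + config.exercise_duration_cv * rng.normal())
                if start + dur < horizon_min:
                    exercise.append({"day": day, "start_min": float(start),
                                     "duration_min": float(max(10.0, dur))})
    return Schedule(
        meals=meals,
        exercise=exercise,
        horizon_samples=config.days * SAMPLES_PER_DAY,
        config=config,
    )


def schedule_events(schedule: Schedule) -> tuple:
    """Meal + night event offsets/labels (hypo events are added during sim)."""
    cfg = schedule.config
    period = cfg.sampling_period
    horizon = schedule.horizon_samples
    events = []  # (offset, label)
    for meal in schedule.meals:
        off = int(round(meal["time_min"] / period))
        events.append((off, meal["label"]))
        if meal["slot"] == 2:  # night starts a fixed delay after dinner
            night_off = int(round((meal["time_min"] + cfg.night_delay * 60.0) / period))
            if night_off < horizon:
                events.append((night_off, NIGHT))
    return events


def _gamma_kernel(n: int, tau_samples: float) -> np.ndarray:
    """Gamma response h(t; τ) = (t/τ²)·exp(−t/τ) sampled on the grid.

    Effects multiply this by τ, giving the dimensionless response
    r(t) = (t/τ)·exp(−t/τ), which peaks at e⁻¹ at t = τ, so a dose of
    ``grams × gain`` produces an excursion of about 0.37·grams·gain mg/dL.
    """
    t = np.arange(n, dtype=float)
    h = (t / tau_samples**2) * np.exp(-t / tau_samples)
    return h


def simulate_glucose(schedule: Schedule, patient: VirtualPatient,
                     config: ScenarioConfig | None = None,
                     seed: int = 1) -> SimOutput:
    """Run the impulse-response glucose model over a drawn schedule.

    Rescue carbs follow the 15-15 rule on the measured (noisy) trace; each
    episode's first rescue is logged as a single HypoTreatment event.  Output
    is clamped to the CGM range [40, 400] mg/dL.
    """
    cfg = config or schedule.config
    rng = np.random.default_rng(seed)
    period = cfg.sampling_period
    n = schedule.horizon_samples
    minutes = np.arange(n, dtype=float) * period

    # circadian insulin-sensitivity modulation
    S = 1.0 + cfg.circadian_amp * np.sin(2.0 * np.pi * minutes / MINUTES_PER_DAY)

    # exercise: sensitivity ×1.5 during the session + 3 h tail; accumulated
    # glucose drop (−0.5 mg/dL/min while exercising) decays over the tail
    ex_drop = np.zeros(n)
    for ex in schedule.exercise:
        s0 = int(round(ex["start_min"] / period))
        s1 = min(n, int(round((ex["start_min"] + ex["duration_min"]) / period)))
        tail = min(n, s1 + int(round(180.0 / period)))
        S[s0:tail] *= 1.5
        during = np.arange(s0, s1)
        ex_drop[during] -= 0.5 * (during - s0 + 1) * period
        total = -0.5 * max(0, s1 - s0) * period
        after = np.arange(s1, n)
        ex_drop[s1:] += total * np.exp(-(after - s1) * period / 90.0)

    meal_effect = np.zeros(n)
    insulin_action = np.zeros(n)
    kernel_len = SAMPLES_PER_DAY  # 24 h tail is ample for both kernels
    for meal in schedule.meals:
        off = int(round(meal["time_min"] / period))
        if off >= n:
            continue
        bio = 1.0 + rng.uniform(-cfg.bioavail_jitter, cfg.bioavail_jitter)
        tau_m = patient.tau_meal * (1.0 + rng.uniform(-cfg.pk_jitter, cfg.pk_jitter))
        k = _gamma_kernel(min(kernel_len, n - off), tau_m / period)
        meal_effect[off:off + k.size] += meal["grams"] * bio * patient.meal_gain * k * (tau_m / period)
        units = meal["units_per_ratio"] / patient.carb_ratio
        if units > 0:
            tau_i = patient.tau_insulin * (1.0 + rng.uniform(-cfg.pk_jitter, cfg.pk_jitter))
            ki = _gamma_kernel(min(kernel_len, n - off), tau_i / period)
            insulin_action[off:off + ki.size] += units * patient.insulin_gain * ki * (tau_i / period)

    # AR(1) sensor noise with the requested stationary SD
    innov_sd = patient.noise_sd * np.sqrt(1.0 - patient.noise_ar**2)
    noise = np.empty(n)
    noise[0] = rng.normal(0.0, patient.noise_sd)
    eps = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        noise[t] = patient.noise_ar * noise[t - 1] + eps[t]

    base = patient.basal_glucose + meal_effect - S * insulin_action + ex_drop + noise

    # 15-15 rescue rule on the measured trace
    rescue = np.zeros(n)
    recheck = int(round(cfg.rescue_recheck / period))
    tau_rescue = 15.0 / period  # fast carbs
    episodes = []               # first-rescue offsets
    rescues = []
    next_check = 0
    in_episode = False
    g = np.empty(n)
    for t in range(n):
        g[t] = min(400.0, max(40.0, base[t] + rescue[t]))
        if t < next_check:
            continue
        if g[t] < cfg.hypo_threshold:
            k = _gamma_kernel(min(kernel_len, n - t), tau_rescue)
            rescue[t:t + k.size] += cfg.rescue_grams * patient.meal_gain * k * tau_rescue
            rescues.append(t)
            if not in_episode:
                episodes.append(t)
                in_episode = True
            next_check = t + recheck
        else:
            in_episode = False

    cgm = GlucoseSeries(pd.Timestamp(cfg.start_time), g, sampling_period=period)

    # assemble the event log: meals + nights + hypo-treatment episodes
    raw_events = schedule_events(schedule) + [(t, HYPO_TREATMENT) for t in episodes]
    raw_events.sort(key=lambda e: (e[0], e[1]))
    used = set()
    final = []
    for off, label in raw_events:
        while off in used:
            off += 1            # nudge grid collisions to the next free sample
        if off >= n:
            continue
        used.add(off)
        final.append((off, label))
    final.sort(key=lambda e: e[0])
    times = [cgm.timestamp(off) for off, _ in final]
    labels = [label for _, label in final]
    events = EventLog(times, labels)

    # training-mode exclusions: missed-bolus meal event to the next event
    exclusions = []
    for meal in schedule.meals:
        if not meal["missed"]:
            continue
        off = int(round(meal["time_min"] / period))
        candidates = [i for i, (o, lab) in enumerate(final)
                      if lab == meal["label"] and abs(o - off) <= 1]
        exclusions.extend(candidates)

    ground_truth = {
        "meals": schedule.meals,
        "exercise": schedule.exercise,
        "rescues": [int(t) for t in rescues],
        "episodes": [int(t) for t in episodes],
    }
    return SimOutput(cgm=cgm, events=events,
                     exclusion_flags=sorted(set(exclusions)),
                     ground_truth=ground_truth)


def build_datasets(patient: VirtualPatient | None = None,
                   seeds: tuple = (11, 12, 13),
                   days_train: int = 120, days_val: int = 60) -> dict:
    """Training (sporadic missed boluses), 'normal' and 'abnormal' datasets."""
    patient = patient or VirtualPatient()
    cfg_train = ScenarioConfig(days=days_train, missed_bolus_mode="sporadic")
    cfg_val1 = ScenarioConfig(days=days_val, missed_bolus_mode="sporadic")
    cfg_val2 = ScenarioConfig(days=days_val, missed_bolus_mode="weekly", exercise=True)
    if len(set(seeds)) < 3:
        import warnings
        warnings.warn("overlapping seeds across datasets", stacklevel=2)
    out = {}
    for name, cfg, seed in [("train", cfg_train, seeds[0]),
                            ("val_normal", cfg_val1, seeds[1]),
                            ("val_abnormal", cfg_val2, seeds[2])]:
        sched = generate_schedule(cfg, seed=seed)
        out[name] = simulate_glucose(sched, patient, cfg, seed=seed + 10_000)
    return out


def write_dataset(sim: SimOutput, directory) -> None:
    """Persist a dataset: CGM + events CSV, ground truth and exclusions."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_cgm_csv(sim.cgm, directory / "cgm.csv")
    write_events_csv(sim.events, directory / "events.csv")
    (directory / "ground_truth.json").write_text(
        json.dumps(sim.ground_truth), encoding="utf-8")
    lines = ["event_index"] + [str(i) for i in sim.exclusion_flags]
    (directory / "exclusions.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")
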