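"""Monte Carlo virtual-population generation and lifestyle classification.

Virtual patients are sampled per sex x lifestyle group from truncated-normal
marginals (group mean +- SD, truncated at +-3 SD with physiological floors)
following the dependency order of the generation scheme: age and height
first, then body-mass index -- body weight is derived as ``BMI * height^2``
so the BMI identity holds exactly -- then basal glucose, daily carbohydrate
quantity and the activity-intensity repertoire, optionally shifted linearly
by the BMI z-score. The number of meals (3 or 4) follows from the
carbohydrate quantity.

A person is classified *physically active* when they spend at least 8 hours
of the day on activities above 1.5 metabolic equivalents (MET), and
*sedentary* otherwise.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import METParams
from .signals import (MINUTES_PER_DAY, ActivityEvent, DaySchedule, MealEvent,
                      activity_names_for, met_from_intensity, read_text_or_path)

__all__ = [
    "VirtualPatient", "PopulationSpec", "GroupSpec", "FieldDist",
    "ParticipantRecord", "generate_patient", "generate_population",
    "generate_schedule", "classify_lifestyle", "classify_cohort",
    "met_hours", "activity_intensity_trace", "load_table_records",
    "default_population_spec",
]

SEXES = ("male", "female")
LIFESTYLES = ("active", "sedentary")
ACTIVE_HOURS_THRESHOLD = 8.0
MET_CUTOFF = 1.5

#: activities contemplated per virtual patient per day
N_ACTIVITIES = 5
#: activities start within this many minutes after a meal
MAX_DELAY_AFTER_MEAL = 180.0

# meal-time windows (min from midnight), breakfast/lunch/snack/dinner
MEAL_WINDOWS_4 = ((450.0, 570.0), (780.0, 900.0), (1020.0, 1110.0), (1200.0, 1290.0))
MEAL_WINDOWS_3 = ((450.0, 570.0), (780.0, 900.0), (1200.0, 1290.0))

# activity duration ranges (min). Active days are built from long walks with
# at most one short higher-effort run, so the five activities total >= 8 h
# (4 * 115 + 25 = 485 min at minimum); sedentary blocks total < 8 h always.
WALK_DURATION = (115.0, 150.0)
RUN_DURATION = (25.0, 45.0)
SEDENTARY_DURATION = (40.0, 80.0)
RUN_PROBABILITY = 0.5  # chance the active day's effort slot is a run

#: Beta(alpha, beta) for the slow-carbohydrate fraction of each meal
SLOW_FRACTION_BETA = (9.0, 1.0)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class VirtualPatient:
    """A synthetic subject: demographics, physiology, diet and lifestyle."""

    sex: str
    lifestyle: str
    age: float          # years
    height: float       # m
    weight: float       # kg
    bmi: float          # kg/m^2
    basal_glucose: float  # mg/dL
    cho_total: float    # g/day
    n_meals: int        # 3 or 4
    hr_rest: float      # bpm
    hr_max: float       # bpm
    id: str | None = None
    occupation: str | None = None  # metadata only

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.lifestyle not in LIFESTYLES:
            raise ValueError(f"lifestyle must be one of {LIFESTYLES}")
        if abs(self.bmi - self.weight / self.height ** 2) > 0.05:
            raise ValueError("bmi inconsistent with weight/height^2")
        if not 60.0 < self.basal_glucose < 130.0:
            raise ValueError(f"basal glucose out of range: {self.basal_glucose}")
        if not 3 <= self.n_meals <= 4:
            raise ValueError("n_meals must be 3 or 4")
        if self.hr_rest >= self.hr_max:
            raise ValueError("resting heart rate must lie below HRmax")


@dataclass(frozen=True)
class FieldDist:
    """Truncated-normal marginal: mean, SD and truncation bounds."""

    mean: float
    sd: float
    lower: float | None = None
    upper: float | None = None

    def bounds(self, n_sd: float) -> tuple[float, float]:
        lo = self.mean - n_sd * self.sd if self.lower is None else self.lower
        hi = self.mean + n_sd * self.sd if self.upper is None else self.upper
        return lo, hi


@dataclass
class GroupSpec:
    """Counts and marginal distributions for one sex x lifestyle group."""

    n: int
    fields: dict[str, FieldDist]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group count must be non-negative")
        for name, dist in self.fields.items():
            if dist.sd < 0:
                raise ValueError(f"negative SD for field {name!r}")
            lo, hi = dist.bounds(3.0)
            if lo > hi:
                raise ValueError(f"unordered truncation bounds for field {name!r}")


@dataclass
class PopulationSpec:
    """Full population recipe: per-group counts and marginals plus knobs."""

    groups: dict[tuple[str, str], GroupSpec]
    hr_rest: FieldDist = FieldDist(75.4, 7.32, lower=45.0)
    truncation_sd: float = 3.0
    bmi_slope: float = 0.0  # z(BMI) shift, in field SDs, of glucose/CHO means
    age_floor: float = 20.0

    def group(self, sex: str, lifestyle: str) -> GroupSpec:
        try:
            return self.groups[(sex, lifestyle)]
        except KeyError:
            raise KeyError(f"population spec has no ({sex}, {lifestyle}) group") from None

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PopulationSpec":
        text = read_text_or_path(source)
        raw = yaml.safe_load(text)
        groups = {}
        for key, g in raw["groups"].items():
            lifestyle, sex = key.split("_")
            fields = {name: FieldDist(**fd) if isinstance(fd, dict)
                      else FieldDist(mean=fd[0], sd=fd[1])
                      for name, fd in g["fields"].items()}
            groups[(sex, lifestyle)] = GroupSpec(n=g.get("n", 0), fields=fields)
        kwargs = {}
        if "hr_rest" in raw:
            kwargs["hr_rest"] = FieldDist(**raw["hr_rest"])
        for k in ("truncation_sd", "bmi_slope", "age_floor"):
            if k in raw:
                kwargs[k] = raw[k]
        return cls(groups=groups, **kwargs)


@dataclass(frozen=True)
class ParticipantRecord:
    """An observed participant: occupation and daily time above 1.5 MET."""

    id: str
    occupation: str
    active_time: float  # hours/day

    def __post_init__(self) -> None:
        if not 0.0 <= self.active_time <= 24.0:
            raise ValueError(f"active_time must lie in [0, 24] h, got {self.active_time}")


# ---------------------------------------------------------------------------
# packaged specs and records
# ---------------------------------------------------------------------------

def default_population_spec() -> PopulationSpec:
    """The packaged virtual-population recipe (group means +- SD per factor)."""
    ref = resources.files("glycosim.data").joinpath("population_groups.yaml")
    return PopulationSpec.from_yaml(ref.read_text())


def load_table_records(source: str | Path | None = None) -> list[ParticipantRecord]:
    """Load participant occupation/activity-time records (packaged 20-person set)."""
    if source is None:
        text = resources.files("glycosim.data").joinpath(
            "participants_activity_time.csv").read_text()
    else:
        text = read_text_or_path(source)
    records = []
    for row in csv.DictReader(io.StringIO(text)):
        records.append(ParticipantRecord(id=row["id"], occupation=row["occupation"],
                                         active_time=float(row["active_time"])))
    return records


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _draw_truncnorm(rng: np.random.Generator, dist: FieldDist,
                    n_sd: float, mean_shift: float = 0.0,
                    floor: float | None = None) -> float:
    """Rejection-sample one truncated-normal value; error after 1000 misses."""
    mean = dist.mean + mean_shift
    if dist.sd == 0.0:
        return mean
    lo, hi = dist.bounds(n_sd)
    if floor is not None:
        lo = max(lo, floor)
    for _ in range(1000):
        x = rng.normal(mean, dist.sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError(
        f"rejection sampling exhausted for mean={mean}, sd={dist.sd}, "
        f"bounds=({lo}, {hi}); check the population spec")


def generate_patient(sex: str, lifestyle: str, spec: PopulationSpec,
                     rng: np.random.Generator, pid: str | None = None) -> VirtualPatient:
    """Sample one virtual patient in the generation scheme's dependency order.

    Age and height are drawn first; BMI is drawn and weight derived as
    ``BMI * height^2`` (keeping the BMI identity exact); basal glucose and
    daily carbohydrate quantity follow, their means optionally shifted by
    ``bmi_slope`` field-SDs per BMI z-score (0 by default, which reproduces
    the configured marginals exactly). Meals per day: 4 when the
    carbohydrate draw exceeds the group mean, else 3.
    """
    g = spec.group(sex, lifestyle)
    nsd = spec.truncation_sd
    age = _draw_truncnorm(rng, g.fields["age"], nsd, floor=spec.age_floor)
    height = _draw_truncnorm(rng, g.fields["height"], nsd)
    bmi_dist = g.fields["bmi"]
    bmi = _draw_truncnorm(rng, bmi_dist, nsd)
    weight = bmi * height ** 2
    z_bmi = 0.0 if bmi_dist.sd == 0 else (bmi - bmi_dist.mean) / bmi_dist.sd
    glu_dist = g.fields["basal_glucose"]
    cho_dist = g.fields["cho_total"]
    basal_glucose = _draw_truncnorm(
        rng, glu_dist, nsd, mean_shift=spec.bmi_slope * z_bmi * glu_dist.sd)
    cho_total = _draw_truncnorm(
        rng, cho_dist, nsd, mean_shift=spec.bmi_slope * z_bmi * cho_dist.sd)
    hr_rest = _draw_truncnorm(rng, spec.hr_rest, nsd)
    return VirtualPatient(
        sex=sex, lifestyle=lifestyle, age=age, height=height, weight=weight,
        bmi=bmi, basal_glucose=basal_glucose, cho_total=cho_total,
        n_meals=4 if cho_total > cho_dist.mean else 3,
        hr_rest=hr_rest, hr_max=220.0 - age, id=pid)


def generate_population(spec: PopulationSpec,
                        seed: int | np.random.Generator = 0) -> list[VirtualPatient]:
    """Sample a full deck, iterating groups in a fixed order for reproducibility."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    deck: list[VirtualPatient] = []
    for lifestyle in LIFESTYLES:
        for sex in SEXES:
            if (sex, lifestyle) not in spec.groups:
                continue
            g = spec.group(sex, lifestyle)
            for i in range(g.n):
                deck.append(generate_patient(
                    sex, lifestyle, spec, rng, pid=f"{lifestyle}_{sex}_{i:04d}"))
    return deck


# ---------------------------------------------------------------------------
# schedule generation
# ---------------------------------------------------------------------------

def _meal_times(n_meals: int, rng: np.random.Generator) -> list[float]:
    windows = MEAL_WINDOWS_4 if n_meals == 4 else MEAL_WINDOWS_3
    return [float(rng.uniform(lo, hi)) for lo, hi in windows]


def _split_cho(total: float, n_meals: int, rng: np.random.Generator) -> list[float]:
    weights = rng.dirichlet(np.full(n_meals, 5.0))
    return list(total * weights)


_WALK_NAMES = ("walk_55", "walk_70", "walk_85", "walk_100")


def _draw_activity_slots(lifestyle: str,
                         rng: np.random.Generator) -> list[tuple[str, float]]:
    """Names and durations for the day's five activities (unordered slots)."""
    slots: list[tuple[str, float]] = []
    if lifestyle == "active":
        for _ in range(N_ACTIVITIES - 1):
            slots.append((str(rng.choice(_WALK_NAMES)),
                          float(rng.uniform(*WALK_DURATION))))
        if rng.random() < RUN_PROBABILITY:  # one higher-effort slot at most
            slots.append(("run_130", float(rng.uniform(*RUN_DURATION))))
        else:
            slots.append((str(rng.choice(_WALK_NAMES)),
                          float(rng.uniform(*WALK_DURATION))))
    else:
        names = sorted(activity_names_for("sedentary"))
        for _ in range(N_ACTIVITIES):
            slots.append((str(rng.choice(names)),
                          float(rng.uniform(*SEDENTARY_DURATION))))
    rng.shuffle(slots)
    return slots


def generate_schedule(patient: VirtualPatient, rng: np.random.Generator,
                      max_day_retries: int = 200) -> DaySchedule:
    """Random day: 3-4 meals partitioning the daily carbohydrates plus 5
    physical activities, each starting within 3 h after some intake.

    Meal times fall in breakfast/lunch(/snack)/dinner windows; each meal's
    slow/fast split is Beta-distributed toward slow absorption. Activities
    are placed greedily in chronological anchor order; an infeasible day
    (overlap that cannot be resolved) is resampled wholesale.
    """
    table = activity_names_for(patient.lifestyle)

    for _ in range(max_day_retries):
        times = _meal_times(patient.n_meals, rng)
        grams = _split_cho(patient.cho_total, patient.n_meals, rng)
        meals = []
        for t0, gr in zip(times, grams):
            slow_frac = rng.beta(*SLOW_FRACTION_BETA)
            meals.append(MealEvent(t0=t0, DGS=slow_frac * gr, DGF=(1 - slow_frac) * gr))

        # cycle activity anchors over meals so at most two share an intake
        anchor_idx = sorted((i % patient.n_meals) for i in range(N_ACTIVITIES))
        slots = _draw_activity_slots(patient.lifestyle, rng)
        activities: list[ActivityEvent] = []
        prev_end = 0.0
        feasible = True
        for ai, (name, duration) in zip(anchor_idx, slots):
            anchor = times[ai]
            lo = max(anchor, prev_end)
            hi = min(anchor + MAX_DELAY_AFTER_MEAL, MINUTES_PER_DAY - duration)
            if lo > hi:
                feasible = False
                break
            start = float(rng.uniform(lo, hi))
            activities.append(ActivityEvent(t0=start, duration=duration,
                                            hr_pct=table[name], name=name))
            prev_end = start + duration
        if feasible:
            return DaySchedule(meals=meals, activities=activities)
    raise RuntimeError(
        f"could not place {N_ACTIVITIES} non-overlapping activities for "
        f"patient {patient.id or '?'} after {max_day_retries} day resamples")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_lifestyle(active_time: float) -> str:
    """'active' when time above 1.5 MET is >= 8 h/day, else 'sedentary'."""
    if not 0.0 <= active_time <= 24.0:
        raise ValueError(f"active_time must lie in [0, 24] h, got {active_time}")
    return "active" if active_time >= ACTIVE_HOURS_THRESHOLD else "sedentary"


def classify_cohort(records: list[ParticipantRecord]) -> dict:
    """Apply the 8-hour rule to a cohort; per-class counts and membership."""
    if not records:
        raise ValueError("cannot classify an empty cohort")
    membership = {"active": [], "sedentary": []}
    for rec in records:
        membership[classify_lifestyle(rec.active_time)].append(rec.id)
    return {
        "counts": {k: len(v) for k, v in membership.items()},
        "membership": membership,
    }


def activity_intensity_trace(schedule: DaySchedule,
                             horizon: float = MINUTES_PER_DAY) -> np.ndarray:
    """Intensity trace on a 1-min grid with zero baseline outside activities.

    Used for activity-time accounting (sitting still is 0 on this trace, in
    contrast with the physiological input trace whose baseline is u_basal).
    """
    t = np.arange(0.0, horizon + 1.0)
    u = np.zeros_like(t)
    for a in schedule.activities:
        u[(t >= a.t0) & (t < a.end)] = a.resolve_intensity()
    return u


def met_hours(u_trace: np.ndarray, mp: METParams = METParams(),
              dt: float = 1.0) -> float:
    """Hours of the day spent above 1.5 MET, from a uniform intensity trace."""
    met = met_from_intensity(np.asarray(u_trace, dtype=float), mp)
    return float(dt * np.count_nonzero(np.atleast_1d(met)[:-1] > MET_CUTOFF) / 60.0)


# ---------------------------------------------------------------------------
# deck I/O
# ---------------------------------------------------------------------------

DECK_COLUMNS = ["id", "sex", "lifestyle", "age", "height", "weight", "bmi",
                "basal_glucose", "cho_total", "n_meals", "hr_rest", "hr_max",
                "occupation"]


def deck_to_dataframe(deck: list[VirtualPatient]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(p, c) for c in DECK_COLUMNS} for p in deck])


def deck_to_csv(deck: list[VirtualPatient], path: str | Path) -> None:
    deck_to_dataframe(deck).to_csv(path, index=False)


def deck_from_csv(path: str | Path) -> list[VirtualPatient]:
    df = pd.read_csv(path)
    deck = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in DECK_COLUMNS if c in df.columns}
        for opt in ("id", "occupation"):
            if opt in kwargs and pd.isna(kwargs[opt]):
                kwargs[opt] = None
        kwargs["n_meals"] = int(kwargs["n_meals"])
        deck.append(VirtualPatient(**kwargs))
    return deck
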