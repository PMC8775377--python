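"""Exogenous signals: meal glucose appearance, heart-rate intensity, MET.

Builds the two inputs that drive the day model -- the alimentary bolus
``d(t)`` from timed slow/fast carbohydrate intakes and the exercise
intensity ``u(t)`` from heart-rate percentages -- plus the Gaussian
heart-rate-to-MET estimator and the duration-intensity threshold ATH used
by the glycogen-depletion logic.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .params import METParams, ModelParams

__all__ = [
    "MealEvent",
    "ActivityEvent",
    "DaySchedule",
    "meal_rate",
    "intensity_from_hr",
    "met_from_intensity",
    "ath_threshold",
    "build_signals",
    "named_activity_table",
]

MINUTES_PER_DAY = 1440


def read_text_or_path(source) -> str:
    """Return file contents when ``source`` is an existing path, else the text itself."""
    s = str(source)
    if "\n" not in s and len(s) < 1000 and Path(s).exists():
        return Path(s).read_text()
    return s

#: coefficients of the critical-threshold parabola ATH(u) = c2*u^2 + c1*u
ATH_QUADRATIC = -1.152
ATH_LINEAR = 87.471


@dataclass(frozen=True)
class MealEvent:
    """A carbohydrate intake: onset time and slow/fast gram loads.

    ``t0`` is clock time in minutes from midnight; ``DGS``/``DGF`` are grams
    of slow- and fast-absorbing carbohydrate.
    """

    t0: float
    DGS: float = 0.0
    DGF: float = 0.0

    def __post_init__(self) -> None:
        if self.DGS < 0 or self.DGF < 0:
            raise ValueError("carbohydrate masses must be non-negative")
        if self.DGS + self.DGF <= 0:
            raise ValueError("a meal must carry a positive carbohydrate mass")
        if not 0 <= self.t0 < MINUTES_PER_DAY:
            raise ValueError(f"meal time must lie in [0, {MINUTES_PER_DAY}) min, got {self.t0}")

    @property
    def grams(self) -> float:
        return self.DGS + self.DGF


@dataclass(frozen=True)
class ActivityEvent:
    """A physical-activity block with a constant heart-rate-derived intensity.

    The intensity may be given directly as ``hr_pct`` (% of maximal heart
    rate), as an absolute heart rate ``hr`` (bpm, resolved against the
    subject's HRmax), or as a named activity from the packaged table.
    """

    t0: float
    duration: float
    hr_pct: float | None = None
    hr: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("activity duration must be positive")
        if not 0 <= self.t0 < MINUTES_PER_DAY:
            raise ValueError("activity start must lie within the day")
        if self.hr_pct is None and self.hr is None and self.name is None:
            raise ValueError("activity needs hr_pct, hr, or a named intensity")
        if self.hr_pct is not None and not 0 < self.hr_pct <= 100:
            raise ValueError(f"hr_pct must lie in (0, 100], got {self.hr_pct}")

    @property
    def end(self) -> float:
        return self.t0 + self.duration

    def resolve_intensity(self, hr_max: float | None = None) -> float:
        """Absolute intensity u (% HRmax) for this block."""
        if self.hr_pct is not None:
            return float(self.hr_pct)
        if self.hr is not None:
            if hr_max is None:
                raise ValueError("absolute heart rate given but no subject HRmax")
            return intensity_from_hr(self.hr, hr_max)
        return named_activity_table()[self.name]


def _read_activity_yaml() -> dict:
    ref = resources.files("glycosim.data").joinpath("activities.yaml")
    return yaml.safe_load(ref.read_text())


_ACTIVITY_CACHE: dict[str, float] = {}


def named_activity_table() -> dict[str, float]:
    """Map of named activities to heart-rate percentages (% HRmax).

    Calibrated so that active-lifestyle activities span ~30-80 % oxygen
    consumption (walks at 55-100 m/min, runs at 130 m/min) and sedentary
    activities stay in the 8-30 % band (desk work, reading, sweeping).
    """
    if not _ACTIVITY_CACHE:
        raw = _read_activity_yaml()
        for group in raw.values():
            _ACTIVITY_CACHE.update(group)
    return dict(_ACTIVITY_CACHE)


def activity_names_for(lifestyle: str) -> dict[str, float]:
    """Named-activity intensities available to one lifestyle group."""
    raw = _read_activity_yaml()
    key = {"active": "active", "sedentary": "sedentary"}.get(lifestyle)
    if key is None:
        raise ValueError(f"unknown lifestyle {lifestyle!r}")
    return dict(raw[key])


# ---------------------------------------------------------------------------
# elementary signal maps
# ---------------------------------------------------------------------------

def intensity_from_hr(hr, hr_max: float):
    """Exercise intensity u = 100 * HR / HRmax, clipped to [0, 100].

    A slight overshoot (up to 5 % above HRmax) is tolerated and clipped;
    anything larger is rejected as a data error.
    """
    if hr_max <= 0:
        raise ValueError("hr_max must be positive")
    hr = np.asarray(hr, dtype=float)
    if np.any(hr < 0) or np.any(hr > 1.05 * hr_max):
        raise ValueError("heart rate outside the plausible (0, 1.05*HRmax] range")
    u = np.clip(100.0 * hr / hr_max, 0.0, 100.0)
    return float(u) if u.ndim == 0 else u


def met_from_intensity(u, mp: METParams = METParams()):
    """Metabolic equivalents for a heart-rate percentage, MET = a*exp(-((u-b)/c)^2)."""
    u = np.asarray(u, dtype=float)
    met = mp.a * np.exp(-(((u - mp.b) / mp.c) ** 2))
    return float(met) if met.ndim == 0 else met


def ath_threshold(u):
    """Critical threshold of accumulated intensity, ATH(u) = -1.152 u^2 + 87.471 u.

    Clamped at zero: beyond the parabola's positive root any ongoing exercise
    is immediately past threshold.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("intensity must be non-negative")
    ath = np.maximum(ATH_QUADRATIC * u ** 2 + ATH_LINEAR * u, 0.0)
    return float(ath) if ath.ndim == 0 else ath


def _kernel(tau: np.ndarray, ra: float, rb: float) -> np.ndarray:
    """Unit-mass two-compartment absorption density, zero for tau < 0."""
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau >= 0
    tp = tau[pos]
    out[pos] = ra * rb / (rb - ra) * (np.exp(-ra * tp) - np.exp(-rb * tp))
    return out


def meal_rate(t, meals, params: ModelParams):
    """Glucose appearance d(t) in mg/dL/min from a list of meals.

    Each meal contributes its slow and fast carbohydrate masses through the
    two-compartment kernel; grams convert to concentration by
    ``meal_yield * 1000 mg/g / VolG dL``, so the time kernel is a unit-mass
    density and the integral of d over a long horizon equals
    ``sum(grams) * 1000 / VolG`` mg/dL.
    """
    t = np.asarray(t, dtype=float)
    d = np.zeros_like(t)
    scale = params.meal_yield * 1000.0 / params.VolG
    for m in meals:
        tau = t - m.t0
        if m.DGS:
            d = d + scale * m.DGS * _kernel(tau, params.r1, params.r2)
        if m.DGF:
            d = d + scale * m.DGF * _kernel(tau, params.r3, params.r4)
    return float(d) if d.ndim == 0 else d


# ---------------------------------------------------------------------------
# day schedules
# ---------------------------------------------------------------------------

@dataclass
class DaySchedule:
    """Timed meal and activity events for one simulated day."""

    meals: list[MealEvent] = field(default_factory=list)
    activities: list[ActivityEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.meals = sorted(self.meals, key=lambda m: m.t0)
        self.activities = sorted(self.activities, key=lambda a: a.t0)
        for prev, nxt in zip(self.activities, self.activities[1:]):
            if nxt.t0 < prev.end:
                raise ValueError(
                    f"overlapping activities at t={prev.t0:.0f} and t={nxt.t0:.0f} min")

    # -- serialization ---------------------------------------------------
    _CSV_FIELDS = ("kind", "t0", "duration", "DGS", "DGF", "hr_pct", "name")

    def to_rows(self) -> list[dict]:
        rows = []
        for m in self.meals:
            rows.append({"kind": "meal", "t0": m.t0, "duration": "",
                         "DGS": m.DGS, "DGF": m.DGF, "hr_pct": "", "name": ""})
        for a in self.activities:
            rows.append({"kind": "activity", "t0": a.t0, "duration": a.duration,
                         "DGS": "", "DGF": "",
                         "hr_pct": "" if a.hr_pct is None else a.hr_pct,
                         "name": a.name or ""})
        return rows

    def to_csv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=self._CSV_FIELDS)
        writer.writeheader()
        writer.writerows(self.to_rows())
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, source: str | Path) -> "DaySchedule":
        text = read_text_or_path(source)
        meals, acts = [], []
        for row in csv.DictReader(io.StringIO(text)):
            if row["kind"] == "meal":
                meals.append(MealEvent(t0=float(row["t0"]),
                                       DGS=float(row["DGS"] or 0),
                                       DGF=float(row["DGF"] or 0)))
            elif row["kind"] == "activity":
                acts.append(ActivityEvent(
                    t0=float(row["t0"]), duration=float(row["duration"]),
                    hr_pct=float(row["hr_pct"]) if row.get("hr_pct") else None,
                    name=row.get("name") or None))
            else:
                raise ValueError(f"unknown event kind {row['kind']!r}")
        return cls(meals=meals, activities=acts)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "meals": [{"t0": m.t0, "DGS": m.DGS, "DGF": m.DGF} for m in self.meals],
            "activities": [
                {"t0": a.t0, "duration": a.duration,
                 **({"hr_pct": a.hr_pct} if a.hr_pct is not None else {}),
                 **({"name": a.name} if a.name else {})}
                for a in self.activities],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DaySchedule":
        text = read_text_or_path(source)
        payload = json.loads(text)
        return cls(meals=[MealEvent(**m) for m in payload.get("meals", [])],
                   activities=[ActivityEvent(**a) for a in payload.get("activities", [])])

    @property
    def total_grams(self) -> float:
        return sum(m.grams for m in self.meals)


def build_signals(schedule: DaySchedule, params: ModelParams,
                  hr_max: float | None = None,
                  horizon: float = MINUTES_PER_DAY) -> dict[str, np.ndarray]:
    """Assemble the model's exogenous traces on a uniform 1-minute grid.

    Returns a dict with keys ``t`` (min), ``u`` (absolute intensity, % HRmax;
    ``u_basal`` between activity blocks), ``d`` (meal appearance, mg/dL/min)
    and ``t_meal_ref`` (minutes since the most recent meal onset, 0 before
    the first meal).
    """
    t = np.arange(0.0, horizon + 1.0)
    u = np.full_like(t, params.u_basal)
    for a in schedule.activities:
        mask = (t >= a.t0) & (t < a.end)
        u[mask] = a.resolve_intensity(hr_max)
    d = meal_rate(t, schedule.meals, params)
    t_ref = np.zeros_like(t)
    for m in schedule.meals:
        after = t >= m.t0
        t_ref[after] = t[after] - m.t0
    return {"t": t, "u": u, "d": np.atleast_1d(d), "t_meal_ref": t_ref}
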