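"""Whole-day integration of the extended Bergman model for one subject.

The day runs 00:00-24:00 on a clock-time axis in minutes. Integration is
event-driven: the horizon is split at every meal onset, every activity
start/stop, and at each crossing of the integrated intensity ``A`` through
the ATH threshold, so the discontinuous branches of the intensity and
glycogenolysis dynamics switch only at segment boundaries and each segment
presents the stiff-capable adaptive solver with a smooth right-hand side.
Output is resampled to a uniform 1-minute grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import STATE_NAMES, ModelState
from .params import METParams, ModelParams
from .signals import (MINUTES_PER_DAY, DaySchedule, ath_threshold,
                      meal_rate, met_from_intensity)

__all__ = ["SimResult", "GlycemicSummary", "SolverOptions", "simulate_day", "summarize"]

#: glucose floor used when a trajectory is clamped (mg/dL)
G_EPSILON = 1e-6
HYPO_THRESHOLD = 70.0
RANGE_LOW, RANGE_HIGH = 80.0, 120.0
ACTIVE_MET_CUTOFF = 1.5


@dataclass(frozen=True)
class SolverOptions:
    """Adaptive-integration settings for :func:`simulate_day`."""

    method: str = "LSODA"
    rtol: float = 1e-7
    atol: float = 1e-9
    no_exercise: bool = False   # force u_eff == 0 (diet-only contrast run)


@dataclass
class GlycemicSummary:
    """Daily glycemic and activity metrics of one simulated trajectory."""

    g_min: float
    g_max: float
    g_mean: float
    time_below_70: float    # min
    time_in_80_120: float   # min
    active_hours: float     # h with MET > 1.5

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SimResult:
    """Uniform-grid trajectories of one simulated day.

    ``states`` is an ``(n, 9)`` array in :data:`glycosim.model.STATE_NAMES`
    order; ``u`` is the absolute intensity trace (% HRmax), ``d`` the meal
    appearance (mg/dL/min) and ``met`` the MET trace derived from ``u``.
    """

    t: np.ndarray
    states: np.ndarray
    u: np.ndarray
    d: np.ndarray
    met: np.ndarray
    summary: GlycemicSummary
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if len(self.t) != len(self.states):
            raise ValueError("trajectory length must equal grid length")

    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def G(self) -> np.ndarray:
        return self.state("G")

    @property
    def I(self) -> np.ndarray:
        return self.state("I")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "t", self.t)
        df["u"] = self.u
        df["d"] = self.d
        df["MET"] = self.met
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.summary.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def plot(self, path: str | Path | None = None):
        """Three-panel trace plot (glucose / meal appearance / intensity)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(3, 1, sharex=True, figsize=(9, 7))
        hours = self.t / 60.0
        axes[0].plot(hours, self.G, color="tab:blue")
        axes[0].axhline(HYPO_THRESHOLD, color="tab:red", ls=":", lw=0.8)
        axes[0].set_ylabel("glucose (mg/dL)")
        axes[1].plot(hours, self.d, color="tab:green")
        axes[1].set_ylabel("d(t) (mg/dL/min)")
        axes[2].plot(hours, self.u, color="tab:orange")
        axes[2].set_ylabel("u(t) (% HRmax)")
        axes[2].set_xlabel("time of day (h)")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def summarize(t: np.ndarray, G: np.ndarray, met: np.ndarray) -> GlycemicSummary:
    """Glycemic summary on a uniform grid by the left-rectangle rule."""
    if len(t) < 2:
        raise ValueError("need a non-empty trajectory on a grid of >= 2 points")
    dt = float(t[1] - t[0])
    Gl, metl = G[:-1], met[:-1]
    return GlycemicSummary(
        g_min=float(G.min()),
        g_max=float(G.max()),
        g_mean=float(Gl.mean()),
        time_below_70=float(dt * np.count_nonzero(Gl < HYPO_THRESHOLD)),
        time_in_80_120=float(dt * np.count_nonzero((Gl >= RANGE_LOW) & (Gl <= RANGE_HIGH))),
        active_hours=float(dt * np.count_nonzero(metl > ACTIVE_MET_CUTOFF) / 60.0),
    )


# ---------------------------------------------------------------------------
# event-driven integration
# ---------------------------------------------------------------------------

def _segment_breakpoints(schedule: DaySchedule, horizon: float) -> np.ndarray:
    pts = {0.0, float(horizon)}
    for m in schedule.meals:
        if m.t0 < horizon:
            pts.add(float(m.t0))
    for a in schedule.activities:
        if a.t0 < horizon:
            pts.add(float(a.t0))
        if a.end < horizon:
            pts.add(float(a.end))
    return np.array(sorted(pts))


def _segment_intensity(schedule: DaySchedule, t_mid: float, hr_max: float | None,
                       params: ModelParams) -> float:
    for a in schedule.activities:
        if a.t0 <= t_mid < a.end:
            return a.resolve_intensity(hr_max)
    return params.u_basal


def _last_meal_onset(schedule: DaySchedule, t: float) -> float | None:
    onset = None
    for m in schedule.meals:
        if m.t0 <= t:
            onset = m.t0
    return onset


def simulate_day(schedule: DaySchedule, params: ModelParams | None = None,
                 subject=None, options: SolverOptions | None = None,
                 met_params: METParams | None = None,
                 horizon: float = MINUTES_PER_DAY,
                 initial_state: ModelState | None = None) -> SimResult:
    """Integrate the 9-state day model and return uniform 1-minute traces.

    Parameters
    ----------
    schedule
        Meal and activity events for the day.
    params
        Model parameter set; defaults to the packaged healthy-subject set.
        If ``subject`` is given, weight, basal glucose and distribution
        volume are rescaled to the subject.
    subject
        Optional subject descriptor with ``weight``, ``basal_glucose`` and
        ``hr_max`` attributes (e.g. a :class:`glycosim.population.VirtualPatient`).
    options
        Solver settings; ``no_exercise=True`` removes the above-basal
        intensity input, reducing the system to the 3-state Bergman core.
    initial_state
        Defaults to the fasted rest equilibrium ``(Ib, 0, Gb, 0, ..., 0)``.
    """
    from .params import default_params  # local import keeps module load light

    params = params if params is not None else default_params()
    options = options or SolverOptions()
    met_params = met_params or METParams()
    hr_max = None
    if subject is not None:
        params = params.for_subject(subject.weight, subject.basal_glucose)
        hr_max = getattr(subject, "hr_max", None)

    y0 = (initial_state or ModelState.rest_equilibrium(params)).as_array()
    breaks = _segment_breakpoints(schedule, horizon)
    grid = np.arange(0.0, horizon + 1.0)
    traj = np.empty((len(grid), 9))
    traj[0] = y0
    w_over_v = params.W / params.VolG
    meta: dict = {"clamped_minutes": 0, "segments": 0}

    def make_rhs(u_eff: float, gly_on: bool, t_meal0: float | None):
        def f(t, y):
            I, X, G, Gprod, Gup, Ie, P, A, Ggly = y
            d = meal_rate(t, schedule.meals, params)
            t_ref = 0.0 if t_meal0 is None else t - t_meal0
            release = params.gamma * max(G - params.h_eff, 0.0) * t_ref
            dI = -params.eta * (I - params.Ib) + release - Ie
            dX = -params.p2 * X + params.p3 * (I - params.Ib)
            dG = (-params.p1 * (G - params.Gb) - X * G
                  + w_over_v * (Gprod - Ggly) - w_over_v * Gup + d)
            dGprod = params.a1 * P - params.a2 * Gprod
            dGup = params.a3 * P - params.a4 * Gup
            dIe = params.a5 * P - params.a6 * Ie
            dP = 0.8 * (u_eff - P)
            if u_eff > 0:
                dA = u_eff
                dGgly = params.K if gly_on else 0.0
            else:
                dA = -A / params.a_reset_tau
                dGgly = -Ggly / params.T1
            return (dI, dX, dG, dGprod, dGup, dIe, dP, dA, dGgly)
        return f

    def integrate(t0: float, t1: float, y: np.ndarray, u_eff: float,
                  gly_on: bool, t_meal0: float | None) -> np.ndarray:
        pts = grid[(grid > t0) & (grid <= t1)]
        t_eval = np.concatenate([pts, [t1]]) if (len(pts) == 0 or pts[-1] != t1) \
            else pts
        sol = solve_ivp(make_rhs(u_eff, gly_on, t_meal0), (t0, t1), y,
                        method=options.method, rtol=options.rtol,
                        atol=options.atol, t_eval=t_eval, max_step=t1 - t0)
        if not sol.success:
            raise RuntimeError(
                f"integration failed on [{t0:.2f}, {t1:.2f}] min: {sol.message}; "
                f"last state {y.tolist()}")
        for tv, yv in zip(sol.t, sol.y.T):
            idx = int(round(tv))
            if abs(tv - idx) < 1e-9 and 0 <= idx < len(grid):
                traj[idx] = yv
        meta["segments"] += 1
        return sol.y[:, -1].copy()

    y = y0.copy()
    for s0, s1 in zip(breaks[:-1], breaks[1:]):
        t_mid = 0.5 * (s0 + s1)
        u_abs = _segment_intensity(schedule, t_mid, hr_max, params)
        u_eff = 0.0 if options.no_exercise else max(u_abs - params.u_basal, 0.0)
        t_meal0 = _last_meal_onset(schedule, s0)
        if u_eff > 0:
            ath = ath_threshold(u_eff)
            gly_on = y[7] >= ath
            if not gly_on:
                t_cross = s0 + (ath - y[7]) / u_eff
                if t_cross < s1:  # split at the A-ATH crossing
                    y = integrate(s0, t_cross, y, u_eff, False, t_meal0)
                    y = integrate(t_cross, s1, y, u_eff, True, t_meal0)
                    continue
            y = integrate(s0, s1, y, u_eff, gly_on, t_meal0)
        else:
            y = integrate(s0, s1, y, 0.0, False, t_meal0)

    G = traj[:, 2]
    n_clamped = int(np.count_nonzero(G < G_EPSILON))
    if n_clamped:
        traj[:, 2] = np.maximum(G, G_EPSILON)
        meta["clamped_minutes"] = n_clamped
        meta["warning"] = "glucose trace clamped at epsilon; inputs drove G non-positive"

    # exogenous traces on the same grid
    u_trace = np.full_like(grid, params.u_basal)
    for a in schedule.activities:
        mask = (grid >= a.t0) & (grid < a.end)
        u_trace[mask] = a.resolve_intensity(hr_max)
    if options.no_exercise:
        u_model = np.full_like(grid, params.u_basal)
    else:
        u_model = u_trace
    d_trace = np.atleast_1d(meal_rate(grid, schedule.meals, params))
    met_trace = np.atleast_1d(met_from_intensity(u_model, met_params))
    summary = summarize(grid, traj[:, 2], met_trace)
    meta["no_exercise"] = options.no_exercise
    return SimResult(t=grid, states=traj, u=u_model, d=d_trace,
                     met=met_trace, summary=summary, metadata=meta)
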