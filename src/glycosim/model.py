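"""Right-hand side of the extended Bergman minimal model.

State vector (9 variables, all per-minute dynamics):

====  =========  =============================================================
idx   symbol     meaning
====  =========  =============================================================
0     I          plasma insulin (uU/mL)
1     X          insulin action on glucose clearance (1/min)
2     G          plasma glucose (mg/dL)
3     Gprod      exercise-induced hepatic glucose production (mg/kg/min)
4     Gup        exercise-induced glucose uptake (mg/kg/min)
5     Ie         exercise-induced insulin removal (uU/mL/min)
6     PVO2max    oxygen-consumption rate above basal (% of maximum)
7     A          integrated exercise intensity (% * min)
8     Ggly       glycogenolysis-rate decline (mg/kg/min)
====  =========  =============================================================

The model equations:

.. math::

    dI/dt &= -\\eta (I - I_b) + \\gamma\\,[G - h]^+\\, t_{ref} - I_e \\\\
    dX/dt &= -p_2 X + p_3 (I - I_b) \\\\
    dG/dt &= -p_1 (G - G_b) - X G
             + \\tfrac{W}{Vol_G}(G_{prod} - G_{gly}) - \\tfrac{W}{Vol_G} G_{up}
             + d(t)

with first-order exercise filters driven by PVO2max
(``dGprod/dt = a1*P - a2*Gprod`` etc., ``dP/dt = -0.8 P + 0.8 u``) and the
piecewise integrated-intensity / glycogenolysis logic of
:func:`integrated_intensity_change` and :func:`glycogenolysis_rate_change`.

The pancreatic release term is taken as the *positive part* ``[G - h]^+``
multiplied by the time elapsed since the most recent meal onset, so a fasted
subject sits at an exact rest equilibrium ``(Ib, 0, Gb, 0, ..., 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams
from .signals import ath_threshold

__all__ = [
    "ModelState",
    "ExogenousInput",
    "rhs",
    "glycogenolysis_rate_change",
    "integrated_intensity_change",
    "STATE_NAMES",
]

STATE_NAMES = ("I", "X", "G", "Gprod", "Gup", "Ie", "PVO2max", "A", "Ggly")

#: first-order rate of the oxygen-consumption filter (1/min); printed model constant
PVO2_RATE = 0.8


@dataclass
class ModelState:
    """One point of the 9-dimensional model state."""

    I: float
    X: float
    G: float
    Gprod: float = 0.0
    Gup: float = 0.0
    Ie: float = 0.0
    PVO2max: float = 0.0
    A: float = 0.0
    Ggly: float = 0.0

    @classmethod
    def rest_equilibrium(cls, params: ModelParams) -> "ModelState":
        """Fasted steady state: basal insulin and glucose, no exercise fluxes."""
        return cls(I=params.Ib, X=0.0, G=params.Gb)

    def as_array(self) -> np.ndarray:
        return np.array([self.I, self.X, self.G, self.Gprod, self.Gup,
                         self.Ie, self.PVO2max, self.A, self.Ggly])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(*map(float, y))


@dataclass(frozen=True)
class ExogenousInput:
    """Model inputs at one instant.

    ``u`` is the exercise intensity *above basal* (% of the HRmax-derived
    scale; 0 at rest), ``d`` the meal glucose appearance (mg/dL/min) and
    ``t_meal_ref`` the minutes elapsed since the most recent meal onset
    (0 before the first meal) driving the pancreatic release ramp.
    """

    u: float = 0.0
    d: float = 0.0
    t_meal_ref: float = 0.0

    def __post_init__(self) -> None:
        if self.u < 0 or self.d < 0 or self.t_meal_ref < 0:
            raise ValueError("exogenous inputs u, d, t_meal_ref must be non-negative")


def integrated_intensity_change(A: float, u: float, reset_tau: float = 0.001) -> float:
    """Rate of change of the integrated exercise intensity ``A``.

    While exercising (``u > 0``) the intensity accumulates at rate ``u``;
    at rest ``A`` resets rapidly toward zero (first-order with the short
    ``reset_tau``), marking the start of the glycogen replenishment period.
    """
    if u > 0:
        return u
    return -A / reset_tau


def glycogenolysis_rate_change(Ggly: float, A: float, u: float,
                               params: ModelParams) -> float:
    """Rate of change of the glycogenolysis-rate decline ``Ggly``.

    During exercise the hepatic glycogenolysis rate is unaffected while the
    accumulated intensity ``A`` stays below the duration-intensity threshold
    ATH(u); once ``A`` reaches it, liver glycogen is considered depleting and
    the decline grows at the constant rate ``K``. At rest the decline
    recovers first-order with time constant ``T1``.
    """
    if u <= 0:
        return -Ggly / params.T1
    if A >= ath_threshold(u):
        return params.K
    return 0.0


def rhs(state: ModelState | np.ndarray, inp: ExogenousInput,
        params: ModelParams) -> np.ndarray:
    """Time derivative of the full 9-state system at one instant.

    Parameters
    ----------
    state
        Current model state (a :class:`ModelState` or a length-9 array in
        :data:`STATE_NAMES` order).
    inp
        Exogenous inputs (above-basal intensity, meal appearance, meal clock).
    params
        Model parameter set.

    Returns
    -------
    numpy.ndarray
        d/dt of ``(I, X, G, Gprod, Gup, Ie, PVO2max, A, Ggly)`` per minute.
    """
    y = state.as_array() if isinstance(state, ModelState) else np.asarray(state, dtype=float)
    if y.shape != (9,):
        raise ValueError(f"state must have 9 components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite model state: integration blew up")

    I, X, G, Gprod, Gup, Ie, P, A, Ggly = y
    u, d = inp.u, inp.d

    release = params.gamma * max(G - params.h_eff, 0.0) * inp.t_meal_ref
    w_over_v = params.W / params.VolG

    dI = -params.eta * (I - params.Ib) + release - Ie
    dX = -params.p2 * X + params.p3 * (I - params.Ib)
    dG = (-params.p1 * (G - params.Gb) - X * G
          + w_over_v * (Gprod - Ggly) - w_over_v * Gup + d)
    dGprod = params.a1 * P - params.a2 * Gprod
    dGup = params.a3 * P - params.a4 * Gup
    dIe = params.a5 * P - params.a6 * Ie
    dP = -PVO2_RATE * P + PVO2_RATE * u
    dA = integrated_intensity_change(A, u, params.a_reset_tau)
    dGgly = glycogenolysis_rate_change(Ggly, A, u, params)

    return np.array([dI, dX, dG, dGprod, dGup, dIe, dP, dA, dGgly])
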