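"""Model parameters for the extended Bergman minimal model.

The parameter set couples a three-state Bergman glucose--insulin core
(plasma insulin ``I``, insulin action ``X``, plasma glucose ``G``) with a
Roy--Parker exercise subsystem (hepatic glucose production ``Gprod``,
glucose uptake ``Gup``, insulin removal ``Ie``, oxygen-consumption proxy
``PVO2max``, integrated intensity ``A`` and glycogenolysis decline ``Ggly``)
and a two-pool (slow/fast carbohydrate) meal-absorption kernel.

Defaults ship in :data:`DEFAULT_PARAM_FILE` and come from the healthy-subject
parameterizations of the source models this extension combines; every value
is overridable per subject or per study through YAML round-trip I/O.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["ModelParams", "METParams", "load_params", "save_params", "default_params"]

#: packaged YAML with default parameter values and their units sidecar
DEFAULT_PARAM_FILE = "default_params.yaml"


@dataclass
class ModelParams:
    """Rate constants, basal states and input coefficients of the day model.

    Units follow the conventional Bergman/Roy--Parker bookkeeping: glucose in
    mg/dL, insulin in uU/mL, time in minutes, exercise fluxes in mg/kg/min.
    """

    # Bergman core
    p1: float = 0.0317          # insulin-independent glucose clearance (1/min)
    p2: float = 0.0123          # insulin-action decay rate (1/min)
    p3: float = 4.92e-6         # insulin-dependent action gain ((uU/mL)^-1 min^-2)
    eta: float = 0.2659         # first-order insulin decay rate (1/min)
    gamma: float = 0.02         # pancreatic release gain ((uU/mL)/(min^2 mg/dL))
    h: float | None = None      # glucose threshold for beta-cell release; None -> Gb
    Gb: float = 85.0            # basal glucose (mg/dL)
    Ib: float = 7.0             # basal insulin (uU/mL)
    W: float = 70.0             # body weight (kg)
    VolG: float = 117.0         # glucose distribution volume (dL)
    # exercise subsystem
    a1: float = 0.00158         # Gprod gain (mg/kg/min^2 per % PVO2max)
    a2: float = 0.056           # Gprod decay (1/min)
    a3: float = 0.00195         # Gup gain (mg/kg/min^2 per % PVO2max)
    a4: float = 0.0485          # Gup decay (1/min)
    a5: float = 0.00125         # Ie gain (uU/mL/min^2 per % PVO2max)
    a6: float = 0.075           # Ie decay (1/min)
    T1: float = 6.0             # glycogenolysis recovery time constant (min)
    K: float = 0.0108           # glycogenolysis-rate decline once A >= ATH (mg/kg/min per min)
    # meal absorption
    r1: float = 0.007           # slow-CH absorption rate (1/min)
    r2: float = 0.009           # slow-CH absorption rate (1/min)
    r3: float = 0.028           # fast-CH absorption rate (1/min)
    r4: float = 0.035           # fast-CH absorption rate (1/min)
    meal_yield: float = 1.0     # carbohydrate bioavailability multiplier (dimensionless)
    # intensity handling
    u_basal: float = 8.0        # basal oxygen consumption, % of PVO2max
    a_reset_tau: float = 0.001  # time constant of the integrated-intensity reset (min)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ValueError` on a physically meaningless configuration."""
        positive = (
            "p1 p2 p3 eta gamma Gb Ib W VolG a1 a2 a3 a4 a5 a6 T1 K "
            "r1 r2 r3 r4 a_reset_tau"
        ).split()
        for name in positive:
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"parameter {name} must be strictly positive, got {v!r}")
        if self.r1 == self.r2:
            raise ValueError("slow-absorption kernel is singular when r1 == r2")
        if self.r3 == self.r4:
            raise ValueError("fast-absorption kernel is singular when r3 == r4")
        if not 0.0 <= self.u_basal < 100.0:
            raise ValueError(f"u_basal must lie in [0, 100), got {self.u_basal!r}")
        if self.meal_yield <= 0:
            raise ValueError("meal_yield must be strictly positive")
        if self.h is not None and self.h <= 0:
            raise ValueError("glucose threshold h must be positive (or None for h=Gb)")

    # -- derived ---------------------------------------------------------
    @property
    def h_eff(self) -> float:
        """Effective beta-cell release threshold: ``h`` or, by default, ``Gb``."""
        return self.Gb if self.h is None else self.h

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def for_subject(self, weight: float, basal_glucose: float,
                    vol_g_per_kg: float = 1.67) -> "ModelParams":
        """Rescale the basal state and distribution volume to one subject.

        The glucose distribution volume is taken proportional to body weight
        (``vol_g_per_kg`` dL/kg, ~117 dL at 70 kg).
        """
        return self.replace(W=weight, Gb=basal_glucose, VolG=vol_g_per_kg * weight)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class METParams:
    """Gaussian map from heart-rate percentage to metabolic equivalents.

    ``MET(u) = a * exp(-((u - b) / c)^2)`` with the fit against the
    Caballero heart-rate/MET activity table: peak ``a`` in MET, center ``b``
    and width ``c`` in % of maximal heart rate.
    """

    a: float = 10.25
    b: float = 89.26
    c: float = 62.36

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.c > 0):
            raise ValueError("MET curve requires a > 0 and c > 0")
        if not 0 < self.b <= 150:
            raise ValueError(f"MET curve center b out of range: {self.b!r}")


#: units sidecar written next to every serialized parameter set
PARAM_UNITS: dict[str, str] = {
    "p1": "1/min", "p2": "1/min", "p3": "(uU/mL)^-1 min^-2", "eta": "1/min",
    "gamma": "(uU/mL)/(min^2 mg/dL)", "h": "mg/dL", "Gb": "mg/dL", "Ib": "uU/mL",
    "W": "kg", "VolG": "dL",
    "a1": "mg/kg/min^2 per %", "a2": "1/min", "a3": "mg/kg/min^2 per %",
    "a4": "1/min", "a5": "uU/mL/min^2 per %", "a6": "1/min",
    "T1": "min", "K": "mg/kg/min per min",
    "r1": "1/min", "r2": "1/min", "r3": "1/min", "r4": "1/min",
    "meal_yield": "dimensionless", "u_basal": "% PVO2max", "a_reset_tau": "min",
}


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a parameter set as a flat YAML mapping plus a ``units`` sidecar."""
    payload = {"params": params.to_dict(), "units": dict(PARAM_UNITS)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_params(path: str | Path) -> ModelParams:
    """Read a parameter set written by :func:`save_params` (round-trip lossless)."""
    payload = yaml.safe_load(Path(path).read_text())
    mapping = payload["params"] if isinstance(payload, dict) and "params" in payload else payload
    known = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown parameter names in {path}: {sorted(unknown)}")
    return ModelParams(**mapping)


def default_params() -> ModelParams:
    """Load the packaged default parameter set."""
    ref = resources.files("glycosim.data").joinpath(DEFAULT_PARAM_FILE)
    payload = yaml.safe_load(ref.read_text())
    return ModelParams(**payload["params"])
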