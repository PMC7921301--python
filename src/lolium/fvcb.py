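"""Farquhar–von Caemmerer–Berry (FvCB) model of C3 leaf photosynthesis.

Net CO2 assimilation is the minimum of a Rubisco-limited rate

    A_C = Vcmax * (Ci - Gamma*) / (Ci + Kc * (1 + O/Ko)) - Rd

and a light-saturated RuBP-regeneration-limited rate

    A_J = Jmax * (Ci - Gamma*) / (4*Ci + 8*Gamma*) - Rd

where Ci is the intercellular CO2 mole fraction [umol mol-1], Vcmax the
maximum Rubisco carboxylation rate, Jmax the maximum RuBP-regeneration
rate, Rd respiration continuing in the light (all [umol m-2 s-1]),
Gamma* the photorespiratory CO2 compensation point [umol mol-1], Kc and
Ko the Rubisco Michaelis constants for CO2 [umol mol-1] and O2
[mmol mol-1], and O the chloroplastic O2 mole fraction [mmol mol-1].

Mole fractions are used throughout; at 1 atm total pressure a mole
fraction in umol mol-1 is numerically equal to a partial pressure in
ubar, so the parameterization is interchangeable with the
partial-pressure convention at standard pressure.

Kinetic constants and their temperature responses follow the Bernacchi
in-vivo parameterization (values at 25 C with single-exponential
Arrhenius scaling); they live in :data:`BERNACCHI_KINETICS_25C` and
:data:`BERNACCHI_ARRHENIUS` and are plain module-level data so that an
alternative parameterization can be swapped in from configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "R_GAS",
    "KineticConstants",
    "FvCBParams",
    "ArrheniusSpec",
    "Limitation",
    "BERNACCHI_KINETICS_25C",
    "BERNACCHI_ARRHENIUS",
    "ac_assimilation",
    "aj_assimilation",
    "predict_envelope",
    "arrhenius_scale",
    "kinetics_at_temperature",
    "params_to_temperature",
]

#: Universal gas constant [J mol-1 K-1].
R_GAS = 8.314

_T0_KELVIN = 273.15


class Limitation(str, Enum):
    """Which biochemical process limits assimilation at a point."""

    RUBISCO = "RUBISCO"
    RUBP = "RUBP"


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetic constants at a reference leaf temperature.

    Parameters
    ----------
    Kc
        Michaelis constant for CO2 [umol mol-1].
    Ko
        Michaelis constant for O2 [mmol mol-1].
    gamma_star
        Photorespiratory CO2 compensation point Gamma* [umol mol-1].
    O
        Chloroplastic O2 mole fraction [mmol mol-1]; defaults to the
        atmospheric value for 21% O2.
    T_ref
        Temperature the values refer to [C].
    """

    Kc: float
    Ko: float
    gamma_star: float
    O: float = 210.0
    T_ref: float = 25.0

    def __post_init__(self) -> None:
        for name in ("Kc", "Ko", "gamma_star", "O"):
            if not getattr(self, name) > 0:
                raise ValueError(f"kinetic constant {name} must be strictly positive")
        if not self.gamma_star < self.Kc:
            raise ValueError("gamma_star must be smaller than Kc")


@dataclass(frozen=True)
class FvCBParams:
    """Fitted FvCB parameters referenced to one leaf temperature.

    ``Jmax/Vcmax`` usually falls between 1 and 3 for healthy C3 leaves;
    values outside that band are accepted but worth inspecting.
    """

    Vcmax: float
    Jmax: float
    Rd: float
    at_temperature: float = 25.0

    def __post_init__(self) -> None:
        if not self.Vcmax > 0:
            raise ValueError("Vcmax must be strictly positive")
        if not self.Jmax > 0:
            raise ValueError("Jmax must be strictly positive")
        if self.Rd < 0:
            raise ValueError("Rd must be non-negative")

    @property
    def jv_ratio(self) -> float:
        return self.Jmax / self.Vcmax


@dataclass(frozen=True)
class ArrheniusSpec:
    """Single-exponential Arrhenius temperature response.

    ``dHa`` is the activation energy [J mol-1]. The optional scaling
    constant ``c`` fixes the absolute value at the reference
    temperature in the `exp(c - dHa/(R T))` form; relative scaling
    between two temperatures depends on ``dHa`` only.
    """

    dHa: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if not self.dHa > 0:
            raise ValueError("activation energy dHa must be strictly positive")


#: In-vivo Rubisco kinetics at 25 C (Bernacchi parameterization).
BERNACCHI_KINETICS_25C = KineticConstants(
    Kc=404.9,  # umol mol-1
    Ko=278.4,  # mmol mol-1
    gamma_star=42.75,  # umol mol-1
    O=210.0,  # mmol mol-1
    T_ref=25.0,
)

#: Activation energies [J mol-1] for the Arrhenius responses of the
#: kinetic constants and of the fitted parameters.
BERNACCHI_ARRHENIUS: dict[str, ArrheniusSpec] = {
    "Kc": ArrheniusSpec(dHa=79430.0),
    "Ko": ArrheniusSpec(dHa=36380.0),
    "gamma_star": ArrheniusSpec(dHa=37830.0),
    "Vcmax": ArrheniusSpec(dHa=65330.0),
    "Jmax": ArrheniusSpec(dHa=43900.0),
    "Rd": ArrheniusSpec(dHa=46390.0),
}


def _check_ci(Ci) -> np.ndarray:
    Ci = np.asarray(Ci, dtype=float)
    if np.any(Ci < 0):
        raise ValueError("Ci must be non-negative")
    return Ci


def ac_assimilation(Ci, params: FvCBParams, kin: KineticConstants):
    """Rubisco-limited net assimilation A_C [umol m-2 s-1].

    Strictly increasing and concave in ``Ci``; tends to ``Vcmax - Rd``
    as Ci grows and equals ``-Rd`` exactly at Ci = Gamma*.
    """
    Ci = _check_ci(Ci)
    km = kin.Kc * (1.0 + kin.O / kin.Ko)
    out = params.Vcmax * (Ci - kin.gamma_star) / (Ci + km) - params.Rd
    return float(out) if out.ndim == 0 else out


def aj_assimilation(Ci, params: FvCBParams, gamma_star: float):
    """RuBP-regeneration-limited net assimilation A_J [umol m-2 s-1].

    Tends to ``Jmax/4 - Rd`` as Ci grows; equals ``-Rd`` at Ci = Gamma*.
    """
    if not gamma_star > 0:
        raise ValueError("gamma_star must be strictly positive")
    Ci = _check_ci(Ci)
    out = params.Jmax * (Ci - gamma_star) / (4.0 * Ci + 8.0 * gamma_star) - params.Rd
    return float(out) if out.ndim == 0 else out


def predict_envelope(
    Ci_values, params: FvCBParams, kin: KineticConstants
) -> tuple[np.ndarray, list[Limitation]]:
    """Pointwise minimum of the two limitation branches.

    Returns the net assimilation vector and, per point, which branch is
    active. Ties are labelled RUBISCO (the lower-Ci branch).
    """
    Ci = _check_ci(Ci_values)
    if Ci.size == 0:
        raise ValueError("Ci_values must be non-empty")
    a_c = np.atleast_1d(ac_assimilation(Ci, params, kin))
    a_j = np.atleast_1d(aj_assimilation(Ci, params, kin.gamma_star))
    a = np.minimum(a_c, a_j)
    labels = [
        Limitation.RUBISCO if c <= j else Limitation.RUBP for c, j in zip(a_c, a_j)
    ]
    return a, labels


def arrhenius_scale(
    value_at_Tref: float, spec: ArrheniusSpec, T_target: float, T_ref: float
) -> float:
    """Scale a quantity from ``T_ref`` to ``T_target`` [both C].

    Multiplies by ``exp(dHa * (Tt - Tr) / (R * Tt * Tr))`` with
    temperatures in kelvin. The transform is multiplicative and exactly
    invertible: scaling there and back is the identity.
    """
    for T in (T_target, T_ref):
        if not (0.0 <= T <= 50.0):
            raise ValueError(f"temperature {T} C outside the physiological 0-50 C range")
    tt = T_target + _T0_KELVIN
    tr = T_ref + _T0_KELVIN
    return value_at_Tref * float(np.exp(spec.dHa * (tt - tr) / (R_GAS * tt * tr)))


def kinetics_at_temperature(
    kin: KineticConstants,
    T_leaf: float,
    arrhenius: dict[str, ArrheniusSpec] | None = None,
) -> KineticConstants:
    """Arrhenius-adjust Kc, Ko and Gamma* from ``kin.T_ref`` to ``T_leaf``."""
    arr = BERNACCHI_ARRHENIUS if arrhenius is None else arrhenius
    return replace(
        kin,
        Kc=arrhenius_scale(kin.Kc, arr["Kc"], T_leaf, kin.T_ref),
        Ko=arrhenius_scale(kin.Ko, arr["Ko"], T_leaf, kin.T_ref),
        gamma_star=arrhenius_scale(kin.gamma_star, arr["gamma_star"], T_leaf, kin.T_ref),
        T_ref=T_leaf,
    )


def params_to_temperature(
    params: FvCBParams,
    T_target: float,
    arrhenius: dict[str, ArrheniusSpec] | None = None,
) -> FvCBParams:
    """Arrhenius-adjust fitted Vcmax, Jmax and Rd to another temperature.

    Used for the small final normalization of fitted values to 25 C when
    the leaf temperature during measurement drifted from the setpoint.
    """
    arr = BERNACCHI_ARRHENIUS if arrhenius is None else arrhenius
    t0 = params.at_temperature
    return FvCBParams(
        Vcmax=arrhenius_scale(params.Vcmax, arr["Vcmax"], T_target, t0),
        Jmax=arrhenius_scale(params.Jmax, arr["Jmax"], T_target, t0),
        Rd=arrhenius_scale(params.Rd, arr["Rd"], T_target, t0),
        at_temperature=T_target,
    )
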