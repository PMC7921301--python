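"""Measured-to-derived trait transforms for per-plant records.

Each plant carries directly measured quantities (aboveground dry mass
DW, tiller count, leaf mass per area LMA, leaf C and N content,
operational gas exchange A_op / g_sop / E_op) plus derived quantities:

* ``LMA``        = leaf dry mass / leaf area              [g m-2]
* ``CN_ratio``   = C_mass / N_mass                        [-]
* ``WUE_op``     = A_op / E_op                            [umol mmol-1]
* ``LA_tiller``  = DW * LMF_ab / (LMA * tiller_count)     [m2 per tiller]
* ``A_plant``    = A_op * DW * LMF_ab / LMA               [umol s-1 per plant]

``LMF_ab`` is the aboveground leaf dry-mass fraction, a species- and
CO2-treatment-level constant. ``A_plant`` approximates whole-plant net
carbon gain by assuming every leaf operates at the single measured
A_op; total plant leaf area is ``DW * LMF_ab / LMA``, so
``A_plant = A_op * LA_tiller * tiller_count`` identically.

Water-use efficiency is defined flux-over-flux (CO2 uptake per unit
transpiration), which is what gives it its umol CO2 per mmol H2O units.

The vectorized entry point :func:`derive_traits` fills every derivable
column of a tidy per-plant DataFrame, leaving NaN wherever an input is
missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STATUS_LEVELS",
    "TREATMENTS",
    "SpeciesConstants",
    "DEFAULT_LMF_AB",
    "compute_lma",
    "compute_cn_ratio",
    "compute_la_tiller",
    "compute_a_plant",
    "compute_wue",
    "percent_response",
    "derive_traits",
]

STATUS_LEVELS = ("cultivar", "semi-natural", "wild", "annual", "hybrid")
TREATMENTS = ("ambient", "high_CO2")


@dataclass(frozen=True)
class SpeciesConstants:
    """Aboveground leaf dry-mass fraction LMF_ab per (species, treatment)."""

    lmf_ab: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for key, v in self.lmf_ab.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"LMF_ab for {key} must lie in (0, 1), got {v}")

    def get(self, species: str, treatment: str) -> float:
        return self.lmf_ab[(species, treatment)]


#: LMF_ab is highly conserved among ryegrass genotypes; only annual
#: ryegrass differs. Perennial values are also used for the hybrid.
DEFAULT_LMF_AB = SpeciesConstants(
    lmf_ab={
        ("perennial", "ambient"): 0.66,
        ("perennial", "high_CO2"): 0.59,
        ("annual", "ambient"): 0.57,
        ("annual", "high_CO2"): 0.53,
    }
)


def _as_array(x):
    return np.asarray(x, dtype=float)


def compute_lma(leaf_dry_mass, leaf_area):
    """Leaf mass per area [g m-2] from blade dry mass [g] and area [m2]."""
    mass, area = _as_array(leaf_dry_mass), _as_array(leaf_area)
    if np.any(area <= 0):
        raise ValueError("leaf_area must be strictly positive")
    if np.any(mass < 0):
        raise ValueError("leaf_dry_mass must be non-negative")
    out = mass / area
    return float(out) if out.ndim == 0 else out


def compute_cn_ratio(c_mass, n_mass):
    """Leaf C:N ratio from C and N content [% dry mass]."""
    c, n = _as_array(c_mass), _as_array(n_mass)
    if np.any(n <= 0):
        raise ValueError("N_mass must be strictly positive")
    out = c / n
    return float(out) if out.ndim == 0 else out


def compute_la_tiller(DW, tiller_count, LMA, LMF_ab):
    """Mean leaf area per tiller [m2]: DW * LMF_ab / (LMA * tiller count)."""
    dw, tc, lma, lmf = map(_as_array, (DW, tiller_count, LMA, LMF_ab))
    if np.any(tc <= 0):
        raise ValueError("tiller_count must be at least 1")
    if np.any(lma <= 0):
        raise ValueError("LMA must be strictly positive")
    out = dw * lmf / (lma * tc)
    return float(out) if out.ndim == 0 else out


def compute_a_plant(A_op, DW, LMF_ab, LMA):
    """Whole-plant net carbon gain [umol s-1]: A_op * DW * LMF_ab / LMA."""
    a, dw, lmf, lma = map(_as_array, (A_op, DW, LMF_ab, LMA))
    if np.any(lma <= 0):
        raise ValueError("LMA must be strictly positive")
    out = a * dw * lmf / lma
    return float(out) if out.ndim == 0 else out


def compute_wue(A_op, E_op):
    """Operational water-use efficiency [umol CO2 per mmol H2O]."""
    a, e = _as_array(A_op), _as_array(E_op)
    if np.any(e <= 0):
        raise ValueError("transpiration E_op must be strictly positive")
    out = a / e
    return float(out) if out.ndim == 0 else out


def percent_response(mean_ambient, mean_high):
    """Relative change [%] of a trait mean from ambient to high CO2."""
    a, h = _as_array(mean_ambient), _as_array(mean_high)
    if np.any(a == 0):
        raise ValueError("ambient baseline must be non-zero")
    out = 100.0 * (h - a) / a
    return float(out) if out.ndim == 0 else out


def lmf_for(df: pd.DataFrame, constants: SpeciesConstants = DEFAULT_LMF_AB) -> pd.Series:
    """Per-row LMF_ab from each plant's species and treatment.

    ``status`` 'annual' maps to the annual-ryegrass constants; every
    other status (perennial cultivar/semi-natural/wild and the hybrid)
    uses the perennial values.
    """
    species = np.where(df["status"] == "annual", "annual", "perennial")
    return pd.Series(
        [constants.get(sp, tr) for sp, tr in zip(species, df["treatment"])],
        index=df.index,
        name="LMF_ab",
    )


def derive_traits(
    df: pd.DataFrame, constants: SpeciesConstants = DEFAULT_LMF_AB
) -> pd.DataFrame:
    """Populate every derivable trait column of a tidy per-plant table.

    Missing inputs propagate to NaN in the derived columns. Existing
    derived columns are recomputed from their inputs.
    """
    out = df.copy()
    if {"leaf_dry_mass", "leaf_area"}.issubset(out.columns):
        ok = out["leaf_area"] > 0
        out.loc[ok, "LMA"] = out.loc[ok, "leaf_dry_mass"] / out.loc[ok, "leaf_area"]
    if {"C_mass", "N_mass"}.issubset(out.columns):
        ok = out["N_mass"] > 0
        out.loc[ok, "CN_ratio"] = out.loc[ok, "C_mass"] / out.loc[ok, "N_mass"]
    if {"A_op", "E_op"}.issubset(out.columns):
        ok = out["E_op"] > 0
        out.loc[ok, "WUE_op"] = out.loc[ok, "A_op"] / out.loc[ok, "E_op"]
    lmf = lmf_for(out, constants)
    out["LMF_ab"] = lmf
    if {"DW", "tiller_count", "LMA"}.issubset(out.columns):
        ok = (out["LMA"] > 0) & (out["tiller_count"] > 0)
        out.loc[ok, "LA_tiller"] = (
            out.loc[ok, "DW"] * lmf[ok] / (out.loc[ok, "LMA"] * out.loc[ok, "tiller_count"])
        )
    if {"A_op", "DW", "LMA"}.issubset(out.columns):
        ok = out["LMA"] > 0
        out.loc[ok, "A_plant"] = (
            out.loc[ok, "A_op"] * out.loc[ok, "DW"] * lmf[ok] / out.loc[ok, "LMA"]
        )
    return out
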