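"""Synthetic genotype-by-CO2 trait datasets, A-Ci curves and germination tables.

The generator emulates the design of a controlled-environment ryegrass
experiment: ~38 genotypes of mixed accession status grown under two CO2
treatments (400 vs 800 umol mol-1), two growth chambers per treatment,
and about five plants per genotype per treatment. It exists so that
every downstream stage of the pipeline (mixed-model comparisons, trait
relationships, clustering) can be exercised and validated without the
unreleased raw data of any particular experiment.

Trait model
-----------
Strictly positive traits are log-normal. On the log scale, a plant's
trait value decomposes as

    log y = mu_t + sqrt(f_g) * sigma_t * G + sqrt(1 - f_g) * sigma_t * e
            + chamber effect

where ``sigma_t`` reproduces the configured per-treatment mean/SD,
``f_g`` is the genotype fraction of variance, ``e`` is plant-level
noise, and ``G`` is the genotype deviation. Under high CO2 the genotype
deviation is ``rho * Z + sqrt(1 - rho^2) * U`` with ``Z`` the ambient
deviation and ``U`` an independent draw: ``rho`` (the response
concordance) sets how strongly genotype rankings persist across
treatments, and thereby the spread of genotype-specific CO2 responses.
Cross-trait correlations (tillering vs per-tiller leaf area, tillering
vs leaf N, photosynthesis vs water-use efficiency ...) are imposed on
the standard-normal deviations at both the genotype and plant level.

When the mechanistic link is on (default), aboveground dry mass is not
drawn but composed,

    DW = tiller_count * LA_tiller * LMA / LMF_ab * noise,

so tiller number is by construction the dominant axis of biomass
variation — the hierarchical structure the analysis is meant to
recover. A closed-form log-normal mean correction calibrates E[DW] to
the configured treatment means.

Defaults reproduce the summary statistics of the emulated study design
(e.g. ambient DW 23.0 +/- 10.8 g, 131 +/- 51 tillers, A_op 13.5 +/- 3.2
umol m-2 s-1, and a ~45% mean DW response to elevated CO2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aci import MEASUREMENT_CI_GRID, ACiCurve
from .fvcb import BERNACCHI_KINETICS_25C, FvCBParams, KineticConstants, predict_envelope
from .traits import DEFAULT_LMF_AB, SpeciesConstants, derive_traits

__all__ = [
    "TraitSpec",
    "GeneratorConfig",
    "null_config",
    "generate_plants",
    "generate_aci",
    "generate_germination",
]


@dataclass(frozen=True)
class TraitSpec:
    """Calibration of one generated trait.

    ``mean``/``sd`` are (ambient, high CO2) targets on the natural
    scale; ``genotype_fraction`` is the share of log-scale variance
    between genotypes; ``response_concordance`` is the correlation of a
    genotype's deviation across the two treatments (1 = perfectly
    parallel responses, 0 = independent re-draw under high CO2).
    """

    mean: tuple[float, float]
    sd: tuple[float, float]
    genotype_fraction: float = 0.5
    response_concordance: float = 0.9

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.mean):
            raise ValueError("trait means must be strictly positive")
        if any(s < 0 for s in self.sd):
            raise ValueError("trait SDs must be non-negative")
        if not 0.0 <= self.genotype_fraction <= 1.0:
            raise ValueError("genotype_fraction must lie in [0, 1]")
        if not -1.0 <= self.response_concordance <= 1.0:
            raise ValueError("response_concordance must lie in [-1, 1]")

    def log_sigma(self, arm: int) -> float:
        """Log-scale SD reproducing the target CV of treatment ``arm``."""
        cv = self.sd[arm] / self.mean[arm]
        return float(np.sqrt(np.log1p(cv * cv)))


def _default_traits() -> dict[str, TraitSpec]:
    return {
        # growth / morphology: strong genotype signal, stable rankings
        "tiller_count": TraitSpec((131.0, 146.0), (51.0, 65.0), 0.65, 0.90),
        "la_tiller": TraitSpec((0.0040, 0.0045), (0.0016, 0.0018), 0.65, 0.90),
        "LMA": TraitSpec((30.9, 31.8), (7.5, 9.9), 0.65, 0.85),
        # operational gas exchange: weak genotype signal, labile rankings
        "A_op": TraitSpec((13.5, 16.8), (3.2, 3.1), 0.10, 0.90),
        "WUE_op": TraitSpec((5.0, 7.9), (1.4, 2.7), 0.20, 0.93),
        "g_sop": TraitSpec((0.32, 0.26), (0.14, 0.11), 0.20, 0.93),
        # leaf composition: responses nearly parallel across genotypes
        "N_mass": TraitSpec((4.9, 4.7), (0.6, 0.6), 0.50, 0.99),
        "C_mass": TraitSpec((38.7, 39.1), (1.5, 1.6), 0.40, 0.95),
        # biochemical capacity (A-Ci subsample only)
        "Vcmax": TraitSpec((71.1, 59.4), (12.5, 13.5), 0.30, 0.95),
        "Rd": TraitSpec((0.89, 0.84), (0.25, 0.28), 0.30, 0.95),
        "A_sat": TraitSpec((20.3, 23.3), (3.4, 5.6), 0.30, 0.95),
        # sampled blade area [m2] (dry mass follows from LMA)
        "leaf_area": TraitSpec((1.5e-4, 1.5e-4), (4e-5, 4e-5), 0.30, 0.90),
    }


#: Cross-trait correlations of the standard-normal deviations, applied
#: at both the genotype and the plant level. Negative tillering vs
#: per-tiller area (size-number trade-off) and vs leaf N (growth
#: dilution); positive photosynthesis vs water-use efficiency; negative
#: conductance vs water-use efficiency (collinear pair).
DEFAULT_TRAIT_CORRELATIONS: tuple[tuple[str, str, float], ...] = (
    ("tiller_count", "la_tiller", -0.25),
    ("la_tiller", "LMA", -0.45),
    ("tiller_count", "N_mass", -0.45),
    ("tiller_count", "C_mass", 0.20),
    ("A_op", "WUE_op", 0.30),
    ("g_sop", "WUE_op", -0.75),
    ("g_sop", "A_op", 0.30),
    ("Vcmax", "A_sat", 0.80),
)

_STATUS_COUNTS = {"cultivar": 11, "semi-natural": 16, "wild": 9, "annual": 1, "hybrid": 1}
_STATUS_PREFIX = {"cultivar": "C", "semi-natural": "S", "wild": "W", "annual": "AR", "hybrid": "HR"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and calibration knobs of the generator."""

    n_genotypes: int = 38
    status_counts: dict[str, int] = field(default_factory=lambda: dict(_STATUS_COUNTS))
    plants_per_genotype_per_treatment: int = 5
    n_chambers_per_treatment: int = 2
    chamber_sd: float = 0.005  # log-scale SD of chamber offsets
    tetraploid_fraction: float = 0.25
    mechanistic_link: bool = True
    mechanistic_noise_sd: float = 0.05  # log-scale SD of the DW closure term
    dw_mean: tuple[float, float] = (23.0, 33.4)  # calibration targets [g]
    aci_plants_per_genotype: int = 2
    traits: dict[str, TraitSpec] = field(default_factory=_default_traits)
    trait_correlations: tuple[tuple[str, str, float], ...] = DEFAULT_TRAIT_CORRELATIONS
    jmax_vcmax_ratio: tuple[float, float] = (1.889, 1.899)
    jmax_ratio_noise_sd: float = 0.05
    lmf: SpeciesConstants = field(default_factory=lambda: DEFAULT_LMF_AB)

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValueError("need at least two genotypes")
        if sum(self.status_counts.values()) != self.n_genotypes:
            raise ValueError("status_counts must sum to n_genotypes")
        if self.plants_per_genotype_per_treatment < 1:
            raise ValueError("need at least one plant per genotype per treatment")
        if self.chamber_sd < 0 or self.mechanistic_noise_sd < 0:
            raise ValueError("SDs must be non-negative")


_TREATMENT_ARMS = ("ambient", "high_CO2")


def null_config(**overrides) -> GeneratorConfig:
    """A no-treatment-effect configuration for inference calibration.

    Ambient means and SDs are used in both arms, genotype responses are
    perfectly parallel (concordance 1), and chamber offsets are zero,
    so the treatment-comparison model's null hypothesis holds exactly.
    Genotype-level variance is retained.
    """
    base = _default_traits()
    traits = {
        k: TraitSpec(
            (v.mean[0], v.mean[0]), (v.sd[0], v.sd[0]), v.genotype_fraction, 1.0
        )
        for k, v in base.items()
    }
    defaults = dict(traits=traits, dw_mean=(23.0, 23.0), chamber_sd=0.0)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def _correlation_cholesky(names: list[str], pairs) -> np.ndarray:
    k = len(names)
    corr = np.eye(k)
    idx = {n: i for i, n in enumerate(names)}
    for a, b, r in pairs:
        if a in idx and b in idx:
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError("trait correlation matrix is not positive definite") from err


def _genotype_table(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for status, count in config.status_counts.items():
        prefix = _STATUS_PREFIX.get(status, status[:2].upper())
        for i in range(count):
            gid = prefix if count == 1 else f"{prefix}{i + 1}"
            rows.append((gid, status))
    table = pd.DataFrame(rows, columns=["genotype_id", "status"])
    ploidy = np.where(
        rng.random(len(table)) < config.tetraploid_fraction, "4n", "2n"
    )
    table["ploidy"] = ploidy
    return table


def _log_cov(spec_a: TraitSpec, spec_b: TraitSpec, r: float, arm: int) -> float:
    """Total log-scale covariance between two traits in one treatment arm."""
    sa, sb = spec_a.log_sigma(arm), spec_b.log_sigma(arm)
    fa, fb = spec_a.genotype_fraction, spec_b.genotype_fraction
    if arm == 0:
        geno = np.sqrt(fa * fb)
    else:
        ra, rb = spec_a.response_concordance, spec_b.response_concordance
        geno = np.sqrt(fa * fb) * (ra * rb + np.sqrt((1 - ra**2) * (1 - rb**2)))
    resid = np.sqrt((1 - fa) * (1 - fb))
    return float(r * sa * sb * (geno + resid))


def generate_plants(
    config: GeneratorConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a complete per-plant trait table.

    Returns a tidy DataFrame with one row per plant carrying design
    labels (genotype, status, ploidy, treatment, chamber), generated
    measurements, and all derived traits filled in via
    :func:`lolium.traits.derive_traits`. Biochemical-capacity traits
    (Vcmax, Jmax, Rd, A_sat) are populated only for the A-Ci subsample
    (first ``aci_plants_per_genotype`` plants of each genotype x
    treatment cell) and are NaN elsewhere, mirroring designs where
    CO2-response curves are measured on a subset of plants.

    Fully reproducible: a fixed ``seed`` yields an identical table.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    names = list(config.traits)
    specs = config.traits
    chol = _correlation_cholesky(names, config.trait_correlations)
    k = len(names)
    g = config.n_genotypes
    ppt = config.plants_per_genotype_per_treatment
    n_plants = g * ppt * len(_TREATMENT_ARMS)

    genotypes = _genotype_table(config, rng)
    Z = rng.standard_normal((g, k)) @ chol.T  # ambient genotype deviations
    U = rng.standard_normal((g, k)) @ chol.T  # independent high-CO2 component
    E = rng.standard_normal((n_plants, k)) @ chol.T  # plant-level deviations
    n_chambers = 2 * config.n_chambers_per_treatment
    chamber_offsets = rng.normal(0.0, config.chamber_sd, size=n_chambers)
    mech_noise = rng.normal(0.0, config.mechanistic_noise_sd, size=n_plants)

    rows = []
    plant_idx = 0
    for arm, treatment in enumerate(_TREATMENT_ARMS):
        for gi in range(g):
            for rep in range(ppt):
                chamber_local = rep % config.n_chambers_per_treatment
                chamber = arm * config.n_chambers_per_treatment + chamber_local
                values = {}
                for j, name in enumerate(names):
                    spec = specs[name]
                    sigma = spec.log_sigma(arm)
                    rho = spec.response_concordance
                    dev_g = Z[gi, j] if arm == 0 else rho * Z[gi, j] + np.sqrt(1 - rho**2) * U[gi, j]
                    mu = (
                        np.log(spec.mean[arm])
                        - 0.5 * (sigma**2 + config.chamber_sd**2)
                    )
                    log_y = (
                        mu
                        + np.sqrt(spec.genotype_fraction) * sigma * dev_g
                        + np.sqrt(1 - spec.genotype_fraction) * sigma * E[plant_idx, j]
                        + chamber_offsets[chamber]
                    )
                    values[name] = np.exp(log_y)
                rows.append(
                    {
                        "plant_id": f"P{plant_idx + 1:04d}",
                        "genotype_id": genotypes.loc[gi, "genotype_id"],
                        "status": genotypes.loc[gi, "status"],
                        "ploidy": genotypes.loc[gi, "ploidy"],
                        "treatment": treatment,
                        "chamber_id": f"CH{chamber + 1}",
                        "_arm": arm,
                        "_mech": mech_noise[plant_idx],
                        "_aci": rep < config.aci_plants_per_genotype,
                        **values,
                    }
                )
                plant_idx += 1

    df = pd.DataFrame(rows)
    df["tiller_count"] = np.maximum(1, np.rint(df["tiller_count"])).astype(int)

    # species-level leaf mass fraction, then mechanistic biomass closure
    species = np.where(df["status"] == "annual", "annual", "perennial")
    lmf = np.array(
        [config.lmf.get(sp, tr) for sp, tr in zip(species, df["treatment"])]
    )
    if config.mechanistic_link:
        factors = ("tiller_count", "la_tiller", "LMA")
        corr = {frozenset((a, b)): r for a, b, r in config.trait_correlations}
        lmf_ref = config.lmf.get("perennial", "ambient"), config.lmf.get("perennial", "high_CO2")
        for arm in (0, 1):
            mask = df["_arm"] == arm
            cov_sum = sum(
                _log_cov(specs[a], specs[b], corr.get(frozenset((a, b)), 0.0), arm)
                for i, a in enumerate(factors)
                for b in factors[i + 1:]
            )
            implied = (
                specs["tiller_count"].mean[arm]
                * specs["la_tiller"].mean[arm]
                * specs["LMA"].mean[arm]
                / lmf_ref[arm]
                * np.exp(cov_sum)
            )
            calib = config.dw_mean[arm] / implied
            df.loc[mask, "DW"] = (
                calib
                * df.loc[mask, "tiller_count"]
                * df.loc[mask, "la_tiller"]
                * df.loc[mask, "LMA"]
                / lmf[mask]
                * np.exp(df.loc[mask, "_mech"] - 0.5 * config.mechanistic_noise_sd**2)
            )
    else:
        # draw DW directly with the tiller trait's variance structure
        spec_t = specs["tiller_count"]
        for arm in (0, 1):
            mask = df["_arm"] == arm
            cv = spec_t.sd[arm] / spec_t.mean[arm]
            sigma = float(np.sqrt(np.log1p(cv * cv)))
            draws = rng.normal(0.0, 1.0, size=int(mask.sum()))
            df.loc[mask, "DW"] = config.dw_mean[arm] * np.exp(
                sigma * draws - 0.5 * sigma**2
            )

    # measured blade dry mass consistent with LMA and blade area
    df["leaf_dry_mass"] = df["LMA"] * df["leaf_area"]
    # transpiration implied by assimilation and water-use efficiency
    df["E_op"] = df["A_op"] / df["WUE_op"]
    # RuBP-regeneration capacity tied to carboxylation capacity
    ratio = np.where(
        df["_arm"] == 0, config.jmax_vcmax_ratio[0], config.jmax_vcmax_ratio[1]
    )
    df["Jmax"] = (
        df["Vcmax"]
        * ratio
        * np.exp(
            rng.normal(0.0, config.jmax_ratio_noise_sd, size=len(df))
            - 0.5 * config.jmax_ratio_noise_sd**2
        )
    )
    subsample = df.pop("_aci")
    for col in ("Vcmax", "Jmax", "Rd", "A_sat"):
        df.loc[~subsample, col] = np.nan
    df = df.drop(columns=["_arm", "_mech", "la_tiller"])
    df = derive_traits(df, config.lmf)
    ordered = [
        "plant_id", "genotype_id", "status", "ploidy", "treatment", "chamber_id",
        "DW", "tiller_count", "leaf_dry_mass", "leaf_area", "LMA",
        "N_mass", "C_mass", "CN_ratio", "A_op", "g_sop", "E_op", "WUE_op",
        "LMF_ab", "LA_tiller", "A_plant", "Vcmax", "Jmax", "Rd", "A_sat",
    ]
    return df[ordered]


def generate_aci(
    params: FvCBParams,
    Ci_grid=MEASUREMENT_CI_GRID,
    noise_sd: float = 0.0,
    with_tpu: bool = False,
    seed: int | np.random.Generator = 0,
    kin: KineticConstants = BERNACCHI_KINETICS_25C,
    curve_id: str = "synthetic",
    tpu_onset_ci: float = 1000.0,
    tpu_decline: float = 1.0,
) -> ACiCurve:
    """Simulate one A-Ci curve from the FvCB envelope.

    Gaussian iid noise with SD ``noise_sd`` is added to the envelope
    prediction. With ``with_tpu`` the curve is given a triose-phosphate
    -use-limited tail: for Ci >= ``tpu_onset_ci`` assimilation is capped
    at the pre-onset plateau and declines by ``tpu_decline`` per
    1000 umol mol-1 beyond the onset, exercising the exclusion rule.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    Ci = np.asarray(Ci_grid, dtype=float)
    if Ci.size == 0:
        raise ValueError("Ci_grid must be non-empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a, _ = predict_envelope(Ci, params, kin)
    a = np.atleast_1d(np.asarray(a, dtype=float)).copy()
    if with_tpu:
        tail = Ci >= tpu_onset_ci
        if tail.any() and (~tail).any():
            plateau = a[~tail].max()
            a[tail] = plateau - tpu_decline * (1.0 + (Ci[tail] - tpu_onset_ci) / 1000.0)
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    return ACiCurve(
        curve_id=curve_id,
        Ci=Ci,
        A=a,
        leaf_temperature=params.at_temperature,
        O2_fraction=kin.O,
    )


def generate_germination(
    rates: tuple[float, float] = (0.75, 0.73),
    n_seeds: tuple[int, int] = (600, 600),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Binomial germination counts per treatment as a 2x2 table.

    Rows are treatments, columns 'germinated' / 'failed'. Defaults match
    a 40-genotype x 30-seed sowing split equally between treatments with
    germination rates of 75% (ambient) and 73% (high CO2).
    """
    if not all(0.0 <= r <= 1.0 for r in rates):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    germ = [int(rng.binomial(n, r)) for n, r in zip(n_seeds, rates)]
    return pd.DataFrame(
        {
            "germinated": germ,
            "failed": [n - g for n, g in zip(n_seeds, germ)],
        },
        index=pd.Index(list(_TREATMENT_ARMS), name="treatment"),
    )
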