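"""Readers, writers, run configuration and the full-pipeline driver.

The single tabular interchange format is CSV with a header row; every
file the pipeline writes starts with a provenance comment line
(``# lolium seed=<seed> config=<hash>``) so a result can always be
traced to the configuration and seed that produced it. Configuration
is TOML.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cluster_mod
from . import stats as stats_mod
from .aci import ACiCurve, exclude_tpu_points, fit_aci, leak_correct
from .fvcb import BERNACCHI_KINETICS_25C, ArrheniusSpec, KineticConstants
from .simulate import GeneratorConfig, generate_germination, generate_plants
from .traits import derive_traits

__all__ = [
    "RunConfig",
    "load_plants",
    "write_table",
    "read_table",
    "load_aci_curves",
    "fit_aci_table",
    "run_full_pipeline",
]

log = logging.getLogger("lolium")

MANDATORY_COLUMNS = ("plant_id", "genotype_id", "status", "treatment", "chamber_id")
KNOWN_COLUMNS = MANDATORY_COLUMNS + (
    "ploidy", "DW", "tiller_count", "leaf_dry_mass", "leaf_area", "LMA",
    "N_mass", "C_mass", "CN_ratio", "A_op", "g_sop", "E_op", "WUE_op",
    "LMF_ab", "LA_tiller", "A_plant", "Vcmax", "Jmax", "Rd", "A_sat",
)

#: Traits summarized in the treatment-comparison table, in report order.
SUMMARY_TRAITS = (
    "DW", "A_op", "A_sat", "Vcmax", "Jmax", "Rd", "g_sop", "WUE_op",
    "N_mass", "C_mass", "CN_ratio", "LMA", "tiller_count", "LA_tiller",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a pipeline run."""

    seed: int = 0
    out_dir: Path = Path("lolium_out")
    input_plants: Path | None = None  # None -> simulate
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    kinetics: KineticConstants = field(default_factory=lambda: BERNACCHI_KINETICS_25C)
    leak_coefficient: float = 0.0
    tpu_drop_threshold: float = 0.5
    tpu_min_ci: float = 800.0
    germination_rates: tuple[float, float] = (0.75, 0.73)
    germination_seeds: tuple[int, int] = (600, 600)
    cluster_k_range: tuple[int, int] = (2, 6)
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        kwargs: dict = {}
        for key in ("seed", "leak_coefficient", "tpu_drop_threshold", "tpu_min_ci", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "out_dir" in raw:
            kwargs["out_dir"] = Path(raw["out_dir"])
        if "input_plants" in raw:
            p = Path(raw["input_plants"])
            if not p.exists():
                raise FileNotFoundError(f"input_plants path does not exist: {p}")
            kwargs["input_plants"] = p
        if "generator" in raw:
            kwargs["generator"] = GeneratorConfig(**raw["generator"])
        if "kinetics" in raw:
            kwargs["kinetics"] = KineticConstants(**raw["kinetics"])
        if "germination" in raw:
            g = raw["germination"]
            kwargs["germination_rates"] = tuple(g.get("rates", (0.75, 0.73)))
            kwargs["germination_seeds"] = tuple(g.get("n_seeds", (600, 600)))
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: str(v) for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, seed: int, config_hash: str) -> None:
    """Write a CSV with a provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# lolium seed={seed} config={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_plants(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-plant trait CSV.

    Rows violating record invariants (non-positive DW or LMA,
    tiller_count < 1, N_mass/C_mass out of order, inconsistent stored
    C:N ratio) are rejected; a diagnostic naming the offending line is
    logged for each. Unknown columns raise a warning, missing mandatory
    columns an error. Empty cells stay missing (NaN).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"plant table not found: {path}")
    df = read_table(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    unknown = [c for c in df.columns if c not in KNOWN_COLUMNS]
    if unknown:
        log.warning("ignoring unknown column(s): %s", unknown)

    bad = pd.Series(False, index=df.index)

    def _flag(mask: pd.Series, reason: str) -> None:
        nonlocal bad
        mask = mask.fillna(False)
        for i in df.index[mask & ~bad]:
            log.warning("rejecting line %d: %s", i + 2, reason)
        bad |= mask

    if "DW" in df:
        _flag(df["DW"] <= 0, "DW must be positive")
    if "LMA" in df:
        _flag(df["LMA"] <= 0, "LMA must be positive")
    if "tiller_count" in df:
        _flag(df["tiller_count"] < 1, "tiller_count must be at least 1")
    if {"N_mass", "C_mass"}.issubset(df.columns):
        _flag(
            ~((df["N_mass"] > 0) & (df["N_mass"] < df["C_mass"]) & (df["C_mass"] < 100)),
            "need 0 < N_mass < C_mass < 100",
        )
    if {"CN_ratio", "N_mass", "C_mass"}.issubset(df.columns):
        recomputed = df["C_mass"] / df["N_mass"]
        _flag(
            (df["CN_ratio"] - recomputed).abs() > 1e-6 * recomputed.abs(),
            "stored CN_ratio inconsistent with C_mass/N_mass",
        )
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("rejected %d of %d rows", n_bad, len(df))
    return df[~bad].reset_index(drop=True)


def load_aci_curves(path: str | Path) -> list[ACiCurve]:
    """Read long-format A-Ci measurements (curve_id, Ci, A, T_leaf, O2)."""
    df = read_table(path)
    needed = {"curve_id", "Ci", "A"}
    if not needed <= set(df.columns):
        raise ValueError(f"A-Ci table must contain columns {sorted(needed)}")
    curves = []
    for cid, sub in df.groupby("curve_id", sort=False):
        curves.append(
            ACiCurve(
                curve_id=str(cid),
                Ci=sub["Ci"].to_numpy(float),
                A=sub["A"].to_numpy(float),
                leaf_temperature=float(sub["T_leaf"].iloc[0]) if "T_leaf" in sub else 25.0,
                O2_fraction=float(sub["O2"].iloc[0]) if "O2" in sub else 210.0,
                genotype_id=str(sub["genotype_id"].iloc[0]) if "genotype_id" in sub else None,
                treatment=str(sub["treatment"].iloc[0]) if "treatment" in sub else None,
            )
        )
    return curves


def fit_aci_table(
    curves: list[ACiCurve],
    kin: KineticConstants = BERNACCHI_KINETICS_25C,
    arrhenius: dict[str, ArrheniusSpec] | None = None,
    leak_coefficient: float = 0.0,
    tpu_drop_threshold: float = 0.5,
    tpu_min_ci: float = 800.0,
) -> pd.DataFrame:
    """Run the full per-curve chain: leak correction, TPU trim, fit."""
    rows = []
    for curve in curves:
        corrected = leak_correct(curve, leak_coefficient)
        trimmed, excluded = exclude_tpu_points(corrected, tpu_drop_threshold, tpu_min_ci)
        res = fit_aci(trimmed, kin, arrhenius)
        rows.append(
            {
                "curve_id": curve.curve_id,
                "genotype_id": curve.genotype_id,
                "treatment": curve.treatment,
                "Vcmax_leafT": res.params_at_leafT.Vcmax,
                "Jmax_leafT": res.params_at_leafT.Jmax,
                "Rd_leafT": res.params_at_leafT.Rd,
                "Vcmax_25C": res.params_at_25C.Vcmax,
                "Jmax_25C": res.params_at_25C.Jmax,
                "Rd_25C": res.params_at_25C.Rd,
                "transition_Ci": res.transition_Ci,
                "sum_of_squares": res.sum_of_squares,
                "n_excluded_tpu": len(excluded),
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)


def _summary_table(plants: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for trait in SUMMARY_TRAITS:
        if trait not in plants.columns or plants[trait].dropna().empty:
            continue
        res = stats_mod.compare_treatments(plants, trait)
        for arm in ("ambient", "high_CO2"):
            mean, lo, hi = res.treatment_means[arm]
            n = int(plants.dropna(subset=[trait]).query("treatment == @arm").shape[0])
            rows.append(
                {
                    "trait": trait, "treatment": arm, "n": n, "mean": mean,
                    "sd": float(plants.loc[plants["treatment"] == arm, trait].std()),
                    "ci_low": lo, "ci_high": hi,
                    "t_value": res.t_value, "df": res.df, "p_value": res.p_value,
                    "significance": res.stars, "model_path": res.model_path,
                }
            )
    return pd.DataFrame(rows)


def run_full_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute simulate/load -> traits -> analyze -> cluster.

    Writes a report bundle of CSVs plus a machine-readable provenance
    log into ``config.out_dir`` and returns the in-memory results.
    Any stage failure is re-raised annotated with the stage name.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed, chash = config.seed, config.config_hash()
    results: dict[str, object] = {}

    stage = "simulate" if config.input_plants is None else "load"
    try:
        if config.input_plants is None:
            plants = generate_plants(config.generator, seed=seed)
        else:
            plants = derive_traits(load_plants(config.input_plants))
        results["plants"] = plants
        write_table(plants, out / "plants.csv", seed, chash)

        stage = "analyze"
        summary = _summary_table(plants)
        results["summary"] = summary
        write_table(summary, out / "treatment_summary.csv", seed, chash)

        responses = stats_mod.genotype_mean_responses(plants, ["DW", "A_op"])
        results["genotype_responses"] = responses
        write_table(responses, out / "genotype_responses.csv", seed, chash)
        rho_dw, r2_dw = stats_mod.rank_concordance(
            responses["DW_mean_ambient"], responses["DW_mean_high"]
        )
        rho_a, r2_a = stats_mod.rank_concordance(
            responses["A_op_mean_ambient"], responses["A_op_mean_high"]
        )
        results["rank_concordance"] = {
            "DW": {"spearman_rho": rho_dw, "rank_r2": r2_dw},
            "A_op": {"spearman_rho": rho_a, "rank_r2": r2_a},
        }

        relationships = {}
        for covariate in ("tiller_count", "LA_tiller", "CN_ratio", "A_plant", "A_op"):
            relationships[covariate] = stats_mod.fit_relationship(plants, "DW", covariate)
        results["relationships"] = relationships
        rel_rows = [
            {
                "covariate": cov, "treatment": arm,
                "slope": fit.slopes[arm], "intercept": fit.intercepts[arm],
                "slope_p": fit.slope_p[arm],
                "marginal_r2": fit.marginal_r2[arm],
                "conditional_r2": fit.conditional_r2[arm],
                "interaction_p": fit.interaction_p,
            }
            for cov, fit in relationships.items()
            for arm in fit.slopes
        ]
        write_table(pd.DataFrame(rel_rows), out / "relationships.csv", seed, chash)

        neat = {}
        for arm in ("ambient", "high_CO2"):
            neat[arm] = stats_mod.neat_analysis(plants[plants["treatment"] == arm])
        results["neat"] = neat
        neat_rows = [
            {
                "treatment": arm, "predictor": p,
                "std_coefficient": n.std_coefficients[p],
                "delta_r2": n.delta_r2[p], "vif": n.vif[p],
                "full_r2": n.full_r2,
            }
            for arm, n in neat.items()
            for p in n.predictors
        ]
        write_table(pd.DataFrame(neat_rows), out / "neat_analysis.csv", seed, chash)

        corr_traits = [t for t in cluster_mod.CLUSTERING_TRAITS if t in plants.columns]
        rho, pmat = stats_mod.correlogram(plants, corr_traits)
        results["correlogram"] = (rho, pmat)
        write_table(rho.reset_index(names="trait"), out / "correlogram_rho.csv", seed, chash)
        write_table(pmat.reset_index(names="trait"), out / "correlogram_p.csv", seed, chash)

        germ = generate_germination(
            config.germination_rates, config.germination_seeds, seed=seed
        )
        results["germination"] = {
            "table": germ,
            "tests": stats_mod.germination_test(germ),
        }

        stage = "cluster"
        cluster_out = {}
        for arm in ("ambient", "high_CO2"):
            sub = plants[plants["treatment"] == arm]
            means = (
                sub.groupby("genotype_id")[list(cluster_mod.CLUSTERING_TRAITS)]
                .mean()
                .dropna()
            )
            solutions = cluster_mod.select_clustering(
                means, k_range=range(config.cluster_k_range[0], config.cluster_k_range[1] + 1)
            )
            best = solutions[0]
            sizes = best.cluster_sizes()
            table = (
                cluster_mod.compare_cluster_traits(means, best.assignments)
                if best.k == 2 and sizes.min() >= 3
                else None
            )
            if table is None:
                log.info("%s: no 2-cluster trait table (k=%d, sizes=%s)",
                         arm, best.k, sizes.to_dict())
            cluster_out[arm] = {"solutions": solutions, "best": best, "trait_table": table}
            write_table(
                best.assignments.rename_axis("genotype_id").reset_index(),
                out / f"clusters_{arm}.csv", seed, chash,
            )
            if table is not None:
                write_table(table.reset_index(), out / f"cluster_traits_{arm}.csv", seed, chash)
            if best.linkage_matrix is not None:
                (out / f"dendrogram_{arm}.nwk").write_text(
                    cluster_mod.dendrogram_newick(
                        best.linkage_matrix, list(means.index)
                    )
                )
        results["clusters"] = cluster_out
    except Exception as err:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    provenance = {
        "seed": seed,
        "config_hash": chash,
        "n_plants": int(len(results["plants"])),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    results["provenance"] = provenance
    return results
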