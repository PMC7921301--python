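"""Treatment inference, relationships, rank statistics, neat analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from statsmodels.stats.multitest import multipletests

from lolium.stats import (
    compare_status_groups,
    compare_treatments,
    correlogram,
    fit_relationship,
    genotype_mean_responses,
    germination_test,
    neat_analysis,
    rank_concordance,
)


def toy_frame(y, genotype, treatment=None, chamber=None):
    n = len(y)
    df = pd.DataFrame(
        {
            "genotype_id": genotype,
            "treatment": treatment if treatment is not None else ["ambient"] * n,
            "chamber_id": chamber if chamber is not None else ["CH1"] * n,
        }
    )
    df["y"] = np.asarray(y, float)
    return df


class TestCompareTreatments:
    def test_constant_response_takes_degenerate_path(self):
        rng = np.random.default_rng(0)
        geno = np.repeat([f"g{i}" for i in range(6)], 4)
        df = toy_frame(
            np.ones(24), geno,
            treatment=np.tile(["ambient", "high_CO2"], 12),
            chamber=np.tile(["CH1", "CH2", "CH3", "CH4"], 6),
        )
        res = compare_treatments(df, "y")
        assert res.estimate == 0.0
        assert res.model_path == "ols"
        assert res.p_value == 1.0

    def test_missing_arm_rejected(self, default_plants):
        sub = default_plants[default_plants["treatment"] == "ambient"]
        with pytest.raises(ValueError, match="missing"):
            compare_treatments(sub, "DW")

    def test_zero_genotype_variance_falls_through_to_ols(self, rng):
        n = 200
        treatment = np.tile(["ambient", "high_CO2"], n // 2)
        chamber = np.where(
            treatment == "ambient",
            np.tile(["CH1", "CH2"], n // 2),
            np.tile(["CH3", "CH4"], n // 2),
        )
        geno = np.repeat([f"g{i}" for i in range(20)], 10)
        y = 5.0 + (treatment == "high_CO2") * 1.0 + rng.normal(0, 1, n)
        df = toy_frame(y, geno, treatment, chamber)
        res = compare_treatments(df, "y")
        assert res.model_path in ("ols", "ols_hc")
        assert res.estimate == pytest.approx(1.0, abs=0.5)

    def test_mixed_path_on_gaussian_data_recovers_effect(self, rng):
        G, r = 30, 6
        geno = np.repeat([f"g{i}" for i in range(G)], 2 * r)
        treatment = np.tile(np.repeat(["ambient", "high_CO2"], r), G)
        chamber = np.where(
            treatment == "ambient",
            np.tile(["CH1", "CH2"], G * r),
            np.tile(["CH3", "CH4"], G * r),
        )
        g_eff = rng.normal(0, 2, G)
        y = 20 + 3.0 * (treatment == "high_CO2") + g_eff[np.repeat(np.arange(G), 2 * r)]
        y = y + rng.normal(0, 1.5, len(y))
        res = compare_treatments(toy_frame(y, geno, treatment, chamber), "y")
        assert res.model_path == "mixed"
        assert res.estimate == pytest.approx(3.0, abs=2.5 * res.se)
        assert res.p_value < 0.001

    def test_heavy_tailed_residuals_trigger_robust_path(self, rng):
        G, r = 25, 8
        geno = np.repeat([f"g{i}" for i in range(G)], r)
        treatment = np.tile(np.repeat(["ambient", "high_CO2"], r // 2), G)
        chamber = np.where(treatment == "ambient", "CH1", "CH3")
        y = 10 + rng.normal(0, 3, G)[np.repeat(np.arange(G), r)] + rng.standard_cauchy(G * r)
        res = compare_treatments(toy_frame(y, geno, treatment, chamber), "y")
        assert res.model_path == "robust_mixed"


class TestStatusGroups:
    def test_shifted_group_detected_others_not(self, rng):
        G = 18
        status = np.repeat(["cultivar", "semi-natural", "wild"], G // 3)
        rows = []
        for gi in range(G):
            for arm, ch in (("ambient", "CH1"), ("high_CO2", "CH3")):
                for k in range(4):
                    shift = 5.0 if status[gi] == "wild" else 0.0
                    rows.append(
                        {
                            "genotype_id": f"g{gi}",
                            "status": status[gi],
                            "treatment": arm,
                            "chamber_id": ch,
                            "y": shift + rng.normal(0, 1),
                        }
                    )
        out = compare_status_groups(pd.DataFrame(rows), "y")
        sig = out[out["p_adjusted"] < 0.01]
        involves_wild = sig[["status_a", "status_b"]].apply(
            lambda r: "wild" in r.values, axis=1
        )
        assert involves_wild.all()
        assert len(sig) == 4  # wild vs each other group, in both arms

    def test_bh_adjustment_hand_example(self):
        padj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(padj, [0.04, 0.04, 0.04, 0.04])


class TestRelationships:
    def test_exact_line_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 80)
        df = pd.DataFrame(
            {
                "genotype_id": np.repeat([f"g{i}" for i in range(20)], 4),
                "treatment": "ambient",
                "chamber_id": np.tile(["CH1", "CH2"], 40),
                "x": x,
                "y": 2.0 * x,
            }
        )
        fit = fit_relationship(df, "y", "x", by_treatment=False)
        assert fit.slopes["pooled"] == pytest.approx(2.0, rel=1e-6)
        assert fit.marginal_r2["pooled"] == pytest.approx(1.0, abs=1e-6)

    def test_independent_covariate_gives_null_slope(self, rng):
        n = 400
        df = pd.DataFrame(
            {
                "genotype_id": np.repeat([f"g{i}" for i in range(40)], 10),
                "treatment": "ambient",
                "chamber_id": np.tile(["CH1", "CH2"], n // 2),
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
            }
        )
        fit = fit_relationship(df, "y", "x", by_treatment=False)
        lo, hi = fit.slope_ci["pooled"]
        assert lo < 0 < hi
        assert fit.marginal_r2["pooled"] < 0.03

    def test_r2_ordering_and_affine_invariance(self, default_plants):
        f1 = fit_relationship(default_plants, "DW", "tiller_count")
        scaled = default_plants.assign(
            tiller_count=3.0 * default_plants["tiller_count"] + 7.0
        )
        f2 = fit_relationship(scaled, "DW", "tiller_count")
        for arm in ("ambient", "high_CO2"):
            assert 0 <= f1.marginal_r2[arm] <= f1.conditional_r2[arm] <= 1
            assert f1.marginal_r2[arm] == pytest.approx(f2.marginal_r2[arm], abs=1e-6)

    def test_constant_covariate_rejected(self, default_plants):
        df = default_plants.assign(const=1.0)
        with pytest.raises(ValueError, match="constant"):
            fit_relationship(df, "DW", "const")


class TestGenotypeResponses:
    def test_hand_computed_means(self):
        df = pd.DataFrame(
            {
                "genotype_id": ["g1"] * 4,
                "status": "wild",
                "treatment": ["ambient", "ambient", "high_CO2", "high_CO2"],
                "chamber_id": ["CH1", "CH2", "CH3", "CH4"],
                "DW": [10.0, 12.0, 20.0, 24.0],
            }
        )
        out = genotype_mean_responses(df, ["DW"])
        assert out.loc[0, "DW_mean_ambient"] == 11.0
        assert out.loc[0, "DW_mean_high"] == 22.0
        assert out.loc[0, "DW_response_pct"] == pytest.approx(100.0)

    def test_upper_bound_response(self):
        assert_frame = pd.DataFrame(
            {
                "genotype_id": ["g"] * 2,
                "status": "wild",
                "treatment": ["ambient", "high_CO2"],
                "chamber_id": ["CH1", "CH3"],
                "DW": [10.0, 38.0],
            }
        )
        out = genotype_mean_responses(assert_frame, ["DW"])
        assert out.loc[0, "DW_response_pct"] == pytest.approx(280.0)

    def test_genotype_missing_arm_excluded_with_warning(self, default_plants):
        df = default_plants[
            ~(
                (default_plants["genotype_id"] == "C1")
                & (default_plants["treatment"] == "high_CO2")
            )
        ]
        with pytest.warns(UserWarning, match="C1"):
            out = genotype_mean_responses(df, ["DW"])
        assert "C1" not in set(out["genotype_id"])


class TestRankConcordance:
    def test_identical_and_reversed_rankings(self):
        x = [1.0, 2, 3, 4, 5]
        assert rank_concordance(x, x)[0] == pytest.approx(1.0)
        assert rank_concordance(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # d^2 = (1,1,1,1) -> rho = 1 - 6*4/(4*15) = 0.6
        rho, r2 = rank_concordance([1.0, 2, 3, 4], [2.0, 1, 4, 3])
        assert rho == pytest.approx(0.6)
        assert r2 == pytest.approx(0.36)

    def test_too_few_genotypes_rejected(self):
        with pytest.raises(ValueError):
            rank_concordance([1.0, 2], [2.0, 1])


class TestCorrelogram:
    def test_diagonal_and_symmetry(self, default_plants):
        rho, p = correlogram(default_plants, ["DW", "tiller_count", "A_op"])
        np.testing.assert_allclose(np.diag(rho), 1.0)
        np.testing.assert_allclose(rho, rho.T)

    def test_monotone_transform_invariance(self, default_plants):
        df = default_plants.assign(logDW=np.log(default_plants["DW"]))
        rho, _ = correlogram(df, ["DW", "logDW"])
        assert rho.loc["DW", "logDW"] == pytest.approx(1.0)

    def test_independent_traits_star_rate(self, rng):
        n = 500
        df = pd.DataFrame(rng.normal(size=(n, 8)), columns=[f"t{i}" for i in range(8)])
        rho, p = correlogram(df, list(df.columns))
        off = p.to_numpy()[np.triu_indices(8, 1)]
        assert np.mean(off <= 0.05) < 0.2
        assert np.abs(rho.to_numpy()[np.triu_indices(8, 1)]).max() < 0.2

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 1, 3]})
        with pytest.raises(ValueError):
            correlogram(df, ["a", "b"])


def helmert_design(n_levels: int, reps: int) -> np.ndarray:
    """Zero-mean mutually orthogonal columns (Helmert contrasts)."""
    H = np.zeros((n_levels, n_levels - 1))
    for j in range(1, n_levels):
        H[:j, j - 1] = 1.0
        H[j, j - 1] = -j
    return np.repeat(H, reps, axis=0)


class TestNeatAnalysis:
    def test_orthogonal_design_matches_all_subsets_oracle(self, rng):
        X = helmert_design(5, 10)  # 50 x 4 orthogonal, zero-mean
        beta = np.array([1.0, -0.5, 0.25, 2.0])
        y = X @ beta + rng.normal(0, 1, len(X))
        names = [f"x{j}" for j in range(4)]
        df = pd.DataFrame(X, columns=names).assign(y=y)
        res = neat_analysis(df, "y", names)

        # oracle 1: exhaustive subset R2 via lstsq
        zy = (y - y.mean()) / y.std(ddof=1)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)

        def subset_r2(S):
            if not S:
                return 0.0
            b = np.linalg.lstsq(Z[:, S], zy, rcond=None)[0]
            return 1.0 - np.sum((zy - Z[:, S] @ b) ** 2) / np.sum(zy**2)

        full = subset_r2(list(range(4)))
        for j, name in enumerate(names):
            drop = [k for k in range(4) if k != j]
            assert res.delta_r2[name] == pytest.approx(full - subset_r2(drop), abs=1e-10)
            # oracle 2: orthogonality makes delta-R2 the squared simple r
            r = np.corrcoef(Z[:, j], zy)[0, 1]
            assert res.delta_r2[name] == pytest.approx(r * r, abs=1e-10)

    def test_single_predictor_delta_equals_full_r2(self, rng):
        x = rng.normal(size=60)
        y = 2 * x + rng.normal(size=60)
        df = pd.DataFrame({"x": x, "y": y})
        res = neat_analysis(df, "y", ["x"])
        assert res.delta_r2["x"] == pytest.approx(res.full_r2, abs=1e-12)

    def test_duplicated_predictor_raises_naming_pair(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"x1": x, "x2": x, "y": rng.normal(size=50)})
        with pytest.raises(ValueError, match="x1.*x2"):
            neat_analysis(df, "y", ["x1", "x2"])

    def test_near_collinear_predictor_flagged(self, rng):
        x = rng.normal(size=300)
        df = pd.DataFrame(
            {
                "x1": x,
                "x2": x + rng.normal(0, 0.05, 300),
                "x3": rng.normal(size=300),
                "y": x + rng.normal(size=300),
            }
        )
        res = neat_analysis(df, "y", ["x1", "x2", "x3"])
        assert "x1" in res.collinear_flagged and "x2" in res.collinear_flagged
        assert "x3" not in res.collinear_flagged

    def test_delta_r2_bounds(self, default_plants):
        res = neat_analysis(default_plants[default_plants["treatment"] == "ambient"])
        for v in res.delta_r2.values():
            assert 0.0 <= v <= res.full_r2 + 1e-12


class TestGermination:
    def test_identical_columns_null(self):
        out = germination_test(np.array([[50, 50], [50, 50]]))
        assert out["chi2"] == pytest.approx(0.0)
        assert out["fisher_p"] == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        out = germination_test(np.array([[450, 150], [438, 162]]))
        assert out["chi2"] == pytest.approx(0.62, abs=0.01)

    def test_fisher_extreme_table_by_enumeration(self):
        # P(X = 10) + P(X = 0) under hypergeometric(20, 10, 10)
        expected = 2.0 / comb(20, 10, exact=True)
        out = germination_test(np.array([[10, 0], [0, 10]]))
        assert out["fisher_p"] == pytest.approx(expected, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            germination_test(np.array([[0, 10], [0, 12]]))
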