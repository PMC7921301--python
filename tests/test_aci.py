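"""A-Ci curve preprocessing and two-phase FvCB estimation."""

import numpy as np
import pytest
from scipy.stats import qmc

from lolium.aci import (
    MEASUREMENT_CI_GRID,
    ACiCurve,
    _fit_split,
    exclude_tpu_points,
    fit_aci,
    leak_correct,
)
from lolium.fvcb import (
    BERNACCHI_KINETICS_25C as KIN,
    FvCBParams,
    Limitation,
    arrhenius_scale,
    BERNACCHI_ARRHENIUS,
    predict_envelope,
)
from lolium.simulate import generate_aci

TABLE_PARAMS = FvCBParams(Vcmax=71.1, Jmax=134.3, Rd=0.89)


def envelope_curve(params=TABLE_PARAMS, grid=MEASUREMENT_CI_GRID, T=25.0):
    a, _ = predict_envelope(np.asarray(grid), params, KIN)
    return ACiCurve("c1", np.asarray(grid, float), a, leaf_temperature=T)


class TestCurveContainer:
    def test_points_sorted_ascending(self):
        c = ACiCurve("x", [400.0, 50.0, 100.0, 200.0, 300.0], [10.0, 1.0, 3.0, 6.0, 8.0])
        assert np.all(np.diff(c.Ci) > 0)
        assert c.A[0] == 1.0

    def test_duplicate_ci_rejected(self):
        with pytest.raises(ValueError):
            ACiCurve("x", [50.0, 50.0, 100, 200, 300], [1.0, 1, 2, 3, 4])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ACiCurve("x", [50.0, 100, 200], [1.0, 2, 3])


class TestLeakCorrection:
    def test_zero_coefficient_is_identity(self):
        c = envelope_curve()
        assert leak_correct(c, 0.0) is c

    def test_linear_in_coefficient(self):
        c = envelope_curve()
        d1 = c.A - leak_correct(c, 0.01).A
        d2 = c.A - leak_correct(c, 0.02).A
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-12)

    def test_injected_leak_round_trip(self):
        clean = envelope_curve()
        k = 0.003
        leaky = ACiCurve(
            "leaky", clean.Ci, clean.A + k * (clean.Ci - 400.0), clean.leaf_temperature
        )
        recovered = leak_correct(leaky, k)
        np.testing.assert_allclose(recovered.A, clean.A, atol=1e-10)

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError):
            leak_correct(envelope_curve(), -0.1)


class TestTpuExclusion:
    def test_monotone_curve_untouched(self):
        c = envelope_curve()
        kept, excluded = exclude_tpu_points(c)
        assert excluded == []
        assert kept.n_points == c.n_points

    def test_declining_tail_removed(self):
        grid = MEASUREMENT_CI_GRID
        a = np.linspace(5, 28, len(grid))
        a[-2:] = a[-3] - 1.0  # plateau then 1.0 drop at Ci = 1200, 1500
        c = ACiCurve("tpu", grid, a)
        kept, excluded = exclude_tpu_points(c)
        assert [ci for ci, _ in excluded] == [1200.0, 1500.0]
        assert kept.n_points == len(grid) - 2

    def test_low_ci_dip_never_removed(self):
        grid = MEASUREMENT_CI_GRID
        a = np.linspace(5, 28, len(grid))
        a[list(grid).index(400.0)] -= 1.0
        kept, excluded = exclude_tpu_points(ACiCurve("dip", grid, a))
        assert excluded == []
        assert kept.n_points == len(grid)

    def test_error_when_too_few_points_would_remain(self):
        grid = np.array([700.0, 800, 1000, 1200, 1500])
        a = np.array([20.0, 10, 9, 8, 7])
        with pytest.raises(ValueError, match="unusable"):
            exclude_tpu_points(ACiCurve("bad", grid, a))

    def test_synthetic_tpu_tail_is_excluded(self):
        c = generate_aci(TABLE_PARAMS, noise_sd=0.0, with_tpu=True)
        kept, excluded = exclude_tpu_points(c)
        assert [ci for ci, _ in excluded] == [1000.0, 1200.0, 1500.0]
        np.testing.assert_allclose(kept.A, envelope_curve().A[:8], atol=1e-12)


class TestFit:
    def test_noiseless_round_trip_table_values(self):
        res = fit_aci(envelope_curve())
        assert res.converged
        assert res.sum_of_squares < 1e-8
        assert res.params_at_leafT.Vcmax == pytest.approx(71.1, rel=1e-6)
        assert res.params_at_leafT.Jmax == pytest.approx(134.3, rel=1e-6)
        assert res.params_at_leafT.Rd == pytest.approx(0.89, rel=1e-4)
        lo, hi = MEASUREMENT_CI_GRID[0], MEASUREMENT_CI_GRID[-1]
        assert lo <= res.transition_Ci <= hi

    def test_selected_split_beats_every_candidate(self):
        c = generate_aci(TABLE_PARAMS, noise_sd=0.4, seed=7)
        res = fit_aci(c)
        n = c.n_points
        sses = [
            _fit_split(c.Ci, c.A, k, KIN)[3] for k in [0, n] + list(range(2, n - 1))
        ]
        assert res.sum_of_squares <= min(sses) + 1e-12

    def test_reported_sse_matches_recomputation(self):
        c = generate_aci(TABLE_PARAMS, noise_sd=0.3, seed=3)
        res = fit_aci(c)
        n_pre = sum(1 for l in res.phase_labels if l == Limitation.RUBISCO)
        from lolium.fvcb import ac_assimilation, aj_assimilation

        pred = np.concatenate(
            [
                np.atleast_1d(ac_assimilation(c.Ci[:n_pre], res.params_at_leafT, KIN)),
                np.atleast_1d(
                    aj_assimilation(c.Ci[n_pre:], res.params_at_leafT, KIN.gamma_star)
                ),
            ]
        )
        assert res.sum_of_squares == pytest.approx(float(np.sum((c.A - pred) ** 2)), abs=1e-9)

    def test_latin_hypercube_round_trip(self):
        sampler = qmc.LatinHypercube(d=3, seed=0)
        lows, highs = np.array([30.0, 60.0, 0.3]), np.array([120.0, 250.0, 2.0])
        thetas = qmc.scale(sampler.random(10), lows, highs)
        for vc, jm, rd in thetas:
            true = FvCBParams(Vcmax=vc, Jmax=jm, Rd=rd)
            _, labels = predict_envelope(MEASUREMENT_CI_GRID, true, KIN)
            n_rub = sum(1 for l in labels if l == Limitation.RUBISCO)
            res = fit_aci(envelope_curve(true))
            if n_rub in (1, len(labels) - 1):
                # one-point phase: not representable by a >=2-point split
                assert res.sum_of_squares < 0.05
                continue
            assert res.sum_of_squares < 1e-8
            if 2 <= n_rub <= len(labels) - 2:
                assert res.params_at_leafT.Vcmax == pytest.approx(vc, rel=1e-4)
                assert res.params_at_leafT.Jmax == pytest.approx(jm, rel=1e-4)
                assert res.params_at_leafT.Rd == pytest.approx(rd, rel=1e-3)

    def test_one_phase_rubisco_only_flagged(self):
        p = FvCBParams(Vcmax=60.0, Jmax=1e5, Rd=1.0)
        res = fit_aci(envelope_curve(p))
        assert not res.jmax_identifiable
        assert res.params_at_leafT.Vcmax == pytest.approx(60.0, rel=1e-6)

    def test_temperature_normalization_consistency(self):
        # params fitted at 27 C, normalized to 25 C, must equal the
        # leaf-T estimates passed through arrhenius_scale
        p27 = FvCBParams(Vcmax=75.0, Jmax=140.0, Rd=1.1, at_temperature=27.0)
        from lolium.fvcb import kinetics_at_temperature

        kin27 = kinetics_at_temperature(KIN, 27.0)
        a, _ = predict_envelope(MEASUREMENT_CI_GRID, p27, kin27)
        res = fit_aci(ACiCurve("t27", MEASUREMENT_CI_GRID, a, leaf_temperature=27.0))
        expected = arrhenius_scale(
            res.params_at_leafT.Vcmax, BERNACCHI_ARRHENIUS["Vcmax"], 25.0, 27.0
        )
        assert res.params_at_25C.Vcmax == pytest.approx(expected, rel=1e-10)
        assert res.params_at_leafT.Vcmax == pytest.approx(75.0, rel=1e-4)

    def test_degenerate_curve_below_compensation_rejected(self):
        ci = np.array([5.0, 10, 15, 20, 25])
        with pytest.raises(ValueError, match="degenerate"):
            fit_aci(ACiCurve("low", ci, np.full(5, -0.5)))

    def test_noisy_recovery_statistics(self):
        rng = np.random.default_rng(5)
        biases, sses = [], []
        for _ in range(100):
            c = generate_aci(TABLE_PARAMS, noise_sd=0.3, seed=rng)
            r = fit_aci(c)
            biases.append(abs(r.params_at_leafT.Vcmax - 71.1) / 71.1)
            sses.append(r.sum_of_squares)
        assert np.median(biases) < 0.03
        assert np.median(sses) < 1.0
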