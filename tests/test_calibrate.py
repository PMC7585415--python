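"""Ballpark initializers, wild-type calibration and mutant prediction."""

import numpy as np
import pytest

from gabakin.calibrate import (
    BallparkRangeError,
    ObservableTargets,
    ballpark_init_model_I,
    ballpark_init_model_II,
    calibrate_wt,
    fit_mutation_ratios,
    model_I_equilibrium_from_amplitude,
    model_II_equilibrium_from_amplitude,
    model_comparison_report,
    predict_construct,
    predict_observables,
    restrict_targets,
)
from gabakin.params import ModelVariant, MutationProfile, RateParameters


class TestBallparkInversions:
    def test_model_I_equilibrium_from_third_share(self):
        d = model_I_equilibrium_from_amplitude(1.0 / 3.0)
        assert d == pytest.approx(1.0 / 6.0)
        assert abs(d - 0.2) < 0.05  # consistent with the rounded value

    def test_model_I_zero_amplitude(self):
        assert model_I_equilibrium_from_amplitude(0.0) == 0.0

    def test_model_II_quadratic_root(self):
        # positive root of D^2 = f (1 + 2 D), cross-checked with np.roots
        f = 0.30
        d = model_II_equilibrium_from_amplitude(f)
        roots = np.roots([1.0, -2.0 * f, -f])
        assert d == pytest.approx(float(roots[roots > 0][0]))
        assert d == pytest.approx(0.9245, abs=1e-4)
        assert abs(d - 0.9) < 0.15

    def test_model_II_zero_amplitude(self):
        assert model_II_equilibrium_from_amplitude(0.0) == 0.0

    def test_model_II_printed_delta_plus(self, targets):
        """The stated inversion reproduces the printed delta+ ~ 0.14 1/s."""
        init = ballpark_init_model_II(targets["CWT"])
        assert 0.09 < init.delta_plus < 0.19
        d = init.delta_plus / init.delta_minus
        assert abs(d - 0.9) < 0.15

    def test_out_of_range_amplitude(self):
        tgt = ObservableTargets("X", tau_fast=2.0, tau_slow=10.0,
                                pct_A_fast=70.0, pct_I_res=10.0)
        with pytest.raises(BallparkRangeError):
            ballpark_init_model_I(tgt)


class TestWildTypeCalibration:
    def test_model_I_exact_fit(self, targets):
        """Four free rates against four observables: model I fits exactly."""
        res = calibrate_wt(ModelVariant.I, targets["CWT"])
        assert res.converged
        assert res.loss < 1e-6
        pred = res.predictions["CWT"]
        assert pred.tau_fast == pytest.approx(4.8, rel=0.01)
        assert pred.tau_slow == pytest.approx(24.4, rel=0.01)

    def test_model_III_predictions_within_20_percent(self, model_III_wt, targets):
        pred = model_III_wt.predictions["CWT"]
        tgt = targets["CWT"]
        assert pred.tau_fast == pytest.approx(tgt.tau_fast, rel=0.20)
        assert pred.tau_slow == pytest.approx(tgt.tau_slow, rel=0.20)
        assert pred.pct_A_fast == pytest.approx(tgt.pct_A_fast, rel=0.20)
        assert pred.pct_I_res == pytest.approx(tgt.pct_I_res, rel=0.20)

    def test_self_consistency_parameter_recovery(self):
        """Observables generated from known rates are inverted to within a
        few percent by the deterministic calibration."""
        true = RateParameters(
            delta_plus=0.05, delta_minus=0.2, delta3_plus=0.03, delta3_minus=0.004
        )
        obs = predict_observables(ModelVariant.I, true)
        tgt = ObservableTargets(
            "SYN", tau_fast=obs.tau_fast, tau_slow=obs.tau_slow,
            pct_A_fast=obs.pct_A_fast, pct_I_res=obs.pct_I_res,
        )
        res = calibrate_wt(ModelVariant.I, tgt)
        for name in ("delta_plus", "delta_minus", "delta3_plus", "delta3_minus"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(true, name), rel=0.02
            ), name

    def test_couplings_rejected_outside_model_III(self, targets):
        with pytest.raises(ValueError):
            calibrate_wt(ModelVariant.I, targets["CWT"], (10.0, 10.0))


class TestMutantFits:
    def test_unit_multipliers_reproduce_wild_type_predictions(self, model_III_wt):
        wt_pred = model_III_wt.predictions["CWT"]
        pred = predict_construct(
            ModelVariant.III, model_III_wt.params, MutationProfile()
        )
        assert pred.tau_fast == pytest.approx(wt_pred.tau_fast, rel=1e-6)

    def test_model_II_beta_c3_has_two_components(self, targets):
        """The SU3->SU4 cross-effect restores a bi-exponential C3 decay."""
        res = calibrate_wt(ModelVariant.II_BETA, targets["CWT"], max_nfev=120)
        mult = fit_mutation_ratios(
            ModelVariant.II_BETA, res, {"C3": targets["C3"]}
        )
        pred = predict_construct(
            ModelVariant.II_BETA, res.params, mult.profile_for("C3")
        )
        assert not pred.mono
        assert pred.pct_A_fast < 99.0
        assert pred.tau_slow / pred.tau_fast > 1.5

    def test_mutant_order_invariance(self, targets):
        res = calibrate_wt(ModelVariant.I, targets["CWT"])
        order_a = {c: targets[c] for c in ("C3", "C4", "C5")}
        order_b = {c: targets[c] for c in ("C5", "C3", "C4")}
        ma = fit_mutation_ratios(ModelVariant.I, res, order_a,
                                 fields=("tau_fast", "tau_slow"))
        mb = fit_mutation_ratios(ModelVariant.I, res, order_b,
                                 fields=("tau_fast", "tau_slow"))
        assert ma.c4[0] == pytest.approx(mb.c4[0], rel=1e-6)
        assert ma.c3[0] == pytest.approx(mb.c3[0], rel=1e-6)


class TestModelIStructuralFailure:
    def test_no_parameter_set_matches_wt_single_and_double(self, targets):
        """Model I cannot reconcile the wild-type, single-mutant and
        double-mutant fast time constants: on a 20x20 log grid of the
        SU4/SU5 rates (entry multiplier solved per point), no parameter set
        puts all three predicted tau_fast within 30% of the data."""
        tgt_wt, tgt_c4, tgt_c45 = (
            targets["CWT"].tau_fast,
            targets["C4"].tau_fast,
            targets["C45"].tau_fast,
        )
        base = calibrate_wt(ModelVariant.I, targets["CWT"]).params
        from gabakin.params import profile_from_multipliers
        from gabakin.states import SubunitID

        def tau_fast(params, profile=MutationProfile(), warm=None):
            return predict_observables(
                ModelVariant.I, params, profile, coarse=True, warm_taus=warm
            ).tau_fast

        n_triple = 0
        for dp in np.geomspace(0.005, 0.5, 20):
            for dm in np.geomspace(0.02, 2.0, 20):
                params = base.evolve(delta_plus=float(dp), delta_minus=float(dm))
                tw = tau_fast(params, warm=(tgt_wt, 24.0))
                if not (0.7 <= tw / tgt_wt <= 1.3):
                    continue
                # entry multiplier solved to match the single mutant
                lo, hi = 1.0, 1000.0
                for _ in range(25):
                    c = np.sqrt(lo * hi)
                    prof = profile_from_multipliers({SubunitID.SU4}, c4=(c, 1.0))
                    t4 = tau_fast(params, prof, warm=(tgt_c4, 20.0))
                    if t4 > tgt_c4:
                        lo = c
                    else:
                        hi = c
                prof = profile_from_multipliers({SubunitID.SU4}, c4=(c, 1.0))
                if not (0.7 <= tau_fast(params, prof, warm=(tgt_c4, 20.0)) / tgt_c4 <= 1.3):
                    continue
                prof45 = profile_from_multipliers(
                    {SubunitID.SU4, SubunitID.SU5}, c4=(c, 1.0), c5=(c, 1.0)
                )
                t45 = tau_fast(params, prof45, warm=(tgt_c45, 10.0))
                if 0.7 <= t45 / tgt_c45 <= 1.3:
                    n_triple += 1
        assert n_triple == 0


class TestComparisonReport:
    def test_flags_and_fold_errors(self, model_I_sim_a, model_II_full,
                                   model_III_full, targets):
        table, flags = model_comparison_report(
            {"I": model_I_sim_a, "II": model_II_full, "III": model_III_full},
            targets,
        )
        assert flags["I"] == "anti-synergy"
        assert flags["II"] == "synergy"
        assert flags["III"] == "synergy"
        row = table[(table.variant == "I") & (table.construct == "C4")].iloc[0]
        assert row["tau_fast_fold_error"] == pytest.approx(
            row["tau_fast_pred"] / targets["C4"].tau_fast
        )

    def test_identical_predictions_zero_fold_error(self, model_III_wt, targets):
        pred = model_III_wt.predictions["CWT"]
        synthetic_targets = {
            "CWT": ObservableTargets(
                "CWT", tau_fast=pred.tau_fast, tau_slow=pred.tau_slow,
                pct_A_fast=pred.pct_A_fast, pct_I_res=pred.pct_I_res,
            )
        }
        table, _ = model_comparison_report({"III": model_III_wt}, synthetic_targets)
        assert table.iloc[0]["tau_fast_fold_error"] == pytest.approx(1.0)


def test_restrict_targets_zeroes_other_weights(targets):
    r = restrict_targets(targets["C4"], ("tau_fast",))
    assert r.weights["tau_fast"] == 1.0
    assert r.weights["tau_slow"] == 0.0
    assert r.weights["pct_A_fast"] == 0.0
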