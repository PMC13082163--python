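"""Screening and D/M-vs-NL classification tests."""

import numpy as np
import pytest

import pvtuning as pv
from pvtuning.synth import CohortConfig, build_manipulation, control_rate, laser_rate
from pvtuning.tuning import TuningCurve, VonMisesFit, fit_von_mises

DENSE = np.arange(0.0, 360.0, 0.1)


def dense_curve(fit, role):
    return TuningCurve(DENSE, np.asarray(fit.evaluate(DENSE)), role=role)


def power_law_low_fit(fit_high: VonMisesFit, p: float, peak_ratio: float) -> VonMisesFit:
    """Low-rate fit L = c * H^p with L_P/H_P = peak_ratio (exact in the family)."""
    a0 = p * fit_high.a0 + np.log(peak_ratio)
    return VonMisesFit(fit_high.phi, p * fit_high.kappa, p * fit_high.v, a0, 1.0)


class TestScreen:
    def test_cv_threshold(self):
        assert pv.screen_unit(0.97, [-0.4], "PVA") == "NONSELECTIVE"

    def test_tagged_by_sign(self):
        assert pv.screen_unit(0.5, [0.4, 0.4, 0.4], "PVA") == "PV_TAGGED"
        assert pv.screen_unit(0.5, [-0.4, -0.4], "PVI") == "PV_TAGGED"

    def test_keep(self):
        assert pv.screen_unit(0.5, [-0.4], "PVA") == "KEEP"
        assert pv.screen_unit(0.5, [0.4], "PVI") == "KEEP"

    def test_empty_d_fr_raises(self):
        with pytest.raises(ValueError):
            pv.screen_unit(0.5, [], "PVA")


class TestMultiplicativeRatio:
    @pytest.mark.parametrize(
        "args,expected",
        [((10, 2, 5, 1), 0.0), ((10, 2, 5, 0.5), 0.1), ((10, 0, 5, 0), 0.0)],
    )
    def test_values(self, args, expected):
        assert pv.multiplicative_ratio(*args) == pytest.approx(expected)

    def test_proportional_scaling_is_dm_side(self):
        mr = pv.multiplicative_ratio(10, 2, 5, 1)
        assert abs(mr) < pv.classify.MR_THRESHOLD if hasattr(pv, "classify") else True
        assert abs(mr) < 0.02

    def test_zero_preferred_rate_raises(self):
        with pytest.raises(ValueError):
            pv.multiplicative_ratio(0.0, 1.0, 5.0, 1.0)


class TestEffectCurves:
    def test_identity(self):
        hi = VonMisesFit(90.0, 1.0, 0.2, np.log(20.0), 1.0)
        eff = pv.effect_curves(dense_curve(hi, "highFr"), dense_curve(hi, "lowFr"))
        assert np.allclose(eff.delta_t, 0.0)
        assert np.allclose(eff.ratio_t[np.isfinite(eff.ratio_t)], 1.0)
        assert eff.cov_ratio_t == pytest.approx(0.0, abs=1e-12)

    def test_pure_multiplicative(self):
        """T_low = 0.5 T_high: RT flat at 0.5, CoV(dT) = CoV(T_high)."""
        hi_fit = VonMisesFit(90.0, 1.0, 0.2, np.log(20.0), 1.0)
        hi = dense_curve(hi_fit, "highFr")
        lo = TuningCurve(DENSE, 0.5 * hi.mean_rate, role="lowFr")
        eff = pv.effect_curves(hi, lo)
        valid = np.isfinite(eff.ratio_t)
        assert np.allclose(eff.ratio_t[valid], 0.5)
        assert eff.cov_ratio_t == pytest.approx(0.0, abs=1e-9)
        cov_hi = np.std(hi.mean_rate) / np.mean(hi.mean_rate)
        assert eff.cov_delta_t == pytest.approx(cov_hi, rel=1e-9)
        assert eff.mr == pytest.approx(0.0, abs=1e-12)

    def test_nl_pair_mexican_hat(self):
        """For a beta-steepened generator pair, |dT| peaks away from theta_P."""
        from tests.test_synth import make_unit

        cfg = CohortConfig()
        unit = make_unit("NL", kappa=0.8)  # phi_true = 90
        manip = build_manipulation(unit, cfg.intensities[1], cfg)
        hi_fit = fit_von_mises(TuningCurve(unit.directions, control_rate(unit)))
        lo_fit = fit_von_mises(TuningCurve(unit.directions, laser_rate(unit, manip)))
        eff = pv.effect_curves(dense_curve(hi_fit, "highFr"), dense_curve(lo_fit, "lowFr"))
        argmax_dt = DENSE[int(np.argmax(np.abs(eff.delta_t)))]
        assert abs((argmax_dt - 90.0 + 180) % 360 - 180) > 20.0
        assert eff.cov_ratio_t > 0.01

    def test_rate_floor_masks_rt(self):
        hi_fit = VonMisesFit(90.0, 3.0, 0.5, np.log(20.0), 1.0)
        eff = pv.effect_curves(dense_curve(hi_fit, "highFr"), dense_curve(hi_fit, "lowFr"))
        assert np.isnan(eff.ratio_t).any()

    def test_grid_mismatch_raises(self):
        hi = VonMisesFit(90.0, 1.0, 0.2, np.log(20.0), 1.0)
        a = dense_curve(hi, "highFr")
        b = TuningCurve(np.arange(0, 360, 0.5), np.asarray(hi.evaluate(np.arange(0, 360, 0.5))))
        with pytest.raises(ValueError):
            pv.effect_curves(a, b)


class TestClassifyIntensity:
    def test_pure_multiplicative_is_dm(self):
        hi = VonMisesFit(90.0, 1.0, 0.2, np.log(20.0), 1.0)
        lo = VonMisesFit(90.0, 1.0, 0.2, np.log(10.0), 1.0)
        eff = pv.effect_curves(dense_curve(hi, "highFr"), dense_curve(lo, "lowFr"))
        assert pv.classify_intensity(eff, hi, lo) == "DM"

    def test_upward_bump_is_nl(self):
        hi = VonMisesFit(90.0, 0.8, 0.2, np.log(20.0), 1.0)
        lo = power_law_low_fit(hi, p=2.0, peak_ratio=0.8)
        eff = pv.effect_curves(dense_curve(hi, "highFr"), dense_curve(lo, "lowFr"))
        assert pv.classify_intensity(eff, hi, lo) == "NL"

    def test_flat_dt_is_other(self):
        hi = VonMisesFit(90.0, 1.0, 0.2, np.log(20.0), 1.0)
        eff = pv.effect_curves(dense_curve(hi, "highFr"), dense_curve(hi, "lowFr"))
        assert pv.classify_intensity(eff, hi, hi) == "OTHER"

    def test_scaled_nonmultiplicative_is_other(self):
        """Downward dT peak with large MR: neither D/M nor NL."""
        hi = VonMisesFit(90.0, 0.8, 0.2, np.log(20.0), 1.0)
        # sub-linear map p < 1 broadens tuning: downward-peak dT, large MR
        lo = power_law_low_fit(hi, p=0.5, peak_ratio=0.5)
        eff = pv.effect_curves(dense_curve(hi, "highFr"), dense_curve(lo, "lowFr"))
        assert pv.classify_intensity(eff, hi, lo, mr_threshold=0.02) == "OTHER"

    @pytest.mark.parametrize("manipulation", ["PVA", "PVI"])
    @pytest.mark.parametrize("effect_class", ["DM", "NL"])
    def test_noiseless_generator_round_trip(self, manipulation, effect_class):
        """Generator mechanisms are recovered at every intensity, both directions."""
        from tests.test_synth import make_unit

        cfg = CohortConfig(manipulation=manipulation)
        unit = make_unit(effect_class, kappa=0.8)
        for level in cfg.intensities:
            manip = build_manipulation(unit, level, cfg)
            ctrl = TuningCurve(unit.directions, control_rate(unit))
            las = TuningCurve(unit.directions, laser_rate(unit, manip))
            f_ctrl, f_las = fit_von_mises(ctrl), fit_von_mises(las)
            f_hi, f_lo = (
                (f_ctrl, f_las) if manipulation == "PVA" else (f_las, f_ctrl)
            )
            eff = pv.effect_curves(dense_curve(f_hi, "highFr"), dense_curve(f_lo, "lowFr"))
            label = pv.classify_intensity(eff, f_hi, f_lo)
            assert label == effect_class, (manipulation, level.intensity_id, label)
            if effect_class == "DM":
                assert eff.cov_ratio_t == pytest.approx(0.0, abs=1e-6)
            else:
                assert eff.cov_ratio_t > 1e-3


class TestConsolidate:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            ({"i1": "DM", "i2": "DM", "i3": "DM"}, "DM"),
            ({"i1": "NL", "i2": "NL"}, "NL"),
            ({"i1": "DM", "i2": "NL"}, "MIX"),
            ({"i1": "NL", "i2": "OTHER"}, "UCT"),
            ({"i1": "OTHER"}, "UCT"),
        ],
    )
    def test_rules(self, labels, expected):
        assert pv.consolidate_unit(labels) == expected

    def test_waveform_mismatch_is_uct(self):
        assert pv.consolidate_unit({"i1": "DM", "i2": "DM"}, waveform_matched=False) == "UCT"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pv.consolidate_unit({})


class TestCohortAccuracy:
    def test_confusion_matrix(self, analyzed_small_cohort):
        """Most DM- and NL-generated units receive their generating label."""
        from tests.conftest import truth_frame

        cfg, units, analysis = analyzed_small_cohort
        lab = analysis.unit_labels.merge(truth_frame(units), on="unit_id")
        for cls in ("DM", "NL"):
            sub = lab[lab["true_class"] == cls]
            assert (sub["unit_label"] == cls).mean() >= 0.8

    def test_screen_separates_tagged_and_nonselective(self, analyzed_small_cohort):
        from tests.conftest import truth_frame

        cfg, units, analysis = analyzed_small_cohort
        scr = analysis.screen.merge(truth_frame(units), on="unit_id")
        tagged = scr[scr["true_class"] == "PV_TAGGED"]
        flat = scr[scr["true_class"] == "NONSELECTIVE"]
        if len(tagged):
            assert (tagged["status"] == "PV_TAGGED").mean() >= 0.8
        if len(flat):
            assert (flat["status"] == "NONSELECTIVE").mean() >= 0.8
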