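"""Von Mises fitting and tuning-metric unit tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvtuning as pv
from pvtuning.tuning import FlatTuningError, NoFitError, TuningCurve, VonMisesFit


def make_curve(directions, phi=90.0, kappa=2.0, v=0.5, a0=1.0, role="control"):
    return TuningCurve(directions, pv.von_mises_rate(directions, phi, kappa, v, a0), role=role)


class TestFit:
    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 5.0, 10.0])
    @pytest.mark.parametrize("v", [0.0, 0.5, 2.0])
    def test_noiseless_round_trip(self, directions24, kappa, v):
        """Generate-then-fit recovers the generating parameters."""
        curve = make_curve(directions24, phi=72.0, kappa=kappa, v=v, a0=1.3)
        fit = pv.fit_von_mises(curve)
        assert fit.kappa == pytest.approx(kappa, rel=1e-3, abs=1e-4)
        assert fit.v == pytest.approx(v, rel=1e-3, abs=1e-4)
        assert fit.a0 == pytest.approx(1.3, rel=1e-3)
        if v > 0:
            assert fit.phi == pytest.approx(72.0, abs=0.1)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_curve_limit(self, directions24):
        """A constant 5 Hz curve fits with no modulation and exp(a0) = 5."""
        curve = TuningCurve(directions24, np.full(24, 5.0))
        fit = pv.fit_von_mises(curve)
        assert fit.kappa == pytest.approx(0.0, abs=1e-6)
        assert fit.v == pytest.approx(0.0, abs=1e-6)
        assert np.exp(fit.a0) == pytest.approx(5.0, rel=1e-6)

    def test_antipodal_phi_degeneracy(self, directions24):
        """With v = 0 the model is 180-degree symmetric: fitted curves agree."""
        c1 = make_curve(directions24, phi=90.0, kappa=2.0, v=0.0)
        c2 = make_curve(directions24, phi=270.0, kappa=2.0, v=0.0)
        assert np.allclose(c1.mean_rate, c2.mean_rate)
        f1, f2 = pv.fit_von_mises(c1), pv.fit_von_mises(c2)
        grid = np.arange(0, 360, 1.0)
        assert np.allclose(f1.evaluate(grid), f2.evaluate(grid), rtol=1e-6)

    def test_peak_near_data_argmax(self, directions24):
        curve = make_curve(directions24, phi=142.0, kappa=1.5, v=0.4)
        fit = pv.fit_von_mises(curve)
        theta_p, *_ = pv.preferred_orientations(fit)
        argmax = curve.directions[int(np.argmax(curve.mean_rate))]
        assert abs((theta_p - argmax + 180) % 360 - 180) <= 15.0

    def test_all_zero_curve_raises(self, directions24):
        with pytest.raises(NoFitError):
            pv.fit_von_mises(TuningCurve(directions24, np.zeros(24)))

    def test_too_few_directions_raises(self):
        dirs = np.arange(6) * 60.0
        with pytest.raises(NoFitError):
            pv.fit_von_mises(TuningCurve(dirs, np.ones(6)))


class TestPreferredOrientations:
    def test_symmetric_fit(self):
        """With v = 0, theta_P is phi (mod 180) and theta_NP sits 90 deg away."""
        fit = VonMisesFit(phi=45.0, kappa=2.0, v=0.0, a0=1.0, r_squared=1.0)
        theta_p, theta_np, r_p, r_np = pv.preferred_orientations(fit)
        assert theta_p % 180.0 == pytest.approx(45.0, abs=0.01)
        ori_dist = abs((theta_p - theta_np + 90) % 180 - 90)
        assert ori_dist == pytest.approx(90.0, abs=0.1)
        assert r_p > r_np

    def test_against_dense_grid_oracle(self):
        """theta_NP matches a 0.01-degree brute-force argmin."""
        fit = VonMisesFit(phi=45.0, kappa=2.0, v=1.0, a0=1.0, r_squared=1.0)
        theta_p, theta_np, _, _ = pv.preferred_orientations(fit)
        assert theta_p == pytest.approx(45.0, abs=0.01)
        dense = np.arange(0.0, 360.0, 0.01)
        oracle = dense[int(np.argmin(fit.evaluate(dense)))]
        assert abs((theta_np - oracle + 180) % 360 - 180) < 0.05

    def test_flat_fit_raises(self):
        fit = VonMisesFit(phi=0.0, kappa=0.0, v=0.0, a0=1.0, r_squared=1.0)
        with pytest.raises(FlatTuningError):
            pv.preferred_orientations(fit)


class TestOSI:
    @pytest.mark.parametrize(
        "r_p,r_np,expected", [(10.0, 10.0, 0.0), (10.0, 0.0, 1.0), (3.0, 1.0, 0.5)]
    )
    def test_values(self, r_p, r_np, expected):
        assert pv.osi(r_p, r_np) == pytest.approx(expected)

    def test_both_zero_raises(self):
        with pytest.raises(FlatTuningError):
            pv.osi(0.0, 0.0)


class TestCircularVariance:
    def test_uniform_is_one(self, directions24):
        assert pv.circular_variance(directions24, np.full(24, 5.0)) == pytest.approx(1.0)

    def test_single_orientation_is_zero(self, directions24):
        rates = np.zeros(24)
        rates[3] = 10.0
        assert pv.circular_variance(directions24, rates) == pytest.approx(0.0)

    def test_antipodal_cancellation(self):
        """Equal responses at orientations 0 and 90 cancel on the 2-theta circle."""
        assert pv.circular_variance(np.array([0.0, 90.0]), np.array([3.0, 3.0])) == (
            pytest.approx(1.0)
        )

    def test_direction_folding(self, directions24):
        """Responses at theta and theta+180 add constructively (same orientation)."""
        rates = np.zeros(24)
        rates[2] = 4.0
        rates[14] = 6.0  # 30 and 210 deg: same orientation
        assert pv.circular_variance(directions24, rates) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_raises(self, directions24):
        with pytest.raises(FlatTuningError):
            pv.circular_variance(directions24, np.zeros(24))


class TestHalfBandwidth:
    def test_scale_invariance(self):
        f1 = VonMisesFit(phi=90.0, kappa=2.0, v=0.0, a0=1.0, r_squared=1.0)
        f2 = VonMisesFit(phi=90.0, kappa=2.0, v=0.0, a0=3.0, r_squared=1.0)
        assert pv.half_bandwidth(f1) == pytest.approx(pv.half_bandwidth(f2), rel=1e-9)

    def test_against_dense_grid_oracle(self):
        """HBW matches a 0.01-degree brute-force half-level crossing search."""
        fit = VonMisesFit(phi=90.0, kappa=2.0, v=0.0, a0=1.0, r_squared=1.0)
        theta_p, _, r_p, r_np = pv.preferred_orientations(fit)
        level = r_np + 0.5 * (r_p - r_np)
        dense = np.arange(theta_p - 90.0, theta_p + 90.0, 0.01)
        vals = np.asarray(fit.evaluate(dense))
        above = dense[vals >= level]
        oracle = 0.5 * (above.max() - above.min())
        assert pv.half_bandwidth(fit) == pytest.approx(oracle, abs=0.02)

    def test_monotone_decreasing_in_kappa(self):
        hbws = [
            pv.half_bandwidth(VonMisesFit(90.0, k, 0.0, 1.0, 1.0))
            for k in (1.0, 2.0, 5.0, 10.0, 50.0)
        ]
        assert all(a > b for a, b in zip(hbws, hbws[1:]))
        assert hbws[-1] < 10.0

    def test_flat_fit_raises(self):
        with pytest.raises(FlatTuningError):
            pv.half_bandwidth(VonMisesFit(0.0, 0.0, 0.0, 1.0, 1.0))


class TestDeltaFr:
    @pytest.mark.parametrize(
        "fr_l,fr_c,expected", [(5.0, 10.0, -0.5), (10.0, 10.0, 0.0), (30.0, 10.0, 2.0)]
    )
    def test_values(self, fr_l, fr_c, expected):
        assert pv.delta_fr(fr_l, fr_c) == pytest.approx(expected)

    def test_zero_control_raises(self):
        with pytest.raises(ValueError):
            pv.delta_fr(5.0, 0.0)


class TestMetricProperties:
    @given(
        scale=st.floats(min_value=0.01, max_value=100.0),
        kappa=st.floats(min_value=0.3, max_value=5.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_osi_cv_scale_invariant(self, scale, kappa):
        """OSI and CV are unchanged by multiplicative rate scaling."""
        dirs = np.arange(24) * 15.0
        rates = np.asarray(pv.von_mises_rate(dirs, 30.0, kappa, 0.2, 1.0))
        cv1 = pv.circular_variance(dirs, rates)
        cv2 = pv.circular_variance(dirs, rates * scale)
        assert cv1 == pytest.approx(cv2, rel=1e-9)

    @given(
        rates=st.lists(
            st.floats(min_value=0.0, max_value=100.0), min_size=8, max_size=36
        ).filter(lambda r: sum(r) > 0)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_cv_bounded(self, rates):
        n = len(rates)
        dirs = np.arange(n) * (360.0 / n)
        cv = pv.circular_variance(dirs, np.array(rates))
        assert -1e-12 <= cv <= 1.0 + 1e-12

    def test_monotone_in_kappa(self):
        """For symmetric tuning, OSI rises and CV falls as kappa grows."""
        grid = np.arange(0.0, 360.0, 0.5)
        osis, cvs = [], []
        for k in (0.5, 1.0, 2.0, 5.0):
            fit = VonMisesFit(90.0, k, 0.0, 1.0, 1.0)
            m = pv.compute_metrics(fit)
            osis.append(m.osi)
            cvs.append(m.cv)
        assert all(a < b for a, b in zip(osis, osis[1:]))
        assert all(a > b for a, b in zip(cvs, cvs[1:]))

    def test_grid_metrics_match_fit_metrics(self, directions24):
        """Dense-grid metrics agree with the analytic-fit metrics."""
        fit = VonMisesFit(60.0, 1.2, 0.3, np.log(20.0), 1.0)
        dense = np.arange(0.0, 360.0, 0.1)
        gm = pv.grid_metrics(dense, np.asarray(fit.evaluate(dense)))
        fm = pv.compute_metrics(fit)
        assert gm.hbw == pytest.approx(fm.hbw, abs=0.2)
        assert gm.osi == pytest.approx(fm.osi, abs=1e-3)
        assert gm.cv == pytest.approx(fm.cv, abs=1e-3)
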