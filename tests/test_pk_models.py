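"""Unit and property tests for the pharmacokinetic core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsedce.pk_models import (
    ConcentrationCurve,
    DegeneratePlasmaError,
    InvalidInputError,
    RelaxationConstants,
    SingularFitError,
    TissueParams,
    VIFModel,
    blood_to_plasma,
    concentration_to_t1,
    extended_tofts,
    monoexp_fit,
    patlak_coords,
    patlak_fit,
    t1_to_concentration,
)

TIMES = np.array([4.0 + 20.0 / 60.0, 25.0])


class TestExtendedTofts:
    def test_no_exchange_limit_is_vp_times_plasma(self):
        vif = VIFModel()
        params = TissueParams(ktrans=0.0, vp=0.04, ve=0.05)
        t = np.linspace(0.5, 30, 40)
        curve = extended_tofts(vif, params, t)
        np.testing.assert_allclose(curve.values, 0.04 * vif.concentration(t))

    def test_zero_input_gives_zero_tissue(self):
        params = TissueParams(ktrans=1e-3, vp=0.04, ve=0.05)
        curve = extended_tofts(lambda t: np.zeros_like(np.asarray(t, float)),
                               params, np.linspace(1, 20, 10))
        np.testing.assert_array_equal(curve.values, 0.0)

    def test_matches_closed_form_convolution_of_exponentials(self):
        # C_p = exp(-t), ktrans = 0.01, ve = 0.05, vp = 0:
        # C_t(t) = ktrans (exp(-kep t) - exp(-t)) / (1 - kep), kep = 0.2
        params = TissueParams(ktrans=0.01, vp=0.0, ve=0.05)
        t = np.linspace(0.25, 5.0, 20)
        curve = extended_tofts(lambda u: np.exp(-np.asarray(u, float)), params, t)
        kep = params.kep
        expected = 0.01 * (np.exp(-kep * t) - np.exp(-t)) / (1.0 - kep)
        np.testing.assert_allclose(curve.values, expected, atol=1e-6)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(InvalidInputError):
            extended_tofts(VIFModel(), TissueParams(1e-3, 0.04, 0.05), [5.0, 2.0])
        with pytest.raises(InvalidInputError):
            extended_tofts(VIFModel(), TissueParams(1e-3, 0.04, 0.05), [-1.0, 2.0])

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(0.1, 10.0))
    def test_vif_amplitude_scale_invariance_of_patlak(self, scale):
        """Scaling the VIF leaves the Patlak slope and intercept unchanged."""
        params = TissueParams(ktrans=8e-4, vp=0.049, ve=0.05)
        base = VIFModel()
        scaled = VIFModel(a_peak=base.a_peak * scale)
        fits = []
        for vif in (base, scaled):
            curve = extended_tofts(vif, params, TIMES)
            fits.append(patlak_fit(patlak_coords(curve, vif)))
        assert fits[1].ki == pytest.approx(fits[0].ki, rel=1e-8)
        assert fits[1].vp == pytest.approx(fits[0].vp, rel=1e-8)

    def test_negligible_backflux_recovers_truth(self):
        # ve -> large (kep -> 0): Patlak on noiseless output recovers
        # ktrans and vp to integration tolerance
        vif = VIFModel()
        params = TissueParams(ktrans=5e-4, vp=0.036, ve=0.96)
        curve = extended_tofts(vif, params, TIMES)
        fit = patlak_fit(patlak_coords(curve, vif))
        assert fit.ki == pytest.approx(5e-4, rel=2e-2)
        assert fit.vp == pytest.approx(0.036, rel=1e-2)

    def test_backflux_bias_monotone_in_ktrans_and_last_time(self):
        vif = VIFModel()

        def bias(ktrans, t_last):
            p = TissueParams(ktrans=ktrans, vp=0.036, ve=0.05)
            curve = extended_tofts(vif, p, np.array([TIMES[0], t_last]))
            return abs(patlak_fit(patlak_coords(curve, vif)).ki / ktrans - 1.0)

        biases_k = [bias(k, 25.0) for k in (2e-4, 5e-4, 8e-4, 1.6e-3)]
        assert np.all(np.diff(biases_k) >= 0)
        biases_t = [bias(5e-4, t) for t in (9.0, 17.0, 25.0, 33.0, 39.0)]
        assert np.all(np.diff(biases_t) >= 0)


class TestPatlakCoords:
    def test_constant_plasma_identity(self):
        t = np.array([2.0, 10.0, 20.0])
        ct = np.array([0.01, 0.02, 0.03])
        pts = patlak_coords(
            ConcentrationCurve(t, ct), lambda u: np.full_like(np.asarray(u, float), 2.0)
        )
        np.testing.assert_allclose(pts.x, t, rtol=1e-10)
        np.testing.assert_allclose(pts.y, ct / 2.0, rtol=1e-12)

    def test_exponential_plasma_analytic_integral(self):
        # C_p = A exp(-m t), m = 0.1: x(10) = (e^{m t} - 1)/m = 17.1828 min
        m = 0.1
        pts = patlak_coords(
            ConcentrationCurve(np.array([5.0, 10.0]), np.array([0.01, 0.01])),
            lambda u: 2.0 * np.exp(-m * np.asarray(u, float)),
        )
        assert pts.x[-1] == pytest.approx((np.exp(m * 10.0) - 1.0) / m, rel=1e-5)

    def test_nonpositive_plasma_raises_with_time(self):
        vif = VIFModel(t0=1.0, t_peak=2.0)  # zero before t = 1
        with pytest.raises(DegeneratePlasmaError, match="0.5"):
            patlak_coords(
                ConcentrationCurve(np.array([0.5, 5.0]), np.array([0.0, 0.01])), vif
            )


class TestPatlakFit:
    def test_exact_line_recovered(self):
        x = np.array([4.0, 10.0, 25.0])
        y = 8.0e-4 * x + 0.049
        fit = patlak_fit(patlak_coords_like(x, y))
        assert fit.ki == pytest.approx(8.0e-4, rel=1e-12)
        assert fit.vp == pytest.approx(0.049, rel=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_two_points_interpolated(self):
        fit = patlak_fit(patlak_coords_like(np.array([4.0, 30.0]),
                                            np.array([0.05, 0.06])))
        assert fit.n_points == 2
        assert fit.rss == pytest.approx(0.0, abs=1e-25)

    def test_matches_normal_equations_oracle(self, rng):
        x = np.sort(rng.uniform(1, 40, size=7))
        y = 5e-4 * x + 0.04 + rng.normal(0, 1e-3, size=7)
        fit = patlak_fit(patlak_coords_like(x, y))
        # brute-force normal equations
        A = np.array([[x.size, x.sum()], [x.sum(), (x * x).sum()]])
        b = np.array([y.sum(), (x * y).sum()])
        vp_ref, ki_ref = np.linalg.solve(A, b)
        assert fit.ki == pytest.approx(ki_ref, rel=1e-12)
        assert fit.vp == pytest.approx(vp_ref, rel=1e-12)

    def test_singular_when_all_x_equal(self):
        with pytest.raises(SingularFitError):
            patlak_fit(patlak_coords_like(np.array([3.0, 3.0]), np.array([1.0, 2.0])))


def patlak_coords_like(x, y):
    from sparsedce.pk_models import PatlakPoints

    return PatlakPoints(x=x, y=y)


class TestConversions:
    CONSTS = RelaxationConstants()

    def test_no_change_gives_zero(self):
        assert t1_to_concentration(1.5, 1.5, self.CONSTS) == 0.0

    def test_hand_computed_value(self):
        # (1/1.8 - 1/2.0)/4.2 = 0.013228 mM
        c = t1_to_concentration(2.0, 1.8, self.CONSTS)
        assert c == pytest.approx(0.0132275, rel=1e-4)

    def test_unit_delta_r1_gives_unit_concentration(self):
        # Delta R1 = 4.2 s^-1 with r1 = 4.2 mM^-1 s^-1 -> 1.000 mM
        t1_post = 1.0 / (1.0 / 2.0 + 4.2)
        assert t1_to_concentration(2.0, t1_post, self.CONSTS) == pytest.approx(1.0)

    def test_nonpositive_t1_flagged_as_nan(self):
        out = t1_to_concentration(np.array([2.0, -1.0, 0.0]),
                                  np.array([1.8, 1.8, 1.8]), self.CONSTS)
        assert np.isfinite(out[0]) and np.isnan(out[1]) and np.isnan(out[2])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(t1=st.floats(0.3, 4.0), c=st.floats(0.0, 2.0))
    def test_concentration_t1_round_trip_identity(self, t1, c):
        t1_post = concentration_to_t1(t1, c, self.CONSTS)
        assert t1_to_concentration(t1, t1_post, self.CONSTS) == pytest.approx(
            c, abs=1e-10
        )

    def test_hematocrit_correction(self):
        assert blood_to_plasma(0.55, RelaxationConstants(hct=0.45)) == pytest.approx(1.0)
        assert blood_to_plasma(0.7, RelaxationConstants(hct=0.0)) == 0.7
        assert blood_to_plasma(0.0, self.CONSTS) == 0.0

    def test_invalid_constants_rejected(self):
        with pytest.raises(InvalidInputError):
            RelaxationConstants(hct=1.2)
        with pytest.raises(InvalidInputError):
            RelaxationConstants(r1=-1.0)


class TestMonoExpFit:
    def test_exact_recovery(self):
        t = np.array([2.7, 4.3, 25.0])
        fit = monoexp_fit(t, 1.0 * np.exp(-0.05 * t))
        assert fit.amplitude == pytest.approx(1.0, rel=1e-12)
        assert fit.rate == pytest.approx(0.05, rel=1e-12)
        assert not fit.clamped

    def test_flat_limit(self):
        fit = monoexp_fit(np.array([1.0, 5.0, 9.0]), np.array([0.8, 0.8, 0.8]))
        assert fit.rate == 0.0
        assert fit.amplitude == pytest.approx(0.8)

    def test_rising_concentrations_clamped_and_flagged(self):
        fit = monoexp_fit(np.array([1.0, 5.0, 9.0]), np.array([0.5, 0.6, 0.8]))
        assert fit.rate == 0.0
        assert fit.clamped

    def test_matches_numeric_log_sse_minimizer(self, rng):
        from scipy.optimize import minimize

        t = np.array([2.7, 4.3, 25.0])
        c = 1.2 * np.exp(-0.04 * t) * np.exp(rng.normal(0, 0.05, size=3))
        fit = monoexp_fit(t, c)

        def sse(p):
            log_a, m = p
            return np.sum((np.log(c) - (log_a - m * t)) ** 2)

        res = minimize(sse, x0=[0.0, 0.01], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16})
        assert fit.rate == pytest.approx(res.x[1], abs=1e-6)
        assert np.log(fit.amplitude) == pytest.approx(res.x[0], abs=1e-6)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            monoexp_fit(np.array([1.0, 2.0]), np.array([0.5, -0.1]))


class TestDomainTypes:
    def test_tissue_params_invariants(self):
        with pytest.raises(InvalidInputError):
            TissueParams(ktrans=-1e-4, vp=0.03, ve=0.05)
        with pytest.raises(InvalidInputError):
            TissueParams(ktrans=1e-4, vp=0.5, ve=0.6)  # vp + ve > 1

    def test_vif_invariants(self):
        with pytest.raises(InvalidInputError):
            VIFModel(t_peak=0.0)
        with pytest.raises(InvalidInputError):
            VIFModel(shape="boxcar")
        vif = VIFModel()
        assert vif.concentration(-1.0) == 0.0
        assert vif.concentration(0.93) == pytest.approx(1.5)

    def test_gamma_shape_continuous_at_peak(self):
        vif = VIFModel(shape="gamma")
        eps = 1e-6
        assert vif.concentration(0.93 - eps) == pytest.approx(
            vif.concentration(0.93 + eps), rel=1e-3
        )
        # cumulative integral consistent with dense trapezoid
        t = np.linspace(0, 10, 24001)
        dense = np.trapezoid(vif.concentration(t), t)
        assert vif.cumulative_integral(10.0) == pytest.approx(dense, rel=1e-5)

    def test_curve_requires_increasing_times(self):
        with pytest.raises(InvalidInputError):
            ConcentrationCurve(np.array([1.0, 1.0]), np.array([0.1, 0.2]))
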