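"""FCS model evaluation, fitting, calibration and concentration."""

import numpy as np
import pytest

from poudimer import synth
from poudimer.fcs import (
    AVOGADRO,
    Calibration,
    FcsCurve,
    FcsModel,
    autocorrelation,
    calibrate,
    concentration,
    diffusion_coefficient,
    diffusion_time,
    effective_volume,
    fit_curve,
    read_curve_tsv,
    write_curve_tsv,
)

TAU_D = 3.676e-5  # s, a fluorescein-like diffusion time at w0 = 0.25 um
LAGS = np.geomspace(1e-7, 1e-2, 200)


def single(n=1.747, td=TAU_D, s=5.0, t=0.0, tau_t=2e-6, offset=1.0):
    return FcsModel(
        n_mean=n, tau_d=(td,), s_param=s, triplet_frac=t, tau_t=tau_t, offset=offset
    )


class TestAutocorrelation:
    def test_amplitude_limit_without_triplet(self):
        model = single(n=2.0, t=0.0)
        g0 = autocorrelation(model, [1e-15])[0]
        assert g0 == pytest.approx(1.0 + 1.0 / 2.0, rel=1e-9)

    def test_amplitude_identity_with_triplet(self):
        # G(0) - offset = 1 / (N (1 - T))
        model = single(n=1.5, t=0.3)
        g0 = autocorrelation(model, [1e-15])[0]
        assert g0 - model.offset == pytest.approx(1.0 / (1.5 * 0.7), rel=1e-9)

    def test_two_particle_with_zero_second_fraction_reduces(self):
        m1 = single()
        m2 = FcsModel(
            n_mean=1.747,
            tau_d=(TAU_D, 5 * TAU_D),
            fractions=(1.0, 0.0),
            s_param=5.0,
        )
        assert np.allclose(
            autocorrelation(m1, LAGS), autocorrelation(m2, LAGS), rtol=1e-12
        )

    def test_value_at_diffusion_time(self):
        model = single(n=1.0, s=50.0)
        g = autocorrelation(model, [TAU_D])[0]
        expected = 1.0 + 0.5 * (1.0 + 1.0 / 50.0**2) ** -0.5
        assert g == pytest.approx(expected, rel=1e-12)
        # large S: approaches offset + 1/(2N)
        assert g == pytest.approx(1.5, abs=1e-4)

    def test_strictly_decreasing(self):
        g = autocorrelation(single(t=0.15), LAGS)
        assert np.all(np.diff(g) < 0)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            FcsModel(n_mean=0.0, tau_d=(1e-4,))
        with pytest.raises(ValueError):
            FcsModel(n_mean=1.0, tau_d=(1e-4,), fractions=(0.5,))
        with pytest.raises(ValueError):
            FcsModel(n_mean=1.0, tau_d=(1e-4, 1e-3), fractions=(0.7, 0.4))
        with pytest.raises(ValueError):
            FcsModel(n_mean=1.0, tau_d=(1e-4,), s_param=0.5)


class TestFitCurve:
    def test_noiseless_self_consistency(self):
        truth = single(n=1.747, t=0.15)
        curve = FcsCurve(LAGS, autocorrelation(truth, LAGS))
        model, _ = fit_curve(curve, 1, fixed={"s_param": 5.0})
        assert model.n_mean == pytest.approx(truth.n_mean, rel=1e-6)
        assert model.tau_d[0] == pytest.approx(truth.tau_d[0], rel=1e-6)
        assert model.triplet_frac == pytest.approx(truth.triplet_frac, rel=1e-4)
        assert model.tau_t == pytest.approx(truth.tau_t, rel=1e-4)

    def test_round_trip_bias_under_noise(self):
        # simulate -> fit: < 2% median bias on N and tau_D
        truth = single(n=1.747, t=0.15)
        ns, tds = [], []
        for seed in range(60):
            curve = synth.generate_fcs_curve(truth, LAGS, seed=seed)
            model, _ = fit_curve(curve, 1, fixed={"s_param": 5.0})
            ns.append(model.n_mean)
            tds.append(model.tau_d[0])
        assert abs(np.median(ns) - truth.n_mean) / truth.n_mean < 0.02
        assert abs(np.median(tds) - truth.tau_d[0]) / truth.tau_d[0] < 0.02

    def test_two_component_bound_fraction_recovery(self):
        truth = FcsModel(
            n_mean=1.5,
            tau_d=(TAU_D, 3 * TAU_D),
            fractions=(0.7, 0.3),
            s_param=5.0,
            triplet_frac=0.15,
        )
        fb = []
        for seed in range(50):
            curve = synth.generate_fcs_curve(truth, LAGS, seed=seed)
            model, _ = fit_curve(
                curve, 2, fixed={"s_param": 5.0, "tau_d1": TAU_D, "tau_d2": 3 * TAU_D}
            )
            fb.append(model.fractions[1])
        assert np.mean(fb) == pytest.approx(0.30, abs=0.02)

    def test_two_component_requires_fixed_diffusion_time(self):
        curve = FcsCurve(LAGS, autocorrelation(single(), LAGS))
        with pytest.raises(ValueError, match="fixed"):
            fit_curve(curve, 2)

    def test_too_few_points_rejected(self):
        lags = LAGS[:20]
        curve = FcsCurve(lags, autocorrelation(single(), lags))
        with pytest.raises(ValueError, match="30"):
            fit_curve(curve, 1)


class TestCalibration:
    W0, S, D = 0.25, 5.0, 4.25e-6

    def make_curve(self, w0=None, s=None, noise=0.0, seed=0):
        w0 = w0 or self.W0
        s = s or self.S
        td = diffusion_time(self.D, w0)
        model = single(td=td, s=s, t=0.15)
        return synth.generate_fcs_curve(
            model, LAGS, synth.SnrDesign(noise_scale=noise), seed=seed
        )

    def test_forward_model_round_trip(self):
        cal = calibrate(self.make_curve(), self.D)
        assert cal.veff == pytest.approx(effective_volume(self.W0, self.S), rel=1e-3)
        assert cal.w0 == pytest.approx(self.W0, rel=1e-3)

    def test_doubling_dye_d_scales_volume(self):
        cal1 = calibrate(self.make_curve(), self.D)
        cal2 = calibrate(self.make_curve(), 2 * self.D)
        assert cal2.w0**2 == pytest.approx(2 * cal1.w0**2, rel=1e-9)
        assert cal2.veff == pytest.approx(2**1.5 * cal1.veff, rel=1e-9)

    def test_reproduces_488nm_calibration_volume(self):
        # beam waist chosen so that pi^1.5 w0^3 S = 0.58 fL
        veff_target = 0.58e-15
        w0 = (veff_target / (np.pi**1.5 * self.S * 1e-15)) ** (1 / 3)
        cal = calibrate(self.make_curve(w0=w0), self.D)
        assert cal.veff == pytest.approx(veff_target, rel=1e-3)

    def test_consistency_of_derived_fields(self):
        cal = Calibration(dye_d=self.D, tau_d=TAU_D, s_param=self.S)
        assert cal.veff == pytest.approx(
            np.pi**1.5 * cal.w0**3 * cal.s_param * 1e-15, rel=1e-9
        )
        assert diffusion_coefficient(cal.tau_d, cal.w0) == pytest.approx(self.D, rel=1e-9)


class TestConcentration:
    def test_printed_example(self):
        # N = 1.747 molecules in 0.58 fL is 5.0 nM
        cal = 0.58e-15
        assert concentration(1.747, cal) == pytest.approx(5.0, rel=1e-3)
        # closed form: N = C * N_A * V_eff
        assert 5.0e-9 * AVOGADRO * cal == pytest.approx(1.747, rel=1e-3)

    def test_zero_and_linearity(self):
        assert concentration(0.0, 0.58e-15) == 0.0
        assert concentration(3.494, 0.58e-15) == pytest.approx(
            2 * concentration(1.747, 0.58e-15), rel=1e-12
        )


class TestIO:
    def test_round_trip(self, tmp_path):
        curve = FcsCurve(LAGS, autocorrelation(single(), LAGS), np.ones_like(LAGS))
        path = tmp_path / "curve.tsv"
        write_curve_tsv(curve, path)
        back = read_curve_tsv(path)
        assert np.allclose(back.lags, curve.lags)
        assert np.allclose(back.g, curve.g)
        assert np.allclose(back.weights, curve.weights)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            FcsCurve(np.array([1e-3, 1e-4]), np.array([1.0, 1.0]))
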