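"""SNR metrics, photostability/recovery, power fits, resolution curves."""

import numpy as np
import pytest

from voltim.performance_metrics import (
    PowerSeries,
    fit_power_response,
    photorecovery,
    photostability,
    resolution_curve,
    snr_metrics,
)
from voltim.trace_extraction import Trace


def _trace_with(dff, raw=None, photons_per_unit=1.0, epochs=None):
    n = len(dff)
    return Trace(
        time=np.arange(float(n)),
        raw_f=np.asarray(raw if raw is not None else np.ones(n), dtype=float),
        baseline_f=np.asarray(raw if raw is not None else np.ones(n), dtype=float),
        dff=np.asarray(dff, dtype=float),
        f0=float(raw[0]) if raw is not None else 1.0,
        epochs=epochs or [(0, n)],
        photons_per_unit=photons_per_unit,
        frame_rate=1000.0,
    )


class TestSnrMetrics:
    def test_shot_snr_identity(self):
        # (-dF/F0) sqrt(F0): 0.5 * sqrt(400) = 10
        dff = 1e-9 * np.sin(np.arange(200))  # negligible baseline jitter
        dff[100:150] = -0.5
        tr = _trace_with(dff, raw=np.full(200, 400.0))
        resp = np.zeros(200, bool)
        resp[100:150] = True
        base = np.zeros(200, bool)
        base[:100] = True
        _, snr_shot = snr_metrics(tr, resp, base)
        assert snr_shot == pytest.approx(10.0)

    def test_poisson_step_empirical_equals_shot(self):
        # pure-Poisson trace: empirical SNR should sit at the shot limit
        rng = np.random.default_rng(0)
        f0 = 2000.0
        n = 3000
        lam = np.full(n, f0)
        lam[1500:2000] *= 0.7
        raw = rng.poisson(lam).astype(float)
        base_mean = raw[:1500].mean()
        tr = Trace(time=np.arange(float(n)), raw_f=raw,
                   baseline_f=np.full(n, base_mean),
                   dff=raw / base_mean - 1.0, f0=base_mean,
                   epochs=[(0, n)], photons_per_unit=1.0, frame_rate=1000.0)
        resp = np.zeros(n, bool)
        resp[1500:2000] = True
        base = np.zeros(n, bool)
        base[:1500] = True
        snr_emp, snr_shot = snr_metrics(tr, resp, base)
        assert snr_emp / snr_shot == pytest.approx(1.0, abs=0.1)

    def test_snr_shot_scales_with_sqrt_f0(self):
        dff = 1e-9 * np.sin(np.arange(200))
        dff[100:150] = -0.2
        resp = np.zeros(200, bool)
        resp[100:150] = True
        base = np.zeros(200, bool)
        base[:100] = True
        _, s1 = snr_metrics(_trace_with(dff, raw=np.full(200, 500.0)),
                            resp, base)
        _, s2 = snr_metrics(_trace_with(dff, raw=np.full(200, 2000.0)),
                            resp, base)
        assert s2 / s1 == pytest.approx(2.0, abs=1e-9)

    def test_overlapping_windows_raise(self):
        tr = _trace_with(np.zeros(100))
        sel = np.ones(100, bool)
        with pytest.raises(ValueError, match="disjoint"):
            snr_metrics(tr, sel, sel)


class TestPhotostability:
    def test_constant_trace(self):
        tr = _trace_with(np.zeros(100), raw=np.full(100, 500.0))
        assert photostability(tr) == pytest.approx(1.0)

    def test_linear_decay_trapezoid(self):
        # linear decay to 0.6 F0 -> mean 0.8 F0
        raw = np.linspace(1000.0, 600.0, 1001)
        tr = _trace_with(np.zeros(1001), raw=raw)
        assert photostability(tr) == pytest.approx(0.8, abs=1e-3)

    def test_invariant_under_rescaling(self):
        raw = np.linspace(900.0, 700.0, 300)
        t1 = photostability(_trace_with(np.zeros(300), raw=raw))
        t2 = photostability(_trace_with(np.zeros(300), raw=raw * 17.0))
        assert t1 == pytest.approx(t2)

    def test_nonpositive_f0_raises(self):
        tr = _trace_with(np.zeros(100), raw=np.zeros(100))
        with pytest.raises(ValueError):
            photostability(tr)


class TestPhotorecovery:
    def test_no_bleach_all_ones(self):
        raw = np.full(300, 800.0)
        tr = _trace_with(np.zeros(300), raw=raw,
                         epochs=[(0, 100), (100, 200), (200, 300)])
        mean, ratios = photorecovery(tr)
        assert np.allclose(ratios, 1.0)
        assert mean == pytest.approx(1.0)

    def test_bleach_without_recovery_decreasing(self):
        raw = np.concatenate([np.full(100, 1000.0), np.full(100, 850.0),
                              np.full(100, 700.0)])
        tr = _trace_with(np.zeros(300), raw=raw,
                         epochs=[(0, 100), (100, 200), (200, 300)])
        _, ratios = photorecovery(tr)
        assert np.all(ratios < 1.0)

    def test_single_epoch_raises(self):
        tr = _trace_with(np.zeros(100), raw=np.ones(100), epochs=[(0, 100)])
        with pytest.raises(ValueError):
            photorecovery(tr)

    def test_generator_recovery_fraction_recovered(self):
        # movie-level: recovery_fraction 0.97 with equilibrated fast bleach
        from voltim.scenarios import extract_protocol2_snr
        from voltim.synthetic_movies import (
            AcquisitionSpec, CellSpec, SensorModel, make_protocol,
            render_movie,
        )
        from voltim.trace_extraction import illumination_epochs

        sensor = SensorModel(bleach_fast_amp=1.0, bleach_fast_tau=0.02,
                             bleach_slow_tau=1e9, recovery_fraction=0.97)
        prot = make_protocol("protocol2", {"acquisition_rate": 1000.0})
        # zero readout: frames tile the epochs identically, so the
        # self-similar within-epoch decay cancels exactly in the ratios
        acq = AcquisitionSpec(exposure=1.0, readout=0.0, n_rows=60, n_cols=60)
        movie, truth = render_movie(CellSpec(radius=4.0, expression=200.0),
                                    None, prot, acq, sensor, seed=5,
                                    background_rate=0.0)
        res = extract_protocol2_snr(movie, truth)
        eps = illumination_epochs(truth.illumination)
        mean, _ = photorecovery(res["trace"], eps, pre_window=45)
        assert mean == pytest.approx(0.97, abs=0.01)


class TestPowerFits:
    @staticmethod
    def _series(exponent=2.0, seed=0, snr_noise=0.0):
        rng = np.random.default_rng(seed)
        p = np.array([0.66, 0.88, 1.11, 1.33, 1.55])
        f0 = 1e6 * p**exponent
        snr = 430.0 * p * (1 + rng.normal(0, snr_noise, p.size))
        dff = np.full(p.size, 43.0)
        return PowerSeries(power_density=p, f0=f0, snr=snr, dff=dff)

    def test_quadratic_exponent(self):
        exp, _, _ = fit_power_response(self._series(2.0))
        assert exp == pytest.approx(2.0, abs=1e-9)

    def test_linear_one_photon_control(self):
        exp, _, _ = fit_power_response(self._series(1.0))
        assert exp == pytest.approx(1.0, abs=1e-9)

    def test_shot_limited_r2(self):
        _, r2, _ = fit_power_response(self._series(2.0, snr_noise=0.0))
        assert r2 >= 0.999

    def test_exponent_recovery_bias(self):
        # small multiplicative noise on F0: recovered exponent unbiased
        rng = np.random.default_rng(1)
        errs = []
        for seed in range(100):
            s = self._series(2.0, seed=seed)
            s.f0 = s.f0 * (1 + rng.normal(0, 0.02, 5))
            exp, _, _ = fit_power_response(s)
            errs.append(exp - 2.0)
        assert abs(np.mean(errs)) < 0.05

    def test_nonpositive_f0_raises(self):
        s = self._series()
        s.f0[0] = 0.0
        with pytest.raises(ValueError):
            fit_power_response(s)


class TestResolutionCurve:
    def test_spot_scan_fwhm_brackets_cell(self):
        # 12 um flat-top spot swept across a 12 um soma in densely
        # labelled tissue.  The scan response is the spike -%dF/F0 of the
        # extracted trace: a ratio, whose denominator includes the
        # fluorescence the displaced spot excites in neighbouring
        # (non-spiking) labelled somata -- modelled as half the on-target
        # signal.  The resulting FWHM lands between the spot size and the
        # spot-plus-soma convolution.
        from voltim.lightsculpt import SpotSpec, gpc_synthesize, make_gpc_mask
        from voltim.synthetic_movies import AcquisitionSpec

        acq = AcquisitionSpec(n_rows=240, n_cols=240)
        cgrid = (np.arange(240) - 119.5) * acq.pixel_size
        gx, gy = np.meshgrid(cgrid, cgrid)
        mask = gx**2 + gy**2 <= 6.0**2  # projected soma
        emap, _ = gpc_synthesize(make_gpc_mask(SpotSpec(diameter=12.0)),
                                 n_grid=1024)
        tp = emap.intensity**2
        tp /= tp.max()
        n = tp.shape[0]
        disp = np.arange(-16.0, 16.5, 1.0)
        signal = []
        for d in disp:
            rr = np.clip(np.round(gy / 0.1625 + (n - 1) / 2).astype(int),
                         0, n - 1)
            cc = np.clip(np.round((gx - d) / 0.1625 + (n - 1) / 2).astype(int),
                         0, n - 1)
            signal.append(tp[rr, cc][mask].sum())
        signal = np.asarray(signal)
        background = 0.5 * signal.max()  # dense-labelling neighbours
        dff = 0.43 * signal / (signal + background)
        fwhm = resolution_curve(dff, disp)
        assert 12.0 <= fwhm <= 16.0

    def test_delta_response_returns_step(self):
        disp = np.arange(-5.0, 6.0, 1.0)
        resp = np.zeros(disp.size)
        resp[5] = 1.0
        assert resolution_curve(resp, disp) == pytest.approx(1.0)

    def test_symmetric_curve_symmetric_crossings(self):
        disp = np.arange(-10.0, 10.5, 0.5)
        resp = np.exp(-(disp**2) / 18.0)
        fwhm = resolution_curve(resp, disp)
        assert fwhm == pytest.approx(2 * np.sqrt(18.0 * np.log(2)), rel=0.01)

    def test_non_bracketing_raises(self):
        disp = np.arange(0.0, 5.0)
        resp = np.exp(-(disp**2) / 100.0)
        with pytest.raises(ValueError, match="bracket"):
            resolution_curve(resp, disp)
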