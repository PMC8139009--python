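"""Pulse harmonics, frequency-domain drive and time-domain reconstruction."""

import numpy as np
import pytest

from tpbecm.dielectric import ElectrodeGeometry, TabulatedMaterial
from tpbecm.network import LayeredBody, TissueLayer
from tpbecm.stimulation import (
    HarmonicSpectrum,
    PulseSpec,
    dose_map,
    pulse_harmonics,
    respond,
    respond_harmonics,
)

GEO = ElectrodeGeometry(width_m=0.01, length_m=0.01, separation_m=0.01)


def _single_layer_body(eps_rel, sigma, gel, g2=0.01):
    f = np.array([1e-4, 1e8])
    mat = TabulatedMaterial("layer", f, np.full(2, float(eps_rel)),
                            np.full(2, float(sigma)))
    return LayeredBody(layers=(TissueLayer(material=mat, infinite=True),),
                       geometry=GEO, gel_resistance=gel, g2=g2)


def _trapezoid(t, spec):
    """Reference time-domain trapezoid sampled analytically."""
    a, w, tr = spec.intensity, spec.width_ms * 1e-3, spec.ramp_time_us * 1e-6
    t = np.asarray(t) % spec.period_s
    up = np.clip(t / tr, 0, 1)
    down = np.clip((t - w) / tr, 0, 1)
    return a * (up - down)


class TestPulseSpec:
    def test_duty_must_stay_below_one(self):
        with pytest.raises(ValueError, match="duty"):
            PulseSpec(width_ms=150.0, frequency_hz=10.0)

    def test_ramp_must_fit_in_width(self):
        with pytest.raises(ValueError, match="ramp"):
            PulseSpec(width_ms=0.001, frequency_hz=10.0, ramp_time_us=2.0)

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError):
            PulseSpec(intensity=0.0)


class TestPulseHarmonics:
    def test_dc_term_is_duty_weighted_average(self):
        h = pulse_harmonics(PulseSpec(intensity=1.0, width_ms=3.0,
                                      frequency_hz=10.0), 16)
        assert h.coefficients[0].real == pytest.approx(0.03, rel=1e-12)

    def test_fundamental_matches_ideal_square_series(self):
        spec = PulseSpec(intensity=1.0, width_ms=3.0, frequency_hz=10.0,
                         ramp_time_us=1.0)
        h = pulse_harmonics(spec, 8)
        # one-sided amplitude 2|c_k| vs (2A/(pi k))|sin(pi k W F)|
        for k in (1, 2, 5):
            ideal = (2.0 / (np.pi * k)) * abs(np.sin(np.pi * k * 0.03))
            assert 2 * abs(h.coefficients[k]) == pytest.approx(ideal, rel=1e-6)

    def test_reconstruction_matches_trapezoid_away_from_edges(self):
        spec = PulseSpec(intensity=1.0, width_ms=3.0, frequency_hz=10.0,
                         ramp_time_us=1.0)
        h = pulse_harmonics(spec, 2000)
        t, x = h.reconstruct()
        ref = _trapezoid(t, spec)
        # exclude the Gibbs-ringing neighbourhood of both edges; at 2000
        # harmonics the ringing envelope falls below 1% ~20 samples out
        guard = 20 * (t[1] - t[0])
        w = spec.width_ms * 1e-3
        mask = (np.abs(t - 0) > guard) & (np.abs(t - w) > guard) \
            & (np.abs(t - spec.period_s) > guard)
        assert np.max(np.abs(x - ref)[mask]) <= 0.01 * spec.intensity

    def test_parseval_identity(self):
        h = pulse_harmonics(PulseSpec(), 1024)
        _, x = h.reconstruct()
        assert np.mean(x**2) == pytest.approx(h.power(), rel=1e-6)

    def test_material_validity_truncates_with_warning(self, agar_pair):
        body = LayeredBody(
            layers=(TissueLayer(material=agar_pair.pure, infinite=True),),
            geometry=GEO, g2=0.01)
        with pytest.warns(UserWarning, match="truncating harmonics"):
            respond(body, PulseSpec(frequency_hz=10.0), n_harmonics=4096)


class TestRespond:
    def test_resistive_body_preserves_pulse_shape(self):
        body = _single_layer_body(eps_rel=1.0, sigma=5.0, gel=160.0)
        spec = PulseSpec(intensity=1.0)
        tr = respond(body, spec, 2048)
        r_total = 1.0 / (5.0 * 0.01) + 160.0
        np.testing.assert_allclose(tr.total_current, tr.source / r_total,
                                   rtol=0, atol=1e-3 / r_total)

    def test_single_rc_layer_matches_exponential_transient(self):
        # parallel RC layer behind a series gel resistor, driven by a square
        # voltage pulse: the periodic steady state is piecewise exponential
        eps_rel, sigma, gel, g2 = 1e7, 0.02, 1000.0, 0.01
        from tpbecm.dielectric import EPS0

        r = 1.0 / (sigma * g2)
        c = eps_rel * EPS0 * g2
        body = _single_layer_body(eps_rel, sigma, gel, g2)
        spec = PulseSpec(intensity=1.0, width_ms=3.0, frequency_hz=10.0)
        tr = respond(body, spec, 4096)

        tau = 1.0 / (1.0 / (gel * c) + 1.0 / (r * c))
        v_inf = spec.intensity * r / (r + gel)
        w, t_per = spec.width_ms * 1e-3, spec.period_s
        # periodic boundary: v0 at pulse onset, v_w at pulse end
        e_on, e_off = np.exp(-w / tau), np.exp(-(t_per - w) / tau)
        v0 = v_inf * (1 - e_on) * e_off / (1 - e_on * e_off)
        v_w = v_inf + (v0 - v_inf) * e_on
        t = tr.time_s
        v_layer = np.where(
            t < w,
            v_inf + (v0 - v_inf) * np.exp(-t / tau),
            v_w * np.exp(-(t - w) / tau),
        )
        i_ref = (_trapezoid(t, spec) - v_layer) / gel
        guard = 16 * (t[1] - t[0])
        mask = (t > guard) & (np.abs(t - w) > guard) & (t < t_per - guard)
        err = np.abs(tr.total_current - i_ref)[mask]
        assert np.max(err) <= 0.01 * np.max(np.abs(i_ref))

    def test_kirchhoff_closure_every_sample(self, forearm_calibrated):
        tr = respond(forearm_calibrated, PulseSpec(), 2048)
        total = tr.gel_voltage + sum(tr.layer_voltages.values())
        scale = np.max(np.abs(tr.source))
        assert np.max(np.abs(total - tr.source)) <= 1e-8 * scale

    def test_skin_voltage_tracks_source_deep_layers_track_current(
            self, forearm_calibrated):
        tr = respond(forearm_calibrated, PulseSpec(), 2048)
        v_skin = tr.layer_voltages["skin_dry"]
        # skin takes nearly all of the source; deep layers take little
        assert np.max(np.abs(v_skin)) > 0.8 * np.max(np.abs(tr.source))
        for name in ("fat", "muscle"):
            v = tr.layer_voltages[name]
            assert np.max(np.abs(v)) < 0.1 * np.max(np.abs(tr.source))
            # deep-layer voltage is shaped like the total current
            rho = np.corrcoef(v, tr.total_current)[0, 1]
            assert rho > 0.95

    def test_mode_round_trip(self, forearm_calibrated):
        spec_v = PulseSpec(mode="voltage", intensity=1.0)
        tr = respond(forearm_calibrated, spec_v, 2048)
        # re-drive with the computed current harmonics as a current source
        n = len(tr.total_current)
        i_k = np.fft.rfft(tr.total_current)[:2049] / n
        source_i = HarmonicSpectrum(fundamental_hz=spec_v.frequency_hz,
                                    coefficients=i_k)
        spec_i = PulseSpec(mode="current", intensity=1.0,
                           width_ms=spec_v.width_ms,
                           frequency_hz=spec_v.frequency_hz)
        back = respond_harmonics(forearm_calibrated, source_i, spec_i)
        err = np.max(np.abs(back.source_voltage - tr.source))
        assert err <= 0.01 * np.max(np.abs(tr.source))

    def test_current_drive_reports_compliance_voltage(self, forearm_calibrated):
        tr = respond(forearm_calibrated,
                     PulseSpec(mode="current", intensity=1e-3), 2048)
        peak_v = np.max(np.abs(tr.source_voltage))
        assert peak_v > 1.0  # tens of volts across a ~30 kOhm skin barrier


class TestDoseMap:
    def test_single_cell_equals_direct_respond(self, forearm_calibrated):
        spec = PulseSpec()
        grid = dose_map(forearm_calibrated, spec, [3.0], [10.0], n_harmonics=1024)
        tr = respond(forearm_calibrated, spec, 1024)
        on = tr.time_s <= 3e-3
        expected = np.mean(np.abs(tr.total_current[on]))
        assert grid.iloc[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_current_decreases_with_pulse_width(self, forearm_calibrated):
        widths = [0.05, 0.15, 0.5, 1.5, 5.0]
        grid = dose_map(forearm_calibrated, PulseSpec(), widths, [10.0],
                        n_harmonics=2048)
        vals = grid.to_numpy().ravel()
        assert np.all(np.diff(vals) <= 1e-9 * vals[:-1])

    def test_duty_violations_skipped_with_warning(self, forearm_calibrated):
        with pytest.warns(UserWarning, match="duty"):
            grid = dose_map(forearm_calibrated, PulseSpec(), [5.0],
                            [10.0, 300.0], n_harmonics=256)
        assert np.isnan(grid.loc[5.0, 300.0])
        assert np.isfinite(grid.loc[5.0, 10.0])

    def test_empty_grid_rejected(self, forearm_calibrated):
        with pytest.raises(ValueError):
            dose_map(forearm_calibrated, PulseSpec(), [], [10.0])
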