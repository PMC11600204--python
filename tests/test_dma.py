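"""Spectral viscoelasticity extraction, Lissajous modulus, CF summaries."""

import math
from dataclasses import replace

import numpy as np
import pytest

from fibermech.bench import Recording, run_length_sweep, run_oscillation
from fibermech.dma import (
    cf_criterion_value,
    extract_viscoelasticity,
    find_optimal_length,
    lissajous_modulus,
    stress_strain,
)
from fibermech.samples import PlantParams, complex_modulus_closed_form

OMEGA = 2 * math.pi * 0.1


def make_recording(force, lm, x, dt=0.2, d0=110e-6, l0=5e-3):
    n = len(force)
    return Recording(
        sample_id="t",
        time=np.arange(n) * dt,
        probe_displacement=np.asarray(lm, dtype=float),
        tip_deflection=np.asarray(x, dtype=float),
        force=np.asarray(force, dtype=float),
        stimulus=np.zeros(n, dtype=bool),
        medium="solution",
        protocol="oscillation",
        metadata={"diameter": d0, "rest_length": l0, "stiffness": 1.0,
                  "pixel_size": 1e-6},
    )


class TestStressStrain:
    def test_printed_force_and_smallest_diameter(self):
        rec = make_recording([8.32e-6], [0.0], [0.0], d0=110e-6)
        sigma, _ = stress_strain(rec)
        assert sigma[0] == pytest.approx(875.6, rel=1e-3)

    def test_probe_absorbing_all_motion_gives_zero_strain(self):
        rec = make_recording([0.0], [0.3e-3], [0.3e-3])
        _, eps = stress_strain(rec)
        assert eps[0] == 0.0

    def test_nine_percent_strain(self):
        rec = make_recording([0.0], [0.50e-3], [0.05e-3], l0=5e-3)
        _, eps = stress_strain(rec)
        assert eps[0] == pytest.approx(0.09)

    def test_scale_equivariance_in_diameter(self):
        """Doubling d_0 quarters the stress, hence quarters E*."""
        t = np.arange(0, 60, 0.2)
        f = 5e-6 * np.sin(OMEGA * t)
        lm = 0.5e-3 * np.sin(OMEGA * t)
        r1 = make_recording(f, lm, np.zeros_like(t), d0=110e-6)
        r2 = make_recording(f, lm, np.zeros_like(t), d0=220e-6)
        s1, e1 = stress_strain(r1)
        s2, e2 = stress_strain(r2)
        np.testing.assert_allclose(s1, 4 * s2)
        v1 = extract_viscoelasticity(s1, e1, t, 0.1)
        v2 = extract_viscoelasticity(s2, e2, t, 0.1)
        assert v1.e_star == pytest.approx(4 * v2.e_star)


class TestSpectralExtraction:
    def test_constructed_sinusoids(self):
        """sigma leading eps by 0.3805 rad at an amplitude ratio of 1 kPa
        gives E* = 1 kPa and tan delta = 0.4."""
        t = np.arange(0, 60, 0.2)
        sigma = 100.0 * np.sin(OMEGA * t + 0.3805)
        eps = 0.1 * np.sin(OMEGA * t)
        vs = extract_viscoelasticity(sigma, eps, t, 0.1, settle_cycles=1)
        assert vs.e_star == pytest.approx(1000.0, rel=1e-6)
        assert vs.tan_delta == pytest.approx(math.tan(0.3805), rel=1e-6)

    def test_zero_phase_difference(self):
        t = np.arange(0, 60, 0.2)
        s = 50.0 * np.sin(OMEGA * t)
        vs = extract_viscoelasticity(s, s / 1000.0, t, 0.1)
        assert vs.tan_delta == pytest.approx(0.0, abs=1e-9)

    def test_kelvin_voigt_fixture_within_one_percent(self, short_probe):
        params = PlantParams(
            equilibrium_modulus=3000.0,
            drag_coefficient=1200.0 / OMEGA,
            diameter=200e-6,
        )
        rec = run_oscillation(params, short_probe, noise_px=0, quantize=False)
        sigma, eps = stress_strain(rec)
        vs = extract_viscoelasticity(sigma, eps, rec.time, 0.1)
        assert vs.e_star == pytest.approx(3231.1, rel=0.01)
        assert vs.tan_delta == pytest.approx(0.4, rel=0.01)

    def test_too_few_periods_rejected(self):
        t = np.arange(0, 25, 0.2)  # 2.5 periods at 0.1 Hz
        s = np.sin(OMEGA * t)
        with pytest.raises(ValueError, match="periods"):
            extract_viscoelasticity(s, s, t, 0.1, settle_cycles=0)

    def test_no_excitation_rejected(self):
        t = np.arange(0, 60, 0.2)
        with pytest.raises(ValueError, match="excitation"):
            extract_viscoelasticity(np.sin(OMEGA * t), np.zeros_like(t), t, 0.1)

    def test_leakage_flagged_on_partial_cycle(self):
        t = np.arange(0, 63.4, 0.2)
        sigma = 100.0 * np.sin(OMEGA * t + 0.2)
        eps = 0.1 * np.sin(OMEGA * t)
        vs = extract_viscoelasticity(sigma, eps, t, 0.1)
        assert "leakage_trimmed" in vs.flags
        assert vs.e_star == pytest.approx(1000.0, rel=1e-3)


class TestLissajous:
    def test_elastic_amplitude_ratio(self):
        t = np.arange(0, 60, 0.2)
        eps = 0.1 * np.sin(OMEGA * t)
        assert lissajous_modulus(3000.0 * eps, eps, t, 0.1) == pytest.approx(
            3000.0
        )

    def test_matches_complex_modulus_for_linear_plant(self, short_probe,
                                                      linear_core):
        rec = run_oscillation(linear_core, short_probe, noise_px=0,
                              quantize=False)
        sigma, eps = stress_strain(rec)
        vs = extract_viscoelasticity(sigma, eps, rec.time, 0.1)
        assert vs.e_lissajous == pytest.approx(vs.e_star, rel=0.02)

    def test_uses_final_loop_only(self):
        """With a decaying transient the all-record estimate differs; the
        final-loop estimate recovers the steady amplitude ratio."""
        t = np.arange(0, 60, 0.2)
        eps = 0.1 * np.sin(OMEGA * t)
        transient = 200.0 * np.exp(-t / 5.0)
        sigma = 3000.0 * eps + transient
        final = lissajous_modulus(sigma, eps, t, 0.1)
        whole = (sigma.max() - sigma.min()) / (eps.max() - eps.min())
        assert final == pytest.approx(3000.0, rel=5e-3)
        assert abs(whole - 3000.0) > 10 * abs(final - 3000.0)

    def test_constant_strain_rejected(self):
        t = np.arange(0, 60, 0.2)
        with pytest.raises(ValueError, match="strain"):
            lissajous_modulus(np.sin(OMEGA * t), np.ones_like(t), t, 0.1)


class TestOracleEquivalence:
    def test_linear_plants_noise_free(self, short_probe):
        """Simulate->extract matches the closed form within 1 % for random
        linear Zener+drag plants, noise and quantization off."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            params = PlantParams(
                equilibrium_modulus=rng.uniform(800, 4000),
                arm_modulus=rng.uniform(200, 3000),
                arm_viscosity=rng.uniform(100, 2000),
                drag_coefficient=rng.uniform(0, 2500),
                diameter=200e-6,
            )
            rec = run_oscillation(params, short_probe, noise_px=0,
                                  quantize=False)
            sigma, eps = stress_strain(rec)
            vs = extract_viscoelasticity(sigma, eps, rec.time, 0.1)
            es, td = complex_modulus_closed_form(params, 0.1, "solution")
            assert vs.e_star == pytest.approx(es, rel=0.01)
            assert vs.tan_delta == pytest.approx(td, abs=max(0.01 * td, 5e-3))

    def test_quantization_error_bounded(self, short_probe, linear_core):
        """The E* error due to pixel quantization is bounded by
        force_per_pixel / (A_eps * A_0)."""
        from fibermech.samples import cross_section_area

        clean = run_oscillation(linear_core, short_probe, noise_px=0,
                                quantize=False)
        quant = run_oscillation(linear_core, short_probe, noise_px=0,
                                quantize=True)
        vc = extract_viscoelasticity(*stress_strain(clean), clean.time, 0.1)
        vq = extract_viscoelasticity(*stress_strain(quant), quant.time, 0.1)
        bound = short_probe.calibration.force_per_pixel / (
            vc.strain_amplitude * cross_section_area(linear_core)
        )
        assert abs(vq.e_star - vc.e_star) <= bound


class TestContraction:
    def test_optimal_length_recovery(self, long_probe, myobundle):
        stim = run_length_sweep(myobundle, long_probe, stimulate=True,
                                noise_px=0)
        passive = run_length_sweep(myobundle, long_probe, stimulate=False,
                                   noise_px=0)
        cs = find_optimal_length(stim, passive)
        assert 0.04 <= cs.optimal_strain <= 0.07
        assert cs.cf_generated
        assert cs.force_at_optimum > cs.passive_at_optimum

    def test_dead_plant_generates_nothing(self, long_probe, myobundle):
        dead = replace(myobundle, active_peak=0.0)
        stim = run_length_sweep(dead, long_probe, stimulate=True, noise_px=0)
        passive = run_length_sweep(dead, long_probe, stimulate=False,
                                   noise_px=0)
        cs = find_optimal_length(stim, passive)
        assert abs(cs.active_peak) < 0.5e-6
        assert not cs.cf_generated

    def test_cf_criterion_thresholds(self):
        diff, ok, _ = cf_criterion_value(10e-6, [6.5e-6, 6.5e-6])
        assert diff == pytest.approx(3.5e-6)
        assert ok
        diff, ok, _ = cf_criterion_value(8.5e-6, [6.5e-6, 6.5e-6])
        assert diff == pytest.approx(2.0e-6)
        assert not ok

    def test_all_passive_group(self):
        diff, ok, _ = cf_criterion_value(6.5e-6, [6.4e-6, 6.6e-6])
        assert abs(diff) < 0.2e-6
        assert not ok

    def test_singleton_group_uses_own_baseline(self):
        diff, ok, flags = cf_criterion_value(10e-6, [], own_passive=6e-6)
        assert "singleton_group_own_baseline" in flags
        assert ok
        with pytest.raises(ValueError):
            cf_criterion_value(10e-6, [])
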