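"""Digital-twin protocols: force balance, quantization, populations."""

from dataclasses import replace

import numpy as np
import pytest

from fibermech.bench import (
    FixationError,
    PlantSimulator,
    Recording,
    generate_population,
    run_length_sweep,
    run_oscillation,
    run_stimulation,
)
from fibermech.dma import stress_strain
from fibermech.probe import stiffness
from fibermech.samples import condition_grid


class TestForceBalance:
    def test_rigid_sample_moves_the_probe(self, short_probe, core):
        rigid = replace(core, equilibrium_modulus=1e9, arm_modulus=0.0,
                        arm_viscosity=0.0, drag_coefficient=0.0,
                        passive_stiffening=0.0)
        rec = run_oscillation(rigid, short_probe, amplitude_strain=1e-4,
                              noise_px=0, quantize=False)
        # all displacement appears at the probe tip
        mask = rec.probe_displacement > 0.01 * rec.probe_displacement.max()
        ratio = rec.tip_deflection[mask] / rec.probe_displacement[mask]
        assert np.all(ratio > 0.999)

    def test_limp_sample_leaves_probe_still(self, short_probe, core):
        limp = replace(core, equilibrium_modulus=1e-3, arm_modulus=0.0,
                       arm_viscosity=0.0, drag_coefficient=0.0,
                       passive_stiffening=0.0)
        rec = run_oscillation(limp, short_probe, noise_px=0, quantize=False)
        assert np.max(np.abs(rec.tip_deflection)) < 1e-4 * np.max(
            rec.probe_displacement
        )

    def test_force_is_exactly_stiffness_times_deflection(self, short_probe,
                                                         core):
        rec = run_oscillation(core, short_probe, seed=1)
        k = stiffness(short_probe)
        np.testing.assert_array_equal(rec.force, k * rec.tip_deflection)

    def test_prequantization_balance_residual(self, short_probe,
                                              elastic_plant):
        """For an elastic sample the balance has the closed form
        x = L_m k_s/(k_s + k); the solver must close it to < 1e-9 N."""
        from fibermech.samples import cross_section_area

        sim = PlantSimulator(elastic_plant, short_probe)
        k = stiffness(short_probe)
        ks = (cross_section_area(elastic_plant)
              * elastic_plant.equilibrium_modulus
              / elastic_plant.rest_length)
        for lm in np.linspace(0.0, 0.5e-3, 20)[1:]:
            x = sim.advance(lm, 0.2, n_sub=2)
            assert abs(k * x - k * lm * ks / (ks + k)) < 1e-9

    def test_pixel_quantization_floor(self, short_probe, core):
        rec = run_oscillation(core, short_probe, seed=2)
        px = short_probe.pixel_size
        counts = rec.tip_deflection / px
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)

    def test_uniform_sampling_enforced(self, short_probe, core):
        rec = run_oscillation(core, short_probe, seed=3)
        dt = np.diff(rec.time)
        assert np.allclose(dt, dt[0])
        assert rec.sample_rate == pytest.approx(5.0)

    def test_fixation_failure_raises(self, short_probe):
        from fibermech.samples import plant_preset

        stiff = plant_preset("ca_alginate_fiber")
        with pytest.raises(FixationError):
            run_oscillation(stiff, short_probe, amplitude_strain=0.25,
                            noise_px=0)


class TestDissipation:
    def test_loop_area_positive_for_viscous(self, short_probe, linear_core):
        rec = run_oscillation(linear_core, short_probe, noise_px=0,
                              quantize=False)
        sigma, eps = stress_strain(rec)
        n = int(round(rec.sample_rate / 0.1))
        s, e = sigma[-n - 1:], eps[-n - 1:]
        area = np.trapezoid(s, e)
        assert area > 0.0

    def test_elastic_in_air_dissipates_nothing(self, short_probe,
                                               elastic_plant):
        rec = run_oscillation(elastic_plant, short_probe, medium="air",
                              noise_px=0, quantize=False)
        sigma, eps = stress_strain(rec)
        n = int(round(rec.sample_rate / 0.1))
        area = np.trapezoid(sigma[-n - 1:], eps[-n - 1:])
        scale = np.ptp(sigma) * np.ptp(eps)
        assert abs(area) < 1e-6 * scale


class TestProtocols:
    def test_passive_ramp_monotone(self, short_probe, core):
        rec = run_length_sweep(core, short_probe, noise_px=0)
        # allow quantization plateaus but no decreases
        assert np.all(np.diff(rec.force) >= -1e-12)

    def test_stimulated_sweep_shows_active_bump(self, long_probe, myobundle):
        stim = run_length_sweep(myobundle, long_probe, stimulate=True,
                                noise_px=0)
        passive = run_length_sweep(myobundle, long_probe, stimulate=False,
                                   noise_px=0)
        active = stim.force - passive.force
        s_opt = stim.strain[int(np.argmax(active))]
        assert 0.04 <= s_opt <= 0.06
        assert active.max() > 3e-6

    def test_sweep_respects_stretch_cap(self, short_probe, core):
        with pytest.raises(ValueError):
            run_length_sweep(core, short_probe, max_strain=0.35)

    def test_twitches_resolved_at_one_hertz(self, long_probe, myobundle):
        rec = run_stimulation(myobundle, long_probe, pulse_frequency=1.0,
                              duration=6.0, noise_px=0, sample_rate=20)
        f = rec.force - rec.force.min()
        # distinct twitch peaks: force returns near baseline between pulses
        tail = f[int(2 * 20):]
        assert tail.max() > 4 * np.percentile(tail, 10)

    def test_tetanus_exceeds_twitch(self, long_probe, myobundle):
        r1 = run_stimulation(myobundle, long_probe, pulse_frequency=1.0,
                             duration=6.0, noise_px=0, sample_rate=20)
        r5 = run_stimulation(myobundle, long_probe, pulse_frequency=5.0,
                             duration=6.0, noise_px=0, sample_rate=20)
        plateau = r5.force[-40:]
        assert plateau.min() > r1.force.max()

    def test_dead_sample_is_flat(self, long_probe, myobundle):
        dead = replace(myobundle, active_peak=0.0)
        rec = run_stimulation(dead, long_probe, pulse_frequency=5.0,
                              duration=4.0, noise_px=0)
        assert np.ptp(rec.force[5:]) <= stiffness(long_probe) \
            * long_probe.pixel_size + 1e-12

    def test_stimulation_requires_solution(self, long_probe, myobundle):
        with pytest.raises(ValueError, match="solution"):
            run_stimulation(myobundle, long_probe, medium="air")


class TestPopulations:
    def test_manifest_covers_grid_and_reps(self, short_probe):
        grid = condition_grid("gelma12")
        recs, manifest = generate_population(grid, 2, short_probe, seed=11)
        assert len(manifest) == 24
        # sphere-forming combinations produce no recordings
        assert not manifest[manifest.combination.isin([1, 2, 3, 5, 6])][
            "measurable"
        ].any()
        assert len(recs) == manifest["measurable"].sum()

    def test_same_seed_reproduces_traces(self, short_probe):
        grid = condition_grid("gelma12")[6:8]
        r1, m1 = generate_population(grid, 2, short_probe, seed=5)
        r2, m2 = generate_population(grid, 2, short_probe, seed=5)
        assert m1.equals(m2)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.force, b.force)

    def test_different_seed_differs(self, short_probe):
        grid = condition_grid("gelma12")[6:7]
        r1, _ = generate_population(grid, 1, short_probe, seed=5)
        r2, _ = generate_population(grid, 1, short_probe, seed=6)
        assert not np.array_equal(r1[0].force, r2[0].force)
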