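import math

import numpy as np
import pytest

from thermomorph.config import Normal, SimConfig
from thermomorph.physiology import newton_backbone
from thermomorph.spectra import WAVELENGTH_GRID, process_individual
from thermomorph.synthetic import (
    Individual,
    generate_cohort,
    simulate_gradient_track,
    simulate_heatup_trace,
    simulate_reflectance,
    time_grid,
)

from conftest import make_individual


class TestGenerateCohort:
    def test_study_counts_give_432(self):
        cohort = generate_cohort(SimConfig())
        assert len(cohort) == 432

    def test_empty_config_gives_empty_cohort(self):
        cfg = SimConfig()
        cfg.counts = {}
        cohort = generate_cohort(cfg)
        assert len(cohort) == 0
        assert cohort.traces == {}

    def test_determinism_bit_identical(self, tiny_counts):
        cfg = SimConfig()
        cfg.counts = tiny_counts
        cfg.seed = 9
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert [i.id for i in a.individuals] == [i.id for i in b.individuals]
        for key in a.traces:
            np.testing.assert_array_equal(
                a.traces[key].temperatures_c, b.traces[key].temperatures_c
            )
        for ind_id in a.tracks:
            np.testing.assert_array_equal(
                a.tracks[ind_id].positions_cm, b.tracks[ind_id].positions_cm
            )
        for ind_id in a.spectra:
            for sa, sb in zip(a.spectra[ind_id], b.spectra[ind_id]):
                np.testing.assert_array_equal(sa.reflectance_pct, sb.reflectance_pct)

    def test_count_conservation_per_group(self, tiny_counts):
        cfg = SimConfig()
        cfg.counts = tiny_counts
        cohort = generate_cohort(cfg)
        for sp, sex, morph, n in cfg.iter_groups():
            got = sum(
                1
                for i in cohort.individuals
                if (i.species, i.sex, i.morph) == (sp, sex, morph)
            )
            assert got == n

    def test_every_individual_fully_equipped(self, tiny_counts):
        cfg = SimConfig()
        cfg.counts = tiny_counts
        cohort = generate_cohort(cfg)
        for ind in cohort.individuals:
            assert (ind.id, "internal") in cohort.traces
            assert (ind.id, "external") in cohort.traces
            assert ind.id in cohort.tracks
            assert len(cohort.spectra[ind.id]) == 10
            parts = {s.body_part for s in cohort.spectra[ind.id]}
            assert len(parts) == 2
            assert cohort.tracks[ind.id].runway_id in cohort.calibrations

    def test_adding_individuals_does_not_perturb_existing(self, tiny_counts):
        cfg1 = SimConfig()
        cfg1.counts = {"ungarica": {"F": {"green": 2}}}
        cfg2 = SimConfig()
        cfg2.counts = {"ungarica": {"F": {"green": 4, "brown": 2}}}
        a = generate_cohort(cfg1)
        b = generate_cohort(cfg2)
        for ind in a.individuals:
            np.testing.assert_array_equal(
                a.traces[(ind.id, "internal")].temperatures_c,
                b.traces[(ind.id, "internal")].temperatures_c,
            )

    def test_null_morph_groups_share_parameters(self):
        cfg = SimConfig()
        for sp, by_sex in cfg.brightness.items():
            for sex, by_morph in by_sex.items():
                assert len({v for v in by_morph.values()}) == 1
        assert set(cfg.morph_k_scale.values()) == {1.0}
        assert set(cfg.morph_teq_offset_c.values()) == {0.0}


class TestIndividual:
    def test_invalid_morph_rejected(self):
        with pytest.raises(ValueError):
            Individual(id="x", species="sibiricus", sex="F",
                       morph="dorsal-green", mass_g=0.2)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            Individual(id="x", species="ungarica", sex="F", morph="green", mass_g=0.0)


class TestHeatupTrace:
    def test_closed_form_endpoints(self, clean_sim):
        ind = make_individual(mass_g=clean_sim.m_ref_g)
        clean_sim.k0_per_s = 0.01
        trace = simulate_heatup_trace(ind, clean_sim)
        assert trace.temperatures_c[0] == pytest.approx(5.0)
        # t -> infinity limit: late samples close to T_eq = 40
        assert trace.temperatures_c[-1] == pytest.approx(40.0, abs=0.05)

    def test_closed_form_at_100s(self, clean_sim):
        # T(100) = 40 - 35 e^-1, evaluated independently
        clean_sim.k0_per_s = 0.01
        ind = make_individual(mass_g=clean_sim.m_ref_g)
        trace = simulate_heatup_trace(ind, clean_sim)
        idx = np.nonzero(trace.times_s == 100.0)[0][0]
        expected = 40.0 - 35.0 * math.exp(-1.0)
        assert trace.temperatures_c[idx] == pytest.approx(expected, rel=1e-10)

    def test_heavier_individual_cooler_everywhere(self, clean_sim):
        light = make_individual(mass_g=0.1, ident="light")
        heavy = make_individual(mass_g=0.4, ident="heavy")
        tl = simulate_heatup_trace(light, clean_sim)
        th = simulate_heatup_trace(heavy, clean_sim)
        assert np.all(th.temperatures_c[1:] < tl.temperatures_c[1:])
        assert th.temperatures_c[0] == tl.temperatures_c[0]

    def test_trace_lengths(self, clean_sim):
        ind = make_individual()
        internal = simulate_heatup_trace(ind, clean_sim, channel="internal")
        external = simulate_heatup_trace(ind, clean_sim, channel="external")
        assert len(internal) == 159
        assert len(external) == 40

    def test_dip_replaces_first_20s(self, clean_sim):
        clean_sim.dip_prob = 1.0
        ind = make_individual(mass_g=clean_sim.m_ref_g)
        trace = simulate_heatup_trace(ind, clean_sim)
        pre = trace.times_s < 20.0
        # declining segment from T0 + dip_depth
        assert trace.temperatures_c[0] == pytest.approx(
            5.0 + clean_sim.dip_depth_c
        )
        assert np.all(np.diff(trace.temperatures_c[pre]) < 0)
        # samples from 20 s onwards follow the backbone
        k = clean_sim.k0_per_s
        backbone = newton_backbone(trace.times_s[~pre], 5.0, 40.0, k)
        np.testing.assert_allclose(trace.temperatures_c[~pre], backbone)

    def test_dip_absent_on_external_channel(self, clean_sim):
        clean_sim.dip_prob = 1.0
        ind = make_individual(mass_g=clean_sim.m_ref_g)
        trace = simulate_heatup_trace(ind, clean_sim, channel="external")
        assert np.all(np.diff(trace.temperatures_c) > 0)

    def test_backbone_strictly_increasing_without_dip(self, clean_sim):
        trace = simulate_heatup_trace(make_individual(), clean_sim)
        assert np.all(np.diff(trace.temperatures_c) > 0)

    def test_bad_k0_rejected(self, clean_sim):
        clean_sim.k0_per_s = -1.0
        with pytest.raises(ValueError):
            simulate_heatup_trace(make_individual(), clean_sim)


class TestGradientTrackSim:
    def _calibration(self, cfg):
        from thermomorph.gradient import fit_calibration

        pos = np.asarray(cfg.calibration_positions_cm)
        return fit_calibration(pos, 10.0 + 0.5 * pos, runway_id="runway-1")

    def test_fixed_point_when_noise_free(self):
        cfg = SimConfig()
        cfg.position_noise_cm = 0.0
        cfg.missing_prob = 0.0
        cal = self._calibration(cfg)
        # preferred temperature equals calibrated temperature at 60 cm
        track = simulate_gradient_track(
            make_individual(), cal, cfg, preferred_c=10.0 + 0.5 * 60.0
        )
        np.testing.assert_allclose(track.positions_cm, 60.0)

    def test_all_missing_at_prob_one(self):
        cfg = SimConfig()
        cfg.missing_prob = 1.0
        cal = self._calibration(cfg)
        track = simulate_gradient_track(make_individual(), cal, cfg, preferred_c=30.0)
        assert np.all(np.isnan(track.positions_cm))

    def test_missing_fraction_matches_probability(self):
        # ~10000 sightings; empirical missing fraction within 3 binomial SEs
        cfg = SimConfig()
        cfg.missing_prob = 0.016
        cal = self._calibration(cfg)
        rng = np.random.default_rng(123)
        n_total = n_missing = 0
        for i in range(1700):
            track = simulate_gradient_track(
                make_individual(ident=f"i{i}"), cal, cfg, rng=rng, preferred_c=30.0
            )
            n_total += track.positions_cm.size
            n_missing += int(np.isnan(track.positions_cm).sum())
        se = math.sqrt(0.016 * (1 - 0.016) / n_total)
        assert abs(n_missing / n_total - 0.016) < 3 * se

    def test_out_of_range_preference_clamped_and_flagged(self):
        cfg = SimConfig()
        cfg.position_noise_cm = 0.0
        cfg.missing_prob = 0.0
        cal = self._calibration(cfg)
        track = simulate_gradient_track(make_individual(), cal, cfg, preferred_c=90.0)
        assert "preference_clamped" in track.flags
        np.testing.assert_allclose(track.positions_cm, 80.0)

    def test_positions_clamped_to_runway(self):
        cfg = SimConfig()
        cfg.position_noise_cm = 30.0
        cal = self._calibration(cfg)
        rng = np.random.default_rng(5)
        for i in range(20):
            track = simulate_gradient_track(
                make_individual(ident=f"c{i}"), cal, cfg, rng=rng, preferred_c=50.0
            )
            present = track.positions_cm[~np.isnan(track.positions_cm)]
            assert np.all((present >= 0.0) & (present <= 80.0))


class TestReflectanceSim:
    def test_deterministic_flat_case(self):
        cfg = SimConfig()
        cfg.jitter_sd = 0.0
        cfg.spike_magnitude_pct = 0.0
        cfg.body_part_delta = 0.0
        ind = make_individual(morph="brown")
        specs = simulate_reflectance(ind, cfg, brightness_target_pct=10.0)
        assert len(specs) == 10
        _, summary = process_individual(specs)
        # artefact correction shifts 4 of 701 samples of the sloped base
        # shape by a sub-nm offset: bias is bounded by ~1e-4 %
        assert summary.brightness_pct == pytest.approx(10.0, abs=1e-3)

    def test_spike_exceeds_flanks(self):
        cfg = SimConfig()
        cfg.jitter_sd = 0.0
        cfg.spike_magnitude_pct = 15.0
        specs = simulate_reflectance(
            make_individual(), cfg, brightness_target_pct=10.0
        )
        spec = specs[0].reflectance_pct
        band = (WAVELENGTH_GRID >= 655) & (WAVELENGTH_GRID <= 658)
        left = (WAVELENGTH_GRID >= 650) & (WAVELENGTH_GRID <= 654)
        right = (WAVELENGTH_GRID >= 659) & (WAVELENGTH_GRID <= 664)
        assert spec[band].min() > spec[left].max()
        assert spec[band].min() > spec[right].max()

    def test_green_morph_peaks_near_550(self):
        cfg = SimConfig()
        cfg.jitter_sd = 0.0
        cfg.spike_magnitude_pct = 0.0
        specs = simulate_reflectance(
            make_individual(morph="green"), cfg, brightness_target_pct=15.0
        )
        spec = specs[0].reflectance_pct
        peak_wl = WAVELENGTH_GRID[np.argmax(spec[WAVELENGTH_GRID < 700])]
        assert 500 <= peak_wl <= 600

    def test_monte_carlo_brightness_hits_target(self):
        # processed brightness across many individuals centred on the target
        cfg = SimConfig()
        ind_template = dict(species="parallelus", sex="F", morph="green")
        rng = np.random.default_rng(77)
        target = 13.2
        values = []
        for i in range(400):
            ind = make_individual(**ind_template, ident=f"mc{i}")
            specs = simulate_reflectance(
                ind, cfg, rng=rng,
                brightness_target_pct=target + 2.7 * rng.standard_normal(),
            )
            _, summary = process_individual(specs)
            values.append(summary.brightness_pct)
        values = np.asarray(values)
        se = values.std(ddof=1) / math.sqrt(values.size)
        assert abs(values.mean() - target) < 3 * se


def test_time_grid_floors_duration():
    grid = time_grid(792.0, 5.0)
    assert grid[0] == 0.0
    assert grid[-1] == 790.0
    assert grid.size == 159
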