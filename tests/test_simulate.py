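"""Synthetic cohort generators: determinism, spectral content, coverage,
and end-to-end recovery of the planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from ieegnorm import (SimulationConfig, ValidationError, band_power,
                      build_normative_map, canonical_bands,
                      simulate_normative_cohort, simulate_normative_tables,
                      simulate_patient, simulate_patient_cohort_tables,
                      simulate_patient_tables, welch_psd)
from ieegnorm.simulate import (expected_relative_band_power,
                               make_parcellation, make_region_profiles,
                               simulate_channel)


def small_cfg(**kw):
    defaults = dict(seed=11, n_regions=10, n_normative=12, n_patients=3,
                    n_abnormal=2, n_resected=2, duration=20.0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestChannelSynthesis:
    def test_same_seed_bit_identical(self):
        cfg = small_cfg()
        amps = make_region_profiles(cfg).iloc[0]
        a = simulate_channel(amps, cfg, np.random.default_rng(5))
        b = simulate_channel(amps, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_different_seed_different_output(self):
        cfg = small_cfg()
        amps = make_region_profiles(cfg).iloc[0]
        a = simulate_channel(amps, cfg, np.random.default_rng(5))
        b = simulate_channel(amps, cfg, np.random.default_rng(6))
        assert not np.array_equal(a, b)

    def test_pure_alpha_profile_dominates_alpha_band(self):
        cfg = small_cfg(background_scale=1e-6)
        amps = pd.Series(0.0, index=[b.name for b in canonical_bands()])
        amps["alpha"] = 10.0
        x = simulate_channel(amps, cfg, np.random.default_rng(0))
        psd = welch_psd(x, cfg.fs)
        powers = {b.name: band_power(psd, b) for b in canonical_bands()}
        assert all(powers["alpha"] > v
                   for k, v in powers.items() if k != "alpha")

    def test_zero_profile_and_background_is_silent(self):
        cfg = small_cfg(background_scale=0.0)
        amps = pd.Series(0.0, index=[b.name for b in canonical_bands()])
        x = simulate_channel(amps, cfg, np.random.default_rng(0))
        assert np.allclose(x, 0.0)

    def test_background_psd_matches_target_slope(self):
        """Shaped noise reproduces scale * f^-chi in expectation."""
        cfg = small_cfg(duration=60.0, background_exponent=1.0,
                        background_scale=10.0)
        amps = pd.Series(0.0, index=[b.name for b in canonical_bands()])
        rng = np.random.default_rng(1)
        dens = np.mean([welch_psd(simulate_channel(amps, cfg, rng),
                                  cfg.fs).density for _ in range(30)], axis=0)
        freqs = welch_psd(np.zeros(int(cfg.duration * cfg.fs)), cfg.fs).freqs
        sel = (freqs >= 5) & (freqs <= 50)
        np.testing.assert_allclose(dens[sel], 10.0 / freqs[sel], rtol=0.25)


class TestCohortGeneration:
    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SimulationConfig(coverage=0.0)
        with pytest.raises(ValidationError):
            SimulationConfig(effect_size=-1)
        with pytest.raises(ValidationError):
            SimulationConfig(n_regions=5, n_abnormal=3, n_resected=3)

    def test_coverage_probability_matches_binomial_expectation(self):
        cfg = small_cfg(n_normative=60, coverage=0.5, n_regions=20)
        tables = simulate_normative_tables(cfg)
        per_region = sum((t.coverage >= 1).astype(int) for t in tables)
        expected = 0.5 * 60
        sd = np.sqrt(60 * 0.25)
        assert np.all(np.abs(per_region - expected) < 4.5 * sd)

    def test_full_coverage(self):
        cfg = small_cfg(coverage=1.0)
        tables = simulate_normative_tables(cfg)
        assert all((t.coverage >= 1).all() for t in tables)

    def test_generators_deterministic_given_seed(self):
        cfg = small_cfg()
        a = simulate_normative_tables(cfg)
        b = simulate_normative_tables(cfg)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta.values, tb.values)

    def test_patient_truth_record_consistency(self):
        cfg = small_cfg()
        rng = cfg.rng()
        pat = simulate_patient_tables(cfg, "poor", rng)
        truth = pat.truth
        assert len(truth["planted_regions"]) == cfg.n_abnormal
        assert len(truth["resected_regions"]) == cfg.n_resected
        # poor outcome: surgery misses every planted region
        assert not set(truth["planted_regions"]) & set(truth["resected_regions"])
        flagged = set(pat.tables.resected.index[pat.tables.resected])
        assert flagged == set(truth["resected_regions"])

    def test_good_outcome_resection_covers_planted(self):
        cfg = small_cfg()
        pat = simulate_patient_tables(cfg, "good", cfg.rng())
        assert set(pat.truth["planted_regions"]) <= \
            set(pat.truth["resected_regions"])


class TestEndToEndRecovery:
    def test_signal_cohort_recovers_band_dominance(self):
        """Normative map from the full signal pipeline rank-correlates
        with the generating profiles' relative band power per band."""
        from ieegnorm.config import PipelineConfig
        from ieegnorm.pipeline import participant_region_tables

        cfg = SimulationConfig(seed=3, n_regions=10, n_normative=25,
                               n_abnormal=2, n_resected=2,
                               coverage=0.8, duration=70.0)
        pcfg = PipelineConfig()
        parc = make_parcellation(cfg)
        cohort = [
            participant_region_tables(p.recording, p.channels, parc,
                                      "normative", pcfg, p.participant_id)
            for p in simulate_normative_cohort(cfg)
        ]
        nmap = build_normative_map(cohort, min_participants=5)
        truth = expected_relative_band_power(make_region_profiles(cfg), cfg)
        for band in truth.columns:
            rho = spearmanr(nmap.mu[band], truth[band]).statistic
            assert rho > 0.8, f"{band}: rank correlation {rho:.2f}"

    def test_signal_patients_produce_directional_drs(self):
        """Resecting the planted regions pushes DRS below 0.5; sparing
        them pushes it above, in >=95% of seeded repeats."""
        from ieegnorm.config import PipelineConfig
        from ieegnorm.pipeline import (build_map_from_cohort,
                                       participant_region_tables,
                                       profile_drs, score_patient)

        cfg = SimulationConfig(seed=21, effect_size=5.0)
        pcfg = PipelineConfig(min_participants=5)
        parc = make_parcellation(cfg)
        cohort = [
            participant_region_tables(p.recording, p.channels, parc,
                                      "normative", pcfg, p.participant_id)
            for p in simulate_normative_cohort(cfg)
        ]
        nmap = build_map_from_cohort(cohort, pcfg)
        rng = cfg.rng()
        reps = 20
        correct = {"good": 0, "poor": 0}
        for outcome in correct:
            for i in range(reps):
                pat = simulate_patient(cfg, outcome, rng, f"{outcome}{i}")
                prof = score_patient(pat.recording, pat.channels, parc,
                                     pat.mask, nmap, pcfg, pat.patient_id)
                d = profile_drs(prof).drs
                correct[outcome] += (d < 0.5) if outcome == "good" else (d > 0.5)
        assert correct["good"] + correct["poor"] >= 0.95 * 2 * reps

    def test_null_effect_size_gives_chance_level_drs(self):
        """Effect size 0 leaves nothing to distinguish: mean DRS within
        0.5 +/- 0.05 over 100 fast-path patients."""
        from ieegnorm.abnormality import abnormality_profile
        from ieegnorm.pipeline import profile_drs

        cfg = SimulationConfig(seed=17, effect_size=0.0, n_normative=100,
                               n_patients=50, coverage=1.0)
        rng = cfg.rng()
        nmap = build_normative_map(simulate_normative_tables(cfg, rng))
        ds = []
        for pat in simulate_patient_cohort_tables(cfg, rng):
            prof = abnormality_profile(pat.tables, nmap)
            ds.append(profile_drs(prof).drs)
        assert np.mean(ds) == pytest.approx(0.5, abs=0.05)
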