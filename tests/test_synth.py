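"""Synthetic walking-psychophysics generator: ground truth and contracts."""

import numpy as np
import pytest
from scipy.stats import chisquare

from stridecycle.gait import detect_troughs, detrend_height
from stridecycle.synth import (CohortSpec, ParticipantSpec, SessionConfig,
                               draw_participant_spec, file_checksum,
                               generate_cohort, hit_probability,
                               observer_hit_probability, read_ground_truth,
                               schedule_targets, simulate_head_trace,
                               simulate_outcomes)

from conftest import deterministic_spec


class TestHeadTrace:
    def test_fixed_step_duration_gives_15_troughs_in_9s(self, session_config,
                                                        det_spec, rng):
        sim = simulate_head_trace(det_spec, session_config, rng,
                                  initial_step_fraction=1.0)
        assert sim.true_troughs.size == 15
        np.testing.assert_allclose(np.diff(sim.true_troughs), 0.59,
                                   atol=1e-9)

    def test_detected_stride_durations_average_to_configured(self,
                                                             session_config):
        """Over 140 trials, detected mean stride duration is within 0.02 s
        of the configured 1.18 s."""
        rng = np.random.default_rng(21)
        spec = ParticipantSpec("P00", stride_duration_mean=1.18,
                               stride_duration_sd=0.069)
        durations = []
        for _ in range(140):
            sim = simulate_head_trace(spec, session_config, rng)
            trace = detrend_height(sim.trace)
            tt = trace.t[detect_troughs(trace)]
            durations.extend((tt[2:] - tt[:-2])[::2].tolist())
        assert abs(np.mean(durations) - 1.18) < 0.02

    def test_ground_truth_phase_matches_loop_oracle(self, session_config,
                                                    rng):
        from oracle_utils import tiled_stride_phase
        spec = deterministic_spec(stride_duration_sd=0.05)
        sim = simulate_head_trace(spec, session_config, rng)
        t = sim.trace.t
        expected = tiled_stride_phase(t, sim.true_troughs)
        got = sim.true_phase(t)
        np.testing.assert_allclose(got, expected, atol=1e-9, equal_nan=True)

    def test_invalid_config_rejected(self, det_spec, rng):
        bad = SessionConfig(target_anchors=tuple(np.linspace(0.6, 8.4, 9)))
        with pytest.raises(ValueError):
            simulate_head_trace(det_spec, bad, rng)

    def test_noise_free_troughs_match_detector_within_one_sample(
            self, session_config, rng):
        spec = deterministic_spec(stride_duration_sd=0.04)
        sim = simulate_head_trace(spec, session_config, rng,
                                  gait_onset_delay=0.5)
        trace = detrend_height(sim.trace)
        det = trace.t[detect_troughs(trace)]
        for tt in sim.true_troughs:
            assert np.min(np.abs(det - tt)) <= 1 / 90 + 1e-9


class TestSchedule:
    def test_full_withholding_gives_empty_trials(self, rng):
        cfg = SessionConfig(withhold_probability=1.0)
        for _ in range(50):
            assert schedule_targets(cfg, rng).size == 0

    def test_mean_onsets_per_trial_matches_design(self, session_config):
        """8 anchors with 10% withholding: expectation 7.2 onsets/trial."""
        rng = np.random.default_rng(2)
        n = np.array([schedule_targets(session_config, rng).size
                      for _ in range(20000)])
        assert abs(n.mean() - 7.2) < 0.02

    def test_minimum_gap_respected(self, session_config):
        rng = np.random.default_rng(4)
        min_gap = np.inf
        for _ in range(5000):
            on = schedule_targets(session_config, rng)
            if on.size >= 2:
                gaps = on[None, :] - on[:, None]
                min_gap = min(min_gap, np.abs(
                    gaps[~np.eye(on.size, dtype=bool)]).min())
        assert min_gap >= session_config.min_iti

    def test_onsets_inside_trial(self, session_config):
        rng = np.random.default_rng(6)
        for _ in range(2000):
            on = schedule_targets(session_config, rng)
            assert np.all(on > 0)
            assert np.all(on < session_config.trial_duration
                          - session_config.target_duration)

    def test_targets_per_participant_in_emulation_band(self, session_config):
        rng = np.random.default_rng(8)
        total = sum(schedule_targets(session_config, rng).size
                    for _ in range(140))
        assert 700 <= total <= 1050


class TestOutcomes:
    def test_unmodulated_hit_rate_within_binomial_ci(self, rng):
        spec = ParticipantSpec("P00", osc_amplitude_acc=0.0)
        phases = rng.uniform(0, 100, 20000)
        hit, _ = simulate_outcomes(np.arange(20000.0), spec, phases, rng)
        se = np.sqrt(0.75 * 0.25 / 20000)
        assert abs(hit.mean() - 0.75) < 2.58 * se

    def test_binned_hit_rate_matches_generating_cosine(self):
        rng = np.random.default_rng(42)
        spec = ParticipantSpec("P00")
        phases = rng.uniform(0, 100, 10000)
        hit, _ = simulate_outcomes(np.arange(10000.0), spec, phases, rng)
        from stridecycle.projection import bin_series
        s = bin_series(phases, hit.astype(float), 40, "mean")
        p_bin = hit_probability(s.bin_centers, spec)
        se = np.sqrt(p_bin * (1 - p_bin) / s.counts)
        assert (np.abs(s.values - p_bin) <= 1.96 * se).sum() >= 36

    def test_phase_shift_symmetry(self):
        """Shifting the injected phase by pi shifts the fitted phase by pi."""
        from stridecycle.oscillation import fit_fixed_frequency
        from stridecycle.projection import bin_series
        fits = []
        for phi in (-1.0, -1.0 + np.pi):
            rng = np.random.default_rng(10)
            spec = ParticipantSpec("P00", osc_phase=phi)
            phases = rng.uniform(0, 100, 30000)
            hit, _ = simulate_outcomes(np.arange(30000.0), spec, phases, rng)
            fits.append(fit_fixed_frequency(
                bin_series(phases, hit.astype(float), 40), 2.0).phi)
        dphi = np.angle(np.exp(1j * (fits[1] - fits[0])))
        assert abs(abs(dphi) - np.pi) < 0.2

    def test_rt_floor_and_response_pairing(self, rng):
        spec = ParticipantSpec("P00", base_rt=0.2, osc_amplitude_rt=0.04,
                               rt_noise_sd=0.2)
        phases = rng.uniform(0, 100, 5000)
        hit, rt = simulate_outcomes(np.arange(5000.0), spec, phases, rng)
        assert np.all(rt[hit == 1] >= 0.15)
        assert np.isnan(rt[hit == 0]).all()


class TestObserver:
    def test_ceiling_probability(self):
        spec = ParticipantSpec("P00", observer_width=1e-9)
        assert observer_hit_probability(1.0, spec) == pytest.approx(0.99)

    def test_probability_at_threshold(self):
        spec = ParticipantSpec("P00")
        assert observer_hit_probability(spec.observer_threshold, spec) == \
            pytest.approx(0.745)

    def test_out_of_range_intensity_rejected(self):
        with pytest.raises(ValueError):
            observer_hit_probability(0.2, ParticipantSpec("P00"))

    def test_monte_carlo_matches_closed_form(self, rng):
        spec = ParticipantSpec("P00")
        p = observer_hit_probability(0.45, spec)
        n = 100_000
        draws = rng.random(n) < p
        se = np.sqrt(p * (1 - p) / n)
        assert abs(draws.mean() - p) < 3 * se


class TestCohort:
    def _small(self, tmp_path, seed, name):
        cfg = SessionConfig(n_participants=2, n_walking_trials=4,
                            n_stationary_trials=1)
        return generate_cohort(cfg, CohortSpec(), tmp_path / name,
                               seed=seed, with_staircase=False)

    def test_same_seed_is_byte_identical(self, tmp_path):
        p1 = self._small(tmp_path, 7, "a")
        p2 = self._small(tmp_path, 7, "b")
        for attr in ("frames", "targets", "responses", "ground_truth",
                     "true_troughs"):
            assert file_checksum(getattr(p1, attr)) == \
                file_checksum(getattr(p2, attr))

    def test_different_seed_differs(self, tmp_path):
        p1 = self._small(tmp_path, 7, "a")
        p2 = self._small(tmp_path, 8, "b")
        assert file_checksum(p1.targets) != file_checksum(p2.targets)

    def test_ground_truth_roundtrip(self, tmp_path):
        paths = self._small(tmp_path, 3, "rt")
        specs = read_ground_truth(paths.ground_truth)
        assert len(specs) == 2
        rng = np.random.default_rng(np.random.SeedSequence(3).spawn(2)[0])
        expected = draw_participant_spec(CohortSpec(), "P00", rng)
        assert specs[0] == expected

    def test_pooled_target_phase_distribution_uniform(self, session_config):
        """Target phases over ground-truth strides are uniform when pooled
        over a cohort (chi-square GOF at n=1e4)."""
        rng = np.random.default_rng(42)
        cohort = CohortSpec()
        phases = []
        for i in range(8):
            spec = draw_participant_spec(cohort, f"P{i:02d}", rng)
            while_count = 0
            while while_count < 1500:
                sim = simulate_head_trace(spec, session_config, rng)
                on = schedule_targets(session_config, rng)
                ph = sim.true_phase(on)
                phases.extend(ph[~np.isnan(ph)].tolist())
                while_count += len(on)
        counts, _ = np.histogram(np.asarray(phases)[:10000], bins=20,
                                 range=(0, 100))
        assert chisquare(counts).pvalue > 0.01
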