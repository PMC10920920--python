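"""Fixed-frequency Fourier fitting, sweeps, and permutation testing."""

import numpy as np
import pytest
from scipy.stats import chisquare

from stridecycle.oscillation import (FREQ_GRID, ParticipantEvents,
                                     PermutationNull, SweepResult,
                                     classify_band, cohort_summary,
                                     fit_fixed_frequency, group_series,
                                     participant_test, permutation_null,
                                     r2_matrix, significant_ranges,
                                     stride_duration_correlation, sweep)
from stridecycle.projection import bin_centers, bin_series

X40 = bin_centers(40) / 100.0


def cosine_series(w, amp=1.0, phi=0.0, a0=0.0, n_bins=40):
    x = bin_centers(n_bins) / 100.0
    return x, a0 + amp * np.cos(2 * np.pi * w * x + phi)


class TestFixedFrequencyFit:
    def test_exact_cosine_recovered(self):
        x, y = cosine_series(2.0)
        f = fit_fixed_frequency((x, y), 2.0)
        assert abs(f.a1 - 1) < 1e-10 and abs(f.b1) < 1e-10
        assert abs(f.a0) < 1e-10 and abs(f.r2 - 1) < 1e-10

    def test_constant_series_degenerate_r2(self):
        f = fit_fixed_frequency((X40, np.full(40, 0.75)), 2.0)
        assert f.amplitude < 1e-10 and f.r2 == 0.0

    def test_amplitude_phase_identity(self, rng):
        """A^2 = a1^2 + b1^2 and the phase-form reconstruction hold
        pointwise for random fits."""
        for _ in range(20):
            y = rng.normal(0.5, 0.2, 40)
            w = float(rng.choice(FREQ_GRID))
            f = fit_fixed_frequency((X40, y), w)
            assert abs(f.amplitude**2 - (f.a1**2 + f.b1**2)) < 1e-10
            lhs = (f.a1 * np.cos(2 * np.pi * w * X40)
                   + f.b1 * np.sin(2 * np.pi * w * X40))
            rhs = f.amplitude * np.cos(2 * np.pi * w * X40 + f.phi)
            np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_matches_brute_force_grid_search(self, rng):
        """Closed-form OLS equals an independent (a0, A, phi) grid search on
        noisy cosines."""
        from oracle_utils import brute_force_cosine_fit
        for _ in range(10):
            w = float(rng.choice([1.0, 2.0, 3.4]))
            amp = rng.uniform(0.05, 0.3)
            phi = rng.uniform(-np.pi, np.pi)
            y = (0.5 + amp * np.cos(2 * np.pi * w * X40 + phi)
                 + rng.normal(0, 0.05, 40))
            f = fit_fixed_frequency((X40, y), w)
            a0_b, A_b, phi_b, sse_b = brute_force_cosine_fit(X40, y, w)
            sse_f = np.sum((y - f.predict(X40)) ** 2)
            assert sse_f <= sse_b + 1e-9
            assert abs(f.a0 - a0_b) < 5e-3
            assert abs(f.amplitude - A_b) < 5e-3
            assert abs(np.angle(np.exp(1j * (f.phi - phi_b)))) < 0.05

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            fit_fixed_frequency((X40, np.ones(40)), 0.0)


class TestSweep:
    def test_recovers_injected_frequency(self):
        hits = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ph = rng.uniform(0, 100, 900)
            p = 0.75 + 0.12 * np.cos(2 * np.pi * 2 * ph / 100 - 1.0)
            y = (rng.random(900) < p).astype(float)
            sr = sweep(bin_series(ph, y, 40))
            hits.append(abs(sr.best_freq - 2.0) <= 0.2 + 1e-9)
        assert sum(hits) >= 9

    def test_white_noise_best_freq_near_uniform_over_grid(self):
        """Under white noise the argmax frequency is close to uniform over
        the interior of the grid.  The extremes are structurally special:
        sub-cycle frequencies (< 0.8 cps over one stride) are nearly
        collinear with the intercept and rarely win, and the top grid
        frequency absorbs the high tail - which is exactly why inference
        uses the max-statistic null rather than argmax symmetry."""
        rng = np.random.default_rng(0)
        Y = rng.normal(0, 1, size=(1000, 40))
        r2 = r2_matrix(Y, X40)
        counts = np.bincount(np.argmax(r2, axis=1), minlength=50)
        interior = counts[4:49]
        assert chisquare(interior).pvalue > 0.01

    def test_r2_monotone_in_injected_amplitude(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.05, 40)
        r2s = []
        for amp in (0.0, 0.05, 0.1, 0.15):
            y = 0.75 + amp * np.cos(2 * np.pi * 2 * X40 - 1.0) + noise
            r2s.append(fit_fixed_frequency((X40, y), 2.0).r2)
        assert np.all(np.diff(r2s) >= 0)

    def test_vectorized_r2_agrees_with_scalar_path(self, rng):
        Y = rng.normal(0.5, 0.1, size=(5, 40))
        mat = r2_matrix(Y, X40)
        for i in range(5):
            for j in (0, 9, 19, 49):
                f = fit_fixed_frequency((X40, Y[i]), FREQ_GRID[j])
                assert abs(mat[i, j] - f.r2) < 1e-10


def make_null_participants(rng, n_participants=6, n_events=400):
    parts = []
    for _ in range(n_participants):
        ph = rng.uniform(0, 100, n_events)
        y = (rng.random(n_events) < 0.75).astype(float)
        parts.append(ParticipantEvents(ph, y))
    return parts


class TestPermutationNull:
    def test_shuffle_conserves_outcome_multiset(self, rng):
        from stridecycle.oscillation import _binned_matrix_null
        ph = rng.uniform(0, 100, 300)
        y = rng.normal(0.5, 0.2, 300)
        part = ParticipantEvents(ph, y)
        mat, counts = _binned_matrix_null(part, 40, "mean", 50, rng)
        # per-permutation sum over bins of mean*count equals the total sum
        sums = np.nansum(mat * counts, axis=1)
        np.testing.assert_allclose(sums, y.sum(), atol=1e-8)

    def test_crit95_stable_across_seeds(self, rng):
        parts = make_null_participants(rng)
        n1 = permutation_null(parts, 40, "mean", 1000, np.random.default_rng(1))
        n2 = permutation_null(parts, 40, "mean", 1000, np.random.default_rng(2))
        assert abs(n1.crit95 - n2.crit95) < 0.05

    def test_low_n_perm_warns(self, rng):
        parts = make_null_participants(rng, 2, 100)
        with pytest.warns(UserWarning):
            permutation_null(parts, 40, "mean", 50, rng)

    def test_injected_signal_detected_against_null(self):
        rng = np.random.default_rng(5)
        parts = []
        for _ in range(6):
            ph = rng.uniform(0, 100, 900)
            p = 0.75 + 0.12 * np.cos(2 * np.pi * 2 * ph / 100 - 1.0)
            parts.append(ParticipantEvents(
                ph, (rng.random(900) < p).astype(float)))
        gs = group_series(parts, 40)
        obs = sweep(gs)
        null = permutation_null(parts, 40, "mean", 300,
                                np.random.default_rng(0))
        assert np.nanmax(obs.r2_by_freq) > null.crit95
        ranges = significant_ranges(obs, null)
        assert any(lo <= 2.0 <= hi for lo, hi in ranges)


class TestSignificantRanges:
    def test_exact_tie_excluded(self):
        grid = FREQ_GRID
        r2 = np.zeros(50)
        r2[9] = 0.5
        sr = SweepResult(grid, r2, grid[9],
                         fit_fixed_frequency((X40, np.cos(2 * np.pi * 2 * X40)),
                                             2.0))
        null = PermutationNull(n_perm=1, grid=grid,
                               null_r2=np.full((1, 50), 0.5),
                               maxstat=np.array([0.5]), crit95=0.5)
        assert significant_ranges(sr, null) == []

    def test_contiguous_runs_reported(self):
        grid = FREQ_GRID
        r2 = np.zeros(50)
        r2[[8, 9, 10, 30]] = 0.9
        sr = SweepResult(grid, r2, grid[8],
                         fit_fixed_frequency((X40, np.cos(2 * np.pi * X40)),
                                             1.0))
        null = PermutationNull(n_perm=1, grid=grid,
                               null_r2=np.full((1, 50), 0.1),
                               maxstat=np.array([0.1]), crit95=0.1)
        assert significant_ranges(sr, null) == [
            (pytest.approx(1.8), pytest.approx(2.2)),
            (pytest.approx(6.2), pytest.approx(6.2)),
        ]


class TestParticipantLevel:
    def test_huge_amplitude_always_significant(self, rng):
        ph = rng.uniform(0, 100, 900)
        p = 0.5 + 0.5 * np.cos(2 * np.pi * 2 * ph / 100)
        ev = ParticipantEvents(ph, (rng.random(900) < p).astype(float))
        ps = sweep(bin_series(ev.phase_pct, ev.values, 40))
        null = permutation_null([ev], 40, "mean", 200, rng,
                                level="participant")
        res = participant_test("P00", "accuracy", ps, null)
        assert res.significant and res.band == "two_cps"

    def test_band_classification(self):
        assert classify_band(2.0, True) == "two_cps"
        assert classify_band(4.2, True) == "four_cps"
        assert classify_band(7.0, True) == "high"
        assert classify_band(3.0, True) == "none"
        assert classify_band(2.0, False) == "none"

    def test_cohort_summary_counts_ground_truth(self):
        from stridecycle.oscillation import ParticipantResult as PR
        res = {
            "accuracy": [PR("a", "accuracy", 2.0, 0.9, True, "two_cps"),
                         PR("b", "accuracy", 4.0, 0.8, True, "four_cps"),
                         PR("c", "accuracy", 1.0, 0.1, False, "none")],
            "rt": [PR("a", "rt", 2.0, 0.9, True, "two_cps"),
                   PR("b", "rt", 2.2, 0.7, True, "two_cps"),
                   PR("c", "rt", 6.0, 0.1, False, "none")],
        }
        s = cohort_summary(res)
        assert s["bands"]["accuracy"]["two_cps"] == 1
        assert s["bands"]["rt"]["two_cps"] == 2
        assert s["n"]["accuracy"] == 3
        # a agrees across measures, b does not -> 1/2
        assert s["cross_measure_agreement"] == pytest.approx(0.5)

    def test_all_null_cohort_counts_zero(self):
        rng = np.random.default_rng(17)
        results = []
        for i in range(4):
            ev = make_null_participants(rng, 1, 500)[0]
            ps = sweep(bin_series(ev.phase_pct, ev.values, 40))
            null = permutation_null([ev], 40, "mean", 200, rng,
                                    level="participant")
            results.append(participant_test(f"P{i}", "accuracy", ps, null))
        s = cohort_summary({"accuracy": results})
        counts = s["bands"]["accuracy"]
        assert counts["two_cps"] + counts["four_cps"] + counts["high"] <= 1


class TestStrideDurationCorrelation:
    def _sweeps(self, rng, n, freq_jitter=0.2):
        sweeps, durations = {}, {}
        for i in range(n):
            pid = f"P{i:02d}"
            r2 = rng.uniform(0, 0.2, 50)
            best = 2.0 + rng.choice([-1, 0, 1]) * freq_jitter
            bi = int(np.argmin(np.abs(FREQ_GRID - best)))
            r2[bi] = 0.5
            fit = fit_fixed_frequency(
                (X40, 0.5 + 0.1 * np.cos(2 * np.pi * best * X40)), best)
            sweeps[pid] = SweepResult(FREQ_GRID, r2, float(FREQ_GRID[bi]), fit)
            durations[pid] = float(rng.normal(1.18, 0.069))
        return durations, sweeps

    def test_fixed_cps_gives_negative_hz_correlation(self, rng):
        durations, sweeps = self._sweeps(rng, 36)
        rows = {r["metric"]: r for r in
                stride_duration_correlation(durations, sweeps)}
        assert rows["best_freq_hz"]["rho"] < 0
        assert rows["best_freq_hz"]["p"] < 0.05
        assert abs(rows["best_freq_cps"]["rho"]) < 0.3

    def test_constant_durations_flagged(self, rng):
        durations, sweeps = self._sweeps(rng, 10)
        durations = {k: 1.18 for k in durations}
        rows = {r["metric"]: r for r in
                stride_duration_correlation(durations, sweeps)}
        assert rows["best_freq_hz"]["flag"] == "degenerate" or \
            np.isnan(rows["best_freq_cps"]["rho"])

    def test_too_few_participants_refused(self, rng):
        durations, sweeps = self._sweeps(rng, 4)
        with pytest.raises(ValueError):
            stride_duration_correlation(durations, sweeps)
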