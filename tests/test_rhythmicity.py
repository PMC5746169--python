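"""Autocorrelogram arithmetic, normalisation, and the rhythmicity fit."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import msephys as m
from msephys.core import InsufficientDataError
from msephys.rhythmicity import (
    BIN_MS,
    NormalizationError,
    fit_rhythmicity,
    normalize_acg,
)


def brute_force_acg_counts(times_s, max_lag_ms=500.0, bin_ms=10.0):
    """O(n^2) double loop over ordered pairs — the independent oracle."""
    n_bins = int(max_lag_ms / bin_ms)
    counts = np.zeros(n_bins, dtype=int)
    t = np.asarray(times_s) * 1000.0
    for i in range(t.size):
        for j in range(i + 1, t.size):
            lag = t[j] - t[i]
            if lag < max_lag_ms:
                counts[int(lag // bin_ms)] += 1
    return counts


class TestAutocorrelogram:
    def test_regular_train_pair_counts(self):
        """Spikes every 100 ms: lag-bin [100k, 100k+10) holds 11-k pairs."""
        t = np.arange(0, 1.001, 0.1)
        train = m.SpikeTrain("u", t, 0.0, 2.0)
        acg = m.autocorrelogram(train, min_spikes=1)
        expect = np.zeros(50, dtype=int)
        for k in range(1, 5):  # lags 100..400 ms; 500 ms is outside [0, 500)
            expect[10 * k] = 11 - k
        np.testing.assert_array_equal(acg.counts, expect)

    def test_single_spike_all_zero(self):
        train = m.SpikeTrain("u", [1.0], 0.0, 2.0)
        acg = m.autocorrelogram(train, min_spikes=1)
        assert acg.counts.sum() == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0.0, 20.0, 500))
        train = m.SpikeTrain("u", np.unique(t), 0.0, 20.0)
        acg = m.autocorrelogram(train)
        np.testing.assert_array_equal(
            acg.counts, brute_force_acg_counts(train.spike_times))

    def test_within_epoch_pairs_only(self):
        """Pairs spanning an epoch gap are not counted."""
        rng = np.random.default_rng(8)
        a = np.sort(rng.uniform(0.0, 5.0, 200))
        b = np.sort(rng.uniform(5.0, 10.0, 200))
        train = m.SpikeTrain("u", np.unique(np.concatenate([a, b])), 0.0, 10.0)
        ep = m.EpochSet([("RUN", 0.0, 5.0), ("REST", 5.0, 7.0),
                         ("RUN", 7.0, 10.0)])
        acg = m.autocorrelogram(train, ep, "RUN", min_spikes=1)
        seg_a = train.spike_times[train.spike_times < 5.0]
        seg_b = train.spike_times[train.spike_times >= 7.0]
        expect = (brute_force_acg_counts(seg_a)
                  + brute_force_acg_counts(seg_b))
        np.testing.assert_array_equal(acg.counts, expect)

    def test_min_spikes_threshold(self):
        train = m.SpikeTrain("u", np.linspace(0, 10, 100), 0.0, 11.0)
        with pytest.raises(InsufficientDataError, match="300"):
            m.autocorrelogram(train)


class TestNormalize:
    def _acg(self, counts):
        counts = np.asarray(counts)
        return m.Autocorrelogram((np.arange(50) + 0.5) * BIN_MS, counts,
                                 1000, 100.0)

    def test_band_peak_and_centre_clip(self):
        counts = np.ones(50, dtype=int) * 10
        counts[12] = 50    # band peak, 120-130 ms
        counts[0] = 400    # near-zero-lag centre
        values = normalize_acg(self._acg(counts))
        assert values[12] == 1.0
        assert values[0] == 1.0          # clipped
        assert values[25] == pytest.approx(10 / 50)

    def test_all_equal_counts_all_one(self):
        values = normalize_acg(self._acg(np.full(50, 7)))
        np.testing.assert_array_equal(values, np.ones(50))

    def test_max_is_one_for_any_valid_input(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            counts = rng.integers(0, 100, 50)
            counts[15] = max(counts[15], 1)  # keep the band nonzero
            assert normalize_acg(self._acg(counts)).max() == 1.0

    def test_zero_band_raises(self):
        counts = np.zeros(50, dtype=int)
        counts[0] = 10
        with pytest.raises(NormalizationError):
            normalize_acg(self._acg(counts))

    def test_two_sided_acg_is_equivalent(self):
        """A symmetric two-sided ACG doubles counts, leaving values equal."""
        rng = np.random.default_rng(10)
        counts = rng.integers(1, 100, 50)
        one_sided = normalize_acg(self._acg(counts))
        two_sided = normalize_acg(self._acg(2 * counts))
        np.testing.assert_allclose(one_sided, two_sided)


class TestFit:
    def _analytic_values(self, f=7.0, A=0.5, sigma=150.0, trend=0.5):
        lags = (np.arange(50) + 0.5) * BIN_MS
        g = A * np.exp(-lags**2 / (2 * sigma**2)) * np.cos(2e-3 * np.pi * f * lags)
        return lags, g + trend

    def test_recovers_frequency_and_ri_of_analytic_acg(self):
        """f recovered within 0.05 Hz; RI close to the generating-function
        evaluation of the index (the OLS trend absorbs a little of the
        decaying envelope, so agreement is ~1e-2, not exact)."""
        f, A, sigma, trend = 7.0, 0.5, 150.0, 0.5
        lags, values = self._analytic_values(f, A, sigma, trend)
        fit = fit_rhythmicity(values)
        assert abs(fit.f - f) < 0.05
        sel = (lags >= 50) & (lags <= 500)
        slope, intercept = np.polyfit(lags[sel], values[sel], 1)
        t_k = np.arange(1, 8) * (1000.0 / f) / 2
        t_k = t_k[(t_k >= 50) & (t_k <= 500)]
        g_k = A * np.exp(-t_k**2 / (2 * sigma**2)) * np.cos(2e-3 * np.pi * f * t_k)
        ri_oracle = np.clip(np.mean(np.abs(g_k) / (intercept + slope * t_k)), 0, 1)
        assert fit.RI == pytest.approx(ri_oracle, abs=0.015)
        assert fit.r2 > 0.9

    def test_ri_formula_matches_independent_evaluation(self):
        """Given the fitted parameters, RI equals a from-scratch evaluation
        of the trend-normalised extremum mean to 1e-12."""
        _, values = self._analytic_values()
        fit = fit_rhythmicity(values)
        period = 1000.0 / fit.f
        t_k = np.arange(1, 20) * period / 2
        t_k = t_k[(t_k >= 50.0) & (t_k <= 500.0)]
        g = (fit.A * np.exp(-t_k**2 / (2 * fit.sigma_ms**2))
             * np.cos(2e-3 * np.pi * fit.f * t_k))
        trend = fit.trend_intercept + fit.trend_slope * t_k
        expect = float(np.clip(np.mean(np.abs(g[trend > 0]) / trend[trend > 0]),
                               0.0, 1.0))
        assert fit.RI == pytest.approx(expect, abs=1e-12)

    def test_flat_acg_not_rhythmic(self):
        values = np.full(50, 1.0)
        fit = fit_rhythmicity(values)
        assert fit.A < 1e-3
        assert fit.RI < 0.02

    def test_teevra_archetype_recovery(self, teevra_session):
        """A 7 Hz bursting unit yields OF in 7 +- 0.25 Hz and high RI."""
        train, epochs, _, _ = teevra_session
        fit = m.RhythmicityModel.from_spike_train(train, epochs, "RUN").fit()
        assert abs(fit.OF - 7.0) < 0.25
        assert fit.RI > 0.4

    def test_run_more_rhythmic_than_rest(self, teevra_session):
        """REST bursting is cycle-free, so RI(RUN) > RI(REST)."""
        train, epochs, _, _ = teevra_session
        run = m.RhythmicityModel.from_spike_train(train, epochs, "RUN").fit()
        rest = m.RhythmicityModel.from_spike_train(train, epochs, "REST").fit()
        assert run.RI > rest.RI

    def test_ri_monotone_in_phase_concentration(self, epochs_300):
        """Tighter phase locking (larger kappa) gives larger RI."""
        _, truth = m.generate_lfp(m.LfpSpec(seed=21), epochs_300)
        mean_ri = []
        for kappa in (0.25, 0.5, 1.0, 2.0, 4.0):
            ris = []
            for seed in (1, 2, 3):
                spec = m.UnitSpec(archetype="teevra", rate_rest=30.0,
                                  rate_run=30.0, phase_kappa=kappa, seed=seed)
                tr = m.generate_unit(spec, epochs_300, truth["trough_times"])
                fit = m.RhythmicityModel.from_spike_train(tr, epochs_300, "RUN").fit()
                ris.append(fit.RI)
            mean_ri.append(np.mean(ris))
        from scipy.stats import spearmanr
        rho = spearmanr(np.arange(len(mean_ri)), mean_ri).statistic
        assert rho > 0.9

    @given(st.lists(st.floats(0.0, 1.0), min_size=50, max_size=50))
    def test_ri_always_in_unit_interval(self, values):
        values = np.asarray(values)
        values[15] = 1.0  # keep the normalisation band convention
        fit = fit_rhythmicity(values)
        assert 0.0 <= fit.RI <= 1.0

    def test_summary_and_plot(self, teevra_session):
        import matplotlib
        matplotlib.use("Agg")
        train, epochs, _, _ = teevra_session
        fit = m.RhythmicityModel.from_spike_train(train, epochs, "RUN").fit()
        text = fit.summary()
        assert "rhythmicity index" in text and f"{fit.RI:7.3f}" in text
        ax = fit.plot()
        assert ax.get_xlabel() == "lag (ms)"


class TestFilterRhythmic:
    def test_strict_threshold_boundary(self):
        import pandas as pd
        df = pd.DataFrame({"unit_id": ["a", "b", "c"],
                           "RI": [0.05, 0.1, 0.11]})
        kept = m.filter_rhythmic(df)
        assert list(kept["unit_id"]) == ["c"]

    def test_empty_input(self):
        import pandas as pd
        df = pd.DataFrame({"unit_id": [], "RI": []})
        assert len(m.filter_rhythmic(df)) == 0

    def test_object_sequence_input(self):
        rows = [m.UnitMetrics("a", RI=0.5), m.UnitMetrics("b", RI=0.02)]
        kept = m.filter_rhythmic(rows)
        assert [r.unit_id for r in kept] == ["a"]
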