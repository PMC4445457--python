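import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pulsecraft import (
    Pulse,
    ValidationError,
    curate_pulses,
    detect_pulses,
    f_test_accept,
    fit_model,
)
from pulsecraft.detect import FitResult, BackgroundModel


TIMES = np.arange(0.0, 600.0, 6.0)
BACKGROUND = 5.0 + 0.02 * np.exp(0.01 * TIMES)


def gaussian(t, amp, mu, sigma):
    return amp * np.exp(-((t - mu) ** 2) / (2 * sigma**2))


class TestFitModel:
    def test_background_only_recovery(self):
        fit = fit_model(TIMES, BACKGROUND, 0)
        assert fit.rss == pytest.approx(0.0, abs=1e-8)
        assert fit.background.offset == pytest.approx(5.0, rel=0.01)
        assert fit.background.scale == pytest.approx(0.02, rel=0.01)
        assert fit.background.rate == pytest.approx(0.01, rel=0.01)

    def test_single_gaussian_recovery(self):
        y = BACKGROUND + gaussian(TIMES, 50.0, 300.0, 15.0)
        fit = fit_model(TIMES, y, 1)
        (comp,) = fit.components
        assert comp.amplitude == pytest.approx(50.0, rel=0.02)
        assert comp.mu == pytest.approx(300.0, rel=0.02)
        assert comp.sigma == pytest.approx(15.0, rel=0.02)

    def test_all_zero_trace(self):
        fit = fit_model(TIMES, np.zeros_like(TIMES), 0)
        assert fit.rss == pytest.approx(0.0, abs=1e-8)
        assert fit.background.scale == pytest.approx(0.0, abs=1e-6)

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            fit_model(TIMES[:5], BACKGROUND[:5], 1)

    def test_missing_samples_excluded(self):
        y = BACKGROUND.copy()
        y[10:15] = np.nan
        fit = fit_model(TIMES, y, 0)
        assert fit.n_samples == len(TIMES) - 5
        assert fit.rss == pytest.approx(0.0, abs=1e-8)

    def test_parameter_bounds_respected(self):
        rng = np.random.default_rng(0)
        y = BACKGROUND + gaussian(TIMES, 40.0, 200.0, 12.0) + rng.normal(0, 2, len(TIMES))
        fit = fit_model(TIMES, y, 1)
        for c in fit.components:
            assert c.amplitude >= 0
            assert 10.0 <= c.sigma <= 30.0
            assert TIMES[0] <= c.mu <= TIMES[-1]
        assert fit.background.scale >= 0 and fit.background.rate >= 0


def _fit(rss, df, n_comp=0):
    return FitResult(
        components=[None] * n_comp, background=BackgroundModel(0, 0, 0),
        rss=rss, df=df, n_samples=df + 3 * n_comp + 3,
    )


class TestFTest:
    def test_no_improvement_rejected(self):
        assert not f_test_accept(_fit(100.0, 50), _fit(100.0, 50, 1))

    def test_decision_matches_f_distribution(self):
        """Worked case checked against an independent CDF evaluation."""
        small, large = _fit(120.0, 54), _fit(80.0, 51, 1)
        f_stat = (120.0 / 54) / (80.0 / 51)
        expected = f_stat > stats.f.ppf(0.99, 54, 51)
        assert f_test_accept(small, large, alpha=0.01) == expected
        # and the direction flips at a permissive alpha
        permissive = f_stat > stats.f.ppf(0.5, 54, 51)
        assert f_test_accept(small, large, alpha=0.5) == permissive

    def test_perfect_large_fit_accepted(self):
        assert f_test_accept(_fit(50.0, 54), _fit(0.0, 51, 1))

    def test_worse_large_fit_rejected_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert not f_test_accept(_fit(50.0, 54), _fit(60.0, 51, 1))

    def test_bad_df_raises(self):
        with pytest.raises(ValidationError):
            f_test_accept(_fit(50.0, 0), _fit(10.0, 5, 1))


class TestDetectPulses:
    def test_zero_noise_single_pulse_exact(self):
        y = BACKGROUND + gaussian(TIMES, 50.0, 300.0, 15.0)
        pulses, fit, _ = detect_pulses(TIMES, y)
        assert len(pulses) == 1
        assert pulses[0].amplitude == pytest.approx(50.0, rel=1e-3)
        assert pulses[0].center == pytest.approx(300.0, abs=0.1)
        assert pulses[0].width == pytest.approx(15.0, rel=1e-3)

    def test_flat_zero_trace_empty(self):
        pulses, _, _ = detect_pulses(TIMES, np.zeros_like(TIMES))
        assert pulses == []

    @pytest.mark.parametrize("seed", range(10))
    def test_specificity_on_pure_background(self, seed):
        """Background + 2% noise must not yield spurious pulses."""
        rng = np.random.default_rng(seed)
        y = BACKGROUND + rng.normal(0, 0.02 * BACKGROUND.mean(), len(TIMES))
        pulses, _, _ = detect_pulses(TIMES, y)
        assert pulses == []

    def test_intensity_rescaling_equivariance(self):
        """x c scales amplitudes/background but not count, centers, widths."""
        rng = np.random.default_rng(3)
        y = BACKGROUND + gaussian(TIMES, 50.0, 250.0, 15.0) + gaussian(
            TIMES, 45.0, 450.0, 18.0
        ) + rng.normal(0, 2.0, len(TIMES))
        base, _, _ = detect_pulses(TIMES, y)
        scaled, _, _ = detect_pulses(TIMES, 10.0 * y)
        assert len(base) == len(scaled) == 2
        for p, q in zip(base, scaled):
            assert q.amplitude == pytest.approx(10 * p.amplitude, rel=0.05)
            assert q.center == pytest.approx(p.center, abs=1.0)
            assert q.width == pytest.approx(p.width, rel=0.05)

    def test_nested_rss_monotone(self):
        rng = np.random.default_rng(1)
        y = BACKGROUND + gaussian(TIMES, 60.0, 300.0, 20.0) + rng.normal(0, 3, len(TIMES))
        prev = fit_model(TIMES, y, 0)
        for n in range(1, 4):
            fit = fit_model(TIMES, y, n, init=prev)
            assert fit.rss <= prev.rss + 1e-6
            prev = fit


def _pulse(cell, center, sigma=12.0, pid="p"):
    return Pulse(pulse_id=pid, cell_id=cell, embryo_id="e", amplitude=10.0,
                 center=center, width=sigma)


def _manual(rows):
    return pd.DataFrame(rows, columns=["track_id", "cell_id", "first_frame", "last_frame"])


class TestCuration:
    FI = 6.0  # frame interval

    def test_identical_supports_are_one_to_one(self):
        detected = [_pulse("a", 120.0, pid="d0"), _pulse("a", 300.0, pid="d1")]
        manual = _manual([
            ("m0", "a", 16, 24), ("m1", "a", 46, 54),
        ])
        res = curate_pulses(detected, manual, self.FI)
        assert res.counts["one_to_one"] == 2
        assert sum(res.counts.values()) == 2
        assert all(p.curation_status == "one_to_one" for p in detected)

    def test_split_by_fitting(self):
        """One manual track covered by two detected pulses."""
        detected = [_pulse("a", 84.0, sigma=12.0, pid="d0"),
                    _pulse("a", 156.0, sigma=12.0, pid="d1")]
        manual = _manual([("m0", "a", 10, 30)])
        res = curate_pulses(detected, manual, self.FI)
        assert res.counts["split_by_fitting"] == 1
        assert sum(res.counts.values()) == 1

    def test_merged_by_fitting(self):
        detected = [_pulse("a", 135.0, sigma=22.0, pid="d0")]  # frames ~15..30
        manual = _manual([("m0", "a", 14, 21), ("m1", "a", 24, 31)])
        res = curate_pulses(detected, manual, self.FI)
        assert res.counts["merged_by_fitting"] == 1

    def test_missed_and_added(self):
        detected = [_pulse("a", 120.0, pid="d0")]
        manual = _manual([("m0", "a", 80, 95)])  # far from the detected pulse
        res = curate_pulses(detected, manual, self.FI)
        assert res.counts["missed_by_fitting"] == 1
        assert res.counts["added_by_fitting"] == 1

    def test_counts_partition_all_tracks(self):
        detected = [_pulse("a", 120.0, pid="d0"), _pulse("a", 400.0, pid="d1")]
        manual = _manual([("m0", "a", 16, 24), ("m1", "a", 200, 210)])
        res = curate_pulses(detected, manual, self.FI)
        # every detected pulse and manual track lands in exactly one component
        n_items = sum(len(m["detected"]) + len(m["manual"]) for m in res.mapping)
        assert n_items == 4

    def test_unknown_cell_raises(self):
        with pytest.raises(ValidationError, match="ghost"):
            curate_pulses([], _manual([("m0", "ghost", 0, 5)]), self.FI,
                          known_cells={"a"})
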