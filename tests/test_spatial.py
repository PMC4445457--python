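import numpy as np
import pandas as pd
import pytest

from pulsecraft import (
    EmbryoDataset,
    ValidationError,
    compare_class_z,
    competition_analysis,
    neighbor_enrichment,
    neighbor_pulse_counts,
    partial_correlation,
    poisson_pattern,
    polyserial_correlation,
    randomize_pulses,
    stpcf,
)
from pulsecraft.spatial import (
    PointPattern,
    RandomizationNull,
    Window,
    _polyserial_nll,
    fit_interval_gamma,
    pulse_connectivities,
    within_cell_intervals,
)

from conftest import make_track


def line_dataset():
    """Four cells in a row: a - b - c - d (so connectivities 1, 2, 2, 1)."""
    times = np.arange(0.0, 300.0, 6.0)
    flat = np.full_like(times, 36.0)
    myo = np.full_like(times, 10.0)
    cells = {}
    for i, (cid, nbrs) in enumerate(
        [("a", ["b"]), ("b", ["a", "c"]), ("c", ["b", "d"]), ("d", ["c"])]
    ):
        cells[cid] = make_track(cid, times, myo, flat, nbrs, centroid=(7.0 * i, 0.0))
    return EmbryoDataset(embryo_id="e1", cells=cells)


def pulses_df(rows):
    df = pd.DataFrame(rows)
    if "pulse_id" not in df:
        df["pulse_id"] = [f"p{i}" for i in range(len(df))]
    if "class_label" not in df:
        df["class_label"] = "ratcheted"
    df["embryo_id"] = "e1"
    return df


class TestNeighborCounts:
    def test_window_boundaries_inclusive(self):
        """Neighbour pulses at 90, 112, 130 s around a 100 s centre: two hits;
        one at exactly 115 s is still counted (closed interval)."""
        ds = line_dataset()
        df = pulses_df([
            {"cell_id": "b", "center": 100.0},
            {"cell_id": "a", "center": 90.0},
            {"cell_id": "a", "center": 112.0},
            {"cell_id": "c", "center": 130.0},
        ])
        assert neighbor_pulse_counts(df, ds)[0] == 2
        df2 = pulses_df([
            {"cell_id": "b", "center": 100.0},
            {"cell_id": "c", "center": 115.0},
        ])
        assert neighbor_pulse_counts(df2, ds)[0] == 1

    def test_no_neighbour_pulses(self):
        ds = line_dataset()
        df = pulses_df([{"cell_id": "a", "center": 100.0},
                        {"cell_id": "d", "center": 105.0}])  # d not adjacent to a
        assert neighbor_pulse_counts(df, ds)[0] == 0

    def test_same_cell_never_counted(self):
        ds = line_dataset()
        df = pulses_df([{"cell_id": "b", "center": 100.0},
                        {"cell_id": "b", "center": 105.0}])
        assert list(neighbor_pulse_counts(df, ds)) == [0, 0]

    def test_unknown_cell_raises(self):
        with pytest.raises(ValidationError):
            neighbor_pulse_counts(pulses_df([{"cell_id": "zz", "center": 1.0}]), line_dataset())

    def test_time_reversal_symmetry(self):
        ds = line_dataset()
        rng = np.random.default_rng(0)
        rows = [{"cell_id": c, "center": float(t)}
                for c in "abcd" for t in rng.uniform(0, 280, 6)]
        df = pulses_df(rows)
        fwd = neighbor_pulse_counts(df, ds)
        rev = df.copy()
        rev["center"] = 280.0 - rev["center"]
        np.testing.assert_array_equal(fwd, neighbor_pulse_counts(rev, ds))


class TestSTPCF:
    def test_csr_pattern_is_near_one(self):
        pat = poisson_pattern(2000, seed=0)
        grid = stpcf(pat, np.array([8.0, 12.0]), np.array([40.0, 80.0]),
                     spatial_halfwidth=4.0, temporal_sd=12.0, seed=1)
        assert np.all(grid.g > 0.8) and np.all(grid.g < 1.2)
        assert grid.lambda_hat == pytest.approx(2000 / (200.0 * 200.0 * 1800.0))

    def test_planted_offset_is_the_maximum(self):
        """Every event paired at (8 um, 45 s) lights up that grid cell."""
        rng = np.random.default_rng(2)
        n = 400
        x = rng.uniform(0, 200, n); y = rng.uniform(0, 200, n)
        t = rng.uniform(0, 1800, n)
        theta = rng.uniform(0, 2 * np.pi, n)
        pat = PointPattern(
            x=np.concatenate([x, x + 8.0 * np.cos(theta)]),
            y=np.concatenate([y, y + 8.0 * np.sin(theta)]),
            t=np.concatenate([t, t + 45.0]),
            window=Window.rectangle(-10, 210, -10, 210, 0, 1845),
        )
        eta = np.array([4.0, 8.0, 12.0, 16.0])
        tau = np.array([15.0, 45.0, 75.0])
        grid = stpcf(pat, eta, tau, spatial_halfwidth=2.0, temporal_sd=8.0, seed=3)
        i, j = np.unravel_index(np.argmax(grid.g), grid.g.shape)
        assert (eta[i], tau[j]) == (8.0, 45.0)

    def test_single_event_raises(self):
        pat = poisson_pattern(1, seed=0)
        with pytest.raises(ValidationError):
            stpcf(pat, np.array([5.0]), np.array([10.0]), 2.0, 5.0)

    def test_bad_bandwidth_raises(self):
        pat = poisson_pattern(50, seed=0)
        with pytest.raises(ValidationError):
            stpcf(pat, np.array([5.0]), np.array([10.0]), -1.0, 5.0)


class TestRandomization:
    def _pulses(self, rng, ds, per_cell=5):
        rows = []
        for cid in ds.cells:
            t = rng.uniform(0, 40)
            for _ in range(per_cell):
                rows.append({"cell_id": cid, "center": float(t)})
                t += rng.gamma(3.0, 18.0)
        return pulses_df(rows)

    def test_exact_preservation(self, coupled_embryo):
        ds, pulses, _ = coupled_embryo
        sub = pulses.iloc[:400].reset_index(drop=True)
        conn = pulse_connectivities(sub, ds)
        for assign in randomize_pulses(ds, sub, 2, seed=9):
            moved = sub.copy()
            moved["cell_id"] = assign
            # times, class labels, connectivities all preserved exactly
            np.testing.assert_array_equal(moved["center"], sub["center"])
            np.testing.assert_array_equal(moved["class_label"], sub["class_label"])
            np.testing.assert_array_equal(pulse_connectivities(moved, ds), conn)

    def test_unique_connectivity_forces_identity(self):
        """With every connectivity class a singleton, pulses cannot move."""
        times = np.arange(0.0, 400.0, 6.0)
        flat = np.full_like(times, 36.0)
        myo = np.full_like(times, 10.0)
        cells = {
            "a": make_track("a", times, myo, flat, ["x1"]),
            "b": make_track("b", times, myo, flat, ["x1", "x2"]),
            "c": make_track("c", times, myo, flat, ["x1", "x2", "x3"]),
        }
        ds = EmbryoDataset(embryo_id="e1", cells=cells,
                           external_ids={"x1", "x2", "x3"})
        rng = np.random.default_rng(1)
        df = self._pulses(rng, ds)
        for assign in randomize_pulses(ds, df, 3, seed=2):
            np.testing.assert_array_equal(assign, df["cell_id"].to_numpy())

    def test_gamma_fit_moments(self):
        rng = np.random.default_rng(0)
        samples = rng.gamma(4.0, 20.0, 20000)
        shape, scale = fit_interval_gamma(samples)
        assert shape == pytest.approx(4.0, rel=0.1)
        assert scale == pytest.approx(20.0, rel=0.1)

    def test_interval_multiset_size_conserved(self, coupled_embryo):
        ds, pulses, _ = coupled_embryo
        sub = pulses.iloc[:600].reset_index(drop=True)
        emp = within_cell_intervals(sub)
        assign = next(randomize_pulses(ds, sub, 1, seed=3))
        moved = sub.copy()
        moved["cell_id"] = assign
        rnd = within_cell_intervals(moved)
        # pulse count fixed; interval count varies only with occupied-cell count
        assert len(rnd) + moved["cell_id"].nunique() == len(sub)
        assert len(emp) + sub["cell_id"].nunique() == len(sub)


class TestEnrichment:
    def test_all_boundary_cells_raise(self):
        ds = line_dataset()
        for c in ds.cells.values():
            c.is_boundary = True
        df = pulses_df([{"cell_id": "a", "center": 50.0},
                        {"cell_id": "b", "center": 60.0},
                        {"cell_id": "b", "center": 140.0},
                        {"cell_id": "a", "center": 160.0}])
        with pytest.raises(ValidationError, match="boundary"):
            neighbor_enrichment(df, ds, n_iter=5, seed=0)

    def test_compare_identical_classes_zero_difference(self):
        stats_df = pd.DataFrame({
            "ratcheted": np.random.default_rng(0).normal(3.0, 0.1, 100),
        })
        stats_df["unratcheted"] = stats_df["ratcheted"]
        null = RandomizationNull(
            classes=("ratcheted", "unratcheted"),
            empirical={"ratcheted": 3.2, "unratcheted": 3.2},
            null_mean={}, null_sd={}, z_scores={},
            iteration_stats=stats_df, n_iter=100, seed=0,
        )
        res = compare_class_z(null, "ratcheted", "unratcheted",
                              n_subsamples=20, subsample_size=50, seed=1)
        assert res.mean_difference == pytest.approx(0.0, abs=1e-12)

    def test_subsample_validation(self):
        stats_df = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)})
        null = RandomizationNull(("a", "b"), {"a": 1.0, "b": 1.0}, {}, {}, {},
                                 stats_df, 10, 0)
        with pytest.raises(ValidationError):
            compare_class_z(null, "a", "b", subsample_size=50)
        with pytest.raises(ValidationError):
            compare_class_z(null, "a", "b", n_subsamples=1, subsample_size=5)


class TestPartialCorrelation:
    def test_uncorrelated_confounder_reduces_to_pearson(self):
        rng = np.random.default_rng(0)
        n = 2000
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        z = rng.normal(size=n)  # independent of both
        plain = np.corrcoef(x, y)[0, 1]
        part = partial_correlation(x, y, z).rho
        assert part == pytest.approx(plain, abs=0.02)

    def test_exact_closed_form_value(self):
        """All three pairwise correlations exactly 0.5 -> partial = 1/3."""
        rng = np.random.default_rng(1)
        a = rng.normal(size=(40, 3))
        a -= a.mean(axis=0)
        q, _ = np.linalg.qr(a)
        u1, u2, u3 = q[:, 0], q[:, 1], q[:, 2]
        x = u1
        z = 0.5 * u1 + np.sqrt(0.75) * u2
        alpha = 0.25 / np.sqrt(0.75)
        y = 0.5 * u1 + alpha * u2 + np.sqrt(1 - 0.25 - alpha**2) * u3
        res = partial_correlation(x, y, z)
        assert res.rho == pytest.approx(1 / 3, abs=1e-12)

    def test_residual_and_closed_form_agree(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x, y, z = rng.normal(size=(3, 30))
            a = partial_correlation(x, y, z).rho
            b = partial_correlation(x, y, z, method="residuals").rho
            assert a == pytest.approx(b, abs=1e-12)

    def test_identical_confounder_degenerate(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        x = rng.normal(size=50)
        res = partial_correlation(x, y, y)
        assert res.flagged

    def test_zero_variance_raises(self):
        with pytest.raises(ValidationError):
            partial_correlation([1.0] * 10, np.arange(10.0), np.arange(10.0))


class TestPolyserial:
    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        y = rng.integers(0, 3, size=2000)
        assert abs(polyserial_correlation(x, y).rho) < 0.06

    def test_latent_tertile_recovery(self):
        rng = np.random.default_rng(1)
        lat = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 2000)
        y = np.digitize(lat[:, 1], [-0.43, 0.43])
        res = polyserial_correlation(lat[:, 0], y)
        assert 0.44 <= res.rho <= 0.56
        assert res.sd == pytest.approx(np.sqrt(1 / 2000), rel=1.0)  # order of magnitude

    def test_balanced_binary_likelihood_symmetric_in_rho(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=50)
        x = np.concatenate([v, v])
        y = np.concatenate([np.zeros(50), np.ones(50)])
        levels, idx = np.unique(y, return_inverse=True)
        from scipy import stats as sps
        cum = np.cumsum(np.bincount(idx)) / len(y)
        thresholds = np.concatenate([[-np.inf], sps.norm.ppf(cum[:-1]), [np.inf]])
        x_std = (x - x.mean()) / x.std(ddof=1)
        for rho in (0.2, 0.5, 0.8):
            assert _polyserial_nll(rho, x_std, idx, thresholds) == pytest.approx(
                _polyserial_nll(-rho, x_std, idx, thresholds), rel=1e-12
            )
        assert abs(polyserial_correlation(x, y).rho) < 0.05

    def test_constant_ordinal_raises(self):
        with pytest.raises(ValidationError):
            polyserial_correlation(np.random.default_rng(0).normal(size=30),
                                   np.zeros(30))


class TestCompetitionAnalysis:
    def _dataset_and_pulses(self, effect, seed=0):
        """Hex-lattice-free construction: line of many cells with controlled
        neighbour counts and constriction rates."""
        rng = np.random.default_rng(seed)
        n_cells = 40
        times = np.arange(0.0, 600.0, 6.0)
        flat = np.full_like(times, 36.0)
        myo = np.full_like(times, 10.0)
        cells = {}
        for i in range(n_cells):
            nbrs = [f"c{i-1}"] if i else []
            if i < n_cells - 1:
                nbrs.append(f"c{i+1}")
            cells[f"c{i}"] = make_track(f"c{i}", times, myo, flat, nbrs,
                                        centroid=(7.0 * i, 0.0))
        ds = EmbryoDataset(embryo_id="e1", cells=cells)
        rows = []
        for i in range(n_cells):
            for k in range(6):
                rows.append({"cell_id": f"c{i}", "center": 40.0 + 90.0 * k
                             + rng.uniform(-20, 20)})
        df = pulses_df(rows)
        df["amplitude"] = rng.uniform(10, 50, len(df))
        df["amplitude_bin"] = np.where(df["amplitude"] > 30.0, 6, 5)
        counts = neighbor_pulse_counts(df, ds)
        df["max_constriction_rate"] = (
            0.3 + effect * counts + rng.normal(0, 0.02, len(df))
        )
        return ds, df

    def test_null_effect_gives_small_rho(self):
        ds, df = self._dataset_and_pulses(effect=0.0)
        res = competition_analysis(df, ds)
        for stratum in res.strata.values():
            assert abs(stratum["polyserial"].rho) < 0.15

    def test_negative_effect_detected(self):
        """Rate reduced 0.05 per neighbouring pulse: competition signature."""
        ds, df = self._dataset_and_pulses(effect=-0.05)
        res = competition_analysis(df, ds)
        for stratum in res.strata.values():
            assert stratum["polyserial"].rho < -0.5
        assert res.pooled_partial.rho < 0
        assert res.pooled_partial.p < 0.01

    def test_constant_neighbour_count_skipped(self):
        ds, df = self._dataset_and_pulses(effect=0.0)
        df = df.iloc[:8].copy()
        df["center"] = np.arange(8) * 200.0  # no temporal neighbours at all
        df["cell_id"] = [f"c{2*i}" for i in range(8)]  # no adjacent cells
        res = competition_analysis(df, ds)
        assert res.strata == {} or all(
            s["polyserial"] is None for s in res.strata.values()
        )
        assert res.skipped
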