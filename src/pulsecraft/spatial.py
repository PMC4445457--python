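"""Spatial coordination of pulses.

Contents:

* neighbour-pulse counting (pulses in adjacent cells within +/-15 s)
* the spatiotemporal pair correlation function g(eta, tau) of the pulse
  point pattern (box spatial kernel, Gaussian temporal kernel), normalized
  so that complete spatiotemporal randomness gives g = 1
* a connectivity-preserving spatial randomization null: pulses are moved to
  cells with the same local connectivity, accepting placements with
  probability proportional to the fitted gamma density of inter-pulse
  intervals, which preserves pulse times, class labels, connectivity and
  the interval statistics
* Z-score enrichment of neighbour pulses per behaviour class against that
  null, and the paired subsampling comparison of class Z-scores
* partial and polyserial correlation, and the neighbour-competition
  analysis built from them
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import ConvexHull, Delaunay
from scipy.spatial.distance import pdist

from .datatypes import CLASS_LABELS, EmbryoDataset, ValidationError


# --- point patterns & stPCF ---------------------------------------------------------


@dataclass
class Window:
    """Observation window: a spatial region (rectangle or convex hull) x a time span."""

    area: float
    t0: float
    t1: float
    bounds: tuple  # (x0, x1, y0, y1)
    hull: Delaunay | None = None  # None => rectangle

    @property
    def t_span(self) -> float:
        return self.t1 - self.t0

    @classmethod
    def rectangle(cls, x0, x1, y0, y1, t0, t1) -> "Window":
        return cls(area=float((x1 - x0) * (y1 - y0)), t0=float(t0), t1=float(t1),
                   bounds=(float(x0), float(x1), float(y0), float(y1)))

    @classmethod
    def from_points(cls, x, y, t) -> "Window":
        pts = np.column_stack([x, y])
        hull = ConvexHull(pts)
        tri = Delaunay(pts[hull.vertices])
        return cls(
            area=float(hull.volume),  # 2-D ConvexHull volume is the area
            t0=float(np.min(t)),
            t1=float(np.max(t)),
            bounds=(float(np.min(x)), float(np.max(x)), float(np.min(y)), float(np.max(y))),
            hull=tri,
        )

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points in the spatial region (rejection from the bbox)."""
        x0, x1, y0, y1 = self.bounds
        out = np.empty((0, 2))
        while len(out) < n:
            cand = rng.uniform([x0, y0], [x1, y1], size=(2 * (n - len(out)) + 16, 2))
            if self.hull is not None:
                cand = cand[self.hull.find_simplex(cand) >= 0]
            out = np.vstack([out, cand])
        return out[:n]


@dataclass
class PointPattern:
    """Pulse events as a spatiotemporal point pattern."""

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    window: Window
    pulse_id: np.ndarray | None = None
    cell_id: np.ndarray | None = None
    class_label: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.t)


def pattern_from_pulses(pulses: pd.DataFrame, dataset: EmbryoDataset) -> PointPattern:
    """Build the point pattern from a pulses table: each event at the pulsing
    cell's centroid (at the frame nearest the Gaussian centre) and the pulse time."""
    xs, ys = [], []
    for _, row in pulses.iterrows():
        track = dataset.cells[str(row["cell_id"])]
        i = track.frame_of_time(float(row["center"]))
        xs.append(track.centroid[i, 0])
        ys.append(track.centroid[i, 1])
    x = np.asarray(xs)
    y = np.asarray(ys)
    t = pulses["center"].to_numpy(dtype=float)
    return PointPattern(
        x=x, y=y, t=t,
        window=Window.from_points(x, y, t),
        pulse_id=pulses["pulse_id"].to_numpy(),
        cell_id=pulses["cell_id"].to_numpy(),
        class_label=pulses["class_label"].to_numpy() if "class_label" in pulses else None,
    )


@dataclass
class STPCFGrid:
    eta: np.ndarray            # μm
    tau: np.ndarray            # s
    g: np.ndarray              # shape (len(eta), len(tau))
    lambda_hat: float          # events per μm²·s
    spatial_halfwidth: float   # μm (box kernel half-width)
    temporal_sd: float         # s (Gaussian kernel s.d.)


def _csr_temporal_density(tau: np.ndarray, sd: float, t_span: float) -> np.ndarray:
    """E[k_gauss(tau - |dt|)] for |dt| of a uniform pair on [0, T].

    |dt| has the triangular density 2(T-u)/T^2; the Gaussian-kernel smoothing
    of it has the closed form used here.
    """
    tau = np.asarray(tau, dtype=float)
    T = t_span
    a = (tau - T) / sd
    b = tau / sd
    cdf_term = stats.norm.cdf(b) - stats.norm.cdf(a)
    pdf_term = stats.norm.pdf(a) - stats.norm.pdf(b)
    return (2.0 / T**2) * ((T - tau) * cdf_term + sd**2 * pdf_term / sd)


def stpcf(
    pattern: PointPattern,
    eta_grid: np.ndarray,
    tau_grid: np.ndarray,
    spatial_halfwidth: float | None = None,
    temporal_sd: float = 10.0,
    n_ref_pairs: int = 200_000,
    seed: int = 0,
) -> STPCFGrid:
    """Kernel estimate of the spatiotemporal pair correlation function.

    g(eta, tau) measures how much more (or less) likely than chance it is
    that two pulses occur eta μm and tau s apart; 1 means complete
    spatiotemporal randomness (CSR), > 1 clustering at that offset.

    The estimator smooths the observed pair offsets with a box kernel in
    space (half-width ``spatial_halfwidth``; default half the median
    nearest-neighbour distance) and a Gaussian kernel in time (s.d.
    ``temporal_sd``), and divides by the expected kernel mass of a uniform
    pair in the same window: a Monte-Carlo estimate of the pair-distance
    density in space times the closed-form triangular density in time.
    Normalizing by the CSR pair expectation (rather than an asymptotic
    2*pi*eta rule) keeps g at 1 under CSR on a finite window without any
    per-pair edge correction.
    """
    n = len(pattern)
    if n < 2:
        raise ValidationError("need at least two events for pair correlation")
    eta_grid = np.asarray(eta_grid, dtype=float)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if len(eta_grid) == 0 or len(tau_grid) == 0:
        raise ValidationError("empty evaluation grid")
    pts = np.column_stack([pattern.x, pattern.y])
    if spatial_halfwidth is None:
        d_nn = _median_nn_distance(pts)
        spatial_halfwidth = 0.5 * d_nn
    if spatial_halfwidth <= 0 or temporal_sd <= 0:
        raise ValidationError("bandwidths must be positive")
    h, sd = float(spatial_halfwidth), float(temporal_sd)

    d = pdist(pts)
    dt = pdist(pattern.t[:, None])
    n_pairs = len(d)

    # CSR reference: spatial pair-distance density smoothed by the same box kernel
    rng = np.random.default_rng(seed)
    ref = pattern.window.sample_points(2 * n_ref_pairs, rng)
    d_ref = np.linalg.norm(ref[:n_ref_pairs] - ref[n_ref_pairs:], axis=1)
    e_spatial = np.array([
        np.count_nonzero(np.abs(d_ref - e) <= h) / (len(d_ref) * 2 * h) for e in eta_grid
    ])
    e_temporal = _csr_temporal_density(tau_grid, sd, pattern.window.t_span)

    g = np.empty((len(eta_grid), len(tau_grid)))
    norm_const = 1.0 / (sd * math.sqrt(2 * math.pi))
    for i, e in enumerate(eta_grid):
        sub = dt[np.abs(d - e) <= h]
        for j, tau in enumerate(tau_grid):
            kern = norm_const * np.exp(-((tau - sub) ** 2) / (2 * sd**2))
            s = kern.sum() / (2 * h)
            g[i, j] = s / (n_pairs * e_spatial[i] * e_temporal[j])

    lam = n / (pattern.window.area * pattern.window.t_span)
    return STPCFGrid(eta=eta_grid, tau=tau_grid, g=g, lambda_hat=lam,
                     spatial_halfwidth=h, temporal_sd=sd)


def _median_nn_distance(pts: np.ndarray) -> float:
    """Median nearest-neighbour distance among distinct locations (events in
    the same cell share a centroid, so duplicates are collapsed first)."""
    from scipy.spatial import cKDTree

    uniq = np.unique(pts, axis=0)
    if len(uniq) < 2:
        raise ValidationError("need at least two distinct event locations")
    tree = cKDTree(uniq)
    dists, _ = tree.query(uniq, k=2)
    return float(np.median(dists[:, 1]))


# --- neighbour-pulse counting -------------------------------------------------------


def _neighbor_sets(dataset: EmbryoDataset, pulses: pd.DataFrame) -> list[set]:
    """Neighbour cell-id set for each pulse's cell at the pulse-centre frame."""
    out = []
    for _, row in pulses.iterrows():
        cid = str(row["cell_id"])
        if cid not in dataset.cells:
            raise ValidationError(f"pulse references unknown cell {cid!r}")
        track = dataset.cells[cid]
        out.append(set(track.neighbors_at(track.frame_of_time(float(row["center"])))))
    return out


def neighbor_pulse_counts(
    pulses: pd.DataFrame,
    dataset: EmbryoDataset,
    half_window: float = 15.0,
    assignments: np.ndarray | None = None,
) -> np.ndarray:
    """Number of neighbouring pulses per pulse.

    A neighbouring pulse is any pulse in an adjacent cell whose centre is
    within the closed interval +/- ``half_window`` seconds of the central
    pulse's centre. Same-cell pulses are never counted. ``assignments``
    optionally overrides the pulses' cell ids (used by the randomization).
    """
    t = pulses["center"].to_numpy(dtype=float)
    cells = (
        np.asarray(assignments)
        if assignments is not None
        else pulses["cell_id"].to_numpy(dtype=object)
    )
    by_cell: dict[str, np.ndarray] = {}
    order = np.argsort(t, kind="stable")
    for idx in order:
        by_cell.setdefault(str(cells[idx]), []).append(t[idx])  # type: ignore[arg-type]
    by_cell = {c: np.asarray(v) for c, v in by_cell.items()}

    counts = np.zeros(len(pulses), dtype=int)
    for i in range(len(pulses)):
        cid = str(cells[i])
        if cid not in dataset.cells:
            raise ValidationError(f"pulse assigned to unknown cell {cid!r}")
        track = dataset.cells[cid]
        nbrs = track.neighbors_at(track.frame_of_time(t[i]))
        c = 0
        for nb in nbrs:
            times = by_cell.get(str(nb))
            if times is None:
                continue
            lo = np.searchsorted(times, t[i] - half_window, side="left")
            hi = np.searchsorted(times, t[i] + half_window, side="right")
            c += hi - lo
        counts[i] = c
    return counts


def neighbor_pulse_count(
    pulse_idx: int, pulses: pd.DataFrame, dataset: EmbryoDataset, half_window: float = 15.0
) -> int:
    """Neighbour-pulse count for a single pulse (row position in the table)."""
    return int(neighbor_pulse_counts(pulses, dataset, half_window)[pulse_idx])


# --- connectivity-preserving randomization ------------------------------------------


def within_cell_intervals(pulses: pd.DataFrame) -> np.ndarray:
    """Consecutive within-cell inter-pulse intervals (seconds)."""
    out: list[float] = []
    for _, grp in pulses.groupby("cell_id"):
        t = np.sort(grp["center"].to_numpy(dtype=float))
        out.extend(np.diff(t))
    return np.asarray(out)


def fit_interval_gamma(values: np.ndarray) -> tuple[float, float]:
    """Method-of-moments gamma fit (shape, scale) to positive samples."""
    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    if len(values) < 2:
        raise ValidationError("need at least two inter-pulse intervals for the gamma fit")
    m = float(np.mean(values))
    v = float(np.var(values, ddof=1))
    if v <= 0:
        raise ValidationError("zero-variance intervals; gamma fit undefined")
    return m * m / v, v / m


def _gamma_accept_ratio(x: float, shape: float, scale: float, mode: float) -> float:
    """f_Gamma(x) / f_Gamma(mode), capped at 1."""
    if x <= 0:
        return 0.0
    log_ratio = (shape - 1) * (math.log(x) - math.log(mode)) - (x - mode) / scale
    return math.exp(min(log_ratio, 0.0))


def pulse_connectivities(pulses: pd.DataFrame, dataset: EmbryoDataset) -> np.ndarray:
    """Local cell connectivity of each pulse: the number of cells neighbouring
    the pulsing cell at the pulse's Gaussian centre."""
    return np.array([len(s) for s in _neighbor_sets(dataset, pulses)])


def randomize_pulses(
    dataset: EmbryoDataset,
    pulses: pd.DataFrame,
    n_iter: int,
    seed: int | None = None,
    max_retries: int = 100,
):
    """Yield randomized pulse-to-cell assignments (one array per iteration).

    Pulses are processed in centre-time order (ties by pulse_id). Each pulse
    may move to any cell with the same local connectivity at the pulse's
    centre frame (the original cell included). A uniformly drawn candidate
    is accepted with probability f_G(1/dt)/f_G(mode), where dt is the
    interval to the candidate cell's previous (already placed) pulse and
    f_G the gamma density fitted to the empirical pulse frequencies (the
    reciprocals of the within-cell intervals); candidate cells with no
    prior pulse accept unconditionally. After ``max_retries`` failed draws
    the pulse stays in its original cell. Pulse times, class labels and
    per-pulse connectivity counts are preserved exactly; the interval
    distribution is preserved statistically by the acceptance rule.
    """
    rng = np.random.default_rng(seed)
    t = pulses["center"].to_numpy(dtype=float)
    pid = pulses["pulse_id"].to_numpy()
    orig_cells = pulses["cell_id"].to_numpy(dtype=object)
    order = np.lexsort((pid, t))

    conn = pulse_connectivities(pulses, dataset)
    freqs = 1.0 / within_cell_intervals(pulses)
    shape, scale = fit_interval_gamma(freqs)
    mode = (shape - 1) * scale if shape > 1 else float(np.min(freqs[freqs > 0]))

    # candidate lists keyed by connectivity; static adjacency -> one global map
    any_per_frame = any(c.has_per_frame_neighbors for c in dataset)
    if not any_per_frame:
        cell_conn = {cid: len(c.neighbors_at(0)) for cid, c in dataset.cells.items()}
        groups: dict[int, list] = {}
        for cid, c in cell_conn.items():
            groups.setdefault(c, []).append(cid)
        pulse_candidates = [groups.get(int(c), []) for c in conn]
    else:
        pulse_candidates = []
        for i in range(len(pulses)):
            ti = t[i]
            cands = [
                cid
                for cid, track in dataset.cells.items()
                if len(track.neighbors_at(track.frame_of_time(ti))) == conn[i]
            ]
            pulse_candidates.append(cands)

    for _ in range(n_iter):
        assign = np.empty(len(pulses), dtype=object)
        last_time: dict[str, float] = {}
        for idx in order:
            cands = pulse_candidates[idx]
            placed = None
            if cands:
                for _retry in range(max_retries):
                    c = cands[int(rng.integers(len(cands)))]
                    lt = last_time.get(c)
                    if lt is None:
                        placed = c
                        break
                    dt = t[idx] - lt
                    ratio = _gamma_accept_ratio(1.0 / dt, shape, scale, mode) if dt > 0 else 0.0
                    if rng.random() < ratio:
                        placed = c
                        break
            if placed is None:
                placed = str(orig_cells[idx])
            last_time[placed] = t[idx]
            assign[idx] = placed
        yield assign


@dataclass
class RandomizationNull:
    classes: tuple
    empirical: dict[str, float]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    z_scores: dict[str, float]
    iteration_stats: pd.DataFrame  # n_iter x classes per-iteration mean counts
    n_iter: int
    seed: int | None


def _class_means(counts, labels, central, classes) -> dict[str, float]:
    out = {}
    for c in classes:
        mask = central & (labels == c)
        out[c] = float(np.mean(counts[mask])) if mask.any() else float("nan")
    return out


def neighbor_enrichment(
    pulses: pd.DataFrame,
    dataset: EmbryoDataset,
    n_iter: int = 1000,
    seed: int | None = None,
    half_window: float = 15.0,
    classes: tuple = CLASS_LABELS,
    max_retries: int = 100,
) -> RandomizationNull:
    """Per-class Z-scores of the mean neighbour-pulse count against the
    connectivity-preserving randomization null.

    Boundary cells are excluded as *centres* (edge cells miss neighbours
    outside the segmented tissue) but still count as neighbours of interior
    centres. Classes with no central pulse are flagged with NaN.
    """
    if n_iter < 2:
        raise ValidationError("need at least two null iterations")
    labels = pulses["class_label"].to_numpy(dtype=object)
    boundary = {cid for cid, c in dataset.cells.items() if c.is_boundary}

    emp_counts = neighbor_pulse_counts(pulses, dataset, half_window)
    emp_central = np.array([str(c) not in boundary for c in pulses["cell_id"]])
    if not emp_central.any():
        raise ValidationError("no central pulses: all pulses lie on boundary cells")
    empirical = _class_means(emp_counts, labels, emp_central, classes)

    rows = []
    for assign in randomize_pulses(dataset, pulses, n_iter, seed=seed, max_retries=max_retries):
        counts = neighbor_pulse_counts(pulses, dataset, half_window, assignments=assign)
        central = np.array([str(c) not in boundary for c in assign])
        rows.append(_class_means(counts, labels, central, classes))
    stats_df = pd.DataFrame(rows, columns=list(classes))

    null_mean = {c: float(stats_df[c].mean()) for c in classes}
    null_sd = {c: float(stats_df[c].std(ddof=1)) for c in classes}
    z = {}
    for c in classes:
        if np.isnan(empirical[c]) or not null_sd[c] > 0:
            z[c] = float("nan")
        else:
            z[c] = (empirical[c] - null_mean[c]) / null_sd[c]
    return RandomizationNull(
        classes=tuple(classes),
        empirical=empirical,
        null_mean=null_mean,
        null_sd=null_sd,
        z_scores=z,
        iteration_stats=stats_df,
        n_iter=n_iter,
        seed=seed,
    )


@dataclass
class ClassZComparison:
    class_a: str
    class_b: str
    mean_difference: float  # mean of (Z_a - Z_b) over subsamples
    t: float
    p: float
    n_subsamples: int


def compare_class_z(
    null: RandomizationNull,
    class_a: str,
    class_b: str,
    n_subsamples: int = 200,
    subsample_size: int = 500,
    seed: int | None = None,
) -> ClassZComparison:
    """Paired comparison of two classes' enrichment Z-scores.

    Z-scores are recomputed on subsamples (drawn without replacement) of the
    null iterations to estimate their sampling variance; a paired t-test
    across subsamples compares the classes.
    """
    if subsample_size > null.n_iter:
        raise ValidationError("subsample_size exceeds the number of null iterations")
    if n_subsamples < 2:
        raise ValidationError("need at least two subsamples for a paired test")
    for c in (class_a, class_b):
        if np.isnan(null.empirical[c]):
            raise ValidationError(f"class {c!r} has no Z-score")
    rng = np.random.default_rng(seed)
    a_stats = null.iteration_stats[class_a].to_numpy()
    b_stats = null.iteration_stats[class_b].to_numpy()
    za, zb = [], []
    for _ in range(n_subsamples):
        idx = rng.choice(null.n_iter, size=subsample_size, replace=False)
        za.append((null.empirical[class_a] - a_stats[idx].mean()) / a_stats[idx].std(ddof=1))
        zb.append((null.empirical[class_b] - b_stats[idx].mean()) / b_stats[idx].std(ddof=1))
    res = stats.ttest_rel(za, zb)
    return ClassZComparison(
        class_a=class_a,
        class_b=class_b,
        mean_difference=float(np.mean(np.asarray(za) - np.asarray(zb))),
        t=float(res.statistic),
        p=float(res.pvalue),
        n_subsamples=n_subsamples,
    )


# --- correlation machinery ----------------------------------------------------------


@dataclass
class CorrelationResult:
    rho: float
    n: int
    method: str
    p: float | None = None
    sd: float | None = None
    flagged: bool = False


def partial_correlation(x, y, z, method: str = "closed_form") -> CorrelationResult:
    """Correlation of x and y with the linear influence of z removed.

    Equivalent definitions: the Pearson correlation of the residuals of the
    regressions x~z and y~z (``method="residuals"``), or the closed form
    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)). The p-value uses
    the Fisher transform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if not (len(y) == n == len(z)) or n < 4:
        raise ValidationError("x, y, z must have equal length >= 4")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.std(v) == 0:
            raise ValidationError(f"zero variance in {name}")

    if method == "closed_form":
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        denom = (1 - r_xz**2) * (1 - r_yz**2)
        if denom <= 1e-15:
            return CorrelationResult(
                rho=float(np.sign(r_xy) if r_xy else 0.0), n=n,
                method="partial", flagged=True,
            )
        rho = (r_xy - r_xz * r_yz) / math.sqrt(denom)
    elif method == "residuals":
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        if np.std(rx) == 0 or np.std(ry) == 0:
            return CorrelationResult(rho=0.0, n=n, method="partial", flagged=True)
        rho = float(np.corrcoef(rx, ry)[0, 1])
    else:
        raise ValueError(f"unknown method {method!r}")

    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) >= 1.0:
        return CorrelationResult(rho=rho, n=n, method="partial", p=0.0, flagged=True)
    z_fisher = math.atanh(rho) * math.sqrt(n - 3)
    p = 2 * stats.norm.sf(abs(z_fisher))
    return CorrelationResult(rho=rho, n=n, method="partial", p=float(p))


def _polyserial_nll(rho, x_std, level_idx, thresholds):
    s = math.sqrt(1.0 - rho * rho)
    upper = (thresholds[level_idx + 1] - rho * x_std) / s
    lower = (thresholds[level_idx] - rho * x_std) / s
    probs = stats.norm.cdf(upper) - stats.norm.cdf(lower)
    return -float(np.sum(np.log(np.clip(probs, 1e-300, None))))


def polyserial_correlation(x, y) -> CorrelationResult:
    """Two-step maximum-likelihood polyserial correlation.

    Models the ordinal y as a thresholded latent standard normal that is
    bivariate-normal with the continuous x. Thresholds are fixed at the
    standard-normal quantiles of the cumulative level frequencies and x is
    standardized by its sample moments; rho then maximizes the conditional
    likelihood over (-0.999, 0.999). The s.d. of rho comes from the observed
    information at the optimum (numerical second derivative).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n = len(x)
    if n != len(y) or n < 20:
        raise ValidationError("need paired samples with n >= 20")
    levels, level_idx = np.unique(y, return_inverse=True)
    if len(levels) < 2:
        raise ValidationError("ordinal variable is constant")
    if np.std(x) == 0:
        raise ValidationError("zero variance in x")
    cum = np.cumsum(np.bincount(level_idx)) / n
    thresholds = np.concatenate([[-np.inf], stats.norm.ppf(cum[:-1]), [np.inf]])
    x_std = (x - x.mean()) / x.std(ddof=1)

    res = optimize.minimize_scalar(
        _polyserial_nll,
        bounds=(-0.999, 0.999),
        args=(x_std, level_idx, thresholds),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    flagged = abs(rho) > 0.995

    h = 1e-4
    lo, hi = max(rho - h, -0.999), min(rho + h, 0.999)
    f0 = _polyserial_nll(rho, x_std, level_idx, thresholds)
    f_lo = _polyserial_nll(lo, x_std, level_idx, thresholds)
    f_hi = _polyserial_nll(hi, x_std, level_idx, thresholds)
    d2 = (f_hi - 2 * f0 + f_lo) / ((hi - rho) * (rho - lo))
    sd = 1.0 / math.sqrt(d2) if d2 > 0 else float("nan")
    return CorrelationResult(rho=rho, n=n, method="polyserial", sd=sd, flagged=flagged)


# --- neighbour-competition analysis -------------------------------------------------


@dataclass
class CompetitionResult:
    strata: dict            # amplitude_bin -> {n, polyserial, by_count}
    pooled_partial: CorrelationResult | None
    skipped: list = field(default_factory=list)


def competition_analysis(
    pulses: pd.DataFrame,
    dataset: EmbryoDataset,
    classes: tuple | None = None,
    bins: tuple | None = None,
    half_window: float = 15.0,
    min_stratum: int = 5,
) -> CompetitionResult:
    """Does a pulse constrict worse (competition) or better (cooperation)
    when its neighbours also pulse?

    Within each amplitude-bin stratum (optionally restricted to given
    behaviour classes), pairs the maximum constriction rate with the
    neighbour-pulse count: per-stratum means by neighbour count and a
    polyserial correlation; pooled across strata, a partial correlation of
    rate vs neighbour count controlling for amplitude bin.
    """
    required = {"amplitude_bin", "max_constriction_rate"}
    missing = required - set(pulses.columns)
    if missing:
        raise ValidationError(f"pulses table lacks columns {sorted(missing)}")
    df = pulses.copy()
    df["n_neighbor_pulses"] = neighbor_pulse_counts(df, dataset, half_window)
    if classes is not None:
        df = df[df["class_label"].isin(classes)]
    if bins is not None:
        df = df[df["amplitude_bin"].isin(bins)]
    df = df.dropna(subset=["amplitude_bin", "max_constriction_rate"])

    strata, skipped = {}, []
    for b, grp in df.groupby("amplitude_bin"):
        if len(grp) < min_stratum:
            skipped.append((b, f"only {len(grp)} pulses"))
            continue
        by_count = (
            grp.groupby("n_neighbor_pulses")["max_constriction_rate"]
            .agg(["mean", "std", "count"])
        )
        try:
            rho = polyserial_correlation(
                grp["max_constriction_rate"].to_numpy(),
                grp["n_neighbor_pulses"].to_numpy(),
            )
        except ValidationError as err:
            skipped.append((b, str(err)))
            rho = None
        strata[b] = {"n": len(grp), "polyserial": rho, "by_count": by_count}

    pooled = None
    if len(df) >= 4 and df["amplitude_bin"].nunique() >= 1:
        try:
            pooled = partial_correlation(
                df["max_constriction_rate"].to_numpy(dtype=float),
                df["n_neighbor_pulses"].to_numpy(dtype=float),
                df["amplitude_bin"].to_numpy(dtype=float),
            )
        except ValidationError as err:
            skipped.append(("pooled", str(err)))
    return CompetitionResult(strata=strata, pooled_partial=pooled, skipped=skipped)
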