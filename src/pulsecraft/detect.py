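"""Pulse detection by iterative multi-Gaussian fitting over an exponential background.

The myosin-intensity trace of a cell is modelled as

    y(t) = offset + scale * exp(rate * t) + sum_i  a_i * exp(-(t - mu_i)^2 / (2 sigma_i^2))

where the exponential term captures the developmental ramp of apical myosin
and each Gaussian component is one contractile pulse. Models with an
increasing number of Gaussians are fitted by bounded nonlinear least squares;
an F test on the reduced residuals (alpha = 0.01) decides when adding a
component stops improving the fit, and the retained model is finally tested
against the background-only model so that pulse-free traces return no pulses.

Pulse duration is constrained by bounding sigma to [10, 30] s; amplitudes and
the background scale/rate are non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import Pulse, ValidationError

SIGMA_BOUNDS = (10.0, 30.0)
RATE_MAX = 0.05  # 1/s; generous cap on the background growth rate


@dataclass
class GaussianComponent:
    amplitude: float  # a.u., > 0
    mu: float         # s
    sigma: float      # s, within SIGMA_BOUNDS


@dataclass
class BackgroundModel:
    """offset + scale * exp(rate * t), non-decreasing for scale, rate >= 0."""

    offset: float
    scale: float
    rate: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.offset + self.scale * np.exp(self.rate * np.asarray(t, float))


@dataclass
class FitResult:
    components: list[GaussianComponent]
    background: BackgroundModel
    rss: float
    df: int
    n_samples: int
    converged: bool = True

    @property
    def n_gaussians(self) -> int:
        return len(self.components)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = self.background(t)
        for c in self.components:
            y = y + c.amplitude * np.exp(-((t - c.mu) ** 2) / (2 * c.sigma**2))
        return y


def _pack(background: BackgroundModel, components, t0: float) -> np.ndarray:
    # internal parametrization anchors the exponential at the trace start to
    # keep the optimizer well-scaled; converted back on unpacking
    params = [background.offset, background.scale * np.exp(background.rate * t0), background.rate]
    for c in components:
        params.extend([c.amplitude, c.mu, c.sigma])
    return np.array(params, dtype=float)


def _unpack(params: np.ndarray, t0: float) -> tuple[BackgroundModel, list[GaussianComponent]]:
    offset, scale0, rate = params[:3]
    background = BackgroundModel(
        offset=float(offset), scale=float(scale0 * np.exp(-rate * t0)), rate=float(rate)
    )
    comps = [
        GaussianComponent(float(params[i]), float(params[i + 1]), float(params[i + 2]))
        for i in range(3, len(params), 3)
    ]
    return background, comps


def _model(params: np.ndarray, t: np.ndarray, t0: float) -> np.ndarray:
    offset, scale0, rate = params[:3]
    y = offset + scale0 * np.exp(rate * (t - t0))
    for i in range(3, len(params), 3):
        a, mu, sigma = params[i : i + 3]
        y = y + a * np.exp(-((t - mu) ** 2) / (2 * sigma**2))
    return y


def fit_model(
    times: np.ndarray,
    values: np.ndarray,
    n_gaussians: int,
    init: FitResult | None = None,
    max_nfev: int = 4000,
) -> FitResult:
    """Bounded least-squares fit of the n-Gaussian-plus-background model.

    Missing samples (NaN) are excluded from the objective. Deterministic for
    a given ``init``; with ``init=None`` a fixed heuristic start is used.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values)
    t, y = times[keep], values[keep]
    n = len(t)
    if n < 3 * n_gaussians + 4:
        raise ValidationError(
            f"trace has {n} samples; need >= {3 * n_gaussians + 4} for "
            f"{n_gaussians} Gaussians"
        )
    t0, t1 = float(t[0]), float(t[-1])

    if init is not None:
        x0 = _pack(init.background, init.components[:n_gaussians], t0)
    else:
        offset0 = max(float(np.percentile(y, 5)), 0.0)
        scale0 = max(float(np.median(y[-max(3, n // 10):]) - offset0), 1e-6)
        x0 = np.array([offset0, scale0, 1e-3])
    while (len(x0) - 3) // 3 < n_gaussians:
        resid = y - _model(x0, t, t0)
        j = int(np.argmax(resid))
        x0 = np.concatenate([x0, [max(resid[j], 1e-6), t[j], 15.0]])

    lo = [0.0, 0.0, 0.0] + [0.0, t0, SIGMA_BOUNDS[0]] * n_gaussians
    hi = [np.inf, np.inf, RATE_MAX] + [np.inf, t1, SIGMA_BOUNDS[1]] * n_gaussians
    x0 = np.clip(x0, lo, hi)

    res = optimize.least_squares(
        lambda p: _model(p, t, t0) - y,
        x0,
        bounds=(lo, hi),
        method="trf",
        max_nfev=max_nfev,
    )
    if res.status <= 0:
        warnings.warn("pulse-model optimizer did not converge", RuntimeWarning)
    background, comps = _unpack(res.x, t0)
    rss = float(np.sum(res.fun**2))
    df = n - (3 * n_gaussians + 3)
    return FitResult(
        components=comps,
        background=background,
        rss=rss,
        df=df,
        n_samples=n,
        converged=res.status > 0,
    )


def f_test_accept(fit_small: FitResult, fit_large: FitResult, alpha: float = 0.01) -> bool:
    """Accept the larger (more-Gaussian) model iff its reduced RSS is
    significantly smaller: F = (rss_s/df_s) / (rss_l/df_l) above the upper-alpha
    quantile of F(df_s, df_l)."""
    if fit_small.df <= 0 or fit_large.df <= 0:
        raise ValidationError("non-positive residual degrees of freedom")
    if fit_large.rss > fit_small.rss:
        warnings.warn(
            "nested larger model fit worse than smaller model (optimizer issue); "
            "rejecting larger model",
            RuntimeWarning,
        )
        return False
    if fit_large.rss == 0.0:
        return fit_small.rss > 0.0
    f_stat = (fit_small.rss / fit_small.df) / (fit_large.rss / fit_large.df)
    crit = stats.f.ppf(1.0 - alpha, fit_small.df, fit_large.df)
    return bool(f_stat > crit)


@dataclass
class DetectionReport:
    n_accepted: int
    rss_path: list[float]
    decisions: list[str] = field(default_factory=list)


def detect_pulses(
    times: np.ndarray,
    values: np.ndarray,
    cell_id: str = "cell",
    embryo_id: str = "embryo",
    alpha: float = 0.01,
    max_components: int = 8,
    min_amplitude: float = 1e-9,
) -> tuple[list[Pulse], FitResult, DetectionReport]:
    """Detect pulses in one myosin trace.

    Fits models with n = 1, 2, ... Gaussians (warm-started from the n-1 fit
    with the new component seeded at the largest positive residual), stopping
    when the F test rejects n+1 vs n; the retained model must then beat the
    background-only model by the same test, otherwise no pulses are reported.
    """
    fit_bg = fit_model(times, values, 0)
    rss_path = [fit_bg.rss]
    decisions: list[str] = []

    fits = [fit_bg]
    prev = fit_bg
    retained_n = 0
    for n in range(1, max_components + 1):
        try:
            fit_n = fit_model(times, values, n, init=prev)
        except ValidationError:
            decisions.append(f"n={n}: too few samples, stop")
            break
        if fit_n.rss > prev.rss:  # warm start should prevent this; keep best
            fit_n = prev if n > 1 else fit_n
        fits.append(fit_n)
        rss_path.append(fit_n.rss)
        if n == 1:
            prev, retained_n = fit_n, 1
            continue
        if f_test_accept(fits[n - 1], fit_n, alpha=alpha):
            decisions.append(f"n={n} vs n={n-1}: accepted")
            prev, retained_n = fit_n, n
        else:
            decisions.append(f"n={n} vs n={n-1}: rejected, stop")
            break

    best = fits[retained_n] if retained_n > 0 else fit_bg
    if retained_n == 0 or not f_test_accept(fit_bg, best, alpha=alpha):
        decisions.append("retained model not better than background-only")
        return [], fit_bg, DetectionReport(0, rss_path, decisions)
    decisions.append(f"retained n={retained_n} over background-only")

    pulses = []
    for i, comp in enumerate(sorted(best.components, key=lambda c: c.mu)):
        if comp.amplitude <= min_amplitude:
            continue
        pulses.append(
            Pulse(
                pulse_id=f"{cell_id}:p{i}",
                cell_id=cell_id,
                embryo_id=embryo_id,
                amplitude=comp.amplitude,
                center=comp.mu,
                width=float(np.clip(comp.sigma, *SIGMA_BOUNDS)),
            )
        )
    return pulses, best, DetectionReport(len(pulses), rss_path, decisions)


def detect_pulses_dataset(dataset, alpha: float = 0.01, max_components: int = 8):
    """Run :func:`detect_pulses` on every cell; returns (pulses table, reports)."""
    all_pulses, reports = [], {}
    for track in dataset:
        pulses, _, report = detect_pulses(
            track.times,
            track.myosin,
            cell_id=track.cell_id,
            embryo_id=track.embryo_id,
            alpha=alpha,
            max_components=max_components,
        )
        all_pulses.extend(pulses)
        reports[track.cell_id] = report
    from .datatypes import pulses_to_frame

    return pulses_to_frame(all_pulses), reports


# --- curation against manual tracks -------------------------------------------------


@dataclass
class CurationResult:
    counts: dict[str, int]
    mapping: list[dict]

    def total(self) -> int:
        return sum(self.counts.values())


def pulse_frame_support(pulse: Pulse, frame_interval: float, t_origin: float = 0.0) -> tuple[int, int]:
    """Frame range covered by a pulse: center +/- 2 sigma, rounded to frames."""
    first = int(round((pulse.center - 2 * pulse.width - t_origin) / frame_interval))
    last = int(round((pulse.center + 2 * pulse.width - t_origin) / frame_interval))
    return first, last


def curate_pulses(
    detected: list[Pulse],
    manual: pd.DataFrame,
    frame_interval: float,
    known_cells: set | None = None,
    t_origin: float = 0.0,
    min_overlap: int = 2,
) -> CurationResult:
    """Map detected pulses onto manual tracks and categorize agreement.

    Builds the bipartite overlap graph (an edge whenever a detected pulse's
    frame support and a manual track overlap by more than ``min_overlap``
    frames, within the same cell) and classifies each connected component:
    1-1 -> one_to_one; unmatched manual -> missed_by_fitting; unmatched
    detected -> added_by_fitting; 1 manual to k>1 detected -> split_by_fitting;
    k>1 manual to 1 detected -> merged_by_fitting; anything with several of
    both sides -> ambiguous (flagged for review).
    """
    if known_cells is not None:
        unknown = set(manual["cell_id"].astype(str)) - set(map(str, known_cells))
        if unknown:
            raise ValidationError(f"manual tracks reference unknown cells: {sorted(unknown)}")

    g = nx.Graph()
    det_nodes, man_nodes = [], []
    for i, p in enumerate(detected):
        node = ("det", i)
        first, last = pulse_frame_support(p, frame_interval, t_origin)
        g.add_node(node, cell=p.cell_id, first=first, last=last)
        det_nodes.append(node)
    for j, row in manual.reset_index(drop=True).iterrows():
        node = ("man", j)
        g.add_node(node, cell=str(row["cell_id"]), first=int(row["first_frame"]), last=int(row["last_frame"]))
        man_nodes.append(node)

    for d in det_nodes:
        for m in man_nodes:
            if g.nodes[d]["cell"] != g.nodes[m]["cell"]:
                continue
            overlap = (
                min(g.nodes[d]["last"], g.nodes[m]["last"])
                - max(g.nodes[d]["first"], g.nodes[m]["first"])
                + 1
            )
            if overlap > min_overlap:
                g.add_edge(d, m)

    counts = {
        "one_to_one": 0,
        "missed_by_fitting": 0,
        "added_by_fitting": 0,
        "split_by_fitting": 0,
        "merged_by_fitting": 0,
        "ambiguous": 0,
    }
    mapping = []
    for comp in nx.connected_components(g):
        dets = sorted(i for kind, i in comp if kind == "det")
        mans = sorted(j for kind, j in comp if kind == "man")
        if len(dets) == 1 and len(mans) == 1:
            cat = "one_to_one"
        elif len(dets) == 0:
            cat = "missed_by_fitting"
        elif len(mans) == 0:
            cat = "added_by_fitting"
        elif len(mans) == 1:
            cat = "split_by_fitting"
        elif len(dets) == 1:
            cat = "merged_by_fitting"
        else:
            cat = "ambiguous"
        counts[cat] += 1
        mapping.append({"detected": dets, "manual": mans, "category": cat})
        for i in dets:
            detected[i].curation_status = cat if cat != "ambiguous" else "unreviewed"
    return CurationResult(counts=counts, mapping=mapping)
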