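"""Synthetic pulsing-epithelium generator.

Emits per-cell time series with known ground truth so that every analysis
stage is testable without live-imaging data. Cells sit on a hexagonal
lattice (interior connectivity 6); each cell's myosin trace is an
exponential background ramp plus Gaussian pulses whose period shortens and
whose amplitude grows over developmental time; each pulse carries one of
three behaviour classes that determines its additive area-response template
(ratcheted: persistent step-down; unratcheted: transient dip that recovers;
unconstricting: no area change). A pulse can optionally trigger a pulse in
a random neighbour cell within +/-15 s (neighbour coupling), and ratcheted
pulses deposit a slowly decaying myosin plateau so persistence analyses
have signal.

Two presets encode the studied conditions: the wild-type programme (85 s
baseline period shortening by 8 s per minute; 15% ratcheted pulses before
t = 0 rising to 65% after) and the Twist-depleted programme (95 s period
shortening by only 2 s per minute; time-invariant class mixture). Area
dynamics are additive templates on a tissue-contraction ramp whose mean
apical area crosses 40 μm² at t = 0 — not a mechanical model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CellTrack, EmbryoDataset, ValidationError


@dataclass
class SynthConfig:
    """Generator parameters; defaults are the wild-type programme."""

    rows: int = 10
    cols: int = 10
    spacing: float = 7.0            # μm between lattice centroids
    periodic: bool = False          # wrap the lattice (uniform connectivity 6)
    frame_interval: float = 6.0     # s; must resolve sigma >= 10 s pulses
    duration: float = 900.0         # s of movie
    t_zero_frac: float = 0.5        # position of t=0 in the movie

    # myosin background: offset + scale * exp(rate * raw_time)
    background_offset: float = 5.0
    background_scale: float = 2.0
    background_rate: float = 0.0025  # 1/s

    # pulse programme
    baseline_period: float = 85.0    # s, before t=0
    period_slope: float = -8.0       # s per minute after t=0
    min_period: float = 40.0
    interval_shape: float = 3.0      # gamma shape of inter-pulse intervals (CV ~ 0.6)
    amp_base: float = 40.0           # a.u. at t=0
    amp_trend: float = 4.0           # a.u. per minute of developmental time
    amp_min: float = 8.0
    amp_noise: float = 0.25          # lognormal sigma on amplitudes
    sigma_range: tuple = (11.0, 25.0)

    # class programme: (ratcheted, unratcheted, unconstricting)
    class_probs_before: tuple = (0.15, 0.45, 0.40)
    class_probs_after: tuple = (0.65, 0.20, 0.15)

    # area programme: cells start near the end-of-cellularization area (~44 μm²)
    # and net tissue contraction is produced mostly by the accumulation of
    # ratcheted step-downs; the base ramp slope is solved at generation time
    # so the population mean apical area crosses 40 μm² at t = 0.
    area_initial: float = 44.0       # μm² pre-contraction plateau
    area_floor: float = 12.0
    onset_time: float = -100.0       # s, onset of the base contraction ramp
    area_sd_between_cells: float = 1.5
    response_per_amp: float = 0.12   # μm² of response per a.u. of amplitude
    response_timescale: float = 10.0
    # amplitude multiplier per class (unconstricting pulses are weak)
    class_amp_factor: dict = field(
        default_factory=lambda: {"ratcheted": 1.1, "unratcheted": 0.95, "unconstricting": 0.6}
    )

    # ratcheted myosin persistence plateau
    plateau_frac: float = 0.3
    plateau_decay: float = 200.0     # s

    # neighbour coupling: class -> probability of triggering a neighbour pulse
    coupling: dict = field(default_factory=dict)
    coupling_window: float = 15.0

    # measurement noise (segmentation jitter on areas is substantial in practice)
    myosin_noise: float = 1.0
    area_noise: float = 0.8

    def validate(self) -> None:
        if self.frame_interval > 10.0:
            raise ValidationError("frame_interval must be <= 10 s to resolve pulses")
        for probs in (self.class_probs_before, self.class_probs_after):
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValidationError("class probabilities must be a distribution")
        for p in self.coupling.values():
            if not 0.0 <= p <= 1.0:
                raise ValidationError("coupling probabilities must be in [0, 1]")
        if self.baseline_period <= 0 or self.min_period <= 0:
            raise ValidationError("periods must be positive")

    @classmethod
    def wild_type(cls, **overrides) -> "SynthConfig":
        return cls(**overrides)

    @classmethod
    def twi_rnai(cls, **overrides) -> "SynthConfig":
        params = dict(
            baseline_period=95.0,
            period_slope=-2.0,
            class_probs_before=(0.30, 0.45, 0.25),
            class_probs_after=(0.30, 0.45, 0.25),
            amp_trend=0.0,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class GroundTruth:
    pulses: pd.DataFrame       # cell_id, center (aligned s), amplitude, sigma, class, triggered_by
    t_zero_raw: float          # raw-clock time of t=0
    adjacency: dict            # cell_id -> neighbour list
    boundary: set
    coupling_events: list      # (source pulse row, target pulse row)


CLASSES = ("ratcheted", "unratcheted", "unconstricting")


def hex_lattice(rows: int, cols: int, spacing: float, periodic: bool = False):
    """Hexagonal lattice ("odd-r" offset rows): centroids, adjacency, boundary set.

    Interior cells have exactly six neighbours; with ``periodic`` the lattice
    wraps in both directions so every cell has connectivity 6 and the
    boundary set is empty.
    """
    centroids: dict[str, tuple[float, float]] = {}
    for r in range(rows):
        for c in range(cols):
            x = spacing * (c + 0.5 * (r % 2))
            y = spacing * (math.sqrt(3) / 2) * r
            centroids[f"c{r}_{c}"] = (x, y)

    even_offsets = [(0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0)]
    odd_offsets = [(0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1)]
    adjacency: dict[str, list] = {}
    for r in range(rows):
        for c in range(cols):
            nbrs = []
            for dr, dc in (odd_offsets if r % 2 else even_offsets):
                rr, cc = r + dr, c + dc
                if periodic:
                    rr, cc = rr % rows, cc % cols
                if 0 <= rr < rows and 0 <= cc < cols:
                    nbrs.append(f"c{rr}_{cc}")
            adjacency[f"c{r}_{c}"] = sorted(set(nbrs))
    boundary = set() if periodic else {
        cid for cid, nbrs in adjacency.items() if len(nbrs) < 6
    }
    return centroids, adjacency, boundary


def _period_at(tau: float, cfg: SynthConfig) -> float:
    if tau < 0:
        return cfg.baseline_period
    return max(cfg.min_period, cfg.baseline_period + cfg.period_slope * tau / 60.0)


def _draw_class(tau: float, cfg: SynthConfig, rng) -> str:
    probs = cfg.class_probs_before if tau < 0 else cfg.class_probs_after
    return CLASSES[rng.choice(3, p=probs)]


def _draw_amplitude(tau: float, cfg: SynthConfig, rng) -> float:
    mean = max(cfg.amp_min, cfg.amp_base + cfg.amp_trend * tau / 60.0)
    return mean * float(rng.lognormal(0.0, cfg.amp_noise))


def generate_embryo(
    config: SynthConfig | None = None,
    seed: int | None = None,
    embryo_id: str = "synthetic",
    genotype: str = "wild_type",
) -> tuple[EmbryoDataset, GroundTruth]:
    """Generate one synthetic embryo plus its ground truth.

    Times in the emitted dataset run on a raw movie clock starting at zero;
    the aligned-time origin (mean apical area crossing 40 μm²) sits at
    ``t_zero_frac * duration`` and is recorded in the ground truth so that
    alignment can be exercised and verified. Fully reproducible from the seed.
    """
    cfg = config or SynthConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    centroids, adjacency, boundary = hex_lattice(cfg.rows, cfg.cols, cfg.spacing, cfg.periodic)
    t_zero = cfg.t_zero_frac * cfg.duration
    raw_times = np.arange(0.0, cfg.duration + 1e-9, cfg.frame_interval)
    tau_grid = raw_times - t_zero  # aligned time per frame
    tau_min, tau_max = tau_grid[0], tau_grid[-1]

    # --- schedule pulses per cell (gamma renewal with time-varying mean period)
    pulse_rows: list[dict] = []
    for cid in centroids:
        tau = tau_min + float(rng.uniform(0.0, _period_at(tau_min, cfg)))
        while tau <= tau_max:
            if tau - 2 * cfg.sigma_range[0] > tau_min:  # keep pulse inside the movie
                pulse_rows.append(_make_pulse(cid, tau, cfg, rng, triggered_by=None))
            mean_period = _period_at(tau, cfg)
            shape = cfg.interval_shape
            tau += float(rng.gamma(shape, mean_period / shape))

    # --- neighbour coupling
    coupling_events = []
    if cfg.coupling:
        for i, row in enumerate(list(pulse_rows)):
            p = cfg.coupling.get(row["class_label"], 0.0)
            if p > 0 and rng.random() < p:
                nbrs = adjacency[row["cell_id"]]
                if not nbrs:
                    continue
                target = nbrs[int(rng.integers(len(nbrs)))]
                offset = float(rng.uniform(-cfg.coupling_window, cfg.coupling_window))
                tau_t = row["center"] + offset
                if not (tau_min + 2 * cfg.sigma_range[0] < tau_t < tau_max):
                    continue
                new = _make_pulse(target, tau_t, cfg, rng, triggered_by=i)
                pulse_rows.append(new)
                coupling_events.append((i, len(pulse_rows) - 1))

    truth = pd.DataFrame(pulse_rows)
    if len(truth):
        truth = truth.sort_values(["cell_id", "center"], kind="stable").reset_index(drop=True)
        truth["pulse_id"] = [f"t{i}" for i in range(len(truth))]

    # --- render per-cell traces
    # base-ramp slope solved so the mean area (base minus the expected
    # accumulated ratcheted step-downs) crosses 40 μm² at tau = 0
    drawdown = _expected_ratchet_drawdown(tau_grid, cfg)
    drawdown0 = float(np.interp(0.0, tau_grid, drawdown))
    base_slope = max(0.0, (cfg.area_initial - 40.0 - drawdown0) / (0.0 - cfg.onset_time))
    cells: dict[str, CellTrack] = {}
    for cid, (cx, cy) in centroids.items():
        sub = truth[truth["cell_id"] == cid] if len(truth) else truth
        myosin = cfg.background_offset + cfg.background_scale * np.exp(
            cfg.background_rate * raw_times
        )
        a0 = cfg.area_initial + float(rng.normal(0.0, cfg.area_sd_between_cells))
        area = _area_base(tau_grid, a0, base_slope, cfg)
        for _, p in sub.iterrows():
            myosin = myosin + p["amplitude"] * np.exp(
                -((tau_grid - p["center"]) ** 2) / (2 * p["sigma"] ** 2)
            )
            if p["class_label"] == "ratcheted":
                after = tau_grid > p["center"]
                myosin[after] += (
                    cfg.plateau_frac
                    * p["amplitude"]
                    * np.exp(-(tau_grid[after] - p["center"]) / cfg.plateau_decay)
                )
            area = area + _response_template(
                tau_grid, p["center"], p["class_label"], p["amplitude"], cfg
            )
        if cfg.myosin_noise > 0:
            myosin = myosin + rng.normal(0.0, cfg.myosin_noise, len(raw_times))
        if cfg.area_noise > 0:
            area = area + rng.normal(0.0, cfg.area_noise, len(raw_times))
        myosin = np.clip(myosin, 0.0, None)
        area = np.clip(area, 1.0, None)
        cells[cid] = CellTrack(
            cell_id=cid,
            embryo_id=embryo_id,
            times=raw_times.copy(),
            myosin=myosin,
            area=area,
            centroid=np.tile([cx, cy], (len(raw_times), 1)),
            neighbors=list(adjacency[cid]),
            is_boundary=cid in boundary,
        )

    dataset = EmbryoDataset(
        embryo_id=embryo_id,
        cells=cells,
        genotype=genotype,
        frame_interval=cfg.frame_interval,
    )
    ground_truth = GroundTruth(
        pulses=truth,
        t_zero_raw=t_zero,
        adjacency=adjacency,
        boundary=boundary,
        coupling_events=coupling_events,
    )
    return dataset, ground_truth


def _make_pulse(cid, tau, cfg, rng, triggered_by) -> dict:
    label = _draw_class(tau, cfg, rng)
    return {
        "cell_id": cid,
        "center": float(tau),
        "amplitude": _draw_amplitude(tau, cfg, rng) * cfg.class_amp_factor.get(label, 1.0),
        "sigma": float(rng.uniform(*cfg.sigma_range)),
        "class_label": label,
        "triggered_by": triggered_by,
    }


def _area_base(tau: np.ndarray, a0: float, slope: float, cfg: SynthConfig) -> np.ndarray:
    """Shallow base ramp: plateau at a0, then linear decline after onset,
    clipped at the floor. Most of the net contraction comes from the
    accumulated ratcheted pulse responses, not from this ramp."""
    out = np.full_like(tau, a0, dtype=float)
    after = tau >= cfg.onset_time
    out[after] = a0 - slope * (tau[after] - cfg.onset_time)
    return np.clip(out, cfg.area_floor, None)


def _expected_ratchet_drawdown(tau_grid: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Expected area offset from pulse responses: the accumulated ratcheted
    step-downs plus the stationary occupancy of unratcheted dips."""
    dt = np.gradient(tau_grid)
    cum_rate = np.empty_like(tau_grid)
    dip_occ = np.empty_like(tau_grid)
    depth = np.empty_like(tau_grid)
    lognorm = math.exp(cfg.amp_noise**2 / 2.0)
    f_r = cfg.class_amp_factor.get("ratcheted", 1.0)
    f_u = cfg.class_amp_factor.get("unratcheted", 1.0)
    dip_mass = math.sqrt(2 * math.pi) * 1.5 * cfg.response_timescale  # s, area of the dip
    for i, tau in enumerate(tau_grid):
        p_r, p_u, _ = cfg.class_probs_before if tau < 0 else cfg.class_probs_after
        period = _period_at(tau, cfg)
        mean_amp = max(cfg.amp_min, cfg.amp_base + cfg.amp_trend * tau / 60.0)
        depth[i] = cfg.response_per_amp * mean_amp * lognorm
        cum_rate[i] = p_r * f_r / period
        dip_occ[i] = p_u * f_u * depth[i] * dip_mass / period
    return np.cumsum(cum_rate * depth * dt) + dip_occ


def _response_template(tau, center, class_label, amplitude, cfg) -> np.ndarray:
    """Additive area response of one pulse (μm², scaled by pulse amplitude)."""
    depth = cfg.response_per_amp * amplitude
    s = cfg.response_timescale
    rel = tau - center
    if class_label == "ratcheted":
        return -depth / (1.0 + np.exp(-rel / s))          # lasting step-down
    if class_label == "unratcheted":
        return -depth * np.exp(-(rel**2) / (2 * (1.5 * s) ** 2))  # dip, full recovery
    return np.zeros_like(tau)                              # unconstricting


def generate_manual_tracks(
    truth: GroundTruth,
    frame_interval: float,
    jitter: int = 0,
    drop_rate: float = 0.0,
    add_rate: float = 0.0,
    seed: int | None = None,
    n_frames: int | None = None,
) -> pd.DataFrame:
    """Emulate manually tracked pulses from the ground truth.

    True pulses become frame ranges (centre +/- 2 sigma on the raw clock),
    optionally jittered by up to ``jitter`` frames, dropped with
    ``drop_rate``, and supplemented by spurious tracks with ``add_rate`` —
    enough structure to exercise all curation categories.
    """
    if not (0.0 <= drop_rate < 1.0 and 0.0 <= add_rate < 1.0):
        raise ValidationError("drop_rate and add_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for _, p in truth.pulses.iterrows():
        if rng.random() < drop_rate:
            continue
        raw_center = p["center"] + truth.t_zero_raw
        first = int(round((raw_center - 2 * p["sigma"]) / frame_interval))
        last = int(round((raw_center + 2 * p["sigma"]) / frame_interval))
        if jitter:
            first += int(rng.integers(-jitter, jitter + 1))
            last += int(rng.integers(-jitter, jitter + 1))
            if last < first:
                first, last = last, first
        rows.append({"track_id": f"m{k}", "cell_id": p["cell_id"],
                     "first_frame": first, "last_frame": last})
        k += 1
        if rng.random() < add_rate:
            span = last - first
            shift = int(rng.integers(3 * span, 6 * span + 1))
            rows.append({"track_id": f"m{k}", "cell_id": p["cell_id"],
                         "first_frame": first + shift, "last_frame": last + shift})
            k += 1
    return pd.DataFrame(rows, columns=["track_id", "cell_id", "first_frame", "last_frame"])


# --- fixtures for clustering / point-process tests ----------------------------------


def response_templates(rel_times: np.ndarray) -> dict[str, np.ndarray]:
    """The three canonical area-response shapes on a relative-time grid.

    Non-flat templates are scaled to unit sample s.d.; the unconstricting
    template is identically zero.
    """
    step = -1.0 / (1.0 + np.exp(-rel_times / 8.0))
    dip = -np.exp(-(rel_times**2) / (2 * 15.0**2))
    out = {}
    for name, tmpl in (("ratcheted", step), ("unratcheted", dip)):
        out[name] = (tmpl - 0.0) / np.std(tmpl, ddof=1)
    out["unconstricting"] = np.zeros_like(rel_times)
    return out


def synthesize_response_matrix(
    n: int = 600,
    noise_sd: float = 0.2,
    interval: float = 3.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic area-response matrix from the three behaviour templates.

    ``n`` windows are split evenly over the templates (step-down,
    dip-and-recover, flat) on the standard [-30, +45] s grid; i.i.d. Gaussian
    noise of s.d. ``noise_sd`` (in template units, where the non-flat
    templates have unit s.d.) is added. Returns (matrix, labels, rel_times).
    """
    rng = np.random.default_rng(seed)
    rel = np.arange(-30.0, 45.0 + 1e-9, interval)
    templates = response_templates(rel)
    names = list(templates)
    counts = [n // 3] * 3
    counts[0] += n - sum(counts)
    rows, labels = [], []
    for name, c in zip(names, counts):
        block = templates[name][None, :] + rng.normal(0.0, noise_sd, (c, len(rel)))
        rows.append(block)
        labels.extend([name] * c)
    return np.vstack(rows), np.asarray(labels), rel


def poisson_pattern(
    n: int,
    width: float = 200.0,
    height: float = 200.0,
    duration: float = 1800.0,
    seed: int | None = None,
):
    """Homogeneous Poisson (CSR) spatiotemporal pattern in a box window."""
    from .spatial import PointPattern, Window

    rng = np.random.default_rng(seed)
    return PointPattern(
        x=rng.uniform(0.0, width, n),
        y=rng.uniform(0.0, height, n),
        t=rng.uniform(0.0, duration, n),
        window=Window.rectangle(0.0, width, 0.0, height, 0.0, duration),
    )
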