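# pulsecraft

Detection, classification and spatiotemporal statistics of **pulsed
actomyosin contractions** in epithelial cells, starting from per-cell time
series (apical myosin intensity, apical area, centroid, cell adjacency).

During tissue folding — the canonical example being ventral furrow
formation in the early *Drosophila* embryo — cells constrict their apical
surface through discrete myosin pulses. Whether a pulse actually deforms
the cell, and whether the constriction is then *ratcheted* (stabilized) or
relaxes again, determines how individual contractile events add up to
collective tissue shape change. `pulsecraft` provides the computational
framework for this kind of analysis:

* **Pulse detection** — iterative multi-Gaussian fitting of each cell's
  myosin trace over an exponential background,
  `y(t) = offset + scale·e^{rate·t} + Σ aᵢ·exp(−(t−μᵢ)²/2σᵢ²)` with
  σ ∈ [10, 30] s, using an F test on reduced residuals (α = 0.01) as the
  stopping rule; curation of detected pulses against manual tracks.
* **Per-pulse measurements** — within-embryo amplitude decile bins, the
  mean-centred area response on a standard window (−30 s, +45 s) around the
  pulse centre, myosin persistence
  `(I_min,after − I_min,before)/I_mean`, and the maximum constriction rate
  max(−dA/dt).
* **Behaviour classification** — fuzzy c-means (m = 2) on unit-s.d.
  normalized area responses, k = 3, with semantic labelling into
  *ratcheted*, *unratcheted* and *unconstricting* classes plus clustering
  diagnostics (distortion, silhouette, PCA variance, replicate Rand index).
* **Temporal statistics** — pulse-timing distributions by amplitude bin or
  class, Jensen–Shannon divergence `½KL(R‖M) + ½KL(Q‖M)`, the inter-pulse
  period trend over developmental time, and class-transition matrices.
* **Spatial statistics** — neighbour-pulse counts (±15 s in adjacent
  cells), the spatiotemporal pair correlation function g(η, τ) normalized
  so complete spatiotemporal randomness gives 1, a connectivity-preserving
  spatial randomization null with per-class enrichment Z-scores, and
  partial / polyserial correlations for the neighbour-competition analysis.
* **Synthetic data** — a seeded pulsing-epithelium generator (hexagonal
  lattice, period/amplitude/class programmes, optional neighbour coupling)
  with full ground truth, so every stage is testable without imaging data.

## Worked example

```python
from pulsecraft import (SynthConfig, generate_embryo, align_embryo,
                        detect_pulses, neighbor_enrichment, period_trend)

cfg = SynthConfig(rows=10, cols=10, duration=600.0,
                  coupling={"ratcheted": 0.5})
dataset, truth = generate_embryo(cfg, seed=7)

offset = align_embryo(dataset, mode="area_threshold", threshold=40.0)
print(f"alignment offset: {offset:.1f} s (truth: {truth.t_zero_raw:.1f} s)")
aligned = dataset.apply_alignment()

track = aligned.cells["c4_4"]
pulses, fit, report = detect_pulses(track.times, track.myosin)
print(f"cell c4_4: {len(pulses)} pulses accepted")
for p in pulses:
    print(f"  amplitude {p.amplitude:5.1f} a.u.  centre {p.center:6.1f} s"
          f"  sigma {p.width:4.1f} s")

trend = period_trend(truth.pulses)
print(f"period trend: {trend.slope_s_per_min:+.1f} s/min"
      f" (r = {trend.r:.3f}, n = {trend.n})")

null = neighbor_enrichment(truth.pulses, aligned, n_iter=200, seed=11)
for c in null.classes:
    print(f"Z({c}) = {null.z_scores[c]:+.2f}")
```

prints

```
alignment offset: 302.8 s (truth: 300.0 s)
cell c4_4: 1 pulses accepted
  amplitude  72.7 a.u.  centre   91.8 s  sigma 28.3 s
period trend: -4.1 s/min (r = -0.250, n = 820)
Z(ratcheted) = +4.49
Z(unratcheted) = -0.34
Z(unconstricting) = +0.80
```

Reading the output: the mean apical area of the synthetic embryo crosses
40 μm² within three seconds of the generator's true t = 0; the detector
accepts one high-confidence pulse on this crowded whole-movie trace (the
F-test stopping rule is deliberately conservative — see
`docs/methods.md` — and the curation workflow reconciles detections with
manual tracks); inter-pulse intervals shorten over developmental time
(negative slope, negative correlation); and because the generator couples
only ratcheted pulses to their neighbours, the ratcheted class shows strong
neighbour-pulse enrichment over the connectivity-preserving null
(Z ≈ +4.5) while the other classes do not.

## Command line

Each stage is also a CLI step writing machine-readable reports (tool
version, seed, config hash) next to its outputs:

```sh
pulsecraft simulate --config cfg.yaml --seed 1 --out out/sim
pulsecraft detect   --data out/sim/dataset --seed 1 --out out/det
pulsecraft classify --data out/sim/dataset --pulses out/det/pulses.csv \
                    --seed 1 --out out/cls
pulsecraft temporal --pulses out/cls/pulses.csv --seed 1 --out out/tmp
pulsecraft spatial  --data out/sim/dataset --pulses out/cls/pulses.csv \
                    --seed 1 --out out/spa
```

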