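# cargokin

Quantification of bidirectional microtubule-based cargo transport and
microtubule-coupled nuclear migration from time-lapse fluorescence
microscopy.

Intracellular cargoes such as peroxisomes coupled to both dynein–dynactin
and kinesin-1 through a bidirectional adaptor move in short processive
runs toward the microtubule minus or plus end, interspersed by pauses. The
same motor machinery, anchored to the nuclear envelope, drives nuclear
migration in developing neurons. `cargokin` implements the full
measurement chain for these systems, for cell biologists analysing
spinning-disk or confocal time-lapse recordings:

* **Spot tracking** — band-pass detection with sub-pixel centroids and
  Hungarian frame-to-frame linking (maximum step length, no gap closing).
* **Motility metrics** — net displacement vs. total travel, a geometric
  active-cargo filter (radial alignment within 45°, travel > 3 µm, cell
  edge excluded), radial intensity profiles, organelle size ratios.
* **Transport kinetics** — kymograph extraction, trajectory projection
  onto a microtubule path, deterministic segmentation into constant-
  velocity runs and pauses, per-direction velocity statistics, minus-run
  fraction with binomial CI, and shifted-exponential run-length fits.
* **Nucleus–microtubule coupling** — nuclear rotation duration,
  photoconverted microtubule-patch speed, normalized nucleus–microtubule
  distance change, EB3 comet polarity fractions.
* **Synthetic data** — a stochastic three-state (minus-run / plus-run /
  pause) motor-switching simulator with exact event times, plus image
  renderers, generating every test input with ground truth retained.

## Model

Runs in direction *d* ∈ {−, +} proceed at speed *v_d* and terminate with
rate *k*end,*d*, so run lengths are exponential with mean *v_d*/*k*end,*d*;
pauses end with rate *k*start,− + *k*start,+ and the next run is
minus-directed with probability *k*start,−/(*k*start,− + *k*start,+).
Observed run lengths are reported above a threshold *L*min (1 µm), hence
fitted as a shifted exponential P(X ≥ x) = exp(−(x − L*min)/µ) whose
maximum-likelihood mean is µ̂ = mean(x) − *L*min.

See `docs/methods.md` for the full model, parameter defaults, numerical
choices, and limitations.

## Worked example

Simulate bidirectional cargo at the default kinetics (1 µm/s in both
directions, 0.3 : 0.2 s⁻¹ initiation-rate bias), segment the traces into
runs, and summarize:

```python
import numpy as np
import cargokin as ck
from cargokin.kinetics import processive_runs

p = ck.MotorModelParams()          # 1 µm/s both ways, 60% minus bias
tracks = ck.simulate_cargo(p, n=24, duration=120.0, dt=0.1, seed=7)
segs = []
for tr in tracks:
    segs += ck.segment_runs(tr.s, ck.SegmentationParams(), dt=0.1)

runs = processive_runs(segs)
vs = ck.velocity_stats(segs, L_min=1.0)
f, ci = ck.fraction_minus(segs)
fit = ck.fit_runlength(
    np.array([r.length for r in runs if r.direction == "minus"]), L_min=1.0
)
```

This prints:

```
processive runs: 526
v_plus  = +0.99 ± 0.06 µm/s (n=212)
v_minus = -0.98 ± 0.06 µm/s (n=314)
minus-run fraction = 59.7% (95% CI 55.5-63.9%)
minus run length µ = 1.30 µm (95% CI 1.16-1.44)
```

The segmentation recovers the generating speeds (±1 µm/s) and the 60 %
minus-end bias; µ̂ is the mean run length *in excess of* the 1 µm
reporting threshold. The same functions accept trajectories tracked from
real TIFF stacks via `detect_spots` / `link_spots` or the CLI:

```sh
cargokin detect stack.tif --pixel-size 0.1 --out spots.csv
cargokin track spots.csv --dt 0.5 --out traj.csv
cargokin kinetics traj.csv --path mt_path.json --out runs.csv
cargokin pipeline stack.tif --geometry geometry.json --out results/
```

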