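# Methods

## Scope

`cargokin` quantifies bidirectional microtubule-based cargo transport and
microtubule-coupled nuclear migration from time-lapse fluorescence
microscopy. Because it is developed and validated against synthetic data,
the package pairs every analysis stage with a generator that produces
inputs with known ground truth: a stochastic motor-switching cargo
simulator, a nuclear-drift simulator, an EB3-comet polarity field, a
photoconverted-patch pair, and a disk-population renderer. All positions
and times at rest are micrometres and seconds; pixel and frame units exist
only at image I/O.

## The three-state cargo model

A cargo (e.g. a peroxisome coupled to dynein–dynactin–BicD2 and kinesin-1
through a bidirectional adaptor) moves along one microtubule axis with
positive direction toward the plus end. It occupies one of three states:

* **minus-run** — processive movement at −v_minus µm/s,
* **plus-run** — processive movement at +v_plus µm/s,
* **pause** — no directed motion, optional diffusion with coefficient
  d_pause µm²/s.

Dwell times are exponential. A pause ends with rate
k_start_minus + k_start_plus and the new run is minus-directed with
probability k_start_minus/(k_start_minus + k_start_plus); a run in
direction d ends with rate k_end_d. Direct reversals pass through the
pause state — transport that proceeds as short runs interspersed by pauses
or detachment is represented naturally, and a high pause-exit rate
approximates immediate reversal. Detachment is modelled as a diffusive
pause rather than a separate off-lattice state so the ground truth stays
one-dimensional.

Consequences used throughout the tests: run lengths in direction d are
exponential with mean v_d/k_end_d, and the long-run fraction of
minus-directed runs is k_start_minus/(k_start_minus + k_start_plus).

State changes are drawn with exact (Gillespie) event times and the
position is integrated piecewise before sampling on the acquisition grid,
so no statistic depends on the sampling interval dt. Velocity jitter
sigma_v is applied per sampling step as a Gaussian perturbation of the run
speed truncated at zero (a run never transiently reverses); localization
noise sigma_loc is added to the observed positions only, with the
noiseless series retained.

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| v_minus, v_plus | 1.0 | µm/s | bidirectional adaptor transport runs at ≈1 µm/s in both directions |
| k_start_minus : k_start_plus | 0.3 : 0.2 | s⁻¹ | yields the measured 60 % minus-end run bias |
| k_end_minus, k_end_plus | 0.5 | s⁻¹ | 2 µm mean run length, typical of intracellular processive runs |
| sigma_v | 0.1 | µm/s | broadens velocity histograms without moving the mean |
| d_pause | 0.005 | µm²/s | sub-diffusive wiggle of a tethered organelle |
| sigma_loc | 0.03 | µm | centroid precision of a bright spot at ~0.1 µm pixels |

The pause↔run rates are **illustrative**: no attachment/detachment rates
are measured for this system, so k_end and the absolute k_start magnitudes
are round numbers chosen to give realistic run statistics. The *ratio* of
the start rates and the speeds are pinned to measured values.

## Nuclear tracks

A migrating nucleus is modelled as a drifting anchor with tethered
fluctuation: position(t) = drift_speed·t·axis + ε(t), with ε isotropic
Gaussian (SD sigma_step per sample, independent between samples, zero at
t = 0). The fluctuation does not accumulate — a nucleus is held by the
cytoskeleton, not freely diffusing — so the expected net displacement
equals drift_speed × duration exactly, while per-interval displacements
show the frequent backward steps characteristic of nuclear migration. An
accumulating random walk was considered and rejected: the Euclidean norm
of a drift-plus-random-walk endpoint is biased upward by the walk variance
(a Rice-distribution mean), which misrepresents slow-migrating nuclei, and
unbounded diffusion is not physical for a tethered organelle. Defaults
(sigma_step 0.5 µm, dt 30 s, duration 1 h) match the recording protocol
the package targets.

## EB3 comets and photoconverted patches

EB3 comets travel at constant speed along radial filaments, outward unless
the filament's polarity is inverted (probability
`polarity_inverted_fraction`, default 0.1 to match the ~10 % inverted
microtubules of radially organized cells). A comet is classified outward
when the radial component of its net displacement at its starting point is
positive.

The photoconversion pair is two 1-D series on a common clock: the nucleus
front and the patch centroid, each drifting linearly with independent
Gaussian localization noise. Patch speed is |Δcentroid|/Δt over a window
conventionally 3–6 min after conversion (bounds configurable), reported in
µm/min; the nucleus–microtubule (NM) distance change over a window is
normalized to the initial distance, making it invariant to a common drift.

## Spot detection and linking

Detection is the classic band-pass recipe: Gaussian blur at the particle
scale (kernel_radius) minus blur at 3× that scale, candidate local maxima
above the (1 − intensity_percentile) quantile of the response, sub-pixel
refinement by the response-weighted centroid within kernel_radius, and a
score cutoff. The score is the response normalized to the frame's response
range — a monotone proxy for the non-particle discrimination score of
interactive tracking plugins, *not* numerically identical to any of them;
the default cutoff 0.01 keeps the conventional value. The intensity
percentile is interpreted as a fraction of brightest response pixels
(quantile from the top); this reading is flagged for sensitivity analysis
because plugin conventions differ.

Linking solves, per consecutive frame pair, the assignment minimizing
total squared displacement (`scipy.optimize.linear_sum_assignment`), with
links beyond max_step (default 7 µm) forbidden and an unlink alternative
at cost max_step² per particle, so a particle is left unlinked exactly
when that lowers the total cost. Link range is fixed at one frame: there
is no gap closing, and a blinking spot splits its trajectory by design.
Tests verify optimality against exhaustive enumeration on ≤6×6 instances.

Coordinates: origin at the top-left pixel centre, x rightward, y downward,
positions in µm (pixel index × pixel size), 0-based frames.

## Active-cargo filter

A trajectory counts as actively transported in a time window when (i) its
travel in the window exceeds d_min (default 3 µm, strict >; "travel" is
total path length by default, net displacement as an option), (ii) the
acute angle between its net-displacement vector and the *undirected*
radial axis through its first point is ≤ theta_max (default 45°; inward
and outward both qualify), and (iii) its mean position is farther than
edge_margin (default 1 µm) from the cell boundary, excluding the
polymerization-driven movements at the cell edge. Counts per window are
normalized to the first window (0–5 min by default). A per-step variant of
the angle criterion is available; the net-vector form is the default
because it gives a single well-defined angle per window.

## Radial profiles and size ratios

Radial profiles sum pixel intensities inside the boundary polygon by
distance from the cell centre in fixed-width bins; pixels beyond the last
edge fold into the final bin so the binned total equals the masked total
exactly (up to float summation order). Organelle size comparisons label
8-connected components and report the ratio of mean component areas in
µm². Rendered disk chains place centres at 0.98 × 2r spacing: exact
tangency cannot guarantee pixel-level connectivity on a raster, and the
≲0.4 % area loss per junction is far below the pixelation error.

## Run segmentation

A projected 1-D position series s(t) is decomposed into piecewise
constant-velocity segments by deterministic bottom-up merging of the
per-interval velocity estimates v_i = Δs_i/dt: the adjacent block pair
with the smallest difference of mean velocities merges first, while that
difference is ≤ eps_v. Min-first order makes the procedure
self-sharpening — blocks absorb their most similar neighbour first, block
means converge to the underlying slope, and genuinely different slopes
stay separated. Blocks with |velocity| < v_pause are pauses; adjacent
same-direction blocks are coalesced; segments with length ≥ L_min
(default 1 µm, the processive-transport reporting threshold) and duration
≥ min_dur are reported as processive runs. The full set of segments
always partitions the time axis.

eps_v (0.2 µm/s), v_pause (0.1 µm/s) and min_dur (0.3 s) quantify the
"constant slope" judgement that is made by eye in manual kymograph
analysis; they are this package's analysis choices, with no measured
counterpart. A practical constraint worth knowing: the per-interval
velocity noise is √2·sigma_loc/dt, and merging degrades when that exceeds
roughly 2× eps_v — at dt = 0.1 s keep localization error below ~0.03 µm
(bright spots) or lengthen dt.

Runs truncated by the observation window are included with no censoring
correction, matching how run-length survival curves are conventionally
fitted; a censored treatment is a known omission.

## Run-length model and fit

Only runs longer than L_min are observed, so run lengths follow a shifted
exponential, P(X ≥ x) = exp(−(x − L_min)/µ) for x ≥ L_min. The maximum-
likelihood estimate of the mean excess run length is µ̂ = mean(x) − L_min
with normal-approximation CI µ̂·(1 ± 1.96/√n); a least-squares fit of the
empirical inverse CDF is provided as the alternative that mirrors how such
curves are usually fitted graphically. The minus-run fraction over pooled
runs carries a binomial CI (normal by default, Wilson optional);
aggregation per cell is available but pooled counting is the default since
the appropriate level is context-dependent.

## Nuclear rotation

The orientation series is decomposed into maximal monotonic episodes, with
a reversal committed only when the counter-movement from the running
extremum exceeds a 1° hysteresis (suppressing measurement jitter); the
durations of episodes whose total angular change exceeds theta_rot
(default 10°) are summed. Summing all qualifying episodes (rather than
only the longest) is an interpretation choice, as is the hysteresis.

## What the synthetic data do and do not show

The generators reproduce the statistical structure each analysis stage
assumes: exponential run/pause dwells, radial geometry, Gaussian PSF spots
with Poisson or Gaussian noise, drifting nuclei and patches with
localization noise. They do not emulate photobleaching, uneven
illumination, motor force or stall behaviour, 3-D defocus, organelle shape
changes, crossing microtubules, or cytoplasmic background structure.
Passing the recovery suite therefore demonstrates that the measurement
chain is unbiased and correctly calibrated under its stated model — not
that it is robust to every artifact of real recordings. Parameter-recovery
checks pin the generators to the measured values (1 µm/s speeds, 0.3:0.2
initiation bias, 12.91 and 7.46 µm/h drifts, 10.33 nm/s patch drift, 1.6-
and 3.8-fold size increases) and require the full chain to recover them.

## Numerical and reproducibility choices

Problem sizes in the test and acceptance runs (tens of cargoes for
hundreds of seconds, 500 comets, 36–38 nuclei, 200 patch replicates, 50
disks) are chosen so Monte-Carlo error is small against each tolerance
while a full run completes in seconds. Every stochastic routine takes an
explicit seed (`numpy.random.default_rng`); the pipeline derives stage
seeds from one top-level seed by SHA-256, keeps them below 2³¹, and stamps
every output with a hash of the canonicalized configuration, so a config +
seed pair reproduces byte-identical tables. Assignment ties in linking and
merge ties in segmentation resolve to the lowest index, making both
deterministic.

## Known limitations

* No gap closing: blinking or briefly occluded particles fragment.
* The detection score is a proxy; its absolute scale is not comparable to
  any plugin's score, only its cutoff role is.
* Segmentation quality degrades sharply once per-interval velocity noise
  exceeds ~2× eps_v (see above).
* Censored runs at the window edges bias the run-length fit downward when
  runs are long relative to the recording.
* Cell boundary and centre are inputs; no segmentation of cell outlines
  from images is attempted.
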