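# Methods

This note documents the model, the algorithmic choices that were
genuinely open, the parameters that matter, and what the synthetic
experiments do and do not demonstrate.

## Tissue model

The tissue is a two-dimensional cellular automaton on an `L x L`
square lattice (`L = 200`). Rows represent muscle fibres: every cell
is coupled to its longitudinal neighbours, with open ends at columns 0
and `L-1`. Transverse couplings between a cell and the cell in the row
above exist independently with probability `ν`; rows wrap periodically
(a cylinder). Decreasing `ν` models fibrotic decoupling of fibres.
Each cell is a three-state machine: resting, excited (one step), then
refractory for `τ` steps. The update is synchronous with double
buffering, so within-step ordering cannot matter. Pacemaker cells
(column 0) fire at t = 0 and every `T` steps thereafter, exciting only
resting cells.

Defaults and units:

| parameter | default | meaning |
|---|---|---|
| `L` | 200 | lattice side (cells) |
| `ν` | 0.2 | transverse coupling fraction; the largest value at which paroxysmal fibrillation is typically seen |
| `δ`, `ε` | 0, 0.05 | dysfunctional-cell fraction and per-attempt failure probability; `δ = 0` is the working limit, the rule is exercised only in tests |
| `τ` | 50 steps | refractory period (150 ms at 3 ms/step) |
| `T` | 220 steps | pacing period (660 ms) |
| `Δt*` | 3.0 ms | physical time per step (metadata; no dynamics depend on it) |

State encoding: a single integer clock per cell — 0 resting, 1
excited, `2..τ+1` refractory counting down. This makes the refractory
countdown directly assertable in tests.

## Artificial re-entrant circuits

With `δ = 0` no circuit can form spontaneously, so drivers are
inserted: the transverse couplings above and below the 28 cells to the
right of a random anchor are removed and the couplings closing the
loop at both ends of the span are forced present, giving a rectangular
two-fibre loop of perimeter `2·29 + 2 = 60 > τ`. Seeding excites the
rightmost cell of the lower fibre and lays a refractory wake of
`min(τ, 59)` cells behind it along the circulation path, guaranteeing
unidirectional circulation; the loop then re-excites every cell on it
with period exactly 60 steps (asserted by brute-force simulation).
Initialization runs until every column has been excited and the
fibrillation criterion (> 1.1·L active cells) has held at least once,
then confirms on a throwaway copy of the simulation that activity
persists without pacing — a transient wave from an unsustainable
circuit (e.g. `τ > 60`) can sweep the tissue once and die, which must
not count as established fibrillation.

Two-driver tissues place the second anchor with a minimum vertical
separation of 10 rows (minimum-image).

## Electrograms

The extracellular potential of an electrode at in-plane position
`r_e` and height `h` is a sum over coupled cell pairs

    Φ = Σ_(i,j) (u_i − u_j) · [(r_i − r_j) · (r_m − r_e)] / |r_m − r_e|³

with `u` the membrane potential (excited → 1, refractory stage `k` →
`1 − k/τ`, resting → 0) and `r_m` the bond midpoint. Transverse bonds
crossing the periodic row seam use minimum-image displacements. The
kernel is the standard unipolar far-field current-dipole form; the
mapping of cell states to source strength (linear repolarization) is
the simplest choice producing a repolarization signal, and voltages
are in arbitrary units throughout, so only morphology carries
information. `h = 1` cell by default.

Two implementations exist and agree to machine precision: a direct
sum for arbitrary continuous electrode positions, and an FFT
cross-correlation engine (circular along rows, zero-padded along
columns) that yields the potential at *every* integer lattice position
in ~1 ms per step, making 576-electrode corpus recording cheap.

**Recording windows.** A multiprobe recording covers 120 steps — two
60-step driver cycles, 360 ms — starting right after initialization.
One measured property shaped the design: the fibrillatory pattern is
not statistically stationary. Over successive 120-step windows the
tissue phase-locks to the driver, and classifiers trained on
post-initialization windows degrade from near-perfect to ~20% recall
five windows later. All probes of a training tissue therefore record
the *same* window (they do in any case — one episode, 64 probes), and
all jumps of a search read from one captured window of the same epoch,
which is both consistent with training and what a mapping study of a
stationary driver measures. The `FibrillationWindow` class snapshots
the potential grid over the window once; recordings are then free.

## Features (schema version 2)

Per electrode (12): max, min, mean, variance, skewness, kurtosis
(plain standardized moments; 0 for a constant series), first
stationary-point index, max |ΔV| per step, intensity Σ|V|, dominant
nonzero Fourier frequency (cycles/window) and its magnitude, and the
number of excursions of |V| above 25% of the window peak. Across the
probe: the mean gradient of each statistic along x and along y over
all parallel electrode pairs (per cell, spacing 3 — averaging over the
six pairs suppresses the zig-zag of discrete wavefronts), the
wavefront direction from a least-squares plane fit of the nine
activation times (first crossing of 25% of each electrode's peak
|V|), and two cross-probe scalars added in schema v2 because waves
radiate *non-planarly* from a driver underneath the probe: the RMS
residual of that plane fit and the activation-time range. 137 features
total; the schema is versioned so persisted models reject mismatched
vectors.

Vector feature maps (mean of a statistic binned by displacement from
the driver centre, with counts, optional mirror folding) are provided
for visualization and are exercised by a focal-source corpus test: the
dominant-frequency-magnitude map separates the source bin and its
fibre band from the off-band bulk by well over two bulk standard
deviations once each tissue's arbitrary amplitude scale is normalized
out.

## The four forests

scikit-learn random forests behind a thin bundle interface:

- `clf_x`, `clf_y`: binary "is the probe on the driver's column/row
  band?" (band = the probe window's 7-cell range overlapping the
  circuit's 30-column / 2-row extent). 200 trees, `min_samples_leaf`
  10, class weight = balanced x 3 on the positive class. Two findings
  drove this: fully-grown trees make class weighting inert (pure
  leaves), so leaves must be regularized for the weighting to bite;
  and the positive boost compensates the asymmetric cost of missing
  the band versus a false alarm, whose rate far from the driver stays
  ~0.
- `prob_x`, `prob_y`: locators over signed displacement classes
  (driver minus probe). x uses 5-cell bins — quantization is
  irrelevant against the circuit's ±15-column extent; y uses 2-cell
  bins because the 2-row band demands near-cell resolution at the
  final approach (5-cell y-bins measurably lowered end-to-end
  success). Displacements rather than absolute coordinates are
  learned: the features are translation-covariant and the probe's
  known position converts a displacement distribution into per-row/
  column probabilities. Class probabilities are ensemble vote
  fractions `P_i = k_i/k`, computed by explicit per-tree voting.

Hyperparameters were selected on held-out validation placements
(dedicated tissues, probes at controlled displacements), not on the
evaluation ensembles. Training uses one recording per probe, 64
probes per tissue on a uniform 8 x 8 grid given a random phase per
tissue so that, across the corpus, every centre position is covered
(a fixed grid leaves coverage holes near the open boundaries that
showed up as far-field false positives).

## The search

Each jump: record the probe, extract features, then

1. stop test: both band classifiers fire *and* the y-locator's best
   in-region class moves the probe by ≤ 2 rows ("the driver band is
   here"), or the walk has looped back to within 2 cells of an
   earlier positive. A bare conjunction fires in a halo a few cells
   wide around the true window; requiring the (row-accurate) y-locator
   to agree converts most halo stops into one further refining jump.
   If the search exhausts its jump limit or errors after passing
   positives, the most recent positive stands as the final answer.
2. proposal: per axis, zero the vote mass outside the constraint
   region, renormalize, take the argmax class (ties → nearest region
   midpoint, then smaller coordinate), map to an absolute position,
   clamp to valid placements. Already-visited centres are skipped by
   descending joint vote mass.
3. constraints: per axis, if ≥ 75% of the in-region vote mass lies
   strictly on one side of the probe, intersect the region with that
   half-space (an arc on the periodic row circle). The mass threshold
   exists because the side inference from a near-zero predicted
   displacement is a coin flip, and a wrong cut permanently excludes
   the driver. Prediction error is declared when the region drops
   below one probe footprint (7 cells; except x-slivers flush against
   an open boundary, which one placement still covers) or a proposal
   revisits a centre.

Success is judged against ground truth as footprint overlap of the
final probe's 7 x 7 region — the position, if ablated, would sever the
loop. Prediction-error and jump-limit searches count as failures.

**Multiple drivers.** Wavefronts from a lone driver collide at its
antipodal row. After the first driver is found, the search probes the
antipode and bisects along the row circle for the sign change of the
activation-time slope along y (pairwise differences are aliased into
±30 steps because electrodes can straddle consecutive 60-step beats).
A collision row displaced from the antipode mirrors the second driver
(`row₂ = 2·ĉ − row₁`, equal wave speeds), and the second search is
constrained to a ±25-row arc around it. A collision *at* the antipode
is treated as inconclusive rather than proof of a single driver —
measured activation fields far from any driver are often dominated by
fast longitudinal sweeps whose transverse slope is ~0 — so the second
search still runs over the remaining rows with the first driver's
band excluded; in a genuinely single-driver tissue it simply ends
without a positive. Collision-hunt recordings count toward the second
driver's jumps.

## Problem sizes and what the numbers mean

The package's experiments run at desk scale: 500 training tissues
(32 000 probe recordings) and 200 evaluation searches per scenario,
versus 5000/1500 in the full-scale study the defaults mirror. At this
scale the pipeline locates roughly six of ten single drivers (mean
jumps ≈ 5–7, inside the published 5.0 ± 1.7 band) and beats the
0.74% random-placement baseline by nearly two orders of magnitude;
success rises monotonically with corpus size (≈ 0.53 at 250 tissues,
≈ 0.6 at 500, ≈ 0.73 at 1000), consistent with the classifier
boundary being data-limited, but full-scale accuracy is not reproduced
at desk scale. Three components are reconstructions from incomplete
source material — the electrogram kernel, parts of the feature list,
and the constraint/"prediction error" mechanism — and each is a
plausible but not verified match to the original.

What passing tests show: the automaton's dynamics (conduction speed,
refractory cycle, circuit period, symmetries) are exact; the
electrogram kernel is internally consistent and physically sensible;
the learning problem is well-posed and the search machinery sound
(with ground-truth side inferences the region never loses the driver).
What they do not show: clinical realism. The tissue is a flat
cylinder, fibres are straight, refractory periods uniform, electrodes
noiseless, and drivers are stationary rectangles — none of which holds
in real atria.

## Numerical notes

- All randomness flows through explicit `numpy.random.Generator`
  objects; (config, seed) reproduces tissues, corpora, searches and
  summaries bit-for-bit.
- The FFT engine caches kernel transforms per (L, h); transverse
  kernel offsets are minimum-imaged *after* adding the half-cell bond
  offset, which is what makes the antipodal row tie resolve to the
  nearer image and the engine agree with the direct sum exactly.
- Skewness/kurtosis guard against zero variance; silent electrodes
  yield NaN activation times, excluded from plane fits (≥ 3 finite
  times required, else the direction is flagged undefined).
- Forest memory scales with leaves x classes; the locator bin widths
  and leaf sizes keep the four fitted forests under ~1 GB resident.
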