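# afloc

Electrogram-guided localization of re-entrant drivers of atrial
fibrillation (AF) in a cellular-automaton model of atrial tissue.

Catheter ablation of AF is limited by mapping resolution: a single
electrode recording rarely pinpoints the re-entrant circuit that drives
the arrhythmia. This package implements, end to end, a simulation
test-bed for a different strategy — combine many *indirect* multi-
electrode recordings, each summarized by statistical features and
cross-electrode gradients, and let an ensemble classifier triangulate
the driver recursively. It is aimed at computational
electrophysiologists and machine-learning researchers studying mapping
strategies in excitable-media models.

## The model and the algorithm

**Tissue.** An `L x L` (default 200 x 200) lattice of cells. Cells are
fully coupled along rows (muscle fibres, open ends); vertical couplings
between fibres exist independently with probability `ν` (default 0.2,
the regime where paroxysmal AF appears); rows are periodic (cylindrical
atrium). Each cell cycles resting → excited (1 step) → refractory
(`τ = 50` steps) → resting; a pacemaker excites the left column every
`T = 220` steps. One step is `Δt* = 3 ms`, so the refractory period is
150 ms and sinus rhythm beats every 660 ms.

**Drivers.** A re-entrant circuit is inserted by removing the vertical
couplings above and below 28 consecutive cells, leaving a closed
rectangular loop of perimeter 60 > τ between two fibres. A wave seeded
on the loop circulates every 60 steps indefinitely and radiates
fibrillatory activity into the bulk (fibrillation: > 1.1·L = 220
simultaneously excited cells).

**Electrograms.** Unipolar point electrodes at height `h = 1` cell
above the plane. Every coupled cell pair contributes as a current
dipole, `Φ = Σ (u_i − u_j) (r_i − r_j)·(r_m − r_e)/|r_m − r_e|³`, with
`u` the membrane potential (excited 1, linear repolarization over τ).
An FFT engine evaluates Φ on the whole lattice per step, exactly
matching the direct sum.

**Localization.** A 3 x 3 probe (electrode spacing 3, a 7 x 7-cell
region) records two fibrillatory cycles (120 steps < 400 ms). Each
recording becomes a 137-dimensional feature vector (12 waveform
statistics per electrode, their mean spatial gradients along x and y,
wavefront direction from an activation-time plane fit, plus the fit
residual and activation-time range). Four random forests are trained on
simulated tissues with known driver positions: two classifiers ("is the
probe on the driver's column/row band?") and two probabilistic locators
over signed displacement bins whose class probabilities are ensemble
vote fractions, `P_i = k_i / k`. The search records at a random
position, predicts a displacement, clips it to a shrinking constraint
region (half-space cuts from confident side inferences; prediction
error when the region collapses or positions repeat), jumps, and stops
when both classifiers assert the probe is on the driver. A second
driver is sought by locating where wavefronts from the first driver
collide — a collision row displaced from the antipode mirrors the
second driver's position — and re-running the search in the implied
arc.

## Worked example

```python
import numpy as np
from afloc import (ModelConfig, build_tissue, insert_circuit, initialize_af,
                   sample_anchor, locate_driver, generate_training_set,
                   train_models)

# train the four forests on a small corpus (use ~500 tissues for real runs)
table = generate_training_set(50, rng=np.random.default_rng(0))
bundle = train_models(table, rng=0)

# one fresh fibrillating tissue with a hidden driver
cfg = ModelConfig()
rng = np.random.default_rng(42)
tissue = build_tissue(cfg, rng)
circuit = insert_circuit(tissue, sample_anchor(cfg, rng))
sim, t_ready = initialize_af(tissue, circuit, rng=rng)

result = locate_driver(sim, bundle, rng, circuits=[circuit])
print("driver centre:", circuit.centre(cfg.L))
print("found:", result.centre, "in", result.jumps, "jumps;",
      "success:", result.success)
```

Typical output (seeds as above):

```
driver centre: (195.5, 124.5)
found: (198, 108) in 5 jumps; success: True
```

The found centre is the final probe position; `success` means its
7 x 7 region overlaps the circuit footprint, i.e. ablating there would
interrupt the loop. A command-line interface mirrors the library:
`afloc train`, `afloc locate`, `afloc evaluate`, `afloc baseline`.

At the package's desk scale (500 training tissues, 200 evaluation
searches; the reference study used 5000/1500) the evaluation harness
reports the per-driver success fraction and mean jumps ± SD alongside
the published full-scale values; see `afloc evaluate` and
`docs/methods.md` for what the scaled-down numbers do and do not show.

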