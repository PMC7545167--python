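# septasm

Kinetic modeling and image quantification of septin filament assembly on
supported surfaces, as observed by high-speed atomic force microscopy
(HS-AFM).

Yeast septins form palindromic hetero-octamers
(Cdc11-Cdc12-Cdc3-Cdc10-Cdc10-Cdc3-Cdc12-Cdc11) — ~32-nm "rods" of eight
~4-nm subunits — that adsorb onto surfaces and grow into filaments,
tight filament pairs, and stacked layers.  This package provides, for
biophysicists analyzing such data:

* **kinetics** — a size-structured coagulation model of diffusion-driven
  annealing: the surface density f(t, j) of j-rod assemblies evolves under
  a sigmoidal adsorption source and the generalized sum kernel

      K(r, s) = k_P (r⁻ᵅ + s⁻ᵅ),

  integrated by the explicit Δt = 1 s recurrence over j = 1..12.  α is
  the mobility exponent (large assemblies diffuse less), k_P a diffusivity
  prefactor in μm² s⁻¹.
* **fitting** — three-parameter sigmoid fits of coverage traces, and
  estimation of (α, k_P) by SSE grid search against normalized length
  histograms (SSE scaled by the number of experimental histograms).
* **image_metrics** — morphometry of height maps: surface coverage,
  alignment (FWHH of a Gaussian fit to the structure-tensor orientation
  distribution), centerline tracing, length histograms in rod units,
  pairing fraction, 32-nm octamer periodicity, pair registry offsets
  (0 = matched, ~4 nm = one-subunit stagger), top-to-top distances,
  layer decomposition and inter-layer angular correlation.
* **synthetic_data** — seeded generators for every input: model-driven
  histogram series, noisy coverage traces, and rendered pseudo-topographs
  with ground truth (tip-PSF blur, pixel noise, pairs, lipid clusters,
  stacked layers).
* **charge_model** — net-charge arithmetic for the structurally
  unresolved N/C-terminal extensions and the alternating charge pattern
  along a palindromic filament.
* a `septasm` CLI (`simulate`, `fit-sigmoid`, `fit-kinetics`, `metrics`,
  `synth`, `charge`) over CSV tables, 16-bit TIFF + YAML sidecars, and
  FASTA.

## Worked example

Simulate assembly at the high-salt/low-pH best-fit kinetics, then recover
the parameters from the simulated histograms by grid search:

```python
import numpy as np
from septasm import (KernelParams, SigmoidParams, SimulationConfig,
                     simulate, grid_search)

sig = SigmoidParams(a=0.9, b=0.1, c=60.0)      # coverage sigmoid
cfg = SimulationConfig(dt=1.0, j_max=12, t_end=300.0)
truth = KernelParams(k_p=1.8e-5, alpha=5.6)

hist = simulate(truth, sig, cfg)               # normalized length histograms
print(np.round(hist.populations[-1], 3))

alpha_grid = np.round(np.arange(3.0, 8.01, 0.2), 10)
kp_grid = 1.8e-5 * 10.0 ** np.arange(-2.25, 0.80, 0.25)
fit = grid_search(hist, sig, alpha_grid, kp_grid, cfg)
print("alpha = %.1f, k_P = %.2g, SSE = %.3g" % fit.best)
```

prints

```
[0.009 0.07  0.164 0.205 0.191 0.147 0.098 0.058 0.031 0.016 0.007 0.003]
alpha = 5.6, k_P = 1.8e-05, SSE = 0
```

The first line is the size distribution at t = 300 s — the population
peaks at 4-rod filaments with the positive skew characteristic of
size-dependent annealing.  The grid search recovers the generating
mobility exponent and prefactor exactly, with zero residual.

A morphometry example on a rendered scene:

```python
from septasm import scene, render_topograph, trace_filaments
from septasm.image_metrics import filament_periodicity
import numpy as np

topo, truth = render_topograph(scene("aligned_paired", seed=1))
fs = trace_filaments(topo)
per = [filament_periodicity(topo, f) for f in fs.filaments if f.length > 150]
print(len(fs), "traces; octamer repeat %.1f nm" % np.median(per))
```

prints `12 traces; octamer repeat 32.1 nm` — the 32-nm rod repeat read
back from blurred, noisy synthetic filaments.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch (~35 s on one CPU): the mobility exponent at the
SSE minimum of a grid search against self-generated histograms (t1), and
the morphometric round-trips on the standard seeded scenes — octamer
periodicity (t4), lipid-cluster spacing (t5), pair registry offset of
one-subunit-staggered pairs (t6), the maximum top-to-top distance of
tightly paired filaments (t7), and the chance-corrected inter-layer
angular correlation of the two-layer scene (t8) — writing one JSON record
per target.
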