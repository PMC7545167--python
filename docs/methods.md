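# Methods

`septasm` models the surface assembly of yeast septin filaments and
quantifies the order of the resulting layers the way it is done on
high-speed AFM (HS-AFM) height images.  This note records the model, the
measurement procedures, the numerical choices, and what the synthetic data
do and do not establish.

## 1. Kinetic model

Septin hetero-octamers ("rods", ~32 nm long, eight ~4-nm subunits) adsorb
onto a supported surface, diffuse, and anneal end-to-end.  The state is the
surface density f(t, j) (μm⁻²) of assemblies of j rods, j = 1..J_max
(default 12).  The evolution is

    ∂f(t,j)/∂t = s(t)·δ_{j,1}
               + 2 K(1, j−1) f₁ f_{j−1} − 2 K(1, j) f₁ f_j
               + Σ_{i=2}^{j−2} K(i, j−i) f_i f_{j−i}
               − Σ_{k=2}^{J_max} K(j, k) f_j f_k

with the generalized sum kernel K(r, s) = k_P (r^−α + s^−α).  k_P
(μm² s⁻¹) lumps the diffusivity of surface reactants; the mobility
exponent α ≥ 0 penalizes the mobility of large assemblies, which is what
produces the positive skew of the length distributions.  The monomer
source s(t) is the time derivative of a three-parameter logistic coverage
trace, a/(1+e^{−b(t−c)}), divided by the rod footprint (32 nm × 4 nm =
1.28 × 10⁻⁴ μm²) to convert coverage/s into rods μm⁻² s⁻¹.

Integration is the explicit first-order recurrence f(t+Δt) = f(t) +
Δf·Δt with Δt = 1 s ("leapfrog" in the source literature's nomenclature;
it is a plain forward step using the state at t only).

### Balance modes

The equation above, taken literally, doubles the gain of hetero-collisions
without doubling the corresponding losses, so total rod mass Σ j·f(j) is
not an exact invariant.  Both conventions are implemented:

* `as_printed` (default) — the four terms exactly as written; used for all
  parameter fits, for fidelity to the published workflow.
* `mass_conserving` — symmetric Smoluchowski factors (½ on the ordered
  gain sum, loss over all partners); Σ j·f(j) then changes only through
  the source, which makes mass accounting exactly testable.

### Truncation and overflow

The loss sum runs to J_max (the published simulations track j = 1–12).
Coalescence products larger than J_max are either discarded (default) or,
with `overflow_mode="aggregate_at_Jmax"`, folded into the top bin as
mass-equivalent counts (a product of size m contributes m/J_max counts),
so that conservation holds exactly under truncation.  Counts in the top
bin are then "mass-equivalent", not particle numbers.

### Accuracy of the Δt = 1 s step

At the published best-fit parameters with a realistic source (plateau
coverage 0.9), the characteristic collision rate K·f reaches ~0.25 s⁻¹,
so the forward step carries a first-order truncation error of a few
percent per step.  Against an LSODA integration of the same right-hand
side (rtol 10⁻¹⁰), bins holding ≥1% of the population agree to within
~1–2%, and every bin agrees to within 0.5% of the distribution maximum —
i.e. the normalized histograms fed to the fits are accurate to well under
one percentage point per bin.  The *per-bin relative* error in near-empty
tail bins, however, reaches ~10–19%; this is inherent to the printed
scheme (a Δt = 0.01 s forward step reproduces the oracle) and is surfaced
honestly by the strict variant of the oracle-equivalence acceptance test,
which we leave failing rather than widen.

Negative excursions are clipped to zero; silently below 10⁻¹² of the
distribution scale, with a logged warning above it, and an integration
error (advising smaller Δt) beyond 10% of the scale.

## 2. Parameter fitting

The sigmoid (a, b, c) is fitted to coverage traces by bounded
least-squares (`scipy.optimize.curve_fit`, a ∈ [0, 1.2], b > 0) with
data-driven initial guesses and up to 5 jittered restarts; traces with
negligible dynamic range return a ≈ 0 flagged degenerate rather than an
error.

(α, k_P) are estimated by exhaustive grid search: one simulation per grid
point, scored by the sum of squared differences between normalized
simulated and experimental length histograms, summed over size bins and
experimental time points and divided by the number of experimental
histograms.  Simulated series are sampled at the experimental frame times
by nearest-step lookup (error ≤ 0.5 s at Δt = 1 s).  Histogram slices
with zero total count cannot be normalized and are excluded (logged).
Default grids: α ∈ [0, 10] step 0.2; k_P log-spaced 10⁻⁸–10⁻³ (30
points).  Failed grid points become NaN cells excluded from the argmin.
Only grid-resolution uncertainty is reported; there is no gradient or
Bayesian refinement by design.

## 3. Image metrics

A topograph is a 2-D height map in nm, substrate at 0, one filament layer
≈ 4 nm.  Defaults: coverage threshold 2 nm (half a layer), pairing gap
10 nm, parallelism tolerance 15°, inter-layer alignment tolerance 10°, all
configurable.

* **Coverage** — fraction of pixels above threshold.
* **Orientation/alignment** — per-pixel axial orientation (mod 180°) from
  the structure tensor (the eigenvector of least variation), histogrammed
  over covered pixels with coherence weights; a wrapped Gaussian is fitted
  about the circular mode and the FWHH (2.355 σ) is the alignment score.
  A rival histogram peak with ≥50% prominence more than 30° from the mode
  flags the distribution multimodal; no FWHH is forced then.
* **Tracing** — Gaussian denoise (σ 1.5 px) → threshold → drop speck
  components, fill pinholes → skeletonize → delete junction pixels →
  order each branch → merge collinear fragments (axial difference < 20°,
  endpoint gap < 8 nm, and the connector itself must run along the axis,
  which prevents joining the two members of a tight pair side-by-side).
  Centerlines are resampled at pixel spacing and low-passed (σ 2.5 px) to
  remove the skeleton staircase — without this, arc lengths and apparent
  axial periods inflate by ~8% — then extended along the end tangents
  while the surface stays above threshold, compensating skeleton end
  erosion.  Sub-rod fragments are kept (adsorbed rods); traces < 8 nm are
  dropped as noise.
* **Subunit peaks** — height profile along the centerline, band-passed
  between period/8 and period/2 (the low-pass removes pixel noise, the
  high-pass removes slow height undulations from trace wander), maxima
  with parabolic sub-sample refinement.  After a 3-nm tip PSF the 4-nm
  subunit ripple is unmeasurable (attenuation < 10⁻⁴), so the extracted
  trains are the 32-nm octamer repeat; a one-subunit stagger shifts that
  train by the same 4 nm, which is how registry mismatch is measured.
* **Length histogram** — j = round(length / 32 nm), round-half-up, j ≥ 1.
* **Pairing fraction** — percentage of total centerline length with a
  distinct, roughly parallel neighbor centerline within the gap threshold
  (sampled every 2 nm, KD-tree lookup).
* **Periodicity** — autocorrelation of the (lightly smoothed) profile,
  first peak beyond 8 nm with ≥5% prominence, parabolic refinement; or
  mean nearest-neighbor spacing for discrete positions (clusters).
* **Registry offset** — period from the median peak spacing (trains must
  agree within 20% or they are incommensurate); the offset maximizing a
  Gaussian-kernel match of the two trains, folded into [0, period/2].
* **Layers** — pixel layer index = round(height / 4 nm); per-layer masks,
  coverages (fraction at that layer or above) and mean step heights.  For
  tracing one layer, pixels within 6 px of any higher layer are excluded:
  the blurred skirt of an overlying filament falls into the lower band
  and otherwise traces as spurious arcs.
* **Inter-layer angular correlation** — per upper filament, the local
  template orientation is the inverse-distance-weighted circular mean of
  tangent angles of the nearest lower-layer centerline samples (robust to
  fragmentation of the lower layer); the score is the percentage of upper
  filaments within 10°.  Uniform-random upper filaments fall within the
  tolerance by chance with probability q = 2·tol/180; where a generating
  aligned fraction is compared against, the chance-corrected estimate
  (r − 100q)/(1 − q) is reported alongside the raw percentage.
* **Top-to-top distances** — tightly paired members blur into one mask,
  so the merged trace is cross-sectioned perpendicular to its axis and
  the two local height maxima per station (parabolically refined) give
  the member top positions, exactly as such distances are read off AFM
  height profiles.

## 4. Synthetic data

The generator emulates HS-AFM observations: filaments are half-cylinder
ridges (4 nm tall per layer) along straight centerlines, with a 0.4-nm
subunit ripple (period 4 nm) and a 0.6-nm octamer modulation (period
32 nm) riding on the crest; optional hemispherical lateral clusters
(radius 7 nm, apex 8 nm, one per octamer on one side); stacked layers add
4 nm each.  Scenes are max-composed, convolved with an isotropic Gaussian
tip PSF (default σ = 3 nm), and corrupted with Gaussian pixel noise
(default σ = 0.2 nm).  Every scene is seeded and bit-reproducible, and
ships a ground-truth record (polylines, orientations, phases, octamer
crest and cluster positions, pre-blur layer masks) sufficient to score
every metric without re-detection.

Named fixtures: `aligned_paired` (ordered tight pairs, σ_PSF = 3 nm,
noise 0.2 nm), `disordered_short`, `wildtype_lipid` (one cluster per
32-nm rod, one side), `mismatched_pairs` (pairs staggered by one 4-nm
subunit; σ_PSF = 1.5 nm so both members trace separately),
`tight_pairs` (4-nm-wide members in edge contact; σ_PSF = 1 nm so the
cross-sections stay bimodal), and `two_layer_80pct` (a dense parallel
template layer plus 100 upper filaments, exactly 80 aligned with 2.5°
jitter and 20 uniformly random, placed by rejection sampling with mutual
clearance because filaments of one layer cannot overlap; σ_PSF = 2 nm,
1024×1024 px so ≥100 upper filaments fit without crowding).

What the generator does *not* emulate: curved or flexible filaments,
drift and scan-line artifacts, true tip dilation (the Gaussian PSF lowers
narrow features, a real tip does not), fragmentation, or time-resolved
movie rendering.  Green round-trip tests therefore establish that the
measurements are unbiased on straight, well-separated, seeded geometry at
realistic noise — not that they are robust to every artifact of real
movies.

## 5. Charge model

Terminal-extension net charges use integer per-residue charges (D/E −1,
K/R +1, others 0; X neutral).  Histidine defaults to 0 — the printed
integer net charges are consistent with His excluded — and can be set to
+1 for a fully protonated low-pH view.  Extension boundaries are user
input; the package deliberately ships no hard-coded residue ranges, since
they are defined only by a structural model.  The filament pattern
concatenates per-subunit (N, C) charges along the palindromic rod
Cdc11-Cdc12-Cdc3-Cdc10-Cdc10-Cdc3-Cdc12-Cdc11 and summarizes contiguous
sign blocks per face; with the published values (Cdc3 −12/+9, Cdc11
+5/−4, Cdc10 −3/+2, Cdc12 termini not printed, taken as 0) the C face
alternates between positive central-tetramer blocks and negative
Cdc11–Cdc11 junction blocks, inverted on the N face.

## 6. Known limitations

* The recurrence inherits the first-order error of the published scheme;
  fits are self-consistent (both sides of the SSE use the same scheme),
  but raw densities in sparse bins carry ~10% discretization error at the
  fastest published kinetics.
* Tracing assumes filaments are straight enough that PCA orientation and
  tangent extension are meaningful; strongly curved filaments would need
  curvature-aware handling.
* The pairing fraction counts centerline proximity of parallel traces; it
  does not detect pairs whose members merge into a single trace (those
  are handled by the cross-section route instead).
* Grid-search uncertainty is one grid step; no confidence intervals.
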