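"""Seeded generators for every input the pipeline consumes.

Three families of synthetic data emulate HS-AFM observations of septin
assembly on a supported surface:

* model-driven length-histogram time series (the kinetic simulator's own
  output, optionally resampled as multinomial counts of a finite number of
  imaged rods);
* sigmoidal surface-coverage traces with additive Gaussian noise;
* rendered pseudo-topographs: filaments drawn as half-cylinder ridges of
  4 nm height per layer, with a 4-nm subunit repeat and a 32-nm octamer
  super-repeat, optional tight pairs (matched or one-subunit staggered),
  periodic lateral clusters on one side, and stacked layers — convolved
  with a Gaussian tip point-spread function and corrupted with pixel noise.

Every generator takes an explicit seed and is bit-reproducible; rendered
scenes come with a ground-truth record sufficient to evaluate every
morphometric operation without re-detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image_metrics import LAYER_HEIGHT_NM, ROD_LENGTH_NM, SUBUNIT_LENGTH_NM, Topograph
from .kinetics import (
    HistogramSeries,
    KernelParams,
    SigmoidParams,
    SimulationConfig,
    simulate,
)

#: Palindromic subunit order of the yeast septin rod.
OCTAMER_ORDER = ("Cdc11", "Cdc12", "Cdc3", "Cdc10", "Cdc10", "Cdc3", "Cdc12", "Cdc11")


# ---------------------------------------------------------------------------
# Model-level series
# ---------------------------------------------------------------------------

def generate_histogram_series(
    params: KernelParams,
    sig: SigmoidParams,
    cfg: SimulationConfig,
    noise: str = "none",
    n_rods: int = 300,
    seed: int = 0,
) -> HistogramSeries:
    """Simulated length-histogram series, optionally with counting noise.

    ``noise='multinomial'`` resamples each non-empty time slice as a
    multinomial draw of ``n_rods`` observed assemblies (a few hundred on a
    real scan area) and renormalizes — emulating the finite sampling of an
    experimental histogram.  ``noise='none'`` returns the simulator output
    unchanged.
    """
    if noise not in ("none", "multinomial"):
        raise ValueError(f"unknown noise mode {noise!r}")
    series = simulate(params, sig, cfg)
    if noise == "none":
        return series
    if n_rods <= 0:
        raise ValueError("n_rods must be > 0 for multinomial noise")
    rng = np.random.default_rng(seed)
    pops = series.populations.copy()
    for i in range(pops.shape[0]):
        if i in series.empty_slices:
            continue
        counts = rng.multinomial(n_rods, pops[i] / pops[i].sum())
        pops[i] = counts / counts.sum()
    return HistogramSeries(times=series.times.copy(), populations=pops,
                           normalized=True, empty_slices=list(series.empty_slices))


def generate_coverage_trace(
    sig: SigmoidParams, times, noise_sigma: float = 0.0, seed: int = 0
):
    """Sigmoid coverage samples plus Gaussian noise, clipped to [0, 1].

    Returns (times, coverage) arrays.
    """
    t = np.asarray(times, float)
    y = sig.coverage(t)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=t.shape)
    return t, np.clip(y, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------

@dataclass
class FilamentSpec:
    """One rendered filament: a straight rod chain from p0 to p1 (nm).

    ``phase`` shifts the axial subunit pattern (a one-subunit stagger
    between pair members is phase difference 4 nm).  ``pair_id`` links the
    two members of a tight pair; ``layer`` counts from 1.
    """

    p0: tuple
    p1: tuple
    layer: int = 1
    width: float = 6.0  # apparent lateral width, nm
    phase: float = 0.0
    pair_id: int | None = None
    clusters: bool = False
    cluster_side: int = 1  # +1 / -1: which side of the axis
    cluster_spacing: float = ROD_LENGTH_NM

    @property
    def length(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])

    @property
    def orientation(self) -> float:
        ang = math.degrees(
            math.atan2(self.p1[1] - self.p0[1], self.p1[0] - self.p0[0])
        ) % 180.0
        return ang


@dataclass
class SceneSpec:
    """Full description of a rendered pseudo-topograph.

    Geometry is in nm; the subunit repeat is 4 nm with a 32-nm octamer
    super-repeat; each layer adds 4 nm of height.  The tip point-spread
    function is an isotropic Gaussian (sigma in nm); pixel noise is
    additive Gaussian on the height.
    """

    size_px: tuple = (512, 512)
    pixel_size: float = 1.0
    filaments: list = field(default_factory=list)
    subunit_period: float = SUBUNIT_LENGTH_NM
    octamer_period: float = ROD_LENGTH_NM
    subunit_amp: float = 0.4
    octamer_amp: float = 0.6
    layer_height: float = LAYER_HEIGHT_NM
    cluster_height: float = 8.0
    cluster_radius: float = 7.0
    cluster_offset: float = 5.0  # lateral offset of cluster centers, nm
    psf_sigma: float = 3.0
    noise_sigma: float = 0.2
    seed: int = 0

    @property
    def extent(self):
        """(width, height) of the field of view in nm."""
        return (self.size_px[1] * self.pixel_size, self.size_px[0] * self.pixel_size)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_filament(h: np.ndarray, spec: SceneSpec, fil: FilamentSpec,
                     gt: dict) -> None:
    ny, nx = h.shape
    px = spec.pixel_size
    x = np.arange(nx) * px
    y = np.arange(ny) * px
    xx, yy = np.meshgrid(x, y)
    p0 = np.asarray(fil.p0, float)
    p1 = np.asarray(fil.p1, float)
    d = p1 - p0
    length = np.hypot(*d)
    if length <= 0:
        raise ValueError("degenerate filament")
    u = d / length
    n = np.array([-u[1], u[0]])
    # axial and lateral coordinates of every pixel
    rel_x = xx - p0[0]
    rel_y = yy - p0[1]
    s = rel_x * u[0] + rel_y * u[1]
    q = rel_x * n[0] + rel_y * n[1]
    half_w = fil.width / 2.0
    inside = (s >= 0) & (s <= length) & (np.abs(q) <= half_w)
    if not inside.any():
        gt.setdefault("clipped", []).append(gt["index"])
        return
    base = (fil.layer - 1) * spec.layer_height
    cross = np.sqrt(np.clip(1.0 - (q / half_w) ** 2, 0.0, 1.0))
    sp = s + fil.phase
    axial = (
        spec.subunit_amp * 0.5 * (1 + np.cos(2 * np.pi * sp / spec.subunit_period))
        + spec.octamer_amp * 0.5 * (1 + np.cos(2 * np.pi * sp / spec.octamer_period))
    )
    prof = np.where(inside, base + spec.layer_height * cross + axial * cross, 0.0)
    np.maximum(h, prof, out=h)

    # octamer-crest positions along the axis (height maxima of the repeat)
    first = math.ceil(-fil.phase / spec.octamer_period)
    crests = []
    k = first
    while k * spec.octamer_period - fil.phase <= length:
        sc = k * spec.octamer_period - fil.phase
        if sc >= 0:
            crests.append(sc)
        k += 1
    gt["octamer_crests"] = np.asarray(crests)

    if fil.clusters:
        centers = []
        sc = spec.octamer_period / 2.0 - fil.phase % spec.octamer_period
        while sc < 0:
            sc += spec.octamer_period
        positions = np.arange(sc, length, fil.cluster_spacing)
        off = fil.cluster_side * (half_w + spec.cluster_offset)
        for pos in positions:
            c = p0 + pos * u + off * n
            centers.append(c)
            r2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2
            dome = spec.cluster_height * np.sqrt(
                np.clip(1.0 - r2 / spec.cluster_radius**2, 0.0, 1.0)
            )
            np.maximum(h, dome, out=h)
        gt["cluster_centers"] = np.asarray(centers)
        gt["cluster_axial_positions"] = positions


def render_topograph(spec: SceneSpec):
    """Render a scene into a :class:`Topograph` plus its ground truth.

    The height map is the max-composition of all filament ridges (and
    clusters), blurred with the Gaussian tip PSF and corrupted with
    Gaussian pixel noise (seeded).  The ground-truth dict records, per
    filament: endpoint polyline, orientation, length, layer, pair id,
    phase, octamer crest positions, and cluster centers where present,
    plus per-layer masks computed before blurring.  Filaments extending
    beyond the frame are clipped and listed under ``clipped``.
    """
    ny, nx = spec.size_px
    h = np.zeros((ny, nx))
    gt_fil = []
    clipped = []
    ext_x, ext_y = spec.extent
    for i, fil in enumerate(spec.filaments):
        rec = {
            "index": i,
            "p0": tuple(fil.p0),
            "p1": tuple(fil.p1),
            "layer": fil.layer,
            "orientation": fil.orientation,
            "length": fil.length,
            "phase": fil.phase,
            "pair_id": fil.pair_id,
        }
        for p in (fil.p0, fil.p1):
            if not (0 <= p[0] <= ext_x and 0 <= p[1] <= ext_y):
                clipped.append(i)
                break
        _render_filament(h, spec, fil, rec)
        gt_fil.append(rec)

    layer_idx = np.clip(np.round(h / spec.layer_height).astype(int), 0, None)
    n_layers = int(layer_idx.max())
    layer_masks = [layer_idx == k for k in range(n_layers + 1)]

    if spec.psf_sigma > 0:
        h = ndimage.gaussian_filter(h, sigma=spec.psf_sigma / spec.pixel_size)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        h = h + rng.normal(0.0, spec.noise_sigma, size=h.shape)

    topo = Topograph(heights=h, pixel_size=spec.pixel_size,
                     layer_height=spec.layer_height)
    ground_truth = {
        "seed": spec.seed,
        "spec": spec,
        "filaments": gt_fil,
        "clipped": sorted(set(clipped)),
        "layer_masks": layer_masks,
    }
    return topo, ground_truth


# ---------------------------------------------------------------------------
# Scene builders
# ---------------------------------------------------------------------------

def _paired_scene(
    n_pairs: int,
    mean_angle: float,
    angle_sigma: float,
    separation: float,
    registry_offset: float,
    seed: int,
    width: float = 4.0,
    length: float = 400.0,
    psf_sigma: float = 3.0,
    noise_sigma: float = 0.2,
    size_px: tuple = (512, 512),
) -> SceneSpec:
    """Lay out non-overlapping tight pairs in parallel lanes."""
    rng = np.random.default_rng(seed)
    ny, nx = size_px
    ext = min(nx, ny) * 1.0  # pixel_size 1 nm
    filaments = []
    lane_gap = ext / (n_pairs + 1)
    th0 = math.radians(mean_angle)
    axis = np.array([math.cos(th0), math.sin(th0)])
    normal = np.array([-axis[1], axis[0]])
    center = np.array([ext / 2, ext / 2])
    for i in range(n_pairs):
        lane = (i - (n_pairs - 1) / 2) * lane_gap
        ang = math.radians(rng.normal(mean_angle, angle_sigma))
        u = np.array([math.cos(ang), math.sin(ang)])
        n = np.array([-u[1], u[0]])
        mid = center + lane * normal
        jitter = rng.uniform(-lane_gap / 6, lane_gap / 6)
        mid = mid + jitter * normal
        half = length / 2
        for member, (off, phase) in enumerate(
            [(-separation / 2, 0.0), (separation / 2, registry_offset)]
        ):
            c = mid + off * n
            filaments.append(FilamentSpec(
                p0=tuple(c - half * u), p1=tuple(c + half * u),
                width=width, phase=phase, pair_id=i,
            ))
    return SceneSpec(size_px=size_px, filaments=filaments, psf_sigma=psf_sigma,
                     noise_sigma=noise_sigma, seed=seed)


def _scene_aligned_paired(seed: int) -> SceneSpec:
    """Highly ordered, paired filaments (high-salt, low-pH-like order)."""
    return _paired_scene(
        n_pairs=12, mean_angle=60.0, angle_sigma=3.0, separation=8.0,
        registry_offset=0.0, seed=seed, width=6.0, length=420.0,
        psf_sigma=3.0, noise_sigma=0.2,
    )


def _scene_disordered_short(seed: int) -> SceneSpec:
    """Sparse, short, randomly oriented filaments (low-salt-like disorder)."""
    rng = np.random.default_rng(seed)
    filaments = []
    # short rods/filaments on a coarse grid with random orientation
    for gy in range(4):
        for gx in range(4):
            cx = 64 + gx * 128 + rng.uniform(-20, 20)
            cy = 64 + gy * 128 + rng.uniform(-20, 20)
            ang = rng.uniform(0, 180)
            u = np.array([math.cos(math.radians(ang)), math.sin(math.radians(ang))])
            half = rng.choice([16.0, 32.0, 48.0])  # 1-3 rods
            filaments.append(FilamentSpec(
                p0=(cx - half * u[0], cy - half * u[1]),
                p1=(cx + half * u[0], cy + half * u[1]),
                width=6.0,
            ))
    return SceneSpec(filaments=filaments, psf_sigma=3.0, noise_sigma=0.2, seed=seed)


def _scene_wildtype_lipid(seed: int) -> SceneSpec:
    """Isolated filaments carrying one lateral lipid cluster per 32-nm rod."""
    rng = np.random.default_rng(seed)
    filaments = []
    n_fil = 7
    lane_gap = 512.0 / (n_fil + 1)
    for i in range(n_fil):
        yc = (i + 1) * lane_gap
        ang = rng.normal(0.0, 4.0)
        u = np.array([math.cos(math.radians(ang)), math.sin(math.radians(ang))])
        c = np.array([256.0, yc])
        half = 210.0
        filaments.append(FilamentSpec(
            p0=tuple(c - half * u), p1=tuple(c + half * u), width=6.0,
            clusters=True, cluster_side=+1, cluster_spacing=ROD_LENGTH_NM,
        ))
    return SceneSpec(filaments=filaments, psf_sigma=3.0, noise_sigma=0.2, seed=seed)


def _scene_mismatched_pairs(seed: int) -> SceneSpec:
    """Tight pairs staggered by one 4-nm subunit (registry offset 4 nm)."""
    return _paired_scene(
        n_pairs=10, mean_angle=0.0, angle_sigma=2.0, separation=8.0,
        registry_offset=SUBUNIT_LENGTH_NM, seed=seed, width=4.0, length=440.0,
        psf_sigma=1.5, noise_sigma=0.15,
    )


def _scene_tight_pairs(seed: int) -> SceneSpec:
    """4-nm-wide members in lateral (edge) contact: top-to-top ~4 nm."""
    return _paired_scene(
        n_pairs=8, mean_angle=90.0, angle_sigma=2.0, separation=4.0,
        registry_offset=0.0, seed=seed, width=4.0, length=400.0,
        psf_sigma=1.0, noise_sigma=0.1,
    )


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 2-D segments."""
    def _pt_seg(p, a, b):
        ab = b - a
        t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-12), 0.0, 1.0)
        return float(np.linalg.norm(p - (a + t * ab)))

    if _segments_intersect(p0, p1, q0, q1):
        return 0.0
    return min(_pt_seg(p0, q0, q1), _pt_seg(p1, q0, q1),
               _pt_seg(q0, p0, p1), _pt_seg(q1, p0, p1))


def _segments_intersect(p0, p1, q0, q1) -> bool:
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(q0, q1, p0)
    d2 = cross(q0, q1, p1)
    d3 = cross(p0, p1, q0)
    d4 = cross(p0, p1, q1)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _scene_two_layer(seed: int, aligned_fraction: float = 0.8,
                     n_upper: int = 100) -> SceneSpec:
    """Dense aligned first layer plus a second layer, 80% aligned by default.

    The upper layer mixes ``aligned_fraction`` filaments parallel to the
    template (small angular jitter) with the rest at uniform random
    orientations.  Counts are exact (round(n_upper * fraction)), so the
    generated aligned fraction is deterministic.  Upper-layer filaments are
    placed by rejection sampling with a mutual clearance — filaments in one
    layer cannot overlap physically — random-orientation filaments first,
    since they are the hardest to place.
    """
    rng = np.random.default_rng(seed)
    size = (1024, 1024)
    ext = 1024.0
    base_angle = 0.0
    filaments = []
    # layer 1: parallel lanes spanning the frame
    lane_spacing = 13.0
    y = lane_spacing / 2
    while y < ext:
        filaments.append(FilamentSpec(
            p0=(-8.0, y + rng.uniform(-1.0, 1.0)),
            p1=(ext + 8.0, y + rng.uniform(-1.0, 1.0)),
            layer=1, width=6.0, phase=rng.uniform(0, ROD_LENGTH_NM),
        ))
        y += lane_spacing
    # layer 2: exact mixture, non-overlapping placement
    n_aligned = int(round(aligned_fraction * n_upper))
    n_random = n_upper - n_aligned
    length = 160.0
    clearance = 18.0
    placed = []  # (p0, p1) arrays
    angles = [rng.uniform(0.0, 180.0) for _ in range(n_random)]
    angles += [base_angle + rng.normal(0.0, 2.5) for _ in range(n_aligned)]
    for ang in angles:
        u = np.array([math.cos(math.radians(ang)), math.sin(math.radians(ang))])
        half = length / 2
        # progressive clearance relaxation keeps placement deterministic and
        # guarantees termination when the field gets crowded
        placed_ok = False
        clear = clearance
        while not placed_ok and clear >= 10.0:
            for _ in range(3000):
                c = np.array([rng.uniform(95, ext - 95), rng.uniform(95, ext - 95)])
                p0, p1 = c - half * u, c + half * u
                if all(_segment_distance(p0, p1, q0, q1) >= clear
                       for q0, q1 in placed):
                    placed.append((p0, p1))
                    filaments.append(FilamentSpec(
                        p0=tuple(p0), p1=tuple(p1), layer=2, width=8.0,
                        phase=rng.uniform(0, ROD_LENGTH_NM),
                    ))
                    placed_ok = True
                    break
            clear *= 0.85
        if not placed_ok:
            raise RuntimeError("could not place upper-layer filament")
    return SceneSpec(size_px=size, filaments=filaments, psf_sigma=2.0,
                     noise_sigma=0.2, seed=seed)


_SCENE_BUILDERS = {
    "aligned_paired": _scene_aligned_paired,
    "disordered_short": _scene_disordered_short,
    "wildtype_lipid": _scene_wildtype_lipid,
    "mismatched_pairs": _scene_mismatched_pairs,
    "tight_pairs": _scene_tight_pairs,
    "two_layer_80pct": _scene_two_layer,
}

#: Names of the deterministic scene fixtures.
SCENE_NAMES = tuple(sorted(_SCENE_BUILDERS))


def standard_scenes(seed: int = 0) -> dict:
    """Named deterministic scene fixtures.

    - ``aligned_paired``: highly ordered tight pairs (high-salt-like order);
    - ``disordered_short``: sparse short filaments, random orientations;
    - ``wildtype_lipid``: lateral clusters every 32-nm rod, one side;
    - ``mismatched_pairs``: pairs staggered by one 4-nm subunit;
    - ``tight_pairs``: 4-nm-wide members in edge contact (top-to-top ~4 nm);
    - ``two_layer_80pct``: second layer 80% aligned with the template layer.

    The same ``seed`` always yields bit-identical scenes.
    """
    return {name: build(seed) for name, build in _SCENE_BUILDERS.items()}


def scene(name: str, seed: int = 0, **overrides) -> SceneSpec:
    """One named fixture (built lazily), optionally with field overrides."""
    if name not in _SCENE_BUILDERS:
        raise KeyError(f"unknown scene {name!r}; options: {sorted(_SCENE_BUILDERS)}")
    spec = _SCENE_BUILDERS[name](seed)
    if overrides:
        spec = replace(spec, **overrides)
    return spec
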