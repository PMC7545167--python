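"""Morphometry of HS-AFM topographs of septin filament layers.

A topograph is a 2-D height map (nm) with the bare substrate at 0 and each
filament layer ~4 nm tall.  The functions here automate the measurements
used to characterize septin order on such maps:

* surface coverage above a height threshold;
* the filament orientation distribution from a structure-tensor field,
  summarized as the FWHH of a Gaussian fit (alignment score);
* centerline tracing (threshold -> skeletonize -> split at junctions ->
  merge collinear fragments) with per-filament length, axial orientation
  and subunit-peak positions;
* filament length histograms in units of the 32-nm rod;
* the paired fraction of total filament length;
* axial periodicity (autocorrelation of height profiles, or mean
  nearest-neighbor spacing of discrete positions such as lipid clusters);
* the registry (phase) offset between the subunit trains of a filament
  pair — 0 for matched pairs, ~4 nm for a one-subunit stagger;
* layer decomposition into ~4-nm height bands and the angular correlation
  between consecutive layers.

Orientations are axial (filaments are non-polar): all angles live on
[0, 180) degrees and angular differences are taken modulo 180.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max, structure_tensor
from skimage.morphology import skeletonize

logger = logging.getLogger("septasm")

ROD_LENGTH_NM = 32.0
SUBUNIT_LENGTH_NM = 4.0
LAYER_HEIGHT_NM = 4.0


@dataclass
class Topograph:
    """2-D height map in nm with a physical pixel size (nm/pixel)."""

    heights: np.ndarray
    pixel_size: float
    layer_height: float = LAYER_HEIGHT_NM

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise ValueError("heights must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self):
        return self.heights.shape


@dataclass
class Filament:
    """A traced filament centerline.

    ``points`` are (x, y) positions in nm (x = column * pixel_size,
    y = row * pixel_size); ``peaks`` are arc-length positions (nm) of
    subunit/octamer height maxima along the centerline.
    """

    points: np.ndarray
    length: float
    orientation: float  # degrees, axial, in [0, 180)
    peaks: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.peaks = np.asarray(self.peaks, dtype=float)
        if self.length <= 0:
            raise ValueError("filament length must be > 0")
        if not (0.0 <= self.orientation < 180.0):
            raise ValueError("orientation must be in [0, 180)")

    def resample(self, step: float) -> np.ndarray:
        """Equally spaced points (nm) along the centerline."""
        seg = np.diff(self.points, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        s = np.concatenate([[0.0], np.cumsum(seglen)])
        total = s[-1]
        if total <= 0:
            return self.points[:1]
        si = np.arange(0.0, total + step / 2, step)
        x = np.interp(si, s, self.points[:, 0])
        y = np.interp(si, s, self.points[:, 1])
        return np.column_stack([x, y])


@dataclass
class FilamentSet:
    """Collection of traced filaments from one topograph."""

    filaments: list

    def __len__(self) -> int:
        return len(self.filaments)

    def __iter__(self):
        return iter(self.filaments)

    def total_length(self) -> float:
        return float(sum(f.length for f in self.filaments))


@dataclass
class AlignmentResult:
    """Angular distribution summary: Gaussian center/FWHH on [0, 180)."""

    bin_centers: np.ndarray
    histogram: np.ndarray
    center: float
    fwhh: float
    r_squared: float
    multimodal: bool = False


@dataclass
class LayerDecomposition:
    """Per-layer masks, coverages and step heights of a multilayer scene."""

    masks: list  # masks[k]: pixels whose height rounds to layer k (k=0 substrate)
    coverage: np.ndarray  # coverage[k]: fraction of pixels at layer >= k
    mean_heights: np.ndarray  # mean height of pixels in each layer band
    step_heights: np.ndarray  # differences of consecutive mean heights

    @property
    def n_layers(self) -> int:
        return len(self.masks) - 1


def axial_difference(a: float, b: float) -> float:
    """Smallest difference between two axial angles, in [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def surface_coverage(topo: Topograph, threshold: float | None = None) -> float:
    """Fraction of pixels above the height threshold.

    The default threshold is half the layer height (2 nm), separating the
    substrate from the first filament layer.
    """
    if threshold is None:
        threshold = topo.layer_height / 2.0
    h = topo.heights
    if np.all(np.isnan(h)):
        raise ValueError("all-NaN topograph")
    return float(np.mean(h > threshold))


# ---------------------------------------------------------------------------
# Orientation distribution / alignment
# ---------------------------------------------------------------------------

def orientation_field(topo: Topograph, sigma_px: float = 2.0):
    """Per-pixel axial orientation (deg) and coherence from the structure tensor.

    The filament direction is the eigenvector of the structure tensor with
    the smaller eigenvalue (least intensity variation along the ridge).
    """
    arr, arc, acc = structure_tensor(topo.heights, sigma=sigma_px, order="rc")
    # angle of least variation, measured from the +x (column) axis toward +y (row)
    theta = 0.5 * np.arctan2(2 * arc, acc - arr) + np.pi / 2
    theta_deg = np.degrees(theta) % 180.0
    tr = arr + acc
    det_term = np.sqrt((arr - acc) ** 2 + 4 * arc**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(tr > 0, det_term / np.maximum(tr, 1e-30), 0.0)
    energy = tr
    return theta_deg, coherence, energy


def _wrapped_gaussian(x, amp, mu, sigma, base):
    # sum of Gaussian images at mu + 180k — adequate for sigma << 180
    out = np.full_like(np.asarray(x, float), base)
    for k in (-1, 0, 1):
        out = out + amp * np.exp(-((x - mu - 180.0 * k) ** 2) / (2 * sigma**2))
    return out


def orientation_distribution(
    topo: Topograph,
    threshold: float | None = None,
    bin_width: float = 2.0,
    tensor_sigma_px: float = 2.0,
    min_coverage: float = 1e-3,
) -> AlignmentResult:
    """Axial orientation histogram with a Gaussian fit about the mode.

    Covered pixels (above the coverage threshold) contribute their local
    structure-tensor orientation, weighted by tensor coherence.  The FWHH
    of the Gaussian fit (2*sqrt(2 ln 2) * sigma) is the alignment score:
    smaller means better aligned.  If a second histogram peak of comparable
    prominence sits far from the mode, the distribution is flagged
    multimodal and no FWHH is forced (fwhh = nan).
    """
    if threshold is None:
        threshold = topo.layer_height / 2.0
    cov = surface_coverage(topo, threshold)
    if cov < min_coverage:
        raise ValueError(
            f"insufficient signal: coverage {cov:.2g} < {min_coverage:.2g}"
        )
    theta, coherence, _ = orientation_field(topo, sigma_px=tensor_sigma_px)
    mask = topo.heights > threshold
    angles = theta[mask]
    weights = coherence[mask]
    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    hist, _ = np.histogram(angles, bins=edges, weights=weights)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # circular mode via the maximum of the (lightly smoothed) wrapped histogram
    smooth = ndimage.uniform_filter1d(hist.astype(float), size=3, mode="wrap")
    mode = centers[int(np.argmax(smooth))]

    # multimodality: a rival peak of >= 50% prominence further than 30 deg away
    ext = np.concatenate([smooth, smooth, smooth])
    pk, props = find_peaks(ext, prominence=0.5 * smooth.max())
    rivals = []
    for p in pk:
        ang = centers[p % centers.size]
        if axial_difference(ang, mode) > 30.0:
            rivals.append(ang)
    multimodal = len(rivals) > 0
    if multimodal:
        return AlignmentResult(
            bin_centers=centers, histogram=hist, center=float(mode),
            fwhh=float("nan"), r_squared=0.0, multimodal=True,
        )

    # recenter angles on the mode and fit a wrapped Gaussian
    x = (centers - mode + 90.0) % 180.0 - 90.0 + mode
    order = np.argsort(x)
    try:
        popt, _ = curve_fit(
            _wrapped_gaussian, x[order], hist[order],
            p0=[hist.max(), mode, 10.0, 0.0],
            bounds=([0, mode - 90.0, bin_width / 2, 0], [np.inf, mode + 90.0, 90.0, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as err:
        raise ValueError(f"orientation Gaussian fit failed: {err}") from err
    model = _wrapped_gaussian(x[order], *popt)
    ss_res = float(np.sum((hist[order] - model) ** 2))
    ss_tot = float(np.sum((hist - hist.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    fwhh = 2.0 * math.sqrt(2.0 * math.log(2.0)) * float(popt[2])
    return AlignmentResult(
        bin_centers=centers, histogram=hist, center=float(popt[1]) % 180.0,
        fwhh=fwhh, r_squared=r2, multimodal=False,
    )


# ---------------------------------------------------------------------------
# Tracing
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _order_path(pixels: set) -> list:
    """Order a junction-free 8-connected pixel set into a path."""
    if not pixels:
        return []
    neigh = {}
    for p in pixels:
        neigh[p] = [
            (p[0] + dr, p[1] + dc)
            for dr, dc in _NEIGHBORS
            if (p[0] + dr, p[1] + dc) in pixels
        ]
    ends = [p for p, ns in neigh.items() if len(ns) <= 1]
    start = min(ends) if ends else min(pixels)  # closed loops: arbitrary start
    path = [start]
    visited = {start}
    cur = start
    while True:
        nxt = [n for n in neigh[cur] if n not in visited]
        if not nxt:
            break
        # prefer 4-connected continuation to avoid zig-zag skips
        nxt.sort(key=lambda n: abs(n[0] - cur[0]) + abs(n[1] - cur[1]))
        cur = nxt[0]
        visited.add(cur)
        path.append(cur)
    return path


def _polyline_length(points: np.ndarray) -> float:
    seg = np.diff(points, axis=0)
    return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))


def _axial_orientation(points: np.ndarray) -> float:
    """Dominant axis of a polyline via PCA, as an axial angle in degrees."""
    xy = points - points.mean(axis=0)
    cov = xy.T @ xy
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, int(np.argmax(evals))]
    ang = math.degrees(math.atan2(v[1], v[0])) % 180.0
    return ang


def _profile_along(topo: Topograph, points_nm: np.ndarray, step: float = 1.0):
    """Height profile sampled along a polyline (bilinear interpolation)."""
    seg = np.diff(points_nm, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    si = np.arange(0.0, total + step / 2, step)
    x = np.interp(si, s, points_nm[:, 0])
    y = np.interp(si, s, points_nm[:, 1])
    coords = np.vstack([y / topo.pixel_size, x / topo.pixel_size])
    vals = ndimage.map_coordinates(topo.heights, coords, order=1, mode="nearest")
    return si, vals


def _subunit_peaks(
    topo: Topograph, points_nm: np.ndarray, min_spacing: float, prominence: float
) -> np.ndarray:
    step = min(1.0, topo.pixel_size)
    si, vals = _profile_along(topo, points_nm, step=step)
    if si.size < 5:
        return np.empty(0)
    # band-pass matched to the expected repeat: the low-pass suppresses
    # pixel noise, the high-pass removes slow height undulations (trace
    # wander) that would shift the apparent maxima; parabolic refinement
    # recovers sub-sample positions
    v = (
        ndimage.gaussian_filter1d(vals, (min_spacing / 8.0) / step)
        - ndimage.gaussian_filter1d(vals, (min_spacing / 2.0) / step)
    )
    dist = max(int(round(min_spacing / step)), 1)
    pk, _ = find_peaks(v, distance=dist, prominence=prominence)
    out = []
    for k in pk:
        if 1 <= k < v.size - 1:
            y0, y1, y2 = v[k - 1], v[k], v[k + 1]
            den = y0 - 2 * y1 + y2
            d = 0.5 * (y0 - y2) / den if den != 0 else 0.0
            out.append(si[k] + float(np.clip(d, -0.5, 0.5)) * step)
        else:
            out.append(si[k])
    return np.asarray(out)


def trace_filaments(
    topo: Topograph,
    threshold: float | None = None,
    min_length_nm: float = 8.0,
    merge_angle: float = 20.0,
    merge_gap_nm: float = 8.0,
    peak_min_spacing_nm: float = 24.0,
    peak_prominence: float = 0.05,
    denoise_sigma_px: float = 1.5,
) -> FilamentSet:
    """Trace filament centerlines from a height map.

    Pipeline: light Gaussian denoise -> threshold -> drop speck components
    and fill pinholes -> skeletonize -> delete junction pixels (so each
    branch becomes a simple path) -> order each path -> merge fragments
    that are collinear (axial angle difference < ``merge_angle``) and whose
    endpoints are closer than ``merge_gap_nm``.  Fragments shorter than one
    rod are retained (they are adsorbed rods); only traces below
    ``min_length_nm`` (sub-rod noise specks) are dropped.  Subunit-scale
    height peaks along each centerline are recorded for periodicity and
    registry analyses.
    """
    if threshold is None:
        threshold = topo.layer_height / 2.0
    h = topo.heights
    if denoise_sigma_px > 0:
        h = ndimage.gaussian_filter(h, denoise_sigma_px)
    mask = h > threshold
    if not mask.any():
        return FilamentSet(filaments=[])
    # drop components smaller than a rod footprint's worth of pixels,
    # fill pinholes so the skeleton does not loop around them
    min_area = max(int((min_length_nm / topo.pixel_size) ** 2 / 4), 4)
    labels0, n0 = ndimage.label(mask, structure=np.ones((3, 3)))
    if n0:
        sizes = np.bincount(labels0.ravel())
        keep = sizes >= min_area
        keep[0] = False
        mask = keep[labels0]
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return FilamentSet(filaments=[])
    skel = skeletonize(mask)
    # junction removal: pixels with >2 skeleton neighbors
    nb = ndimage.convolve(skel.astype(int), np.ones((3, 3)), mode="constant")
    junctions = skel & (nb - 1 > 2)
    branches = skel & ~junctions
    labels, n = ndimage.label(branches, structure=np.ones((3, 3)))
    pieces = []
    for lab in range(1, n + 1):
        pix = set(map(tuple, np.argwhere(labels == lab)))
        path = _order_path(pix)
        if len(path) < 3:
            continue
        pts = np.array([(c * topo.pixel_size, r * topo.pixel_size) for r, c in path])
        pieces.append(pts)

    pieces = _merge_collinear(pieces, merge_angle, merge_gap_nm)

    filaments = []
    for pts in pieces:
        pts = _smooth_polyline(pts, topo.pixel_size)
        pts = _extend_to_threshold(pts, h, topo.pixel_size, threshold)
        length = _polyline_length(pts)
        if length < min_length_nm:
            continue
        peaks = _subunit_peaks(topo, pts, peak_min_spacing_nm, peak_prominence)
        filaments.append(
            Filament(points=pts, length=length,
                     orientation=_axial_orientation(pts), peaks=peaks)
        )
    return FilamentSet(filaments=filaments)


def _smooth_polyline(pts: np.ndarray, pixel_size: float, sigma_px: float = 2.5) -> np.ndarray:
    """Resample at pixel spacing and low-pass the coordinates.

    Removes the skeleton's pixel staircase, which otherwise inflates arc
    length (and hence apparent axial periods) by several percent.
    """
    seg = np.diff(pts, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    if s[-1] <= 0:
        return pts
    si = np.arange(0.0, s[-1] + pixel_size / 2, pixel_size)
    x = np.interp(si, s, pts[:, 0])
    y = np.interp(si, s, pts[:, 1])
    return np.column_stack([
        ndimage.gaussian_filter1d(x, sigma_px, mode="nearest"),
        ndimage.gaussian_filter1d(y, sigma_px, mode="nearest"),
    ])


def _extend_to_threshold(
    pts: np.ndarray, heights: np.ndarray, pixel_size: float, threshold: float,
    max_extension_px: int = 12,
) -> np.ndarray:
    """Grow both polyline ends along the local tangent while above threshold.

    Compensates the end erosion of skeletonization and coordinate
    smoothing so traced lengths track the physical filament extent.
    """
    if pts.shape[0] < 4:
        return pts
    out = pts
    for end in (0, 1):
        p_end = out[-1] if end else out[0]
        ref = out[-4] if end else out[3]
        t = p_end - ref
        norm = np.hypot(*t)
        if norm == 0:
            continue
        t = t / norm
        added = []
        for k in range(1, max_extension_px + 1):
            q = p_end + t * k * pixel_size
            r, c = q[1] / pixel_size, q[0] / pixel_size
            if not (0 <= r < heights.shape[0] - 1 and 0 <= c < heights.shape[1] - 1):
                break
            val = ndimage.map_coordinates(heights, [[r], [c]], order=1)[0]
            if val <= threshold:
                break
            added.append(q)
        if added:
            out = np.vstack([out, added]) if end else np.vstack([added[::-1], out])
    return out


def _merge_collinear(pieces, merge_angle, merge_gap_nm):
    """Greedy end-to-end merge of collinear polyline fragments."""
    pieces = [np.asarray(p) for p in pieces]
    changed = True
    while changed and len(pieces) > 1:
        changed = False
        out = []
        used = [False] * len(pieces)
        for i in range(len(pieces)):
            if used[i]:
                continue
            a = pieces[i]
            best = None
            for j in range(i + 1, len(pieces)):
                if used[j]:
                    continue
                b = pieces[j]
                if axial_difference(_axial_orientation(a), _axial_orientation(b)) > merge_angle:
                    continue
                # closest pairing of endpoints
                combos = [
                    (np.linalg.norm(a[-1] - b[0]), False, False),
                    (np.linalg.norm(a[-1] - b[-1]), False, True),
                    (np.linalg.norm(a[0] - b[0]), True, False),
                    (np.linalg.norm(a[0] - b[-1]), True, True),
                ]
                d, flip_a, flip_b = min(combos, key=lambda c: c[0])
                if d <= merge_gap_nm:
                    # the connector must run along the filament axis, else the
                    # fragments are side-by-side (e.g. the two members of a
                    # tight pair), not a broken single filament
                    ea = a[0] if flip_a else a[-1]
                    eb = b[-1] if flip_b else b[0]
                    gap_vec = eb - ea
                    if d > 2.0:
                        gap_ang = math.degrees(math.atan2(gap_vec[1], gap_vec[0])) % 180.0
                        if axial_difference(gap_ang, _axial_orientation(a)) > merge_angle:
                            continue
                    best = (j, flip_a, flip_b)
                    break
            if best is not None:
                j, flip_a, flip_b = best
                b = pieces[j]
                aa = a[::-1] if flip_a else a
                bb = b[::-1] if flip_b else b
                out.append(np.vstack([aa, bb]))
                used[i] = used[j] = True
                changed = True
            else:
                out.append(a)
                used[i] = True
        pieces = out
    return pieces


# ---------------------------------------------------------------------------
# Length histogram
# ---------------------------------------------------------------------------

def length_histogram(fs: FilamentSet, rod_length: float = ROD_LENGTH_NM) -> dict:
    """Counts per size bin j = round(length / rod_length), round-half-up, j >= 1.

    Filaments shorter than half a rod still count as single rods (j = 1).
    """
    if len(fs) == 0:
        raise ValueError("empty filament set")
    out: dict[int, int] = {}
    for f in fs:
        j = max(int(math.floor(f.length / rod_length + 0.5)), 1)
        out[j] = out.get(j, 0) + 1
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def pairing_fraction(
    fs: FilamentSet,
    max_gap: float = 10.0,
    angle_tol: float = 15.0,
    sample_step: float = 2.0,
) -> float:
    """Percentage of total centerline length that is paired.

    A centerline sample point is paired when a *different*, roughly
    parallel (axial angle difference <= ``angle_tol``) filament passes
    within ``max_gap`` nm (top-to-top).  Returns 100 * paired length /
    total length, in [0, 100].
    """
    if len(fs) == 0:
        raise ValueError("empty filament set")
    if len(fs) == 1:
        return 0.0
    samples = [f.resample(sample_step) for f in fs]
    paired = 0
    total = 0
    for i, f in enumerate(fs):
        candidates = [
            j for j, g in enumerate(fs.filaments)
            if j != i and axial_difference(f.orientation, g.orientation) <= angle_tol
        ]
        pts = samples[i]
        total += pts.shape[0]
        if not candidates:
            continue
        other = np.vstack([samples[j] for j in candidates])
        tree = cKDTree(other)
        d, _ = tree.query(pts)
        paired += int(np.sum(d <= max_gap))
    return 100.0 * paired / total if total else 0.0


# ---------------------------------------------------------------------------
# Periodicity
# ---------------------------------------------------------------------------

def periodicity_from_profile(
    values, sample_spacing: float, min_period: float = 8.0
) -> float:
    """Dominant spacing (nm) of a 1-D height profile via autocorrelation.

    The profile is mean-subtracted, autocorrelated, and the first
    autocorrelation peak beyond ``min_period`` is returned, with parabolic
    sub-sample refinement.
    """
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("profile too short for periodicity analysis")
    v = v - v.mean()
    # light smoothing so pixel noise does not seed spurious first peaks
    smooth_sigma = 1.0 / sample_spacing
    if smooth_sigma > 0.3:
        v = ndimage.gaussian_filter1d(v, smooth_sigma)
    ac = np.correlate(v, v, mode="full")[v.size - 1:]
    norm = np.arange(v.size, 0, -1)
    ac = ac / norm  # unbiased estimate
    lag0 = max(int(round(min_period / sample_spacing)), 1)
    pk, _ = find_peaks(ac[lag0:], prominence=0.05 * ac[0])
    if pk.size == 0:
        raise ValueError("no periodicity peak found in autocorrelation")
    k = pk[0] + lag0
    # parabolic refinement around the integer-lag peak
    if 1 <= k < ac.size - 1:
        y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return (k + delta) * sample_spacing


def periodicity_from_positions(positions) -> float:
    """Mean nearest-neighbor spacing (nm) of sorted 1-D positions."""
    pos = np.sort(np.asarray(positions, float))
    if pos.size < 3:
        raise ValueError("need >= 3 positions for a spacing estimate")
    return float(np.mean(np.diff(pos)))


def periodicity(signal, sample_spacing: float | None = None) -> float:
    """Dominant spacing of either a height profile or a position list.

    With ``sample_spacing`` the input is a regularly sampled height
    profile (autocorrelation peak); without it the input is a list of
    positions along an axis (mean nearest-neighbor spacing).
    """
    if sample_spacing is None:
        return periodicity_from_positions(signal)
    return periodicity_from_profile(signal, sample_spacing)


def filament_periodicity(topo: Topograph, fil: Filament, step: float = 1.0) -> float:
    """Dominant axial spacing of the height profile along one centerline."""
    si, vals = _profile_along(topo, fil.points, step=step)
    return periodicity_from_profile(vals, si[1] - si[0])


# ---------------------------------------------------------------------------
# Pair registry
# ---------------------------------------------------------------------------

def pair_registry_offset(
    peaks_a, peaks_b, period: float | None = None, resolution: float = 0.05
) -> float:
    """Phase offset (nm) between two periodic peak trains, in [0, period/2].

    The period is estimated from the median peak spacing of each train
    (they must agree within 20%, else the trains are incommensurate and an
    error is raised).  The offset maximizing the cross-correlation of the
    two trains (rendered as narrow Gaussians) is folded into [0, period/2]:
    0 means matched registry, ~4 nm a one-subunit mismatch for the 32-nm
    octamer repeat.
    """
    a = np.sort(np.asarray(peaks_a, float))
    b = np.sort(np.asarray(peaks_b, float))
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 peaks in each train")
    pa = float(np.median(np.diff(a)))
    pb = float(np.median(np.diff(b)))
    if period is None:
        if abs(pa - pb) > 0.2 * max(pa, pb):
            raise ValueError(
                f"incommensurate periods: {pa:.2f} vs {pb:.2f} nm"
            )
        period = 0.5 * (pa + pb)
    sigma = max(period / 16.0, resolution)
    lags = np.arange(0.0, period, resolution)
    # score(lag): how well b - lag lands on a (wrapped to the repeat)
    db = (b[:, None] - lags[None, :])  # (nb, nlag)
    score = np.zeros(lags.size)
    for i in range(lags.size):
        d = np.abs(db[:, i][:, None] - a[None, :])
        d = np.minimum(d % period, period - d % period)
        nearest = d.min(axis=1)
        score[i] = np.sum(np.exp(-(nearest**2) / (2 * sigma**2)))
    best = float(lags[int(np.argmax(score))])
    return min(best, period - best)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def layer_decomposition(topo: Topograph) -> LayerDecomposition:
    """Assign pixels to ~4-nm height bands (layer 0 = substrate).

    Pixel layer index = round(height / layer_height).  Reports per-layer
    masks, the coverage of each layer (fraction of pixels at that layer or
    above), mean band heights, and the step heights between consecutive
    occupied bands.
    """
    u = topo.layer_height
    idx = np.clip(np.round(topo.heights / u).astype(int), 0, None)
    n_layers = int(idx.max())
    masks = [(idx == k) for k in range(n_layers + 1)]
    coverage = np.array([float(np.mean(idx >= k)) for k in range(n_layers + 1)])
    mean_heights = np.array([
        float(topo.heights[m].mean()) if m.any() else np.nan for m in masks
    ])
    steps = np.diff(mean_heights)
    return LayerDecomposition(masks=masks, coverage=coverage,
                              mean_heights=mean_heights, step_heights=steps)


def layer_topograph(
    topo: Topograph, decomp: LayerDecomposition, layer: int, halo_px: int = 6
) -> Topograph:
    """Height map of one layer relative to the layer below, elsewhere 0.

    Useful for tracing the filaments of a single layer: heights are
    re-referenced to (layer-1)*layer_height and pixels outside the layer's
    band are zeroed.  Pixels within ``halo_px`` of any higher layer are
    excluded as well — the blurred skirt of an overlying filament falls
    into this layer's height band and would otherwise trace as spurious
    arcs around the upper filament.
    """
    if layer >= len(decomp.masks):
        raise ValueError(f"scene has no layer {layer}")
    base = (layer - 1) * topo.layer_height
    band = decomp.masks[layer].copy()
    above = np.zeros_like(band)
    for k in range(layer + 1, len(decomp.masks)):
        above |= decomp.masks[k]
    if above.any() and halo_px > 0:
        above = ndimage.binary_dilation(above, iterations=halo_px)
        band &= ~above
    h = np.where(band, topo.heights - base, 0.0)
    h = np.clip(h, 0.0, None)
    return Topograph(heights=h, pixel_size=topo.pixel_size,
                     layer_height=topo.layer_height)


def interlayer_angular_correlation(
    lower: FilamentSet, upper: FilamentSet, tol: float = 10.0
) -> float:
    """Percentage of upper-layer filaments aligned with the local sub-layer.

    Each upper filament is compared (axially, modulo 180) with the nearest
    lower-layer filament — nearest by distance from the upper filament's
    midpoint to the lower centerlines.  Alignment within ``tol`` degrees
    counts; the result is in [0, 100].
    """
    if len(lower) == 0 or len(upper) == 0:
        raise ValueError("both layers must contain filaments")
    lower_pts = []
    lower_ang = []
    for g in lower:
        pts = g.resample(4.0)
        # local tangent angle at each sample point (more robust than one
        # per-filament orientation when the lower layer is fragmented)
        tang = np.gradient(pts, axis=0)
        ang = np.degrees(np.arctan2(tang[:, 1], tang[:, 0])) % 180.0
        lower_pts.append(pts)
        lower_ang.append(ang)
    lower_pts = np.vstack(lower_pts)
    lower_ang = np.concatenate(lower_ang)
    tree = cKDTree(lower_pts)
    aligned = 0
    for f in upper:
        mid = f.points[f.points.shape[0] // 2]
        # circular mean (axial, doubled angles) over the nearest lower
        # samples, inverse-distance weighted — one stray fragment cannot
        # dominate the local template orientation
        dist, idx = tree.query(mid, k=min(12, lower_ang.size))
        dist = np.atleast_1d(dist)
        idx = np.atleast_1d(idx)
        w = 1.0 / np.maximum(dist, 1.0)
        doubled = np.radians(2.0 * lower_ang[idx])
        local = 0.5 * math.degrees(math.atan2(
            float(np.sum(w * np.sin(doubled))), float(np.sum(w * np.cos(doubled)))
        )) % 180.0
        if axial_difference(f.orientation, local) <= tol:
            aligned += 1
    return 100.0 * aligned / len(upper)


# ---------------------------------------------------------------------------
# Paired-filament profiles (top-to-top)
# ---------------------------------------------------------------------------

def paired_centerlines(
    topo: Topograph,
    trace: Filament,
    max_sep: float = 16.0,
    step: float = 2.0,
):
    """Recover the two member top-lines of a filament pair from cross-sections.

    Tightly paired filaments blur into a single mask, so the merged
    skeleton runs between the two tops.  At regular stations along the
    merged trace, the perpendicular height profile is sampled and its two
    local maxima (parabolically refined) give the member top positions.
    Returns (line_a, line_b, distances): two (n, 2) nm polylines and the
    per-station top-to-top distances (nm).  Stations where the cross
    profile is not bimodal are skipped.
    """
    pts = trace.resample(step)
    if pts.shape[0] < 3:
        raise ValueError("trace too short")
    ds = max(topo.pixel_size / 2.0, 0.5)
    offsets = np.arange(-max_sep, max_sep + ds / 2, ds)
    line_a, line_b, dists = [], [], []
    for i in range(1, pts.shape[0] - 1):
        tangent = pts[i + 1] - pts[i - 1]
        norm = np.hypot(*tangent)
        if norm == 0:
            continue
        tangent = tangent / norm
        normal = np.array([-tangent[1], tangent[0]])
        coords_nm = pts[i][None, :] + offsets[:, None] * normal[None, :]
        rows = coords_nm[:, 1] / topo.pixel_size
        cols = coords_nm[:, 0] / topo.pixel_size
        prof = ndimage.map_coordinates(topo.heights, np.vstack([rows, cols]),
                                       order=1, mode="nearest")
        pk, _ = find_peaks(prof, prominence=0.05 * max(prof.max(), 1e-9))
        if pk.size < 2:
            continue
        # two strongest maxima, ordered along the normal
        top2 = pk[np.argsort(prof[pk])[-2:]]
        top2 = np.sort(top2)
        refined = []
        for k in top2:
            if 1 <= k < prof.size - 1:
                y0, y1, y2 = prof[k - 1], prof[k], prof[k + 1]
                den = y0 - 2 * y1 + y2
                d = 0.5 * (y0 - y2) / den if den != 0 else 0.0
                refined.append(offsets[k] + float(np.clip(d, -0.5, 0.5)) * ds)
            else:
                refined.append(offsets[k])
        a_pt = pts[i] + refined[0] * normal
        b_pt = pts[i] + refined[1] * normal
        line_a.append(a_pt)
        line_b.append(b_pt)
        dists.append(abs(refined[1] - refined[0]))
    if not dists:
        raise ValueError("no bimodal cross-sections found: not a resolved pair")
    return np.asarray(line_a), np.asarray(line_b), np.asarray(dists)


def peak_positions_xy(fil: Filament) -> np.ndarray:
    """2-D (x, y) nm positions of a filament's subunit/octamer peaks."""
    seg = np.diff(fil.points, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    x = np.interp(fil.peaks, s, fil.points[:, 0])
    y = np.interp(fil.peaks, s, fil.points[:, 1])
    return np.column_stack([x, y])


def registry_offset_for_pair(fa: Filament, fb: Filament) -> float:
    """Registry offset (nm) between two traced pair members.

    The peak trains of both filaments are projected onto their mean axial
    direction so the phase comparison happens in a shared coordinate, then
    folded into [0, period/2] — 0 for matched pairs, ~4 nm for a
    one-subunit stagger of the 32-nm repeat.
    """
    if fa.peaks.size < 3 or fb.peaks.size < 3:
        raise ValueError("need >= 3 subunit peaks on both pair members")
    # mean axial direction (axial angles: average via doubled-angle vectors)
    angs = np.radians([2 * fa.orientation, 2 * fb.orientation])
    mean_ang = 0.5 * math.atan2(np.sin(angs).mean(), np.cos(angs).mean())
    pa = project_onto_axis(peak_positions_xy(fa), math.degrees(mean_ang))
    pb = project_onto_axis(peak_positions_xy(fb), math.degrees(mean_ang))
    return pair_registry_offset(pa, pb)


def detect_clusters(
    topo: Topograph, min_height: float, min_distance_nm: float = 10.0
) -> np.ndarray:
    """Local height maxima above ``min_height``, as (x, y) nm positions.

    Intended for laterally bound globular clusters that protrude above the
    filament layer.
    """
    min_dist_px = max(int(round(min_distance_nm / topo.pixel_size)), 1)
    peaks_rc = peak_local_max(
        topo.heights, min_distance=min_dist_px, threshold_abs=min_height,
        exclude_border=False,
    )
    if peaks_rc.size == 0:
        return np.empty((0, 2))
    return np.column_stack([
        peaks_rc[:, 1] * topo.pixel_size, peaks_rc[:, 0] * topo.pixel_size
    ])


def project_onto_axis(points_xy: np.ndarray, orientation_deg: float) -> np.ndarray:
    """Project 2-D points (nm) onto an axis with the given axial direction."""
    th = math.radians(orientation_deg)
    axis = np.array([math.cos(th), math.sin(th)])
    return np.asarray(points_xy, float) @ axis
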