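"""Size-structured coagulation model of septin surface assembly.

Septin hetero-octamers ("rods", ~32 nm) adsorb onto a supported surface and
grow into filaments by end-on annealing of diffusing reactants.  The model
tracks the surface density f(t, j) (unit: um^-2) of assemblies of j rods and
evolves it with a Smoluchowski-type coagulation equation fed by a sigmoidal
monomer source:

    df(t,j)/dt = d/dt[a / (1 + exp(-b (t - c)))] * delta_{j,1}        (source)
               + 2 K(1, j-1) f(t,1) f(t,j-1) - 2 K(1, j) f(t,1) f(t,j)
               + sum_{i=2}^{j-2} K(i, j-i) f(t,i) f(t,j-i)
               - sum_{k=2}^{Jmax} K(j, k) f(t,j) f(t,k)

with the generalized sum kernel

    K(r, s) = k_P (r^-alpha + s^-alpha),

so that small, mobile assemblies anneal faster than large, sluggish ones.
The update is the explicit first-order recurrence
f(t+dt, j) = f(t, j) + df(t, j)/dt * dt with dt = 1 s by default.

Two bookkeeping conventions are provided (see :class:`SimulationConfig`):

``as_printed``
    The four terms above applied literally.  The gain factors are doubled
    for hetero-collisions while the losses are not, so total rod mass is
    not an exact invariant; this convention reproduces the published fits.
``mass_conserving``
    The standard symmetric Smoluchowski factors (1/2 on the ordered-pair
    gain sum, full loss sum over all partners) so that the total rod mass
    sum_j j*f(j) changes only through the source term — used for physical
    sanity checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("septasm")

#: Physical footprint of one rod: 32 nm x 4 nm in um^2.
ROD_FOOTPRINT_UM2 = 32e-3 * 4e-3

#: Published best-fit kernel parameters (600 mM KCl, pH 5.8 condition).
BEST_FIT_HIGH_SALT = {"alpha": 5.6, "k_p": 1.8e-5}
#: Published best-fit kernel parameters (150 mM KCl, pH 7.5 condition).
BEST_FIT_LOW_SALT = {"alpha": 5.6, "k_p": 9.1e-7}


class IntegrationError(RuntimeError):
    """Raised when an explicit step produces unphysical densities."""


@dataclass(frozen=True)
class KernelParams:
    """Annealing-rate parameters of the generalized sum kernel.

    Parameters
    ----------
    k_p : float
        Diffusivity prefactor, um^2 s^-1; must be > 0 (0 allowed to switch
        annealing off entirely in limit tests).
    alpha : float
        Mobility exponent (dimensionless, >= 0).  Larger alpha penalizes
        the mobility of large assemblies more strongly.
    """

    k_p: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.k_p >= 0 and math.isfinite(self.k_p)):
            raise ValueError(f"k_p must be finite and >= 0, got {self.k_p}")
        if not (self.alpha >= 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha}")


@dataclass(frozen=True)
class SigmoidParams:
    """Three-parameter logistic describing the surface-coverage trace.

    coverage(t) = a / (1 + exp(-b (t - c)))

    a is the plateau (coverage fraction, or density amplitude after
    footprint scaling), b the steepness in s^-1, c the midpoint time in s.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"plateau a must be >= 0, got {self.a}")
        if self.b <= 0:
            raise ValueError(f"steepness b must be > 0, got {self.b}")
        if self.c < 0:
            raise ValueError(f"midpoint c must be >= 0, got {self.c}")

    def coverage(self, t):
        """Sigmoid value at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        return self.a / (1.0 + np.exp(-self.b * (t - self.c)))


@dataclass
class SizeDistribution:
    """Surface densities of assemblies of j = 1..J_max rods at one time.

    ``f[j-1]`` is the density (um^-2) of j-rod assemblies.
    """

    t: float
    f: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 1 or self.f.size < 2:
            raise ValueError("f must be a 1-D vector of length >= 2")
        if np.any(self.f < 0):
            raise ValueError("densities must be non-negative")

    @property
    def j_max(self) -> int:
        return self.f.size

    def total_rods(self) -> float:
        """Total rod mass sum_j j*f(j), um^-2."""
        j = np.arange(1, self.f.size + 1)
        return float(np.dot(j, self.f))


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical configuration of the explicit recurrence.

    dt defaults to 1 s and J_max to 12, matching the published scheme.
    ``rod_footprint`` (um^2) converts d(coverage)/dt into a rod source
    density; the default is the 32 nm x 4 nm rod footprint.
    """

    dt: float = 1.0
    j_max: int = 12
    t_end: float = 300.0
    balance_mode: str = "as_printed"  # or "mass_conserving"
    overflow_mode: str = "discard"  # or "aggregate_at_Jmax"
    rod_footprint: float = ROD_FOOTPRINT_UM2
    scan_area: float = 1.0
    clip_tolerance_factor: float = 1e-12

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.j_max < 2:
            raise ValueError("j_max must be >= 2")
        if self.t_end < self.dt:
            raise ValueError("t_end must be >= dt")
        if self.balance_mode not in ("as_printed", "mass_conserving"):
            raise ValueError(f"unknown balance_mode {self.balance_mode!r}")
        if self.overflow_mode not in ("discard", "aggregate_at_Jmax"):
            raise ValueError(f"unknown overflow_mode {self.overflow_mode!r}")
        if self.rod_footprint <= 0:
            raise ValueError("rod_footprint must be > 0")


@dataclass
class HistogramSeries:
    """Per-time-point size histograms over j = 1..J_max.

    ``populations[i]`` is the vector over j at ``times[i]``.  When
    ``normalized`` each non-empty slice sums to 1; all-zero slices are
    listed in ``empty_slices`` and left as zeros.
    """

    times: np.ndarray
    populations: np.ndarray
    normalized: bool = True
    empty_slices: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        if self.populations.ndim != 2:
            raise ValueError("populations must be 2-D (time x size)")
        if self.populations.shape[0] != self.times.size:
            raise ValueError("times and populations disagree in length")
        if self.normalized:
            sums = self.populations.sum(axis=1)
            nonzero = ~np.isin(np.arange(self.times.size), self.empty_slices)
            if np.any(np.abs(sums[nonzero] - 1.0) > 1e-9):
                raise ValueError("normalized slices must sum to 1 +- 1e-9")

    @property
    def j_max(self) -> int:
        return self.populations.shape[1]


def normalize_histograms(
    times: np.ndarray, counts: np.ndarray
) -> HistogramSeries:
    """Normalize each time slice to sum 1; all-zero slices are flagged."""
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=1)
    empty = [int(i) for i in np.nonzero(sums <= 0)[0]]
    pops = counts.copy()
    nonzero = sums > 0
    pops[nonzero] = counts[nonzero] / sums[nonzero, None]
    return HistogramSeries(times=np.asarray(times, float), populations=pops,
                           normalized=True, empty_slices=empty)


# ---------------------------------------------------------------------------
# Kernel and source
# ---------------------------------------------------------------------------

def kernel_rate(r: int, s: int, params: KernelParams) -> float:
    """Annealing rate constant K(r, s) = k_P (r^-alpha + s^-alpha), um^2/s.

    Symmetric in (r, s) and non-increasing in each argument for alpha > 0.
    """
    for name, v in (("r", r), ("s", s)):
        if not float(v).is_integer() or v < 1:
            raise ValueError(f"size {name} must be a positive integer, got {v}")
    r, s = int(r), int(s)
    return params.k_p * (r ** -params.alpha + s ** -params.alpha)


def kernel_matrix(j_max: int, params: KernelParams) -> np.ndarray:
    """K(r, s) tabulated for r, s = 1..j_max (shape j_max x j_max)."""
    j = np.arange(1, j_max + 1, dtype=float)
    mob = j ** -params.alpha
    return params.k_p * (mob[:, None] + mob[None, :])


def adsorption_rate(t, sig: SigmoidParams):
    """Rod adsorption rate: the time derivative of the coverage sigmoid.

    d/dt [a / (1 + e^{-b(t-c)})] = a b e^{-b(t-c)} / (1 + e^{-b(t-c)})^2,
    non-negative everywhere and maximal (a*b/4) at t = c.
    """
    t = np.asarray(t, dtype=float)
    # Write in terms of the sigmoid value for overflow safety at large |t-c|.
    sigval = 1.0 / (1.0 + np.exp(-sig.b * (t - sig.c)))
    out = sig.a * sig.b * sigval * (1.0 - sigval)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Explicit recurrence
# ---------------------------------------------------------------------------

def _rate_of_change(
    f: np.ndarray,
    kmat: np.ndarray,
    source: float,
    balance_mode: str,
    overflow_mode: str,
) -> np.ndarray:
    """Right-hand side df/dt for one state, excluding the time step."""
    jmax = f.size
    df = np.zeros(jmax)
    df[0] += source

    if balance_mode == "as_printed":
        f1 = f[0]
        # monomer-addition gain: +2 K(1, j-1) f1 f_{j-1} for j >= 2
        df[1:] += 2.0 * kmat[0, : jmax - 1] * f1 * f[: jmax - 1]
        # monomer-addition loss: -2 K(1, j) f1 f_j for all j
        df -= 2.0 * kmat[0, :] * f1 * f
        # filament-filament gain: sum_{i=2}^{j-2} K(i, j-i) f_i f_{j-i}
        for j in range(4, jmax + 1):
            i = np.arange(2, j - 1)
            df[j - 1] += float(np.sum(kmat[i - 1, j - i - 1] * f[i - 1] * f[j - i - 1]))
        # filament-filament loss: -sum_{k=2}^{Jmax} K(j, k) f_j f_k for j >= 2
        df[1:] -= f[1:] * (kmat[1:, 1:] @ f[1:])
        if overflow_mode == "aggregate_at_Jmax":
            # products j = i + k > Jmax from the monomer and filament channels,
            # folded into the top bin as mass-equivalent counts (i+k)/Jmax.
            over = 0.0
            # monomer channel: (1, k) with 1 + k > jmax, i.e. k = jmax only
            over += 2.0 * kmat[0, jmax - 1] * f[0] * f[jmax - 1] * (1 + jmax) / jmax
            for i in range(2, jmax + 1):
                for k in range(max(2, jmax + 1 - i), jmax + 1):
                    over += 0.5 * kmat[i - 1, k - 1] * f[i - 1] * f[k - 1] * (i + k) / jmax
            df[jmax - 1] += over
    else:  # mass_conserving
        loss_partner = kmat @ f  # sum_k K(j,k) f_k over all k = 1..Jmax
        df -= f * loss_partner
        for j in range(2, jmax + 1):
            i = np.arange(1, j)
            df[j - 1] += 0.5 * float(
                np.sum(kmat[i - 1, j - i - 1] * f[i - 1] * f[j - i - 1])
            )
        if overflow_mode == "aggregate_at_Jmax":
            over = 0.0
            for i in range(1, jmax + 1):
                for k in range(max(1, jmax + 1 - i), jmax + 1):
                    over += 0.5 * kmat[i - 1, k - 1] * f[i - 1] * f[k - 1] * (i + k) / jmax
            df[jmax - 1] += over
    return df


def step(
    dist: SizeDistribution,
    params: KernelParams,
    sig: SigmoidParams,
    cfg: SimulationConfig,
    kmat: np.ndarray | None = None,
) -> SizeDistribution:
    """One explicit update f(t+dt) = f(t) + df/dt * dt.

    The monomer source injects the adsorption rate divided by the rod
    footprint (coverage/s -> rods um^-2 s^-1), evaluated at the current t.
    Small negative excursions (below ``clip_tolerance_factor * max(f)``)
    are clipped to zero silently; larger ones are clipped with a warning;
    excursions beyond 10% of the bin scale raise :class:`IntegrationError`.
    """
    if dist.j_max != cfg.j_max:
        raise ValueError(
            f"distribution has J_max={dist.j_max}, config expects {cfg.j_max}"
        )
    if kmat is None:
        kmat = kernel_matrix(cfg.j_max, params)
    source = adsorption_rate(dist.t, sig) / cfg.rod_footprint
    df = _rate_of_change(f=dist.f, kmat=kmat, source=source,
                         balance_mode=cfg.balance_mode,
                         overflow_mode=cfg.overflow_mode)
    f_new = dist.f + df * cfg.dt
    fmax = float(np.max(np.abs(f_new))) if f_new.size else 0.0
    neg = f_new < 0
    if np.any(neg):
        worst = float(-f_new[neg].min())
        if fmax > 0 and worst > 0.1 * fmax:
            raise IntegrationError(
                f"density undershoot {worst:.3g} exceeds 10% of scale "
                f"{fmax:.3g} at t={dist.t:.3g}s; reduce dt"
            )
        if fmax > 0 and worst > cfg.clip_tolerance_factor * fmax:
            logger.warning(
                "clipping negative densities (worst %.3g, scale %.3g) at t=%.3g s",
                worst, fmax, dist.t,
            )
        f_new = np.where(neg, 0.0, f_new)
    return SizeDistribution(t=dist.t + cfg.dt, f=f_new)


def simulate(
    params: KernelParams,
    sig: SigmoidParams,
    cfg: SimulationConfig,
    initial: SizeDistribution | None = None,
    return_trajectory: bool = False,
):
    """Integrate the recurrence from t = 0 to t_end.

    Returns a normalized :class:`HistogramSeries` (populations of j-mers per
    time point normalized to 1, all-zero slices flagged).  With
    ``return_trajectory`` also returns the raw density trajectory as an
    (n_times, J_max) array of um^-2 values.

    Deterministic: no randomness enters the integration.
    """
    n_steps = int(round(cfg.t_end / cfg.dt))
    times = np.arange(n_steps + 1) * cfg.dt
    if initial is None:
        dist = SizeDistribution(t=0.0, f=np.zeros(cfg.j_max))
    else:
        dist = SizeDistribution(t=0.0, f=np.asarray(initial.f, float).copy())
    kmat = kernel_matrix(cfg.j_max, params)
    traj = np.empty((n_steps + 1, cfg.j_max))
    traj[0] = dist.f
    for i in range(n_steps):
        dist = step(dist, params, sig, cfg, kmat=kmat)
        traj[i + 1] = dist.f
    series = normalize_histograms(times, traj)
    if return_trajectory:
        return series, traj
    return series


def coverage_from_distribution(dist: SizeDistribution, cfg: SimulationConfig) -> float:
    """Surface coverage fraction implied by a size distribution.

    sum_j j * f(j) * rod_footprint — i.e. total rod mass times the area a
    rod occupies; in [0, ~1] for physical states.
    """
    return dist.total_rods() * cfg.rod_footprint


def replace_config(cfg: SimulationConfig, **kwargs) -> SimulationConfig:
    """Functional update helper for frozen configs."""
    return replace(cfg, **kwargs)
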