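"""Parameter estimation: adsorption sigmoid fits and SSE grid search.

The assembly model has two free kernel parameters, the mobility exponent
alpha and the diffusivity prefactor k_P.  They are estimated exactly as in
the published workflow: simulate normalized length-histogram time series on
a grid of (alpha, k_P), score each simulation against the experimental
histograms with a sum of squared errors scaled by the number of
experimental histograms, and take the grid argmin.  The adsorption sigmoid
a / (1 + exp(-b (t - c))) is fitted to the coverage trace beforehand and
held fixed during the grid search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .kinetics import (
    HistogramSeries,
    KernelParams,
    SigmoidParams,
    SimulationConfig,
    simulate,
)

logger = logging.getLogger("septasm")


class FitError(RuntimeError):
    """Raised when a least-squares fit fails to converge."""


@dataclass
class SigmoidFit:
    """Result of a coverage-trace sigmoid fit."""

    params: SigmoidParams
    residual: float  # root-mean-square residual of the fit
    degenerate: bool = False  # flat/zero trace: parameters not identifiable


@dataclass
class SSEMap:
    """SSE landscape over an (alpha, k_P) grid.

    ``sse[i, j]`` scores ``alpha_grid[i]`` with ``kp_grid[j]``.
    ``min_path`` holds, per alpha, the best k_P and its SSE (the red trace
    of the published maps); ``best`` is the global argmin.
    """

    alpha_grid: np.ndarray
    kp_grid: np.ndarray
    sse: np.ndarray
    min_path: list = field(default_factory=list)  # (alpha, kp, sse) per row
    best: tuple = ()  # (alpha, kp, sse)

    def __post_init__(self) -> None:
        self.alpha_grid = np.asarray(self.alpha_grid, float)
        self.kp_grid = np.asarray(self.kp_grid, float)
        self.sse = np.asarray(self.sse, float)
        if self.sse.shape != (self.alpha_grid.size, self.kp_grid.size):
            raise ValueError("sse matrix shape must be (n_alpha, n_kp)")


def _sigmoid(t, a, b, c):
    return a / (1.0 + np.exp(-b * (t - c)))


def fit_sigmoid(
    times,
    coverage,
    max_restarts: int = 5,
    seed: int = 0,
) -> SigmoidFit:
    """Least-squares fit of the three-parameter coverage sigmoid.

    ``a`` is constrained to [0, 1.2] (coverage cannot much exceed a full
    monolayer) and ``b`` to be positive.  On convergence failure the fit is
    restarted from jittered initial guesses up to ``max_restarts`` times.
    A trace with negligible dynamic range is returned with a ~ 0 and the
    ``degenerate`` flag set instead of an error.
    """
    t = np.asarray(times, float)
    y = np.asarray(coverage, float)
    if t.size < 4:
        raise ValueError("need at least 4 time points to fit a sigmoid")
    if np.any((y < -1e-9) | (y > 1.0 + 1e-9)):
        raise ValueError("coverage values must lie in [0, 1]")

    span = float(y.max() - y.min())
    if span < 1e-6:
        params = SigmoidParams(a=max(float(y.max()), 0.0) or 0.0, b=1.0, c=max(float(t.mean()), 0.0)) \
            if y.max() > 0 else SigmoidParams(a=0.0, b=1.0, c=max(float(t.mean()), 0.0))
        return SigmoidFit(params=params, residual=float(np.std(y)), degenerate=True)

    # initial guesses: plateau from the top of the trace, midpoint where the
    # trace crosses half-plateau, steepness from the 10-90% rise time.
    a0 = float(y.max())
    half_idx = int(np.argmin(np.abs(y - a0 / 2)))
    c0 = float(t[half_idx])
    rise = np.where((y > 0.1 * a0) & (y < 0.9 * a0))[0]
    b0 = 4.0 / max(float(t[rise[-1]] - t[rise[0]]), float(t[1] - t[0])) if rise.size >= 2 else 0.1
    rng = np.random.default_rng(seed)

    bounds = ([0.0, 1e-9, 0.0], [1.2, np.inf, np.inf])
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        p0 = [a0, b0, max(c0, 0.0)]
        if attempt > 0:
            p0 = [
                min(max(a0 * rng.uniform(0.5, 1.5), 1e-3), 1.2),
                b0 * rng.uniform(0.3, 3.0),
                max(c0 * rng.uniform(0.5, 1.5), 0.0),
            ]
        try:
            popt, _ = curve_fit(_sigmoid, t, y, p0=p0, bounds=bounds, maxfev=20000)
            resid = float(np.sqrt(np.mean((_sigmoid(t, *popt) - y) ** 2)))
            return SigmoidFit(
                params=SigmoidParams(a=float(popt[0]), b=float(popt[1]), c=float(popt[2])),
                residual=resid,
            )
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
    raise FitError(
        f"sigmoid fit failed after {max_restarts} restarts: {last_err}"
    )


def sse(sim: HistogramSeries, exp: HistogramSeries) -> float:
    """Sum of squared errors between simulated and experimental histograms.

    Sums (sim - exp)^2 over all size bins and experimental time points,
    then divides by the number of experimental histograms so the score does
    not grow with the sampling density.  The simulated series is sampled at
    the experimental times by nearest-step lookup.  Experimental all-zero
    slices (flagged on normalization) are excluded.
    """
    if sim.j_max != exp.j_max:
        raise ValueError(
            f"size ranges differ: sim J_max={sim.j_max}, exp J_max={exp.j_max}"
        )
    usable = [i for i in range(exp.times.size) if i not in set(exp.empty_slices)]
    if not usable:
        raise ValueError("no non-empty experimental histograms to compare")
    total = 0.0
    for i in usable:
        k = int(np.argmin(np.abs(sim.times - exp.times[i])))
        diff = sim.populations[k] - exp.populations[i]
        total += float(np.dot(diff, diff))
    return total / len(usable)


def grid_search(
    exp: HistogramSeries,
    sig: SigmoidParams,
    alpha_grid,
    kp_grid,
    cfg: SimulationConfig,
) -> SSEMap:
    """Exhaustive SSE scan over an (alpha, k_P) grid.

    One deterministic simulation per grid point.  Failed simulations are
    recorded as NaN cells, logged, and excluded from the argmin.
    """
    alpha_grid = np.asarray(alpha_grid, float)
    kp_grid = np.asarray(kp_grid, float)
    if alpha_grid.size == 0 or kp_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")
    sse_mat = np.full((alpha_grid.size, kp_grid.size), np.nan)
    for i, alpha in enumerate(alpha_grid):
        for j, kp in enumerate(kp_grid):
            try:
                sim = simulate(KernelParams(k_p=float(kp), alpha=float(alpha)), sig, cfg)
                sse_mat[i, j] = sse(sim, exp)
            except Exception as err:
                logger.warning(
                    "simulation failed at alpha=%.3g, k_p=%.3g: %s", alpha, kp, err
                )
    if np.all(np.isnan(sse_mat)):
        raise FitError("every grid point failed to simulate")
    min_path = []
    for i, alpha in enumerate(alpha_grid):
        row = sse_mat[i]
        if np.all(np.isnan(row)):
            min_path.append((float(alpha), np.nan, np.nan))
            continue
        j = int(np.nanargmin(row))
        min_path.append((float(alpha), float(kp_grid[j]), float(row[j])))
    flat = int(np.nanargmin(sse_mat))
    bi, bj = np.unravel_index(flat, sse_mat.shape)
    best = (float(alpha_grid[bi]), float(kp_grid[bj]), float(sse_mat[bi, bj]))
    return SSEMap(alpha_grid=alpha_grid, kp_grid=kp_grid, sse=sse_mat,
                  min_path=min_path, best=best)


def default_alpha_grid() -> np.ndarray:
    """Default mobility-exponent grid: 0 to 10 in steps of 0.2."""
    return np.round(np.arange(0.0, 10.0 + 1e-9, 0.2), 10)


def default_kp_grid(n: int = 30) -> np.ndarray:
    """Default log-spaced k_P grid spanning 1e-8 to 1e-3 um^2/s."""
    return np.logspace(-8, -3, n)
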