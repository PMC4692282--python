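"""Noise-level inference by summary-statistic contour intersection.

The intrinsic noise scale Omega and the extrinsic parameter-variability
CV Gamma are not separately identifiable from the amplitude CV alone: a
decrease in intrinsic noise can be compensated by more parameter
variability.  They are identifiable jointly because intrinsic noise
dominates the decay of sister-cell correlations while extrinsic noise
dominates amplitude variability.  The estimator scans simulations over an
(Omega, Gamma) grid, maps the amplitude-CV mismatch |CV_sim - CV_ref| and
the L2 mismatch of the sister-correlation function, extracts the
Gamma-minimising contour of each map per Omega, and returns the crossing
of the two contours.  A failure to cross (beyond grid resolution) is a
meaningful outcome: it is what happens when the model lacks lineage
memory (q = 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .lineage import LineageTree
from .stats import SummaryStats, corr_distance, cv_distance, summarize

__all__ = ["NoiseGrid", "NoiseEstimate", "scan_grid", "min_contours",
           "intersect_contours"]

#: simulator signature: (omega, gamma, seed) -> list of LineageTree
Simulator = Callable[[float, float, int], list[LineageTree]]


@dataclass
class NoiseGrid:
    omega_values: np.ndarray
    gamma_values: np.ndarray
    cv_map: np.ndarray  # |CV_sim - CV_ref|, shape (n_omega, n_gamma)
    corr_map: np.ndarray  # L2 correlation distance, same shape

    def __post_init__(self) -> None:
        self.omega_values = np.asarray(self.omega_values, dtype=float)
        self.gamma_values = np.asarray(self.gamma_values, dtype=float)
        shape = (self.omega_values.size, self.gamma_values.size)
        if self.cv_map.shape != shape or self.corr_map.shape != shape:
            raise ValueError("map shapes must be (n_omega, n_gamma)")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, om in enumerate(self.omega_values):
            for j, ga in enumerate(self.gamma_values):
                rows.append((om, ga, self.cv_map[i, j], self.corr_map[i, j]))
        return pd.DataFrame(rows, columns=["omega", "gamma", "cv_distance",
                                           "corr_distance"])


@dataclass
class Contour:
    """Per-Omega minimising Gamma curve of one distance map."""

    omegas: np.ndarray
    gammas: np.ndarray


@dataclass
class NoiseEstimate:
    omega_hat: float | None
    gamma_hat: float | None
    intersected: bool
    cv_contour: Contour
    corr_contour: Contour

    def to_dict(self) -> dict:
        return {
            "omega_hat": self.omega_hat,
            "gamma_hat": self.gamma_hat,
            "intersected": self.intersected,
            "cv_contour": {"omega": self.cv_contour.omegas.tolist(),
                           "gamma": self.cv_contour.gammas.tolist()},
            "corr_contour": {"omega": self.corr_contour.omegas.tolist(),
                             "gamma": self.corr_contour.gammas.tolist()},
        }


def scan_grid(
    reference: SummaryStats,
    simulate: Simulator,
    omega_values: Sequence[float],
    gamma_values: Sequence[float],
    seed: int = 0,
    max_lag: float = 30.0,
) -> NoiseGrid:
    """Fill the two distance maps over the (Omega, Gamma) grid.

    Each grid cell runs ``simulate`` with a seed derived deterministically
    from ``seed`` and the cell indices, summarises the resulting lineages,
    and records |CV_sim - CV_ref| and the L2 correlation distance over the
    shared lag range.  Cells whose simulations yield too few peaks for the
    statistics are recorded as +inf.
    """
    omega_values = np.asarray(sorted(omega_values), dtype=float)
    gamma_values = np.asarray(sorted(gamma_values), dtype=float)
    cv_map = np.full((omega_values.size, gamma_values.size), np.inf)
    corr_map = np.full_like(cv_map, np.inf)
    for i, om in enumerate(omega_values):
        for j, ga in enumerate(gamma_values):
            cell_seed = int(
                np.random.SeedSequence((seed, i, j)).generate_state(1)[0]
                % (2**31 - 1)
            )
            trees = simulate(float(om), float(ga), cell_seed)
            try:
                s = summarize(trees, max_lag=max_lag)
                cv_map[i, j] = cv_distance(s.amplitude_cv,
                                           reference.amplitude_cv)
                corr_map[i, j] = corr_distance(s.corr, reference.corr)
            except ValueError:
                pass  # too few peaks / no shared lags: leave +inf sentinel
    return NoiseGrid(omega_values, gamma_values, cv_map, corr_map)


def _column_min(gammas: np.ndarray, col: np.ndarray) -> float | None:
    """Gamma minimising one map column, with quadratic sub-grid refinement.

    Ties break toward the smallest Gamma.  Returns None for all-infinite
    columns.
    """
    finite = np.isfinite(col)
    if not np.any(finite):
        return None
    masked = np.where(finite, col, np.inf)
    j = int(np.argmin(masked))  # argmin takes the first (smallest Gamma) tie
    if 0 < j < col.size - 1 and finite[j - 1] and finite[j + 1]:
        d0, d1, d2 = col[j - 1], col[j], col[j + 1]
        denom = d0 - 2.0 * d1 + d2
        if denom > 0:
            offset = 0.5 * (d0 - d2) / denom
            offset = float(np.clip(offset, -1.0, 1.0))
            # local grid may be non-uniform; interpolate piecewise
            if offset >= 0:
                return float(gammas[j] + offset * (gammas[j + 1] - gammas[j]))
            return float(gammas[j] + offset * (gammas[j] - gammas[j - 1]))
    return float(gammas[j])


def min_contours(grid: NoiseGrid) -> tuple[Contour, Contour]:
    """Per-Omega minimising Gamma curves of the two distance maps."""
    out = []
    for m in (grid.cv_map, grid.corr_map):
        oms, gms = [], []
        for i, om in enumerate(grid.omega_values):
            g = _column_min(grid.gamma_values, m[i])
            if g is not None:
                oms.append(om)
                gms.append(g)
        out.append(Contour(np.asarray(oms), np.asarray(gms)))
    return out[0], out[1]


def intersect_contours(
    cv_contour: Contour,
    corr_contour: Contour,
    gamma_tol: float | None = None,
    boundary_gammas: Sequence[float] = (),
    grid: NoiseGrid | None = None,
) -> NoiseEstimate:
    """Crossing point of the two minimising contours.

    The contours are compared on their shared Omega values; a sign change
    of Gamma_cv(Omega) - Gamma_corr(Omega) is resolved by linear
    interpolation in Omega.  Omega values where both contours sit exactly
    on a Gamma-grid boundary (``boundary_gammas``) are excluded: there the
    argmin is saturated, so an apparent tie carries no crossing
    information.  Without a sign change, the point of closest approach is
    accepted if within ``gamma_tol`` (default: half the median Gamma
    spacing implied by the contours); otherwise the result reports no
    intersection.
    """
    shared = np.intersect1d(cv_contour.omegas, corr_contour.omegas)
    if shared.size < 2:
        return NoiseEstimate(None, None, False, cv_contour, corr_contour)
    g_cv = np.interp(shared, cv_contour.omegas, cv_contour.gammas)
    g_corr = np.interp(shared, corr_contour.omegas, corr_contour.gammas)

    def saturated(k: int) -> bool:
        return any(
            abs(g_cv[k] - b) < 1e-12 and abs(g_corr[k] - b) < 1e-12
            for b in boundary_gammas
        )

    keep = np.array([not saturated(k) for k in range(shared.size)])
    shared, g_cv, g_corr = shared[keep], g_cv[keep], g_corr[keep]
    if shared.size < 2:
        return NoiseEstimate(None, None, False, cv_contour, corr_contour)
    d = g_cv - g_corr
    if gamma_tol is None:
        if grid is not None and grid.gamma_values.size > 1:
            # half a grid step: closer than the scan can resolve
            gamma_tol = 0.5 * float(np.median(np.diff(grid.gamma_values)))
        elif len(boundary_gammas) >= 2:
            gamma_tol = 0.1 * (max(boundary_gammas) - min(boundary_gammas))
        else:
            spac = np.diff(np.unique(np.concatenate([cv_contour.gammas,
                                                     corr_contour.gammas])))
            gamma_tol = 0.5 * float(np.median(spac)) if spac.size else 0.0

    candidates: list[tuple[float, float]] = []
    for k in range(shared.size - 1):
        if d[k] == 0.0:
            candidates.append((float(shared[k]), float(g_cv[k])))
        elif d[k] * d[k + 1] < 0:
            frac = d[k] / (d[k] - d[k + 1])
            om = shared[k] + frac * (shared[k + 1] - shared[k])
            ga = g_cv[k] + frac * (g_cv[k + 1] - g_cv[k])
            candidates.append((float(om), float(ga)))
    if d[-1] == 0.0:
        candidates.append((float(shared[-1]), float(g_cv[-1])))
    if len(candidates) == 1:
        om, ga = candidates[0]
        return NoiseEstimate(om, ga, True, cv_contour, corr_contour)
    if len(candidates) > 1:
        # several noisy crossings: prefer the one where both mismatches are
        # actually small (the true intersection sits near both map minima)
        if grid is not None:
            def score(c: tuple[float, float]) -> float:
                i = int(np.argmin(np.abs(grid.omega_values - c[0])))
                j = int(np.argmin(np.abs(grid.gamma_values - c[1])))
                return float(grid.cv_map[i, j] + grid.corr_map[i, j])

            om, ga = min(candidates, key=score)
        else:
            om, ga = candidates[0]
        return NoiseEstimate(om, ga, True, cv_contour, corr_contour)
    k = int(np.argmin(np.abs(d)))
    if abs(d[k]) <= gamma_tol:
        return NoiseEstimate(float(shared[k]),
                             float(0.5 * (g_cv[k] + g_corr[k])), True,
                             cv_contour, corr_contour)
    return NoiseEstimate(None, None, False, cv_contour, corr_contour)
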