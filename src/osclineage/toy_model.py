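"""Amplitude/phase toy oscillator for validating the inference method.

A noisy limit-cycle oscillator reduced to polar coordinates:

    dr     = rho (r0 - r) dt + Omega^{-1/2} dW1
    dtheta = (2 pi / T) (r0 / r) dt + (r sqrt(Omega))^{-1} dW2

where r is the oscillation amplitude relaxing to r0 at rate rho, theta is
the phase advancing at 2 pi / T on the cycle, and Omega sets the intrinsic
noise (with Gamma = 0 the stationary amplitude is Ornstein-Uhlenbeck with
variance 1/(2 rho Omega)).  Extrinsic noise enters exactly as in the full
model: r0 is resampled at every division by the homeostatic recursion with
memory q and CV Gamma, subject to the sister mean constraint.  The
observable is x = r cos(theta), run through the same lineage schema and
statistics pipeline as the full model, which lets the whole inference
stack be validated end to end against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .lineage import (LineageNode, LineageTree, Q_FIVE_GENERATIONS,
                      resample_sister_params, sample_stationary_param)
from .trajectory import FRAME_INTERVAL_MIN, Trajectory

__all__ = ["ToyParams", "em_simulate", "toy_lineage", "toy_lineages",
           "toy_recovery_experiment"]


@dataclass(frozen=True)
class ToyParams:
    """Toy oscillator parameters.

    The division interval defaults to the mean generation time of the cell
    population, ln 2 / beta0; the amplitude floor keeps the 1/r phase
    drift finite.
    """

    r0_mean: float = 1.0  # AU; arbitrary scale, cancels in every CV
    rho: float = 0.1  # min^-1, limit-cycle stability
    period: float = 41.0  # min
    omega: float = 200.0
    gamma_ext: float = 0.15
    q: float = Q_FIVE_GENERATIONS
    division_interval: float = math.log(2.0) / 0.0295  # min
    dt: float = 0.05  # min, Euler-Maruyama step
    r_floor_frac: float = 0.05

    def __post_init__(self) -> None:
        for name in ("r0_mean", "rho", "period", "omega",
                     "division_interval", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt > 0.01 * self.period:
            raise ValueError("dt must not exceed 1% of the period")


def em_simulate(
    params: ToyParams,
    t_end: float,
    seed: int,
    frame_interval: float = FRAME_INTERVAL_MIN,
    return_amplitude: bool = False,
) -> Trajectory | tuple[Trajectory, Trajectory]:
    """Euler-Maruyama path of a single (non-dividing) toy oscillator.

    Returns x = r cos(theta) on the frame grid; with
    ``return_amplitude=True`` also the amplitude series r(t).
    """
    frames = np.arange(0.0, t_end - 1e-9, frame_interval)
    x = np.empty(frames.shape)
    r_series = np.empty(frames.shape)
    _kernels.toy_em(
        int(seed) % (2**31 - 1) or 1, 0.0, t_end,
        params.r0_mean, 0.0, params.r0_mean, params.rho, params.period,
        params.omega, params.dt, params.r_floor_frac * params.r0_mean,
        frames, x, r_series,
    )
    traj = Trajectory(frames, x)
    if return_amplitude:
        return traj, Trajectory(frames, r_series)
    return traj


def toy_lineage(
    params: ToyParams,
    n_generations: int = 6,
    seed: int = 0,
    lineage_id: int = 0,
    t_max: float | None = None,
    frame_interval: float = FRAME_INTERVAL_MIN,
) -> LineageTree:
    """Binary-tree toy simulation emitting the shared lineage schema.

    Divisions occur every ``division_interval`` minutes.  Both daughters
    start from the mother's exact (r, theta) -- all sister divergence comes
    from the r0 resampling and subsequent intrinsic noise.
    """
    rng = np.random.default_rng(seed)
    r0_root = sample_stationary_param(params.r0_mean, params.gamma_ext,
                                      params.q, rng)
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    tree = LineageTree(lineage_id, frame_interval)
    floor = params.r_floor_frac * params.r0_mean

    # frontier entries: (cell_id, parent_id, generation, t_birth, r, theta, r0)
    frontier = [(0, None, 0, 0.0, r0_root, theta0, r0_root)]
    next_id = 1
    while frontier:
        new_frontier = []
        for cid, pid, gen, t_birth, r, theta, r0 in frontier:
            t_div = t_birth + params.division_interval
            t_stop = t_div if t_max is None else min(t_div, t_max)
            first = math.ceil(t_birth / frame_interval - 1e-9) * frame_interval
            frames = (np.arange(first, t_stop - 1e-9, frame_interval)
                      if first < t_stop else np.empty(0))
            x = np.empty(frames.shape)
            r_out = np.empty(frames.shape)
            r, theta, _ = _kernels.toy_em(
                int(rng.integers(1, 2**31 - 1)), t_birth, t_stop,
                r, theta, r0, params.rho, params.period, params.omega,
                params.dt, floor, frames, x, r_out,
            )
            divides = (t_max is None or t_div <= t_max) and gen < n_generations
            tree.add(LineageNode(cid, pid, gen, t_birth, t_stop, divides,
                                 frames, x))
            if not divides:
                continue
            r0_1, r0_2 = resample_sister_params(r0, params.r0_mean,
                                                params.gamma_ext, params.q, rng)
            new_frontier.append((next_id, cid, gen + 1, t_div, r, theta, r0_1))
            new_frontier.append((next_id + 1, cid, gen + 1, t_div, r, theta, r0_2))
            next_id += 2
        frontier = new_frontier
    return tree


def toy_lineages(
    params: ToyParams,
    n_lineages: int,
    n_generations: int = 6,
    seed: int = 0,
    t_max: float | None = None,
) -> list[LineageTree]:
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_lineages) % (2**31 - 1)
    return [
        toy_lineage(params, n_generations, seed=int(s), lineage_id=i, t_max=t_max)
        for i, s in enumerate(seeds)
    ]


DEFAULT_TOY_OMEGA_GRID = (50.0, 100.0, 150.0, 200.0, 300.0, 400.0)
DEFAULT_TOY_GAMMA_GRID = (0.05, 0.10, 0.15, 0.20, 0.25)


def toy_recovery_experiment(
    true_omega: float = 200.0,
    true_gamma: float = 0.15,
    omega_values=DEFAULT_TOY_OMEGA_GRID,
    gamma_values=DEFAULT_TOY_GAMMA_GRID,
    seed: int = 0,
    n_ref_lineages: int = 40,
    n_sim_lineages: int = 15,
    n_generations: int = 6,
    base: ToyParams | None = None,
):
    """End-to-end in-silico validation of the noise inference.

    Generates reference lineages at the true (Omega, Gamma), then scans
    toy simulations over the grid and intersects the minimising contours
    of the amplitude-CV distance and the correlation distance.  Returns
    (NoiseEstimate, NoiseGrid, reference SummaryStats).
    """
    from . import inference, stats

    if base is None:
        base = ToyParams()
    ref_params = replace(base, omega=true_omega, gamma_ext=true_gamma)
    ss = np.random.SeedSequence(seed)
    ref_seed, scan_seed = (int(s % (2**31 - 1)) for s in ss.generate_state(2))
    ref_trees = toy_lineages(ref_params, n_ref_lineages, n_generations,
                             seed=ref_seed)
    reference = stats.summarize(ref_trees)

    def simulate(omega: float, gamma: float, cell_seed: int):
        p = replace(base, omega=omega, gamma_ext=gamma)
        return toy_lineages(p, n_sim_lineages, n_generations, seed=cell_seed)

    grid = inference.scan_grid(reference, simulate, omega_values,
                               gamma_values, seed=scan_seed)
    estimate = inference.intersect_contours(
        *inference.min_contours(grid),
        boundary_gammas=(min(gamma_values), max(gamma_values)),
        grid=grid,
    )
    return estimate, grid, reference
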