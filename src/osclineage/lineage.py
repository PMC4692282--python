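"""Lineage simulation with explicit cell growth, division and inheritance.

A progenitor cell grows exponentially at its own rate ``beta`` and divides
when its volume reaches its own division size ``V_max``; both quantities
are redrawn for every newborn cell.  Between divisions the intracellular
reaction network runs under the delayed stochastic simulation algorithm
with volume-scaled propensities.  At division the volume is halved, every
molecule (and every in-flight delayed production event) is assigned to one
of the two daughters with probability 1/2, and the heritable production
parameters are resampled around the mother's values with a homeostatic
pull toward the population mean.  The result is a branched fluorescence
trajectory mirroring what time-lapse microscopy records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .model_core import OscillatorParams, limit_cycle_samples, rescale_params
from .trajectory import FRAME_INTERVAL_MIN

__all__ = [
    "CellCycleParams",
    "NoiseParams",
    "CellState",
    "LineageNode",
    "LineageTree",
    "sample_growth_rate",
    "sample_division_volume",
    "resample_sister_params",
    "sample_stationary_param",
    "stationary_param_cv",
    "divide",
    "simulate_lineage",
    "simulate_lineages",
]

#: homeostatic memory corresponding to a five-generation relaxation time
Q_FIVE_GENERATIONS = math.exp(-math.log(2.0) / 5.0)


@dataclass(frozen=True)
class CellCycleParams:
    """Growth-rate and division-size statistics of the cell population.

    ``beta`` is normal, ``beta0 * (1 + Gamma_beta * eta)``; the division
    volume is shifted-gamma, ``V_base + Gamma(k, theta)`` (units of cell
    length, micrometres).
    """

    beta0: float = 0.0295  # min^-1
    gamma_beta: float = 0.099
    v_base: float = 4.5  # um
    k_gamma: float = 2.5
    theta_gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("beta0", "gamma_beta", "v_base", "k_gamma", "theta_gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def mean_division_volume(self) -> float:
        return self.v_base + self.k_gamma * self.theta_gamma

    @property
    def newborn_volume(self) -> float:
        """Mean size of a newborn cell (half the mean division size), um."""
        return 0.5 * self.mean_division_volume

    @property
    def mean_generation_time(self) -> float:
        return math.log(2.0) / self.beta0


@dataclass(frozen=True)
class NoiseParams:
    """The two inferred noise levels plus the heritability of parameters.

    omega: molecule-number scale (larger = more molecules = less intrinsic
    noise); gamma_ext: CV of the division-time resampling of the production
    rates (extrinsic noise); q in [0, 1]: autoregressive memory of that
    resampling (q=0 forgets the mother entirely, q=1 never reverts to the
    mean).  Defaults are the fitted values.
    """

    omega: float = 2.1
    gamma_ext: float = 0.12
    q: float = Q_FIVE_GENERATIONS

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.gamma_ext < 0:
            raise ValueError("gamma_ext must be nonnegative")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [0, 1]")


@dataclass
class CellState:
    """Snapshot of one live cell used by the stochastic simulator."""

    counts: np.ndarray  # int64[4]: r, a, g, G molecules
    v: float
    t: float
    queues: tuple[np.ndarray, np.ndarray, np.ndarray]  # pending completion times
    alpha_r: float  # per-cell (already molecule-number-scaled) production rates
    alpha_a: float
    alpha_g: float
    beta: float
    v_max: float


@dataclass
class LineageNode:
    cell_id: int
    parent_id: int | None
    generation: int
    birth_time: float
    division_time: float  # end of tracking for leaves
    divided: bool  # False when tracking ended before division
    frame_times: np.ndarray
    fluorescence: np.ndarray


class LineageTree:
    """Branched fluorescence record of one progenitor and its descendants."""

    def __init__(self, lineage_id: int = 0,
                 frame_interval: float = FRAME_INTERVAL_MIN) -> None:
        self.lineage_id = lineage_id
        self.frame_interval = frame_interval
        self.nodes: dict[int, LineageNode] = {}
        self._children: dict[int, list[int]] = {}

    def add(self, node: LineageNode) -> None:
        if node.cell_id in self.nodes:
            raise ValueError(f"duplicate cell id {node.cell_id}")
        if node.parent_id is not None:
            if node.parent_id not in self.nodes:
                raise ValueError(
                    f"cell {node.cell_id} references unknown parent {node.parent_id}"
                )
            self._children.setdefault(node.parent_id, []).append(node.cell_id)
            if len(self._children[node.parent_id]) > 2:
                raise ValueError("a cell cannot have more than two daughters")
        self.nodes[node.cell_id] = node

    def children(self, cell_id: int) -> list[int]:
        return self._children.get(cell_id, [])

    @property
    def root_id(self) -> int:
        roots = [cid for cid, n in self.nodes.items() if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one progenitor")
        return roots[0]

    def paths(self) -> list[list[int]]:
        """All root-to-leaf cell-id paths (the branches of the trajectory)."""
        out: list[list[int]] = []

        def walk(cid: int, acc: list[int]) -> None:
            acc = acc + [cid]
            kids = self.children(cid)
            if not kids:
                out.append(acc)
            else:
                for k in kids:
                    walk(k, acc)

        walk(self.root_id, [])
        return out

    def sister_pairs(self) -> list[tuple[float, int, int]]:
        """(division time, daughter 1 id, daughter 2 id) for every division."""
        pairs = []
        for pid, kids in self._children.items():
            if len(kids) == 2:
                pairs.append((self.nodes[kids[0]].birth_time, kids[0], kids[1]))
        return sorted(pairs)

    def branch_series(self, path: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenated (times, fluorescence, owning cell id) along a path."""
        ts, xs, owner = [], [], []
        for cid in path:
            n = self.nodes[cid]
            ts.append(n.frame_times)
            xs.append(n.fluorescence)
            owner.append(np.full(n.frame_times.shape, cid, dtype=np.int64))
        return np.concatenate(ts), np.concatenate(xs), np.concatenate(owner)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in sorted(self.nodes.values(), key=lambda n: n.cell_id):
            for t, x in zip(n.frame_times, n.fluorescence):
                rows.append((self.lineage_id, n.cell_id,
                             -1 if n.parent_id is None else n.parent_id,
                             n.birth_time, n.division_time, t, x))
        return pd.DataFrame(
            rows,
            columns=["lineage_id", "cell_id", "parent_id", "birth_time_min",
                     "division_time_min", "frame_time_min", "fluorescence"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   frame_interval: float = FRAME_INTERVAL_MIN) -> "LineageTree":
        lineage_ids = df["lineage_id"].unique()
        if len(lineage_ids) != 1:
            raise ValueError("from_frame expects a single lineage")
        tree = cls(int(lineage_ids[0]), frame_interval)
        cells = df.sort_values("frame_time_min").groupby("cell_id", sort=True)
        records = []
        for cid, sub in cells:
            parent = int(sub["parent_id"].iloc[0])
            records.append(
                LineageNode(
                    cell_id=int(cid),
                    parent_id=None if parent < 0 else parent,
                    generation=-1,
                    birth_time=float(sub["birth_time_min"].iloc[0]),
                    division_time=float(sub["division_time_min"].iloc[0]),
                    divided=False,
                    frame_times=sub["frame_time_min"].to_numpy(dtype=float),
                    fluorescence=sub["fluorescence"].to_numpy(dtype=float),
                )
            )
        # insert parents before children regardless of id order
        records.sort(key=lambda n: n.birth_time)
        seen: set[int] = set()
        pending = records
        while pending:
            rest = []
            progressed = False
            for n in pending:
                if n.parent_id is None or n.parent_id in seen:
                    tree.add(n)
                    seen.add(n.cell_id)
                    progressed = True
                else:
                    rest.append(n)
            if not progressed:
                missing = sorted({n.parent_id for n in rest} - seen)
                raise ValueError(f"orphan cells reference unknown parents {missing}")
            pending = rest
        # fill generations from the topology
        def set_gen(cid: int, g: int) -> None:
            tree.nodes[cid] = dataclass_replace_generation(tree.nodes[cid], g)
            for k in tree.children(cid):
                set_gen(k, g + 1)

        set_gen(tree.root_id, 0)
        return tree


def dataclass_replace_generation(node: LineageNode, g: int) -> LineageNode:
    node.generation = g
    return node


def equilibrium_queues(
    params: OscillatorParams,
    omega: float,
    concentrations,
    volume: float,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pending delayed productions consistent with a steady promoter state.

    If production had been running at the given (unscaled) concentrations,
    each species queue would hold Poisson(rate * tau) events with
    completion times uniform on (t0, t0 + tau).  Starting from an empty
    queue instead silences production for the first tau minutes and lags
    the oscillation phase.
    """
    conc = np.asarray(concentrations, dtype=float)
    h = (1.0 / params.f + conc[1] / params.C_a) / (
        (1.0 + conc[1] / params.C_a) * (1.0 + conc[0] / params.C_r) ** 2
    )
    queues = []
    for alpha, tau in ((params.alpha_r, params.tau_r),
                       (params.alpha_a, params.tau_a),
                       (params.alpha_g, params.tau_g)):
        n = rng.poisson(volume * omega * alpha * h * tau)
        queues.append(np.sort(t0 + rng.uniform(0.0, tau, size=n)))
    return queues[0], queues[1], queues[2]


def sample_growth_rate(cc: CellCycleParams, rng: np.random.Generator) -> float:
    """beta = beta0 (1 + Gamma_beta eta), eta ~ N(0,1); resampled if <= 0."""
    for _ in range(100):
        beta = cc.beta0 * (1.0 + cc.gamma_beta * rng.standard_normal())
        if beta > 0:
            return beta
    raise RuntimeError("growth-rate sampling kept producing nonpositive values")


def sample_division_volume(cc: CellCycleParams, rng: np.random.Generator,
                           min_volume: float = 0.0) -> float:
    """V_max = V_base + Gamma(k, theta) draw; fixed until the cell divides.

    ``min_volume`` (the newborn's birth volume) truncates the draw from
    below: a cell must grow before it can divide, so daughters of
    unusually large mothers redraw until their division size exceeds their
    birth size.
    """
    for _ in range(1000):
        v = cc.v_base + rng.gamma(cc.k_gamma, cc.theta_gamma)
        if v > min_volume:
            return v
    raise RuntimeError("division-volume sampling could not exceed the birth volume")


def stationary_param_cv(gamma: float, q: float) -> float:
    """Stationary CV of the division-time parameter recursion.

    For p' = (q p + (1-q) <p>)(1 + Gamma eta) the stationary mean is <p>
    and the stationary CV solves CV^2 = Gamma^2 / (1 - q^2 (1 + Gamma^2)),
    provided q^2 (1 + Gamma^2) < 1 (otherwise the variance diverges).
    """
    denom = 1.0 - q * q * (1.0 + gamma * gamma)
    if denom <= 0:
        return float("inf")
    return gamma / math.sqrt(denom)


def sample_stationary_param(mean: float, gamma: float, q: float,
                            rng: np.random.Generator, burn: int = 50) -> float:
    """Draw from the stationary distribution by burning in the recursion."""
    p = mean
    for _ in range(burn):
        p = (q * p + (1.0 - q) * mean) * (1.0 + gamma * rng.standard_normal())
        if p <= 0:
            p = mean  # extremely rare for the Gammas of interest; restart
    return p


def resample_sister_params(p_mother: float, p_mean: float, gamma: float,
                           q: float, rng: np.random.Generator) -> tuple[float, float]:
    """Division-time resampling with the sister mean constraint.

    The target mean is m = q p_mother + (1-q) p_mean; one deviate eta is
    drawn per parameter per division and the daughters receive
    p1 = m (1 + Gamma eta), p2 = m (1 - Gamma eta), so each daughter is
    marginally distributed with CV Gamma about m while (p1+p2)/2 = m holds
    exactly.
    """
    m = q * p_mother + (1.0 - q) * p_mean
    for _ in range(100):
        eta = rng.standard_normal()
        p1 = m * (1.0 + gamma * eta)
        p2 = m * (1.0 - gamma * eta)
        if p1 > 0 and p2 > 0:
            return p1, p2
    raise RuntimeError("sister parameter resampling kept leaving the positive domain")


def _partition_queue(queue: np.ndarray, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    if queue.size == 0:
        return queue.copy(), queue.copy()
    mask = rng.random(queue.size) < 0.5
    return queue[mask], queue[~mask]


def divide(cell: CellState, noise: NoiseParams, cc: CellCycleParams,
           means: tuple[float, float, float], rng: np.random.Generator
           ) -> tuple[CellState, CellState]:
    """Split a cell at its division volume into two daughters.

    Volume is halved; every molecule count is split Binomial(n, 1/2); every
    pending delayed production event keeps its completion time and goes to
    either daughter with probability 1/2; each daughter draws a fresh
    growth rate and division volume; the three production rates are
    resampled independently per parameter by the homeostatic recursion with
    the sister mean constraint.  ``means`` are the population-mean
    production rates on the same (scaled) scale as the cell's parameters.
    """
    if cell.v < cell.v_max * (1.0 - 1e-9):
        raise ValueError("division triggered below the cell's division volume")
    c1 = np.array([rng.binomial(int(n), 0.5) for n in cell.counts], dtype=np.int64)
    c2 = cell.counts.astype(np.int64) - c1
    queues1, queues2 = [], []
    for q_arr in cell.queues:
        qa, qb = _partition_queue(np.asarray(q_arr, dtype=float), rng)
        queues1.append(qa)
        queues2.append(qb)
    a_r = resample_sister_params(cell.alpha_r, means[0], noise.gamma_ext, noise.q, rng)
    a_a = resample_sister_params(cell.alpha_a, means[1], noise.gamma_ext, noise.q, rng)
    a_g = resample_sister_params(cell.alpha_g, means[2], noise.gamma_ext, noise.q, rng)
    v_half = cell.v / 2.0
    d1 = CellState(c1, v_half, cell.t, tuple(queues1), a_r[0], a_a[0], a_g[0],
                   sample_growth_rate(cc, rng),
                   sample_division_volume(cc, rng, min_volume=v_half))
    d2 = CellState(c2, v_half, cell.t, tuple(queues2), a_r[1], a_a[1], a_g[1],
                   sample_growth_rate(cc, rng),
                   sample_division_volume(cc, rng, min_volume=v_half))
    return d1, d2


def _frames_in(t0: float, t1: float, interval: float) -> np.ndarray:
    first = math.ceil(t0 / interval - 1e-9) * interval
    if first >= t1:
        return np.empty(0)
    return np.arange(first, t1 - 1e-9, interval)


def simulate_lineage(
    params: OscillatorParams,
    noise: NoiseParams,
    cc: CellCycleParams | None = None,
    n_generations: int = 6,
    seed: int = 0,
    t_max: float | None = None,
    lineage_id: int = 0,
    init_cycle: np.ndarray | None = None,
    frame_interval: float = FRAME_INTERVAL_MIN,
) -> LineageTree:
    """Simulate a full lineage of the oscillator.

    Every branch is followed for ``n_generations`` divisions (optionally
    truncated at ``t_max`` minutes, emulating the end of a movie).  The
    progenitor starts as a newborn cell at half its division volume, with
    heritable parameters drawn from their stationary distribution and
    molecule numbers Poisson-initialised from a random phase of the
    deterministic limit cycle.  Fluorescence is the mature-reporter
    concentration G/V sampled on the global frame grid.

    The volume multiplying the propensities is dimensionless: cell size
    divided by the mean newborn size, so a typical newborn has volume 1
    and a typical dividing cell volume 2.  This pins the molecule-number
    scale of a single newborn-sized cell to Omega itself (matching the
    fixed-volume single-cell mode) while the division-size statistics
    keep their measured micrometre units.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    if cc is None:
        cc = CellCycleParams()
    rng = np.random.default_rng(seed)
    scaled = rescale_params(params, noise.omega)
    means = (scaled.alpha_r, scaled.alpha_a, scaled.alpha_g)
    if init_cycle is None:
        init_cycle = limit_cycle_samples(params)

    v_unit = cc.newborn_volume  # propensity volume is measured in newborn sizes
    v_max0 = sample_division_volume(cc, rng)
    v0 = v_max0 / 2.0
    phase = init_cycle[rng.integers(init_cycle.shape[0])]
    counts0 = rng.poisson(noise.omega * (v0 / v_unit) * phase).astype(np.int64)
    root = CellState(
        counts0, v0, 0.0,
        equilibrium_queues(params, noise.omega, phase, v0 / v_unit, rng),
        sample_stationary_param(means[0], noise.gamma_ext, noise.q, rng),
        sample_stationary_param(means[1], noise.gamma_ext, noise.q, rng),
        sample_stationary_param(means[2], noise.gamma_ext, noise.q, rng),
        sample_growth_rate(cc, rng),
        v_max0,
    )

    tree = LineageTree(lineage_id, frame_interval)
    next_id = 0
    # breadth-first over (cell_id, parent_id, generation, state)
    frontier: list[tuple[int, int | None, int, CellState]] = [(0, None, 0, root)]
    next_id = 1
    while frontier:
        new_frontier = []
        for cid, pid, gen, cell in frontier:
            t_div = cell.t + math.log(cell.v_max / cell.v) / cell.beta
            t_stop = t_div if t_max is None else min(t_div, t_max)
            frames = _frames_in(cell.t, t_stop, frame_interval)
            fluor = np.empty(frames.shape)
            kseed = int(rng.integers(1, 2**31 - 1))
            q_r, q_a, q_g, status = _kernels.ssa_cell(
                kseed, cell.t, t_stop, cell.counts, cell.v / v_unit,
                cell.beta, 0.0,
                cell.alpha_r, cell.alpha_a, cell.alpha_g,
                scaled.gamma_r, scaled.gamma_a, scaled.gamma_g, scaled.gamma_G,
                scaled.R0, scaled.C_a, scaled.C_r, scaled.f,
                scaled.tau_r, scaled.tau_a, scaled.tau_g, scaled.lambda_mat,
                np.asarray(cell.queues[0], dtype=float),
                np.asarray(cell.queues[1], dtype=float),
                np.asarray(cell.queues[2], dtype=float),
                frames, fluor,
            )
            if status != 0:
                raise RuntimeError(
                    f"event budget exhausted in cell {cid} of lineage {lineage_id}"
                )
            divides = (t_max is None or t_div <= t_max) and gen < n_generations
            tree.add(LineageNode(cid, pid, gen, cell.t, t_stop, divides,
                                 frames, fluor))
            if not divides:
                continue
            cell.v = cell.v_max
            cell.t = t_div
            cell.queues = (q_r, q_a, q_g)
            d1, d2 = divide(cell, noise, cc, means, rng)
            new_frontier.append((next_id, cid, gen + 1, d1))
            new_frontier.append((next_id + 1, cid, gen + 1, d2))
            next_id += 2
        frontier = new_frontier
    return tree


def simulate_lineages(
    params: OscillatorParams,
    noise: NoiseParams,
    cc: CellCycleParams | None = None,
    n_lineages: int = 50,
    n_generations: int = 6,
    seed: int = 0,
    t_max: float | None = None,
) -> list[LineageTree]:
    """Simulate independent lineages with per-lineage seeds derived from ``seed``."""
    init_cycle = limit_cycle_samples(params)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_lineages) % (2**31 - 1)
    return [
        simulate_lineage(params, noise, cc, n_generations,
                         seed=int(s), t_max=t_max, lineage_id=i,
                         init_cycle=init_cycle)
        for i, s in enumerate(seeds)
    ]
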