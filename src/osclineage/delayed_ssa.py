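"""Delayed stochastic simulation of the oscillator reaction network.

The reaction system has eight channels: three delayed production reactions
(one per protein, firing ``tau`` minutes after being scheduled, held in a
queue of pending events until then), four first-order losses combining
dilution with saturated Michaelis-Menten proteolysis shared across all
species, and GFP maturation.  Propensities are evaluated on
concentrations with the production terms proportional to volume, so the
molecule-number scale ``omega`` and the cell volume enter symmetrically.

Two execution paths are provided: a compiled kernel specialised to this
network (the production path), and a small generic event-queue engine
(:func:`simulate_reactions`) that accepts arbitrary reaction lists and is
used as an independent cross-check at small scale.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import _kernels, stats
from .lineage import CellState, equilibrium_queues
from .model_core import OscillatorParams, limit_cycle_samples, rescale_params
from .trajectory import FRAME_INTERVAL_MIN, Trajectory

__all__ = [
    "Reaction",
    "build_reactions",
    "simulate_reactions",
    "simulate_cell",
    "simulate_cells",
    "equilibrium_queues",
    "amplitude_cv_vs_omega",
    "fit_inverse_scaling",
]

SPECIES = ("r", "a", "g", "G")


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: propensity(counts, volume) -> rate in 1/min.

    ``delta`` is the integer state change applied when the reaction
    completes; for delayed reactions completion happens ``delay`` minutes
    after the reaction fires.
    """

    name: str
    propensity: Callable[[np.ndarray, float], float]
    delta: np.ndarray
    delay: float = 0.0


def build_reactions(
    params: OscillatorParams,
    omega: float = 1.0,
    fixed_volume: bool = True,
) -> list[Reaction]:
    """The eight oscillator reactions at molecule-number scale ``omega``.

    All rate and affinity parameters are pre-scaled by ``omega``.  With
    ``fixed_volume`` (single-cell mode) the loss channels include explicit
    dilution at rate ``beta``; in growing-cell mode dilution is implicit in
    the volume growth and the loss channels carry proteolysis only.
    """
    p = rescale_params(params, omega)
    beta_dil = p.beta if fixed_volume else 0.0

    def hill(counts: np.ndarray, v: float) -> float:
        u = counts[1] / v / p.C_a
        return (1.0 / p.f + u) / ((1.0 + u) * (1.0 + counts[0] / v / p.C_r) ** 2)

    def mm(counts: np.ndarray, v: float) -> float:
        return 1.0 / (p.R0 + counts.sum() / v)

    def delta(**kw) -> np.ndarray:
        d = np.zeros(4, dtype=np.int64)
        for k, v in kw.items():
            d[SPECIES.index(k)] = v
        return d

    rxns = [
        Reaction("produce_r", lambda c, v: v * p.alpha_r * hill(c, v),
                 delta(r=1), p.tau_r),
        Reaction("produce_a", lambda c, v: v * p.alpha_a * hill(c, v),
                 delta(a=1), p.tau_a),
        Reaction("produce_g", lambda c, v: v * p.alpha_g * hill(c, v),
                 delta(g=1), p.tau_g),
        Reaction("loss_r", lambda c, v: c[0] * (beta_dil + p.gamma_r * mm(c, v)),
                 delta(r=-1)),
        Reaction("loss_a", lambda c, v: c[1] * (beta_dil + p.gamma_a * mm(c, v)),
                 delta(a=-1)),
        Reaction("loss_g", lambda c, v: c[2] * (beta_dil + p.gamma_g * mm(c, v)),
                 delta(g=-1)),
        Reaction("loss_G", lambda c, v: c[3] * (beta_dil + p.gamma_G * mm(c, v)),
                 delta(G=-1)),
        Reaction("mature", lambda c, v: p.lambda_mat * c[2],
                 delta(g=-1, G=1)),
    ]
    return rxns


def simulate_reactions(
    reactions: Sequence[Reaction],
    init_counts: Sequence[int],
    t_end: float,
    seed: int,
    volume: float = 1.0,
    record_times: np.ndarray | None = None,
    n_species: int | None = None,
) -> np.ndarray:
    """Generic delayed SSA over an arbitrary reaction list (reference engine).

    Delayed reactions push their state change onto a time-ordered event
    queue; whenever the earliest pending completion precedes the next
    reaction time it is applied first.  Returns the counts at
    ``record_times`` (shape n_times x n_species), or the final counts when
    ``record_times`` is None.
    """
    rng = np.random.default_rng(seed)
    counts = np.asarray(init_counts, dtype=np.int64).copy()
    if n_species is None:
        n_species = counts.size
    t = 0.0
    pending: list[tuple[float, int, np.ndarray]] = []
    tiebreak = 0
    out = None
    ri = 0
    if record_times is not None:
        out = np.zeros((len(record_times), n_species), dtype=np.int64)

    def emit_until(t_new: float) -> None:
        nonlocal ri
        if out is None:
            return
        while ri < len(record_times) and record_times[ri] < t_new:
            out[ri] = counts
            ri += 1

    while t < t_end:
        props = np.array([max(0.0, r.propensity(counts, volume)) for r in reactions])
        total = props.sum()
        t_queue = pending[0][0] if pending else math.inf
        t_next = t + rng.exponential() / total if total > 0 else math.inf
        t_new = min(t_queue, t_next, t_end)
        emit_until(t_new)
        if t_new >= t_end:
            break
        t = t_new
        if t_queue <= t_next:
            _, _, d = heapq.heappop(pending)
            counts += d
        else:
            k = int(rng.choice(len(reactions), p=props / total))
            rxn = reactions[k]
            if rxn.delay > 0:
                heapq.heappush(pending, (t + rxn.delay, tiebreak, rxn.delta))
                tiebreak += 1
            else:
                counts += rxn.delta
        if np.any(counts < 0):
            raise RuntimeError(f"negative count after reaction at t={t:.3f}")
    emit_until(t_end + 1e-9)
    if out is not None and ri < len(record_times):
        out[ri:] = counts
    return out if out is not None else counts


def simulate_cell(
    params: OscillatorParams,
    omega: float,
    t_end: float,
    seed: int,
    init_counts: Sequence[int] | None = None,
    init_queues: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    volume: float = 1.0,
    frame_interval: float = FRAME_INTERVAL_MIN,
) -> Trajectory:
    """Single fixed-volume cell: fluorescence G/V on the frame grid.

    Cell growth enters only through dilution at rate ``beta`` (no volume
    growth, no division) -- the regime used to isolate intrinsic noise.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    scaled = rescale_params(params, omega)
    counts = (np.zeros(4, dtype=np.int64) if init_counts is None
              else np.asarray(init_counts, dtype=np.int64).copy())
    frames = np.arange(0.0, t_end - 1e-9, frame_interval)
    fluor = np.empty(frames.shape)
    if init_queues is None:
        empty = np.empty(0)
        q_r, q_a, q_g = empty, empty, empty
    else:
        q_r, q_a, q_g = (np.asarray(q, dtype=float) for q in init_queues)
    _, _, _, status = _kernels.ssa_cell(
        int(seed) % (2**31 - 1) or 1, 0.0, t_end, counts, volume,
        0.0, scaled.beta,
        scaled.alpha_r, scaled.alpha_a, scaled.alpha_g,
        scaled.gamma_r, scaled.gamma_a, scaled.gamma_g, scaled.gamma_G,
        scaled.R0, scaled.C_a, scaled.C_r, scaled.f,
        scaled.tau_r, scaled.tau_a, scaled.tau_g, scaled.lambda_mat,
        q_r, q_a, q_g, frames, fluor,
    )
    if status != 0:
        raise RuntimeError("event budget exhausted in single-cell simulation")
    return Trajectory(frames, fluor)


def simulate_cells(
    params: OscillatorParams,
    omega: float,
    n_sims: int,
    t_end: float,
    seed: int,
    init_cycle: np.ndarray | None = None,
) -> list[Trajectory]:
    """Ensemble of single cells initialised at random limit-cycle phases."""
    if init_cycle is None:
        init_cycle = limit_cycle_samples(params)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sims):
        phase = init_cycle[rng.integers(init_cycle.shape[0])]
        counts = rng.poisson(omega * phase).astype(np.int64)
        queues = equilibrium_queues(params, omega, phase, 1.0, rng)
        out.append(
            simulate_cell(params, omega, t_end,
                          seed=int(rng.integers(1, 2**31 - 1)),
                          init_counts=counts, init_queues=queues)
        )
    return out


def amplitude_cv_vs_omega(
    params: OscillatorParams,
    omegas: Sequence[float],
    n_sims: int = 100,
    t_end: float = 500.0,
    seed: int = 0,
    transient: float = 100.0,
) -> "pd.DataFrame":
    """Pooled amplitude and period CV of single-cell ensembles per omega.

    For each molecule-number scale the peak heights of ``n_sims``
    independent fixed-volume cells are pooled (discarding an initial
    transient) and their coefficient of variation reported.  Entries with
    too few detected peaks are flagged with NaN.
    """
    import pandas as pd

    init_cycle = limit_cycle_samples(params)
    ss = np.random.SeedSequence(seed)
    rows = []
    for omega, sub in zip(omegas, ss.spawn(len(omegas))):
        trajs = simulate_cells(params, omega, n_sims, t_end,
                               seed=int(sub.generate_state(1)[0] % (2**31 - 1)),
                               init_cycle=init_cycle)
        heights, intervals = [], []
        for tr in trajs:
            ps = stats.find_peaks(tr)
            keep = ps.peak_times >= transient
            heights.append(ps.heights[keep])
            if np.sum(keep) >= 2:
                intervals.append(np.diff(ps.peak_times[keep]))
        heights = np.concatenate(heights) if heights else np.empty(0)
        intervals = np.concatenate(intervals) if intervals else np.empty(0)
        if heights.size < 20 or intervals.size < 20:
            rows.append((omega, np.nan, np.nan, heights.size))
            continue
        rows.append((
            omega,
            float(heights.std(ddof=1) / heights.mean()),
            float(intervals.std(ddof=1) / intervals.mean()),
            heights.size,
        ))
    return pd.DataFrame(rows, columns=["omega", "amplitude_cv", "period_cv",
                                       "n_peaks"])


def fit_inverse_scaling(omegas: np.ndarray, cvs: np.ndarray) -> float:
    """Least-squares coefficient c of the law CV(omega) = c / omega."""
    omegas = np.asarray(omegas, dtype=float)
    cvs = np.asarray(cvs, dtype=float)
    keep = np.isfinite(cvs)
    if not np.any(keep):
        return float("nan")
    x = 1.0 / omegas[keep]
    return float(np.dot(x, cvs[keep]) / np.dot(x, x))
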