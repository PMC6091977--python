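"""Exact stochastic simulation of the two-site hopping scheme.

A direct Gillespie algorithm samples the continuous-time Markov jump
process whose stationary behaviour `cngperm.kinetics` solves analytically.
Because the transition rates span many orders of magnitude (hops ~ e^-0.5,
single-ion exit ~ e^-15), the simulation is kept exact -- exponential
waiting times from the total propensity of the current state, no leaping.
The simulator is the independent oracle against which the closed-form flux
and the linear-solve occupancies are validated.

Randomness comes from numpy's seedable PCG64 generator, so trajectories are
reproducible across platforms for a fixed seed.
"""

from __future__ import annotations

import math
from array import array
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np

from .kinetics import StationaryState, TwoSiteRates
from .profiles import block_error

__all__ = [
    "Trajectory",
    "FluxEstimate",
    "STATE_NAMES",
    "TRANSITION_LABELS",
    "simulate",
    "simulate_single_site",
    "empirical_flux",
    "empirical_occupancy",
    "occupancy_blocks",
    "occupancy_se",
]

STATE_NAMES = ("E", "L", "R", "D")
TRANSITION_LABELS = (
    "entryL",  # E -> L
    "hopLR",  # L -> R
    "hopRL",  # R -> L
    "exitR_single",  # R -> E
    "entryD",  # R -> D
    "exitR_double",  # D -> L
)
_EXIT_CODES = (3, 5)


@dataclass
class Trajectory:
    """Event record of one stochastic realization.

    `times` holds the jump times (strictly increasing), `labels` the
    transition codes (indices into TRANSITION_LABELS) and `states` the state
    entered at each jump (indices into STATE_NAMES).  `state_dwell`
    accumulates occupancy time per state over [0, total_time].
    """

    times: np.ndarray
    labels: np.ndarray
    states: np.ndarray
    total_time: float
    seed: int
    initial_state: int = 0
    terminated_early: bool = False
    state_dwell: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.state_dwell is None:
            self.state_dwell = self._dwell(0.0, self.total_time)

    @property
    def n_events(self) -> int:
        return len(self.times)

    @property
    def events(self) -> Iterator[tuple[float, str]]:
        """Lazily iterate (time, label) pairs."""
        for t, c in zip(self.times, self.labels):
            yield float(t), TRANSITION_LABELS[c]

    def exit_times(self) -> np.ndarray:
        """Times of permeation events (exits to the extracellular side)."""
        mask = np.isin(self.labels, _EXIT_CODES)
        return self.times[mask]

    def _dwell(self, t0: float, t1: float) -> np.ndarray:
        """Occupancy time per state over the window [t0, t1]."""
        starts = np.concatenate(([0.0], self.times))
        ends = np.concatenate((self.times, [self.total_time]))
        occupant = np.concatenate(([self.initial_state], self.states))
        overlap = np.clip(ends, t0, t1) - np.clip(starts, t0, t1)
        dwell = np.zeros(4)
        np.add.at(dwell, occupant, overlap)
        return dwell


class FluxEstimate(NamedTuple):
    flux: float
    se: float
    n_exits: int


def _run_gillespie(
    table: list[tuple[list[float], list[int], list[int]]],
    initial_state: int,
    t_max: float,
    seed: int,
) -> tuple[array, array, array, bool]:
    """Direct-method core: per-state (rates, next-states, labels) table."""
    rng = np.random.default_rng(seed)
    totals = [sum(rates) for rates, _, _ in table]
    cums = []
    for rates, _, _ in table:
        c, acc = [], 0.0
        for r in rates:
            acc += r
            c.append(acc)
        cums.append(c)
    nexts = [nxt for _, nxt, _ in table]
    labs = [lab for _, _, lab in table]

    times = array("d")
    labels = array("b")
    states = array("b")
    log = math.log
    s = initial_state
    t = 0.0
    early = False
    buf = rng.random(1 << 16)
    i = 0
    n_buf = len(buf)
    while True:
        total = totals[s]
        if total <= 0.0:
            early = True
            break
        if i + 2 > n_buf:
            buf = rng.random(1 << 16)
            i = 0
        u1 = buf[i]
        u2 = buf[i + 1]
        i += 2
        t_next = t + (-log(1.0 - u1) / total)
        if t_next >= t_max:
            break
        t = t_next
        r = u2 * total
        cs = cums[s]
        k = 0
        while r > cs[k]:
            k += 1
        labels.append(labs[s][k])
        s = nexts[s][k]
        times.append(t)
        states.append(s)
    return times, labels, states, early


def simulate(rates: TwoSiteRates, X: float, t_max: float, seed: int) -> Trajectory:
    """Exact Gillespie realization of the two-site scheme at concentration X.

    Starts from the empty channel.  If every transition out of the current
    state has zero propensity the trajectory terminates early and is
    flagged.  Identical seeds give identical event lists.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if X < 0:
        raise ValueError("concentration must be non-negative")
    kLX = rates.kL * X
    # state -> (rates, next states, transition labels)
    table = [
        ([kLX], [1], [0]),  # E -> L
        ([rates.kplus], [2], [1]),  # L -> R
        ([rates.kminus, rates.kR, kLX], [1, 0, 3], [2, 3, 4]),  # R -> L/E/D
        ([rates.kRtilde], [1], [5]),  # D -> L
    ]
    times, labels, states, early = _run_gillespie(table, 0, t_max, seed)
    return Trajectory(
        times=np.frombuffer(times, dtype=float).copy(),
        labels=np.frombuffer(labels, dtype=np.int8).copy(),
        states=np.frombuffer(states, dtype=np.int8).copy(),
        total_time=t_max,
        seed=seed,
        terminated_early=early,
    )


def simulate_single_site(kL: float, kR: float, X: float, t_max: float, seed: int) -> Trajectory:
    """Gillespie realization of the single-site (E/occupied) model.

    The occupied state is recorded as L; exits use the exitR_single label,
    so `empirical_flux` applies unchanged.  Oracle for the Michaelis-Menten
    closed form.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if X < 0 or kL < 0 or kR < 0:
        raise ValueError("inputs must be non-negative")
    table = [
        ([kL * X], [1], [0]),  # E -> occupied
        ([kR], [0], [3]),  # occupied -> E (permeation)
        ([], [], []),
        ([], [], []),
    ]
    times, labels, states, early = _run_gillespie(table, 0, t_max, seed)
    return Trajectory(
        times=np.frombuffer(times, dtype=float).copy(),
        labels=np.frombuffer(labels, dtype=np.int8).copy(),
        states=np.frombuffer(states, dtype=np.int8).copy(),
        total_time=t_max,
        seed=seed,
        terminated_early=early,
    )


def _post_window(traj: Trajectory, burn_in: float) -> tuple[float, float]:
    if not 0 <= burn_in < 1:
        raise ValueError("burn_in must be in [0, 1)")
    t0 = burn_in * traj.total_time
    if traj.total_time - t0 <= 0:
        raise ValueError("zero post-burn-in time")
    return t0, traj.total_time


def empirical_flux(
    traj: Trajectory,
    burn_in: float = 0.1,
    n_bins: int = 200,
    n_blocks: int = 20,
) -> FluxEstimate:
    """Permeation flux from a trajectory, with a block-analysis SE.

    Exits after the burn-in window are binned in time; the flux is the mean
    bin count over the bin width and its standard error comes from block
    analysis of the bin counts, which absorbs serial correlation between
    bins.
    """
    t0, t1 = _post_window(traj, burn_in)
    exits = traj.exit_times()
    exits = exits[exits > t0]
    edges = np.linspace(t0, t1, n_bins + 1)
    counts, _ = np.histogram(exits, bins=edges)
    width = (t1 - t0) / n_bins
    flux = counts.sum() / (t1 - t0)
    se = block_error(counts, n_blocks) / width
    return FluxEstimate(flux=float(flux), se=float(se), n_exits=int(counts.sum()))


def empirical_occupancy(traj: Trajectory, burn_in: float = 0.1) -> StationaryState:
    """Dwell-time occupancy fractions after burn-in (probabilities only)."""
    t0, t1 = _post_window(traj, burn_in)
    dwell = traj._dwell(t0, t1)
    p = dwell / dwell.sum()
    return StationaryState(float(p[0]), float(p[1]), float(p[2]), float(p[3]), None)


def occupancy_se(
    traj: Trajectory,
    rates: TwoSiteRates,
    X: float,
    burn_in: float = 0.1,
    n_blocks: int = 20,
) -> np.ndarray:
    """Monte-Carlo standard errors for the four occupancy fractions.

    Block analysis of per-block dwell fractions, plus a resolution floor of
    one mean sojourn time per state over the window: a state the chain is
    expected to visit less than about once per run (e.g. the empty state at
    high concentration, reachable only through the very slow single-ion
    exit) has an occupancy that cannot be measured below the dwell a single
    visit would contribute, and the block scatter alone would understate
    that uncertainty.  Mean sojourn times come from the generator's total
    exit propensities, not from any analytic solution.
    """
    t0, t1 = _post_window(traj, burn_in)
    blocks = occupancy_blocks(traj, burn_in, n_blocks)
    se = blocks.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    kLX = rates.kL * X
    out_rate = np.array(
        [kLX, rates.kplus, rates.kminus + rates.kR + kLX, rates.kRtilde]
    )
    with np.errstate(divide="ignore"):
        sojourn = np.where(out_rate > 0, 1.0 / np.where(out_rate > 0, out_rate, 1.0), t1 - t0)
    return np.sqrt(se**2 + (sojourn / (t1 - t0)) ** 2)


def occupancy_blocks(traj: Trajectory, burn_in: float = 0.1, n_blocks: int = 20) -> np.ndarray:
    """Per-block dwell fractions, shape (n_blocks, 4).

    Splitting the post-burn-in window into contiguous blocks gives roughly
    independent occupancy estimates; their scatter yields Monte-Carlo SEs
    for the stationary probabilities.
    """
    t0, t1 = _post_window(traj, burn_in)
    edges = np.linspace(t0, t1, n_blocks + 1)
    out = np.empty((n_blocks, 4))
    for k in range(n_blocks):
        dwell = traj._dwell(edges[k], edges[k + 1])
        out[k] = dwell / dwell.sum()
    return out
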