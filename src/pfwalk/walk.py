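"""Stochastic simulation of the discrete per-follicle random walk, and exact
lattice-occupancy propagation of its law.

The discrete walk lives on the lattice ``i * dx``: each time step the activity
moves up ``dx`` with probability ``p`` and down ``dx`` otherwise, and the
follicle exits at the first step where the position is <= 0 (growth
activation) or >= L (death).  ``p`` may vary with age, which is how
time-variant drift schedules are realised.

Two realisations of the same law are provided:

* Monte-Carlo path sampling (:func:`sample_exit_times`), vectorised in blocks
  so that millions of step draws stay in numpy; all walks advance in lockstep,
  so an age-dependent ``p`` applies uniformly across active walkers.
* deterministic occupancy propagation (:func:`propagate_occupancy`), which
  pushes the full probability mass through one step at a time and therefore
  yields the *exact* marginal survival curve and per-step exit hazards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .first_passage import DiscreteParams, InvalidParameterError

__all__ = [
    "WalkConfig",
    "ExitRecord",
    "ExitRecords",
    "OccupancyGrid",
    "GROWTH",
    "DEATH",
    "CENSORED",
    "simulate_exit",
    "sample_exit_times",
    "propagate_occupancy",
    "occupancy_from_config",
]

# exit-side codes
GROWTH, DEATH, CENSORED = 0, 1, 2
_SIDE_NAMES = {GROWTH: "growth", DEATH: "death", CENSORED: "censored"}


@dataclass(frozen=True)
class WalkConfig:
    """Configuration of the lattice walk.

    ``x0`` and ``L`` are snapped to the nearest lattice multiple of ``dx``;
    snapping ``x0`` onto (or beyond) a boundary is an error.  ``L = inf``
    leaves the walk unbounded above.  ``p_by_age`` optionally gives an
    age-dependent up-probability (callable age -> p) overriding ``disc.p``.
    """

    disc: DiscreteParams
    x0: float = 1.0
    L: float = math.inf
    max_age: float = 120.0
    p_by_age: object = None  # Callable[[float], float] | None

    def __post_init__(self) -> None:
        if self.max_age <= 0:
            raise InvalidParameterError("max_age must be > 0")
        i0, K = self.lattice()
        if K is not None and not 0 < i0 < K:
            raise InvalidParameterError(
                f"x0={self.x0} snaps to lattice site {i0} outside (0, {K})"
            )
        if K is None and i0 <= 0:
            raise InvalidParameterError(f"x0={self.x0} snaps onto the growth boundary")

    def lattice(self) -> tuple[int, int | None]:
        """(initial site index, upper boundary index or None for L = inf)."""
        i0 = round(self.x0 / self.disc.dx)
        K = None if math.isinf(self.L) else round(self.L / self.disc.dx)
        return i0, K

    def n_steps(self) -> int:
        return math.ceil(self.max_age / self.disc.dt - 1e-9)

    def p_of_step(self, k: int) -> float:
        if self.p_by_age is None:
            return self.disc.p
        p = float(self.p_by_age(k * self.disc.dt))
        if not 0.0 <= p <= 1.0:
            raise InvalidParameterError(f"schedule gives p={p} outside [0, 1]")
        return p


@dataclass(frozen=True)
class ExitRecord:
    """One follicle's exit: time (years, a multiple of dt; equals max_age when
    censored) and side (growth / death / censored)."""

    exit_time: float
    exit_side: int

    @property
    def side_name(self) -> str:
        return _SIDE_NAMES[self.exit_side]


@dataclass
class ExitRecords:
    """Struct-of-arrays container for many exits."""

    exit_times: np.ndarray
    exit_sides: np.ndarray

    def __len__(self) -> int:
        return self.exit_times.size

    def __getitem__(self, i: int) -> ExitRecord:
        return ExitRecord(float(self.exit_times[i]), int(self.exit_sides[i]))

    @property
    def censored(self) -> np.ndarray:
        return self.exit_sides == CENSORED


def simulate_exit(cfg: WalkConfig, rng: np.random.Generator) -> ExitRecord:
    """Walk a single follicle step by step until absorption or censoring."""
    i, K = cfg.lattice()
    n_steps = cfg.n_steps()
    dt = cfg.disc.dt
    for k in range(n_steps):
        p = cfg.p_of_step(k)
        i += 1 if rng.random() < p else -1
        if i <= 0:
            return ExitRecord((k + 1) * dt, GROWTH)
        if K is not None and i >= K:
            return ExitRecord((k + 1) * dt, DEATH)
    return ExitRecord(cfg.max_age, CENSORED)


# block sizes for the vectorised sampler; fixed so that a given (seed, cfg)
# always consumes the random stream in the same order
_STEP_BLOCK = 2048
_WALKER_CHUNK = 8192


def sample_exit_times(
    n: int, cfg: WalkConfig, seed_or_rng: "int | np.random.Generator"
) -> ExitRecords:
    """Sample ``n`` independent exit records of the configured walk.

    Walkers are processed in fixed-size chunks; within a chunk all walkers
    advance through blocks of steps at once (positions are integer lattice
    sites accumulated by cumulative sums), and a walker's exit is the first
    step within the block at which it touches a boundary.  Reproducible given
    (seed, cfg).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    times = np.empty(n, dtype=float)
    sides = np.empty(n, dtype=np.int8)
    for lo in range(0, n, _WALKER_CHUNK):
        hi = min(lo + _WALKER_CHUNK, n)
        t, s = _sample_chunk(hi - lo, cfg, rng)
        times[lo:hi] = t
        sides[lo:hi] = s
    return ExitRecords(times, sides)


def _sample_chunk(
    n: int, cfg: WalkConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    i0, K = cfg.lattice()
    dt = cfg.disc.dt
    n_steps = cfg.n_steps()

    times = np.full(n, cfg.max_age, dtype=float)
    sides = np.full(n, CENSORED, dtype=np.int8)
    alive = np.arange(n)
    pos = np.full(n, i0, dtype=np.int64)

    step0 = 0
    while alive.size and step0 < n_steps:
        m = min(_STEP_BLOCK, n_steps - step0)
        if cfg.p_by_age is None:
            p_blk = cfg.disc.p
        else:
            p_blk = np.array([cfg.p_of_step(step0 + j) for j in range(m)])
        u = rng.random((alive.size, m), dtype=np.float32)
        steps = np.where(u < p_blk, 1, -1).astype(np.int32)
        del u
        traj = np.cumsum(steps, axis=1, dtype=np.int64)
        del steps
        traj += pos[alive, None]

        hit_low = traj <= 0
        hit = hit_low if K is None else (hit_low | (traj >= K))
        any_hit = hit.any(axis=1)
        if np.any(any_hit):
            rows = np.flatnonzero(any_hit)
            first = np.argmax(hit[rows], axis=1)
            w = alive[rows]
            times[w] = (step0 + first + 1) * dt
            sides[w] = np.where(hit_low[rows, first], GROWTH, DEATH)
        keep = ~any_hit
        pos[alive[keep]] = traj[keep, -1]
        alive = alive[keep]
        step0 += m
    return times, sides


@dataclass
class OccupancyGrid:
    """Probability mass over interior lattice sites ``1..K-1`` plus the mass
    absorbed at each boundary.  ``from_point(i0, K)`` starts all mass at one
    site."""

    interior: np.ndarray  # length K-1; entry j is mass at site j+1
    absorbed_growth: float = 0.0
    absorbed_death: float = 0.0

    @classmethod
    def from_point(cls, i0: int, K: int) -> "OccupancyGrid":
        if not 0 < i0 < K:
            raise InvalidParameterError(f"start site {i0} outside (0, {K})")
        mass = np.zeros(K - 1)
        mass[i0 - 1] = 1.0
        return cls(interior=mass)

    def total(self) -> float:
        return float(self.interior.sum() + self.absorbed_growth + self.absorbed_death)

    def check(self, tol: float = 1e-12) -> None:
        if np.any(self.interior < -tol):
            raise InvalidParameterError("negative occupancy mass")
        if abs(self.total() - 1.0) > 1e-9:
            raise InvalidParameterError(f"occupancy mass {self.total()} != 1")


def propagate_occupancy(
    grid: OccupancyGrid,
    p_by_step: "float | Sequence[float] | np.ndarray",
    steps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Push the occupancy mass through ``steps`` walk steps in place.

    Each step sends a fraction ``p`` of every interior site's mass one site up
    and ``1 - p`` one site down; mass stepping past the ends joins the
    absorbed totals.  Returns the survival curve ``S(k dt)`` (interior mass
    after step k, k = 1..steps) and the per-step hazards
    ``h_k = (S_{k-1} - S_k) / S_{k-1}`` (0 once no mass remains).

    This is the exact expectation of the Monte-Carlo walk, including under
    age-varying ``p``.
    """
    p_arr = np.broadcast_to(np.asarray(p_by_step, dtype=float), (steps,))
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise InvalidParameterError("all step probabilities must be in [0, 1]")
    mass = grid.interior
    surv = np.empty(steps)
    haz = np.empty(steps)
    s_prev = float(mass.sum())
    new = np.empty_like(mass)
    for k in range(steps):
        p = p_arr[k]
        q = 1.0 - p
        new[:] = 0.0
        new[1:] = p * mass[:-1]  # up-moves
        new[:-1] += q * mass[1:]  # down-moves
        grid.absorbed_growth += q * mass[0]
        grid.absorbed_death += p * mass[-1]
        mass, new = new, mass
        s = float(mass.sum())
        surv[k] = s
        haz[k] = 0.0 if s_prev <= 0.0 else (s_prev - s) / s_prev
        s_prev = s
    grid.interior = mass
    return surv, haz


def occupancy_from_config(cfg: WalkConfig) -> tuple[OccupancyGrid, np.ndarray]:
    """Build the point-mass grid for ``cfg`` and its per-step p sequence.

    An infinite ``L`` is replaced by a lattice ceiling high enough that the
    upper boundary is unreachable within the horizon (start site + number of
    steps), so the truncation is exact.
    """
    i0, K = cfg.lattice()
    n_steps = cfg.n_steps()
    if K is None:
        K = i0 + n_steps + 1
    if cfg.p_by_age is None:
        p_seq = np.full(n_steps, cfg.disc.p)
    else:
        p_seq = np.array([cfg.p_of_step(k) for k in range(n_steps)])
    return OccupancyGrid.from_point(i0, K), p_seq
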