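"""Momentum-driven multi-objective artificial bee colony (MMOABC).

A bi-objective ABC that tunes the three free PCNN parameters
(alpha_L, beta, alpha_theta).  Employed bees take heavy-ball momentum steps,
onlooker bees take Nesterov-style steps, and the nondominated solutions are
kept in a bounded Pareto archive whose density is controlled by a per-
objective grid: crowded members (small total grid-index distance to the rest
of the archive) are the most likely to be deleted when the archive overflows.

Objectives default to maximizing both cross entropy (CE) and mutual
information (MI) of the fused image against the two sources; the
conventional minimize-CE sense is available through ``OptimizerConfig.senses``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FoodSource",
    "OptimizerConfig",
    "ParetoArchive",
    "init_population",
    "employed_update",
    "onlooker_update",
    "onlooker_probability",
    "grid_index",
    "deletion_probability",
    "dominates",
    "optimize",
]

DEFAULT_BOUNDS = ((0.01, 3.0), (0.01, 1.0), (0.01, 3.0))  # alpha_L, beta, alpha_theta


@dataclass
class FoodSource:
    """A candidate parameter point with its fitness vector, stagnation
    counter and per-dimension momentum memories (``a``: employed-bee steps,
    ``b``: onlooker-bee steps)."""

    x: np.ndarray
    fitness: np.ndarray | None = None
    trial: int = 0
    a: np.ndarray = field(default=None)
    b: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.a is None:
            self.a = np.zeros_like(self.x)
        if self.b is None:
            self.b = np.zeros_like(self.x)

    def copy(self) -> "FoodSource":
        return FoodSource(
            x=self.x.copy(),
            fitness=None if self.fitness is None else np.asarray(self.fitness, float).copy(),
            trial=self.trial,
            a=self.a.copy(),
            b=self.b.copy(),
        )


@dataclass
class OptimizerConfig:
    NP: int = 20
    limit: int = 20
    max_cycle: int = 30
    gamma: float = 0.9
    n_grid: int = 7
    rep: int = 20
    bounds: tuple = DEFAULT_BOUNDS
    senses: tuple = (1, 1)  # +1 maximize, -1 minimize, one per objective
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.NP < 2:
            raise ValueError("NP must be >= 2")
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must lie in [0, 1)")
        if self.n_grid < 1 or self.rep < 1:
            raise ValueError("n_grid and rep must be >= 1")
        for lo, hi in self.bounds:
            if lo >= hi:
                raise ValueError(f"degenerate bounds ({lo}, {hi})")


def init_population(config: OptimizerConfig, rng: np.random.Generator) -> list:
    """NP sources drawn uniformly within the per-dimension bounds,
    momenta zeroed."""
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    return [FoodSource(x=lo + rng.uniform(0.0, 1.0, size=lo.size) * (hi - lo))
            for _ in range(config.NP)]


def _clip(x: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo, hi)


def employed_update(source: FoodSource, partner: FoodSource, j: int, r: float,
                    gamma: float, bounds=DEFAULT_BOUNDS) -> FoodSource:
    """Heavy-ball step on dimension j:
    a_new = r (x_j - partner_j) + gamma a_j;  x_new_j = x_j + a_new."""
    if not 0 <= j < source.x.size:
        raise IndexError(f"dimension {j} out of range")
    cand = source.copy()
    a_new = r * (source.x[j] - partner.x[j]) + gamma * source.a[j]
    cand.a[j] = a_new
    cand.x[j] = source.x[j] + a_new
    cand.x = _clip(cand.x, bounds)
    cand.fitness = None
    cand.trial = 0
    return cand


def onlooker_update(source: FoodSource, partner: FoodSource, j: int, r: float,
                    gamma: float, bounds=DEFAULT_BOUNDS) -> FoodSource:
    """Nesterov-style step on dimension j:
    b_new = r (x_j - partner_j - gamma b_j) + gamma b_j;  x_new_j = x_j + b_new."""
    if not 0 <= j < source.x.size:
        raise IndexError(f"dimension {j} out of range")
    cand = source.copy()
    b_new = r * (source.x[j] - partner.x[j] - gamma * source.b[j]) + gamma * source.b[j]
    cand.b[j] = b_new
    cand.x[j] = source.x[j] + b_new
    cand.x = _clip(cand.x, bounds)
    cand.fitness = None
    cand.trial = 0
    return cand


def onlooker_probability(fitness_matrix: np.ndarray) -> np.ndarray:
    """Roulette weights per source: mean over objectives of
    0.9 f / max(f) + 0.1.  Columns with non-positive entries are shifted
    positive (min subtracted, tiny offset added) before the ratio."""
    f = np.asarray(fitness_matrix, dtype=float).copy()
    if f.ndim != 2:
        raise ValueError("fitness matrix must be NP x Target")
    for k in range(f.shape[1]):
        col = f[:, k]
        if col.min() <= 0:
            col = col - col.min() + 1e-9
        f[:, k] = col / col.max()
    return (0.9 * f + 0.1).mean(axis=1)


def grid_index(fitnesses: np.ndarray, n_grid: int) -> np.ndarray:
    """Per-member, per-objective grid bins over the archive's fitness range.

    Finite edges sit at low + j (high - low) / n_grid for j = 1..n_grid-1;
    the outer intervals extend to -inf/+inf so every member falls in a bin.
    """
    f = np.atleast_2d(np.asarray(fitnesses, dtype=float))
    bins = np.zeros(f.shape, dtype=int)
    for k in range(f.shape[1]):
        lo, hi = f[:, k].min(), f[:, k].max()
        edges = lo + np.arange(1, n_grid) * (hi - lo) / n_grid
        bins[:, k] = np.searchsorted(edges, f[:, k], side="left")
    return bins


def deletion_probability(grid_bins: np.ndarray) -> tuple:
    """Isolation score and deletion weight per archive member.

    poss_i = sum over members j and objectives k of |grid_ik - grid_jk|;
    Poss_i = 1 / (poss_i + 1).  Isolated members (large poss) get small
    deletion weight.
    """
    g = np.atleast_2d(np.asarray(grid_bins, dtype=float))
    poss = np.abs(g[:, None, :] - g[None, :, :]).sum(axis=(1, 2))
    return poss, 1.0 / (poss + 1.0)


def dominates(fa: np.ndarray, fb: np.ndarray, senses=(1, 1)) -> bool:
    """Pareto dominance of fitness fa over fb under the objective senses."""
    s = np.asarray(senses, dtype=float)
    da = s * np.asarray(fa, dtype=float)
    db = s * np.asarray(fb, dtype=float)
    return bool(np.all(da >= db) and np.any(da > db))


class ParetoArchive:
    """Bounded store of mutually nondominated food sources."""

    def __init__(self, senses=(1, 1), n_grid: int = 7):
        self.senses = senses
        self.n_grid = n_grid
        self.members: list = []

    def fitness_matrix(self) -> np.ndarray:
        return np.array([m.fitness for m in self.members], dtype=float)

    def add(self, candidate: FoodSource) -> None:
        """Insert a copy if no member dominates it; evict members it dominates."""
        for m in self.members:
            if dominates(m.fitness, candidate.fitness, self.senses) or np.array_equal(
                np.asarray(m.fitness, float), np.asarray(candidate.fitness, float)
            ):
                return
        self.members = [
            m for m in self.members if not dominates(candidate.fitness, m.fitness, self.senses)
        ]
        self.members.append(candidate.copy())

    def update(self, population: list) -> None:
        for src in population:
            if src.fitness is not None:
                self.add(src)

    def prune(self, rep: int, rng: np.random.Generator) -> None:
        """Delete members sampled proportional to the deletion weight until
        the archive fits in ``rep`` slots."""
        while len(self.members) > rep:
            bins = grid_index(self.fitness_matrix(), self.n_grid)
            _, weight = deletion_probability(bins)
            p = weight / weight.sum()
            idx = int(rng.choice(len(self.members), p=p))
            del self.members[idx]

    def select_triplet(self) -> np.ndarray:
        """Pick the most isolated member (largest poss; lowest index on ties)."""
        if not self.members:
            raise ValueError("empty archive")
        bins = grid_index(self.fitness_matrix(), self.n_grid)
        poss, _ = deletion_probability(bins)
        return self.members[int(np.argmax(poss))].x.copy()


def _roulette(probs: np.ndarray, rng: np.random.Generator) -> int:
    cum = np.cumsum(probs)
    u = rng.uniform(0.0, cum[-1])
    return int(np.searchsorted(cum, u, side="left"))


def _draw_partner(i: int, NP: int, rng: np.random.Generator) -> int:
    k = int(rng.integers(NP - 1))
    return k + 1 if k >= i else k


def _evaluate(x: np.ndarray, objective, senses) -> np.ndarray:
    try:
        f = np.asarray(objective(x), dtype=float)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError("non-finite fitness")
        return f
    except Exception:  # failed evaluation gets the worst possible fitness
        return -np.asarray(senses, dtype=float) * 1e18


def optimize(config: OptimizerConfig, objective) -> tuple:
    """Run the full colony; returns (archive, chosen parameter vector).

    ``objective(x) -> tuple`` returns the fitness vector (CE, MI) for a
    parameter point.  RNG draw order per cycle: employed phase (dimension,
    partner, step size per source), onlooker phase (roulette pick, dimension,
    partner, step size per onlooker), one scout re-draw at most.
    """
    rng = np.random.default_rng(config.seed)
    senses = config.senses
    pop = init_population(config, rng)
    for src in pop:
        src.fitness = _evaluate(src.x, objective, senses)

    archive = ParetoArchive(senses=senses, n_grid=config.n_grid)
    archive.update(pop)
    archive.prune(config.rep, rng)

    def greedy(i: int, cand: FoodSource) -> None:
        cand.fitness = _evaluate(cand.x, objective, senses)
        if dominates(cand.fitness, pop[i].fitness, senses):
            pop[i] = cand
        else:
            pop[i].trial += 1

    for _ in range(config.max_cycle):
        for i in range(config.NP):
            j = int(rng.integers(len(config.bounds)))
            k = _draw_partner(i, config.NP, rng)
            r = rng.uniform(-1.0, 1.0)
            greedy(i, employed_update(pop[i], pop[k], j, r, config.gamma, config.bounds))

        probs = onlooker_probability(np.array([s.fitness for s in pop]) * np.asarray(senses))
        for _ in range(config.NP):
            i = _roulette(probs, rng)
            j = int(rng.integers(len(config.bounds)))
            k = _draw_partner(i, config.NP, rng)
            r = rng.uniform(-1.0, 1.0)
            greedy(i, onlooker_update(pop[i], pop[k], j, r, config.gamma, config.bounds))

        worst = int(np.argmax([s.trial for s in pop]))
        if pop[worst].trial > config.limit:
            lo = np.array([b[0] for b in config.bounds])
            hi = np.array([b[1] for b in config.bounds])
            fresh = FoodSource(x=lo + rng.uniform(0.0, 1.0, size=lo.size) * (hi - lo))
            fresh.fitness = _evaluate(fresh.x, objective, senses)
            pop[worst] = fresh

        archive.update(pop)
        archive.prune(config.rep, rng)

    return archive, archive.select_triplet()
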