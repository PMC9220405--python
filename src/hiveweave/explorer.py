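"""Cluster-oriented genetic algorithm over the parametric hive model.

A genome is a named vector of real design parameters (cavity radius
and height, weave cell size, zone widths, roof layers) confined to a
box of bounds.  Each generation the population is evaluated, bred
(tournament selection, uniform crossover, Gaussian mutation, elitism),
and clustered by k-means in normalized genome space; the medoid of
each cluster is surfaced as a representative design.  Fitness is
either a weighted scalarization of the objectives (batch mode) or
proximity to the clusters of user-preferred representatives
(interactive mode, the preference passed as a list of representative
indices per generation).

All randomness flows through one seeded generator, so a (population,
seed) pair reproduces every crossover point, mutation draw and k-means
initialisation byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .geometry_core import GeometryError, PlanarRegion
from .units import cm_to_mm
from .vo_pipeline import OffsetSchedule, generate_slice
from .weaving import path_length


@dataclass(frozen=True)
class GenomeSpace:
    """Named real parameters with inclusive bounds."""
    bounds: dict[str, tuple[float, float]]

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def validate(self, genome: dict) -> None:
        unknown = set(genome) - set(self.bounds)
        if unknown:
            raise GeometryError(f"unknown genome parameters: {sorted(unknown)}")
        missing = set(self.bounds) - set(genome)
        if missing:
            raise GeometryError(f"missing genome parameters: {sorted(missing)}")
        for name, v in genome.items():
            lo, hi = self.bounds[name]
            if not (lo <= v <= hi):
                raise GeometryError(
                    f"parameter {name}={v} outside bounds [{lo}, {hi}]")

    def clip(self, genome: dict) -> dict:
        return {n: float(np.clip(genome[n], *self.bounds[n])) for n in self.names}

    def sample(self, rng: np.random.Generator) -> dict:
        return {n: float(rng.uniform(lo, hi))
                for n, (lo, hi) in self.bounds.items()}

    def to_array(self, genome: dict) -> np.ndarray:
        return np.array([genome[n] for n in self.names])

    def normalize(self, arr: np.ndarray) -> np.ndarray:
        lo = np.array([b[0] for b in self.bounds.values()])
        hi = np.array([b[1] for b in self.bounds.values()])
        return (arr - lo) / np.where(hi > lo, hi - lo, 1.0)


@dataclass(frozen=True)
class ObjectiveVector:
    toolpath_length_m: float       # print time / material proxy
    cavity_volume_error_l: float   # |achieved - target| in litres
    channel_capacity: int          # reserved inoculation cells per layer
    penalty: float = 0.0           # constraint violation, finite

    def __post_init__(self):
        vals = (self.toolpath_length_m, self.cavity_volume_error_l,
                float(self.channel_capacity), self.penalty)
        if not all(math.isfinite(v) for v in vals):
            raise GeometryError("objective components must be finite")
        if self.penalty < 0:
            raise GeometryError("penalty must be >= 0")


#: Default VO genome: zone widths and weave resolution of a standing hive.
DEFAULT_SPACE = GenomeSpace({
    "cavity_radius": (100.0, 180.0),    # mm
    "cavity_height": (40.0, 90.0),      # cm
    "cell_size": (4.0, 12.0),           # mm, weave circumradius
    "wall_width": (2.0, 6.0),           # mm
    "weave_width": (12.0, 40.0),        # mm
    "channel_width": (15.0, 35.0),      # mm
})

DEFAULT_WEIGHTS = {"toolpath_length_m": 1.0, "cavity_volume_error_l": 5.0,
                   "channel_capacity": -0.2, "penalty": 100.0}


class VOEvaluator:
    """Deterministic objective evaluation of a VO genome.

    One representative slice is generated per genome (the hive body is
    a stack of near-identical slices) and its toolpath length is
    multiplied by the layer count; cavity volume follows from the
    cylinder closed form.  Infeasible genomes (bed overflow, schedule
    exhausting the contour) are scored with a finite penalty, never an
    exception.  Results are memoized on the rounded genome.
    """

    def __init__(self, space: GenomeSpace = DEFAULT_SPACE,
                 target_volume: float = 30.0, layer_height: float = 2.0,
                 max_print_diameter: float = 50.0):
        self.space = space
        self.target_volume = target_volume
        self.layer_height = layer_height
        self.max_print_diameter = max_print_diameter
        self._cache: dict[tuple, ObjectiveVector] = {}

    def __call__(self, genome: dict) -> ObjectiveVector:
        self.space.validate(genome)
        key = tuple(round(genome[n], 9) for n in self.space.names)
        if key not in self._cache:
            self._cache[key] = self._evaluate(genome)
        return self._cache[key]

    def _evaluate(self, g: dict) -> ObjectiveVector:
        r = g["cavity_radius"]
        h_mm = cm_to_mm(g["cavity_height"])
        volume_l = np.pi * r * r * h_mm / 1e6
        vol_err = abs(volume_l - self.target_volume)
        schedule = OffsetSchedule((
            (g["wall_width"], "wall"),
            (g["weave_width"], "weave"),
            (g["channel_width"], "channel"),
            (g["wall_width"], "wall"),
        ))
        r_outer = r + schedule.total_width
        penalty = 0.0
        if 2 * r_outer > cm_to_mm(self.max_print_diameter):
            penalty += (2 * r_outer - cm_to_mm(self.max_print_diameter)) / 10.0
        contour = PlanarRegion.circle(r_outer, segments=64)
        try:
            pattern = generate_slice(contour, schedule, g["cell_size"])
        except GeometryError:
            return ObjectiveVector(0.0, vol_err, 0, penalty + 100.0)
        layer_len = sum(path_length(tp) for tp in pattern.toolpaths)
        n_layers = max(1, int(round(h_mm / self.layer_height)))
        return ObjectiveVector(
            toolpath_length_m=layer_len * n_layers / 1000.0,
            cavity_volume_error_l=vol_err,
            channel_capacity=len(pattern.channel_cells),
            penalty=penalty)


def evaluate(genome: dict, evaluator: VOEvaluator) -> ObjectiveVector:
    """Module-level convenience wrapper (see VOEvaluator)."""
    return evaluator(genome)


def scalarize(obj: ObjectiveVector, weights: dict | None = None) -> float:
    w = DEFAULT_WEIGHTS if weights is None else weights
    return (w.get("toolpath_length_m", 0) * obj.toolpath_length_m
            + w.get("cavity_volume_error_l", 0) * obj.cavity_volume_error_l
            + w.get("channel_capacity", 0) * obj.channel_capacity
            + w.get("penalty", 0) * obj.penalty)


@dataclass
class GenerationLog:
    generation: int
    genomes: list[dict]
    objectives: list[ObjectiveVector]
    fitness: list[float]
    clusters: list[int]
    representatives: list[int]     # population indices of cluster medoids
    best_fitness: float


@dataclass
class EvolutionResult:
    population: list[dict]
    representatives: list[dict]
    log: list[GenerationLog] = field(default_factory=list)


def _cluster(space: GenomeSpace, population: list[dict], k: int,
             seed: int) -> tuple[list[int], list[int]]:
    X = space.normalize(np.array([space.to_array(g) for g in population]))
    if k >= len(population):
        return list(range(len(population))), list(range(len(population)))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2 ** 31))
    labels = km.fit_predict(X)
    reps = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if len(members) == 0:
            reps.append(int(np.argmin(np.linalg.norm(
                X - km.cluster_centers_[c], axis=1))))
            continue
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        reps.append(int(members[np.argmin(d)]))
    return labels.tolist(), reps


def evolve(population: list[dict] | int, k: int, generations: int, seed: int,
           evaluator: VOEvaluator | None = None, selection=None,
           mode: str = "batch", weights: dict | None = None,
           crossover_rate: float = 0.8, mutation_rate: float = 0.1,
           mutation_sigma: float = 0.05, tournament: int = 2) -> EvolutionResult:
    """Run the cluster-oriented GA.

    ``population`` is either an initial genome list or a size to sample.
    ``selection`` (interactive mode) is a list of preferred
    representative indices applied every generation; batch mode
    minimizes the weighted objective scalarization.  Elitism: the best
    individual survives unchanged.
    """
    evaluator = evaluator or VOEvaluator()
    space = evaluator.space
    rng = np.random.default_rng(seed)
    if isinstance(population, int):
        population = [space.sample(rng) for _ in range(population)]
    else:
        population = [space.clip(dict(g)) for g in population]
    if not (1 <= k <= len(population)):
        raise GeometryError(f"need population size >= k >= 1, got "
                            f"{len(population)} and {k}")

    lo = np.array([b[0] for b in space.bounds.values()])
    hi = np.array([b[1] for b in space.bounds.values()])
    sigma = mutation_sigma * (hi - lo)
    result = EvolutionResult(population=population, representatives=[])

    for gen in range(generations):
        objs = [evaluator(g) for g in population]
        labels, reps = _cluster(space, population, k, seed + gen)
        if mode == "batch" or not selection:
            fitness = [scalarize(o, weights) for o in objs]
        else:
            # interactive: prefer genomes near the selected representatives
            X = space.normalize(np.array([space.to_array(g)
                                          for g in population]))
            sel_pts = X[[reps[i] for i in selection]]
            fitness = np.min(np.linalg.norm(
                X[:, None, :] - sel_pts[None, :, :], axis=2), axis=1).tolist()
        best_idx = int(np.argmin(fitness))
        result.log.append(GenerationLog(
            generation=gen, genomes=[dict(g) for g in population],
            objectives=objs, fitness=list(fitness), clusters=labels,
            representatives=reps, best_fitness=fitness[best_idx]))

        if gen == generations - 1:
            result.population = population
            result.representatives = [dict(population[i]) for i in reps]
            break

        # breed: elitism + tournament / uniform crossover / gaussian mutation
        new_pop = [dict(population[best_idx])]
        while len(new_pop) < len(population):
            pa = _tournament(rng, fitness, tournament)
            pb = _tournament(rng, fitness, tournament)
            a = space.to_array(population[pa]).copy()
            b = space.to_array(population[pb])
            if rng.random() < crossover_rate:
                mask = rng.random(len(a)) < 0.5
                a[mask] = b[mask]
            mut = rng.random(len(a)) < mutation_rate
            a = a + mut * rng.normal(0.0, sigma)
            a = np.clip(a, lo, hi)
            new_pop.append(dict(zip(space.names, map(float, a))))
        population = new_pop

    return result


def _tournament(rng: np.random.Generator, fitness: list[float], size: int) -> int:
    idx = rng.integers(0, len(fitness), size=size)
    return int(min(idx, key=lambda i: fitness[i]))
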