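"""Population evolution: fluctuating-resource lifetimes, fitness-proportional
reproduction, the 80-environment perturbation panel and the two-stage
(adapt -> perturb -> re-adapt) protocol.

Every generation each of the N cells experiences 1-3 resource conditions
(external A levels drawn from the fluctuation range), its fitness is the
geometric mean of its homeostasis scores in those conditions, and N
offspring are drawn by fitness-proportional sampling with replacement; each
offspring is a mutated copy of its parent.  Population size is strictly
constant.  The trace records parent pointers and mutation events for every
generation (plus periodic full-population genome snapshots), which is enough
to reconstruct any line of descent exactly by replay.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .dynamics import (CHANGEABLE_PARAMS, STANDARD_ENV, DEFAULT_K_OP,
                       EnvironmentParams, cell_fitness, steady_state_arrays,
                       _gene_positions)
from .genome import Genome, genome_from_text, genome_to_text, stamp_ancestry
from .mutation import (MutationEvent, MutationRates, WGD, apply_all,
                       whole_genome_duplicate, read_event_log, write_event_log)

__all__ = [
    "EnvironmentPanel",
    "ExperimentProtocol",
    "Population",
    "Cell",
    "SimulationTrace",
    "FitnessEvaluator",
    "DEFAULT_LEVEL_FACTORS",
    "make_default_levels",
    "make_environment_panel",
    "lifetime_environments",
    "fluctuation_levels",
    "init_population",
    "run_generation",
    "evolve",
    "apply_environmental_change",
    "run_experiment",
    "save_trace",
    "load_trace",
]

#: Low/high multipliers on the standard value for each changeable parameter
#: ("a factor 2 to 4 different from the standard environment"; the severest
#: change is on the degradation rate).
DEFAULT_LEVEL_FACTORS: Mapping[str, Tuple[float, float]] = {
    "permeability": (0.5, 2.0),
    "degradation": (0.25, 4.0),
    "conversion_rate": (0.5, 2.0),
    "target_A": (0.5, 2.0),
    "target_X": (0.5, 2.0),
}

#: Default fluctuation of the external resource within a lifetime.
DEFAULT_FLUCTUATION = (0.1, 10.0)
DEFAULT_N_LEVELS = 5


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Environment panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvironmentPanel:
    standard: EnvironmentParams
    levels: Mapping[str, Tuple[float, float]]
    environments: Tuple[EnvironmentParams, ...]

    def __len__(self):
        return len(self.environments)

    def by_label(self, label: str) -> EnvironmentParams:
        for env in self.environments:
            if env.label == label:
                return env
        raise KeyError(label)


def make_default_levels(standard: EnvironmentParams = STANDARD_ENV,
                        factors: Mapping[str, Tuple[float, float]] = DEFAULT_LEVEL_FACTORS
                        ) -> Dict[str, Tuple[float, float]]:
    """Concrete low/high values per changeable parameter."""
    return {p: (getattr(standard, p) * factors[p][0],
                getattr(standard, p) * factors[p][1])
            for p in CHANGEABLE_PARAMS}


def make_environment_panel(standard: EnvironmentParams = STANDARD_ENV,
                           levels: Optional[Mapping[str, Tuple[float, float]]] = None,
                           n_changed: int = 3) -> EnvironmentPanel:
    """Systematic perturbation set: all combinations in which exactly
    ``n_changed`` of the five parameters take their low or high level.

    With 5 parameters, 3 changed and 2 levels this is C(5,3) * 2^3 = 80
    environments.  Labels are deterministic, e.g.
    ``degradation=high|target_A=low|target_X=high``.
    """
    if levels is None:
        levels = make_default_levels(standard)
    for p in CHANGEABLE_PARAMS:
        if p not in levels or len(levels[p]) != 2:
            raise ConfigError(f"missing low/high levels for parameter {p!r}")
    envs = []
    for subset in itertools.combinations(CHANGEABLE_PARAMS, n_changed):
        for choice in itertools.product((0, 1), repeat=n_changed):
            changes = {p: levels[p][c] for p, c in zip(subset, choice)}
            label = "|".join(f"{p}={'high' if c else 'low'}"
                             for p, c in zip(subset, choice)) or "standard"
            envs.append(standard.replace(label=label, **changes))
    return EnvironmentPanel(standard=standard, levels=dict(levels),
                            environments=tuple(envs))


def write_panel(panel: EnvironmentPanel, path) -> None:
    def _write(fh):
        fh.write("#label\tA_ext\tpermeability\tdegradation\tconversion_rate"
                 "\ttarget_A\ttarget_X\n")
        for env in panel.environments:
            fh.write("\t".join([env.label] + [repr(getattr(env, p)) for p in (
                "A_ext", "permeability", "degradation", "conversion_rate",
                "target_A", "target_X")]) + "\n")
    if hasattr(path, "write"):
        _write(path)
    else:
        with open(path, "w") as fh:
            _write(fh)


def read_panel_row(path, label: str) -> EnvironmentParams:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] == label:
                return EnvironmentParams(*(float(x) for x in f[1:7]), label=f[0])
    raise KeyError(label)


# ---------------------------------------------------------------------------
# Lifetime resource fluctuation
# ---------------------------------------------------------------------------

def fluctuation_levels(standard: EnvironmentParams,
                       fluctuation: Tuple[float, float] = DEFAULT_FLUCTUATION,
                       n_levels: int = DEFAULT_N_LEVELS) -> np.ndarray:
    """Log-spaced external-resource levels spanning the fluctuation range."""
    lo, hi = fluctuation
    return np.geomspace(lo * standard.A_ext, hi * standard.A_ext, n_levels)


def lifetime_environments(standard: EnvironmentParams, rng, *,
                          fluctuation: Tuple[float, float] = DEFAULT_FLUCTUATION,
                          n_levels: Optional[int] = DEFAULT_N_LEVELS,
                          n_draws: Optional[int] = None
                          ) -> List[EnvironmentParams]:
    """Resource conditions seen in one cell's lifetime.

    Draws k uniform in {1, 2, 3} external-resource concentrations.  By
    default levels come from a symmetric log-spaced grid over the fluctuation
    range (the grid keeps evaluations cacheable; its mean log equals the
    midpoint of the log-range); ``n_levels=None`` samples log-uniformly and
    continuously instead.
    """
    k = n_draws if n_draws is not None else int(rng.integers(1, 4))
    lo, hi = fluctuation
    out = []
    if n_levels is None:
        draws = np.exp(rng.uniform(np.log(lo * standard.A_ext),
                                   np.log(hi * standard.A_ext), size=k))
    else:
        grid = fluctuation_levels(standard, fluctuation, n_levels)
        draws = grid[rng.integers(0, len(grid), size=k)]
    for a in draws:
        out.append(standard.replace(A_ext=float(a), label=f"A_ext={float(a):g}"))
    return out


# ---------------------------------------------------------------------------
# Population and trace
# ---------------------------------------------------------------------------

@dataclass
class Cell:
    cell_id: int
    genome: Genome
    parent_index: int        # index in previous generation; -1 for founders
    fitness: Optional[float] = None
    events: Tuple[MutationEvent, ...] = ()
    #: parent's genome, kept one generation deep so fitness evaluation can
    #: warm-start integration from the parent's steady state
    parent_genome: Optional[Genome] = None


@dataclass
class Population:
    cells: List[Cell]
    generation: int = 0

    @property
    def size(self) -> int:
        return len(self.cells)

    def genomes(self) -> List[Genome]:
        return [c.genome for c in self.cells]

    def fitnesses(self) -> np.ndarray:
        return np.array([c.fitness if c.fitness is not None else 0.0
                         for c in self.cells])


@dataclass(frozen=True)
class ExperimentProtocol:
    """Two-stage protocol constants."""
    high_fitness_cutoff: float = 0.85
    post_cutoff_delay: int = 1000
    max_generations: int = 15000


@dataclass
class SimulationTrace:
    """Per-generation records sufficient to reconstruct any line of descent.

    ``parents[g][i]`` is the parent index (in generation g-1) of cell i of
    generation g; ``events[g]`` maps cell index -> events that produced it;
    ``snapshots`` stores full population genome lists at generation 0 and
    every ``snapshot_interval`` generations (and at the final generation).
    """
    snapshot_interval: int = 100
    parents: List[np.ndarray] = field(default_factory=list)
    events: List[Dict[int, Tuple[MutationEvent, ...]]] = field(default_factory=list)
    fitness: List[np.ndarray] = field(default_factory=list)
    snapshots: Dict[int, List[Genome]] = field(default_factory=dict)
    summary: List[dict] = field(default_factory=list)
    change_generation: Optional[int] = None

    @property
    def n_generations(self) -> int:
        return len(self.parents) - 1

    def record(self, pop: Population, best_standard_fitness: float = math.nan,
               force_snapshot: bool = False) -> None:
        g = pop.generation
        assert g == len(self.parents), "generations must be recorded in order"
        self.parents.append(np.array([c.parent_index for c in pop.cells],
                                     dtype=np.int64))
        self.events.append({i: c.events for i, c in enumerate(pop.cells)
                            if c.events})
        self.fitness.append(pop.fitnesses())
        sizes = np.array([len(c.genome) for c in pop.cells])
        fits = self.fitness[-1]
        n_wgd = sum(1 for evs in self.events[-1].values()
                    for ev in evs if ev.kind == WGD)
        self.summary.append({
            "generation": g, "best_fitness": float(fits.max(initial=0.0)),
            "mean_fitness": float(fits.mean()) if len(fits) else 0.0,
            "best_standard_fitness": best_standard_fitness,
            "mean_genome_size": float(sizes.mean()) if len(sizes) else 0.0,
            "wgd_events": int(n_wgd)})
        if g == 0 or force_snapshot or (self.snapshot_interval > 0 and
                                        g % self.snapshot_interval == 0):
            self.snapshots[g] = pop.genomes()

    def finalize(self, pop: Population) -> None:
        if pop.generation not in self.snapshots:
            self.snapshots[pop.generation] = pop.genomes()


# ---------------------------------------------------------------------------
# Fitness evaluation with caching
# ---------------------------------------------------------------------------

class FitnessEvaluator:
    """Scores genomes in environments, memoising steady-state results.

    Steady-state evaluation is deterministic per (genome, environment), so
    results are cached by genome fingerprint and environment key -- unmutated
    offspring and recurring resource levels cost nothing.
    """

    def __init__(self, standard: EnvironmentParams = STANDARD_ENV, *,
                 fluctuation: Tuple[float, float] = DEFAULT_FLUCTUATION,
                 n_levels: Optional[int] = DEFAULT_N_LEVELS,
                 k_op: float = DEFAULT_K_OP, t_max: float = 150.0,
                 tol: float = 1e-6, dt_max: float = 1.0,
                 max_genome_size: Optional[int] = None,
                 max_cache: int = 200_000):
        self.standard = standard
        #: genomes above this size are inviable (fitness 0); used by the
        #: scaled-down protocols as an explicit carrying constraint
        self.max_genome_size = max_genome_size
        self.fluctuation = fluctuation
        self.n_levels = n_levels
        self.k_op = k_op
        self.t_max = t_max
        self.tol = tol
        self.dt_max = dt_max
        self._cache: Dict[tuple, float] = {}
        self._max_cache = max_cache
        # converged end states, used to warm-start offspring integrations;
        # the fixed point does not depend on the start, only speed does
        self._states: Dict[tuple, tuple] = {}
        self._max_states = 30_000
        grid = fluctuation_levels(standard, fluctuation,
                                  n_levels if n_levels else DEFAULT_N_LEVELS)
        self._grid_envs = [standard.replace(A_ext=float(a), label=f"A_ext={a:g}")
                           for a in grid]
        #: fixed reference resource set for the standardized fitness
        self.reference_A_ext = (float(grid[0]), float(grid[len(grid) // 2]),
                                float(grid[-1]))
        self._reference_envs = [standard.replace(A_ext=a, label=f"A_ext={a:g}")
                                for a in self.reference_A_ext]

    def score(self, genome: Genome, env: EnvironmentParams,
              warm_from: Optional[Genome] = None) -> float:
        env_key = env.key()
        key = (genome.fingerprint, env_key)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        a0 = None
        x0 = 0.0
        p0 = None
        if warm_from is not None:
            prev = self._states.get((warm_from.fingerprint, env_key))
            if prev is not None:
                a0, x0, parent_p = prev
                pos = _gene_positions(warm_from)
                p0 = np.empty(len(genome))
                for i, g in enumerate(genome):
                    j = pos.get(g.gene_id)
                    p0[i] = parent_p[j] if j is not None \
                        else g.promoter.basal_rate / env.degradation
        A, X, P, status, score = steady_state_arrays(
            genome, env, k_op=self.k_op, a0=a0, x0=x0, p0=p0,
            t_max=self.t_max, tol=self.tol, dt_max=self.dt_max)
        if len(self._cache) >= self._max_cache:
            self._cache.clear()
        self._cache[key] = score
        if status == 0:
            if len(self._states) >= self._max_states:
                self._states.clear()
            self._states[key] = (A, X, P)
        return score

    def _inviable(self, genome: Genome) -> bool:
        return len(genome) == 0 or (self.max_genome_size is not None and
                                    len(genome) > self.max_genome_size)

    def lifetime_fitness(self, genome: Genome, rng,
                         warm_from: Optional[Genome] = None) -> float:
        if self._inviable(genome):
            return 0.0
        k = int(rng.integers(1, 4))
        if self.n_levels is None:
            envs = lifetime_environments(self.standard, rng,
                                         fluctuation=self.fluctuation,
                                         n_levels=None, n_draws=k)
        else:
            idx = rng.integers(0, len(self._grid_envs), size=k)
            envs = [self._grid_envs[int(i)] for i in idx]
        return cell_fitness([self.score(genome, env, warm_from)
                             for env in envs])

    def standardized_fitness(self, genome: Genome) -> float:
        """Fitness on the fixed reference resource set (no stochastic
        fluctuation); used for the high-fitness cutoff."""
        if self._inviable(genome):
            return 0.0
        return cell_fitness([self.score(genome, env)
                             for env in self._reference_envs])


# ---------------------------------------------------------------------------
# Generation loop
# ---------------------------------------------------------------------------

def init_population(n_cells: int, rng, genome_factory) -> Population:
    """Founding population; ``genome_factory(rng)`` supplies each genome."""
    cells = [Cell(cell_id=i, genome=stamp_ancestry(genome_factory(rng)),
                  parent_index=-1) for i in range(n_cells)]
    return Population(cells=cells, generation=0)


def evaluate_fitness(pop: Population, evaluator: FitnessEvaluator, rng) -> None:
    for cell in pop.cells:
        cell.fitness = evaluator.lifetime_fitness(cell.genome, rng,
                                                  cell.parent_genome)


def run_generation(pop: Population, evaluator: FitnessEvaluator,
                   rates: MutationRates, rng) -> Population:
    """One Wright-Fisher generation: evaluate, select, mutate.

    Offspring are drawn fitness-proportionally with replacement until they
    completely replace the previous population.  A generation in which every
    cell has fitness zero falls back to uniform parent sampling so harsh
    environmental changes do not deadlock the simulation.
    """
    if any(c.fitness is None for c in pop.cells):
        evaluate_fitness(pop, evaluator, rng)
    fits = pop.fitnesses()
    total = fits.sum()
    probs = fits / total if total > 0 else None
    n = pop.size
    parent_idx = rng.choice(n, size=n, replace=True, p=probs)
    gen = pop.generation + 1
    cells = []
    for i, pi in enumerate(parent_idx):
        parent = pop.cells[int(pi)]
        child_genome, events = apply_all(parent.genome, rates, rng, gen)
        cells.append(Cell(cell_id=i, genome=child_genome,
                          parent_index=int(pi), events=tuple(events),
                          parent_genome=parent.genome))
    return Population(cells=cells, generation=gen)


def evolve(pop: Population, evaluator: FitnessEvaluator, rates: MutationRates,
           rng, n_generations: int, trace: Optional[SimulationTrace] = None,
           stop_cutoff: Optional[float] = None,
           std_every: int = 10) -> Tuple[Population, Optional[int]]:
    """Run up to ``n_generations`` generations, recording into ``trace``.

    If ``stop_cutoff`` is given, returns as soon as the population's best
    standardized fitness first exceeds it (checked every ``std_every``
    generations, which sets the resolution of the cutoff trigger); otherwise
    runs the full span.  ``std_every=0`` disables standardized-fitness
    tracking entirely (it is only a progress/trigger quantity).  Returns
    (population, cutoff_generation).
    """
    cutoff_gen = None
    if trace is not None and pop.generation == 0 and not trace.parents:
        evaluate_fitness(pop, evaluator, rng)
        trace.record(pop, _best_standard(pop, evaluator)
                     if std_every > 0 or stop_cutoff is not None else math.nan)
    for _ in range(n_generations):
        pop = run_generation(pop, evaluator, rates, rng)
        evaluate_fitness(pop, evaluator, rng)
        check_std = stop_cutoff is not None or (
            std_every > 0 and pop.generation % std_every == 0)
        best_std = _best_standard(pop, evaluator) if check_std else math.nan
        if trace is not None:
            trace.record(pop, best_std)
        if stop_cutoff is not None and best_std > stop_cutoff:
            cutoff_gen = pop.generation
            break
    if trace is not None:
        trace.finalize(pop)
    return pop, cutoff_gen


def _best_standard(pop: Population, evaluator: FitnessEvaluator) -> float:
    return max((evaluator.standardized_fitness(c.genome) for c in pop.cells),
               default=0.0)


def apply_environmental_change(pop: Population, trace: Optional[SimulationTrace],
                               *, force_wgd: bool = False,
                               stamp: bool = True) -> Population:
    """Mark the environmental change at the current generation.

    Re-stamps every genome with fresh ancestry tags (the change-time ancestor
    is the reference for gene-content conservation) and optionally applies a
    WGD to every cell, logged as an accepted event so lineage classification
    and the WGD reference genome work exactly as for spontaneous WGDs.
    """
    g = pop.generation
    for i, cell in enumerate(pop.cells):
        genome = stamp_ancestry(cell.genome) if stamp else cell.genome
        events = list(cell.events)
        if force_wgd and len(genome) > 0:
            genome, ev = whole_genome_duplicate(genome, g)
            events.append(ev)
        cell.genome = genome
        cell.events = tuple(events)
        cell.fitness = None
        if trace is not None:
            if events:
                trace.events[g][i] = tuple(events)
            if g in trace.snapshots:
                trace.snapshots[g][i] = genome
    if trace is not None:
        trace.change_generation = g
    return pop


def run_experiment(*, n_cells: int, rng, genome_factory,
                   rates: MutationRates = MutationRates(),
                   standard: EnvironmentParams = STANDARD_ENV,
                   protocol: ExperimentProtocol = ExperimentProtocol(),
                   change_env: Optional[EnvironmentParams] = None,
                   post_change_generations: int = 0,
                   force_wgd_at_change: bool = False,
                   snapshot_interval: int = 100,
                   evaluator_kwargs: Optional[dict] = None) -> SimulationTrace:
    """Two-stage experiment: adapt under the standard environment until the
    high-fitness cutoff plus delay (capped at max_generations), then -- if a
    change environment is given -- switch every cell into it and continue.

    Returns the full trace (parents, events, snapshots, per-generation
    summary) with the change generation marked.
    """
    evaluator_kwargs = evaluator_kwargs or {}
    evaluator = FitnessEvaluator(standard, **evaluator_kwargs)
    trace = SimulationTrace(snapshot_interval=snapshot_interval)
    pop = init_population(n_cells, rng, genome_factory)
    pop, cutoff_gen = evolve(pop, evaluator, rates, rng,
                             protocol.max_generations, trace,
                             stop_cutoff=protocol.high_fitness_cutoff)
    if cutoff_gen is not None:
        remaining = min(protocol.post_cutoff_delay,
                        protocol.max_generations - pop.generation)
        pop, _ = evolve(pop, evaluator, rates, rng, remaining, trace)
    if change_env is not None:
        pop = apply_environmental_change(pop, trace,
                                         force_wgd=force_wgd_at_change)
        post_evaluator = FitnessEvaluator(change_env, **evaluator_kwargs)
        pop, _ = evolve(pop, post_evaluator, rates, rng,
                        post_change_generations, trace)
    trace.finalize(pop)
    return trace


# ---------------------------------------------------------------------------
# Trace persistence (directory of plain-text files)
# ---------------------------------------------------------------------------

def save_trace(trace: SimulationTrace, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "summary.tsv"), "w") as fh:
        fh.write("#generation\tbest_fitness\tmean_fitness\tbest_standard_fitness"
                 "\tmean_genome_size\twgd_events\n")
        for row in trace.summary:
            fh.write("\t".join(repr(row[k]) if isinstance(row[k], float)
                               else str(row[k]) for k in (
                "generation", "best_fitness", "mean_fitness",
                "best_standard_fitness", "mean_genome_size", "wgd_events")) + "\n")
    with open(os.path.join(outdir, "parents.tsv"), "w") as fh:
        for arr in trace.parents:
            fh.write("\t".join(str(int(x)) for x in arr) + "\n")
    with open(os.path.join(outdir, "fitness.tsv"), "w") as fh:
        for arr in trace.fitness:
            fh.write("\t".join(repr(float(x)) for x in arr) + "\n")
    rows = [(f"{g}:{i}", ev) for g, evmap in enumerate(trace.events)
            for i, evs in sorted(evmap.items()) for ev in evs]
    write_event_log(os.path.join(outdir, "events.tsv"),
                    ((cid, ev) for cid, ev in rows))
    snapdir = os.path.join(outdir, "snapshots")
    os.makedirs(snapdir, exist_ok=True)
    for g, genomes in sorted(trace.snapshots.items()):
        with open(os.path.join(snapdir, f"gen{g:06d}.tsv"), "w") as fh:
            for i, genome in enumerate(genomes):
                fh.write(f"##cell\t{i}\n")
                fh.write(genome_to_text(genome))
    meta = {"snapshot_interval": trace.snapshot_interval,
            "change_generation": trace.change_generation,
            "n_generations": trace.n_generations}
    with open(os.path.join(outdir, "trace.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_trace(outdir: str) -> SimulationTrace:
    with open(os.path.join(outdir, "trace.json")) as fh:
        meta = json.load(fh)
    trace = SimulationTrace(snapshot_interval=meta["snapshot_interval"])
    trace.change_generation = meta["change_generation"]
    with open(os.path.join(outdir, "parents.tsv")) as fh:
        for line in fh:
            trace.parents.append(np.array([int(x) for x in line.split()],
                                          dtype=np.int64))
    with open(os.path.join(outdir, "fitness.tsv")) as fh:
        for line in fh:
            trace.fitness.append(np.array([float(x) for x in line.split()]))
    trace.events = [dict() for _ in trace.parents]
    for cid, ev in read_event_log(os.path.join(outdir, "events.tsv")):
        g, i = (int(x) for x in str(cid).split(":")) if isinstance(cid, str) \
            else (ev.generation, cid)
        trace.events[g].setdefault(i, ())
        trace.events[g][i] = trace.events[g][i] + (ev,)
    snapdir = os.path.join(outdir, "snapshots")
    for fname in sorted(os.listdir(snapdir)):
        g = int(fname[3:9])
        genomes = []
        with open(os.path.join(snapdir, fname)) as fh:
            chunks = fh.read().split("##cell\t")
        for chunk in chunks[1:]:
            _, _, body = chunk.partition("\n")
            genomes.append(genome_from_text(body))
        trace.snapshots[g] = genomes
    with open(os.path.join(outdir, "summary.tsv")) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.split()
            trace.summary.append({
                "generation": int(f[0]), "best_fitness": float(f[1]),
                "mean_fitness": float(f[2]), "best_standard_fitness": float(f[3]),
                "mean_genome_size": float(f[4]), "wgd_events": int(f[5])})
    return trace
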