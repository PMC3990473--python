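"""Intracellular dynamics: ODE metabolism, steady state, homeostasis fitness.

The cell state is (A_int, X_int, P_1..P_n): internal resource, internal
energy and one protein level per gene.  Reactions:

* passive diffusion of A across the membrane:  permeability * (A_ext - A)
* pumps import external A at cost ``energy_cost`` X per A:
      v_p = k_cat * P * A_ext/(K_Aext + A_ext) * X/(K_X + X)
* catabolic enzymes convert A -> X:
      v_c = k_cat * P * A/(K_A + A)          (X yield scaled by conversion_rate)
* anabolic enzymes consume A and X into a downstream sink:
      v_a = k_cat * P * A/(K_A + A) * X/(K_X + X)
* proteins: dP/dt = expression_rate - degradation * P

Ligand-TF and TF-operator binding are fast relative to these reactions and
treated in quasi-steady state: a TF's ligand-bound fraction is
b = L/(L + K_ligand) with L the internal concentration of its ligand.  Each
promoter has one operator, for which all matching TFs compete; the
occupancy of TF t on a given promoter is P_t/(K_op + sum_s P_s) over that
promoter's regulators (P/(P + K_op) when it is the only one).  Each
regulator contributes w = occ * (b*effect_bound + (1-b)*effect_free) to the
log expression rate, so rate = basal * exp(sum w) -- continuous, signed and
strictly positive regulation whose total occupancy never exceeds one site.

Fitness is homeostasis: the relative deviations of A and X from their target
concentrations at steady state give a per-environment score
1/(1 + dev_A + dev_X), and a cell's fitness is the geometric mean of the
scores of the (up to three) resource conditions it experienced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .genome import (ANABOLIC, CATABOLIC, ENZYME, LIGAND_A, PUMP, TF, Gene,
                     Genome, RegulatoryNetwork, derive_network)

__all__ = [
    "EnvironmentParams",
    "CellState",
    "SteadyStateResult",
    "STANDARD_ENV",
    "DEFAULT_K_OP",
    "tf_activity",
    "expression_rate",
    "derivatives",
    "steady_state",
    "steady_state_arrays",
    "environment_score",
    "cell_fitness",
    "initial_state",
]

#: Promoter occupancy half-saturation for TF-operator binding (concentration).
DEFAULT_K_OP = 1.0

#: Default integration cap (time units) and convergence tolerance on the
#: maximum relative time-derivative of the state.
DEFAULT_T_MAX = 1000.0
DEFAULT_TOL = 1e-9
DEFAULT_DT_MAX = 0.2

_ENV_FIELDS = ("A_ext", "permeability", "degradation", "conversion_rate",
               "target_A", "target_X")
#: The five globally fixed parameters varied by the environmental-change set
#: (A_ext is the fluctuating resource and is not part of the panel).
CHANGEABLE_PARAMS = ("permeability", "degradation", "conversion_rate",
                     "target_A", "target_X")


@dataclass(frozen=True)
class EnvironmentParams:
    """Global (non-evolvable) parameters of one environment.

    Units: concentrations are arbitrary concentration units, rates are per
    time unit; ``conversion_rate`` is the dimensionless X yield per catabolised
    A; targets are the homeostasis set points for internal A and X.
    """
    A_ext: float
    permeability: float
    degradation: float
    conversion_rate: float
    target_A: float
    target_X: float
    label: str = field(default="standard", compare=False)

    def __post_init__(self):
        for name in _ENV_FIELDS:
            if getattr(self, name) <= 0:
                raise ValueError(f"environment parameter {name} must be > 0")

    def replace(self, **kw) -> "EnvironmentParams":
        vals = {name: getattr(self, name) for name in _ENV_FIELDS}
        label = kw.pop("label", self.label)
        vals.update(kw)
        return EnvironmentParams(label=label, **vals)

    def key(self) -> tuple:
        k = getattr(self, "_key", None)
        if k is None:
            k = tuple(getattr(self, name) for name in _ENV_FIELDS)
            object.__setattr__(self, "_key", k)
        return k


#: Standard environment used for initial adaptation (concrete values are the
#: package's calibration; see docs/methods.md).
STANDARD_ENV = EnvironmentParams(
    A_ext=1.0, permeability=0.3, degradation=0.5, conversion_rate=1.0,
    target_A=0.3, target_X=0.3, label="standard")


@dataclass
class CellState:
    A_int: float
    X_int: float
    protein: Dict[int, float]

    def __post_init__(self):
        if self.A_int < 0 or self.X_int < 0 or any(p < 0 for p in self.protein.values()):
            raise ValueError("concentrations must be >= 0")


@dataclass
class SteadyStateResult:
    state: CellState
    converged: bool
    diverged: bool
    deviation_A: float
    deviation_X: float
    score: float


class CategoryError(TypeError):
    pass


def tf_activity(tf: Gene, state: CellState) -> Tuple[float, float]:
    """Quasi-steady-state ligand binding: (bound fraction, free fraction)."""
    if tf.category != TF:
        raise CategoryError(f"gene {tf.gene_id} is not a TF")
    ligand = state.A_int if tf.trait.ligand == LIGAND_A else state.X_int
    bound = ligand / (ligand + tf.trait.k_ligand)
    return bound, 1.0 - bound


def expression_rate(gene: Gene, genome: Genome, network: RegulatoryNetwork,
                    state: CellState, k_op: float = DEFAULT_K_OP) -> float:
    """Promoter output: basal rate modulated by the TFs matching the operator.

    A promoter carries a single operator, so all matching TFs compete for
    one site: occupancy of TF t is P_t/(k_op + sum_s P_s) over the
    regulators s of this gene (for one regulator this is the familiar
    P/(P + k_op) saturation).  Each regulator contributes its
    occupancy-weighted, ligand-state-mixed effect to the log rate.
    """
    regs = network.regulators_of(gene.gene_id)
    if not regs:
        return gene.promoter.basal_rate
    total = sum(state.protein.get(t, 0.0) for t in regs)
    if total <= 0.0:
        return gene.promoter.basal_rate
    denom = k_op + total
    w = 0.0
    for tf_id in regs:
        tf = genome.gene(tf_id)
        bound, free = tf_activity(tf, state)
        p = state.protein.get(tf_id, 0.0)
        w += (p / denom) * (bound * tf.trait.effect_bound
                            + free * tf.trait.effect_free)
    return gene.promoter.basal_rate * math.exp(w)


def derivatives(state: CellState, genome: Genome, network: RegulatoryNetwork,
                env: EnvironmentParams, k_op: float = DEFAULT_K_OP,
                ) -> Tuple[float, float, Dict[int, float]]:
    """Time derivatives (dA, dX, dP) of the full cell state.

    Reference implementation in plain Python; the integrator uses a compiled
    equivalent (`_integrate`) over flat arrays.
    """
    A, X = state.A_int, state.X_int
    dA = env.permeability * (env.A_ext - A)
    dX = 0.0
    dP: Dict[int, float] = {}
    for g in genome:
        p = state.protein.get(g.gene_id, 0.0)
        t = g.trait
        if g.category == ENZYME:
            if t.reaction == CATABOLIC:
                v = t.k_cat * p * A / (t.K_A + A)
                dA -= v
                dX += env.conversion_rate * v
            else:
                v = t.k_cat * p * (A / (t.K_A + A)) * (X / (t.K_X + X))
                dA -= v
                dX -= v
        elif g.category == PUMP:
            v = t.k_cat * p * (env.A_ext / (t.K_Aext + env.A_ext)) * (X / (t.K_X + X))
            dA += v
            dX -= t.energy_cost * v
        dP[g.gene_id] = expression_rate(g, genome, network, state, k_op) \
            - env.degradation * p
    return dA, dX, dP


# ---------------------------------------------------------------------------
# Compiled integrator
# ---------------------------------------------------------------------------

_CAT_TF, _CAT_CATABOLIC, _CAT_ANABOLIC, _CAT_PUMP = 0, 1, 2, 3


@njit(cache=True, fastmath=True)
def _integrate(cat, ka, kx, kcat, ecost, basal, lig_is_a, eb, ef,
               reg_ptr, reg_idx,
               a_ext, perm, deg, conv, k_op,
               a0, x0, p0, t_max, tol, dt_max, max_steps):
    """Integrate the cell ODEs to steady state.

    Each species has the form dy/dt = production(t) - decay_rate(t) * y, so
    all updates are exponential relaxations toward the local equilibrium
    production/decay (linearly-implicit, unconditionally stable for any
    step).  The fixed point of the scheme is the exact fixed point of the
    ODEs, so converged results do not depend on dt_max.  Returns
    (A, X, P, status) with status 0 = converged, 1 = hit the time cap,
    2 = non-finite/diverged.
    """
    n = cat.shape[0]
    A = a0
    X = x0
    P = p0.copy()
    w = np.zeros(n)
    expr = np.empty(n)
    t = 0.0
    status = 1
    floor = 1e-8
    for _step in range(max_steps):
        # quasi-steady-state TF activity: per-TF ligand-weighted effect
        for i in range(n):
            if cat[i] == 0:
                L = A if lig_is_a[i] == 1 else X
                b = L / (L + ka[i])
                w[i] = b * eb[i] + (1.0 - b) * ef[i]
        # expression rates; regulators of one promoter compete for its
        # single operator, so occupancies share one saturation denominator
        for i in range(n):
            tot = 0.0
            for e in range(reg_ptr[i], reg_ptr[i + 1]):
                tot += P[reg_idx[e]]
            s = 0.0
            if tot > 0.0:
                denom = k_op + tot
                for e in range(reg_ptr[i], reg_ptr[i + 1]):
                    j = reg_idx[e]
                    s += (P[j] / denom) * w[j]
            expr[i] = basal[i] * math.exp(s)
        # metabolite production and per-concentration loss rates
        prodA = perm * a_ext
        lossA = perm
        prodX = 0.0
        lossX = 0.0
        for i in range(n):
            c = cat[i]
            if c == 1:
                lossA += kcat[i] * P[i] / (ka[i] + A)
                prodX += conv * kcat[i] * P[i] * A / (ka[i] + A)
            elif c == 2:
                sx = X / (kx[i] + X)
                sa = A / (ka[i] + A)
                lossA += kcat[i] * P[i] * sx / (ka[i] + A)
                lossX += kcat[i] * P[i] * sa / (kx[i] + X)
            elif c == 3:
                sa = a_ext / (ka[i] + a_ext)
                prodA += kcat[i] * P[i] * sa * X / (kx[i] + X)
                lossX += ecost[i] * kcat[i] * P[i] * sa / (kx[i] + X)
        dA = prodA - lossA * A
        dX = prodX - lossX * X
        # convergence check on current derivatives
        r = abs(dA) / max(A, floor)
        rx = abs(dX) / max(X, floor)
        if rx > r:
            r = rx
        for i in range(n):
            dp = expr[i] - deg * P[i]
            rp = abs(dp) / max(P[i], floor)
            if rp > r:
                r = rp
        if r < tol:
            status = 0
            break
        if t >= t_max:
            status = 1
            break
        dt = dt_max
        if t + dt > t_max:
            dt = t_max - t
        A = prodA / lossA + (A - prodA / lossA) * math.exp(-lossA * dt)
        if lossX > 1e-300:
            X = prodX / lossX + (X - prodX / lossX) * math.exp(-lossX * dt)
        else:
            X += dt * prodX
        f = 1.0 - math.exp(-deg * dt)
        for i in range(n):
            P[i] += (expr[i] / deg - P[i]) * f
        t += dt
        if not (math.isfinite(A) and math.isfinite(X)) or A > 1e12 or X > 1e12:
            status = 2
            break
    return A, X, P, status


def _compile_genome(genome: Genome, k_op: float):
    """Flatten a genome + its network into arrays for the compiled kernel."""
    cache = getattr(genome, "_dyn_cache", None)
    if cache is not None and cache[0] == k_op:
        return cache[1]
    n = len(genome)
    cat = np.zeros(n, dtype=np.int64)
    ka = np.ones(n)
    kx = np.ones(n)
    kcat = np.zeros(n)
    ecost = np.zeros(n)
    basal = np.empty(n)
    lig_is_a = np.zeros(n, dtype=np.int64)
    eb = np.zeros(n)
    ef = np.zeros(n)
    index_of = {g.gene_id: i for i, g in enumerate(genome)}
    network = derive_network(genome)
    regulators: List[List[int]] = [[] for _ in range(n)]
    for tf_id, targets in network.edges.items():
        for tgt in targets:
            regulators[index_of[tgt]].append(index_of[tf_id])
    reg_ptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        reg_ptr[i + 1] = reg_ptr[i] + len(regulators[i])
    reg_idx = np.array([r for regs in regulators for r in regs], dtype=np.int64) \
        if n else np.zeros(0, dtype=np.int64)
    for i, g in enumerate(genome):
        basal[i] = g.promoter.basal_rate
        t = g.trait
        if g.category == TF:
            cat[i] = _CAT_TF
            ka[i] = t.k_ligand
            lig_is_a[i] = 1 if t.ligand == LIGAND_A else 0
            eb[i] = t.effect_bound
            ef[i] = t.effect_free
        elif g.category == ENZYME:
            cat[i] = _CAT_CATABOLIC if t.reaction == CATABOLIC else _CAT_ANABOLIC
            ka[i] = t.K_A
            kx[i] = t.K_X if t.K_X is not None else 1.0
            kcat[i] = t.k_cat
        else:
            cat[i] = _CAT_PUMP
            ka[i] = t.K_Aext
            kx[i] = t.K_X
            kcat[i] = t.k_cat
            ecost[i] = t.energy_cost
    arrays = (cat, ka, kx, kcat, ecost, basal, lig_is_a, eb, ef, reg_ptr, reg_idx)
    object.__setattr__(genome, "_dyn_cache", (k_op, arrays))
    return arrays


def _gene_positions(genome: Genome) -> dict:
    idx = getattr(genome, "_gid_pos", None)
    if idx is None:
        idx = {g.gene_id: i for i, g in enumerate(genome)}
        object.__setattr__(genome, "_gid_pos", idx)
    return idx


def steady_state_arrays(genome: Genome, env: EnvironmentParams, *,
                        k_op: float = DEFAULT_K_OP, a0: Optional[float] = None,
                        x0: float = 0.0, p0: Optional[np.ndarray] = None,
                        t_max: float = DEFAULT_T_MAX, tol: float = DEFAULT_TOL,
                        dt_max: float = DEFAULT_DT_MAX,
                        max_steps: int = 400_000):
    """Array-level steady state: returns (A, X, P, status, score).

    Same computation as `steady_state` without building CellState/dict
    results; used by the evolutionary loop where the per-call overhead
    matters.  ``p0`` is ordered by genome position.
    """
    arrays = _compile_genome(genome, k_op)
    if a0 is None:
        a0 = env.A_ext
    if p0 is None:
        p0 = arrays[5] / env.degradation          # basal / degradation
    A, X, P, status = _integrate(
        *arrays, env.A_ext, env.permeability, env.degradation,
        env.conversion_rate, k_op, float(a0), float(x0), p0,
        float(t_max), float(tol), float(dt_max), max_steps)
    if status == 0:
        dev = abs(A - env.target_A) / env.target_A \
            + abs(X - env.target_X) / env.target_X
        score = 1.0 / (1.0 + dev)
    else:
        score = 0.0
    return A, X, P, status, score


def initial_state(genome: Genome, env: EnvironmentParams) -> CellState:
    """Deterministic start: A at the external level, no stored energy,
    proteins at their unregulated steady level basal/degradation."""
    protein = {g.gene_id: g.promoter.basal_rate / env.degradation for g in genome}
    return CellState(A_int=env.A_ext, X_int=0.0, protein=protein)


def steady_state(genome: Genome, env: EnvironmentParams,
                 init: Optional[CellState] = None, *,
                 k_op: float = DEFAULT_K_OP, t_max: float = DEFAULT_T_MAX,
                 tol: float = DEFAULT_TOL, dt_max: float = DEFAULT_DT_MAX,
                 max_steps: int = 400_000) -> SteadyStateResult:
    """Integrate the cell to steady state and score homeostasis.

    Cells whose dynamics do not settle (oscillation, divergence) within the
    time cap are reported non-converged and score 0: failure to reach a
    steady state is failure of homeostasis by definition.
    """
    if init is None:
        init = initial_state(genome, env)
    arrays = _compile_genome(genome, k_op)
    p0 = np.array([init.protein.get(g.gene_id, 0.0) for g in genome], dtype=float)
    A, X, P, status = _integrate(
        *arrays, env.A_ext, env.permeability, env.degradation,
        env.conversion_rate, k_op, float(init.A_int), float(init.X_int), p0,
        float(t_max), float(tol), float(dt_max), max_steps)
    converged = status == 0
    diverged = status == 2
    if diverged:
        state = CellState(0.0, 0.0, {})
        dev_a = dev_x = math.inf
    else:
        state = CellState(float(max(A, 0.0)), float(max(X, 0.0)),
                          dict(zip((g.gene_id for g in genome), P.tolist())))
        dev_a = abs(state.A_int - env.target_A) / env.target_A
        dev_x = abs(state.X_int - env.target_X) / env.target_X
    score = 1.0 / (1.0 + dev_a + dev_x) if converged else 0.0
    return SteadyStateResult(state=state, converged=converged, diverged=diverged,
                             deviation_A=dev_a, deviation_X=dev_x, score=score)


def environment_score(ss: SteadyStateResult) -> float:
    """Per-environment performance in (0, 1]: inverse of 1 + total relative
    deviation from the homeostasis targets; 0 for non-converged dynamics."""
    if not ss.converged or ss.diverged:
        return 0.0
    return 1.0 / (1.0 + ss.deviation_A + ss.deviation_X)


def cell_fitness(scores: Sequence[float]) -> float:
    """Geometric mean of the per-environment scores seen in a cell's lifetime.

    Non-decreasing in every score, and harsh on failure in any single
    condition -- which is what selects for regulation instead of a fixed
    compromise phenotype.
    """
    scores = list(scores)
    if not 1 <= len(scores) <= 3:
        raise ValueError(f"expected 1-3 environment scores, got {len(scores)}")
    if any(s < 0 or s > 1 for s in scores):
        raise ValueError("scores must lie in [0, 1]")
    if any(s == 0.0 for s in scores):
        return 0.0
    return math.exp(sum(math.log(s) for s in scores) / len(scores))
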