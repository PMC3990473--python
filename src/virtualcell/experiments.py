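"""Desk-scale two-stage campaigns: adapt, then re-adapt / neutral arms.

The full-scale protocol (100 populations of 1024 cells, 15000
generations, 10 x 80 perturbation runs) is far beyond a single-CPU session,
so this module runs the same two-stage design at reduced size:

* N = 100 cells, founding genomes of 12-18 genes, external-resource
  fluctuation over a 10-fold log-range;
* stage 1: adaptation to the standard environment;
* arm "neutral": continued evolution without change (streamlining /
  gene-content turnover control);
* arm "wgd": environmental change combined with a whole-genome duplication
  fixed at the change point, for the post-WGD retention analyses (the change
  raises protein degradation and both homeostasis targets, the regime in
  which WGD fixation is most favoured);
* arm "natural": the same environmental change without the imposed WGD, to
  observe whether WGD fixes spontaneously in the line of descent.

Each arm restarts generation numbering at the change point, so bins and
references are relative to the change as in the retention analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import stream_rng
from .dynamics import STANDARD_ENV, EnvironmentParams
from .evolution import (Cell, FitnessEvaluator, Population, SimulationTrace,
                        apply_environmental_change, evolve, init_population,
                        make_default_levels, make_environment_panel)
from .fixtures import random_genome
from .genome import TF, Genome
from .lineage import (ancestral_content_fraction, trace_line_of_descent,
                      LineOfDescent)
from .mutation import MutationRates
from .retention import (UNIFORM, classify_ohnologs, divergence_over_lod,
                        null_retention_fractions, null_spec_from_lod)

__all__ = ["CampaignConfig", "ReplicateResult", "CampaignResult",
           "run_campaign", "change_environment", "natural_arm_environment"]

#: Default bin width for the scaled retention/conservation analyses.
SCALED_BIN = 1000


@dataclass(frozen=True)
class CampaignConfig:
    n_replicates: int = 10
    n_cells: int = 100
    adapt_generations: int = 600
    #: one fifth of the full-scale 15000-generation neutral horizon, long
    #: enough for long-run content turnover to express
    neutral_generations: int = 3000
    #: retention is analysed while conserved WGD content still exists in
    #: these small genomes: one full 1000-generation bin after the change
    wgd_arm_generations: int = 1000
    #: spontaneous WGDs fix almost exclusively shortly after the change, so
    #: the natural arm needs only a short window
    natural_arm_generations: int = 500
    genome_size_range: Tuple[int, int] = (12, 18)
    fluctuation: Tuple[float, float] = (1 / 3.16, 3.16)
    #: genomes above this size are inviable; doubled in the post-WGD arm so
    #: the per-ploidy limit is unchanged after genome doubling
    max_genome_size: int = 60
    null_replicates: int = 100
    bin_width: int = SCALED_BIN
    rates: MutationRates = field(default_factory=MutationRates)


def change_environment(standard: EnvironmentParams = STANDARD_ENV
                       ) -> EnvironmentParams:
    """The perturbation used for the retention (forced-WGD) arm: degradation
    and both homeostasis targets at their high level — three of five
    parameters changed, one member of the systematic 80-environment panel,
    and the regime in which dosage effects matter most."""
    levels = make_default_levels(standard)
    return standard.replace(
        degradation=levels["degradation"][1],
        target_A=levels["target_A"][1],
        target_X=levels["target_X"][1],
        label="degradation=high|target_A=high|target_X=high")


def natural_arm_environment(idx: int,
                            standard: EnvironmentParams = STANDARD_ENV
                            ) -> EnvironmentParams:
    """Per-replicate panel environment for the spontaneous-WGD arm.

    WGD-fixation frequency is a property of the whole environmental-change
    set, not of a single favourable environment, so each replicate re-adapts
    in a different member of the 80-environment panel (stride 17 is coprime
    with 80 and spreads draws over all parameter subsets)."""
    panel = make_environment_panel(standard)
    return panel.environments[(idx * 17) % len(panel)]


@dataclass
class ReplicateResult:
    seed_index: int
    #: per-generation mean experienced fitness during stage 1
    adapt_mean_fitness: np.ndarray
    #: per-generation mean genome size during the neutral arm
    neutral_mean_size: np.ndarray
    #: conserved ancestral content of the final neutral-arm individual
    neutral_content_final: float
    neutral_has_wgd: bool
    #: post-change (WGD arm) analyses
    tf_retention_evolved: Optional[float]
    tf_retention_null: Optional[float]
    all_retention_evolved: Optional[float]
    all_retention_null: Optional[float]
    relative_outdegree_retained: Optional[float]
    relative_outdegree_ohnolog: Optional[float]
    relative_outdegree_single: Optional[float]
    bs_conservation_ohnolog: Optional[float]
    wgd_content_final: float
    wgd_arm_mean_fitness_final: float
    #: natural re-adaptation arm
    natural_has_wgd: bool
    natural_mean_fitness_final: float


@dataclass
class CampaignResult:
    config: CampaignConfig
    replicates: List[ReplicateResult]

    def fraction_natural_wgd(self) -> float:
        return float(np.mean([r.natural_has_wgd for r in self.replicates]))

    def mean_neutral_content_final(self) -> float:
        return float(np.mean([r.neutral_content_final
                              for r in self.replicates]))


def _clone_for_arm(pop: Population, *, force_wgd: bool,
                   trace: SimulationTrace) -> Population:
    """Fresh arm population founded by the current cells (generation reset
    to 0, ancestry re-stamped, optional WGD applied to every cell)."""
    cells = [Cell(cell_id=i, genome=c.genome, parent_index=-1)
             for i, c in enumerate(pop.cells)]
    arm = Population(cells=cells, generation=0)
    arm = apply_environmental_change(arm, None, force_wgd=force_wgd,
                                     stamp=True)
    trace.change_generation = 0
    return arm


def _final_lod(trace: SimulationTrace) -> LineOfDescent:
    return trace_line_of_descent(trace, final_cell_index=None)


def _run_replicate(idx: int, root_seed: int, cfg: CampaignConfig
                   ) -> ReplicateResult:
    rng = stream_rng(root_seed, "evolution")
    rng = np.random.default_rng(rng.integers(2**31) + idx)
    init_rng = np.random.default_rng(rng.integers(2**31))
    evaluator = FitnessEvaluator(STANDARD_ENV, fluctuation=cfg.fluctuation,
                                 max_genome_size=cfg.max_genome_size)

    # ---- stage 1: adaptation under the standard environment
    pop = init_population(
        cfg.n_cells, init_rng,
        lambda r: random_genome(r, size_range=cfg.genome_size_range))
    stage1 = SimulationTrace(snapshot_interval=200)
    pop, _ = evolve(pop, evaluator, cfg.rates, rng, cfg.adapt_generations,
                    stage1, std_every=0)
    adapt_fit = np.array([s["mean_fitness"] for s in stage1.summary])

    # ---- neutral continuation (no environmental change)
    tr_neutral = SimulationTrace(snapshot_interval=200)
    arm = _clone_for_arm(pop, force_wgd=False, trace=tr_neutral)
    arm_pop, _ = evolve(arm, evaluator, cfg.rates, rng,
                        cfg.neutral_generations, tr_neutral, std_every=0)
    lod_n = _final_lod(tr_neutral)
    neutral_sizes = np.array([s["mean_genome_size"]
                              for s in tr_neutral.summary])
    reference_n = lod_n.genome_at(0)
    neutral_content = ancestral_content_fraction(reference_n,
                                                 lod_n.final_genome)

    # ---- environmental change with WGD fixed at the change point
    change_env = change_environment(STANDARD_ENV)
    eval_change = FitnessEvaluator(change_env, fluctuation=cfg.fluctuation,
                                   max_genome_size=2 * cfg.max_genome_size)
    tr_wgd = SimulationTrace(snapshot_interval=200)
    arm = _clone_for_arm(pop, force_wgd=True, trace=tr_wgd)
    arm_pop, _ = evolve(arm, eval_change, cfg.rates, rng,
                        cfg.wgd_arm_generations, tr_wgd, std_every=0)
    lod_w = _final_lod(tr_wgd)
    wgd_reference = lod_w.genome_at(0)
    null_rng = stream_rng(root_seed, "null_model")
    null_rng = np.random.default_rng(null_rng.integers(2**31) + idx)
    analysis_rng = np.random.default_rng(null_rng.integers(2**31))
    census = classify_ohnologs(wgd_reference, lod_w.final_genome,
                               generation=lod_w.steps[-1].generation)
    spec = null_spec_from_lod(wgd_reference, lod_w, 0, mode=UNIFORM,
                              bin_width=cfg.bin_width)
    null = null_retention_fractions(wgd_reference, spec, null_rng,
                                    cfg.null_replicates)
    tf_row = census.per_category[TF]
    total_row = census.total()
    null_tf = float(null["fractions"][TF][-1])
    null_all_parts = [null["fractions"][c][-1] for c in null["fractions"]]
    null_all = float(np.nanmean(null_all_parts))
    div = divergence_over_lod(wgd_reference, lod_w, 0, analysis_rng,
                              bin_width=cfg.bin_width)
    last = div[-1]
    wgd_content = ancestral_content_fraction(wgd_reference, lod_w.final_genome)

    # ---- environmental change without imposed WGD (spontaneous WGDs may
    # still double the genome, so the same doubled cap applies); each
    # replicate draws a different panel environment
    nat_env = natural_arm_environment(idx)
    eval_nat = FitnessEvaluator(nat_env, fluctuation=cfg.fluctuation,
                                max_genome_size=2 * cfg.max_genome_size)
    tr_nat = SimulationTrace(snapshot_interval=200)
    arm = _clone_for_arm(pop, force_wgd=False, trace=tr_nat)
    arm_pop, _ = evolve(arm, eval_nat, cfg.rates, rng,
                        cfg.natural_arm_generations, tr_nat, std_every=0)
    lod_nat = _final_lod(tr_nat)

    return ReplicateResult(
        seed_index=idx,
        adapt_mean_fitness=adapt_fit,
        neutral_mean_size=neutral_sizes,
        neutral_content_final=neutral_content,
        neutral_has_wgd=lod_n.has_wgd,
        tf_retention_evolved=tf_row.retention_fraction,
        tf_retention_null=None if np.isnan(null_tf) else null_tf,
        all_retention_evolved=total_row.retention_fraction,
        all_retention_null=None if np.isnan(null_all) else null_all,
        relative_outdegree_retained=last.relative_outdegree["all_retained"],
        relative_outdegree_ohnolog=last.relative_outdegree["ohnolog"],
        relative_outdegree_single=last.relative_outdegree["single"],
        bs_conservation_ohnolog=last.bs_conservation["ohnolog"],
        wgd_content_final=wgd_content,
        wgd_arm_mean_fitness_final=float(tr_wgd.summary[-1]["mean_fitness"]),
        natural_has_wgd=lod_nat.has_wgd,
        natural_mean_fitness_final=float(tr_nat.summary[-1]["mean_fitness"]),
    )


def run_campaign(seed: int, config: Optional[CampaignConfig] = None,
                 progress: bool = False) -> CampaignResult:
    """Run the full scaled campaign: ``n_replicates`` independent seeds, each
    with stage-1 adaptation and the three continuation arms."""
    cfg = config or CampaignConfig()
    replicates = []
    for idx in range(cfg.n_replicates):
        replicates.append(_run_replicate(idx, seed, cfg))
        if progress:
            r = replicates[-1]
            print(f"[campaign] replicate {idx}: "
                  f"adapt fitness {r.adapt_mean_fitness[-1]:.3f}, "
                  f"neutral content {r.neutral_content_final:.3f}, "
                  f"TF retention {r.tf_retention_evolved} "
                  f"(null {r.tf_retention_null}), "
                  f"ohnolog outdeg {r.relative_outdegree_ohnolog}, "
                  f"single outdeg {r.relative_outdegree_single}, "
                  f"natural WGD {r.natural_has_wgd}", flush=True)
    return CampaignResult(config=cfg, replicates=replicates)
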