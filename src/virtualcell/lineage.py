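"""Line-of-descent tracing, accepted-mutation rates, ancestral gene content.

The line of descent (LOD) is the unique backward parent chain from one
sampled individual of the final population to generation zero.  Mutations on
this chain are the "accepted" mutations; they are converted to effective
rates by averaging over 1000-generation bins.  Ancestral gene-content
conservation is measured against a stamped reference genome: a reference
gene counts as conserved if at least one descendant copy of it survives, and
when several copies exist (WGD or segmental duplication) exactly one random
copy is considered the original -- the count, not the identity, decides the
conserved fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .genome import ENZYME, PUMP, TF, Genome
from .mutation import (DELETION, DUPLICATION, POINT, TRANSLOCATION, WGD,
                       MutationEvent, replay_events)

__all__ = [
    "LODStep",
    "LineOfDescent",
    "RateBins",
    "BinRates",
    "CorruptTraceError",
    "trace_line_of_descent",
    "ancestral_content_fraction",
    "select_original_copies",
    "effective_rates",
    "rates_from_events",
    "conservation_curve",
    "export_conservation",
    "export_lod",
]

DEFAULT_BIN_WIDTH = 1000


class CorruptTraceError(RuntimeError):
    pass


@dataclass(frozen=True)
class LODStep:
    generation: int
    cell_id: int
    genome: Genome
    events: Tuple[MutationEvent, ...]


@dataclass(frozen=True)
class LineOfDescent:
    """Ordered oldest -> newest ancestor chain with per-step accepted events."""
    steps: Tuple[LODStep, ...]
    change_generation: Optional[int] = None
    wgd_generation: Optional[int] = None

    @property
    def has_wgd(self) -> bool:
        """True if a WGD event lies on the chain (after the environmental
        change when one is marked) -- the standard WGD-lineage classification."""
        return self.wgd_generation is not None

    @property
    def final_genome(self) -> Genome:
        return self.steps[-1].genome

    def genome_at(self, generation: int) -> Genome:
        """Genome of the most recent step at or before ``generation``."""
        best = None
        for step in self.steps:
            if step.generation <= generation:
                best = step
            else:
                break
        if best is None:
            raise KeyError(f"no LOD step at or before generation {generation}")
        return best.genome

    def all_events(self) -> List[MutationEvent]:
        return [ev for step in self.steps for ev in step.events]


def trace_line_of_descent(trace, final_cell_index: Optional[int] = None
                          ) -> LineOfDescent:
    """Trace one individual of the final population back to generation zero.

    ``trace`` is a simulation trace exposing ``n_generations``, per-generation
    ``parents`` arrays, sparse ``events`` dicts, ``snapshots`` (gen 0 always
    present), per-generation ``fitness`` arrays and an optional
    ``change_generation`` marker.  Genomes along the chain are reconstructed
    by deterministic event replay from the generation-0 snapshot and verified
    against stored snapshots on the way.
    """
    n_gen = trace.n_generations
    if final_cell_index is None:
        fit = trace.fitness[n_gen]
        final_cell_index = int(max(range(len(fit)), key=lambda i: fit[i]))
    chain = [0] * (n_gen + 1)
    chain[n_gen] = final_cell_index
    for g in range(n_gen, 0, -1):
        parent = int(trace.parents[g][chain[g]])
        if parent < 0:
            raise CorruptTraceError(f"broken parent pointer at generation {g}")
        chain[g - 1] = parent
    genome = trace.snapshots[0][chain[0]]
    change_gen = getattr(trace, "change_generation", None)
    steps = [LODStep(0, chain[0], genome, ())]
    wgd_generation = None
    for g in range(1, n_gen + 1):
        events = tuple(trace.events[g].get(chain[g], ()))
        if events:
            genome = replay_events(genome, events)
            for ev in events:
                if ev.kind == WGD and not ev.payload.get("noop"):
                    if change_gen is None or g >= change_gen:
                        if wgd_generation is None:
                            wgd_generation = g
        if g in trace.snapshots and trace.snapshots[g][chain[g]] != genome:
            raise CorruptTraceError(
                f"replayed genome disagrees with snapshot at generation {g}")
        steps.append(LODStep(g, chain[g], genome, events))
    return LineOfDescent(steps=tuple(steps), change_generation=change_gen,
                         wgd_generation=wgd_generation)


# ---------------------------------------------------------------------------
# Ancestral gene content
# ---------------------------------------------------------------------------

def select_original_copies(reference: Genome, descendant: Genome, rng
                           ) -> Dict[int, int]:
    """For each surviving ancestral gene pick one random copy as the original.

    Returns ancestry_tag -> gene_id of the chosen descendant copy.  Copies
    beyond the chosen one do not count towards ancestral content.
    """
    copies: Dict[int, List[int]] = {}
    ref_tags = {g.ancestry_tag for g in reference if g.ancestry_tag is not None}
    for g in descendant:
        if g.ancestry_tag in ref_tags:
            copies.setdefault(g.ancestry_tag, []).append(g.gene_id)
    return {tag: ids[int(rng.integers(len(ids)))]
            for tag, ids in sorted(copies.items())}


def ancestral_content_fraction(reference: Genome, descendant: Genome,
                               rng=None) -> float:
    """Fraction of ancestral genes with at least one surviving one-to-one copy.

    The random choice of which duplicate counts as the original does not
    change the fraction (one copy counts either way), so ``rng`` is optional
    and only consulted for the tie-break bookkeeping.  If the reference
    itself contains duplicates of an ancestral gene (e.g. a post-WGD genome
    measured against the pre-WGD stamping), each ancestral gene still counts
    once in the denominator.
    """
    if len(reference) == 0:
        raise ValueError("reference genome is empty")
    ref_tags = {g.ancestry_tag for g in reference if g.ancestry_tag is not None}
    if not ref_tags:
        raise ValueError("reference genes carry no ancestry tags")
    surviving = {g.ancestry_tag for g in descendant} & ref_tags
    return len(surviving) / len(ref_tags)


def conservation_curve(lod: LineOfDescent, reference: Genome,
                       reference_generation: int = 0,
                       bin_width: int = DEFAULT_BIN_WIDTH
                       ) -> List[Tuple[int, float]]:
    """Conserved ancestral-content fraction at bin boundaries along the LOD."""
    final_gen = lod.steps[-1].generation
    out = []
    g = reference_generation
    while g <= final_gen:
        out.append((g, ancestral_content_fraction(reference, lod.genome_at(g))))
        g += bin_width
    if out[-1][0] != final_gen:
        out.append((final_gen, ancestral_content_fraction(reference,
                                                          lod.final_genome)))
    return out


# ---------------------------------------------------------------------------
# Effective (accepted) mutation rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinRates:
    start: int                      # inclusive, relative to LOD start
    end: int                        # exclusive
    counts: Dict[str, int]
    deleted_fraction_per_event: float   # nan if no deletions in bin
    deleted_fraction_per_generation: float
    point_fraction_per_generation: float


@dataclass(frozen=True)
class RateBins:
    bin_width: int
    bins: Tuple[BinRates, ...]

    def total_counts(self) -> Dict[str, int]:
        totals = {k: 0 for k in (POINT, DUPLICATION, DELETION, TRANSLOCATION, WGD)}
        for b in self.bins:
            for k, v in b.counts.items():
                totals[k] += v
        return totals


def effective_rates(lod: LineOfDescent,
                    bin_width: int = DEFAULT_BIN_WIDTH) -> RateBins:
    """Accepted-mutation rates in fixed-width generation bins.

    Per bin: event counts by kind; genes deleted per accepted deletion event
    as a fraction of the genome size at the event (averaged over events);
    the same quantity per generation; and accepted point mutations per
    generation as a fraction of genome size.  All fractions are relative to
    the genome size when the event happened, and bins are independent of the
    order of events within them.
    """
    return rates_from_events(lod.all_events(), lod.steps[0].generation,
                             lod.steps[-1].generation, bin_width)


def rates_from_events(events: Sequence[MutationEvent], start_gen: int,
                      final_gen: int,
                      bin_width: int = DEFAULT_BIN_WIDTH) -> RateBins:
    """Bin an accepted-event stream into rates; order within bins is
    irrelevant because every event records its own genome size."""
    total = final_gen - start_gen
    n_bins = max(1, math.ceil(total / bin_width)) if total > 0 else 1
    bins = []
    for b in range(n_bins):
        lo = start_gen + b * bin_width
        hi = min(start_gen + (b + 1) * bin_width, final_gen)
        n_gens = max(1, hi - lo)
        in_bin = [ev for ev in events if lo < ev.generation <= hi] if b > 0 else \
            [ev for ev in events if lo <= ev.generation <= hi]
        counts = {k: 0 for k in (POINT, DUPLICATION, DELETION, TRANSLOCATION, WGD)}
        del_fracs = []
        point_frac = 0.0
        for ev in in_bin:
            counts[ev.kind] += 1
            if ev.kind == DELETION:
                del_fracs.append(len(ev.gene_ids) / ev.genome_size_before)
            elif ev.kind == POINT:
                point_frac += 1.0 / ev.genome_size_before
        bins.append(BinRates(
            start=lo - start_gen, end=hi - start_gen, counts=counts,
            deleted_fraction_per_event=(sum(del_fracs) / len(del_fracs)
                                        if del_fracs else math.nan),
            deleted_fraction_per_generation=sum(del_fracs) / n_gens,
            point_fraction_per_generation=point_frac / n_gens))
    return RateBins(bin_width=bin_width, bins=tuple(bins))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_conservation(curves: Sequence[Sequence[Tuple[int, float]]],
                        path) -> None:
    """Summarise conservation curves from several lines of descent.

    ``curves`` holds per-run (generation, fraction) series on a shared bin
    grid; the output has one row per bin with mean, median and quartiles
    across runs (the box-plot summary of conserved ancestral content).
    """
    by_gen: Dict[int, List[float]] = {}
    for curve in curves:
        for gen, frac in curve:
            by_gen.setdefault(gen, []).append(frac)

    def _write(fh):
        fh.write("#generation_bin\tn_runs\tmean_fraction\tmedian\tq1\tq3\n")
        import numpy as np
        for gen in sorted(by_gen):
            vals = np.asarray(by_gen[gen])
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            fh.write(f"{gen}\t{len(vals)}\t{vals.mean():.6g}\t{med:.6g}\t"
                     f"{q1:.6g}\t{q3:.6g}\n")
    if hasattr(path, "write"):
        _write(path)
    else:
        with open(path, "w") as fh:
            _write(fh)


def export_lod(lod: LineOfDescent, path) -> None:
    """Tab-separated LOD summary: one step per line."""
    def _write(fh):
        fh.write("#generation\tcell_id\tgenome_size\tn_tf\tn_enzyme\tn_pump\tevents\n")
        for step in lod.steps:
            counts = step.genome.category_counts()
            summary = ",".join(ev.kind for ev in step.events) or "-"
            fh.write(f"{step.generation}\t{step.cell_id}\t{len(step.genome)}\t"
                     f"{counts[TF]}\t{counts[ENZYME]}\t{counts[PUMP]}\t{summary}\n")
    if hasattr(path, "write"):
        _write(path)
    else:
        with open(path, "w") as fh:
            _write(fh)
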