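"""Mutation operators: point mutations, segmental events, WGD; event logging.

Default rates follow the reference regime: segmental duplications and deletions each
occur at 0.024 per cell per generation, translocations at 0.048, for a
genome at the reference size (50 genes), scaling linearly with gene count so
the per-gene rate is constant.  Whole-genome duplication is per cell,
size-independent, at 0.003 (roughly a factor 10 below small-scale events,
0.3% of the population per generation).  Point mutations hit genes
independently at a per-gene probability calibrated so the expected number of
point events at the reference size is 5x the expected number of large-scale
events: 5 * (0.024 + 0.024 + 0.048) / 50 = 0.0096 per gene per generation.

Every operator returns a fresh genome plus a list of `MutationEvent`s whose
payload is sufficient to replay the child deterministically from the parent
(`replay_events`), which is how lines of descent are reconstructed between
snapshots and how the event log is verified.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

from .genome import (ANABOLIC, CATABOLIC, ENZYME, LIGAND_A, LIGAND_X, PUMP,
                     TF, Gene, Genome, GenomeError)

__all__ = [
    "MutationRates",
    "MutationEvent",
    "point_mutate",
    "segmental_mutate",
    "whole_genome_duplicate",
    "apply_all",
    "replay_events",
    "write_event_log",
    "read_event_log",
]

POINT = "point"
DUPLICATION = "duplication"
DELETION = "deletion"
TRANSLOCATION = "translocation"
WGD = "wgd"


@dataclass(frozen=True)
class MutationRates:
    """Per-generation mutation probabilities at reference genome size G_ref."""
    point_per_gene: float = 0.0096
    dup_per_genome_ref: float = 0.024
    del_per_genome_ref: float = 0.024
    trans_per_genome_ref: float = 0.048
    wgd_per_cell: float = 0.003
    max_segment_fraction: float = 0.25
    G_ref: int = 50
    #: log-normal sigma for multiplicative steps on positive parameters
    point_sigma: float = 0.3
    #: additive Gaussian sigma for signed TF effect values
    effect_sigma: float = 0.5

    def __post_init__(self):
        for name in ("point_per_gene", "dup_per_genome_ref", "del_per_genome_ref",
                     "trans_per_genome_ref", "wgd_per_cell", "max_segment_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.G_ref < 1:
            raise ValueError("G_ref must be >= 1")

    def segmental_prob(self, kind: str, n_genes: int) -> float:
        base = {DUPLICATION: self.dup_per_genome_ref,
                DELETION: self.del_per_genome_ref,
                TRANSLOCATION: self.trans_per_genome_ref}[kind]
        return min(1.0, base * n_genes / self.G_ref)


@dataclass
class MutationEvent:
    generation: int
    kind: str
    gene_ids: Tuple[int, ...]
    payload: dict
    fraction_of_genome: float
    genome_size_before: int

    def __post_init__(self):
        if not 0.0 <= self.fraction_of_genome <= 1.0:
            raise ValueError("fraction_of_genome must be in [0, 1]")


# ---------------------------------------------------------------------------
# Point mutations
# ---------------------------------------------------------------------------

_COMMON_ATTRS = ("operator", "basal_rate")
_CATEGORY_ATTRS = {
    TF: ("binding_motif", "k_ligand", "ligand", "effect_bound", "effect_free"),
    PUMP: ("k_cat", "K_Aext", "K_X"),
}


def _mutable_attrs(gene: Gene) -> Tuple[str, ...]:
    if gene.category == ENZYME:
        extra = ("k_cat", "K_A") if gene.trait.reaction == CATABOLIC \
            else ("k_cat", "K_A", "K_X")
    else:
        extra = _CATEGORY_ATTRS[gene.category]
    return _COMMON_ATTRS + extra


def _flip_motif(motif: Tuple[int, ...], rng, alphabet_size: int) -> Tuple[int, ...]:
    pos = int(rng.integers(len(motif)))
    old = motif[pos]
    if alphabet_size == 2:
        new = 1 - old
    else:
        new = int(rng.integers(alphabet_size - 1))
        if new >= old:
            new += 1
    return motif[:pos] + (new,) + motif[pos + 1:]


def _mutated_value(gene: Gene, attr: str, rng, rates: MutationRates,
                   alphabet_size: int):
    if attr == "operator":
        return _flip_motif(gene.promoter.operator, rng, alphabet_size)
    if attr == "binding_motif":
        return _flip_motif(gene.trait.binding_motif, rng, alphabet_size)
    if attr == "ligand":
        return LIGAND_X if gene.trait.ligand == LIGAND_A else LIGAND_A
    if attr in ("effect_bound", "effect_free"):
        return getattr(gene.trait, attr) + rates.effect_sigma * float(rng.standard_normal())
    factor = math.exp(rates.point_sigma * float(rng.standard_normal()))
    if attr == "basal_rate":
        return gene.promoter.basal_rate * factor
    return getattr(gene.trait, attr) * factor


def _apply_point(gene: Gene, attr: str, value) -> Gene:
    if attr == "operator":
        return replace(gene, promoter=replace(gene.promoter, operator=tuple(value)))
    if attr == "basal_rate":
        return replace(gene, promoter=replace(gene.promoter, basal_rate=value))
    if attr == "binding_motif":
        return replace(gene, trait=replace(gene.trait, binding_motif=tuple(value)))
    return replace(gene, trait=replace(gene.trait, **{attr: value}))


def point_mutate(genome: Genome, rates: MutationRates, rng,
                 generation: int = 0) -> Tuple[Genome, List[MutationEvent]]:
    """Hit each gene independently with probability ``point_per_gene``.

    A hit picks one mutable attribute of the gene uniformly: continuous
    parameters take a log-normal multiplicative step, motifs/operators flip
    one random symbol, the TF ligand toggles and TF effect values take an
    additive Gaussian step (so regulation sign can flip).
    """
    n = len(genome)
    if n == 0 or rates.point_per_gene == 0.0:
        return genome, []
    hits = rng.random(n) < rates.point_per_gene
    if not hits.any():
        return genome, []
    genes = list(genome.genes)
    events = []
    for i in range(n):
        if not hits[i]:
            continue
        gene = genes[i]
        attrs = _mutable_attrs(gene)
        attr = attrs[int(rng.integers(len(attrs)))]
        if attr == "basal_rate":
            old = gene.promoter.basal_rate
        elif attr == "operator":
            old = gene.promoter.operator
        else:
            old = getattr(gene.trait, attr)
        new = _mutated_value(gene, attr, rng, rates, genome.alphabet_size)
        genes[i] = _apply_point(gene, attr, new)
        events.append(MutationEvent(
            generation=generation, kind=POINT, gene_ids=(gene.gene_id,),
            payload={"gene_id": gene.gene_id, "attr": attr,
                     "old": _jsonable(old), "new": _jsonable(new)},
            fraction_of_genome=1.0 / n, genome_size_before=n))
    return genome.with_genes(genes), events


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    return v


def _from_jsonable(attr: str, v):
    if attr in ("operator", "binding_motif"):
        return tuple(v)
    return v


# ---------------------------------------------------------------------------
# Segmental events on the circular genome
# ---------------------------------------------------------------------------

def _max_segment(n: int, rates: MutationRates) -> int:
    return max(1, math.ceil(rates.max_segment_fraction * n))


def _circular_segment(genes: Sequence[Gene], start: int, length: int):
    """Split into (segment, remainder-in-order-starting-after-segment-origin).

    The remainder keeps the linear order of the non-segment genes with the
    genome's origin preserved where possible.
    """
    n = len(genes)
    idx = [(start + k) % n for k in range(length)]
    chosen = set(idx)
    segment = [genes[i] for i in idx]
    rest = [g for i, g in enumerate(genes) if i not in chosen]
    return segment, rest


def _duplicate(genome: Genome, start: int, length: int) -> Genome:
    genes = list(genome.genes)
    n = len(genes)
    segment = [genes[(start + k) % n] for k in range(length)]
    next_id = genome.next_gene_id()
    copies = [replace(g, gene_id=next_id + k) for k, g in enumerate(segment)]
    insert_at = (start + length) % n if start + length > n else start + length
    new = genes[:insert_at] + copies + genes[insert_at:]
    return genome.with_genes(new)


def _delete(genome: Genome, start: int, length: int) -> Tuple[Genome, List[int]]:
    segment, rest = _circular_segment(genome.genes, start, length)
    return genome.with_genes(rest), [g.gene_id for g in segment]


def _translocate(genome: Genome, start: int, length: int, insert_at: int) -> Genome:
    segment, rest = _circular_segment(genome.genes, start, length)
    insert_at = insert_at % (len(rest) + 1) if rest else 0
    new = rest[:insert_at] + segment + rest[insert_at:]
    return genome.with_genes(new)


def segmental_mutate(genome: Genome, rates: MutationRates, rng,
                     generation: int = 0) -> Tuple[Genome, List[MutationEvent]]:
    """At most one duplication, one deletion and one translocation attempt
    per generation (Bernoulli each, probability scaled by n/G_ref).

    Segment lengths are uniform on [1, ceil(max_segment_fraction * n)].
    Deleting the last remaining gene leaves an empty (inviable) genome.
    """
    events: List[MutationEvent] = []
    for kind in (DUPLICATION, DELETION, TRANSLOCATION):
        n = len(genome)
        if n == 0:
            break
        if rng.random() >= rates.segmental_prob(kind, n):
            continue
        length = int(rng.integers(1, _max_segment(n, rates) + 1))
        start = int(rng.integers(n))
        size_before = n
        if kind == DUPLICATION:
            next_id = genome.next_gene_id()
            genome = _duplicate(genome, start, length)
            new_ids = tuple(range(next_id, next_id + length))
            affected = new_ids
            payload = {"start": start, "length": length}
        elif kind == DELETION:
            genome, deleted = _delete(genome, start, length)
            affected = tuple(deleted)
            payload = {"start": start, "length": length}
        else:
            insert_at = int(rng.integers(size_before - length + 1))
            moved = [genome.genes[(start + k) % n].gene_id for k in range(length)]
            genome = _translocate(genome, start, length, insert_at)
            affected = tuple(moved)
            payload = {"start": start, "length": length, "insert_at": insert_at}
        events.append(MutationEvent(
            generation=generation, kind=kind, gene_ids=affected, payload=payload,
            fraction_of_genome=length / size_before, genome_size_before=size_before))
    return genome, events


def whole_genome_duplicate(genome: Genome, generation: int = 0
                           ) -> Tuple[Genome, MutationEvent]:
    """Duplicate every gene (autopolyploidization).

    The duplicate block is appended preserving circular order.  Each
    ancestral gene and its copy get a fresh shared ``wgd_tag`` pair id
    (members 0 and 1); parameters are copied bit-exactly.
    """
    n = len(genome)
    if n == 0:
        event = MutationEvent(generation=generation, kind=WGD, gene_ids=(),
                              payload={"noop": True}, fraction_of_genome=0.0,
                              genome_size_before=0)
        return genome, event
    next_id = genome.next_gene_id()
    originals = [replace(g, wgd_tag=(i, 0)) for i, g in enumerate(genome)]
    copies = [replace(g, gene_id=next_id + i, wgd_tag=(i, 1))
              for i, g in enumerate(genome)]
    event = MutationEvent(
        generation=generation, kind=WGD,
        gene_ids=tuple(g.gene_id for g in copies),
        payload={"n": n}, fraction_of_genome=1.0, genome_size_before=n)
    return genome.with_genes(originals + copies), event


def apply_all(genome: Genome, rates: MutationRates, rng, generation: int = 0
              ) -> Tuple[Genome, List[MutationEvent]]:
    """One generation of mutation: WGD decision first, then segmental events,
    then point mutations.  Returns the child genome and the ordered event log."""
    events: List[MutationEvent] = []
    if len(genome) > 0 and rng.random() < rates.wgd_per_cell:
        genome, ev = whole_genome_duplicate(genome, generation)
        events.append(ev)
    genome, seg_events = segmental_mutate(genome, rates, rng, generation)
    events.extend(seg_events)
    genome, point_events = point_mutate(genome, rates, rng, generation)
    events.extend(point_events)
    return genome, events


# ---------------------------------------------------------------------------
# Deterministic replay
# ---------------------------------------------------------------------------

def replay_events(genome: Genome, events: Sequence[MutationEvent]) -> Genome:
    """Reconstruct a child genome from (parent, ordered event list)."""
    for ev in events:
        if ev.kind == WGD:
            if ev.payload.get("noop"):
                continue
            genome, _ = whole_genome_duplicate(genome, ev.generation)
        elif ev.kind == DUPLICATION:
            genome = _duplicate(genome, ev.payload["start"], ev.payload["length"])
        elif ev.kind == DELETION:
            genome, _ = _delete(genome, ev.payload["start"], ev.payload["length"])
        elif ev.kind == TRANSLOCATION:
            genome = _translocate(genome, ev.payload["start"], ev.payload["length"],
                                  ev.payload["insert_at"])
        elif ev.kind == POINT:
            p = ev.payload
            genes = list(genome.genes)
            for i, g in enumerate(genes):
                if g.gene_id == p["gene_id"]:
                    genes[i] = _apply_point(g, p["attr"],
                                            _from_jsonable(p["attr"], p["new"]))
                    break
            else:
                raise GenomeError(f"replay: gene {p['gene_id']} not found")
            genome = genome.with_genes(genes)
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return genome


# ---------------------------------------------------------------------------
# Event log I/O (tab-separated, one event per line, JSON payload column)
# ---------------------------------------------------------------------------

def _event_line(cell_id, ev: MutationEvent) -> str:
    return "\t".join([
        str(ev.generation), str(cell_id), ev.kind,
        ",".join(str(i) for i in ev.gene_ids) or "-",
        repr(ev.fraction_of_genome), str(ev.genome_size_before),
        json.dumps(ev.payload, sort_keys=True),
    ])


def write_event_log(path, rows) -> None:
    """``rows`` yields (cell_id, MutationEvent) pairs."""
    def _write(fh):
        fh.write("#generation\tcell_id\tkind\tgene_ids\tfraction\tsize_before\tpayload\n")
        for cell_id, ev in rows:
            fh.write(_event_line(cell_id, ev) + "\n")
    if hasattr(path, "write"):
        _write(path)
    else:
        with open(path, "w") as fh:
            _write(fh)


def read_event_log(path):
    """Yield (cell_id, MutationEvent) pairs from a written event log."""
    def _parse(fh):
        out = []
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gen, cell_id, kind, ids, frac, size, payload = line.rstrip("\n").split("\t")
            if cell_id.isdigit():
                cell_id = int(cell_id)
            out.append((cell_id, MutationEvent(
                generation=int(gen), kind=kind,
                gene_ids=() if ids == "-" else tuple(int(i) for i in ids.split(",")),
                payload=json.loads(payload), fraction_of_genome=float(frac),
                genome_size_before=int(size))))
        return out
    if hasattr(path, "read"):
        return _parse(path)
    with open(path) as fh:
        return _parse(fh)
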