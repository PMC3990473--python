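"""Structured circular genomes and the regulatory network they encode.

A genome is an ordered circular sequence of genes.  Each gene is one of three
functional categories -- transcription factor (TF), metabolic enzyme or
membrane pump -- and carries a promoter with a discrete operator motif.  A TF
regulates exactly those genes whose operator is identical to its binding
motif (exact, position-by-position match over a small discrete alphabet), so
the regulatory network is a pure function of the genome.

Genes additionally carry two bookkeeping tags used by the lineage and
retention analyses:

``ancestry_tag``
    identity of the ancestral-reference gene this gene descends from.  Tags
    are copied verbatim to every duplicate, so "descends one-to-one" is
    decided later by the random-original rule, not here.
``wgd_tag``
    ``(pair_id, member)`` assigned at a whole-genome duplication; the two
    copies of an ancestral gene share ``pair_id`` and differ in ``member``
    (0 for the pre-existing copy, 1 for the new one).  Copied on subsequent
    segmental duplication so post-WGD duplicates remain attributable.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

__all__ = [
    "DEFAULT_MOTIF_LENGTH",
    "DEFAULT_ALPHABET_SIZE",
    "Motif",
    "MotifError",
    "GenomeError",
    "Promoter",
    "TFTrait",
    "EnzymeTrait",
    "PumpTrait",
    "Gene",
    "Genome",
    "RegulatoryNetwork",
    "motif_matches",
    "random_motif",
    "derive_network",
    "stamp_ancestry",
    "read_genome",
    "write_genome",
    "genome_to_text",
    "genome_from_text",
]

DEFAULT_MOTIF_LENGTH = 12
DEFAULT_ALPHABET_SIZE = 2

#: A motif is a fixed-length tuple of symbols drawn from {0, ..., S-1}.
Motif = Tuple[int, ...]

TF = "tf"
ENZYME = "enzyme"
PUMP = "pump"
CATEGORIES = (TF, ENZYME, PUMP)

CATABOLIC = "catabolic"
ANABOLIC = "anabolic"

LIGAND_A = "A"
LIGAND_X = "X"


class MotifError(ValueError):
    """Raised when motifs have mismatched length or invalid symbols."""


class GenomeError(ValueError):
    """Raised on structurally invalid genomes (e.g. duplicate gene ids)."""


def _check_motif(motif: Sequence[int], length: int, alphabet_size: int) -> Motif:
    m = tuple(int(s) for s in motif)
    if len(m) != length:
        raise MotifError(f"motif length {len(m)} != expected {length}")
    for s in m:
        if not 0 <= s < alphabet_size:
            raise MotifError(f"symbol {s} outside alphabet of size {alphabet_size}")
    return m


def motif_matches(tf_motif: Sequence[int], operator: Sequence[int]) -> bool:
    """Exact position-by-position motif comparison.

    Regulation in this model is discrete: a TF binds a promoter if and only
    if its binding motif is identical to the operator.  There is no partial
    or mismatch-tolerant binding.
    """
    a, b = tuple(tf_motif), tuple(operator)
    if len(a) != len(b):
        raise MotifError(f"motif lengths differ: {len(a)} vs {len(b)}")
    return a == b


def random_motif(rng, length: int = DEFAULT_MOTIF_LENGTH,
                 alphabet_size: int = DEFAULT_ALPHABET_SIZE) -> Motif:
    return tuple(int(x) for x in rng.integers(0, alphabet_size, size=length))


@dataclass(frozen=True)
class Promoter:
    operator: Motif
    basal_rate: float

    def __post_init__(self):
        object.__setattr__(self, "operator", tuple(self.operator))
        if self.basal_rate < 0:
            raise GenomeError(f"basal_rate must be >= 0, got {self.basal_rate}")


@dataclass(frozen=True)
class TFTrait:
    """Transcription factor: senses one ligand (internal A or X).

    ``effect_bound`` / ``effect_free`` are signed log-scale regulation
    strengths applied to targets, depending on whether the TF is
    ligand-bound or ligand-free.
    """
    ligand: str
    binding_motif: Motif
    k_ligand: float
    effect_bound: float
    effect_free: float

    def __post_init__(self):
        object.__setattr__(self, "binding_motif", tuple(self.binding_motif))
        if self.ligand not in (LIGAND_A, LIGAND_X):
            raise GenomeError(f"TF ligand must be 'A' or 'X', got {self.ligand!r}")
        if self.k_ligand <= 0:
            raise GenomeError("k_ligand must be > 0")


@dataclass(frozen=True)
class EnzymeTrait:
    """Metabolic enzyme: catabolic (A -> X) or anabolic (A + X -> product)."""
    reaction: str
    k_cat: float
    K_A: float
    K_X: Optional[float] = None

    def __post_init__(self):
        if self.reaction not in (CATABOLIC, ANABOLIC):
            raise GenomeError(f"unknown enzyme reaction {self.reaction!r}")
        if self.k_cat <= 0 or self.K_A <= 0:
            raise GenomeError("enzyme k_cat and K_A must be > 0")
        if self.reaction == ANABOLIC:
            if self.K_X is None or self.K_X <= 0:
                raise GenomeError("anabolic enzymes need K_X > 0")


@dataclass(frozen=True)
class PumpTrait:
    """Active importer of external A, consuming ``energy_cost`` X per A."""
    k_cat: float
    K_Aext: float
    K_X: float
    energy_cost: float = 0.5

    def __post_init__(self):
        if min(self.k_cat, self.K_Aext, self.K_X) <= 0:
            raise GenomeError("pump k_cat, K_Aext and K_X must be > 0")
        if self.energy_cost < 0:
            raise GenomeError("energy_cost must be >= 0")


Trait = Union[TFTrait, EnzymeTrait, PumpTrait]

_TRAIT_FOR_CATEGORY = {TF: TFTrait, ENZYME: EnzymeTrait, PUMP: PumpTrait}


@dataclass(frozen=True)
class Gene:
    gene_id: int
    category: str
    promoter: Promoter
    trait: Trait
    ancestry_tag: Optional[int] = None
    wgd_tag: Optional[Tuple[int, int]] = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise GenomeError(f"unknown gene category {self.category!r}")
        expected = _TRAIT_FOR_CATEGORY[self.category]
        if not isinstance(self.trait, expected):
            raise GenomeError(
                f"gene {self.gene_id}: category {self.category!r} requires "
                f"{expected.__name__}, got {type(self.trait).__name__}")
        if self.wgd_tag is not None:
            object.__setattr__(self, "wgd_tag", (int(self.wgd_tag[0]), int(self.wgd_tag[1])))


@dataclass(frozen=True)
class Genome:
    """Circular ordered gene sequence; successor of the last gene is the first.

    Immutable by convention: mutation operators return new genomes, which
    lets derived quantities (regulatory network, compiled ODE arrays,
    fitness) be cached safely per object.
    """
    genes: Tuple[Gene, ...]
    motif_length: int = DEFAULT_MOTIF_LENGTH
    alphabet_size: int = DEFAULT_ALPHABET_SIZE
    _fingerprint: Optional[int] = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise GenomeError("gene_ids must be unique within a genome")
        for g in self.genes:
            _check_motif(g.promoter.operator, self.motif_length, self.alphabet_size)
            if g.category == TF:
                _check_motif(g.trait.binding_motif, self.motif_length, self.alphabet_size)

    @property
    def size(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def gene(self, gene_id: int) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"no gene with id {gene_id}")

    def category_counts(self) -> Mapping[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for g in self.genes:
            counts[g.category] += 1
        return counts

    def with_genes(self, genes: Iterable[Gene]) -> "Genome":
        """Derived genome sharing this genome's motif geometry.

        Skips per-gene motif re-validation: the mutation operators only
        rearrange, copy or symbol-flip already-valid genes, so lengths and
        alphabets cannot change.  Gene-id uniqueness is still enforced.
        """
        return Genome._trusted(tuple(genes), self.motif_length,
                               self.alphabet_size)

    @classmethod
    def _trusted(cls, genes: Tuple[Gene, ...], motif_length: int,
                 alphabet_size: int) -> "Genome":
        self = object.__new__(cls)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "motif_length", motif_length)
        object.__setattr__(self, "alphabet_size", alphabet_size)
        object.__setattr__(self, "_fingerprint", None)
        ids = {g.gene_id for g in genes}
        if len(ids) != len(genes):
            raise GenomeError("gene_ids must be unique within a genome")
        return self

    def next_gene_id(self) -> int:
        return max((g.gene_id for g in self.genes), default=-1) + 1

    @property
    def fingerprint(self) -> int:
        """In-process identity token (unique per genome object).

        Genomes are immutable, so object identity is content identity for
        everything created in one run; the token is used as a cheap cache
        key by fitness evaluation.
        """
        if self._fingerprint is None:
            object.__setattr__(self, "_fingerprint", next(_GENOME_SERIAL))
        return self._fingerprint


_GENOME_SERIAL = itertools.count()


@dataclass(frozen=True)
class RegulatoryNetwork:
    """TF -> target edges plus per-TF outdegree, derived from motif identity."""
    edges: Mapping[int, Tuple[int, ...]]        # tf gene_id -> target gene_ids
    outdegrees: Mapping[int, int]               # tf gene_id -> number of targets

    def edge_set(self) -> set:
        return {(tf, tgt) for tf, tgts in self.edges.items() for tgt in tgts}

    def outdegree(self, tf_id: int) -> int:
        if tf_id not in self.outdegrees:
            raise KeyError(f"{tf_id} is not a TF in this network")
        return self.outdegrees[tf_id]

    def regulators_of(self, gene_id: int) -> Tuple[int, ...]:
        return tuple(tf for tf, tgts in self.edges.items() if gene_id in tgts)


def derive_network(genome: Genome) -> RegulatoryNetwork:
    """Derive the regulatory network: edge iff TF motif == gene operator.

    A TF may regulate itself and other TFs.  TFs with no matching operator
    are present with outdegree zero.
    """
    by_operator: dict = {}
    for g in genome:
        by_operator.setdefault(g.promoter.operator, []).append(g.gene_id)
    edges = {}
    for g in genome:
        if g.category == TF:
            edges[g.gene_id] = tuple(by_operator.get(g.trait.binding_motif, ()))
    outdeg = {tf: len(tgts) for tf, tgts in edges.items()}
    return RegulatoryNetwork(edges=edges, outdegrees=outdeg)


def stamp_ancestry(genome: Genome) -> Genome:
    """Assign fresh ancestry tags (positional) to every gene.

    Used to declare a genome an ancestral reference point; descendants then
    carry these tags through duplications so conserved one-to-one content can
    be measured against this genome.
    """
    return genome.with_genes(
        replace(g, ancestry_tag=i) for i, g in enumerate(genome))


# ---------------------------------------------------------------------------
# Genome text format (tab-separated, one gene per line)
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def _fmt_float(x: float) -> str:
    return repr(float(x))


def _fmt_motif(m: Motif) -> str:
    return "".join(str(s) for s in m)


def _parse_motif(s: str) -> Motif:
    return tuple(int(c) for c in s)


def _fmt_opt(x) -> str:
    return "-" if x is None else str(x)


def genome_to_text(genome: Genome) -> str:
    if genome.alphabet_size > 10:
        raise GenomeError("text format supports alphabet sizes up to 10")
    lines = [f"#virtualcell-genome\tv{_FORMAT_VERSION}\tL={genome.motif_length}"
             f"\tS={genome.alphabet_size}"]
    for pos, g in enumerate(genome):
        wgd = "-" if g.wgd_tag is None else f"{g.wgd_tag[0]}:{g.wgd_tag[1]}"
        fields = [str(pos), str(g.gene_id), g.category,
                  _fmt_motif(g.promoter.operator), _fmt_float(g.promoter.basal_rate),
                  _fmt_opt(g.ancestry_tag), wgd]
        t = g.trait
        if g.category == TF:
            fields += [t.ligand, _fmt_motif(t.binding_motif), _fmt_float(t.k_ligand),
                       _fmt_float(t.effect_bound), _fmt_float(t.effect_free)]
        elif g.category == ENZYME:
            fields += [t.reaction, _fmt_float(t.k_cat), _fmt_float(t.K_A),
                       "-" if t.K_X is None else _fmt_float(t.K_X)]
        else:
            fields += [_fmt_float(t.k_cat), _fmt_float(t.K_Aext),
                       _fmt_float(t.K_X), _fmt_float(t.energy_cost)]
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def genome_from_text(text: str) -> Genome:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#virtualcell-genome"):
        raise GenomeError("not a virtualcell genome file (missing header)")
    header = lines[0].split("\t")
    meta = {}
    for part in header[1:]:
        if "=" in part:
            k, v = part.split("=", 1)
            meta[k] = int(v)
    length = meta.get("L", DEFAULT_MOTIF_LENGTH)
    alphabet = meta.get("S", DEFAULT_ALPHABET_SIZE)
    genes = []
    for ln in lines[1:]:
        f = ln.split("\t")
        _pos, gid, cat = int(f[0]), int(f[1]), f[2]
        promoter = Promoter(_parse_motif(f[3]), float(f[4]))
        ancestry = None if f[5] == "-" else int(f[5])
        wgd = None
        if f[6] != "-":
            p, m = f[6].split(":")
            wgd = (int(p), int(m))
        if cat == TF:
            trait = TFTrait(f[7], _parse_motif(f[8]), float(f[9]),
                            float(f[10]), float(f[11]))
        elif cat == ENZYME:
            trait = EnzymeTrait(f[7], float(f[8]), float(f[9]),
                                None if f[10] == "-" else float(f[10]))
        elif cat == PUMP:
            trait = PumpTrait(float(f[7]), float(f[8]), float(f[9]), float(f[10]))
        else:
            raise GenomeError(f"unknown category {cat!r} in genome file")
        genes.append(Gene(gid, cat, promoter, trait, ancestry, wgd))
    return Genome(tuple(genes), motif_length=length, alphabet_size=alphabet)


def write_genome(genome: Genome, path) -> None:
    if hasattr(path, "write"):
        path.write(genome_to_text(genome))
    else:
        with io.open(path, "w", newline="") as fh:
            fh.write(genome_to_text(genome))


def read_genome(path) -> Genome:
    if hasattr(path, "read"):
        return genome_from_text(path.read())
    with io.open(path, "r") as fh:
        return genome_from_text(fh.read())
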