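"""Post-WGD analysis: ohnolog retention, random-deletion nulls, divergence.

The reference is the first post-WGD genome, in which every gene carries a
``wgd_tag = (pair_id, member)``.  Along the line of descent each pair member
either survives (at least one one-to-one copy of it remains; copies created
by later duplications are attributed to the member via the inherited tag and
only one random copy counts as the original) or is lost.  Surviving WGD
genes are classified as ohnologs (both pair members survive) or singles
(partner lost); the retention fraction is genes-in-intact-pairs divided by
all surviving WGD genes, per functional category.

Null models replay the observed number of per-category losses on the
reference content without selection -- either uniformly within a category or
with TF deletion probabilities biased by ancestral-connectivity bin -- to
give the retention expected from neutral loss alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .genome import ENZYME, PUMP, TF, Gene, Genome, derive_network
from .lineage import LineOfDescent

__all__ = [
    "CensusRow",
    "OhnologCensus",
    "NullModelSpec",
    "DivergenceRow",
    "classify_ohnologs",
    "census_over_lod",
    "deletion_counts_from_lod",
    "null_spec_from_lod",
    "random_deletion_null",
    "bs_conservation",
    "relative_outdegree",
    "divergence_over_lod",
    "rank_sum_compare",
    "write_retention_report",
]

CATEGORIES = (TF, ENZYME, PUMP)
UNIFORM = "uniform"
CONNECTIVITY = "connectivity_binned"

MemberTag = Tuple[int, int]          # (pair_id, member 0/1)


@dataclass(frozen=True)
class CensusRow:
    n_conserved: int         # surviving ancestral WGD genes (members)
    n_in_pairs: int          # members whose partner also survives (even)
    n_singles: int

    @property
    def retention_fraction(self) -> Optional[float]:
        """Intact-ohnolog genes / conserved WGD genes; None when no WGD gene
        of the category survives (empty denominator)."""
        if self.n_conserved == 0:
            return None
        return self.n_in_pairs / self.n_conserved


@dataclass(frozen=True)
class OhnologCensus:
    generation: int
    per_category: Mapping[str, CensusRow]

    def total(self) -> CensusRow:
        return CensusRow(
            sum(r.n_conserved for r in self.per_category.values()),
            sum(r.n_in_pairs for r in self.per_category.values()),
            sum(r.n_singles for r in self.per_category.values()))


def _member_index(wgd_reference: Genome) -> Dict[MemberTag, Gene]:
    idx: Dict[MemberTag, Gene] = {}
    for g in wgd_reference:
        if g.wgd_tag is None:
            raise ValueError(
                "wgd_reference must be a first post-WGD genome (all genes tagged)")
        idx[g.wgd_tag] = g
    return idx


def surviving_members(wgd_reference: Genome, descendant: Genome) -> Set[MemberTag]:
    """WGD pair members with at least one surviving copy in the descendant."""
    ref_tags = set(_member_index(wgd_reference))
    return {g.wgd_tag for g in descendant
            if g.wgd_tag is not None and g.wgd_tag in ref_tags}


def _census_from_members(wgd_reference: Genome, members: Set[MemberTag],
                         generation: int = 0) -> OhnologCensus:
    ref = _member_index(wgd_reference)
    per_cat = {}
    for cat in CATEGORIES:
        cat_members = [m for m in members if ref[m].category == cat]
        pairs = sum(1 for (pair, mem) in cat_members
                    if mem == 0 and (pair, 1) in members)
        in_pairs = 2 * pairs
        per_cat[cat] = CensusRow(n_conserved=len(cat_members),
                                 n_in_pairs=in_pairs,
                                 n_singles=len(cat_members) - in_pairs)
    return OhnologCensus(generation=generation, per_category=per_cat)


def classify_ohnologs(wgd_reference: Genome, descendant: Genome,
                      generation: int = 0) -> OhnologCensus:
    """Split surviving ancestral WGD genes into intact pairs and singles.

    Duplicates that arose after the WGD reference point inherit the member
    tag of their template and therefore count as survival of that member,
    never as extra WGD genes.  Descendants lacking tags entirely are
    rejected.
    """
    if len(descendant) > 0 and all(g.wgd_tag is None for g in descendant):
        raise ValueError("descendant carries no WGD tags; wrong reference?")
    members = surviving_members(wgd_reference, descendant)
    return _census_from_members(wgd_reference, members, generation)


def census_over_lod(wgd_reference: Genome, lod: LineOfDescent,
                    reference_generation: int,
                    bin_width: int = 1000) -> List[OhnologCensus]:
    """Ohnolog census at successive bin boundaries after the WGD reference."""
    final = lod.steps[-1].generation
    out = []
    g = reference_generation
    while True:
        genome = lod.genome_at(min(g, final))
        out.append(classify_ohnologs(wgd_reference, genome,
                                     generation=min(g, final)))
        if g >= final:
            break
        g += bin_width
        if g > final:
            g = final
    return out


# ---------------------------------------------------------------------------
# Random-deletion null models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullModelSpec:
    """Loss counts (and optional connectivity bias) for the null replay.

    ``deletion_counts[b][category]`` is the number of ancestral WGD members
    of that category lost during bin ``b`` of the matched evolutionary line
    of descent.  In connectivity mode, TF members are additionally weighted
    by ``tf_bin_probs[b][k]``, the per-bin deletion likelihood of ancestral
    relative-outdegree bin ``k`` (bin edges in ``tf_bin_edges``).
    """
    mode: str
    deletion_counts: Tuple[Mapping[str, int], ...]
    tf_bin_edges: Optional[np.ndarray] = None
    tf_bin_probs: Optional[Tuple[np.ndarray, ...]] = None

    def __post_init__(self):
        if self.mode not in (UNIFORM, CONNECTIVITY):
            raise ValueError(f"unknown null mode {self.mode!r}")
        if self.mode == CONNECTIVITY and (self.tf_bin_edges is None or
                                          self.tf_bin_probs is None):
            raise ValueError("connectivity mode needs bin edges and probabilities")


def deletion_counts_from_lod(wgd_reference: Genome, lod: LineOfDescent,
                             reference_generation: int, bin_width: int = 1000
                             ) -> List[Dict[str, int]]:
    """Per-bin, per-category counts of ancestral WGD members lost on the LOD."""
    ref = _member_index(wgd_reference)
    censuses = census_over_lod(wgd_reference, lod, reference_generation, bin_width)
    boundaries = [c.generation for c in censuses]
    survivors = [surviving_members(wgd_reference, lod.genome_at(g))
                 for g in boundaries]
    counts = []
    for prev, cur in zip(survivors[:-1], survivors[1:]):
        lost = prev - cur
        counts.append({cat: sum(1 for m in lost if ref[m].category == cat)
                       for cat in CATEGORIES})
    return counts


def _relative_outdegrees(wgd_reference: Genome) -> Dict[MemberTag, float]:
    """Ancestral outdegree of each TF member relative to the TF mean."""
    net = derive_network(wgd_reference)
    tf_members = {g.wgd_tag: net.outdegrees[g.gene_id]
                  for g in wgd_reference if g.category == TF}
    mean = np.mean(list(tf_members.values())) if tf_members else 0.0
    if mean == 0:
        return {m: 0.0 for m in tf_members}
    return {m: d / mean for m, d in tf_members.items()}


def connectivity_bins(wgd_reference: Genome, n_bins: int = 5) -> np.ndarray:
    """Quantile edges over relative ancestral TF outdegree (n_bins bins)."""
    rel = list(_relative_outdegrees(wgd_reference).values())
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    inner = np.quantile(rel, qs) if rel else np.zeros(n_bins - 1)
    return np.concatenate(([-np.inf], inner, [np.inf]))


def null_spec_from_lod(wgd_reference: Genome, lod: LineOfDescent,
                       reference_generation: int, *, mode: str = UNIFORM,
                       bin_width: int = 1000, n_bins: int = 5) -> NullModelSpec:
    """Build the null-model specification matched to an evolutionary run."""
    counts = deletion_counts_from_lod(wgd_reference, lod, reference_generation,
                                      bin_width)
    if mode == UNIFORM:
        return NullModelSpec(mode=UNIFORM, deletion_counts=tuple(counts))
    edges = connectivity_bins(wgd_reference, n_bins)
    rel = _relative_outdegrees(wgd_reference)
    bin_of = {m: int(np.searchsorted(edges, r, side="right") - 1)
              for m, r in rel.items()}
    boundaries = [reference_generation + b * bin_width
                  for b in range(len(counts) + 1)]
    final = lod.steps[-1].generation
    survivors = [surviving_members(wgd_reference, lod.genome_at(min(g, final)))
                 for g in boundaries]
    probs = []
    for prev, cur in zip(survivors[:-1], survivors[1:]):
        at_risk = np.zeros(n_bins)
        lost = np.zeros(n_bins)
        for m in prev:
            if m in bin_of:
                at_risk[bin_of[m]] += 1
                if m not in cur:
                    lost[bin_of[m]] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(at_risk > 0, lost / np.maximum(at_risk, 1), 0.0)
        if p.sum() == 0:
            p = np.ones(n_bins)
        probs.append(p)
    return NullModelSpec(mode=CONNECTIVITY, deletion_counts=tuple(counts),
                         tf_bin_edges=edges, tf_bin_probs=tuple(probs))


def random_deletion_null(wgd_reference: Genome, spec: NullModelSpec, rng,
                         n_replicates: int = 100) -> List[OhnologCensus]:
    """Replay the observed per-category losses without selection.

    Returns, per bin boundary, the census averaged over replicates (counts
    are means rounded to the nearest integer for reporting; retention
    fractions are averaged exactly via `null_retention_fractions`).
    """
    fractions = null_retention_fractions(wgd_reference, spec, rng, n_replicates)
    # build mean censuses for reporting
    out = []
    for b, per_cat in enumerate(fractions["mean_counts"]):
        rows = {cat: CensusRow(*[int(round(x)) for x in per_cat[cat]])
                for cat in CATEGORIES}
        out.append(OhnologCensus(generation=b, per_category=rows))
    return out


def null_retention_fractions(wgd_reference: Genome, spec: NullModelSpec, rng,
                             n_replicates: int = 100) -> dict:
    """Monte-Carlo expectation of the null retention fractions per bin.

    Returns a dict with ``fractions[cat]`` -- array (n_boundaries,) of mean
    retention fraction per category (nan where the denominator was always
    empty), ``sd[cat]`` the replicate standard deviation, and raw per-bin
    mean member counts.
    """
    ref = _member_index(wgd_reference)
    members_by_cat = {cat: sorted(m for m, g in ref.items()
                                  if g.category == cat)
                      for cat in CATEGORIES}
    n_boundaries = len(spec.deletion_counts) + 1
    rel_bin = None
    if spec.mode == CONNECTIVITY:
        rel = _relative_outdegrees(wgd_reference)
        rel_bin = {m: int(np.searchsorted(spec.tf_bin_edges, r, side="right") - 1)
                   for m, r in rel.items()}
    frac_samples = {cat: np.full((n_replicates, n_boundaries), np.nan)
                    for cat in CATEGORIES}
    count_acc = [{cat: np.zeros(3) for cat in CATEGORIES}
                 for _ in range(n_boundaries)]
    for r in range(n_replicates):
        alive = {cat: set(members_by_cat[cat]) for cat in CATEGORIES}
        for b in range(n_boundaries):
            if b > 0:
                counts = spec.deletion_counts[b - 1]
                for cat in CATEGORIES:
                    k = counts.get(cat, 0)
                    pool = sorted(alive[cat])
                    if k > len(pool):
                        raise ValueError(
                            f"null spec deletes {k} {cat} members but only "
                            f"{len(pool)} remain")
                    if k == 0 or not pool:
                        continue
                    if spec.mode == CONNECTIVITY and cat == TF:
                        w = np.array([spec.tf_bin_probs[b - 1][rel_bin[m]]
                                      for m in pool])
                        if w.sum() <= 0:
                            w = np.ones(len(pool))
                        w = w / w.sum()
                        idx = rng.choice(len(pool), size=k, replace=False, p=w)
                    else:
                        idx = rng.choice(len(pool), size=k, replace=False)
                    for j in idx:
                        alive[cat].discard(pool[int(j)])
            all_alive = set().union(*alive.values())
            census = _census_from_members(wgd_reference, all_alive)
            for cat in CATEGORIES:
                row = census.per_category[cat]
                if row.n_conserved > 0:
                    frac_samples[cat][r, b] = row.retention_fraction
                count_acc[b][cat] += np.array([row.n_conserved, row.n_in_pairs,
                                               row.n_singles])
    result = {"fractions": {}, "sd": {}, "mean_counts": []}
    for cat in CATEGORIES:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            result["fractions"][cat] = np.nanmean(frac_samples[cat], axis=0)
            result["sd"][cat] = np.nanstd(frac_samples[cat], axis=0)
    for b in range(n_boundaries):
        result["mean_counts"].append(
            {cat: count_acc[b][cat] / n_replicates for cat in CATEGORIES})
    return result


# ---------------------------------------------------------------------------
# Binding-site conservation and connectivity of retained TFs
# ---------------------------------------------------------------------------

def bs_conservation(reference_tf: Gene, descendant_tf: Gene) -> int:
    """1 if the descendant TF kept the ancestral binding motif, else 0."""
    if reference_tf.category != TF or descendant_tf.category != TF:
        raise TypeError("bs_conservation compares two TFs")
    return int(tuple(reference_tf.trait.binding_motif) ==
               tuple(descendant_tf.trait.binding_motif))


def relative_outdegree(outdegrees: Mapping[int, int],
                       ancestral_tf_ids: Sequence[int],
                       retained_tf_ids: Sequence[int]) -> Optional[float]:
    """Mean ancestral outdegree of retained TFs over the mean of all
    ancestral TFs; None for an empty retained set."""
    retained = list(retained_tf_ids)
    if not retained:
        return None
    if not set(retained) <= set(ancestral_tf_ids):
        raise ValueError("retained TFs must be a subset of ancestral TFs")
    mean_all = np.mean([outdegrees[i] for i in ancestral_tf_ids])
    if mean_all == 0:
        return None
    return float(np.mean([outdegrees[i] for i in retained]) / mean_all)


@dataclass(frozen=True)
class DivergenceRow:
    generation: int
    bs_conservation: Dict[str, float]      # group -> mean 0/1 score (nan if empty)
    relative_outdegree: Dict[str, Optional[float]]


def divergence_over_lod(wgd_reference: Genome, lod: LineOfDescent,
                        reference_generation: int, rng,
                        bin_width: int = 1000) -> List[DivergenceRow]:
    """Binding-site conservation and relative ancestral outdegree of
    conserved TFs along the LOD, separately for ohnologs and singles.

    For each surviving TF member one random surviving copy is compared with
    the ancestral gene (motif identical -> score 1).  Relative outdegrees use
    the ancestral (reference) network only.
    """
    ref = _member_index(wgd_reference)
    net = derive_network(wgd_reference)
    tf_members = [m for m, g in ref.items() if g.category == TF]
    final = lod.steps[-1].generation
    rows = []
    g = reference_generation
    while True:
        genome = lod.genome_at(min(g, final))
        alive = surviving_members(wgd_reference, genome)
        copies: Dict[MemberTag, List[Gene]] = {}
        for gene in genome:
            if gene.wgd_tag in alive and gene.category == TF:
                copies.setdefault(gene.wgd_tag, []).append(gene)
        groups = {
            "ohnolog": [m for m in tf_members
                        if m in alive and (m[0], 1 - m[1]) in alive],
            "single": [m for m in tf_members
                       if m in alive and (m[0], 1 - m[1]) not in alive],
        }
        groups["all_retained"] = groups["ohnolog"] + groups["single"]
        bs = {}
        rod = {}
        for name, members in groups.items():
            scores = []
            for m in members:
                cands = copies.get(m, [])
                if not cands:
                    continue
                pick = cands[int(rng.integers(len(cands)))]
                scores.append(bs_conservation(ref[m], pick))
            bs[name] = float(np.mean(scores)) if scores else math.nan
            rod[name] = relative_outdegree(
                net.outdegrees, [ref[m].gene_id for m in tf_members],
                [ref[m].gene_id for m in members])
        rows.append(DivergenceRow(generation=min(g, final),
                                  bs_conservation=bs, relative_outdegree=rod))
        if g >= final:
            break
        g += bin_width
        if g > final:
            g = final
    return rows


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def rank_sum_compare(scores_a: Sequence[float], scores_b: Sequence[float],
                     alternative: str = "two-sided") -> Tuple[float, float]:
    """Mann-Whitney U comparison of per-run scores between two subsets.

    Uses the exact null distribution when sample sizes allow and there are
    no ties, with tie correction otherwise.  Degenerate input in which every
    pooled value is identical returns p = 1 with a warning.
    """
    a, b = list(scores_a), list(scores_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    pooled = a + b
    if all(x == pooled[0] for x in pooled):
        warnings.warn("all pooled scores identical; rank-sum test is degenerate")
        return (len(a) * len(b) / 2.0, 1.0)
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def write_retention_report(path, censuses: Sequence[OhnologCensus],
                           null: Optional[dict] = None,
                           n_replicates: Optional[int] = None) -> None:
    """Tab-separated per (bin, category) retention report."""
    def _write(fh):
        fh.write("#generation\tcategory\tconserved\tin_pairs\tsingles\tfraction"
                 "\tnull_mean\tnull_sd\tn_replicates\n")
        for b, census in enumerate(censuses):
            for cat in CATEGORIES:
                row = census.per_category[cat]
                frac = row.retention_fraction
                nm = ns = ""
                if null is not None:
                    nm = f"{null['fractions'][cat][b]:.6g}"
                    ns = f"{null['sd'][cat][b]:.6g}"
                fh.write(f"{census.generation}\t{cat}\t{row.n_conserved}\t"
                         f"{row.n_in_pairs}\t{row.n_singles}\t"
                         f"{'' if frac is None else f'{frac:.6g}'}\t{nm}\t{ns}\t"
                         f"{n_replicates or ''}\n")
    if hasattr(path, "write"):
        _write(path)
    else:
        with open(path, "w") as fh:
            _write(fh)
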