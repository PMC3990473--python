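"""Ohnolog classification, random-deletion nulls, divergence statistics."""

import itertools
import math

import numpy as np
import pytest

from virtualcell.fixtures import (FixtureSpec, GeneSpec, make_synthetic_lod,
                                  make_viable_genome, random_genome)
from virtualcell.genome import TF, ENZYME, PUMP, derive_network, stamp_ancestry
from virtualcell.lineage import LineOfDescent
from virtualcell.mutation import whole_genome_duplicate
from virtualcell.retention import (CONNECTIVITY, UNIFORM, NullModelSpec,
                                   bs_conservation, classify_ohnologs,
                                   deletion_counts_from_lod,
                                   null_retention_fractions, null_spec_from_lod,
                                   rank_sum_compare, relative_outdegree,
                                   divergence_over_lod, surviving_members)


def wired_genome():
    """Deterministic 8-gene genome: 2 TFs (outdegrees 3 and 1), 4 enzymes,
    2 pumps."""
    from virtualcell.genome import CATABOLIC, ANABOLIC, LIGAND_X, LIGAND_A
    spec = FixtureSpec(
        name="wired",
        genes=(
            GeneSpec("tf1", TF, {"ligand": LIGAND_X}),
            GeneSpec("tf2", TF, {"ligand": LIGAND_A}),
            GeneSpec("e1", ENZYME, {"reaction": CATABOLIC}),
            GeneSpec("e2", ENZYME, {"reaction": CATABOLIC}),
            GeneSpec("e3", ENZYME, {"reaction": ANABOLIC, "K_X": 0.5}),
            GeneSpec("e4", ENZYME, {"reaction": CATABOLIC}),
            GeneSpec("p1", PUMP, {}),
            GeneSpec("p2", PUMP, {}),
        ),
        wiring={"tf1": ("e1", "e2", "p1"), "tf2": ("e3",)})
    return stamp_ancestry(make_viable_genome(spec))


@pytest.fixture
def wgd_reference():
    doubled, _ = whole_genome_duplicate(wired_genome())
    return doubled


def delete_members(reference, tags):
    """Descendant of the reference with all copies of given members removed."""
    return reference.with_genes(g for g in reference if g.wgd_tag not in tags)


class TestClassification:
    def test_intact_reference_fully_retained(self, wgd_reference):
        census = classify_ohnologs(wgd_reference, wgd_reference)
        for cat, row in census.per_category.items():
            if row.n_conserved:
                assert row.retention_fraction == 1.0
                assert row.n_singles == 0
        assert census.total().n_conserved == 16

    def test_one_member_lost_creates_single(self, rng):
        g = stamp_ancestry(random_genome(rng, n_genes=3))
        ref, _ = whole_genome_duplicate(g)
        desc = delete_members(ref, {(0, 1)})
        total = classify_ohnologs(ref, desc).total()
        assert total.n_conserved == 5
        assert total.n_in_pairs == 4
        assert total.n_singles == 1
        assert total.retention_fraction == pytest.approx(4 / 5)

    def test_empty_denominator_reported_as_none(self, rng):
        g = stamp_ancestry(random_genome(rng, n_genes=4))
        ref, _ = whole_genome_duplicate(g)
        desc = ref.with_genes(())
        census = classify_ohnologs(ref, desc)
        assert all(row.retention_fraction is None
                   for row in census.per_category.values())

    def test_post_wgd_duplicates_not_counted(self, rng):
        """A segmental duplicate of a surviving member does not add to the
        conserved count, and keeps its member attribution."""
        g = stamp_ancestry(random_genome(rng, n_genes=4))
        ref, _ = whole_genome_duplicate(g)
        lod = make_synthetic_lod(ref, [(10, [("duplication", 0, 2)])])
        census = classify_ohnologs(ref, lod.final_genome)
        assert census.total().n_conserved == 8

    def test_untagged_descendant_rejected(self, rng):
        g = stamp_ancestry(random_genome(rng, n_genes=4))
        ref, _ = whole_genome_duplicate(g)
        with pytest.raises(ValueError):
            classify_ohnologs(ref, g)

    def test_single_status_is_absorbing(self, rng):
        """Members move ohnolog -> single when the partner's line dies and
        never return (no re-creation of lost members)."""
        g = stamp_ancestry(random_genome(rng, n_genes=5))
        ref, _ = whole_genome_duplicate(g)
        lod = make_synthetic_lod(ref, [
            (100, [("deletion", 0, 1)]),
            (300, [("duplication", 3, 2)]),
            (700, [("deletion", 2, 2)]),
        ], final_generation=1000)
        statuses = []
        for step in lod.steps:
            alive = surviving_members(ref, step.genome)
            singles = {m for m in alive if (m[0], 1 - m[1]) not in alive}
            statuses.append(singles)
        for earlier, later in zip(statuses, statuses[1:]):
            assert earlier <= later | (earlier - set().union(later))
            # once a member is single it stays single (unless itself lost)
            for m in earlier:
                assert m in later or m not in surviving_members(
                    ref, lod.final_genome) or m in later


class TestUniformNull:
    def test_zero_deletions_keeps_everything(self, rng, wgd_reference):
        spec = NullModelSpec(UNIFORM, ({TF: 0, ENZYME: 0, PUMP: 0},))
        result = null_retention_fractions(wgd_reference, spec, rng, 20)
        for cat, arr in result["fractions"].items():
            if not math.isnan(arr[0]):
                assert arr[0] == 1.0 and arr[1] == 1.0

    def test_two_pair_enumeration(self, rng):
        """2 pairs, 2 uniform deletions: exhaustive enumeration over the
        C(4,2)=6 deletion sets gives expected intact-pair fraction 1/3."""
        g = stamp_ancestry(random_genome(rng, n_genes=20))
        # restrict to a 2-gene reference of one category
        tf_like = [x for x in g if x.category == TF][:2]
        base = g.with_genes(tf_like)
        ref, _ = whole_genome_duplicate(base)
        members = [x.wgd_tag for x in ref]
        # exhaustive: delete every 2-subset of the 4 members
        fracs = []
        for lost in itertools.combinations(members, 2):
            desc = delete_members(ref, set(lost))
            row = classify_ohnologs(ref, desc).per_category[TF]
            fracs.append(row.retention_fraction)
        exact = np.mean(fracs)
        assert exact == pytest.approx(1 / 3)
        spec = NullModelSpec(UNIFORM, ({TF: 2, ENZYME: 0, PUMP: 0},))
        n_rep = 10_000
        result = null_retention_fractions(ref, spec, rng, n_rep)
        mc = result["fractions"][TF][1]
        se = result["sd"][TF][1] / math.sqrt(n_rep)
        assert abs(mc - exact) < 3 * max(se, 1e-4)

    def test_infeasible_spec_rejected(self, rng, wgd_reference):
        n_tf = sum(1 for g in wgd_reference if g.category == TF)
        spec = NullModelSpec(UNIFORM, ({TF: n_tf + 1, ENZYME: 0, PUMP: 0},))
        with pytest.raises(ValueError):
            null_retention_fractions(wgd_reference, spec, rng, 5)


class TestConnectivityNull:
    def test_flat_bias_equals_uniform(self, rng, wgd_reference):
        """Connectivity mode with equal bin probabilities reproduces the
        uniform null within Monte-Carlo error."""
        edges = np.array([-np.inf, 0.5, 1.5, np.inf])
        counts = ({TF: 2, ENZYME: 3, PUMP: 0},)
        flat = NullModelSpec(CONNECTIVITY, counts, tf_bin_edges=edges,
                             tf_bin_probs=(np.ones(3),))
        uni = NullModelSpec(UNIFORM, counts)
        n = 4000
        res_flat = null_retention_fractions(wgd_reference, flat,
                                            np.random.default_rng(1), n)
        res_uni = null_retention_fractions(wgd_reference, uni,
                                           np.random.default_rng(2), n)
        for cat in (TF, ENZYME):
            a, b = res_flat["fractions"][cat][1], res_uni["fractions"][cat][1]
            se = (res_uni["sd"][cat][1] + res_flat["sd"][cat][1]) / math.sqrt(n)
            assert abs(a - b) < 4 * max(se, 1e-3)

    def test_spec_estimated_from_lod(self, rng):
        g = stamp_ancestry(random_genome(rng, n_genes=12))
        ref, _ = whole_genome_duplicate(g)
        lod = make_synthetic_lod(ref, [(200, [("deletion", 0, 3)]),
                                       (1400, [("deletion", 0, 2)])],
                                 final_generation=2000)
        spec = null_spec_from_lod(ref, lod, 0, mode=CONNECTIVITY,
                                  bin_width=1000)
        counts = deletion_counts_from_lod(ref, lod, 0, 1000)
        assert spec.deletion_counts == tuple(counts)
        total_lost = sum(sum(c.values()) for c in counts)
        assert total_lost == len(surviving_members(ref, ref)) - len(
            surviving_members(ref, lod.final_genome))


class TestDivergence:
    def test_bs_conservation_identity_and_flip(self, rng):
        g = stamp_ancestry(random_genome(rng, n_genes=10))
        tfs = [x for x in g if x.category == TF]
        assert bs_conservation(tfs[0], tfs[0]) == 1
        motif = list(tfs[0].trait.binding_motif)
        motif[0] = 1 - motif[0]
        from dataclasses import replace
        changed = replace(tfs[0], trait=replace(tfs[0].trait,
                                                binding_motif=tuple(motif)))
        assert bs_conservation(tfs[0], changed) == 0
        with pytest.raises(TypeError):
            bs_conservation(tfs[0], next(x for x in g if x.category != TF))

    def test_relative_outdegree_arithmetic(self):
        outdeg = {0: 0, 1: 2, 2: 4}
        assert relative_outdegree(outdeg, [0, 1, 2], [2]) == pytest.approx(2.0)
        assert relative_outdegree(outdeg, [0, 1, 2], [0, 1, 2]) == 1.0
        assert relative_outdegree(outdeg, [0, 1, 2], [0]) < 1.0
        assert relative_outdegree(outdeg, [0, 1, 2], []) is None

    def test_divergence_rows_over_synthetic_lod(self, rng):
        ref, _ = whole_genome_duplicate(wired_genome())
        tf_gene = next(x for x in ref if x.category == TF)
        flipped = list(tf_gene.trait.binding_motif)
        flipped[0] = 1 - flipped[0]
        lod = make_synthetic_lod(ref, [
            (100, [("point", tf_gene.gene_id, "binding_motif", tuple(flipped))]),
        ], final_generation=1000)
        rows = divergence_over_lod(ref, lod, 0, rng, bin_width=1000)
        assert rows[0].bs_conservation["all_retained"] == 1.0
        n_tf = sum(1 for x in ref if x.category == TF)
        # one of n_tf member-representatives diverged
        assert rows[-1].bs_conservation["all_retained"] == pytest.approx(
            1 - 1 / n_tf)
        assert rows[-1].relative_outdegree["all_retained"] == pytest.approx(1.0)


class TestRankSum:
    def test_identical_groups_degenerate(self):
        with pytest.warns(UserWarning):
            _, p = rank_sum_compare([1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_separated_groups_exact_p(self):
        """(1,2,3) vs (4,5,6): U=0, exact two-sided p = 2/20 = 0.1."""
        u, p = rank_sum_compare([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_invariant_under_monotone_transform(self, rng):
        a = list(rng.normal(0, 1, 12))
        b = list(rng.normal(0.8, 1, 10))
        u1, p1 = rank_sum_compare(a, b)
        f = lambda xs: [math.exp(3 * x) + 1 for x in xs]
        u2, p2 = rank_sum_compare(f(a), f(b))
        assert u1 == u2 and p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_compare([], [1.0])
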