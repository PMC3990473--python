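"""Cell dynamics: TF activity, expression, ODE steady state, fitness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from virtualcell.dynamics import (CellState, EnvironmentParams, STANDARD_ENV,
                                  cell_fitness, derivatives, environment_score,
                                  expression_rate, initial_state, steady_state,
                                  tf_activity, CategoryError, SteadyStateResult)
from virtualcell.genome import (Gene, Genome, Promoter, TFTrait, EnzymeTrait,
                                PumpTrait, derive_network, TF, ENZYME, PUMP,
                                CATABOLIC, LIGAND_A, LIGAND_X)

L = 4


def make_tf(gene_id, ligand=LIGAND_X, k=0.5, eb=-1.0, ef=1.0,
            motif=(1, 0, 0, 0), operator=(0, 0, 0, 0), basal=0.3):
    return Gene(gene_id, TF, Promoter(operator, basal),
                TFTrait(ligand, motif, k, eb, ef))


def empty_genome():
    return Genome((), motif_length=L)


def constitutive_toy():
    """One pump + one catabolic enzyme, no TFs (expression = basal).

    The pump's energy cost exceeds the catabolic yield so X has a sink and
    the flux balance has a root (at A=0.5, X=0.3 under the standard
    environment).
    """
    pump = Gene(0, PUMP, Promoter((0,) * L, 0.3),
                PumpTrait(k_cat=1.0, K_Aext=1.0, K_X=0.3, energy_cost=2.0))
    cat = Gene(1, ENZYME, Promoter((0,) * L, 0.3),
               EnzymeTrait(CATABOLIC, k_cat=1.0, K_A=0.5))
    return Genome((pump, cat), motif_length=L)


class TestTFActivity:
    def test_half_saturation(self):
        tf = make_tf(0, ligand=LIGAND_A, k=0.5)
        bound, free = tf_activity(tf, CellState(0.5, 0.0, {}))
        assert bound == pytest.approx(0.5)
        assert free == pytest.approx(0.5)

    def test_zero_ligand_unbound(self):
        tf = make_tf(0, ligand=LIGAND_X, k=0.5)
        bound, _ = tf_activity(tf, CellState(9.0, 0.0, {}))
        assert bound == 0.0

    def test_three_k_gives_three_quarters(self):
        tf = make_tf(0, ligand=LIGAND_A, k=0.4)
        bound, _ = tf_activity(tf, CellState(1.2, 0.0, {}))
        assert bound == pytest.approx(1.2 / (1.2 + 0.4)) == pytest.approx(0.75)

    def test_non_tf_rejected(self):
        enzyme = constitutive_toy().genes[1]
        with pytest.raises(CategoryError):
            tf_activity(enzyme, CellState(1.0, 1.0, {}))


class TestExpressionRate:
    def test_no_regulators_gives_basal(self):
        g = constitutive_toy()
        net = derive_network(g)
        rate = expression_rate(g.genes[0], g, net, CellState(1.0, 1.0, {0: 2.0}))
        assert rate == pytest.approx(0.3)

    def test_neutral_regulator_gives_basal(self):
        op = (1, 1, 1, 1)
        tf = make_tf(0, eb=0.0, ef=0.0)
        tf = Gene(0, TF, tf.promoter,
                  TFTrait(LIGAND_X, op, 0.5, 0.0, 0.0))
        target = Gene(1, ENZYME, Promoter(op, 0.7), EnzymeTrait(CATABOLIC, 1.0, 0.5))
        g = Genome((tf, target), motif_length=L)
        net = derive_network(g)
        state = CellState(1.0, 3.0, {0: 5.0, 1: 0.0})
        assert expression_rate(target, g, net, state) == pytest.approx(0.7)

    def test_two_regulators_hand_computed(self):
        """Two TFs sharing the operator compete for it: occupancies share
        one saturation denominator k_op + P1 + P2."""
        op = (1, 1, 1, 1)
        tf1 = Gene(0, TF, Promoter((0,) * L, 0.3),
                   TFTrait(LIGAND_X, op, 0.5, -2.0, 1.0))
        tf2 = Gene(1, TF, Promoter((0,) * L, 0.3),
                   TFTrait(LIGAND_A, op, 1.0, 0.5, -0.5))
        target = Gene(2, ENZYME, Promoter(op, 0.4), EnzymeTrait(CATABOLIC, 1.0, 0.5))
        g = Genome((tf1, tf2, target), motif_length=L)
        net = derive_network(g)
        state = CellState(A_int=1.0, X_int=0.5, protein={0: 1.0, 1: 3.0, 2: 0.0})
        denom = 1.0 + 1.0 + 3.0          # k_op + P1 + P2
        b1 = 0.5 / (0.5 + 0.5)
        w1 = (1.0 / denom) * (b1 * -2.0 + (1 - b1) * 1.0)
        b2 = 1.0 / (1.0 + 1.0)
        w2 = (3.0 / denom) * (b2 * 0.5 + (1 - b2) * -0.5)
        expected = 0.4 * math.exp(w1 + w2)
        assert expression_rate(target, g, net, state) == pytest.approx(expected)

    def test_single_regulator_matches_simple_saturation(self):
        """With one regulator the competitive form reduces to the familiar
        P/(P + k_op) occupancy."""
        op = (1, 1, 1, 1)
        tf = Gene(0, TF, Promoter((0,) * L, 0.3),
                  TFTrait(LIGAND_X, op, 0.5, -2.0, 1.0))
        target = Gene(1, ENZYME, Promoter(op, 0.4), EnzymeTrait(CATABOLIC, 1.0, 0.5))
        g = Genome((tf, target), motif_length=L)
        net = derive_network(g)
        state = CellState(A_int=1.0, X_int=0.5, protein={0: 2.0, 1: 0.0})
        b = 0.5 / (0.5 + 0.5)
        w = (2.0 / (2.0 + 1.0)) * (b * -2.0 + (1 - b) * 1.0)
        assert expression_rate(target, g, net, state) == \
            pytest.approx(0.4 * math.exp(w))


class TestDerivatives:
    def test_empty_genome_at_equilibrium(self):
        g = empty_genome()
        state = CellState(STANDARD_ENV.A_ext, 0.0, {})
        dA, dX, dP = derivatives(state, g, derive_network(g), STANDARD_ENV)
        assert dA == 0.0 and dX == 0.0 and dP == {}

    def test_saturated_catabolic_flux(self):
        cat = Gene(0, ENZYME, Promoter((0,) * L, 0.3),
                   EnzymeTrait(CATABOLIC, k_cat=2.0, K_A=0.01))
        g = Genome((cat,), motif_length=L)
        state = CellState(A_int=100.0, X_int=0.0, protein={0: 1.5})
        dA, dX, _ = derivatives(state, g, derive_network(g), STANDARD_ENV)
        sat_flux = 2.0 * 1.5 * 100.0 / (0.01 + 100.0)
        assert dX == pytest.approx(STANDARD_ENV.conversion_rate * sat_flux,
                                   rel=1e-12)
        assert dA == pytest.approx(
            STANDARD_ENV.permeability * (STANDARD_ENV.A_ext - 100.0) - sat_flux)


class TestSteadyState:
    def test_empty_genome_reaches_external_equilibrium(self):
        ss = steady_state(empty_genome(), STANDARD_ENV)
        assert ss.converged
        assert ss.state.A_int == pytest.approx(STANDARD_ENV.A_ext, rel=1e-6)
        assert ss.state.X_int == 0.0

    def test_deviation_zero_at_target(self):
        env = STANDARD_ENV.replace(target_A=STANDARD_ENV.A_ext, target_X=0.3)
        ss = steady_state(empty_genome(), env)
        assert ss.deviation_A == pytest.approx(0.0, abs=1e-6)

    def test_constitutive_protein_level(self):
        """With constant expression P converges to basal/degradation."""
        g = constitutive_toy()
        ss = steady_state(g, STANDARD_ENV)
        assert ss.converged
        for gid in (0, 1):
            assert ss.state.protein[gid] == pytest.approx(
                0.3 / STANDARD_ENV.degradation, rel=1e-5)

    def test_matches_root_finding_oracle(self):
        """Steady state of the pump+enzyme toy equals an independent
        nonlinear solve of the flux-balance equations to 1e-6 relative."""
        g = constitutive_toy()
        env = STANDARD_ENV
        ss = steady_state(g, env, tol=1e-11)
        P = 0.3 / env.degradation          # constitutive level, both genes

        def flux_balance(y):
            A, X = y
            v_p = 1.0 * P * (env.A_ext / (1.0 + env.A_ext)) * (X / (0.3 + X))
            v_c = 1.0 * P * (A / (0.5 + A))
            return [env.permeability * (env.A_ext - A) + v_p - v_c,
                    env.conversion_rate * v_c - 2.0 * v_p]

        root = optimize.fsolve(flux_balance, [env.A_ext, 0.1], full_output=False,
                               xtol=1e-12)
        assert ss.converged
        assert ss.state.A_int == pytest.approx(root[0], rel=1e-6)
        assert ss.state.X_int == pytest.approx(root[1], rel=1e-6)

    def test_step_size_independent(self):
        """Converged steady states agree across integrator step sizes."""
        g = constitutive_toy()
        a = steady_state(g, STANDARD_ENV, dt_max=0.2, tol=1e-11)
        b = steady_state(g, STANDARD_ENV, dt_max=0.02, tol=1e-11)
        assert a.converged and b.converged
        assert a.state.A_int == pytest.approx(b.state.A_int, rel=1e-6)
        assert a.state.X_int == pytest.approx(b.state.X_int, rel=1e-6)
        for gid in a.state.protein:
            assert a.state.protein[gid] == pytest.approx(
                b.state.protein[gid], rel=1e-6)

    @pytest.mark.parametrize("perm", [0.05, 0.3, 2.0])
    def test_diffusion_equilibrium_for_any_permeability(self, perm):
        env = STANDARD_ENV.replace(permeability=perm)
        ss = steady_state(empty_genome(), env)
        assert ss.converged
        assert ss.state.A_int == pytest.approx(env.A_ext, rel=1e-5)


class TestScores:
    def test_perfect_homeostasis_scores_one(self):
        ss = SteadyStateResult(CellState(0.3, 0.3, {}), True, False, 0.0, 0.0, 1.0)
        assert environment_score(ss) == 1.0

    def test_unit_deviation_halves_score(self):
        ss = SteadyStateResult(CellState(0.6, 0.3, {}), True, False, 1.0, 0.0, 0.5)
        assert environment_score(ss) == pytest.approx(0.5)

    def test_non_converged_scores_zero(self):
        ss = SteadyStateResult(CellState(0.3, 0.3, {}), False, False, 0.1, 0.1, 0.0)
        assert environment_score(ss) == 0.0

    def test_score_strictly_decreasing_in_deviation(self):
        devs = np.linspace(0, 3, 7)
        scores = [1.0 / (1.0 + d) for d in devs]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestCellFitness:
    def test_perfect_scores(self):
        assert cell_fitness([1.0, 1.0, 1.0]) == 1.0

    def test_geometric_mean(self):
        assert cell_fitness([0.25, 1.0]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cell_fitness([])

    def test_too_many_rejected(self):
        with pytest.raises(ValueError):
            cell_fitness([0.5] * 4)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=3),
           st.data())
    def test_monotone_in_each_score(self, scores, data):
        """Raising any single score never lowers fitness."""
        i = data.draw(st.integers(0, len(scores) - 1))
        bump = data.draw(st.floats(0.0, 1.0 - scores[i]))
        bumped = list(scores)
        bumped[i] = scores[i] + bump
        assert cell_fitness(bumped) >= cell_fitness(scores) - 1e-12
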