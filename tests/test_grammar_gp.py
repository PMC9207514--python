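"""Grammar construction, tree generation, and the genetic operators."""

import numpy as np
import pytest

import fntscreen.fnt_core as fc
import fntscreen.grammar_gp as gg
from fntscreen.errors import ConfigError


def leaf_multiset(tree):
    out = []

    def walk(node):
        if not node.children and node.production is None:
            out.append(node.symbol)
        for c in node.children:
            walk(c)

    walk(tree)
    return sorted(out)


def test_default_grammar_symbol_sets():
    g = gg.build_default_grammar({2, 3}, 4)
    assert g.nonterminals == frozenset({"s", "exp", "var", "op2", "op3"})
    assert g.terminals == frozenset({"+2", "+3", "x1", "x2", "x3", "x4"})
    assert g.start == "s"
    assert not (g.nonterminals & g.terminals)


def test_experiment_arity_set_yields_one_rule_per_arity():
    g = gg.build_default_grammar({2, 3, 4, 5}, 8)
    exp_op_rules = [p for p in g.rules_for("exp") if p.rhs != ("var",)]
    assert len(exp_op_rules) == 4
    assert {p.rhs[0] for p in exp_op_rules} == {"op2", "op3", "op4", "op5"}


def test_empty_arity_set_rejected():
    with pytest.raises(ConfigError):
        gg.build_default_grammar(set(), 4)


def test_depth2_arity2_forces_unique_shape():
    # with one arity and depth budget 2, the only legal tree is +2 over terminals
    g = gg.build_default_grammar({2}, 2)
    rng = np.random.default_rng(0)
    for _ in range(20):
        t = gg.random_derivation(g, 2, rng)
        assert gg.induced_depth(t) == 2
        model = gg.derivation_to_fnt(t, 2, (-1, 1), rng)
        assert model.root.kind == "operator"
        assert all(c.kind == "terminal" for c in model.root.children)


def test_generation_respects_depth_bound():
    g = gg.build_default_grammar({2, 3, 4, 5}, 8)
    rng = np.random.default_rng(1)
    for _ in range(300):
        t = gg.random_derivation(g, 5, rng)
        assert 2 <= gg.induced_depth(t) <= 5


def test_generation_deterministic_per_seed():
    g = gg.build_default_grammar({2, 3}, 5)
    t1 = gg.random_derivation(g, 5, np.random.default_rng(99))
    t2 = gg.random_derivation(g, 5, np.random.default_rng(99))
    assert gg.to_sexpr(t1) == gg.to_sexpr(t2)


def test_derivation_to_fnt_valid_and_deterministic():
    g = gg.build_default_grammar({2, 3}, 6)
    for seed in range(50):
        rng = np.random.default_rng(seed)
        t = gg.random_derivation(g, 5, rng)
        m = gg.derivation_to_fnt(t, 6, (-1, 1), rng)
        m.validate()
        assert fc.tree_depth(m) == gg.induced_depth(t) <= 5
    rng_a, rng_b = np.random.default_rng(7), np.random.default_rng(7)
    ta = gg.random_derivation(g, 5, rng_a)
    tb = gg.random_derivation(g, 5, rng_b)
    ma = gg.derivation_to_fnt(ta, 6, (-1, 1), rng_a)
    mb = gg.derivation_to_fnt(tb, 6, (-1, 1), rng_b)
    assert np.array_equal(fc.extract_parameters(ma), fc.extract_parameters(mb))


def test_crossover_identical_parents_is_identity():
    g = gg.build_default_grammar({2, 3}, 4)
    rng = np.random.default_rng(2)
    t = gg.random_derivation(g, 5, rng)
    o1, o2 = gg.crossover(t, t, g, 5, np.random.default_rng(0))
    assert gg.to_sexpr(o1) == gg.to_sexpr(t)
    assert gg.to_sexpr(o2) == gg.to_sexpr(t)


def test_crossover_conserves_leaf_material_and_depth():
    g = gg.build_default_grammar({2, 3}, 4)
    rng = np.random.default_rng(3)
    for _ in range(200):
        t1 = gg.random_derivation(g, 5, rng)
        t2 = gg.random_derivation(g, 5, rng)
        o1, o2 = gg.crossover(t1, t2, g, 5, rng)
        assert gg.induced_depth(o1) <= 5 and gg.induced_depth(o2) <= 5
        # the swap conserves the combined leaf multiset unless an offspring
        # was rejected for depth and replaced by its (unswapped) parent
        both_swapped = gg.to_sexpr(o1) != gg.to_sexpr(t1) and gg.to_sexpr(
            o2
        ) != gg.to_sexpr(t2)
        if both_swapped:
            assert sorted(leaf_multiset(o1) + leaf_multiset(o2)) == sorted(
                leaf_multiset(t1) + leaf_multiset(t2)
            )
        for o in (o1, o2):
            gg.derivation_to_fnt(o, 4, (-1, 1), rng).validate()


def test_mutation_valid_within_depth_and_deterministic():
    g = gg.build_default_grammar({2, 3}, 4)
    rng = np.random.default_rng(4)
    for _ in range(200):
        t = gg.random_derivation(g, 5, rng)
        m = gg.mutate(t, g, 5, rng)
        assert gg.induced_depth(m) <= 5
        gg.derivation_to_fnt(m, 4, (-1, 1), rng).validate()
    t = gg.random_derivation(g, 5, np.random.default_rng(5))
    m1 = gg.mutate(t, g, 5, np.random.default_rng(6))
    m2 = gg.mutate(t, g, 5, np.random.default_rng(6))
    assert gg.to_sexpr(m1) == gg.to_sexpr(m2)


def test_tournament_selection_single_and_ties():
    g = gg.build_default_grammar({2}, 2)
    rng = np.random.default_rng(0)
    t = gg.random_derivation(g, 3, rng)
    assert gg.select_parent([(t, 1.0)], rng) is t
    # equal fitness: tie broken by population index inside the tournament
    pop = [(gg.random_derivation(g, 3, rng), 0.5) for _ in range(5)]
    winner = gg.select_parent(pop, np.random.default_rng(1), tournament_size=5)
    assert winner is pop[0][0]


def test_elite_survives_every_generation(blobs):
    import fntscreen.hybrid_trainer as ht

    X, y = blobs
    cfg = ht.TrainConfig(
        population_size=6, gp_generations=4, ssa_iterations_screen=3,
        ssa_population_screen=3, ssa_iterations_final=3, seed=21,
    )
    tm = ht.train(X, y, cfg)
    trace = tm.fitness_trace
    assert all(trace[i + 1] <= trace[i] + 1e-12 for i in range(len(trace) - 1))
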