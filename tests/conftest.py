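import numpy as np
import pytest

import fntscreen as fs
import fntscreen.fnt_core as fnt_core
import fntscreen.grammar_gp as grammar_gp


def random_model(rng: np.random.Generator, input_dim: int = 5,
                 max_depth: int = 4, arities=(2, 3)) -> fnt_core.FNTModel:
    """A random tree for oracle comparisons."""
    grammar = grammar_gp.build_default_grammar(set(arities), input_dim)
    tree = grammar_gp.random_derivation(grammar, max_depth, rng)
    return grammar_gp.derivation_to_fnt(tree, input_dim, (-1.0, 1.0), rng)


def oracle_evaluate(node: fnt_core.FNTNode, x) -> float:
    """Independent scalar recursive evaluator (pure Python, no numpy ops)."""
    import math

    if node.kind == "terminal":
        return float(x[node.feature_index])
    net = 0.0
    for w, child in zip(node.weights, node.children):
        net += float(w) * oracle_evaluate(child, x)
    z = (net - float(node.a)) / float(node.b)
    return math.exp(-z * z)


@pytest.fixture(scope="session")
def blobs():
    fm, y = fs.make_continuous_blobs(fs.BlobSpec(n_pos=60, n_neg=60, d=8, seed=7))
    return fm.matrix, y


@pytest.fixture(scope="session")
def trained_blobs(blobs):
    """One shared hybrid-training run on the separable-blobs fixture."""
    X, y = blobs
    cfg = fs.TrainConfig(seed=11, gp_generations=10, ssa_iterations_screen=20)
    return fs.train(X, y, cfg), X, y, cfg
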