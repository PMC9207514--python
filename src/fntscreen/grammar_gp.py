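"""Grammar-guided genetic programming over flexible neural tree structures.

Candidate topologies are derivation trees of a small context-free grammar
G = {N, T, P, S}: non-terminals N = {s, exp, var, op_k...}, terminals
T = {+_k...} U {x_1..x_n}, start symbol s, and prefix productions

    s    -> exp
    exp  -> op_k exp^k      (one rule per admissible arity k)
    exp  -> var
    op_k -> +_k
    var  -> x_i             (one rule per input feature)

Because every genetic operator (generation, crossover, mutation) manipulates
derivation trees and re-derives through the grammar, all offspring are
syntactically valid by construction; a depth bound on the induced FNT is
enforced by rejection, mirroring the generate-and-discard scheme of the
underlying neuroevolution method.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import fnt_core
from .errors import ConfigError, GenerationError, InputError

__all__ = [
    "Production",
    "Grammar",
    "DerivationNode",
    "build_default_grammar",
    "random_derivation",
    "induced_depth",
    "derivation_to_fnt",
    "crossover",
    "mutate",
    "select_parent",
    "to_sexpr",
]

#: Retry budget for rejection sampling of depth-bounded derivations.
MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class Production:
    lhs: str
    rhs: tuple[str, ...]


@dataclass
class Grammar:
    """Context-free grammar quadruple {N, T, P, start}."""

    nonterminals: frozenset[str]
    terminals: frozenset[str]
    productions: list[Production]
    start: str

    def validate(self) -> None:
        if self.nonterminals & self.terminals:
            raise ConfigError("non-terminal and terminal sets must be disjoint")
        if self.start not in self.nonterminals:
            raise ConfigError("start symbol must be a non-terminal")
        for p in self.productions:
            if p.lhs not in self.nonterminals:
                raise ConfigError(f"production lhs {p.lhs!r} is not a non-terminal")
            for s in p.rhs:
                if s not in self.nonterminals and s not in self.terminals:
                    raise ConfigError(f"unknown symbol {s!r} in production rhs")

    def rules_for(self, symbol: str) -> list[Production]:
        return [p for p in self.productions if p.lhs == symbol]


@dataclass
class DerivationNode:
    """A node of a derivation tree: symbol, applied production, children."""

    symbol: str
    production: Production | None = None  # None for terminal leaves
    children: list["DerivationNode"] = field(default_factory=list)


def build_default_grammar(arities: set[int] | tuple[int, ...], n_features: int) -> Grammar:
    """Construct the FNT grammar for the given operator arities and features."""
    arities = sorted(set(arities))
    if not arities:
        raise ConfigError("arity set must be non-empty")
    if any(k < 2 or k > 8 for k in arities):
        raise ConfigError(f"arities must lie in 2..8, got {arities}")
    if n_features < 1:
        raise ConfigError("n_features must be >= 1")

    nonterminals = {"s", "exp", "var"} | {f"op{k}" for k in arities}
    terminals = {f"+{k}" for k in arities} | {f"x{i}" for i in range(1, n_features + 1)}
    productions = [Production("s", ("exp",))]
    for k in arities:
        productions.append(Production("exp", (f"op{k}",) + ("exp",) * k))
    productions.append(Production("exp", ("var",)))
    for k in arities:
        productions.append(Production(f"op{k}", (f"+{k}",)))
    for i in range(1, n_features + 1):
        productions.append(Production("var", (f"x{i}",)))

    g = Grammar(frozenset(nonterminals), frozenset(terminals), productions, "s")
    g.validate()
    return g


# ---------------------------------------------------------------------------
# Random generation (top-down, left-right, rejection on depth overflow)


class _DepthOverflow(Exception):
    pass


def _expand(
    grammar: Grammar,
    symbol: str,
    level: int,
    max_depth: int,
    rng: np.random.Generator,
    force_operator: bool,
) -> DerivationNode:
    """Derive `symbol` occupying FNT level `level`; raise on depth overflow.

    `exp` nodes either become an operator (children occupy level + 1) or a
    single terminal feature at the current level.
    """
    if symbol in grammar.terminals:
        return DerivationNode(symbol=symbol)
    if level > max_depth:
        raise _DepthOverflow

    rules = grammar.rules_for(symbol)
    if symbol == "exp":
        if force_operator:
            rules = [p for p in rules if p.rhs != ("var",)]
        prod = rules[rng.integers(len(rules))]
        node = DerivationNode(symbol=symbol, production=prod)
        if prod.rhs == ("var",):
            node.children = [_expand(grammar, "var", level, max_depth, rng, False)]
        else:
            # operator expansion: op_k marker + k child expressions one level down
            op_sym = prod.rhs[0]
            node.children = [_expand(grammar, op_sym, level, max_depth, rng, False)]
            for child_sym in prod.rhs[1:]:
                node.children.append(
                    _expand(grammar, child_sym, level + 1, max_depth, rng, False)
                )
        return node

    prod = rules[rng.integers(len(rules))]
    node = DerivationNode(symbol=symbol, production=prod)
    node.children = [
        _expand(grammar, s, level, max_depth, rng, False) for s in prod.rhs
    ]
    return node


def random_derivation(
    grammar: Grammar, max_depth: int, rng: np.random.Generator
) -> DerivationNode:
    """Draw a random derivation whose induced FNT depth is <= max_depth.

    The root expression is forced to expand into an operator (the output
    neuron). Trees that overflow the depth bound during top-down derivation
    are discarded and regenerated, up to :data:`MAX_REJECTIONS` attempts.
    """
    if max_depth < 2:
        raise ConfigError("max_depth must be >= 2 (operator over terminals)")
    for _ in range(MAX_REJECTIONS):
        try:
            exp = _expand(grammar, "exp", 1, max_depth, rng, force_operator=True)
        except _DepthOverflow:
            continue
        root = DerivationNode(
            symbol="s", production=Production("s", ("exp",)), children=[exp]
        )
        return root
    raise GenerationError(
        f"failed to generate a depth-<= {max_depth} tree in "
        f"{MAX_REJECTIONS} attempts; grammar/depth misconfigured?"
    )


def induced_depth(tree: DerivationNode) -> int:
    """Depth of the FNT this derivation induces (root operator = level 1)."""

    def depth_of_exp(node: DerivationNode) -> int:
        assert node.symbol == "exp"
        if node.production is not None and node.production.rhs == ("var",):
            return 1
        return 1 + max(depth_of_exp(c) for c in node.children if c.symbol == "exp")

    exp = tree.children[0] if tree.symbol == "s" else tree
    return depth_of_exp(exp)


# ---------------------------------------------------------------------------
# Genotype -> phenotype


def _exp_to_fnt_node(
    node: DerivationNode,
    init_bounds: tuple[float, float],
    rng: np.random.Generator,
) -> fnt_core.FNTNode:
    assert node.symbol == "exp" and node.production is not None
    low, high = init_bounds
    if node.production.rhs == ("var",):
        var_node = node.children[0]
        leaf = var_node.children[0]  # terminal x_i
        index = int(leaf.symbol[1:]) - 1
        return fnt_core.FNTNode(kind="terminal", feature_index=index)
    children = [
        _exp_to_fnt_node(c, init_bounds, rng)
        for c in node.children
        if c.symbol == "exp"
    ]
    n = len(children)
    b = float(rng.uniform(low, high))
    while abs(b) < fnt_core.B_EPSILON:
        b = float(rng.uniform(low, high))
    return fnt_core.FNTNode(
        kind="operator",
        children=children,
        weights=rng.uniform(low, high, size=n),
        a=float(rng.uniform(low, high)),
        b=b,
    )


def derivation_to_fnt(
    tree: DerivationNode,
    input_dim: int,
    init_bounds: tuple[float, float],
    rng: np.random.Generator,
) -> fnt_core.FNTModel:
    """Read the FNT topology off a derivation tree with random parameters."""
    exp = tree.children[0] if tree.symbol == "s" else tree
    root = _exp_to_fnt_node(exp, init_bounds, rng)
    model = fnt_core.FNTModel(root=root, input_dim=input_dim)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Genetic operators


def _collect_nonterminal_nodes(
    tree: DerivationNode, grammar: Grammar, include_root: bool = False
) -> list[DerivationNode]:
    out: list[DerivationNode] = []

    def walk(node: DerivationNode, is_root: bool) -> None:
        if node.symbol in grammar.nonterminals and (include_root or not is_root):
            out.append(node)
        for c in node.children:
            walk(c, False)

    walk(tree, True)
    return out


def crossover(
    t1: DerivationNode,
    t2: DerivationNode,
    grammar: Grammar,
    max_depth: int,
    rng: np.random.Generator,
) -> tuple[DerivationNode, DerivationNode]:
    """Swap two subtrees rooted at a shared non-terminal label.

    An offspring whose induced depth exceeds max_depth is discarded and its
    parent returned unchanged; parents are never modified in place.
    """
    o1, o2 = copy.deepcopy(t1), copy.deepcopy(t2)
    nodes1 = _collect_nonterminal_nodes(o1, grammar)
    nodes2 = _collect_nonterminal_nodes(o2, grammar)
    labels = sorted({n.symbol for n in nodes1} & {n.symbol for n in nodes2})
    if not labels:
        return copy.deepcopy(t1), copy.deepcopy(t2)
    label = labels[rng.integers(len(labels))]
    cands1 = [n for n in nodes1 if n.symbol == label]
    cands2 = [n for n in nodes2 if n.symbol == label]
    a = cands1[rng.integers(len(cands1))]
    b = cands2[rng.integers(len(cands2))]
    a.production, b.production = b.production, a.production
    a.children, b.children = b.children, a.children
    if not _valid_offspring(o1, max_depth):
        o1 = copy.deepcopy(t1)
    if not _valid_offspring(o2, max_depth):
        o2 = copy.deepcopy(t2)
    return o1, o2


def _valid_offspring(tree: DerivationNode, max_depth: int) -> bool:
    """Depth within budget and root expression still an operator."""
    root_exp = tree.children[0] if tree.symbol == "s" else tree
    if root_exp.production is not None and root_exp.production.rhs == ("var",):
        return False
    return induced_depth(tree) <= max_depth


def _node_level(tree: DerivationNode, target: DerivationNode) -> int:
    """FNT level occupied by the subtree rooted at `target` (root exp = 1)."""

    def search(node: DerivationNode, level: int) -> int | None:
        if node is target:
            return level
        for c in node.children:
            child_level = level
            if node.symbol == "exp" and c.symbol == "exp":
                child_level = level + 1
            found = search(c, child_level)
            if found is not None:
                return found
        return None

    start = tree.children[0] if tree.symbol == "s" else tree
    level = search(start, 1)
    if level is None:
        raise InputError("target node not found in tree")
    return level


def mutate(
    tree: DerivationNode,
    grammar: Grammar,
    max_depth: int,
    rng: np.random.Generator,
) -> DerivationNode:
    """Regrow a uniformly chosen non-terminal subtree within the depth budget."""
    mutant = copy.deepcopy(tree)
    nodes = _collect_nonterminal_nodes(mutant, grammar)
    target = nodes[rng.integers(len(nodes))]
    level = _node_level(mutant, target)
    root_exp = mutant.children[0] if mutant.symbol == "s" else mutant
    force_op = target is root_exp
    for _ in range(MAX_REJECTIONS):
        try:
            fresh = _expand(grammar, target.symbol, level, max_depth, rng, force_op)
        except _DepthOverflow:
            continue
        target.production = fresh.production
        target.children = fresh.children
        return mutant
    raise GenerationError("mutation failed to regrow a valid subtree")


def select_parent(
    population: list[tuple[DerivationNode, float]],
    rng: np.random.Generator,
    tournament_size: int = 3,
) -> DerivationNode:
    """Tournament selection (lower fitness = better; ties by population index)."""
    if not population:
        raise InputError("cannot select from an empty population")
    k = min(tournament_size, len(population))
    idx = rng.choice(len(population), size=k, replace=False)
    best = min(idx, key=lambda i: (population[int(i)][1], int(i)))
    return population[int(best)][0]


def to_sexpr(tree: DerivationNode) -> str:
    """S-expression rendering of the induced FNT topology, for logs."""

    def render(node: DerivationNode) -> str:
        if node.symbol == "s":
            return render(node.children[0])
        if node.symbol == "exp":
            if node.production is not None and node.production.rhs == ("var",):
                return node.children[0].children[0].symbol
            op = node.children[0].children[0].symbol
            kids = " ".join(render(c) for c in node.children if c.symbol == "exp")
            return f"({op} {kids})"
        return node.symbol

    return render(tree)
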