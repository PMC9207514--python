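"""Flexible neural trees (FNTs): representation, evaluation, parameter I/O.

A flexible neural tree is a tree-shaped neural network with variable
topology. Leaves are *terminal* nodes that emit one input feature each;
internal nodes are *flexible neuron operators* ``+_n`` of arity ``n`` that
compute a weighted sum of their children

    net = sum_j w_j * child_j

followed by a two-parameter Gaussian activation

    y = exp(-((net - a) / b)**2)

so every operator output lies in ``(0, 1]``. The root is always an operator
(the single output neuron); its output is the classifier score. Topology is
searched by grammar-guided genetic programming (:mod:`fntscreen.grammar_gp`)
and the continuous parameters ``(w_1..w_n, a, b)`` of every operator are
tuned by the salp swarm optimizer (:mod:`fntscreen.ssa`); to that end this
module flattens all parameters into a single vector in a fixed pre-order
layout and injects them back losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = [
    "FNTNode",
    "FNTModel",
    "evaluate",
    "evaluate_batch",
    "predict_label",
    "extract_parameters",
    "inject_parameters",
    "parameter_count",
    "tree_depth",
    "model_to_json",
    "model_from_json",
]

#: Smallest admissible magnitude for the activation width ``b`` (it sits in a
#: denominator); injected values closer to zero are pushed to this epsilon.
B_EPSILON = 1e-8

FORMAT_TAG = "fntscreen-model/1"


@dataclass
class FNTNode:
    """One node of a flexible neural tree.

    ``kind`` is ``"operator"`` or ``"terminal"``. A terminal carries only
    ``feature_index``; an operator carries ``children`` (arity n >= 2),
    ``weights`` (length n), and the activation parameters ``a`` and ``b``.
    """

    kind: str
    feature_index: int = -1
    children: list["FNTNode"] = field(default_factory=list)
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    a: float = 0.0
    b: float = 1.0

    @property
    def arity(self) -> int:
        return len(self.children)

    def validate(self, input_dim: int) -> None:
        if self.kind == "terminal":
            if self.children or len(np.atleast_1d(self.weights)):
                raise InputError("terminal node must have no children/weights")
            if not (0 <= self.feature_index < input_dim):
                raise InputError(
                    f"feature_index {self.feature_index} out of range "
                    f"for input_dim {input_dim}"
                )
        elif self.kind == "operator":
            if self.arity < 2:
                raise InputError(f"operator arity must be >= 2, got {self.arity}")
            if len(self.weights) != self.arity:
                raise InputError(
                    f"operator has {self.arity} children but "
                    f"{len(self.weights)} weights"
                )
            if self.b == 0:
                raise InputError("activation width b must be non-zero")
            for child in self.children:
                child.validate(input_dim)
        else:
            raise InputError(f"unknown node kind {self.kind!r}")


@dataclass
class FNTModel:
    """A flexible neural tree classifier: root operator + input dimension."""

    root: FNTNode
    input_dim: int
    max_depth: int = 0  # 0 = unconstrained record; checked only if > 0

    def validate(self) -> None:
        if self.root.kind != "operator":
            raise InputError("FNT root must be an operator node")
        self.root.validate(self.input_dim)
        if self.max_depth > 0 and tree_depth(self) > self.max_depth:
            raise InputError(
                f"tree depth {tree_depth(self)} exceeds max_depth {self.max_depth}"
            )

    def copy(self) -> "FNTModel":
        return FNTModel(_copy_node(self.root), self.input_dim, self.max_depth)


def _copy_node(node: FNTNode) -> FNTNode:
    if node.kind == "terminal":
        return FNTNode(kind="terminal", feature_index=node.feature_index)
    return FNTNode(
        kind="operator",
        children=[_copy_node(c) for c in node.children],
        weights=np.array(node.weights, dtype=float),
        a=float(node.a),
        b=float(node.b),
    )


# ---------------------------------------------------------------------------
# Evaluation


def _eval_node(node: FNTNode, X: np.ndarray) -> np.ndarray:
    """Bottom-up evaluation of one subtree over all rows of X at once."""
    if node.kind == "terminal":
        return X[:, node.feature_index]
    net = np.zeros(X.shape[0])
    for w, child in zip(node.weights, node.children):
        net += w * _eval_node(child, X)
    z = (net - node.a) / node.b
    return np.exp(-(z * z))


def evaluate_batch(model: FNTModel, X: np.ndarray) -> np.ndarray:
    """Evaluate the tree on every row of an (n_samples, input_dim) matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise InputError(
            f"expected matrix with {model.input_dim} columns, got shape {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise InputError("input matrix contains non-finite values")
    return _eval_node(model.root, X)


def evaluate(model: FNTModel, x: np.ndarray) -> float:
    """Evaluate the tree on a single input vector; returns the root output.

    The root is an operator, so the result is in ``(0, 1]``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != model.input_dim:
        raise InputError(
            f"expected vector of length {model.input_dim}, got shape {x.shape}"
        )
    return float(evaluate_batch(model, x[None, :])[0])


def predict_label(model: FNTModel, x: np.ndarray, threshold: float = 0.5) -> int:
    """Binary decision: 1 (related) iff the score is strictly above threshold."""
    return int(evaluate(model, x) > threshold)


# ---------------------------------------------------------------------------
# Parameter flattening (pre-order: per operator node, weights then a then b)


def _operator_nodes(node: FNTNode) -> list[FNTNode]:
    """All operator nodes in pre-order (node before its children)."""
    if node.kind == "terminal":
        return []
    out = [node]
    for child in node.children:
        out.extend(_operator_nodes(child))
    return out


def parameter_count(model: FNTModel) -> int:
    return sum(op.arity + 2 for op in _operator_nodes(model.root))


def extract_parameters(model: FNTModel) -> np.ndarray:
    """Flatten all tunable parameters into one vector.

    Layout: operator nodes in pre-order; for each, its ``n`` weights followed
    by ``a`` then ``b``. Round-trips losslessly through
    :func:`inject_parameters`.
    """
    parts: list[np.ndarray] = []
    for op in _operator_nodes(model.root):
        parts.append(np.asarray(op.weights, dtype=float))
        parts.append(np.array([op.a, op.b], dtype=float))
    return np.concatenate(parts) if parts else np.empty(0)


def inject_parameters(
    model: FNTModel, values: np.ndarray, inplace: bool = False
) -> FNTModel:
    """Write a flat parameter vector back into the tree (pre-order layout).

    Any ``b`` with magnitude below :data:`B_EPSILON` is pushed to
    ``+/-B_EPSILON`` so the Gaussian activation stays finite.
    """
    values = np.asarray(values, dtype=float)
    expected = parameter_count(model)
    if values.shape != (expected,):
        raise InputError(
            f"parameter vector length {values.shape} does not match "
            f"model parameter count {expected}"
        )
    target = model if inplace else model.copy()
    pos = 0
    for op in _operator_nodes(target.root):
        n = op.arity
        op.weights = values[pos : pos + n].copy()
        op.a = float(values[pos + n])
        b = float(values[pos + n + 1])
        if abs(b) < B_EPSILON:
            b = B_EPSILON if b >= 0 else -B_EPSILON
        op.b = b
        pos += n + 2
    return target


# ---------------------------------------------------------------------------
# Depth and serialization


def _node_depth(node: FNTNode) -> int:
    if node.kind == "terminal":
        return 1
    return 1 + max(_node_depth(c) for c in node.children)


def tree_depth(model: FNTModel) -> int:
    """Number of node levels; a root operator over terminals has depth 2."""
    return _node_depth(model.root)


def _node_to_dict(node: FNTNode) -> dict:
    if node.kind == "terminal":
        return {"kind": "terminal", "feature_index": node.feature_index}
    return {
        "kind": "operator",
        "arity": node.arity,
        "weights": [float(w) for w in node.weights],
        "a": node.a,
        "b": node.b,
        "children": [_node_to_dict(c) for c in node.children],
    }


def _node_from_dict(d: dict) -> FNTNode:
    if d["kind"] == "terminal":
        return FNTNode(kind="terminal", feature_index=int(d["feature_index"]))
    return FNTNode(
        kind="operator",
        children=[_node_from_dict(c) for c in d["children"]],
        weights=np.asarray(d["weights"], dtype=float),
        a=float(d["a"]),
        b=float(d["b"]),
    )


def model_to_json(model: FNTModel) -> str:
    doc = {
        "format": FORMAT_TAG,
        "input_dim": model.input_dim,
        "max_depth": model.max_depth,
        "root": _node_to_dict(model.root),
    }
    return json.dumps(doc, indent=2)


def model_from_json(text: str) -> FNTModel:
    doc = json.loads(text)
    if doc.get("format") != FORMAT_TAG:
        raise InputError(f"unrecognized model format tag {doc.get('format')!r}")
    model = FNTModel(
        root=_node_from_dict(doc["root"]),
        input_dim=int(doc["input_dim"]),
        max_depth=int(doc.get("max_depth", 0)),
    )
    model.validate()
    return model
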