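"""Flexible neural tree evaluation, parameter layout, serialization."""

import math

import numpy as np
import pytest

import fntscreen.fnt_core as fc
from fntscreen.errors import InputError

from conftest import oracle_evaluate, random_model


def two_input_tree(a=1.0, b=1.0, weights=(1.0, 1.0)):
    root = fc.FNTNode(
        kind="operator",
        children=[
            fc.FNTNode(kind="terminal", feature_index=0),
            fc.FNTNode(kind="terminal", feature_index=1),
        ],
        weights=np.asarray(weights, float),
        a=a,
        b=b,
    )
    return fc.FNTModel(root=root, input_dim=2)


def test_net_equal_a_gives_exactly_one():
    model = two_input_tree(a=1.0, b=1.0)
    assert fc.evaluate(model, [0.5, 0.5]) == 1.0


def test_gaussian_closed_form():
    model = two_input_tree(a=0.0, b=1.0)
    assert fc.evaluate(model, [0.5, 0.5]) == pytest.approx(math.exp(-1.0), abs=1e-12)


@pytest.mark.parametrize(
    "score,expected", [(0.51, 1), (0.50, 0), (0.49, 0)],
    ids=["above", "boundary-strict", "below"],
)
def test_predict_label_strict_threshold(score, expected, monkeypatch):
    model = two_input_tree()
    monkeypatch.setattr(fc, "evaluate", lambda m, x: score)
    assert fc.predict_label(model, [0.0, 0.0]) == expected


def test_matches_independent_recursive_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        model = random_model(rng)
        x = rng.random(model.input_dim)
        assert fc.evaluate(model, x) == pytest.approx(
            oracle_evaluate(model.root, x), abs=1e-12
        )


def test_operator_outputs_in_unit_interval():
    # Gaussian activation range; b kept away from 0 so exp(-z^2) cannot
    # underflow to exactly 0 in float64 on the [0,1] feature domain
    rng = np.random.default_rng(7)
    for _ in range(50):
        model = random_model(rng)
        n_params = fc.parameter_count(model)
        params = rng.uniform(-1, 1, n_params)
        pos = 0
        for op in fc._operator_nodes(model.root):
            params[pos + op.arity + 1] = rng.uniform(0.5, 1.0)  # b slot
            pos += op.arity + 2
        model = fc.inject_parameters(model, params)
        X = rng.random((20, model.input_dim))
        out = fc.evaluate_batch(model, X)
        assert np.all(out > 0) and np.all(out <= 1)


def test_dimension_mismatch_rejected():
    model = two_input_tree()
    with pytest.raises(InputError):
        fc.evaluate(model, [0.1, 0.2, 0.3])


def test_parameter_count_layout():
    # single +2 root over terminals: w1, w2, a, b
    assert fc.parameter_count(two_input_tree()) == 4
    # root +2 with a +3 child over terminals: (2+2) + (3+2)
    inner = fc.FNTNode(
        kind="operator",
        children=[fc.FNTNode(kind="terminal", feature_index=i) for i in range(3)],
        weights=np.ones(3), a=0.2, b=0.5,
    )
    root = fc.FNTNode(
        kind="operator",
        children=[inner, fc.FNTNode(kind="terminal", feature_index=3)],
        weights=np.ones(2), a=0.1, b=0.9,
    )
    assert fc.parameter_count(fc.FNTModel(root, input_dim=4)) == 9


def test_extract_inject_roundtrip_identity():
    rng = np.random.default_rng(3)
    model = random_model(rng)
    vec = fc.extract_parameters(model)
    restored = fc.inject_parameters(model, vec)
    assert np.array_equal(fc.extract_parameters(restored), vec)


def test_inject_transfers_behavior_between_same_topology_models():
    rng = np.random.default_rng(5)
    donor = two_input_tree(a=0.3, b=0.7, weights=(0.2, -0.9))
    recipient = two_input_tree(a=0.9, b=0.1, weights=(1.0, 1.0))
    recipient = fc.inject_parameters(recipient, fc.extract_parameters(donor))
    for _ in range(50):
        x = rng.random(2)
        assert fc.evaluate(recipient, x) == fc.evaluate(donor, x)


def test_inject_guards_zero_b():
    model = two_input_tree()
    injected = fc.inject_parameters(model, np.array([1.0, 1.0, 0.5, 0.0]))
    assert injected.root.b == fc.B_EPSILON
    assert np.isfinite(fc.evaluate(injected, [0.9, 0.9]))


def test_inject_length_mismatch_rejected():
    with pytest.raises(InputError):
        fc.inject_parameters(two_input_tree(), np.zeros(3))


def test_tree_depth():
    assert fc.tree_depth(two_input_tree()) == 2
    inner = fc.FNTNode(
        kind="operator",
        children=[fc.FNTNode(kind="terminal", feature_index=i) for i in range(2)],
        weights=np.ones(2), a=0.0, b=1.0,
    )
    root = fc.FNTNode(
        kind="operator",
        children=[inner, fc.FNTNode(kind="terminal", feature_index=2)],
        weights=np.ones(2), a=0.0, b=1.0,
    )
    assert fc.tree_depth(fc.FNTModel(root, input_dim=3)) == 3


def test_terminal_root_rejected():
    model = fc.FNTModel(
        root=fc.FNTNode(kind="terminal", feature_index=0), input_dim=1
    )
    with pytest.raises(InputError):
        model.validate()


def test_json_roundtrip_preserves_evaluation():
    rng = np.random.default_rng(17)
    model = random_model(rng)
    restored = fc.model_from_json(fc.model_to_json(model))
    x = rng.random(model.input_dim)
    assert fc.evaluate(restored, x) == fc.evaluate(model, x)


def test_json_rejects_unknown_format():
    with pytest.raises(InputError):
        fc.model_from_json('{"format": "something-else"}')
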