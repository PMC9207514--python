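"""Evaluate a hand-built flexible neural tree.

A flexible neuron operator computes net = sum(w_j * x_j) and then the
Gaussian activation y = exp(-((net - a)/b)^2), so its output peaks at 1
exactly when the weighted sum hits the center a.
"""

import numpy as np

from fntscreen.fnt_core import FNTModel, FNTNode, evaluate, predict_label, tree_depth

root = FNTNode(
    kind="operator",
    children=[
        FNTNode(kind="terminal", feature_index=0),
        FNTNode(kind="terminal", feature_index=1),
    ],
    weights=np.array([1.0, 1.0]),
    a=1.0,
    b=1.0,
)
model = FNTModel(root=root, input_dim=2)
model.validate()

print(f"tree depth: {tree_depth(model)}")
for x in ([0.5, 0.5], [0.2, 0.2], [0.9, 0.9]):
    score = evaluate(model, x)
    label = predict_label(model, x)
    print(f"x={x}  score={score:.6f}  related={bool(label)}")
# x=[0.5,0.5] gives net=1.0=a, hence the maximal score 1.0; scores fall off
# as the weighted sum moves away from the center, and the strict >0.5 rule
# turns the score into a related/unrelated call.
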