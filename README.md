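# fntscreen

Ligand-based virtual screening with **flexible neural trees** (FNTs): a
variable-topology neural classifier whose structure is evolved by
grammar-guided genetic programming (GGGP) and whose continuous parameters
are tuned by the salp swarm algorithm (SSA). The package is aimed at
cheminformatics practitioners who need to triage candidate compounds for a
disease — e.g. to narrow a network-pharmacology analysis — from a modest
set of known actives and a large decoy pool.

## The model

An FNT is a tree whose leaves emit input features `x_i` and whose internal
nodes are *flexible neuron operators* `+_n` of arity `n`. Each operator
computes a weighted sum of its children followed by a two-parameter
Gaussian activation:

```
net_n = Σ_j w_j · x_j
y     = exp(−((net_n − a_n) / b_n)²)        ∈ (0, 1]
```

The root operator's output is the classifier score; a compound is called
*disease-related* iff the score is strictly greater than 0.5.

Topology search uses a context-free grammar `G = {N, T, P, Σ}` with prefix
productions (`exp → op_k exp…exp | var`, `var → x_i`), so every tree
produced by generation, crossover, or mutation is syntactically valid and
respects the depth bound. Parameter search minimizes the RMSE of the tree's
continuous output against the 0/1 labels: one swarm leader explores around
the best-so-far ("food") position with convergence factor
`c1 = 2·exp(−(4t/T)²)`, while followers move to sequential midpoints down
the salp chain.

The pipeline around the classifier:

* **Featurization** (RDKit): ECFP6 (radius-3 circular fingerprint, 2048
  bits), the 166 MACCS keys, the RDKit 2D descriptor panel, or any
  precomputed CSV table (e.g. 1,613-column macrocycle descriptors).
* **Negative-sample selection**: each pool decoy is scored by its summed
  Tanimoto similarity `T(A,B) = |A∩B|/|A∪B|` to all `m` positives; the
  `ratio·m` least similar decoys (default ratio 2) become the negative
  class.
* **Evaluation**: TPR, FPR, precision, specificity, F1, rank-based AUC;
  stratified k-fold cross-validation; cross-dataset method ranking; a
  positive:negative ratio sweep.
* **Synthetic data**: seeded generators for fingerprint classes, decoy
  pools with a controlled similarity gradient, and separable Gaussian
  blobs, so the whole pipeline is testable without proprietary compound
  lists.

## Worked example

`examples/04_train_and_screen.py` trains on two seeded Gaussian blobs
(n = 120, d = 8) and screens the training set:

```
evolved structure: (+2 (+2 x1 x1) (+2 (+2 x1 x1) x1))
final RMSE fitness: 0.0657
training AUC: 1.0000
TPR 1.000  FPR 0.017  F1 0.992
```

The S-expression is the evolved topology (here the tree discovered that
feature `x1` — the informative axis of the blobs — suffices), the fitness
is the final RMSE of the tree's scores against the labels, and the metrics
summarize the strict `score > 0.5` decisions. The other scripts in
`examples/` demonstrate tree evaluation, the swarm optimizer, decoy
selection (67 positives → exactly 134 negatives at the default ratio),
SMILES featurization, and the imbalance sweep.

The same pipeline is scriptable from the shell:

```bash
fntscreen featurize --in actives.smi --descriptor maccs --out actives.csv
fntscreen select-decoys --positives actives.smi --pool pool.smi --ratio 2 --out negatives.txt
fntscreen cv --features labeled.csv --k 10 --seed 7 --out-dir cv_report/
```

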