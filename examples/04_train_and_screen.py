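"""Train the hybrid-evolved tree classifier on separable synthetic data.

Grammar-guided genetic programming proposes tree topologies; every
candidate gets a short salp-swarm polish of its weights and activation
parameters; the best structure then receives a deeper parameter run.
"""

from fntscreen import BlobSpec, TrainConfig, auc, make_continuous_blobs, predict, train
from fntscreen.evaluation import compute_metrics

fm, y = make_continuous_blobs(BlobSpec(n_pos=60, n_neg=60, d=8, separation=4.0, seed=7))
cfg = TrainConfig(seed=11, gp_generations=10, ssa_iterations_screen=20)
tm = train(fm.matrix, y, cfg)

scores, labels = predict(tm, fm.matrix)
report = compute_metrics(y, scores, cfg.threshold)

print(f"evolved structure: {tm.structure}")
print(f"final RMSE fitness: {tm.fitness_trace[-1]:.4f}")
print(f"training AUC: {auc(y, scores):.4f}")
print(f"TPR {report.tpr:.3f}  FPR {report.fpr:.3f}  F1 {report.f1:.3f}")
# The S-expression shows which features the evolved tree actually uses;
# on well-separated blobs the classifier should reach AUC near 1.
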