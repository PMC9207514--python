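"""Minimize a 2-D sphere function with the salp swarm algorithm.

One leader explores around the best-so-far ("food") position with a
convergence factor that decays from 2 to ~0; followers chain toward their
predecessor by sequential midpoints. The food-fitness trace is monotone.
"""

import numpy as np

from fntscreen.ssa import SSAConfig, run_ssa

cfg = SSAConfig(m=30, n=2, xmin=-5.0, xmax=5.0, T=200, seed=42)
result = run_ssa(lambda v: float(np.sum(v * v)), cfg)

print(f"best point:   {result.best}")
print(f"best fitness: {result.best_fitness:.3e}")
print(f"trace head:   {np.round(result.history[:5], 4)}")
print(f"monotone:     {bool(np.all(np.diff(result.history) <= 0))}")
# The swarm contracts onto the global minimum at the origin; the printed
# fitness is the squared distance from it (smaller is better).
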