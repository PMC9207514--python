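"""Select negative samples (decoys) least similar to a positive set.

Each pool decoy is scored by the sum of its Tanimoto similarities to every
positive compound; the 2m smallest sums become the negative class (a 1:2
positive:negative balance).
"""

import numpy as np

from fntscreen import (
    FingerprintSpec,
    make_decoy_pool,
    make_fingerprint_classes,
    select_negatives,
)

positives, _ = make_fingerprint_classes(FingerprintSpec(n_pos=67, n_neg=0, seed=1))
pool = make_decoy_pool(positives, pool_size=500, dissimilarity=0.1, rng=2)

sel = select_negatives(positives, pool, ratio=2)
chosen = sel.summed_similarity[sel.indices]
rest = np.delete(sel.summed_similarity, sel.indices)

print(f"positives m={len(positives)}, pool={len(pool)}, selected={len(sel.ids)}")
print(f"selected summed similarity: max {chosen.max():.3f}")
print(f"unselected summed similarity: min {rest.min():.3f}")
# 67 positives at the default ratio give exactly 134 negatives, and every
# selected decoy is no more similar to the actives than any unselected one.
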