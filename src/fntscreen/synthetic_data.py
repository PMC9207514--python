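"""Synthetic fixtures: fingerprint classes, decoy pools, separable blobs.

The screening study's compound lists are not deposited, so every stage of
the pipeline is exercised on generated data with the same structure:

* :func:`make_fingerprint_classes` — two classes of binary fingerprints
  drawn from per-class bit-probability profiles, giving controllable
  within- vs between-class Tanimoto similarity.
* :func:`make_decoy_pool` — a pool whose members span a gradient of summed
  similarity to a given positive set, so the least-similar-first selection
  has a non-trivial ordering to recover.
* :func:`make_continuous_blobs` — two Gaussian blobs in [0,1]^d with
  configurable separation, the training surface for the tree classifier.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoy_selection import Fingerprint, FingerprintSet
from .errors import ConfigError
from .featurization import FeatureMatrix

__all__ = [
    "FingerprintSpec",
    "BlobSpec",
    "make_fingerprint_classes",
    "make_decoy_pool",
    "make_continuous_blobs",
]


@dataclass
class FingerprintSpec:
    """Two-class binary fingerprint generator settings.

    Each class turns on bits independently: bits inside the class's
    "profile block" with probability ``p_on``, all other bits with the
    background probability ``p_background``. Distinct blocks give the
    classes distinct substructure vocabularies, like actives vs decoys.
    """

    n_pos: int = 50
    n_neg: int = 50
    n_bits: int = 128
    block_size: int = 24
    p_on: float = 0.6
    p_background: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bits < 8:
            raise ConfigError("n_bits must be >= 8")
        for p in (self.p_on, self.p_background):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("bit probabilities must lie in [0, 1]")
        if 2 * self.block_size > self.n_bits:
            raise ConfigError("two disjoint blocks must fit in n_bits")


def _draw_fingerprints(
    n: int, probs: np.ndarray, rng: np.random.Generator
) -> list[Fingerprint]:
    n_bits = len(probs)
    out = []
    for _ in range(n):
        on = np.nonzero(rng.random(n_bits) < probs)[0]
        out.append(Fingerprint(bits=frozenset(int(b) for b in on), n_bits=n_bits))
    return out


def make_fingerprint_classes(
    spec: FingerprintSpec,
) -> tuple[FingerprintSet, np.ndarray]:
    """Two fingerprint classes with disjoint high-probability bit blocks."""
    rng = np.random.default_rng(spec.seed)
    probs_pos = np.full(spec.n_bits, spec.p_background)
    probs_pos[: spec.block_size] = spec.p_on
    probs_neg = np.full(spec.n_bits, spec.p_background)
    probs_neg[spec.block_size : 2 * spec.block_size] = spec.p_on

    fps = _draw_fingerprints(spec.n_pos, probs_pos, rng)
    fps += _draw_fingerprints(spec.n_neg, probs_neg, rng)
    ids = [f"pos_{i}" for i in range(spec.n_pos)]
    ids += [f"neg_{i}" for i in range(spec.n_neg)]
    labels = np.concatenate([np.ones(spec.n_pos), np.zeros(spec.n_neg)]).astype(int)
    return FingerprintSet(ids=ids, fingerprints=fps), labels


def make_decoy_pool(
    positives: FingerprintSet,
    pool_size: int,
    dissimilarity: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> FingerprintSet:
    """Decoy pool with a graded distance from the positive set.

    Decoy ``i`` copies the bits of a random positive, then replaces a
    fraction ``f_i`` of them with bits the positives never use, where
    ``f_i`` ramps linearly from ``dissimilarity`` to 1 across the pool.
    ``dissimilarity=1`` therefore yields bit sets fully disjoint from every
    positive (summed Tanimoto similarity 0 for the whole pool), while small
    values produce the smooth ordering the selection algorithm sorts.
    """
    if pool_size < 1:
        raise ConfigError("pool_size must be >= 1")
    if not 0.0 <= dissimilarity <= 1.0:
        raise ConfigError("dissimilarity must lie in [0, 1]")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    n_bits = positives.n_bits
    used = sorted(set().union(*(fp.bits for fp in positives.fingerprints)))
    unused = np.array(sorted(set(range(n_bits)) - set(used)))
    if unused.size == 0:
        raise ConfigError("positives use every bit; cannot build dissimilar decoys")

    fractions = (
        np.linspace(dissimilarity, 1.0, pool_size)
        if pool_size > 1
        else np.array([dissimilarity])
    )

    fps = []
    for i in range(pool_size):
        donor = positives.fingerprints[int(rng.integers(len(positives)))]
        donor_bits = np.array(sorted(donor.bits))
        if donor_bits.size == 0:
            donor_bits = np.array([int(rng.integers(n_bits))])
        n_replace = int(round(fractions[i] * donor_bits.size))
        keep = donor_bits[
            rng.choice(donor_bits.size, donor_bits.size - n_replace, replace=False)
        ]
        fresh = unused[
            rng.choice(unused.size, min(n_replace, unused.size), replace=False)
        ]
        bits = frozenset(int(b) for b in np.concatenate([keep, fresh]))
        fps.append(Fingerprint(bits=bits, n_bits=n_bits))
    ids = [f"decoy_{i}" for i in range(pool_size)]
    return FingerprintSet(ids=ids, fingerprints=fps)


@dataclass
class BlobSpec:
    """Two Gaussian blobs in d dimensions, `separation` pooled-sd apart."""

    n_pos: int = 60
    n_neg: int = 60
    d: int = 8
    separation: float = 4.0
    sd: float = 1.0
    seed: int = 0


def make_continuous_blobs(spec: BlobSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Two isotropic Gaussian classes, min-max scaled into [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    mu_pos = np.zeros(spec.d)
    mu_pos[0] = spec.separation * spec.sd  # classes differ along axis 0
    X_pos = rng.normal(mu_pos, spec.sd, size=(spec.n_pos, spec.d))
    X_neg = rng.normal(np.zeros(spec.d), spec.sd, size=(spec.n_neg, spec.d))
    X = np.vstack([X_pos, X_neg])
    col_min, col_max = X.min(axis=0), X.max(axis=0)
    span = np.where(col_max > col_min, col_max - col_min, 1.0)
    X = (X - col_min) / span
    y = np.concatenate([np.ones(spec.n_pos), np.zeros(spec.n_neg)]).astype(int)
    ids = [f"c{i}" for i in range(len(y))]
    return FeatureMatrix(ids, "blobs", X), y
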