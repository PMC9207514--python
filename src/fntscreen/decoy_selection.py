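"""Tanimoto similarity and negative-sample (decoy) selection.

Virtual-screening classifiers need presumed-inactive compounds as negative
examples. Given a positive compound set and a large decoy pool (e.g. from
DUD-E), this module scores each decoy by its summed Tanimoto similarity to
all positives,

    T(A, B) = |A & B| / |A | B|     (bit sets of binary fingerprints)

and keeps the ``ratio * m`` decoys with the smallest sums (default ratio 2,
i.e. a 1:2 positive:negative class balance) — the pool members least like
any known active. Ties are broken by input order so the selection is
reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, SelectionError

__all__ = [
    "Fingerprint",
    "FingerprintSet",
    "tanimoto",
    "summed_similarity_profile",
    "select_negatives",
    "SelectionResult",
]


@dataclass(frozen=True)
class Fingerprint:
    """Binary fingerprint stored as the set of on-bit indices."""

    bits: frozenset[int]
    n_bits: int

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise InputError("fingerprint bit index out of range")


@dataclass
class FingerprintSet:
    """Parallel sequences of compound ids and fingerprints of shared width."""

    ids: list[str]
    fingerprints: list[Fingerprint]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.fingerprints):
            raise InputError("ids and fingerprints must have equal length")
        widths = {fp.n_bits for fp in self.fingerprints}
        if len(widths) > 1:
            raise InputError(f"inconsistent fingerprint widths {sorted(widths)}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_bits(self) -> int:
        return self.fingerprints[0].n_bits if self.fingerprints else 0

    def to_dense(self) -> np.ndarray:
        """(n_compounds, n_bits) 0/1 matrix view of the set."""
        mat = np.zeros((len(self), self.n_bits))
        for i, fp in enumerate(self.fingerprints):
            mat[i, sorted(fp.bits)] = 1.0
        return mat


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A&B| / |A|B|; two empty fingerprints score 0 by convention."""
    if a.n_bits != b.n_bits:
        raise InputError(f"fingerprint widths differ: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def summed_similarity_profile(
    positives: FingerprintSet, decoys: FingerprintSet
) -> np.ndarray:
    """For each decoy, the sum of its Tanimoto similarities to all positives."""
    if positives.fingerprints and decoys.fingerprints:
        if positives.n_bits != decoys.n_bits:
            raise InputError("positive and decoy fingerprint widths differ")
    sums = np.zeros(len(decoys))
    for i, g in enumerate(decoys.fingerprints):
        sums[i] = sum(tanimoto(g, c) for c in positives.fingerprints)
    return sums


@dataclass
class SelectionResult:
    ids: list[str]
    indices: np.ndarray  # positions within the decoy pool, selection order
    summed_similarity: np.ndarray  # full profile over the whole pool


def select_negatives(
    positives: FingerprintSet,
    decoys: FingerprintSet,
    ratio: int = 2,
) -> SelectionResult:
    """Pick the ``ratio * m`` pool decoys least similar to the positive set.

    Sorting is ascending by summed similarity, stable on pool index, so the
    result is deterministic for fixed inputs.
    """
    m = len(positives)
    needed = ratio * m
    if len(decoys) < needed:
        raise SelectionError(
            f"decoy pool too small: need {needed} (ratio {ratio} x {m} "
            f"positives) but only {len(decoys)} available"
        )
    sums = summed_similarity_profile(positives, decoys)
    order = np.argsort(sums, kind="stable")
    chosen = order[:needed]
    return SelectionResult(
        ids=[decoys.ids[int(i)] for i in chosen],
        indices=np.asarray(chosen, dtype=int),
        summed_similarity=sums,
    )
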