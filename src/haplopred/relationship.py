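"""Pedigree-based additive (numerator) relationship matrix.

The tabular method processes animals parents-first: for animal i with parents
s and d,

    A[i, j] = 0.5 * (A[j, s] + A[j, d])      for every earlier animal j,
    A[i, i] = 1 + 0.5 * A[s, d],

terms involving an unknown parent dropping out.  Founders are taken as
unrelated and non-inbred, so diag(A) = 1 + F with inbreeding F >= 0.
The matrix is dense; the intended scale is simulated pedigrees of at most a
few thousand animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .panel import Pedigree

__all__ = ["RelationshipMatrix", "additive_relationship"]


@dataclass(frozen=True)
class RelationshipMatrix:
    animal_ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != (len(self.animal_ids), len(self.animal_ids)):
            raise InputError("relationship matrix shape does not match animal ids")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise InputError("relationship matrix is not symmetric")
        object.__setattr__(self, "values", vals)

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.values) - 1.0

    def submatrix(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([pos[a] for a in ids])
        return self.values[np.ix_(idx, idx)]


def additive_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Tabular-method A over all pedigree animals, in pedigree (parents-first) order."""
    sire, dam = pedigree.parent_indices()
    n = pedigree.n_animals
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * a[s, :i]
        if d >= 0:
            row += 0.5 * a[d, :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(tuple(pedigree.animals), a)
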