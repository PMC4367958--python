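"""Two-locus linkage disequilibrium: haplotype frequencies, D, D' and r².

For two bi-allelic loci with alleles A1/A2 and B1/B2, the raw disequilibrium
coefficient is ``D = f(A1B1) - p(A1)·p(B1)``.  Lewontin's D' rescales |D| by
its maximum attainable value given the allele frequencies, so D' = 1 whenever
at least one of the four haplotype classes is absent — which is why D' runs
high at loci with rare alleles.  r² is the squared correlation of the allele
indicators, ``D² / (p_A1·p_A2·p_B1·p_B2)``.

Frequencies are obtained by direct counting over the phased haplotypes of a
panel; no EM step is required because the panel is phased by contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, MonomorphicLocusError
from .panel import HaplotypePanel

__all__ = ["TwoLocusTable", "haplotype_freqs", "d_raw", "dprime", "rsquared",
           "dprime_matrix"]

_FREQ_TOL = 1e-12


@dataclass(frozen=True)
class TwoLocusTable:
    """Joint haplotype frequencies of two bi-allelic loci.

    Cell ``freq_A1B1`` is the frequency of the haplotype carrying allele 1
    (here: the reference allele, code 0) at both loci, and so on.  The four
    cells must sum to one.
    """

    freq_A1B1: float
    freq_A1B2: float
    freq_A2B1: float
    freq_A2B2: float

    def __post_init__(self) -> None:
        cells = (self.freq_A1B1, self.freq_A1B2, self.freq_A2B1, self.freq_A2B2)
        if any(c < -_FREQ_TOL or c > 1 + _FREQ_TOL for c in cells):
            raise InputError(f"haplotype frequencies outside [0,1]: {cells}")
        if abs(sum(cells) - 1.0) > 1e-9:
            raise InputError(f"haplotype frequencies sum to {sum(cells)}, not 1")

    @property
    def p_A1(self) -> float:
        return self.freq_A1B1 + self.freq_A1B2

    @property
    def p_B1(self) -> float:
        return self.freq_A1B1 + self.freq_A2B1

    def is_polymorphic(self) -> bool:
        eps = _FREQ_TOL
        return (eps < self.p_A1 < 1 - eps) and (eps < self.p_B1 < 1 - eps)


def haplotype_freqs(panel: HaplotypePanel, i: int, j: int) -> TwoLocusTable:
    """Joint two-locus haplotype frequencies by direct counting over all
    2n phased haplotypes of the panel.

    Allele "1" of the table corresponds to allele code 0 (reference).
    """
    m = panel.n_markers
    if i == j:
        raise InputError("marker indices must differ")
    for idx in (i, j):
        if not (0 <= idx < m):
            raise InputError(f"marker index {idx} out of range [0, {m})")
    haps = panel.haplotypes()
    hi = haps[:, i].astype(np.int64)
    hj = haps[:, j].astype(np.int64)
    counts = np.bincount(2 * hi + hj, minlength=4)
    total = counts.sum()
    f = counts / total
    # code 0 at both loci = A1B1
    return TwoLocusTable(freq_A1B1=f[0], freq_A1B2=f[1], freq_A2B1=f[2], freq_A2B2=f[3])


def d_raw(table: TwoLocusTable) -> float:
    """Raw disequilibrium coefficient D = f(A1B1) − p(A1)·p(B1) ∈ [−0.25, 0.25]."""
    return table.freq_A1B1 - table.p_A1 * table.p_B1


def _require_polymorphic(table: TwoLocusTable) -> None:
    if not table.is_polymorphic():
        raise MonomorphicLocusError(
            "LD is undefined for a monomorphic locus "
            f"(p_A1={table.p_A1:.3g}, p_B1={table.p_B1:.3g})"
        )


def dprime(table: TwoLocusTable) -> float:
    """Lewontin's D' = |D| / D_max in [0, 1]; 0 when D = 0 (independence)."""
    _require_polymorphic(table)
    d = d_raw(table)
    if d == 0.0:
        return 0.0
    pa, pb = table.p_A1, table.p_B1
    qa, qb = 1.0 - pa, 1.0 - pb
    if d > 0:
        d_max = min(pa * qb, qa * pb)
    else:
        d_max = min(pa * pb, qa * qb)
    return min(abs(d) / d_max, 1.0)


def rsquared(table: TwoLocusTable) -> float:
    """Squared allele-indicator correlation r² = D² / (p_A1 p_A2 p_B1 p_B2)."""
    _require_polymorphic(table)
    d = d_raw(table)
    pa, pb = table.p_A1, table.p_B1
    return min(d * d / (pa * (1 - pa) * pb * (1 - pb)), 1.0)


def dprime_matrix(haps: np.ndarray) -> np.ndarray:
    """All-pairs D' over the columns of a 2n x m haplotype matrix.

    Convenience for small windows (block certification, heat maps); the block
    builder itself only evaluates the local pairs it needs.
    """
    m = haps.shape[1]
    out = np.zeros((m, m))
    tables = {}
    for i in range(m):
        for j in range(i + 1, m):
            key = (i, j)
            if key not in tables:
                hi = haps[:, i].astype(np.int64)
                hj = haps[:, j].astype(np.int64)
                f = np.bincount(2 * hi + hj, minlength=4) / haps.shape[0]
                tables[key] = TwoLocusTable(f[0], f[1], f[2], f[3])
            out[i, j] = out[j, i] = dprime(tables[key])
    return out
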