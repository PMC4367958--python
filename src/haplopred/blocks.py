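"""LD-based haploblock construction, variant enumeration and design encoding.

A haploblock is a contiguous run of SNPs on one chromosome in which **every**
pair of SNPs has D' at or above a threshold ``d``.  Blocks are found per
chromosome by greedy left-to-right maximal extension: a candidate block grows
while the next adjacent marker keeps D' >= d with all current members; when
extension fails the candidate is emitted (if it holds at least two SNPs —
singletons become "non-blocked" SNPs) and the search restarts at the marker
that failed.

The distinct haplotype strings observed within a block across all phased
haplotypes are its *variants*; each animal carries exactly two of them (with
multiplicity), so in the block encodings the variant columns of one block
always sum to 2 per animal.  Because LD constrains which allele combinations
occur, the number of variant columns is typically far below the 2x(block
size) worst case — the variable-reduction property that motivates blocking.

Three design-matrix encodings are supported: individual-SNP minor-allele
dosage, block variants plus non-blocked SNP dosages, and block variants only.

The threshold grid conventionally explored is ``DEFAULT_THRESHOLDS``
(0.25 … 0.75); ``d = 0`` merges each whole chromosome into a single block and
``d`` above the panel's maximum pairwise D' leaves every SNP non-blocked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .ld import TwoLocusTable, dprime
from .panel import HaplotypePanel, MarkerMap

__all__ = [
    "DEFAULT_THRESHOLDS",
    "Haploblock",
    "BlockPartition",
    "BlockVariantCatalog",
    "DesignMatrix",
    "build_blocks",
    "enumerate_block_variants",
    "build_design",
    "partition_summary",
    "PartitionSummary",
    "ENCODING_MODES",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.25, 0.35, 0.45, 0.55, 0.65, 0.75)
ENCODING_MODES = ("snp", "blocks_plus_nonblocked", "blocks_only")


@dataclass(frozen=True)
class Haploblock:
    chromosome: str
    start: int  # 0-based marker index into the QC'd map, inclusive
    end: int    # exclusive

    def __post_init__(self) -> None:
        if self.end - self.start < 2:
            raise InputError("a haploblock holds at least 2 markers")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def marker_indices(self) -> range:
        return range(self.start, self.end)


@dataclass(frozen=True)
class BlockPartition:
    """Ordered disjoint haploblocks plus the non-blocked marker indices;
    together they cover every marker of the map the partition was built on."""

    threshold_d: float
    blocks: tuple
    nonblocked: tuple
    n_markers: int

    def __post_init__(self) -> None:
        covered: list[int] = []
        for b in self.blocks:
            covered.extend(b.marker_indices)
        covered.extend(self.nonblocked)
        if sorted(covered) != list(range(self.n_markers)):
            raise InputError("blocks and non-blocked markers do not partition the map")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_nonblocked(self) -> int:
        return len(self.nonblocked)


def _pair_dprime(haps: np.ndarray, i: int, j: int, cache: dict) -> float:
    key = (i, j)
    val = cache.get(key)
    if val is None:
        counts = np.bincount(2 * haps[:, i] + haps[:, j], minlength=4)
        table = TwoLocusTable(*(counts / haps.shape[0]))
        val = dprime(table)
        cache[key] = val
    return val


def build_blocks(panel: HaplotypePanel, marker_map: MarkerMap, d: float) -> BlockPartition:
    """Partition each chromosome into haploblocks under the all-pairs D' >= d rule.

    The panel must be QC'd (no monomorphic markers) unless ``d == 0``, where
    every chromosome with >= 2 markers trivially forms one block.
    """
    if not (0.0 <= d <= 1.0):
        raise InputError(f"threshold d must lie in [0, 1]; got {d}")
    if panel.n_markers != marker_map.n_markers:
        raise InputError("panel and marker map disagree on marker count")
    blocks: list[Haploblock] = []
    nonblocked: list[int] = []
    haps = panel.haplotypes().astype(np.int64)
    cache: dict = {}
    for chrom, start, end in marker_map.chromosome_ranges():
        if d == 0.0:
            # every pair satisfies D' >= 0: the whole chromosome is one block
            if end - start >= 2:
                blocks.append(Haploblock(chrom, start, end))
            else:
                nonblocked.extend(range(start, end))
            continue
        j = start
        while j < end:
            block_end = j + 1
            while block_end < end and all(
                _pair_dprime(haps, i, block_end, cache) >= d
                for i in range(j, block_end)
            ):
                block_end += 1
            if block_end - j >= 2:
                blocks.append(Haploblock(chrom, j, block_end))
            else:
                nonblocked.append(j)
            j = block_end
    return BlockPartition(
        threshold_d=d,
        blocks=tuple(blocks),
        nonblocked=tuple(nonblocked),
        n_markers=marker_map.n_markers,
    )


@dataclass(frozen=True)
class BlockVariantCatalog:
    """Per block: the distinct observed haplotype strings with frequencies,
    ordered by descending frequency then lexicographically."""

    variants: tuple      # tuple per block: tuple of '01...' strings
    frequencies: tuple   # tuple per block: tuple of floats summing to 1

    def n_variants(self, block_index: int) -> int:
        return len(self.variants[block_index])

    @property
    def total_variants(self) -> int:
        return sum(len(v) for v in self.variants)


def enumerate_block_variants(
    panel: HaplotypePanel, partition: BlockPartition
) -> BlockVariantCatalog:
    """Enumerate distinct within-block haplotype strings over all 2n haplotypes."""
    if partition.n_markers != panel.n_markers:
        raise InputError("partition was not built on this panel's map")
    haps = panel.haplotypes()
    variants: list[tuple] = []
    freqs: list[tuple] = []
    for block in partition.blocks:
        sub = haps[:, block.start:block.end]
        strings = ["".join(map(str, row)) for row in sub]
        counts: dict[str, int] = {}
        for s in strings:
            counts[s] = counts.get(s, 0) + 1
        total = len(strings)
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        variants.append(tuple(s for s, _ in ordered))
        freqs.append(tuple(c / total for _, c in ordered))
    return BlockVariantCatalog(variants=tuple(variants), frequencies=tuple(freqs))


@dataclass(frozen=True)
class DesignMatrix:
    """n x q count matrix (0/1/2) over SNP-dosage or block-variant columns."""

    values: np.ndarray          # uint8, animals x columns
    column_meta: tuple          # per column: ("snp", marker_id) or ("block", block_idx, variant)
    encoding_mode: str
    animal_ids: tuple

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.uint8)
        if vals.ndim != 2:
            raise InputError("design values must be 2-D")
        if vals.shape[1] != len(self.column_meta):
            raise InputError("column metadata does not match design width")
        if vals.shape[0] != len(self.animal_ids):
            raise InputError("animal ids do not match design height")
        object.__setattr__(self, "values", vals)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def subset_animals(self, ids) -> "DesignMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            rows = [pos[a] for a in ids]
        except KeyError as exc:
            raise InputError(f"animal {exc.args[0]!r} not in design") from exc
        return DesignMatrix(self.values[rows], self.column_meta,
                            self.encoding_mode, tuple(ids))


def _minor_dosage(panel: HaplotypePanel, j: int) -> np.ndarray:
    """Minor-allele dosage of marker j; alt is taken as minor on a 0.5 tie."""
    col = panel.alleles[:, :, j]
    alt_dose = col.sum(axis=1, dtype=np.int16)
    if col.mean() > 0.5:
        return (2 - alt_dose).astype(np.uint8)
    return alt_dose.astype(np.uint8)


def build_design(
    panel: HaplotypePanel,
    partition: BlockPartition,
    catalog: BlockVariantCatalog | None,
    mode: str,
    marker_map: MarkerMap | None = None,
) -> DesignMatrix:
    """Encode the panel under one of the three variable sets.

    Columns follow map order; within a block, variant columns follow the
    catalog order.  ``marker_map`` supplies SNP column names (marker ids);
    falling back to ``m<j>`` labels when omitted.  A haplotype not present in
    the catalog (possible only when encoding animals outside the panel the
    catalog was enumerated on) contributes to no column and logs a warning.
    """
    if mode not in ENCODING_MODES:
        raise InputError(f"unknown encoding mode {mode!r}; expected one of {ENCODING_MODES}")
    if mode != "snp" and catalog is None:
        raise InputError("block encodings require a variant catalog")
    n = panel.n_animals
    m = panel.n_markers
    if partition.n_markers != m:
        raise InputError("partition does not match panel markers")

    def snp_name(j: int) -> str:
        return str(marker_map.marker_id[j]) if marker_map is not None else f"m{j}"

    block_at = {b.start: (bi, b) for bi, b in enumerate(partition.blocks)}
    in_block = set()
    for b in partition.blocks:
        in_block.update(b.marker_indices)

    columns: list[np.ndarray] = []
    meta: list[tuple] = []
    if mode == "snp":
        for j in range(m):
            columns.append(_minor_dosage(panel, j))
            meta.append(("snp", snp_name(j)))
    else:
        haps = panel.haplotypes()
        j = 0
        while j < m:
            if j in block_at:
                bi, block = block_at[j]
                index = {s: k for k, s in enumerate(catalog.variants[bi])}
                counts = np.zeros((n, len(index)), dtype=np.uint8)
                sub = haps[:, block.start:block.end]
                for h in range(2 * n):
                    s = "".join(map(str, sub[h]))
                    k = index.get(s)
                    if k is None:
                        logger.warning(
                            "haplotype %s not in catalog for block %d; encoded as zeros",
                            s, bi,
                        )
                        continue
                    counts[h // 2, k] += 1
                for k, s in enumerate(catalog.variants[bi]):
                    columns.append(counts[:, k])
                    meta.append(("block", bi, s))
                j = block.end
            else:
                if mode == "blocks_plus_nonblocked":
                    columns.append(_minor_dosage(panel, j))
                    meta.append(("snp", snp_name(j)))
                j += 1
    values = np.stack(columns, axis=1) if columns else np.zeros((n, 0), dtype=np.uint8)
    return DesignMatrix(values=values, column_meta=tuple(meta),
                        encoding_mode=mode, animal_ids=panel.animal_ids)


@dataclass(frozen=True)
class PartitionSummary:
    """Block accounting at one threshold: block count, block-variant column
    count (``n_variables``) and non-blocked SNP count are reported separately
    so either convention for "variables" can be recovered."""

    threshold: float
    n_blocks: int
    n_variables: int
    n_nonblocked: int


def partition_summary(
    partition: BlockPartition, catalog: BlockVariantCatalog
) -> PartitionSummary:
    if len(catalog.variants) != partition.n_blocks:
        raise InputError("catalog does not match partition")
    return PartitionSummary(
        threshold=partition.threshold_d,
        n_blocks=partition.n_blocks,
        n_variables=catalog.total_variants,
        n_nonblocked=partition.n_nonblocked,
    )
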