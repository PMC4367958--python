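"""File I/O and marker QC.

Formats:

* phased VCF (GT-only, bi-allelic, no missing calls) for haplotype panels;
* pedigree CSV with columns ``animal,sire,dam,generation`` (empty = unknown);
* DRP CSV with columns ``animal,trait,drp,reliability``.

QC mirrors the standard editing of an imputed high-density panel: markers
with minor-allele frequency below a cut-off are dropped first, then markers
in complete LD (r² = 1) with the nearest retained marker to their left on the
same chromosome are dropped as informationally redundant.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import InputError, ParseError
from .ld import TwoLocusTable, rsquared
from .panel import DRPTable, HaplotypePanel, MarkerMap, Pedigree, QCReport

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "qc_filter",
    "read_pedigree",
    "write_pedigree",
    "read_drp",
    "write_drp",
]

_COMPLETE_LD_TOL = 1e-12


def read_phased_vcf(path: str | os.PathLike) -> tuple[HaplotypePanel, MarkerMap]:
    """Read a phased, bi-allelic, GT-only VCF into a panel and marker map.

    Raises :class:`ParseError` on unphased or missing genotypes and on
    multi-allelic sites, naming the offending record.
    """
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, positions, ids, refs, alts = [], [], [], [], []
    allele_rows = []
    for variant in vcf:
        label = f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            raise ParseError(f"multi-allelic site at {label}")
        gts = variant.genotypes  # [allele_a, allele_b, phased] per sample
        row = np.empty((len(samples), 2), dtype=np.uint8)
        for s, gt in enumerate(gts):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise ParseError(f"missing genotype for sample {samples[s]} at {label}")
            if not phased:
                raise ParseError(f"unphased genotype for sample {samples[s]} at {label}")
            row[s, 0], row[s, 1] = a, b
        allele_rows.append(row)
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        ids.append(variant.ID if variant.ID not in (None, ".") else f"{label}")
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
    marker_map = MarkerMap(
        chromosome=np.array(chroms, dtype=object),
        position=np.array(positions, dtype=np.int64),
        marker_id=np.array(ids, dtype=object),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
    )
    if allele_rows:
        alleles = np.stack(allele_rows, axis=2)  # markers stacked on last axis
    else:
        alleles = np.zeros((len(samples), 2, 0), dtype=np.uint8)
    return HaplotypePanel(tuple(samples), alleles), marker_map


def write_phased_vcf(panel: HaplotypePanel, marker_map: MarkerMap,
                     path: str | os.PathLike) -> None:
    """Write a minimal phased VCF4.2 (GT field only)."""
    if panel.n_markers != marker_map.n_markers:
        raise InputError(
            f"panel has {panel.n_markers} markers but map has {marker_map.n_markers}"
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplopred\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, start, end in marker_map.chromosome_ranges():
            length = int(marker_map.position[end - 1]) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                          "FILTER", "INFO", "FORMAT", *panel.animal_ids])
        fh.write(cols + "\n")
        alleles = panel.alleles
        for j in range(marker_map.n_markers):
            gts = "\t".join(
                f"{alleles[i, 0, j]}|{alleles[i, 1, j]}" for i in range(panel.n_animals)
            )
            fields = [
                str(marker_map.chromosome[j]),
                str(int(marker_map.position[j])),
                str(marker_map.marker_id[j]),
                str(marker_map.ref_allele[j]),
                str(marker_map.alt_allele[j]),
                ".", "PASS", ".", "GT",
            ]
            line = "\t".join(fields)
            fh.write(line + ("\t" + gts if gts else "") + "\n")


def qc_filter(
    panel: HaplotypePanel,
    marker_map: MarkerMap,
    maf_min: float = 0.01,
    drop_complete_ld_adjacent: bool = True,
) -> tuple[HaplotypePanel, MarkerMap, QCReport]:
    """Apply the two marker-editing rules in sequence.

    1. Remove markers with minor-allele frequency below ``maf_min`` (computed
       over all haplotypes of all panel animals).
    2. Scanning each chromosome left-to-right over the survivors, remove a
       marker whose r² with the nearest retained marker to its left equals 1
       within 1e-12 (keep-left convention).
    """
    if not (0.0 <= maf_min < 0.5):
        raise InputError(f"maf_min must lie in [0, 0.5); got {maf_min}")
    m = marker_map.n_markers
    freqs = panel.alt_freq()
    maf = np.minimum(freqs, 1.0 - freqs)
    keep_maf = maf >= maf_min
    n_removed_maf = int((~keep_maf).sum())

    removed_ld: list[int] = []
    if drop_complete_ld_adjacent:
        haps = panel.haplotypes().astype(np.int64)
        nh = haps.shape[0]
        for _, start, end in marker_map.chromosome_ranges():
            left = -1
            for j in range(start, end):
                if not keep_maf[j]:
                    continue
                if left >= 0:
                    both_poly = (0 < freqs[left] < 1) and (0 < freqs[j] < 1)
                    if both_poly:
                        counts = np.bincount(2 * haps[:, left] + haps[:, j], minlength=4)
                        table = TwoLocusTable(*(counts / nh))
                        if rsquared(table) >= 1.0 - _COMPLETE_LD_TOL:
                            removed_ld.append(j)
                            continue
                left = j
    keep = keep_maf.copy()
    keep[removed_ld] = False
    retained = np.flatnonzero(keep)
    removed_ids = tuple(marker_map.marker_id[~keep])
    report = QCReport(
        n_input=m,
        n_removed_maf=n_removed_maf,
        n_removed_complete_ld=len(removed_ld),
        n_retained=len(retained),
        removed_ids=removed_ids,
    )
    return panel.subset_markers(retained), marker_map.subset(retained), report


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Read a pedigree CSV (``animal,sire,dam,generation``; empty = unknown)."""
    df = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str})
    return Pedigree(df)


def write_pedigree(pedigree: Pedigree, path: str | os.PathLike) -> None:
    pedigree.frame.to_csv(path, index=False)


def read_drp(path: str | os.PathLike) -> DRPTable:
    """Read a DRP CSV (``animal,trait,drp,reliability``)."""
    df = pd.read_csv(path, dtype={"animal": str, "trait": str})
    return DRPTable(df)


def write_drp(table: DRPTable, path: str | os.PathLike) -> None:
    table.frame.to_csv(path, index=False)
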