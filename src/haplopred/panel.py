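"""Core data containers: marker map, phased haplotype panel, pedigree, DRP table.

A :class:`HaplotypePanel` stores phased diploid genotypes as an
``individuals x 2 x markers`` array of 0/1 allele codes (0 = reference,
1 = alternate).  The panel is post-phasing by contract: entries are never
missing and every genotype is phased.  The :class:`MarkerMap` carries the
genomic coordinates of the panel's columns and must be grouped by chromosome
with strictly increasing positions within each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError, PedigreeCycleError

__all__ = ["MarkerMap", "HaplotypePanel", "Pedigree", "DRPTable", "QCReport"]


@dataclass(frozen=True)
class MarkerMap:
    """Marker coordinates for the columns of a panel.

    Positions are 1-based (VCF convention); internal marker indices are
    0-based and all ranges over markers are half-open ``[start, end)``.
    """

    chromosome: np.ndarray  # str per marker
    position: np.ndarray  # int bp, 1-based
    marker_id: np.ndarray  # unique str per marker
    ref_allele: np.ndarray
    alt_allele: np.ndarray

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chromosome, dtype=object)
        pos = np.asarray(self.position, dtype=np.int64)
        ids = np.asarray(self.marker_id, dtype=object)
        ref = np.asarray(self.ref_allele, dtype=object)
        alt = np.asarray(self.alt_allele, dtype=object)
        n = len(chrom)
        for name, arr in (("position", pos), ("marker_id", ids),
                          ("ref_allele", ref), ("alt_allele", alt)):
            if len(arr) != n:
                raise InputError(f"MarkerMap field {name!r} has length {len(arr)}, expected {n}")
        if len(set(ids)) != n:
            raise InputError("MarkerMap marker_ids are not unique")
        # chromosomes must form contiguous runs, positions strictly increasing within
        seen: set[str] = set()
        prev_chrom: str | None = None
        for j in range(n):
            c = chrom[j]
            if c != prev_chrom:
                if c in seen:
                    raise InputError(f"chromosome {c!r} appears in non-contiguous runs")
                seen.add(c)
                prev_chrom = c
            elif pos[j] <= pos[j - 1]:
                raise InputError(
                    f"positions not strictly increasing on chromosome {c!r} at index {j}"
                )
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "marker_id", ids)
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def chromosome_ranges(self) -> list[tuple[str, int, int]]:
        """Half-open marker-index range of each chromosome, in map order."""
        out: list[tuple[str, int, int]] = []
        n = self.n_markers
        j = 0
        while j < n:
            c = self.chromosome[j]
            k = j
            while k < n and self.chromosome[k] == c:
                k += 1
            out.append((c, j, k))
            j = k
        return out

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        idx = np.asarray(indices)
        return MarkerMap(
            chromosome=self.chromosome[idx],
            position=self.position[idx],
            marker_id=self.marker_id[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "position": self.position,
                "marker_id": self.marker_id,
                "ref_allele": self.ref_allele,
                "alt_allele": self.alt_allele,
            }
        )


@dataclass(frozen=True)
class HaplotypePanel:
    """Phased diploid allele matrix: ``n_animals x 2 x n_markers`` in {0, 1}."""

    animal_ids: tuple
    alleles: np.ndarray  # uint8

    def __post_init__(self) -> None:
        ids = tuple(self.animal_ids)
        alleles = np.asarray(self.alleles, dtype=np.uint8)
        if alleles.ndim != 3 or alleles.shape[1] != 2:
            raise InputError(f"alleles must be (n, 2, m); got shape {alleles.shape}")
        if alleles.shape[0] != len(ids):
            raise InputError(
                f"{len(ids)} animal ids but {alleles.shape[0]} rows of alleles"
            )
        if alleles.size and alleles.max() > 1:
            raise InputError("allele codes must be 0 or 1")
        if len(set(ids)) != len(ids):
            raise InputError("animal ids are not unique")
        object.__setattr__(self, "animal_ids", ids)
        object.__setattr__(self, "alleles", alleles)

    @property
    def n_animals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[2]

    def haplotypes(self) -> np.ndarray:
        """All phased haplotypes as a ``2n x m`` matrix (animal-major order)."""
        n, _, m = self.alleles.shape
        return self.alleles.reshape(2 * n, m)

    def alt_dosage(self) -> np.ndarray:
        """Per-animal count of the alternate allele, ``n x m`` in {0,1,2}."""
        return self.alleles.sum(axis=1, dtype=np.int16)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker over all 2n haplotypes."""
        return self.haplotypes().mean(axis=0)

    def subset_markers(self, indices: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(self.animal_ids, self.alleles[:, :, np.asarray(indices)])

    def subset_animals(self, ids) -> "HaplotypePanel":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            rows = [pos[a] for a in ids]
        except KeyError as exc:
            raise InputError(f"animal {exc.args[0]!r} not in panel") from exc
        return HaplotypePanel(tuple(ids), self.alleles[rows])


class Pedigree:
    """Pedigree table (animal, sire, dam, generation), parents-first.

    Unknown parents are ``None``.  Construction validates that every named
    parent is itself an animal, that the graph is acyclic, and reorders rows
    topologically (parents before offspring) if needed.
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["animal", "sire", "dam", "generation"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise InputError(f"pedigree table missing columns {missing}")
        df = frame[required].copy()
        df["animal"] = df["animal"].astype(str)
        for col in ("sire", "dam"):
            df[col] = df[col].where(df[col].notna(), None)
            df[col] = df[col].map(lambda v: None if v in (None, "") else str(v))
        df["generation"] = df["generation"].astype(int)
        if df["animal"].duplicated().any():
            dup = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
            raise InputError(f"duplicated animal id {dup!r} in pedigree")
        known = set(df["animal"])
        for col in ("sire", "dam"):
            for parent in df[col]:
                if parent is not None and parent not in known:
                    raise InputError(f"{col} {parent!r} is not listed as an animal")
        graph = nx.DiGraph()
        graph.add_nodes_from(df["animal"])
        for _, row in df.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent is not None:
                    graph.add_edge(parent, row["animal"])
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise PedigreeCycleError(f"pedigree contains a cycle: {path}")
        order = list(nx.topological_sort(graph))
        rank = {a: i for i, a in enumerate(order)}
        df = df.sort_values("animal", kind="stable")  # deterministic tie-break
        df = df.iloc[np.argsort([rank[a] for a in df["animal"]], kind="stable")]
        self._df = df.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def animals(self) -> list[str]:
        return list(self._df["animal"])

    @property
    def n_animals(self) -> int:
        return len(self._df)

    def generations(self) -> np.ndarray:
        return self._df["generation"].to_numpy()

    def founders(self) -> list[str]:
        mask = self._df["sire"].isna() & self._df["dam"].isna()
        return list(self._df.loc[mask, "animal"])

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row index of each animal's sire/dam (-1 when unknown); rows are
        parents-first so both indices are < the animal's own row."""
        pos = {a: i for i, a in enumerate(self._df["animal"])}
        sire = np.array([pos[s] if s is not None else -1 for s in self._df["sire"]])
        dam = np.array([pos[d] if d is not None else -1 for d in self._df["dam"]])
        return sire, dam

    def __eq__(self, other) -> bool:
        return isinstance(other, Pedigree) and self._df.equals(other._df)

    def __repr__(self) -> str:
        gens = self._df["generation"].nunique()
        return f"Pedigree(n_animals={self.n_animals}, n_generations={gens})"


class DRPTable:
    """De-regressed proof records: one row per (animal, trait), with the
    record's reliability strictly inside (0, 1)."""

    def __init__(self, frame: pd.DataFrame):
        required = ["animal", "trait", "drp", "reliability"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise InputError(f"DRP table missing columns {missing}")
        df = frame[required].copy()
        df["animal"] = df["animal"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["drp"] = df["drp"].astype(float)
        df["reliability"] = df["reliability"].astype(float)
        if df.duplicated(["animal", "trait"]).any():
            raise InputError("duplicate (animal, trait) record in DRP table")
        bad = ~((df["reliability"] > 0.0) & (df["reliability"] < 1.0))
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise InputError(
                f"reliability must lie strictly in (0,1); animal {row['animal']!r} "
                f"has {row['reliability']}"
            )
        self._df = df.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def traits(self) -> list[str]:
        return sorted(self._df["trait"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self._df[self._df["trait"] == trait]
        if sub.empty:
            raise InputError(f"no DRP records for trait {trait!r}")
        return sub.set_index("animal")[["drp", "reliability"]]

    def __len__(self) -> int:
        return len(self._df)


@dataclass(frozen=True)
class QCReport:
    """Accounting of the marker QC filters; counts always reconcile."""

    n_input: int
    n_removed_maf: int
    n_removed_complete_ld: int
    n_retained: int
    removed_ids: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed_maf + self.n_removed_complete_ld + self.n_retained:
            raise InputError("QCReport counts do not reconcile")
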