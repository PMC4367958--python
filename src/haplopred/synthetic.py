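"""Synthetic phased panels, pedigrees, QTL architectures and DRP phenotypes.

The generator emulates the data regime the prediction pipeline assumes — a
progeny-tested dairy population with phased high-density genotypes and
de-regressed proofs (DRP) — at desk scale:

* **Founder haplotypes** follow a first-order Markov chain along each
  chromosome: locus j+1 copies locus j's allele with probability
  ``adjacent_corr`` and otherwise draws a fresh allele at that locus's MAF.
  This gives direct single-parameter control of adjacent-pair LD, which is
  all the block builder consumes.
* **Pedigree** grows by random sire x dam matings among the previous
  generation; every animal carries a birth-generation label used for the
  train/test cut-off split.
* **Gene dropping** transmits one recombinant gamete per parent, switching
  parental haplotype between adjacent loci with a fixed per-interval
  probability, never across chromosome boundaries.
* **Phenotypes**: QTL effects are drawn from a four-component normal mixture
  (most effects tiny, few large); TBV is the centred QTL dosage sum; an
  environmental deviate calibrates realized heritability; DRP adds noise with
  variance ``var(TBV) * (1 - r²) / r²`` for a per-animal reliability r² drawn
  uniformly — the standard de-regression error-variance relation.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .panel import DRPTable, HaplotypePanel, MarkerMap, Pedigree

__all__ = [
    "SimConfig",
    "SimPhenotypes",
    "SimulatedDataset",
    "simulate_haplotype_panel",
    "simulate_pedigree",
    "drop_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study population.

    Defaults emulate a compact dairy-cattle-like design: strong adjacent LD
    (so blocking is non-trivial), a sparse-mixture QTL architecture with the
    conventional proportions (0.889, 0.1, 0.01, 0.001), a protein-like
    heritability of 0.39, and DRP reliabilities in the range typical of
    progeny-tested bulls.
    """

    n_founders: int = 100
    n_generations: int = 3
    offspring_per_mating: int = 2
    n_chromosomes: int = 3
    snps_per_chromosome: int = 100
    adjacent_corr: float = 0.95
    weak_ld_prob: float = 0.05
    weak_ld_corr: float = 0.3
    n_ancestral_haplotypes: int | None = 30
    maf_range: tuple = (0.05, 0.5)
    recomb_prob_per_interval: float = 5e-4
    n_qtl: int = 30
    mixture_props: tuple = (0.889, 0.1, 0.01, 0.001)
    mixture_sds: tuple = (0.01, 0.1, 0.5, 1.0)
    h2: float = 0.39
    drp_reliability_range: tuple = (0.7, 0.95)
    seed: int = 0
    trait: str = "sim"

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_generations", "offspring_per_mating",
                     "n_chromosomes", "snps_per_chromosome", "n_qtl"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be a count >= 1; got {v!r}")
        if not (0.0 <= self.adjacent_corr < 1.0):
            raise ConfigurationError(
                f"adjacent_corr must lie in [0, 1); got {self.adjacent_corr}")
        if not (0.0 <= self.weak_ld_prob <= 1.0):
            raise ConfigurationError(
                f"weak_ld_prob must lie in [0, 1]; got {self.weak_ld_prob}")
        if not (0.0 <= self.weak_ld_corr < 1.0):
            raise ConfigurationError(
                f"weak_ld_corr must lie in [0, 1); got {self.weak_ld_corr}")
        if self.n_ancestral_haplotypes is not None and self.n_ancestral_haplotypes < 2:
            raise ConfigurationError(
                "n_ancestral_haplotypes must be >= 2 (or None for unbounded diversity)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must be ordered within (0, 0.5]; got {self.maf_range}")
        if not (0.0 <= self.recomb_prob_per_interval <= 0.5):
            raise ConfigurationError(
                f"recomb_prob_per_interval must lie in [0, 0.5]; got {self.recomb_prob_per_interval}")
        props = np.asarray(self.mixture_props, dtype=float)
        sds = np.asarray(self.mixture_sds, dtype=float)
        if props.shape != (4,) or sds.shape != (4,):
            raise ConfigurationError("mixture_props and mixture_sds must have 4 entries")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ConfigurationError(f"mixture_props must sum to 1; got sum {props.sum()!r}")
        if (props < 0).any():
            raise ConfigurationError("mixture_props must be non-negative")
        if (sds < 0).any():
            raise ConfigurationError("mixture_sds must be non-negative")
        if not (0.0 < self.h2 < 1.0):
            raise ConfigurationError(f"h2 must lie in (0, 1); got {self.h2}")
        rlo, rhi = self.drp_reliability_range
        if not (0.0 < rlo <= rhi < 1.0):
            raise ConfigurationError(
                f"drp_reliability_range must be ordered within (0, 1); got {self.drp_reliability_range}")
        if self.n_generations > 1 and self.n_founders < 2:
            raise ConfigurationError("n_founders must be >= 2 to form matings")
        if self.n_qtl > self.n_chromosomes * self.snps_per_chromosome:
            raise ConfigurationError("n_qtl exceeds the number of markers")
        object.__setattr__(self, "maf_range", (float(lo), float(hi)))
        object.__setattr__(self, "mixture_props", tuple(props))
        object.__setattr__(self, "mixture_sds", tuple(sds))
        object.__setattr__(self, "drp_reliability_range", (float(rlo), float(rhi)))

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _founder_id(i: int) -> str:
    return f"G0_{i:05d}"


def simulate_haplotype_panel(config: SimConfig) -> tuple[HaplotypePanel, MarkerMap]:
    """Markov-chain founder haplotypes plus a marker map.

    Per chromosome, each locus's MAF is drawn uniformly from ``maf_range``
    (the alternate allele is the minor one in expectation); allele values
    propagate along the chromosome with copy probability ``adjacent_corr``.
    With a finite ``n_ancestral_haplotypes``, the Markov chains form an
    ancestral pool from which founder haplotypes are sampled with
    replacement, bounding local haplotype diversity the way a small
    effective population size does; ``None`` gives every founder haplotype
    its own independent chain.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_founders
    m_c = config.snps_per_chromosome
    nh = 2 * n
    pool = config.n_ancestral_haplotypes
    n_chains = pool if pool is not None else nh
    chrom_blocks = []
    chroms, positions, ids = [], [], []
    for c in range(config.n_chromosomes):
        mafs = rng.uniform(*config.maf_range, size=m_c)
        # a fraction of intervals are weak-LD breakpoints (the hotspot-like
        # gaps that separate haploblocks in real genomes)
        interval_corr = np.where(
            rng.random(m_c - 1) < config.weak_ld_prob if m_c > 1 else [],
            config.weak_ld_corr,
            config.adjacent_corr,
        ) if m_c > 1 else np.empty(0)
        chains = np.empty((n_chains, m_c), dtype=np.uint8)
        chains[:, 0] = rng.random(n_chains) < mafs[0]
        for j in range(1, m_c):
            copy = rng.random(n_chains) < interval_corr[j - 1]
            fresh = rng.random(n_chains) < mafs[j]
            chains[:, j] = np.where(copy, chains[:, j - 1], fresh)
        if pool is not None:
            # finite ancestral pool: founder haplotypes are drawn (with
            # replacement) from the Markov-generated ancestral haplotypes,
            # emulating the small effective population size that bounds
            # local haplotype diversity in real livestock panels
            haps = chains[rng.integers(0, pool, size=nh)]
        else:
            haps = chains
        chrom_blocks.append(haps)
        label = str(c + 1)
        chroms.extend([label] * m_c)
        positions.extend(1000 * (j + 1) for j in range(m_c))
        ids.extend(f"c{label}_s{j + 1}" for j in range(m_c))
    all_haps = np.concatenate(chrom_blocks, axis=1)
    alleles = all_haps.reshape(n, 2, all_haps.shape[1])
    marker_map = MarkerMap(
        chromosome=np.array(chroms, dtype=object),
        position=np.array(positions, dtype=np.int64),
        marker_id=np.array(ids, dtype=object),
        ref_allele=np.array(["A"] * len(ids), dtype=object),
        alt_allele=np.array(["G"] * len(ids), dtype=object),
    )
    panel = HaplotypePanel(tuple(_founder_id(i) for i in range(n)), alleles)
    return panel, marker_map


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Multi-generation pedigree by random sire x dam matings.

    Generation g >= 1 forms ``len(previous) // 2`` matings (distinct sire and
    dam drawn from the previous generation), each producing
    ``offspring_per_mating`` offspring, so the census is stable at the
    default of two offspring per mating.
    """
    rng = np.random.default_rng([config.seed, 1])
    rows = [
        {"animal": _founder_id(i), "sire": None, "dam": None, "generation": 0}
        for i in range(config.n_founders)
    ]
    previous = [r["animal"] for r in rows]
    for g in range(1, config.n_generations):
        n_matings = max(1, len(previous) // 2)
        current: list[str] = []
        counter = 0
        for _ in range(n_matings):
            sire, dam = rng.choice(previous, size=2, replace=False)
            for _ in range(config.offspring_per_mating):
                aid = f"G{g}_{counter:05d}"
                counter += 1
                rows.append({"animal": aid, "sire": str(sire), "dam": str(dam),
                             "generation": g})
                current.append(aid)
        previous = current
    return Pedigree(pd.DataFrame(rows))


def drop_genotypes(
    pedigree: Pedigree,
    founder_panel: HaplotypePanel,
    marker_map: MarkerMap,
    recomb_prob: float,
    seed: int,
) -> HaplotypePanel:
    """Gene-drop founder haplotypes through the pedigree with recombination.

    Each non-founder receives one gamete from each parent; a gamete starts on
    a random parental haplotype and switches between adjacent loci with
    probability ``recomb_prob`` independently per interval, restarting on a
    fresh random haplotype at each chromosome boundary.
    """
    if not (0.0 <= recomb_prob <= 0.5):
        raise InputError(f"recomb_prob must lie in [0, 0.5]; got {recomb_prob}")
    founders = pedigree.founders()
    if len(founders) != founder_panel.n_animals:
        raise InputError(
            f"pedigree has {len(founders)} founders but panel has "
            f"{founder_panel.n_animals} individuals"
        )
    if set(founders) == set(founder_panel.animal_ids):
        founder_rows = {a: founder_panel.animal_ids.index(a) for a in founders}
    else:  # fall back to positional correspondence
        founder_rows = {a: i for i, a in enumerate(founders)}
    rng = np.random.default_rng([seed, 2])
    m = founder_panel.n_markers
    ranges = marker_map.chromosome_ranges()
    if marker_map.n_markers != m:
        raise InputError("marker map does not match founder panel")
    genomes: dict[str, np.ndarray] = {}
    order = pedigree.animals
    sire_idx, dam_idx = pedigree.parent_indices()
    alleles = np.empty((len(order), 2, m), dtype=np.uint8)
    for i, animal in enumerate(order):
        if sire_idx[i] < 0 and dam_idx[i] < 0:
            alleles[i] = founder_panel.alleles[founder_rows[animal]]
            continue
        for h, parent_row in enumerate((sire_idx[i], dam_idx[i])):
            parent = alleles[parent_row]
            gamete = np.empty(m, dtype=np.uint8)
            for _, start, end in ranges:
                span = end - start
                first = rng.integers(2)
                if span > 1:
                    switches = rng.random(span - 1) < recomb_prob
                    selector = (first + np.concatenate(
                        ([0], np.cumsum(switches)))) % 2
                else:
                    selector = np.array([first])
                gamete[start:end] = parent[selector, np.arange(start, end)]
            alleles[i, h] = gamete
    return HaplotypePanel(tuple(order), alleles)


@dataclass(frozen=True)
class SimPhenotypes:
    """True breeding values, raw phenotypes and DRP records."""

    tbv: pd.Series          # true breeding value per animal
    phenotype: pd.Series    # TBV + environmental deviate at realized h2
    drp: DRPTable
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray


def simulate_phenotypes(
    panel: HaplotypePanel, marker_map: MarkerMap, config: SimConfig
) -> SimPhenotypes:
    """QTL-mixture phenotypes and DRP with heterogeneous reliabilities."""
    if config.n_qtl > panel.n_markers:
        raise ConfigurationError("n_qtl exceeds the number of panel markers")
    rng = np.random.default_rng([config.seed, 3])
    n = panel.n_animals
    dosage = panel.alt_dosage().astype(np.float64)
    qtl = np.sort(rng.choice(panel.n_markers, size=config.n_qtl, replace=False))
    comp = rng.choice(4, size=config.n_qtl, p=np.asarray(config.mixture_props))
    sds = np.asarray(config.mixture_sds)[comp]
    effects = rng.normal(0.0, 1.0, size=config.n_qtl) * sds
    tbv = dosage[:, qtl] @ effects
    tbv = tbv - tbv.mean()
    var_t = float(tbv.var())
    if var_t > 0:
        env_sd = np.sqrt(var_t * (1.0 - config.h2) / config.h2)
        env = rng.normal(0.0, 1.0, size=n)
        env = (env - env.mean()) / env.std()  # exact realized variance
        env = env * env_sd
    else:
        env = np.zeros(n)
    phenotype = tbv + env
    r2 = rng.uniform(*config.drp_reliability_range, size=n)
    noise_sd = np.sqrt(var_t * (1.0 - r2) / r2)
    drp_vals = tbv + rng.normal(0.0, 1.0, size=n) * noise_sd
    ids = list(panel.animal_ids)
    drp = DRPTable(pd.DataFrame({
        "animal": ids,
        "trait": config.trait,
        "drp": drp_vals,
        "reliability": r2,
    }))
    return SimPhenotypes(
        tbv=pd.Series(tbv, index=ids, name="tbv"),
        phenotype=pd.Series(phenotype, index=ids, name="phenotype"),
        drp=drp,
        qtl_indices=qtl,
        qtl_effects=effects,
    )


@dataclass(frozen=True)
class SimulatedDataset:
    """A complete synthetic study: phased panel over all pedigree animals,
    marker map, pedigree, phenotypes."""

    panel: HaplotypePanel
    marker_map: MarkerMap
    pedigree: Pedigree
    phenotypes: SimPhenotypes
    config: SimConfig

    def train_test_ids(self, n_test_generations: int = 1) -> tuple[list, list]:
        """Split by birth generation: the last ``n_test_generations``
        generations form the test set (the cut-off-date analogue)."""
        gens = self.pedigree.generations()
        cut = gens.max() - n_test_generations + 1
        animals = self.pedigree.animals
        train = [a for a, g in zip(animals, gens) if g < cut]
        test = [a for a, g in zip(animals, gens) if g >= cut]
        return train, test


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Founders -> pedigree -> gene dropping -> phenotypes, end to end."""
    founder_panel, marker_map = simulate_haplotype_panel(config)
    pedigree = simulate_pedigree(config)
    panel = drop_genotypes(
        pedigree, founder_panel, marker_map,
        config.recomb_prob_per_interval, config.seed,
    )
    phenotypes = simulate_phenotypes(panel, marker_map, config)
    return SimulatedDataset(panel, marker_map, pedigree, phenotypes, config)
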