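"""Synthetic-data generator: LD control, pedigree structure, gene dropping,
phenotype calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from haplopred import (
    ConfigurationError,
    SimConfig,
    additive_relationship,
    drop_genotypes,
    simulate_dataset,
    simulate_haplotype_panel,
    simulate_pedigree,
    simulate_phenotypes,
)

from _util import dprime_oracle, make_map, panel_from_haps


def _mean_adjacent_dprime(haps: np.ndarray) -> float:
    vals = [dprime_oracle(haps, j, j + 1) for j in range(haps.shape[1] - 1)]
    return float(np.mean(vals))


@pytest.mark.parametrize(
    "kwargs, field",
    [
        ({"n_founders": 0}, "n_founders"),
        ({"adjacent_corr": 1.0}, "adjacent_corr"),
        ({"maf_range": (0.4, 0.1)}, "maf_range"),
        ({"mixture_props": (0.5, 0.5, 0.5, -0.5)}, "mixture_props"),
        ({"mixture_props": (0.25, 0.25, 0.25, 0.2)}, "mixture_props"),
        ({"h2": 1.5}, "h2"),
        ({"drp_reliability_range": (0.0, 0.9)}, "drp_reliability_range"),
        ({"recomb_prob_per_interval": 0.7}, "recomb_prob_per_interval"),
    ],
)
def test_invalid_config_names_the_field(kwargs, field):
    with pytest.raises(ConfigurationError, match=field):
        SimConfig(**kwargs)


def test_panel_determinism_and_allele_domain():
    cfg = SimConfig(n_founders=30, snps_per_chromosome=40, seed=11)
    p1, m1 = simulate_haplotype_panel(cfg)
    p2, m2 = simulate_haplotype_panel(cfg)
    assert np.array_equal(p1.alleles, p2.alleles)
    assert list(m1.marker_id) == list(m2.marker_id)
    assert set(np.unique(p1.alleles)) <= {0, 1}
    p3, _ = simulate_haplotype_panel(cfg.with_seed(12))
    assert not np.array_equal(p1.alleles, p3.alleles)


def test_zero_adjacent_corr_matches_independent_null():
    """With no allele copying (and no ancestral bottleneck) the mean adjacent
    |D'| is indistinguishable from the permuted-loci null."""
    cfg = SimConfig(n_founders=300, n_chromosomes=1, snps_per_chromosome=60,
                    adjacent_corr=0.0, weak_ld_prob=0.0,
                    n_ancestral_haplotypes=None, maf_range=(0.3, 0.5), seed=5)
    panel, _ = simulate_haplotype_panel(cfg)
    haps = panel.haplotypes()
    observed = _mean_adjacent_dprime(haps)
    rng = np.random.default_rng(99)
    null = []
    for _ in range(60):
        perm = haps[:, rng.permutation(haps.shape[1])]
        # permute each column's haplotype assignment independently to break
        # any residual pairing while preserving allele frequencies
        shuffled = np.stack(
            [perm[rng.permutation(perm.shape[0]), j] for j in range(perm.shape[1])],
            axis=1,
        )
        null.append(_mean_adjacent_dprime(shuffled))
    lo, hi = np.quantile(null, [0.005, 0.995])
    assert lo <= observed <= hi + 0.05 * (hi - lo)


def test_high_adjacent_corr_gives_strong_adjacent_dprime():
    """Copy probability 0.99 with common alleles: mean adjacent D' > 0.8
    (direct-counting oracle, 200 founders x 100 loci)."""
    cfg = SimConfig(n_founders=200, n_chromosomes=1, snps_per_chromosome=100,
                    adjacent_corr=0.99, weak_ld_prob=0.0,
                    n_ancestral_haplotypes=None, maf_range=(0.3, 0.5), seed=1)
    panel, _ = simulate_haplotype_panel(cfg)
    assert _mean_adjacent_dprime(panel.haplotypes()) > 0.8


def test_adjacent_dprime_increases_with_adjacent_corr():
    means = []
    for c in (0.2, 0.6, 0.95):
        vals = []
        for seed in (1, 2, 3):
            cfg = SimConfig(n_founders=200, n_chromosomes=1,
                            snps_per_chromosome=60, adjacent_corr=c,
                            weak_ld_prob=0.0, n_ancestral_haplotypes=None,
                            maf_range=(0.2, 0.5), seed=seed)
            panel, _ = simulate_haplotype_panel(cfg)
            vals.append(_mean_adjacent_dprime(panel.haplotypes()))
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_single_generation_pedigree_is_founders_only():
    ped = simulate_pedigree(SimConfig(n_founders=7, n_generations=1, seed=0))
    assert ped.n_animals == 7
    assert ped.founders() == ped.animals


def test_pedigree_structure_and_parent_offspring_relationship():
    cfg = SimConfig(n_founders=10, n_generations=3, offspring_per_mating=2, seed=7)
    ped = simulate_pedigree(cfg)
    sire, dam = ped.parent_indices()
    # parents-first ordering and no self-ancestry are certified at
    # construction; every non-founder has both parents recorded
    non_founders = [i for i in range(ped.n_animals) if sire[i] >= 0 or dam[i] >= 0]
    assert all(sire[i] >= 0 and dam[i] >= 0 for i in non_founders)
    A = additive_relationship(ped)
    gens = ped.generations()
    # offspring of two non-inbred founders: a = 0.5 with each parent
    i = next(i for i in range(ped.n_animals) if gens[i] == 1)
    assert A.values[i, sire[i]] == pytest.approx(0.5)
    assert A.values[i, dam[i]] == pytest.approx(0.5)


def test_gene_drop_zero_recombination_transmits_intact_haplotypes():
    cfg = SimConfig(n_founders=12, n_generations=3, snps_per_chromosome=30,
                    n_chromosomes=2, seed=3)
    founder_panel, mm = simulate_haplotype_panel(cfg)
    ped = simulate_pedigree(cfg)
    panel = drop_genotypes(ped, founder_panel, mm, recomb_prob=0.0, seed=4)
    pos = {a: i for i, a in enumerate(panel.animal_ids)}
    sire, dam = ped.parent_indices()
    ranges = mm.chromosome_ranges()
    for i, animal in enumerate(ped.animals):
        if sire[i] < 0:
            continue
        for h, parent in ((0, sire[i]), (1, dam[i])):
            gamete = panel.alleles[pos[animal], h]
            parent_haps = panel.alleles[pos[ped.animals[parent]]]
            for _, s, e in ranges:
                seg = gamete[s:e]
                assert (np.array_equal(seg, parent_haps[0, s:e])
                        or np.array_equal(seg, parent_haps[1, s:e]))


def test_gene_drop_switch_rate_matches_recombination_probability():
    """With distinguishable parental haplotypes (all-0 vs all-1), the gamete
    switch rate between adjacent loci is a direct count of recombinations."""
    m = 51
    n_off = 2500
    rows = [{"animal": "p0", "sire": None, "dam": None, "generation": 0},
            {"animal": "p1", "sire": None, "dam": None, "generation": 0}]
    rows += [{"animal": f"o{k}", "sire": "p0", "dam": "p1", "generation": 1}
             for k in range(n_off)]
    from haplopred.panel import Pedigree, HaplotypePanel
    ped = Pedigree(pd.DataFrame(rows))
    founder = HaplotypePanel(
        ("p0", "p1"),
        np.stack([
            np.stack([np.zeros(m), np.ones(m)]),
            np.stack([np.zeros(m), np.ones(m)]),
        ]).astype(np.uint8),
    )
    mm = make_map(m)
    panel = drop_genotypes(ped, founder, mm, recomb_prob=0.5, seed=9)
    pos = {a: i for i, a in enumerate(panel.animal_ids)}
    switches = total = 0
    for k in range(n_off):
        for h in range(2):
            g = panel.alleles[pos[f"o{k}"], h]
            switches += int(np.sum(g[1:] != g[:-1]))
            total += m - 1
    rate = switches / total
    se = np.sqrt(0.25 / total)
    assert abs(rate - 0.5) < 4 * se


def test_gene_drop_no_systematic_frequency_drift():
    cfg = SimConfig(n_founders=200, n_generations=3, snps_per_chromosome=50,
                    n_chromosomes=1, seed=21)
    founder_panel, mm = simulate_haplotype_panel(cfg)
    ped = simulate_pedigree(cfg)
    panel = drop_genotypes(ped, founder_panel, mm, recomb_prob=0.01, seed=22)
    f0 = founder_panel.alt_freq()
    gens = ped.generations()
    last = [a for a, g in zip(ped.animals, gens) if g == gens.max()]
    f_last = panel.subset_animals(last).alt_freq()
    nh = 2 * len(last)
    se = np.sqrt(np.maximum(f0 * (1 - f0), 1e-4) / nh)
    # drift accumulates over generations; 6-sigma-per-locus bound catches
    # systematic bias while tolerating genuine binomial wobble
    assert np.all(np.abs(f_last - f0) < 6 * se + 0.02)


def test_perfect_reliability_makes_drp_equal_tbv():
    cfg = SimConfig(n_founders=50, n_generations=1, snps_per_chromosome=50,
                    n_qtl=20, drp_reliability_range=(1 - 1e-9, 1 - 1e-9), seed=2)
    panel, mm = simulate_haplotype_panel(cfg)
    ph = simulate_phenotypes(panel, mm, cfg)
    drp = ph.drp.for_trait("sim")["drp"]
    assert np.allclose(drp.to_numpy(), ph.tbv.loc[drp.index].to_numpy(), atol=1e-3)


def test_realized_heritability_calibration():
    cfg = SimConfig(n_founders=2000, n_generations=1, snps_per_chromosome=120,
                    n_chromosomes=2, n_qtl=60, h2=0.39, seed=3)
    panel, mm = simulate_haplotype_panel(cfg)
    ph = simulate_phenotypes(panel, mm, cfg)
    r2 = np.corrcoef(ph.tbv, ph.phenotype)[0, 1] ** 2
    assert abs(r2 - 0.39) < 0.03


def test_null_qtl_architecture_gives_zero_tbv():
    cfg = SimConfig(n_founders=40, n_generations=1, snps_per_chromosome=30,
                    n_qtl=10, mixture_props=(1, 0, 0, 0),
                    mixture_sds=(0.0, 0.1, 0.5, 1.0), seed=4)
    panel, mm = simulate_haplotype_panel(cfg)
    ph = simulate_phenotypes(panel, mm, cfg)
    assert np.all(ph.tbv.to_numpy() == 0.0)
    assert np.all(ph.drp.for_trait("sim")["drp"].to_numpy() == 0.0)


def test_squared_drp_tbv_correlation_approaches_mean_reliability():
    cfg = SimConfig(n_founders=4000, n_generations=1, snps_per_chromosome=100,
                    n_qtl=50, drp_reliability_range=(0.6, 0.9), seed=6)
    panel, mm = simulate_haplotype_panel(cfg)
    ph = simulate_phenotypes(panel, mm, cfg)
    drp = ph.drp.for_trait("sim")
    r2 = np.corrcoef(ph.tbv.loc[drp.index], drp["drp"])[0, 1] ** 2
    # with heterogeneous reliabilities the squared correlation tracks a
    # weighted average of r2; the arithmetic mean is close at this range
    assert abs(r2 - drp["reliability"].mean()) < 0.04


def test_dataset_determinism_and_split():
    cfg = SimConfig(n_founders=20, n_generations=3, snps_per_chromosome=20, seed=8)
    d1 = simulate_dataset(cfg)
    d2 = simulate_dataset(cfg)
    assert np.array_equal(d1.panel.alleles, d2.panel.alleles)
    assert d1.pedigree == d2.pedigree
    pd.testing.assert_series_equal(d1.phenotypes.tbv, d2.phenotypes.tbv)
    train, test = d1.train_test_ids()
    gens = dict(zip(d1.pedigree.animals, d1.pedigree.generations()))
    assert set(train).isdisjoint(test)
    assert {gens[a] for a in test} == {2}
    assert max(gens[a] for a in train) < 2
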