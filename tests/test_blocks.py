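"""Haploblock construction, variant enumeration and design encodings."""

import numpy as np
import pytest

from haplopred import (
    InputError,
    SimConfig,
    build_blocks,
    build_design,
    enumerate_block_variants,
    partition_summary,
    qc_filter,
    simulate_dataset,
)
from haplopred.blocks import DEFAULT_THRESHOLDS
from haplopred.ld import dprime_matrix

from _util import greedy_partition_oracle, panel_from_haps


def _two_pattern_panel(m=3, n_each=10):
    """Only two complementary haplotypes occur -> all pairwise D' = 1."""
    haps = np.array([[0] * m] * n_each + [[1] * m] * n_each)
    return panel_from_haps(haps)


def test_all_pairs_complete_ld_forms_one_block():
    panel, mm = _two_pattern_panel()
    part = build_blocks(panel, mm, 0.75)
    assert part.n_blocks == 1
    assert part.blocks[0].size == 3
    assert part.nonblocked == ()


def test_threshold_zero_gives_one_block_per_chromosome():
    cfg = SimConfig(n_founders=30, n_chromosomes=3, snps_per_chromosome=20,
                    n_qtl=5, seed=1)
    ds = simulate_dataset(cfg)
    part = build_blocks(ds.panel, ds.marker_map, 0.0)
    assert part.n_blocks == 3
    assert [b.size for b in part.blocks] == [20, 20, 20]
    assert part.n_nonblocked == 0


def test_threshold_above_max_dprime_blocks_nothing():
    rng = np.random.default_rng(3)
    haps = (rng.random((600, 12)) < 0.5).astype(np.uint8)  # independent loci
    panel, mm = panel_from_haps(haps)
    dmat = dprime_matrix(panel.haplotypes())
    d = float(dmat[np.triu_indices(12, 1)].max()) + 1e-6
    part = build_blocks(panel, mm, d)
    assert part.n_blocks == 0
    assert len(part.nonblocked) == 12


def test_threshold_outside_unit_interval_is_an_error():
    panel, mm = _two_pattern_panel()
    with pytest.raises(InputError):
        build_blocks(panel, mm, 1.5)


@pytest.mark.parametrize("seed", range(8))
def test_partition_matches_brute_force_oracle(seed):
    cfg = SimConfig(n_founders=60, n_chromosomes=1,
                    snps_per_chromosome=int(np.random.default_rng(seed).integers(20, 51)),
                    n_qtl=5, seed=seed)
    ds = simulate_dataset(cfg)
    panel, mm, _ = qc_filter(ds.panel, ds.marker_map, 0.01,
                             drop_complete_ld_adjacent=False)
    d = 0.45
    part = build_blocks(panel, mm, d)
    dmat = dprime_matrix(panel.haplotypes())
    blocks, nonblocked = greedy_partition_oracle(dmat, d)
    assert [(b.start, b.end) for b in part.blocks] == blocks
    assert list(part.nonblocked) == nonblocked
    # certification: every within-block pair satisfies the threshold
    for b in part.blocks:
        for i in range(b.start, b.end):
            for j in range(i + 1, b.end):
                assert dmat[i, j] >= d


def test_block_variant_enumeration_counts_and_ordering():
    panel, mm = _two_pattern_panel(m=2, n_each=6)
    part = build_blocks(panel, mm, 0.5)
    cat = enumerate_block_variants(panel, part)
    assert cat.variants[0] == ("00", "11")  # tie broken lexicographically
    assert cat.frequencies[0] == (0.5, 0.5)


def test_variant_frequencies_match_direct_counting():
    cfg = SimConfig(n_founders=40, n_chromosomes=2, snps_per_chromosome=30,
                    n_qtl=5, seed=5)
    ds = simulate_dataset(cfg)
    panel, mm, _ = qc_filter(ds.panel, ds.marker_map, 0.01,
                             drop_complete_ld_adjacent=False)
    part = build_blocks(panel, mm, 0.45)
    cat = enumerate_block_variants(panel, part)
    haps = panel.haplotypes()
    n2 = haps.shape[0]
    for bi, b in enumerate(part.blocks):
        strings = ["".join(map(str, row)) for row in haps[:, b.start:b.end]]
        assert sum(cat.frequencies[bi]) == pytest.approx(1.0)
        assert len(cat.variants[bi]) <= min(2 ** b.size, n2)
        for v, f in zip(cat.variants[bi], cat.frequencies[bi]):
            assert f == pytest.approx(strings.count(v) / n2)


def test_design_snp_mode_equals_minor_allele_dosage():
    rng = np.random.default_rng(11)
    haps = (rng.random((30, 5)) < [0.2, 0.8, 0.5, 0.35, 0.9]).astype(np.uint8)
    panel, mm = panel_from_haps(haps)
    part = build_blocks(panel, mm, 1.0)  # nothing blocks at d=1 w.h.p. here
    design = build_design(panel, part, None, "snp", mm)
    freqs = haps.mean(axis=0)
    dosage = haps.reshape(15, 2, 5).sum(axis=1)
    for j in range(5):
        expected = dosage[:, j] if freqs[j] <= 0.5 else 2 - dosage[:, j]
        assert np.array_equal(design.values[:, j], expected)
        assert design.column_meta[j] == ("snp", f"1_m{j}")


def test_block_columns_sum_to_two_per_animal_and_encode_variant_copies():
    panel, mm = _two_pattern_panel(m=3, n_each=8)
    part = build_blocks(panel, mm, 0.5)
    cat = enumerate_block_variants(panel, part)
    for mode in ("blocks_plus_nonblocked", "blocks_only"):
        design = build_design(panel, part, cat, mode, mm)
        block_cols = [k for k, meta in enumerate(design.column_meta)
                      if meta[0] == "block"]
        sums = design.values[:, block_cols].sum(axis=1)
        assert np.all(sums == 2)
    # an animal homozygous for variant "000" counts 2 in that column only
    design = build_design(panel, part, cat, "blocks_only", mm)
    col_of = {meta[2]: k for k, meta in enumerate(design.column_meta)}
    assert design.values[0, col_of["000"]] == 2
    assert design.values[0, col_of["111"]] == 0


def test_unknown_encoding_mode_is_an_error():
    panel, mm = _two_pattern_panel()
    part = build_blocks(panel, mm, 0.5)
    cat = enumerate_block_variants(panel, part)
    with pytest.raises(InputError, match="mode"):
        build_design(panel, part, cat, "haplotype_soup", mm)


def test_partition_summary_on_single_chromosome_limits():
    panel, mm = _two_pattern_panel(m=4, n_each=5)
    part = build_blocks(panel, mm, 0.0)
    cat = enumerate_block_variants(panel, part)
    s = partition_summary(part, cat)
    assert (s.n_blocks, s.n_nonblocked) == (1, 0)
    assert s.threshold == 0.0
    assert s.n_variables == 2  # only two haplotype strings exist


def test_partition_cover_and_disjointness_across_thresholds():
    cfg = SimConfig(n_founders=50, n_chromosomes=2, snps_per_chromosome=40,
                    n_qtl=5, seed=9)
    ds = simulate_dataset(cfg)
    panel, mm, _ = qc_filter(ds.panel, ds.marker_map, 0.01,
                             drop_complete_ld_adjacent=False)
    for d in DEFAULT_THRESHOLDS:
        part = build_blocks(panel, mm, d)
        covered = sorted(
            [i for b in part.blocks for i in b.marker_indices] + list(part.nonblocked)
        )
        assert covered == list(range(mm.n_markers))  # cover + disjoint
        assert all(b.size >= 2 for b in part.blocks)
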