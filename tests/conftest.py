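import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import haplopred as hp
from haplopred.evaluation import _trivial_partition


@pytest.fixture(scope="session")
def small_instance():
    """A 50-training-animal, ~30-column instance shared by sampler tests."""
    cfg = hp.SimConfig(n_founders=40, n_generations=2, n_chromosomes=1,
                       snps_per_chromosome=30, n_qtl=10, h2=0.4,
                       drp_reliability_range=(0.5, 0.95), seed=123)
    ds = hp.simulate_dataset(cfg)
    panel, mm, _ = hp.qc_filter(ds.panel, ds.marker_map, 0.05,
                                drop_complete_ld_adjacent=True)
    design = hp.build_design(panel, _trivial_partition(mm), None, "snp", mm)
    A = hp.additive_relationship(ds.pedigree)
    train, test = ds.train_test_ids()
    train = train[:50]
    frame = ds.phenotypes.drp.for_trait("sim")
    minput = hp.build_model_input(design, frame, A, train)
    return {
        "dataset": ds, "panel": panel, "map": mm, "design": design,
        "A": A, "train": train, "test": test, "frame": frame,
        "model_input": minput,
    }


@pytest.fixture(scope="session")
def recovery_instance():
    """The larger parameter-recovery setting: ~1,000 training and ~340 test
    animals on a 600-marker panel with a sparse 10-QTL architecture."""
    cfg = hp.SimConfig(
        n_founders=340, n_generations=4, n_chromosomes=2,
        snps_per_chromosome=300, n_qtl=10,
        mixture_props=(0.0, 0.0, 0.0, 1.0), mixture_sds=(0.0, 0.1, 0.5, 1.0),
        h2=0.39, drp_reliability_range=(0.75, 0.95), seed=2024,
    )
    ds = hp.simulate_dataset(cfg)
    panel, mm, _ = hp.qc_filter(ds.panel, ds.marker_map, 0.01,
                                drop_complete_ld_adjacent=False)
    design = hp.build_design(panel, _trivial_partition(mm), None, "snp", mm)
    A = hp.additive_relationship(ds.pedigree)
    train, test = ds.train_test_ids()
    frame = ds.phenotypes.drp.for_trait("sim")
    minput = hp.build_model_input(design, frame, A, train)
    return {
        "dataset": ds, "panel": panel, "map": mm, "design": design,
        "A": A, "train": train, "test": test, "frame": frame,
        "model_input": minput,
    }
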