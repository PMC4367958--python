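"""Shared helpers for the test suite: tiny panel builders and independent
oracles (coded from scratch here, separate from the package's own paths)."""

from __future__ import annotations

import numpy as np

from haplopred.panel import HaplotypePanel, MarkerMap


def make_map(n_markers: int, chrom: str = "1", start_index: int = 0) -> MarkerMap:
    return MarkerMap(
        chromosome=np.array([chrom] * n_markers, dtype=object),
        position=np.arange(1, n_markers + 1) * 100,
        marker_id=np.array(
            [f"{chrom}_m{j + start_index}" for j in range(n_markers)], dtype=object
        ),
        ref_allele=np.array(["A"] * n_markers, dtype=object),
        alt_allele=np.array(["G"] * n_markers, dtype=object),
    )


def panel_from_haps(haps: np.ndarray, chrom: str = "1") -> tuple[HaplotypePanel, MarkerMap]:
    """Build a panel from a 2n x m haplotype matrix (rows paired per animal)."""
    haps = np.asarray(haps, dtype=np.uint8)
    nh, m = haps.shape
    assert nh % 2 == 0
    n = nh // 2
    panel = HaplotypePanel(
        tuple(f"a{i}" for i in range(n)), haps.reshape(n, 2, m)
    )
    return panel, make_map(m, chrom)


def dprime_oracle(haps: np.ndarray, i: int, j: int) -> float:
    """D' by direct counting of the four haplotype classes (independent of
    the package's LD code path)."""
    hi, hj = haps[:, i], haps[:, j]
    nh = len(hi)
    f00 = np.sum((hi == 0) & (hj == 0)) / nh
    p0 = np.mean(hi == 0)
    q0 = np.mean(hj == 0)
    d = f00 - p0 * q0
    if d == 0:
        return 0.0
    if d > 0:
        dmax = min(p0 * (1 - q0), (1 - p0) * q0)
    else:
        dmax = min(p0 * q0, (1 - p0) * (1 - q0))
    return abs(d) / dmax


def greedy_partition_oracle(dmat: np.ndarray, d: float):
    """Brute-force greedy left-to-right maximal extension from a full D'
    matrix; returns (blocks as (start, end) tuples, non-blocked indices)."""
    m = dmat.shape[0]
    blocks, nonblocked = [], []
    j = 0
    while j < m:
        end = j + 1
        while end < m and all(dmat[i, end] >= d for i in range(j, end)):
            end += 1
        if end - j >= 2:
            blocks.append((j, end))
        else:
            nonblocked.append(j)
        j = end
    return blocks, nonblocked


def solve_mme(model_input, sigma2_g: float, sigma2_a: float, sigma2_e: float):
    """Direct weighted mixed-model-equation solution (Henderson's equations
    with a diagonal residual weight matrix) — the fixed-variance oracle."""
    y, w, M = model_input.y, model_input.weights, model_input.M
    n, q = M.shape
    na = model_input.A.values.shape[0]
    Ainv = np.linalg.inv(model_input.A.values)
    Z = np.zeros((n, na))
    Z[np.arange(n), model_input.record_animal_index] = 1.0
    X = np.ones((n, 1))
    W = np.diag(w) / sigma2_e
    C = np.block([
        [X.T @ W @ X, X.T @ W @ M, X.T @ W @ Z],
        [M.T @ W @ X, M.T @ W @ M + np.eye(q) / sigma2_g, M.T @ W @ Z],
        [Z.T @ W @ X, Z.T @ W @ M, Z.T @ W @ Z + Ainv / sigma2_a],
    ])
    rhs = np.concatenate([X.T @ W @ y, M.T @ W @ y, Z.T @ W @ y])
    sol = np.linalg.solve(C, rhs)
    return float(sol[0]), sol[1:1 + q], sol[1 + q:]


def batch_means_se(samples: np.ndarray, n_batches: int = 20) -> np.ndarray:
    """Monte-Carlo standard error of the chain mean by batch means."""
    samples = np.atleast_2d(samples.T).T
    n = samples.shape[0] // n_batches * n_batches
    batches = samples[:n].reshape(n_batches, -1, samples.shape[1]).mean(axis=1)
    return batches.std(axis=0, ddof=1) / np.sqrt(n_batches)


def random_pedigree_frame(rng: np.random.Generator, n_founders: int, n_extra: int):
    """Random valid pedigree rows for fuzzing (parents always earlier)."""
    import pandas as pd

    rows = [
        {"animal": f"f{i}", "sire": None, "dam": None, "generation": 0}
        for i in range(n_founders)
    ]
    for k in range(n_extra):
        n_avail = len(rows)
        s = rng.integers(0, n_avail)
        d = rng.integers(0, n_avail)
        rows.append({
            "animal": f"x{k}",
            "sire": rows[s]["animal"] if rng.random() < 0.9 else None,
            "dam": rows[d]["animal"] if rng.random() < 0.9 else None,
            "generation": 1 + k,
        })
    return pd.DataFrame(rows)
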