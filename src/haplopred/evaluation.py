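"""Prediction evaluation: GEBV, reliability, bias, Hotelling's test, top-k
overlap, and the scenario grid driver.

GEBV of animal i is  ``sum_j m_ij * g_hat_j + a_hat_i``  (posterior means).
Predictive performance on the test set is summarised by:

* **reliability**  r2 = cor(DRP, GEBV)^2 / mean(r2_DRP) — the squared
  DRP-GEBV correlation corrected for the average reliability of the DRP
  themselves;
* **bias** b = OLS slope of DRP on GEBV (1 = unbiased dispersion);
* **Hotelling's test** for two dependent correlations sharing the DRP
  vector:  t = (r1y - r2y) * sqrt((n-3)(1+r12) / (2|R|)),  df = n-3, with
  |R| the determinant of the 3x3 correlation matrix of (DRP, GEBV_1, GEBV_2).

The scenario grid enumerates, per trait: the individual-SNP encoding, plus
blocks-with-non-blocked-SNPs and blocks-only at each D' threshold — 13
scenarios at the conventional six thresholds — and fits each under each
requested model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import (
    DEFAULT_THRESHOLDS,
    DesignMatrix,
    build_blocks,
    build_design,
    enumerate_block_variants,
    partition_summary,
)
from .errors import InputError, UndefinedCorrelationError
from .models import (
    MCMCConfig,
    MixturePrior,
    FitResult,
    build_model_input,
    fit_blup,
    fit_mixture,
)
from .panel import DRPTable, HaplotypePanel, MarkerMap, Pedigree
from .relationship import additive_relationship

__all__ = [
    "GEBVTable",
    "EvaluationResult",
    "HotellingResult",
    "predict_gebv",
    "reliability",
    "hotelling_test",
    "topk_overlap",
    "list_scenarios",
    "run_scenarios",
]


@dataclass(frozen=True)
class GEBVTable:
    animal_ids: tuple
    gebv: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.gebv, dtype=np.float64)
        if vals.shape != (len(self.animal_ids),):
            raise InputError("one GEBV per animal required")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise InputError("duplicate animal in GEBV table")
        object.__setattr__(self, "gebv", vals)
        object.__setattr__(self, "animal_ids", tuple(self.animal_ids))

    def series(self) -> pd.Series:
        return pd.Series(self.gebv, index=list(self.animal_ids), name="gebv")


@dataclass(frozen=True)
class EvaluationResult:
    reliability: float
    bias_slope_b: float
    raw_correlation: float
    mean_drp_reliability: float
    n_test: int

    def __post_init__(self) -> None:
        expected = self.raw_correlation**2 / self.mean_drp_reliability
        if abs(self.reliability - expected) > 1e-12:
            raise InputError("reliability does not satisfy its defining identity")


@dataclass(frozen=True)
class HotellingResult:
    t_statistic: float
    p_value: float
    r_1y: float
    r_2y: float
    r_12: float
    determinant_D: float
    n: int
    sidedness: str


def predict_gebv(fit: FitResult, design_test: DesignMatrix) -> GEBVTable:
    """GEBV = M_test @ g_hat + a_hat for the design's animals."""
    if design_test.column_meta != fit.column_meta:
        raise InputError("test design columns do not match the fitted model")
    marker_part = design_test.values.astype(np.float64) @ fit.g_mean
    poly_part = fit.a_for(design_test.animal_ids)
    return GEBVTable(design_test.animal_ids, marker_part + poly_part)


def reliability(
    drp: np.ndarray, gebv: np.ndarray, drp_reliabilities: np.ndarray
) -> EvaluationResult:
    """Reliability-corrected squared correlation and the bias slope b."""
    drp = np.asarray(drp, dtype=np.float64)
    gebv = np.asarray(gebv, dtype=np.float64)
    r2d = np.asarray(drp_reliabilities, dtype=np.float64)
    n = len(drp)
    if n < 3 or len(gebv) != n or len(r2d) != n:
        raise InputError("need >= 3 aligned (drp, gebv, reliability) triples")
    if np.std(gebv) == 0 or np.std(drp) == 0:
        raise UndefinedCorrelationError("constant DRP or GEBV vector")
    r = float(np.corrcoef(drp, gebv)[0, 1])
    rbar = float(np.mean(r2d))
    b = float(np.cov(drp, gebv, ddof=1)[0, 1] / np.var(gebv, ddof=1))
    return EvaluationResult(
        reliability=r * r / rbar,
        bias_slope_b=b,
        raw_correlation=r,
        mean_drp_reliability=rbar,
        n_test=n,
    )


def hotelling_test(
    drp: np.ndarray,
    gebv_1: np.ndarray,
    gebv_2: np.ndarray,
    sidedness: str = "two",
) -> HotellingResult:
    """Hotelling's test of equality of two correlations sharing the DRP.

    Two-sided tests H0: rho_1y = rho_2y.  One-sided reports p = P(T >= t),
    the test of H0: rho_1y <= rho_2y — a small p means the first GEBV is
    significantly *more* correlated with DRP than the second.  t = 0 and the
    two-sided p = 1 when the two GEBV vectors are identical.
    """
    if sidedness not in ("one", "two"):
        raise InputError(f"sidedness must be 'one' or 'two'; got {sidedness!r}")
    y = np.asarray(drp, dtype=np.float64)
    g1 = np.asarray(gebv_1, dtype=np.float64)
    g2 = np.asarray(gebv_2, dtype=np.float64)
    n = len(y)
    if n < 5 or len(g1) != n or len(g2) != n:
        raise InputError("need >= 5 aligned observations")
    for name, v in (("drp", y), ("gebv_1", g1), ("gebv_2", g2)):
        if np.std(v) == 0:
            raise UndefinedCorrelationError(f"{name} is constant")
    r1y = float(np.corrcoef(y, g1)[0, 1])
    r2y = float(np.corrcoef(y, g2)[0, 1])
    r12 = float(np.corrcoef(g1, g2)[0, 1])
    det = float(
        1.0 - r1y**2 - r2y**2 - r12**2 + 2.0 * r1y * r2y * r12
    )
    df = n - 3
    if det <= 0 or np.isclose(r1y, r2y, atol=1e-15):
        t = 0.0 if np.isclose(r1y, r2y, atol=1e-15) else np.inf * np.sign(r1y - r2y)
    else:
        t = (r1y - r2y) * np.sqrt(df * (1.0 + r12) / (2.0 * det))
    if sidedness == "two":
        p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        p = min(p, 1.0)
    else:
        p = float(stats.t.sf(t, df)) if np.isfinite(t) else (0.0 if t > 0 else 1.0)
    return HotellingResult(
        t_statistic=float(t), p_value=p,
        r_1y=r1y, r_2y=r2y, r_12=r12,
        determinant_D=det, n=n, sidedness=sidedness,
    )


def topk_overlap(gebv_a: GEBVTable, gebv_b: GEBVTable, k: int) -> float:
    """Percent of the top-k animals (by descending GEBV, ties by animal id)
    shared between two rankings over the same animal set."""
    if set(gebv_a.animal_ids) != set(gebv_b.animal_ids):
        raise InputError("GEBV tables cover different animal sets")
    n = len(gebv_a.animal_ids)
    if not (1 <= k <= n):
        raise InputError(f"k must lie in [1, {n}]; got {k}")

    def top(table: GEBVTable) -> set:
        order = sorted(
            zip(table.animal_ids, table.gebv), key=lambda t: (-t[1], t[0])
        )
        return {aid for aid, _ in order[:k]}

    return 100.0 * len(top(gebv_a) & top(gebv_b)) / k


def list_scenarios(thresholds=DEFAULT_THRESHOLDS) -> list[tuple[str, float | None]]:
    """The scenario grid: one SNP scenario plus two block encodings per
    threshold (13 scenarios at the six conventional thresholds)."""
    thresholds = list(thresholds)
    if not thresholds:
        raise InputError("at least one threshold is required")
    out: list[tuple[str, float | None]] = [("snp", None)]
    out += [("blocks_plus_nonblocked", d) for d in thresholds]
    out += [("blocks_only", d) for d in thresholds]
    return out


def run_scenarios(
    panel: HaplotypePanel,
    marker_map: MarkerMap,
    pedigree: Pedigree,
    drp: DRPTable,
    train_ids,
    test_ids,
    thresholds=DEFAULT_THRESHOLDS,
    models=("blup", "mixture"),
    cfg: MCMCConfig = MCMCConfig(),
    mixture_prior: MixturePrior = MixturePrior(),
    tbv=None,
    top_k: int = 10,
) -> pd.DataFrame:
    """Fit and evaluate every scenario for every trait and model.

    Returns one row per (trait, scenario, model) with the block accounting,
    reliability, bias slope, raw correlation, top-k overlap with the SNP
    baseline of the same model, and the Hotelling p-value against that
    baseline.  When ``tbv`` (a Series keyed by animal) is given, the
    correlation of GEBV with true breeding values on the test set is added.
    """
    for model in models:
        if model not in ("blup", "mixture"):
            raise InputError(f"unknown model {model!r}")
    scenarios = list_scenarios(thresholds)
    A = additive_relationship(pedigree)

    partitions: dict[float, tuple] = {}
    designs: dict[tuple, DesignMatrix] = {}
    summaries: dict[float, object] = {}
    for mode, d in scenarios:
        if mode == "snp":
            designs[(mode, None)] = build_design(panel, _trivial_partition(marker_map),
                                                 None, "snp", marker_map)
        else:
            if d not in partitions:
                part = build_blocks(panel, marker_map, d)
                cat = enumerate_block_variants(panel, part)
                partitions[d] = (part, cat)
                summaries[d] = partition_summary(part, cat)
            part, cat = partitions[d]
            designs[(mode, d)] = build_design(panel, part, cat, mode, marker_map)

    rows = []
    for trait in drp.traits:
        frame = drp.for_trait(trait)
        train = [a for a in train_ids if a in frame.index]
        test = [a for a in test_ids if a in frame.index]
        baselines: dict[str, GEBVTable] = {}
        for model in models:
            for idx, (mode, d) in enumerate(scenarios):
                design = designs[(mode, d)]
                minput = build_model_input(design, frame, A, train)
                scenario_seed = (int(cfg.seed) + 7919 * idx) % (2**31)
                run_cfg = MCMCConfig(cfg.n_cycles, cfg.burn_in, cfg.thin,
                                     scenario_seed, cfg.keep_samples)
                if model == "blup":
                    fit = fit_blup(minput, run_cfg)
                else:
                    fit = fit_mixture(minput, mixture_prior, run_cfg)
                gebv = predict_gebv(fit, design.subset_animals(test))
                ev = reliability(
                    frame.loc[test, "drp"].to_numpy(),
                    gebv.gebv,
                    frame.loc[test, "reliability"].to_numpy(),
                )
                row = {
                    "trait": trait,
                    "model": model,
                    "encoding": mode,
                    "threshold": d,
                    "n_columns": design.n_columns,
                    "reliability": ev.reliability,
                    "bias_b": ev.bias_slope_b,
                    "raw_correlation": ev.raw_correlation,
                    "n_train": len(train),
                    "n_test": ev.n_test,
                }
                if d is not None:
                    s = summaries[d]
                    row.update(n_blocks=s.n_blocks, n_variables=s.n_variables,
                               n_nonblocked=s.n_nonblocked)
                else:
                    row.update(n_blocks=0, n_variables=0,
                               n_nonblocked=marker_map.n_markers)
                if mode == "snp":
                    baselines[model] = gebv
                    row.update(hotelling_p_vs_snp=np.nan, topk_overlap_vs_snp=np.nan)
                else:
                    base = baselines[model]
                    ht = hotelling_test(
                        frame.loc[test, "drp"].to_numpy(), gebv.gebv, base.gebv
                    )
                    row.update(
                        hotelling_p_vs_snp=ht.p_value,
                        topk_overlap_vs_snp=topk_overlap(gebv, base,
                                                         min(top_k, len(test))),
                    )
                if tbv is not None:
                    row["cor_gebv_tbv"] = float(
                        np.corrcoef(gebv.gebv, tbv.loc[test].to_numpy())[0, 1]
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def _trivial_partition(marker_map: MarkerMap):
    """An all-non-blocked partition, used to drive the SNP encoding."""
    from .blocks import BlockPartition

    return BlockPartition(
        threshold_d=1.0,
        blocks=(),
        nonblocked=tuple(range(marker_map.n_markers)),
        n_markers=marker_map.n_markers,
    )
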