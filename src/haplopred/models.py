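"""Weighted BLUP and Bayesian four-component mixture models for DRP.

Both models share the linear predictor

    y = 1*mu + M g + Z a + eps

where ``y`` holds the training animals' de-regressed proofs, ``M`` is the
SNP/haploblock design, ``a`` is a residual polygenic effect with covariance
``A * sigma2_a`` over *all* animals (training and candidates — candidate
animals carry no records and their effect is sampled from its pedigree
conditional), and the residual of record i has variance ``sigma2_e / w_i``
with the de-regression weight ``w_i = r2_i / (1 - r2_i)``.

The BLUP model places a single normal prior N(0, sigma2_g) on every column
effect; the mixture model replaces it with a four-component normal mixture
with fixed proportions (defaults 0.889 / 0.1 / 0.01 / 0.001) and
order-constrained, uniformly distributed component variances, so most
effects stay near zero while a few may be large.  Both are fit by
single-chain Gibbs sampling; the default schedule is 50,000 cycles with a
20,000-cycle burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from . import _gibbs
from .blocks import DesignMatrix
from .errors import ConfigurationError, InputError
from .relationship import RelationshipMatrix

__all__ = [
    "MCMCConfig",
    "MixturePrior",
    "ModelInput",
    "FitResult",
    "drp_weights",
    "build_model_input",
    "fit_blup",
    "fit_mixture",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain schedule; the default mirrors the conventional 50k/20k run."""

    n_cycles: int = 50_000
    burn_in: int = 20_000
    thin: int = 1
    seed: int = 0
    keep_samples: bool = False

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.burn_in < 0 or self.thin < 1:
            raise ConfigurationError("n_cycles, burn_in, thin must be positive counts")
        if self.burn_in >= self.n_cycles:
            raise ConfigurationError(
                f"burn_in ({self.burn_in}) must be smaller than n_cycles ({self.n_cycles})"
            )


@dataclass(frozen=True)
class MixturePrior:
    """Fixed mixing proportions; component variances are sampled subject to
    the ordering constraint sigma2_1 <= ... <= sigma2_4."""

    proportions: tuple = (0.889, 0.1, 0.01, 0.001)

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        if props.shape != (4,):
            raise ConfigurationError("mixture prior needs exactly 4 proportions")
        if (props < 0).any():
            raise ConfigurationError("mixture proportions must be non-negative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"mixture proportions must sum to 1; got {props.sum()!r}"
            )
        object.__setattr__(self, "proportions", tuple(props))


@dataclass(frozen=True)
class ModelInput:
    """Aligned training data: records, weights, design rows and the
    relationship matrix over every animal appearing in the analysis."""

    y: np.ndarray               # DRP per training record
    weights: np.ndarray         # w_i > 0 per record
    M: np.ndarray               # training rows of the design, float64
    A: RelationshipMatrix       # over all animals (training + candidates)
    record_animal_index: np.ndarray  # index into A's animal order, per record
    column_meta: tuple = ()

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=np.float64)
        w = np.asarray(self.weights, dtype=np.float64)
        M = np.ascontiguousarray(np.asarray(self.M, dtype=np.float64))
        rec = np.asarray(self.record_animal_index, dtype=np.int64)
        n = len(y)
        if w.shape != (n,) or M.shape[0] != n or rec.shape != (n,):
            raise InputError("model input dimensions are inconsistent")
        if not np.all(np.isfinite(w)) or (w <= 0).any():
            raise InputError("weights must be finite and strictly positive")
        na = len(self.A.animal_ids)
        if rec.min(initial=0) < 0 or (n and rec.max() >= na):
            raise InputError("record_animal_index out of range of A")
        if len(np.unique(rec)) != n:
            raise InputError("each animal may carry at most one record")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "record_animal_index", rec)


@dataclass(frozen=True)
class FitResult:
    """Posterior summaries of one Gibbs run."""

    model: str                      # "blup" or "mixture"
    mu_mean: float
    mu_sd: float
    g_mean: np.ndarray
    g_sd: np.ndarray
    a_mean: np.ndarray              # per animal, in A's order
    a_sd: np.ndarray
    animal_ids: tuple
    column_meta: tuple
    variances: dict                 # posterior means/sds of variance components
    comp_freq: np.ndarray | None    # q x 4 membership frequencies (mixture)
    diagnostics: dict
    samples: dict | None = None

    def a_for(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        return self.a_mean[[pos[a] for a in ids]]


def drp_weights(reliabilities: np.ndarray) -> np.ndarray:
    """De-regression weights w = r2 / (1 - r2); residual variance of record i
    is sigma2_e / w_i."""
    r2 = np.asarray(reliabilities, dtype=np.float64)
    if ((r2 <= 0.0) | (r2 >= 1.0)).any():
        bad = r2[(r2 <= 0.0) | (r2 >= 1.0)][0]
        raise InputError(f"reliability must lie strictly in (0,1); got {bad}")
    return r2 / (1.0 - r2)


def build_model_input(
    design: DesignMatrix,
    drp_frame,              # DataFrame indexed by animal: columns drp, reliability
    A: RelationshipMatrix,
    train_ids,
) -> ModelInput:
    """Assemble aligned training arrays from a design matrix, a one-trait DRP
    table and the relationship matrix."""
    train_ids = list(train_ids)
    missing = [a for a in train_ids if a not in drp_frame.index]
    if missing:
        raise InputError(f"no DRP record for training animal {missing[0]!r}")
    sub = drp_frame.loc[train_ids]
    M = design.subset_animals(train_ids).values.astype(np.float64)
    pos = {a: i for i, a in enumerate(A.animal_ids)}
    try:
        rec = np.array([pos[a] for a in train_ids], dtype=np.int64)
    except KeyError as exc:
        raise InputError(f"training animal {exc.args[0]!r} absent from A") from exc
    return ModelInput(
        y=sub["drp"].to_numpy(),
        weights=drp_weights(sub["reliability"].to_numpy()),
        M=M,
        A=A,
        record_animal_index=rec,
        column_meta=design.column_meta,
    )


def _inverse_psd(A: np.ndarray) -> np.ndarray:
    eigmin = float(scipy.linalg.eigvalsh(A, subset_by_index=[0, 0])[0])
    if eigmin < -1e-8:
        raise InputError(f"relationship matrix is not PSD (min eigenvalue {eigmin:.3g})")
    jitter = 0.0 if eigmin > 1e-10 else 1e-8
    c, low = scipy.linalg.cho_factor(A + jitter * np.eye(A.shape[0]))
    return scipy.linalg.cho_solve((c, low), np.eye(A.shape[0]))


def _run(
    model_input: ModelInput,
    cfg: MCMCConfig,
    mixture: bool,
    prior: MixturePrior | None,
    fix_variances: dict | None,
) -> FitResult:
    y = model_input.y
    w = model_input.weights
    M = model_input.M
    n, q = M.shape
    Ainv = _inverse_psd(model_input.A.values)
    na = Ainv.shape[0]
    rec_of_anim = np.full(na, -1, dtype=np.int64)
    for r, ai in enumerate(model_input.record_animal_index):
        rec_of_anim[ai] = r

    var_y = float(np.var(y)) if n > 1 else 1.0
    if var_y <= 0:
        var_y = 1.0
    vmax = 1e4 * var_y
    qq = max(q, 1)
    if fix_variances is None:
        vg0 = var_y / (2.0 * qq)
        va0 = 0.25 * var_y
        ve0 = 0.5 * var_y
        vcomp0 = np.array([1e-4, 1e-3, 1e-2, 1e-1]) * var_y * 10.0 / qq
        update = True
    else:
        vg0 = float(fix_variances.get("sigma2_g", var_y / qq))
        va0 = float(fix_variances["sigma2_a"])
        ve0 = float(fix_variances["sigma2_e"])
        vcomp0 = np.asarray(
            fix_variances.get("sigma2_comp", [vg0, vg0, vg0, vg0]), dtype=float
        )
        update = False
    pi = np.asarray(prior.proportions if prior is not None else (1.0, 0.0, 0.0, 0.0))

    (mu_sum, mu_sq, g_sum, g_sq, a_sum, a_sq, var_sum, var_sq,
     comp_count, n_kept, order_rejects, mu_s, g_s, a_s, var_s) = _gibbs.run_chain(
        y, w, M, Ainv, rec_of_anim,
        cfg.n_cycles, cfg.burn_in, cfg.thin, int(cfg.seed) % (2**31),
        mixture, pi,
        vcomp0.copy(), vg0, va0, ve0, vmax,
        update, cfg.keep_samples,
    )

    def _mean_sd(s, sq):
        mean = s / n_kept
        var = np.maximum(sq / n_kept - mean**2, 0.0)
        return mean, np.sqrt(var)

    mu_mean, mu_sd = _mean_sd(mu_sum, mu_sq)
    g_mean, g_sd = _mean_sd(g_sum, g_sq)
    a_mean, a_sd = _mean_sd(a_sum, a_sq)
    v_mean, v_sd = _mean_sd(var_sum, var_sq)
    variances = {
        "sigma2_a": (v_mean[5], v_sd[5]),
        "sigma2_e": (v_mean[6], v_sd[6]),
    }
    if mixture:
        variances["sigma2_comp"] = (v_mean[1:5].copy(), v_sd[1:5].copy())
    else:
        variances["sigma2_g"] = (v_mean[0], v_sd[0])
    samples = None
    if cfg.keep_samples:
        samples = {"mu": mu_s, "g": g_s, "a": a_s, "variances": var_s}
    return FitResult(
        model="mixture" if mixture else "blup",
        mu_mean=float(mu_mean),
        mu_sd=float(mu_sd),
        g_mean=g_mean,
        g_sd=g_sd,
        a_mean=a_mean,
        a_sd=a_sd,
        animal_ids=model_input.A.animal_ids,
        column_meta=model_input.column_meta,
        variances=variances,
        comp_freq=(comp_count / n_kept) if mixture else None,
        diagnostics={
            "n_kept": int(n_kept),
            "order_rejects": int(order_rejects),
            "n_cycles": cfg.n_cycles,
            "burn_in": cfg.burn_in,
            "seed": cfg.seed,
        },
        samples=samples,
    )


def fit_blup(
    model_input: ModelInput,
    cfg: MCMCConfig,
    fix_variances: dict | None = None,
) -> FitResult:
    """Gibbs sampler for the weighted SNP/haploblock BLUP model.

    ``fix_variances={"sigma2_g":..., "sigma2_a":..., "sigma2_e":...}`` holds
    the variance components at given values (no variance updates), which is
    the configuration whose posterior mean equals the weighted
    mixed-model-equation solution.
    """
    return _run(model_input, cfg, mixture=False, prior=None,
                fix_variances=fix_variances)


def fit_mixture(
    model_input: ModelInput,
    prior: MixturePrior = MixturePrior(),
    cfg: MCMCConfig = MCMCConfig(),
    fix_variances: dict | None = None,
) -> FitResult:
    """Gibbs sampler for the four-component mixture model.

    Each column effect carries a categorical component indicator with fixed
    prior proportions; component variances are updated under bounded-uniform
    priors subject to the ordering constraint, effects and variances sampled
    simultaneously within each cycle.
    """
    return _run(model_input, cfg, mixture=True, prior=prior,
                fix_variances=fix_variances)
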