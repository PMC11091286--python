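"""Causal-effect estimators for two-sample Mendelian randomization.

All methods consume a :class:`~mrmediate.sumstats.HarmonizedInstrumentSet`
and summarize the per-SNP Wald ratios theta_j = outcome_beta_j /
exposure_beta_j under different identifying assumptions:

* ``ivw`` — all instruments valid; precision-weighted mean of the ratios,
  equivalent to weighted through-origin regression of outcome on exposure
  effects.
* ``mr_egger`` — pleiotropy may be directional but independent of
  instrument strength (InSIDE); weighted regression with an intercept,
  where the intercept estimates the average pleiotropic effect.
* ``weighted_median`` — at least half the weight comes from valid
  instruments.
* ``weighted_mode`` — the largest cluster of instruments is valid
  (zero-modal pleiotropy assumption).
* ``mvmr_ivw`` — multivariable IVW: conditional direct effects of several
  exposures fitted jointly.

Standard errors for the median and mode come from a parametric bootstrap
with an explicit seed; there is no hidden global RNG anywhere.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .sumstats import HarmonizedInstrumentSet

__all__ = [
    "MREstimate",
    "WaldRatio",
    "Z_95",
    "wald_ratios",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "mvmr_ivw",
    "to_odds_ratio",
]

log = logging.getLogger(__name__)

#: 97.5% normal quantile used for every 95% CI, fixed for cross-method
#: consistency.
Z_95 = 1.959964


class EstimatorError(ValueError):
    """Raised when an estimator's preconditions are not met."""


@dataclass(frozen=True)
class WaldRatio:
    """Single-SNP causal estimate: outcome effect over exposure effect."""

    snp_id: str
    theta: float
    se_theta: float  # first-order: outcome_se / |exposure_beta|

    @property
    def weight(self) -> float:
        return 1.0 / self.se_theta**2


@dataclass
class MREstimate:
    """A causal-effect estimate on the beta (log-odds or SD-unit) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise EstimatorError(
                f"{self.method}: CI [{self.ci_low}, {self.ci_high}] "
                f"does not bracket beta {self.beta}"
            )
        if not (0.0 < self.pval <= 1.0):
            raise EstimatorError(f"{self.method}: pval {self.pval} outside (0, 1]")


def _norm_p(z: float) -> float:
    p = 2.0 * stats.norm.sf(abs(z))
    if p == 0.0:
        p = math.exp(math.log(2.0) + stats.norm.logsf(abs(z)))
    return max(min(p, 1.0), 5e-324)


def _t_p(t: float, df: int) -> float:
    p = 2.0 * stats.t.sf(abs(t), df)
    if p == 0.0:
        p = math.exp(math.log(2.0) + stats.t.logsf(abs(t), df))
    return max(min(p, 1.0), 5e-324)


def _estimate(method: str, beta: float, se: float, pval: float, n_snp: int,
              extras: dict | None = None) -> MREstimate:
    return MREstimate(
        method=method, beta=beta, se=se,
        ci_low=beta - Z_95 * se, ci_high=beta + Z_95 * se,
        pval=pval, n_snp=n_snp, extras=extras or {},
    )


def _arrays(iset: HarmonizedInstrumentSet):
    be = np.array([p.exposure_beta for p in iset.pairs], dtype=float)
    se_e = np.array([p.exposure_se for p in iset.pairs], dtype=float)
    bo = np.array([p.outcome_beta for p in iset.pairs], dtype=float)
    so = np.array([p.outcome_se for p in iset.pairs], dtype=float)
    return be, se_e, bo, so


def wald_ratios(iset: HarmonizedInstrumentSet) -> list[WaldRatio]:
    """Per-SNP Wald ratios theta_j = outcome beta / exposure beta with
    first-order SE = outcome se / |exposure beta| (input order preserved)."""
    out = []
    for p in iset.pairs:
        if p.exposure_beta == 0:
            raise EstimatorError(f"{p.snp_id}: exposure beta is zero, Wald ratio undefined")
        out.append(WaldRatio(
            snp_id=p.snp_id,
            theta=p.outcome_beta / p.exposure_beta,
            se_theta=p.outcome_se / abs(p.exposure_beta),
        ))
    return out


def _ivw_core(theta: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Return (beta, fixed se, Cochran Q at the estimate)."""
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (theta - beta) ** 2))
    return beta, se_fixed, q


def ivw(iset: HarmonizedInstrumentSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate: precision-weighted mean of the
    Wald ratios, with weights 1/se_theta^2.

    ``model="fixed"`` uses SE = (sum w)^-1/2; ``"multiplicative_random"``
    (default) inflates it by max(1, sqrt(Q/(J-1))) where Q is Cochran's Q at
    the point estimate, so overdispersion widens the interval but
    underdispersion never narrows it.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise EstimatorError(f"unknown IVW model {model!r}")
    ratios = wald_ratios(iset)
    j = len(ratios)
    if j == 0:
        raise EstimatorError("ivw requires at least one instrument")
    theta = np.array([r.theta for r in ratios])
    w = np.array([r.weight for r in ratios])
    beta, se, q = _ivw_core(theta, w)
    scale = 1.0
    if model == "multiplicative_random":
        if j == 1:
            warnings.warn("single instrument: random-effects IVW falls back to fixed")
        else:
            scale = max(1.0, math.sqrt(q / (j - 1)))
    se *= scale
    return _estimate(
        "ivw", beta, se, _norm_p(beta / se), j,
        extras={"model": model, "cochran_q": q, "scale_factor": scale},
    )


def mr_egger(iset: HarmonizedInstrumentSet) -> MREstimate:
    """MR-Egger regression: weighted least squares of outcome betas on
    exposure betas *with* an intercept, weights 1/outcome_se^2.

    SNPs are oriented internally so every exposure beta is positive (the
    estimator is not invariant to allele coding).  The slope is the causal
    estimate; the intercept (reported in ``extras``) estimates average
    directional pleiotropy — intercept p > 0.05 is the usual no-pleiotropy
    check.  Residual scale is multiplicative and floored at 1; inference
    uses the t distribution with J - 2 df.
    """
    j = len(iset)
    if j < 3:
        raise EstimatorError(f"mr_egger requires >= 3 instruments, got {j}")
    be, _, bo, so = _arrays(iset)
    sign = np.where(be < 0, -1.0, 1.0)
    x = be * sign
    y = bo * sign
    w = 1.0 / so**2

    X = np.column_stack([np.ones(j), x])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    scale2 = max(1.0, float(np.sum(w * resid**2)) / (j - 2))
    cov = scale2 * np.linalg.inv(xtwx)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    return _estimate(
        "egger_slope", slope, se_slope, _t_p(slope / se_slope, j - 2), j,
        extras={
            "intercept": intercept,
            "intercept_se": se_int,
            "intercept_pval": _t_p(intercept / se_int, j - 2),
            "scale_factor": math.sqrt(scale2),
            "df": j - 2,
        },
    )


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    th = theta[order]
    ww = w[order] / np.sum(w)
    s = np.cumsum(ww) - 0.5 * ww  # midpoint cumulative weight
    return float(np.interp(0.5, s, th))


def weighted_median(
    iset: HarmonizedInstrumentSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median estimator.

    Wald ratios are ordered and the estimate interpolates the ratio at
    cumulative normalized weight 0.5 (midpoint convention).  Consistent as
    long as valid instruments carry more than half of the total weight.
    SE from a parametric bootstrap: exposure and outcome betas are redrawn
    from their normal sampling distributions ``n_boot`` times.
    """
    j = len(iset)
    if j < 3:
        raise EstimatorError(f"weighted_median requires >= 3 instruments, got {j}")
    if seed is None:
        raise EstimatorError("weighted_median requires an explicit seed")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; bootstrap SE will be noisy")
    be, se_e, bo, so = _arrays(iset)
    theta = bo / be
    w = be**2 / so**2
    beta = _weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    be_b = rng.normal(be, se_e, size=(n_boot, j))
    bo_b = rng.normal(bo, so, size=(n_boot, j))
    ests = np.empty(n_boot)
    for i in range(n_boot):
        ests[i] = _weighted_median_point(bo_b[i] / be_b[i], be_b[i] ** 2 / so**2)
    se = float(np.std(ests, ddof=1))
    return _estimate(
        "weighted_median", beta, se, _norm_p(beta / se), j,
        extras={"n_boot": n_boot, "seed": seed},
    )


def _mode_bandwidth(theta: np.ndarray, factor: float) -> float:
    """Rule-of-thumb bandwidth: 0.9 * min(sd, normalized MAD) * J^(-1/5),
    scaled by ``factor``; falls back to sd when the MAD degenerates."""
    sd = float(np.std(theta, ddof=1))
    mad = float(stats.median_abs_deviation(theta, scale="normal"))
    base = min(x for x in (sd, mad) if x > 0) if max(sd, mad) > 0 else 0.0
    return factor * 0.9 * base * len(theta) ** (-1 / 5)


def _mode_point(theta: np.ndarray, w: np.ndarray, h: float) -> float:
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2)).sum(axis=1)
    x0 = grid[int(np.argmax(dens))]
    step = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        lambda x: -(w * np.exp(-0.5 * ((x - theta) / h) ** 2)).sum(),
        bounds=(x0 - step, x0 + step), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def weighted_mode(
    iset: HarmonizedInstrumentSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-mode estimator: maximizer of a weighted Gaussian kernel
    density over the Wald ratios.

    Bandwidth = ``bandwidth_factor`` x the rule-of-thumb
    0.9*min(sd, normalized MAD)*J^(-1/5) of the ratios (fixed rule, so runs
    are reproducible bit-for-bit at a given seed).  Consistent when the
    largest group of instruments sharing one causal value is valid.
    """
    j = len(iset)
    if j < 3:
        raise EstimatorError(f"weighted_mode requires >= 3 instruments, got {j}")
    if seed is None:
        raise EstimatorError("weighted_mode requires an explicit seed")
    if bandwidth_factor <= 0:
        raise EstimatorError("bandwidth_factor must be positive")
    be, se_e, bo, so = _arrays(iset)
    theta = bo / be
    w = be**2 / so**2
    w = w / w.sum()
    h = _mode_bandwidth(theta, bandwidth_factor)
    if h == 0.0:  # all ratios identical
        beta = float(theta[0])
        se = float((np.sum(be**2 / so**2)) ** -0.5)
        return _estimate("weighted_mode", beta, se, _norm_p(beta / se), j,
                         extras={"bandwidth": 0.0, "n_boot": n_boot, "seed": seed})
    beta = _mode_point(theta, w, h)

    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for i in range(n_boot):
        be_b = rng.normal(be, se_e)
        bo_b = rng.normal(bo, so)
        th_b = bo_b / be_b
        w_b = be_b**2 / so**2
        h_b = _mode_bandwidth(th_b, bandwidth_factor)
        if h_b == 0.0:
            ests[i] = th_b[0]
            continue
        grid = np.linspace(th_b.min() - 3 * h_b, th_b.max() + 3 * h_b, 512)
        dens = (w_b[None, :] * np.exp(
            -0.5 * ((grid[:, None] - th_b[None, :]) / h_b) ** 2)).sum(axis=1)
        ests[i] = grid[int(np.argmax(dens))]
    se = float(np.std(ests, ddof=1))
    return _estimate(
        "weighted_mode", beta, se, _norm_p(beta / se), j,
        extras={"bandwidth": h, "bandwidth_factor": bandwidth_factor,
                "n_boot": n_boot, "seed": seed},
    )


def mvmr_ivw(
    outcome_beta: Sequence[float],
    outcome_se: Sequence[float],
    exposure_betas: np.ndarray,
    exposure_labels: Sequence[str] | None = None,
) -> list[MREstimate]:
    """Multivariable IVW: conditional direct effect of each exposure.

    Weighted least squares of outcome betas on the (J x K) exposure-beta
    matrix without intercept, weights 1/outcome_se^2.  All effects must be
    pre-harmonized to a common effect allele per SNP.  Residual scale is
    multiplicative and floored at 1, as in univariable IVW.
    """
    y = np.asarray(outcome_beta, dtype=float)
    so = np.asarray(outcome_se, dtype=float)
    X = np.atleast_2d(np.asarray(exposure_betas, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    j, k = X.shape
    if k < 2:
        raise EstimatorError("mvmr_ivw needs >= 2 exposures; use ivw for one")
    if j < k + 1:
        raise EstimatorError(f"mvmr_ivw needs >= {k + 1} SNPs for {k} exposures, got {j}")
    if exposure_labels is None:
        exposure_labels = [f"exposure_{i + 1}" for i in range(k)]

    # an all-zero column contributes nothing: report a null estimate for it
    # and fit the rest, rather than failing the rank check
    active = [i for i in range(k) if np.any(X[:, i] != 0.0)]
    Xa = X[:, active]
    ka = len(active)
    if ka and np.linalg.matrix_rank(Xa) < ka:
        raise EstimatorError("collinear exposures: exposure-beta matrix is rank deficient")

    w = 1.0 / so**2
    xtwx = Xa.T @ (w[:, None] * Xa)
    coef_a = np.linalg.solve(xtwx, Xa.T @ (w * y))
    resid = y - Xa @ coef_a
    scale2 = max(1.0, float(np.sum(w * resid**2)) / (j - ka))
    cov_a = scale2 * np.linalg.inv(xtwx)
    out = []
    for i, label in enumerate(exposure_labels):
        if i not in active:
            out.append(_estimate(
                "mvmr_ivw", 0.0, math.inf, 1.0, j,
                extras={"exposure": label, "zero_column": True, "k": k},
            ))
            continue
        ia = active.index(i)
        b = float(coef_a[ia])
        se = float(np.sqrt(cov_a[ia, ia]))
        out.append(_estimate(
            "mvmr_ivw", b, se, _norm_p(b / se), j,
            extras={"exposure": label, "scale_factor": math.sqrt(scale2), "k": k},
        ))
    return out


def to_odds_ratio(est: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate and its CI to the odds-ratio scale.

    Returns (or, ci_low, ci_high) at full precision; display rounding is
    half-even to 3 decimals (Python's built-in ``round``).
    """
    return math.exp(est.beta), math.exp(est.ci_low), math.exp(est.ci_high)
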