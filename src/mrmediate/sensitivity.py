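"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

MR estimates lean on the assumption that every instrument affects the
outcome only through the exposure.  This module provides the standard
checks: Cochran's Q for heterogeneity among Wald ratios, the Egger
intercept test for directional pleiotropy, MR-PRESSO for global pleiotropy
and per-SNP outliers, leave-one-out influence analysis, and a reverse-MR
driver that swaps the exposure and outcome roles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedInstrumentSet, SumstatRecord, harmonize
from .estimators import (
    EstimatorError,
    MREstimate,
    ivw,
    mr_egger,
    wald_ratios,
    weighted_median,
    weighted_mode,
)
from . import instruments as ivsel

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "LooTable",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "reverse_mr",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity test for the Wald ratios."""

    q: float
    df: int
    pval: float


@dataclass
class PressoResult:
    """MR-PRESSO global and per-SNP outlier test results."""

    observed_rss: float
    global_pval: float
    per_snp_pvals: pd.DataFrame  # snp_id, pval_raw, pval_adjusted
    outliers: list[str]
    corrected_estimate: MREstimate | None
    n_sim: int
    seed: int
    outlier_alpha: float = 0.05
    uncorrected_beta: float | None = None

    @property
    def distortion_pct(self) -> float | None:
        """Percent change of the IVW estimate after outlier removal
        (descriptive only; no distortion p-value is computed)."""
        if self.corrected_estimate is None or not self.uncorrected_beta:
            return None
        return 100.0 * (self.corrected_estimate.beta - self.uncorrected_beta) / self.uncorrected_beta


@dataclass
class LooTable:
    """Leave-one-out estimates: one row per omitted SNP plus the all-SNP row."""

    rows: pd.DataFrame  # omitted, beta, se, ci_low, ci_high, pval, n_snp, influential
    method: str

    @property
    def influential(self) -> list[str]:
        mask = self.rows["influential"] & (self.rows["omitted"] != "(none)")
        return self.rows.loc[mask, "omitted"].tolist()


def cochran_q(iset: HarmonizedInstrumentSet, at: MREstimate) -> HeterogeneityResult:
    """Q = sum_j w_j (theta_j - beta)^2 against chi-square with J - 1 df.

    p < 0.05 conventionally signals heterogeneity among the instruments'
    causal estimates (possible pleiotropy or multiple mechanisms).
    """
    ratios = wald_ratios(iset)
    j = len(ratios)
    if j < 2:
        raise EstimatorError("cochran_q requires >= 2 instruments")
    q = sum(r.weight * (r.theta - at.beta) ** 2 for r in ratios)
    df = j - 1
    return HeterogeneityResult(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger_intercept_test(iset: HarmonizedInstrumentSet) -> dict:
    """Egger intercept, SE and p-value: a nonzero intercept indicates
    directional horizontal pleiotropy."""
    est = mr_egger(iset)
    return {
        "intercept": est.extras["intercept"],
        "se": est.extras["intercept_se"],
        "pval": est.extras["intercept_pval"],
    }


def _loo_ivw_beta(be: np.ndarray, bo: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW slope excluding each SNP in turn (vectorized).

    Uses the through-origin identity: beta = sum(w be bo) / sum(w be^2)
    with w = 1/outcome_se^2.
    """
    s_xy = np.sum(w * be * bo)
    s_xx = np.sum(w * be**2)
    return (s_xy - w * be * bo) / (s_xx - w * be**2)


def mr_presso(
    iset: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> PressoResult:
    """MR-PRESSO: residual-sum-of-squares test for horizontal pleiotropy.

    The observed RSS sums, over SNPs, the squared deviation of each
    outcome beta from the value predicted by the fixed-effect IVW slope
    fitted *without* that SNP.  The null distribution comes from ``n_sim``
    parametric simulations that redraw every exposure and outcome beta
    from its sampling distribution around the no-pleiotropy prediction.
    The global p-value uses the add-one Monte-Carlo estimator
    (1 + #{sim >= obs}) / (n_sim + 1), so it is never zero and never
    smaller than 1/(n_sim + 1).  Per-SNP outlier p-values compare each
    SNP's own residual term to its simulated distribution, with Bonferroni
    adjustment by default; SNPs below ``outlier_alpha`` after adjustment
    are flagged, and a corrected IVW estimate excluding them is returned.
    """
    j = len(iset)
    if j < 4:
        raise EstimatorError(f"insufficient instruments for MR-PRESSO (need >= 4, got {j})")
    if seed is None:
        raise EstimatorError("mr_presso requires an explicit seed")
    if n_sim < 500:
        raise EstimatorError("mr_presso requires n_sim >= 500")

    be = np.array([p.exposure_beta for p in iset.pairs])
    se_e = np.array([p.exposure_se for p in iset.pairs])
    bo = np.array([p.outcome_beta for p in iset.pairs])
    so = np.array([p.outcome_se for p in iset.pairs])
    w = 1.0 / so**2

    b_loo = _loo_ivw_beta(be, bo, w)
    obs_terms = (bo - b_loo * be) ** 2
    obs_rss = float(np.sum(obs_terms))

    rng = np.random.default_rng(seed)
    expected_bo = b_loo * be  # no-pleiotropy prediction per SNP
    sim_rss = np.empty(n_sim)
    exceed_terms = np.zeros(j)
    for s in range(n_sim):
        be_s = rng.normal(be, se_e)
        bo_s = rng.normal(expected_bo, so)
        b_loo_s = _loo_ivw_beta(be_s, bo_s, w)
        terms_s = (bo_s - b_loo_s * be_s) ** 2
        sim_rss[s] = terms_s.sum()
        exceed_terms += terms_s >= obs_terms
    global_pval = float((1 + np.sum(sim_rss >= obs_rss)) / (n_sim + 1))

    p_raw = (1 + exceed_terms) / (n_sim + 1)
    if adjust == "bonferroni":
        p_adj = np.minimum(p_raw * j, 1.0)
    elif adjust == "none":
        p_adj = p_raw.copy()
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    per_snp = pd.DataFrame({
        "snp_id": iset.snp_ids,
        "pval_raw": p_raw,
        "pval_adjusted": p_adj,
    })
    outliers = per_snp.loc[per_snp["pval_adjusted"] < outlier_alpha, "snp_id"].tolist()

    corrected = None
    uncorrected_beta = None
    if outliers:
        uncorrected_beta = ivw(iset).beta
        keep = [s for s in iset.snp_ids if s not in set(outliers)]
        if keep:
            corrected = ivw(iset.subset(keep))
    return PressoResult(
        observed_rss=obs_rss,
        global_pval=global_pval,
        per_snp_pvals=per_snp,
        outliers=outliers,
        corrected_estimate=corrected,
        n_sim=n_sim,
        seed=seed,
        outlier_alpha=outlier_alpha,
        uncorrected_beta=uncorrected_beta,
    )


_METHODS = {
    "ivw": ivw,
    "egger": mr_egger,
    "weighted_median": weighted_median,
    "weighted_mode": weighted_mode,
}


def leave_one_out(
    iset: HarmonizedInstrumentSet,
    method: str = "ivw",
    **method_kwargs,
) -> LooTable:
    """Re-estimate with each SNP omitted in turn.

    A SNP is flagged influential when its omission moves the estimate
    outside the all-SNP 95% CI, when the all-SNP estimate falls outside the
    omission row's 95% CI (an outlier widens the full-set interval, so the
    escape must be checked both ways), or when the sign flips.
    """
    if method not in _METHODS:
        raise EstimatorError(f"unknown method {method!r}")
    j = len(iset)
    if j < 3:
        raise EstimatorError("leave_one_out requires >= 3 instruments")
    fn = _METHODS[method]

    full = fn(iset, **method_kwargs)
    rows = []
    for sid in iset.snp_ids:
        sub = iset.subset([s for s in iset.snp_ids if s != sid])
        try:
            est = fn(sub, **method_kwargs)
        except EstimatorError as exc:
            raise EstimatorError(f"omitting {sid}: {exc}") from exc
        influential = (
            est.beta < full.ci_low or est.beta > full.ci_high
            or full.beta < est.ci_low or full.beta > est.ci_high
            or (est.beta * full.beta < 0)
        )
        rows.append({
            "omitted": sid, "beta": est.beta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "pval": est.pval, "n_snp": est.n_snp, "influential": influential,
        })
    rows.append({
        "omitted": "(none)", "beta": full.beta, "se": full.se,
        "ci_low": full.ci_low, "ci_high": full.ci_high,
        "pval": full.pval, "n_snp": full.n_snp, "influential": False,
    })
    return LooTable(rows=pd.DataFrame(rows), method=method)


def render_loo(table: LooTable, width: int = 40) -> str:
    """Plain-text forest-style rendering of a leave-one-out table."""
    df = table.rows
    lo, hi = df["ci_low"].min(), df["ci_high"].max()
    span = hi - lo or 1.0
    lines = []
    for _, r in df.iterrows():
        a = int((r["ci_low"] - lo) / span * (width - 1))
        b = int((r["ci_high"] - lo) / span * (width - 1))
        m = int((r["beta"] - lo) / span * (width - 1))
        bar = [" "] * width
        for i in range(a, b + 1):
            bar[i] = "-"
        bar[m] = "o"
        flag = " *" if r["influential"] else ""
        lines.append(f"{r['omitted']:>14s} |{''.join(bar)}| "
                     f"{r['beta']: .4f} [{r['ci_low']: .4f}, {r['ci_high']: .4f}]{flag}")
    return "\n".join(lines)


def reverse_mr(
    exposure_sumstats: Sequence[SumstatRecord],
    outcome_sumstats: Sequence[SumstatRecord],
    p_threshold: float = ivsel.GENOME_WIDE_P,
    clump_spec: ivsel.ClumpSpec | None = None,
    f_min: float = 10.0,
    seed: int | None = None,
    palindrome_eaf_limit: float = 0.42,
) -> dict:
    """Run the MR pipeline with exposure and outcome roles swapped.

    The former *outcome* records are screened for their own genome-wide
    significant, clumped, strong instruments; those instruments are then
    harmonized against the former *exposure* as the new outcome.  Returns a
    dict with ``direction="reverse"`` and either a ``no_instruments`` flag
    or the estimates/diagnostics block.
    """
    prov: dict = {}
    sel = ivsel.select_significant(outcome_sumstats, p_threshold, provenance=prov)
    if clump_spec is not None:
        has_pos = all(r.chrom is not None and r.pos is not None for r in sel)
        if has_pos:
            sel = ivsel.clump(sel, clump_spec, provenance=prov)
    if sel:
        _, sel = ivsel.f_statistics(sel, formula="ratio", f_min=f_min, provenance=prov)

    if not sel:
        return {"direction": "reverse", "no_instruments": True, "provenance": prov}

    iset = harmonize(
        sel, list(exposure_sumstats),
        palindrome_eaf_limit=palindrome_eaf_limit,
        exposure_label="reverse_exposure", outcome_label="reverse_outcome",
    )
    if len(iset) == 0:
        return {"direction": "reverse", "no_instruments": True, "provenance": prov}
    prov.update(iset.provenance)

    result: dict = {"direction": "reverse", "no_instruments": False,
                    "n_snp": len(iset), "provenance": prov}
    result["ivw"] = ivw(iset)
    if len(iset) >= 3:
        result["egger"] = mr_egger(iset)
        if seed is not None:
            result["weighted_median"] = weighted_median(iset, seed=seed)
    if len(iset) >= 2:
        result["cochran_q"] = cochran_q(iset, ivw(iset, model="fixed"))
    return result
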