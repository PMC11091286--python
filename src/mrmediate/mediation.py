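"""Two-step MR mediation analysis.

The total effect (TE) of exposure on outcome is decomposed into an indirect
effect (IE) running through a mediator and a direct effect (DE):

    IE = beta_a * beta_b        DE = TE - IE        prop = IE / TE

where beta_a is the exposure -> mediator effect (step one, the exposure's
instruments against the mediator GWAS) and beta_b is the mediator -> outcome
effect conditional on the exposure (step two, multivariable IVW by default).
Uncertainty for the product uses the multivariate delta method (Sobel SE);
IE and TE are treated as independent, as they come from separate two-sample
analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats import HarmonizedInstrumentSet, SumstatRecord, harmonize
from .estimators import EstimatorError, MREstimate, ivw, mvmr_ivw, _norm_p

__all__ = ["MediationResult", "sobel_se", "two_step", "mediation_screen"]

log = logging.getLogger(__name__)

SCREEN_ALPHA = 0.05


@dataclass
class MediationResult:
    """Decomposition of a total effect into direct and mediated parts."""

    mediator: str
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    te: float
    se_te: float
    ie: float
    se_ie: float
    de: float
    pval_ie: float
    pval_a: float | None = None
    pval_b: float | None = None
    prop: float | None = None
    se_prop: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        # de = te - ie must hold exactly, by construction
        if self.de != self.te - self.ie:
            raise ValueError("de must equal te - ie exactly")


def sobel_se(
    beta_a: float, se_a: float, beta_b: float, se_b: float,
    second_order: bool = False,
) -> float:
    """Delta-method SE of the product beta_a * beta_b.

    First order (default): sqrt(beta_b^2 se_a^2 + beta_a^2 se_b^2).
    ``second_order=True`` adds the exact-variance term se_a^2 se_b^2.
    """
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be non-negative")
    var = beta_b**2 * se_a**2 + beta_a**2 * se_b**2
    if second_order:
        var += se_a**2 * se_b**2
    return float(np.sqrt(var))


def two_step(
    beta_a: float, se_a: float,
    beta_b: float, se_b: float,
    te: float, se_te: float,
    mediator: str = "mediator",
    second_order: bool = False,
) -> MediationResult:
    """Assemble a mediation decomposition from the three MR estimates.

    The proportion mediated prop = IE/TE gets a delta-method SE treating IE
    and TE as independent: sqrt(se_ie^2/te^2 + ie^2 se_te^2/te^4).  When
    te = 0 the proportion fields are absent and a ``zero-total-effect``
    flag is set; prop outside [0, 1] sets ``inconsistent-mediation`` (the
    decomposition is still reported).
    """
    for name, v in (("beta_a", beta_a), ("beta_b", beta_b), ("te", te)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    ie = beta_a * beta_b
    de = te - ie
    se_ie = sobel_se(beta_a, se_a, beta_b, se_b, second_order=second_order)
    pval_ie = _norm_p(ie / se_ie) if se_ie > 0 else 1.0

    flags: list[str] = []
    prop = se_prop = None
    if te == 0:
        flags.append("zero-total-effect")
    else:
        prop = ie / te
        se_prop = float(np.sqrt(se_ie**2 / te**2 + ie**2 * se_te**2 / te**4))
        if prop < 0 or prop > 1:
            flags.append("inconsistent-mediation")
    return MediationResult(
        mediator=mediator,
        beta_a=beta_a, se_a=se_a, beta_b=beta_b, se_b=se_b,
        te=te, se_te=se_te, ie=ie, se_ie=se_ie, de=de,
        pval_ie=pval_ie, prop=prop, se_prop=se_prop, flags=flags,
    )


def _step_two_mvmr(
    exposure_instruments: Sequence[SumstatRecord],
    mediator_instruments: Sequence[SumstatRecord],
    exposure_gwas: Sequence[SumstatRecord],
    mediator_gwas: Sequence[SumstatRecord],
    outcome_gwas: Sequence[SumstatRecord],
    palindrome_eaf_limit: float,
) -> MREstimate:
    """Mediator -> outcome effect conditional on the exposure, by MVMR.

    The instrument set is the union of exposure and mediator instruments;
    each SNP needs effects on both exposures and on the outcome.
    """
    union: dict[str, SumstatRecord] = {}
    for r in list(exposure_instruments) + list(mediator_instruments):
        union.setdefault(r.snp_id, r)
    insts = list(union.values())

    on_exp = harmonize(insts, list(exposure_gwas), palindrome_eaf_limit)
    on_med = harmonize(insts, list(mediator_gwas), palindrome_eaf_limit)
    on_out = harmonize(insts, list(outcome_gwas), palindrome_eaf_limit)
    by_exp = {p.snp_id: p for p in on_exp.pairs}
    by_med = {p.snp_id: p for p in on_med.pairs}
    by_out = {p.snp_id: p for p in on_out.pairs}
    common = [s for s in union if s in by_exp and s in by_med and s in by_out]
    if len(common) < 3:
        raise EstimatorError("too few SNPs with effects on exposure, mediator and outcome")

    X = np.array([[by_med[s].outcome_beta, by_exp[s].outcome_beta] for s in common])
    y = [by_out[s].outcome_beta for s in common]
    so = [by_out[s].outcome_se for s in common]
    ests = mvmr_ivw(y, so, X, exposure_labels=["mediator", "exposure"])
    return ests[0]


def mediation_screen(
    exposure_instruments: Sequence[SumstatRecord],
    exposure_gwas: Sequence[SumstatRecord],
    mediators: dict[str, dict],
    outcome_gwas: Sequence[SumstatRecord],
    te_estimate: MREstimate,
    alpha: float = SCREEN_ALPHA,
    step_two: str = "mvmr",
    palindrome_eaf_limit: float = 0.42,
    adjust: str | None = None,
) -> tuple[list[MediationResult], pd.DataFrame]:
    """Screen candidate mediators of an exposure -> outcome effect.

    For each candidate: step one regresses the mediator on the exposure's
    instruments (IVW) to get beta_a; step two estimates the mediator ->
    outcome effect beta_b by multivariable IVW including the exposure
    (``step_two="mvmr"``, default) or by univariable IVW on the mediator's
    own instruments (``step_two="univariable"``).  A mediator passes the
    screen when beta_a, beta_b and the indirect effect are all significant
    at ``alpha``.  No multiplicity correction is applied across candidates
    unless ``adjust="bonferroni"``.

    ``mediators`` maps name -> {"gwas": mediator GWAS records,
    "instruments": the mediator's own instrument records}.

    Returns all candidate results (pass and fail) plus a tidy screen table.
    """
    results: list[MediationResult] = []
    rows = []
    n_cand = max(len(mediators), 1)
    eff_alpha = alpha / n_cand if adjust == "bonferroni" else alpha

    for name, blocks in mediators.items():
        med_gwas = blocks["gwas"]
        med_insts = blocks.get("instruments", [])
        try:
            step1 = harmonize(list(exposure_instruments), list(med_gwas),
                              palindrome_eaf_limit)
            est_a = ivw(step1)
        except Exception as exc:
            log.warning("mediator %s: step one failed (%s)", name, exc)
            rows.append({"mediator": name, "status": "no-instruments",
                         "passes": False})
            continue

        try:
            if step_two == "mvmr":
                if not med_insts:
                    raise EstimatorError("mediator has no instruments")
                est_b = _step_two_mvmr(
                    exposure_instruments, med_insts, exposure_gwas,
                    med_gwas, outcome_gwas, palindrome_eaf_limit,
                )
            elif step_two == "univariable":
                if not med_insts:
                    raise EstimatorError("mediator has no instruments")
                s2 = harmonize(list(med_insts), list(outcome_gwas),
                               palindrome_eaf_limit)
                est_b = ivw(s2)
            else:
                raise ValueError(f"unknown step_two mode {step_two!r}")
        except (EstimatorError, Exception) as exc:
            if not isinstance(exc, (EstimatorError, ValueError)):
                raise
            log.warning("mediator %s: step two failed (%s)", name, exc)
            rows.append({"mediator": name, "status": "no-instruments",
                         "passes": False})
            continue

        res = two_step(
            est_a.beta, est_a.se, est_b.beta, est_b.se,
            te_estimate.beta, te_estimate.se, mediator=name,
        )
        res.pval_a = est_a.pval
        res.pval_b = est_b.pval
        passes = (est_a.pval < eff_alpha and est_b.pval < eff_alpha
                  and res.pval_ie < eff_alpha)
        results.append(res)
        rows.append({
            "mediator": name, "status": "ok",
            "beta_a": res.beta_a, "pval_a": est_a.pval,
            "beta_b": res.beta_b, "pval_b": est_b.pval,
            "ie": res.ie, "pval_ie": res.pval_ie,
            "de": res.de, "te": res.te, "prop": res.prop,
            "passes": passes,
        })
    return results, pd.DataFrame(rows)
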