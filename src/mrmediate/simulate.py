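"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the statistical shape of post-clumping GWAS summary
data: independent instruments, per-SNP effects with sampling noise whose SE
shrinks as 1/sqrt(2*eaf*(1-eaf)*n), a configurable true causal effect of
exposure on outcome, optional horizontal pleiotropy (balanced or
directional), and an exposure -> mediator -> outcome chain with known
beta_a, beta_b and direct effect.  Binary-trait outcomes are approximated
on the log-odds scale with the same normal sampling model, since every
estimator here operates on summary statistics only.

Every generator is a pure function of its config (seed mandatory): the
random stream for effect sizes is separated from the stream for allele
bookkeeping, so turning the harmonization stress (allele flips, palindromic
SNPs) on or off never changes the simulated effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .sumstats import SumstatRecord, pval_from_effect

__all__ = [
    "Pleiotropy",
    "SimConfig",
    "SyntheticTruth",
    "simulate_pair",
    "simulate_mediation",
    "inject_outlier",
]

# allele pairs that survive strand checks unambiguously
_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC = [("A", "T"), ("C", "G")]


@dataclass(frozen=True)
class Pleiotropy:
    """Horizontal-pleiotropy model: a ``fraction`` of SNPs receive a direct
    outcome effect drawn from Normal(mean, sd^2).  kind "balanced" forces
    mean = 0; "directional" allows a systematic offset."""

    kind: str = "none"  # none | balanced | directional
    fraction: float = 0.0
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.kind == "balanced" and self.mean != 0.0:
            raise ValueError("balanced pleiotropy must have mean 0")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("pleiotropy fraction outside [0, 1]")

    @classmethod
    def balanced(cls, sd: float, fraction: float = 0.3) -> "Pleiotropy":
        return cls(kind="balanced", fraction=fraction, sd=sd)

    @classmethod
    def directional(cls, mean: float, sd: float, fraction: float = 0.3) -> "Pleiotropy":
        return cls(kind="directional", fraction=fraction, mean=mean, sd=sd)


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for a synthetic two-sample MR dataset.

    Defaults describe a well-powered post-GWAS setting: 50 independent
    instruments, 1e5 samples per study, SNP -> exposure effects of SD 0.05
    (mean instrument F around 100), no pleiotropy, no causal effect.
    """

    seed: int
    n_snps: int = 50
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    n_mediator: int = 100_000
    gamma_sd: float = 0.05
    theta: float = 0.0
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    mediator_chain: tuple[float, float, float] | None = None  # (beta_a, beta_b, direct)
    n_mediator_snps: int = 50
    delta_sd: float = 0.05
    eaf_range: tuple[float, float] = (0.05, 0.95)
    flip_fraction: float = 0.3
    palindromic_fraction: float = 0.1
    inside_violation: float = 0.0  # corr(pleiotropy offset, gamma); breaks InSIDE

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for n in (self.n_exposure, self.n_outcome, self.n_mediator):
            if n < 2:
                raise ValueError("sample sizes must be >= 2")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("eaf_range bounds must satisfy 0 < lo < hi < 1")


@dataclass
class SyntheticTruth:
    """The generating parameters and realized latent effects of one draw."""

    config: SimConfig
    snp_ids: list[str]
    gamma: np.ndarray  # true SNP -> exposure effects
    alpha: np.ndarray  # pleiotropy offsets on the outcome
    eaf: np.ndarray
    mediator_snp_ids: list[str] = field(default_factory=list)
    delta: np.ndarray | None = None  # mediator-specific instrument effects

    @property
    def implied_total_effect(self) -> float:
        c = self.config
        if c.mediator_chain is None:
            return c.theta
        beta_a, beta_b, direct = c.mediator_chain
        return direct + beta_a * beta_b


def _se(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _draw_eaf(rng: np.random.Generator, k: int, lo: float, hi: float,
              palindromic: np.ndarray) -> np.ndarray:
    """Frequencies uniform over the range; palindromic SNPs are kept out of
    the ambiguous band around 0.5 so frequency inference can resolve them."""
    eaf = rng.uniform(lo, hi, size=k)
    amb_lo, amb_hi = 0.40, 0.60
    for i in np.where(palindromic)[0]:
        while amb_lo < eaf[i] < amb_hi:
            eaf[i] = rng.uniform(lo, hi)
    return eaf


def _records(
    ids: Sequence[str], chrom: np.ndarray, pos: np.ndarray,
    alleles: list[tuple[str, str]], eaf: np.ndarray,
    beta: np.ndarray, se: np.ndarray, n: int,
    swap: np.ndarray,
) -> list[SumstatRecord]:
    out = []
    for i, sid in enumerate(ids):
        a1, a2 = alleles[i]
        b, f = float(beta[i]), float(eaf[i])
        if swap[i]:
            a1, a2 = a2, a1
            b, f = -b, 1.0 - f
        out.append(SumstatRecord(
            snp_id=sid, chrom=str(chrom[i]), pos=int(pos[i]),
            effect_allele=a1, other_allele=a2, eaf=f,
            beta=b, se=float(se[i]),
            pval=pval_from_effect(b, float(se[i])), n=n,
        ))
    return out


def _layout(rng: np.random.Generator, config: SimConfig, k: int, offset: int = 0):
    """Allele/position bookkeeping, drawn from the stress stream."""
    palindromic = rng.random(k) < config.palindromic_fraction
    alleles = []
    for i in range(k):
        pool = _PALINDROMIC if palindromic[i] else _NONPALINDROMIC
        alleles.append(pool[rng.integers(len(pool))])
    swap = rng.random(k) < config.flip_fraction
    chrom = rng.integers(1, 23, size=k)
    pos = rng.integers(1, 250_000_000, size=k) + offset
    eaf = _draw_eaf(rng, k, *config.eaf_range, palindromic)
    return palindromic, alleles, swap, chrom, pos, eaf


def simulate_pair(
    config: SimConfig,
) -> tuple[list[SumstatRecord], list[SumstatRecord], SyntheticTruth]:
    """Simulate exposure and outcome GWAS for the same set of instruments.

    Per SNP j: gamma_j ~ Normal(0, gamma_sd^2) is the true SNP -> exposure
    effect; the true outcome effect is theta*gamma_j plus a pleiotropy
    offset.  Observed betas add sampling noise with SE determined by allele
    frequency and the study sample size.  A ``flip_fraction`` of outcome
    records is stated for the opposite effect allele and a
    ``palindromic_fraction`` of SNPs is A/T or C/G, so harmonization is
    always exercised.
    """
    ss = np.random.SeedSequence(config.seed)
    eff_rng, stress_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    k = config.n_snps
    ids = [f"rs{i + 1}" for i in range(k)]
    palindromic, alleles, swap, chrom, pos, eaf = _layout(stress_rng, config, k)

    gamma = eff_rng.normal(0.0, config.gamma_sd, size=k)
    alpha = np.zeros(k)
    pl = config.pleiotropy
    if pl.kind != "none":
        which = eff_rng.random(k) < pl.fraction
        offsets = eff_rng.normal(pl.mean, pl.sd, size=k)
        if config.inside_violation:
            # correlate offsets with instrument strength to break InSIDE
            z = (gamma - gamma.mean()) / (gamma.std() or 1.0)
            offsets = offsets + config.inside_violation * pl.sd * z
        alpha = np.where(which, offsets, 0.0)

    big_gamma = config.theta * gamma + alpha
    se_x = _se(eaf, config.n_exposure)
    se_y = _se(eaf, config.n_outcome)
    beta_x = eff_rng.normal(gamma, se_x)
    beta_y = eff_rng.normal(big_gamma, se_y)

    no_swap = np.zeros(k, dtype=bool)
    exposure = _records(ids, chrom, pos, alleles, eaf, beta_x, se_x,
                        config.n_exposure, no_swap)
    outcome = _records(ids, chrom, pos, alleles, eaf, beta_y, se_y,
                       config.n_outcome, swap)
    truth = SyntheticTruth(config=config, snp_ids=ids, gamma=gamma,
                           alpha=alpha, eaf=eaf)
    return exposure, outcome, truth


def simulate_mediation(
    config: SimConfig,
) -> tuple[list[SumstatRecord], list[SumstatRecord], list[SumstatRecord], SyntheticTruth]:
    """Simulate an exposure -> mediator -> outcome chain.

    The exposure's instruments (gamma_j) affect the mediator through
    beta_a and the outcome through direct + beta_a*beta_b; the mediator has
    its own disjoint instruments (delta_k) that hit the outcome through
    beta_b only.  The implied total effect is direct + beta_a*beta_b.
    Returns (exposure, mediator, outcome) record sets over the union of
    instruments, plus the truth object.
    """
    if config.mediator_chain is None:
        raise ValueError("simulate_mediation needs config.mediator_chain")
    beta_a, beta_b, direct = config.mediator_chain

    ss = np.random.SeedSequence(config.seed)
    eff_rng, stress_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    kx, km = config.n_snps, config.n_mediator_snps
    ids_x = [f"rs{i + 1}" for i in range(kx)]
    ids_m = [f"rs{100_000 + i + 1}" for i in range(km)]
    if set(ids_x) & set(ids_m):
        raise ValueError("exposure and mediator instrument IDs overlap")
    k = kx + km
    ids = ids_x + ids_m
    palindromic, alleles, swap, chrom, pos, eaf = _layout(stress_rng, config, k)

    gamma = eff_rng.normal(0.0, config.gamma_sd, size=kx)
    delta = eff_rng.normal(0.0, config.delta_sd, size=km)

    true_x = np.concatenate([gamma, np.zeros(km)])
    true_m = np.concatenate([beta_a * gamma, delta])
    total = direct + beta_a * beta_b
    true_y = np.concatenate([total * gamma, beta_b * delta])

    se_x = _se(eaf, config.n_exposure)
    se_m = _se(eaf, config.n_mediator)
    se_y = _se(eaf, config.n_outcome)
    beta_x = eff_rng.normal(true_x, se_x)
    beta_m = eff_rng.normal(true_m, se_m)
    beta_y = eff_rng.normal(true_y, se_y)

    no_swap = np.zeros(k, dtype=bool)
    exposure = _records(ids, chrom, pos, alleles, eaf, beta_x, se_x,
                        config.n_exposure, no_swap)
    mediator = _records(ids, chrom, pos, alleles, eaf, beta_m, se_m,
                        config.n_mediator, no_swap)
    outcome = _records(ids, chrom, pos, alleles, eaf, beta_y, se_y,
                       config.n_outcome, swap)
    truth = SyntheticTruth(
        config=config, snp_ids=ids_x, gamma=gamma,
        alpha=np.zeros(kx), eaf=eaf,
        mediator_snp_ids=ids_m, delta=delta,
    )
    return exposure, mediator, outcome, truth


def inject_outlier(
    records: Sequence[SumstatRecord], snp_id: str, shift_in_ses: float,
) -> list[SumstatRecord]:
    """Shift one SNP's beta by ``shift_in_ses`` standard errors.

    Returns a new record list; the input is untouched.  Used to plant a
    known pleiotropic outlier for MR-PRESSO / leave-one-out tests.
    """
    ids = {r.snp_id for r in records}
    if snp_id not in ids:
        raise ValueError(f"unknown snp_id {snp_id!r}")
    out = []
    for r in records:
        if r.snp_id == snp_id:
            b = r.beta + shift_in_ses * r.se
            out.append(replace(r, beta=b, pval=pval_from_effect(b, r.se)))
        else:
            out.append(r)
    return out
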