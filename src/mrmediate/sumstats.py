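"""Reading, validating and harmonizing GWAS summary statistics.

Two-sample Mendelian randomization combines per-SNP effect estimates from an
exposure GWAS and an outcome GWAS.  Before any estimator can run, the two
studies must refer each SNP's effect to the *same* effect allele: this module
aligns alleles (including strand flips), resolves palindromic A/T and C/G
variants by effect-allele frequency, and records the disposition of every SNP.

Positions are 1-based throughout.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "SumstatRecord",
    "HarmonizedPair",
    "HarmonizedInstrumentSet",
    "DIALECTS",
    "read_sumstats",
    "records_to_frame",
    "harmonize",
    "pval_from_effect",
]

log = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical field name -> column name in common download formats.
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {},
    "gwas-catalog": {
        "snp_id": "variant_id",
        "chrom": "chromosome",
        "pos": "base_pair_location",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "effect_allele_frequency",
        "beta": "beta",
        "se": "standard_error",
        "pval": "p_value",
        "n": "n",
    },
    "ieu-opengwas": {
        "snp_id": "SNP",
        "chrom": "chr",
        "pos": "position",
        "effect_allele": "ea",
        "other_allele": "nea",
        "eaf": "eaf",
        "beta": "beta",
        "se": "se",
        "pval": "p",
        "n": "n",
    },
}

_REQUIRED = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval")
_OPTIONAL = ("chrom", "pos", "n")


class SumstatError(ValueError):
    """Raised for unusable summary-statistic input."""


@dataclass(frozen=True)
class SumstatRecord:
    """One SNP's association summary from a single GWAS.

    ``beta`` is the per-effect-allele effect: log-odds for a binary trait,
    trait-SD units for a continuous one.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _BASES or self.other_allele not in _BASES:
            raise SumstatError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise SumstatError(f"{self.snp_id}: effect and other allele identical")
        if not (0.0 < self.eaf < 1.0):
            raise SumstatError(f"{self.snp_id}: eaf {self.eaf} outside (0, 1)")
        if not (self.se > 0.0) or not math.isfinite(self.se):
            raise SumstatError(f"{self.snp_id}: se {self.se} must be > 0")
        if not math.isfinite(self.beta):
            raise SumstatError(f"{self.snp_id}: non-finite beta")
        if not (0.0 < self.pval <= 1.0):
            raise SumstatError(f"{self.snp_id}: pval {self.pval} outside (0, 1]")
        if self.pos is not None and self.pos < 1:
            raise SumstatError(f"{self.snp_id}: position {self.pos} is not 1-based")
        if self.n is not None and self.n < 1:
            raise SumstatError(f"{self.snp_id}: sample size {self.n} must be positive")

    @property
    def maf(self) -> float:
        """Minor-allele frequency, min(eaf, 1 - eaf)."""
        return min(self.eaf, 1.0 - self.eaf)

    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, which are strand-ambiguous."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    def allele_flipped(self) -> "SumstatRecord":
        """The same association stated for the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP after allele alignment."""

    snp_id: str
    action: str  # kept | flipped | dropped_palindromic | dropped_incompatible
    exposure_beta: float | None = None
    exposure_se: float | None = None
    exposure_eaf: float | None = None
    outcome_beta: float | None = None
    outcome_se: float | None = None
    outcome_eaf: float | None = None

    def is_kept(self) -> bool:
        return self.action in ("kept", "flipped")


@dataclass
class HarmonizedInstrumentSet:
    """Aligned instrument effects plus a record of what happened to each SNP.

    ``pairs`` holds only usable SNPs (action kept/flipped); dropped SNPs live
    in ``dropped`` with no effect values.  ``provenance`` accumulates filter
    bookkeeping as {step: {"before": .., "after": .., ...}}.
    """

    pairs: list[HarmonizedPair]
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    dropped: list[HarmonizedPair] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.snp_id for p in self.pairs]
        if len(ids) != len(set(ids)):
            raise SumstatError("duplicate snp_id in harmonized set")
        for p in self.pairs:
            if not p.is_kept():
                raise SumstatError(f"{p.snp_id}: dropped pair in kept list")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    def subset(self, keep: Iterable[str]) -> "HarmonizedInstrumentSet":
        keep = set(keep)
        return HarmonizedInstrumentSet(
            pairs=[p for p in self.pairs if p.snp_id in keep],
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            provenance=dict(self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per SNP (kept and dropped) with an ``action`` column."""
        rows = [vars(p) for p in self.pairs] + [vars(p) for p in self.dropped]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sumstats(
    path: str | Path,
    dialect: str | Mapping[str, str] = "canonical",
    sep: str | None = None,
    strict: bool = False,
) -> list[SumstatRecord]:
    """Read delimited summary statistics into validated records.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header; ``.gz`` transparent.
    dialect
        Either a preset name (``canonical``, ``gwas-catalog``,
        ``ieu-opengwas``) or a mapping from canonical field names
        (snp_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
        pval, n) to the file's column names.
    sep
        Field separator; autodetected from the header line when omitted.
    strict
        When True, any invalid row raises; otherwise invalid rows are
        skipped with a row-numbered log message and counted.

    Returns
    -------
    list of SumstatRecord in file order.
    """
    if isinstance(dialect, str):
        try:
            colmap = DIALECTS[dialect]
        except KeyError:
            raise SumstatError(f"unknown dialect {dialect!r}") from None
    else:
        colmap = dict(dialect)

    with _open_text(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise SumstatError(f"{path}: empty file")
    if sep is None:
        sep = "\t" if "\t" in header else ","

    df = pd.read_csv(path, sep=sep, dtype=str)
    rename = {v: k for k, v in colmap.items()}
    df = df.rename(columns=rename)

    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SumstatError(f"{path}: missing mapped column(s): {', '.join(missing)}")

    if df.empty:
        log.warning("%s: header-only file, no records", path)
        return []

    records: list[SumstatRecord] = []
    n_bad = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        row = row._asdict()
        try:
            rec = SumstatRecord(
                snp_id=str(row["snp_id"]).strip(),
                effect_allele=str(row["effect_allele"]).strip().upper(),
                other_allele=str(row["other_allele"]).strip().upper(),
                eaf=float(row["eaf"]),
                beta=float(row["beta"]),
                se=float(row["se"]),
                pval=float(row["pval"]),
                chrom=str(row["chrom"]).strip() if "chrom" in row and pd.notna(row["chrom"]) else None,
                pos=int(float(row["pos"])) if "pos" in row and pd.notna(row["pos"]) else None,
                n=int(float(row["n"])) if "n" in row and pd.notna(row["n"]) else None,
            )
        except (SumstatError, ValueError, TypeError) as exc:
            if strict:
                raise SumstatError(f"{path} line {i}: {exc}") from exc
            n_bad += 1
            log.warning("%s line %d rejected: %s", path, i, exc)
            continue
        records.append(rec)
    if n_bad:
        log.warning("%s: %d row(s) rejected, %d kept", path, n_bad, len(records))
    return records


def records_to_frame(records: Sequence[SumstatRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of a record list (canonical column names)."""
    return pd.DataFrame([vars(r) for r in records])


def pval_from_effect(beta: float, se: float) -> float:
    """Two-sided normal p-value 2*Phi(-|beta/se|).

    Computed through the log-scale survival function so genome-wide signals
    far beyond machine-epsilon tails (p < 1e-300) stay representable down to
    the subnormal range.
    """
    if se <= 0:
        raise SumstatError(f"se must be > 0, got {se}")
    z = abs(beta / se)
    p = 2.0 * stats.norm.sf(z)
    if p == 0.0:
        p = math.exp(math.log(2.0) + stats.norm.logsf(z))
    return max(min(p, 1.0), 5e-324)  # floor at the smallest subnormal


def _match(exp: SumstatRecord, out: SumstatRecord, allow_strand_flip: bool) -> str:
    """Classify outcome alleles against exposure's: same | swapped | none."""
    e1, e2 = exp.effect_allele, exp.other_allele
    o1, o2 = out.effect_allele, out.other_allele
    if (o1, o2) == (e1, e2):
        return "same"
    if (o1, o2) == (e2, e1):
        return "swapped"
    if allow_strand_flip and not exp.is_palindromic():
        c1, c2 = _COMPLEMENT[o1], _COMPLEMENT[o2]
        if (c1, c2) == (e1, e2):
            return "same"
        if (c1, c2) == (e2, e1):
            return "swapped"
    return "none"


def harmonize(
    exposure: Sequence[SumstatRecord],
    outcome: Sequence[SumstatRecord],
    palindrome_eaf_limit: float = 0.42,
    allow_strand_flip: bool = True,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> HarmonizedInstrumentSet:
    """Align exposure and outcome effects to the exposure's effect allele.

    SNPs are joined by rsID.  When the outcome lists the alleles the other
    way round, its beta is negated and eaf replaced by 1 - eaf (action
    ``flipped``).  Strand-complement matches are resolved the same way when
    ``allow_strand_flip`` (default).  For palindromic SNPs (A/T, C/G) the
    allele letters are strand-ambiguous, so orientation is inferred from
    frequency: both studies' effect-allele frequencies on the same side of
    0.5 means the effects are aligned, opposite sides means flipped — but
    only when both minor-allele frequencies are below
    ``palindrome_eaf_limit``; near 0.5 the inference is unreliable and the
    SNP is dropped (action ``dropped_palindromic``).  Irreconcilable allele
    sets become ``dropped_incompatible``.
    """
    out_by_id = {r.snp_id: r for r in outcome}
    pairs: list[HarmonizedPair] = []
    dropped: list[HarmonizedPair] = []
    seen: set[str] = set()

    for exp in exposure:
        if exp.snp_id in seen:
            continue
        seen.add(exp.snp_id)
        out = out_by_id.get(exp.snp_id)
        if out is None:
            continue

        if exp.is_palindromic() and out.is_palindromic():
            if {exp.effect_allele, exp.other_allele} != {out.effect_allele, out.other_allele}:
                dropped.append(HarmonizedPair(exp.snp_id, "dropped_incompatible"))
                continue
            if exp.maf >= palindrome_eaf_limit or out.maf >= palindrome_eaf_limit:
                dropped.append(HarmonizedPair(exp.snp_id, "dropped_palindromic"))
                continue
            # letters are strand-ambiguous here; frequency decides the
            # orientation: same side of 0.5 means the same effect allele
            same_side = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
            match = "same" if same_side else "swapped"
        else:
            match = _match(exp, out, allow_strand_flip)

        if match == "none":
            dropped.append(HarmonizedPair(exp.snp_id, "dropped_incompatible"))
            continue
        if match == "swapped":
            out = out.allele_flipped()
            action = "flipped"
        else:
            action = "kept"
        pairs.append(
            HarmonizedPair(
                snp_id=exp.snp_id,
                action=action,
                exposure_beta=exp.beta,
                exposure_se=exp.se,
                exposure_eaf=exp.eaf,
                outcome_beta=out.beta,
                outcome_se=out.se,
                outcome_eaf=out.eaf,
            )
        )

    if not pairs and not dropped:
        raise SumstatError("no overlapping instruments between exposure and outcome")

    prov = {
        "harmonize": {
            "before": len(seen),
            "after": len(pairs),
            "dropped_palindromic": sum(d.action == "dropped_palindromic" for d in dropped),
            "dropped_incompatible": sum(d.action == "dropped_incompatible" for d in dropped),
            "flipped": sum(p.action == "flipped" for p in pairs),
            "palindrome_eaf_limit": palindrome_eaf_limit,
        }
    }
    return HarmonizedInstrumentSet(
        pairs=pairs,
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        dropped=dropped,
        provenance=prov,
    )
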