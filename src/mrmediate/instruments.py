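"""Instrument selection: significance filter, LD clumping, F statistics,
and exclusion of known outcome-risk loci.

A valid instrument must be strongly associated with the exposure
(genome-wide significance, conventionally P < 5e-8), approximately
independent of the other instruments (LD clumping), strong enough to avoid
weak-instrument bias (F >= 10), and free of direct outcome associations
(user-supplied blocklist of risk loci).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .sumstats import SumstatRecord, SumstatError

__all__ = [
    "ClumpSpec",
    "FStatReport",
    "select_significant",
    "clump",
    "f_statistics",
    "exclude_blocklist",
    "load_ld_table",
    "load_blocklist",
]

GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class ClumpSpec:
    """LD-clumping rule: prune any SNP correlated at r2 >= ``r2_threshold``
    with a better hit within ``window_bp`` on the same chromosome."""

    r2_threshold: float = 0.001
    window_bp: int = 10_000_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError(f"r2_threshold {self.r2_threshold} outside [0, 1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass
class FStatReport:
    """Per-SNP instrument-strength F values and the formula that produced them."""

    per_snp_f: list[tuple[str, float]]
    formula_used: str  # "ratio" | "r2_based"
    n: int | None = None
    k: int | None = None
    f_min_threshold: float = 10.0
    removed: list[str] = field(default_factory=list)

    @property
    def min_f(self) -> float:
        return min(f for _, f in self.per_snp_f)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_snp_f, columns=["snp_id", "f"])
        df["weak"] = df["snp_id"].isin(self.removed)
        return df


def select_significant(
    records: Sequence[SumstatRecord],
    p_threshold: float = GENOME_WIDE_P,
    provenance: dict | None = None,
) -> list[SumstatRecord]:
    """Keep records with pval strictly below ``p_threshold`` (order preserved)."""
    kept = [r for r in records if r.pval < p_threshold]
    if provenance is not None:
        provenance["select_significant"] = {
            "p_threshold": p_threshold,
            "before": len(records),
            "after": len(kept),
        }
    return kept


def clump(
    records: Sequence[SumstatRecord],
    spec: ClumpSpec = ClumpSpec(),
    ld: Callable[[str, str], float] | None = None,
    provenance: dict | None = None,
) -> list[SumstatRecord]:
    """Greedy LD clumping by ascending p-value.

    Iterating records from smallest p (ties broken by rsID), a record is
    pruned when it lies within ``spec.window_bp`` of an already-kept record
    on the same chromosome and either no LD source is given (distance-only
    clumping) or its r2 with that record is >= ``spec.r2_threshold``.

    ``ld`` is any callable (snp_a, snp_b) -> r2 for same-chromosome pairs;
    see :func:`load_ld_table`.
    """
    for r in records:
        if r.chrom is None or r.pos is None:
            raise SumstatError(f"{r.snp_id}: clumping requires chrom and pos")

    order = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept: list[SumstatRecord] = []
    for cand in order:
        pruned = False
        for lead in kept:
            if lead.chrom != cand.chrom:
                continue
            if abs(lead.pos - cand.pos) > spec.window_bp:
                continue
            if ld is None:
                pruned = True
                break
            try:
                r2 = float(ld(lead.snp_id, cand.snp_id))
            except Exception as exc:
                raise SumstatError(
                    f"LD lookup failed for pair ({lead.snp_id}, {cand.snp_id}): {exc}"
                ) from exc
            if r2 >= spec.r2_threshold:
                pruned = True
                break
        if not pruned:
            kept.append(cand)

    input_order = {r.snp_id: i for i, r in enumerate(records)}
    kept.sort(key=lambda r: input_order[r.snp_id])
    if provenance is not None:
        provenance["clump"] = {
            "r2_threshold": spec.r2_threshold,
            "window_bp": spec.window_bp,
            "before": len(records),
            "after": len(kept),
        }
    return kept


def f_statistics(
    records: Sequence[SumstatRecord],
    n: int | None = None,
    formula: str = "ratio",
    f_min: float = 10.0,
    provenance: dict | None = None,
) -> tuple[FStatReport, list[SumstatRecord]]:
    """Instrument-strength F per SNP; weak instruments (F < ``f_min``) removed.

    formula="ratio"
        F_j = (beta_j / se_j)^2 — needs only the association estimate.
    formula="r2_based"
        Variance explained R2_j = 2*eaf_j*(1-eaf_j)*beta_j^2 (standardized
        trait), then F_j = R2_j * (n - k - 1) / (k * (1 - sum R2)) with
        k = number of instruments — the form computed from sample size,
        instrument count, allele frequency and beta.
    """
    if formula not in ("ratio", "r2_based"):
        raise ValueError(f"unknown F formula {formula!r}")

    k = len(records)
    if formula == "ratio":
        fvals = [(r.snp_id, (r.beta / r.se) ** 2) for r in records]
    else:
        if n is None:
            n_set = {r.n for r in records if r.n is not None}
            if len(n_set) == 1:
                n = n_set.pop()
            else:
                raise SumstatError("r2_based F requires a sample size n")
        r2s = [2.0 * r.eaf * (1.0 - r.eaf) * r.beta**2 for r in records]
        total_r2 = sum(r2s)
        if total_r2 >= 1.0:
            raise SumstatError(
                f"sum of per-SNP R2 = {total_r2:.3f} >= 1; "
                "r2_based approximation invalid (betas likely unstandardized)"
            )
        scale = (n - k - 1) / (k * (1.0 - total_r2))
        fvals = [(r.snp_id, r2 * scale) for r, r2 in zip(records, r2s)]

    removed = [sid for sid, f in fvals if f < f_min]
    report = FStatReport(
        per_snp_f=fvals, formula_used=formula, n=n, k=k,
        f_min_threshold=f_min, removed=removed,
    )
    kept = [r for r in records if r.snp_id not in set(removed)]
    if provenance is not None:
        provenance["f_statistics"] = {
            "formula": formula,
            "f_min": f_min,
            "min_f": report.min_f if fvals else math.nan,
            "before": len(records),
            "after": len(kept),
        }
    return report, kept


def exclude_blocklist(
    records: Sequence[SumstatRecord],
    blocklist: Iterable,
    provenance: dict | None = None,
) -> list[SumstatRecord]:
    """Drop records matching a blocklisted rsID or genomic interval.

    Blocklist entries are rsID strings or (chrom, start, end) tuples with
    1-based closed coordinates — typically loci already established as
    outcome risk factors, which would violate the exclusion-restriction
    assumption.
    """
    rsids: set[str] = set()
    intervals: list[tuple[str, int, int]] = []
    for entry in blocklist:
        if isinstance(entry, str):
            rsids.add(entry)
        else:
            chrom, start, end = entry
            start, end = int(start), int(end)
            if start > end:
                raise SumstatError(f"malformed interval {chrom}:{start}-{end} (start > end)")
            intervals.append((str(chrom), start, end))

    def blocked(r: SumstatRecord) -> bool:
        if r.snp_id in rsids:
            return True
        if r.chrom is not None and r.pos is not None:
            return any(c == r.chrom and s <= r.pos <= e for c, s, e in intervals)
        return False

    kept = [r for r in records if not blocked(r)]
    if provenance is not None:
        provenance["exclude_blocklist"] = {
            "n_rsids": len(rsids),
            "n_intervals": len(intervals),
            "before": len(records),
            "after": len(kept),
        }
    return kept


def load_ld_table(path: str | Path) -> Callable[[str, str], float]:
    """LD lookup from a 3-column TSV (snp_a, snp_b, r2) or a square matrix
    with rsID header row and first column.  Missing pairs return r2 = 0."""
    df = pd.read_csv(path, sep="\t")
    table: dict[frozenset, float] = {}
    if list(df.columns[:3]) == ["snp_a", "snp_b", "r2"]:
        for a, b, r2 in df.itertuples(index=False):
            table[frozenset((a, b))] = float(r2)
    else:
        mat = pd.read_csv(path, sep="\t", index_col=0)
        for a in mat.index:
            for b in mat.columns:
                table[frozenset((a, b))] = float(mat.loc[a, b])

    def lookup(a: str, b: str) -> float:
        return table.get(frozenset((a, b)), 0.0)

    return lookup


def load_blocklist(path: str | Path) -> list:
    """Blocklist file: one rsID or ``chrom:start-end`` per line; '#' comments."""
    entries: list = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" in line:
            chrom, span = line.split(":", 1)
            start, end = span.split("-", 1)
            entries.append((chrom, int(start), int(end)))
        else:
            entries.append(line)
    return entries
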