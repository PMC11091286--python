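"""End-to-end study orchestration.

``run_study`` wires the full design together: instrument selection
(significance -> clumping -> blocklist -> F screen), harmonization, the
four univariable estimators, the sensitivity suite (Cochran's Q, Egger
intercept, MR-PRESSO, leave-one-out), reverse MR, and — when mediators are
configured — the two-step mediation screen.  Everything is deterministic
given (config, master seed): per-stage seeds are derived from the master
seed with ``stage_seed``, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .sumstats import (
    HarmonizedInstrumentSet, SumstatRecord, harmonize, read_sumstats,
    records_to_frame,
)
from . import instruments as ivsel
from .instruments import ClumpSpec
from .estimators import (
    MREstimate, ivw, mr_egger, to_odds_ratio, weighted_median, weighted_mode,
)
from .sensitivity import (
    cochran_q, egger_intercept_test, leave_one_out, mr_presso, reverse_mr,
)
from .mediation import MediationResult, mediation_screen
from .simulate import Pleiotropy, SimConfig, simulate_mediation, simulate_pair

__all__ = ["StudyConfig", "StudyReport", "run_study", "report_tables", "stage_seed"]

log = logging.getLogger(__name__)

#: Fixed stage codes for the seed-splitting scheme.
_STAGES = {"simulate": 0, "weighted_median": 1, "weighted_mode": 2,
           "mr_presso": 3, "reverse": 4, "mediation": 5}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed.

    Scheme: the first word of ``numpy.random.SeedSequence([master, code])``
    reduced mod 2**31, with a fixed code per stage name.  Documented so any
    stage can be reproduced without running the rest of the pipeline.
    """
    code = _STAGES[stage]
    return int(np.random.SeedSequence([master_seed, code]).generate_state(1)[0] % (2**31))


@dataclass
class StudyConfig:
    """Everything needed to run (or re-run) one exposure -> outcome study."""

    seed: int
    # file inputs (ignored when `simulate` is given)
    exposure_path: str | None = None
    outcome_path: str | None = None
    exposure_dialect: str = "canonical"
    outcome_dialect: str = "canonical"
    mediator_paths: dict[str, str] = field(default_factory=dict)
    mediator_dialect: str = "canonical"
    # or a synthetic dataset
    simulate: SimConfig | None = None
    # selection
    p_threshold: float = ivsel.GENOME_WIDE_P
    clump: ClumpSpec | None = field(default_factory=ClumpSpec)
    f_min: float = 10.0
    f_formula: str = "ratio"
    blocklist_path: str | None = None
    # harmonization / estimation
    palindrome_eaf_limit: float = 0.42
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    run_reverse: bool = True
    # mediation
    mediation_step_two: str = "mvmr"
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    strict: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            sim.setdefault("seed", raw.get("seed"))
            if "pleiotropy" in sim and isinstance(sim["pleiotropy"], dict):
                sim["pleiotropy"] = Pleiotropy(**sim["pleiotropy"])
            if "mediator_chain" in sim and sim["mediator_chain"] is not None:
                sim["mediator_chain"] = tuple(sim["mediator_chain"])
            if "eaf_range" in sim:
                sim["eaf_range"] = tuple(sim["eaf_range"])
            raw["simulate"] = SimConfig(**sim)
        if "clump" in raw and isinstance(raw["clump"], dict):
            raw["clump"] = ClumpSpec(**raw["clump"])
        return cls(**raw)


@dataclass
class StudyReport:
    """All results of one study run, serializable to JSON and TSV."""

    config: dict
    provenance: dict
    estimates: list[MREstimate]
    heterogeneity: Any = None
    egger_intercept: dict | None = None
    presso: Any = None
    loo: Any = None
    reverse: dict | None = None
    mediation: list[MediationResult] = field(default_factory=list)
    mediation_screen_table: pd.DataFrame | None = None
    errors: dict = field(default_factory=dict)
    version: str = ""

    def estimates_frame(self, odds_ratio: bool = True) -> pd.DataFrame:
        rows = []
        for e in self.estimates:
            row = {"method": e.method, "beta": e.beta, "se": e.se,
                   "ci_low": e.ci_low, "ci_high": e.ci_high,
                   "pval": e.pval, "n_snp": e.n_snp}
            if odds_ratio:
                o, lo, hi = to_odds_ratio(e)
                row.update({"or": o, "or_ci_low": lo, "or_ci_high": hi})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(_jsonable(self), indent=2, sort_keys=True)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.estimates_frame().to_csv(out / "estimates.tsv", sep="\t", index=False)
        if self.loo is not None:
            self.loo.rows.to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
        if self.mediation_screen_table is not None:
            self.mediation_screen_table.to_csv(
                out / "mediation_screen.tsv", sep="\t", index=False)
        tables = report_tables(self)
        (out / "summary.txt").write_text(
            "\n\n".join(f"== {k} ==\n{v}" for k, v in tables.items()))


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "rows") and isinstance(getattr(obj, "rows"), pd.DataFrame):
        return _jsonable(vars(obj))
    return obj


def _load_inputs(config: StudyConfig):
    """Returns (exposure records, outcome records, mediators dict, truth)."""
    mediators: dict[str, dict] = {}
    truth = None
    if config.simulate is not None:
        sim = config.simulate
        if sim.mediator_chain is not None:
            exp, med, out, truth = simulate_mediation(sim)
            med_insts = [r for r in med if r.snp_id in set(truth.mediator_snp_ids)]
            mediators["mediator"] = {"gwas": med, "instruments": med_insts}
        else:
            exp, out, truth = simulate_pair(sim)
        return exp, out, mediators, truth

    if config.exposure_path is None or config.outcome_path is None:
        raise ValueError("config needs exposure_path and outcome_path, or a simulate block")
    exp = read_sumstats(config.exposure_path, config.exposure_dialect, strict=config.strict)
    out = read_sumstats(config.outcome_path, config.outcome_dialect, strict=config.strict)
    for name, path in config.mediator_paths.items():
        gwas = read_sumstats(path, config.mediator_dialect, strict=config.strict)
        insts = ivsel.select_significant(gwas, config.p_threshold)
        if config.clump is not None and all(
                r.chrom is not None and r.pos is not None for r in insts):
            insts = ivsel.clump(insts, config.clump)
        mediators[name] = {"gwas": gwas, "instruments": insts}
    return exp, out, mediators, truth


def select_instruments(
    records: list[SumstatRecord], config: StudyConfig, provenance: dict,
) -> list[SumstatRecord]:
    """The §selection cascade: significance, clumping, blocklist, F screen."""
    sel = ivsel.select_significant(records, config.p_threshold, provenance=provenance)
    if config.clump is not None and sel and all(
            r.chrom is not None and r.pos is not None for r in sel):
        sel = ivsel.clump(sel, config.clump, provenance=provenance)
    if config.blocklist_path:
        blocklist = ivsel.load_blocklist(config.blocklist_path)
        sel = ivsel.exclude_blocklist(sel, blocklist, provenance=provenance)
    if sel:
        _, sel = ivsel.f_statistics(sel, formula=config.f_formula,
                                    f_min=config.f_min, provenance=provenance)
    return sel


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full study; stage failures are recorded, not fatal.

    The exit contract is: the report is always produced, and
    ``report.errors`` names any stage that failed (an empty dict means a
    clean run).  Statistical significance never affects success.
    """
    provenance: dict = {"master_seed": config.seed}
    errors: dict = {}
    exposure, outcome, mediators, truth = _load_inputs(config)

    selected = select_instruments(exposure, config, provenance)
    if not selected:
        return StudyReport(
            config=_jsonable(config), provenance=provenance, estimates=[],
            errors={"selection": "no instruments pass selection"},
            version=__version__,
        )

    iset = harmonize(
        selected, outcome, palindrome_eaf_limit=config.palindrome_eaf_limit,
        exposure_label=config.exposure_label, outcome_label=config.outcome_label,
    )
    provenance.update(iset.provenance)

    estimates: list[MREstimate] = []
    het = egger_int = presso = loo = None
    estimates.append(ivw(iset, model=config.ivw_model))
    if len(iset) >= 3:
        try:
            estimates.append(mr_egger(iset))
            egger_int = egger_intercept_test(iset)
        except Exception as exc:
            errors["egger"] = str(exc)
        try:
            estimates.append(weighted_median(
                iset, n_boot=config.n_boot,
                seed=stage_seed(config.seed, "weighted_median")))
            estimates.append(weighted_mode(
                iset, n_boot=config.n_boot,
                seed=stage_seed(config.seed, "weighted_mode")))
        except Exception as exc:
            errors["robust_estimators"] = str(exc)
    if len(iset) >= 2:
        het = cochran_q(iset, ivw(iset, model="fixed"))
    if len(iset) >= 4:
        try:
            presso = mr_presso(iset, n_sim=config.presso_n_sim,
                               seed=stage_seed(config.seed, "mr_presso"))
        except Exception as exc:
            errors["mr_presso"] = str(exc)
    if len(iset) >= 3:
        try:
            loo = leave_one_out(iset, method="ivw")
        except Exception as exc:
            errors["leave_one_out"] = str(exc)

    reverse = None
    if config.run_reverse:
        try:
            reverse = reverse_mr(
                exposure, outcome, p_threshold=config.p_threshold,
                clump_spec=config.clump, f_min=config.f_min,
                seed=stage_seed(config.seed, "reverse"),
                palindrome_eaf_limit=config.palindrome_eaf_limit,
            )
        except Exception as exc:
            errors["reverse_mr"] = str(exc)

    med_results: list[MediationResult] = []
    med_table = None
    if mediators:
        try:
            med_results, med_table = mediation_screen(
                selected, exposure, mediators, outcome,
                te_estimate=estimates[0],
                step_two=config.mediation_step_two,
                palindrome_eaf_limit=config.palindrome_eaf_limit,
            )
        except Exception as exc:
            errors["mediation"] = str(exc)

    return StudyReport(
        config=_jsonable(config), provenance=provenance,
        estimates=estimates, heterogeneity=het, egger_intercept=egger_int,
        presso=presso, loo=loo, reverse=reverse,
        mediation=med_results, mediation_screen_table=med_table,
        errors=errors, version=__version__,
    )


def fmt_effect(x: float) -> str:
    """Effects to 3 decimals, half-even."""
    return f"{round(x, 3):.3f}"


def fmt_p(p: float) -> str:
    """p-values: scientific (2.952E-04 style) below 0.001, 3 decimals above."""
    return f"{p:.3E}" if p < 1e-3 else f"{round(p, 3):.3f}"


def report_tables(report: StudyReport) -> dict[str, str]:
    """Render the report as display tables.

    1. per-method estimates with OR-scale columns,
    2. a mediation table (IE, DE, TE, IE/TE, Pval),
    3. the leave-one-out listing.
    """
    out: dict[str, str] = {}
    rows = []
    for e in report.estimates:
        o, lo, hi = to_odds_ratio(e)
        rows.append({
            "method": e.method, "beta": fmt_effect(e.beta),
            "or": fmt_effect(o),
            "or_95ci": f"{fmt_effect(lo)}-{fmt_effect(hi)}",
            "pval": fmt_p(e.pval), "n_snp": e.n_snp,
        })
    out["estimates"] = pd.DataFrame(rows).to_string(index=False)

    if report.mediation:
        mrows = []
        for m in report.mediation:
            mrows.append({
                "mediator": m.mediator,
                "IE": fmt_effect(m.ie), "DE": fmt_effect(m.de),
                "TE": fmt_effect(m.te),
                "IE/TE": fmt_effect(m.prop) if m.prop is not None else "NA",
                "Pval": fmt_p(m.pval_ie),
            })
        out["mediation"] = pd.DataFrame(mrows).to_string(index=False)

    if report.loo is not None:
        df = report.loo.rows.copy()
        for c in ("beta", "ci_low", "ci_high"):
            df[c] = df[c].map(fmt_effect)
        df["pval"] = df["pval"].map(fmt_p)
        out["leave_one_out"] = df.to_string(index=False)
    return out
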