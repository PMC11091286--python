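"""Packaged reference tables.

Two small published tables ship with the package:

* ``icp_instruments()`` — the 11 genome-wide-significant, LD-independent
  SNPs instrumenting intrahepatic cholestasis of pregnancy (ICP), with
  effect/other allele, effect-allele frequency, beta, SE and p-value.
* ``icp_mediation_effects()`` — the published two-step mediation
  decompositions (indirect, direct and total effects on the log-odds
  scale) for ICP acting on cardiovascular outcomes through lipid and
  blood-pressure mediators.

Both are loaded from TSV files inside the package; no network access.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .sumstats import SumstatRecord, read_sumstats

__all__ = ["icp_instruments", "icp_instruments_frame", "icp_mediation_effects"]


def _data_path(name: str):
    return resources.files("mrmediate").joinpath("data", name)


def icp_instruments() -> list[SumstatRecord]:
    """The 11 published ICP instrument SNPs as validated records."""
    with resources.as_file(_data_path("icp_instruments.tsv")) as p:
        return read_sumstats(p, dialect="canonical", strict=True)


def icp_instruments_frame() -> pd.DataFrame:
    """Same table as a DataFrame (canonical column names)."""
    with resources.as_file(_data_path("icp_instruments.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def icp_mediation_effects() -> pd.DataFrame:
    """Published mediation decompositions: exposure, mediator, outcome,
    ie, de, te, ie_over_te, pval (effects on the log-odds scale)."""
    with resources.as_file(_data_path("icp_mediation_effects.tsv")) as p:
        return pd.read_csv(p, sep="\t")
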