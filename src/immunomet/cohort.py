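"""Clinical annotation: ingest, response coding and cohort summary.

Tumor response to neoadjuvant chemotherapy is coded from the residual
cancer burden (RCB) index when available — RCB 0 (pathologic complete
response) or 1 (minimal residual disease) count as a positive response —
and otherwise from the pCR flag. Everything else with outcome data is a
negative response; samples with no outcome data stay missing and are
dropped from analyses (complete-case).
"""

from __future__ import annotations

import logging
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CLINICAL_COLUMNS",
    "round_percentage",
    "read_clinical",
    "code_response",
    "summarize_cohort",
    "load_table1_counts",
]

log = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("sample_id", "rcb", "pcr", "er_status", "her2_status",
                    "treatment", "subtype")

TREATMENTS = ("FAC", "FAC+paclitaxel", "FAC+docetaxel", "FEC",
              "FEC+paclitaxel", "paclitaxel", "docetaxel", "unspecified")


class ClinicalFormatError(ValueError):
    pass


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical CSV and validate its categorical fields.

    Entries recorded as ``uncertain`` (discordant across source datasets)
    are mapped to missing, so downstream complete-case handling censors
    them.
    """
    table = pd.read_csv(path, dtype={"sample_id": str})
    missing_cols = set(CLINICAL_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ClinicalFormatError(f"clinical table lacks columns {sorted(missing_cols)}")
    table = table.replace({"uncertain": pd.NA, "": pd.NA})
    rcb = pd.to_numeric(table["rcb"], errors="coerce")
    bad = rcb.dropna()[~rcb.dropna().isin([0, 1, 2, 3])]
    if len(bad):
        raise ClinicalFormatError(f"RCB values outside 0-3: {sorted(bad.unique())}")
    table["rcb"] = rcb
    pcr = table["pcr"].astype("object")
    bad_pcr = set(pcr.dropna()) - {"yes", "no"}
    if bad_pcr:
        raise ClinicalFormatError(f"pcr values must be yes/no: {sorted(bad_pcr)}")
    return table


def code_response(table: pd.DataFrame) -> pd.DataFrame:
    """Derive the binary response column from RCB and the pCR flag.

    response = 1 when RCB is 0 or 1, or — with RCB unassigned — when
    pCR = yes; 0 for any other case with outcome data; missing when both
    RCB and pCR are missing. RCB wins over a contradictory pCR flag
    (logged), being the finer-grained measure. Idempotent and
    row-order independent.
    """
    out = table.copy()
    rcb = pd.to_numeric(out["rcb"], errors="coerce")
    pcr = out["pcr"]
    response = pd.Series(pd.NA, index=out.index, dtype="object")
    response[rcb.isin([0, 1])] = 1
    response[rcb.isin([2, 3])] = 0
    no_rcb = rcb.isna()
    response[no_rcb & (pcr == "yes")] = 1
    response[no_rcb & (pcr == "no")] = 0

    # pCR corresponds to RCB 0: a flag disagreeing with an assigned RCB
    # (rcb=0 with pcr=no, or rcb>0 with pcr=yes) is contradictory
    contr = ((rcb == 0) & (pcr == "no")) | (rcb.isin([1, 2, 3]) & (pcr == "yes"))
    if contr.any():
        log.warning("code_response: %d row(s) with RCB/pCR contradiction, coded by RCB",
                    int(contr.sum()))
    out["response"] = pd.array(response, dtype="Int64")
    return out


def round_percentage(count: int, total: int) -> int:
    """Integer percentage of ``total``, rounded half-up (presentation rule)."""
    if total == 0:
        return 0
    frac = Decimal(count) * 100 / Decimal(total)
    return int(frac.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Category counts and integer percentages per clinical characteristic.

    Missing values appear as their own ``unspecified`` category so the
    counts of every characteristic sum to the cohort size. Percentages
    are of the total cohort, rounded half-up to integers.
    """
    total = len(table)
    rows = []
    chars = [c for c in ("age_group", "treatment", "response", "er_status",
                         "her2_status", "subtype") if c in table.columns]
    for char in chars:
        col = table[char].astype("object").where(table[char].notna(), "unspecified")
        counts = col.value_counts()
        for cat, cnt in counts.items():
            rows.append({"characteristic": char, "category": str(cat),
                         "count": int(cnt),
                         "percentage": round_percentage(int(cnt), total)})
    return pd.DataFrame(rows, columns=["characteristic", "category", "count", "percentage"])


def load_table1_counts() -> pd.DataFrame:
    """Packaged printed marginal counts of the pooled neoadjuvant cohort.

    Columns characteristic, category, count; every characteristic's
    counts sum to the cohort size. Used by validation and the
    reproduction script; never required for analysis of user data.
    """
    with resources.files("immunomet.data").joinpath("table1_counts.csv").open() as fh:
        return pd.read_csv(fh)
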