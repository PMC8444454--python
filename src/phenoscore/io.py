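"""File contracts: long-format measure CSV, DEG TSV, score exports.

Measure tables are tidy CSV with header
``animal_id,sex,group,cohort,test,measure,value,is_timeout``; unknown
extra columns are preserved.  DEG contrast tables are TSV with header
``gene,log2fc,pval[,adj_pval]``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .deg import ContrastTable

log = logging.getLogger("phenoscore")

MEASURE_COLUMNS = [
    "animal_id", "sex", "group", "cohort", "test", "measure", "value", "is_timeout",
]


class IOError_(ValueError):
    pass


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(raw, line_no: int, path) -> bool:
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return False
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise IOError_(f"{path}: line {line_no}: unparseable is_timeout value {raw!r}")


def read_measures(path: str | Path) -> pd.DataFrame:
    """Read a long-format measure table, validating the header contract.

    A missing mandatory column raises with the column named; an
    unparseable value raises with the line number.  A missing value cell
    yields a missing value (NaN), never 0.  Extra columns pass through.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in MEASURE_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing mandatory column(s): {missing}")
    extra = [c for c in df.columns if c not in MEASURE_COLUMNS]
    if extra:
        log.info("%s: extra columns preserved as metadata: %s", path, extra)

    values = np.empty(len(df), dtype=float)
    for i, raw in enumerate(df["value"]):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
            values[i] = np.nan
            continue
        try:
            values[i] = float(raw)
        except ValueError:
            raise IOError_(
                f"{path}: line {i + 2}: unparseable value {raw!r} in column 'value'"
            ) from None
    df["value"] = values
    df["is_timeout"] = [
        _parse_bool(raw, i + 2, path) for i, raw in enumerate(df["is_timeout"])
    ]
    log.info("%s: read %d measure records", path, len(df))
    return df[MEASURE_COLUMNS + extra]


def write_measures(records: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MEASURE_COLUMNS if c not in records.columns]
    if missing:
        raise IOError_(f"cannot write measure table: missing column(s) {missing}")
    out = records.copy()
    out["is_timeout"] = out["is_timeout"].astype(bool)
    out.to_csv(path, index=False)
    log.info("%s: wrote %d measure records", path, len(out))


def read_deg_table(
    path: str | Path, *, contrast: str, region: str = "", sex: str = ""
) -> ContrastTable:
    """Read one DEG contrast TSV (gene, log2fc, pval[, adj_pval])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "log2fc", "pval"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing mandatory column(s): {missing}")
    log.info("%s: read %d genes for contrast %s", path, len(df), contrast)
    return ContrastTable(contrast=contrast, data=df, region=region, sex=sex)


def write_deg_table(table: ContrastTable, path: str | Path) -> None:
    cols = ["gene", "log2fc", "pval"] + (
        ["adj_pval"] if "adj_pval" in table.data.columns else []
    )
    table.data[cols].to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
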