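"""Numeric encoding of a cohort table for network estimation.

Binary variables map to 0/1 (accepting yes/no-style strings), ordinal
variables to integers, and continuous variables are standardized to mean 0,
sd 1.  The event flags are re-expressed as censoring indicator columns
(``os_censoring``/``ttf_censoring``, 1 = censored) so the censoring processes
appear as nodes of the estimated network.  Rows with a missing response value
are dropped; missing explanatory values are mean/mode-imputed; constant
columns are excluded from testing.  All of these actions are counted in the
returned report so the missing-data policy is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import VariableSpec

logger = logging.getLogger(__name__)

_TRUTHY = {"yes", "y", "true", "1", "present"}
_FALSY = {"no", "n", "false", "0", "absent"}


class EncodingError(ValueError):
    pass


@dataclass
class EncodingReport:
    dropped_rows: int = 0
    imputed: dict[str, int] = field(default_factory=dict)
    excluded_constant: list[str] = field(default_factory=list)
    columns: list[str] = field(default_factory=list)


def _to_binary(col: pd.Series, name: str) -> pd.Series:
    if col.dtype == object:
        def conv(v):
            if pd.isna(v):
                return np.nan
            s = str(v).strip().lower()
            if s in _TRUTHY:
                return 1.0
            if s in _FALSY:
                return 0.0
            raise EncodingError(f"column {name!r}: unrecognized binary value {v!r}")
        col = col.map(conv)
    col = col.astype(float)
    bad = set(col.dropna().unique()) - {0.0, 1.0}
    if bad:
        raise EncodingError(f"column {name!r}: non-binary values {sorted(bad)}")
    return col


def encode_table(table: pd.DataFrame,
                 dictionary: list[VariableSpec]) -> tuple[pd.DataFrame, EncodingReport]:
    """Encode a raw cohort table into the numeric analysis matrix.

    Returns the encoded DataFrame (response, censoring, bookkeeping and
    explanatory columns, all numeric) and an :class:`EncodingReport` of the
    rows dropped, values imputed and columns excluded.
    """
    specs = {v.name: v for v in dictionary}
    unknown = [c for c in table.columns if c not in specs]
    if unknown:
        raise EncodingError(f"columns not in the data dictionary: {unknown}")
    missing = [v.name for v in dictionary if v.name not in table.columns]
    if missing:
        raise EncodingError(f"dictionary columns absent from the table: {missing}")
    if len(set(table.columns)) != len(table.columns):
        raise EncodingError("duplicate column names")

    df = table.copy()
    report = EncodingReport()

    # drop rows with missing response values
    response_cols = [v.name for v in dictionary if v.role == "response"]
    before = len(df)
    df = df.dropna(subset=response_cols)
    report.dropped_rows = before - len(df)
    if report.dropped_rows:
        logger.info("dropped %d row(s) with missing response values", report.dropped_rows)

    out: dict[str, pd.Series] = {}
    for spec in dictionary:
        col = df[spec.name]
        if spec.kind == "binary":
            col = _to_binary(col, spec.name)
        elif spec.kind in ("ordinal", "count"):
            col = col.astype(float).round()
        elif spec.kind == "continuous":
            col = col.astype(float)
        else:
            raise EncodingError(f"column {spec.name!r}: unknown kind {spec.kind!r}")
        n_miss = int(col.isna().sum())
        if n_miss:
            if spec.role == "explanatory":
                if spec.kind == "continuous":
                    col = col.fillna(col.mean())
                else:
                    col = col.fillna(col.mode().iloc[0])
                report.imputed[spec.name] = n_miss
                logger.info("imputed %d value(s) in %r", n_miss, spec.name)
            else:
                raise EncodingError(
                    f"response/bookkeeping column {spec.name!r} still has missing values")
        out[spec.name] = col

    enc = pd.DataFrame(out, index=df.index)

    # censoring indicator nodes replace the raw event flags
    if "os_event" in enc.columns:
        enc["os_censoring"] = 1.0 - enc.pop("os_event")
    if "ttf_event" in enc.columns:
        enc["ttf_censoring"] = 1.0 - enc.pop("ttf_event")

    # exclude constant columns from testing
    for name in list(enc.columns):
        if enc[name].nunique() <= 1:
            report.excluded_constant.append(name)
            enc = enc.drop(columns=name)
    if report.excluded_constant:
        logger.warning("excluded constant column(s): %s", report.excluded_constant)

    # standardize continuous columns (correlation-invariant; keeps scales tame)
    kinds = {v.name: v.kind for v in dictionary}
    for name in enc.columns:
        if kinds.get(name, "continuous") == "continuous" and name in kinds:
            sd = enc[name].std(ddof=1)
            if sd > 0:
                enc[name] = (enc[name] - enc[name].mean()) / sd

    report.columns = list(enc.columns)
    return enc.reset_index(drop=True), report
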