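"""Delimited-text I/O for sample tables and analysis reports.

All tables are plain CSV with a '.' decimal separator regardless of locale;
missing values (e.g. the temperature of initial-condition samples) are empty
fields.  Reports round-trip losslessly through JSON.
"""

from __future__ import annotations

import pandas as pd

from .adequacy import AdequacyReport
from .design import SAMPLE_COLUMNS, validate_samples
from .modeling import FittedModel

_DTYPES = {
    "bed_type": str,
    "cycle": "int64",
    "condition": str,
    "replicate": "int64",
}


def write_samples(df: pd.DataFrame, path) -> None:
    """Write a litter-sample table as CSV with the documented header."""
    df[list(SAMPLE_COLUMNS)].to_csv(path, index=False)


def read_samples(path, strict: bool = True) -> pd.DataFrame:
    """Read a litter-sample CSV and enforce the physical invariants.

    Malformed rows are reported with their (0-based, header-excluded) row
    numbers; ``strict=False`` returns the table with the problems attached in
    ``df.attrs["problems"]`` instead of raising.  A header-only file yields
    an empty table.
    """
    df = pd.read_csv(path, dtype={k: v for k, v in _DTYPES.items()})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[list(SAMPLE_COLUMNS)]
    if df.empty:
        df.attrs["problems"] = []
        return df
    problems = validate_samples(df, strict=False)
    if strict and problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    df.attrs["problems"] = problems
    return df


def write_report(report, path) -> None:
    """Serialize a fitted model or adequacy report to JSON."""
    report.to_json(path)


def read_report(path):
    """Read back a JSON report, dispatching on its payload."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    if "retained_terms" in payload:
        return FittedModel.from_json(json.dumps(payload))
    return AdequacyReport(**payload)
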