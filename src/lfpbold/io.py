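"""CSV interchange for component, condition and BOLD tables.

All tables are plain CSV with a one-line header. The component table
(columns ``site, condition, broadband, gamma, alpha`` plus optional
``ci_low_*``/``ci_high_*`` and ``half``) is the interchange format between
the spectral, calibration and analysis stages, and the ingestion point for
user-supplied summaries of real recordings.
"""

from __future__ import annotations

import pandas as pd

COMPONENT_COLUMNS = ("condition", "broadband", "gamma", "alpha")
CONDITION_COLUMNS = ("condition", "c1_sigma", "c2_coherence", "c3_amplitude")
BOLD_COLUMNS = ("condition", "bold")


def _check_columns(df: pd.DataFrame, required, kind: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table is missing columns {missing}")
    return df


def read_component_table(path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), COMPONENT_COLUMNS, "component")


def write_component_table(df: pd.DataFrame, path) -> None:
    _check_columns(df, COMPONENT_COLUMNS, "component").to_csv(path, index=False)


def read_condition_table(path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), CONDITION_COLUMNS, "condition")


def write_condition_table(df: pd.DataFrame, path) -> None:
    _check_columns(df, CONDITION_COLUMNS, "condition").to_csv(path, index=False)


def read_bold_table(path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), BOLD_COLUMNS, "BOLD")


def write_bold_table(df: pd.DataFrame, path) -> None:
    _check_columns(df, BOLD_COLUMNS, "BOLD").to_csv(path, index=False)
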