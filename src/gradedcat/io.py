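"""Response-matrix CSV reading and writing.

The on-disk dialect is one row per respondent: a ``respondent_id``
column followed by one integer-category column per item in bank order;
empty cells mean missing / not administered.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bank import ItemBank

__all__ = ["read_responses", "write_responses"]


def read_responses(path: str | Path, bank: ItemBank | None = None) -> pd.DataFrame:
    """Read a respondent-by-item CSV; NaN marks missing entries.

    When *bank* is given, columns are checked against and ordered by the
    bank, and category codes validated against each item's range.
    """
    df = pd.read_csv(path, index_col=0)
    if bank is not None:
        missing = [i for i in bank.ids if i not in df.columns]
        if missing:
            raise ValueError(f"response file lacks item columns: {missing}")
        df = df[bank.ids]
        for it in bank:
            col = df[it.id]
            bad = col.dropna()[(col.dropna() < 1) | (col.dropna() > it.n_categories)]
            if len(bad):
                raise ValueError(
                    f"item {it.id!r}: categories outside 1..{it.n_categories} "
                    f"for respondents {list(bad.index[:5])}"
                )
    return df


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    """Write a response matrix with blank cells for missing entries."""
    out = responses.copy()
    for col in out.columns:
        out[col] = out[col].map(lambda x: "" if pd.isna(x) else int(x))
    out.index.name = out.index.name or "respondent_id"
    out.to_csv(path)
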