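"""Item-level response tables and construct-level scale scores."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .items import Construct, ItemMetadata, validate_items


@dataclass
class ItemResponseTable:
    """A complete n x p table of integer item responses.

    Missing values are rejected rather than imputed: every entry must lie
    inside its item's admissible score range.
    """

    items: list[ItemMetadata]
    responses: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        validate_items(self.items)
        resp = np.asarray(self.responses)
        if resp.ndim != 2 or resp.shape[1] != len(self.items):
            raise ValueError(
                f"responses must be n x {len(self.items)}, got shape {resp.shape}"
            )
        if not np.issubdtype(resp.dtype, np.integer):
            as_int = resp.astype(np.int64, copy=True)
            if np.isnan(np.asarray(resp, dtype=float)).any():
                raise ValueError("missing values are not supported; reject, do not impute")
            if not np.array_equal(as_int, np.asarray(resp, dtype=float)):
                raise ValueError("responses must be integers")
            resp = as_int
        for j, it in enumerate(self.items):
            col = resp[:, j]
            if col.size and (col.min() < it.min_score or col.max() > it.max_score):
                raise ValueError(
                    f"item {it.item_id!r}: responses outside "
                    f"[{it.min_score}, {it.max_score}]"
                )
        self.responses = resp

    @property
    def n(self) -> int:
        return int(self.responses.shape[0])

    @property
    def p(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.responses, columns=self.item_ids)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, items: Sequence[ItemMetadata]
    ) -> "ItemResponseTable":
        ids = [it.item_id for it in items]
        missing = set(ids) - set(df.columns)
        if missing:
            raise ValueError(f"columns missing from table: {sorted(missing)}")
        return cls(items=list(items), responses=df[ids].to_numpy())

    @classmethod
    def read_csv(
        cls, path: str | Path, items: Sequence[ItemMetadata], sep: str = ","
    ) -> "ItemResponseTable":
        df = pd.read_csv(path, sep=sep)
        if df.isna().any().any():
            raise ValueError(f"{path}: missing values are not supported")
        return cls.from_dataframe(df, items)


@dataclass
class ScaleScores:
    """Per-respondent construct totals with summary statistics.

    ``totals`` has one column per construct (loneliness, depression,
    anxiety); ``correlations`` is the 3x3 Pearson correlation matrix of the
    totals; means/SDs use the n-1 (sample) denominator.
    """

    totals: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    mins: pd.Series
    maxs: pd.Series
    correlations: pd.DataFrame


def compute_scale_scores(data: ItemResponseTable) -> ScaleScores:
    """Sum items within each construct and summarize the totals.

    Raises ValueError if any construct has no items. Totals are invariant to
    the column order of ``data``.
    """
    cols: dict[str, np.ndarray] = {}
    for construct in Construct:
        idx = [j for j, it in enumerate(data.items) if it.construct is construct]
        if not idx:
            raise ValueError(f"no items for construct {construct.value!r}")
        cols[construct.value] = data.responses[:, idx].sum(axis=1)
    totals = pd.DataFrame(cols)
    return ScaleScores(
        totals=totals,
        means=totals.mean(),
        sds=totals.std(ddof=1),
        mins=totals.min(),
        maxs=totals.max(),
        correlations=totals.corr(),
    )
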