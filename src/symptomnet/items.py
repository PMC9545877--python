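"""Item metadata for the three questionnaire instruments.

The default instrument set is the 19-item battery used throughout this
package: the Three-Item Loneliness Scale (items scored 1-3), the PHQ-9
depression scale and the GAD-7 anxiety scale (both scored 0-3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class Construct(str, Enum):
    """The a-priori symptom cluster an item belongs to."""

    LONELINESS = "loneliness"
    DEPRESSION = "depression"
    ANXIETY = "anxiety"


@dataclass(frozen=True)
class ItemMetadata:
    """One questionnaire item: label, construct and admissible score range."""

    item_id: str
    construct: Construct
    min_score: int
    max_score: int

    def __post_init__(self) -> None:
        if not self.item_id:
            raise ValueError("item_id must be a non-empty string")
        if self.min_score >= self.max_score:
            raise ValueError(
                f"item {self.item_id!r}: min_score ({self.min_score}) must be "
                f"strictly below max_score ({self.max_score})"
            )

    @property
    def n_categories(self) -> int:
        return self.max_score - self.min_score + 1


def default_items() -> list[ItemMetadata]:
    """The 19-item loneliness/depression/anxiety battery in canonical order.

    Order convention: Ln1-Ln3, PHQ1-PHQ9, GAD1-GAD7.
    """
    items = [ItemMetadata(f"Ln{i}", Construct.LONELINESS, 1, 3) for i in (1, 2, 3)]
    items += [ItemMetadata(f"PHQ{i}", Construct.DEPRESSION, 0, 3) for i in range(1, 10)]
    items += [ItemMetadata(f"GAD{i}", Construct.ANXIETY, 0, 3) for i in range(1, 8)]
    return items


def validate_items(items: Sequence[ItemMetadata]) -> None:
    """Check uniqueness of item ids; raise ValueError on violation."""
    ids = [it.item_id for it in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate item_ids: {dupes}")


def construct_counts(items: Iterable[ItemMetadata]) -> dict[Construct, int]:
    counts: dict[Construct, int] = {c: 0 for c in Construct}
    for it in items:
        counts[it.construct] += 1
    return counts


def items_to_json(items: Sequence[ItemMetadata], path: str | Path) -> None:
    payload = [
        {
            "item_id": it.item_id,
            "construct": it.construct.value,
            "min_score": it.min_score,
            "max_score": it.max_score,
        }
        for it in items
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def items_from_json(path: str | Path) -> list[ItemMetadata]:
    payload = json.loads(Path(path).read_text())
    items = [
        ItemMetadata(
            item_id=d["item_id"],
            construct=Construct(d["construct"]),
            min_score=int(d["min_score"]),
            max_score=int(d["max_score"]),
        )
        for d in payload
    ]
    validate_items(items)
    return items
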