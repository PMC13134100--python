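"""Symptom panel layout: the 20-item instrument set used throughout.

The panel mirrors the item structure of routine-outcome measures in primary
care psychological services: nine depression items (severity 0-3), seven
generalised-anxiety items (severity 0-3), and four work/social functioning
items (impairment 0-8; the work-ability item is excluded because it is not
applicable to people out of employment).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Item:
    """One scored item: instrument tag, 1-based index within it, score range."""

    instrument: str  # "depression" | "anxiety" | "functioning"
    index: int
    min_score: int
    max_score: int

    @property
    def name(self) -> str:
        prefix = {"depression": "dep", "anxiety": "anx", "functioning": "fun"}[
            self.instrument
        ]
        return f"{prefix}{self.index}"


@dataclass(frozen=True)
class SymptomPanel:
    """Ordered 20-item layout: depression 1-9, anxiety 1-7, functioning 2-5."""

    items: tuple[Item, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [it.name for it in self.items]
        if len(names) != len(set(names)):
            raise ValueError("item names must be unique")
        counts = {}
        for it in self.items:
            counts[it.instrument] = counts.get(it.instrument, 0) + 1
        expected = {"depression": 9, "anxiety": 7, "functioning": 4}
        if counts != expected:
            raise ValueError(f"panel must have {expected} items, got {counts}")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    @property
    def min_scores(self) -> list[int]:
        return [it.min_score for it in self.items]

    @property
    def max_scores(self) -> list[int]:
        return [it.max_score for it in self.items]


def default_panel() -> SymptomPanel:
    """The standard 20-item panel (9 depression, 7 anxiety, 4 functioning)."""
    items = (
        [Item("depression", i, 0, 3) for i in range(1, 10)]
        + [Item("anxiety", i, 0, 3) for i in range(1, 8)]
        # functioning items are numbered 2-5: the work-ability item (1) is
        # excluded from analysis
        + [Item("functioning", i, 0, 8) for i in range(2, 6)]
    )
    return SymptomPanel(items=tuple(items))
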