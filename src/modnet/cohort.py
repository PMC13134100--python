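"""Person-level cohort table: 20 item scores, group label, age, gender.

A :class:`CohortTable` wraps a pandas DataFrame whose columns are the panel's
item names (in panel order) followed by ``group``, ``age`` and ``gender``.
All analyses are complete-case: rows with any missing item or demographic
value are dropped at construction/load time and the drop count is retained.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import SymptomPanel, default_panel

log = logging.getLogger(__name__)

META_COLUMNS = ["group", "age", "gender"]


@dataclass
class CohortTable:
    """Complete-case person x (items, group, age, gender) table."""

    data: pd.DataFrame
    panel: SymptomPanel = field(default_factory=default_panel)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        expected = self.panel.item_names + META_COLUMNS
        missing = [c for c in expected if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort is missing columns: {missing}")
        self.data = self.data[expected].reset_index(drop=True)
        if self.data.isna().any().any():
            raise ValueError("cohort contains missing values; use from_raw()")
        if self.data["group"].nunique() < 2:
            raise ValueError("cohort must contain at least 2 groups")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_raw(
        cls, raw: pd.DataFrame, panel: SymptomPanel | None = None
    ) -> "CohortTable":
        """Apply the complete-case rule to a raw table and log the drop count."""
        panel = panel or default_panel()
        cols = panel.item_names + META_COLUMNS
        missing = [c for c in cols if c not in raw.columns]
        if missing:
            raise ValueError(f"raw table is missing columns: {missing}")
        sub = raw[cols]
        keep = sub.notna().all(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            log.info("complete-case filter dropped %d of %d rows", n_dropped, len(sub))
        kept = sub.loc[keep].reset_index(drop=True)
        if kept.empty:
            raise ValueError("no rows remain after complete-case filtering")
        return cls(data=kept, panel=panel, n_dropped=n_dropped)

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def groups(self) -> list[str]:
        """Group labels, sorted for a stable ordering."""
        return sorted(self.data["group"].unique())

    @property
    def group_sizes(self) -> dict[str, int]:
        return self.data["group"].value_counts().to_dict()

    def items_matrix(self) -> np.ndarray:
        """(n, 20) float array of item scores in panel order."""
        return self.data[self.panel.item_names].to_numpy(dtype=float)

    def fingerprint(self) -> dict:
        """Row count, group sizes and a content hash; ties fits to their data."""
        h = pd.util.hash_pandas_object(self.data, index=False).sum()
        return {
            "n": self.n,
            "group_sizes": {g: int(s) for g, s in sorted(self.group_sizes.items())},
            "hash": int(np.uint64(h)),
        }

    def check_ordinal_ranges(self) -> pd.DataFrame:
        """Per-item count of values outside the panel's score range."""
        records = []
        for it in self.panel.items:
            vals = self.data[it.name]
            bad = int(((vals < it.min_score) | (vals > it.max_score)).sum())
            records.append({"item": it.name, "out_of_range": bad})
        return pd.DataFrame(records)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def load_cohort_csv(path, panel: SymptomPanel | None = None) -> CohortTable:
    """Load a cohort CSV, enforce the header contract and the complete-case rule.

    The header must contain the panel item columns plus ``group``, ``age``,
    ``gender``; duplicated headers are rejected. Rows with any missing value in
    those columns are dropped (count logged). Item-range violations are logged
    but not dropped, since range checking is a reporting concern.
    """
    panel = panel or default_panel()
    # pandas silently renames duplicated headers, so inspect the raw header row
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    dupes = [c for c, k in Counter(header).items() if k > 1]
    if dupes:
        raise ValueError(f"duplicate column header(s): {dupes}")
    raw = pd.read_csv(path)
    expected = panel.item_names + META_COLUMNS
    missing = [c for c in expected if c not in raw.columns]
    if missing:
        raise ValueError(f"CSV header is missing columns: {missing}")
    cohort = CohortTable.from_raw(raw, panel=panel)
    violations = cohort.check_ordinal_ranges()
    n_bad = int(violations["out_of_range"].sum())
    if n_bad:
        bad = violations[violations["out_of_range"] > 0]
        log.warning("item score range violations:\n%s", bad.to_string(index=False))
    return cohort
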