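"""Aggregate reporting surfaces: proportion tables, heatmap matrices,
group rankings, and per-group descriptives.

Proportions of significant differences are reported per group pair out of a
fixed denominator — 20 symptoms for intercepts and, by default, the ordered
co-occurrence count p(p-1) = 380 for edges (each unordered edge occupies two
directed slots); the unordered convention (190) is also available. Rankings
sum significant *counts* (not proportions) per group across all its pairs so
unequal denominators cannot distort the ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .contrasts import PairwiseContrast


@dataclass
class ProportionTable:
    """Upper-triangular group x group table of proportions of differences."""

    kind: str  # "intercept" | "edge"
    groups: list[str]
    counts: pd.DataFrame  # upper triangle populated, NaN elsewhere
    proportions: pd.DataFrame
    denominator: int

    def rendered(self, decimals: int = 2) -> pd.DataFrame:
        """Proportions rounded for display (full precision stays in exports)."""
        return self.proportions.round(decimals)


def proportion_table(
    contrasts: dict[tuple[str, str], PairwiseContrast],
    kind: str,
    alpha: float | None = None,
    ordered: bool = True,
) -> ProportionTable:
    """Per-pair proportion of significant differences for one parameter kind."""
    if kind not in ("intercept", "edge"):
        raise ValueError("kind must be 'intercept' or 'edge'")
    groups = sorted({g for pair in contrasts for g in pair})
    expected = {(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]}
    if expected - set(contrasts):
        raise ValueError(f"missing contrasts for pairs: {sorted(expected - set(contrasts))}")

    some = next(iter(contrasts.values()))
    p = len(some.item_names)
    if kind == "intercept":
        denominator = p
    else:
        denominator = p * (p - 1) if ordered else p * (p - 1) // 2

    counts = pd.DataFrame(np.nan, index=groups, columns=groups)
    for (a, b), c in contrasts.items():
        cts = c.counts(alpha)
        if kind == "intercept":
            k = cts["intercept"]
        else:
            k = cts["edge_ordered"] if ordered else cts["edge_unordered"]
        i, j = sorted((groups.index(a), groups.index(b)))
        counts.iloc[i, j] = k
    proportions = counts / denominator
    return ProportionTable(
        kind=kind,
        groups=groups,
        counts=counts,
        proportions=proportions,
        denominator=denominator,
    )


def heatmap_matrix(
    contrasts: dict[tuple[str, str], PairwiseContrast],
    kind: str,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Pairs x parameters matrix of percent differences, NaN where not significant.

    The emptiness pattern equals the significance pattern exactly; all filled
    values lie in [-200, 200].
    """
    if kind not in ("intercept", "edge"):
        raise ValueError("kind must be 'intercept' or 'edge'")
    rows = {}
    for (a, b), c in sorted(contrasts.items()):
        label = f"{a} vs {b}"
        if kind == "intercept":
            sig = c.intercept_significant(alpha)
            rows[label] = {
                name: (c.intercept_percent[j] if sig[j] else np.nan)
                for j, name in enumerate(c.item_names)
            }
        else:
            sig = c.edge_significant(alpha)
            p = len(c.item_names)
            rows[label] = {
                f"{c.item_names[s]}--{c.item_names[t]}": (
                    c.edge_percent[s, t] if sig[s, t] else np.nan
                )
                for s in range(p)
                for t in range(s + 1, p)
            }
    return pd.DataFrame.from_dict(rows, orient="index")


def group_difference_ranking(table: ProportionTable) -> pd.DataFrame:
    """Per group, total significant count against all other groups, descending.

    Ties are broken alphabetically and flagged in the ``tied`` column.
    """
    totals = {g: 0.0 for g in table.groups}
    for i, a in enumerate(table.groups):
        for j in range(i + 1, len(table.groups)):
            k = table.counts.iloc[i, j]
            if np.isnan(k):
                continue
            totals[a] += k
            totals[table.groups[j]] += k
    frame = pd.DataFrame(
        sorted(totals.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["group", "total_significant"],
    )
    frame["tied"] = frame["total_significant"].duplicated(keep=False)
    return frame


def demographics_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-group descriptives: n, % of total, gender split, age and item means (SD).

    Percentages are computed from the counts themselves. A final ``overall``
    row describes the whole cohort.
    """
    blocks = []
    total_n = cohort.n
    frames = [(g, cohort.data[cohort.data["group"] == g]) for g in cohort.groups]
    frames.append(("overall", cohort.data))
    for label, sub in frames:
        n = len(sub)
        n_female = int((sub["gender"] == 1).sum())
        row = {
            "group": label,
            "n": n,
            "pct_of_total": 100.0 * n / total_n,
            "n_female": n_female,
            "pct_female": 100.0 * n_female / n,
            "n_male": n - n_female,
            "pct_male": 100.0 * (n - n_female) / n,
            "age_mean": sub["age"].mean(),
            "age_sd": sub["age"].std(ddof=1),
        }
        for name in cohort.panel.item_names:
            row[f"{name}_mean"] = sub[name].mean()
            row[f"{name}_sd"] = sub[name].std(ddof=1)
        blocks.append(row)
    return pd.DataFrame(blocks)


def proportion_table_markdown(table: ProportionTable, decimals: int = 2) -> str:
    """Render a proportion table as Markdown (upper triangle only)."""
    disp = table.rendered(decimals).copy()
    disp = disp.where(~disp.isna(), "")
    lines = ["| |" + "|".join(table.groups) + "|"]
    lines.append("|" + "---|" * (len(table.groups) + 1))
    for g, row in disp.iterrows():
        lines.append(f"|{g}|" + "|".join(str(v) for v in row) + "|")
    return "\n".join(lines)
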